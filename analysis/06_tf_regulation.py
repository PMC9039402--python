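"""TF-lncRNA crosstalk: shared-miRNA pairing plus motif scanning.

TFs (a subset of the coding genes) are mapped into the miRNA-mRNA network;
TF-lncRNA pairs sharing significantly many miRNAs (hypergeometric p < 0.05)
are then checked for motif support: PWM hits at p < 1e-4 in the +/-2 kb
promoter window or in enhancers assigned within +/-2 kb of the TSS.
"""

import pandas as pd

from cernet import cerna, regulatory
from common import THRESHOLDS, bundle, networks, save


def main():
    b = bundle()
    mm, ml = networks()
    pairs = regulatory.tf_lncrna_pairs(mm, ml, set(b.tf_names))
    save(
        cerna.pairs_frame(pairs).rename(columns={"mrna_id": "tf_id"}),
        "06_tf_lncrna_pairs.tsv",
    )
    print(f"{len(pairs)} TF-lncRNA pairs at hypergeometric p < 0.05 "
          f"(TF list: {b.tf_names})")

    pwms = {p.motif_id: p for p in b.pwms}
    enhancer_seqs = {}
    for lnc, tss in b.lnc_tss.items():
        assigned = regulatory.assign_enhancers(
            [e for e in b.enhancers if e.chrom == f"chr_{lnc}"],
            tss, flank=THRESHOLDS["flank"],
        )
        named = dict(b.enhancer_seqs.get(lnc, []))
        enhancer_seqs[lnc] = [(e.name, named[e.name]) for e in assigned if e.name in named]
    calls = regulatory.binding_calls(
        pairs, pwms, b.promoter_seqs, enhancer_seqs, p_threshold=THRESHOLDS["fimo_p"]
    )
    save(
        pd.DataFrame(calls, columns=["tf", "lncrna", "region_type", "region_id",
                                     "n_hits", "best_p", "best_offset", "best_strand"]),
        "06_tf_binding_calls.tsv",
    )
    print(f"{len(calls)} motif-supported binding calls "
          f"({sum(c['region_type'] == 'promoter' for c in calls)} promoter, "
          f"{sum(c['region_type'] == 'enhancer' for c in calls)} enhancer)")


if __name__ == "__main__":
    main()
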