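"""Generate the synthetic tumor/normal study and record what was planted.

Writes the full bundle (counts, sequences, intervals, clinical, truth) under
scratch/bundle/ and a compact planted-truth manifest to results/.
"""

import pandas as pd

from common import SCRATCH, bundle, save


def main():
    b = bundle()
    b.to_dir(SCRATCH / "bundle")
    t = b.truth
    manifest = pd.DataFrame(
        [
            ("tumor samples", b.config.n_tumor),
            ("normal samples", b.config.n_normal),
            ("planted DE miRNAs", len(t.de_features["miRNA"])),
            ("planted DE lncRNAs", len(t.de_features["lncRNA"])),
            ("planted DE mRNAs", len(t.de_features["mRNA"])),
            ("planted regulator->target edges", len(t.true_edges)),
            ("planted ceRNA triplets", len(t.triplets)),
            ("planted prognostic genes (beta=%.1f)" % b.config.beta_prognostic,
             len(t.prognostic)),
            ("planted seed sites", len(t.seed_sites)),
            ("planted motif occurrences", len(t.motif_sites)),
            ("events observed", int(b.clinical.table["event"].sum())),
        ],
        columns=["quantity", "value"],
    )
    path = save(manifest, "01_planted_truth.tsv")
    print(f"synthetic study written to {SCRATCH / 'bundle'}")
    print(manifest.to_string(index=False))
    print(f"manifest -> {path}")


if __name__ == "__main__":
    main()
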