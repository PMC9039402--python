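"""lncRNA-immune-infiltration correlation and miRNA-target over-representation.

Pearson correlation of each lncRNA's log2 expression with each cell type's
infiltration score across tumor samples (the generator plants one pair at
r = 0.5), and a generic over-representation test of the DE mRNAs in each
miRNA's curated target set.
"""

import pandas as pd

from cernet.association import infiltration_correlation, ora
from common import bundle, de_analysis, log2_matrices, save


def main():
    b = bundle()
    logm = log2_matrices()
    r, p = infiltration_correlation(logm["lncRNA"], b.infiltration)
    flat = r.stack().dropna().sort_values(ascending=False)
    top = flat.head(5)
    print("strongest lncRNA-infiltration correlations:")
    for (lnc, cell), val in top.items():
        print(f"  {lnc} ~ {cell}: r = {val:.3f}")
    planted = b.truth.infiltration_pairs[0]
    print(f"planted pair: {planted[0]} ~ {planted[1]} at r = {planted[2]}")
    save(
        r.reset_index().rename(columns={"index": "lncrna_id"}),
        "08_infiltration_correlation.tsv",
    )

    de = de_analysis()
    collections = {
        str(m): set(g["target_id"])
        for m, g in b.interactions.edges.groupby("regulator_id")
    }
    universe = set(b.interactions.edges["target_id"])
    res = ora(de["mRNA"]["selected"] & universe, collections, universe)
    df = pd.DataFrame(
        {"set_id": [x.set_id for x in res],
         "overlap": [x.overlap for x in res],
         "p_value": [x.p_value for x in res],
         "bh_adjusted_p": [x.bh_adjusted_p for x in res]}
    ).sort_values("p_value")
    save(df, "08_ora_mirna_targets.tsv")
    print(f"{(df['bh_adjusted_p'] < 0.05).sum()} miRNA target sets enriched "
          f"in DE mRNAs at BH < 0.05 (of {len(df)})")


if __name__ == "__main__":
    main()
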