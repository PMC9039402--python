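"""Shared state for the numbered analysis scripts.

Every script regenerates the same seeded synthetic study (cheap and exactly
reproducible) instead of passing binary intermediates around; small result
tables go to results/, bulky raw data to scratch/.
"""

from functools import lru_cache
from pathlib import Path

import pandas as pd

from cernet.diffexpr import de_test, results_frame, select_de
from cernet.ingest import log2_standardize
from cernet.synthdata import SynthConfig, generate_study

SEED = 7
RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"

THRESHOLDS = dict(fc=2.0, p=0.05, pcc=0.9, fimo_p=1e-4, hub_fraction=0.2,
                  n_null=1000, flank=2000)


@lru_cache(maxsize=1)
def bundle():
    return generate_study(SynthConfig(seed=SEED))


@lru_cache(maxsize=1)
def de_analysis():
    """DE results and selected feature sets per class."""
    b = bundle()
    out = {}
    for cls, mat in (("miRNA", b.mirna), ("lncRNA", b.lncrna), ("mRNA", b.mrna)):
        res = de_test(mat, b.groups, THRESHOLDS["fc"], THRESHOLDS["p"])
        out[cls] = {
            "results": res,
            "frame": results_frame(res),
            "selected": select_de(res, THRESHOLDS["fc"], THRESHOLDS["p"]),
        }
    return out


@lru_cache(maxsize=1)
def log2_matrices():
    b = bundle()
    return {
        "miRNA": log2_standardize(b.mirna),
        "lncRNA": log2_standardize(b.lncrna),
        "mRNA": log2_standardize(b.mrna),
    }


@lru_cache(maxsize=1)
def networks():
    """The two negative-correlation regulatory networks."""
    from cernet import interactions, netcore

    b = bundle()
    de = de_analysis()
    logm = log2_matrices()
    classes = {
        **{m: "miRNA" for m in b.mirna.feature_ids},
        **{l: "lncRNA" for l in b.lncrna.feature_ids},
        **{g: "mRNA" for g in b.mrna.feature_ids},
    }
    de_edges = interactions.map_de_edges(
        b.interactions, de["miRNA"]["selected"], de["mRNA"]["selected"]
    )
    mm = netcore.build_network(
        interactions.correlation_filter(de_edges, logm["miRNA"], logm["mRNA"]),
        classes,
    )
    seed_tab = interactions.seed_edges(
        {m: s for m, s in b.mirna_seqs.items() if m in de["miRNA"]["selected"]},
        {l: s for l, s in b.lncrna_seqs.items() if l in de["lncRNA"]["selected"]},
    )
    ml = netcore.build_network(
        interactions.correlation_filter(seed_tab, logm["miRNA"], logm["lncRNA"]),
        classes,
    )
    return mm, ml


def save(df: pd.DataFrame, name: str) -> Path:
    RESULTS.mkdir(exist_ok=True)
    path = RESULTS / name
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path
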