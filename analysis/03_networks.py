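"""Build the miRNA-mRNA and miRNA-lncRNA networks and test their topology.

Curated-edge mapping (miRNA-mRNA) and seed matching (miRNA-lncRNA) restricted
to DE features, then the negative-correlation filter.  Topology: degree
distribution power-law fit, clustering and average path length against 1,000
degree-preserving rewirings, and the top-20% hub set.
"""

import json

import pandas as pd

from cernet import netcore
from common import RESULTS, SEED, THRESHOLDS, bundle, networks, save


def main():
    b = bundle()
    mm, ml = networks()
    report = {}
    for name, net in (("mirna_mrna", mm), ("mirna_lncrna", ml)):
        save(netcore.edges_frame(net), f"03_{name}_edges.tsv")
        t = netcore.topology(net)
        entry = {
            "nodes": net.number_of_nodes(),
            "edges": net.number_of_edges(),
            "mean_clustering": t.mean_clustering,
            "avg_path_length": t.avg_path_length,
            "powerlaw_r2": t.powerlaw_r2,
        }
        for stat in ("clustering", "path_length"):
            null = netcore.degree_preserving_null(
                net, stat, n_null=THRESHOLDS["n_null"], seed=SEED
            )
            entry[f"{stat}_empirical_p"] = null.empirical_p
        report[name] = entry
        print(f"{name}: {entry}")

    hubs = netcore.select_hubs(ml, THRESHOLDS["hub_fraction"])
    report["hubs_mirna_lncrna"] = sorted(hubs)
    print(f"top-{THRESHOLDS['hub_fraction']:.0%} hubs of the miRNA-lncRNA "
          f"network: {len(hubs)} nodes")

    planted = set(map(tuple, b.truth.true_edges))
    got = {tuple(sorted(e)) for e in mm.edges} | {tuple(sorted(e)) for e in ml.edges}
    planted_sorted = {tuple(sorted(e)) for e in planted}
    report["planted_edge_recall"] = round(
        len(got & planted_sorted) / len(planted_sorted), 4
    )
    print(f"planted edge recall: {report['planted_edge_recall']}")

    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "03_topology.json").write_text(json.dumps(report, indent=1, sort_keys=True))


if __name__ == "__main__":
    main()
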