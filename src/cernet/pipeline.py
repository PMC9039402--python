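"""End-to-end orchestration of the regulatory-network analysis.

``run_pipeline`` executes the stage graph

    ingest → de → network (+ topology null) → modules → cerna → tf →
    survival → association

from a single declarative configuration (YAML file or dict), writing TSV edge
lists, GraphML graphs, module/triplet/KM tables and a machine-readable JSON
run summary into the output directory.  Every stochastic step is seeded from
one master seed, so two runs with the same config and seed are byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association as assoc_mod
from . import cerna as cerna_mod
from . import diffexpr, interactions, mcode, netcore, regulatory, survival
from .ingest import ClinicalTable, ExpressionMatrix, log2_standardize, read_fasta
from .interactions import InteractionTable
from .synthdata import SynthConfig, StudyBundle, generate_study

logger = logging.getLogger(__name__)

STAGES = ("de", "network", "modules", "cerna", "tf", "survival", "association")

DEFAULT_THRESHOLDS = {
    "fc": 2.0,
    "p": 0.05,
    "pcc": 0.9,
    "fimo_p": 1e-4,
    "hub_fraction": 0.2,
    "n_null": 1000,
    "flank": 2000,
    "corr_p": 0.05,
    "hyper_p": 0.05,
    "top_k_de": 20,
}

_DEPS = {
    "de": (),
    "network": ("de",),
    "modules": ("network",),
    "cerna": ("network",),
    "tf": ("network",),
    "survival": ("de",),
    "association": ("de",),
}


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh) or {}
    return dict(config or {})


def _load_bundle(cfg: dict, master_seed: int) -> StudyBundle:
    block = dict(cfg.get("synthdata") or {})
    block.setdefault("seed", master_seed)
    return generate_study(SynthConfig(**block))


def _write(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return len(df)


def run_pipeline(config, out_dir, seed: int | None = None) -> dict:
    """Run the configured stages; return (and write) the run summary."""
    cfg = _load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master_seed = int(seed if seed is not None else cfg.get("seed", 0))
    thresholds = {**DEFAULT_THRESHOLDS, **(cfg.get("thresholds") or {})}
    requested = list(cfg.get("stages") or STAGES)
    for s in requested:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}")

    summary: dict = {
        "seed": master_seed,
        "thresholds": thresholds,
        "stages_run": [],
        "skipped_stages": [],
        "outputs": {},
        "recovery": {},
    }

    # ------------------------------------------------------------- ingest
    if "inputs" in cfg:
        bundle = _load_real_inputs(cfg["inputs"])
    else:
        bundle = _load_bundle(cfg, master_seed)
    groups = bundle.groups
    summary["n_samples"] = {
        "tumor": int((groups == "tumor").sum()),
        "normal": int((groups == "normal").sum()),
    }
    truth = bundle.truth

    done: set[str] = set()

    def runnable(stage: str) -> bool:
        if stage not in requested:
            return False
        missing = [d for d in _DEPS[stage] if d not in done]
        if missing:
            summary["skipped_stages"].append(
                {"stage": stage, "reason": f"requires {missing}"}
            )
            return False
        return True

    for stage in STAGES:
        if stage not in requested:
            summary["skipped_stages"].append({"stage": stage, "reason": "not requested"})

    state: dict = {}

    # ----------------------------------------------------------------- de
    if runnable("de"):
        de_sets: dict[str, set] = {}
        for cls, mat in (("miRNA", bundle.mirna), ("lncRNA", bundle.lncrna), ("mRNA", bundle.mrna)):
            res = diffexpr.de_test(
                mat, groups, fc_threshold=thresholds["fc"], p_threshold=thresholds["p"]
            )
            de_sets[cls] = diffexpr.select_de(res, thresholds["fc"], thresholds["p"])
            frame = diffexpr.results_frame(res).sort_values("feature_id")
            n = _write(frame, out / f"de_{cls.lower()}.tsv")
            summary["outputs"][f"de_{cls.lower()}.tsv"] = n
            summary[f"n_de_{cls.lower()}"] = len(de_sets[cls])
            state[f"de_results_{cls}"] = res
        state["de_sets"] = de_sets
        if truth is not None:
            rec = {}
            for cls in ("miRNA", "lncRNA", "mRNA"):
                planted = set(truth.de_features.get(cls, {}))
                found = de_sets[cls]
                rec[cls] = {
                    "sensitivity": (len(planted & found) / len(planted)) if planted else None,
                    "n_planted": len(planted),
                    "n_called": len(found),
                }
            summary["recovery"]["de"] = rec
        done.add("de")
        summary["stages_run"].append("de")

    # log2 matrices shared by later stages
    mirna_log = log2_standardize(bundle.mirna)
    lnc_log = log2_standardize(bundle.lncrna)
    mrna_log = log2_standardize(bundle.mrna)

    # ------------------------------------------------------------ network
    if runnable("network"):
        de_sets = state["de_sets"]
        node_classes = {
            **{f: "miRNA" for f in bundle.mirna.feature_ids},
            **{f: "lncRNA" for f in bundle.lncrna.feature_ids},
            **{f: "mRNA" for f in bundle.mrna.feature_ids},
        }
        # miRNA-mRNA: curated table -> DE endpoints -> negative correlation
        de_edges = interactions.map_de_edges(
            bundle.interactions, de_sets["miRNA"], de_sets["mRNA"]
        )
        mm_edges = interactions.correlation_filter(
            de_edges, mirna_log, mrna_log, p_threshold=thresholds["corr_p"]
        )
        mir_mrna_net = netcore.build_network(mm_edges, node_classes)
        # miRNA-lncRNA: seed matching on sequences -> negative correlation
        de_mir_seqs = {m: s for m, s in bundle.mirna_seqs.items() if m in de_sets["miRNA"]}
        de_lnc_seqs = {l: s for l, s in bundle.lncrna_seqs.items() if l in de_sets["lncRNA"]}
        seed_tab = interactions.seed_edges(de_mir_seqs, de_lnc_seqs)
        ml_edges = interactions.correlation_filter(
            seed_tab, mirna_log, lnc_log, p_threshold=thresholds["corr_p"]
        )
        mir_lnc_net = netcore.build_network(ml_edges, node_classes)

        for name, net in (("mirna_mrna", mir_mrna_net), ("mirna_lncrna", mir_lnc_net)):
            n = _write(netcore.edges_frame(net), out / f"{name}_edges.tsv")
            summary["outputs"][f"{name}_edges.tsv"] = n
            netcore.to_graphml(net, out / f"{name}.graphml")
            summary[f"n_{name}_edges"] = net.number_of_edges()
            summary[f"n_{name}_nodes"] = net.number_of_nodes()

        topo = {}
        if mir_mrna_net.number_of_nodes() >= 2:
            t = netcore.topology(mir_mrna_net)
            topo = {
                "mean_clustering": t.mean_clustering,
                "avg_path_length": t.avg_path_length,
                "powerlaw_r2": t.powerlaw_r2,
            }
            if mir_mrna_net.number_of_edges() >= 2:
                for stat, offset in (("clustering", 1), ("path_length", 2)):
                    null = netcore.degree_preserving_null(
                        mir_mrna_net,
                        stat,
                        n_null=int(thresholds["n_null"]),
                        seed=master_seed + offset,
                    )
                    topo[f"{stat}_empirical_p"] = null.empirical_p
        summary["topology_mirna_mrna"] = topo
        hubs: set = set()
        try:
            hubs = netcore.select_hubs(mir_lnc_net, thresholds["hub_fraction"])
        except ValueError:
            pass
        summary["n_hubs_mirna_lncrna"] = len(hubs)
        state.update(
            mir_mrna_net=mir_mrna_net, mir_lnc_net=mir_lnc_net, hubs=hubs
        )
        if truth is not None:
            retained = {(e.regulator_id, e.target_id) for e in mm_edges} | {
                (e.regulator_id, e.target_id) for e in ml_edges
            }
            planted = set(map(tuple, truth.true_edges))
            inter = len(retained & planted)
            union = len(retained | planted)
            summary["recovery"]["edges"] = {
                "recall": inter / len(planted) if planted else None,
                "jaccard": inter / union if union else None,
                "n_retained": len(retained),
            }
        done.add("network")
        summary["stages_run"].append("network")

    # ------------------------------------------------------------ modules
    if runnable("modules"):
        params = mcode.McodeParams()
        modules = mcode.find_modules(state["mir_mrna_net"], params)
        rows = [
            {
                "module": i + 1,
                "score": m.score,
                "n_nodes": len(m.nodes),
                "seed_node": m.seed_node,
                "nodes": ",".join(sorted(map(str, m.nodes))),
            }
            for i, m in enumerate(modules)
        ]
        n = _write(pd.DataFrame(rows, columns=["module", "score", "n_nodes", "seed_node", "nodes"]), out / "modules.tsv")
        summary["outputs"]["modules.tsv"] = n
        summary["n_modules"] = len(modules)
        summary["top_module_score"] = modules[0].score if modules else None
        state["modules"] = modules
        done.add("modules")
        summary["stages_run"].append("modules")

    # -------------------------------------------------------------- cerna
    if runnable("cerna"):
        pairs = cerna_mod.shared_pairs(state["mir_mrna_net"], state["mir_lnc_net"])
        net, triplets, retained = cerna_mod.cerna_network(
            pairs, lnc_log, mrna_log, pcc_threshold=thresholds["pcc"]
        )
        n = _write(cerna_mod.pairs_frame(retained), out / "cerna_pairs.tsv")
        summary["outputs"]["cerna_pairs.tsv"] = n
        n = _write(cerna_mod.triplets_frame(triplets), out / "cerna_triplets.tsv")
        summary["outputs"]["cerna_triplets.tsv"] = n
        netcore.to_graphml(net, out / "cerna.graphml")
        summary["n_cerna_pairs"] = len(retained)
        summary["n_cerna_triplets"] = len(triplets)
        if truth is not None and truth.triplets:
            planted_pairs = {(l, m) for l, _, m in truth.triplets}
            got = {(p.lncrna_id, p.mrna_id) for p in retained}
            summary["recovery"]["cerna_pairs"] = {
                "recall": len(planted_pairs & got) / len(planted_pairs),
                "n_planted": len(planted_pairs),
            }
        state["triplets"] = triplets
        done.add("cerna")
        summary["stages_run"].append("cerna")

    # ----------------------------------------------------------------- tf
    if runnable("tf"):
        tf_set = set(bundle.tf_names)
        pairs = regulatory.tf_lncrna_pairs(
            state["mir_mrna_net"], state["mir_lnc_net"], tf_set,
            p_threshold=thresholds["hyper_p"],
        )
        n = _write(cerna_mod.pairs_frame(pairs).rename(columns={"mrna_id": "tf_id"}),
                   out / "tf_lncrna_pairs.tsv")
        summary["outputs"]["tf_lncrna_pairs.tsv"] = n
        summary["n_tf_lncrna_pairs"] = len(pairs)
        pwms = {p.motif_id: p for p in bundle.pwms}
        enhancer_seqs: dict[str, list[tuple[str, str]]] = {}
        for lnc, tss in bundle.lnc_tss.items():
            assigned = regulatory.assign_enhancers(
                [e for e in bundle.enhancers if e.chrom == f"chr_{lnc}"],
                tss, flank=int(thresholds["flank"]),
            )
            named = dict(bundle.enhancer_seqs.get(lnc, []))
            enhancer_seqs[lnc] = [
                (e.name, named[e.name]) for e in assigned if e.name in named
            ]
        calls = regulatory.binding_calls(
            pairs, pwms, bundle.promoter_seqs, enhancer_seqs,
            p_threshold=thresholds["fimo_p"],
        )
        n = _write(pd.DataFrame(calls, columns=[
            "tf", "lncrna", "region_type", "region_id", "n_hits",
            "best_p", "best_offset", "best_strand"]), out / "tf_binding_calls.tsv")
        summary["outputs"]["tf_binding_calls.tsv"] = n
        summary["n_tf_binding_calls"] = len(calls)
        done.add("tf")
        summary["stages_run"].append("tf")

    # ------------------------------------------------------------ survival
    if runnable("survival"):
        res = state["de_results_miRNA"]
        ranked = sorted(res, key=lambda r: (r.p_value, -abs(r.log2fc), r.feature_id))
        top = [r.feature_id for r in ranked[: int(thresholds["top_k_de"])]]
        tumor_samples = [s for s in bundle.mirna.sample_ids if groups[s] == "tumor"]
        expr_t = mirna_log.subset_samples(
            [s for s in tumor_samples if s in set(bundle.clinical.sample_ids)]
        )
        model, fits = survival.fit_risk_model(top, expr_t, bundle.clinical)
        strat = survival.risk_score(model, expr_t)
        clin = bundle.clinical.aligned(expr_t.sample_ids)
        if strat.degenerate or strat.groups.nunique() < 2:
            summary["risk_model"] = {"degenerate": True}
        else:
            km = survival.km_logrank(clin, strat.groups)
            auc = survival.roc_auc(
                strat.scores.loc[clin.table["sample_id"]].to_numpy(),
                clin.table["event"].to_numpy(),
            )
            summary["risk_model"] = {
                "features": model.features,
                "betas": [round(b, 6) for b in model.betas],
                "cutoff": round(strat.cutoff, 6),
                "n_high": int((strat.groups == "high").sum()),
                "n_low": int((strat.groups == "low").sum()),
                "logrank_chi2": round(km.logrank_chi2, 6),
                "logrank_p": round(km.logrank_p, 8),
                "roc_auc": round(auc, 6),
            }
            km_rows = []
            for lv, curve in km.curves.items():
                c = curve.copy()
                c.insert(0, "group", lv)
                km_rows.append(c)
            n = _write(pd.concat(km_rows, ignore_index=True), out / "km_curves.tsv")
            summary["outputs"]["km_curves.tsv"] = n
        scores_df = pd.DataFrame(
            {"sample_id": strat.scores.index, "risk_score": strat.scores.to_numpy(),
             "group": strat.groups.to_numpy()}
        )
        n = _write(scores_df, out / "risk_scores.tsv")
        summary["outputs"]["risk_scores.tsv"] = n
        done.add("survival")
        summary["stages_run"].append("survival")

    # --------------------------------------------------------- association
    if runnable("association"):
        if bundle.infiltration is not None and len(bundle.infiltration):
            r_df, p_df = assoc_mod.infiltration_correlation(lnc_log, bundle.infiltration)
            r_out = r_df.reset_index().rename(columns={"index": "lncrna_id"})
            n = _write(r_out, out / "infiltration_correlation.tsv")
            summary["outputs"]["infiltration_correlation.tsv"] = n
            flat = r_df.stack().dropna()
            if len(flat):
                (lnc, cell), rmax = max(flat.items(), key=lambda kv: kv[1])
                summary["max_infiltration_correlation"] = {
                    "lncrna": lnc, "cell_type": cell, "r": round(float(rmax), 6)
                }
        # generic over-representation: each miRNA's curated target set as one
        # collection; query = DE mRNAs, universe = all curated targets
        de_sets = state["de_sets"]
        collections: dict[str, set] = {}
        for mir, grp in bundle.interactions.edges.groupby("regulator_id"):
            collections[str(mir)] = set(grp["target_id"])
        universe = set(bundle.interactions.edges["target_id"])
        query = de_sets["mRNA"] & universe
        if universe and collections:
            results = assoc_mod.ora(query, collections, universe)
            df = pd.DataFrame(
                {
                    "set_id": [r.set_id for r in results],
                    "overlap": [r.overlap for r in results],
                    "p_value": [r.p_value for r in results],
                    "bh_adjusted_p": [r.bh_adjusted_p for r in results],
                }
            )
            n = _write(df, out / "ora_mirna_targets.tsv")
            summary["outputs"]["ora_mirna_targets.tsv"] = n
            summary["n_ora_sets_bh05"] = int((df["bh_adjusted_p"] < 0.05).sum())
        done.add("association")
        summary["stages_run"].append("association")

    (out / "run_summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True, default=str) + "\n"
    )
    return summary


def _load_real_inputs(inputs: dict) -> StudyBundle:
    """Assemble a StudyBundle from user-supplied files (TSV/FASTA/BED/JSON)."""
    mirna = ExpressionMatrix.from_tsv(inputs["mirna_counts"], "miRNA")
    lncrna = ExpressionMatrix.from_tsv(inputs["lncrna_counts"], "lncRNA")
    mrna = ExpressionMatrix.from_tsv(inputs["mrna_counts"], "mRNA")
    clinical = ClinicalTable.from_tsv(inputs["clinical"])
    inter = InteractionTable.from_tsv(inputs["interactions"])
    mirna_seqs = read_fasta(inputs["mirna_fasta"]) if "mirna_fasta" in inputs else {}
    lncrna_seqs = read_fasta(inputs["lncrna_fasta"]) if "lncrna_fasta" in inputs else {}
    groups = pd.read_csv(inputs["groups"], sep="\t") if "groups" in inputs else None
    infil = (
        pd.read_csv(inputs["infiltration"], sep="\t", index_col=0)
        if "infiltration" in inputs
        else pd.DataFrame()
    )
    bundle = StudyBundle(
        config=None,
        mirna=mirna,
        lncrna=lncrna,
        mrna=mrna,
        clinical=clinical,
        interactions=inter,
        mirna_seqs=mirna_seqs,
        lncrna_seqs=lncrna_seqs,
        promoter_seqs=read_fasta(inputs["promoters"]) if "promoters" in inputs else {},
        lnc_tss={},
        enhancers=[],
        enhancer_seqs={},
        pwms=[],
        tf_names=list(pd.read_csv(inputs["tf_list"], sep="\t").iloc[:, 0])
        if "tf_list" in inputs
        else [],
        infiltration=infil,
        truth=None,
    )
    if groups is not None:
        lab = pd.Series(groups.iloc[:, 1].to_numpy(), index=groups.iloc[:, 0])
        bundle.__dict__["_groups_override"] = lab
    return bundle
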