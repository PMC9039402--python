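"""Synthetic tumor/normal study generator with planted ground truth.

The generator emulates the statistical structure the pipeline assumes in a
sequencing cohort: negative-binomial miRNA/lncRNA/mRNA count matrices over
tumor and adjacent-normal samples with planted fold changes; curated
regulator→target interaction tables containing true edges plus decoys; miRNA
and transcript sequences with planted seed sites; TF position-weight matrices
with planted promoter/enhancer occurrences; survival times whose hazard
depends on planted prognostic features; and per-sample immune-infiltration
scores correlated with chosen lncRNAs.

Regulation model: a regulator miRNA carries a standardized latent per-sample
level z; the miRNA's count mean is multiplied by exp(tau·z) and each target's
mean by exp(−edge_effect·z), so the two are negatively correlated on the log2
scale without breaking the count marginals.  Planted ceRNA triplets give
their lncRNA and mRNA the same miRNA repressor (and the same differential-
expression sign), so the pair is positively correlated.  Survival times are
exponential with hazard h₀·exp(Σ β_i·Exp_i) over centered log2 expression of
the planted prognostic features, with independent exponential censoring
calibrated so the expected censored fraction equals ``censor_rate``.

Everything is drawn from a single seeded generator: the same config and seed
give a bit-identical bundle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .ingest import ClinicalTable, ExpressionMatrix, write_fasta
from .interactions import InteractionTable
from .regulatory import DNA, GenomicInterval, PWM

__all__ = ["SynthConfig", "SyntheticTruth", "StudyBundle", "generate_study", "simulate_survival"]

RNA = "ACGU"
_RNA_TO_DNA_COMP = {"A": "T", "C": "G", "G": "C", "U": "A"}

# latent amplitude of a regulator's own per-sample variation (log-scale)
TAU = 0.4
# baseline hazard, per day
H0 = 1.0 / 1000.0
PROMOTER_FLANK = 2000
PROMOTER_LEN = 2 * PROMOTER_FLANK
TRANSCRIPT_LEN = 500
MIRNA_LEN = 22
ENHANCER_LEN = 300


@dataclass
class SynthConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the shape of the cohort the pipeline targets: 89 tumor
    and 3 adjacent-normal samples, deep libraries (moderate biological
    dispersion), strong planted fold changes, and well-expressed planted
    ceRNA transcripts.
    """

    n_tumor: int = 89
    n_normal: int = 3
    n_mirna: int = 150
    n_lncrna: int = 100
    n_mrna: int = 300
    frac_de: float = 0.3
    log2fc_de: float = 2.5
    nb_dispersion: float = 0.05
    n_true_edges: int = 120
    edge_effect: float = 0.7
    n_triplets: int = 8
    n_prognostic: int = 5
    beta_prognostic: float = 0.7
    censor_rate: float = 0.3
    motif_width: int = 8
    n_tf: int = 4
    seed: int = 0

    def validate(self) -> None:
        counts = dict(
            n_tumor=self.n_tumor, n_normal=self.n_normal, n_mirna=self.n_mirna,
            n_lncrna=self.n_lncrna, n_mrna=self.n_mrna,
            n_true_edges=self.n_true_edges, n_triplets=self.n_triplets,
            n_prognostic=self.n_prognostic, motif_width=self.motif_width,
            n_tf=self.n_tf,
        )
        for name, v in counts.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        for name, v in (("frac_de", self.frac_de), ("censor_rate", self.censor_rate)):
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0 <= self.edge_effect <= 1:
            raise ValueError("edge_effect must be in [0, 1]")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.n_triplets > min(self.n_lncrna, self.n_mrna):
            raise ValueError("n_triplets must be <= min(n_lncrna, n_mrna)")


@dataclass
class SyntheticTruth:
    """Record of every planted effect, for recovery testing."""

    de_features: dict  # class -> {feature_id: +1/-1 (tumor direction)}
    true_edges: list  # (mirna_id, target_id) pairs
    triplets: list  # (lncrna_id, mirna_id, mrna_id)
    prognostic: dict  # feature_id -> beta
    motif_sites: list  # (sequence_id, offset, strand, motif_id)
    seed_sites: list  # (mirna_id, lncrna_id, offset)
    infiltration_pairs: list  # (lncrna_id, cell_type, target_r)

    def validate(self) -> None:
        edge_set = set(self.true_edges)
        for lnc, mir, mr in self.triplets:
            if (mir, lnc) not in edge_set or (mir, mr) not in edge_set:
                raise AssertionError("triplet miRNA missing a true edge to lncRNA/mRNA")


@dataclass
class StudyBundle:
    config: SynthConfig
    mirna: ExpressionMatrix
    lncrna: ExpressionMatrix
    mrna: ExpressionMatrix
    clinical: ClinicalTable
    interactions: InteractionTable  # curated miRNA–mRNA table (true + decoys)
    mirna_seqs: dict
    lncrna_seqs: dict
    promoter_seqs: dict  # lncRNA id -> promoter window sequence
    lnc_tss: dict  # lncRNA id -> TSS coordinate on its virtual chromosome
    enhancers: list  # GenomicInterval, name = "<lnc>|enh<k>" (incl. decoys)
    enhancer_seqs: dict  # lncRNA id -> [(enhancer id, sequence)] (assigned only)
    pwms: list  # PWM per TF
    tf_names: list
    infiltration: pd.DataFrame  # samples × cell types
    truth: SyntheticTruth

    @property
    def groups(self) -> pd.Series:
        override = self.__dict__.get("_groups_override")
        if override is not None:
            return override
        labels = {
            s: ("tumor" if s.startswith("T") else "normal") for s in self.mirna.sample_ids
        }
        return pd.Series(labels)

    def to_dir(self, path: str | Path) -> None:
        """Write the bundle as plain-text files (TSV / FASTA / BED / JSON)."""
        import json

        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.mirna.to_tsv(path / "mirna_counts.tsv")
        self.lncrna.to_tsv(path / "lncrna_counts.tsv")
        self.mrna.to_tsv(path / "mrna_counts.tsv")
        self.clinical.to_tsv(path / "clinical.tsv")
        self.interactions.to_tsv(path / "mirna_mrna_interactions.tsv")
        write_fasta(self.mirna_seqs, path / "mirna.fasta")
        write_fasta(self.lncrna_seqs, path / "lncrna.fasta")
        write_fasta(self.promoter_seqs, path / "promoters.fasta")
        from .ingest import write_bed

        write_bed(self.enhancers, path / "enhancers.bed")
        self.infiltration.to_csv(path / "infiltration.tsv", sep="\t", index_label="sample_id")
        pwm_json = {
            p.motif_id: np.round(p.probabilities, 6).tolist() for p in self.pwms
        }
        (path / "pwms.json").write_text(json.dumps(pwm_json, indent=1, sort_keys=True))
        truth = {
            "de_features": self.truth.de_features,
            "true_edges": self.truth.true_edges,
            "triplets": self.truth.triplets,
            "prognostic": self.truth.prognostic,
            "motif_sites": self.truth.motif_sites,
            "seed_sites": self.truth.seed_sites,
            "infiltration_pairs": self.truth.infiltration_pairs,
        }
        (path / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))


def _random_seq(rng: np.random.Generator, alphabet: str, length: int) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=length))


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """Negative-binomial draws with variance μ + φμ² (Poisson when φ = 0)."""
    mean = np.maximum(mean, 1e-8)
    if phi == 0:
        return rng.poisson(mean)
    r = 1.0 / phi
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def calibrate_censoring(hazards: np.ndarray, censor_rate: float) -> float:
    """Exponential censoring rate μ with E[fraction censored] = censor_rate.

    With T ~ Exp(λ_s) and C ~ Exp(μ) independent, P(C < T | λ_s) = μ/(μ+λ_s);
    μ solves the mean of that over samples equal to the target rate.
    """
    if censor_rate <= 0:
        return 0.0
    if censor_rate >= 1:
        return float("inf")

    def f(log_mu):
        mu = np.exp(log_mu)
        return float(np.mean(mu / (mu + hazards))) - censor_rate

    lo, hi = np.log(hazards.min()) - 20, np.log(hazards.max()) + 20
    return float(np.exp(brentq(f, lo, hi)))


def simulate_survival(
    rng: np.random.Generator,
    covariates: np.ndarray,
    betas: np.ndarray,
    censor_rate: float,
    sample_ids: list[str],
    h0: float = H0,
) -> ClinicalTable:
    """Exponential survival with hazard h0·exp(Σ β_i x_is), censored independently.

    ``covariates`` is features × samples (centered by the caller as desired).
    """
    lp = betas @ covariates if len(betas) else np.zeros(covariates.shape[1] if covariates.ndim == 2 else len(sample_ids))
    hazards = h0 * np.exp(lp)
    t_event = rng.exponential(1.0 / hazards)
    mu = calibrate_censoring(hazards, censor_rate)
    if mu > 0:
        t_cens = rng.exponential(1.0 / mu, size=len(hazards))
    else:
        t_cens = np.full(len(hazards), np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    time = np.maximum(time, 1e-3)  # follow-up strictly positive
    return ClinicalTable(
        pd.DataFrame({"sample_id": sample_ids, "time": time, "event": event})
    )


def generate_study(config: SynthConfig) -> StudyBundle:
    """Generate the full self-consistent synthetic study bundle."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_samples = config.n_tumor + config.n_normal
    samples = [f"T{i + 1:03d}" for i in range(config.n_tumor)] + [
        f"N{i + 1:03d}" for i in range(config.n_normal)
    ]
    tumor_mask = np.array([1] * config.n_tumor + [0] * config.n_normal, dtype=bool)

    ids = {
        "miRNA": [f"miR-{i + 1:04d}" for i in range(config.n_mirna)],
        "lncRNA": [f"LNC-{i + 1:04d}" for i in range(config.n_lncrna)],
        "mRNA": [f"GENE-{i + 1:04d}" for i in range(config.n_mrna)],
    }

    # ------------------------------------------------------------------ DE
    de_features: dict[str, dict[str, int]] = {}
    for cls, fids in ids.items():
        n_de = int(round(config.frac_de * len(fids)))
        chosen = rng.choice(len(fids), size=n_de, replace=False)
        signs = rng.choice([-1, 1], size=n_de)
        de_features[cls] = {fids[i]: int(s) for i, s in zip(sorted(chosen), signs)}

    # -------------------------------------------------- planted regulation
    de_mirnas = sorted(de_features["miRNA"])
    de_lncs = sorted(de_features["lncRNA"])
    de_mrnas = sorted(de_features["mRNA"])
    true_edges: list[tuple[str, str]] = []
    triplets: list[tuple[str, str, str]] = []
    regulators_of: dict[str, list[str]] = {}  # target -> [mirna]

    def add_edge(mir: str, tgt: str) -> None:
        true_edges.append((mir, tgt))
        regulators_of.setdefault(tgt, []).append(mir)

    n_triplets = min(config.n_triplets, len(de_mirnas), len(de_lncs), len(de_mrnas))
    trip_mirs = list(rng.choice(de_mirnas, size=n_triplets, replace=False)) if n_triplets else []
    trip_lncs = list(rng.choice(de_lncs, size=n_triplets, replace=False)) if n_triplets else []
    trip_mrnas = list(rng.choice(de_mrnas, size=n_triplets, replace=False)) if n_triplets else []
    for mir, lnc, mr in zip(trip_mirs, trip_lncs, trip_mrnas):
        add_edge(mir, lnc)
        add_edge(mir, mr)
        triplets.append((lnc, mir, mr))
        # ceRNA partners share the repressor's sign (opposite the miRNA's)
        s = -de_features["miRNA"][mir]
        de_features["lncRNA"][lnc] = s
        de_features["mRNA"][mr] = s

    # remaining true edges split between mRNA and lncRNA targets,
    # avoiding triplet transcripts so their correlation stays clean
    free_lncs = [x for x in de_lncs if x not in set(trip_lncs)]
    free_mrnas = [x for x in de_mrnas if x not in set(trip_mrnas)]
    edge_set = set(true_edges)
    n_extra = max(0, config.n_true_edges - len(true_edges))
    guard = 0
    while n_extra > 0 and guard <= 50 * (config.n_true_edges + 1):
        guard += 1
        if not de_mirnas:
            break
        mir = de_mirnas[int(rng.integers(0, len(de_mirnas)))]
        pool = free_mrnas if (rng.random() < 0.5 and free_mrnas) else free_lncs
        if not pool:
            pool = free_mrnas or free_lncs
            if not pool:
                break
        tgt = pool[int(rng.integers(0, len(pool)))]
        if (mir, tgt) in edge_set:
            continue
        edge_set.add((mir, tgt))
        add_edge(mir, tgt)
        # target sign opposite its (first) regulator, for realism
        cls = "mRNA" if tgt.startswith("GENE") else "lncRNA"
        de_features[cls][tgt] = -de_features["miRNA"][mir]
        n_extra -= 1

    # ------------------------------------------------------------- means
    def base_means(n: int) -> np.ndarray:
        return np.exp(rng.normal(np.log(100.0), 1.0, size=n)).clip(5, 5000)

    means = {cls: base_means(len(fids)) for cls, fids in ids.items()}
    # planted ceRNA transcripts are well expressed so a >0.9 PCC is attainable
    for cls, members in (("lncRNA", trip_lncs), ("mRNA", trip_mrnas)):
        for fid in members:
            means[cls][ids[cls].index(fid)] = rng.uniform(300, 800)

    z = {mir: rng.standard_normal(n_samples) for mir in ids["miRNA"]}

    matrices: dict[str, ExpressionMatrix] = {}
    for cls, fids in ids.items():
        mu = np.tile(means[cls][:, None], (1, n_samples))
        for i, fid in enumerate(fids):
            sign = de_features[cls].get(fid)
            if sign:
                mu[i, tumor_mask] *= 2.0 ** (sign * config.log2fc_de)
            if cls == "miRNA":
                mu[i] *= np.exp(TAU * z[fid])
            else:
                for mir in regulators_of.get(fid, ()):
                    mu[i] *= np.exp(-config.edge_effect * z[mir])
        counts = _nb_counts(rng, mu, config.nb_dispersion)
        matrices[cls] = ExpressionMatrix(
            pd.DataFrame(counts, index=fids, columns=samples), cls, "raw"
        )

    # ----------------------------------------------------------- clinical
    prognostic_ids = (
        list(rng.choice(ids["mRNA"], size=min(config.n_prognostic, config.n_mrna), replace=False))
        if config.n_prognostic
        else []
    )
    tumor_samples = samples[: config.n_tumor]
    if prognostic_ids:
        expr = np.log2(
            matrices["mRNA"].values.loc[prognostic_ids, tumor_samples].to_numpy(dtype=float) + 1
        )
        expr = expr - expr.mean(axis=1, keepdims=True)
    else:
        expr = np.zeros((0, config.n_tumor))
    betas = np.full(len(prognostic_ids), config.beta_prognostic)
    clinical = simulate_survival(rng, expr, betas, config.censor_rate, tumor_samples)

    # ------------------------------------------------- curated interactions
    true_mrna_edges = [(m, t) for m, t in true_edges if t.startswith("GENE")]
    decoy_rows = []
    n_decoys = 3 * len(true_mrna_edges)
    existing = set(true_mrna_edges)
    guard = 0
    while len(decoy_rows) < n_decoys and guard < 50 * (n_decoys + 1):
        guard += 1
        mir = ids["miRNA"][int(rng.integers(0, config.n_mirna))]
        tgt = ids["mRNA"][int(rng.integers(0, config.n_mrna))]
        if (mir, tgt) in existing:
            continue
        existing.add((mir, tgt))
        decoy_rows.append((mir, tgt))
    rows = [(m, t, "synthetic_curated") for m, t in true_mrna_edges] + [
        (m, t, "synthetic_curated") for m, t in decoy_rows
    ]
    interactions = InteractionTable(
        pd.DataFrame(rows, columns=["regulator_id", "target_id", "source"])
    )

    # ---------------------------------------------------------- sequences
    mirna_seqs = {mir: _random_seq(rng, RNA, MIRNA_LEN) for mir in ids["miRNA"]}
    lncrna_seqs = {lnc: _random_seq(rng, DNA, TRANSCRIPT_LEN) for lnc in ids["lncRNA"]}
    seed_sites = []
    for mir, tgt in true_edges:
        if not tgt.startswith("LNC"):
            continue
        m = mirna_seqs[mir]
        # 8mer site: reverse complement of positions 2-8, then A opposite pos 1
        site = "".join(_RNA_TO_DNA_COMP[b] for b in reversed(m[1:8])) + "A"
        off = int(rng.integers(0, TRANSCRIPT_LEN - len(site)))
        s = lncrna_seqs[tgt]
        lncrna_seqs[tgt] = s[:off] + site + s[off + len(site):]
        seed_sites.append((mir, tgt, off))

    # -------------------------------------------------------------- motifs
    # TFs are mRNAs regulated by planted miRNA edges, so they appear in the
    # miRNA-mRNA network (a TF list is a subset of the coding genes);
    # prefer targets of miRNAs that also regulate lncRNAs, so shared-miRNA
    # TF-lncRNA pairs exist by construction
    mirs_with_lnc = {m for m, t in true_edges if t.startswith("LNC")}
    preferred = sorted(
        {t for m, t in true_edges if t.startswith("GENE") and m in mirs_with_lnc}
    )
    mrna_targets = preferred or sorted({t for _, t in true_edges if t.startswith("GENE")})
    n_tf = min(config.n_tf, len(mrna_targets))
    tf_names = (
        sorted(str(x) for x in rng.choice(mrna_targets, size=n_tf, replace=False))
        if n_tf
        else []
    )
    pwms = []
    for tf in tf_names:
        cons = rng.integers(0, 4, size=config.motif_width)
        probs = np.full((4, config.motif_width), 0.03)
        probs[cons, np.arange(config.motif_width)] = 0.91
        pwms.append(PWM(tf, probs))

    lnc_tss = {lnc: 5000 for lnc in ids["lncRNA"]}
    promoter_seqs = {
        lnc: _random_seq(rng, DNA, PROMOTER_LEN) for lnc in ids["lncRNA"]
    }
    enhancers: list[GenomicInterval] = []
    enhancer_seqs: dict[str, list[tuple[str, str]]] = {}
    motif_sites = []
    # plant each TF's consensus in the promoters of lncRNAs that share a
    # regulator miRNA with the TF, so motif-supported TF-lncRNA crosstalk
    # exists by construction
    lnc_targets_of: dict[str, list[str]] = {}
    for mir, tgt in true_edges:
        if tgt.startswith("LNC"):
            lnc_targets_of.setdefault(mir, []).append(tgt)
    for k, (tf, pwm) in enumerate(zip(tf_names, pwms)):
        cons = pwm.consensus
        if config.n_lncrna == 0:
            continue
        partners = sorted(
            {lnc for mir in regulators_of.get(tf, ()) for lnc in lnc_targets_of.get(mir, ())}
        )
        if not partners:
            partners = ids["lncRNA"]
        chosen = rng.choice(partners, size=min(3, len(partners)), replace=False)
        for lnc in chosen:
            off = int(rng.integers(0, PROMOTER_LEN - len(cons)))
            s = promoter_seqs[lnc]
            promoter_seqs[lnc] = s[:off] + cons + s[off + len(cons):]
            motif_sites.append((f"{lnc}|promoter", off, "+", tf))
        # one assigned enhancer (within ±2 kb of the TSS) carrying the motif
        lnc = str(chosen[0])
        tss = lnc_tss[lnc]
        start = tss + 800 + 50 * k
        enh = GenomicInterval(f"chr_{lnc}", start, start + ENHANCER_LEN, "+", f"{lnc}|enh{k}")
        enhancers.append(enh)
        eseq = _random_seq(rng, DNA, ENHANCER_LEN)
        off = int(rng.integers(0, ENHANCER_LEN - len(cons)))
        eseq = eseq[:off] + cons + eseq[off + len(cons):]
        enhancer_seqs.setdefault(lnc, []).append((enh.name, eseq))
        motif_sites.append((enh.name, off, "+", tf))
    # decoy enhancers beyond the ±2 kb window
    for j, lnc in enumerate(ids["lncRNA"][: min(5, config.n_lncrna)]):
        tss = lnc_tss[lnc]
        start = tss + 3000 + 100 * j
        enhancers.append(
            GenomicInterval(f"chr_{lnc}", start, start + ENHANCER_LEN, "+", f"{lnc}|far{j}")
        )

    # -------------------------------------------------------- infiltration
    cell_types = [
        "B_cell", "CD4_T_cell", "CD8_T_cell", "macrophage",
        "myeloid_dendritic", "neutrophil",
    ]
    infil = rng.standard_normal((config.n_tumor, len(cell_types)))
    infiltration_pairs = []
    if config.n_lncrna:
        rho = 0.5
        target_lnc = ids["lncRNA"][0]
        lexpr = np.log2(
            matrices["lncRNA"].values.loc[target_lnc, tumor_samples].to_numpy(dtype=float) + 1
        )
        zl = (lexpr - lexpr.mean()) / (lexpr.std() if lexpr.std() else 1.0)
        j = cell_types.index("myeloid_dendritic")
        infil[:, j] = rho * zl + np.sqrt(1 - rho**2) * rng.standard_normal(config.n_tumor)
        infiltration_pairs.append((target_lnc, "myeloid_dendritic", rho))
    infiltration = pd.DataFrame(infil, index=tumor_samples, columns=cell_types)

    truth = SyntheticTruth(
        de_features=de_features,
        true_edges=true_edges,
        triplets=triplets,
        prognostic={f: float(config.beta_prognostic) for f in prognostic_ids},
        motif_sites=motif_sites,
        seed_sites=seed_sites,
        infiltration_pairs=infiltration_pairs,
    )
    truth.validate()

    return StudyBundle(
        config=config,
        mirna=matrices["miRNA"],
        lncrna=matrices["lncRNA"],
        mrna=matrices["mRNA"],
        clinical=clinical,
        interactions=interactions,
        mirna_seqs=mirna_seqs,
        lncrna_seqs=lncrna_seqs,
        promoter_seqs=promoter_seqs,
        lnc_tss=lnc_tss,
        enhancers=enhancers,
        enhancer_seqs=enhancer_seqs,
        pwms=pwms,
        tf_names=tf_names,
        infiltration=infiltration,
        truth=truth,
    )
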