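"""Expression-matrix containers, standard-format I/O and preprocessing.

The pipeline's primary container is :class:`ExpressionMatrix`, a features ×
samples table of one feature class (miRNA, lncRNA or mRNA) on either the raw
count scale or the ``log2(x + 1)`` scale.  Transcript-level tables are first
collapsed to gene level (arithmetic mean over a gene's transcripts, on the raw
scale) and then log2-standardized; that ordering is the package default and is
kept configurable at the call sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

FEATURE_CLASSES = ("miRNA", "lncRNA", "mRNA", "TF")
SCALES = ("raw", "log2")


@dataclass
class ExpressionMatrix:
    """Features × samples expression table for one feature class.

    Parameters
    ----------
    values
        DataFrame indexed by feature id with sample ids as columns.
    feature_class
        One of ``miRNA``, ``lncRNA``, ``mRNA`` (``TF`` allowed for subsets).
    scale
        ``raw`` (non-negative counts/abundances) or ``log2``.
    """

    values: pd.DataFrame
    feature_class: str
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {self.feature_class!r}")
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicated feature ids: {list(dups)[:5]}")
        if self.scale == "raw" and (self.values.to_numpy() < 0).any():
            raise ValueError("raw-scale matrix contains negative values")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_features(self, features: Iterable[str]) -> "ExpressionMatrix":
        keep = [f for f in features if f in self.values.index]
        return ExpressionMatrix(self.values.loc[keep], self.feature_class, self.scale)

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[:, list(samples)], self.feature_class, self.scale
        )

    @classmethod
    def from_tsv(
        cls, path: str | Path, feature_class: str, scale: str = "raw"
    ) -> "ExpressionMatrix":
        """Read an expression TSV (first column feature id, header row)."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        return cls(df, feature_class, scale)

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="feature_id")


@dataclass
class IdMap:
    """Transcript → (gene, gene_class) map; every transcript maps to one gene."""

    table: pd.DataFrame  # columns: transcript_id, gene_id, gene_class

    def __post_init__(self) -> None:
        required = {"transcript_id", "gene_id", "gene_class"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"IdMap needs columns {sorted(required)}")
        if self.table["transcript_id"].duplicated().any():
            raise ValueError("a transcript maps to more than one gene")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "IdMap":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class ClinicalTable:
    """Per-sample follow-up time (days, > 0) and event indicator (1 = event)."""

    table: pd.DataFrame  # columns: sample_id, time, event

    def __post_init__(self) -> None:
        required = {"sample_id", "time", "event"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"ClinicalTable needs columns {sorted(required)}")
        if (self.table["time"].to_numpy() <= 0).any():
            raise ValueError("follow-up times must be positive")
        if not set(np.unique(self.table["event"])) <= {0, 1}:
            raise ValueError("event must be 0 or 1")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("duplicated sample ids in clinical table")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def aligned(self, samples: Iterable[str]) -> "ClinicalTable":
        """Restrict and reorder to the given samples (all must be present)."""
        idx = self.table.set_index("sample_id")
        samples = list(samples)
        missing = [s for s in samples if s not in idx.index]
        if missing:
            raise KeyError(f"samples missing from clinical table: {missing[:5]}")
        return ClinicalTable(idx.loc[samples].reset_index())

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ClinicalTable":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def aggregate_transcripts(
    transcript_matrix: ExpressionMatrix, id_map: IdMap
) -> dict[str, ExpressionMatrix]:
    """Collapse a raw transcript-level matrix to gene level, per gene class.

    Each gene's row is the arithmetic mean of its transcripts' rows (raw
    scale).  Transcripts absent from the map are dropped with a logged count.
    Returns one matrix per gene class present in the map.
    """
    if transcript_matrix.scale != "raw":
        raise ValueError("aggregation operates on the raw scale")
    mapping = id_map.table.set_index("transcript_id")
    present = transcript_matrix.values.index.intersection(mapping.index)
    n_dropped = transcript_matrix.shape[0] - len(present)
    if len(present) == 0:
        raise ValueError("no transcript of the matrix is present in the id map")
    if n_dropped:
        logger.info("dropping %d unmapped transcripts", n_dropped)

    sub = transcript_matrix.values.loc[present]
    meta = mapping.loc[present]
    out: dict[str, ExpressionMatrix] = {}
    for gene_class, grp in meta.groupby("gene_class", sort=True):
        rows = sub.loc[grp.index]
        agg = rows.groupby(grp["gene_id"]).mean()
        agg.index.name = "feature_id"
        out[str(gene_class)] = ExpressionMatrix(agg, str(gene_class), "raw")
    return out


def log2_standardize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Return ``log2(x + 1)`` of a raw matrix (pseudocount guards zeros)."""
    if m.scale != "raw":
        raise ValueError("matrix is already on the log2 scale")
    vals = m.values.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("negative values in raw matrix")
    return ExpressionMatrix(
        pd.DataFrame(np.log2(vals + 1.0), index=m.values.index, columns=m.values.columns),
        m.feature_class,
        "log2",
    )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_bed(path: str | Path) -> list:
    """Read a BED file (0-based half-open) into GenomicInterval records."""
    from .regulatory import GenomicInterval

    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else ""
            strand = parts[5] if len(parts) > 5 else "+"
            out.append(GenomicInterval(chrom, start, end, strand, name))
    return out


def write_bed(intervals: Iterable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{iv.strand}\n")
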