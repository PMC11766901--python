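"""Domain types and I/O for fungal-record tables and community matrices.

The sampling unit is a *foliar lesion* (a "sample"); a *fungal record* is the
isolation of one fungal taxon from one lesion.  Records carry a genus label
and, once fingerprint clustering has run, a MOTU (molecular operational
taxonomic unit, species proxy) and GT (genomic type, strain proxy) label.
Community matrices are samples x taxa count tables at a chosen rank and are
the object every downstream statistic consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

LESION_TYPES = ("TDB", "LLS", "SLS", "PP")

ASSEMBLAGE_TYPES = (
    "coelomycete",
    "hyphomycete",
    "ascomycete",
    "basidiomycete",
    "zygomycete",
)

RECORD_COLUMNS = ["record_id", "sample_id", "genus", "motu_id", "gt_id", "assemblage_type"]
METADATA_COLUMNS = ["sample_id", "tree_id", "host_species", "parish", "lesion_type"]

FACTORS = {"host": "host_species", "parish": "parish", "lesion_type": "lesion_type"}


class SchemaError(ValueError):
    """A table is missing declared columns."""


class IntegrityError(ValueError):
    """Referential integrity between records and metadata is violated."""


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------

@dataclass
class CommunityMatrix:
    """Samples x taxa matrix of record counts at a given taxonomic rank."""

    counts: pd.DataFrame          # index: sample_id, columns: taxon labels
    rank: str                     # "genus" | "motu"

    def __post_init__(self) -> None:
        if self.rank not in ("genus", "motu"):
            raise ValueError(f"rank must be 'genus' or 'motu', got {self.rank!r}")
        values = self.counts.to_numpy()
        if (values < 0).any():
            raise ValueError("community matrix entries must be non-negative")
        if not np.allclose(values, np.round(values)):
            raise ValueError("community matrix entries must be integral")
        self.counts = self.counts.astype(int)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_records(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def richness(self) -> int:
        return int((self.counts.sum(axis=0) > 0).sum())

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path: str | Path, rank: str) -> "CommunityMatrix":
        counts = pd.read_csv(path, sep="\t", index_col="sample_id")
        return cls(counts=counts, rank=rank)

    def to_long(self) -> pd.DataFrame:
        """Long-format (sample_id, taxon_id, count) with zero cells dropped."""
        long = self.counts.stack().rename("count").reset_index()
        long.columns = ["sample_id", "taxon_id", "count"]
        return long[long["count"] > 0].reset_index(drop=True)


@dataclass
class AbundanceVector:
    """Per-taxon record counts with frequency-of-frequencies bookkeeping.

    f_k = number of taxa with exactly k records (abundance based);
    Q_k = number of taxa occurring in exactly k samples (incidence based).
    """

    counts: pd.Series             # index: taxon, values: n_i > 0
    incidence: pd.Series          # index: taxon, values: number of samples
    m: int                        # number of samples

    def __post_init__(self) -> None:
        self.counts = self.counts[self.counts > 0]
        self.incidence = self.incidence.loc[self.counts.index]

    @property
    def N(self) -> int:
        return int(self.counts.sum())

    @property
    def S(self) -> int:
        return int(len(self.counts))

    @property
    def p(self) -> np.ndarray:
        return self.counts.to_numpy() / self.N

    def f(self, k: int) -> int:
        """Number of taxa with exactly k records."""
        return int((self.counts == k).sum())

    def Q(self, k: int) -> int:
        """Number of taxa present in exactly k samples."""
        return int((self.incidence == k).sum())

    @classmethod
    def from_matrix(cls, matrix: CommunityMatrix) -> "AbundanceVector":
        counts = matrix.counts.sum(axis=0)
        incidence = (matrix.counts > 0).sum(axis=0)
        return cls(counts=counts, incidence=incidence, m=matrix.n_samples)


# ---------------------------------------------------------------------------
# Readers / validation
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing columns: {missing}")


def validate_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    _require_columns(metadata, METADATA_COLUMNS, "sample metadata")
    if metadata["sample_id"].duplicated().any():
        dupes = metadata.loc[metadata["sample_id"].duplicated(), "sample_id"].tolist()
        raise IntegrityError(f"duplicate sample_id values: {dupes}")
    bad = set(metadata["lesion_type"]) - set(LESION_TYPES)
    if bad:
        raise IntegrityError(f"unknown lesion types: {sorted(bad)}")
    return metadata.reset_index(drop=True)


def validate_records(records: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    _require_columns(records, ["record_id", "sample_id", "genus"], "fungal records")
    for col in ("motu_id", "gt_id", "assemblage_type"):
        if col not in records.columns:
            records = records.copy()
            records[col] = pd.NA
    if records["record_id"].duplicated().any():
        dupes = records.loc[records["record_id"].duplicated(), "record_id"].tolist()
        raise IntegrityError(f"duplicate record_id values: {dupes}")
    known = set(metadata["sample_id"])
    orphans = records.loc[~records["sample_id"].isin(known), "record_id"].tolist()
    if orphans:
        raise IntegrityError(f"records reference unknown sample_id: {orphans}")
    return records.reset_index(drop=True)


def read_records(path: str | Path, metadata_path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate records.tsv and samples.tsv.

    Returns (records, metadata) with referential integrity enforced:
    every record's sample_id exists in the metadata.
    """
    records = pd.read_csv(path, sep="\t", dtype=str)
    metadata = pd.read_csv(metadata_path, sep="\t", dtype=str)
    metadata = validate_metadata(metadata)
    records = validate_records(records, metadata)
    return records, metadata


def write_records(records: pd.DataFrame, metadata: pd.DataFrame,
                  records_path: str | Path, metadata_path: str | Path) -> None:
    records.to_csv(records_path, sep="\t", index=False)
    metadata.to_csv(metadata_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Matrix construction and grouping
# ---------------------------------------------------------------------------

def build_matrix(records: pd.DataFrame, metadata: pd.DataFrame, rank: str = "genus",
                 include_empty_samples: bool = False) -> CommunityMatrix:
    """Cross-tabulate records into a samples x taxa count matrix.

    counts[s, t] = number of records of taxon t isolated from sample s.
    Samples without records are excluded unless include_empty_samples, in
    which case they appear as zero rows (the analyses consider only
    colonised lesions by default).
    """
    if rank not in ("genus", "motu"):
        raise ValueError(f"rank must be 'genus' or 'motu', got {rank!r}")
    col = "genus" if rank == "genus" else "motu_id"
    if col == "motu_id":
        missing = records.loc[records["motu_id"].isna(), "record_id"].tolist()
        if missing:
            raise IntegrityError(
                f"records lack motu_id required at rank='motu': {missing}")
    table = pd.crosstab(records["sample_id"], records[col])
    table.index.name = "sample_id"
    table.columns.name = None
    if include_empty_samples:
        table = table.reindex(metadata["sample_id"], fill_value=0)
    else:
        order = [s for s in metadata["sample_id"] if s in table.index]
        table = table.loc[order]
    return CommunityMatrix(counts=table, rank=rank)


def subset_by(matrix: CommunityMatrix, metadata: pd.DataFrame, factor: str,
              level: str, drop_empty_taxa: bool = True) -> CommunityMatrix:
    """Restrict a community matrix to samples at one level of a metadata factor."""
    if factor not in FACTORS:
        raise ValueError(f"factor must be one of {sorted(FACTORS)}, got {factor!r}")
    col = FACTORS[factor]
    levels = set(metadata[col])
    if level not in levels:
        raise ValueError(f"unknown level {level!r} for factor {factor!r}")
    keep = set(metadata.loc[metadata[col] == level, "sample_id"])
    rows = [s for s in matrix.sample_ids if s in keep]
    if not rows:
        raise ValueError(f"no samples with records at {factor}={level!r}")
    counts = matrix.counts.loc[rows]
    if drop_empty_taxa:
        counts = counts.loc[:, counts.sum(axis=0) > 0]
    return CommunityMatrix(counts=counts, rank=matrix.rank)


def matrices_by(matrix: CommunityMatrix, metadata: pd.DataFrame,
                factor: str) -> dict[str, CommunityMatrix]:
    """Partition a matrix into one sub-matrix per observed factor level."""
    col = FACTORS[factor]
    present = metadata.set_index("sample_id").loc[matrix.sample_ids, col]
    out: dict[str, CommunityMatrix] = {}
    for level in sorted(present.unique()):
        out[level] = subset_by(matrix, metadata, factor, level)
    return out
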