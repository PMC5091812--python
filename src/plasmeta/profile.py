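"""Sample x taxon count matrices built from per-read assignment tables.

Assignment tables are Kraken/MEGAN-style long TSVs with one row per
assigned read (``read_id``, ``mate``, ``sample``, ``taxon``, ``rank``).
Reads assigned to the reserved ``HOST`` taxon, or unassigned, never enter
a matrix. Normalization divides each sample's counts by its filtered-read
denominator (the post-QC read count, before host subtraction) and rescales
to counts per ``scale`` reads (counts per million by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

HOST_TAXON = "HOST"
RANKS = ("phylum", "genus")

METADATA_COLUMNS = ("sample_id", "group", "batch", "filtered_read_count")
CONTROL_GROUPS = ("NegControl", "PosControl")
STUDY_GROUPS = ("CFS", "ADCLS", "SLE", "Healthy")


@dataclass
class TaxonCountMatrix:
    """Counts with samples as rows and taxa as columns, at one rank."""

    data: pd.DataFrame
    rank: str
    normalized: bool = False
    scale: float | None = None
    denominators: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.data.to_numpy() < 0).any():
            raise ValueError("count matrix has negative cells")

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.data.columns)

    def to_tsv(self, path: str | Path) -> None:
        # Conventional on-disk layout: taxa as rows, samples as columns.
        self.data.T.to_csv(path, sep="\t", index_label="taxon")

    @classmethod
    def from_tsv(cls, path: str | Path, rank: str) -> "TaxonCountMatrix":
        frame = pd.read_csv(path, sep="\t", index_col="taxon")
        return cls(frame.T, rank=rank)


def validate_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in METADATA_COLUMNS if c not in metadata.columns]
    if missing:
        raise ValueError(f"metadata lacks required columns: {missing}")
    for col in ("group", "batch"):
        if metadata[col].isna().any():
            bad = metadata.loc[metadata[col].isna(), "sample_id"].tolist()
            raise ValueError(f"metadata has missing {col} for samples {bad}")
    if "replicate_of" not in metadata.columns:
        metadata = metadata.assign(replicate_of=pd.NA)
    return metadata


def read_metadata(path: str | Path) -> pd.DataFrame:
    return validate_metadata(pd.read_csv(path, sep="\t", dtype={"sample_id": str}))


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, sep="\t", index=False)


def read_assignments(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"read_id": str, "sample": str})


def build_count_matrix(
    assignments: pd.DataFrame, metadata: pd.DataFrame, rank: str
) -> TaxonCountMatrix:
    """Roll per-read assignments up to a sample x taxon count matrix.

    Cell (s, t) is the number of reads (mates counted individually) of
    sample s assigned to taxon t at the requested rank; HOST-assigned and
    unassigned reads are excluded.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    metadata = validate_metadata(metadata)
    roster = list(metadata["sample_id"])

    if len(assignments):
        unknown = sorted(set(assignments["sample"]) - set(roster))
        if unknown:
            raise ValueError(f"assignments reference unknown samples: {unknown}")
        rows = assignments[
            (assignments["rank"] == rank)
            & (assignments["taxon"] != HOST_TAXON)
            & assignments["taxon"].notna()
        ]
        table = (
            rows.groupby(["sample", "taxon"]).size().unstack(fill_value=0)
            if len(rows)
            else pd.DataFrame(index=pd.Index([], name="sample"))
        )
    else:
        table = pd.DataFrame(index=pd.Index([], name="sample"))

    table = table.reindex(index=roster, fill_value=0).fillna(0).astype(int)
    table.index.name = "sample"
    denominators = pd.Series(
        metadata["filtered_read_count"].to_numpy(), index=roster, name="filtered_read_count"
    )
    return TaxonCountMatrix(table, rank=rank, denominators=denominators)


def normalize_counts(
    matrix: TaxonCountMatrix,
    metadata: pd.DataFrame | None = None,
    scale: float = 1e6,
) -> TaxonCountMatrix:
    """Counts per ``scale`` filtered reads (CPM by default)."""
    if matrix.normalized:
        raise ValueError("matrix is already normalized")
    if metadata is not None:
        metadata = validate_metadata(metadata)
        denominators = pd.Series(
            metadata["filtered_read_count"].to_numpy(),
            index=list(metadata["sample_id"]),
        ).reindex(matrix.samples)
    elif matrix.denominators is not None:
        denominators = matrix.denominators.reindex(matrix.samples)
    else:
        raise ValueError("no denominators available; pass metadata")
    if denominators.isna().any():
        bad = denominators.index[denominators.isna()].tolist()
        raise ValueError(f"no filtered_read_count for samples {bad}")
    zero = denominators.index[denominators <= 0].tolist()
    if zero:
        raise ValueError(f"zero filtered_read_count for samples {zero}")
    data = matrix.data.div(denominators, axis=0) * scale
    return TaxonCountMatrix(
        data, rank=matrix.rank, normalized=True, scale=scale, denominators=denominators
    )


def drop_duplicates(
    matrix: TaxonCountMatrix, metadata: pd.DataFrame, seed: int
) -> tuple[TaxonCountMatrix, pd.DataFrame]:
    """Randomly keep one member of each re-sequenced replicate set.

    Replicate sets are the transitive groups formed by ``replicate_of``
    links; the retained member is a seeded uniform draw, so the result is
    reproducible per seed.
    """
    metadata = validate_metadata(metadata)
    rng = np.random.default_rng(seed)
    parent = {}
    for _, row in metadata.iterrows():
        rep = row.get("replicate_of")
        if pd.notna(rep) and rep != "":
            parent[row["sample_id"]] = rep

    def root(s: str) -> str:
        while s in parent:
            s = parent[s]
        return s

    groups: dict[str, list[str]] = {}
    for s in metadata["sample_id"]:
        groups.setdefault(root(s), []).append(s)

    keep: set[str] = set()
    for members in groups.values():
        keep.add(members[int(rng.integers(len(members)))])

    meta_kept = metadata[metadata["sample_id"].isin(keep)].reset_index(drop=True)
    data = matrix.data.loc[matrix.data.index.isin(keep)]
    denom = (
        matrix.denominators.loc[data.index]
        if matrix.denominators is not None
        else None
    )
    return (
        replace(matrix, data=data, denominators=denom),
        meta_kept,
    )


__all__ = [
    "HOST_TAXON",
    "RANKS",
    "STUDY_GROUPS",
    "CONTROL_GROUPS",
    "TaxonCountMatrix",
    "validate_metadata",
    "read_metadata",
    "write_metadata",
    "read_assignments",
    "build_count_matrix",
    "normalize_counts",
    "drop_duplicates",
]
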