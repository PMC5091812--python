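"""Negative-control overlap screening for reagent contamination.

In low-biomass sequencing, taxa detected in plasma-free negative controls
(nuclease-free water carried through extraction, library preparation and
sequencing) indicate reagent or handling contamination. The screen counts
how many observed taxa also appear in at least one negative control and
flags them, optionally cross-referencing a catalog of genera repeatedly
reported as kit contaminants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .profile import TaxonCountMatrix, validate_metadata


@dataclass
class OverlapStats:
    rank: str
    total_taxa: int
    taxa_in_negatives: int
    negctrl_taxa: frozenset[str]
    observed_taxa: frozenset[str]

    @property
    def overlap_pct(self) -> float:
        if self.total_taxa == 0:
            return 0.0
        return round(100.0 * self.taxa_in_negatives / self.total_taxa, 1)

    def to_dict(self) -> dict:
        return {
            "rank": self.rank,
            "total_taxa": self.total_taxa,
            "taxa_in_negatives": self.taxa_in_negatives,
            "overlap_pct": self.overlap_pct,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def negcontrol_overlap(
    matrix: TaxonCountMatrix,
    metadata: pd.DataFrame,
    presence_threshold: int = 1,
) -> OverlapStats:
    """Overlap between all observed taxa and negative-control taxa.

    A taxon is "present" in a sample when its raw count reaches
    ``presence_threshold``. All negative controls are pooled: one hit in any
    of them marks the taxon.
    """
    if matrix.normalized:
        raise ValueError("overlap screening uses raw counts")
    metadata = validate_metadata(metadata)
    neg_samples = metadata.loc[metadata["group"] == "NegControl", "sample_id"]
    if neg_samples.empty:
        raise ValueError(
            "no negative-control samples: contamination screening is "
            "impossible without plasma-free negative controls"
        )
    present = matrix.data >= presence_threshold
    observed = frozenset(matrix.data.columns[present.any(axis=0)])
    neg_present = present.loc[present.index.isin(neg_samples)]
    in_neg = frozenset(matrix.data.columns[neg_present.any(axis=0)]) & observed
    return OverlapStats(
        rank=matrix.rank,
        total_taxa=len(observed),
        taxa_in_negatives=len(in_neg),
        negctrl_taxa=in_neg,
        observed_taxa=observed,
    )


def load_known_contaminants(path: str | Path | None = None) -> set[str]:
    """Genus catalog of common reagent contaminants (editable text file)."""
    if path is None:
        text = (
            resources.files("plasmeta.data")
            .joinpath("known_contaminants.txt")
            .read_text()
        )
    else:
        text = Path(path).read_text()
    return {
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    }


def flag_contaminants(
    stats: OverlapStats, known_list: set[str] | None = None
) -> pd.Series:
    """Per-taxon flag: negctrl / known / both / clean."""
    known = known_list if known_list is not None else load_known_contaminants()
    flags = {}
    for taxon in sorted(stats.observed_taxa):
        in_neg = taxon in stats.negctrl_taxa
        in_cat = taxon in known
        if in_neg and in_cat:
            flags[taxon] = "both"
        elif in_neg:
            flags[taxon] = "negctrl"
        elif in_cat:
            flags[taxon] = "known"
        else:
            flags[taxon] = "clean"
    return pd.Series(flags, name="contaminant_flag", dtype="object")


def write_flags_tsv(flags: pd.Series, path: str | Path) -> None:
    flags.rename_axis("taxon").to_frame().to_csv(path, sep="\t")


__all__ = [
    "OverlapStats",
    "negcontrol_overlap",
    "flag_contaminants",
    "load_known_contaminants",
    "write_flags_tsv",
]
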