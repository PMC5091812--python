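"""Paired-read concordance audit for low-abundance taxon calls.

A single mate aligning to a taxon is weak evidence — spurious alignments of
low-complexity or conserved fragments routinely produce them. A *concordant
pair* (both mates assigned the same taxon) and confirmation by an
independent classifier are much stronger. This module counts both and turns
them into a supported/unsupported verdict under explicit thresholds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd


@dataclass
class ConcordanceStats:
    taxon: str
    total_reads: int
    concordant_pairs: int
    samples_contributing: int
    confirmed_reads: int | None = None

    def __post_init__(self) -> None:
        if 2 * self.concordant_pairs > self.total_reads:
            raise ValueError("2 * concordant pairs cannot exceed total reads")
        if self.confirmed_reads is not None and self.confirmed_reads > self.total_reads:
            raise ValueError("confirmed reads cannot exceed total reads")

    def to_dict(self) -> dict:
        return {
            "taxon": self.taxon,
            "total_reads": self.total_reads,
            "concordant_pairs": self.concordant_pairs,
            "samples_contributing": self.samples_contributing,
            "confirmed_reads": self.confirmed_reads,
        }


def pair_concordance(
    assignments: pd.DataFrame,
    taxon: str,
    second_assignments: pd.DataFrame | None = None,
) -> ConcordanceStats:
    """Count reads, concordant mate pairs, and cross-classifier confirmations.

    ``assignments`` is a long table with ``read_id``, ``mate``, ``sample``
    and ``taxon`` columns; reads are mates counted individually. A pair is
    concordant when both mates of one ``read_id`` are assigned ``taxon``.
    With a second table, a read is confirmed when the same (read_id, mate)
    is assigned ``taxon`` there too. An absent taxon yields zeros.
    """
    hits = assignments[assignments["taxon"] == taxon]
    total = len(hits)
    mates_per_read = hits.groupby("read_id")["mate"].nunique() if total else pd.Series(dtype=int)
    concordant = int((mates_per_read >= 2).sum())
    samples = int(hits["sample"].nunique()) if "sample" in hits.columns and total else 0

    confirmed = None
    if second_assignments is not None:
        second_hits = second_assignments[second_assignments["taxon"] == taxon]
        first_keys = set(zip(hits["read_id"], hits["mate"]))
        second_keys = set(zip(second_hits["read_id"], second_hits["mate"]))
        confirmed = len(first_keys & second_keys)

    return ConcordanceStats(
        taxon=taxon,
        total_reads=total,
        concordant_pairs=concordant,
        samples_contributing=samples,
        confirmed_reads=confirmed,
    )


@dataclass(frozen=True)
class VerdictConfig:
    """Explicit thresholds behind the supported/unsupported call.

    The presence call is judged *unsupported* when concordant pairs do not
    exceed ``max_pairs_per_sample`` per profiled sample AND (when a second
    classifier is available) the confirmed fraction is below
    ``min_confirm_fraction``.
    """

    max_pairs_per_sample: float = 1.0
    min_confirm_fraction: float = 0.1


def concordance_report(
    stats: ConcordanceStats,
    total_samples: int,
    config: VerdictConfig | None = None,
) -> dict:
    """Verdict plus the evidence table, with the thresholds spelled out."""
    config = config or VerdictConfig()
    pair_floor = config.max_pairs_per_sample * total_samples
    weak_pairs = stats.concordant_pairs <= pair_floor
    if stats.confirmed_reads is None:
        weak_confirm = True
    elif stats.total_reads == 0:
        weak_confirm = True
    else:
        weak_confirm = (
            stats.confirmed_reads / stats.total_reads < config.min_confirm_fraction
        )
    verdict = "unsupported" if (weak_pairs and weak_confirm) else "supported"
    return {
        "taxon": stats.taxon,
        "verdict": verdict,
        "evidence": stats.to_dict(),
        "total_samples": total_samples,
        "thresholds": {
            "max_concordant_pairs_per_sample": config.max_pairs_per_sample,
            "min_confirm_fraction": config.min_confirm_fraction,
        },
    }


def write_report(report: dict, json_path: str | Path, tsv_path: str | Path | None = None) -> None:
    Path(json_path).write_text(json.dumps(report, indent=2) + "\n")
    if tsv_path is not None:
        ev = report["evidence"]
        lines = ["field\tvalue"]
        lines.append(f"taxon\t{ev['taxon']}")
        lines.append(f"verdict\t{report['verdict']}")
        for key in ("total_reads", "concordant_pairs", "samples_contributing",
                    "confirmed_reads"):
            lines.append(f"{key}\t{ev[key]}")
        Path(tsv_path).write_text("\n".join(lines) + "\n")


__all__ = [
    "ConcordanceStats",
    "VerdictConfig",
    "pair_concordance",
    "concordance_report",
    "write_report",
]
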