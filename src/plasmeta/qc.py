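"""Read cleaning for Sol-B-tagged plasma RNA libraries.

The stack mirrors the published pipeline order for these libraries:

1. DUST low-complexity removal (rescaled 0-100 score, threshold 7),
2. pair-aware dereplication (exact and reverse-complement duplicates),
3. 5' B-tail trimming (residual Sol-B primer suffix left after BpmI digestion),
4. the bespoke seven-rule filter (chastity flag, homopolymer runs > 20,
   any 'N', low-quality first half, residual Sol-B primer, minimum length),
5. single-read dereplication pooling both mates, not accounting for pairs.

A pair is dropped when either mate fails; the attrition report charges each
dropped pair to the first failing stage/rule so that input pairs are
accounted exactly once.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from .fastq import ReadPair, ReadRecord, read_fastq_pairs, write_fastq_pairs

SOLB_PRIMER = "GTTTCCCACTGGAGGATA"

# Attribution order: pipeline stages first (DUST, pair dedup), then the
# bespoke rules in the order the filter states them, then the single-read
# dedup that closes the pipeline.
RULE_ORDER = (
    "low_complexity",
    "duplicate_pair",
    "chastity",
    "homopolymer",
    "n_content",
    "lowq_half",
    "solb_contained",
    "too_short",
    "duplicate_single",
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the cleaning stack.

    ``q_fraction`` is the minimum fraction of first-half bases that must
    reach ``q_threshold`` ("less than 2/3 ... >= 30" removes). The B-tail
    matcher requires at least ``tail_min_match`` 5' bases to match a suffix
    of the primer, exactly below ``tail_exact_below`` and with up to
    ``tail_max_mismatch`` mismatches at or above it.
    """

    solb_primer: str = SOLB_PRIMER
    min_length: int = 70
    homopolymer_max: int = 20
    q_threshold: int = 30
    q_fraction: float = 2.0 / 3.0
    dust_threshold: float = 7.0
    dust_window: int = 64
    tail_max_mismatch: int = 1
    tail_min_match: int = 5
    tail_exact_below: int = 10

    def __post_init__(self) -> None:
        if self.min_length <= 0:
            raise ValueError("min_length must be positive")
        if not (0 < self.q_fraction <= 1):
            raise ValueError("q_fraction must be in (0, 1]")


@dataclass
class AttritionReport:
    """Per-rule pair removals plus the normalization denominator."""

    input_pairs: int = 0
    removed: dict[str, int] = field(
        default_factory=lambda: {rule: 0 for rule in RULE_ORDER}
    )
    surviving_pairs: int = 0

    @property
    def filtered_read_count(self) -> int:
        return 2 * self.surviving_pairs

    def charge(self, rule: str) -> None:
        self.removed[rule] += 1

    def validate(self) -> None:
        total = self.surviving_pairs + sum(self.removed.values())
        if total != self.input_pairs:
            raise AssertionError(
                f"attrition does not balance: {self.input_pairs} in, "
                f"{self.surviving_pairs} kept + {sum(self.removed.values())} removed"
            )

    def to_dict(self) -> dict:
        return {
            "input_pairs": self.input_pairs,
            "removed": dict(self.removed),
            "surviving_pairs": self.surviving_pairs,
            "filtered_read_count": self.filtered_read_count,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def to_tsv(self, path: str | Path) -> None:
        lines = ["metric\tpairs"]
        lines.append(f"input\t{self.input_pairs}")
        for rule in RULE_ORDER:
            lines.append(f"removed_{rule}\t{self.removed[rule]}")
        lines.append(f"surviving\t{self.surviving_pairs}")
        lines.append(f"filtered_read_count\t{self.filtered_read_count}")
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# DUST low-complexity score
# ---------------------------------------------------------------------------

def dust_score(sequence: str, window: int = 64) -> float:
    """Rescaled DUST score in [0, 100]; a mononucleotide run scores 100.

    Overlapping 3-mers are counted in sliding windows of up to ``window``
    bases; each window scores sum(c*(c-1)/2) / (w-3), rescaled by the
    window's maximum (w-2)/2 so a single repeated 3-mer attains 100. The
    read score is the maximum over windows. Sequences shorter than 4 bases
    cannot repeat a 3-mer and score 0.
    """
    L = len(sequence)
    w = min(window, L)
    if w < 4:
        return 0.0
    n_windows = L - w + 1
    rescale = 100.0 / ((w - 3) * (w - 2) / 2.0)

    counts: dict[str, int] = {}
    raw = 0  # running sum of c*(c-1)/2 over triplets in the window
    for i in range(w - 2):
        t = sequence[i : i + 3]
        c = counts.get(t, 0)
        raw += c  # adding one occurrence raises c*(c-1)/2 by c
        counts[t] = c + 1
    best = raw
    for start in range(1, n_windows):
        old = sequence[start - 1 : start + 2]
        c = counts[old]
        raw -= c - 1
        counts[old] = c - 1
        new = sequence[start + w - 3 : start + w]
        c = counts.get(new, 0)
        raw += c
        counts[new] = c + 1
        if raw > best:
            best = raw
    return best * rescale


# ---------------------------------------------------------------------------
# Dereplication
# ---------------------------------------------------------------------------

def dereplicate_pairs(pairs: Sequence[ReadPair]) -> tuple[list[ReadPair], int]:
    """Keep the first occurrence of each pair; drop exact duplicates and
    exact reverse-complement duplicates with mates swapped."""
    seen: set[tuple[str, str]] = set()
    kept: list[ReadPair] = []
    removed = 0
    for pair in pairs:
        key = (pair.mate1.sequence, pair.mate2.sequence)
        rc_key = (
            reverse_complement(pair.mate2.sequence),
            reverse_complement(pair.mate1.sequence),
        )
        if key in seen or rc_key in seen:
            removed += 1
            continue
        seen.add(key)
        kept.append(pair)
    return kept, removed


def dereplicate_single(reads: Sequence[ReadRecord]) -> list[ReadRecord]:
    """Exact-sequence dedup across all reads pooled, first occurrence kept."""
    seen: set[str] = set()
    kept: list[ReadRecord] = []
    for read in reads:
        if read.sequence in seen:
            continue
        seen.add(read.sequence)
        kept.append(read)
    return kept


# ---------------------------------------------------------------------------
# B-tail trimming
# ---------------------------------------------------------------------------

def _tail_match_length(sequence: str, config: FilterConfig) -> int:
    """Longest 5' prefix length matching a suffix of the Sol-B primer."""
    primer = config.solb_primer
    top = min(len(primer), len(sequence))
    for k in range(top, config.tail_min_match - 1, -1):
        allowed = config.tail_max_mismatch if k >= config.tail_exact_below else 0
        suffix = primer[len(primer) - k :]
        mismatches = 0
        for a, b in zip(sequence[:k], suffix):
            if a != b:
                mismatches += 1
                if mismatches > allowed:
                    break
        else:
            return k
    return 0


def trim_b_tail(read: ReadRecord, config: FilterConfig | None = None) -> ReadRecord:
    """Remove a residual Sol-B primer suffix from the 5' end, if present."""
    config = config or FilterConfig()
    k = _tail_match_length(read.sequence, config)
    if k == 0:
        return read
    return replace(read, sequence=read.sequence[k:], quality=read.quality[k:])


# ---------------------------------------------------------------------------
# Bespoke seven-rule filter
# ---------------------------------------------------------------------------

def _max_run(sequence: str) -> int:
    best = run = 0
    prev = ""
    for ch in sequence:
        run = run + 1 if ch == prev else 1
        prev = ch
        if run > best:
            best = run
    return best


def _fails_lowq_half(read: ReadRecord, config: FilterConfig) -> bool:
    half = len(read.quality) // 2
    if half == 0:
        return False
    good = sum(1 for q in read.quality[:half] if q >= config.q_threshold)
    return good < config.q_fraction * half


def failing_rule(read: ReadRecord, config: FilterConfig) -> str | None:
    """First bespoke rule the mate violates, or None if it is clean."""
    if not read.sequence:
        return "too_short"
    if not read.chastity_pass:
        return "chastity"
    if _max_run(read.sequence) > config.homopolymer_max:
        return "homopolymer"
    if "N" in read.sequence:
        return "n_content"
    if _fails_lowq_half(read, config):
        return "lowq_half"
    if config.solb_primer in read.sequence:
        return "solb_contained"
    if len(read.sequence) < config.min_length:
        return "too_short"
    return None


_BESPOKE_ORDER = (
    "chastity",
    "homopolymer",
    "n_content",
    "lowq_half",
    "solb_contained",
    "too_short",
)


def apply_bespoke_filter(
    pair: ReadPair, config: FilterConfig | None = None
) -> str | None:
    """Removal rule for the pair, or None to keep.

    Both mates are evaluated; the pair is charged to the first rule (in the
    published order) that either mate violates.
    """
    config = config or FilterConfig()
    r1 = failing_rule(pair.mate1, config)
    r2 = failing_rule(pair.mate2, config)
    hits = {r for r in (r1, r2) if r is not None}
    if not hits:
        return None
    for rule in _BESPOKE_ORDER:
        if rule in hits:
            return rule
    raise AssertionError(f"unknown rule(s): {hits}")  # pragma: no cover


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def qc_pairs(
    pairs: Sequence[ReadPair], config: FilterConfig | None = None
) -> tuple[list[ReadPair], AttritionReport]:
    """Run the cleaning stack on in-memory pairs."""
    config = config or FilterConfig()
    report = AttritionReport(input_pairs=len(pairs))

    # Stage 1: DUST on either mate.
    survivors: list[ReadPair] = []
    for pair in pairs:
        if (
            dust_score(pair.mate1.sequence, config.dust_window) > config.dust_threshold
            or dust_score(pair.mate2.sequence, config.dust_window) > config.dust_threshold
        ):
            report.charge("low_complexity")
        else:
            survivors.append(pair)

    # Stage 2: pair-aware dereplication.
    survivors, n_dup = dereplicate_pairs(survivors)
    report.removed["duplicate_pair"] += n_dup

    # Stage 3: B-tail trimming (never removes a pair by itself).
    survivors = [
        ReadPair(trim_b_tail(p.mate1, config), trim_b_tail(p.mate2, config))
        for p in survivors
    ]

    # Stage 4: bespoke rules.
    kept: list[ReadPair] = []
    for pair in survivors:
        rule = apply_bespoke_filter(pair, config)
        if rule is None:
            kept.append(pair)
        else:
            report.charge(rule)

    # Stage 5: single-read dedup pooling both mates; a pair goes if either
    # mate's sequence was already seen.
    seen: set[str] = set()
    final: list[ReadPair] = []
    for pair in kept:
        s1, s2 = pair.mate1.sequence, pair.mate2.sequence
        if s1 in seen or s2 in seen or s1 == s2:
            report.charge("duplicate_single")
            continue
        seen.add(s1)
        seen.add(s2)
        final.append(pair)

    report.surviving_pairs = len(final)
    report.validate()
    return final, report


def run_qc(
    in1: str | Path,
    in2: str | Path,
    out1: str | Path,
    out2: str | Path,
    config: FilterConfig | None = None,
) -> AttritionReport:
    """File-level cleaning: paired FASTQ in, filtered paired FASTQ out."""
    pairs = read_fastq_pairs(in1, in2)
    kept, report = qc_pairs(pairs, config)
    write_fastq_pairs(out1, out2, kept)
    return report


__all__ = [
    "SOLB_PRIMER",
    "RULE_ORDER",
    "FilterConfig",
    "AttritionReport",
    "reverse_complement",
    "dust_score",
    "dereplicate_pairs",
    "dereplicate_single",
    "trim_b_tail",
    "apply_bespoke_filter",
    "failing_rule",
    "qc_pairs",
    "run_qc",
]
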