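"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive quantities from first principles
(per-window recomputation, explicit mate pairing) so that agreement with the
implementation is evidence, not tautology.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from plasmeta.fastq import ReadPair, ReadRecord


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------

def dust_brute(sequence: str, window: int = 64) -> float:
    """Recompute the rescaled DUST score window by window, from scratch."""
    L = len(sequence)
    w = min(window, L)
    if w < 4:
        return 0.0
    best = 0.0
    for start in range(L - w + 1):
        chunk = sequence[start : start + w]
        counts: dict[str, int] = {}
        for i in range(w - 2):
            t = chunk[i : i + 3]
            counts[t] = counts.get(t, 0) + 1
        raw = sum(c * (c - 1) / 2 for c in counts.values())
        best = max(best, raw)
    return best * 100.0 / ((w - 3) * (w - 2) / 2.0)


def concordance_brute(assignments: pd.DataFrame, taxon: str) -> tuple[int, int]:
    """(total reads, concordant pairs) by explicit mate pairing."""
    total = 0
    mates: dict[str, set[int]] = {}
    for _, row in assignments.iterrows():
        if row["taxon"] != taxon:
            continue
        total += 1
        mates.setdefault(row["read_id"], set()).add(int(row["mate"]))
    concordant = sum(1 for s in mates.values() if {1, 2} <= s)
    return total, concordant


def de_bruijn_64mer() -> str:
    """64 bases in which every overlapping 3-mer is distinct.

    Standard greedy (prefer-largest) de Bruijn construction over ACGT at
    order 3; the cyclic sequence visits each 3-mer once, so any 64-base
    window of the linearization has all-distinct triplets.
    """
    k, alphabet = 3, "ACGT"
    seen = set()
    seq = ["A"] * k
    seen.add("".join(seq))
    while len(seq) < 64 + k - 1:
        suffix = "".join(seq[-(k - 1) :])
        for ch in reversed(alphabet):
            cand = suffix + ch
            if cand not in seen:
                seen.add(cand)
                seq.append(ch)
                break
        else:  # pragma: no cover - construction always completes for 4^3
            raise RuntimeError("de Bruijn construction stalled")
    return "".join(seq[:64])


# ---------------------------------------------------------------------------
# Read construction helpers
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def random_clean_sequence(rng: np.random.Generator, length: int = 100) -> str:
    from plasmeta.qc import SOLB_PRIMER, dust_score

    while True:
        seq = "".join(_BASES[rng.integers(0, 4, length)])
        if SOLB_PRIMER not in seq and dust_score(seq) <= 7.0:
            return seq


def make_read(
    read_id: str = "r1",
    mate: int = 1,
    sequence: str | None = None,
    quality: tuple[int, ...] | None = None,
    chastity_pass: bool = True,
    length: int = 100,
    seed: int = 0,
) -> ReadRecord:
    if sequence is None:
        sequence = random_clean_sequence(np.random.default_rng(seed), length)
    if quality is None:
        quality = tuple([38] * len(sequence))
    return ReadRecord(read_id, mate, sequence, quality, chastity_pass)


def make_pair(read_id: str = "r1", seed: int = 0, **kwargs) -> ReadPair:
    rng = np.random.default_rng(seed)
    return ReadPair(
        make_read(read_id, 1, random_clean_sequence(rng), **kwargs),
        make_read(read_id, 2, random_clean_sequence(rng), **kwargs),
    )


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def defect_config():
    """One-sample library with each defect planted at rate 0.05."""
    from plasmeta.simulate import DEFECTS, SimulationConfig

    return SimulationConfig(
        seed=20,
        n_per_group={"Healthy": 1},
        library_size_mean=1500.0,
        library_size_cv=0.0,
        defect_rates={d: 0.05 for d in DEFECTS},
    )


@pytest.fixture(scope="session")
def defect_pairs(defect_config):
    """(pairs, truth) for the defect library above."""
    from plasmeta.simulate import ReadTruth, simulate_sample_pairs

    truth = ReadTruth()
    rng = np.random.default_rng(defect_config.seed)
    pairs = simulate_sample_pairs(defect_config, "Healthy01", 1500, rng, truth)
    return pairs, truth


@pytest.fixture(scope="session")
def default_counts():
    """Default synthetic cohort: matrix, metadata, truth."""
    from plasmeta.simulate import SimulationConfig, simulate_counts

    return simulate_counts(SimulationConfig(seed=7))
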