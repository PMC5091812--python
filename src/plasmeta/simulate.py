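"""Truth-labelled synthetic data for every pipeline stage.

The generator emulates a low-biomass plasma RNA sequencing study: four study
groups (CFS, ADCLS, SLE, Healthy) plus plasma-free negative controls and a
spiked positive control, sequenced in three batches with batch-specific
reagent-lot effects; reagent contaminant taxa appear in negative controls and
samples alike, while biological taxa never do. Reads carry the Sol-B tag
chemistry's failure modes as *planted, truth-labelled defects* so the QC
stack can be scored against known ground truth.

Defects are mutually exclusive per read pair (rates must sum to <= 1), which
keeps every removal attributable to exactly one planted cause.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .fastq import ReadPair, ReadRecord, write_fastq_pairs
from .profile import (
    CONTROL_GROUPS,
    HOST_TAXON,
    STUDY_GROUPS,
    TaxonCountMatrix,
    validate_metadata,
)
from .qc import SOLB_PRIMER, dust_score, reverse_complement

DEFECTS = (
    "chastity_fail",
    "homopolymer",
    "contains_n",
    "lowq_half",
    "solb_full",
    "solb_tail",
    "short",
    "duplicate_pair",
    "revcomp_duplicate",
    "low_complexity",
)

# Defects that the QC stack repairs rather than removes.
REPAIRABLE_DEFECTS = frozenset({"solb_tail"})

_BASES = np.array(list("ACGT"))

DEFAULT_COHORT = {
    "CFS": 25,
    "Healthy": 25,
    "ADCLS": 13,
    "SLE": 11,
    "NegControl": 7,
    "PosControl": 1,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generator.

    Defaults mirror the emulated cohort (25 CFS / 25 healthy / 13 ADCLS /
    11 SLE, seven plasma-free negatives, one positive control, three
    sequencing batches) and a 28-taxon profile of which 20 are reagent
    contaminants. Library sizes are the *filtered-read* totals and default
    to a desk-scale 50,000 pairs per sample.
    """

    seed: int = 0
    n_per_group: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_COHORT)
    )
    n_batches: int = 3
    n_taxa: int = 28
    n_contaminant_taxa: int = 20
    n_group_effect_taxa: int = 6
    batch_effect_sd: float = 0.5
    group_effect_fold: float = 5.0
    host_fraction: float = 0.98
    library_size_mean: float = 50_000.0
    library_size_cv: float = 0.5
    dispersion: float = 0.3
    defect_rates: dict[str, float] = field(
        default_factory=lambda: {d: 0.02 for d in DEFECTS}
    )
    read_length: int = 100
    rank: str = "genus"
    base_abundance_mean: float = 2e-4
    base_abundance_sd: float = 1.0
    assignment_concordance: float = 0.8

    def __post_init__(self) -> None:
        for name, rate in self.defect_rates.items():
            if name not in DEFECTS:
                raise ValueError(f"unknown defect {name!r}")
            if not 0 <= rate <= 1:
                raise ValueError(f"defect rate {name}={rate} outside [0, 1]")
        if sum(self.defect_rates.values()) > 1 + 1e-9:
            raise ValueError("defect rates must sum to <= 1 (defects are exclusive)")
        if not 0 <= self.host_fraction <= 1:
            raise ValueError("host_fraction must be in [0, 1]")
        for name in ("n_batches", "n_taxa", "n_contaminant_taxa",
                     "n_group_effect_taxa", "read_length"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(n < 0 for n in self.n_per_group.values()):
            raise ValueError("group sizes must be >= 0")
        if self.n_contaminant_taxa > self.n_taxa:
            raise ValueError("n_contaminant_taxa exceeds n_taxa")
        if self.n_batches < 2 and self.batch_effect_sd > 0:
            raise ValueError(
                "batch effects need at least two batches (n_batches < 2 "
                "with nonzero batch_effect_sd)"
            )
        if not (0 <= self.assignment_concordance <= 1):
            raise ValueError("assignment_concordance must be in [0, 1]")


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

def make_metadata(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Sample roster with groups, round-robin batches, and library sizes."""
    rows = []
    for group in sorted(config.n_per_group):
        for i in range(config.n_per_group[group]):
            rows.append(
                {
                    "sample_id": f"{group}{i + 1:02d}",
                    "group": group,
                    "batch": (i % config.n_batches) + 1,
                }
            )
    meta = pd.DataFrame(rows, columns=["sample_id", "group", "batch"])
    sizes = _library_sizes(config, rng, len(meta))
    meta["filtered_read_count"] = sizes
    meta["replicate_of"] = pd.NA
    return meta


def _library_sizes(
    config: SimulationConfig, rng: np.random.Generator, n: int
) -> np.ndarray:
    if config.library_size_cv <= 0:
        return np.full(n, int(round(config.library_size_mean)))
    sigma2 = np.log1p(config.library_size_cv**2)
    mu = np.log(config.library_size_mean) - sigma2 / 2
    return np.maximum(1, np.round(rng.lognormal(mu, np.sqrt(sigma2), n))).astype(int)


# ---------------------------------------------------------------------------
# Count-matrix simulation
# ---------------------------------------------------------------------------

@dataclass
class CountTruth:
    """Planted parameters behind a simulated count matrix."""

    taxa: list[str]
    contaminant: dict[str, bool]
    base_abundance: dict[str, float]
    batch_mult: pd.DataFrame  # taxa x batch (columns 1..n_batches)
    group_mult: pd.DataFrame  # taxa x group (study groups + controls)
    group_effect_taxa: dict[str, str]  # taxon -> affected group
    expected_library_size: dict[str, float] = field(default_factory=dict)
    realized_total: dict[str, int] = field(default_factory=dict)

    def expected_count(self, sample: str, taxon: str, group: str, batch: int) -> float:
        return (
            self.expected_library_size[sample]
            * self.base_abundance[taxon]
            * self.batch_mult.loc[taxon, batch]
            * self.group_mult.loc[taxon, group]
        )


def make_count_truth(
    config: SimulationConfig, rng: np.random.Generator
) -> CountTruth:
    width = max(3, len(str(config.n_taxa)))
    taxa = [f"Taxon{i + 1:0{width}d}" for i in range(config.n_taxa)]
    contaminant_taxa = set(taxa[: config.n_contaminant_taxa])

    base = rng.lognormal(
        np.log(config.base_abundance_mean), config.base_abundance_sd, config.n_taxa
    )

    batches = list(range(1, config.n_batches + 1))
    batch_mult = pd.DataFrame(1.0, index=taxa, columns=batches)
    if config.batch_effect_sd > 0:
        batch_mult.loc[:, batches[1:]] = rng.lognormal(
            0.0, config.batch_effect_sd, (config.n_taxa, len(batches) - 1)
        )

    groups = list(STUDY_GROUPS) + list(CONTROL_GROUPS)
    group_mult = pd.DataFrame(1.0, index=taxa, columns=groups)
    # Biological (non-contaminant) taxa never appear in plasma-free negatives.
    for t in taxa:
        if t not in contaminant_taxa:
            group_mult.loc[t, "NegControl"] = 0.0

    effect_taxa: dict[str, str] = {}
    if config.n_group_effect_taxa > 0 and config.group_effect_fold != 1.0:
        chosen = rng.choice(config.n_taxa, size=min(config.n_group_effect_taxa, config.n_taxa), replace=False)
        target_groups = [g for g in STUDY_GROUPS if g != "Healthy"]
        for idx in chosen:
            g = target_groups[int(rng.integers(len(target_groups)))]
            group_mult.loc[taxa[idx], g] = config.group_effect_fold
            effect_taxa[taxa[idx]] = g

    return CountTruth(
        taxa=taxa,
        contaminant={t: t in contaminant_taxa for t in taxa},
        base_abundance=dict(zip(taxa, base)),
        batch_mult=batch_mult,
        group_mult=group_mult,
        group_effect_taxa=effect_taxa,
    )


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative-binomial counts with var = mu + dispersion * mu^2."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_counts(
    config: SimulationConfig,
    truth: CountTruth | None = None,
    metadata: pd.DataFrame | None = None,
) -> tuple[TaxonCountMatrix, pd.DataFrame, CountTruth]:
    """Draw a sample x taxon count matrix from the stated generative model.

    Expected count for taxon t in sample s is
    ``library_size(s) * base_abundance(t) * batch_mult(t, batch(s)) *
    group_mult(t, group(s))`` with negative-binomial noise
    (var = mu + dispersion * mu^2). Contaminant taxa have nonzero expectation
    in negative controls; biological taxa have expectation exactly zero there.
    """
    rng = np.random.default_rng(config.seed)
    if metadata is None:
        metadata = make_metadata(config, rng)
    else:
        metadata = validate_metadata(metadata)
    if truth is None:
        truth = make_count_truth(config, rng)

    samples = list(metadata["sample_id"])
    truth.expected_library_size = dict(
        zip(samples, metadata["filtered_read_count"].astype(float))
    )

    abund = np.array([truth.base_abundance[t] for t in truth.taxa])
    rows = []
    for _, srow in metadata.iterrows():
        lib = float(srow["filtered_read_count"])
        mult = (
            truth.batch_mult[srow["batch"]].to_numpy()
            * truth.group_mult[srow["group"]].to_numpy()
        )
        rows.append(_nb_draw(rng, lib * abund * mult, config.dispersion))
    data = pd.DataFrame(rows, index=samples, columns=truth.taxa)
    data.index.name = "sample"
    truth.realized_total = {s: int(v) for s, v in data.sum(axis=1).items()}

    denominators = pd.Series(
        metadata["filtered_read_count"].to_numpy(), index=samples,
        name="filtered_read_count",
    )
    matrix = TaxonCountMatrix(data, rank=config.rank, denominators=denominators)
    return matrix, metadata, truth


# ---------------------------------------------------------------------------
# Read simulation with planted defects
# ---------------------------------------------------------------------------

@dataclass
class ReadTruth:
    """Per-pair planted defects and ancillary labels."""

    defects: dict[str, tuple[str, ...]] = field(default_factory=dict)
    tail_length: dict[str, int] = field(default_factory=dict)
    duplicate_of: dict[str, str] = field(default_factory=dict)
    pairs_per_sample: dict[str, int] = field(default_factory=dict)

    def expected_kept_ids(self) -> set[str]:
        """Pairs the QC stack should retain: clean or repairable-only."""
        return {
            rid
            for rid, defs in self.defects.items()
            if all(d in REPAIRABLE_DEFECTS for d in defs)
        }

    def defect_counts(self) -> dict[str, int]:
        counts = {d: 0 for d in DEFECTS}
        for defs in self.defects.values():
            for d in defs:
                counts[d] += 1
        return counts


def _max_run_ok(seq: str, limit: int = 20) -> bool:
    run, prev = 0, ""
    for ch in seq:
        run = run + 1 if ch == prev else 1
        prev = ch
        if run > limit:
            return False
    return True


def _random_quality(
    rng: np.random.Generator, length: int, low: int = 35, high: int = 40
) -> tuple[int, ...]:
    return tuple(int(q) for q in rng.integers(low, high + 1, length))


def _random_clean_sequence(
    rng: np.random.Generator, length: int, config: SimulationConfig
) -> str:
    """Random sequence violating no filter rule (rejection-sampled)."""
    while True:
        seq = "".join(_BASES[rng.integers(0, 4, length)])
        if SOLB_PRIMER in seq:
            continue
        if dust_score(seq) > 7.0:
            continue
        return seq


def _clean_read(
    rng: np.random.Generator, read_id: str, mate: int, config: SimulationConfig
) -> ReadRecord:
    seq = _random_clean_sequence(rng, config.read_length, config)
    return ReadRecord(read_id, mate, seq, _random_quality(rng, config.read_length))


def _plant_defect(
    pair: ReadPair,
    defect: str,
    rng: np.random.Generator,
    config: SimulationConfig,
    truth: ReadTruth,
) -> ReadPair:
    """Return a copy of the (clean) pair carrying exactly one defect."""
    L = config.read_length
    target = int(rng.integers(2)) + 1  # mate to deface where one suffices
    m1, m2 = pair.mate1, pair.mate2

    def on_target(fn):
        nonlocal m1, m2
        if target == 1:
            m1 = fn(m1)
        else:
            m2 = fn(m2)

    if defect == "chastity_fail":
        m1 = replace(m1, chastity_pass=False)
    elif defect == "homopolymer":
        run = int(rng.integers(21, 31))
        base = str(_BASES[rng.integers(0, 4)])
        pos = int(rng.integers(0, L - run + 1))

        def plant(r: ReadRecord) -> ReadRecord:
            seq = r.sequence[:pos] + base * run + r.sequence[pos + run :]
            return replace(r, sequence=seq)

        on_target(plant)
    elif defect == "contains_n":
        def plant(r: ReadRecord) -> ReadRecord:
            # rejection-sample so the N substitution never pushes the read
            # over another rule (the truth label must stay exactly this one)
            while True:
                k = int(rng.integers(1, 4))
                pos = rng.choice(L, size=k, replace=False)
                seq = list(r.sequence)
                for p in pos:
                    seq[p] = "N"
                planted = "".join(seq)
                if dust_score(planted) <= 7.0 and SOLB_PRIMER not in planted:
                    return replace(r, sequence=planted)

        m1, m2 = plant(m1), plant(m2)
    elif defect == "lowq_half":
        def plant(r: ReadRecord) -> ReadRecord:
            half = len(r.quality) // 2
            qual = tuple(int(q) for q in rng.integers(2, 30, half)) + r.quality[half:]
            return replace(r, quality=qual)

        on_target(plant)
    elif defect == "solb_full":
        def plant(r: ReadRecord) -> ReadRecord:
            # offset >= 1 so the primer is a containment hit, never a
            # trimmable 5' tail; re-draw if the splice trips another rule
            while True:
                pos = int(rng.integers(1, L - len(SOLB_PRIMER)))
                seq = (
                    r.sequence[:pos] + SOLB_PRIMER
                    + r.sequence[pos + len(SOLB_PRIMER) :]
                )
                if dust_score(seq) <= 7.0 and _max_run_ok(seq):
                    return replace(r, sequence=seq)

        on_target(plant)
    elif defect == "solb_tail":
        t = int(rng.integers(5, 18))
        truth.tail_length[pair.read_id] = t
        tail = SOLB_PRIMER[-t:]

        def plant(r: ReadRecord) -> ReadRecord:
            return replace(r, sequence=tail + r.sequence[t:])

        on_target(plant)
    elif defect == "short":
        # fresh clean draws at the short length: truncation alone could by
        # chance produce a high-DUST window in the shorter frame
        n = int(rng.integers(20, 70))
        m1 = replace(
            m1, sequence=_random_clean_sequence(rng, n, config),
            quality=m1.quality[:n],
        )
        m2 = replace(
            m2, sequence=_random_clean_sequence(rng, n, config),
            quality=m2.quality[:n],
        )
    elif defect == "low_complexity":
        a, b = rng.choice(4, size=2, replace=False)
        unit = str(_BASES[a]) + str(_BASES[b])
        stretch = (unit * 20)[:40]
        pos = int(rng.integers(0, L - 40 + 1))

        def plant(r: ReadRecord) -> ReadRecord:
            seq = r.sequence[:pos] + stretch + r.sequence[pos + 40 :]
            return replace(r, sequence=seq)

        on_target(plant)
    else:  # pragma: no cover
        raise ValueError(f"cannot plant defect {defect!r}")
    return ReadPair(m1, m2)


def simulate_sample_pairs(
    config: SimulationConfig,
    sample: str,
    n_pairs: int,
    rng: np.random.Generator,
    truth: ReadTruth,
) -> list[ReadPair]:
    """Simulate one library: clean pairs plus planted exclusive defects.

    Duplicate defects (exact and reverse-complement copies of an earlier
    clean pair) are emitted after all other pairs so the first occurrence
    in file order is always the clean source.
    """
    names = list(config.defect_rates)
    probs = [config.defect_rates[d] for d in names]
    p_clean = 1.0 - sum(probs)
    labels = rng.choice(
        names + ["__clean__"], size=n_pairs, p=probs + [p_clean]
    )

    dup_labels = [l for l in labels if l in ("duplicate_pair", "revcomp_duplicate")]
    main_labels = [l for l in labels if l not in ("duplicate_pair", "revcomp_duplicate")]

    pairs: list[ReadPair] = []
    clean_pairs: list[ReadPair] = []
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"{sample}:{counter:06d}"

    for label in main_labels:
        rid = next_id()
        pair = ReadPair(_clean_read(rng, rid, 1, config), _clean_read(rng, rid, 2, config))
        if label == "__clean__":
            truth.defects[rid] = ()
            clean_pairs.append(pair)
        else:
            pair = _plant_defect(pair, label, rng, config, truth)
            truth.defects[rid] = (label,)
        pairs.append(pair)

    if dup_labels and not clean_pairs:
        raise ValueError(
            "duplicate defects require at least one clean pair to copy; "
            "lower the defect rates or the duplicate rates"
        )
    for label in dup_labels:
        rid = next_id()
        src = clean_pairs[int(rng.integers(len(clean_pairs)))]
        if label == "duplicate_pair":
            pair = ReadPair(
                replace(src.mate1, read_id=rid),
                replace(src.mate2, read_id=rid),
            )
        else:
            pair = ReadPair(
                ReadRecord(rid, 1, reverse_complement(src.mate2.sequence),
                           src.mate2.quality[::-1]),
                ReadRecord(rid, 2, reverse_complement(src.mate1.sequence),
                           src.mate1.quality[::-1]),
            )
        truth.defects[rid] = (label,)
        truth.duplicate_of[rid] = src.read_id
        pairs.append(pair)

    truth.pairs_per_sample[sample] = n_pairs
    return pairs


def simulate_reads(
    config: SimulationConfig, out_dir: str | Path
) -> tuple[dict[str, tuple[Path, Path]], ReadTruth]:
    """Write per-sample mate FASTQ files with truth-labelled defects."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    truth = ReadTruth()
    files: dict[str, tuple[Path, Path]] = {}
    for group in sorted(config.n_per_group):
        for i in range(config.n_per_group[group]):
            sample = f"{group}{i + 1:02d}"
            n_pairs = int(_library_sizes(config, rng, 1)[0]) if config.library_size_cv > 0 \
                else int(round(config.library_size_mean))
            pairs = simulate_sample_pairs(config, sample, n_pairs, rng, truth)
            p1 = out_dir / f"{sample}_R1.fastq"
            p2 = out_dir / f"{sample}_R2.fastq"
            write_fastq_pairs(p1, p2, pairs)
            files[sample] = (p1, p2)
    return files, truth


# ---------------------------------------------------------------------------
# Per-read taxon assignments
# ---------------------------------------------------------------------------

@dataclass
class AssignmentTruth:
    reads_per_taxon: dict[str, int] = field(default_factory=dict)
    concordant_pairs: dict[str, int] = field(default_factory=dict)


def simulate_assignments(
    config: SimulationConfig,
    matrix: TaxonCountMatrix | None = None,
    metadata: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, AssignmentTruth]:
    """Per-read assignment table whose rollup equals the count matrix.

    For each cell (s, t) with count c, ``floor(concordance * c / 2)`` read
    pairs are concordant (both mates assigned t); the remaining reads are
    lone mates whose partners are HOST-assigned or absent, exercising host
    exclusion downstream.
    """
    if matrix is None or metadata is None:
        matrix, metadata, _ = simulate_counts(config)
    rng = np.random.default_rng(np.random.default_rng(config.seed).integers(2**31))

    rows: list[tuple[str, int, str, str, str]] = []
    truth = AssignmentTruth(
        reads_per_taxon={t: 0 for t in matrix.taxa},
        concordant_pairs={t: 0 for t in matrix.taxa},
    )
    for sample in matrix.samples:
        counter = 0
        for taxon in matrix.taxa:
            c = int(matrix.data.loc[sample, taxon])
            if c == 0:
                continue
            n_conc = int(np.floor(config.assignment_concordance * c / 2))
            truth.reads_per_taxon[taxon] += c
            truth.concordant_pairs[taxon] += n_conc
            for _ in range(n_conc):
                counter += 1
                rid = f"{sample}:A{counter:06d}"
                rows.append((rid, 1, sample, taxon, config.rank))
                rows.append((rid, 2, sample, taxon, config.rank))
            for _ in range(c - 2 * n_conc):
                counter += 1
                rid = f"{sample}:A{counter:06d}"
                mate = int(rng.integers(2)) + 1
                rows.append((rid, mate, sample, taxon, config.rank))
                if rng.random() < config.host_fraction:
                    rows.append((rid, 3 - mate, sample, HOST_TAXON, config.rank))
    table = pd.DataFrame(
        rows, columns=["read_id", "mate", "sample", "taxon", "rank"]
    )
    return table, truth


def make_rare_taxon_tables(
    taxon: str = "Borrelia",
    total_reads: int = 47,
    concordant_pairs: int = 5,
    confirmed_reads: int = 1,
    n_samples: int = 16,
    seed: int = 0,
    rank: str = "genus",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assignment tables for a low-abundance taxon audit.

    Plants ``total_reads`` reads on one taxon of which ``concordant_pairs``
    pairs have both mates assigned, spread over ``n_samples`` samples, plus
    a second (cross-classifier) table confirming ``confirmed_reads`` of them.
    """
    if 2 * concordant_pairs > total_reads:
        raise ValueError("2 * concordant_pairs cannot exceed total_reads")
    rng = np.random.default_rng(seed)
    samples = [f"S{i + 1:03d}" for i in range(n_samples)]
    rows = []
    k = 0
    for _ in range(concordant_pairs):
        k += 1
        s = samples[int(rng.integers(n_samples))]
        rid = f"{s}:B{k:04d}"
        rows.append((rid, 1, s, taxon, rank))
        rows.append((rid, 2, s, taxon, rank))
    for _ in range(total_reads - 2 * concordant_pairs):
        k += 1
        s = samples[int(rng.integers(n_samples))]
        rid = f"{s}:B{k:04d}"
        rows.append((rid, int(rng.integers(2)) + 1, s, taxon, rank))
    table = pd.DataFrame(rows, columns=["read_id", "mate", "sample", "taxon", "rank"])

    confirm_idx = rng.choice(len(table), size=confirmed_reads, replace=False)
    second_rows = []
    for i, row in table.iterrows():
        assigned = taxon if i in set(confirm_idx) else "Other"
        second_rows.append((row.read_id, row.mate, row["sample"], assigned, rank))
    second = pd.DataFrame(
        second_rows, columns=["read_id", "mate", "sample", "taxon", "rank"]
    )
    return table, second


# ---------------------------------------------------------------------------
# Truth serialization and helpers
# ---------------------------------------------------------------------------

def write_truth_json(truth: ReadTruth | CountTruth, path: str | Path) -> None:
    if isinstance(truth, ReadTruth):
        payload = {
            "defects": {k: list(v) for k, v in truth.defects.items()},
            "tail_length": truth.tail_length,
            "duplicate_of": truth.duplicate_of,
            "pairs_per_sample": truth.pairs_per_sample,
        }
    else:
        payload = {
            "taxa": truth.taxa,
            "contaminant": truth.contaminant,
            "base_abundance": truth.base_abundance,
            "batch_mult": truth.batch_mult.to_dict(),
            "group_mult": truth.group_mult.to_dict(),
            "group_effect_taxa": truth.group_effect_taxa,
            "expected_library_size": truth.expected_library_size,
            "realized_total": truth.realized_total,
        }
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")


def sha256_of(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


__all__ = [
    "DEFECTS",
    "REPAIRABLE_DEFECTS",
    "DEFAULT_COHORT",
    "SimulationConfig",
    "CountTruth",
    "ReadTruth",
    "AssignmentTruth",
    "make_metadata",
    "make_count_truth",
    "simulate_counts",
    "simulate_sample_pairs",
    "simulate_reads",
    "simulate_assignments",
    "make_rare_taxon_tables",
    "write_truth_json",
    "sha256_of",
]
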