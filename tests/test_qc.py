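"""Read-cleaning stack: DUST, dereplication, B-tail trimming, bespoke rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import de_bruijn_64mer, dust_brute, make_pair, make_read, random_clean_sequence
from plasmeta.fastq import ReadPair, FastqFormatError, read_fastq_pairs, write_fastq_pairs
from plasmeta.qc import (
    SOLB_PRIMER,
    FilterConfig,
    apply_bespoke_filter,
    dereplicate_pairs,
    dereplicate_single,
    dust_score,
    qc_pairs,
    reverse_complement,
    run_qc,
    trim_b_tail,
)

CFG = FilterConfig()


class TestDust:
    def test_mononucleotide_run_scores_100(self):
        assert dust_score("A" * 64) == pytest.approx(100.0)

    def test_all_distinct_triplets_score_0(self):
        seq = de_bruijn_64mer()
        assert len(seq) == 64
        triplets = {seq[i : i + 3] for i in range(62)}
        assert len(triplets) == 62  # construction sanity
        assert dust_score(seq) == 0.0

    def test_too_short_scores_0(self):
        assert dust_score("AC") == 0.0
        assert dust_score("ACG") == 0.0

    def test_tandem_repeat_agrees_with_brute_force(self):
        seq = "ACGT" * 16
        assert dust_score(seq) == pytest.approx(dust_brute(seq), abs=1e-9)

    @pytest.mark.parametrize("seed", range(4))
    def test_agrees_with_brute_force_on_random_sequences(self, seed):
        rng = np.random.default_rng(seed)
        bases = np.array(list("ACGT"))
        for _ in range(60):
            length = int(rng.integers(3, 150))
            seq = "".join(bases[rng.integers(0, 4, length)])
            assert dust_score(seq) == pytest.approx(dust_brute(seq), abs=1e-9)

    @given(st.text(alphabet="ACGT", min_size=0, max_size=200))
    @settings(max_examples=100, deadline=None)
    def test_score_bounded(self, seq):
        assert 0.0 <= dust_score(seq) <= 100.0 + 1e-12


class TestDereplication:
    def test_exact_duplicate_pair_removed(self):
        a = make_pair("a", seed=1)
        b = ReadPair(
            make_read("b", 1, a.mate1.sequence), make_read("b", 2, a.mate2.sequence)
        )
        kept, removed = dereplicate_pairs([a, b])
        assert [p.read_id for p in kept] == ["a"]
        assert removed == 1

    def test_revcomp_swapped_duplicate_removed(self):
        a = make_pair("a", seed=2)
        b = ReadPair(
            make_read("b", 1, reverse_complement(a.mate2.sequence)),
            make_read("b", 2, reverse_complement(a.mate1.sequence)),
        )
        kept, removed = dereplicate_pairs([a, b])
        assert [p.read_id for p in kept] == ["a"]
        assert removed == 1

    def test_distinct_pairs_kept_in_order(self):
        pairs = [make_pair(f"p{i}", seed=10 + i) for i in range(5)]
        kept, removed = dereplicate_pairs(pairs)
        assert [p.read_id for p in kept] == [f"p{i}" for i in range(5)]
        assert removed == 0

    def test_single_read_dedup_pools_mates(self):
        r1 = make_read("x", 1, seed=3)
        r2 = make_read("y", 2, r1.sequence)  # same sequence, different pair/mate
        r3 = make_read("z", 1, seed=4)
        kept = dereplicate_single([r1, r2, r3])
        assert [r.read_id for r in kept] == ["x", "z"]

    def test_single_read_dedup_empty(self):
        assert dereplicate_single([]) == []

    def test_planted_duplicates_recovered(self, defect_pairs):
        pairs, truth = defect_pairs
        planted = truth.defect_counts()
        n_dup = planted["duplicate_pair"] + planted["revcomp_duplicate"]
        _, removed = dereplicate_pairs(pairs)
        assert removed == n_dup


class TestBTailTrim:
    def test_five_base_suffix_trimmed(self):
        core = random_clean_sequence(np.random.default_rng(5), 95)
        read = make_read("t", 1, "GGATA" + core)
        trimmed = trim_b_tail(read, CFG)
        assert trimmed.sequence == core
        assert len(trimmed.quality) == len(core)

    def test_full_primer_prefix_trimmed(self):
        core = random_clean_sequence(np.random.default_rng(6), 82)
        read = make_read("t", 1, SOLB_PRIMER + core)
        assert trim_b_tail(read, CFG).sequence == core

    def test_one_mismatch_tolerated_for_long_tails(self):
        tail = list(SOLB_PRIMER[-12:])
        tail[4] = "A" if tail[4] != "A" else "C"
        core = random_clean_sequence(np.random.default_rng(7), 88)
        read = make_read("t", 1, "".join(tail) + core)
        assert trim_b_tail(read, CFG).sequence == core

    def test_no_primer_prefix_unchanged(self):
        read = make_read("t", 1, "TTTTT" + random_clean_sequence(np.random.default_rng(8), 95))
        # TTTTT is not a suffix of the primer (which ends ...GGATA)
        assert trim_b_tail(read, CFG) == read

    def test_quality_trimmed_in_lockstep(self):
        core = random_clean_sequence(np.random.default_rng(9), 90)
        qual = tuple(range(30, 30 + 95))
        read = make_read("t", 1, "GGATA" + core, quality=qual)
        trimmed = trim_b_tail(read, CFG)
        assert trimmed.quality == qual[5:]

    def test_planted_tails_trimmed_to_truth_length(self, defect_pairs):
        pairs, truth = defect_pairs
        checked = mismatched = 0
        by_id = {p.read_id: p for p in pairs}
        for rid, t in truth.tail_length.items():
            pair = by_id[rid]
            m1 = trim_b_tail(pair.mate1, CFG)
            m2 = trim_b_tail(pair.mate2, CFG)
            checked += 1
            if len(m1) + len(m2) != 2 * len(pair.mate1) - t:
                mismatched += 1
        assert checked > 20
        assert mismatched <= 0.01 * checked


def _pair_with(seq1=None, seq2=None, **kwargs):
    rng = np.random.default_rng(11)
    s1 = seq1 if seq1 is not None else random_clean_sequence(rng)
    s2 = seq2 if seq2 is not None else random_clean_sequence(rng)
    return ReadPair(make_read("p", 1, s1, **kwargs), make_read("p", 2, s2, **kwargs))


class TestBespokeFilter:
    def test_homopolymer_boundary(self):
        rng = np.random.default_rng(12)
        base = random_clean_sequence(rng)
        over = base[:40] + "A" * 21 + base[61:]
        # "more than 20": exactly 20, bracketed by different bases, is kept
        under = base[:40] + "C" + "G" * 20 + "A" + base[62:]
        assert apply_bespoke_filter(_pair_with(seq1=over), CFG) == "homopolymer"
        assert SOLB_PRIMER not in under and "N" not in under
        assert apply_bespoke_filter(_pair_with(seq1=under), CFG) is None

    def test_n_content(self):
        rng = np.random.default_rng(13)
        seq = random_clean_sequence(rng)
        seq = seq[:50] + "N" + seq[51:]
        assert apply_bespoke_filter(_pair_with(seq2=seq), CFG) == "n_content"

    def test_lowq_half_boundary(self):
        # 100-base read: first half = 50 bases; 2/3 * 50 = 33.33, so 33
        # good bases fail ("less than 2/3") and 34 pass.
        for good, expected in [(33, "lowq_half"), (34, None)]:
            qual = tuple([35] * good + [20] * (50 - good) + [38] * 50)
            pair = _pair_with()
            bad = make_read("p", 1, pair.mate1.sequence, quality=qual)
            decision = apply_bespoke_filter(ReadPair(bad, pair.mate2), CFG)
            assert decision == expected

    def test_solb_containment_at_any_offset(self):
        rng = np.random.default_rng(14)
        base = random_clean_sequence(rng)
        for offset in (0, 37, 82):
            seq = base[:offset] + SOLB_PRIMER + base[offset + 18 :]
            assert apply_bespoke_filter(_pair_with(seq1=seq), CFG) == "solb_contained"

    def test_chastity_failure(self):
        pair = make_pair("c", seed=15)
        failed = ReadPair(
            make_read("c", 1, pair.mate1.sequence, chastity_pass=False), pair.mate2
        )
        assert apply_bespoke_filter(failed, CFG) == "chastity"

    def test_short_read_removed(self):
        seq = random_clean_sequence(np.random.default_rng(16), 69)
        assert apply_bespoke_filter(_pair_with(seq2=seq), CFG) == "too_short"

    def test_empty_sequence_removed_as_too_short(self):
        pair = _pair_with(seq1="")
        assert apply_bespoke_filter(pair, CFG) == "too_short"

    def test_attribution_follows_rule_order(self):
        # chastity on mate1 and N on mate2: chastity is charged first.
        rng = np.random.default_rng(17)
        s2 = random_clean_sequence(rng)
        s2 = s2[:10] + "N" + s2[11:]
        pair = ReadPair(
            make_read("o", 1, random_clean_sequence(rng), chastity_pass=False),
            make_read("o", 2, s2),
        )
        assert apply_bespoke_filter(pair, CFG) == "chastity"

    def test_either_mate_failing_removes_pair(self):
        clean = make_pair("e", seed=18)
        assert apply_bespoke_filter(clean, CFG) is None
        seq = clean.mate2.sequence[:50] + "N" + clean.mate2.sequence[51:]
        dirty = ReadPair(clean.mate1, make_read("e", 2, seq))
        assert apply_bespoke_filter(dirty, CFG) == "n_content"


class TestRunQC:
    def test_all_clean_input_fully_retained(self, tmp_path):
        from plasmeta.simulate import DEFECTS, SimulationConfig, simulate_reads

        config = SimulationConfig(
            seed=30, n_per_group={"Healthy": 1}, library_size_mean=100.0,
            library_size_cv=0.0, defect_rates={d: 0.0 for d in DEFECTS},
        )
        files, _ = simulate_reads(config, tmp_path / "reads")
        in1, in2 = files["Healthy01"]
        report = run_qc(in1, in2, tmp_path / "o1.fastq", tmp_path / "o2.fastq")
        assert report.input_pairs == 100
        assert report.surviving_pairs == 100
        assert all(v == 0 for v in report.removed.values())
        assert report.filtered_read_count == 200

    def test_kept_set_matches_truth(self, defect_pairs):
        pairs, truth = defect_pairs
        kept, report = qc_pairs(pairs)
        assert {p.read_id for p in kept} == truth.expected_kept_ids()
        report.validate()

    def test_per_rule_attrition_matches_truth(self, defect_pairs):
        pairs, truth = defect_pairs
        _, report = qc_pairs(pairs)
        planted = truth.defect_counts()
        assert report.removed["chastity"] == planted["chastity_fail"]
        assert report.removed["n_content"] == planted["contains_n"]
        assert report.removed["lowq_half"] == planted["lowq_half"]
        assert report.removed["solb_contained"] == planted["solb_full"]
        assert report.removed["too_short"] == planted["short"]
        assert report.removed["duplicate_pair"] == (
            planted["duplicate_pair"] + planted["revcomp_duplicate"]
        )
        # Homopolymer runs >= 21 always exceed the DUST threshold inside a
        # 64-base window, so with DUST first they land in low_complexity.
        assert report.removed["low_complexity"] + report.removed["homopolymer"] == (
            planted["low_complexity"] + planted["homopolymer"]
        )

    def test_idempotent_on_own_output(self, defect_pairs, tmp_path):
        pairs, _ = defect_pairs
        kept, _ = qc_pairs(pairs)
        write_fastq_pairs(tmp_path / "a1.fastq", tmp_path / "a2.fastq", kept)
        report2 = run_qc(
            tmp_path / "a1.fastq", tmp_path / "a2.fastq",
            tmp_path / "b1.fastq", tmp_path / "b2.fastq",
        )
        assert report2.surviving_pairs == report2.input_pairs == len(kept)
        assert all(v == 0 for v in report2.removed.values())
        rerun = read_fastq_pairs(tmp_path / "b1.fastq", tmp_path / "b2.fastq")
        assert [p.read_id for p in rerun] == [p.read_id for p in kept]

    def test_conservation(self, defect_pairs):
        pairs, _ = defect_pairs
        _, report = qc_pairs(pairs)
        assert report.input_pairs == report.surviving_pairs + sum(
            report.removed.values()
        )

    def test_malformed_fastq_reports_record_number(self, tmp_path):
        good = "@r1 1:N:0:1\nACGTACGTAC\n+\nIIIIIIIIII\n"
        bad = good + "@r2 1:N:0:1\nACGTACGTAC\n+\nIIIII\n"  # truncated quality
        (tmp_path / "m1.fastq").write_text(bad)
        (tmp_path / "m2.fastq").write_text(good + good)
        with pytest.raises(FastqFormatError, match="record 2"):
            run_qc(
                tmp_path / "m1.fastq", tmp_path / "m2.fastq",
                tmp_path / "x1.fastq", tmp_path / "x2.fastq",
            )

    def test_chastity_flag_survives_io_roundtrip(self, tmp_path):
        pair = make_pair("rt", seed=40)
        flagged = ReadPair(
            make_read("rt", 1, pair.mate1.sequence, chastity_pass=False),
            pair.mate2,
        )
        write_fastq_pairs(tmp_path / "r1.fastq", tmp_path / "r2.fastq", [flagged])
        back = read_fastq_pairs(tmp_path / "r1.fastq", tmp_path / "r2.fastq")
        assert back[0].mate1.chastity_pass is False
        assert back[0].mate2.chastity_pass is True
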