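import numpy as np
import pytest

from conftest import random_promoters
from phylofoot.aggregation import Peak
from phylofoot.iodata import (
    DatabaseMotif,
    MotifDatabase,
    PromoterRecord,
    reverse_complement,
)
from phylofoot.motifcompare import (
    MatchScore,
    aggregate_peak_stats,
    build_consolidated_alignment,
    compare_pwms,
    presence_map,
    score_consolidated,
)
from phylofoot.motifdiscovery import Instance, build_motif
from phylofoot.synthdata import pwm_from_consensus


def rc_pwm(pwm):
    return pwm[::-1, ::-1]


def random_sharp_pwm(rng, width, dominance=0.9):
    cons = "".join("ACGT"[i] for i in rng.integers(0, 4, width))
    return pwm_from_consensus(cons, dominance)


class TestComparePwms:
    def test_self_match_is_perfect_and_most_significant(self, rng):
        q = random_sharp_pwm(rng, 10)
        db = MotifDatabase(
            motifs=[DatabaseMotif("SELF", q)]
            + [DatabaseMotif(f"R{i}", random_sharp_pwm(rng, 10)) for i in range(5)]
        )
        matches = {m.db_motif_name: m for m in compare_pwms(q, db, seed=1)}
        self_m = matches["SELF"]
        assert self_m.offset == 0 and self_m.orientation == "+"
        assert self_m.score == pytest.approx(1.0)
        assert self_m.p_value == min(m.p_value for m in matches.values())

    def test_reverse_complement_matches_on_minus_strand(self, rng):
        q = random_sharp_pwm(rng, 9)
        db = MotifDatabase(motifs=[DatabaseMotif("M", rc_pwm(q))])
        (m,) = compare_pwms(q, db, seed=1)
        assert m.orientation == "-" and m.score == pytest.approx(1.0)

    def test_e_value_scales_with_database_size(self, rng):
        q = random_sharp_pwm(rng, 10)
        target = DatabaseMotif("T", random_sharp_pwm(rng, 12))
        decoys = [DatabaseMotif(f"D{i}", random_sharp_pwm(rng, 12)) for i in range(9)]
        m1 = compare_pwms(q, MotifDatabase(motifs=[target]), seed=5)[0]
        m10 = compare_pwms(q, MotifDatabase(motifs=[target] + decoys), seed=5)[0]
        assert m1.p_value == m10.p_value  # same motif, same shuffles
        assert m10.e_value == pytest.approx(10 * m1.p_value)
        assert m1.e_value == pytest.approx(1 * m1.p_value)

    def test_orientation_symmetry(self, rng):
        q = random_sharp_pwm(rng, 8)
        db = MotifDatabase(
            motifs=[DatabaseMotif(f"M{i}", random_sharp_pwm(rng, 11)) for i in range(4)]
        )
        fwd = compare_pwms(q, db, seed=2)
        rev = compare_pwms(rc_pwm(q), db, seed=2)
        for a, b in zip(fwd, rev):
            assert a.score == pytest.approx(b.score, abs=1e-9)
            assert {a.orientation, b.orientation} == {"+", "-"} or a.score == b.score

    def test_uniform_columns_are_well_defined(self):
        q = np.full((6, 4), 0.25)  # all-N style query
        db = MotifDatabase(motifs=[DatabaseMotif("M", pwm_from_consensus("ACGTAC"))])
        (m,) = compare_pwms(q, db, seed=0)
        assert np.isfinite(m.score) and 0 < m.p_value <= 1

    def test_empty_database_raises(self, rng):
        with pytest.raises(ValueError):
            compare_pwms(random_sharp_pwm(rng, 8), MotifDatabase(motifs=[]))


def ms(tf, e, peak=1, score=0.5):
    return MatchScore("q", tf, 0, "+", score, e / 20, e)


class TestAggregatePeakStats:
    def test_top_candidate_frequency_is_run_fraction(self):
        peak = Peak(1, 10, 20, 5, 0.5)
        runs = []
        for i in range(25):
            if i < 18:
                runs.append({1: [ms("FNR", 0.01), ms("CRP", 0.2)]})
            else:
                runs.append({1: [ms("FNR", 0.3), ms("CRP", 0.04)]})
        (stats,) = aggregate_peak_stats(runs, [peak])
        assert stats.per_tf["FNR"].top_candidate_freq == pytest.approx(0.72)
        assert stats.per_tf["CRP"].top_candidate_freq == pytest.approx(0.28)

    def test_unmatched_runs_dilute_frequencies(self):
        peak = Peak(1, 10, 20, 5, 0.5)
        runs = [{1: [ms("FNR", 0.01)]}] * 3 + [{}] * 1
        (stats,) = aggregate_peak_stats(runs, [peak])
        assert stats.per_tf["FNR"].top_candidate_freq == pytest.approx(0.75)
        assert stats.n_matched_runs == 3

    def test_all_evalues_above_alpha_give_zero_significant(self):
        peak = Peak(1, 0, 10, 5, 0.5)
        runs = [{1: [ms("X", 0.9)]}, {1: [ms("X", 2.0)]}]
        (stats,) = aggregate_peak_stats(runs, [peak], alpha=0.05)
        assert stats.per_tf["X"].frac_significant == 0.0

    def test_single_run_quartiles_collapse_to_median(self):
        peak = Peak(1, 0, 10, 5, 0.5)
        (stats,) = aggregate_peak_stats([{1: [ms("X", 0.7)]}], [peak])
        s = stats.per_tf["X"]
        assert s.median == s.q1 == s.q3 == pytest.approx(0.7)

    def test_peak_without_matches_has_empty_stats(self):
        peak = Peak(2, 0, 10, 5, 0.5)
        (stats,) = aggregate_peak_stats([{}, {}], [peak])
        assert stats.n_matched_runs == 0 and stats.per_tf == {}


def make_records(rng, n=5, length=60):
    recs = random_promoters(rng, n, length)
    recs[0].is_target = True
    return recs


class TestConsolidatedAlignment:
    def test_identical_offsets_give_stacked_rows(self, rng):
        recs = make_records(rng)
        sequences = {r.id: r.sequence for r in recs}
        motif = build_motif(
            [Instance(r.id, 20, "+") for r in recs[:4]], sequences, 8
        )
        peak = Peak(1, 20, 28, 1, 1.0)
        aln = build_consolidated_alignment(peak, [[motif]], recs)
        assert len(aln.rows) == 4
        assert all(len(r.segment) == 8 for r in aln.rows)
        assert aln.rows[0].promoter_id == "s0"  # target row first
        for row in aln.rows:
            assert row.segment == sequences[row.promoter_id][20:28]

    def test_undetected_promoter_absent(self, rng):
        recs = make_records(rng)
        sequences = {r.id: r.sequence for r in recs}
        motif = build_motif(
            [Instance("s0", 20, "+"), Instance("s1", 20, "+")], sequences, 8
        )
        aln = build_consolidated_alignment(Peak(1, 20, 28, 1, 1.0), [[motif]], recs)
        assert {r.promoter_id for r in aln.rows} == {"s0", "s1"}

    def test_majority_position_wins(self, rng):
        recs = make_records(rng)
        sequences = {r.id: r.sequence for r in recs}
        runs = []
        for _ in range(3):
            runs.append(
                [build_motif([Instance("s0", 20, "+"), Instance("s1", 30, "+")], sequences, 8)]
            )
        runs.append(
            [build_motif([Instance("s0", 20, "+"), Instance("s1", 10, "+")], sequences, 8)]
        )
        aln = build_consolidated_alignment(Peak(1, 20, 28, 1, 1.0), runs, recs)
        s1_row = next(r for r in aln.rows if r.promoter_id == "s1")
        assert s1_row.start == 30

    def test_peak_wider_than_motif_extends_flanks(self, rng):
        recs = make_records(rng)
        sequences = {r.id: r.sequence for r in recs}
        motif = build_motif(
            [Instance("s0", 20, "+"), Instance("s1", 25, "+")], sequences, 8
        )
        # peak extends 2 left and 2 right of the target instance
        aln = build_consolidated_alignment(Peak(1, 18, 30, 1, 1.0), [[motif]], recs)
        s1_row = next(r for r in aln.rows if r.promoter_id == "s1")
        assert s1_row.start == 23 and s1_row.segment == sequences["s1"][23:35]

    def test_out_of_bounds_row_padded_with_n(self, rng):
        recs = make_records(rng)
        sequences = {r.id: r.sequence for r in recs}
        motif = build_motif(
            [Instance("s0", 20, "+"), Instance("s1", 0, "+")], sequences, 8
        )
        aln = build_consolidated_alignment(Peak(1, 15, 28, 1, 1.0), [[motif]], recs)
        s1_row = next(r for r in aln.rows if r.promoter_id == "s1")
        assert s1_row.padded and s1_row.segment.startswith("NNNNN")

    def test_minus_strand_row_reverse_complemented(self, rng):
        recs = make_records(rng)
        sequences = {r.id: r.sequence for r in recs}
        motif = build_motif(
            [Instance("s0", 20, "+"), Instance("s1", 30, "-")], sequences, 8
        )
        aln = build_consolidated_alignment(Peak(1, 20, 28, 1, 1.0), [[motif]], recs)
        s1_row = next(r for r in aln.rows if r.promoter_id == "s1")
        assert s1_row.segment == reverse_complement(sequences["s1"][30:38])

    def test_no_supporting_run_raises(self, rng):
        recs = make_records(rng)
        with pytest.raises(ValueError):
            build_consolidated_alignment(Peak(1, 20, 28, 1, 1.0), [[]], recs)


class TestScoreConsolidated:
    def test_alignment_of_db_consensus_ranks_that_motif_first(self, rng):
        cons = "TTGACCGGTCAA"
        recs = [
            PromoterRecord(id=("s0"), sequence="A" * 20 + cons + "A" * 20, is_target=True)
        ] + [
            PromoterRecord(id=f"s{i}", sequence="C" * 20 + cons + "C" * 20)
            for i in range(1, 4)
        ]
        sequences = {r.id: r.sequence for r in recs}
        motif = build_motif([Instance(r.id, 20, "+") for r in recs], sequences, 12)
        aln = build_consolidated_alignment(Peak(1, 20, 32, 1, 1.0), [[motif]], recs)
        db = MotifDatabase(
            motifs=[DatabaseMotif("TRUE", pwm_from_consensus(cons))]
            + [DatabaseMotif(f"D{i}", random_sharp_pwm(rng, 12)) for i in range(5)]
        )
        scores = score_consolidated(aln, db, seed=2)
        best = min(scores, key=lambda m: (m.e_value, -m.score))
        assert best.db_motif_name == "TRUE"

    def test_single_row_alignment_rejected(self, rng):
        recs = make_records(rng)
        sequences = {r.id: r.sequence for r in recs}
        motif = build_motif([Instance("s0", 20, "+"), Instance("s1", 20, "+")], sequences, 8)
        aln = build_consolidated_alignment(Peak(1, 20, 28, 1, 1.0), [[motif]], recs)
        aln.rows = aln.rows[:1]
        with pytest.raises(ValueError):
            score_consolidated(aln, MotifDatabase(motifs=[DatabaseMotif("M", pwm_from_consensus("ACGTACGT"))]))


class TestPresenceMap:
    def test_detected_unsampled_and_target_taxa(self, rng):
        recs = make_records(rng)
        sequences = {r.id: r.sequence for r in recs}
        motif = build_motif(
            [Instance("s0", 20, "+"), Instance("s1", 20, "+")], sequences, 8
        )
        pm = presence_map(
            Peak(1, 20, 28, 1, 1.0),
            [[motif]],
            recs,
            sampled_ids={"s1", "s2"},
        )
        assert pm.present["s0"] and pm.present["s1"]
        assert not pm.present["s2"]
        assert pm.sampled["s2"] and not pm.sampled["s3"]
        assert pm.sampled["s0"]  # the target is always analyzed
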