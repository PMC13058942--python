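import numpy as np
import pytest

from conftest import plant_word, random_promoters
from phylofoot.iodata import PromoterRecord, reverse_complement
from phylofoot.motifdiscovery import (
    FinderResult,
    GibbsConfig,
    Instance,
    Motif,
    build_motif,
    consensus_finder,
    gibbs_finder,
    information_content,
    vote_combine,
)


def exact_word_oracle(seqs, width):
    """Rank all words of the data (both strands) by (support, occ, lex)."""
    words = {}
    for s in seqs:
        wins = [s[i : i + width] for i in range(len(s) - width + 1)]
        wins = [w for w in wins if "N" not in w]
        for c in set(wins) | {reverse_complement(w) for w in wins}:
            words.setdefault(c, None)
    for c in words:
        supp = occ = 0
        for s in seqs:
            wins = [s[i : i + width] for i in range(len(s) - width + 1)]
            n = sum(1 for w in wins if w == c or reverse_complement(w) == c)
            occ += n
            supp += n > 0
        words[c] = (supp, occ)
    return sorted(words.items(), key=lambda kv: (-kv[1][0], -kv[1][1], kv[0]))


class TestGibbsFinder:
    def test_recovers_planted_identical_word(self, rng):
        word = "TTGATCAA"
        seqs = random_promoters(rng, 10, 200)
        positions = {}
        for rec in seqs:
            pos = int(rng.integers(0, 200 - len(word)))
            plant_word(rec, word, pos)
            positions[rec.id] = pos
        res = gibbs_finder(seqs, 8, GibbsConfig(seed=3))
        (motif,) = res.motifs
        # phase shifts of a base or two are inherent to site sampling;
        # localization within +/-2 bp counts as recovery
        hits = sum(
            1
            for inst in motif.instances
            if abs(inst.start - positions[inst.promoter_id]) <= 2
        )
        assert hits >= 9

    def test_deterministic_for_fixed_seed(self, rng):
        seqs = random_promoters(rng, 6, 80)
        r1 = gibbs_finder(seqs, 8, GibbsConfig(seed=11, restarts=2, max_iters=60))
        r2 = gibbs_finder(seqs, 8, GibbsConfig(seed=11, restarts=2, max_iters=60))
        assert r1.motifs[0].instances == r2.motifs[0].instances
        np.testing.assert_array_equal(r1.motifs[0].pwm, r2.motifs[0].pwm)

    def test_width_longer_than_sequence_errors(self, rng):
        seqs = random_promoters(rng, 3, 10)
        with pytest.raises(ValueError, match="s0"):
            gibbs_finder(seqs, 12)


class TestConsensusFinder:
    def test_planted_exact_word_ranks_first_with_full_support(self, rng):
        word = "TTGATCTTGA"
        seqs = random_promoters(rng, 8, 150)
        for rec in seqs:
            plant_word(rec, word, int(rng.integers(0, 140)))
        res = consensus_finder(seqs, 10, max_mismatch=0)
        motif = res.motifs[0]
        assert len(motif.instances) == 8
        top = exact_word_oracle([r.sequence for r in seqs], 10)[0][0]
        assert motif.consensus() == top

    def test_matches_brute_force_oracle_on_random_input(self, rng):
        seqs = random_promoters(rng, 5, 60)
        res = consensus_finder(seqs, 6, max_mismatch=0)
        oracle = exact_word_oracle([r.sequence for r in seqs], 6)
        top_word, (supp, _occ) = oracle[0]
        if supp < 2:
            assert res.motifs == []
        else:
            assert res.motifs[0].consensus() == top_word
            assert len(res.motifs[0].instances) == supp

    def test_reverse_complement_pair_tie_breaks_lexicographically(self):
        # a word and its reverse complement always tie on support and
        # occurrences; the lexicographically smaller one must be reported
        s = "CCGCCG" + "ACACAC" + "CCGCCG" + "AGAGAG" + "CCGCCG"
        seqs = [PromoterRecord(id=f"s{i}", sequence=s) for i in range(2)]
        res = consensus_finder(seqs, 6, max_mismatch=0)
        assert res.motifs[0].consensus() == "CCGCCG"  # not CGGCGG

    def test_width_guard(self, rng):
        with pytest.raises(ValueError, match="width"):
            consensus_finder(random_promoters(rng, 3, 50), 13)

    def test_no_shared_word_gives_empty_result(self):
        seqs = [
            PromoterRecord(id="a", sequence="AAAAAAAA"),
            PromoterRecord(id="b", sequence="CACACACG"),
        ]
        res = consensus_finder(seqs, 8, max_mismatch=0)
        assert res.motifs == []


def single_instance_motif(sequences, pid, start, width, finder_width=None):
    return build_motif([Instance(pid, start, "+")], sequences, width)


class TestVoteCombine:
    def test_identical_results_merge_idempotently(self, rng):
        seqs = random_promoters(rng, 6, 60)
        sequences = {r.id: r.sequence for r in seqs}
        insts = [Instance(r.id, 10, "+") for r in seqs]
        motif = build_motif(insts, sequences, 8)
        ra = FinderResult("gibbs", [motif])
        rb = FinderResult("consensus", [build_motif(insts, sequences, 8)])
        merged = vote_combine([ra, rb], sequences, quorum=2)
        assert len(merged) == 1
        assert sorted(merged[0].instances) == sorted(insts)

    def test_single_finder_quorum_auto_lowered(self, rng):
        seqs = random_promoters(rng, 4, 60)
        sequences = {r.id: r.sequence for r in seqs}
        motif = build_motif([Instance(r.id, 5, "+") for r in seqs], sequences, 8)
        merged = vote_combine([FinderResult("gibbs", [motif])], sequences, quorum=2)
        assert len(merged) == 1

    def test_insufficient_overlap_not_grouped(self, rng):
        # 3 bp of width 8 is 0.375 < 0.5: the two finders' motifs stay
        # apart and neither reaches the quorum of 2
        seqs = random_promoters(rng, 2, 40)
        sequences = {r.id: r.sequence for r in seqs}
        ma = build_motif([Instance("s0", 10, "+"), Instance("s1", 10, "+")], sequences, 8)
        mb = build_motif([Instance("s0", 15, "+"), Instance("s1", 15, "+")], sequences, 8)
        merged = vote_combine(
            [FinderResult("gibbs", [ma]), FinderResult("consensus", [mb])],
            sequences,
            quorum=2,
        )
        assert merged == []

    def test_sufficient_overlap_grouped(self, rng):
        seqs = random_promoters(rng, 2, 40)
        sequences = {r.id: r.sequence for r in seqs}
        ma = build_motif([Instance("s0", 10, "+"), Instance("s1", 10, "+")], sequences, 8)
        mb = build_motif([Instance("s0", 14, "+"), Instance("s1", 14, "+")], sequences, 8)
        merged = vote_combine(
            [FinderResult("gibbs", [ma]), FinderResult("consensus", [mb])],
            sequences,
            quorum=2,
        )
        assert len(merged) == 1

    def test_no_fabricated_instances(self, rng):
        # every output instance overlaps an input instance on the same
        # promoter and strand
        seqs = random_promoters(rng, 8, 120)
        sequences = {r.id: r.sequence for r in seqs}
        results = []
        for fi, name in enumerate(["gibbs", "consensus"]):
            insts = [
                Instance(r.id, int(rng.integers(0, 100)), "+" if rng.random() < 0.7 else "-")
                for r in seqs
            ]
            results.append(FinderResult(name, [build_motif(insts, sequences, 10)]))
        merged = vote_combine(results, sequences, quorum=1)
        inputs = [
            (i.promoter_id, i.strand, i.start, i.start + m.width)
            for r in results
            for m in r.motifs
            for i in m.instances
        ]
        for motif in merged:
            for inst in motif.instances:
                assert any(
                    pid == inst.promoter_id
                    and strand == inst.strand
                    and inst.start < e
                    and inst.start + motif.width > s
                    for pid, strand, s, e in inputs
                )


class TestInformationContent:
    def test_uniform_pwm_has_zero_ic(self):
        assert information_content(np.full((7, 4), 0.25)) == pytest.approx(0.0)

    def test_deterministic_pwm_has_two_bits_per_column(self):
        w = 9
        pwm = np.zeros((w, 4))
        pwm[:, 2] = 1.0
        assert information_content(pwm) == pytest.approx(2.0 * w)
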