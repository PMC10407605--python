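"""Centromere miner: array discovery vs a brute-force oracle, clustering,
matching, merging, scoring and planted-truth recovery."""

import numpy as np
import pytest

from t2tkit.centromere import (
    MatchBlock,
    TandemArray,
    cluster_monomers,
    find_tandem_arrays,
    is_low_complexity,
    map_monomers,
    merge_candidates,
    report_top,
    rotation_identity,
    run_centrominer,
    score_and_rank,
    select_centromeric_monomers,
)
from t2tkit.seqio import Interval, SequenceRecord, TeAnnotation, revcomp, \
    reciprocal_overlap
from t2tkit.synth import GenomeSpec, make_truth_genome


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


def brute_force_tandem_scan(seq: str, period_range, min_copies=2):
    """Exhaustive exact-tandem scan: for every period and start, extend the
    run while seq[i] == seq[i + p]; report maximal runs of >= min_copies
    exact copies.  Quadratic; only usable on short sequences."""
    found = []
    lo, hi = period_range
    for p in range(lo, hi + 1):
        i = 0
        while i + 2 * p <= len(seq):
            run = 0
            while i + p + run < len(seq) and seq[i + run] == seq[i + p + run]:
                run += 1
            span = run + p  # bases covered by the repeated region
            if span >= min_copies * p:
                found.append((i, i + span, p))
                i += span - p + 1
            else:
                i += max(1, run + 1)
    return found


class TestFindTandemArrays:
    def test_planted_exact_array(self):
        rng = np.random.default_rng(61)
        monomer = _random_seq(rng, 178)
        seq = _random_seq(rng, 5_000) + monomer * 30 + _random_seq(rng, 5_000)
        arrays = find_tandem_arrays(seq, period_range=(150, 200))
        assert len(arrays) == 1
        a = arrays[0]
        assert a.period == 178
        assert a.copy_number == pytest.approx(30, abs=0.5)
        assert a.consensus in {monomer[i:] + monomer[:i] for i in range(178)}

    def test_random_sequence_has_no_centromeric_arrays(self):
        rng = np.random.default_rng(62)
        arrays = find_tandem_arrays(_random_seq(rng, 100_000),
                                    period_range=(50, 300))
        assert all(a.copy_number < 5 for a in arrays)

    def test_homopolymer_collapses_to_smallest_period(self):
        seq = "A" * 1_000
        arrays = find_tandem_arrays(seq, period_range=(50, 300))
        assert len(arrays) == 1
        assert arrays[0].period == 1
        assert arrays[0].low_complexity

    def test_agrees_with_brute_force_oracle(self):
        """Independent oracle: exhaustive periodicity scan on short strings
        with exact arrays, compared for period and span (+/- one period)."""
        rng = np.random.default_rng(63)
        for trial in range(8):
            p = int(rng.integers(10, 51))
            copies = int(rng.integers(3, 8))
            monomer = _random_seq(rng, p)
            left = _random_seq(rng, int(rng.integers(200, 800)))
            right = _random_seq(rng, int(rng.integers(200, 800)))
            seq = left + monomer * copies + right
            oracle = brute_force_tandem_scan(seq, (10, 50), min_copies=3)
            mine = find_tandem_arrays(seq, period_range=(10, 50), min_copies=3)
            mine = [a for a in mine if not a.low_complexity
                    and a.copy_number >= 3]
            oracle_best = [o for o in oracle if o[2] == p]
            assert oracle_best, "oracle must find the planted array"
            s, e, _ = oracle_best[0]
            match = [a for a in mine if a.period == p
                     and abs(a.span.start - s) <= p
                     and abs(a.span.end - e) <= p]
            assert match, (trial, p, (s, e), [(a.span, a.period) for a in mine])

    def test_mutated_array_still_found(self):
        rng = np.random.default_rng(64)
        monomer = _random_seq(rng, 160)
        copies = [list(monomer) for _ in range(40)]
        for c in copies:  # ~3% per-base divergence
            for i in rng.choice(160, size=5, replace=False):
                c[i] = "ACGT"[int(rng.integers(4))]
        seq = _random_seq(rng, 3_000) + \
            "".join("".join(c) for c in copies) + _random_seq(rng, 3_000)
        arrays = find_tandem_arrays(seq, period_range=(100, 200))
        assert any(a.period == 160 and a.copy_number > 30 for a in arrays)


class TestSelect:
    def _arrays(self, specs):
        return [TandemArray("c", Interval("c", i * 10_000, i * 10_000 + p * n),
                            p, n, "ACGT" * (p // 4 + 1))
                for i, (p, n) in enumerate(specs)]

    def test_period_window(self):
        arrays = self._arrays([(7, 50), (155, 50), (178, 50), (400, 50)])
        kept = select_centromeric_monomers(arrays)
        assert sorted(a.period for a in kept) == [155, 178]

    def test_copy_threshold(self):
        arrays = self._arrays([(178, 3)])
        assert select_centromeric_monomers(arrays) == []

    def test_degenerate_window(self):
        arrays = self._arrays([(178, 50), (177, 50)])
        kept = select_centromeric_monomers(arrays, 178, 178)
        assert [a.period for a in kept] == [178]


class TestClustering:
    def test_one_substitution_joins_cluster(self):
        rng = np.random.default_rng(71)
        mono = _random_seq(rng, 178)
        variant = mono[:100] + ("A" if mono[100] != "A" else "C") + mono[101:]
        arrays = [
            TandemArray("c", Interval("c", 0, 178 * 30), 178, 30, mono),
            TandemArray("c", Interval("c", 10_000, 10_000 + 178 * 20), 178, 20,
                        variant),
        ]
        clusters = cluster_monomers(arrays)
        assert len(clusters) == 1
        assert clusters[0].total_copy_number == 50

    def test_rotation_joins_cluster(self):
        rng = np.random.default_rng(72)
        mono = _random_seq(rng, 150)
        rotated = mono[50:] + mono[:50]
        arrays = [
            TandemArray("c", Interval("c", 0, 150 * 30), 150, 30, mono),
            TandemArray("c", Interval("c", 9_000, 9_000 + 150 * 10), 150, 10,
                        rotated),
        ]
        assert len(cluster_monomers(arrays)) == 1

    def test_reverse_complement_joins_cluster(self):
        rng = np.random.default_rng(73)
        mono = _random_seq(rng, 150)
        arrays = [
            TandemArray("c", Interval("c", 0, 150 * 30), 150, 30, mono),
            TandemArray("c", Interval("c", 9_000, 9_000 + 150 * 10), 150, 10,
                        revcomp(mono)),
        ]
        assert len(cluster_monomers(arrays)) == 1

    def test_unrelated_monomers_stay_apart(self):
        rng = np.random.default_rng(74)
        arrays = [
            TandemArray("c", Interval("c", i * 10_000, i * 10_000 + 150 * 20),
                        150, 20, _random_seq(rng, 150))
            for i in range(2)
        ]
        assert len(cluster_monomers(arrays)) == 2

    def test_every_array_in_exactly_one_cluster(self):
        rng = np.random.default_rng(75)
        arrays = [
            TandemArray("c", Interval("c", i * 10_000, i * 10_000 + 150 * 20),
                        150, 20, _random_seq(rng, 150))
            for i in range(6)
        ]
        clusters = cluster_monomers(arrays)
        members = [id(m) for cl in clusters for m in cl.members]
        assert sorted(members) == sorted(id(a) for a in arrays)

    def test_low_complexity_excluded(self):
        arrays = [TandemArray("c", Interval("c", 0, 300), 150, 2,
                              "AT" * 75, low_complexity=True)]
        assert cluster_monomers(arrays) == []

    def test_rotation_identity_values(self):
        assert rotation_identity("ACGTACGTAA", "GTACGTAAAC") == 1.0
        rng = np.random.default_rng(76)
        a, b = _random_seq(rng, 150), _random_seq(rng, 150)
        assert rotation_identity(a, b) < 0.8


class TestMapMonomers:
    def test_planted_array_fully_covered(self):
        rng = np.random.default_rng(81)
        mono = _random_seq(rng, 178)
        seq = _random_seq(rng, 4_000) + mono * 30 + _random_seq(rng, 4_000)
        blocks = map_monomers([("m1", mono)], SequenceRecord("c", seq))
        assert len(blocks) == 1
        b = blocks[0]
        assert b.identity > 0.99
        assert abs(b.span.start - 4_000) <= 178
        assert abs(b.span.end - (4_000 + 178 * 30)) <= 178

    def test_zero_occurrences(self):
        rng = np.random.default_rng(82)
        blocks = map_monomers([("m1", _random_seq(rng, 178))],
                              SequenceRecord("c", _random_seq(rng, 20_000)))
        assert blocks == []

    def test_minus_strand_found(self):
        rng = np.random.default_rng(83)
        mono = _random_seq(rng, 178)
        seq = _random_seq(rng, 4_000) + revcomp(mono * 30) + \
            _random_seq(rng, 4_000)
        blocks = map_monomers([("m1", mono)], SequenceRecord("c", seq))
        assert blocks and blocks[0].span.end - blocks[0].span.start > 170 * 29


class TestMergeAndScore:
    def _blocks(self, spans, chrom="c"):
        return [MatchBlock(chrom, Interval(chrom, s, e), "m1", 0.9)
                for s, e in spans]

    def test_merge_within_max_gap(self):
        cands = merge_candidates(self._blocks([(0, 10_000), (40_000, 60_000)]),
                                 max_gap=50_000)
        assert len(cands) == 1
        assert (cands[0].span.start, cands[0].span.end) == (0, 60_000)
        assert cands[0].tandem_bp == 30_000

    def test_split_beyond_max_gap(self):
        cands = merge_candidates(
            self._blocks([(0, 10_000), (70_001, 90_000)]), max_gap=50_000)
        assert len(cands) == 2

    def test_short_span_dropped(self):
        assert merge_candidates(self._blocks([(0, 9_000)]),
                                min_span=10_000) == []

    def test_score_formula_and_te_weighting(self):
        cands = merge_candidates(self._blocks([(0, 10_000)]), min_span=5_000)
        te = TeAnnotation(intervals=[
            (Interval("c", 2_000, 4_000), "Gypsy_LTR_retrotransposon", True),
            (Interval("c", 5_000, 5_500), "DNA_transposon", False),
        ])
        ranked = score_and_rank(cands, te, lambda_te=1.0)
        assert ranked[0].te_bp == 2_000  # DNA transposon bases not counted
        assert ranked[0].score == 12_000

    def test_score_without_annotation_is_tandem_bp(self):
        cands = merge_candidates(self._blocks([(0, 10_000)]), min_span=5_000)
        ranked = score_and_rank(cands, None)
        assert ranked[0].score == ranked[0].tandem_bp

    def test_lambda_zero_recovers_length_only(self):
        cands = merge_candidates(
            self._blocks([(0, 10_000), (200_000, 215_000)], chrom="c"),
            max_gap=50_000, min_span=5_000)
        te = TeAnnotation(intervals=[
            (Interval("c", 0, 10_000), "LTR", True)])
        by_len = score_and_rank(cands, te, lambda_te=0.0)
        assert by_len[0].span.start == 200_000  # longer span ranks first

    def test_te_bases_never_lower_score(self):
        cands0 = merge_candidates(self._blocks([(0, 10_000)]), min_span=5_000)
        base = score_and_rank(cands0, None)[0].score
        cands1 = merge_candidates(self._blocks([(0, 10_000)]), min_span=5_000)
        te = TeAnnotation(intervals=[(Interval("c", 0, 1_000), "LINE", True)])
        assert score_and_rank(cands1, te)[0].score >= base

    def test_report_includes_empty_chromosomes(self):
        cands = score_and_rank(
            merge_candidates(self._blocks([(0, 10_000)]), min_span=5_000),
            None)
        report = report_top(cands, ["c", "empty_chrom"], top_n=5)
        assert report["empty_chrom"] == []
        assert len(report["c"]) == 1

    def test_top_n_limits_report(self):
        blocks = []
        for i in range(7):
            blocks += self._blocks([(i * 100_000, i * 100_000 + 20_000)])
        cands = score_and_rank(merge_candidates(blocks, max_gap=10_000), None)
        report = report_top(cands, ["c"], top_n=5)
        assert len(report["c"]) == 5


class TestPlantedRecovery:
    def test_rank1_overlaps_planted_span_across_seeds(self):
        """Rank-1 candidate has >= 0.8 reciprocal overlap with the planted
        satellite array in at least 19 of 20 seeded replicates."""
        hits = 0
        for seed in range(20):
            spec = GenomeSpec(
                chrom_lengths=(400_000,), telomere_copies=120,
                centromere_period=int(150 + (seed % 4) * 10),
                centromere_copies=80, te_count=8, seed=1_000 + seed,
            )
            genome, te_ann, truth = make_truth_genome(spec)
            result = run_centrominer(genome, te_ann)
            top = result["top"]["chr1"]
            if not top:
                continue
            planted = Interval("chr1", *truth.centromeres["chr1"]["span"])
            if reciprocal_overlap(top[0].span, planted) >= 0.8:
                hits += 1
        assert hits >= 19

    def test_strand_symmetry_of_candidates(self, small_fixture):
        genome = small_fixture["genome"]
        rec = genome[0]
        fwd = run_centrominer([rec])["candidates"]
        rev = run_centrominer(
            [SequenceRecord(rec.id, revcomp(rec.seq))])["candidates"]
        L = len(rec.seq)
        fwd_spans = sorted((c.span.start, c.span.end) for c in fwd)
        rev_spans = sorted((L - c.span.end, L - c.span.start) for c in rev)
        for (fs, fe), (rs, re_) in zip(fwd_spans, rev_spans):
            assert abs(fs - rs) < 1_000 and abs(fe - re_) < 1_000

    def test_deterministic(self, small_fixture):
        rec = small_fixture["genome"][0]
        r1 = run_centrominer([rec])
        r2 = run_centrominer([rec])
        assert [(c.chrom, c.span, c.rank, c.score) for c in r1["candidates"]] \
            == [(c.chrom, c.span, c.rank, c.score) for c in r2["candidates"]]


def test_low_complexity_detector():
    assert is_low_complexity("A" * 150)
    assert is_low_complexity("AT" * 75)
    rng = np.random.default_rng(91)
    assert not is_low_complexity(_random_seq(rng, 150))
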