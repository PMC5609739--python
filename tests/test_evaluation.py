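"""Clustering metrics: OS, FMeasure, Sn/PPV/Acc, MMR, filtering, histograms."""
import math
import random
from itertools import permutations

import pytest

from dapgminer import (
    ComplexSet,
    EvalConfig,
    PPINetwork,
    accuracy_stats,
    evaluate,
    filter_reference,
    fmeasure_stats,
    mmr,
    mmr_matching,
    overlap_histogram,
    overlap_score,
    perfect_match_count,
)

from conftest import random_complex_set


def cs(*sets):
    return ComplexSet([frozenset(s) for s in sets])


def brute_force_mmr(pred: ComplexSet, ref: ComplexSet, min_os: float) -> float:
    """Exhaustive search over all one-to-one assignments (small instances)."""
    weights = [
        [overlap_score(pc, rc) if overlap_score(pc, rc) >= min_os else 0.0 for pc in pred]
        for rc in ref
    ]
    n_ref, n_pred = len(ref), len(pred)
    best = 0.0
    if n_pred >= n_ref:
        for perm in permutations(range(n_pred), n_ref):
            best = max(best, sum(weights[i][perm[i]] for i in range(n_ref)))
    else:
        for perm in permutations(range(n_ref), n_pred):
            best = max(best, sum(weights[perm[j]][j] for j in range(n_pred)))
    return best / n_ref


class TestOverlapScore:
    def test_identity(self):
        assert overlap_score(frozenset("abc"), frozenset("abc")) == 1.0

    def test_disjoint(self):
        assert overlap_score(frozenset("ab"), frozenset("cd")) == 0.0

    def test_hand_value(self):
        assert overlap_score(frozenset("1234"), frozenset("345")) == pytest.approx(4 / 12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            overlap_score(frozenset(), frozenset("a"))


class TestFMeasure:
    def test_identical_sets(self):
        a = cs("abc", "def")
        p, r, f, tp, fp, fn = fmeasure_stats(a, a, 0.25)
        assert (p, r, f) == (1.0, 1.0, 1.0) and (tp, fp, fn) == (2, 0, 0)

    def test_half_precision(self):
        pred = cs("abc", "xyz")
        ref = cs("abc")
        p, r, f, tp, fp, fn = fmeasure_stats(pred, ref, 0.25)
        assert p == 0.5 and r == 1.0 and f == pytest.approx(2 / 3)
        assert (tp, fp, fn) == (1, 1, 0)

    def test_no_overlap(self):
        p, r, f, *_ = fmeasure_stats(cs("abc"), cs("xyz"), 0.25)
        assert (p, r, f) == (0.0, 0.0, 0.0)

    def test_threshold_boundary_is_inclusive(self):
        pred, ref = cs("1234"), cs("345")
        # OS = 1/3 exactly matches w = 1/3
        *_, tp, fp, fn = fmeasure_stats(pred, ref, 1 / 3)
        assert tp == 1 and fn == 0


class TestAccuracy:
    def test_hand_value(self):
        sn, ppv, acc = accuracy_stats(cs("ab"), cs("abc"))
        assert sn == pytest.approx(2 / 3)
        assert ppv == 1.0
        assert acc == pytest.approx(math.sqrt(2 / 3))

    def test_identical(self):
        a = cs("abc", "de")
        assert accuracy_stats(a, a) == pytest.approx((1.0, 1.0, 1.0))

    def test_disjoint_gives_zero(self):
        assert accuracy_stats(cs("xyz"), cs("abc"))[2] == 0.0

    def test_size_denominator_variant(self):
        pred, ref = cs("abcx"), cs("abc")
        _, ppv_overlap, _ = accuracy_stats(pred, ref, "overlap")
        _, ppv_size, _ = accuracy_stats(pred, ref, "size")
        assert ppv_overlap == 1.0
        assert ppv_size == pytest.approx(3 / 4)


class TestMMR:
    def test_single_pair(self):
        assert mmr(cs("abcd"), cs("abc")) == pytest.approx(0.75)

    def test_identical_sets(self):
        a = cs("abc", "def", "ghij")
        assert mmr(a, a) == 1.0

    def test_one_prediction_two_references(self):
        ref = cs("abc", "abd")
        pred = cs("abc")
        # one-to-one: only one reference can be matched; best single OS = 1
        assert mmr(pred, ref) == pytest.approx(0.5)

    def test_below_floor_edges_excluded(self):
        ref = cs("abcdefghij")
        pred = cs("axyz")  # OS = 1/40 < 0.2
        assert mmr(pred, ref, 0.2) == 0.0

    @pytest.mark.parametrize("seed", range(25))
    def test_equals_brute_force(self, seed):
        rng = random.Random(seed)
        ref = random_complex_set(rng, rng.randint(1, 6))
        pred = random_complex_set(rng, rng.randint(1, 6))
        assert mmr(pred, ref, 0.2) == pytest.approx(
            brute_force_mmr(pred, ref, 0.2), abs=1e-12
        )

    def test_monotone_in_min_os(self):
        rng = random.Random(99)
        ref = random_complex_set(rng, 5)
        pred = random_complex_set(rng, 5)
        values = [mmr(pred, ref, x) for x in (0.2, 0.4, 0.6, 0.8, 1.0)]
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_matching_is_one_to_one(self):
        rng = random.Random(7)
        ref = random_complex_set(rng, 6)
        pred = random_complex_set(rng, 4)
        pairs = mmr_matching(pred, ref)
        assert len({i for i, _, _ in pairs}) == len(pairs)
        assert len({j for _, j, _ in pairs}) == len(pairs)


class TestFilterReference:
    def net_with(self, names):
        net = PPINetwork()
        prev = None
        for n in names:
            net.add_protein(n)
        return net

    def test_mostly_missing_complex_removed(self):
        net = self.net_with(["a"])
        ref = cs("abcd")  # 1 of 4 present
        assert len(filter_reference(ref, net)) == 0

    def test_mostly_present_complex_truncated(self):
        net = self.net_with(["a", "b", "c"])
        ref = cs("abcd")  # 3 of 4 present
        out = filter_reference(ref, net)
        assert out.member_sets() == {frozenset("abc")}

    def test_fully_present_unchanged(self):
        net = self.net_with(["a", "b", "c"])
        assert filter_reference(cs("abc"), net).member_sets() == {frozenset("abc")}

    def test_never_grows(self):
        rng = random.Random(3)
        ref = random_complex_set(rng, 8)
        net = self.net_with([f"p{i}" for i in range(0, 20, 2)])
        out = filter_reference(ref, net)
        assert len(out) <= len(ref)
        out_sets = out.member_sets()
        for c in out_sets:
            assert any(c <= orig for orig in ref)

    def test_singletons_dropped(self):
        net = self.net_with(["a"])
        assert len(filter_reference(cs("ab"), net)) == 0


class TestPerfectMatches:
    def test_identity(self):
        a = cs("abc", "def")
        assert perfect_match_count(a, a) == 2

    def test_near_miss_is_not_perfect(self):
        assert perfect_match_count(cs("abcd"), cs("abc")) == 0

    def test_bounded_by_tp(self):
        rng = random.Random(5)
        ref = random_complex_set(rng, 6)
        pred = random_complex_set(rng, 6)
        *_, tp, _, _ = fmeasure_stats(pred, ref, 0.25)
        assert perfect_match_count(pred, ref) <= tp


class TestOverlapHistogram:
    def test_identity_mass_at_one(self):
        a = cs("abc", "def")
        rows = overlap_histogram(a, a)
        assert rows[-1]["threshold"] == pytest.approx(1.0)
        assert all(r["pairs_ge"] == 2 for r in rows)

    def test_single_pair_step(self):
        rows = overlap_histogram(cs("abcd"), cs("abc"), min_os=0.2, step=0.1)
        for r in rows:
            expected = 1 if r["threshold"] <= 0.75 else 0
            assert r["pairs_ge"] == expected

    def test_first_grid_point_matches_mmr(self):
        rng = random.Random(17)
        ref = random_complex_set(rng, 5)
        pred = random_complex_set(rng, 5)
        rows = overlap_histogram(pred, ref, min_os=0.2)
        assert rows[0]["mmr"] == pytest.approx(mmr(pred, ref, 0.2))

    def test_all_pairs_mode_counts_at_least_matched(self):
        rng = random.Random(23)
        ref = random_complex_set(rng, 5)
        pred = random_complex_set(rng, 5)
        matched = overlap_histogram(pred, ref, pairs="matched")
        allp = overlap_histogram(pred, ref, pairs="all")
        for m, a in zip(matched, allp):
            assert a["pairs_ge"] >= m["pairs_ge"]


def test_evaluate_bundles_consistent_report():
    rng = random.Random(41)
    ref = random_complex_set(rng, 6)
    pred = random_complex_set(rng, 6)
    rep = evaluate(pred, ref, EvalConfig())
    assert rep.tp + rep.fp == rep.n_predicted == len(pred)
    for v in (rep.precision, rep.recall, rep.fmeasure, rep.sn, rep.ppv, rep.acc, rep.mmr):
        assert 0.0 <= v <= 1.0


def test_evaluate_empty_prediction_is_all_zero():
    rep = evaluate(ComplexSet([]), cs("abc"))
    assert rep.fmeasure == rep.acc == rep.mmr == 0.0 and rep.fn == 1
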