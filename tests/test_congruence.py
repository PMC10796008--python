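from itertools import combinations
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from modelmatch.congruence import (
    QuadrantCounts,
    congruence_score,
    congruent_gene_lists,
    hypergeom_upper_tail,
    quadrant_counts,
    rank_models,
)
from modelmatch.signature import Signature, extract_signature

from conftest import make_detable


def enum_upper_tail(N, k1, k2, x):
    """Exact enumeration oracle: sum of hypergeometric point masses."""
    num = sum(comb(k2, i) * comb(N - k2, k1 - i) for i in range(x, min(k1, k2) + 1))
    return num / comb(N, k1)


class TestHypergeomUpperTail:
    def test_certain_event(self):
        assert hypergeom_upper_tail(10, 3, 4, 0) == 1.0

    @pytest.mark.parametrize(
        "N,k1,k2,x,expected",
        [
            (10, 3, 4, 2, enum_upper_tail(10, 3, 4, 2)),  # 1/3
            (4, 1, 1, 1, 0.25),  # 1 - C(3,1)/C(4,1)
        ],
    )
    def test_exact_small_cases(self, N, k1, k2, x, expected):
        assert hypergeom_upper_tail(N, k1, k2, x) == pytest.approx(expected, rel=1e-12)

    def test_parameter_ordering_violations(self):
        with pytest.raises(ValueError):
            hypergeom_upper_tail(10, 3, 4, 4)  # x > min(k1, k2)
        with pytest.raises(ValueError):
            hypergeom_upper_tail(3, 5, 2, 1)  # k1 > N

    def test_never_zero(self):
        assert hypergeom_upper_tail(20000, 1000, 1000, 1000) > 0

    @settings(max_examples=100, deadline=None)
    @given(st.data())
    def test_matches_enumeration(self, data):
        N = data.draw(st.integers(1, 30))
        k1 = data.draw(st.integers(0, N))
        k2 = data.draw(st.integers(0, N))
        x = data.draw(st.integers(0, min(k1, k2)))
        assert hypergeom_upper_tail(N, k1, k2, x) == pytest.approx(
            enum_upper_tail(N, k1, k2, x), rel=1e-12
        )

    @settings(max_examples=50, deadline=None)
    @given(st.data())
    def test_strictly_decreasing_in_overlap(self, data):
        N = data.draw(st.integers(2, 40))
        k1 = data.draw(st.integers(1, N))
        k2 = data.draw(st.integers(1, N))
        ps = [hypergeom_upper_tail(N, k1, k2, x) for x in range(min(k1, k2) + 1)]
        # overlaps x <= k1 + k2 - N are forced (p = 1); beyond that the
        # tail is strictly decreasing in x
        forced = max(0, k1 + k2 - N)
        assert all(p == 1.0 for p in ps[: forced + 1])
        assert all(a > b for a, b in zip(ps[forced:], ps[forced + 1 :]))


def sig(dataset_id, universe, up, down, K=None):
    return Signature(
        dataset_id=dataset_id,
        universe=frozenset(universe),
        up=list(up),
        down=list(down),
        K=K or max(len(up), len(down), 1),
    )


UNI = [f"g{i}" for i in range(8)]


class TestQuadrantCounts:
    def test_self_comparison(self):
        s = sig("s", UNI, ["g0", "g1"], ["g2", "g3"])
        c = quadrant_counts(s, s)
        assert (c.A, c.B, c.C, c.D) == (2, 0, 0, 2)

    def test_sign_flip_relabels_quadrants(self):
        m = sig("m", UNI, ["g0", "g1"], ["g2", "g3"])
        h = sig("h", UNI, ["g0", "g2"], ["g1", "g4"])
        c = quadrant_counts(m, h)
        f = quadrant_counts(m.flipped(), h)
        assert (f.A, f.B, f.C, f.D) == (c.C, c.D, c.A, c.B)

    def test_restriction_to_shared_universe(self):
        m = sig("m", ["a", "b", "c", "x"], ["a", "x"], ["b"])
        h = sig("h", ["a", "b", "c", "y"], ["a", "y"], ["b"])
        c = quadrant_counts(m, h)
        assert c.N == 3  # a, b, c
        assert (c.up_m, c.up_h) == (1, 1)  # x and y fall away
        assert (c.A, c.D) == (1, 1)

    def test_empty_shared_universe_raises(self):
        m = sig("m", ["a"], ["a"], [])
        h = sig("h", ["b"], ["b"], [])
        with pytest.raises(ValueError):
            quadrant_counts(m, h)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            QuadrantCounts(N=10, up_m=2, down_m=2, up_h=2, down_h=2, A=3, B=0, C=0, D=0)


class TestCongruenceScore:
    def test_singleton_self_comparison(self):
        # N=4, single up and down gene each side: pA = pD = 0.25
        s = sig("s", ["a", "b", "c", "d"], ["a"], ["b"])
        res = congruence_score(quadrant_counts(s, s))
        lA, lB, lC, lD = res.logs
        assert lA == pytest.approx(-np.log10(0.25), rel=1e-12)
        assert lB == 0 and lC == 0
        assert res.score == pytest.approx(2 * -np.log10(0.25), rel=1e-12)

    def test_flip_negates_score(self):
        s = sig("s", ["a", "b", "c", "d"], ["a"], ["b"])
        res = congruence_score(quadrant_counts(s.flipped(), s))
        assert res.score == pytest.approx(-2 * -np.log10(0.25), rel=1e-12)

    def test_disjoint_sets_score_zero(self):
        m = sig("m", UNI, ["g0"], ["g1"])
        h = sig("h", UNI, ["g2"], ["g3"])
        res = congruence_score(quadrant_counts(m, h))
        assert res.pA == res.pB == res.pC == res.pD == 1.0
        assert res.score == 0.0

    def test_antisymmetry_random_signatures(self):
        rng = np.random.default_rng(3)
        uni = [f"g{i}" for i in range(40)]
        for _ in range(10):
            pick = rng.permutation(uni)
            m = sig("m", uni, pick[:8], pick[8:16])  # equal-size sides
            pick2 = rng.permutation(uni)
            h = sig("h", uni, pick2[:7], pick2[7:12])
            a = congruence_score(quadrant_counts(m, h)).score
            b = congruence_score(quadrant_counts(m.flipped(), h)).score
            assert b == pytest.approx(-a, abs=1e-10)

    def test_self_maximality_enumerated(self):
        """score(t, t) >= score(t, u) over every signature u with the same
        universe and set sizes (exhaustive on 6 genes, 2 up / 2 down)."""
        uni = list("ABCDEF")
        t = sig("t", uni, ["A", "B"], ["C", "D"])
        self_score = congruence_score(quadrant_counts(t, t)).score
        for up in combinations(uni, 2):
            rest = [g for g in uni if g not in up]
            for down in combinations(rest, 2):
                u = sig("u", uni, up, down)
                assert congruence_score(quadrant_counts(t, u)).score <= self_score + 1e-12


class TestCongruentGeneLists:
    def test_self_comparison_no_opposite(self):
        s = sig("s", UNI, ["g0", "g1"], ["g2"])
        up_up, down_down, opposite = congruent_gene_lists(s, s)
        assert up_up == ["g0", "g1"] and down_down == ["g2"] and opposite == []

    def test_lengths_match_quadrants(self):
        rng = np.random.default_rng(5)
        uni = [f"g{i}" for i in range(30)]
        pick = rng.permutation(uni)
        m = sig("m", uni, pick[:6], pick[6:12])
        pick2 = rng.permutation(uni)
        h = sig("h", uni, pick2[:6], pick2[6:12])
        c = quadrant_counts(m, h)
        up_up, down_down, opposite = congruent_gene_lists(m, h)
        assert (len(up_up), len(down_down), len(opposite)) == (c.A, c.D, c.B + c.C)
        assert up_up == sorted(up_up)

    def test_lists_restricted_to_shared_universe(self):
        m = sig("m", ["a", "b", "x"], ["a", "x"], ["b"])
        h = sig("h", ["a", "b", "y"], ["a", "y"], ["b"])
        up_up, down_down, opposite = congruent_gene_lists(m, h)
        assert up_up == ["a"] and down_down == ["b"] and opposite == []


class TestRankModels:
    def _table(self, seed, n=300):
        rng = np.random.default_rng(seed)
        return make_detable({f"g{i:03d}": v for i, v in enumerate(rng.normal(size=n))}, f"t{seed}")

    def test_reference_flip_and_null_ordering(self):
        ref = self._table(0)
        flipped = make_detable(
            {g: -v for g, v in zip(ref.data["gene"], ref.data["signed_sig"])}, "flipped"
        )
        shuffled = self._table(99)
        ref2 = make_detable(dict(zip(ref.data["gene"], ref.data["signed_sig"])), "self")
        df = rank_models([ref2, flipped, shuffled], ref, K=50)
        by_id = df.set_index("dataset_id")
        assert by_id.loc["self", "rank"] == 1
        assert by_id.loc["flipped", "rank"] == 3
        assert by_id.loc["self", "score"] == pytest.approx(-by_id.loc["flipped", "score"])
        assert abs(by_id.loc["t99", "score"]) < by_id.loc["self", "score"] / 4

    def test_single_model_rank_one(self):
        ref = self._table(1)
        df = rank_models([self._table(2)], ref, K=50)
        assert df["rank"].tolist() == [1]

    def test_disjoint_model_reported_skipped(self):
        ref = self._table(1)
        alien = make_detable({"zz1": 1.0, "zz2": -1.0}, "alien")
        df = rank_models([self._table(2), alien], ref, K=50)
        assert df.attrs["skipped"] == ["alien"]
        assert "alien" not in set(df["dataset_id"])

    def test_scores_non_increasing_and_ranks_consecutive(self):
        ref = self._table(0)
        df = rank_models([self._table(s) for s in range(1, 6)], ref, K=50)
        assert (np.diff(df["score"]) <= 1e-12).all()
        assert df["rank"].tolist() == list(range(1, 6))
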