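"""Local shared-metabolite scores against independent oracles."""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from scipy.stats import spearmanr

import metcouple as mc
from metcouple.local import _poisson_llr

from conftest import toy_graph


def ctx(n, n_tot, n1, n2, n12, k1=None, k2=None):
    return mc.PairContext(n=n, n_tot=n_tot, n1=n1, n2=n2, n12=n12,
                          k_list1=np.asarray(k1 if k1 is not None else [], dtype=int),
                          k_list2=np.asarray(k2 if k2 is not None else [], dtype=int))


def hypergeom_tail_exact(n, n1, n2, n12) -> Fraction:
    """Exact upper-tail hypergeometric probability by enumeration."""
    total = Fraction(0)
    for k in range(n12, min(n1, n2) + 1):
        if n2 - k > n - n1:
            continue
        total += Fraction(math.comb(n1, k) * math.comb(n - n1, n2 - k),
                          math.comb(n, n2))
    return total


class TestHypergeometric:
    @pytest.mark.parametrize("n,n1,n2,n12,expected", [
        (4, 2, 2, 2, -math.log(1 / 6)),       # single-table tail
        (10, 5, 4, 4, -math.log(5 / 210)),    # direct tail enumeration
    ])
    def test_frozen_examples(self, n, n1, n2, n12, expected):
        assert mc.hypergeometric_score(ctx(n, 20, n1, n2, n12)) == pytest.approx(expected, rel=1e-12)

    def test_zero_overlap_gives_zero(self):
        assert mc.hypergeometric_score(ctx(12, 20, 4, 5, 0)) == pytest.approx(0.0, abs=1e-12)

    def test_matches_exact_enumeration(self):
        for n, n1, n2, n12 in [(8, 3, 5, 2), (15, 7, 6, 4), (30, 12, 9, 6),
                               (20, 10, 10, 10), (25, 5, 20, 3)]:
            want = -math.log(float(hypergeom_tail_exact(n, n1, n2, n12)))
            got = mc.hypergeometric_score(ctx(n, 50, n1, n2, n12))
            assert got == pytest.approx(want, rel=1e-9)

    def test_nondecreasing_in_overlap(self):
        scores = [mc.hypergeometric_score(ctx(20, 50, 8, 6, k)) for k in range(7)]
        assert all(b >= a - 1e-12 for a, b in zip(scores, scores[1:]))

    def test_impossible_overlap_rejected(self):
        with pytest.raises(ValueError):
            ctx(10, 20, 3, 3, 4)


class TestBayes:
    def test_frozen_example(self):
        # n=4, n1=2, n2=2, n12=2: log[(5*6)/(6*7*1)] - log C(2,0)
        got = mc.bayes_score(ctx(4, 20, 2, 2, 2))
        assert got == pytest.approx(math.log(30 / 42), rel=1e-12)

    def test_full_overlap_second_term_vanishes(self):
        # n12 = n2: -log C(n-n1, 0) = 0; compare to manual first term
        n, n1, n2 = 12, 6, 3
        want = (math.log((n + 1) * math.comb(n, n2))
                - math.log((n + 2) * (n + 3) * math.comb(n1, n2)))
        assert mc.bayes_score(ctx(n, 30, n1, n2, n2)) == pytest.approx(want, rel=1e-12)

    def test_enrichment_fold_below_null_mean(self):
        # null mean n1*n2/n = 2; at n12=0 the score reflects about score(2)
        from metcouple.local import _bayes_raw
        s0 = _bayes_raw(10, 5, 4, 0)
        s_null = _bayes_raw(10, 5, 4, 2.0)
        got = mc.bayes_score(ctx(10, 30, 5, 4, 0))
        assert got == pytest.approx(s0 - abs(s0 - s_null), rel=1e-12)

    def test_below_null_never_outranks_at_null(self):
        for n, n1, n2 in [(20, 8, 10), (15, 5, 6), (40, 20, 10)]:
            null = n1 * n2 / n
            at_null = mc.bayes_score(ctx(n, 50, n1, n2, int(round(null))))
            below = mc.bayes_score(ctx(n, 50, n1, n2, 0))
            assert below <= at_null + 1e-9

    def test_impossible_table_rejected(self):
        with pytest.raises(ValueError):
            mc.bayes_score(ctx(10, 20, 8, 5, 1))  # n2-n12=4 > n-n1=2


class TestPoisson:
    def test_zero_at_null_rate(self):
        # n1*n2/n_tot = 2 = n12
        assert mc.poisson_score(ctx(50, 12, 4, 6, 2)) == pytest.approx(0.0, abs=1e-12)

    def test_zero_overlap_is_minus_lambda(self):
        c = ctx(50, 24, 3, 4, 0)
        assert mc.poisson_score(c) == pytest.approx(-3 * 4 / 24, rel=1e-12)

    def test_frozen_example(self):
        got = mc.poisson_score(ctx(50, 24, 3, 4, 2))
        assert got == pytest.approx(2 * math.log(4) - 1.5, rel=1e-12)


class TestPoissonMetDegree:
    def test_single_metabolite_rate(self):
        lam = mc.degree_corrected_rate(np.array([13]), 5, 100)
        assert lam == pytest.approx(1 - math.exp(-0.65), rel=1e-12)

    def test_reduces_to_flat_null_for_unit_degrees_small_ratio(self):
        # all degrees 1 and n2/n_tot -> 0: lambda -> n1*n2/n_tot
        n1, n2, n_tot = 40, 3, 100_000
        lam = mc.degree_corrected_rate(np.ones(n1, dtype=int), n2, n_tot)
        assert lam == pytest.approx(n1 * n2 / n_tot, rel=1e-3)

    def test_directional_rates_averaged(self):
        c = ctx(100, 1000, 2, 2, 1, k1=[5, 5], k2=[7, 7])
        lam12 = mc.degree_corrected_rate(np.array([5, 5]), 2, 1000)
        lam21 = mc.degree_corrected_rate(np.array([7, 7]), 2, 1000)
        want = _poisson_llr(1, 0.5 * (lam12 + lam21))
        assert mc.poisson_score_metdeg(c) == pytest.approx(want, rel=1e-12)

    def test_zero_exactly_when_overlap_equals_rate(self):
        lam12 = mc.degree_corrected_rate(np.array([3, 3, 3]), 10, 30)
        # engineer n12 = lambda by symmetry: same k-lists both sides
        c = ctx(100, 30, 3, 3, 2, k1=[3, 3, 3], k2=[3, 3, 3])
        lam = mc.degree_corrected_rate(np.array([3, 3, 3]), 3, 30)
        assert mc.poisson_score_metdeg(c) == pytest.approx(_poisson_llr(2, lam))
        assert _poisson_llr(lam, lam) == 0.0


class TestPoissonMetAssoc:
    def test_base_cases(self):
        P = mc.metassoc_distribution(np.array([], dtype=int), 5, 100)
        assert P[0] == 1.0  # P(k=0 | no metabolites) = 1

    def test_one_metabolite_unrolled(self):
        k1, n_E, n_tot = 4, 6, 120
        P = mc.metassoc_distribution(np.array([k1]), n_E, n_tot)
        assert P[1] == pytest.approx(1 - math.exp(-k1 * n_E / n_tot), rel=1e-12)
        assert P[0] == pytest.approx(math.exp(-k1 * n_E / n_tot), rel=1e-12)

    def test_matches_subset_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            n1 = int(rng.integers(2, 7))
            k_list = np.sort(rng.integers(1, 9, size=n1))
            n_E, n_tot = int(rng.integers(2, 10)), 200
            got = mc.metassoc_distribution(k_list, n_E, n_tot)
            # brute force: walk every connect/miss pattern in the same order
            want = np.zeros(min(n1, n_E) + 1)
            for pattern in itertools.product([0, 1], repeat=n1):
                prob, k = 1.0, 0
                for ki, x in zip(k_list, pattern):
                    p_conn = 1 - math.exp(-ki * max(n_E - k, 0) / n_tot)
                    if x:
                        prob *= p_conn
                        k += 1
                    else:
                        prob *= 1 - p_conn
                if k < len(want):
                    want[k] += prob
            assert np.allclose(got, want, atol=1e-12)

    def test_distribution_sums_to_one(self):
        P = mc.metassoc_distribution(np.array([2, 3, 5, 13]), 8, 100)
        assert P.sum() == pytest.approx(1.0, rel=1e-12)

    def test_expected_value_approaches_degree_corrected_rate(self):
        # independent-metabolite, small-probability limit
        k_list = np.array([1, 2, 1, 3, 2])
        n_E, n_tot = 4, 50_000
        P = mc.metassoc_distribution(k_list, n_E, n_tot)
        ev = float(np.arange(len(P)) @ P)
        lam = mc.degree_corrected_rate(k_list, n_E, n_tot)
        assert ev == pytest.approx(lam, rel=1e-3)


class TestScoreAllPairs:
    METHODS = ["shared", "hypergeom", "bayes", "poisson", "poisson_metdeg",
               "poisson_metassoc"]

    @pytest.fixture()
    def toy(self):
        rng = np.random.default_rng(9)
        M = (rng.random((6, 12)) < 0.35).astype(int)
        M[0, :3] = 1  # ensure some structure
        M = M[:, M.sum(axis=0) > 0]
        return toy_graph(M)

    @pytest.mark.parametrize("method", METHODS)
    def test_matrix_matches_scalar_loop(self, toy, method):
        tab = mc.score_all_pairs(toy, method)
        scorer = {
            "shared": mc.shared_count, "hypergeom": mc.hypergeometric_score,
            "bayes": mc.bayes_score, "poisson": mc.poisson_score,
            "poisson_metdeg": mc.poisson_score_metdeg,
            "poisson_metassoc": mc.poisson_score_metassoc,
        }[method]
        for i, j in itertools.combinations(range(len(toy.enzymes)), 2):
            want = scorer(mc.pair_context(toy, i, j))
            assert tab.values[i, j] == pytest.approx(want, rel=1e-10), (i, j)

    @pytest.mark.parametrize("method", METHODS + ["shared_nohub"])
    def test_identical_neighbourhoods_rank_first(self, method):
        M = np.array([
            [1, 1, 1, 1, 0, 0],
            [1, 1, 1, 1, 0, 0],   # twin of enzyme 0
            [1, 0, 0, 0, 1, 0],
            [0, 0, 0, 1, 0, 1],
        ])
        tab = mc.score_all_pairs(toy_graph(M), method)
        iu = np.triu_indices(4, k=1)
        best = np.nanmax(tab.values[iu])
        assert tab.values[0, 1] == pytest.approx(best)

    def test_shared_nohub_equals_shared_on_filtered_graph(self, small_graph):
        sub, _ = mc.remove_hub_metabolites(small_graph, top_fraction=0.05)
        direct = mc.score_all_pairs(sub, "shared")
        via = mc.score_all_pairs(small_graph, "shared_nohub", hub_top_fraction=0.05)
        idx = {e: i for i, e in enumerate(via.enzymes)}
        for a, b in itertools.combinations(direct.enzymes, 2):
            assert via.values[idx[a], idx[b]] == direct.score(a, b)

    def test_unknown_method_lists_valid_names(self, toy):
        with pytest.raises(ValueError, match="poisson_metdeg"):
            mc.score_all_pairs(toy, "nope")

    def test_uncovered_pairs_carry_bottom_values(self, toy):
        tab = mc.score_all_pairs(toy, "hypergeom")
        shared = mc.score_all_pairs(toy, "shared")
        uncovered = ~tab.covered & ~np.eye(len(toy.enzymes), dtype=bool)
        if uncovered.any():
            assert np.all(tab.values[uncovered] == 0.0)
            assert np.all(shared.values[uncovered] == 0.0)


def test_hub_insertion_perturbs_metdeg_less_than_shared(small_graph):
    """Inserting near-universal hub metabolites should barely move the
    degree-corrected ranking but scrambles the raw shared-count ranking."""
    base_shared = mc.score_all_pairs(small_graph, "shared")
    base_metdeg = mc.score_all_pairs(small_graph, "poisson_metdeg")

    rng = np.random.default_rng(4)
    n_e, n_m = small_graph.M.shape
    n_hub = 3
    hub_cols = (rng.random((n_e, n_hub)) < 0.6).astype(int)
    M2 = np.hstack([small_graph.M, hub_cols])
    deg2 = np.append(small_graph.met_degree, hub_cols.sum(axis=0))
    contaminated = mc.BipartiteGraph(
        small_graph.metabolites + [f"hub_extra{i}" for i in range(n_hub)],
        list(small_graph.enzymes), M2, deg2)
    new_shared = mc.score_all_pairs(contaminated, "shared")
    new_metdeg = mc.score_all_pairs(contaminated, "poisson_metdeg")

    iu = np.triu_indices(n_e, k=1)
    rho_shared = spearmanr(base_shared.values[iu], new_shared.values[iu]).statistic
    rho_metdeg = spearmanr(base_metdeg.values[iu], new_metdeg.values[iu]).statistic
    assert rho_metdeg > rho_shared


def test_pair_table_tsv_round_trip(tmp_path, small_graph):
    tab = mc.score_all_pairs(small_graph, "poisson")
    path = tmp_path / "scores.tsv"
    tab.to_tsv(str(path), sidecar=str(tmp_path / "scores.json"))
    back = mc.PairScoreTable.from_tsv(str(path))
    assert back.method == "poisson"
    assert back.enzymes == sorted(small_graph.enzymes)
    for a, b in [("g0000", "g0001"), ("g0002", "g0010")]:
        assert back.score(a, b) == pytest.approx(tab.score(a, b), rel=1e-6)
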