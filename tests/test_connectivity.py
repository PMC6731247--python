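"""Connectivity scoring against exact enumeration and regression oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from sigreverse import (
    CategoricalSignature,
    DrugProfile,
    SignatureProfile,
    binomial_enrichment,
    concordance_score,
    ks_enrichment,
    rank_query,
    regression_z,
    regulation_frequencies,
    reverse_profile,
)


def categorical(senses: dict) -> CategoricalSignature:
    data = pd.DataFrame(
        {
            "sense": list(senses.values()),
            "fraction": [float(s) for s in senses.values()],
            "support": 1,
        },
        index=list(senses),
    )
    return CategoricalSignature(data=data, n_profiles=1)


def drug_profile(values: dict, drug="d") -> DrugProfile:
    data = pd.DataFrame(
        {"value": [float(v) for v in values.values()], "stat": 4.0},
        index=list(values),
    )
    return DrugProfile(data=data, drug=drug)


class TestConcordance:
    def test_identical_senses_score_one(self):
        q = categorical({"a": 1, "b": -1, "c": 1})
        t = drug_profile({"a": 2.0, "b": -3.0, "c": 0.5})
        res = concordance_score(q, t)
        assert res.score == 1.0
        assert res.direction == "concordant"

    def test_flipped_senses_score_minus_one(self):
        q = categorical({"a": 1, "b": -1, "c": 1})
        t = drug_profile({"a": -2.0, "b": 3.0, "c": -0.5})
        res = concordance_score(q, t)
        assert res.score == -1.0
        assert res.direction == "discordant"

    def test_worked_counts_score_and_exact_binomial_tail(self):
        """6 up-up, 2 down-down, 1 up-down, 1 down-up: score 0.6 and the
        uniform-background tail P[Bin(10, 1/2) >= 8] = 56/1024."""
        q, t = {}, {}
        genes = [f"g{i}" for i in range(10)]
        for g in genes[:6]:
            q[g], t[g] = 1, 1.0
        for g in genes[6:8]:
            q[g], t[g] = -1, -1.0
        q[genes[8]], t[genes[8]] = 1, -1.0
        q[genes[9]], t[genes[9]] = -1, 1.0
        res = concordance_score(categorical(q), drug_profile(t))
        assert (res.n_uu, res.n_dd, res.n_ud, res.n_du) == (6, 2, 1, 1)
        assert res.score == pytest.approx(0.6)
        assert res.enrichment_p == pytest.approx(56 / 1024, abs=1e-12)

    def test_zero_overlap_flagged_not_raised(self):
        res = concordance_score(
            categorical({"a": 1}), drug_profile({"b": 1.0})
        )
        assert not res.defined
        assert res.overlap == 0

    def test_negating_target_negates_score(self):
        rng = np.random.default_rng(8)
        genes = [f"g{i}" for i in range(30)]
        q = categorical({g: int(s) for g, s in zip(genes, rng.choice([-1, 1], 30))})
        t = drug_profile({g: v for g, v in zip(genes[10:], rng.normal(0, 1, 20))})
        fwd = concordance_score(q, t)
        rev = concordance_score(q, reverse_profile(t))
        assert rev.score == pytest.approx(-fwd.score)
        assert rev.overlap == fwd.overlap

    def test_symmetric_under_query_target_swap(self):
        q1 = categorical({"a": 1, "b": -1, "c": 1, "d": -1})
        q2 = categorical({"a": 1, "b": 1, "c": -1, "e": 1})
        r12 = concordance_score(q1, q2)
        r21 = concordance_score(q2, q1)
        assert r12.score == r21.score
        assert r12.overlap == r21.overlap
        assert (r12.n_uu, r12.n_dd) == (r21.n_uu, r21.n_dd)
        assert (r12.n_ud, r12.n_du) == (r21.n_du, r21.n_ud)


def poisson_binomial_brute_force(matches: int, probs) -> float:
    """Exhaustive 2^n enumeration of the non-identical Bernoulli tail."""
    n = len(probs)
    total = 0.0
    for outcome in itertools.product([0, 1], repeat=n):
        if sum(outcome) >= matches:
            p = 1.0
            for o, q in zip(outcome, probs):
                p *= q if o else (1 - q)
            total += p
    return total


class TestBinomialEnrichment:
    def test_zero_matches_gives_one(self):
        assert binomial_enrichment(0, 7, 0.3) == 1.0

    def test_all_matches_equal_probs_closed_form(self):
        for n in (3, 8, 12):
            assert binomial_enrichment(n, n, 0.5) == pytest.approx(
                0.5**n, abs=1e-15
            )

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(12)
        probs = rng.uniform(0.05, 0.95, size=12)
        for matches in (0, 3, 6, 9, 12):
            exact = poisson_binomial_brute_force(matches, probs)
            assert binomial_enrichment(matches, 12, probs) == pytest.approx(
                exact, abs=1e-12
            )

    def test_equal_probs_match_binomial_tail(self):
        for matches in (2, 5, 9):
            assert binomial_enrichment(matches, 10, 0.4) == pytest.approx(
                float(stats.binom.sf(matches - 1, 10, 0.4)), abs=1e-12
            )

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0.05, 0.95), min_size=1, max_size=8),
        st.integers(0, 8),
    )
    def test_enumeration_property(self, probs, matches):
        matches = min(matches, len(probs))
        exact = poisson_binomial_brute_force(matches, probs)
        assert binomial_enrichment(matches, len(probs), probs) == pytest.approx(
            exact, abs=1e-10
        )

    def test_bad_probabilities_rejected(self):
        with pytest.raises(ValueError, match="strictly inside"):
            binomial_enrichment(1, 2, [0.5, 1.0])
        with pytest.raises(ValueError, match="exceed"):
            binomial_enrichment(3, 2, 0.5)


def signature(values: dict, kind="zscore") -> SignatureProfile:
    data = pd.DataFrame(
        {"value": [float(v) for v in values.values()], "p_value": 0.01},
        index=list(values),
    )
    return SignatureProfile(data=data, kind=kind)


class TestRegressionZ:
    def test_perfect_fit_hits_positive_cap(self):
        a = signature({f"g{i}": v for i, v in enumerate([1.0, 2.0, 3.0, 4.0, 5.0])})
        b = signature({f"g{i}": 2.0 * v for i, v in enumerate([1.0, 2.0, 3.0, 4.0, 5.0])})
        assert regression_z(a, b) == pytest.approx(8.2)

    def test_orthogonal_vectors_give_zero(self):
        a = signature({"g0": 1.0, "g1": -1.0, "g2": 1.0, "g3": -1.0})
        b = signature({"g0": 1.0, "g1": 1.0, "g2": -1.0, "g3": -1.0})
        assert regression_z(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        """20-gene fixed vectors: slope t, p and Z from explicit X'X algebra."""
        rng = np.random.default_rng(77)
        x = rng.normal(0, 1, 20)
        y = 0.6 * x + rng.normal(0, 0.8, 20)
        a = signature({f"g{i}": v for i, v in enumerate(x)})
        b = signature({f"g{i}": v for i, v in enumerate(y)})
        # oracle: normal equations for [intercept, slope]
        X = np.column_stack([np.ones(20), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        sigma2 = resid @ resid / (20 - 2)
        se = math.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
        t = beta[1] / se
        p = 2 * stats.t.sf(abs(t), 18)
        z_oracle = np.sign(beta[1]) * min(stats.norm.isf(p / 2), 8.2)
        assert regression_z(a, b) == pytest.approx(z_oracle, abs=1e-9)

    def test_zero_variance_undefined(self):
        a = signature({f"g{i}": 1.0 for i in range(5)})
        b = signature({f"g{i}": float(i) for i in range(5)})
        with pytest.warns(UserWarning, match="zero-variance"):
            assert math.isnan(regression_z(a, b))

    def test_small_overlap_undefined(self):
        a = signature({"g0": 1.0, "g1": 2.0, "g2": 3.0})
        b = signature({"g0": 1.0, "g1": 2.0, "g2": 3.0})
        with pytest.warns(UserWarning, match="overlap"):
            assert math.isnan(regression_z(a, b))


class TestRankQuery:
    @pytest.fixture()
    def query(self):
        rng = np.random.default_rng(5)
        return categorical(
            {f"g{i}": int(s) for i, s in enumerate(rng.choice([-1, 1], 20))}
        )

    def test_exact_negation_ranks_first_under_anticorrelate(self, query):
        neg = drug_profile(
            {g: -float(s) for g, s in query.senses.items()}, drug="nemesis"
        )
        rng = np.random.default_rng(6)
        decoys = [
            drug_profile(
                {f"g{i}": v for i, v in enumerate(rng.normal(0, 1, 20))},
                drug=f"decoy{j}",
            )
            for j in range(5)
        ]
        ranked = rank_query(query, decoys + [neg], direction="anticorrelate")
        assert ranked[0][0] == "nemesis"
        assert ranked[0][2] == 1

    def test_query_itself_first_under_correlate_last_under_anti(self, query):
        me = drug_profile({g: float(s) for g, s in query.senses.items()}, drug="self")
        rng = np.random.default_rng(7)
        decoys = [
            drug_profile(
                {f"g{i}": v for i, v in enumerate(rng.normal(0, 1, 20))},
                drug=f"decoy{j}",
            )
            for j in range(4)
        ]
        corr = rank_query(query, decoys + [me], direction="correlate")
        anti = rank_query(query, decoys + [me], direction="anticorrelate")
        assert corr[0][0] == "self"
        defined = [d for d, r, _ in anti if r.defined]
        assert defined[-1] == "self"

    def test_ties_broken_lexicographically(self, query):
        t1 = drug_profile({g: float(s) for g, s in query.senses.items()}, drug="zeta")
        t2 = drug_profile({g: float(s) for g, s in query.senses.items()}, drug="alpha")
        ranked = rank_query(query, [t1, t2], direction="correlate")
        assert [d for d, _, _ in ranked] == ["alpha", "zeta"]

    def test_undefined_overlap_placed_last(self, query):
        stranger = drug_profile({"x1": 1.0, "x2": -1.0}, drug="stranger")
        match = drug_profile({g: float(s) for g, s in query.senses.items()}, drug="m")
        ranked = rank_query(query, [stranger, match], direction="correlate")
        assert ranked[-1][0] == "stranger"
        assert not ranked[-1][1].defined

    def test_empty_db_rejected(self, query):
        with pytest.raises(ValueError, match="empty"):
            rank_query(query, [])


class TestRegulationFrequencies:
    def test_frequencies_reflect_call_balance(self):
        profs = [
            drug_profile({"a": 1.0, "b": -1.0}),
            drug_profile({"a": 1.0, "b": 1.0}),
            drug_profile({"a": -1.0, "c": -1.0}),
        ]
        freqs = regulation_frequencies(profs)
        assert freqs["a"] == pytest.approx(2 / 3)
        assert freqs["b"] == pytest.approx(1 / 2)
        assert freqs["c"] == 0.0


def exact_ks_null_fraction(observed_D, universe, n_hits):
    """Exhaustive D distribution over all hit placements."""
    count = total = 0
    for combo in itertools.combinations(range(1, universe + 1), n_hits):
        ranks = np.asarray(combo)
        dev = np.arange(1, n_hits + 1) / n_hits - ranks / universe
        d = max(dev.max(), 0.0)
        total += 1
        if d >= observed_D:
            count += 1
    return count / total


class TestKsEnrichment:
    def test_front_loaded_hits(self):
        res = ks_enrichment(range(1, 6), universe_size=100, n_permutations=100, seed=0)
        assert res.D == pytest.approx(0.95)

    def test_evenly_spaced_hits_hug_diagonal(self):
        res = ks_enrichment(
            [20, 40, 60, 80, 100], universe_size=100, n_permutations=100, seed=0
        )
        assert res.D == 0.0

    def test_all_items_hits_degenerate(self):
        with pytest.warns(UserWarning, match="every item"):
            res = ks_enrichment([1, 2, 3], universe_size=3, n_permutations=100, seed=0)
        assert res.D == 0.0

    def test_p_respects_add_one_floor(self):
        res = ks_enrichment(range(1, 6), universe_size=100, n_permutations=100, seed=1)
        assert res.p_mc >= 1 / 101

    def test_mc_converges_to_exhaustive_placement_oracle(self):
        """Universe 6, 2 hits: MC p matches the exact fraction over C(6,2)=15."""
        hits = [1, 3]
        res = ks_enrichment(hits, universe_size=6, n_permutations=10_000, seed=3)
        exact = exact_ks_null_fraction(res.D, 6, 2)
        assert res.p_mc == pytest.approx(exact, abs=0.02)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            ks_enrichment([1, 1, 2], 10, 100, 0)
        with pytest.raises(ValueError, match=r"\[1, 10\]"):
            ks_enrichment([0, 5], 10, 100, 0)
        with pytest.raises(ValueError, match="permutations"):
            ks_enrichment([1], 10, 10, 0)

    def test_null_p_values_uniform(self):
        """Over 200 null hit sets the MC p-value is uniform (KS GoF at 1%)."""
        rng = np.random.default_rng(9)
        pvals = []
        for i in range(200):
            hits = rng.choice(1000, size=25, replace=False) + 1
            res = ks_enrichment(hits, 1000, n_permutations=200, seed=int(rng.integers(2**31)))
            pvals.append(res.p_mc)
        gof = stats.kstest(pvals, "uniform")
        assert gof.pvalue > 0.01
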