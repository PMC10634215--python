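"""Cox engine, Kaplan-Meier/log-rank, maxstat, clustering, signatures."""

import math

import numpy as np
import pandas as pd
import pytest

from cfrna import ValidationError
from cfrna.survival import (
    cluster_genes,
    cox_fit,
    kaplan_meier,
    km_logrank,
    maxstat_cutpoint,
    multivariable_fit,
    screen_genes,
    signature_scores,
)


def partial_loglik_oracle(beta, x, time, event):
    """Hand-written Breslow partial log-likelihood for a 1-covariate model."""
    ll = 0.0
    for i in range(len(time)):
        if event[i]:
            risk = [j for j in range(len(time)) if time[j] >= time[i]]
            ll += beta * x[i] - math.log(sum(math.exp(beta * x[j]) for j in risk))
    return ll


SIX = dict(
    time=np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0]),
    event=np.array([0, 0, 1, 1, 1, 0]),
    x=np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0]),
)


class TestCoxFit:
    def test_matches_grid_oracle_on_six_subjects(self):
        """Newton-Raphson estimate equals brute-force maximization of the
        hand-written partial likelihood to 1e-4."""
        fit = cox_fit(SIX["x"][:, None], SIX["time"], SIX["event"])
        grid = np.arange(-6.0, 6.0, 1e-4)
        lls = [partial_loglik_oracle(b, SIX["x"], SIX["time"], SIX["event"]) for b in grid]
        best = grid[int(np.argmax(lls))]
        assert fit.beta[0] == pytest.approx(best, abs=1e-4)
        assert fit.loglik == pytest.approx(
            partial_loglik_oracle(fit.beta[0], SIX["x"], SIX["time"], SIX["event"]),
            abs=1e-8,
        )

    def test_matches_lifelines(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(4)
        n = 120
        X = rng.normal(size=(n, 2))
        t_ev = rng.exponential(np.exp(-(0.8 * X[:, 0] - 0.5 * X[:, 1])))
        c = rng.uniform(0, 2.5, n)
        time, event = np.minimum(t_ev, c), (t_ev <= c).astype(int)
        ours = cox_fit(X, time, event)
        df = pd.DataFrame({"T": time, "E": event, "a": X[:, 0], "b": X[:, 1]})
        ref = CoxPHFitter().fit(df, "T", "E")
        np.testing.assert_allclose(ours.beta, ref.params_[["a", "b"]], atol=1e-4)
        np.testing.assert_allclose(
            ours.se, ref.standard_errors_[["a", "b"]], atol=1e-4
        )

    def test_score_test_equals_logrank_for_binary_covariate(self):
        rng = np.random.default_rng(6)
        n = 80
        x = (rng.random(n) < 0.5).astype(float)
        time = rng.exponential(1.0, n) + rng.random(n) * 1e-9  # tie-free
        event = (rng.random(n) < 0.7).astype(int)
        event[:2] = 1
        fit = cox_fit(x[:, None], time, event)
        km = km_logrank(time, event, np.where(x > 0, "hi", "lo"))
        assert abs(fit.score_test_p - km["logrank_p"]) < 1e-10

    def test_constant_covariate_degenerate(self):
        fit = cox_fit(np.ones((6, 1)), SIX["time"], SIX["event"])
        assert fit.degenerate
        assert fit.beta[0] == 0.0
        assert fit.wald_p[0] == 1.0

    def test_perfect_separation_flagged(self):
        # events only in the high-covariate half, observed strictly earlier
        time = np.r_[np.arange(1, 7), np.arange(10, 16)].astype(float)
        event = np.r_[np.ones(6), np.zeros(6)].astype(int)
        x = np.r_[np.ones(6), np.zeros(6)]
        fit = cox_fit(x[:, None], time, event)
        assert not fit.converged

    def test_recovers_true_beta(self):
        """Mean estimate over replicates within 0.1 of the generating
        log-hazard ratio (z-scored covariate, ~70% events)."""
        rng = np.random.default_rng(11)
        betas = []
        for _ in range(60):
            n = 300
            x = rng.normal(size=n)
            t_ev = rng.exponential(np.exp(-1.0 * x))
            c = rng.uniform(0, 6.0, n)
            time, event = np.minimum(t_ev, c), (t_ev <= c).astype(int)
            betas.append(cox_fit(x[:, None], time, event).beta[0])
        assert np.mean(betas) == pytest.approx(1.0, abs=0.1)

    def test_too_few_events_rejected(self):
        with pytest.raises(ValidationError):
            cox_fit(np.arange(4.0)[:, None], np.arange(1.0, 5.0), np.array([1, 0, 0, 0]))


class TestKaplanMeier:
    def test_product_limit_hand_fixture(self):
        km = kaplan_meier([1.0, 2.0, 3.0], [1, 1, 1])
        np.testing.assert_allclose(km["survival"], [2 / 3, 1 / 3, 0.0])
        np.testing.assert_array_equal(km["n_at_risk"], [3, 2, 1])

    def test_no_events_flat_curve_and_zero_statistic(self):
        time = np.arange(1.0, 9.0)
        event = np.zeros(8, dtype=int)
        km = kaplan_meier(time, event)
        assert km.empty  # no event times -> survival stays at 1
        rep = km_logrank(time, event, np.repeat(["a", "b"], 4))
        assert rep["logrank_statistic"] == 0.0

    def test_identical_groups_zero_statistic(self):
        time = np.r_[1.0, 2, 3, 4, 1, 2, 3, 4]
        event = np.r_[1, 1, 0, 1, 1, 1, 0, 1]
        rep = km_logrank(time, event, np.repeat(["a", "b"], 4))
        assert rep["logrank_statistic"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_lifelines_logrank(self):
        from lifelines.statistics import logrank_test

        rng = np.random.default_rng(8)
        n = 60
        g = rng.random(n) < 0.5
        time = rng.exponential(np.where(g, 0.5, 1.0))
        event = (rng.random(n) < 0.8).astype(int)
        rep = km_logrank(time, event, np.where(g, "a", "b"))
        ref = logrank_test(time[g], time[~g], event[g], event[~g])
        assert rep["logrank_p"] == pytest.approx(ref.p_value, abs=1e-9)


class TestMaxstat:
    def _bimodal(self, rng, n=40):
        scores = np.r_[rng.normal(0, 0.3, n // 2), rng.normal(5, 0.3, n // 2)]
        event = np.r_[np.zeros(n // 2), np.ones(n // 2)].astype(int)
        time = np.r_[rng.uniform(5, 10, n // 2), rng.uniform(0.1, 2, n // 2)]
        return scores, time, event

    def test_cutpoint_falls_in_gap_between_modes(self):
        scores, time, event = self._bimodal(np.random.default_rng(0))
        out = maxstat_cutpoint(scores, time, event)
        assert 1.5 < out["cutpoint"] < 3.5

    def test_sign_reversal_symmetry(self):
        scores, time, event = self._bimodal(np.random.default_rng(1))
        a = maxstat_cutpoint(scores, time, event)
        b = maxstat_cutpoint(-scores, time, event)
        assert a["max_statistic"] == pytest.approx(b["max_statistic"], abs=1e-9)
        assert b["cutpoint"] == pytest.approx(-a["cutpoint"], abs=1e-9)

    def test_all_tied_scores_rejected(self):
        with pytest.raises(ValidationError):
            maxstat_cutpoint(np.ones(10), np.arange(1.0, 11), np.ones(10, dtype=int))

    def test_null_statistic_matches_permutation_null(self):
        """With scores independent of survival, the observed max statistic is
        not extreme under the permutation null."""
        rng = np.random.default_rng(2)
        n = 40
        scores = rng.normal(size=n)
        time = rng.exponential(1.0, n)
        event = (rng.random(n) < 0.7).astype(int)
        out = maxstat_cutpoint(scores, time, event, rng=rng, n_permutations=100)
        assert out["permutation_p"] > 0.01


class TestClusterGenes:
    def _blocks(self, rng, n_per=8, n_samples=40, rho=0.9):
        rows = []
        for _ in range(2):
            latent = rng.normal(size=n_samples)
            for _ in range(n_per):
                noise = rng.normal(size=n_samples) * math.sqrt(1 - rho)
                rows.append(latent * math.sqrt(rho) + noise)
        return pd.DataFrame(rows, index=[f"g{i}" for i in range(2 * n_per)])

    def test_two_blocks_recovered(self):
        expr = self._blocks(np.random.default_rng(0))
        clusters = cluster_genes(expr)
        assert len(clusters) == 2
        assert sorted(map(len, clusters)) == [8, 8]
        assert {frozenset(c) for c in clusters} == {
            frozenset(f"g{i}" for i in range(8)),
            frozenset(f"g{i}" for i in range(8, 16)),
        }

    def test_identical_profiles_single_cluster(self):
        expr = pd.DataFrame(
            np.tile(np.arange(10.0), (5, 1)), index=[f"g{i}" for i in range(5)]
        )
        assert len(cluster_genes(expr)) == 1

    def test_gene_order_invariance(self):
        expr = self._blocks(np.random.default_rng(3))
        perm = expr.sample(frac=1.0, random_state=1)
        c1 = {frozenset(c) for c in cluster_genes(expr)}
        c2 = {frozenset(c) for c in cluster_genes(perm)}
        assert c1 == c2

    def test_single_gene_singleton(self):
        expr = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g0"])
        assert cluster_genes(expr) == [["g0"]]


class TestSignatureScores:
    def test_mean_arithmetic_and_linearity(self):
        expr = pd.DataFrame(
            [[2.0, 1.0], [4.0, 5.0]], index=["g1", "g2"], columns=["s1", "s2"]
        )
        scores = signature_scores(expr, ["g1", "g2"])
        assert scores["s1"] == pytest.approx(3.0)
        single = signature_scores(expr, ["g1"])
        assert single["s1"] == pytest.approx(2.0)
        shifted = signature_scores(expr + 5.0, ["g1", "g2"])
        np.testing.assert_allclose(shifted, scores + 5.0)

    def test_all_missing_rejected(self):
        expr = pd.DataFrame([[1.0]], index=["g1"], columns=["s1"])
        with pytest.raises(ValidationError):
            signature_scores(expr, ["nope"])


class TestScreen:
    def test_beta_threshold_rule(self):
        """A gene passing the p rule but failing |beta| >= 2 is excluded."""
        rng = np.random.default_rng(5)
        n = 400
        x = rng.normal(size=n)
        t_ev = rng.exponential(np.exp(-1.0 * x))  # true beta 1, highly significant
        time = np.minimum(t_ev, 3.0)
        event = (t_ev <= 3.0).astype(int)
        expr = pd.DataFrame([x], index=["gene_mid_effect"])
        fav, unfav, table = screen_genes(
            expr, time, event, p_threshold=0.01, beta_threshold=2.0
        )
        assert table.loc["gene_mid_effect", "score_test_p"] < 0.001
        assert not table.loc["gene_mid_effect", "retained"]
        # same gene passes once the threshold matches its effect scale
        fav2, unfav2, _ = screen_genes(
            expr, time, event, p_threshold=0.01, beta_threshold=0.5
        )
        # exponential scale exp(-x): high expression shortens survival
        assert fav2 == []
        assert unfav2 == ["gene_mid_effect"]

    def test_null_genes_rarely_retained(self):
        rng = np.random.default_rng(6)
        n = 100
        expr = pd.DataFrame(
            rng.normal(size=(80, n)), index=[f"g{i}" for i in range(80)]
        )
        time = rng.exponential(1.0, n)
        event = (rng.random(n) < 0.6).astype(int)
        fav, unfav, table = screen_genes(
            expr, time, event, p_threshold=0.01, beta_threshold=1.0
        )
        assert len(fav) + len(unfav) <= 2


class TestMultivariable:
    def test_signature_and_ipi_jointly_recovered(self):
        rng = np.random.default_rng(7)
        n = 200
        sig = rng.normal(size=n)
        ipi = rng.integers(0, 4, n).astype(float)
        t_ev = rng.exponential(np.exp(-(0.8 * sig + 0.5 * ipi)))
        c = rng.uniform(0, 1.0, n)
        time, event = np.minimum(t_ev, c), (t_ev <= c).astype(int)
        sigs = pd.DataFrame({"sig": sig}, index=[f"s{i}" for i in range(n)])
        levels = np.array(["low", "low_int", "high_int", "high"])
        ipi_cat = pd.Series(levels[ipi.astype(int)], index=sigs.index)
        fit = multivariable_fit(sigs, ipi_cat, time, event)
        assert fit.covariates == ["sig", "nccn_ipi"]
        assert fit.wald_p[0] < 0.001 and fit.wald_p[1] < 0.001
        assert fit.beta[0] == pytest.approx(0.8, abs=0.25)

    def test_shuffled_ipi_is_null(self):
        rng = np.random.default_rng(8)
        n = 200
        sig = rng.normal(size=n)
        t_ev = rng.exponential(np.exp(-0.8 * sig))
        c = rng.uniform(0, 1.5, n)
        time, event = np.minimum(t_ev, c), (t_ev <= c).astype(int)
        ps = []
        levels = np.array(["low", "low_int", "high_int", "high"])
        for _ in range(20):
            ipi_cat = pd.Series(
                levels[rng.integers(0, 4, n)], index=[f"s{i}" for i in range(n)]
            )
            sigs = pd.DataFrame({"sig": sig}, index=ipi_cat.index)
            fit = multivariable_fit(sigs, ipi_cat, time, event)
            ps.append(fit.wald_p[1])
        assert np.mean(np.asarray(ps) < 0.05) <= 0.2
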