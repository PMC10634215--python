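"""Properties of the synthetic cohort generator."""

import numpy as np
import pandas as pd
import pytest

import cfrna
from cfrna import (
    CircDesign,
    PrognosticCluster,
    SimulationDesign,
    ValidationError,
    default_design,
    generate_circ,
    generate_counts,
    generate_survival,
)
from cfrna.survival import _logrank_U_V, cox_fit
from scipy import stats as sps


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        d1 = default_design(seed=77, n_genes=120)
        d2 = default_design(seed=77, n_genes=120)
        cm1, st1, _ = generate_counts(d1)
        cm2, st2, _ = generate_counts(d2)
        pd.testing.assert_frame_equal(cm1.counts, cm2.counts)
        pd.testing.assert_frame_equal(st1.table, st2.table)

    def test_different_seed_differs(self):
        cm1, _, _ = generate_counts(default_design(seed=1, n_genes=50))
        cm2, _, _ = generate_counts(default_design(seed=2, n_genes=50))
        assert not cm1.counts.equals(cm2.counts)


class TestCountModel:
    def test_group_means_match_design(self):
        """Per-gene sample means track the designed NB means (no effects,
        no depth variation, n = 50)."""
        d = SimulationDesign(
            seed=3, n_genes=200, n_control=50, n_dlbcl_gcb=0,
            n_dlbcl_nongcb=0, n_pmbcl=0, depth_cv=0.0,
            baseline_log2_loc=5.0, baseline_log2_scale=0.5,
        )
        cm, _, _ = generate_counts(d)
        rng = np.random.default_rng(cfrna.simulate._subseed(3, 0))
        baseline = rng.normal(5.0, 0.5, 200)
        expected = np.exp2(baseline)
        observed = cm.counts.mean(axis=1).to_numpy()
        big = expected >= 10
        rel = observed[big] / expected[big] - 1.0
        assert abs(rel.mean()) < 0.02
        assert np.median(np.abs(rel)) < 0.05

    def test_effect_gene_must_exist(self):
        d = SimulationDesign(seed=0, n_genes=10)
        d.dlbcl_effects = {"NOPE": 2.0}
        with pytest.raises(ValidationError, match="NOPE"):
            generate_counts(d)

    def test_null_design_gives_uniform_da_p(self):
        """With all effects zero the NB Wald p-values are uniform (KS)."""
        d = SimulationDesign(
            seed=5, n_genes=1500, n_control=20, n_dlbcl_gcb=20,
            n_dlbcl_nongcb=0, n_pmbcl=0,
        )
        cm, st, _ = generate_counts(d)
        res = cfrna.run_contrast(cm, st, st.table["group"], group_a="DLBCL")
        p = res["wald_p"].dropna()
        assert len(p) > 500
        assert sps.kstest(p, "uniform").pvalue > 0.01


class TestSurvivalGeneration:
    def test_zero_censoring_window_all_events(self):
        d = default_design(seed=8, n_genes=60)
        d.censoring_window_days = 0
        cm, st, _ = generate_counts(d)
        st = generate_survival(d, st, cm)
        dl = st.table[st.table["group"] == "DLBCL"]
        assert (dl["pfs_event"] == 1).all()
        assert (dl["os_event"] == 1).all()

    def test_null_hazard_logrank_type_i_error(self):
        """beta_sim = 0, gamma = 0: a median split on the planted-cluster
        score keeps the log-rank test at its nominal level."""
        hits = 0
        n_rep = 200
        for seed in range(n_rep):
            d = SimulationDesign(
                seed=seed, n_genes=12, n_control=0, n_dlbcl_gcb=30,
                n_dlbcl_nongcb=30, n_pmbcl=0, ipi_gamma=0.0,
                prognostic_clusters=[
                    PrognosticCluster(
                        [f"G{i:05d}" for i in range(6)], beta_sim=0.0,
                        endpoint="PFS", latent_loading=1.0,
                    )
                ],
            )
            cm, st, _ = generate_counts(d)
            st = generate_survival(d, st, cm)
            dl = st.table[st.table["group"] == "DLBCL"]
            ids = list(dl.index)
            score = np.log2(cm.counts[ids].iloc[:6] + 1).mean(axis=0)
            split = score > score.median()
            t = dl["pfs_time"].to_numpy(float)
            e = dl["pfs_event"].to_numpy(int)
            if e.sum() < 2:
                continue
            U, V = _logrank_U_V(t, e, split.to_numpy())
            p = sps.chi2.sf(U**2 / V, 1) if V > 0 else 1.0
            hits += p < 0.05
        assert hits / n_rep <= 0.08

    def test_cluster_score_beta_recovery(self):
        """Univariate Cox on the averaged planted-cluster score recovers the
        coefficient implied by the generating model (oracle at large n)."""

        def score_beta(seed, n_per_arm):
            d = SimulationDesign(
                seed=seed, n_genes=30, n_control=0, n_dlbcl_gcb=n_per_arm,
                n_dlbcl_nongcb=n_per_arm, n_pmbcl=0, ipi_gamma=0.0,
                censoring_window_days=2500,
                prognostic_clusters=[
                    PrognosticCluster(
                        [f"G{i:05d}" for i in range(9)], beta_sim=0.25,
                        endpoint="PFS", latent_loading=1.0,
                    )
                ],
            )
            cm, st, _ = generate_counts(d)
            st = generate_survival(d, st, cm)
            dl = st.table[st.table["group"] == "DLBCL"]
            ids = list(dl.index)
            score = np.log2(cm.counts[ids].iloc[:9] + 1).mean(axis=0).to_numpy()
            z = (score - score.mean()) / score.std()
            return cox_fit(
                z[:, None], dl["pfs_time"].to_numpy(float),
                dl["pfs_event"].to_numpy(int),
            ).beta[0]

        oracle = np.mean([score_beta(1000 + r, 400) for r in range(3)])
        small = np.mean([score_beta(2000 + r, 60) for r in range(25)])
        assert small == pytest.approx(oracle, abs=0.25)


class TestCirc:
    def test_zero_circ_is_empty_append(self, small_cohort):
        design, counts, samples, _ = small_cohort
        cm, ann, truth = generate_circ(design, counts, samples)
        assert cm.shape == counts.shape
        assert truth["circ_hosts"] == {}

    def test_copy_proportion_one_gives_full_concordance(self):
        d = default_design(seed=5, n_genes=800)
        d.circ = CircDesign(n_circ=50, copy_proportion=1.0)
        cm, st, ann, spikes, truth = cfrna.generate_cohort(d)
        meta = st.table
        groups = meta.loc[
            meta["group"].isin(["control", "DLBCL"])
            & (meta["timepoint"] == "diagnosis"),
            "group",
        ]
        res = cfrna.run_contrast(cm, st, groups, group_a="DLBCL")
        rep = cfrna.circ_linear_concordance(res, ann)
        assert rep["n_both_significant"] >= 20
        assert rep["host_also_significant_fraction"] >= 0.9
        assert rep["direction_match_fraction"] >= 0.99

    def test_hosts_are_linear_genes(self):
        d = default_design(seed=6, n_genes=300)
        d.circ = CircDesign(n_circ=20, copy_proportion=0.5)
        cm, st, ann, _, truth = cfrna.generate_cohort(d)
        host_of = ann.host_of()
        assert len(host_of) == 20
        for circ, host in host_of.items():
            assert cm.biotype[circ] == "circRNA"
            assert cm.biotype[host] != "circRNA"


class TestDirectionConcordance:
    def _da(self, genes, lfcs, sig):
        return pd.DataFrame(
            {"log2_fold_change": lfcs, "significant": sig}, index=genes
        )

    def test_self_concordance_is_one(self):
        genes = [f"g{i}" for i in range(10)]
        da = self._da(genes, np.linspace(-2, 2, 10), [True] * 10)
        rep = cfrna.direction_concordance(da, da)
        assert rep["same_direction_fraction"] == 1.0
        assert rep["fraction_of_b_in_a"] == 1.0

    def test_negated_concordance_is_zero(self):
        genes = [f"g{i}" for i in range(10)]
        lfc = np.r_[np.linspace(-2, -0.5, 5), np.linspace(0.5, 2, 5)]
        da = self._da(genes, lfc, [True] * 10)
        db = self._da(genes, -lfc, [True] * 10)
        assert cfrna.direction_concordance(da, db)["same_direction_fraction"] == 0.0

    def test_half_agreement_within_binomial_ci(self):
        rng = np.random.default_rng(0)
        n = 400
        genes = [f"g{i}" for i in range(n)]
        a = rng.choice([-1.0, 1.0], n)
        b = np.where(rng.random(n) < 0.5, a, -a)  # 50% planted agreement
        rep = cfrna.direction_concordance(
            self._da(genes, a, [True] * n), self._da(genes, b, [True] * n)
        )
        ci = 3 * 0.5 / np.sqrt(n)
        assert abs(rep["same_direction_fraction"] - 0.5) < ci

    def test_no_shared_genes_is_nan(self):
        da = self._da(["a"], [1.0], [True])
        db = self._da(["a"], [1.0], [False])
        assert np.isnan(cfrna.direction_concordance(da, db)["same_direction_fraction"])
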