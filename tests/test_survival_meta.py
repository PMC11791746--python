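"""Cox fitting, horizon restriction, heterogeneity-gated pooling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from statsmodels.stats.meta_analysis import combine_effects

from prolifmeta.survival_meta import (
    ConvergenceError,
    EffectEstimate,
    SurvivalError,
    cochran_q,
    cox_fit,
    forest_table,
    meta_effect,
    per_dataset_gene_hr,
    restrict_followup,
)
from prolifmeta.syndata import SimulationConfig, simulate_cohort_collection


def efron_loglik(beta: float, times, events, x) -> float:
    """Independent scalar Efron partial log-likelihood (loop-based oracle)."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    x = np.asarray(x, float)
    eta = beta * x
    w = np.exp(eta)
    ll = 0.0
    for t in np.unique(times[events == 1]):
        risk = times >= t
        dead = (times == t) & (events == 1)
        d = dead.sum()
        ll += eta[dead].sum()
        for ell in range(d):
            ll -= np.log(w[risk].sum() - (ell / d) * w[dead].sum())
    return ll


class TestRestrictFollowup:
    def test_late_event_administratively_censored(self):
        t, e = restrict_followup([80.0], [1], 60.0)
        assert t[0] == 60.0 and e[0] == 0

    def test_early_event_unchanged(self):
        t, e = restrict_followup([40.0], [1], 60.0)
        assert t[0] == 40.0 and e[0] == 1

    def test_no_op_when_all_within_horizon(self):
        times = [10.0, 59.9, 60.0]
        events = [1, 0, 1]
        t, e = restrict_followup(times, events, 60.0)
        np.testing.assert_array_equal(t, times)
        np.testing.assert_array_equal(e, events)

    def test_negative_time_rejected(self):
        with pytest.raises(SurvivalError, match="negative"):
            restrict_followup([-1.0], [1])

    @given(st.lists(st.tuples(st.floats(0, 200), st.integers(0, 1)),
                    min_size=1, max_size=30),
           st.floats(1, 150))
    def test_never_increases_time_or_creates_events(self, obs, horizon):
        times = [t for t, _ in obs]
        events = [e for _, e in obs]
        t, e = restrict_followup(times, events, horizon)
        assert (t <= np.asarray(times)).all()
        assert (e <= np.asarray(events)).all()


class TestCoxFit:
    def test_four_subject_grid_oracle(self):
        times = [1.0, 2.0, 3.0, 4.0]
        events = [1, 1, 1, 1]
        x = [1.0, 0.0, 1.0, 0.0]
        fit = cox_fit(times, events, x)
        grid = np.arange(-5, 5, 1e-4)
        lls = np.array([efron_loglik(b, times, events, x) for b in grid])
        assert fit.loc["x0", "coef"] == pytest.approx(grid[lls.argmax()], abs=1e-4)

    def test_scaling_covariate_rescales_coefficient(self, rng):
        n = 80
        x = rng.normal(size=n)
        t = rng.exponential(scale=1 / np.exp(0.5 * x))
        e = np.ones(n, int)
        f1 = cox_fit(t, e, x)
        f2 = cox_fit(t, e, 10.0 * x)
        assert f2.iloc[0]["coef"] == pytest.approx(f1.iloc[0]["coef"] / 10.0,
                                                   rel=1e-6)
        assert f2.iloc[0]["z"] == pytest.approx(f1.iloc[0]["z"], rel=1e-6)

    def test_matches_lifelines_with_ties(self, rng):
        lifelines = pytest.importorskip("lifelines")
        n = 120
        x = rng.normal(size=n)
        x2 = rng.normal(size=n)
        t = np.ceil(5 * rng.exponential(scale=1 / np.exp(0.4 * x)))  # many ties
        e = (rng.random(n) < 0.7).astype(int)
        df = pd.DataFrame({"t": t, "e": e, "x": x, "x2": x2})
        ref = lifelines.CoxPHFitter().fit(df, "t", "e")
        fit = cox_fit(t, e, df[["x", "x2"]])
        np.testing.assert_allclose(fit["coef"], ref.params_.to_numpy(), atol=1e-5)
        np.testing.assert_allclose(fit["se"], ref.standard_errors_.to_numpy(),
                                   atol=1e-5)

    def test_null_covariate_rarely_significant(self, rng):
        extreme = 0
        reps = 200
        for _ in range(reps):
            n = 300
            x = rng.normal(size=n)
            t = rng.exponential(scale=1.0, size=n)
            e = (rng.random(n) < 0.6).astype(int)
            z = cox_fit(t, e, x).iloc[0]["z"]
            extreme += abs(z) >= 3
        assert extreme / reps <= 0.01

    def test_zero_events_rejected(self):
        with pytest.raises(SurvivalError, match="event"):
            cox_fit([1.0, 2.0], [0, 0], [0.0, 1.0])

    def test_constant_covariate_rejected(self):
        with pytest.raises(SurvivalError, match="constant"):
            cox_fit([1.0, 2.0, 3.0], [1, 1, 0], [2.0, 2.0, 2.0])

    def test_perfect_separation_diagnosed(self):
        times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        events = [1, 1, 1, 1, 1, 1]
        x = [5.0, 4.0, 3.0, 2.0, 1.0, 0.0]  # risk perfectly ordered
        with pytest.raises(ConvergenceError, match="separation"):
            cox_fit(times, events, x)

    def test_breslow_option_runs_and_differs_with_ties(self):
        t = [1.0, 1.0, 2.0, 2.0, 3.0]
        e = [1, 1, 1, 1, 0]
        x = [0.2, 1.0, -0.5, 0.7, 0.0]
        efron = cox_fit(t, e, x)
        breslow = cox_fit(t, e, x, ties="breslow")
        assert efron.iloc[0]["coef"] != pytest.approx(breslow.iloc[0]["coef"])


class TestCochranQ:
    def est(self, effect, se=1.0, cid="C"):
        return EffectEstimate(cohort_id=cid, effect=effect, se=se, n=100,
                              effect_type="log_hr")

    def test_identical_effects_give_zero_q(self):
        ests = [self.est(0.3, cid=f"C{i}") for i in range(4)]
        Q, df, p = cochran_q(ests)
        assert Q == pytest.approx(0.0, abs=1e-12)
        assert df == 3 and p == pytest.approx(1.0)

    def test_hand_computed_q(self):
        Q, df, p = cochran_q([self.est(0.0, cid="A"), self.est(2.0, cid="B")])
        assert Q == pytest.approx(2.0)
        assert df == 1
        assert p == pytest.approx(0.15729920705028105, rel=1e-6)

    def test_requires_two_estimates(self):
        with pytest.raises(SurvivalError, match="2"):
            cochran_q([self.est(0.5)])


class TestMetaEffect:
    def est(self, effect, se=1.0, cid="C"):
        return EffectEstimate(cohort_id=cid, effect=effect, se=se, n=100,
                              effect_type="log_hr")

    def test_three_identical_unit_variance_effects(self):
        meta = meta_effect([self.est(1.0, cid=f"C{i}") for i in range(3)])
        assert meta.pooled_effect == pytest.approx(1.0)
        assert meta.se == pytest.approx(1 / np.sqrt(3))
        assert meta.Q == pytest.approx(0.0, abs=1e-12)
        assert meta.model == "fixed" and meta.tau2 == 0.0

    def test_moderate_heterogeneity_keeps_fixed_model(self):
        meta = meta_effect([self.est(0.0, cid="A"), self.est(2.0, cid="B")])
        assert meta.model == "fixed"
        assert meta.pooled_effect == pytest.approx(1.0)
        assert meta.se == pytest.approx(1 / np.sqrt(2))

    def test_single_estimate_reduction(self):
        meta = meta_effect([self.est(0.7, se=0.2)])
        assert meta.pooled_effect == pytest.approx(0.7)
        assert meta.se == pytest.approx(0.2)
        assert meta.Q == 0.0 and meta.df == 0 and meta.model == "fixed"

    def test_forced_random_equals_fixed_when_tau2_zero(self):
        ests = [self.est(0.5, cid=f"C{i}") for i in range(3)]
        fixed = meta_effect(ests, model="fixed")
        random = meta_effect(ests, model="random")
        assert random.tau2 == 0.0
        assert random.pooled_effect == pytest.approx(fixed.pooled_effect)
        assert random.se == pytest.approx(fixed.se)

    def test_strong_heterogeneity_switches_to_random(self):
        ests = [self.est(0.0, se=0.1, cid="A"), self.est(2.0, se=0.1, cid="B"),
                self.est(-1.0, se=0.1, cid="C")]
        meta = meta_effect(ests)
        assert meta.p_Q < 0.05
        assert meta.model == "random"
        assert meta.tau2 > 0

    def test_matches_statsmodels_combine_effects(self, rng):
        effects = rng.normal(0.3, 0.4, size=8)
        ses = rng.uniform(0.1, 0.5, size=8)
        ests = [self.est(float(e), se=float(s), cid=f"C{i}")
                for i, (e, s) in enumerate(zip(effects, ses))]
        ref = combine_effects(effects, ses**2, method_re="dl")
        fixed = meta_effect(ests, model="fixed")
        random = meta_effect(ests, model="random")
        frame = ref.summary_frame()
        assert fixed.pooled_effect == pytest.approx(
            frame.loc["fixed effect", "eff"], rel=1e-10)
        assert random.pooled_effect == pytest.approx(
            frame.loc["random effect", "eff"], rel=1e-10)
        assert random.tau2 == pytest.approx(ref.tau2, rel=1e-10)

    def test_empty_list_rejected(self):
        with pytest.raises(SurvivalError, match="at least one"):
            meta_effect([])

    def test_forest_table_has_cohort_rows_and_pooled_footer(self):
        ests = [self.est(0.2, se=0.3, cid="A"), self.est(0.4, se=0.3, cid="B")]
        meta = meta_effect(ests)
        table = forest_table(ests, meta)
        assert len(table) == 3
        assert table.iloc[-1]["cohort_id"].startswith("POOLED")
        assert table.iloc[0]["hr"] == pytest.approx(np.exp(0.2))


class TestPerDatasetGeneHR:
    def test_global_null_ci_covers_one(self):
        cfg = SimulationConfig(n_cohorts=6, samples_per_cohort=150, n_genes=12,
                               n_proliferation_genes=1, log_hazard_per_sd=0.0,
                               marker_loadings={"MARKER": 1.0}, seed=4)
        col = simulate_cohort_collection(cfg)
        meta = meta_effect(per_dataset_gene_hr(col, "MARKER"))
        hr, lo, hi = meta.as_hazard_ratio()
        assert lo <= 1.0 <= hi

    def test_direct_effect_survives_adjustment(self):
        cfg = SimulationConfig(n_cohorts=6, samples_per_cohort=200, n_genes=12,
                               n_proliferation_genes=1, log_hazard_per_sd=0.0,
                               marker_loadings={"MARKER": 1.0},
                               direct_marker="MARKER",
                               direct_marker_log_hazard=0.5, seed=8)
        col = simulate_cohort_collection(cfg)
        scores = {c.cohort_id: c.truth.latent for c in col}
        adj = meta_effect(per_dataset_gene_hr(col, "MARKER", adjust_scores=scores))
        _, lo, _ = adj.as_hazard_ratio()
        assert lo > 1.0  # adjustment does not null a direct hazard effect

    def test_absent_gene_everywhere_is_an_error(self, small_collection):
        with pytest.raises(SurvivalError, match="absent"):
            per_dataset_gene_hr(small_collection, "NO_SUCH_GENE")
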