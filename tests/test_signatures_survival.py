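import numpy as np
import pandas as pd
import pytest

from drivergene import (
    ExpressionMatrix,
    GeneSetCollection,
    gsva_score,
    km_estimate,
    logrank_test,
    maxstat_cutoff,
    survival_by_feature,
)
from drivergene.synthdata import simulate_survival


def _expr(values: np.ndarray, genes=None, samples=None) -> ExpressionMatrix:
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    df = pd.DataFrame(values, index=genes, columns=samples)
    return ExpressionMatrix(df - df.min().min() + 1.0, layer="normalized")


class TestGsvaScore:
    def test_top_ranked_set_scores_positive(self, rng):
        # in sample s0 the set genes sit at their across-sample maximum while
        # every other gene sits at its minimum, so the set occupies the top
        # of s0's ECDF ranking and the walk must peak positive there
        vals = rng.normal(size=(20, 5))
        vals[:4, 0] = vals[:4].max(axis=1) + 1.0
        vals[4:, 0] = vals[4:].min(axis=1) - 1.0
        m = _expr(vals)
        sets = GeneSetCollection.from_dict({"TOP": [f"G{i}" for i in range(4)]})
        scores = gsva_score(m, sets)
        assert scores.loc["TOP", "s0"] > 0

    def test_antisymmetric_under_rank_reversal(self, rng):
        for _ in range(5):
            vals = rng.normal(size=(10, 4))
            sets = GeneSetCollection.from_dict({"S": ["G0", "G1", "G2"]})
            s1 = gsva_score(_expr(vals), sets)
            s2 = gsva_score(_expr(-vals), sets)
            np.testing.assert_allclose(s1.to_numpy(), -s2.to_numpy(), atol=1e-12)

    def test_duplicated_sample_columns_score_identically(self, rng):
        vals = rng.normal(size=(12, 3))
        dup = np.concatenate([vals, vals[:, :1]], axis=1)
        m = _expr(dup)
        sets = GeneSetCollection.from_dict({"S": ["G0", "G3", "G5"]})
        scores = gsva_score(m, sets)
        assert scores.iloc[0, 0] == pytest.approx(scores.iloc[0, 3])

    def test_preconditions(self, rng):
        vals = rng.normal(size=(5, 2))
        sets = GeneSetCollection.from_dict({"S": ["G0", "G1"]})
        with pytest.raises(ValueError, match="3 samples"):
            gsva_score(_expr(vals), sets)
        all_cover = GeneSetCollection.from_dict({"S": [f"G{i}" for i in range(5)]})
        with pytest.raises(ValueError, match="every gene"):
            gsva_score(_expr(rng.normal(size=(5, 4))), all_cover)

    def test_single_gene_sets_skipped(self, rng):
        m = _expr(rng.normal(size=(6, 4)))
        sets = GeneSetCollection.from_dict({"LONE": ["G0"], "PAIR": ["G1", "G2"]})
        with pytest.warns(UserWarning, match="skipped"):
            scores = gsva_score(m, sets)
        assert list(scores.index) == ["PAIR"]


class TestKaplanMeier:
    def test_product_limit_by_hand(self):
        fit = km_estimate([1, 2, 3], [1, 0, 1])
        assert fit.survival_at(1) == pytest.approx(2 / 3)
        assert fit.survival_at(3) == pytest.approx(0.0)

    def test_all_censored_flat_at_one(self):
        fit = km_estimate([5, 8, 11], [0, 0, 0])
        assert fit.survival_at(11) == 1.0

    def test_no_censoring_equals_empirical_survival(self, rng):
        times = rng.exponential(10, size=40)
        fit = km_estimate(times, np.ones(40, dtype=int))
        for t in [1.0, 5.0, 15.0]:
            assert fit.survival_at(t) == pytest.approx((times > t).mean())

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])


class TestLogrank:
    def test_identical_groups_null(self):
        t, e = [1, 2, 3, 4], [1, 1, 0, 1]
        chi2, p = logrank_test((t, e), (t, e))
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_separated_groups_positive_statistic(self):
        chi2, p = logrank_test(([1, 2], [1, 1]), ([10, 20], [1, 1]))
        assert chi2 > 0
        assert p < 1

    def test_hand_tabulated_small_instance(self):
        # A events at 1 and 4, B events at 2 and 3, no censoring.
        # Risk-set tabulation gives O-E = -1/3 and Var = 13/18,
        # hence chi2 = (1/9)/(13/18) = 2/13.
        chi2, _ = logrank_test(([1, 4], [1, 1]), ([2, 3], [1, 1]))
        assert chi2 == pytest.approx(2 / 13, rel=1e-6)

    def test_symmetric_in_group_order(self, rng):
        ta, tb = rng.exponential(5, 20), rng.exponential(8, 25)
        ea, eb = rng.integers(0, 2, 20), rng.integers(0, 2, 25)
        if ea.sum() + eb.sum() == 0:
            ea[0] = 1
        c1, p1 = logrank_test((ta, ea), (tb, eb))
        c2, p2 = logrank_test((tb, eb), (ta, ea))
        assert c1 == pytest.approx(c2)
        assert p1 == pytest.approx(p2)

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError, match="events"):
            logrank_test(([1, 2], [0, 0]), ([3, 4], [0, 0]))


class TestMaxstat:
    def test_degenerate_values_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            maxstat_cutoff(np.ones(20), np.arange(1, 21), np.ones(20, dtype=int))

    def test_cutoff_inside_candidate_range(self, rng):
        vals = rng.normal(size=60)
        t, e, _ = simulate_survival(vals, hazard_ratio=2.0, censor_rate=0.2, seed=3)
        cp = maxstat_cutoff(vals, t, e)
        frac_below = (vals <= cp.cutoff).mean()
        assert 0.1 <= frac_below <= 0.9
        assert cp.statistic >= 0
        assert 0 <= cp.p <= 1

    def test_recovers_planted_threshold(self):
        rng = np.random.default_rng(41)
        vals = rng.normal(size=200)
        t, e, truth = simulate_survival(vals, cutoff_quantile=0.6, hazard_ratio=3.0, censor_rate=0.2, seed=42)
        cp = maxstat_cutoff(vals, t, e)
        err_pct = abs((vals <= cp.cutoff).mean() - 0.6) * 100
        assert err_pct <= 10


class TestSurvivalByFeature:
    def _cohort(self, seed, n=120, hr=1.0):
        rng = np.random.default_rng(seed)
        ids = [f"s{i}" for i in range(n)]
        vals = pd.Series(rng.normal(size=n), index=ids)
        t, e, _ = simulate_survival(
            vals.to_numpy() if hr != 1.0 else np.zeros(n),
            hazard_ratio=hr, censor_rate=0.2, seed=seed + 1,
        )
        clin = pd.DataFrame({"os_time": t, "os_event": e}, index=ids)
        return vals, clin

    def test_deterministic_re_run(self):
        vals, clin = self._cohort(5)
        a = survival_by_feature(vals, clin, feature_name="f")
        b = survival_by_feature(vals, clin, feature_name="f")
        assert a.cutpoint.cutoff == b.cutpoint.cutoff
        assert a.p == b.p
        assert a.logrank_chi2 == pytest.approx(b.logrank_chi2)

    def test_driver_feature_flagged_degenerate(self):
        vals, clin = self._cohort(6)
        rep = survival_by_feature(vals, clin, driver_values=vals, feature_name="DRIVER", is_driver=True)
        assert rep.driver_comparison_p is None
        assert "degenerate" in rep.driver_comparison_flag

    def test_too_few_joinable_samples_rejected(self):
        vals, clin = self._cohort(7)
        with pytest.raises(ValueError, match="joinable"):
            survival_by_feature(vals.iloc[:5], clin, feature_name="f")

    def test_reported_p_is_selection_corrected(self):
        vals, clin = self._cohort(8)
        rep = survival_by_feature(vals, clin, feature_name="f")
        assert rep.p == rep.cutpoint.p
        assert 0 <= rep.p <= 1
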