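import numpy as np
import pandas as pd
import pytest
from scipy import stats

from braintrends.normalization import AnchoredVolumes, anchor_by_group, anchor_normalize
from braintrends.regions import RegionWeights
from braintrends.trends import (
    TrendError,
    classify_effect,
    fit_aggregate_trend,
    fit_region_trends,
    summarize_directions,
)


def _anchored_from_matrix(V, ages, group="g"):
    vp = pd.DataFrame(V, columns=[f"r{i}" for i in range(V.shape[1])])
    fits = pd.DataFrame({"region": vp.columns})
    return AnchoredVolumes(group=group, a0=float(np.min(ages)),
                          ages=pd.Series(ages), vpp=vp, fits=fits)


class TestFitRegionTrends:
    def test_perfect_line_beta_and_unit_beta_s(self):
        ages = np.linspace(46, 83, 30)
        V = (100.0 - 0.5 * (ages - 46.0))[:, None]
        tr = fit_region_trends(_anchored_from_matrix(V, ages))
        assert tr.loc[0, "beta"] == pytest.approx(-0.5, abs=1e-12)
        assert tr.loc[0, "beta_s"] == pytest.approx(-1.0, abs=1e-12)
        assert tr.loc[0, "significant"]

    def test_beta_s_equals_pearson_correlation(self):
        rng = np.random.default_rng(3)
        ages = rng.uniform(46, 83, 200)
        V = rng.normal(100, 5, size=(200, 6)) - 0.3 * (ages - 46)[:, None]
        tr = fit_region_trends(_anchored_from_matrix(V, ages))
        for j in range(6):
            r = stats.pearsonr(ages, V[:, j]).statistic
            assert tr.loc[j, "beta_s"] == pytest.approx(r, abs=1e-10)

    def test_permuted_response_is_null(self):
        """Permuting ages against the response kills the trend: empirical
        p-values are uniform, so about 5% fall below 0.05."""
        rng = np.random.default_rng(12)
        n, n_regions = 120, 400
        ages = rng.uniform(46, 83, n)
        V = rng.normal(100, 5, size=(n, n_regions))  # no age signal at all
        tr = fit_region_trends(_anchored_from_matrix(V, ages))
        frac = (tr["p"] < 0.05).mean()
        assert 0.02 < frac < 0.08
        # the Bonferroni flag fires exactly when p < 0.05/148
        pd.testing.assert_series_equal(
            tr["significant"], tr["p"] < 0.05 / 148, check_names=False
        )

    def test_parameter_recovery_within_ci(self, small_cohort, registry):
        anchored = anchor_by_group(small_cohort, registry)[("reference", "F")]
        tr = fit_region_trends(anchored).set_index("region")
        # reference females decline at -0.15 %/yr in every region
        covered = (
            (tr["beta"] - 1.96 * tr["beta_se"] <= -0.15)
            & (-0.15 <= tr["beta"] + 1.96 * tr["beta_se"])
        )
        assert covered.mean() > 0.90

    def test_zero_variance_region_flagged(self):
        ages = np.linspace(46, 83, 10)
        V = np.column_stack([np.full(10, 100.0), 100 - 0.2 * (ages - 46)])
        tr = fit_region_trends(_anchored_from_matrix(V, ages))
        assert tr.loc[0, "degenerate"]
        assert np.isnan(tr.loc[0, "beta_s"])
        assert tr.loc[0, "effect_class"] == "undefined"
        assert not tr.loc[1, "degenerate"]


class TestClassifyEffect:
    @pytest.mark.parametrize(
        "beta_s, expected",
        [
            (0.0, "negligible"),
            (0.099, "negligible"),
            (0.10, "small"),  # boundaries closed on the left
            (-0.29, "small"),
            (0.30, "medium"),
            (-0.430, "medium"),
            (-0.34, "medium"),
            (0.499, "medium"),
            (0.50, "large"),
            (-0.516, "large"),
        ],
    )
    def test_cutpoints(self, beta_s, expected):
        assert classify_effect(beta_s) == expected

    def test_nonfinite_rejected(self):
        with pytest.raises(TrendError):
            classify_effect(float("nan"))


class TestSummarizeDirections:
    def _trends(self, registry, betas):
        return pd.DataFrame({"region": registry.names, "group": "g", "beta": betas})

    def test_all_negative_saturates(self, registry):
        w = RegionWeights(pd.Series(np.full(148, 1 / 148), index=registry.names))
        s = summarize_directions(self._trends(registry, np.full(148, -0.5)), w, registry)
        assert s.n_negative == 148 and s.n_positive == 0
        assert s.frac_cortex_negative == pytest.approx(1.0)

    def test_weighted_fraction_matches_construction(self, registry):
        """111 negative structures carrying 80% of cortical weight report a
        cortex fraction of 0.80."""
        betas = np.where(np.arange(148) < 111, -0.3, 0.2)
        weights = np.where(np.arange(148) < 111, 0.80 / 111, 0.20 / 37)
        w = RegionWeights(pd.Series(weights, index=registry.names))
        s = summarize_directions(self._trends(registry, betas), w, registry)
        assert s.n_negative == 111
        assert s.frac_cortex_negative == pytest.approx(0.80, abs=1e-12)
        assert s.frac_cortex_positive == pytest.approx(0.20, abs=1e-12)

    def test_equal_weights_half_negative(self, registry):
        betas = np.where(np.arange(148) < 74, -1.0, 1.0)
        w = RegionWeights(pd.Series(np.full(148, 1 / 148), index=registry.names))
        s = summarize_directions(self._trends(registry, betas), w, registry)
        assert s.frac_cortex_negative == pytest.approx(0.5)
        assert s.n_negative + s.n_positive + s.n_zero == 148

    def test_missing_region_listed(self, registry):
        t = self._trends(registry, np.full(148, -1.0)).iloc[:-1]
        w = RegionWeights(pd.Series(np.full(148, 1 / 148), index=registry.names))
        with pytest.raises(TrendError, match=registry.names[-1]):
            summarize_directions(t, w, registry)


class TestAggregateTrend:
    def test_total_cortical_trend_between_extremes(self, small_cohort, registry):
        sub = small_cohort[
            (small_cohort["population"] == "reference") & (small_cohort["sex"] == "M")
        ]
        row = fit_aggregate_trend(sub, registry.names, label="cortical_gm")
        # all reference-male regions decline at -0.35 %/yr, so the total does too
        assert row["beta"] == pytest.approx(-0.35, abs=0.05)
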