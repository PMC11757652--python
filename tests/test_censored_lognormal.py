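"""Censored-lognormal estimation: ranking, q-q fit, imputation, summaries.

Frozen expected values for the packaged late-time-point dataset were
computed with an independent least-squares regression (numpy.linalg.lstsq
on hand-assembled quantiles) over the recombined final results.
"""

import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import optimize, stats

from actinon import censored_lognormal as cln
from actinon.physics import CensoredValue, CensorStatus
from actinon.sessions import filter_campaign, finalize
from actinon.synthetic_data import CampaignSpec, simulate_campaign

P, GT, LT = CensorStatus.POINT, CensorStatus.GREATER_THAN, CensorStatus.LESS_THAN


def cv(value, status=P):
    return CensoredValue(value, status)


def make_points(values):
    return [cv(v) for v in values]


class TestRankDataset:
    def test_three_points_hazen_positions(self):
        ranked = cln.rank_dataset(make_points([3.0, 1.0, 2.0]))
        assert [e.value for e in ranked.entries] == [1.0, 2.0, 3.0]
        assert [e.plotting_position for e in ranked.entries] == pytest.approx(
            [1 / 6, 3 / 6, 5 / 6]
        )

    def test_median_rank_has_zero_quantile(self):
        ranked = cln.rank_dataset(make_points(range(1, 18)))
        mid = ranked.entries[8]  # rank 9 of 17
        assert mid.plotting_position == pytest.approx(0.5)
        assert mid.normal_quantile == pytest.approx(0.0)

    def test_greater_than_occupy_top_ranks(self):
        results = [cv(5.0, GT), cv(1.0), cv(2.0, LT), cv(3.0), cv(4.5, GT)]
        ranked = cln.rank_dataset(results)
        statuses = [e.status for e in ranked.entries]
        assert statuses == [P, LT, P, GT, GT]
        # greater-than entries ordered by bound
        assert [e.value for e in ranked.entries[3:]] == [4.5, 5.0]

    def test_late_campaign_rank_layout(self, late_report):
        ranked = late_report.ranked_concentration
        assert ranked.n == 17
        assert ranked.n_real == 11  # includes the one less-than value
        assert all(e.in_fit for e in ranked.entries[:11])
        assert all(e.status is GT for e in ranked.entries[11:])

    def test_too_few_entries(self):
        with pytest.raises(cln.InsufficientDataError):
            cln.rank_dataset(make_points([1.0, 2.0]))

    def test_unknown_convention(self):
        with pytest.raises(ValueError, match="convention"):
            cln.rank_dataset(make_points([1, 2, 3]), "excel")

    def test_strict_less_than_drops_entry(self):
        results = make_points([1.0, 2.0, 3.0]) + [cv(0.5, LT)]
        ranked = cln.rank_dataset(results, strict_less_than=True)
        assert ranked.n == 3
        assert all(e.status is P for e in ranked.entries)

    @pytest.mark.parametrize(
        "convention, expected_first",
        [("hazen", 0.5 / 4), ("weibull", 1 / 5), ("blom", 0.625 / 4.25)],
    )
    def test_alternative_conventions(self, convention, expected_first):
        ranked = cln.rank_dataset(make_points([1, 2, 3, 4]), convention)
        assert ranked.entries[0].plotting_position == pytest.approx(expected_first)


class TestQQFit:
    def test_late_campaign_fit_frozen(self, late_report):
        """Regression of the 11 measured late entries, checked against an
        independent hand regression (frozen)."""
        fit = late_report.fit_concentration
        assert fit.n_fit == 11
        assert fit.intercept == pytest.approx(1.471571, abs=1e-5)
        assert fit.slope == pytest.approx(0.509493, abs=1e-5)
        assert fit.r_squared == pytest.approx(0.9814, abs=5e-4)
        # slope corresponds to GSD ~ 1.67
        assert np.exp(fit.slope) == pytest.approx(1.67, rel=0.01)

    def test_collinear_log_points_fit_exactly(self):
        # values exp(a + b*q) at the hazen quantiles of n=3
        q = stats.norm.ppf([(i - 0.5) / 3 for i in (1, 2, 3)])
        vals = np.exp(0.7 + 1.3 * q)
        fit = cln.qq_fit(cln.rank_dataset(make_points(vals)))
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.slope == pytest.approx(1.3)
        assert fit.intercept == pytest.approx(0.7)

    @given(k=st.floats(0.05, 50.0))
    def test_scale_equivariance(self, k):
        vals = [1.2, 2.0, 3.5, 4.1, 6.0]
        base = cln.qq_fit(cln.rank_dataset(make_points(vals)))
        scaled = cln.qq_fit(cln.rank_dataset(make_points([v * k for v in vals])))
        assert scaled.intercept == pytest.approx(base.intercept + np.log(k))
        assert scaled.slope == pytest.approx(base.slope)
        assert scaled.r_squared == pytest.approx(base.r_squared)

    def test_too_few_measured_entries(self):
        results = make_points([1.0, 2.0]) + [cv(3.0, GT), cv(3.0, GT)]
        with pytest.raises(cln.InsufficientDataError):
            cln.qq_fit(cln.rank_dataset(results))

    def test_negative_slope_warns(self):
        # forcing a negative slope needs a decreasing rank pattern, which
        # cannot happen after sorting; only degenerate equal values give
        # slope zero, so drive a warning through an adversarial ranked set
        ranked = cln.rank_dataset(make_points([2.0, 2.0, 2.0]))
        entries = tuple(
            cln.RankedEntry(v, P, e.rank, e.plotting_position, e.normal_quantile)
            for v, e in zip([3.0, 2.0, 1.0], ranked.entries)
        )
        adversarial = cln.RankedDataset(entries, "hazen")
        with pytest.warns(UserWarning, match="negative"):
            cln.qq_fit(adversarial)

    def test_appending_censored_entry_only_shifts_positions(self):
        """An extra greater-than entry re-spaces the plotting positions
        (n grows by one) but the measured values, their order and their
        ranks stay put, and the fit equals a direct fit of the re-spaced
        measured entries."""
        vals = [1.2, 2.0, 3.5, 4.1, 6.0]
        base = cln.rank_dataset(make_points(vals))
        extended = cln.rank_dataset(make_points(vals) + [cv(10.0, GT)])
        assert [e.value for e in extended.entries[:5]] == sorted(vals)
        assert [e.rank for e in extended.entries[:5]] == [1, 2, 3, 4, 5]
        for e in extended.entries[:5]:
            assert e.plotting_position == pytest.approx((e.rank - 0.5) / 6)
        assert extended.entries[5].status is GT
        # fit over measured entries at the new quantiles, independently
        q = np.array([e.normal_quantile for e in extended.entries[:5]])
        beta = np.polyfit(q, np.log(sorted(vals)), 1)
        fit = cln.qq_fit(extended)
        assert fit.slope == pytest.approx(beta[0])
        assert fit.intercept == pytest.approx(beta[1])
        assert base.n + 1 == extended.n


class TestImputation:
    def test_late_campaign_imputations_frozen(self, late_report):
        imputed = dict(
            cln.impute_censored(
                late_report.ranked_concentration, late_report.fit_concentration
            )
        )
        assert sorted(imputed) == [12, 13, 14, 15, 16, 17]
        # top rank: exp(intercept + slope * Phi^-1(16.5/17)), frozen
        assert imputed[17] == pytest.approx(11.407, abs=2e-3)
        values = [imputed[r] for r in sorted(imputed)]
        assert values == sorted(values)  # monotone in rank for slope > 0

    def test_early_campaign_imputation_count(self, early_report):
        imputed = cln.impute_censored(
            early_report.ranked_concentration, early_report.fit_concentration
        )
        assert len(imputed) == 12
        assert [r for r, _ in imputed] == list(range(5, 17))

    def test_zero_slope_imputes_constant(self):
        ranked = cln.rank_dataset(make_points([2.0, 2.0, 2.0]) + [cv(2.5, GT)])
        fit = cln.qq_fit(ranked)
        assert fit.slope == pytest.approx(0.0)
        with pytest.warns(UserWarning, match="below its censoring bound"):
            imputed = cln.impute_censored(ranked, fit)
        assert imputed[0][1] == pytest.approx(2.0)


class TestSummarize:
    def test_late_campaign_summary_frozen(self, late_report):
        s = late_report.stats_concentration
        assert (s.n_total, s.n_real, s.n_censored) == (17, 11, 6)
        assert s.geometric_mean == pytest.approx(4.3561, abs=2e-3)
        assert s.geometric_sd == pytest.approx(1.6644, abs=2e-3)
        assert s.percentile_95 == pytest.approx(10.071, abs=5e-3)

    def test_uncensored_gm_equals_sample_geometric_mean(self):
        vals = [1.3, 2.7, 3.1, 4.9, 8.2]
        ranked = cln.rank_dataset(make_points(vals))
        fit = cln.qq_fit(ranked)
        s = cln.summarize(ranked, fit)
        assert s.geometric_mean == pytest.approx(stats.gmean(vals))

    def test_empirical_method(self):
        vals = [1.3, 2.7, 3.1, 4.9, 8.2]
        ranked = cln.rank_dataset(make_points(vals))
        fit = cln.qq_fit(ranked)
        s = cln.summarize(ranked, fit, method="empirical")
        assert s.geometric_sd == pytest.approx(np.exp(np.std(np.log(vals), ddof=1)))
        assert s.percentile_95 == pytest.approx(np.percentile(vals, 95))
        with pytest.raises(ValueError):
            cln.summarize(ranked, fit, method="excel")

    @given(k=st.floats(0.05, 50.0))
    def test_scale_equivariance_of_summary(self, k):
        results = make_points([1.2, 2.0, 3.5, 4.1]) + [cv(5.0, GT), cv(6.0, GT)]
        scaled = [r.scaled(k) for r in results]
        base_r = cln.rank_dataset(results)
        base = cln.summarize(base_r, cln.qq_fit(base_r))
        sc_r = cln.rank_dataset(scaled)
        sc = cln.summarize(sc_r, cln.qq_fit(sc_r))
        assert sc.geometric_mean == pytest.approx(k * base.geometric_mean)
        assert sc.percentile_95 == pytest.approx(k * base.percentile_95)
        assert sc.geometric_sd == pytest.approx(base.geometric_sd)


class TestNaiveStats:
    def test_early_campaign_point_statistics(self, early_report):
        finals = [f.concentration for f in early_report.finals]
        median, vmin, vmax, n = cln.naive_stats(finals)
        assert median == pytest.approx(4.715, abs=1e-3)
        assert (vmin, vmax) == (pytest.approx(4.515), pytest.approx(5.37))
        assert n == 4

    def test_late_campaign_point_statistics(self, late_report):
        finals = [f.concentration for f in late_report.finals]
        median, vmin, vmax, n = cln.naive_stats(finals)
        assert median == pytest.approx(3.585, abs=1e-3)
        assert (vmin, vmax) == (pytest.approx(2.04), pytest.approx(4.82))
        assert n == 10

    def test_single_point(self):
        assert cln.naive_stats([cv(3.3), cv(9.9, GT)]) == (3.3, 3.3, 3.3, 1)

    def test_no_points_rejected(self):
        with pytest.raises(cln.InsufficientDataError):
            cln.naive_stats([cv(1.0, GT)])


class TestAgainstIndependentOracles:
    def _censored_mle(self, finals):
        """Direct numerical optimisation of the censored lognormal
        likelihood — an estimation route fully independent of the q-q
        regression."""

        logs = np.log([f.value for f in finals])
        kinds = np.array([f.status.value for f in finals])

        def negll(theta):
            mu, logsig = theta
            sig = np.exp(logsig)
            ll = np.sum(stats.norm.logpdf(logs[kinds == "point"], mu, sig))
            ll += np.sum(stats.norm.logsf(logs[kinds == "greater_than"], mu, sig))
            ll += np.sum(stats.norm.logcdf(logs[kinds == "less_than"], mu, sig))
            return -ll

        res = optimize.minimize(negll, [1.0, -0.5], method="Nelder-Mead")
        assert res.success
        return float(np.exp(res.x[0])), float(np.exp(np.exp(res.x[1])))

    def test_ros_agrees_with_censored_mle(self):
        """On synthetic right-censored data (n=200, ~35-40% censored) the
        regression-on-order-statistics GM matches the censored MLE."""
        campaign = simulate_campaign(CampaignSpec(n_sessions=200, seed=7))
        retained, _ = filter_campaign(campaign.sessions)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            finals = [
                finalize(s, auto_outlier=True).concentration for s in retained
            ]
            ranked = cln.rank_dataset(finals)
            summary = cln.summarize(ranked, cln.qq_fit(ranked))
        assert summary.n_censored / summary.n_total <= 0.40
        gm_mle, gsd_mle = self._censored_mle(finals)
        assert summary.geometric_mean == pytest.approx(gm_mle, rel=0.10)
        assert summary.geometric_sd == pytest.approx(gsd_mle, rel=0.10)

    def test_uncensored_matches_closed_form_within_bias(self):
        """Without censoring, distributional GM/GSD agree with the sample
        geometric mean/SD up to plotting-position bias (< 2% at n=200)."""
        rng = np.random.default_rng(21)
        vals = np.exp(rng.normal(np.log(4.4), np.log(1.67), size=200))
        ranked = cln.rank_dataset(make_points(vals))
        s = cln.summarize(ranked, cln.qq_fit(ranked))
        assert s.geometric_mean == pytest.approx(stats.gmean(vals), rel=0.02)
        sample_gsd = np.exp(np.std(np.log(vals), ddof=1))
        assert s.geometric_sd == pytest.approx(sample_gsd, rel=0.02)


class TestQQTable:
    def test_export_columns_and_content(self, late_report, tmp_path):
        path = tmp_path / "qq.tsv"
        df = cln.qq_table(
            late_report.ranked_concentration, late_report.fit_concentration, path
        )
        assert list(df["rank"]) == list(range(1, 18))
        assert df["imputed_value"].notna().sum() == 6
        text = path.read_text()
        assert text.startswith("rank\t")
        assert len(text.splitlines()) == 18
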