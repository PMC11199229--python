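"""Pearson machinery, banding, subgroup analysis, and exact power."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from microrest.stats import (
    BAND_BLANK,
    BAND_SIGNIFICANT,
    BAND_TREND,
    band_of,
    correlation_matrix,
    correlation_power,
    pearson,
    r_squared,
    required_n,
    sample_r_pdf,
    subgroup,
)


def _wide(rng, n, coupled=None):
    """Synthetic participants x 21 metric table; optionally one coupled column."""
    cols = {
        f"{metric}_{cls}": rng.standard_normal(n)
        for metric in ("duration", "occurrence", "contribution")
        for cls in range(7)
    }
    frame = pd.DataFrame(cols, index=[f"P{i:03d}" for i in range(n)])
    frame.index.name = "participant"
    if coupled is not None:
        frame[coupled[0]] = coupled[1]
    return frame


def _summary(rng, n, ct=None, ages=None):
    return pd.DataFrame(
        {
            "participant": [f"P{i:03d}" for i in range(n)],
            "CT": rng.standard_normal(n) if ct is None else ct,
            "MV": rng.standard_normal(n),
            "age": np.full(n, 25) if ages is None else ages,
        }
    )


class TestPearson:
    def test_perfect_linear_relations(self):
        x = np.arange(10.0)
        assert pearson(x, 2 * x + 1).r == pytest.approx(1.0)
        assert pearson(x, -x).r == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        res = pearson(np.array([1.0, 2, 3, 4]), np.array([2.0, 1, 4, 3]))
        assert res.r == pytest.approx(0.6, abs=1e-12)
        assert res.df == 2

    def test_p_matches_t_transform_closed_form(self, rng):
        x = rng.standard_normal(30)
        y = 0.5 * x + rng.standard_normal(30)
        res = pearson(x, y)
        t = res.r * np.sqrt(res.df / (1 - res.r**2))
        p = 2 * sstats.t.sf(abs(t), res.df)
        assert res.p == pytest.approx(p, abs=1e-10)

    def test_pairwise_complete_handling(self, rng):
        x = rng.standard_normal(20)
        y = x + 0.1 * rng.standard_normal(20)
        x[3] = np.nan
        y[7] = np.nan
        res = pearson(x, y)
        assert res.n == 18

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            pearson(np.ones(5), np.arange(5.0))

    def test_reporting_style(self):
        res = pearson(np.array([1.0, 2, 3, 4]), np.array([2.0, 1, 4, 3]))
        assert str(res).startswith("r(2) = 0.600")


class TestBanding:
    @pytest.mark.parametrize(
        "p,band",
        [(0.04, BAND_SIGNIFICANT), (0.07, BAND_TREND), (0.2, BAND_BLANK), (0.05, BAND_SIGNIFICANT), (0.10, BAND_TREND)],
    )
    def test_band_rule(self, p, band):
        assert band_of(p) == band


class TestCorrelationMatrix:
    def test_null_cohort_false_positive_rate(self):
        counts = []
        for s in range(50):
            rng = np.random.default_rng(s)
            table = correlation_matrix(_summary(rng, 36), _wide(rng, 36))
            counts.append((table.band == BAND_SIGNIFICANT).sum())
        # 42 independent null cells at alpha .05 -> about 2.1 significant
        assert 1.4 <= np.mean(counts) <= 2.8

    def test_planted_strong_coupling_is_detected(self):
        hits = 0
        for s in range(20):
            rng = np.random.default_rng(1000 + s)
            x = rng.standard_normal(200)
            ct = 0.8 * x + np.sqrt(1 - 0.64) * rng.standard_normal(200)
            table = correlation_matrix(
                _summary(rng, 200, ct=ct), _wide(rng, 200, coupled=("contribution_2", x))
            )
            cell = table[(table.behaviour == "CT") & (table.metric == "contribution_2")]
            hits += int(cell.band.iloc[0] == BAND_SIGNIFICANT)
        assert hits == 20

    def test_dimensions_and_effective_n(self, rng):
        table = correlation_matrix(_summary(rng, 36), _wide(rng, 36))
        assert len(table) == 42
        assert (table.n == 36).all()

    def test_too_few_participants_rejected(self, rng):
        with pytest.raises(ValueError, match="3 aligned"):
            correlation_matrix(_summary(rng, 2), _wide(rng, 2))


class TestSubgroup:
    def test_empty_filter_reproduces_full_analysis(self, rng):
        summary, wide = _summary(rng, 20), _wide(rng, 20)
        full = correlation_matrix(summary, wide)
        filtered, excluded = subgroup(summary, wide)
        assert excluded == 0
        pd.testing.assert_frame_equal(full, filtered)

    def test_two_over_forty_reduce_df_to_32(self, rng):
        ages = np.full(36, 30)
        ages[[4, 17]] = 45
        summary = _summary(rng, 36, ages=ages)
        table, excluded = subgroup(summary, _wide(rng, 36))
        assert excluded == 2
        assert (table.n == 34).all()  # df = n - 2 = 32

    def test_missing_age_covariate_rejected(self, rng):
        summary = _summary(rng, 10).drop(columns="age")
        with pytest.raises(ValueError, match="age"):
            subgroup(summary, _wide(rng, 10))


class TestRSquared:
    def test_published_coefficients_of_determination(self):
        assert round(r_squared(0.403), 4) == 0.1624
        assert round(r_squared(0.277), 4) == 0.0767

    def test_zero(self):
        assert r_squared(0.0) == 0.0


class TestExactPower:
    def test_density_integrates_to_one(self):
        from scipy.integrate import quad

        total, _ = quad(lambda r: sample_r_pdf(r, 0.403, 36), -1, 1)
        assert total == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize(
        "rho,tails,expected",
        [(0.403, 2, 0.7016), (0.403, 1, 0.8026), (0.277, 2, 0.3789), (0.277, 1, 0.5055)],
    )
    def test_published_power_values(self, rho, tails, expected):
        res = correlation_power(rho, 36, 0.05, tails)
        assert res.power == pytest.approx(expected, abs=0.005)

    def test_size_equals_alpha_at_null(self):
        assert correlation_power(0.0, 36, 0.05, 2).power == pytest.approx(0.05, abs=1e-6)

    def test_strictly_increasing_in_n_and_rho(self):
        powers_n = [correlation_power(0.3, n).power for n in (10, 20, 36, 80)]
        assert np.all(np.diff(powers_n) > 0)
        powers_rho = [correlation_power(r, 36).power for r in (0.1, 0.3, 0.5, 0.7)]
        assert np.all(np.diff(powers_rho) > 0)

    def test_monte_carlo_oracle_agreement(self):
        # independent oracle: simulate the sampling distribution of r from
        # bivariate normal draws and count rejections
        for rho, tails, expected in [
            (0.403, 2, 0.7016),
            (0.403, 1, 0.8026),
            (0.277, 2, 0.3789),
            (0.277, 1, 0.5055),
        ]:
            res = correlation_power(rho, 36, 0.05, tails)
            rng = np.random.default_rng(12345)
            n_draws, chunk, hits = 1_000_000, 100_000, 0
            for _ in range(n_draws // chunk):
                x = rng.standard_normal((chunk, 36))
                y = rho * x + np.sqrt(1 - rho**2) * rng.standard_normal((chunk, 36))
                xc = x - x.mean(axis=1, keepdims=True)
                yc = y - y.mean(axis=1, keepdims=True)
                r = np.einsum("ij,ij->i", xc, yc) / np.sqrt(
                    np.einsum("ij,ij->i", xc, xc) * np.einsum("ij,ij->i", yc, yc)
                )
                hits += int((np.abs(r) > res.r_critical).sum() if tails == 2 else (r > res.r_critical).sum())
            assert res.power == pytest.approx(hits / n_draws, abs=0.003)

    def test_fisher_z_approximation_is_close_but_not_the_method(self):
        # sanity oracle only: the normal approximation on atanh(r)
        rho, n = 0.403, 36
        res = correlation_power(rho, n)
        se = 1 / np.sqrt(n - 3)
        z_crit = sstats.norm.ppf(1 - 0.05 / 2)
        mu = np.arctanh(rho)
        approx = sstats.norm.sf(z_crit - mu / se) + sstats.norm.cdf(-z_crit - mu / se)
        assert res.power == pytest.approx(approx, abs=0.02)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            correlation_power(1.0, 36)
        with pytest.raises(ValueError):
            correlation_power(0.3, 3)
        with pytest.raises(ValueError):
            correlation_power(0.3, 36, alpha=0.0)


class TestRequiredN:
    def test_small_observed_effect_needs_about_100_participants(self):
        n = required_n(0.277, 0.80, 0.05, 2)
        assert n >= 100
        # minimality: one fewer participant falls short
        assert correlation_power(0.277, n - 1).power < 0.80 <= correlation_power(0.277, n).power

    def test_large_effect_needs_few(self):
        assert required_n(0.9, 0.5) <= 10

    def test_non_increasing_in_effect_size(self):
        ns = [required_n(r, 0.8) for r in (0.2, 0.4, 0.6, 0.8)]
        assert np.all(np.diff(ns) <= 0)
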