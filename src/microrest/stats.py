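"""Correlational statistics and exact power for Pearson's r.

The brain-behaviour analysis correlates each behavioural metric (completion
time, movement variability) with the 21 microstate metrics (3 metrics x 7
classes) per condition, reports two-sided p-values from the t transform
``t = r * sqrt(df / (1 - r^2))`` with ``df = n - 2``, and bands cells at the
conventional thresholds: significant (p <= .05), trend (.05 < p <= .10),
blank otherwise. No multiple-comparison correction is applied by default;
Benjamini-Hochberg is available behind a flag.

Power calculations use the exact sampling distribution of the sample
correlation coefficient under a bivariate normal population (the "exact
bivariate normal" model of power software). The density, for population
correlation rho and sample size n,

    f(r) = (n-2) * Gamma(n-1) / (sqrt(2*pi) * Gamma(n-1/2))
           * (1-rho^2)^((n-1)/2) * (1-r^2)^((n-4)/2) * (1-rho*r)^(-(n-3/2))
           * 2F1(1/2, 1/2; n-1/2; (1+rho*r)/2),

is integrated numerically over the rejection region defined by the critical
sample correlation from the null t distribution. The Fisher-z normal
approximation is deliberately not used as the production method; it serves
only as a cross-check oracle in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, special
from scipy import stats as sstats

__all__ = [
    "CorrelationResult",
    "PowerResult",
    "pearson",
    "correlation_matrix",
    "subgroup",
    "r_squared",
    "sample_r_pdf",
    "correlation_power",
    "required_n",
    "band_of",
    "BAND_SIGNIFICANT",
    "BAND_TREND",
    "BAND_BLANK",
]

BAND_SIGNIFICANT = "p<=.05"
BAND_TREND = ".05<p<=.10"
BAND_BLANK = "blank"


@dataclass
class CorrelationResult:
    """Pearson correlation with its test and display band."""

    r: float
    n: int
    p: float
    band: str

    @property
    def df(self) -> int:
        return self.n - 2

    def __str__(self) -> str:  # the field's reporting style
        return f"r({self.df}) = {self.r:.3f}, p = {self.p:.3f}"


@dataclass
class PowerResult:
    """Exact power of the test of zero correlation."""

    rho: float
    n: int
    alpha: float
    tails: int
    power: float
    r_critical: float

    @property
    def rho_squared(self) -> float:
        """Coefficient of determination of the assumed effect."""
        return self.rho**2


def band_of(p: float, significant: float = 0.05, trend: float = 0.10) -> str:
    """Display band of a p-value: full box, dotted box, or blank."""
    if p <= significant:
        return BAND_SIGNIFICANT
    if p <= trend:
        return BAND_TREND
    return BAND_BLANK


# ---------------------------------------------------------------------------
# Pearson correlation
# ---------------------------------------------------------------------------

def pearson(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    """Product-moment correlation with a two-sided t-test.

    Missing values are handled pairwise-complete; the effective n after
    dropping incomplete pairs is reported and used for the test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    res = sstats.pearsonr(x, y)
    r, p = float(res.statistic), float(res.pvalue)
    return CorrelationResult(r, n, p, band_of(p))


def correlation_matrix(
    behaviour_summary: pd.DataFrame,
    wide_metrics: pd.DataFrame,
    behaviour_cols: tuple[str, ...] = ("CT", "MV"),
    fdr: bool = False,
) -> pd.DataFrame:
    """Behaviour x microstate-metric correlation table for one condition.

    ``behaviour_summary`` must carry a ``participant`` column plus the
    behaviour columns; ``wide_metrics`` is the participants x 21 matrix from
    :func:`microrest.backfit.widen_metrics`. Rows of the result are one per
    (behaviour, metric) cell with r, effective n, p and the display band
    (cells with p > .10 are blank, exactly the figure-mask rule). With
    ``fdr`` the bands are recomputed on Benjamini-Hochberg adjusted
    p-values; the raw p is always reported.
    """
    beh = behaviour_summary.set_index("participant")
    aligned = beh.join(wide_metrics, how="inner")
    if len(aligned) < 3:
        raise ValueError("fewer than 3 aligned participants")
    rows = []
    for bcol in behaviour_cols:
        for mcol in wide_metrics.columns:
            res = pearson(aligned[bcol].to_numpy(), aligned[mcol].to_numpy())
            rows.append(
                {
                    "behaviour": bcol,
                    "metric": mcol,
                    "r": res.r,
                    "n": res.n,
                    "p": res.p,
                    "band": res.band,
                }
            )
    table = pd.DataFrame(rows)
    if fdr:
        table["p_adjusted"] = _benjamini_hochberg(table["p"].to_numpy())
        table["band"] = [band_of(p) for p in table["p_adjusted"]]
    return table


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def subgroup(
    behaviour_summary: pd.DataFrame,
    wide_metrics: pd.DataFrame,
    max_age: float = 40.0,
    **kwargs,
) -> tuple[pd.DataFrame, int]:
    """Correlation matrix excluding participants older than ``max_age``.

    Identical computation on the filtered cohort; returns the table and the
    number of excluded participants. An empty filter reproduces the full
    analysis exactly.
    """
    if "age" not in behaviour_summary.columns:
        raise ValueError("subgroup analysis requires an age covariate")
    keep = behaviour_summary["age"] <= max_age
    excluded = int((~keep).sum())
    filtered = behaviour_summary[keep]
    if filtered.empty:
        raise ValueError("age filter removed every participant")
    return correlation_matrix(filtered, wide_metrics, **kwargs), excluded


def r_squared(r: float) -> float:
    """Coefficient of determination (reported to 4 decimals in summaries)."""
    if abs(r) > 1:
        raise ValueError("|r| must be <= 1")
    return float(r) ** 2


# ---------------------------------------------------------------------------
# exact bivariate-normal power
# ---------------------------------------------------------------------------

def sample_r_pdf(r: np.ndarray | float, rho: float, n: int) -> np.ndarray | float:
    """Exact density of the sample correlation under a bivariate normal.

    Hotelling's closed form via the Gauss hypergeometric function; valid for
    n >= 4 and |rho| < 1. Evaluated in log space for stability.
    """
    r_arr = np.asarray(r, dtype=float)
    log_const = (
        np.log(n - 2)
        + special.gammaln(n - 1)
        - 0.5 * np.log(2 * np.pi)
        - special.gammaln(n - 0.5)
        + (n - 1) / 2.0 * np.log1p(-rho**2)
    )
    with np.errstate(divide="ignore"):
        log_body = (n - 4) / 2.0 * np.log1p(-r_arr**2) - (n - 1.5) * np.log1p(-rho * r_arr)
    hyp = special.hyp2f1(0.5, 0.5, n - 0.5, (1.0 + rho * r_arr) / 2.0)
    out = np.exp(log_const + log_body) * hyp
    return float(out) if np.isscalar(r) else out


def _critical_r(n: int, alpha: float, tails: int) -> float:
    """Critical sample correlation from the null t distribution."""
    df = n - 2
    t_crit = sstats.t.ppf(1.0 - alpha / tails, df)
    return float(t_crit / np.sqrt(t_crit**2 + df))


def correlation_power(
    rho: float, n: int, alpha: float = 0.05, tails: int = 2
) -> PowerResult:
    """Exact power of the test of H0: rho = 0 against a true correlation.

    The rejection region is |r| > r_crit (two-tailed) or r > r_crit
    (one-tailed, testing in the direction of rho's sign); its probability
    under the exact sampling density of r is obtained by adaptive quadrature.
    At rho = 0 the power equals alpha (the size of the test) by construction.
    """
    if not abs(rho) < 1:
        raise ValueError("|rho| must be < 1")
    if n < 4:
        raise ValueError("exact power needs n >= 4")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    r_crit = _critical_r(n, alpha, tails)

    def pdf(r: float) -> float:
        return sample_r_pdf(r, rho, n)

    if tails == 2:
        upper, err_u = integrate.quad(pdf, r_crit, 1.0, limit=200)
        lower, err_l = integrate.quad(pdf, -1.0, -r_crit, limit=200)
        power, err = upper + lower, err_u + err_l
    elif rho >= 0:
        # one-tailed tests reject in the direction of the hypothesised effect
        power, err = integrate.quad(pdf, r_crit, 1.0, limit=200)
    else:
        power, err = integrate.quad(pdf, -1.0, -r_crit, limit=200)
    if err > 1e-6:
        raise RuntimeError(f"power integration did not converge (error estimate {err:.2e})")
    power = min(max(power, 0.0), 1.0)
    return PowerResult(rho, n, alpha, tails, float(power), r_crit)


def required_n(
    rho: float, target_power: float = 0.80, alpha: float = 0.05, tails: int = 2,
    n_max: int = 100_000,
) -> int:
    """Smallest n whose exact power reaches ``target_power``.

    Power is strictly increasing in n for fixed rho != 0, so a doubling
    bracket followed by bisection finds the minimum exactly.
    """
    if not 0 < target_power < 1:
        raise ValueError("target_power must lie in (0, 1)")
    if rho == 0:
        raise ValueError("no finite n reaches the target when rho = 0")

    def power_at(n: int) -> float:
        return correlation_power(rho, n, alpha, tails).power

    lo, hi = 4, 8
    while power_at(hi) < target_power:
        lo, hi = hi, hi * 2
        if hi > n_max:
            raise RuntimeError(f"required n exceeds {n_max}")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if power_at(mid) >= target_power:
            hi = mid
        else:
            lo = mid
    return hi if power_at(lo) < target_power else lo
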