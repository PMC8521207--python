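"""Comparison statistics: Bland-Altman agreement, Michaelis-Menten
saturation fit, the seeding-bias regression, and the cAMP contrast.

The seeding-bias model deserves a note. With a handful of sera measured in
triplicate at several deliberate cell amounts, a mixed model's random-effect
variance is weakly identified, so the common slope is estimated by ordinary
least squares with a fixed intercept per serum and one shared slope on the
z-scored resazurin net ratio (z over all analysed wells). The estimand — the
change in %CEC per 1 SD of the cell-amount proxy — is the same.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats as sps

from .errors import DataValidationError


@dataclass(frozen=True)
class BlandAltman:
    """Agreement between paired measurements; limits of agreement are the
    mean difference +/- 2 SDs of the differences."""

    n_pairs: int
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float


@dataclass(frozen=True)
class SaturationFit:
    """Michaelis-Menten fit CEC = vmax * A / (km + A)."""

    vmax: float
    km: float
    rss: float
    converged: bool
    at_boundary: bool = False  # km pinned at ~0 (saturated data)


@dataclass(frozen=True)
class SeedingBiasFit:
    """Common slope of CEC on the z-scored resazurin ratio, with per-sample
    fixed intercepts."""

    slope_per_sd: float
    ci95_low: float
    ci95_high: float
    intercepts: dict[str, float]
    n_wells: int


@dataclass(frozen=True)
class GroupContrast:
    """Welch difference of group means with a 95% CI."""

    diff: float
    ci95_low: float
    ci95_high: float
    p_value: float
    n1: int
    n2: int


def bland_altman(m1, m2) -> BlandAltman:
    """Bias and limits of agreement of paired measurements.

    Differences are ``m1 - m2``; pairs with a missing value in either
    measurement are dropped; the SD uses the n-1 denominator and the LoA
    multiplier is exactly 2.
    """
    a = np.asarray(m1, dtype=float)
    b = np.asarray(m2, dtype=float)
    if a.shape != b.shape:
        raise DataValidationError("paired measurements must have equal length")
    keep = ~(np.isnan(a) | np.isnan(b))
    d = a[keep] - b[keep]
    if d.size < 2:
        raise DataValidationError("Bland-Altman requires >=2 complete pairs")
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(
        n_pairs=int(d.size),
        mean_diff=bias,
        sd_diff=sd,
        loa_low=bias - 2.0 * sd,
        loa_high=bias + 2.0 * sd,
    )


def _mm(a: np.ndarray, vmax: float, km: float) -> np.ndarray:
    return vmax * a / (km + a)


def fit_saturation(acceptor_pcts, cecs) -> SaturationFit:
    """Least-squares Michaelis-Menten fit of CEC against acceptor
    concentration (% apoB-depleted serum).

    Deterministic initialisation: vmax0 = max CEC; km0 = acceptor level at
    half-max by linear interpolation of the sorted means. Trust-region
    least squares with non-negativity bounds, ftol 1e-8 (relative cost
    change), at most 500 function evaluations.
    """
    a = np.asarray(acceptor_pcts, dtype=float)
    y = np.asarray(cecs, dtype=float)
    keep = ~(np.isnan(a) | np.isnan(y))
    a, y = a[keep], y[keep]
    if len(np.unique(a)) < 3:
        raise DataValidationError("saturation fit requires >=3 distinct acceptor levels")
    vmax0 = float(y.max())
    if vmax0 <= 0:
        raise DataValidationError("saturation fit requires a positive maximal CEC")
    order = np.argsort(a)
    a_s, y_s = a[order], y[order]
    half = vmax0 / 2.0
    km0 = float(np.interp(half, y_s, a_s)) if y_s[0] < half else float(a_s[0]) / 2.0
    km0 = max(km0, 1e-6)

    res = optimize.least_squares(
        lambda p: _mm(a, p[0], p[1]) - y,
        x0=[vmax0, km0],
        bounds=([0.0, 0.0], [np.inf, np.inf]),
        ftol=1e-8,
        xtol=1e-12,  # step-size stop for exactly-fitting data (zero cost)
        gtol=None,
        max_nfev=500,
    )
    vmax, km = float(res.x[0]), float(res.x[1])
    rss = float(2.0 * res.cost)
    return SaturationFit(
        vmax=vmax,
        km=km,
        rss=rss,
        converged=bool(res.status > 0),
        at_boundary=km < 1e-4 * max(float(a.max()), 1.0),
    )


def seeding_bias(
    cec,
    resazurin,
    sample_ids,
) -> SeedingBiasFit:
    """Regression of per-well CEC on the standardised resazurin net ratio.

    Fixed effect (intercept) per sample, one common slope; the resazurin
    ratio is z-scored over all wells analysed (so the slope is %CEC per
    1 SD of the cell-amount proxy and is invariant to adding a constant to
    every ratio); 95% CI from the t-distribution on the residual df.
    """
    y = np.asarray(cec, dtype=float)
    r = np.asarray(resazurin, dtype=float)
    sid = np.asarray(sample_ids, dtype=object)
    if not (len(y) == len(r) == len(sid)):
        raise DataValidationError("cec, resazurin and sample_ids must align")
    keep = ~(np.isnan(y) | np.isnan(r))
    y, r, sid = y[keep], r[keep], sid[keep]
    samples = pd.unique(sid)
    if len(samples) < 2:
        raise DataValidationError("seeding-bias regression requires >=2 samples")
    counts = pd.Series(sid).value_counts()
    if (counts < 3).any():
        raise DataValidationError("each sample needs >=3 wells")
    r_sd = r.std(ddof=1)
    if not r_sd > 0:
        raise DataValidationError("resazurin ratios have no variance")
    z = (r - r.mean()) / r_sd

    dummies = pd.get_dummies(pd.Series(sid), dtype=float)
    X = np.column_stack([dummies.to_numpy(), z])
    fit = sm.OLS(y, X).fit()
    slope = float(fit.params[-1])
    ci = fit.conf_int(alpha=0.05)
    intercepts = {
        str(s): float(fit.params[i]) for i, s in enumerate(dummies.columns)
    }
    return SeedingBiasFit(
        slope_per_sd=slope,
        ci95_low=float(ci[-1][0]),
        ci95_high=float(ci[-1][1]),
        intercepts=intercepts,
        n_wells=int(len(y)),
    )


def camp_contrast(camp_cecs, no_camp_cecs) -> GroupContrast:
    """Welch contrast of sample-mean CEC between cAMP-treated and untreated
    conditions (difference = cAMP - no_cAMP)."""
    g1 = np.asarray(camp_cecs, dtype=float)
    g2 = np.asarray(no_camp_cecs, dtype=float)
    g1, g2 = g1[~np.isnan(g1)], g2[~np.isnan(g2)]
    if g1.size < 2 or g2.size < 2:
        raise DataValidationError("Welch contrast requires >=2 observations per group")
    diff = float(g1.mean() - g2.mean())
    v1, v2 = g1.var(ddof=1) / g1.size, g2.var(ddof=1) / g2.size
    se = math.sqrt(v1 + v2)
    if se == 0:
        return GroupContrast(diff, diff, diff, 1.0 if diff == 0 else 0.0, g1.size, g2.size)
    df = (v1 + v2) ** 2 / (v1**2 / (g1.size - 1) + v2**2 / (g2.size - 1))
    tcrit = float(sps.t.ppf(0.975, df))
    t_stat = diff / se
    p = float(2.0 * sps.t.sf(abs(t_stat), df))
    return GroupContrast(
        diff=diff,
        ci95_low=diff - tcrit * se,
        ci95_high=diff + tcrit * se,
        p_value=p,
        n1=int(g1.size),
        n2=int(g2.size),
    )
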