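"""Small numeric helpers shared across modules."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero at the given decimal place.

    Bankers' rounding (Python's builtin) would turn 14.5 into 14; assay
    reports conventionally round half up, and the reference report values
    only reproduce under that rule.
    """
    if not np.isfinite(x):
        return float(x)
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def relative_reduction(a: float, b: float) -> float:
    """Percent reduction of ``b`` relative to ``a``: 100*(a-b)/a, rounded
    half-up to a whole percent (the convention of assay-performance tables)."""
    if a == 0:
        raise ZeroDivisionError("relative reduction undefined for a == 0")
    return round_half_up(100.0 * (a - b) / a, 0)


def cv_percent(values, ddof: int = 1) -> float:
    """Coefficient of variation in percent, sample (n-1) SD by default."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        return float("nan")
    m = v.mean()
    if m == 0:
        return float("inf")
    return float(100.0 * v.std(ddof=ddof) / m)


def lognormal_factor(rng_normals: np.ndarray, cv: float) -> np.ndarray:
    """Mean-one lognormal multipliers from standard-normal draws.

    sigma^2 = ln(1+cv^2) and mu = -sigma^2/2 so that E[factor] = 1 exactly;
    cv = 0 returns ones (draws are still consumed by the caller, keeping the
    RNG stream layout independent of parameter values).
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if cv == 0:
        return np.ones_like(np.asarray(rng_normals, dtype=float))
    sigma2 = np.log1p(cv * cv)
    sigma = np.sqrt(sigma2)
    return np.exp(sigma * np.asarray(rng_normals, dtype=float) - 0.5 * sigma2)
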