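"""Core CEC arithmetic: background subtraction, both referencing methods,
passive-efflux subtraction, and resazurin ratios.

Two referencing methods are supported. The per-well method divides the
effluxed fluorescence by the total fluorescence recovered from the same
well::

    CEC_per_well = 100 * FI_sup / (FI_sup + FI_lys)

The t0 method divides by the mean fluorescence of control wells lysed at
time zero, a per-plate surrogate for the label loaded into every well::

    CEC_t0 = 100 * FI_sup / FI_t0_control

All fluorescences are net of the unstained-cell background of the matching
read. Passive efflux (release into acceptor-free medium) is subtracted from
both methods' values afterwards. Both statistics are exactly invariant to a
common multiplicative gain applied to every read on a plate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import cv_percent
from .errors import ConfigError, DataValidationError

PER_WELL = "per_well"
T0 = "t0"
METHODS = (PER_WELL, T0)

_SAMPLE_BEARING = {"sample", "correction_control", "monitoring_control"}


@dataclass(frozen=True)
class BackgroundSet:
    """Per-plate background fluorescence of each read, estimated as the mean
    over unstained-cell wells. ``bg_lys`` is NaN for runs without a lysate
    read (t0-only analyses)."""

    bg_sup: float
    bg_lys: float
    n_wells: int

    def __post_init__(self) -> None:
        if self.n_wells < 3:
            raise DataValidationError(
                f"background requires >=3 unstained wells, found {self.n_wells}"
            )
        if self.bg_sup < 0 or (not math.isnan(self.bg_lys) and self.bg_lys < 0):
            raise DataValidationError("background means must be non-negative")


@dataclass(frozen=True)
class PlateContext:
    """Per-plate reference quantities shared by all wells.

    ``t0_reference`` is the mean background-corrected fluorescence of the
    t0 control wells (NaN when the plate has none and only the per-well
    method is requested); ``passive_cec_*`` are the mean raw CEC of the
    acceptor-free wells under each method.
    """

    t0_reference: float
    t0_cv: float
    passive_cec_per_well: float
    passive_cec_t0: float


@dataclass(frozen=True)
class ResazurinReading:
    """Blank-subtracted 570/600 nm absorbance ratio of one well."""

    net_ratio: float


def subtract_background(
    raw_sup: float, raw_lys: float, bg: BackgroundSet
) -> tuple[float, float, bool, str | None]:
    """Net fluorescences and a per-well-method validity flag.

    A negative net read invalidates the well rather than being clamped:
    clamping to zero would bias CEC upward.
    """
    if raw_sup is None or (isinstance(raw_sup, float) and math.isnan(raw_sup)):
        return math.nan, math.nan, False, "missing supernatant read"
    net_sup = raw_sup - bg.bg_sup
    if raw_lys is None or (isinstance(raw_lys, float) and math.isnan(raw_lys)):
        return net_sup, math.nan, False, "missing lysate read"
    net_lys = raw_lys - bg.bg_lys
    if net_sup < 0:
        return net_sup, net_lys, False, "negative net supernatant"
    if net_lys < 0:
        return net_sup, net_lys, False, "negative net lysate"
    return net_sup, net_lys, True, None


def cec_per_well(fi_sup_net: float, fi_lys_net: float) -> float:
    """Raw per-well CEC (percent of the well's own total fluorescence)."""
    if fi_sup_net < 0 or fi_lys_net < 0:
        raise DataValidationError("per-well CEC requires non-negative net reads")
    total = fi_sup_net + fi_lys_net
    if total <= 0:
        raise DataValidationError("per-well CEC undefined: zero total fluorescence")
    return 100.0 * fi_sup_net / total


def cec_t0(fi_sup_net: float, ctx: PlateContext) -> tuple[float, bool]:
    """Raw t0-method CEC and an over-range flag (value > 100 is retained but
    flagged: the well out-effluxed the t0 controls' estimate of its load)."""
    if not (ctx.t0_reference > 0):
        raise DataValidationError(
            "t0 reference must be positive; plate unusable for the t0 method"
        )
    value = 100.0 * fi_sup_net / ctx.t0_reference
    return value, value > 100.0


def finalize_well_cec(raw_cec: float, ctx: PlateContext, method: str) -> float:
    """Subtract the plate's passive efflux for the matching method.

    Negative results are retained (they are flagged downstream, not clipped).
    """
    if method == PER_WELL:
        return raw_cec - ctx.passive_cec_per_well
    if method == T0:
        return raw_cec - ctx.passive_cec_t0
    raise ConfigError(f"unknown method {method!r}")


def resazurin_ratio(a570: float, a600: float, blank_ratio: float) -> ResazurinReading:
    """Blank-subtracted 570/600 absorbance ratio (cell-amount proxy)."""
    if not a600 > 0:
        raise DataValidationError("resazurin ratio undefined: A600 must be > 0")
    return ResazurinReading(net_ratio=a570 / a600 - blank_ratio)


def normalize_to_resazurin(cec: float, r_well: float, r_plate_mean: float) -> float:
    """Rescale a well's CEC by its relative resazurin signal.

    ``cec / (r_well / r_plate_mean)``; identity when the well sits at the
    plate's mean cell amount. Provided for the normalisation comparison —
    it is not part of the recommended pipeline.
    """
    if r_well <= 0 or r_plate_mean <= 0:
        raise DataValidationError("resazurin normalisation requires positive ratios")
    return cec / (r_well / r_plate_mean)


# ---------------------------------------------------------------------------
# Plate-level processing


def _plate_id(wells: pd.DataFrame) -> str:
    ids = wells["plate_id"].unique()
    if len(ids) != 1:
        raise DataValidationError(f"expected a single plate, found plate_ids {list(ids)}")
    return str(ids[0])


def compute_background(wells: pd.DataFrame) -> BackgroundSet:
    """Background per read from this plate's unstained wells (never global:
    reader gain differs between plates)."""
    un = wells[wells["role"] == "unstained_background"]
    has_lys = "fi_lys_raw" in wells.columns and un["fi_lys_raw"].notna().any()
    n = int(un["fi_sup_raw"].notna().sum()) if "fi_sup_raw" in un.columns else 0
    if n < 3:
        raise DataValidationError(
            f"plate {_plate_id(wells)}: role 'unstained_background' needs >=3 wells, found {n}"
        )
    return BackgroundSet(
        bg_sup=float(un["fi_sup_raw"].mean()),
        bg_lys=float(un["fi_lys_raw"].mean()) if has_lys else math.nan,
        n_wells=n,
    )


def compute_plate_context(
    wells: pd.DataFrame,
    bg: BackgroundSet,
    methods: tuple[str, ...] = METHODS,
) -> PlateContext:
    """t0 reference (mean of the t0 control wells) and passive efflux per
    method, from a joined well table with raw reads."""
    pid = _plate_id(wells)
    need_t0 = T0 in methods
    need_pw = PER_WELL in methods

    t0_ref = math.nan
    t0_cv = math.nan
    if need_t0:
        t0w = wells[wells["role"] == "t0_control"]
        if "fi_t0_raw" in wells.columns and t0w["fi_t0_raw"].notna().any():
            nets = t0w["fi_t0_raw"].dropna().to_numpy() - bg.bg_sup
        else:
            nets = t0w["fi_sup_raw"].dropna().to_numpy() - bg.bg_sup
        if len(nets) < 3:
            raise DataValidationError(
                f"plate {pid}: role 't0_control' needs >=3 wells for the t0 method"
            )
        t0_ref = float(np.mean(nets))
        if not t0_ref > 0:
            raise DataValidationError(
                f"plate {pid}: t0 reference is not positive; plate unusable for t0 method"
            )
        t0_cv = cv_percent(nets)

    pas = wells[wells["role"] == "passive"]
    if len(pas) < 3:
        raise DataValidationError(f"plate {pid}: role 'passive' needs >=3 wells")
    p_pw, p_t0 = [], []
    for rec in pas.to_dict("records"):
        ns, nl, ok, _ = subtract_background(rec.get("fi_sup_raw"), rec.get("fi_lys_raw"), bg)
        if need_pw and ok and ns + nl > 0:
            p_pw.append(cec_per_well(ns, nl))
        if need_t0 and not math.isnan(ns) and ns >= 0:
            p_t0.append(100.0 * ns / t0_ref)
    if need_pw and not p_pw:
        raise DataValidationError(f"plate {pid}: no valid passive wells for per-well method")
    if need_t0 and not p_t0:
        raise DataValidationError(f"plate {pid}: no valid passive wells for t0 method")
    return PlateContext(
        t0_reference=t0_ref,
        t0_cv=t0_cv,
        passive_cec_per_well=float(np.mean(p_pw)) if p_pw else math.nan,
        passive_cec_t0=float(np.mean(p_t0)) if p_t0 else math.nan,
    )


def process_plate(
    wells: pd.DataFrame,
    methods: tuple[str, ...] = METHODS,
) -> tuple[pd.DataFrame, PlateContext, BackgroundSet]:
    """Compute net fluorescences, raw and passive-subtracted CEC under the
    requested methods, and resazurin net ratios for one plate's well table.

    Adds columns ``fi_sup_net, fi_lys_net, invalid_reason, resazurin_net``
    and, per requested method, ``valid_<method>, cec_raw_<method>,
    cec_<method>`` (plus ``t0_over_range``). Validity is method-specific:
    the t0 method needs only a usable supernatant read, the per-well method
    needs both reads with non-negative nets and a positive total.
    """
    wells = wells.copy()
    bg = compute_background(wells)
    ctx = compute_plate_context(wells, bg, methods=methods)
    need_pw = PER_WELL in methods
    need_t0 = T0 in methods

    # resazurin blank from no-cell wells, when absorbance reads exist
    blank_ratio = math.nan
    if {"a570", "a600"}.issubset(wells.columns):
        blanks = wells[(wells["role"] == "no_cell_blank") & (wells["a600"] > 0)]
        if len(blanks) >= 1:
            blank_ratio = float((blanks["a570"] / blanks["a600"]).mean())

    n = len(wells)
    fi_sup_net = np.full(n, np.nan)
    fi_lys_net = np.full(n, np.nan)
    valid_pw = np.zeros(n, dtype=bool)
    valid_t0 = np.zeros(n, dtype=bool)
    reason: list[str | None] = [None] * n
    raw_pw = np.full(n, np.nan)
    fin_pw = np.full(n, np.nan)
    raw_t0 = np.full(n, np.nan)
    fin_t0 = np.full(n, np.nan)
    over = np.zeros(n, dtype=bool)
    resaz = np.full(n, np.nan)

    for i, rec in enumerate(wells.to_dict("records")):
        role = rec["role"]
        if not math.isnan(blank_ratio):
            a570, a600 = rec.get("a570", math.nan), rec.get("a600", math.nan)
            if not math.isnan(a570) and a600 > 0:
                resaz[i] = a570 / a600 - blank_ratio
        if role not in _SAMPLE_BEARING and role != "passive":
            continue
        ns, nl, ok, why = subtract_background(rec.get("fi_sup_raw"), rec.get("fi_lys_raw"), bg)
        fi_sup_net[i], fi_lys_net[i] = ns, nl
        reason[i] = why
        if role not in _SAMPLE_BEARING:
            continue
        if need_pw and ok:
            if ns + nl > 0:
                valid_pw[i] = True
                raw_pw[i] = cec_per_well(ns, nl)
                fin_pw[i] = finalize_well_cec(raw_pw[i], ctx, PER_WELL)
            else:
                reason[i] = "zero total fluorescence"
        if need_t0 and not math.isnan(ns) and ns >= 0:
            valid_t0[i] = True
            raw_t0[i], over[i] = cec_t0(ns, ctx)
            fin_t0[i] = finalize_well_cec(raw_t0[i], ctx, T0)

    wells["fi_sup_net"] = fi_sup_net
    wells["fi_lys_net"] = fi_lys_net
    wells["invalid_reason"] = reason
    if need_pw:
        wells["valid_per_well"] = valid_pw
        wells["cec_raw_per_well"] = raw_pw
        wells["cec_per_well"] = fin_pw
    if need_t0:
        wells["valid_t0"] = valid_t0
        wells["cec_raw_t0"] = raw_t0
        wells["cec_t0"] = fin_t0
        wells["t0_over_range"] = over
    wells["resazurin_net"] = resaz
    return wells, ctx, bg
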