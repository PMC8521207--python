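"""Replicate aggregation, the 15% CV rejection rule, four-control plate
correction, intra-/interassay CV, and the assay-performance report.

Conventions
-----------
* SDs use the sample (n-1) denominator throughout.
* Replicate CV is computed on raw (pre-passive-subtraction) CEC: passive
  subtraction can push means toward zero and blow the CV up for perfectly
  reproducible wells. Switchable via :class:`QCConfig`.
* A sample is rejected when its replicate CV is *strictly* greater than the
  threshold (default 15%), so CV = 15.0 is retained.
* Rates and CVs are reported to 2 decimals; relative reductions to whole
  percent, both rounded half-up.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import cv_percent, relative_reduction, round_half_up
from .errors import ConfigError, DataValidationError

PER_WELL = "per_well"
T0 = "t0"


@dataclass
class QCConfig:
    """Quality-control parameters.

    replicate_cv_max : rejection threshold in percent (replicate CV must be
        strictly greater to reject).
    min_replicates : fewer valid wells than this rejects the sample with
        reason "insufficient wells".
    correction_enabled : apply the four-control plate correction.
    strict_boundary : reject only strictly above the threshold (the
        published rule is "CV of replicates >15%"); set False for >=.
    cv_on_raw : compute replicate CV on pre-passive raw CEC.
    expected_control_values : optional externally supplied reference CEC per
        correction control, ``{method: {control_id: expected}}``; when absent
        the expected value is the control's mean across all plates in the run.
    """

    replicate_cv_max: float = 15.0
    min_replicates: int = 3
    correction_enabled: bool = True
    strict_boundary: bool = True
    cv_on_raw: bool = True
    expected_control_values: dict[str, dict[str, float]] | None = None

    def __post_init__(self) -> None:
        if not self.replicate_cv_max > 0:
            raise ConfigError("replicate_cv_max must be > 0")
        if self.min_replicates < 2:
            raise ConfigError("min_replicates must be >= 2")


@dataclass
class SampleResult:
    """Aggregated replicate CEC for one sample on one plate under one method."""

    sample_id: str
    plate_id: str
    method: str
    role: str
    n_wells: int
    mean_cec: float
    sd_cec: float
    cv: float
    rejected: bool
    reject_reason: str | None = None
    corrected_cec: float = math.nan


@dataclass
class PlateCorrection:
    """Plate-to-plate correction factor from the four on-plate controls.

    ``rel_diff[c] = (expected[c] - observed[c]) / expected[c]`` and the
    factor is ``1 + mean(-rel_diff)``, i.e. the controls' mean
    observed/expected ratio. Corrected values are ``observed / factor``
    (multiplicative, preserving positivity and the percent-of-total scale).
    """

    plate_id: str
    method: str
    control_ids: tuple[str, ...]
    expected: dict[str, float]
    observed: dict[str, float]
    rel_diff: dict[str, float]
    factor: float
    applied: bool
    note: str | None = None


def aggregate_sample(
    raw_cecs,
    passive_cec: float,
    cfg: QCConfig,
    *,
    sample_id: str = "",
    plate_id: str = "",
    method: str = PER_WELL,
    role: str = "sample",
) -> SampleResult:
    """Aggregate one sample's valid replicate wells.

    ``raw_cecs`` are the pre-passive raw CEC values of the valid wells;
    ``passive_cec`` is the plate's passive efflux under the same method
    (subtracted from the reported mean, not from the CV).
    """
    raw = np.asarray([v for v in np.atleast_1d(raw_cecs) if not math.isnan(v)], dtype=float)
    n = raw.size
    if n < cfg.min_replicates:
        mean = float(raw.mean()) - passive_cec if n else math.nan
        return SampleResult(
            sample_id, plate_id, method, role, n, mean, math.nan, math.nan,
            rejected=True, reject_reason="insufficient wells",
        )
    sd = float(raw.std(ddof=1))
    if cfg.cv_on_raw:
        cv = cv_percent(raw)
    else:
        cv = cv_percent(raw - passive_cec)
    over = cv > cfg.replicate_cv_max if cfg.strict_boundary else cv >= cfg.replicate_cv_max
    return SampleResult(
        sample_id, plate_id, method, role, n,
        mean_cec=float(raw.mean()) - passive_cec,
        sd_cec=sd,
        cv=float(cv),
        rejected=bool(over),
        reject_reason="replicate CV above threshold" if over else None,
    )


def aggregate_run(
    well_df: pd.DataFrame,
    cfg: QCConfig,
    method: str,
    passive_by_plate: dict[str, float],
) -> pd.DataFrame:
    """Aggregate every sample-bearing well group of a processed well table.

    ``well_df`` must carry the columns written by
    :func:`cecflux.cec_core.process_plate`; ``passive_by_plate`` maps plate
    to that plate's passive CEC under ``method``.
    """
    raw_col, valid_col = f"cec_raw_{method}", f"valid_{method}"
    if raw_col not in well_df.columns:
        raise ConfigError(f"well table lacks {raw_col!r}; was method {method!r} computed?")
    rows = []
    mask = well_df["role"].isin(("sample", "correction_control", "monitoring_control"))
    for (pid, sid, role), grp in well_df[mask].groupby(
        ["plate_id", "sample_id", "role"], sort=True
    ):
        raw = grp.loc[grp[valid_col], raw_col].to_numpy()
        rows.append(
            aggregate_sample(
                raw, passive_by_plate[pid], cfg,
                sample_id=sid, plate_id=pid, method=method, role=role,
            )
        )
    return pd.DataFrame([vars(r) for r in rows])


def rejection_rate(n_rejected: int, n_total: int) -> float:
    """Percent of samples rejected, to 2 decimals (half-up)."""
    if n_total <= 0:
        raise DataValidationError("rejection rate undefined for n_total <= 0")
    return round_half_up(100.0 * n_rejected / n_total, 2)


def compute_plate_correction(
    observed: dict[str, float],
    expected: dict[str, float],
    cfg: QCConfig,
    *,
    plate_id: str = "",
    method: str = PER_WELL,
) -> PlateCorrection:
    """Correction factor for one plate from its (unrejected) controls.

    ``observed`` holds the controls' mean CEC on this plate — pass only
    controls that survived replicate QC. Four are expected; three are
    accepted with a warning; fewer leave the plate uncorrected.
    """
    ids = tuple(sorted(set(observed) & set(expected)))
    usable = [c for c in ids if expected[c] > 0 and not math.isnan(observed[c])]
    note = None
    if len(usable) < 3:
        return PlateCorrection(
            plate_id, method, tuple(usable), dict(expected), dict(observed),
            {}, math.nan, applied=False,
            note=f"only {len(usable)} usable controls (<3); plate left uncorrected",
        )
    if len(usable) < 4:
        note = f"correction from {len(usable)} controls instead of 4"
        warnings.warn(f"plate {plate_id} ({method}): {note}", stacklevel=2)
    rel_diff = {c: (expected[c] - observed[c]) / expected[c] for c in usable}
    factor = 1.0 + float(np.mean([-d for d in rel_diff.values()]))
    if not factor > 0:
        return PlateCorrection(
            plate_id, method, tuple(usable), dict(expected), dict(observed),
            rel_diff, factor, applied=False,
            note="non-positive correction factor; plate left uncorrected",
        )
    return PlateCorrection(
        plate_id, method, tuple(usable), dict(expected), dict(observed),
        rel_diff, factor, applied=True, note=note,
    )


def expected_from_run(samples: pd.DataFrame) -> dict[str, float]:
    """Two-pass expected values: each correction control's mean CEC over the
    plates where it was not rejected."""
    ctrl = samples[(samples["role"] == "correction_control") & (~samples["rejected"])]
    if ctrl.empty:
        raise DataValidationError("no unrejected correction controls in the run")
    return ctrl.groupby("sample_id")["mean_cec"].mean().to_dict()


def apply_corrections(
    samples: pd.DataFrame,
    cfg: QCConfig,
    method: str,
    expected: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, list[PlateCorrection]]:
    """Compute per-plate factors and fill ``corrected_cec`` for every sample.

    ``expected`` defaults to the two-pass within-run means
    (:func:`expected_from_run`); plates whose correction cannot be computed
    keep ``corrected_cec`` = NaN.
    """
    samples = samples.copy()
    if expected is None:
        if cfg.expected_control_values and method in cfg.expected_control_values:
            expected = cfg.expected_control_values[method]
        else:
            expected = expected_from_run(samples)
    corrections = []
    for pid, grp in samples.groupby("plate_id", sort=True):
        ctrl = grp[(grp["role"] == "correction_control") & (~grp["rejected"])]
        observed = dict(zip(ctrl["sample_id"], ctrl["mean_cec"]))
        corr = compute_plate_correction(
            observed, expected, cfg, plate_id=str(pid), method=method
        )
        corrections.append(corr)
        if corr.applied:
            samples.loc[samples["plate_id"] == pid, "corrected_cec"] = (
                samples.loc[samples["plate_id"] == pid, "mean_cec"] / corr.factor
            )
    return samples, corrections


def interassay_cv(control_cecs) -> float:
    """CV (percent, n-1 SD) of one control's CEC across plates."""
    v = np.asarray(control_cecs, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 2:
        raise DataValidationError("interassay CV requires >=2 plate values")
    return cv_percent(v)


@dataclass
class MethodPerformance:
    """Performance block for one referencing method."""

    method: str
    n_total: int
    n_rejected: int
    rejection_rate: float
    intra_assay_cv: float
    interassay_cv_uncorrected: dict[str, float] = field(default_factory=dict)
    interassay_cv_corrected: dict[str, float] = field(default_factory=dict)


@dataclass
class PerformanceReport:
    """Table-style assay-performance summary for one or two methods.

    ``comparison`` holds whole-percent relative reductions: of the t0
    method's value by the per-well method, and of each method's interassay
    CV by plate correction. All reductions are recomputed from the stored
    (2-decimal) pairs.
    """

    methods: dict[str, MethodPerformance]
    comparison: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "methods": {
                m: {
                    "n_total": p.n_total,
                    "n_rejected": p.n_rejected,
                    "rejection_rate": p.rejection_rate,
                    "intra_assay_cv": p.intra_assay_cv,
                    "interassay_cv_uncorrected": p.interassay_cv_uncorrected,
                    "interassay_cv_corrected": p.interassay_cv_corrected,
                }
                for m, p in self.methods.items()
            },
            "comparison": self.comparison,
        }


def method_performance(
    samples: pd.DataFrame,
    method: str,
    monitoring_ids: tuple[str, ...] = (),
) -> MethodPerformance:
    """Summarise one method's aggregated samples (study samples only count
    toward the rejection rate and intra-assay CV)."""
    study = samples[samples["role"] == "sample"]
    n_total = len(study)
    n_rejected = int(study["rejected"].sum())
    retained = study[~study["rejected"]]
    intra = round_half_up(float(retained["cv"].mean()), 2) if len(retained) else math.nan
    perf = MethodPerformance(
        method=method,
        n_total=n_total,
        n_rejected=n_rejected,
        rejection_rate=rejection_rate(n_rejected, n_total) if n_total else math.nan,
        intra_assay_cv=intra,
    )
    mon = samples[(samples["role"] == "monitoring_control") & (~samples["rejected"])]
    for cid in monitoring_ids:
        series = mon[mon["sample_id"] == cid]
        if len(series) >= 2:
            perf.interassay_cv_uncorrected[cid] = round_half_up(
                interassay_cv(series["mean_cec"]), 2
            )
            corrected = series["corrected_cec"].dropna()
            if len(corrected) >= 2:
                perf.interassay_cv_corrected[cid] = round_half_up(
                    interassay_cv(corrected), 2
                )
    return perf


def performance_report(
    samples_by_method: dict[str, pd.DataFrame],
    monitoring_ids: tuple[str, ...] = (),
) -> PerformanceReport:
    """Build the performance report, with cross-method and correction
    relative reductions when both inputs are available."""
    methods = {
        m: method_performance(df, m, monitoring_ids)
        for m, df in samples_by_method.items()
    }
    comparison: dict[str, float] = {}
    if T0 in methods and PER_WELL in methods:
        a, b = methods[T0], methods[PER_WELL]
        if a.rejection_rate:
            comparison["rejection_rate_reduction"] = relative_reduction(
                a.rejection_rate, b.rejection_rate
            )
        if not math.isnan(a.intra_assay_cv) and a.intra_assay_cv:
            comparison["intra_assay_cv_reduction"] = relative_reduction(
                a.intra_assay_cv, b.intra_assay_cv
            )
        for cid in monitoring_ids:
            for tag, attr in (
                ("uncorrected", "interassay_cv_uncorrected"),
                ("corrected", "interassay_cv_corrected"),
            ):
                va, vb = getattr(a, attr).get(cid), getattr(b, attr).get(cid)
                if va and vb is not None:
                    comparison[f"interassay_cv_{tag}_reduction_{cid}"] = (
                        relative_reduction(va, vb)
                    )
    for m, p in methods.items():
        for cid in monitoring_ids:
            vu = p.interassay_cv_uncorrected.get(cid)
            vc = p.interassay_cv_corrected.get(cid)
            if vu and vc is not None:
                comparison[f"correction_reduction_{m}_{cid}"] = relative_reduction(vu, vc)
    return PerformanceReport(methods=methods, comparison=comparison)
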