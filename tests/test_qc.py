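"""Replicate aggregation, the >15% CV rejection rule, plate correction,
intra-/interassay CV arithmetic and the performance report."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from cecflux._util import relative_reduction, round_half_up
from cecflux.errors import DataValidationError
from cecflux.pipeline import analyze_simulated
from cecflux.qc import (
    QCConfig,
    aggregate_sample,
    compute_plate_correction,
    expected_from_run,
    interassay_cv,
    rejection_rate,
)
from cecflux.synthetic import SampleSpec, simulate_run

from conftest import make_noise_free_config

CFG = QCConfig()


class TestAggregation:
    def test_identical_replicates_not_rejected(self):
        r = aggregate_sample([10.0, 10.0, 10.0], 0.0, CFG)
        assert r.cv == 0.0 and not r.rejected

    def test_boundary_cv_15_retained_strict_rule(self):
        """(8.5, 10, 11.5): mean 10, n-1 SD 1.5, CV exactly 15% — the rule
        is strictly greater, so the sample stays."""
        r = aggregate_sample([8.5, 10.0, 11.5], 0.0, CFG)
        assert r.cv == pytest.approx(15.0)
        assert not r.rejected

    def test_cv_20_rejected(self):
        r = aggregate_sample([8.0, 10.0, 12.0], 0.0, CFG)
        assert r.sd_cec == pytest.approx(2.0)
        assert r.cv == pytest.approx(20.0)
        assert r.rejected

    def test_just_above_boundary_rejected(self):
        r = aggregate_sample([8.5, 10.0, 11.5 + 1e-6], 0.0, CFG)
        assert r.rejected

    def test_insufficient_wells(self):
        r = aggregate_sample([10.0, 11.0], 0.0, CFG)
        assert r.rejected and r.reject_reason == "insufficient wells"

    def test_mean_reported_post_passive_cv_pre_passive(self):
        r = aggregate_sample([8.0, 10.0, 12.0], 4.0, CFG)
        assert r.mean_cec == pytest.approx(6.0)
        assert r.cv == pytest.approx(20.0)  # CV on raw values, not mean-4


class TestRejectionRate:
    @pytest.mark.parametrize(
        "n_rej,n_tot,expected",
        [(68, 506, 13.44), (24, 506, 4.74), (0, 100, 0.0)],
    )
    def test_printed_rates(self, n_rej, n_tot, expected):
        assert rejection_rate(n_rej, n_tot) == expected

    def test_zero_total_undefined(self):
        with pytest.raises(DataValidationError):
            rejection_rate(0, 0)


class TestPlateCorrection:
    def test_uniform_shift_recovered_exactly(self):
        obs = {c: 9.0 for c in "ABCD"}
        exp = {c: 10.0 for c in "ABCD"}
        corr = compute_plate_correction(obs, exp, CFG, plate_id="P1")
        assert corr.factor == pytest.approx(0.9)
        assert corr.applied
        assert 9.0 / corr.factor == pytest.approx(10.0)

    def test_identity_when_observed_equals_expected(self):
        vals = {"A": 8.0, "B": 12.0, "C": 10.0, "D": 11.0}
        corr = compute_plate_correction(vals, vals, CFG)
        assert corr.factor == pytest.approx(1.0)

    def test_three_controls_accepted_with_warning(self):
        obs = {c: 9.0 for c in "ABC"}
        exp = {c: 10.0 for c in "ABCD"}
        with pytest.warns(UserWarning, match="3 controls"):
            corr = compute_plate_correction(obs, exp, CFG)
        assert corr.applied and corr.factor == pytest.approx(0.9)

    def test_fewer_than_three_leaves_plate_uncorrected(self):
        obs = {c: 9.0 for c in "AB"}
        exp = {c: 10.0 for c in "ABCD"}
        corr = compute_plate_correction(obs, exp, CFG)
        assert not corr.applied and math.isnan(corr.factor)

    def test_multiplicative_plate_effect_recovered_exactly(self):
        """Noise-free multiplicative plate biases: after correction the
        monitoring controls are flat across plates to machine precision and
        within-plate sample ratios are untouched."""
        cfg = make_noise_free_config(
            plate_effect_sd=0.25, t0_ref_cv=0.15, plate_gain_sd=0.1, rng_seed=23
        )
        design = [[SampleSpec(f"S{p}_{i}", emax_shift=1 + 0.1 * i) for i in range(4)]
                  for p in range(5)]
        an = analyze_simulated(simulate_run(cfg, design))
        for m in ("per_well", "t0"):
            df = an.samples[m]
            mon = df[df["role"] == "monitoring_control"]
            for _, grp in mon.groupby("sample_id"):
                assert interassay_cv(grp["corrected_cec"]) == pytest.approx(0.0, abs=1e-9)
            for _, grp in df.groupby("plate_id"):
                ratios_raw = grp["mean_cec"] / grp["mean_cec"].iloc[0]
                ratios_corr = grp["corrected_cec"] / grp["corrected_cec"].iloc[0]
                np.testing.assert_allclose(ratios_corr, ratios_raw, rtol=1e-12)

    def test_two_pass_expected_values(self):
        df = pd.DataFrame(
            {
                "sample_id": ["A", "A", "B", "B"],
                "plate_id": ["P1", "P2", "P1", "P2"],
                "role": "correction_control",
                "rejected": [False, False, False, True],
                "mean_cec": [9.0, 11.0, 5.0, 99.0],
            }
        )
        exp = expected_from_run(df)
        assert exp == {"A": 10.0, "B": 5.0}  # rejected plate value excluded


class TestInterassayCV:
    def test_constant_series_zero(self):
        assert interassay_cv([10.0, 10.0, 10.0]) == 0.0

    def test_n_minus_one_convention(self):
        # n-1 SD of (9, 10, 11) is 1 -> CV 10%
        assert interassay_cv([9.0, 10.0, 11.0]) == pytest.approx(10.0)

    def test_requires_two_plates(self):
        with pytest.raises(DataValidationError):
            interassay_cv([10.0])


class TestReportArithmetic:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (13.44, 4.74, 65.0),   # rejection rates
            (5.28, 4.48, 15.0),    # intra-assay CVs
            (16.74, 11.88, 29.0),  # uncorrected interassay, control 1
            (16.34, 11.55, 29.0),  # uncorrected interassay, control 2
            (13.58, 7.85, 42.0),   # corrected interassay, control 1
            (15.29, 9.86, 36.0),   # corrected interassay, control 2
            (16.74, 13.58, 19.0),  # correction gain, t0, control 1
            (16.34, 15.29, 6.0),   # correction gain, t0, control 2
            (11.88, 7.85, 34.0),   # correction gain, per-well, control 1
            (11.55, 9.86, 15.0),   # correction gain, per-well, control 2
            (10.0, 10.0, 0.0),
        ],
    )
    def test_relative_reduction_half_up(self, a, b, expected):
        assert relative_reduction(a, b) == expected

    def test_round_half_up_at_tie(self):
        assert round_half_up(14.5) == 15.0
        assert round_half_up(2.675, 2) == 2.68

    def test_report_structure_on_simulated_run(self, small_analysis):
        doc = small_analysis.report.to_dict()
        for m in ("per_well", "t0"):
            block = doc["methods"][m]
            assert block["n_total"] == 24
            assert 0 <= block["rejection_rate"] <= 100
            assert set(block["interassay_cv_uncorrected"]) == {"PC1", "PC2"}
        assert "rejection_rate_reduction" in doc["comparison"]
        # reductions recompute from the stored pairs
        a = doc["methods"]["t0"]["rejection_rate"]
        b = doc["methods"]["per_well"]["rejection_rate"]
        assert doc["comparison"]["rejection_rate_reduction"] == relative_reduction(a, b)


def test_corrected_values_follow_plate_correction_flags(small_analysis):
    """Every sample on a corrected plate gets a corrected value; plates with
    fewer than three usable controls stay uncorrected (NaN)."""
    for m, df in small_analysis.samples.items():
        applied = {c.plate_id: c.applied for c in small_analysis.corrections[m]}
        for pid, grp in df.groupby("plate_id"):
            if applied[pid]:
                assert grp["corrected_cec"].notna().all()
            else:
                assert grp["corrected_cec"].isna().all()
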