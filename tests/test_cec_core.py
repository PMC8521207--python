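"""CEC arithmetic: background subtraction, both referencing methods, passive
subtraction, resazurin ratios, gain invariance and conservation."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cecflux.cec_core import (
    BackgroundSet,
    PlateContext,
    cec_per_well,
    cec_t0,
    compute_plate_context,
    finalize_well_cec,
    normalize_to_resazurin,
    process_plate,
    resazurin_ratio,
    subtract_background,
)
from cecflux.errors import DataValidationError
from cecflux.pipeline import analyze_simulated
from cecflux.plate_io import PlateGrid, join_layout
from cecflux.synthetic import SimConfig, simulate_run, standard_study

BG = BackgroundSet(bg_sup=30.0, bg_lys=70.0, n_wells=3)


class TestBackground:
    def test_subtraction(self):
        assert subtract_background(130.0, 270.0, BG) == (100.0, 200.0, True, None)

    def test_negative_net_invalidates_not_clamps(self):
        ns, _, ok, reason = subtract_background(20.0, 270.0, BG)
        assert not ok and reason == "negative net supernatant"
        assert ns == -10.0  # value retained for inspection

    def test_missing_read_flagged(self):
        _, _, ok, reason = subtract_background(math.nan, 270.0, BG)
        assert not ok and "supernatant" in reason

    def test_too_few_unstained_wells_rejected(self):
        with pytest.raises(DataValidationError, match="3"):
            BackgroundSet(bg_sup=1.0, bg_lys=1.0, n_wells=2)


class TestPerWell:
    def test_fraction_of_total(self):
        assert cec_per_well(30.0, 70.0) == pytest.approx(30.0)
        assert cec_per_well(0.0, 50.0) == 0.0

    def test_zero_total_is_invalid(self):
        with pytest.raises(DataValidationError, match="zero total"):
            cec_per_well(0.0, 0.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        s=st.floats(0.0, 1e6),
        l=st.floats(1e-6, 1e6),
        g=st.floats(1e-6, 1e6),
    )
    def test_gain_invariance_exact(self, s, l, g):
        """Scaling both nets by any g > 0 leaves per-well CEC unchanged to
        machine precision (ratio of scaled quantities)."""
        assert cec_per_well(s * g, l * g) == pytest.approx(cec_per_well(s, l), rel=1e-12)

    def test_conservation_supernatant_plus_lysate_is_100(self):
        s, l = 37.5, 81.25
        assert cec_per_well(s, l) + cec_per_well(l, s) == pytest.approx(100.0, abs=1e-12)


class TestT0:
    CTX = PlateContext(t0_reference=100.0, t0_cv=1.0,
                       passive_cec_per_well=0.0, passive_cec_t0=0.0)

    def test_reference_fraction(self):
        v, over = cec_t0(25.0, self.CTX)
        assert v == 25.0 and not over

    def test_over_range_flagged_not_dropped(self):
        v, over = cec_t0(110.0, self.CTX)
        assert v == 110.0 and over

    def test_nonpositive_reference_fails_plate(self):
        ctx = PlateContext(t0_reference=0.0, t0_cv=0.0,
                           passive_cec_per_well=0.0, passive_cec_t0=0.0)
        with pytest.raises(DataValidationError, match="t0"):
            cec_t0(25.0, ctx)

    def test_doubling_fluorescence_doubles_t0_cec(self, noise_free_config,
                                                  single_sample_specs):
        """Noise-free simulation: doubling every stained cell's label at a
        fixed t0 reference doubles the mean t0-method CEC."""
        cfg = noise_free_config()
        run = simulate_run(cfg, [single_sample_specs])
        an = analyze_simulated(run)
        base = an.wells.loc[an.wells["role"] == "sample", "cec_raw_t0"].mean()

        grids = dict(run.grids[0])
        layout = run.layouts[0]
        sample_wells = {w for w, a in layout.wells.items() if a.role == "sample"}
        sup = grids["supernatant_fi"].values.copy()
        from cecflux.plate_io import parse_well

        for w in sample_wells:
            r, c = parse_well(w)
            sup[r, c] *= 2.0
        grids["supernatant_fi"] = PlateGrid(layout.plate_id, "supernatant_fi", sup, "optimal")
        wdf, _, _ = process_plate(join_layout(grids, layout))
        doubled = wdf.loc[wdf["role"] == "sample", "cec_raw_t0"].mean()
        assert doubled == pytest.approx(2.0 * base, rel=1e-12)


class TestPlateContext:
    def _wells(self, t0=(95.0, 100.0, 105.0), passive_sup=(4.0, 5.0, 6.0)):
        rows = []
        for i, v in enumerate(t0):
            rows.append({"plate_id": "P", "well_id": f"A{i+1}", "role": "t0_control",
                         "sample_id": None, "fi_sup_raw": v, "fi_lys_raw": 0.0})
        for i, v in enumerate(passive_sup):
            rows.append({"plate_id": "P", "well_id": f"B{i+1}", "role": "passive",
                         "sample_id": None, "fi_sup_raw": v, "fi_lys_raw": 100.0 - v})
        return pd.DataFrame(rows)

    def test_t0_reference_mean_and_cv(self):
        bg = BackgroundSet(0.0, 0.0, 3)
        ctx = compute_plate_context(self._wells(), bg)
        assert ctx.t0_reference == pytest.approx(100.0)
        # n-1 SD of (95, 100, 105) is 5 -> CV 5%
        assert ctx.t0_cv == pytest.approx(5.0)

    def test_passive_mean_per_method(self):
        bg = BackgroundSet(0.0, 0.0, 3)
        ctx = compute_plate_context(self._wells(), bg)
        # passive wells sum to 100 -> per-well raw CEC equals the sup value
        assert ctx.passive_cec_per_well == pytest.approx(5.0)
        assert ctx.passive_cec_t0 == pytest.approx(5.0)

    def test_finalize_subtracts_matching_passive(self):
        ctx = PlateContext(100.0, 0.0, passive_cec_per_well=5.0, passive_cec_t0=7.0)
        assert finalize_well_cec(30.0, ctx, "per_well") == 25.0
        assert finalize_well_cec(7.0, ctx, "t0") == 0.0
        assert finalize_well_cec(5.0, ctx, "t0") == -2.0  # negative retained


class TestResazurin:
    def test_ratio_minus_blank(self):
        assert resazurin_ratio(1.2, 0.8, 0.1).net_ratio == pytest.approx(1.4)
        assert resazurin_ratio(3.3, 3.3, 1.0).net_ratio == pytest.approx(0.0)

    def test_zero_a600_invalid(self):
        with pytest.raises(DataValidationError):
            resazurin_ratio(1.0, 0.0, 0.1)

    def test_normalization_identity_and_scaling(self):
        assert normalize_to_resazurin(20.0, 1.0, 1.0) == 20.0
        assert normalize_to_resazurin(20.0, 2.0, 1.0) == 10.0

    def test_normalization_inflates_per_well_interassay_cv(self):
        """The per-well statistic already self-references cell amount, so
        dividing by the resazurin ratio adds independent noise and raises
        the monitoring controls' interassay CV."""
        cfg = SimConfig(rng_seed=17)
        run = simulate_run(cfg, standard_study(10, 6, seed=17))
        an = analyze_simulated(run)
        w = an.wells
        mon = w[(w["role"] == "monitoring_control") & w["valid_per_well"]].copy()
        plate_mean = (
            w[w["role"] == "sample"].groupby("plate_id")["resazurin_net"].mean()
        )
        mon["norm"] = [
            normalize_to_resazurin(r.cec_per_well, r.resazurin_net,
                                   plate_mean[r.plate_id])
            for r in mon.itertuples()
        ]
        from cecflux._util import cv_percent

        cvs_plain, cvs_norm = [], []
        for _, grp in mon.groupby("sample_id"):
            by_plate = grp.groupby("plate_id")[["cec_per_well", "norm"]].mean()
            cvs_plain.append(cv_percent(by_plate["cec_per_well"]))
            cvs_norm.append(cv_percent(by_plate["norm"]))
        assert np.mean(cvs_norm) > np.mean(cvs_plain)


class TestPlateGainInvariance:
    def test_scaling_all_reads_leaves_both_methods_unchanged(self, small_run):
        """Multiplying every read on a plate by g changes neither method:
        numerators, denominators and backgrounds all scale together."""
        grids = dict(small_run.grids[0])
        layout = small_run.layouts[0]
        base, _, _ = process_plate(join_layout(grids, layout))
        g = 3.7
        scaled = {
            rt: PlateGrid(gr.plate_id, rt, gr.values * g, gr.gain_tag)
            for rt, gr in grids.items()
            if rt in ("supernatant_fi", "lysate_fi")
        }
        scaled.update({rt: gr for rt, gr in grids.items() if rt not in scaled})
        out, _, _ = process_plate(join_layout(scaled, layout))
        for col in ("cec_raw_per_well", "cec_per_well", "cec_raw_t0", "cec_t0"):
            np.testing.assert_allclose(
                out[col].to_numpy(), base[col].to_numpy(), rtol=1e-12, equal_nan=True
            )
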