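"""Synthetic 96-well plate generator emulating the CEC assay's error
structure, so every downstream stage is testable without wet-lab data.

Generative model (per well, see docs/methods.md for rationale):

* cell count ~ mean-one lognormal around ``seed_cells`` x a deliberate
  seeding multiplier (lognormal keeps counts positive at high CV);
* total labelled fluorescence = ``stain_per_cell`` x cells x stain noise;
* efflux fraction = passive + plate_effect x shift x (emax/100) x
  A / (km * (cells/seed_cells) + A), an acceptor-saturation (Michaelis-
  Menten-type) term in which the half-saturation point scales with the
  relative cell number — the acceptor:cell ratio, not the cell number
  itself, drives the per-well bias direction;
* supernatant read  = gain x f x total x noise + background
  lysate read       = gain x (1-f) x total x (1-lysis_residual) x noise + background
  t0-control read   = gain x t0_factor x total x (1-lysis_residual) x noise + background
* resazurin 570/600 ratio = blank + ``resazurin_per_cell`` x live cells,
  realised through a constant-A600 / proportional-A570 pair of absorbance
  grids.

Two heavy-tailed handling-error processes make replicate QC meaningful: a
*well* disturbance (cell-layer loss in a wash) that rescales the well's
total label and so cancels in the per-well method but not in the t0 method,
and a *read* disturbance (droplet/smear on one measurement) that hits both.

One global RNG stream; the draw order is fixed per plate (gain, plate
effect, t0 factor, then eleven length-96 vectors: seeding, stain, well
outlier u/z, sup noise, sup outlier u/z, lys noise, lys outlier u/z,
A570, A600) and is independent of parameter values, so the same
``rng_seed`` gives bit-identical output for a given configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import lognormal_factor
from .errors import ConfigError, LayoutError
from .plate_io import (
    N_COLS,
    N_ROWS,
    PlateGrid,
    PlateLayout,
    WellAssignment,
    parse_well,
    well_name,
    write_layout,
    write_manifest,
    write_plate_grid,
)

__all__ = [
    "SampleSpec",
    "SimConfig",
    "SimulatedRun",
    "build_plate_layout",
    "simulate_run",
    "standard_study",
    "varied_seeding_design",
    "acceptor_sweep",
    "camp_design",
    "write_run",
    "DEFAULT_CORRECTION_CONTROLS",
    "DEFAULT_MONITORING_CONTROLS",
]


@dataclass(frozen=True)
class SampleSpec:
    """One serum to be plated in replicate wells.

    ``emax_shift`` scales the saturating efflux of this serum relative to
    the run default (between-donor heterogeneity); ``seed_multiplier``
    deliberately over-/under-seeds this sample's wells (1.0 = the standard
    7e4 cells/well); ``condition`` toggles cAMP pre-treatment of the cells.
    """

    sample_id: str
    emax_shift: float = 1.0
    acceptor_pct: float = 2.0
    condition: str = "cAMP"
    seed_multiplier: float = 1.0


#: four sera run on every plate for plate-to-plate correction
DEFAULT_CORRECTION_CONTROLS = (
    SampleSpec("QC1", 0.90),
    SampleSpec("QC2", 1.00),
    SampleSpec("QC3", 1.05),
    SampleSpec("QC4", 1.10),
)

#: two sera, disjoint from the correction set, for interassay CV monitoring
DEFAULT_MONITORING_CONTROLS = (
    SampleSpec("PC1", 0.95),
    SampleSpec("PC2", 1.05),
)


@dataclass
class SimConfig:
    """Simulator parameters. Units in comments; fractions are 0-1.

    The defaults describe a routine high-throughput run: 7e4 cells/well,
    ~3% seeding CV, 2% apoB-depleted serum acceptor, cholic-acid lysis
    (2.4% residual label), ~3.5% per-read measurement noise and ~10%
    plate-level biases. See docs/methods.md for how each was chosen.
    """

    n_plates: int = 1
    wells_per_sample: int = 3
    seed_cells: float = 7e4            # cells/well
    seeding_cv: float = 0.03           # fraction; 0.30 mimics a gross seeding error
    stain_per_cell: float = 0.01       # fluorescence units per labelled cell
    stain_cv: float = 0.02             # staining-efficiency noise
    efflux_emax: float = 18.0          # %CEC at acceptor saturation (cAMP cells)
    efflux_km: float = 1.0             # % apoB-depleted serum at half-saturation
    passive_frac: float = 0.04         # fraction released without acceptor
    lysis_residual: float = 0.024      # label not recovered by lysis (cholic acid)
    no_camp_efflux_frac: float = 0.35  # active-efflux fraction without cAMP
    plate_gain_sd: float = 0.10        # per-plate optical gain (cancels in CEC)
    plate_effect_sd: float = 0.10      # per-plate bias on active efflux
    t0_ref_cv: float = 0.08            # per-plate error of the t0 reference wells
    meas_cv: float = 0.035             # per-read multiplicative noise
    background_level: float = 30.0     # fluorescence units (unstained wells)
    resazurin_per_cell: float = 2e-5   # 570/600 ratio units per live cell
    resazurin_blank: float = 0.75      # no-cell 570/600 ratio
    a600_base: float = 0.40            # reference-wavelength absorbance
    well_outlier_rate: float = 0.04    # cell-layer disturbances per well
    well_outlier_sd: float = 0.35      # size (lognormal sigma-scale cv)
    read_outlier_rate: float = 0.015   # per single fluorescence read
    read_outlier_sd: float = 0.20
    rng_seed: int = 0

    def __post_init__(self) -> None:
        fractions = {
            "seeding_cv": self.seeding_cv,
            "stain_cv": self.stain_cv,
            "passive_frac": self.passive_frac,
            "lysis_residual": self.lysis_residual,
            "plate_gain_sd": self.plate_gain_sd,
            "plate_effect_sd": self.plate_effect_sd,
            "t0_ref_cv": self.t0_ref_cv,
            "meas_cv": self.meas_cv,
            "well_outlier_rate": self.well_outlier_rate,
            "well_outlier_sd": self.well_outlier_sd,
            "read_outlier_rate": self.read_outlier_rate,
            "read_outlier_sd": self.read_outlier_sd,
            "no_camp_efflux_frac": self.no_camp_efflux_frac,
        }
        for name, v in fractions.items():
            if not 0 <= v < 1:
                raise ConfigError(f"{name} must be in [0, 1), got {v}")
        positives = {
            "seed_cells": self.seed_cells,
            "stain_per_cell": self.stain_per_cell,
            "efflux_emax": self.efflux_emax,
            "efflux_km": self.efflux_km,
            "resazurin_per_cell": self.resazurin_per_cell,
            "resazurin_blank": self.resazurin_blank,
            "a600_base": self.a600_base,
        }
        for name, v in positives.items():
            if not v > 0:
                raise ConfigError(f"{name} must be > 0, got {v}")
        if self.background_level < 0:
            raise ConfigError("background_level must be >= 0")
        if self.efflux_emax + 100.0 * self.passive_frac > 100.0:
            raise ConfigError(
                "efflux_emax + passive contribution must not exceed 100% CEC"
            )


@dataclass
class SimulatedRun:
    """Output of :func:`simulate_run`: per-plate grids and layouts plus the
    ground-truth table used by recovery tests."""

    config: SimConfig
    grids: list[dict[str, PlateGrid]]
    layouts: list[PlateLayout]
    truth: pd.DataFrame
    plate_effects: pd.DataFrame  # plate_id, gain, efflux_effect, t0_factor


# ---------------------------------------------------------------------------
# Layout construction

_T0_WELLS = ("A1", "A2", "A3")
_PASSIVE_WELLS = ("A4", "A5", "A6")
_UNSTAINED_WELLS = ("A7", "A8", "A9")
_BLANK_WELLS = ("A10", "A11")
_FIRST_SAMPLE_WELL_NO_CORRECTION = "B1"


def build_plate_layout(
    plate_id: str,
    samples: list[SampleSpec],
    correction_controls: tuple[SampleSpec, ...] = DEFAULT_CORRECTION_CONTROLS,
    monitoring_controls: tuple[SampleSpec, ...] = DEFAULT_MONITORING_CONTROLS,
    wells_per_sample: int = 3,
) -> PlateLayout:
    """Standard plate map: row A holds the t0 / passive / unstained / blank
    controls, then correction controls, monitoring controls, and study
    samples in consecutive triplicates; leftover wells are ``empty``.

    Capacity with the default controls is 22 study samples per plate.
    """
    wells: dict[str, WellAssignment] = {}
    for w in _T0_WELLS:
        wells[w] = WellAssignment(role="t0_control")
    for w in _PASSIVE_WELLS:
        wells[w] = WellAssignment(role="passive")
    for w in _UNSTAINED_WELLS:
        wells[w] = WellAssignment(role="unstained_background")
    for w in _BLANK_WELLS:
        wells[w] = WellAssignment(role="no_cell_blank")
    wells["A12"] = WellAssignment(role="empty")

    free = [
        well_name(r, c)
        for r in range(1, N_ROWS)
        for c in range(N_COLS)
    ]

    def take(n: int) -> list[str]:
        if len(free) < n:
            raise LayoutError(
                f"plate {plate_id}: layout capacity exceeded "
                f"({len(samples)} samples do not fit)"
            )
        picked, free[:n] = free[:n], []
        return picked

    for role, specs in (
        ("correction_control", correction_controls),
        ("monitoring_control", monitoring_controls),
        ("sample", tuple(samples)),
    ):
        for spec in specs:
            for rep, w in enumerate(take(wells_per_sample), start=1):
                wells[w] = WellAssignment(
                    role=role,
                    sample_id=spec.sample_id,
                    replicate=rep,
                    condition=spec.condition,
                    acceptor_pct=spec.acceptor_pct,
                )
    for w in free:
        wells[w] = WellAssignment(role="empty")
    return PlateLayout(plate_id=plate_id, wells=wells, wells_per_sample=wells_per_sample)


# ---------------------------------------------------------------------------
# Simulation


def simulate_run(
    config: SimConfig,
    plates_samples: list[list[SampleSpec]] | None = None,
    correction_controls: tuple[SampleSpec, ...] = DEFAULT_CORRECTION_CONTROLS,
    monitoring_controls: tuple[SampleSpec, ...] = DEFAULT_MONITORING_CONTROLS,
    layouts: list[PlateLayout] | None = None,
) -> SimulatedRun:
    """Simulate a multi-plate run.

    ``plates_samples`` lists the study samples of each plate (defaults to
    ``config.n_plates`` empty plates carrying only controls). Custom
    ``layouts`` override the standard builder, in which case every
    sample-bearing well's identity must resolve to one of the given specs.
    """
    if plates_samples is None:
        plates_samples = [[] for _ in range(config.n_plates)]
    spec_map: dict[str, SampleSpec] = {}
    for spec in list(correction_controls) + list(monitoring_controls):
        spec_map[spec.sample_id] = spec
    for plate in plates_samples:
        for spec in plate:
            if spec.sample_id in spec_map and spec_map[spec.sample_id] != spec:
                raise ConfigError(f"conflicting specs for sample {spec.sample_id!r}")
            spec_map[spec.sample_id] = spec

    if layouts is None:
        layouts = [
            build_plate_layout(
                f"P{i + 1}", samples, correction_controls, monitoring_controls,
                wells_per_sample=config.wells_per_sample,
            )
            for i, samples in enumerate(plates_samples)
        ]
    for layout in layouts:
        layout.validate(correction_enabled=len(correction_controls) == 4)
        if len(layout.role_wells("no_cell_blank")) < 1:
            raise LayoutError(f"plate {layout.plate_id}: role 'no_cell_blank' requires >=1 well")
        if len(layout.role_wells("monitoring_control")) < 2:
            raise LayoutError(
                f"plate {layout.plate_id}: role 'monitoring_control' requires >=2 wells"
            )

    rng = np.random.default_rng(config.rng_seed)
    grids, truth_rows, effect_rows = [], [], []
    for layout in layouts:
        g, t, e = _simulate_plate(config, layout, spec_map, rng)
        grids.append(g)
        truth_rows.extend(t)
        effect_rows.append(e)
    return SimulatedRun(
        config=config,
        grids=grids,
        layouts=layouts,
        truth=pd.DataFrame(truth_rows),
        plate_effects=pd.DataFrame(effect_rows),
    )


def _simulate_plate(
    cfg: SimConfig,
    layout: PlateLayout,
    spec_map: dict[str, SampleSpec],
    rng: np.random.Generator,
) -> tuple[dict[str, PlateGrid], list[dict], dict]:
    # plate-level factors (draw order is part of the file contract)
    gain = float(lognormal_factor(rng.standard_normal(1), cfg.plate_gain_sd)[0])
    effect = float(lognormal_factor(rng.standard_normal(1), cfg.plate_effect_sd)[0])
    t0_factor = float(lognormal_factor(rng.standard_normal(1), cfg.t0_ref_cv)[0])

    names = [well_name(r, c) for r in range(N_ROWS) for c in range(N_COLS)]
    nw = len(names)
    z_seed = rng.standard_normal(nw)
    z_stain = rng.standard_normal(nw)
    u_well = rng.random(nw)
    z_well = rng.standard_normal(nw)
    z_sup = rng.standard_normal(nw)
    u_sup_out = rng.random(nw)
    z_sup_out = rng.standard_normal(nw)
    z_lys = rng.standard_normal(nw)
    u_lys_out = rng.random(nw)
    z_lys_out = rng.standard_normal(nw)
    z_a570 = rng.standard_normal(nw)
    z_a600 = rng.standard_normal(nw)
    z_bg_sup = rng.standard_normal(nw)
    z_bg_lys = rng.standard_normal(nw)

    seed_noise = lognormal_factor(z_seed, cfg.seeding_cv)
    stain_noise = lognormal_factor(z_stain, cfg.stain_cv)
    well_mult = np.where(
        u_well < cfg.well_outlier_rate,
        lognormal_factor(z_well, cfg.well_outlier_sd),
        1.0,
    )
    sup_noise = lognormal_factor(z_sup, cfg.meas_cv) * np.where(
        u_sup_out < cfg.read_outlier_rate,
        lognormal_factor(z_sup_out, cfg.read_outlier_sd),
        1.0,
    )
    lys_noise = lognormal_factor(z_lys, cfg.meas_cv) * np.where(
        u_lys_out < cfg.read_outlier_rate,
        lognormal_factor(z_lys_out, cfg.read_outlier_sd),
        1.0,
    )
    a570_noise = lognormal_factor(z_a570, cfg.meas_cv)
    a600_noise = lognormal_factor(z_a600, cfg.meas_cv)
    bg_sup = cfg.background_level * lognormal_factor(z_bg_sup, cfg.meas_cv)
    bg_lys = cfg.background_level * lognormal_factor(z_bg_lys, cfg.meas_cv)

    sup = np.full((N_ROWS, N_COLS), np.nan)
    lys = np.full((N_ROWS, N_COLS), np.nan)
    a570 = np.full((N_ROWS, N_COLS), np.nan)
    a600 = np.full((N_ROWS, N_COLS), np.nan)
    truth_rows = []

    for i, w in enumerate(names):
        assign = layout.wells.get(w)
        if assign is None or assign.role == "empty":
            continue
        r, c = parse_well(w)
        role = assign.role
        has_cells = role in (
            "sample", "correction_control", "monitoring_control",
            "t0_control", "passive", "unstained_background",
        )
        mult = 1.0
        shift = 1.0
        camp = 1.0
        acceptor = assign.acceptor_pct
        if assign.sample_id is not None:
            spec = spec_map.get(assign.sample_id)
            if spec is None:
                raise ConfigError(f"no SampleSpec for sample {assign.sample_id!r}")
            mult, shift = spec.seed_multiplier, spec.emax_shift
            camp = 1.0 if spec.condition == "cAMP" else cfg.no_camp_efflux_frac
            acceptor = spec.acceptor_pct

        cells = cfg.seed_cells * mult * seed_noise[i] if has_cells else 0.0
        cells_eff = cells * well_mult[i]
        stained = has_cells and role != "unstained_background"
        total = cfg.stain_per_cell * cells_eff * stain_noise[i] if stained else 0.0

        if role == "t0_control":
            f = 0.0
            sup_sig = t0_factor * total * (1.0 - cfg.lysis_residual)
            lys_sig = 0.0
            live = 0.0  # lysed at time zero
        elif role == "passive":
            f = cfg.passive_frac
            sup_sig = f * total
            lys_sig = (1.0 - f) * total * (1.0 - cfg.lysis_residual)
            live = cells_eff
        else:
            f = cfg.passive_frac
            if role in ("sample", "correction_control", "monitoring_control"):
                rel_cells = cells_eff / cfg.seed_cells
                sat = acceptor / (cfg.efflux_km * rel_cells + acceptor)
                f = min(cfg.passive_frac + effect * shift * camp
                        * (cfg.efflux_emax / 100.0) * sat, 0.99)
            sup_sig = f * total
            lys_sig = (1.0 - f) * total * (1.0 - cfg.lysis_residual)
            live = cells_eff

        sup[r, c] = gain * sup_sig * sup_noise[i] + bg_sup[i]
        lys[r, c] = gain * lys_sig * lys_noise[i] + bg_lys[i]
        ratio_signal = cfg.resazurin_blank + cfg.resazurin_per_cell * live
        a600[r, c] = cfg.a600_base * a600_noise[i]
        a570[r, c] = a600[r, c] * ratio_signal * a570_noise[i]

        truth_rows.append(
            {
                "plate_id": layout.plate_id,
                "well_id": w,
                "role": role,
                "sample_id": assign.sample_id,
                "cell_count": cells_eff,
                "total_fluorescence": total,
                "efflux_fraction": f if stained else math.nan,
            }
        )

    grids = {
        "supernatant_fi": PlateGrid(layout.plate_id, "supernatant_fi", sup, gain_tag="optimal"),
        "lysate_fi": PlateGrid(layout.plate_id, "lysate_fi", lys, gain_tag="optimal"),
        "absorbance_570": PlateGrid(layout.plate_id, "absorbance_570", a570),
        "absorbance_600": PlateGrid(layout.plate_id, "absorbance_600", a600),
    }
    effects = {
        "plate_id": layout.plate_id,
        "gain": gain,
        "efflux_effect": effect,
        "t0_factor": t0_factor,
    }
    return grids, truth_rows, effects


# ---------------------------------------------------------------------------
# Study designs


def standard_study(
    n_plates: int,
    samples_per_plate: int,
    sample_cv: float = 0.15,
    seed: int | None = None,
) -> list[list[SampleSpec]]:
    """Unique study sera, ``samples_per_plate`` per plate, with lognormal
    between-donor spread of the saturating efflux (CV ``sample_cv``)."""
    rng = np.random.default_rng(seed)
    plates = []
    for p in range(n_plates):
        shifts = lognormal_factor(rng.standard_normal(samples_per_plate), sample_cv)
        plates.append(
            [
                SampleSpec(f"S{p + 1:02d}_{i + 1:02d}", emax_shift=float(shifts[i]))
                for i in range(samples_per_plate)
            ]
        )
    return plates


def varied_seeding_design(
    n_sera: int = 5,
    multipliers: tuple[float, ...] = (0.5, 0.75, 1.0, 1.5),
) -> list[SampleSpec]:
    """Deliberate seeding-error experiment: each serum plated at several
    multiples of the standard cell amount (one triplicate slot per serum x
    multiplier; slot ids are ``S<i>@<multiplier>``)."""
    return [
        SampleSpec(f"S{i + 1}@{m:g}", seed_multiplier=m)
        for i in range(n_sera)
        for m in multipliers
    ]


def acceptor_sweep(
    levels: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0, 4.0),
    sample_id: str = "S1",
) -> list[SampleSpec]:
    """One serum titrated over acceptor concentrations (slot per level)."""
    return [
        SampleSpec(f"{sample_id}@A{a:g}", acceptor_pct=a) for a in levels
    ]


def camp_design(n_sera: int = 5) -> list[SampleSpec]:
    """Each serum measured on cAMP-treated and untreated cells."""
    out = []
    for i in range(n_sera):
        out.append(SampleSpec(f"S{i + 1}+cAMP", condition="cAMP"))
        out.append(SampleSpec(f"S{i + 1}-cAMP", condition="no_cAMP"))
    return out


# ---------------------------------------------------------------------------
# File output


def write_run(run: SimulatedRun, outdir: str | Path) -> Path:
    """Write grids, layouts, a run manifest and the truth table; returns the
    manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for layout, grids in zip(run.layouts, run.grids):
        pid = layout.plate_id
        layout_path = outdir / f"{pid}_layout.yaml"
        write_layout(layout, layout_path)
        reads = {}
        for rt, grid in grids.items():
            p = outdir / f"{pid}_{rt}.csv"
            write_plate_grid(grid, p)
            reads[rt] = p
        entries.append({"layout": layout_path, "reads": reads})
    manifest = outdir / "manifest.yaml"
    write_manifest(entries, manifest)
    run.truth.to_csv(outdir / "truth.csv", index=False)
    return manifest
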