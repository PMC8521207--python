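"""Pre-packaged in-silico experiments at the assay's standard conditions.

Each function simulates one of the canonical study designs with the default
:class:`~cecflux.synthetic.SimConfig` conditions, runs the full analysis
pipeline on the simulated plates, and returns the summary quantities. A
single integer seed controls all randomness; derived child seeds stay below
2**31. Problem sizes (see docs/methods.md): the method-comparison study uses
25 plates of 22 study sera; the repeat-measurement experiment 28 sera
measured on two occasions; the deliberate seeding-error design 5 sera at
4 cell amounts in triplicate.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .cec_core import PER_WELL, T0
from .pipeline import RunAnalysis, analyze_simulated
from .stats import (
    BlandAltman,
    GroupContrast,
    SaturationFit,
    SeedingBiasFit,
    bland_altman,
    camp_contrast,
    fit_saturation,
    seeding_bias,
)
from .synthetic import (
    SampleSpec,
    SimConfig,
    acceptor_sweep,
    build_plate_layout,
    camp_design,
    simulate_run,
    standard_study,
    varied_seeding_design,
)

MONITORING = ("PC1", "PC2")


def _child_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31))


def run_method_comparison_study(
    seed: int = 0,
    n_plates: int = 25,
    samples_per_plate: int = 22,
    config: SimConfig | None = None,
) -> tuple[dict, RunAnalysis]:
    """Multi-plate study comparing the two referencing methods.

    Returns (metrics, analysis); metrics hold per-method rejection rates,
    intra-assay CVs, and the monitoring controls' interassay CVs before and
    after plate correction (also averaged over the two controls).
    """
    cfg = config or SimConfig()
    cfg = replace(cfg, rng_seed=_child_seed(seed, 1))
    design = standard_study(n_plates, samples_per_plate, seed=_child_seed(seed, 2))
    analysis = analyze_simulated(simulate_run(cfg, design))
    doc = analysis.report.to_dict()["methods"]
    metrics: dict = {"n_samples": n_plates * samples_per_plate}
    for m in (T0, PER_WELL):
        blk = doc[m]
        metrics[f"rejection_rate_{m}"] = blk["rejection_rate"]
        metrics[f"intra_cv_{m}"] = blk["intra_assay_cv"]
        unc = blk["interassay_cv_uncorrected"]
        cor = blk["interassay_cv_corrected"]
        metrics[f"interassay_uncorrected_{m}"] = {c: unc[c] for c in MONITORING}
        metrics[f"interassay_corrected_{m}"] = {c: cor[c] for c in MONITORING}
        metrics[f"interassay_uncorrected_mean_{m}"] = float(
            np.mean([unc[c] for c in MONITORING])
        )
        metrics[f"interassay_corrected_mean_{m}"] = float(
            np.mean([cor[c] for c in MONITORING])
        )
    return metrics, analysis


def run_repeat_measurement_experiment(
    seed: int = 0,
    n_samples: int = 28,
    day_effect: float = 0.8,
    config: SimConfig | None = None,
) -> dict[str, dict[str, BlandAltman]]:
    """The same sera measured on two occasions, with a systematic day/batch
    drift (the second occasion's active efflux scaled by ``day_effect``).

    Returns, per method, Bland-Altman results on the paired sample means
    before ("uncorrected") and after ("corrected") plate correction. The
    correction factors are computed within the pooled four-plate run, so a
    real between-day shift is what they must absorb.
    """
    cfg = config or SimConfig()
    half = (n_samples + 1) // 2
    rng = np.random.default_rng(_child_seed(seed, 3))
    shifts = np.exp(rng.normal(0, 0.15, n_samples) - 0.5 * 0.15**2)
    samples = [
        SampleSpec(f"R{i + 1:02d}", emax_shift=float(shifts[i]))
        for i in range(n_samples)
    ]
    plates_1 = [samples[:half], samples[half:]]

    run1 = simulate_run(
        replace(cfg, rng_seed=_child_seed(seed, 4)), plates_1
    )
    cfg2 = replace(
        cfg,
        efflux_emax=cfg.efflux_emax * day_effect,
        rng_seed=_child_seed(seed, 5),
    )
    layouts_2 = [
        build_plate_layout("P3", plates_1[0]),
        build_plate_layout("P4", plates_1[1]),
    ]
    run2 = simulate_run(cfg2, plates_1, layouts=layouts_2)

    entries = [
        {"layout": lo, "grids": gr}
        for lo, gr in zip(run1.layouts + run2.layouts, run1.grids + run2.grids)
    ]
    from .pipeline import analyze_plates

    analysis = analyze_plates(entries)
    first_plates = {"P1", "P2"}
    out: dict[str, dict[str, BlandAltman]] = {}
    for m in (T0, PER_WELL):
        df = analysis.samples[m]
        df = df[(df["role"] == "sample") & (~df["rejected"])]
        occ1 = df[df["plate_id"].isin(first_plates)].set_index("sample_id")
        occ2 = df[~df["plate_id"].isin(first_plates)].set_index("sample_id")
        common = occ1.index.intersection(occ2.index)
        out[m] = {
            "uncorrected": bland_altman(
                occ1.loc[common, "mean_cec"], occ2.loc[common, "mean_cec"]
            ),
            "corrected": bland_altman(
                occ1.loc[common, "corrected_cec"], occ2.loc[common, "corrected_cec"]
            ),
        }
    return out


def run_seeding_bias_experiment(
    seed: int = 0,
    config: SimConfig | None = None,
) -> dict[str, SeedingBiasFit]:
    """Deliberate seeding-error design: 5 sera at 0.5/0.75/1/1.5 times the
    standard cell amount, triplicates, one plate; regression of each
    method's per-well CEC on the z-scored resazurin ratio with per-serum
    intercepts."""
    cfg = config or SimConfig()
    cfg = replace(cfg, rng_seed=_child_seed(seed, 6))
    run = simulate_run(cfg, [varied_seeding_design()])
    analysis = analyze_simulated(run)
    w = analysis.wells[analysis.wells["role"] == "sample"].copy()
    serum = w["sample_id"].str.split("@").str[0]
    return {
        m: seeding_bias(w[f"cec_{m}"], w["resazurin_net"], serum)
        for m in (T0, PER_WELL)
    }


def run_saturation_experiment(
    seed: int = 0,
    levels: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0, 4.0),
    config: SimConfig | None = None,
) -> tuple[SaturationFit, pd.DataFrame]:
    """Acceptor titration of one serum; Michaelis-Menten fit of the mean
    per-well CEC per acceptor level."""
    cfg = config or SimConfig()
    cfg = replace(cfg, rng_seed=_child_seed(seed, 7))
    run = simulate_run(cfg, [acceptor_sweep(levels)])
    analysis = analyze_simulated(run)
    df = analysis.samples[PER_WELL]
    df = df[(df["role"] == "sample") & (~df["rejected"])].copy()
    df["acceptor_pct"] = df["sample_id"].str.split("@A").str[1].astype(float)
    means = df.groupby("acceptor_pct")["mean_cec"].mean().reset_index()
    fit = fit_saturation(means["acceptor_pct"], means["mean_cec"])
    return fit, means


def run_camp_experiment(
    seed: int = 0,
    n_sera: int = 5,
    config: SimConfig | None = None,
) -> GroupContrast:
    """cAMP-treated vs untreated cells for the same sera (per-well CEC)."""
    cfg = config or SimConfig()
    cfg = replace(cfg, rng_seed=_child_seed(seed, 8))
    run = simulate_run(cfg, [camp_design(n_sera)])
    analysis = analyze_simulated(run)
    df = analysis.samples[PER_WELL]
    df = df[df["role"] == "sample"]
    camp = df[df["sample_id"].str.endswith("+cAMP")]["mean_cec"]
    no = df[df["sample_id"].str.endswith("-cAMP")]["mean_cec"]
    return camp_contrast(camp, no)


def run_lysis_residual_comparison(
    seed: int = 0,
    residuals: tuple[float, float] = (0.024, 0.061),
    config: SimConfig | None = None,
) -> dict[float, float]:
    """Mean per-well CEC of the same sera under two lysis-residual levels
    (cholic acid vs sodium hydroxide); matched seeds isolate the reagent
    effect."""
    cfg = config or SimConfig()
    out = {}
    for r in residuals:
        c = replace(cfg, lysis_residual=r, rng_seed=_child_seed(seed, 9))
        run = simulate_run(c, [[SampleSpec(f"S{i + 1}") for i in range(5)]])
        analysis = analyze_simulated(run)
        df = analysis.samples[PER_WELL]
        out[r] = float(df[df["role"] == "sample"]["mean_cec"].mean())
    return out
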