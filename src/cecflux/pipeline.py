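"""End-to-end orchestration: parse -> compute -> QC -> correction -> report.

``analyze_plates`` is the library entry point working on in-memory grids and
layouts; ``run_pipeline`` wraps it with manifest/file handling and writes the
tidy outputs plus ``report.json``.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cec_core import METHODS, PER_WELL, T0, process_plate
from .errors import ConfigError
from .plate_io import PlateGrid, PlateLayout, join_layout, load_manifest
from .qc import (
    PerformanceReport,
    PlateCorrection,
    QCConfig,
    apply_corrections,
    aggregate_run,
    performance_report,
)


@dataclass
class RunConfig:
    """Pipeline configuration (YAML-loadable via :meth:`from_dict`)."""

    manifest: str
    methods: tuple[str, ...] = METHODS
    qc: QCConfig = field(default_factory=QCConfig)
    out_dir: str = "cecflux_out"
    log_level: str = "INFO"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        bad = [m for m in self.methods if m not in METHODS]
        if bad or not self.methods:
            raise ConfigError(f"methods must be a non-empty subset of {METHODS}, got {self.methods}")

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        qc_doc = doc.get("qc", {})
        methods = doc.get("methods", list(METHODS))
        if isinstance(methods, str):
            methods = [methods]
        return cls(
            manifest=doc["manifest"],
            methods=tuple(methods),
            qc=QCConfig(**qc_doc),
            out_dir=doc.get("out_dir", "cecflux_out"),
            log_level=doc.get("log_level", "INFO"),
            rng_seed=int(doc.get("rng_seed", 0)),
        )


@dataclass
class RunAnalysis:
    """All per-stage artifacts of one analysed run."""

    wells: pd.DataFrame
    samples: dict[str, pd.DataFrame]
    corrections: dict[str, list[PlateCorrection]]
    report: PerformanceReport
    monitoring_ids: tuple[str, ...]


def analyze_plates(
    plates: list[dict],
    qc_cfg: QCConfig | None = None,
    methods: tuple[str, ...] = METHODS,
) -> RunAnalysis:
    """Analyse a run given ``[{"layout": PlateLayout, "grids": {...}}, ...]``
    (the structure returned by :func:`cecflux.plate_io.load_manifest` and by
    zipping a :class:`~cecflux.synthetic.SimulatedRun`)."""
    qc_cfg = qc_cfg or QCConfig()
    well_frames = []
    passive: dict[str, dict[str, float]] = {m: {} for m in methods}
    for entry in plates:
        layout: PlateLayout = entry["layout"]
        grids = entry["grids"]
        wdf = join_layout(grids, layout, methods=methods)
        wdf, ctx, _ = process_plate(wdf, methods=methods)
        if PER_WELL in methods:
            passive[PER_WELL][layout.plate_id] = ctx.passive_cec_per_well
        if T0 in methods:
            passive[T0][layout.plate_id] = ctx.passive_cec_t0
        well_frames.append(wdf)
    wells = pd.concat(well_frames, ignore_index=True)

    monitoring_ids = tuple(
        sorted(wells.loc[wells["role"] == "monitoring_control", "sample_id"].dropna().unique())
    )
    samples: dict[str, pd.DataFrame] = {}
    corrections: dict[str, list[PlateCorrection]] = {}
    for m in methods:
        agg = aggregate_run(wells, qc_cfg, m, passive[m])
        if qc_cfg.correction_enabled:
            agg, corrs = apply_corrections(agg, qc_cfg, m)
        else:
            corrs = []
        samples[m] = agg
        corrections[m] = corrs
    report = performance_report(samples, monitoring_ids)
    return RunAnalysis(
        wells=wells,
        samples=samples,
        corrections=corrections,
        report=report,
        monitoring_ids=monitoring_ids,
    )


def analyze_simulated(run, qc_cfg: QCConfig | None = None,
                      methods: tuple[str, ...] = METHODS) -> RunAnalysis:
    """Convenience: analyse a :class:`~cecflux.synthetic.SimulatedRun`
    directly, without a file round-trip."""
    plates = [
        {"layout": layout, "grids": grids}
        for layout, grids in zip(run.layouts, run.grids)
    ]
    return analyze_plates(plates, qc_cfg=qc_cfg, methods=methods)


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(
        {"manifest": cfg.manifest, "methods": list(cfg.methods), "qc": asdict(cfg.qc),
         "rng_seed": cfg.rng_seed},
        sort_keys=True,
    ).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _clean(obj):
    """Make report values JSON-serialisable (NaN -> None, numpy -> python)."""
    if isinstance(obj, dict):
        return {str(k): _clean(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_clean(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return None if math.isnan(float(obj)) else float(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def run_pipeline(cfg: RunConfig) -> RunAnalysis:
    """Run the full pipeline from a manifest and write artifacts to
    ``cfg.out_dir``: wells.csv, samples_<method>.csv, plates_<method>.csv,
    report.json. Deterministic for a given manifest and configuration; the
    only run-dependent report field is the timestamp."""
    manifest = Path(cfg.manifest)
    if not manifest.exists():
        raise ConfigError(f"manifest not found: {manifest}")
    plates = load_manifest(manifest)
    analysis = analyze_plates(plates, qc_cfg=cfg.qc, methods=cfg.methods)

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    analysis.wells.to_csv(out / "wells.csv", index=False)
    for m, df in analysis.samples.items():
        df.to_csv(out / f"samples_{m}.csv", index=False)
        rows = []
        for corr in analysis.corrections[m]:
            rows.append(
                {
                    "plate_id": corr.plate_id,
                    "method": corr.method,
                    "n_controls": len(corr.control_ids),
                    "factor": corr.factor,
                    "applied": corr.applied,
                    "note": corr.note,
                }
            )
        pd.DataFrame(rows).to_csv(out / f"plates_{m}.csv", index=False)

    report_doc = {
        "schema_version": 1,
        "cecflux_version": __version__,
        "config_hash": _config_hash(cfg),
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "counts": {
            "n_plates": len(plates),
            "n_wells": int(len(analysis.wells)),
            "n_samples": {
                m: int((df["role"] == "sample").sum())
                for m, df in analysis.samples.items()
            },
        },
        "monitoring_controls": list(analysis.monitoring_ids),
        "performance": analysis.report.to_dict(),
    }
    tmp = out / "report.json.tmp"
    with open(tmp, "w") as fh:
        json.dump(_clean(report_doc), fh, indent=2, sort_keys=True)
        fh.write("\n")
    tmp.replace(out / "report.json")
    return analysis
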