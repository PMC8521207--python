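"""Reading and writing 96-well plate-reader exports and layout maps.

File dialects
-------------
**Grid CSV** (one plate, one read type). Four header-ish lines then the grid::

    plate_id,read_type,gain_tag
    P1,supernatant_fi,optimal
    ,1,2,...,12
    A,1023.5,988.1,...
    ...
    H,...

Values are written with Python's shortest round-trip ``repr`` so that
``read(write(grid)) == grid`` bit-exactly; empty cells are missing wells
(missing is *not* zero — zero is a valid fluorescence).

**Layout YAML**: a mapping with ``plate_id``, ``wells_per_sample`` and a
``wells`` map from well name ("A1".."H12") to role plus, for sample-bearing
wells, ``sample_id``, ``replicate``, ``condition`` and ``acceptor_pct``
(percent apoB-depleted serum, default 2). A long-format CSV with columns
``plate_id,well,role,sample_id,replicate,condition,acceptor_pct`` is accepted
as an alternative.

**Run manifest YAML**: ``plates:`` list of entries, each with ``layout:`` and
a ``reads:`` map from read type to grid-CSV path (relative to the manifest).
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, LayoutError, PlateParseError

ROW_LABELS = "ABCDEFGH"
N_ROWS = 8
N_COLS = 12

READ_TYPES = (
    "supernatant_fi",
    "lysate_fi",
    "t0_fi",
    "absorbance_570",
    "absorbance_600",
)

ROLES = (
    "sample",
    "t0_control",
    "passive",
    "unstained_background",
    "no_cell_blank",
    "correction_control",
    "monitoring_control",
    "empty",
)

CONDITIONS = ("cAMP", "no_cAMP")

#: roles whose wells carry a sample/control identity and receive acceptor
SAMPLE_BEARING_ROLES = ("sample", "correction_control", "monitoring_control")

#: map read type -> tidy well-table column
READ_COLUMNS = {
    "supernatant_fi": "fi_sup_raw",
    "lysate_fi": "fi_lys_raw",
    "t0_fi": "fi_t0_raw",
    "absorbance_570": "a570",
    "absorbance_600": "a600",
}


def well_name(row: int, col: int) -> str:
    """0-based (row, col) -> conventional name, e.g. (0, 0) -> 'A1'."""
    return f"{ROW_LABELS[row]}{col + 1}"


def parse_well(name: str) -> tuple[int, int]:
    """'A1'..'H12' -> 0-based (row, col)."""
    name = name.strip().upper()
    if len(name) < 2 or name[0] not in ROW_LABELS:
        raise LayoutError(f"invalid well name {name!r}")
    try:
        col = int(name[1:])
    except ValueError:
        raise LayoutError(f"invalid well name {name!r}") from None
    if not 1 <= col <= N_COLS:
        raise LayoutError(f"well column out of range in {name!r}")
    return ROW_LABELS.index(name[0]), col - 1


ALL_WELLS = tuple(well_name(r, c) for r in range(N_ROWS) for c in range(N_COLS))


@dataclass
class PlateGrid:
    """Raw per-well readings for one plate and one read type.

    ``values`` is an 8x12 float array; NaN marks a missing well. Negative
    readings are rejected at construction (a plate reader reports
    non-negative intensities/absorbances).
    """

    plate_id: str
    read_type: str
    values: np.ndarray
    gain_tag: str = ""

    def __post_init__(self) -> None:
        if self.read_type not in READ_TYPES:
            raise PlateParseError(
                f"unknown read_type {self.read_type!r}; expected one of {READ_TYPES}"
            )
        v = np.asarray(self.values, dtype=float)
        if v.shape != (N_ROWS, N_COLS):
            raise PlateParseError(
                f"plate {self.plate_id}: grid must be {N_ROWS}x{N_COLS}, got {v.shape}"
            )
        if np.any(v[~np.isnan(v)] < 0):
            r, c = np.argwhere(np.nan_to_num(v, nan=0.0) < 0)[0]
            raise PlateParseError(
                f"plate {self.plate_id}: negative value at {well_name(int(r), int(c))}"
            )
        self.values = v

    def __eq__(self, other: object) -> bool:  # NaN-aware equality for tests
        if not isinstance(other, PlateGrid):
            return NotImplemented
        return (
            self.plate_id == other.plate_id
            and self.read_type == other.read_type
            and self.gain_tag == other.gain_tag
            and np.array_equal(self.values, other.values, equal_nan=True)
        )

    def get(self, well: str) -> float:
        r, c = parse_well(well)
        return float(self.values[r, c])


@dataclass
class WellAssignment:
    """Role (and, for sample-bearing wells, identity) of one well."""

    role: str
    sample_id: str | None = None
    replicate: int | None = None
    condition: str | None = None
    acceptor_pct: float = 2.0

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise LayoutError(f"unknown role {self.role!r}; expected one of {ROLES}")
        if self.role in SAMPLE_BEARING_ROLES and not self.sample_id:
            raise LayoutError(f"role {self.role!r} requires a sample_id")
        if self.condition is not None and self.condition not in CONDITIONS:
            raise LayoutError(f"unknown condition {self.condition!r}")


@dataclass
class PlateLayout:
    """Well -> role/sample assignment for one plate."""

    plate_id: str
    wells: dict[str, WellAssignment] = field(default_factory=dict)
    wells_per_sample: int = 3

    def __post_init__(self) -> None:
        for w in self.wells:
            parse_well(w)  # raises on bad names

    def role_wells(self, role: str) -> list[str]:
        return [w for w, a in self.wells.items() if a.role == role]

    def sample_wells(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for w, a in self.wells.items():
            if a.role in SAMPLE_BEARING_ROLES:
                out.setdefault(a.sample_id, []).append(w)
        return out

    def validate(self, *, correction_enabled: bool = True, require_t0: bool = True) -> None:
        """Enforce the structural contract of the assay plate.

        Raises :class:`LayoutError` naming the offending role or sample.
        """
        required_min3 = ["passive", "unstained_background"]
        if require_t0:
            required_min3.append("t0_control")
        for role in required_min3:
            n = len(self.role_wells(role))
            if n < 3:
                raise LayoutError(
                    f"plate {self.plate_id}: role '{role}' requires >=3 wells, found {n}"
                )
        for sid, wells in (
            (s, w)
            for s, w in self._wells_by_role_sample("sample").items()
        ):
            if len(wells) != self.wells_per_sample:
                raise LayoutError(
                    f"plate {self.plate_id}: sample '{sid}' has {len(wells)} wells, "
                    f"expected {self.wells_per_sample}"
                )
        if correction_enabled:
            ids = set(self._wells_by_role_sample("correction_control"))
            if len(ids) != 4:
                raise LayoutError(
                    f"plate {self.plate_id}: role 'correction_control' requires exactly "
                    f"4 distinct sample_ids, found {len(ids)}"
                )

    def _wells_by_role_sample(self, role: str) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for w, a in self.wells.items():
            if a.role == role:
                out.setdefault(a.sample_id or "", []).append(w)
        return out


# ---------------------------------------------------------------------------
# Grid CSV


def write_plate_grid(grid: PlateGrid, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["plate_id", "read_type", "gain_tag"])
        w.writerow([grid.plate_id, grid.read_type, grid.gain_tag])
        w.writerow([""] + [str(c + 1) for c in range(N_COLS)])
        for r in range(N_ROWS):
            row = [
                "" if math.isnan(grid.values[r, c]) else repr(float(grid.values[r, c]))
                for c in range(N_COLS)
            ]
            w.writerow([ROW_LABELS[r]] + row)


def read_plate_grid(path: str | Path, read_type: str | None = None) -> PlateGrid:
    """Parse a grid CSV; ``read_type``, if given, must match the file's."""
    path = Path(path)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    rows = [r for r in rows if r]  # drop blank lines
    if len(rows) < 3 or [c.strip() for c in rows[0][:3]] != ["plate_id", "read_type", "gain_tag"]:
        raise PlateParseError(f"{path}: missing 'plate_id,read_type,gain_tag' header")
    meta = rows[1] + ["", "", ""]
    plate_id, file_read_type, gain_tag = (meta[0].strip(), meta[1].strip(), meta[2].strip())
    if read_type is not None and read_type != file_read_type:
        raise PlateParseError(
            f"{path}: read_type mismatch (file says {file_read_type!r}, expected {read_type!r})"
        )
    body = rows[3:]
    if len(body) != N_ROWS:
        raise PlateParseError(f"{path}: expected {N_ROWS} grid rows A-H, found {len(body)}")
    values = np.full((N_ROWS, N_COLS), np.nan)
    for i, row in enumerate(body):
        label = row[0].strip().upper() if row else ""
        if label != ROW_LABELS[i]:
            raise PlateParseError(f"{path}: row {i + 4}: expected label {ROW_LABELS[i]!r}, got {label!r}")
        cells = row[1:]
        if len(cells) != N_COLS:
            raise PlateParseError(
                f"{path}: row {ROW_LABELS[i]}: expected {N_COLS} columns, found {len(cells)}"
            )
        for j, cell in enumerate(cells):
            cell = cell.strip()
            if cell == "":
                continue
            try:
                v = float(cell)
            except ValueError:
                raise PlateParseError(
                    f"{path}: non-numeric value {cell!r} at {well_name(i, j)}"
                ) from None
            if v < 0:
                raise PlateParseError(f"{path}: negative value at {well_name(i, j)}")
            values[i, j] = v
    return PlateGrid(plate_id=plate_id, read_type=file_read_type, values=values, gain_tag=gain_tag)


# ---------------------------------------------------------------------------
# Layouts


def write_layout(layout: PlateLayout, path: str | Path) -> None:
    wells: dict[str, dict] = {}
    for w in sorted(layout.wells, key=parse_well):
        a = layout.wells[w]
        entry: dict = {"role": a.role}
        if a.sample_id is not None:
            entry["sample_id"] = a.sample_id
        if a.replicate is not None:
            entry["replicate"] = int(a.replicate)
        if a.condition is not None:
            entry["condition"] = a.condition
        if a.role in SAMPLE_BEARING_ROLES or a.role == "passive":
            entry["acceptor_pct"] = float(a.acceptor_pct)
        wells[w] = entry
    doc = {
        "plate_id": layout.plate_id,
        "wells_per_sample": layout.wells_per_sample,
        "wells": wells,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_layout(path: str | Path) -> PlateLayout:
    """Read a layout from YAML (or long-format CSV if the suffix is .csv)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return _read_layout_csv(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "plate_id" not in doc or "wells" not in doc:
        raise LayoutError(f"{path}: layout YAML needs 'plate_id' and 'wells' keys")
    wells = {}
    for w, entry in doc["wells"].items():
        entry = dict(entry)
        wells[str(w)] = WellAssignment(
            role=entry.get("role", "empty"),
            sample_id=entry.get("sample_id"),
            replicate=entry.get("replicate"),
            condition=entry.get("condition"),
            acceptor_pct=float(entry.get("acceptor_pct", 2.0)),
        )
    return PlateLayout(
        plate_id=str(doc["plate_id"]),
        wells=wells,
        wells_per_sample=int(doc.get("wells_per_sample", 3)),
    )


def _read_layout_csv(path: Path) -> PlateLayout:
    df = pd.read_csv(path, dtype={"plate_id": str, "well": str, "role": str, "sample_id": str})
    needed = {"plate_id", "well", "role"}
    if not needed.issubset(df.columns):
        raise LayoutError(f"{path}: layout CSV needs columns {sorted(needed)}")
    plate_ids = df["plate_id"].unique()
    if len(plate_ids) != 1:
        raise LayoutError(f"{path}: layout CSV must describe exactly one plate, found {list(plate_ids)}")
    wells = {}
    for rec in df.to_dict("records"):
        rep = rec.get("replicate")
        wells[str(rec["well"])] = WellAssignment(
            role=rec["role"],
            sample_id=None if pd.isna(rec.get("sample_id")) else str(rec["sample_id"]),
            replicate=None if rep is None or pd.isna(rep) else int(rep),
            condition=None if pd.isna(rec.get("condition")) else str(rec["condition"]),
            acceptor_pct=2.0 if pd.isna(rec.get("acceptor_pct")) else float(rec["acceptor_pct"]),
        )
    return PlateLayout(plate_id=str(plate_ids[0]), wells=wells)


# ---------------------------------------------------------------------------
# Joining grids with a layout


def join_layout(
    grids: list[PlateGrid] | dict[str, PlateGrid],
    layout: PlateLayout,
    methods: tuple[str, ...] = ("per_well", "t0"),
) -> pd.DataFrame:
    """Combine one plate's grids with its layout into a tidy well table.

    Returns one row per non-empty well with columns ``plate_id, well_id,
    role, sample_id, replicate, condition, acceptor_pct`` plus one column per
    read type present (see ``READ_COLUMNS``). Missing reads propagate as NaN.
    """
    if isinstance(grids, dict):
        by_type = dict(grids)
    else:
        by_type = {}
        for g in grids:
            if g.read_type in by_type:
                raise LayoutError(f"duplicate read_type {g.read_type!r} for plate {g.plate_id}")
            by_type[g.read_type] = g
    for g in by_type.values():
        if g.plate_id != layout.plate_id:
            raise LayoutError(
                f"plate_id mismatch: grid {g.plate_id!r} vs layout {layout.plate_id!r}"
            )

    if "per_well" in methods:
        for rt in ("supernatant_fi", "lysate_fi"):
            if rt not in by_type:
                raise ConfigError(f"per-well method requires a {rt!r} grid")
    if "t0" in methods:
        if "supernatant_fi" not in by_type:
            raise ConfigError("t0 method requires a 'supernatant_fi' grid")
        if "t0_fi" not in by_type and len(layout.role_wells("t0_control")) < 3:
            raise ConfigError(
                "t0 method requires t0_control wells in the layout or a 't0_fi' grid"
            )

    sup, lys = by_type.get("supernatant_fi"), by_type.get("lysate_fi")
    if sup is not None and lys is not None and sup.gain_tag != lys.gain_tag:
        warnings.warn(
            f"plate {layout.plate_id}: supernatant and lysate gain_tags differ "
            f"({sup.gain_tag!r} vs {lys.gain_tag!r}); the protocol expects one gain",
            stacklevel=2,
        )

    layout.validate(require_t0="t0" in methods and "t0_fi" not in by_type,
                    correction_enabled=False)

    rows = []
    for w in sorted(layout.wells, key=parse_well):
        a = layout.wells[w]
        if a.role == "empty":
            continue
        r, c = parse_well(w)
        rec = {
            "plate_id": layout.plate_id,
            "well_id": w,
            "role": a.role,
            "sample_id": a.sample_id,
            "replicate": a.replicate,
            "condition": a.condition,
            "acceptor_pct": a.acceptor_pct,
        }
        for rt, col in READ_COLUMNS.items():
            if rt in by_type:
                rec[col] = by_type[rt].values[r, c]
        rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Manifests


def write_manifest(entries: list[dict], path: str | Path) -> None:
    """``entries``: [{"layout": path, "reads": {read_type: path}}, ...];
    paths are stored relative to the manifest's directory when possible."""
    base = Path(path).parent
    doc = {"plates": []}
    for e in entries:
        reads = {rt: _relativize(p, base) for rt, p in e["reads"].items()}
        doc["plates"].append({"layout": _relativize(e["layout"], base), "reads": reads})
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def _relativize(p: str | Path, base: Path) -> str:
    p = Path(p)
    try:
        return str(p.relative_to(base))
    except ValueError:
        return str(p)


def load_manifest(path: str | Path) -> list[dict]:
    """Load a run manifest; returns [{"layout": PlateLayout,
    "grids": {read_type: PlateGrid}}, ...]."""
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "plates" not in doc:
        raise ConfigError(f"{path}: manifest needs a 'plates' list")
    base = path.parent
    out = []
    for entry in doc["plates"]:
        layout = read_layout(base / entry["layout"])
        grids = {}
        for rt, p in entry.get("reads", {}).items():
            if rt not in READ_TYPES:
                raise ConfigError(f"{path}: unknown read type {rt!r} in manifest")
            grids[rt] = read_plate_grid(base / p, read_type=rt)
        out.append({"layout": layout, "grids": grids})
    return out
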