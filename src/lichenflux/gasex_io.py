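"""File formats for the hydration-physiology pipeline.

All tabular data travel as comma-separated UTF-8 text with a header row,
'.' decimal separator and ISO-8601 timestamps.  Gas-exchange logs use a
documented dialect emulating what a portable IRGA (LI-6800 class) records
per logged observation; native instrument exports are *not* parsed here —
they must be converted to this dialect first.

Readers validate; writers are atomic (temp file in the destination
directory, then rename), so a crashed write never leaves a truncated file.

Flux convention: net CO2 exchange ``a_net`` is mass-specific
(µmol CO2 g⁻¹ dry mass s⁻¹) and uptake-positive, so dark records are
negative.  Mass-specific rates are the only meaningful basis for fruticose
thalli, whose projected area is ill-defined.
"""

from __future__ import annotations

import csv
import logging
import math
import os
import tempfile
from contextlib import contextmanager
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HYDRATION_SOURCES = ("vapor", "liquid")
CHAMBERS = ("aquatic", "bryophyte")

#: Column schema of the gas-exchange CSV dialect, in file order.
GASEX_COLUMNS = (
    "timestamp",
    "thallus_id",
    "species",
    "genus",
    "hydration",
    "chamber",
    "temperature_C",
    "par_programmed",
    "par_realized",
    "rh_pct",
    "flow_umol_s",
    "co2_ref_ppm",
    "a_net",
    "dry_mass_g",
)

_GASEX_NUMERIC = (
    "temperature_C",
    "par_programmed",
    "par_realized",
    "rh_pct",
    "flow_umol_s",
    "co2_ref_ppm",
    "a_net",
    "dry_mass_g",
)

MICROCLIMATE_COLUMNS = ("timestamp", "temp_C", "rh_pct")
FVFM_COLUMNS = ("minutes", "fvfm")
OCCURRENCE_COLUMNS = ("record_id", "latitude", "longitude")


class FormatError(ValueError):
    """A file violates its documented format (missing column, bad header...)."""


class RowError(FormatError):
    """A single row violates the schema; carries the 1-based line number."""

    def __init__(self, line: int, field: str, message: str):
        super().__init__(f"line {line}, field '{field}': {message}")
        self.line = line
        self.field = field


@contextmanager
def atomic_write(path: str | Path, mode: str = "w"):
    """Write to a temp file next to *path*, rename into place on success."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, mode, encoding="utf-8", newline="") as handle:
            yield handle
        os.replace(tmp, path)
    except BaseException:
        try:
            os.unlink(tmp)
        except OSError:
            pass
        raise


# ---------------------------------------------------------------------------
# gas-exchange dialect
# ---------------------------------------------------------------------------

def _validate_gasex_row(row: pd.Series, line: int) -> None:
    if row["hydration"] not in HYDRATION_SOURCES:
        raise RowError(line, "hydration", f"must be one of {HYDRATION_SOURCES}, got {row['hydration']!r}")
    if row["chamber"] not in CHAMBERS:
        raise RowError(line, "chamber", f"must be one of {CHAMBERS}, got {row['chamber']!r}")
    for field in _GASEX_NUMERIC:
        if not math.isfinite(row[field]):
            raise RowError(line, field, "not a finite number")
    if row["dry_mass_g"] <= 0:
        raise RowError(line, "dry_mass_g", f"must be > 0, got {row['dry_mass_g']}")
    if not 0 <= row["rh_pct"] <= 100:
        raise RowError(line, "rh_pct", f"must be in [0, 100], got {row['rh_pct']}")
    if row["par_programmed"] < 0:
        raise RowError(line, "par_programmed", "must be >= 0")
    if row["par_realized"] < 0:
        raise RowError(line, "par_realized", "must be >= 0")


def read_gas_exchange(path: str | Path, strict: bool = True) -> pd.DataFrame:
    """Read a gas-exchange CSV into a validated DataFrame.

    In strict mode the first invalid row aborts with a :class:`RowError`
    naming the line and field.  In lenient mode invalid rows are dropped
    and logged; the surviving rows keep their file order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in GASEX_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")

    df = raw.copy()
    bad_lines: list[int] = []
    for field in _GASEX_NUMERIC:
        converted = pd.to_numeric(df[field], errors="coerce")
        bad = converted.isna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            if strict:
                raise RowError(line, field, f"unparseable number {raw.loc[bad.idxmax(), field]!r}")
            bad_lines.extend(int(i) + 2 for i in df.index[bad])
        df[field] = converted

    keep = np.ones(len(df), dtype=bool)
    for idx in df.index:
        line = int(idx) + 2
        if line in bad_lines:
            keep[idx] = False
            continue
        try:
            _validate_gasex_row(df.loc[idx], line)
        except RowError as err:
            if strict:
                raise
            keep[idx] = False
            logger.warning("%s: dropping invalid row: %s", path.name, err)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("%s: dropped %d invalid row(s) in lenient mode", path.name, n_dropped)
    out = df[keep].reset_index(drop=True)
    out.attrs["n_dropped"] = n_dropped
    return out


def write_gas_exchange(records: pd.DataFrame, path: str | Path) -> None:
    """Write gas-exchange records in the documented dialect (atomic)."""
    missing = [c for c in GASEX_COLUMNS if c not in records.columns]
    if missing:
        raise FormatError(f"cannot write: missing column(s): {', '.join(missing)}")
    with atomic_write(path) as handle:
        records.loc[:, GASEX_COLUMNS].to_csv(handle, index=False)


# ---------------------------------------------------------------------------
# simple tabular formats
# ---------------------------------------------------------------------------

def read_microclimate(path: str | Path) -> pd.DataFrame:
    """Read a half-hourly (or other fixed-cadence) microclimate CSV."""
    df = pd.read_csv(path)
    missing = [c for c in MICROCLIMATE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def write_microclimate(df: pd.DataFrame, path: str | Path) -> None:
    with atomic_write(path) as handle:
        df.loc[:, list(MICROCLIMATE_COLUMNS)].to_csv(handle, index=False)


def read_fvfm(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in FVFM_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    return df


def write_fvfm(df: pd.DataFrame, path: str | Path) -> None:
    with atomic_write(path) as handle:
        df.loc[:, list(FVFM_COLUMNS)].to_csv(handle, index=False)


def read_occurrences(path: str | Path) -> pd.DataFrame:
    """Read georeferenced occurrence records (id, latitude, longitude)."""
    df = pd.read_csv(path)
    missing = [c for c in OCCURRENCE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    bad_lat = ~df["latitude"].between(-90, 90)
    bad_lon = ~df["longitude"].between(-180, 180)
    if bad_lat.any():
        raise RowError(int(df.index[bad_lat][0]) + 2, "latitude", "outside [-90, 90]")
    if bad_lon.any():
        raise RowError(int(df.index[bad_lon][0]) + 2, "longitude", "outside [-180, 180]")
    return df


def write_occurrences(df: pd.DataFrame, path: str | Path) -> None:
    with atomic_write(path) as handle:
        df.loc[:, list(OCCURRENCE_COLUMNS)].to_csv(handle, index=False)


# ---------------------------------------------------------------------------
# ESRI ASCII grid
# ---------------------------------------------------------------------------

@dataclass
class ClimateGrid:
    """A rectangular geographic raster with cell-center registration.

    ``values`` is (nrows, ncols) with row 0 at the *top* (northernmost);
    nodata cells are NaN in ``values`` and written back with the
    ``nodata`` sentinel.
    """

    values: np.ndarray
    xllcorner: float
    yllcorner: float
    cellsize: float
    nodata: float = -9999.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FormatError("grid values must be 2-D")
        if self.cellsize <= 0:
            raise FormatError("cellsize must be > 0")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(lon, lat) of the center of cell (row, col)."""
        x = self.xllcorner + (col + 0.5) * self.cellsize
        y = self.yllcorner + (self.nrows - row - 0.5) * self.cellsize
        return x, y

    def locate(self, lon: float, lat: float) -> tuple[int, int] | None:
        """Nearest-cell-center lookup; ties break toward the lower index.

        Returns None when the point falls outside the grid extent.
        """
        fx = (lon - self.xllcorner) / self.cellsize
        fy = (self.yllcorner + self.nrows * self.cellsize - lat) / self.cellsize
        if not (0 <= fx <= self.ncols and 0 <= fy <= self.nrows):
            return None
        col = min(int(math.floor(fx)), self.ncols - 1)
        row = min(int(math.floor(fy)), self.nrows - 1)
        # a point exactly on an interior cell edge is equidistant from the
        # two flanking centers: take the lower index
        if fx == math.floor(fx) and 0 < fx and col == fx:
            col -= 1
        if fy == math.floor(fy) and 0 < fy and row == fy:
            row -= 1
        return row, col


_ASCII_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def read_ascii_grid(path: str | Path) -> ClimateGrid:
    """Read an ESRI ASCII grid (.asc)."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path, encoding="utf-8") as handle:
        lines = handle.read().splitlines()
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in _ASCII_HEADER_KEYS + ("nodata_value",):
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    missing = [k for k in _ASCII_HEADER_KEYS if k not in header]
    if missing:
        raise FormatError(f"{path}: malformed ASCII grid header, missing: {', '.join(missing)}")
    nodata = header.get("nodata_value", -9999.0)
    try:
        body = np.loadtxt(lines[i:], dtype=float, ndmin=2)
    except ValueError as err:
        raise FormatError(f"{path}: unparseable grid body: {err}") from None
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if body.shape != (nrows, ncols):
        raise FormatError(
            f"{path}: header promises {nrows}x{ncols} but body is {body.shape[0]}x{body.shape[1]}"
        )
    values = np.where(body == nodata, np.nan, body)
    return ClimateGrid(values, header["xllcorner"], header["yllcorner"], header["cellsize"], nodata)


def write_ascii_grid(grid: ClimateGrid, path: str | Path) -> None:
    body = np.where(np.isnan(grid.values), grid.nodata, grid.values)
    with atomic_write(path) as handle:
        handle.write(f"ncols {grid.ncols}\n")
        handle.write(f"nrows {grid.nrows}\n")
        handle.write(f"xllcorner {grid.xllcorner:.10g}\n")
        handle.write(f"yllcorner {grid.yllcorner:.10g}\n")
        handle.write(f"cellsize {grid.cellsize:.10g}\n")
        handle.write(f"NODATA_value {grid.nodata:.10g}\n")
        for row in body:
            handle.write(" ".join(f"{v:.6f}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# newick tip annotation
# ---------------------------------------------------------------------------

def annotate_newick(
    tree_path: str | Path,
    values: dict[str, float],
    out_path: str | Path,
    key: str = "asymmetry",
) -> list[str]:
    """Attach a trait value to each matching tip of a newick cladogram.

    Tip labels are genus names; matched tips carry the value as a
    ``[&key=value]`` comment in the output, unmatched tips are left
    untouched and returned.  Duplicate tip labels are rejected.
    """
    try:
        tree = dendropy.Tree.get(path=str(tree_path), schema="newick")
    except Exception as err:  # dendropy raises several parse error types
        raise FormatError(f"{tree_path}: unparseable newick: {err}") from None

    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon]
    dupes = sorted({l for l in labels if labels.count(l) > 1})
    if dupes:
        raise FormatError(f"{tree_path}: duplicate tip label(s): {', '.join(dupes)}")

    if not values:
        logger.warning("annotate_newick: empty values mapping, copying tree unchanged")
    matched = set()
    for leaf in tree.leaf_node_iter():
        if leaf.taxon and leaf.taxon.label in values:
            leaf.annotations.add_new(key, float(values[leaf.taxon.label]))
            matched.add(leaf.taxon.label)
    unmatched = [l for l in labels if l not in matched]
    if unmatched:
        logger.info("annotate_newick: %d tip(s) without values: %s", len(unmatched), ", ".join(unmatched))
    with atomic_write(out_path) as handle:
        handle.write(tree.as_string(schema="newick", suppress_annotations=False))
    return unmatched


def read_tip_annotations(tree_path: str | Path, key: str = "asymmetry") -> dict[str, float]:
    """Extract ``[&key=value]`` tip annotations from a newick file."""
    tree = dendropy.Tree.get(path=str(tree_path), schema="newick", extract_comment_metadata=True)
    out: dict[str, float] = {}
    for leaf in tree.leaf_node_iter():
        for ann in leaf.annotations:
            if ann.name == key and leaf.taxon:
                out[leaf.taxon.label] = float(ann.value)
    return out
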