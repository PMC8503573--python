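"""ESRI ASCII grid I/O and aligned multi-layer environment stacks.

The whole pipeline works on pre-aligned single-band rasters in the plain-text
ESRI ASCII (.asc) interchange format: a six-keyword header followed by the
data block, row 0 being the northernmost row.  No projection handling is
attempted; layers are required to share an identical header.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .errors import AlignmentError, AscFormatError, ConfigurationError, DimensionError

__all__ = [
    "GridHeader",
    "RasterGrid",
    "EnvStack",
    "read_asc",
    "write_asc",
    "build_stack",
    "read_manifest",
    "write_stack",
]

DEFAULT_NODATA = -9999.0

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"


@dataclass(frozen=True)
class GridHeader:
    """Georeference of a grid: size, lower-left corner, cell size, nodata code."""

    ncols: int
    nrows: int
    xllcorner: float
    yllcorner: float
    cellsize: float
    nodata_value: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        if self.ncols < 1 or self.nrows < 1:
            raise AscFormatError(
                f"grid must have positive dimensions, got {self.nrows}x{self.ncols}"
            )
        if not self.cellsize > 0:
            raise AscFormatError(f"cellsize must be > 0, got {self.cellsize}")

    def same_georeference(self, other: "GridHeader") -> list[str]:
        """Names of the header fields on which the two headers differ."""
        diff = []
        for name in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
            if getattr(self, name) != getattr(other, name):
                diff.append(name)
        return diff


@dataclass
class RasterGrid:
    """A 2-D georeferenced array with a nodata mask (row 0 = north)."""

    header: GridHeader
    values: np.ndarray
    mask: np.ndarray  # True where nodata

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        shape = (self.header.nrows, self.header.ncols)
        if self.values.shape != shape or self.mask.shape != shape:
            raise DimensionError(
                f"grid arrays must have shape {shape}, got values "
                f"{self.values.shape} and mask {self.mask.shape}"
            )

    @classmethod
    def from_array(
        cls, values: np.ndarray, header: GridHeader, mask: np.ndarray | None = None
    ) -> "RasterGrid":
        values = np.asarray(values, dtype=float)
        if mask is None:
            mask = np.zeros(values.shape, dtype=bool)
        return cls(header=header, values=values, mask=np.asarray(mask, dtype=bool))

    # -- coordinate conventions -------------------------------------------------

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(x, y) map coordinates of the center of cell (row, col)."""
        h = self.header
        x = h.xllcorner + (col + 0.5) * h.cellsize
        y = h.yllcorner + (h.nrows - row - 0.5) * h.cellsize
        return x, y

    def point_to_cell(self, x: float, y: float) -> tuple[int, int] | None:
        """Map a point to its (row, col) cell, or None if outside the grid.

        Cells are half-open: a point exactly on the east or north boundary of
        the grid is rejected, so no point belongs to two cells.
        """
        h = self.header
        col = int(np.floor((x - h.xllcorner) / h.cellsize))
        row_s = int(np.floor((y - h.yllcorner) / h.cellsize))  # from south
        if col < 0 or col >= h.ncols or row_s < 0 or row_s >= h.nrows:
            return None
        return h.nrows - 1 - row_s, col

    # -- conveniences -----------------------------------------------------------

    def masked(self) -> np.ma.MaskedArray:
        return np.ma.MaskedArray(self.values, mask=self.mask)

    def with_values(self, values: np.ndarray, mask: np.ndarray | None = None) -> "RasterGrid":
        return RasterGrid(
            header=self.header,
            values=values,
            mask=self.mask.copy() if mask is None else mask,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RasterGrid):
            return NotImplemented
        if self.header != other.header or not np.array_equal(self.mask, other.mask):
            return False
        ok = ~self.mask
        return bool(np.array_equal(self.values[ok], other.values[ok]))


@dataclass
class EnvStack:
    """Named, header-aligned predictor layers flagged continuous/categorical."""

    layers: dict[str, RasterGrid]
    kinds: dict[str, str]
    joint_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.joint_mask is None:
            mask = np.zeros((self.header.nrows, self.header.ncols), dtype=bool)
            for grid in self.layers.values():
                mask |= grid.mask
            self.joint_mask = mask

    @property
    def header(self) -> GridHeader:
        return next(iter(self.layers.values())).header

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def __getitem__(self, name: str) -> RasterGrid:
        try:
            return self.layers[name]
        except KeyError:
            raise ConfigurationError(f"layer {name!r} not in stack {self.names}") from None

    def valid_cells(self) -> np.ndarray:
        """(n, 2) array of (row, col) indices of jointly unmasked cells."""
        rows, cols = np.nonzero(~self.joint_mask)
        return np.column_stack([rows, cols])

    def cell_values(self, cells: np.ndarray, names: list[str] | None = None) -> np.ndarray:
        """Matrix of layer values at the given (row, col) cells, one column per layer."""
        names = self.names if names is None else names
        cells = np.asarray(cells, dtype=int)
        out = np.empty((len(cells), len(names)), dtype=float)
        for j, name in enumerate(names):
            out[:, j] = self[name].values[cells[:, 0], cells[:, 1]]
        return out


# -- .asc reading / writing ----------------------------------------------------

_HEADER_KEYS = {"ncols", "nrows", "xllcorner", "yllcorner", "xllcenter", "yllcenter",
                "cellsize", "nodata_value"}


def read_asc(path: str | Path) -> RasterGrid:
    """Read an ESRI ASCII grid.

    Both the XLLCORNER and XLLCENTER dialects are accepted; center coordinates
    are converted to the corner convention (shift by cellsize / 2).  Cells
    whose value equals NODATA_VALUE exactly are masked.  NODATA_VALUE defaults
    to -9999 when the keyword is absent.
    """
    path = Path(path)
    text = path.read_text().splitlines()
    fields: dict[str, float] = {}
    center_x = center_y = False
    i = 0
    for i, line in enumerate(text):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS:
            key = parts[0].lower()
            try:
                val = float(parts[1])
            except ValueError:
                raise AscFormatError(f"{path}: cannot parse header line {i + 1}: {line!r}")
            if key == "xllcenter":
                key, center_x = "xllcorner", True
            elif key == "yllcenter":
                key, center_y = "yllcorner", True
            fields[key] = val
        else:
            break
    else:
        i += 1

    required = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")
    missing = [k for k in required if k not in fields]
    if missing:
        raise AscFormatError(f"{path}: header is missing keyword(s) {missing}")
    for key in ("ncols", "nrows"):
        if fields[key] != int(fields[key]):
            raise AscFormatError(f"{path}: {key} must be an integer, got {fields[key]}")

    cellsize = fields["cellsize"]
    if center_x:
        fields["xllcorner"] -= cellsize / 2.0
    if center_y:
        fields["yllcorner"] -= cellsize / 2.0
    header = GridHeader(
        ncols=int(fields["ncols"]),
        nrows=int(fields["nrows"]),
        xllcorner=fields["xllcorner"],
        yllcorner=fields["yllcorner"],
        cellsize=cellsize,
        nodata_value=fields.get("nodata_value", DEFAULT_NODATA),
    )

    body = "\n".join(text[i:])
    try:
        flat = np.array(body.split(), dtype=float) if body.strip() else np.empty(0)
    except ValueError as exc:
        raise AscFormatError(f"{path}: cannot parse data block: {exc}")
    if flat.size != header.nrows * header.ncols:
        raise DimensionError(
            f"{path}: expected {header.nrows * header.ncols} values "
            f"({header.nrows}x{header.ncols}), found {flat.size}"
        )
    values = flat.reshape(header.nrows, header.ncols)
    mask = values == header.nodata_value
    return RasterGrid(header=header, values=values, mask=mask)


def _fmt(v: float) -> str:
    """Shortest decimal text that round-trips the float exactly."""
    if v == int(v) and abs(v) < 1e16:
        return str(int(v))
    return repr(float(v))


def write_asc(grid: RasterGrid, path: str | Path) -> None:
    """Write a grid as an ESRI ASCII file; masked cells become nodata_value."""
    h = grid.header
    out = grid.values.copy()
    out[grid.mask] = h.nodata_value
    lines = [
        f"NCOLS {h.ncols}",
        f"NROWS {h.nrows}",
        f"XLLCORNER {_fmt(h.xllcorner)}",
        f"YLLCORNER {_fmt(h.yllcorner)}",
        f"CELLSIZE {_fmt(h.cellsize)}",
        f"NODATA_VALUE {_fmt(h.nodata_value)}",
    ]
    for row in out:
        lines.append(" ".join(_fmt(v) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


# -- stacks --------------------------------------------------------------------

def build_stack(grids: Mapping[str, RasterGrid], kinds: Mapping[str, str]) -> EnvStack:
    """Assemble named grids into an aligned stack.

    All layers must share an identical georeference header; categorical layers
    must hold integer codes on unmasked cells.  The stack's joint validity
    mask is the intersection of the layers' unmasked cells.
    """
    if not grids:
        raise ConfigurationError("a stack needs at least one layer")
    names = list(grids)
    ref_name, ref = names[0], grids[names[0]]
    for name in names[1:]:
        diff = ref.header.same_georeference(grids[name].header)
        if diff:
            raise AlignmentError(
                f"layer {name!r} disagrees with {ref_name!r} on header field(s) {diff}"
            )
    resolved_kinds: dict[str, str] = {}
    for name in names:
        kind = kinds.get(name, CONTINUOUS)
        if kind not in (CONTINUOUS, CATEGORICAL):
            raise ConfigurationError(f"layer {name!r}: unknown kind {kind!r}")
        if kind == CATEGORICAL:
            vals = grids[name].values[~grids[name].mask]
            if not np.allclose(vals, np.rint(vals)):
                raise ConfigurationError(
                    f"categorical layer {name!r} holds non-integer codes"
                )
        resolved_kinds[name] = kind
    return EnvStack(layers=dict(grids), kinds=resolved_kinds)


def read_manifest(path: str | Path) -> EnvStack:
    """Load a stack from a manifest: delimited text rows of name, path, kind.

    Relative layer paths are resolved against the manifest's directory.
    A header row 'name,path,kind' is recognised and skipped.
    """
    path = Path(path)
    grids: dict[str, RasterGrid] = {}
    kinds: dict[str, str] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or row[0].strip().startswith("#"):
                continue
            cells = [c.strip() for c in row]
            if cells[0].lower() == "name":
                continue
            if len(cells) < 3:
                raise ConfigurationError(f"{path}: manifest row needs name,path,kind: {row}")
            name, layer_path, kind = cells[0], cells[1], cells[2].lower()
            p = Path(layer_path)
            if not p.is_absolute():
                p = path.parent / p
            grids[name] = read_asc(p)
            kinds[name] = kind
    if not grids:
        raise ConfigurationError(f"{path}: manifest declares no layers")
    return build_stack(grids, kinds)


def write_stack(stack: EnvStack, directory: str | Path, manifest_name: str = "stack.csv") -> Path:
    """Write every layer as <name>.asc plus a manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = directory / manifest_name
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["name", "path", "kind"])
        for name, grid in stack.layers.items():
            fname = f"{name}.asc"
            write_asc(grid, directory / fname)
            writer.writerow([name, fname, stack.kinds[name]])
    return manifest
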