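"""Dense prediction products over the pond volume.

Two products: a horizontal DO slice (regular nx-by-ny grid at fixed time
and depth) and the iso-concentration depth surface — for every (x, y),
the shallowest depth at which the predicted DO profile crosses a
threshold such as the 2 mg/L hypoxia line.  Grids are exported as plain
text (long CSV or an ASCII matrix) and round-trip exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rbf import RBFModel

#: sentinel depth for columns whose profile never reaches the threshold
NOT_REACHED = -1.0


@dataclass(frozen=True)
class PondGeometry:
    """Rectangular pond: x along the length, y across, z down from surface."""

    length: float = 130.0
    width: float = 45.0
    max_depth: float = 1.8

    def __post_init__(self) -> None:
        if min(self.length, self.width, self.max_depth) <= 0:
            raise ValueError("pond dimensions must be positive")

    def contains(self, x, y, z) -> bool:
        return (0 <= x <= self.length and 0 <= y <= self.width
                and 0 <= z <= self.max_depth)


@dataclass
class FieldGrid:
    """A gridded scalar field with its axes and the fixed coordinates."""

    x: np.ndarray                 # (nx,)
    y: np.ndarray                 # (ny,)
    values: np.ndarray            # (ny, nx): y is the outer (row) axis
    t: float
    z: float | None = None        # None for a depth-surface product
    kind: str = "do"              # "do" slice or "iso_depth" surface

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.y), len(self.x)):
            raise ValueError(
                f"values shape {self.values.shape} != (ny, nx) = "
                f"({len(self.y)}, {len(self.x)})")
        if not np.isfinite(self.values).all():
            raise ValueError("grid values must be finite")


def horizontal_slice(
    model: RBFModel,
    t: float,
    z: float,
    geom: PondGeometry = PondGeometry(),
    nx: int = 50,
    ny: int = 50,
) -> FieldGrid:
    """Predict DO on an nx-by-ny grid spanning the pond at fixed (t, z)."""
    if nx < 2 or ny < 2:
        raise ValueError("nx and ny must be >= 2")
    if not 0 <= z <= geom.max_depth:
        raise ValueError(f"depth {z} outside pond (0..{geom.max_depth})")
    xs = np.linspace(0.0, geom.length, nx)
    ys = np.linspace(0.0, geom.width, ny)
    xx, yy = np.meshgrid(xs, ys)  # (ny, nx)
    queries = np.column_stack([
        np.full(xx.size, t), xx.ravel(), yy.ravel(), np.full(xx.size, z)])
    values = model.predict(queries).reshape(ny, nx)
    return FieldGrid(x=xs, y=ys, values=values, t=t, z=z, kind="do")


def iso_depth_surface(
    model: RBFModel,
    t: float,
    threshold: float,
    geom: PondGeometry = PondGeometry(),
    nx: int = 50,
    ny: int = 50,
    nz: int = 33,
) -> FieldGrid:
    """Shallowest depth where predicted DO reaches ``threshold``, per (x, y).

    Each column is scanned top-down over ``nz`` depth levels; the first
    bracketing pair is refined by linear interpolation.  Columns whose
    profile stays above the threshold everywhere get the sentinel
    :data:`NOT_REACHED`.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if nz < 3:
        raise ValueError("nz must be >= 3")
    xs = np.linspace(0.0, geom.length, nx)
    ys = np.linspace(0.0, geom.width, ny)
    zs = np.linspace(0.0, geom.max_depth, nz)
    xx, yy = np.meshgrid(xs, ys)

    # predict the whole (ny*nx, nz) profile stack in one vectorized call
    base = np.column_stack([np.full(xx.size, t), xx.ravel(), yy.ravel()])
    queries = np.column_stack([
        np.repeat(base, nz, axis=0),
        np.tile(zs, xx.size),
    ])
    profiles = model.predict(queries).reshape(xx.size, nz)

    depth = np.full(xx.size, NOT_REACHED)
    below = profiles <= threshold
    for i in range(xx.size):
        hits = np.nonzero(below[i])[0]
        if len(hits) == 0:
            continue
        j = hits[0]
        if j == 0:
            depth[i] = zs[0]
            continue
        v0, v1 = profiles[i, j - 1], profiles[i, j]
        # linear refinement between the bracketing levels
        frac = (v0 - threshold) / (v0 - v1) if v0 != v1 else 1.0
        depth[i] = zs[j - 1] + frac * (zs[j] - zs[j - 1])

    return FieldGrid(x=xs, y=ys, values=depth.reshape(ny, nx), t=t,
                     z=None, kind="iso_depth")


# ---------------------------------------------------------------------
# export / import


def export_grid(grid: FieldGrid, path, format: str = "csv-long") -> None:
    """Write a grid as text; node order is row-major (y outer, x inner)."""
    if format == "csv-long":
        xx, yy = np.meshgrid(grid.x, grid.y)
        frame = pd.DataFrame({
            "t": np.full(xx.size, grid.t),
            "x": xx.ravel(),
            "y": yy.ravel(),
            "z": np.full(xx.size, np.nan if grid.z is None else grid.z),
            "value": grid.values.ravel(),
        })
        frame.insert(0, "kind", grid.kind)
        frame.to_csv(path, index=False)
    elif format == "ascii-matrix":
        z_repr = "nan" if grid.z is None else repr(grid.z)
        with open(path, "w") as fh:
            fh.write(f"# kind={grid.kind} t={grid.t!r} z={z_repr}\n")
            fh.write("# x: " + " ".join(repr(float(v)) for v in grid.x) + "\n")
            fh.write("# y: " + " ".join(repr(float(v)) for v in grid.y) + "\n")
            for row in grid.values:
                fh.write(" ".join(repr(float(v)) for v in row) + "\n")
    else:
        raise ValueError(f"unknown grid format {format!r}")


def read_grid(path, format: str = "csv-long") -> FieldGrid:
    """Read back a grid written by :func:`export_grid`."""
    if format == "csv-long":
        frame = pd.read_csv(path)
        xs = np.unique(frame["x"].to_numpy())
        ys = np.unique(frame["y"].to_numpy())
        values = frame["value"].to_numpy().reshape(len(ys), len(xs))
        z = frame["z"].iloc[0]
        return FieldGrid(x=xs, y=ys, values=values, t=float(frame["t"].iloc[0]),
                         z=None if pd.isna(z) else float(z),
                         kind=str(frame["kind"].iloc[0]))
    if format == "ascii-matrix":
        with open(path) as fh:
            header = fh.readline().strip().lstrip("# ").split()
            meta = dict(item.split("=", 1) for item in header)
            xs = np.array([float(v) for v in fh.readline().split(":", 1)[1].split()])
            ys = np.array([float(v) for v in fh.readline().split(":", 1)[1].split()])
            values = np.array([[float(v) for v in line.split()] for line in fh])
        z = float(meta["z"])
        return FieldGrid(x=xs, y=ys, values=values, t=float(meta["t"]),
                         z=None if np.isnan(z) else z, kind=meta["kind"])
    raise ValueError(f"unknown grid format {format!r}")
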