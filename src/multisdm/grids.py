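"""Stacked environmental predictor layers on a regular planar grid.

A :class:`PredictorGrid` holds a (layer, row, col) array plus the
georeference (cell size and origin) and, after rescaling, the per-layer
raw min/max needed to apply the same affine map to prediction-time and
scenario inputs. Rows are counted from the grid origin (row 0 at the
origin's y), cells are half-open, and a point exactly on a shared corner
belongs to the cell up-right of it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ScalingSpec",
    "PredictorGrid",
    "rescale_predictors",
    "save_grid",
    "load_grid",
]


@dataclass(frozen=True)
class ScalingSpec:
    """Per-layer raw minima/maxima used by the [-1, 1] affine rescaling."""

    names: tuple
    mins: np.ndarray
    maxs: np.ndarray

    def scale(self, raw: np.ndarray, axis: int = 0) -> np.ndarray:
        """Apply x -> 2(x - min)/(max - min) - 1 along ``axis``."""
        raw = np.asarray(raw, dtype=float)
        shape = [1] * raw.ndim
        shape[axis] = len(self.names)
        lo = self.mins.reshape(shape)
        hi = self.maxs.reshape(shape)
        span = hi - lo
        with np.errstate(invalid="ignore", divide="ignore"):
            out = 2.0 * (raw - lo) / span - 1.0
        # constant layers (span == 0) map to 0 by convention
        out = np.where(np.broadcast_to(span == 0, raw.shape), 0.0, out)
        return out

    def unscale(self, scaled: np.ndarray, axis: int = 0) -> np.ndarray:
        scaled = np.asarray(scaled, dtype=float)
        shape = [1] * scaled.ndim
        shape[axis] = len(self.names)
        lo = self.mins.reshape(shape)
        hi = self.maxs.reshape(shape)
        mid = 0.5 * (lo + hi)
        out = (scaled + 1.0) * 0.5 * (hi - lo) + lo
        return np.where(np.broadcast_to(hi == lo, scaled.shape), mid, out)

    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "mins": self.mins.tolist(),
            "maxs": self.maxs.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScalingSpec":
        return cls(
            names=tuple(d["names"]),
            mins=np.asarray(d["mins"], dtype=float),
            maxs=np.asarray(d["maxs"], dtype=float),
        )


@dataclass
class PredictorGrid:
    """Environmental layers stacked on one regular grid.

    Attributes
    ----------
    names : list of str
        One name per layer, aligned with axis 0 of ``values``.
    values : ndarray, shape (n_layers, n_rows, n_cols)
    cell_size : float
        Edge length of a square cell, in the planar coordinate units.
    origin : (float, float)
        (x, y) of the grid corner at row 0 / col 0.
    scaling : ScalingSpec or None
        Set once the grid has been rescaled to [-1, 1].
    landcover : ndarray or None
        Optional integer-coded class layer of shape (n_rows, n_cols).
    """

    names: list
    values: np.ndarray
    cell_size: float = 1.0
    origin: tuple = (0.0, 0.0)
    scaling: ScalingSpec | None = None
    landcover: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must have shape (layer, row, col)")
        if len(self.names) != self.values.shape[0]:
            raise ValueError("one name per layer required")
        if self.landcover is not None and self.landcover.shape != self.shape:
            raise ValueError("landcover shape must match grid shape")

    @property
    def shape(self) -> tuple:
        return self.values.shape[1:]

    @property
    def n_layers(self) -> int:
        return self.values.shape[0]

    def layer(self, name: str) -> np.ndarray:
        return self.values[self.names.index(name)]

    def pixel_of(self, x, y) -> tuple:
        """(row, col) of the cell containing planar point(s) (x, y).

        Half-open cells: a point on a shared corner falls in the cell with
        the larger row/col indices ("up-right" rule).
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin[0]) / self.cell_size).astype(int)
        row = np.floor((y - self.origin[1]) / self.cell_size).astype(int)
        return row, col

    def pixel_center(self, row, col) -> tuple:
        x = self.origin[0] + (np.asarray(col) + 0.5) * self.cell_size
        y = self.origin[1] + (np.asarray(row) + 0.5) * self.cell_size
        return x, y

    def flat_features(self) -> np.ndarray:
        """(n_pixels, n_layers) matrix of layer values, row-major pixels."""
        return self.values.reshape(self.n_layers, -1).T


def rescale_predictors(grid: PredictorGrid) -> PredictorGrid:
    """Rescale every layer to [-1, 1], recording the raw min/max.

    Constant layers cannot be rescaled; they map to 0 and a warning is
    emitted so that flat toy fixtures still run.
    """
    vals = grid.values
    flat = vals.reshape(grid.n_layers, -1)
    mins = np.nanmin(flat, axis=1)
    maxs = np.nanmax(flat, axis=1)
    if not (np.all(np.isfinite(mins)) and np.all(np.isfinite(maxs))):
        raise ValueError("every layer needs at least one finite value")
    constant = maxs == mins
    if np.any(constant):
        bad = [grid.names[i] for i in np.flatnonzero(constant)]
        warnings.warn(
            f"constant predictor layer(s) {bad} mapped to 0", stacklevel=2
        )
    spec = ScalingSpec(names=tuple(grid.names), mins=mins, maxs=maxs)
    scaled = spec.scale(vals, axis=0)
    return replace(grid, values=scaled, scaling=spec)


def save_grid(path, grid: PredictorGrid) -> None:
    """Write a grid as a single .npz with an embedded JSON header."""
    header = {
        "names": list(grid.names),
        "cell_size": grid.cell_size,
        "origin": list(grid.origin),
        "scaling": grid.scaling.to_dict() if grid.scaling else None,
    }
    arrays = {"values": grid.values, "header": np.array(json.dumps(header))}
    if grid.landcover is not None:
        arrays["landcover"] = grid.landcover
    np.savez_compressed(path, **arrays)


def load_grid(path) -> PredictorGrid:
    with np.load(path, allow_pickle=False) as z:
        header = json.loads(str(z["header"]))
        landcover = z["landcover"] if "landcover" in z.files else None
        values = z["values"]
    scaling = (
        ScalingSpec.from_dict(header["scaling"]) if header["scaling"] else None
    )
    return PredictorGrid(
        names=list(header["names"]),
        values=values,
        cell_size=float(header["cell_size"]),
        origin=tuple(header["origin"]),
        scaling=scaling,
        landcover=landcover,
    )
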