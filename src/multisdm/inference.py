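"""Prediction, ensembling, phenology and dominance mapping, projection.

All downstream products derive from the :class:`PredictionCube`: softmax
observation probabilities indexed (taxon, day, pixel). Within a cell the
probabilities are conditional on a record existing there — relative, not
absolute, occurrence rates — which is why dominance mapping reweights
rather than renormalizes, and why the shared accessibility bias cancels
between taxa.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .grids import PredictorGrid
from .losses import softmax
from .network import ModelState
from .seasonal import encode_season
from .surveys import SurveyTable

__all__ = [
    "PredictionCube",
    "BiasWeights",
    "PhenologyMap",
    "DominanceMap",
    "ScenarioSpec",
    "SEASON_WINDOWS",
    "predict_probabilities",
    "predict_cube",
    "ensemble_predictions",
    "annual_summary",
    "smooth_seasonal",
    "find_modes",
    "tpmax",
    "phenology_map",
    "aggregate_map",
    "bias_correction_weights",
    "dominance_map",
    "apply_scenario",
    "gradient_profile",
]

#: month-window day ranges (inclusive, non-leap convention)
SEASON_WINDOWS = {
    "mar_sep": (60, 273),
    "apr_sep": (91, 273),
    "feb_nov": (32, 334),
}


@dataclass
class PredictionCube:
    """Softmax observation probabilities indexed (taxon, day, pixel)."""

    probs: np.ndarray  # (n_taxa, n_days, n_pixels)
    taxa: list
    days: np.ndarray
    pixel_index: np.ndarray  # flat row-major indices into the grid
    grid_shape: tuple
    cell_size: float = 1.0
    origin: tuple = (0.0, 0.0)

    def __post_init__(self):
        t, d, p = self.probs.shape
        if t != len(self.taxa) or d != len(self.days) or p != len(self.pixel_index):
            raise ValueError("cube axes misaligned with their indexes")

    def mean_over_days(self) -> np.ndarray:
        """(taxon, pixel) mean daily probability over the cube's days."""
        return self.probs.mean(axis=1)

    def taxon_slice(self, taxon: str) -> np.ndarray:
        return self.probs[self.taxa.index(taxon)]

    def to_grid(self, values: np.ndarray, fill=np.nan) -> np.ndarray:
        """Scatter per-pixel values back onto the (rows, cols) grid."""
        out = np.full(self.grid_shape[0] * self.grid_shape[1], fill, dtype=float)
        out[self.pixel_index] = values
        return out.reshape(self.grid_shape)


def _model_features(model: ModelState, grid: PredictorGrid, pixel_index):
    """Scaled environmental feature rows for the requested pixels."""
    if model.scaling is None:
        raise ValueError("model carries no ScalingSpec; train or load first")
    missing = [n for n in model.scaling.names if n not in grid.names]
    if missing:
        raise ValueError(f"grid is missing predictor layer(s) {missing}")
    flat = np.stack(
        [grid.layer(n).reshape(-1)[pixel_index] for n in model.scaling.names]
    )  # (L, P) raw values in scaling order
    return model.scaling.scale(flat, axis=0).T  # (P, L)


def predict_probabilities(
    model: ModelState, env_features: np.ndarray, days, batch: int = 16384
) -> np.ndarray:
    """(n_taxa, n_days, n_rows) softmax probabilities.

    ``env_features`` are already-scaled environmental rows (no seasonal
    columns); the two seasonal coordinates for each day are appended
    internally. Deterministic (dropout off).
    """
    days = np.atleast_1d(np.asarray(days, dtype=float))
    n_rows = len(env_features)
    out = np.empty((model.config.n_outputs, len(days), n_rows))
    for di, day in enumerate(days):
        s1, s2 = encode_season(
            float(day), model.year_length, model.season_phase, wrap=True
        )
        feats = np.column_stack(
            [env_features, np.full(n_rows, s1), np.full(n_rows, s2)]
        )
        for start in range(0, n_rows, batch):
            scores = model.predict_scores(feats[start : start + batch])
            out[:, di, start : start + batch] = softmax(scores, axis=1).T
    return out


def predict_cube(
    model: ModelState,
    grid: PredictorGrid,
    days,
    pixel_index: np.ndarray | None = None,
) -> PredictionCube:
    """Predict a (taxon, day, pixel) cube on raw-unit predictor layers."""
    n_pix = grid.shape[0] * grid.shape[1]
    pixel_index = (
        np.arange(n_pix) if pixel_index is None else np.asarray(pixel_index)
    )
    env = _model_features(model, grid, pixel_index)
    days = np.atleast_1d(np.asarray(days, dtype=float))
    probs = predict_probabilities(model, env, days)
    return PredictionCube(
        probs=probs,
        taxa=list(model.taxa),
        days=days,
        pixel_index=pixel_index,
        grid_shape=grid.shape,
        cell_size=grid.cell_size,
        origin=grid.origin,
    )


def ensemble_predictions(cubes: list, renormalize: bool = True) -> PredictionCube:
    """Combine member cubes by the square root of the geometric mean.

    For m members, q = (prod_m p_m) ** (1 / (2 m)); any zero member
    probability yields a zero ensemble probability. The concave transform
    preserves within-cell taxon orderings of identical members, so the
    optional renormalization over taxa (default on, keeping the
    probability contract) does not alter ranks.
    """
    first = cubes[0]
    for c in cubes[1:]:
        if (
            c.probs.shape != first.probs.shape
            or c.taxa != first.taxa
            or not np.array_equal(c.days, first.days)
            or not np.array_equal(c.pixel_index, first.pixel_index)
        ):
            raise ValueError("ensemble members are misaligned")
    m = len(cubes)
    stacked = np.stack([c.probs for c in cubes])
    with np.errstate(divide="ignore"):
        logs = np.where(stacked > 0, np.log(stacked), -np.inf)
    q = np.exp(logs.sum(axis=0) / (2.0 * m))
    q[np.isneginf(logs).any(axis=0)] = 0.0
    if renormalize:
        q = q / q.sum(axis=0, keepdims=True)
    return replace(first, probs=q)


def annual_summary(cube: PredictionCube, q: float = 90.0) -> np.ndarray:
    """(taxon, pixel) day-wise percentile summary (linear interpolation).

    By default the 90th percentile over the cube's days — a robust stand-
    in for the seasonal maximum.
    """
    return np.percentile(cube.probs, q, axis=1, method="linear")


def smooth_seasonal(series: np.ndarray, kernel: int = 22) -> np.ndarray:
    """Centred running mean along the last axis with replicate padding.

    For even kernels the extra tap sits toward earlier days (window
    [t - k//2, t + k//2 - 1] for kernel k).
    """
    if kernel < 1:
        raise ValueError("kernel must be >= 1")
    if kernel == 1:
        return np.asarray(series, dtype=float)
    x = np.asarray(series, dtype=float)
    left = kernel // 2
    right = kernel - 1 - left
    pad = [(0, 0)] * (x.ndim - 1) + [(left, right)]
    xp = np.pad(x, pad, mode="edge")
    c = np.cumsum(xp, axis=-1)
    zero = np.zeros_like(c[..., :1])
    c = np.concatenate([zero, c], axis=-1)
    return (c[..., kernel:] - c[..., :-kernel]) / kernel


def find_modes(series: np.ndarray) -> list:
    """Indices of strict interior local maxima of a 1-D series.

    Plateaus count once, at their centre index; window endpoints never
    count as modes. Returned in ascending index order.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    modes = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and x[j + 1] == x[i]:
            j += 1
        left_lower = i > 0 and x[i - 1] < x[i]
        right_lower = j < n - 1 and x[j + 1] < x[i]
        if left_lower and right_lower:
            modes.append((i + j) // 2)
        i = j + 1
    return modes


def tpmax(
    series: np.ndarray,
    days: np.ndarray,
    kernel: int = 22,
    threshold: float = 0.01,
):
    """Day of the highest mode of the smoothed seasonal curve.

    Returns (day, smoothed_max); day is NaN (masked) when the smoothed
    maximum falls below ``threshold`` or no interior mode exists. Ties
    between equally high modes go to the earliest day.
    """
    smooth = smooth_seasonal(series, kernel=kernel)
    smax = float(smooth.max())
    modes = find_modes(smooth)
    if smax < threshold or not modes:
        return np.nan, smax
    heights = smooth[modes]
    best = modes[int(np.argmax(heights))]  # argmax takes first == earliest
    return float(days[best]), smax


def phenology_map(
    cube: PredictionCube,
    taxon: str,
    kernel: int = 22,
    threshold: float = 0.01,
) -> "PhenologyMap":
    """Per-pixel timing of peak observation probability for one taxon."""
    series = cube.taxon_slice(taxon)  # (days, pixels)
    smooth = smooth_seasonal(series.T, kernel=kernel)  # (pixels, days)
    smax = smooth.max(axis=1)
    t_peak = np.full(len(smax), np.nan)
    for i in range(smooth.shape[0]):
        if smax[i] < threshold:
            continue
        modes = find_modes(smooth[i])
        if not modes:
            continue
        best = modes[int(np.argmax(smooth[i][modes]))]
        t_peak[i] = cube.days[best]
    return PhenologyMap(
        taxon=taxon,
        t_peak=cube.to_grid(t_peak),
        smoothed_max=cube.to_grid(smax),
        days=(float(cube.days[0]), float(cube.days[-1])),
    )


@dataclass
class PhenologyMap:
    """Timing of the highest smoothed seasonal mode, NaN where masked."""

    taxon: str
    t_peak: np.ndarray  # (rows, cols), day of year or NaN
    smoothed_max: np.ndarray
    days: tuple  # prediction window (first, last day)


def aggregate_map(
    values: np.ndarray, factor: int, statistic: str = "median"
) -> np.ndarray:
    """Block-aggregate a 2-D map, ignoring masked (NaN / negative) cells.

    ``median`` for continuous maps (NaN masked); ``mode`` for integer
    category maps (negative = masked, ties to the lowest category). A
    fully masked block stays masked.
    """
    a = np.asarray(values)
    r, c = a.shape
    if r % factor or c % factor:
        raise ValueError("map shape must be divisible by the block factor")
    blocks = a.reshape(r // factor, factor, c // factor, factor)
    blocks = blocks.transpose(0, 2, 1, 3).reshape(r // factor, c // factor, -1)
    if statistic == "median":
        with np.errstate(all="ignore"):
            import warnings as _w

            with _w.catch_warnings():
                _w.simplefilter("ignore", RuntimeWarning)
                return np.nanmedian(blocks.astype(float), axis=-1)
    if statistic == "mode":
        out = np.full(blocks.shape[:2], -1, dtype=int)
        for i in range(out.shape[0]):
            for j in range(out.shape[1]):
                vals = blocks[i, j]
                vals = vals[vals >= 0]
                if len(vals):
                    counts = np.bincount(vals.astype(int))
                    out[i, j] = int(np.argmax(counts))  # ties -> lowest index
        return out
    raise ValueError("statistic must be 'median' or 'mode'")


@dataclass
class BiasWeights:
    """Per-taxon reporting-bias multipliers (NaN = not calibratable)."""

    taxa: list
    w: np.ndarray

    def lookup(self, taxa: list) -> np.ndarray:
        idx = {t: i for i, t in enumerate(self.taxa)}
        return np.array([self.w[idx[t]] if t in idx else np.nan for t in taxa])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"taxon": self.taxa, "weight": self.w})


def _survey_pixels(survey: SurveyTable, cube: PredictionCube) -> np.ndarray:
    cell, (x0, y0) = cube.cell_size, cube.origin
    col = np.floor((survey.sites["x"].to_numpy() - x0) / cell).astype(int)
    row = np.floor((survey.sites["y"].to_numpy() - y0) / cell).astype(int)
    flat = row * cube.grid_shape[1] + col
    pos = np.searchsorted(cube.pixel_index, flat)
    pos = np.clip(pos, 0, len(cube.pixel_index) - 1)
    if not np.all(cube.pixel_index[pos] == flat):
        raise ValueError("survey sites fall outside the prediction cube")
    return pos


def bias_correction_weights(
    survey: SurveyTable, cube: PredictionCube
) -> BiasWeights:
    """Reporting-bias weights: summed survey cover / summed predicted prob.

    ``cube`` should span the season of interest (canonically the
    February-November window); its day-mean probability at each survey
    pixel is the denominator. By construction, applying the weights makes
    each taxon's weighted probability sum over the survey sites equal its
    summed cover percentage. Taxa absent from the survey get weight NaN
    and are excluded from dominance candidates.
    """
    pos = _survey_pixels(survey, cube)
    mean_p = cube.mean_over_days()[:, pos]  # (taxa, sites)
    taxa = cube.taxa
    cover_sum = np.array(
        [
            survey.cover[t].to_numpy(dtype=float).sum()
            if t in survey.cover.columns
            else np.nan
            for t in taxa
        ]
    )
    pred_sum = mean_p.sum(axis=1)
    w = np.full(len(taxa), np.nan)
    for i, t in enumerate(taxa):
        if np.isnan(cover_sum[i]):
            continue
        if pred_sum[i] == 0:
            if cover_sum[i] > 0:
                raise ZeroDivisionError(
                    f"taxon {t!r} has survey cover but zero predicted "
                    "probability at the survey sites"
                )
            continue
        w[i] = cover_sum[i] / pred_sum[i]
    return BiasWeights(taxa=list(taxa), w=w)


@dataclass
class DominanceMap:
    """Winning taxon per pixel; -1 where masked (non-wooded / no candidate)."""

    winner: np.ndarray  # (rows, cols) int taxon index, -1 masked
    score: np.ndarray  # winning weighted mean probability
    taxa: list
    corrected: bool


def dominance_map(
    cube: PredictionCube,
    weights: BiasWeights | None,
    wooded_mask: np.ndarray,
) -> DominanceMap:
    """Potentially dominant taxon: argmax of weighted mean probability.

    ``weights=None`` gives the raw (uncorrected) map. Taxa whose weight
    is NaN (not covered by the calibration survey) are excluded from the
    candidate set. Non-wooded pixels are masked.
    """
    mean_p = cube.mean_over_days()  # (taxa, pixels)
    if weights is None:
        w = np.ones(len(cube.taxa))
    else:
        w = weights.lookup(cube.taxa)
    candidates = np.flatnonzero(~np.isnan(w))
    if len(candidates) == 0:
        raise ValueError("no candidate taxa with defined weights")
    weighted = w[candidates, None] * mean_p[candidates]
    win_local = np.argmax(weighted, axis=0)
    winner = candidates[win_local]
    score = weighted[win_local, np.arange(weighted.shape[1])]

    winner_grid = cube.to_grid(winner.astype(float), fill=np.nan)
    score_grid = cube.to_grid(score, fill=np.nan)
    masked = ~wooded_mask.astype(bool) | np.isnan(winner_grid)
    out = np.where(masked, -1, np.nan_to_num(winner_grid, nan=-1)).astype(int)
    score_grid = np.where(masked, np.nan, score_grid)
    return DominanceMap(
        winner=out,
        score=score_grid,
        taxa=list(cube.taxa),
        corrected=weights is not None,
    )


@dataclass
class ScenarioSpec:
    """Per-layer predictor deltas plus optional derived-layer transforms.

    ``add`` entries are additive deltas in raw layer units, ``mul``
    multiplicative factors (e.g. 0.825 for a 17.5% precipitation
    decrease); both are applied before the stored scaling is re-applied.
    ``derived`` maps a layer name to a function of the raw layer dict,
    evaluated after the deltas (e.g. a frost-frequency transform of
    future winter temperature).
    """

    add: dict = field(default_factory=dict)
    mul: dict = field(default_factory=dict)
    flag_extrapolation: bool = True
    derived: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioSpec":
        return cls(
            add=dict(d.get("add", {})),
            mul=dict(d.get("mul", {})),
            flag_extrapolation=bool(d.get("flag_extrapolation", True)),
        )


def apply_scenario(
    grid: PredictorGrid,
    scenario: ScenarioSpec,
    model: ModelState,
    days,
    pixel_index: np.ndarray | None = None,
):
    """Predict under shifted predictors, flagging extrapolated cells.

    Deltas are applied to the raw layers, the model's stored scaling is
    re-applied, and any pixel whose scaled feature leaves [-1, 1] (i.e.
    beyond the training min/max) is flagged. Returns
    (PredictionCube, flags) with flags aligned to the cube's pixels. A
    zero-delta scenario reproduces current predictions bit-exactly.
    """
    for name in list(scenario.add) + list(scenario.mul) + list(scenario.derived):
        if name not in grid.names:
            raise ValueError(f"scenario targets unknown layer {name!r}")
    values = grid.values.copy()
    for name, delta in scenario.add.items():
        values[grid.names.index(name)] += delta
    for name, factor in scenario.mul.items():
        values[grid.names.index(name)] *= factor
    if scenario.derived:
        raw = {n: values[i] for i, n in enumerate(grid.names)}
        for name, fn in scenario.derived.items():
            values[grid.names.index(name)] = fn(raw)
    shifted = replace(grid, values=values, scaling=None)

    cube = predict_cube(model, shifted, days, pixel_index=pixel_index)
    if scenario.flag_extrapolation:
        env_scaled = _model_features(model, shifted, cube.pixel_index)
        flags = np.any((env_scaled < -1.0) | (env_scaled > 1.0), axis=1)
    else:
        flags = np.zeros(len(cube.pixel_index), dtype=bool)
    return cube, flags


def gradient_profile(
    positions: np.ndarray,
    values: np.ndarray,
    span: float = 0.15,
    degree: int = 2,
    eval_at: np.ndarray | None = None,
) -> np.ndarray:
    """Local polynomial (loess-style) fit of values along a transect.

    ``values`` has shape (n_taxa, n_positions) (a single row is also
    accepted); each curve is fitted independently with tricube-weighted
    polynomial regression of the given degree over the ``span`` fraction
    of nearest points. Used to draw smoothed per-taxon probability
    profiles along elevational gradients.
    """
    x = np.asarray(positions, dtype=float)
    v = np.atleast_2d(np.asarray(values, dtype=float))
    if v.shape[1] != len(x):
        raise ValueError("values must align with positions")
    xe = x if eval_at is None else np.asarray(eval_at, dtype=float)
    q = max(int(np.ceil(span * len(x))), degree + 1)
    out = np.empty((v.shape[0], len(xe)))
    for j, x0 in enumerate(xe):
        d = np.abs(x - x0)
        nearest = np.argsort(d, kind="stable")[:q]
        dmax = d[nearest].max()
        if dmax == 0:
            out[:, j] = v[:, nearest].mean(axis=1)
            continue
        wts = (1.0 - (d[nearest] / dmax) ** 3) ** 3
        sw = np.sqrt(np.maximum(wts, 1e-12))
        design = np.vander(x[nearest] - x0, degree + 1, increasing=True)
        # weighted least squares, intercept = fit at x0
        beta, *_ = np.linalg.lstsq(
            design * sw[:, None], v[:, nearest].T * sw[:, None], rcond=None
        )
        out[:, j] = beta[0]
    return out
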