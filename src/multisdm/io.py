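"""Readers and writers for cubes, partitions, and synthetic truth tables.

Tabular data travels as CSV, gridded data as .npz containers with JSON
headers (see :mod:`multisdm.grids` for predictor stacks).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .inference import PredictionCube
from .observations import DatasetPartition

__all__ = [
    "save_cube",
    "load_cube",
    "save_partition",
    "load_partition",
    "export_bundle",
]


def save_cube(path, cube: PredictionCube) -> None:
    header = {
        "taxa": cube.taxa,
        "grid_shape": list(cube.grid_shape),
        "cell_size": cube.cell_size,
        "origin": list(cube.origin),
    }
    np.savez_compressed(
        path,
        probs=cube.probs,
        days=cube.days,
        pixel_index=cube.pixel_index,
        header=np.array(json.dumps(header)),
    )


def load_cube(path) -> PredictionCube:
    with np.load(path, allow_pickle=False) as z:
        header = json.loads(str(z["header"]))
        return PredictionCube(
            probs=z["probs"],
            taxa=list(header["taxa"]),
            days=z["days"],
            pixel_index=z["pixel_index"],
            grid_shape=tuple(header["grid_shape"]),
            cell_size=float(header["cell_size"]),
            origin=tuple(header["origin"]),
        )


def save_partition(path, partition: DatasetPartition) -> None:
    Path(path).write_text(json.dumps(partition.to_dict()))


def load_partition(path) -> DatasetPartition:
    return DatasetPartition.from_dict(json.loads(Path(path).read_text()))


def export_bundle(bundle, out_dir) -> dict:
    """Write a synthetic bundle's data and truth tables to a directory.

    Emits the observation CSV, the raw predictor grid (.npz), the survey
    CSV (long format), and the truth tables: per-taxon true peak days
    and the true dominant taxon per pixel.
    """
    from .grids import save_grid
    from .synth import truth_dominant, truth_peak

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["observations"] = out / "observations.csv"
    bundle.observations.to_csv(paths["observations"])

    paths["grid"] = out / "predictors.npz"
    save_grid(paths["grid"], bundle.landscape.grid)

    paths["surveys"] = out / "surveys.csv"
    bundle.surveys.to_long_csv(paths["surveys"])

    rows, cols = np.indices(bundle.landscape.shape)
    peaks = {
        "row": rows.ravel(),
        "col": cols.ravel(),
    }
    for sp in bundle.species:
        peaks[sp.name] = truth_peak(bundle.landscape, sp).ravel()
    paths["truth_peaks"] = out / "truth_peaks.csv"
    pd.DataFrame(peaks).to_csv(paths["truth_peaks"], index=False)

    dom = truth_dominant(bundle.landscape, bundle.species)
    taxa = np.asarray(bundle.taxa, dtype=object)
    paths["truth_dominant"] = out / "truth_dominant.csv"
    pd.DataFrame(
        {
            "row": rows.ravel(),
            "col": cols.ravel(),
            "wooded": bundle.landscape.wooded.ravel().astype(int),
            "taxon": taxa[dom.ravel()],
        }
    ).to_csv(paths["truth_dominant"], index=False)
    return paths
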