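"""Feature assembly and end-to-end model fitting.

Glue between the data containers and the network: turns observation
records into scaled feature rows (environmental layers at the record's
pixel plus the circular seasonal coordinates of its day) and runs the
standard prepare -> partition -> train sequence.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grids import PredictorGrid, rescale_predictors
from .network import (
    NetworkConfig,
    TrainingConfig,
    build_network,
    train_two_phase,
)
from .observations import DatasetPartition, ObservationTable, partition_train_test
from .seasonal import encode_season

__all__ = ["assemble_features", "fit_model"]


def assemble_features(
    df: pd.DataFrame,
    grid: PredictorGrid,
    scaling,
    year_length: float = 365.25,
    season_phase: float = 0.0,
) -> np.ndarray:
    """Scaled feature rows (env + 2 seasonal) for observation records."""
    col = np.floor((df["x"].to_numpy() - grid.origin[0]) / grid.cell_size)
    row = np.floor((df["y"].to_numpy() - grid.origin[1]) / grid.cell_size)
    row = row.astype(int)
    col = col.astype(int)
    if (
        np.any(row < 0)
        or np.any(row >= grid.shape[0])
        or np.any(col < 0)
        or np.any(col >= grid.shape[1])
    ):
        raise ValueError("observation coordinates fall outside the grid")
    raw = np.stack([grid.layer(n)[row, col] for n in scaling.names])
    env = scaling.scale(raw, axis=0).T
    s1, s2 = encode_season(
        df["doy"].to_numpy(dtype=float), year_length, season_phase, wrap=True
    )
    return np.column_stack([env, s1, s2])


def fit_model(
    table: ObservationTable,
    grid: PredictorGrid,
    network: NetworkConfig | None = None,
    training: TrainingConfig | None = None,
    partition: DatasetPartition | None = None,
    n_test: int = 5,
    min_train: int = 20,
    n_val_per_taxon: int = 5,
    seed: int = 0,
    width: int = 380,
    n_blocks: int = 4,
    year_length: float = 365.25,
    season_phase: float = 0.0,
):
    """Partition, rescale, build and train a model; returns (model, partition).

    The grid is rescaled to [-1, 1] if it has no scaling yet, and the
    resulting ScalingSpec is stored on the model. The validation slice
    used for phase-2 early stopping samples ``n_val_per_taxon`` records
    per taxon from the training data, drawn independently of the
    train/test split.
    """
    training = training or TrainingConfig(seed=seed)
    if grid.scaling is None:
        grid = rescale_predictors(grid)
    if partition is None:
        partition = partition_train_test(
            table, n_test=n_test, min_train=min_train, seed=seed
        )
    if not partition.taxa:
        raise ValueError("no taxon meets the minimum-record thresholds")
    taxa = partition.taxa
    taxon_index = {t: i for i, t in enumerate(taxa)}

    train_rows = partition.all_train_indices()
    df_train = table.df.loc[train_rows]
    X = assemble_features(df_train, grid, grid.scaling, year_length, season_phase)
    y = df_train["taxon"].map(taxon_index).to_numpy(dtype=int)

    rng = np.random.default_rng(seed + 1)
    val_sel = []
    for t in taxa:
        rows = np.flatnonzero(df_train["taxon"].to_numpy() == t)
        take = min(n_val_per_taxon, len(rows))
        val_sel.append(rng.choice(rows, size=take, replace=False))
    val_sel = np.concatenate(val_sel) if val_sel else np.array([], dtype=int)

    network = network or NetworkConfig(
        n_inputs=X.shape[1], n_outputs=len(taxa), width=width, n_blocks=n_blocks
    )
    model = build_network(network, seed=seed, taxa=taxa)
    model.scaling = grid.scaling
    model.year_length = year_length
    model.season_phase = season_phase
    train_two_phase(
        model,
        X,
        y,
        training,
        val_features=X[val_sel] if len(val_sel) else None,
        val_labels=y[val_sel] if len(val_sel) else None,
    )
    return model, partition
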