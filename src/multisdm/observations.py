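"""Presence-only observation tables: filtering, pooling, partitioning.

Observations are single-positive records — one taxon reported at one
place and day, with no information about other taxa. The table is a thin
wrapper over a pandas DataFrame with the canonical columns plus a
taxonomy map used to pool sub-taxon labels (e.g. subspecies) into the
labels the model is trained on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OBS_COLUMNS",
    "ObservationTable",
    "filter_observations",
    "pool_taxa",
    "partition_train_test",
    "DatasetPartition",
]

OBS_COLUMNS = ["taxon", "x", "y", "doy", "year", "coord_uncertainty"]
#: key identifying an exact duplicate record
DEDUP_KEY = ["taxon", "x", "y", "doy", "year"]


@dataclass
class ObservationTable:
    """Ordered presence-only records plus an optional taxonomy map."""

    df: pd.DataFrame
    taxonomy: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in OBS_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"observation table missing columns {missing}")
        if "phenology_state" not in self.df.columns:
            self.df = self.df.assign(phenology_state=pd.NA)
        bad = self.df["taxon"].isna() | (self.df["taxon"].astype(str) == "")
        if bad.any():
            raise ValueError("taxon labels must be non-empty")
        if (self.df["coord_uncertainty"].dropna() < 0).any():
            raise ValueError("coord_uncertainty must be >= 0")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def taxa(self) -> list:
        return sorted(self.df["taxon"].unique())

    def copy(self) -> "ObservationTable":
        return ObservationTable(self.df.copy(), dict(self.taxonomy))

    @classmethod
    def from_csv(cls, path, taxonomy: dict | None = None) -> "ObservationTable":
        df = pd.read_csv(path)
        return cls(df, taxonomy or {})

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


def _dedup(df: pd.DataFrame) -> pd.DataFrame:
    return df.drop_duplicates(subset=DEDUP_KEY, keep="first")


def filter_observations(
    table: ObservationTable,
    max_uncertainty: float = 100.0,
    min_year: int = 1971,
    require_date: bool = True,
) -> ObservationTable:
    """Apply the standard quality filters and drop duplicates.

    Records are kept when their coordinate uncertainty is at most
    ``max_uncertainty`` and their year is ``min_year`` or later. With
    ``require_date`` set, records without a usable day of year are
    dropped: missing ``doy``, and ``doy`` exactly equal to the first or
    the last day of the year, which year-resolution sources use as
    sentinel timestamps (first/last second of the year). The operation is
    idempotent.
    """
    df = table.df
    keep = df["coord_uncertainty"].fillna(np.inf) <= max_uncertainty
    keep &= df["year"].fillna(-np.inf) >= min_year
    if require_date:
        doy = df["doy"]
        keep &= doy.notna()
        keep &= ~doy.isin([1.0, 365.0, 366.0])
    out = _dedup(df.loc[keep]).reset_index(drop=True)
    return ObservationTable(out, dict(table.taxonomy))


def pool_taxa(
    table: ObservationTable, taxonomy: dict | None = None
) -> ObservationTable:
    """Replace sub-taxon labels by their pooled labels and re-deduplicate.

    ``taxonomy`` maps sub-taxon label -> pooled label; labels without an
    entry are left unchanged. Records that become identical after
    relabelling collapse to one.
    """
    mapping = taxonomy if taxonomy is not None else table.taxonomy
    df = table.df.copy()
    df["taxon"] = df["taxon"].map(lambda t: mapping.get(t, t))
    out = _dedup(df).reset_index(drop=True)
    return ObservationTable(out, dict(mapping))


@dataclass
class DatasetPartition:
    """Per-taxon train/test row indices into the observation DataFrame.

    ``n_train`` (the per-taxon training counts) double as the evaluation
    weights used to de-stratify metrics on the taxonomically balanced
    test set.
    """

    train_idx: dict
    test_idx: dict
    n_train: dict
    taxa: list

    def all_train_indices(self) -> np.ndarray:
        if not self.taxa:
            return np.array([], dtype=int)
        return np.concatenate([self.train_idx[t] for t in self.taxa])

    def all_test_indices(self) -> np.ndarray:
        if not self.taxa:
            return np.array([], dtype=int)
        return np.concatenate([self.test_idx[t] for t in self.taxa])

    def to_dict(self) -> dict:
        return {
            "taxa": self.taxa,
            "train_idx": {t: v.tolist() for t, v in self.train_idx.items()},
            "test_idx": {t: v.tolist() for t, v in self.test_idx.items()},
            "n_train": dict(self.n_train),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DatasetPartition":
        return cls(
            train_idx={
                t: np.asarray(v, dtype=int) for t, v in d["train_idx"].items()
            },
            test_idx={
                t: np.asarray(v, dtype=int) for t, v in d["test_idx"].items()
            },
            n_train={t: int(v) for t, v in d["n_train"].items()},
            taxa=list(d["taxa"]),
        )


def partition_train_test(
    table: ObservationTable,
    n_test: int = 5,
    min_train: int = 20,
    seed: int = 0,
) -> DatasetPartition:
    """Split records into a balanced test set and the remaining training set.

    For every taxon with at least ``n_test + min_train`` records,
    ``n_test`` records are sampled without replacement (seeded) as test
    data and the rest become training data; taxa below the threshold are
    excluded entirely.
    """
    if n_test < 1:
        raise ValueError("n_test must be >= 1")
    rng = np.random.default_rng(seed)
    train_idx, test_idx, n_train, taxa = {}, {}, {}, []
    for taxon, sub in table.df.groupby("taxon", sort=True):
        idx = sub.index.to_numpy()
        if len(idx) < n_test + min_train:
            continue
        chosen = rng.choice(len(idx), size=n_test, replace=False)
        mask = np.zeros(len(idx), dtype=bool)
        mask[chosen] = True
        taxa.append(taxon)
        test_idx[taxon] = np.sort(idx[mask])
        train_idx[taxon] = np.sort(idx[~mask])
        n_train[taxon] = int(len(idx) - n_test)
    return DatasetPartition(train_idx, test_idx, n_train, taxa)
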