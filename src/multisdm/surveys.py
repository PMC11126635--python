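"""Cover-abundance survey tables and the Braun-Blanquet translation.

Vegetation plots record semi-quantitative cover-abundance classes
(Braun-Blanquet symbols r, +, 1..5). For calibration of taxonomic
reporting bias these are translated to percent cover with a class ->
midpoint table; the default table is user-overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_COVER_TRANSLATION",
    "CoverTranslationTable",
    "SurveyTable",
    "translate_cover",
]

#: class midpoints in percent cover, strictly increasing with class order
DEFAULT_COVER_TRANSLATION = {
    "r": 0.1,
    "+": 0.5,
    "1": 2.5,
    "2": 15.0,
    "3": 37.5,
    "4": 62.5,
    "5": 87.5,
}


@dataclass(frozen=True)
class CoverTranslationTable:
    """Braun-Blanquet symbol -> percent cover lookup."""

    values: dict = field(
        default_factory=lambda: dict(DEFAULT_COVER_TRANSLATION)
    )

    def __post_init__(self):
        pct = list(self.values.values())
        if any(p <= 0 or p > 100 for p in pct):
            raise ValueError("cover percentages must lie in (0, 100]")
        if any(b <= a for a, b in zip(pct, pct[1:])):
            raise ValueError("cover percentages must increase with class order")

    def lookup(self, symbol) -> float:
        if symbol is None or (isinstance(symbol, float) and np.isnan(symbol)):
            return 0.0
        s = str(symbol).strip()
        if s == "" or s == "0":
            return 0.0
        if s not in self.values:
            raise ValueError(f"unknown Braun-Blanquet symbol {symbol!r}")
        return float(self.values[s])


@dataclass
class SurveyTable:
    """Site coordinates plus a site x taxon matrix of percent cover."""

    sites: pd.DataFrame  # columns: site, x, y
    cover: pd.DataFrame  # index: site, columns: taxon, values in [0, 100]
    layer: str | None = None

    def __post_init__(self):
        for c in ("site", "x", "y"):
            if c not in self.sites.columns:
                raise ValueError(f"sites table missing column {c!r}")
        vals = self.cover.to_numpy(dtype=float)
        if np.any((vals < 0) | (vals > 100)):
            raise ValueError("cover values must lie in [0, 100]")
        if not self.cover.index.equals(pd.Index(self.sites["site"])):
            raise ValueError("cover rows must align with site list")

    @property
    def taxa(self) -> list:
        return list(self.cover.columns)

    @classmethod
    def from_long_csv(cls, path) -> "SurveyTable":
        """Read a long-format CSV with columns site, x, y, taxon, cover."""
        df = pd.read_csv(path)
        sites = (
            df[["site", "x", "y"]].drop_duplicates("site").reset_index(drop=True)
        )
        cover = (
            df.pivot_table(
                index="site", columns="taxon", values="cover", fill_value=0.0
            )
            .reindex(sites["site"])
        )
        cover.columns.name = None
        return cls(sites=sites, cover=cover)

    def to_long_csv(self, path) -> None:
        long = (
            self.cover.reset_index(names="site")
            .melt(id_vars="site", var_name="taxon", value_name="cover")
            .merge(self.sites, on="site")
        )
        long[["site", "x", "y", "taxon", "cover"]].to_csv(path, index=False)


def translate_cover(
    symbols: pd.DataFrame,
    sites: pd.DataFrame,
    table: CoverTranslationTable | None = None,
) -> SurveyTable:
    """Translate a site x taxon matrix of Braun-Blanquet symbols to percent.

    Absent cells (NaN or empty) translate to 0% cover; unknown symbols
    raise a ValueError.
    """
    table = table or CoverTranslationTable()
    cover = symbols.map(table.lookup).astype(float)
    return SurveyTable(sites=sites, cover=cover)
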