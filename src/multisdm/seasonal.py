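"""Circular (sine-cosine) encoding of the day of year.

Observation season enters the model as a point on the unit circle so that
December 31 and January 1 are neighbours. With the default phase of zero,
the cosine coordinate varies roughly like day length over the year and the
sine coordinate like its rate of change; an optional phase offset rotates
the convention (e.g. to align the cosine extreme with a solstice).
"""

from __future__ import annotations

import numpy as np

__all__ = ["encode_season", "DEFAULT_YEAR_LENGTH"]

DEFAULT_YEAR_LENGTH = 365.25


def encode_season(
    doy,
    year_length: float = DEFAULT_YEAR_LENGTH,
    phase: float = 0.0,
    *,
    wrap: bool = False,
):
    """Map day of year to two circular coordinates (s1, s2) = (sin, cos).

    Parameters
    ----------
    doy : float or array-like
        Day of year. Must lie in [0, year_length] unless ``wrap`` is set,
        in which case it is reduced modulo ``year_length``.
    year_length : float
        Length of the seasonal period in days.
    phase : float
        Phase offset in days subtracted from ``doy`` before encoding.
    wrap : bool
        Accept out-of-range days by wrapping instead of raising.

    Returns
    -------
    (s1, s2) : tuple of ndarray or floats on the unit circle.
    """
    d = np.asarray(doy, dtype=float)
    if year_length <= 0:
        raise ValueError("year_length must be positive")
    if wrap:
        d = np.mod(d, year_length)
    elif np.any(d < 0) or np.any(d > year_length):
        raise ValueError(
            f"doy outside [0, {year_length}]; pass wrap=True to reduce modulo"
        )
    theta = 2.0 * np.pi * (d - phase) / year_length
    s1, s2 = np.sin(theta), np.cos(theta)
    if np.isscalar(doy) or (isinstance(doy, np.ndarray) and doy.ndim == 0):
        return float(s1), float(s2)
    return s1, s2
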