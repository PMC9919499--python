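"""Location context encoding.

GPS coordinates are discretized into geohash cells so that "where the user
went sedentary" can enter the behavior model as a categorical context.  A
7-character geohash (35 bits) covers roughly a 150 m x 150 m cell, fine
enough to separate an office from a cafeteria but coarse enough that
repeated visits to the same place collapse onto one label.

Also provides the one-hot factoring of mission-log contexts used by the
model fit, and the frequency-rank relabeling ("top-1" .. "top-k", "other")
used by the outcome analysis so that participants living in different
places become comparable.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GEOHASH_BASE32",
    "UNKNOWN_CONTEXT",
    "encode_geohash",
    "one_hot_contexts",
    "top_k_relabel",
]

#: Standard geohash alphabet: digits + lowercase letters minus a, i, l, o.
GEOHASH_BASE32 = "0123456789bcdefghjkmnpqrstuvwxyz"

#: Context label used when a stationary event has no known location.
UNKNOWN_CONTEXT = "unknown"


def encode_geohash(latitude: float, longitude: float, precision: int = 7) -> str:
    """Encode a WGS-84 coordinate as a base-32 geohash string.

    Bits alternately bisect the longitude and latitude ranges (longitude
    first) and are packed five at a time into base-32 characters.

    Parameters
    ----------
    latitude, longitude
        Degrees; latitude in [-90, 90], longitude in [-180, 180].
    precision
        Number of output characters (>= 1); 7 gives ~150 m cells.
    """
    if precision < 1:
        raise ValueError(f"precision must be >= 1, got {precision}")
    if not (math.isfinite(latitude) and math.isfinite(longitude)):
        raise ValueError("coordinates must be finite")
    if not -90.0 <= latitude <= 90.0:
        raise ValueError(f"latitude out of range: {latitude}")
    if not -180.0 <= longitude <= 180.0:
        raise ValueError(f"longitude out of range: {longitude}")

    lat_lo, lat_hi = -90.0, 90.0
    lon_lo, lon_hi = -180.0, 180.0
    chars: list[str] = []
    bit = 0
    ch = 0
    even = True  # even bit index -> longitude
    while len(chars) < precision:
        if even:
            mid = (lon_lo + lon_hi) / 2.0
            if longitude >= mid:
                ch = (ch << 1) | 1
                lon_lo = mid
            else:
                ch = ch << 1
                lon_hi = mid
        else:
            mid = (lat_lo + lat_hi) / 2.0
            if latitude >= mid:
                ch = (ch << 1) | 1
                lat_lo = mid
            else:
                ch = ch << 1
                lat_hi = mid
        even = not even
        bit += 1
        if bit == 5:
            chars.append(GEOHASH_BASE32[ch])
            bit = 0
            ch = 0
    return "".join(chars)


def one_hot_contexts(records: Sequence) -> tuple[list[str], np.ndarray]:
    """One-hot encode the geohash contexts of a mission log.

    Labels are the distinct geohash codes in first-appearance order; the
    returned indicator matrix has one row per record with exactly one 1.
    Accepts any sequence of objects exposing a ``geohash`` attribute (or
    raw strings).
    """
    codes = [getattr(r, "geohash", r) for r in records]
    labels: list[str] = []
    index: dict[str, int] = {}
    for c in codes:
        if c not in index:
            index[c] = len(labels)
            labels.append(c)
    matrix = np.zeros((len(codes), len(labels)), dtype=float)
    for row, c in enumerate(codes):
        matrix[row, index[c]] = 1.0
    return labels, matrix


def top_k_relabel(records: Iterable, k: int = 5) -> dict[str, str]:
    """Relabel geohash cells by mission frequency: "top-1".."top-k", else "other".

    Cells are ranked by descending mission count; frequency ties are broken
    by the earliest first-mission timestamp, then lexicographically by code,
    so the ranking is deterministic.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    counts: dict[str, int] = {}
    first_seen: dict[str, object] = {}
    order: dict[str, int] = {}  # arrival order fallback when timestamps absent
    for r in records:
        code = getattr(r, "geohash", None)
        ts = getattr(r, "triggered_at", None)
        if code is None:  # plain (code, timestamp) pairs or bare codes
            if isinstance(r, tuple):
                code, ts = r
            else:
                code = r
        counts[code] = counts.get(code, 0) + 1
        if code not in first_seen:
            first_seen[code] = ts
            order[code] = len(order)

    def sort_key(code: str):
        ts = first_seen[code]
        # timestamps may be absent; fall back to arrival order, then code
        ts_key = (0, ts) if ts is not None else (1, order[code])
        return (-counts[code], ts_key, code)

    ranked = sorted(counts, key=sort_key)
    labels: dict[str, str] = {}
    for rank, code in enumerate(ranked, start=1):
        labels[code] = f"top-{rank}" if rank <= k else "other"
    return labels
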