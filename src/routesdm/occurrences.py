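"""Occurrence-record cleaning, spatial thinning, and minimum-count filtering.

Occurrence tables are pandas DataFrames with columns
``species, lon, lat, year, month``.  When read from CSV, lon/lat are kept as
the original strings so that the decimal-place precision filter can operate
on the printed representation (trailing zeros are unrecoverable from
floats); numeric coordinate columns bypass that filter with a logged notice.
"""

from __future__ import annotations

import logging
import re

import numpy as np
import pandas as pd

from .geometry import pairwise_haversine_km

logger = logging.getLogger(__name__)

COLUMNS = ["species", "lon", "lat", "year", "month"]

_NUM_RE = re.compile(r"^[+-]?(\d+)(?:\.(\d+))?$")


def read_occurrences_csv(path, delimiter: str = ",") -> pd.DataFrame:
    """Read an occurrence CSV keeping lon/lat as strings for precision checks."""
    df = pd.read_csv(path, delimiter=delimiter,
                     dtype={"lon": str, "lat": str}, keep_default_na=True)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"occurrence CSV missing columns: {missing}")
    return df[COLUMNS].copy()


def write_occurrences_csv(df: pd.DataFrame, path, delimiter: str = ",") -> None:
    df.to_csv(path, sep=delimiter, index=False)


def _decimals(text: str) -> int | None:
    """Number of decimal places in a printed coordinate; None if malformed."""
    m = _NUM_RE.match(str(text).strip())
    if m is None:
        return None
    return len(m.group(2) or "")


def quality_filter(records: pd.DataFrame, min_year: int = 2000,
                   min_decimals: int = 3, keep_missing_year: bool = False) -> pd.DataFrame:
    """Temporal, positional-precision and duplicate filtering.

    Drops records before ``min_year`` (missing years are dropped unless
    ``keep_missing_year``), records whose printed lon or lat has fewer than
    ``min_decimals`` decimal places (string coordinates only), malformed
    coordinates, coordinates outside valid ranges, and exact duplicates on
    (species, lon, lat, year, month).  Rejection counts are logged.
    """
    if min_decimals < 0:
        raise ValueError("min_decimals must be >= 0")
    df = records.copy()
    n0 = len(df)
    if n0 == 0:
        return df

    year = pd.to_numeric(df["year"], errors="coerce")
    keep = year >= min_year
    if keep_missing_year:
        keep |= year.isna()
    df = df[keep]
    n_year = n0 - len(df)

    lon_is_str = df["lon"].dtype == object
    lat_is_str = df["lat"].dtype == object
    n_prec = n_mal = 0
    if lon_is_str or lat_is_str:
        def ok(row):
            nonlocal n_prec, n_mal
            for v, is_str in ((row["lon"], lon_is_str), (row["lat"], lat_is_str)):
                if not is_str:
                    continue
                d = _decimals(v)
                if d is None:
                    n_mal += 1
                    return False
                if d < min_decimals:
                    n_prec += 1
                    return False
            return True
        df = df[df.apply(ok, axis=1)] if len(df) else df
    else:
        logger.info("numeric coordinate columns: decimal-precision filter bypassed")

    lon = pd.to_numeric(df["lon"], errors="coerce")
    lat = pd.to_numeric(df["lat"], errors="coerce")
    in_range = lon.between(-180, 180) & lat.between(-90, 90) & df["species"].astype(str).str.len().gt(0)
    n_range = int((~in_range).sum())
    df = df[in_range]

    before_dup = len(df)
    df = df.drop_duplicates(subset=COLUMNS)
    logger.info("quality_filter: %d in, dropped %d (year), %d (precision), "
                "%d (malformed), %d (range), %d (duplicates), %d out",
                n0, n_year, n_prec, n_mal, n_range, before_dup - len(df), len(df))
    return df.reset_index(drop=True)


def drop_near_duplicates(records: pd.DataFrame, radius_km: float = 1.0) -> pd.DataFrame:
    """Drop the later record of same-species/year/month pairs within radius_km.

    Mirrors the manual removal of cross-database rounding duplicates: records
    that agree on species, year and month but differ slightly in coordinates.
    """
    df = records.reset_index(drop=True)
    drop = np.zeros(len(df), dtype=bool)
    lon = pd.to_numeric(df["lon"]).to_numpy(float)
    lat = pd.to_numeric(df["lat"]).to_numpy(float)
    for _, idx in df.groupby(["species", "year", "month"], dropna=False).groups.items():
        idx = np.asarray(idx)
        if len(idx) < 2:
            continue
        d = pairwise_haversine_km(lon[idx], lat[idx])
        for a in range(len(idx)):
            if drop[idx[a]]:
                continue
            close = np.nonzero(d[a, a + 1:] <= radius_km)[0] + a + 1
            drop[idx[close]] = True
    return df[~drop].reset_index(drop=True)


def spatial_thin(records: pd.DataFrame, min_dist_km: float = 10.0,
                 n_repeats: int = 10, seed: int = 0) -> pd.DataFrame:
    """Thin one species' records so no pair is closer than ``min_dist_km``.

    Randomized greedy with restarts: each pass iteratively deletes a record
    with the most remaining neighbours within the distance (random
    tie-break); the pass retaining the most records wins.  Exact maximum
    retention is NP-hard (maximum independent set), so this is a heuristic —
    the standard approach of occurrence-thinning tools.  Deterministic for a
    fixed seed.  The result is always a subset of the input with no
    violating pair; thinning an already-thinned set is a no-op.
    """
    if min_dist_km <= 0:
        raise ValueError("min_dist_km must be positive")
    n = len(records)
    if n <= 1:
        return records.copy()
    lon = pd.to_numeric(records["lon"]).to_numpy(float)
    lat = pd.to_numeric(records["lat"]).to_numpy(float)
    d = pairwise_haversine_km(lon, lat)
    adj = (d < min_dist_km)
    np.fill_diagonal(adj, False)
    if not adj.any():
        return records.copy()

    rng = np.random.default_rng(seed)
    best_keep = None
    for _ in range(max(1, n_repeats)):
        keep = np.ones(n, dtype=bool)
        counts = adj.sum(axis=1).astype(int)
        while True:
            active_counts = np.where(keep, counts, -1)
            top = int(active_counts.max())
            if top <= 0:
                break
            cands = np.nonzero(active_counts == top)[0]
            victim = int(rng.choice(cands))
            keep[victim] = False
            counts[adj[victim]] -= 1
            counts[victim] = 0
        if best_keep is None or keep.sum() > best_keep.sum():
            best_keep = keep
    return records[best_keep].reset_index(drop=True)


def min_records_filter(thinned: pd.DataFrame, threshold: int = 40,
                       fallback: pd.DataFrame | None = None) -> pd.DataFrame | None:
    """Retain a species only if it has enough records after thinning.

    Returns the thinned table if it meets the threshold; otherwise the
    (unthinned) fallback if that meets it; otherwise None (species dropped).
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    if len(thinned) >= threshold:
        return thinned
    if fallback is not None and len(fallback) >= threshold:
        return fallback
    return None
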