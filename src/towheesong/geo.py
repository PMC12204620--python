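"""Corpus curation and geographic statistics.

Deduplication rules, breeding-season filtering, per-longitude species
proportions, overlap-zone detection, hybrid-rate estimates, and geodesic
(WGS84) distance matrices.

Record tables are plain :class:`pandas.DataFrame` objects with (at least)
the columns ``id, species, date, latitude, longitude`` plus optional
``recordist`` and ``conversion_status``; :class:`GeoRecord` is the row-level
dataclass used by the synthesizer.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Species label used for putative hybrids / uncertain identifications.
HYBRID_LABEL = "hybrid_unsure"

#: Months considered breeding season (April through August, inclusive).
BREEDING_MONTHS = frozenset({4, 5, 6, 7, 8})

# WGS84 ellipsoid.
_WGS84_A = 6378137.0
_WGS84_F = 1.0 / 298.257223563
_WGS84_B = _WGS84_A * (1.0 - _WGS84_F)


@dataclass
class GeoRecord:
    """One recording's metadata row."""

    id: str
    species: str
    date: str  # ISO-8601
    latitude: float
    longitude: float
    conversion_status: str = "unconverted"
    recordist: str | None = None

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude out of range: {self.latitude}")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude out of range: {self.longitude}")


@dataclass(frozen=True)
class OverlapZone:
    """Longitudinal band where both species co-occur (west < east, degrees)."""

    west_deg: float
    east_deg: float

    def __post_init__(self) -> None:
        if not self.west_deg < self.east_deg:
            raise ValueError("overlap zone requires west_deg < east_deg")

    def contains(self, longitude: float | np.ndarray) -> bool | np.ndarray:
        return (np.asarray(longitude) >= self.west_deg) & (
            np.asarray(longitude) < self.east_deg
        )


#: Default zone of species co-occurrence (102W to 91W).
DEFAULT_OVERLAP_ZONE = OverlapZone(-102.0, -91.0)


def records_to_frame(records: Iterable[GeoRecord]) -> pd.DataFrame:
    rows = [
        {
            "id": r.id,
            "species": r.species,
            "date": r.date,
            "latitude": r.latitude,
            "longitude": r.longitude,
            "conversion_status": r.conversion_status,
            "recordist": r.recordist,
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return records_to_frame(records)


def dedupe_recordings(records) -> pd.DataFrame:
    """Keep at most one record per (recordist, date, location) key.

    First occurrence wins.  Missing recordists are treated as distinct key
    values (NaN != NaN for pandas drop_duplicates would drop them together,
    so missing recordists are exempted from deduplication entirely).
    """
    df = _as_frame(records)
    if df.empty:
        return df.copy()
    has_recordist = df["recordist"].notna() if "recordist" in df else pd.Series(False, index=df.index)
    keyed = df[has_recordist].drop_duplicates(
        subset=["recordist", "date", "latitude", "longitude"], keep="first"
    )
    unkeyed = df[~has_recordist]
    return pd.concat([keyed, unkeyed]).sort_index()


def dedupe_sightings(records) -> pd.DataFrame:
    """Keep at most one record per (date, latitude, longitude) key."""
    df = _as_frame(records)
    if df.empty:
        return df.copy()
    return df.drop_duplicates(subset=["date", "latitude", "longitude"], keep="first")


def breeding_season_filter(records) -> pd.DataFrame:
    """Keep records dated April-August inclusive; drop unparseable dates."""
    df = _as_frame(records)
    if df.empty:
        return df.copy()
    parsed = pd.to_datetime(df["date"], errors="coerce", format="mixed")
    bad = parsed.isna()
    if bad.any():
        logger.warning("dropping %d records with unparseable dates", int(bad.sum()))
    keep = parsed.dt.month.isin(BREEDING_MONTHS) & ~bad
    return df[keep]


def species_proportions_by_longitude(
    records,
    species_a: str,
    species_b: str,
    bin_deg: float = 1.0,
) -> pd.DataFrame:
    """Per-longitude-bin counts and proportions of the two species.

    Bins are half-open intervals ``[d, d + bin_deg)`` labelled by their
    western edge.  Hybrid/unsure records must be excluded by the caller;
    records of other species raise.  Bins with zero total are omitted.
    """
    df = _as_frame(records)
    labels = set(df["species"].unique())
    extra = labels - {species_a, species_b}
    if extra:
        raise ValueError(f"unexpected species labels: {sorted(extra)}")
    bins = np.floor(df["longitude"].to_numpy() / bin_deg) * bin_deg
    out = (
        pd.DataFrame({"bin": bins, "species": df["species"].to_numpy()})
        .groupby("bin")["species"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=[species_a, species_b], fill_value=0)
    )
    total = out[species_a] + out[species_b]
    result = pd.DataFrame(
        {
            "bin": out.index.to_numpy(),
            "n_a": out[species_a].to_numpy(),
            "n_b": out[species_b].to_numpy(),
        }
    )
    result["prop_a"] = result["n_a"] / total.to_numpy()
    result["prop_b"] = result["n_b"] / total.to_numpy()
    return result[total.to_numpy() > 0].reset_index(drop=True)


def find_overlap_zone(
    proportions: pd.DataFrame,
    min_prop: float = 0.05,
    min_count: int = 1,
    bin_deg: float = 1.0,
) -> OverlapZone | None:
    """Widest contiguous run of bins where both species qualify.

    A bin qualifies when each species has count >= ``min_count`` and
    proportion >= ``min_prop``.  Ties go to the westernmost run.  Returns
    ``None`` when no bin qualifies.
    """
    if proportions.empty:
        raise ValueError("empty proportion table")
    df = proportions.sort_values("bin")
    ok = (
        (df["n_a"] >= min_count)
        & (df["n_b"] >= min_count)
        & (df["prop_a"] >= min_prop)
        & (df["prop_b"] >= min_prop)
    ).to_numpy()
    bins = df["bin"].to_numpy()
    best: tuple[float, float] | None = None
    run_start = None
    prev_bin = None
    for qualifies, b in zip(ok, bins):
        contiguous = prev_bin is not None and math.isclose(b, prev_bin + bin_deg)
        if qualifies and run_start is not None and contiguous:
            pass  # run continues
        elif qualifies:
            run_start = b
        else:
            run_start = None
        if run_start is not None:
            width = b + bin_deg - run_start
            if best is None or width > best[1] - best[0]:
                best = (run_start, b + bin_deg)
        prev_bin = b
    if best is None:
        return None
    return OverlapZone(best[0], best[1])


def hybrid_rate(n_hybrid: int, n_species: int) -> float:
    """Percent hybridization, 100 * n_hybrid / n_species, to one decimal."""
    if n_species <= 0:
        raise ValueError("n_species must be positive")
    if n_hybrid < 0:
        raise ValueError("n_hybrid must be non-negative")
    return round(100.0 * n_hybrid / n_species, 1)


def _vincenty_inverse(
    lat1: float, lon1: float, lat2: float, lon2: float, max_iter: int = 200
) -> float:
    """Geodesic distance (m) on the WGS84 ellipsoid (Vincenty inverse).

    Falls back to a great-circle distance on a sphere of mean radius for
    the rare near-antipodal pairs where the lambda iteration fails to
    converge; the fallback error is bounded by the ellipsoid flattening
    (~0.5%) and only ever applies to near-antipodal points.
    """
    if lat1 == lat2 and lon1 == lon2:
        return 0.0
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    L = math.radians(lon2 - lon1)
    U1 = math.atan((1 - _WGS84_F) * math.tan(phi1))
    U2 = math.atan((1 - _WGS84_F) * math.tan(phi2))
    sinU1, cosU1 = math.sin(U1), math.cos(U1)
    sinU2, cosU2 = math.sin(U2), math.cos(U2)

    lam = L
    for _ in range(max_iter):
        sin_lam, cos_lam = math.sin(lam), math.cos(lam)
        sin_sigma = math.hypot(
            cosU2 * sin_lam, cosU1 * sinU2 - sinU1 * cosU2 * cos_lam
        )
        if sin_sigma == 0.0:
            return 0.0
        cos_sigma = sinU1 * sinU2 + cosU1 * cosU2 * cos_lam
        sigma = math.atan2(sin_sigma, cos_sigma)
        sin_alpha = cosU1 * cosU2 * sin_lam / sin_sigma
        cos2_alpha = 1.0 - sin_alpha * sin_alpha
        if cos2_alpha == 0.0:
            cos_2sigma_m = 0.0  # equatorial line
        else:
            cos_2sigma_m = cos_sigma - 2.0 * sinU1 * sinU2 / cos2_alpha
        C = _WGS84_F / 16.0 * cos2_alpha * (4 + _WGS84_F * (4 - 3 * cos2_alpha))
        lam_prev = lam
        lam = L + (1 - C) * _WGS84_F * sin_alpha * (
            sigma
            + C
            * sin_sigma
            * (cos_2sigma_m + C * cos_sigma * (-1 + 2 * cos_2sigma_m**2))
        )
        if abs(lam - lam_prev) < 1e-12:
            break
    else:
        # Near-antipodal: spherical fallback.
        r_mean = (2 * _WGS84_A + _WGS84_B) / 3.0
        d = math.sin(phi1) * math.sin(phi2) + math.cos(phi1) * math.cos(
            phi2
        ) * math.cos(L)
        return r_mean * math.acos(max(-1.0, min(1.0, d)))

    u2 = cos2_alpha * (_WGS84_A**2 - _WGS84_B**2) / _WGS84_B**2
    A = 1 + u2 / 16384 * (4096 + u2 * (-768 + u2 * (320 - 175 * u2)))
    B = u2 / 1024 * (256 + u2 * (-128 + u2 * (74 - 47 * u2)))
    delta_sigma = (
        B
        * sin_sigma
        * (
            cos_2sigma_m
            + B
            / 4
            * (
                cos_sigma * (-1 + 2 * cos_2sigma_m**2)
                - B
                / 6
                * cos_2sigma_m
                * (-3 + 4 * sin_sigma**2)
                * (-3 + 4 * cos_2sigma_m**2)
            )
        )
    )
    return _WGS84_B * A * (sigma - delta_sigma)


def geodesic_distance(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """WGS84 geodesic distance in meters between two points."""
    for lat, lon in ((lat1, lon1), (lat2, lon2)):
        if not (-90 <= lat <= 90 and -180 <= lon <= 180):
            raise ValueError(f"invalid coordinate ({lat}, {lon})")
    return _vincenty_inverse(lat1, lon1, lat2, lon2)


def geodesic_distance_matrix(coords: Sequence[tuple[float, float]] | np.ndarray) -> np.ndarray:
    """Symmetric pairwise geodesic distance matrix (meters).

    ``coords`` is a sequence of (latitude, longitude) pairs.
    """
    pts = np.asarray(coords, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("coords must be an n x 2 array of (lat, lon)")
    n = len(pts)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = geodesic_distance(pts[i, 0], pts[i, 1], pts[j, 0], pts[j, 1])
            out[i, j] = out[j, i] = d
    return out
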