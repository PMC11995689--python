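"""Geodesic distances, nearest-store proximity, and the route shortlist rule.

Neighborhood food access is quantified as the distance (miles) from a
neighborhood's population-weighted centroid to its nearest healthy food
store.  Straight-line (great-circle) distances are cheap and computed for
every neighborhood-store pair; routed "map-based" distances are expensive
and therefore only requested for a shortlist of candidate stores per
neighborhood.  Because a routed road distance can never be shorter than the
straight-line distance between the same two points, the store that is
nearest by road is guaranteed to be found inside the straight-line
shortlist whenever its road distance does not exceed the straight-line
distance of the first excluded store.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Protocol, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EARTH_RADIUS_M",
    "METERS_PER_MILE",
    "GeoPoint",
    "StoreSet",
    "ProximityRecord",
    "DistanceProvider",
    "StraightLineProvider",
    "haversine_miles",
    "proximity",
    "shortlist",
    "all_pairs_straight_line",
    "map_proximity",
    "proximity_table",
]

#: Equatorial earth radius in meters. This is the default radius of the
#: geodesy routines commonly used to build food-access datasets, so
#: distances computed here line up with published straight-line values.
EARTH_RADIUS_M = 6_378_137.0

#: Exact international-mile conversion factor.
METERS_PER_MILE = 1609.344


@dataclass(frozen=True)
class GeoPoint:
    """A point on the sphere in decimal degrees."""

    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")
        if not -180.0 <= self.lon <= 360.0:
            raise ValueError(f"longitude {self.lon} outside [-180, 360]")
        # normalize longitude to [-180, 180)
        lon = ((self.lon + 180.0) % 360.0) - 180.0
        object.__setattr__(self, "lon", lon)


class StoreSet:
    """An ordered collection of stores with unique ids and coordinates."""

    def __init__(self, store_ids: Sequence, lats: Sequence[float], lons: Sequence[float]):
        self.store_ids = np.asarray(store_ids)
        self.lats = np.asarray(lats, dtype=float)
        self.lons = np.asarray(lons, dtype=float)
        if not (len(self.store_ids) == len(self.lats) == len(self.lons)):
            raise ValueError("store_ids, lats, lons must have equal length")
        if len(self.store_ids) < 1:
            raise ValueError("a StoreSet needs at least one store")
        if len(np.unique(self.store_ids)) != len(self.store_ids):
            raise ValueError("store ids must be unique")
        _validate_coords(self.lats, self.lons)

    def __len__(self) -> int:
        return len(self.store_ids)

    def __getitem__(self, idx) -> "StoreSet":
        return StoreSet(self.store_ids[idx], self.lats[idx], self.lons[idx])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "StoreSet":
        """Build from a table with columns ``id``, ``lat``, ``lon``."""
        return cls(frame["id"].to_numpy(), frame["lat"].to_numpy(), frame["lon"].to_numpy())

    def points(self) -> list[GeoPoint]:
        return [GeoPoint(la, lo) for la, lo in zip(self.lats, self.lons)]


@dataclass
class ProximityRecord:
    """Straight-line and (optionally) map-based proximity for one neighborhood.

    ``x_star`` is the straight-line proximity, available for every unit;
    ``x`` is the map-based proximity, present only when ``queried`` is True.
    """

    neighborhood_id: object
    x_star: float
    x: float | None = None
    queried: bool = False

    def __post_init__(self) -> None:
        if self.x_star < 0:
            raise ValueError("x_star must be non-negative")
        if self.queried != (self.x is not None):
            raise ValueError("x must be present exactly when queried is True")


def _validate_coords(lats: np.ndarray, lons: np.ndarray) -> None:
    if np.any((lats < -90) | (lats > 90)):
        raise ValueError("latitude outside [-90, 90]")
    if np.any((lons < -180) | (lons > 360)):
        raise ValueError("longitude outside [-180, 360]")


def _as_latlon(p) -> tuple[float, float]:
    if isinstance(p, GeoPoint):
        return p.lat, p.lon
    lat, lon = p
    return float(lat), float(lon)


def haversine_miles(a, b, *, radius_m: float = EARTH_RADIUS_M) -> float:
    """Great-circle distance between two points, in miles.

    Parameters
    ----------
    a, b : GeoPoint or (lat, lon) pair in decimal degrees.
    radius_m : sphere radius in meters (equatorial radius by default).
    """
    lat1, lon1 = _as_latlon(a)
    lat2, lon2 = _as_latlon(b)
    return float(
        _haversine_matrix(
            np.array([lat1]), np.array([lon1]), np.array([lat2]), np.array([lon2]), radius_m
        )[0, 0]
    )


def _haversine_matrix(
    lat1: np.ndarray,
    lon1: np.ndarray,
    lat2: np.ndarray,
    lon2: np.ndarray,
    radius_m: float = EARTH_RADIUS_M,
) -> np.ndarray:
    """All-pairs haversine distances (miles); rows index the first set."""
    _validate_coords(lat1, lon1)
    _validate_coords(lat2, lon2)
    p1, l1 = np.radians(lat1)[:, None], np.radians(lon1)[:, None]
    p2, l2 = np.radians(lat2)[None, :], np.radians(lon2)[None, :]
    h = np.sin((p2 - p1) / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin((l2 - l1) / 2) ** 2
    meters = 2.0 * radius_m * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    return meters / METERS_PER_MILE


def all_pairs_straight_line(
    neighborhoods: Sequence, stores: StoreSet, *, radius_m: float = EARTH_RADIUS_M
) -> np.ndarray:
    """N x M matrix of straight-line distances (miles).

    ``neighborhoods`` is a sequence of GeoPoint / (lat, lon) pairs; entry
    (i, j) is the haversine distance from neighborhood i to store j.
    """
    if len(neighborhoods) == 0:
        raise ValueError("no neighborhoods given")
    latlon = np.array([_as_latlon(p) for p in neighborhoods], dtype=float)
    return _haversine_matrix(latlon[:, 0], latlon[:, 1], stores.lats, stores.lons, radius_m)


def proximity(center, stores: StoreSet, metric: Callable | None = None) -> float:
    """Distance (miles) from ``center`` to the nearest store.

    ``metric`` defaults to the haversine straight-line distance; any
    callable ``metric(a, b) -> miles`` may be substituted.
    """
    if len(stores) < 1:
        raise ValueError("store set is empty")
    if metric is None:
        lat, lon = _as_latlon(center)
        d = _haversine_matrix(np.array([lat]), np.array([lon]), stores.lats, stores.lons)[0]
        return float(d.min())
    return min(metric(center, p) for p in stores.points())


def shortlist(center, stores: StoreSet, fraction: float = 0.2) -> StoreSet:
    """The floor(M * fraction) stores nearest to ``center`` by straight line.

    Straight-line distance ties are broken by ascending store id so the
    shortlist is deterministic.  A routed distance can never undercut the
    straight-line distance, so the store nearest by road is inside the
    shortlist whenever its road distance is at most the straight-line
    distance of the first excluded store.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    m = len(stores)
    k = int(np.floor(m * fraction))
    if k < 1:
        raise ValueError(f"fraction {fraction} selects zero of {m} stores")
    lat, lon = _as_latlon(center)
    d = _haversine_matrix(np.array([lat]), np.array([lon]), stores.lats, stores.lons)[0]
    order = np.lexsort((stores.store_ids, d))
    return stores[np.sort(order[:k])]


class DistanceProvider(Protocol):
    """Contract for batched map-based (routed) distance queries.

    Implementations answer a batch of (origin, destination) pairs with
    distances in miles.  Individual pairwise distances are consumed
    immediately to form per-neighborhood minima and are never persisted.
    """

    def distances(self, origins: Sequence, destinations: Sequence) -> np.ndarray:
        """Elementwise distances (miles) for paired origins/destinations."""
        ...


class StraightLineProvider:
    """A provider that answers with plain great-circle distances."""

    def __init__(self, radius_m: float = EARTH_RADIUS_M):
        self.radius_m = radius_m

    def distances(self, origins: Sequence, destinations: Sequence) -> np.ndarray:
        o = np.array([_as_latlon(p) for p in origins], dtype=float)
        d = np.array([_as_latlon(p) for p in destinations], dtype=float)
        out = _haversine_matrix(o[:, 0], o[:, 1], d[:, 0], d[:, 1], self.radius_m)
        return np.diagonal(out).copy()


def map_proximity(
    center, stores: StoreSet, provider: DistanceProvider, fraction: float = 0.2
) -> float:
    """Map-based proximity via the shortlist rule.

    Shortlists the nearest ``floor(M * fraction)`` stores by straight-line
    distance, queries the provider for those routes only, and returns the
    minimum.  Only this minimum is retained.
    """
    short = shortlist(center, stores, fraction)
    d = provider.distances([center] * len(short), short.points())
    return float(np.min(d))


def proximity_table(
    neighborhoods: pd.DataFrame,
    stores: StoreSet,
    provider: DistanceProvider | None = None,
    fraction: float = 0.2,
    queried_ids: Sequence | None = None,
) -> pd.DataFrame:
    """Straight-line (and optionally map-based) proximity for every neighborhood.

    Parameters
    ----------
    neighborhoods : table with columns ``id``, ``lat``, ``lon``.
    stores : the store set.
    provider : map-based distance provider; when given, map-based proximity
        ``x`` is computed (via the shortlist rule) for units in
        ``queried_ids`` (all units when ``queried_ids`` is None).
    fraction : shortlist fraction for map-based queries.

    Returns
    -------
    DataFrame with columns ``neighborhood_id``, ``x_star``, ``x`` (NaN when
    unqueried), ``queried``.
    """
    centers = list(zip(neighborhoods["lat"], neighborhoods["lon"]))
    dmat = all_pairs_straight_line(centers, stores)
    x_star = dmat.min(axis=1)
    ids = neighborhoods["id"].to_numpy()
    x = np.full(len(ids), np.nan)
    queried = np.zeros(len(ids), dtype=bool)
    if provider is not None:
        want = set(ids if queried_ids is None else queried_ids)
        for i, (nid, center) in enumerate(zip(ids, centers)):
            if nid in want:
                x[i] = map_proximity(center, stores, provider, fraction)
                queried[i] = True
    return pd.DataFrame(
        {"neighborhood_id": ids, "x_star": x_star, "x": x, "queried": queried}
    )
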