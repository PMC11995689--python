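"""Synthetic data generators for the simulation studies and spatial tests.

The generators reproduce the statistical structure of the simulation
design: true map-based proximity X drawn from a gamma distribution,
error-prone straight-line proximity X* built from truncated-normal
additive or multiplicative errors (so that 0 <= X* <= X always holds),
neighborhood populations and case counts drawn from Poisson laws, and a
grid-based region emulator (counties, contiguity adjacency, metropolitan
flags, road-inflated map distances) for the spatial model and the
stratified two-phase design.

Default parameter values mirror a Piedmont-Triad-like study region:
N = 387 neighborhoods, mean population 4095, baseline log prevalence
-2.2 (about 11% average prevalence), log prevalence ratio 0.01 per mile,
additive error parent mean -0.7 and SD 0.8 miles, multiplicative error
parent mean 0.7 and SD 0.15, queried proportion q = 0.1, and B = 20
imputations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .geo import EARTH_RADIUS_M, METERS_PER_MILE, StoreSet

__all__ = [
    "SimConfig",
    "Region",
    "RoadInflationProvider",
    "gen_truth",
    "gen_error_prone_additive",
    "gen_error_prone_multiplicative",
    "truncated_normal",
    "gen_outcome",
    "simulate_dataset",
    "gen_region",
    "sample_car_effects",
]


@dataclass
class SimConfig:
    """Scenario parameters for one simulation setting.

    Attributes
    ----------
    n : number of neighborhoods N.
    beta0 : log baseline prevalence (intercept of the Poisson model).
    beta1 : log prevalence ratio per mile of proximity.
    mean_pop : expected neighborhood population.
    gamma_shape, gamma_scale : parameters of the gamma law for true X.
    error_kind : "additive" (X* = X + U, U truncated to [-X, 0]) or
        "multiplicative" (X* = W X, W truncated to [0, 1]).
    mu_u, sigma_u : parent-normal mean/SD of the additive error U (miles).
    mu_w, sigma_w : parent-normal mean/SD of the multiplicative error W.
    q : proportion of neighborhoods queried for map-based X.
    b : number of imputations per analysis.
    replicates : Monte Carlo replicates for a scenario run.
    seed : master seed.
    """

    n: int = 387
    beta0: float = -2.2
    beta1: float = 0.01
    mean_pop: float = 4095.0
    gamma_shape: float = 1.0
    gamma_scale: float = 2.5
    error_kind: str = "additive"
    mu_u: float = -0.7
    sigma_u: float = 0.8
    mu_w: float = 0.7
    sigma_w: float = 0.15
    q: float = 0.1
    b: int = 20
    replicates: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be at least 2")
        if self.error_kind not in ("additive", "multiplicative"):
            raise ValueError(f"unknown error_kind {self.error_kind!r}")
        if self.error_kind == "additive" and self.sigma_u <= 0:
            raise ValueError("sigma_u must be positive")
        if self.error_kind == "multiplicative" and self.sigma_w <= 0:
            raise ValueError("sigma_w must be positive")
        if not 0 < self.q <= 1:
            raise ValueError("q must be in (0, 1]")
        if self.b < 2:
            raise ValueError("b must be at least 2")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**d)


def gen_truth(
    n: int,
    shape: float = 1.0,
    scale: float = 2.5,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """True map-based proximity: i.i.d. gamma(shape, scale) draws, in miles."""
    if shape <= 0 or scale <= 0:
        raise ValueError("gamma shape and scale must be positive")
    rng = np.random.default_rng() if rng is None else rng
    return rng.gamma(shape, scale, size=n)


def truncated_normal(
    mu, sigma, lower, upper, rng: np.random.Generator
) -> np.ndarray:
    """Draws from Normal(mu, sigma) truncated to [lower, upper], elementwise.

    mu/sigma are the parameters of the parent normal before truncation.
    Sampling is by inverse CDF, which stays exact for extreme bounds where
    rejection sampling would stall.
    """
    mu, sigma = np.broadcast_arrays(np.asarray(mu, float), np.asarray(sigma, float))
    lower, upper = np.broadcast_arrays(np.asarray(lower, float), np.asarray(upper, float))
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    a = (lower - mu) / sigma
    b = (upper - mu) / sigma
    u = rng.uniform(size=np.broadcast_shapes(mu.shape, a.shape))
    return stats.truncnorm.ppf(u, a, b, loc=mu, scale=sigma)


def gen_error_prone_additive(
    x: np.ndarray, mu_u: float, sigma_u: float, rng: np.random.Generator
) -> np.ndarray:
    """Straight-line proximity X* = X + U, U ~ TN(mu_u, sigma_u, [-X, 0]).

    The per-unit truncation bounds enforce 0 <= X* <= X: a straight line
    can never be longer than the road route it approximates.
    """
    x = np.asarray(x, float)
    u = truncated_normal(mu_u, sigma_u, -x, np.zeros_like(x), rng)
    return x + u


def gen_error_prone_multiplicative(
    x: np.ndarray, mu_w: float, sigma_w: float, rng: np.random.Generator
) -> np.ndarray:
    """Straight-line proximity X* = W X, W ~ TN(mu_w, sigma_w, [0, 1])."""
    x = np.asarray(x, float)
    w = truncated_normal(mu_w, sigma_w, np.zeros_like(x), np.ones_like(x), rng)
    return w * x


def gen_outcome(
    x: np.ndarray,
    beta0: float,
    beta1: float,
    mean_pop: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Population and case counts: Pop ~ Poisson(mean_pop), Y ~ Poisson(Pop e^eta).

    eta = beta0 + beta1 * x. Pop draws of zero are re-drawn (a populated
    neighborhood is assumed); at the default mean of 4095 this is a
    measure-zero event. Y is a pure Poisson draw and is not truncated at
    Pop, matching the log-linear prevalence model.
    """
    if mean_pop <= 0:
        raise ValueError("mean_pop must be positive")
    x = np.asarray(x, float)
    pop = rng.poisson(mean_pop, size=x.shape)
    while np.any(pop == 0):  # at mean_pop >= ~30 this effectively never loops
        zero = pop == 0
        pop[zero] = rng.poisson(mean_pop, size=int(zero.sum()))
    with np.errstate(over="ignore"):
        rate = pop * np.exp(beta0 + beta1 * x)
    if not np.all(np.isfinite(rate)):
        raise OverflowError("Poisson rate overflow: check beta0/beta1/x scales")
    y = rng.poisson(rate)
    return pop, y


def simulate_dataset(config: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """One full simulated two-phase dataset.

    Columns: ``x`` (true map-based proximity), ``x_star`` (error-prone
    straight-line proximity), ``pop``, ``y``, ``queried``. The queried
    subset is a simple random sample of size round(N q).
    """
    from .twophase import Design, sample_phase2  # local import: avoid cycle

    rng = np.random.default_rng(config.seed) if rng is None else rng
    x = gen_truth(config.n, config.gamma_shape, config.gamma_scale, rng)
    if config.error_kind == "additive":
        x_star = gen_error_prone_additive(x, config.mu_u, config.sigma_u, rng)
    else:
        x_star = gen_error_prone_multiplicative(x, config.mu_w, config.sigma_w, rng)
    pop, y = gen_outcome(x, config.beta0, config.beta1, config.mean_pop, rng)
    queried = sample_phase2(config.n, Design(kind="simple_random", q=config.q), rng)
    return pd.DataFrame(
        {"x": x, "x_star": x_star, "pop": pop, "y": y, "queried": queried}
    )


class RoadInflationProvider:
    """Synthetic stand-in for a routed-distance service.

    Answers each (origin, destination) pair with the straight-line
    distance inflated by a deterministic pair-specific factor >= 1,
    emulating roads that wind relative to the great-circle path.  The
    factor for a pair depends only on the two coordinate pairs, so
    repeated queries are consistent.
    """

    def __init__(self, base_factor: float = 1.2, jitter: float = 0.3, seed: int = 0):
        if base_factor < 1.0 or jitter < 0.0:
            raise ValueError("base_factor must be >= 1 and jitter >= 0")
        self.base_factor = base_factor
        self.jitter = jitter
        self.seed = seed

    def _factor(self, o: np.ndarray, d: np.ndarray) -> np.ndarray:
        # deterministic pseudo-random in [0, 1) from the coordinates
        h = np.sin(
            12.9898 * o[:, 0]
            + 78.233 * o[:, 1]
            + 37.719 * d[:, 0]
            + 4.581 * d[:, 1]
            + 0.61803 * self.seed
        )
        u = (h * 43758.5453) % 1.0
        return self.base_factor + self.jitter * u

    def distances(self, origins: Sequence, destinations: Sequence) -> np.ndarray:
        from .geo import _as_latlon, _haversine_matrix

        o = np.array([_as_latlon(p) for p in origins], dtype=float)
        d = np.array([_as_latlon(p) for p in destinations], dtype=float)
        straight = np.diagonal(_haversine_matrix(o[:, 0], o[:, 1], d[:, 0], d[:, 1])).copy()
        return straight * self._factor(o, d)


@dataclass
class Region:
    """A synthetic study region on a tract grid.

    ``tracts`` has columns id, county, lat, lon, metro; ``stores`` has
    columns id, lat, lon; ``adjacency`` is a symmetric, irreflexive edge
    list of tract-id pairs (rook contiguity on the grid).
    """

    tracts: pd.DataFrame
    stores: pd.DataFrame
    adjacency: list[tuple[int, int]]
    provider: RoadInflationProvider = field(repr=False, default_factory=RoadInflationProvider)

    @property
    def store_set(self) -> StoreSet:
        return StoreSet.from_frame(self.stores)


def gen_region(
    n_counties: int = 12,
    tracts_per_county: int = 16,
    n_stores: int = 40,
    rng: np.random.Generator | None = None,
    metro_fraction: float = 0.5,
    road_base_factor: float = 1.2,
    road_jitter: float = 0.3,
    origin: tuple[float, float] = (36.0, -80.0),
    cell_deg: float = 0.05,
) -> Region:
    """Emulate a multi-county region: tract grid, adjacency, stores, roads.

    Counties tile a near-square grid of county blocks; each county is a
    square block of tracts, so the whole region is one rectangular tract
    grid.  Adjacency is rook contiguity over that global grid (tracts in
    different counties can border each other).  Metro flags mark the
    tracts of the most central counties, covering roughly
    ``metro_fraction`` of counties.  Stores are scattered uniformly over
    the region with extra density near the metro center.
    """
    if n_counties < 1:
        raise ValueError("n_counties must be >= 1")
    side = int(np.ceil(np.sqrt(tracts_per_county)))
    if side * side != tracts_per_county:
        raise ValueError("tracts_per_county must be a perfect square (grid layout)")
    rng = np.random.default_rng() if rng is None else rng

    c_cols = int(np.ceil(np.sqrt(n_counties)))
    c_rows = int(np.ceil(n_counties / c_cols))
    lat0, lon0 = origin

    rows = []
    grid_index: dict[tuple[int, int], int] = {}
    tid = 0
    for c in range(n_counties):
        cr, cc = divmod(c, c_cols)
        for t in range(tracts_per_county):
            tr, tc = divmod(t, side)
            gr, gc = cr * side + tr, cc * side + tc
            grid_index[(gr, gc)] = tid
            rows.append(
                {
                    "id": tid,
                    "county": c,
                    "lat": lat0 + gr * cell_deg + 0.5 * cell_deg,
                    "lon": lon0 + gc * cell_deg + 0.5 * cell_deg,
                }
            )
            tid += 1
    tracts = pd.DataFrame(rows)

    # metro = counties nearest the region center, covering ~metro_fraction
    center = np.array([(c_rows - 1) / 2, (c_cols - 1) / 2])
    county_pos = np.array([divmod(c, c_cols) for c in range(n_counties)], dtype=float)
    dist_to_center = np.linalg.norm(county_pos - center, axis=1)
    n_metro = max(1, int(round(metro_fraction * n_counties)))
    metro_counties = set(np.argsort(dist_to_center, kind="stable")[:n_metro].tolist())
    tracts["metro"] = tracts["county"].isin(metro_counties).astype(int)

    adjacency = []
    for (gr, gc), i in grid_index.items():
        for dr, dc in ((0, 1), (1, 0)):
            j = grid_index.get((gr + dr, gc + dc))
            if j is not None:
                adjacency.append((i, j))

    lat_max = lat0 + c_rows * side * cell_deg
    lon_max = lon0 + c_cols * side * cell_deg
    store_lat = rng.uniform(lat0, lat_max, size=n_stores)
    store_lon = rng.uniform(lon0, lon_max, size=n_stores)
    stores = pd.DataFrame({"id": np.arange(n_stores), "lat": store_lat, "lon": store_lon})

    provider = RoadInflationProvider(road_base_factor, road_jitter, seed=int(rng.integers(2**16)))
    return Region(tracts=tracts, stores=stores, adjacency=adjacency, provider=provider)


def sample_car_effects(
    edges: Sequence[tuple[int, int]],
    n: int,
    sigma2: float,
    rho: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw spatial random intercepts from a proper CAR prior.

    r ~ N(0, sigma2 * (D - rho A)^{-1}) with A the binary adjacency matrix
    and D its diagonal degree matrix.  Used to simulate spatially
    autocorrelated outcomes for the mixed-model tests.
    """
    from .models import adjacency_matrix

    a = adjacency_matrix(edges, n)
    d = np.diag(a.sum(axis=1))
    prec = (d - rho * a) / sigma2
    chol = np.linalg.cholesky(prec)
    z = rng.standard_normal(n)
    # solve L^T r = z gives r with covariance prec^{-1}
    return np.linalg.solve(chol.T, z)
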