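"""Synthetic origin–destination trip sets emulating campground reservations.

No public deposit of the national reservation records exists, so this
module generates trip sets with the same statistical structure: point
origins clustered around population centers, point destinations
(campgrounds) whose popularity is heavy-tailed (a few sites dominate),
and a heavy-tailed one-way trip-distance distribution with roughly half
of trips within 100 km and roughly 10% beyond 500 km — the two
quantiles the lognormal distance kernel is calibrated to.

``make_fixture`` emits small self-contained bundles reproducing the two
qualitative origin-risk archetypes seen at the state level: localized
adjacent-origin risk, and risk concentrated in distant urban hubs.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .grid import GridSpec, great_circle_km
from .trips import TripRecord, write_trips

KM_PER_DEG_LAT = 111.19


@dataclass(frozen=True)
class DistanceKernel:
    """Lognormal one-way trip-distance distribution (km)."""

    mu: float
    sigma: float
    family: str = "lognormal"

    def __post_init__(self) -> None:
        if self.sigma <= 0 or not np.isfinite(self.mu):
            raise ValueError("kernel parameters must define a proper distribution")

    @classmethod
    def from_quantiles(
        cls, d1: float = 100.0, p1: float = 0.5, d2: float = 500.0, p2: float = 0.9
    ) -> "DistanceKernel":
        """Solve (mu, sigma) from two CDF constraints P(D <= d_k) = p_k.

        The defaults pin the median at 100 km and the 90th percentile at
        500 km, the two published quantiles of camper travel distance.
        """
        z1, z2 = stats.norm.ppf(p1), stats.norm.ppf(p2)
        sigma = (np.log(d2) - np.log(d1)) / (z2 - z1)
        mu = np.log(d1) - sigma * z1
        return cls(mu=float(mu), sigma=float(sigma))

    def pdf(self, d) -> np.ndarray:
        return stats.lognorm.pdf(np.asarray(d, dtype=float), s=self.sigma, scale=np.exp(self.mu))

    def cdf(self, d) -> np.ndarray:
        return stats.lognorm.cdf(np.asarray(d, dtype=float), s=self.sigma, scale=np.exp(self.mu))


DEFAULT_KERNEL = DistanceKernel.from_quantiles()
# lon/lat rectangle roughly the size of the continental study area
DEFAULT_EXTENT = (-120.0, 28.0, -70.0, 50.0)


@dataclass(frozen=True)
class SyntheticLandscape:
    """Population centers and campgrounds with weights, inside an extent."""

    center_lon: np.ndarray
    center_lat: np.ndarray
    center_weight: np.ndarray  # trip-generation propensity
    camp_lon: np.ndarray
    camp_lat: np.ndarray
    camp_popularity: np.ndarray
    extent: tuple[float, float, float, float]  # lon_min, lat_min, lon_max, lat_max

    def __post_init__(self) -> None:
        if np.any(self.center_weight <= 0) or np.any(self.camp_popularity <= 0):
            raise ValueError("all weights must be positive")


def generate_landscape(
    n_centers: int = 300,
    n_campgrounds: int = 200,
    extent: tuple[float, float, float, float] = DEFAULT_EXTENT,
    seed: int = 0,
) -> SyntheticLandscape:
    """Place clustered population centers and campgrounds.

    Centers follow a Thomas-style cluster process (uniform parents,
    Gaussian offspring) with lognormal weights; campgrounds are a
    mixture of cluster-associated and uniform placements with strongly
    heavy-tailed popularity, so a small number of sites dominate.
    Deterministic for a fixed seed.
    """
    if n_centers < 1 or n_campgrounds < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng([seed, 101])
    lon_min, lat_min, lon_max, lat_max = extent

    n_parents = max(3, n_centers // 15)
    par_lon = rng.uniform(lon_min, lon_max, n_parents)
    par_lat = rng.uniform(lat_min, lat_max, n_parents)

    def _cluster_points(n: int, spread_deg: float, uniform_frac: float):
        n_uni = int(round(uniform_frac * n))
        n_clu = n - n_uni
        parent = rng.integers(0, n_parents, n_clu)
        lon = par_lon[parent] + rng.normal(0.0, spread_deg, n_clu)
        lat = par_lat[parent] + rng.normal(0.0, spread_deg * 0.7, n_clu)
        lon = np.concatenate([lon, rng.uniform(lon_min, lon_max, n_uni)])
        lat = np.concatenate([lat, rng.uniform(lat_min, lat_max, n_uni)])
        return np.clip(lon, lon_min, lon_max), np.clip(lat, lat_min, lat_max)

    # offspring spreads keep campgrounds available at short range from the
    # population clusters, as in the real reservation geography
    c_lon, c_lat = _cluster_points(n_centers, spread_deg=0.5, uniform_frac=0.1)
    g_lon, g_lat = _cluster_points(n_campgrounds, spread_deg=0.7, uniform_frac=0.3)
    center_weight = rng.lognormal(mean=0.0, sigma=1.0, size=n_centers)
    camp_popularity = rng.lognormal(mean=0.0, sigma=1.5, size=n_campgrounds)
    return SyntheticLandscape(
        center_lon=c_lon,
        center_lat=c_lat,
        center_weight=center_weight,
        camp_lon=g_lon,
        camp_lat=g_lat,
        camp_popularity=camp_popularity,
        extent=extent,
    )


def _distance_bin_weights(
    dist: np.ndarray,
    popularity: np.ndarray,
    origin_weight: np.ndarray,
    kernel: DistanceKernel,
    bin_km: float = 25.0,
    n_iter: int = 60,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-distance-bin multipliers that make the marginal match the kernel.

    With origins drawn weight-proportionally and campgrounds drawn
    ∝ popularity × β(d), the marginal trip-distance distribution depends
    on the landscape geometry.  Iterative proportional fitting adjusts
    the bin multipliers β until the predicted marginal mass per distance
    bin equals the kernel's mass, restricted (and renormalised) to the
    distances the landscape actually offers.
    """
    d_max = float(dist.max())
    edges = np.arange(0.0, d_max + 2 * bin_km, bin_km)
    nbin = len(edges) - 1
    bin_idx = np.clip(np.digitize(dist, edges) - 1, 0, nbin - 1)
    target = np.diff(kernel.cdf(edges))
    # bins with no available pairs cannot receive mass; renormalise
    has_pairs = np.zeros(nbin, dtype=bool)
    has_pairs[np.unique(bin_idx)] = True
    target = np.where(has_pairs, target, 0.0)
    target = target / target.sum()
    w_norm = origin_weight / origin_weight.sum()
    beta = np.ones(nbin)
    for _ in range(n_iter):
        w = popularity[None, :] * beta[bin_idx]
        row_tot = w.sum(axis=1)
        probs = w / np.where(row_tot > 0, row_tot, 1.0)[:, None]
        achieved = np.bincount(
            bin_idx.ravel(), weights=(probs * w_norm[:, None]).ravel(), minlength=nbin
        )
        ratio = np.where(achieved > 0, target / np.maximum(achieved, 1e-300), 1.0)
        beta *= np.where(target > 0, ratio, 0.0)
        pos = beta[beta > 0]
        if pos.size:  # rescaling leaves the row-normalised model unchanged
            beta /= pos.max()
        if np.max(np.abs(ratio[target > 0] - 1.0), initial=0.0) < 1e-4:
            break
    return edges, beta


def generate_trips(
    landscape: SyntheticLandscape,
    n_trips: int,
    kernel: DistanceKernel = DEFAULT_KERNEL,
    season_start: dt.date = dt.date(2006, 5, 1),
    season_days: int = 70,
    seed: int = 0,
    jitter_km: float = 3.0,
    subpoints_per_center: int = 3,
) -> list[TripRecord]:
    """Draw trips: origin ∝ center weight, campground ∝ popularity × kernel.

    The campground-selection weight evaluates the distance kernel
    against the landscape's own availability of sites at each distance:
    each campground's popularity is multiplied by a per-distance-bin
    kernel weight, calibrated by iterative proportional fitting so the
    marginal trip distance follows the kernel regardless of the
    synthetic geometry.  The generated set therefore reproduces the
    calibrated quantiles (≈50% of trips ≤ 100 km, ≈10% > 500 km).
    Visit dates are uniform over the season.  Each center carries a few
    fixed jittered sub-points emulating distinct postal codes, so raw
    origin–destination coordinate pairs repeat across trips as they do
    in reservation data; destinations are the exact campground points.
    """
    if n_trips < 0:
        raise ValueError("n_trips must be >= 0")
    if n_trips == 0:
        return []
    rng = np.random.default_rng([seed, 202])
    dist = great_circle_km(
        landscape.center_lon[:, None],
        landscape.center_lat[:, None],
        landscape.camp_lon[None, :],
        landscape.camp_lat[None, :],
    )
    edges, beta = _distance_bin_weights(
        dist, landscape.camp_popularity, landscape.center_weight, kernel
    )
    bin_idx = np.clip(np.digitize(dist, edges) - 1, 0, len(beta) - 1)
    weight = landscape.camp_popularity[None, :] * beta[bin_idx]
    row_tot = weight.sum(axis=1)
    ok = row_tot > 0
    if not np.all(ok):  # origins with no reachable campground never emit trips
        weight = weight[ok]
        row_tot = row_tot[ok]
    cum_rows = np.cumsum(weight, axis=1) / row_tot[:, None]
    c_w = landscape.center_weight[ok]
    origin_cum = np.cumsum(c_w) / c_w.sum()
    o_idx_local = np.searchsorted(origin_cum, rng.random(n_trips), side="right")
    camp_idx = np.empty(n_trips, dtype=np.int64)
    u = rng.random(n_trips)
    for o in np.unique(o_idx_local):
        sel = o_idx_local == o
        camp_idx[sel] = np.searchsorted(cum_rows[o], u[sel], side="right")
    orig_ids = np.nonzero(ok)[0][o_idx_local]

    # fixed "postal code" sub-points per center: coordinates repeat
    jd = jitter_km / KM_PER_DEG_LAT
    n_cent = landscape.center_lat.size
    sub_lat = landscape.center_lat[:, None] + rng.normal(0, jd, (n_cent, subpoints_per_center))
    sub_lon = landscape.center_lon[:, None] + rng.normal(
        0, jd, (n_cent, subpoints_per_center)
    ) / np.cos(np.radians(sub_lat))
    sub_choice = rng.integers(0, subpoints_per_center, n_trips)
    o_lat = sub_lat[orig_ids, sub_choice]
    o_lon = sub_lon[orig_ids, sub_choice]
    d_lat = landscape.camp_lat[camp_idx]
    d_lon = landscape.camp_lon[camp_idx]
    days = rng.integers(0, season_days, n_trips)
    records = [
        TripRecord(
            origin_lon=float(o_lon[k]),
            origin_lat=float(o_lat[k]),
            dest_lon=float(d_lon[k]),
            dest_lat=float(d_lat[k]),
            visit_date=season_start + dt.timedelta(days=int(days[k])),
            count=1,
        )
        for k in range(n_trips)
    ]
    return records


def trip_distances_km(records) -> np.ndarray:
    """One-way great-circle distances of a trip collection."""
    return great_circle_km(
        np.array([r.origin_lon for r in records]),
        np.array([r.origin_lat for r in records]),
        np.array([r.dest_lon for r in records]),
        np.array([r.dest_lat for r in records]),
    )


# ---------------------------------------------------------------------------
# fixture scenarios

SCENARIOS = ("two_state_local", "hub_and_spoke_distant", "mixed")

# local fictional geography (degrees): a target "state", an adjacent
# origin block to its west, and a distant urban hub far to the west
_TARGET_RECT = (0.0, 44.0, 2.5, 46.0)
_ADJACENT_RECT = (-4.0, 43.5, -0.2, 46.5)
_HUB_RECT = (-16.0, 44.0, -14.0, 45.5)


def _rect_points(rng, rect, n):
    lon = rng.uniform(rect[0], rect[2], n)
    lat = rng.uniform(rect[1], rect[3], n)
    return lon, lat


def _scenario_landscape(scenario: str, rng: np.random.Generator) -> SyntheticLandscape:
    camp_lon, camp_lat = _rect_points(rng, _TARGET_RECT, 12)
    camp_pop = rng.lognormal(0.0, 1.0, 12)
    if scenario == "two_state_local":
        # adjacent origins carry ~90% of trip-generation weight
        a_lon, a_lat = _rect_points(rng, _ADJACENT_RECT, 30)
        h_lon, h_lat = _rect_points(rng, _HUB_RECT, 6)
        w = np.concatenate([rng.uniform(2.0, 6.0, 30), rng.uniform(0.1, 0.3, 6)])
    elif scenario == "hub_and_spoke_distant":
        # a distant urban hub dominates trip generation
        a_lon, a_lat = _rect_points(rng, _ADJACENT_RECT, 10)
        h_lon, h_lat = _rect_points(rng, _HUB_RECT, 12)
        w = np.concatenate([rng.uniform(0.1, 0.4, 10), rng.uniform(5.0, 12.0, 12)])
    elif scenario == "mixed":
        a_lon, a_lat = _rect_points(rng, _ADJACENT_RECT, 20)
        h_lon, h_lat = _rect_points(rng, _HUB_RECT, 10)
        w = np.concatenate([rng.uniform(1.0, 3.0, 20), rng.uniform(2.0, 5.0, 10)])
    else:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    lon = np.concatenate([a_lon, h_lon])
    lat = np.concatenate([a_lat, h_lat])
    lon_min = min(lon.min(), camp_lon.min()) - 1.0
    lon_max = max(lon.max(), camp_lon.max()) + 1.0
    lat_min = min(lat.min(), camp_lat.min()) - 1.0
    lat_max = max(lat.max(), camp_lat.max()) + 1.0
    return SyntheticLandscape(
        center_lon=lon,
        center_lat=lat,
        center_weight=w,
        camp_lon=camp_lon,
        camp_lat=camp_lat,
        camp_popularity=camp_pop,
        extent=(float(lon_min), float(lat_min), float(lon_max), float(lat_max)),
    )


def _rect_geojson(rect) -> dict:
    lon0, lat0, lon1, lat1 = rect
    ring = [[lon0, lat0], [lon1, lat0], [lon1, lat1], [lon0, lat1], [lon0, lat0]]
    return {"type": "Polygon", "coordinates": [ring]}


def make_fixture(scenario: str, seed: int, out_dir, n_trips: int = 4000) -> dict:
    """Write a self-contained test bundle for one scenario.

    The bundle holds ``trips.csv`` (the raw trip table), ``grid.json``
    (the grid specification covering the fictional region),
    ``target.geojson`` (the target jurisdiction polygon) and
    ``meta.json`` (scenario, seed and the origin-block rectangles used
    by the archetype checks).  Byte-identical for a fixed seed.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([seed, hash_scenario(scenario)])
    landscape = _scenario_landscape(scenario, rng)
    trips = generate_trips(
        landscape,
        n_trips=n_trips,
        kernel=DEFAULT_KERNEL,
        seed=int(rng.integers(0, 2**31 - 1)),
        jitter_km=2.0,
    )
    grid = GridSpec.from_extent(*(
        landscape.extent[0],
        landscape.extent[1],
        landscape.extent[2],
        landscape.extent[3],
    ))
    paths = {
        "trips": out / "trips.csv",
        "grid": out / "grid.json",
        "target": out / "target.geojson",
        "meta": out / "meta.json",
    }
    write_trips(trips, paths["trips"])
    paths["grid"].write_text(grid.to_json())
    paths["target"].write_text(json.dumps(_rect_geojson(_TARGET_RECT)))
    paths["meta"].write_text(
        json.dumps(
            {
                "scenario": scenario,
                "seed": seed,
                "n_trips": n_trips,
                "target_rect": _TARGET_RECT,
                "adjacent_rect": _ADJACENT_RECT,
                "hub_rect": _HUB_RECT,
            },
            indent=2,
            sort_keys=True,
        )
    )
    return {k: str(v) for k, v in paths.items()}


def hash_scenario(scenario: str) -> int:
    """Stable small integer per scenario name (seed substream key)."""
    return sum((k + 1) * ord(ch) for k, ch in enumerate(scenario)) % 99991
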