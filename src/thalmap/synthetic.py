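"""Synthetic studies: truth surfaces, surveys, population rasters, provinces.

The generator emulates the statistical structure the analysis assumes: the
true logit-scale allele-frequency field of each form is a stationary Gaussian
random field with Matern covariance; surveys observe binomial allele counts
out of 2n chromosomes at point locations; the population raster is
heterogeneous; and the study region is partitioned into "provinces" for areal
aggregation.  Every generator is a pure function of its spec and seed; a
:class:`SyntheticStudy` derives per-component substreams from one master seed.

Default study conditions mirror a Thailand-like analysis: survey sample sizes
are lognormal with mean ~1261 individuals (spanning tens to tens of
thousands), per-form truth fields produce observed frequencies up to ~5%
(alpha0), ~26% (alpha+) and ~16% (non-deletional), the crude birth rate is
10.5 births per 1000 persons per year.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, special

from .geodb import FORMS, SurveyDatabase, SurveyRecord
from .geostat import matern_covariance
from .grids import (
    KM_PER_DEGREE,
    GridSpec,
    Surface,
    pairwise_distances_km,
    surface_from_flat,
)

__all__ = [
    "TruthSpec",
    "SyntheticStudy",
    "ProvincePartition",
    "simulate_truth_surface",
    "sample_surveys",
    "simulate_population",
    "partition_provinces",
    "simulate_study",
    "default_truth_specs",
    "lognormal_sample_sizes",
]

#: cell-count limit for dense covariance factorisation
DENSE_LIMIT = 10_000


@dataclass(frozen=True)
class TruthSpec:
    """Latent-field parameters for one form's true frequency surface.

    ``mean_logit`` and ``variance`` are on the logit scale; ``range_deg`` is
    the Matern range in decimal degrees (converted internally to km at
    111.195 km/degree); ``smoothness`` is the Matern nu.
    """

    grid: GridSpec
    mean_logit: float
    variance: float
    range_deg: float
    smoothness: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.variance < 0:
            raise ValueError("variance must be >= 0")
        if self.range_deg <= 0:
            raise ValueError("range must be > 0")
        if self.smoothness <= 0:
            raise ValueError("smoothness must be > 0")

    @property
    def range_km(self) -> float:
        return self.range_deg * KM_PER_DEGREE


def _grf_logit(
    grid: GridSpec, variance: float, range_km: float, smoothness: float, rng: np.random.Generator
) -> np.ndarray:
    """Zero-mean Matern Gaussian random field at unmasked cell centres.

    Dense Cholesky up to :data:`DENSE_LIMIT` cells (exact); larger grids use a
    random-Fourier-feature approximation (2000 features, spectral sampling of
    the Matern density on a local equirectangular plane).
    """
    lon, lat = grid.unmasked_centers()
    n = lon.size
    if variance == 0:
        return np.zeros(n)
    if n <= DENSE_LIMIT:
        D = pairwise_distances_km(lon, lat)
        C = matern_covariance(D, variance, range_km, smoothness)
        C[np.diag_indices_from(C)] += 1e-10
        try:
            L = linalg.cholesky(C, lower=True)
        except linalg.LinAlgError:
            ev = linalg.eigvalsh(C)
            raise linalg.LinAlgError(
                f"truth covariance not positive definite after jitter; smallest eigenvalue {ev[0]:.3e}"
            )
        return L @ rng.standard_normal(n)
    # spectral (random Fourier feature) sampler: omega ~ multivariate t with
    # 2*nu degrees of freedom and scale 1/rho, the Matern spectral density
    n_feat = 2000
    lat0 = np.radians(lat.mean())
    xy = np.column_stack([lon * KM_PER_DEGREE * np.cos(lat0), lat * KM_PER_DEGREE])
    g = rng.standard_normal((n_feat, 2)) / range_km
    chi = rng.chisquare(2.0 * smoothness, size=n_feat) / (2.0 * smoothness)
    omega = g / np.sqrt(chi)[:, None]
    phase = rng.uniform(0, 2 * np.pi, size=n_feat)
    proj = xy @ omega.T + phase
    return np.sqrt(2.0 * variance / n_feat) * np.cos(proj).sum(axis=1)


def simulate_truth_surface(spec: TruthSpec) -> Surface:
    """True frequency surface: inverse-logit of mean + Matern GRF.

    Values are strictly inside (0, 1); identical seeds give identical fields.
    """
    rng = np.random.default_rng(spec.seed)
    z = spec.mean_logit + _grf_logit(spec.grid, spec.variance, spec.range_km, spec.smoothness, rng)
    return surface_from_flat(spec.grid, special.expit(z), scale="probability")


def lognormal_sample_sizes(rng: np.random.Generator, size: int, mean: float = 1261.0,
                           sigma: float = 1.3, lo: int = 10, hi: int = 50_000) -> np.ndarray:
    """Survey sample sizes (individuals): lognormal with the given mean,
    clipped to a plausible range (tens to tens of thousands)."""
    mu = np.log(mean) - sigma ** 2 / 2.0
    n = np.exp(rng.normal(mu, sigma, size=size))
    return np.clip(np.round(n).astype(int), lo, hi)


def sample_surveys(
    truth: Surface,
    n_sites: int,
    size_sampler=lognormal_sample_sizes,
    seed: int = 0,
    form: str = "a0",
    weights: Surface | None = None,
) -> SurveyDatabase:
    """Simulate the observation process on a single truth surface.

    Sites are drawn uniformly over unmasked cells (without replacement while
    possible); at each site the allele count is Binomial(2n, truth) and the
    recorded frequency is count / 2n.  An optional ``weights`` surface makes
    site placement preferential (probability proportional to weight), which
    emulates the spatial clustering of real evidence bases.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    grid = truth.grid
    n_cells = grid.n_unmasked
    if n_cells == 0:
        raise ValueError("all cells masked: nowhere to place surveys")
    rng = np.random.default_rng(seed)
    prob = None
    if weights is not None:
        w = weights.unmasked()
        if w.shape != (n_cells,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be a non-negative surface on the same grid")
        prob = w / w.sum()
    cells = rng.choice(n_cells, size=n_sites, p=prob,
                       replace=(n_sites > n_cells) or prob is not None)
    lon, lat = grid.unmasked_centers()
    p_true = truth.unmasked()[cells]
    n_ind = size_sampler(rng, n_sites)
    counts = rng.binomial(2 * n_ind, p_true)
    records = [
        SurveyRecord(
            survey_id=f"syn-{form}-{i:04d}",
            country="Synthetica",
            location_name=f"cell-{cells[i]}",
            latitude=float(lat[cells[i]]),
            longitude=float(lon[cells[i]]),
            n_individuals=int(n_ind[i]),
            group="community",
            freq={form: counts[i] / (2 * n_ind[i])},
        )
        for i in range(n_sites)
    ]
    return SurveyDatabase(records=records, provenance={"synthetic": True, "seed": seed})


def simulate_population(
    grid: GridSpec, total_population: float, clustering: float = 1.0, seed: int = 0
) -> Surface:
    """Heterogeneous population raster summing to ``total_population``.

    Cell weights are ``exp(clustering * g)`` for a unit-variance Matern GRF
    ``g`` (range = a quarter of the grid diagonal), normalised to the total;
    ``clustering = 0`` gives exactly uniform density.
    """
    if total_population < 0:
        raise ValueError("total_population must be >= 0")
    if clustering < 0:
        raise ValueError("clustering must be >= 0")
    n = grid.n_unmasked
    if clustering == 0:
        w = np.ones(n)
    else:
        rng = np.random.default_rng(seed)
        diag_km = np.hypot(grid.n_cols, grid.n_rows) * grid.cell_size * KM_PER_DEGREE
        g = _grf_logit(grid, 1.0, diag_km / 4.0, 1.0, rng)
        w = np.exp(clustering * g)
    vals = total_population * w / w.sum() if total_population > 0 else np.zeros(n)
    return surface_from_flat(grid, vals, scale="persons")


@dataclass
class ProvincePartition:
    """Nearest-seed-site partition of the unmasked grid into k provinces.

    ``labels`` is an int raster (-1 at masked cells); ``polygons`` are the
    dissolved cell footprints per label (shapely geometries covering the mask
    with no overlap).
    """

    grid: GridSpec
    labels: np.ndarray
    polygons: list
    k: int

    def label_flat(self) -> np.ndarray:
        return self.labels[self.grid.mask_array()]


def partition_provinces(grid: GridSpec, k: int, seed: int = 0) -> ProvincePartition:
    """Partition the unmasked grid into k contiguous provinces (Voronoi on
    k uniformly drawn seed cells, great-circle metric)."""
    from shapely.geometry import box
    from shapely.ops import unary_union

    n = grid.n_unmasked
    if not (1 <= k <= n):
        raise ValueError(f"k={k} must be between 1 and the {n} unmasked cells")
    rng = np.random.default_rng(seed)
    seeds = rng.choice(n, size=k, replace=False)
    lon, lat = grid.unmasked_centers()
    d = pairwise_distances_km(lon, lat, lon[seeds], lat[seeds])
    assign = np.argmin(d, axis=1)
    labels = np.full(grid.shape, -1, dtype=int)
    labels[grid.mask_array()] = assign
    # dissolve cell rectangles per province
    rows, cols = np.nonzero(grid.mask_array())
    cs = grid.cell_size
    polygons = []
    for lab in range(k):
        cells = [
            box(
                grid.origin_lon + c * cs,
                grid.origin_lat + r * cs,
                grid.origin_lon + (c + 1) * cs,
                grid.origin_lat + (r + 1) * cs,
            )
            for r, c, a in zip(rows, cols, assign)
            if a == lab
        ]
        polygons.append(unary_union(cells))
    return ProvincePartition(grid=grid, labels=labels, polygons=polygons, k=k)


def provinces_to_geojson(part: ProvincePartition, path=None) -> dict:
    """GeoJSON FeatureCollection of the province polygons."""
    import json

    from shapely.geometry import mapping

    fc = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "geometry": mapping(poly), "properties": {"province": i}}
            for i, poly in enumerate(part.polygons)
        ],
    }
    if path is not None:
        with open(path, "w") as fh:
            json.dump(fc, fh)
    return fc


def default_truth_specs(grid: GridSpec, seed: int = 0) -> dict[str, TruthSpec]:
    """Per-form truth fields with realistic Southeast-Asian frequency levels.

    Logit means and variances are chosen so that simulated observed maxima sit
    near the reported regional maxima: alpha0 up to ~5%, alpha+ up to ~26%,
    non-deletional up to ~16%.
    """
    extent = max(grid.n_rows, grid.n_cols) * grid.cell_size
    rng_deg = max(extent / 3.0, grid.cell_size * 2)
    ss = np.random.SeedSequence(seed).spawn(3)
    params = {
        "a0": (-4.2, 0.25),
        "aplus": (-2.2, 0.20),
        "and": (-3.1, 0.30),
    }
    return {
        f: TruthSpec(
            grid=grid,
            mean_logit=params[f][0],
            variance=params[f][1],
            range_deg=rng_deg,
            smoothness=1.0,
            seed=int(s.generate_state(1)[0] % (2 ** 31)),
        )
        for f, s in zip(FORMS, ss)
    }


@dataclass
class SyntheticStudy:
    """A complete synthetic study: truths, surveys, demography, provinces."""

    truth: dict[str, Surface]
    surveys: SurveyDatabase
    population: Surface
    provinces: ProvincePartition
    crude_birth_rate: float
    seed: int


def simulate_study(
    grid: GridSpec,
    n_sites: int = 90,
    total_population: float = 7.0e7,
    n_provinces: int = 12,
    clustering: float = 1.0,
    crude_birth_rate: float = 0.0105,
    truth_specs: dict[str, TruthSpec] | None = None,
    seed: int = 0,
) -> SyntheticStudy:
    """Generate a full synthetic study from one master seed.

    Survey sites are shared across the three forms (each site reports all
    three frequencies, binomially sampled from each form's truth), matching
    how multi-form prevalence surveys are reported.
    """
    ss = np.random.SeedSequence(seed)
    s_sites, s_pop, s_prov = ss.spawn(3)
    sub = {"sites": np.random.default_rng(s_sites), "prov": np.random.default_rng(s_prov)}
    truth_specs = truth_specs or default_truth_specs(grid, seed=seed)
    truths = {f: simulate_truth_surface(truth_specs[f]) for f in FORMS}

    rng = sub["sites"]
    n_cells = grid.n_unmasked
    cells = rng.choice(n_cells, size=n_sites, replace=n_sites > n_cells)
    lon, lat = grid.unmasked_centers()
    n_ind = lognormal_sample_sizes(rng, n_sites)
    records = []
    for i in range(n_sites):
        freq = {}
        for f in FORMS:
            p = truths[f].unmasked()[cells[i]]
            freq[f] = rng.binomial(2 * n_ind[i], p) / (2 * n_ind[i])
        records.append(
            SurveyRecord(
                survey_id=f"syn-{i:04d}",
                country="Synthetica",
                location_name=f"cell-{cells[i]}",
                latitude=float(lat[cells[i]]),
                longitude=float(lon[cells[i]]),
                n_individuals=int(n_ind[i]),
                group="community",
                freq=freq,
            )
        )
    surveys = SurveyDatabase(records=records, provenance={"synthetic": True, "seed": seed})
    population = simulate_population(
        grid, total_population, clustering, seed=int(s_pop.generate_state(1)[0] % 2**31)
    )
    provinces = partition_provinces(
        grid, n_provinces, seed=int(sub["prov"].integers(0, 2**31))
    )
    return SyntheticStudy(
        truth=truths,
        surveys=surveys,
        population=population,
        provinces=provinces,
        crude_birth_rate=crude_birth_rate,
        seed=seed,
    )
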