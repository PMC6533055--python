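"""Empirical-logit Gaussian-process model for allele-frequency surfaces.

Observed allele counts x out of n chromosomes at survey sites are transformed
through the empirical logit

    z = log((x + 1/2) / (n - x + 1/2)),   v = 1/(x + 1/2) + 1/(n - x + 1/2),

which is finite at x = 0 and x = n and approximately Gaussian with known
per-site variance v.  The latent logit-scale frequency field is modelled as a
stationary Gaussian process with constant mean mu and Matern covariance
(variance sigma2, range rho in km, smoothness nu; default nu = 1, the
smoothness implied by the common SPDE choice alpha = 2 in two dimensions),
plus a non-spatial nugget tau2.  Hyperparameters are estimated by maximising
the Gaussian log marginal likelihood (empirical Bayes); prediction and
conditional simulation are exact Gaussian conditioning given those estimates.
Hyperparameter uncertainty is *not* propagated into the posterior ensemble,
a deliberate understatement of uncertainty relative to a fully Bayesian fit.

Distances are great-circle kilometres.  Surveys at identical coordinates are
merged by pooling chromosomes before transformation (repeated sites would
otherwise make the covariance singular).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, special, stats

from .grids import GridSpec, Surface, pairwise_distances_km, surface_from_flat

__all__ = [
    "AlleleFrequencyGP",
    "CVReport",
    "GPModelSpec",
    "GPResults",
    "PosteriorEnsemble",
    "empirical_logit",
    "fit_gp",
    "fold_metrics",
    "kfold_cv",
    "matern_covariance",
    "ppd_summary",
]

_JITTER = 1e-10


def empirical_logit(x, n):
    """Empirical logit of x successes out of n trials, with its variance.

    Returns ``(z, v)`` where ``z = log((x + 1/2)/(n - x + 1/2))`` and
    ``v = 1/(x + 1/2) + 1/(n - x + 1/2)``.  Both are defined at the
    boundaries x = 0 and x = n, unlike the plain logit.
    """
    x = np.asarray(x, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(n < 1):
        raise ValueError("n must be >= 1")
    if np.any(x < 0) or np.any(x > n):
        raise ValueError("x must satisfy 0 <= x <= n")
    z = np.log((x + 0.5) / (n - x + 0.5))
    v = 1.0 / (x + 0.5) + 1.0 / (n - x + 0.5)
    if z.ndim == 0:
        return float(z), float(v)
    return z, v


def matern_covariance(distance, variance, range_, smoothness):
    """Matern covariance C(d) = sigma2 * 2^(1-nu)/Gamma(nu) (u)^nu K_nu(u),
    with u = sqrt(2 nu) d / rho.

    ``range_`` (rho) and ``distance`` share units (km here).  nu = 1/2 gives
    the exponential covariance sigma2 * exp(-d/rho); C(0) = sigma2.
    """
    if range_ <= 0:
        raise ValueError("range must be positive")
    if smoothness <= 0:
        raise ValueError("smoothness must be positive")
    if variance < 0:
        raise ValueError("variance must be non-negative")
    d = np.asarray(distance, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    nu = float(smoothness)
    u = np.sqrt(2.0 * nu) * d / float(range_)
    out = np.empty_like(u)
    zero = u < 1e-12
    out[zero] = 1.0
    uz = u[~zero]
    out[~zero] = (2.0 ** (1.0 - nu) / special.gamma(nu)) * (uz ** nu) * special.kv(nu, uz)
    out = variance * np.clip(out, 0.0, 1.0)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class GPModelSpec:
    """Model configuration: covariance family, search bounds and ensemble size.

    Bounds are (low, high) on the natural scale; optimisation runs on the log
    scale with ``n_restarts`` seeded multi-starts.
    """

    smoothness: float = 1.0
    variance_bounds: tuple[float, float] = (1e-8, 1e2)
    range_bounds_km: tuple[float, float] = (5.0, 5000.0)
    nugget_bounds: tuple[float, float] = (1e-10, 1e1)
    K: int = 100
    level: float = 0.95
    n_restarts: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.K < 2:
            raise ValueError("ensemble size K must be >= 2")
        if not (0.0 < self.level < 1.0):
            raise ValueError("credible level must be in (0, 1)")
        if self.smoothness <= 0:
            raise ValueError("smoothness must be positive")


def _merge_duplicates(lon, lat, x, n):
    """Pool chromosomes at duplicated coordinates (exact match)."""
    key = {}
    order = []
    for i, (lo, la) in enumerate(zip(lon, lat)):
        k = (float(lo), float(la))
        if k not in key:
            key[k] = [0.0, 0.0]
            order.append(k)
        key[k][0] += x[i]
        key[k][1] += n[i]
    lon2 = np.array([k[0] for k in order])
    lat2 = np.array([k[1] for k in order])
    x2 = np.array([key[k][0] for k in order])
    n2 = np.array([key[k][1] for k in order])
    return lon2, lat2, x2, n2


class AlleleFrequencyGP:
    """Gaussian-process model of one allele-frequency surface.

    Parameters
    ----------
    lon, lat : survey coordinates (WGS84 decimal degrees).
    x : alpha-thalassaemia chromosome counts per survey.
    n : total chromosomes per survey (2 x individuals).
    spec : :class:`GPModelSpec`.

    ``fit()`` returns a :class:`GPResults` carrying the empirical-Bayes
    hyperparameter estimates; prediction, conditional simulation and the
    summary table hang off the results object.
    """

    def __init__(self, lon, lat, x, n, spec: GPModelSpec | None = None):
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        x = np.asarray(x, dtype=float)
        n = np.asarray(n, dtype=float)
        if not (lon.shape == lat.shape == x.shape == n.shape):
            raise ValueError("lon, lat, x, n must have equal length")
        self.spec = spec or GPModelSpec()
        self.lon, self.lat, self.x, self.n = _merge_duplicates(lon, lat, x, n)
        if len(self.lon) < 5:
            raise ValueError(
                f"need >= 5 distinct survey sites, have {len(self.lon)} after merging duplicates"
            )
        self.z, self.v = empirical_logit(self.x, self.n)
        self.dist = pairwise_distances_km(self.lon, self.lat)

    @classmethod
    def from_transformed(cls, lon, lat, z, v, spec: GPModelSpec | None = None) -> "AlleleFrequencyGP":
        """Build directly from transformed observations (z, v) at sites,
        bypassing the empirical logit (e.g. exact logits with v = 0)."""
        self = cls.__new__(cls)
        self.spec = spec or GPModelSpec()
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        self.lon, self.lat = lon, lat
        self.x = self.n = None
        self.z = np.asarray(z, dtype=float)
        self.v = np.asarray(v, dtype=float)
        if not (lon.shape == lat.shape == self.z.shape == self.v.shape):
            raise ValueError("lon, lat, z, v must have equal length")
        if len(lon) < 5:
            raise ValueError("need >= 5 distinct survey sites")
        if len({(a, b) for a, b in zip(lon, lat)}) != len(lon):
            raise ValueError("duplicate sites in transformed observations")
        self.dist = pairwise_distances_km(self.lon, self.lat)
        return self

    @classmethod
    def from_database(cls, db, form: str, spec: GPModelSpec | None = None) -> "AlleleFrequencyGP":
        """Build from a :class:`~thalmap.geodb.SurveyDatabase` for one form.

        Chromosome counts are reconstructed as ``round(freq * 2n)``.
        """
        recs = [r for r in db.records if form in r.freq and r.has_point]
        if not recs:
            raise ValueError(f"no point-located surveys with a {form} frequency")
        lon = [r.longitude for r in recs]
        lat = [r.latitude for r in recs]
        n = [2 * r.n_individuals for r in recs]
        x = [round(r.freq[form] * 2 * r.n_individuals) for r in recs]
        return cls(lon, lat, x, n, spec)

    # -- log marginal likelihood -------------------------------------------
    def _lml(self, log_params):
        """Profile log marginal likelihood (mu profiled out by GLS)."""
        sigma2, rho, tau2 = np.exp(log_params)
        K = matern_covariance(self.dist, sigma2, rho, self.spec.smoothness)
        K[np.diag_indices_from(K)] += self.v + tau2 + _JITTER
        try:
            cf = linalg.cho_factor(K, lower=True)
        except linalg.LinAlgError:
            return -np.inf, np.nan
        ones = np.ones_like(self.z)
        Ki1 = linalg.cho_solve(cf, ones)
        Kiz = linalg.cho_solve(cf, self.z)
        mu = float(ones @ Kiz / (ones @ Ki1))
        resid = self.z - mu
        Kir = Kiz - mu * Ki1
        logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
        lml = -0.5 * (resid @ Kir) - 0.5 * logdet - 0.5 * len(self.z) * np.log(2 * np.pi)
        return float(lml), mu

    def log_marginal_likelihood(self, sigma2, rho, tau2):
        """LML at given hyperparameters (mu profiled); for diagnostics/tests."""
        return self._lml(np.log([sigma2, rho, tau2]))[0]

    def fit(self, seed: int | None = None) -> "GPResults":
        """Empirical-Bayes fit: maximise the log marginal likelihood.

        Multi-start L-BFGS-B on log(sigma2, rho, tau2); the first start is a
        moment heuristic, the rest are drawn uniformly in the log bounds.
        """
        spec = self.spec
        rng = np.random.default_rng(spec.seed if seed is None else seed)
        lb = np.log([spec.variance_bounds[0], spec.range_bounds_km[0], spec.nugget_bounds[0]])
        ub = np.log([spec.variance_bounds[1], spec.range_bounds_km[1], spec.nugget_bounds[1]])
        zvar = max(float(np.var(self.z)), spec.variance_bounds[0] * 10)
        pos = self.dist[np.triu_indices_from(self.dist, k=1)]
        med = float(np.median(pos[pos > 0])) if np.any(pos > 0) else spec.range_bounds_km[0] * 10
        starts = [np.clip(np.log([zvar, med, 0.1 * zvar]), lb, ub)]
        for _ in range(max(spec.n_restarts - 1, 0)):
            starts.append(lb + rng.random(3) * (ub - lb))

        best = None
        n_failed = 0
        for s in starts:
            try:
                res = optimize.minimize(
                    lambda p: -self._lml(p)[0],
                    s,
                    method="L-BFGS-B",
                    bounds=list(zip(lb, ub)),
                )
            except Exception:
                n_failed += 1
                continue
            if not np.isfinite(res.fun):
                n_failed += 1
                continue
            if best is None or res.fun < best.fun:
                best = res
        if best is None:
            raise RuntimeError(
                f"hyperparameter optimisation failed in all {len(starts)} restarts"
            )
        lml, mu = self._lml(best.x)
        sigma2, rho, tau2 = np.exp(best.x)
        return GPResults(
            model=self,
            mu=mu,
            sigma2=float(sigma2),
            rho_km=float(rho),
            tau2=float(tau2),
            loglik=float(lml),
            n_restarts_failed=n_failed,
        )


@dataclass
class GPResults:
    """Fitted allele-frequency GP: hyperparameters, prediction, simulation."""

    model: AlleleFrequencyGP
    mu: float
    sigma2: float
    rho_km: float
    tau2: float
    loglik: float
    n_restarts_failed: int = 0
    _cho: object = field(default=None, repr=False)

    @property
    def params(self) -> dict[str, float]:
        return {"mu": self.mu, "sigma2": self.sigma2, "rho_km": self.rho_km, "tau2": self.tau2}

    def _train_chol(self):
        if self._cho is None:
            m = self.model
            K = matern_covariance(m.dist, self.sigma2, self.rho_km, m.spec.smoothness)
            K[np.diag_indices_from(K)] += m.v + self.tau2 + _JITTER
            self._cho = linalg.cho_factor(K, lower=True)
        return self._cho

    def predict_latent(self, lon, lat, full_cov: bool = False):
        """Kriging posterior of the latent logit field at new points.

        Returns ``(mean, var)`` or ``(mean, cov)`` if ``full_cov``.  The
        nugget is treated as observation noise and excluded from the latent
        prediction.
        """
        m = self.model
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        cf = self._train_chol()
        d_pt = pairwise_distances_km(lon, lat, m.lon, m.lat)
        K_pt = matern_covariance(d_pt, self.sigma2, self.rho_km, m.spec.smoothness)
        alpha = linalg.cho_solve(cf, m.z - self.mu)
        mean = self.mu + K_pt @ alpha
        W = linalg.cho_solve(cf, K_pt.T)
        if full_cov:
            d_pp = pairwise_distances_km(lon, lat)
            K_pp = matern_covariance(d_pp, self.sigma2, self.rho_km, m.spec.smoothness)
            cov = K_pp - K_pt @ W
            return mean, cov
        var = self.sigma2 - np.einsum("ij,ji->i", K_pt, W)
        return mean, np.maximum(var, 0.0)

    def predict_frequency(self, lon, lat, n_quad: int = 31) -> np.ndarray:
        """Posterior-predictive mean allele frequency at points.

        E[expit(Z)] under the latent Gaussian posterior, by Gauss-Hermite
        quadrature (deterministic; equals the large-K ensemble mean).
        """
        mean, var = self.predict_latent(lon, lat)
        t, w = np.polynomial.hermite_e.hermegauss(n_quad)
        w = w / np.sqrt(2 * np.pi)
        zz = mean[:, None] + np.sqrt(var)[:, None] * t[None, :]
        return special.expit(zz) @ w

    def conditional_simulate(
        self, grid: GridSpec, K: int | None = None, seed: int = 0, chunk_size: int = 4000
    ) -> "PosteriorEnsemble":
        """K joint draws of the latent field on the grid, inverse-logit mapped.

        Draws come from the exact Gaussian posterior on the logit scale.  For
        grids above ``chunk_size`` unmasked cells, cells are simulated in
        chunks each conditioned on the fixed training set (within-chunk joint,
        across-chunk correlation dropped) to bound the dense factorisation.
        """
        K = K or self.model.spec.K
        rng = np.random.default_rng(seed)
        lon, lat = grid.unmasked_centers()
        n_pred = lon.size
        draws = np.empty((K, n_pred))
        for start in range(0, n_pred, chunk_size):
            sl = slice(start, min(start + chunk_size, n_pred))
            mean, cov = self.predict_latent(lon[sl], lat[sl], full_cov=True)
            cov = cov + np.eye(cov.shape[0]) * max(_JITTER, _JITTER * self.sigma2)
            try:
                L = linalg.cholesky(cov, lower=True)
            except linalg.LinAlgError:
                evals = linalg.eigvalsh(cov)
                raise linalg.LinAlgError(
                    "conditional covariance not positive definite after jitter; "
                    f"smallest eigenvalue {evals[0]:.3e}"
                )
            eps = rng.standard_normal((cov.shape[0], K))
            draws[:, sl] = (mean[:, None] + L @ eps).T
        probs = special.expit(draws)
        real = np.full((K, grid.n_rows, grid.n_cols), np.nan)
        real[:, grid.mask_array()] = probs
        return PosteriorEnsemble(grid=grid, form="", realisations=real, seed=seed)

    def summary(self) -> str:
        """Plain-text fit summary."""
        m = self.model
        lines = [
            "Allele-frequency Gaussian process (empirical logit, Matern covariance)",
            "=" * 70,
            f"sites (after duplicate merging): {len(m.lon)}",
            f"smoothness nu:        {m.spec.smoothness:.3g}",
            f"mean mu (logit):      {self.mu: .4f}",
            f"variance sigma2:      {self.sigma2: .4f}",
            f"range rho (km):       {self.rho_km: .1f}",
            f"nugget tau2:          {self.tau2: .4g}",
            f"log marginal lik.:    {self.loglik: .3f}",
            f"failed restarts:      {self.n_restarts_failed}",
        ]
        return "\n".join(lines)


def fit_gp(lon, lat, x, n, spec: GPModelSpec | None = None, seed: int | None = None) -> GPResults:
    """Convenience wrapper: build an :class:`AlleleFrequencyGP` and fit it."""
    return AlleleFrequencyGP(lon, lat, x, n, spec).fit(seed=seed)


@dataclass
class PosteriorEnsemble:
    """K conditional realisations of a frequency surface (probability scale)."""

    grid: GridSpec
    form: str
    realisations: np.ndarray  # (K, n_rows, n_cols), NaN at masked cells
    seed: int

    def __post_init__(self):
        self.realisations = np.asarray(self.realisations, dtype=float)
        if self.realisations.ndim != 3 or self.realisations.shape[1:] != self.grid.shape:
            raise ValueError("realisations must be (K, n_rows, n_cols) matching the grid")

    @property
    def K(self) -> int:
        return self.realisations.shape[0]

    def unmasked(self) -> np.ndarray:
        """(K, n_unmasked) view of the realisations."""
        return self.realisations[:, self.grid.mask_array()]


def ppd_summary(ensemble: PosteriorEnsemble, level: float = 0.95):
    """Per-cell posterior-predictive mean and credible band.

    Returns ``(mean, lower, upper, width)`` surfaces on the probability
    scale; lower/upper are the empirical (1 -/+ level)/2 quantiles across
    realisations (linear interpolation between order statistics).
    """
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    if ensemble.K < 2:
        raise ValueError("need at least 2 realisations")
    vals = ensemble.unmasked()
    mean = vals.mean(axis=0)
    lo = np.quantile(vals, (1 - level) / 2, axis=0)
    hi = np.quantile(vals, (1 + level) / 2, axis=0)
    g = ensemble.grid
    f = ensemble.form
    return (
        surface_from_flat(g, mean, form=f),
        surface_from_flat(g, lo, form=f),
        surface_from_flat(g, hi, form=f),
        surface_from_flat(g, hi - lo, form=f, scale="probability"),
    )


@dataclass
class CVReport:
    """k-fold cross-validation metrics on the probability scale."""

    folds: "object"  # pandas DataFrame: fold, n_held_out, mae, correlation
    mae: float
    correlation: float
    k: int
    seed: int

    def __str__(self):
        return (
            f"{self.k}-fold CV: MAE={self.mae:.4f} ({100 * self.mae:.2f}%), "
            f"obs-vs-pred r={self.correlation:.3f}"
        )


def fold_metrics(observed, predicted) -> tuple[float, float]:
    """(MAE, Pearson correlation) between observed and predicted frequencies.

    Correlation is NaN (undefined) for fewer than two points or zero variance.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    mae = float(np.abs(observed - predicted).mean())
    if observed.size >= 2 and np.std(observed) > 0 and np.std(predicted) > 0:
        corr = float(stats.pearsonr(observed, predicted)[0])
    else:
        corr = float("nan")
    return mae, corr


def kfold_cv(
    lon, lat, x, n, spec: GPModelSpec | None = None, k: int = 10, seed: int = 0
) -> CVReport:
    """Random k-fold cross-validation of the allele-frequency GP.

    Each fold is held out, the model refitted on the remainder, and the
    posterior-predictive mean frequency compared with the observed frequency
    x/n.  Reports per-fold and average MAE (probability scale) and Pearson
    correlation.  Folds with fewer than two points have undefined correlation;
    these are recorded as missing and excluded from the average.
    """
    import pandas as pd

    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    x = np.asarray(x, dtype=float)
    n = np.asarray(n, dtype=float)
    m = len(lon)
    if m < k:
        raise ValueError(f"need at least k={k} observations, have {m}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(m)
    assignment = np.empty(m, dtype=int)
    assignment[perm] = np.arange(m) % k
    obs_freq = x / n
    rows = []
    for fold in range(k):
        held = assignment == fold
        res = AlleleFrequencyGP(lon[~held], lat[~held], x[~held], n[~held], spec).fit(seed=seed)
        pred = res.predict_frequency(lon[held], lat[held])
        mae, corr = fold_metrics(obs_freq[held], pred)
        if np.isnan(corr):
            warnings.warn(f"fold {fold}: correlation undefined (<2 points or zero variance)")
        rows.append(
            {"fold": fold, "n_held_out": int(held.sum()), "mae": mae, "correlation": corr}
        )
    df = pd.DataFrame(rows)
    return CVReport(
        folds=df,
        mae=float(df["mae"].mean()),
        correlation=float(df["correlation"].mean(skipna=True)),
        k=k,
        seed=seed,
    )
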