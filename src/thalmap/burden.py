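"""Four-allele Hardy-Weinberg genotype arithmetic and newborn burden tables.

The alpha-globin locus is treated as a four-allele system: p = frequency of
the double-gene deletion haplotype (--), q = single-gene deletion (-a),
r = non-deletional mutation (aa_ND) and s = wild type (aa), with
p + q + r + s = 1.  Under random mating the full genotype expansion is

    p2 + 2pq + 2pr + 2ps + q2 + 2qr + 2qs + r2 + 2rs + s2 = 1.

The three severe newborn phenotypes and their frequencies, with an optional
population coefficient of consanguinity F, are

    Hb Bart's hydrops fetalis   --/--      p2 + F p (1 - p)
    deletional HbH disease      -a/--      2pq (1 - F)
    non-deletional HbH disease  aa_ND/--   2pr (1 - F)

Expected affected births follow by multiplying per-cell genotype frequencies
with a birth-count raster (population x crude birth rate) and aggregating
within admin units, per posterior realisation; credible intervals are
empirical quantiles across realisations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geostat import PosteriorEnsemble
from .grids import Surface
from .synthetic import ProvincePartition

__all__ = [
    "AlleleFrequencyVector",
    "BurdenConfig",
    "BurdenTable",
    "DemographySpec",
    "GenotypeFrequencies",
    "affected_births",
    "birth_surface",
    "compare_scenarios",
    "hwe_expansion",
    "severe_genotype_frequencies",
]

GENOTYPES = (
    "--/--", "-a/--", "aaND/--", "aa/--", "-a/-a",
    "-a/aaND", "-a/aa", "aaND/aaND", "aaND/aa", "aa/aa",
)

SEVERE_GENOTYPES = ("--/--", "-a/--", "aaND/--")

DISORDER_NAMES = {
    "--/--": "Hb Bart's hydrops fetalis",
    "-a/--": "Deletional HbH disease",
    "aaND/--": "Non-deletional HbH disease",
}


@dataclass(frozen=True)
class AlleleFrequencyVector:
    """(p, q, r, s) allele frequencies; s may be derived as 1 - p - q - r."""

    p: float
    q: float
    r: float
    s: float

    def __post_init__(self):
        for name, val in zip("pqrs", (self.p, self.q, self.r, self.s)):
            if not (-1e-9 <= val <= 1 + 1e-9):
                raise ValueError(f"allele frequency {name}={val} outside [0,1]")
        total = self.p + self.q + self.r + self.s
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"allele frequencies sum to {total}, not 1")

    @classmethod
    def from_pqr(cls, p: float, q: float, r: float) -> "AlleleFrequencyVector":
        s = 1.0 - p - q - r
        if s < -1e-9:
            raise ValueError(f"p+q+r = {p + q + r} exceeds 1")
        return cls(p, q, r, max(s, 0.0))


@dataclass(frozen=True)
class GenotypeFrequencies:
    """Frequencies of the three severe newborn genotypes."""

    hydrops: float
    hbh_del: float
    hbh_nondel: float


@dataclass(frozen=True)
class BurdenConfig:
    """F: population coefficient of consanguinity; level: credible level."""

    F: float = 0.0
    level: float = 0.95

    def __post_init__(self):
        if not (0.0 <= self.F <= 1.0):
            raise ValueError("F must be in [0,1]")
        if not (0.0 < self.level < 1.0):
            raise ValueError("level must be in (0,1)")


@dataclass
class DemographySpec:
    """Population raster (persons per cell) and crude birth rate.

    ``crude_birth_rate`` is births per person per year; use ``per_1000=True``
    if the input is the conventional per-1000 figure.
    """

    population: Surface
    crude_birth_rate: float
    per_1000: bool = False

    def __post_init__(self):
        if self.per_1000:
            self.crude_birth_rate = self.crude_birth_rate / 1000.0
            self.per_1000 = False
        if not (0.0 <= self.crude_birth_rate <= 0.1):
            raise ValueError(
                f"crude birth rate {self.crude_birth_rate} per person-year implausible"
            )
        vals = self.population.unmasked()
        if np.any(vals[np.isfinite(vals)] < 0):
            raise ValueError("population must be non-negative")


def hwe_expansion(v: AlleleFrequencyVector) -> dict[str, float]:
    """All ten genotype frequencies of the four-allele system (sum to 1)."""
    p, q, r, s = v.p, v.q, v.r, v.s
    return {
        "--/--": p * p,
        "-a/--": 2 * p * q,
        "aaND/--": 2 * p * r,
        "aa/--": 2 * p * s,
        "-a/-a": q * q,
        "-a/aaND": 2 * q * r,
        "-a/aa": 2 * q * s,
        "aaND/aaND": r * r,
        "aaND/aa": 2 * r * s,
        "aa/aa": s * s,
    }


def severe_genotype_frequencies(v: AlleleFrequencyVector, F: float = 0.0) -> GenotypeFrequencies:
    """Severe-genotype frequencies with consanguinity adjustment F.

    hydrops = p^2 + F p (1-p); each HbH term is deflated by (1 - F).
    """
    if not (0.0 <= F <= 1.0):
        raise ValueError("F must be in [0,1]")
    p, q, r = v.p, v.q, v.r
    # integer literals keep exact (e.g. Fraction) inputs exact
    return GenotypeFrequencies(
        hydrops=p * p + F * p * (1 - p),
        hbh_del=2 * p * q * (1 - F),
        hbh_nondel=2 * p * r * (1 - F),
    )


def birth_surface(dem: DemographySpec) -> Surface:
    """Births per cell per year: population times crude birth rate."""
    vals = dem.population.values * dem.crude_birth_rate
    return Surface(dem.population.grid, vals, scale="births")


@dataclass
class BurdenTable:
    """Admin-unit expected affected births per year with credible intervals.

    ``table`` columns: admin_unit, genotype, disorder, mean, ci_lower,
    ci_upper; the national rows carry ``admin_unit = "National"``.
    ``renormalised_fraction`` is the share of (cell, realisation) pairs where
    p + q + r exceeded 1 and was scaled back to the simplex.
    """

    table: pd.DataFrame
    level: float
    F: float
    K: int
    renormalised_fraction: float = 0.0

    def national(self) -> pd.DataFrame:
        return self.table[self.table["admin_unit"] == "National"]

    def provinces(self) -> pd.DataFrame:
        return self.table[self.table["admin_unit"] != "National"]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _severe_freq_arrays(P, Q, R, F):
    """Vectorised severe-genotype frequencies; returns (hydrops, del, nondel)."""
    return (
        P * P + F * P * (1.0 - P),
        2.0 * P * Q * (1.0 - F),
        2.0 * P * R * (1.0 - F),
    )


def affected_births(
    p_ens: PosteriorEnsemble,
    q_ens: PosteriorEnsemble,
    r_ens: PosteriorEnsemble,
    births: Surface,
    provinces: ProvincePartition,
    cfg: BurdenConfig = BurdenConfig(),
) -> BurdenTable:
    """Province-level expected severe births with empirical credible intervals.

    Realisation k of each form's posterior ensemble is paired with realisation
    k of the others; per realisation, per-cell genotype frequencies are
    multiplied by per-cell births and summed within provinces.  Means and
    (1 +/- level)/2 quantiles are taken across the K realisation totals.
    Draws where p + q + r > 1 in a cell are renormalised onto the simplex and
    counted in ``renormalised_fraction``.
    """
    K = p_ens.K
    if not (q_ens.K == K and r_ens.K == K):
        raise ValueError(f"ensembles must share K: got {K}, {q_ens.K}, {r_ens.K}")
    grid = p_ens.grid
    for other, name in ((q_ens.grid, "q"), (r_ens.grid, "r"), (births.grid, "births"),
                        (provinces.grid, "provinces")):
        if not grid.same_geometry(other):
            raise ValueError(f"{name} grid does not match the p ensemble grid")
    labels = provinces.label_flat()
    orphans = np.nonzero(labels < 0)[0]
    if orphans.size:
        raise ValueError(f"province labels do not cover the mask: orphan cells {orphans[:10]}")
    b = births.unmasked()
    P = p_ens.unmasked().copy()
    Q = q_ens.unmasked().copy()
    R = r_ens.unmasked().copy()
    total = P + Q + R
    over = total > 1.0
    if np.any(over):
        scale = np.where(over, 1.0 / total, 1.0)
        P, Q, R = P * scale, Q * scale, R * scale
    renorm_frac = float(np.mean(over))

    k_prov = provinces.k
    hyd, hdel, hnd = _severe_freq_arrays(P, Q, R, cfg.F)
    per_prov = np.empty((3, K, k_prov))
    national = np.empty((3, K))
    for gi, G in enumerate((hyd, hdel, hnd)):
        cellwise = G * b[None, :]  # (K, cells) expected births
        national[gi] = cellwise.sum(axis=1)
        for k in range(K):
            per_prov[gi, k] = np.bincount(labels, weights=cellwise[k], minlength=k_prov)

    lo_q, hi_q = (1 - cfg.level) / 2, (1 + cfg.level) / 2
    rows = []
    for gi, geno in enumerate(SEVERE_GENOTYPES):
        for prov in range(k_prov):
            draws = per_prov[gi, :, prov]
            rows.append(
                {
                    "admin_unit": f"province-{prov}",
                    "genotype": geno,
                    "disorder": DISORDER_NAMES[geno],
                    "mean": float(draws.mean()),
                    "ci_lower": float(np.quantile(draws, lo_q)),
                    "ci_upper": float(np.quantile(draws, hi_q)),
                }
            )
        draws = national[gi]
        rows.append(
            {
                "admin_unit": "National",
                "genotype": geno,
                "disorder": DISORDER_NAMES[geno],
                "mean": float(draws.mean()),
                "ci_lower": float(np.quantile(draws, lo_q)),
                "ci_upper": float(np.quantile(draws, hi_q)),
            }
        )
    return BurdenTable(
        table=pd.DataFrame(rows),
        level=cfg.level,
        F=cfg.F,
        K=K,
        renormalised_fraction=renorm_frac,
    )


def compare_scenarios(base: BurdenTable, alt: BurdenTable) -> pd.DataFrame:
    """Row-wise absolute and relative differences between two burden tables.

    Relative differences are (alt - base) / base (NaN where base mean is 0).
    """
    key = ["admin_unit", "genotype"]
    b = base.table.set_index(key).sort_index()
    a = alt.table.set_index(key).sort_index()
    if not b.index.equals(a.index):
        raise ValueError("burden tables have different admin_unit/genotype indices")
    out = pd.DataFrame(index=b.index)
    out["mean_base"] = b["mean"]
    out["mean_alt"] = a["mean"]
    out["abs_diff"] = a["mean"] - b["mean"]
    with np.errstate(divide="ignore", invalid="ignore"):
        out["rel_diff"] = np.where(b["mean"] != 0, out["abs_diff"] / b["mean"], np.nan)
    return out.reset_index()
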