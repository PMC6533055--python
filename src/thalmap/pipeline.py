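"""Configuration-driven end-to-end runs: simulate -> map -> cv -> burden.

A single YAML config drives every stage; one master seed determines every
stochastic step (per-stage substreams are derived deterministically from it).
Each stage writes its outputs plus a JSON run manifest listing the config
hash, the seed, package versions and a SHA-256 content hash of every file it
produced.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__, burden as burden_mod, geodb, geostat, synthetic
from .grids import GridSpec, Surface, read_ascii_grid, surface_from_flat, write_ascii_grid

logger = logging.getLogger("thalmap")

FORMS = geodb.FORMS


class StageError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""


@dataclass
class PipelineConfig:
    raw: dict
    path: Path | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(raw=raw, path=path)

    def __getitem__(self, key):
        return self.raw[key]

    def get(self, key, default=None):
        return self.raw.get(key, default)

    @property
    def seed(self) -> int:
        return int(self.raw.get("run", {}).get("seed", 0))

    @property
    def output_dir(self) -> Path:
        return Path(self.raw.get("run", {}).get("output_dir", "thalmap_out"))

    def grid(self) -> GridSpec:
        g = self.raw["run"]["grid"]
        return GridSpec(
            origin_lon=float(g["origin_lon"]),
            origin_lat=float(g["origin_lat"]),
            cell_size=float(g["cell_size"]),
            n_rows=int(g["n_rows"]),
            n_cols=int(g["n_cols"]),
        )

    def model_spec(self, seed: int) -> geostat.GPModelSpec:
        m = self.raw.get("model", {})
        kwargs = {}
        for k in ("smoothness", "K", "level", "n_restarts"):
            if k in m:
                kwargs[k] = m[k]
        for k in ("variance_bounds", "range_bounds_km", "nugget_bounds"):
            if k in m:
                kwargs[k] = tuple(m[k])
        return geostat.GPModelSpec(seed=seed, **kwargs)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _substream(master_seed: int, stage: str, index: int = 0) -> int:
    """Deterministic per-stage seed below 2**31."""
    h = hashlib.sha256(f"{master_seed}:{stage}:{index}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(config: PipelineConfig, stage: str, files: list[Path], extra: dict | None = None) -> Path:
    out = config.output_dir
    manifest = {
        "stage": stage,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "thalmap_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "outputs": {str(f.relative_to(out)): _sha256(f) for f in files},
    }
    if extra:
        manifest.update(extra)
    path = out / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def run_simulate(config: PipelineConfig) -> dict:
    """Generate a synthetic study and write it in the formats the pipeline reads."""
    try:
        out = config.output_dir
        out.mkdir(parents=True, exist_ok=True)
        grid = config.grid()
        syn = config.get("synthetic", {})
        study = synthetic.simulate_study(
            grid,
            n_sites=int(syn.get("n_sites", 90)),
            total_population=float(syn.get("total_population", 7.0e7)),
            n_provinces=int(syn.get("n_provinces", 12)),
            clustering=float(syn.get("clustering", 1.0)),
            crude_birth_rate=float(syn.get("crude_birth_rate", 0.0105)),
            seed=_substream(config.seed, "simulate"),
        )
        files = []
        p = out / "surveys.csv"
        geodb.write_survey_table(study.surveys, p)
        files.append(p)
        for f in FORMS:
            p = out / f"truth_{f}.asc"
            write_ascii_grid(study.truth[f], p)
            files.append(p)
        p = out / "population.asc"
        write_ascii_grid(study.population, p)
        files.append(p)
        p = out / "provinces.asc"
        lab = Surface(grid, study.provinces.labels.astype(float), scale="label")
        write_ascii_grid(lab, p)
        files.append(p)
        p = out / "provinces.geojson"
        synthetic.provinces_to_geojson(study.provinces, p)
        files.append(p)
        files.append(write_manifest(config, "simulate", files))
        logger.info("simulate: %d surveys, %d provinces", len(study.surveys), study.provinces.k)
        return {"study": study, "files": files}
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"[simulate] {exc}") from exc


def _load_surveys(config: PipelineConfig) -> tuple[geodb.SurveyDatabase, set | None]:
    paths = config.get("paths", {})
    survey_path = paths.get("surveys", config.output_dir / "surveys.csv")
    db = geodb.load_survey_table(survey_path, "all",
                                 percent=bool(paths.get("surveys_percent", False)))
    countries = config.get("run", {}).get("countries")
    return db, (set(countries) if countries else None)


def run_map(config: PipelineConfig) -> dict:
    """Fit the GP per form, conditionally simulate, summarise, write rasters."""
    try:
        out = config.output_dir
        out.mkdir(parents=True, exist_ok=True)
        grid = config.grid()
        db, countries = _load_surveys(config)
        K = int(config.get("run", {}).get("K", 100))
        level = float(config.get("burden", {}).get("level", 0.95))
        files = []
        ensembles = {}
        counts = {}
        for i, form in enumerate(FORMS):
            sub = db
            if countries:
                sub = geodb.filter_for_modelling(db, countries, form)
            fit_seed = _substream(config.seed, "fit", i)
            spec = config.model_spec(seed=fit_seed)
            model = geostat.AlleleFrequencyGP.from_database(sub, form, spec)
            counts[form] = len(model.lon)
            logger.info("map: fitting %s on %d sites", form, counts[form])
            res = model.fit()
            logger.info("map: %s params %s", form, res.params)
            ens = res.conditional_simulate(grid, K=K, seed=_substream(config.seed, "sim", i))
            ens.form = form
            ensembles[form] = ens
            mean, lo, hi, width = geostat.ppd_summary(ens, level)
            for name, surf in (("mean", mean), ("lower", lo), ("upper", hi), ("width", width)):
                p = out / f"pred_{form}_{name}.asc"
                write_ascii_grid(surf, p)
                files.append(p)
            p = out / f"ensemble_{form}.npz"
            np.savez_compressed(p, realisations=ens.realisations, seed=ens.seed)
            files.append(p)
        files.append(
            write_manifest(config, "map", files, extra={"n_observations": counts, "K": K})
        )
        return {"ensembles": ensembles, "files": files, "n_observations": counts}
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"[map] {exc}") from exc


def run_cv(config: PipelineConfig) -> dict:
    """Per-form k-fold cross-validation; writes one CSV per form plus a summary."""
    try:
        out = config.output_dir
        out.mkdir(parents=True, exist_ok=True)
        db, countries = _load_surveys(config)
        k = int(config.get("cv", {}).get("k", 10))
        files = []
        summary = {}
        for i, form in enumerate(FORMS):
            sub = db
            if countries:
                sub = geodb.filter_for_modelling(db, countries, form)
            model = geostat.AlleleFrequencyGP.from_database(sub, form, config.model_spec(0))
            n_obs = len(model.lon)
            k_eff = k
            if n_obs < k:
                k_eff = n_obs
                logger.warning("cv: only %d observations for %s; k reduced to %d", n_obs, form, k_eff)
            report = geostat.kfold_cv(
                model.lon, model.lat, model.x, model.n,
                spec=config.model_spec(seed=_substream(config.seed, "cvfit", i)),
                k=k_eff,
                seed=_substream(config.seed, "cv", i),
            )
            p = out / f"cv_{form}.csv"
            report.folds.to_csv(p, index=False)
            files.append(p)
            summary[form] = {"mae": report.mae, "correlation": report.correlation, "k": report.k}
            logger.info("cv: %s %s", form, report)
        p = out / "cv_summary.json"
        p.write_text(json.dumps(summary, indent=1))
        files.append(p)
        files.append(write_manifest(config, "cv", files))
        return {"summary": summary, "files": files}
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"[cv] {exc}") from exc


def _load_provinces(config: PipelineConfig, grid: GridSpec) -> synthetic.ProvincePartition:
    paths = config.get("paths", {})
    label_path = paths.get("provinces_labels", config.output_dir / "provinces.asc")
    lab = read_ascii_grid(label_path, scale="label")
    labels = np.where(np.isfinite(lab.values), lab.values, -1).astype(int)
    k = int(labels.max()) + 1
    return synthetic.ProvincePartition(grid=grid, labels=labels, polygons=[], k=k)


def run_burden(config: PipelineConfig, ensembles: dict | None = None) -> dict:
    """Burden tables from the mapped ensembles plus demography and provinces."""
    try:
        out = config.output_dir
        out.mkdir(parents=True, exist_ok=True)
        grid = config.grid()
        paths = config.get("paths", {})
        if ensembles is None:
            ensembles = {}
            for form in FORMS:
                p = Path(paths.get(f"ensemble_{form}", out / f"ensemble_{form}.npz"))
                if not p.exists():
                    raise FileNotFoundError(f"missing ensemble for form {form}: {p}")
                with np.load(p) as npz:
                    ensembles[form] = geostat.PosteriorEnsemble(
                        grid=grid, form=form,
                        realisations=npz["realisations"], seed=int(npz["seed"]),
                    )
        missing = [f for f in FORMS if f not in ensembles]
        if missing:
            raise FileNotFoundError(f"missing ensembles for forms {missing}")
        pop = read_ascii_grid(paths.get("population", out / "population.asc"), scale="persons")
        bcfg = config.get("burden", {})
        dem = burden_mod.DemographySpec(
            population=pop,
            crude_birth_rate=float(bcfg.get("crude_birth_rate", 0.0105)),
            per_1000=bool(bcfg.get("cbr_per_1000", False)),
        )
        births = burden_mod.birth_surface(dem)
        provinces = _load_provinces(config, pop.grid)
        cfg = burden_mod.BurdenConfig(F=float(bcfg.get("F", 0.0)), level=float(bcfg.get("level", 0.95)))
        table = burden_mod.affected_births(
            ensembles["a0"], ensembles["aplus"], ensembles["and"], births, provinces, cfg
        )
        # consistency check: HbH totals must scale exactly by (1 - F)
        if cfg.F > 0:
            base = burden_mod.affected_births(
                ensembles["a0"], ensembles["aplus"], ensembles["and"], births, provinces,
                burden_mod.BurdenConfig(F=0.0, level=cfg.level),
            )
            nat = table.national().set_index("genotype")["mean"]
            nat0 = base.national().set_index("genotype")["mean"]
            hbh = nat["-a/--"] + nat["aaND/--"]
            hbh0 = nat0["-a/--"] + nat0["aaND/--"]
            logger.info("burden: HbH F=%g / F=0 ratio = %.6f (expected %.6f)",
                        cfg.F, hbh / hbh0 if hbh0 else float("nan"), 1 - cfg.F)
        files = []
        p = out / "burden.csv"
        table.to_csv(p)
        files.append(p)
        p = out / "burden_national.csv"
        table.national().to_csv(p, index=False)
        files.append(p)
        files.append(write_manifest(config, "burden", files, extra={
            "F": cfg.F, "K": table.K, "renormalised_fraction": table.renormalised_fraction,
        }))
        logger.info("burden: national means %s",
                    table.national()[["genotype", "mean"]].to_dict("records"))
        return {"table": table, "files": files}
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"[burden] {exc}") from exc


def run_report(config: PipelineConfig) -> dict:
    """Collect stage manifests and summaries into one report JSON."""
    out = config.output_dir
    report = {"config_hash": config.config_hash(), "seed": config.seed, "stages": {}}
    for stage in ("simulate", "map", "cv", "burden"):
        m = out / f"manifest_{stage}.json"
        if m.exists():
            report["stages"][stage] = json.loads(m.read_text())
    p = out / "report.json"
    p.write_text(json.dumps(report, indent=1, sort_keys=True))
    return {"report": report, "files": [p]}
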