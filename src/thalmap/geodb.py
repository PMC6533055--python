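"""Survey database for alpha-thalassaemia allele-frequency and variant data.

A *survey* is a single population sample with a geolocation (or a
national-level flag), a sample size in individuals, observed allele
frequencies for up to three forms of alpha-thalassaemia (``a0`` = double-gene
deletion, ``aplus`` = single-gene deletion, ``and`` = non-deletional), and
optionally per-variant chromosome counts for the eleven variants commonly
assayed in Southeast Asia.

Frequencies are stored as proportions in [0, 1].  Tables whose frequency
columns are percentages must say so explicitly (``percent=True``); the loader
never guesses the unit.  Counts of variant chromosomes are taken out of
``2 * n_individuals`` chromosomes.
"""

from __future__ import annotations

import datetime
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

FORMS = ("a0", "aplus", "and")

#: the eleven canonical variants plus the catch-all bucket
CANONICAL_VARIANTS = (
    "-a3.7",
    "-a4.2",
    "--SEA",
    "--THAI",
    "--MED",
    "--FIL",
    "-(a)20.5",
    "Hb Adana",
    "Hb CS",
    "Hb Pakse",
    "Hb Quong Sze",
    "Other",
)

#: modelling region: target country plus its surveyed neighbours
DEFAULT_MODEL_COUNTRIES = frozenset(
    {"Thailand", "Myanmar", "Lao PDR", "Cambodia", "Malaysia"}
)


class SchemaError(ValueError):
    """A mandatory column is missing or the table layout is unusable."""


class ValidationError(ValueError):
    """A row violates a survey-record invariant."""


class NoDataError(ValueError):
    """A filter or summary matched no records."""


class IncompleteSurveyError(ValueError):
    """An operation needs all three forms but the survey tested fewer."""


@dataclass
class SurveyRecord:
    survey_id: str
    country: str
    n_individuals: int
    source_id: str = ""
    location_name: str = ""
    latitude: float | None = None
    longitude: float | None = None
    national_level: bool = False
    year: int | None = None
    group: str = ""
    freq: dict[str, float] = field(default_factory=dict)
    variants_tested: set[str] = field(default_factory=set)
    variant_chromosomes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        rid = self.survey_id
        if self.n_individuals < 1:
            raise ValidationError(f"{rid}: n_individuals must be >= 1, got {self.n_individuals}")
        for form, f in self.freq.items():
            if form not in FORMS:
                raise ValidationError(f"{rid}: unknown form {form!r}")
            if not (0.0 <= f <= 1.0):
                raise ValidationError(f"{rid}: frequency for {form} outside [0,1]: {f}")
        if self.national_level:
            if self.latitude is not None or self.longitude is not None:
                raise ValidationError(f"{rid}: national-level survey must not carry coordinates")
        else:
            if self.latitude is None or self.longitude is None:
                raise ValidationError(f"{rid}: point survey needs latitude and longitude")
            if not (-90 <= self.latitude <= 90 and -180 <= self.longitude <= 180):
                raise ValidationError(f"{rid}: coordinates out of range")
        unknown = set(self.variant_chromosomes) - self.variants_tested
        if unknown:
            raise ValidationError(f"{rid}: counts for untested variants {sorted(unknown)}")
        # a tested variant with no recorded count was observed on 0 chromosomes
        for variant in self.variants_tested:
            self.variant_chromosomes.setdefault(variant, 0)
        for variant, count in self.variant_chromosomes.items():
            if count < 0:
                raise ValidationError(f"{rid}: negative count for {variant}")
            if count > 2 * self.n_individuals:
                raise ValidationError(
                    f"{rid}: {variant} count {count} exceeds {2 * self.n_individuals} chromosomes"
                )
        bad = self.variants_tested - set(CANONICAL_VARIANTS)
        if bad:
            warnings.warn(
                f"{rid}: unknown variant labels {sorted(bad)} mapped to 'Other'", stacklevel=3
            )
            self.variants_tested = (self.variants_tested - bad) | {"Other"}
            moved = sum(self.variant_chromosomes.pop(v, 0) for v in bad)
            if moved:
                self.variant_chromosomes["Other"] = self.variant_chromosomes.get("Other", 0) + moved

    @property
    def has_point(self) -> bool:
        return not self.national_level


@dataclass
class SurveyDatabase:
    records: list[SurveyRecord] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [r.survey_id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate survey_id(s): {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def chromosomes(rec: SurveyRecord) -> int:
    """Number of chromosomes in the study sample: twice the sample size."""
    return 2 * rec.n_individuals


def overall_frequency(rec: SurveyRecord) -> float:
    """Total alpha-thalassaemia allele frequency, summed over the three forms.

    Defined only for surveys that tested all three forms.
    """
    missing = [f for f in FORMS if f not in rec.freq]
    if missing:
        raise IncompleteSurveyError(
            f"{rec.survey_id}: forms not tested: {missing}; overall frequency undefined"
        )
    total = sum(rec.freq[f] for f in FORMS)
    if total > 1.0 + 1e-9:
        raise ValidationError(f"{rec.survey_id}: form frequencies sum to {total} > 1")
    return total


def form_proportions(rec: SurveyRecord) -> tuple[float, float, float]:
    """Each form's share of all alpha-thalassaemia chromosomes (sums to 1)."""
    total = overall_frequency(rec)
    if total == 0:
        raise ValidationError(
            f"{rec.survey_id}: overall frequency is 0; form proportions undefined"
        )
    return tuple(rec.freq[f] / total for f in FORMS)


def filter_for_modelling(
    db: SurveyDatabase, countries: set[str] | frozenset[str], form: str
) -> SurveyDatabase:
    """Modelling subset: point-located surveys of one form inside a country set.

    National-level surveys are excluded (they cannot anchor a spatial model).
    """
    if form not in FORMS:
        raise ValueError(f"unknown form {form!r}")
    kept = [
        r
        for r in db.records
        if r.country in countries and form in r.freq and r.has_point
    ]
    if not kept:
        raise NoDataError(
            f"no point-located {form} surveys in countries {sorted(countries)}"
        )
    return SurveyDatabase(records=list(kept), provenance={**db.provenance, "filter": form})


def summarize_by_form(db: SurveyDatabase) -> dict[str, int]:
    """Record count per form (a record counts for each form it reports)."""
    return {f: sum(1 for r in db.records if f in r.freq) for f in FORMS}


def observed_range(
    db: SurveyDatabase, form: str, country: str | None = None
) -> tuple[float, float]:
    """(min, max) observed allele frequency for a form, optionally per country."""
    vals = [
        r.freq[form]
        for r in db.records
        if form in r.freq and (country is None or r.country == country)
    ]
    if not vals:
        raise NoDataError(f"no {form} observations" + (f" in {country}" if country else ""))
    return (min(vals), max(vals))


def variant_table(db: SurveyDatabase) -> pd.DataFrame:
    """Long table of per-survey variant allele frequencies.

    One row per (survey, canonical variant).  Variants tested but absent get
    frequency 0 with ``tested=True``; untested variants get ``tested=False``
    and a missing frequency (the 'NA' convention of typed-variant surveys).
    """
    rows = []
    for rec in db.records:
        n_chrom = chromosomes(rec)
        for variant in CANONICAL_VARIANTS:
            tested = variant in rec.variants_tested
            freq = rec.variant_chromosomes.get(variant, 0) / n_chrom if tested else math.nan
            rows.append(
                {"survey_id": rec.survey_id, "variant": variant, "frequency": freq, "tested": tested}
            )
    return pd.DataFrame(rows, columns=["survey_id", "variant", "frequency", "tested"])


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_MANDATORY = ("survey_id", "country", "n_individuals")

_FREQ_COLS = {f: f"freq_{f}" for f in FORMS}
_COUNT_COLS = {f: f"count_{f}" for f in FORMS}


def _get(row, col, default=None):
    v = row.get(col, default)
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return default
    return v


def load_survey_table(
    path: str | Path,
    form_or_kind: str = "all",
    *,
    percent: bool = False,
    errors: str = "raise",
) -> SurveyDatabase:
    """Load a survey CSV into a validated :class:`SurveyDatabase`.

    Parameters
    ----------
    path : CSV file with a header row (see ``docs/column_dictionary.md``).
        Frequency columns ``freq_a0``/``freq_aplus``/``freq_and`` (or
        chromosome-count columns ``count_<form>``, normalised by ``2n`` at
        load); variant columns ``var:<label>`` hold chromosome counts, empty =
        not tested.
    form_or_kind : ``"a0"``, ``"aplus"``, ``"and"`` to require that form's
        frequency on every row; ``"diversity"`` to require variant counts;
        ``"all"`` to accept any mix.
    percent : frequencies are percentages in [0, 100] and are divided by 100.
        Never inferred from the data.
    errors : ``"raise"`` aborts on the first invalid row; ``"drop"`` rejects
        invalid rows, recording row-level diagnostics in
        ``db.provenance["rejected"]``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing mandatory column(s) {missing}")
    has_coords = {"latitude", "longitude"} <= set(df.columns)
    if not has_coords and "national_level" not in df.columns:
        raise SchemaError(f"{path.name}: needs latitude/longitude or a national_level column")
    if form_or_kind not in FORMS + ("diversity", "all"):
        raise ValueError(f"unknown form_or_kind {form_or_kind!r}")

    variant_cols = [c for c in df.columns if c.startswith("var:")]
    records: list[SurveyRecord] = []
    rejected: list[dict] = []
    for idx, row in df.iterrows():
        row = row.to_dict()
        rid = str(row["survey_id"])
        try:
            n = int(row["n_individuals"])
            freq: dict[str, float] = {}
            for form in FORMS:
                f = _get(row, _FREQ_COLS[form])
                if f is None:
                    c = _get(row, _COUNT_COLS[form])
                    if c is not None:
                        freq[form] = float(c) / (2 * n)
                    continue
                f = float(f)
                if percent:
                    if not (0.0 <= f <= 100.0):
                        raise ValidationError(
                            f"{rid}: {form} percentage outside [0,100]: {f}"
                        )
                    f /= 100.0
                freq[form] = f
            if form_or_kind in FORMS and form_or_kind not in freq:
                raise ValidationError(f"{rid}: required form {form_or_kind} missing")
            variants_tested: set[str] = set()
            variant_chromosomes: dict[str, int] = {}
            for col in variant_cols:
                label = col[len("var:"):]
                v = _get(row, col)
                if v is None:
                    continue
                variants_tested.add(label)
                variant_chromosomes[label] = int(v)
            if form_or_kind == "diversity" and not variants_tested:
                raise ValidationError(f"{rid}: diversity table row without variant counts")
            national = bool(_get(row, "national_level", False))
            rec = SurveyRecord(
                survey_id=rid,
                source_id=str(_get(row, "source_id", "") or ""),
                country=str(row["country"]),
                location_name=str(_get(row, "location_name", "") or ""),
                latitude=None if national else float(row["latitude"]),
                longitude=None if national else float(row["longitude"]),
                national_level=national,
                year=int(row["year"]) if _get(row, "year") is not None else None,
                group=str(_get(row, "group", "") or ""),
                n_individuals=n,
                freq=freq,
                variants_tested=variants_tested,
                variant_chromosomes=variant_chromosomes,
            )
        except (ValidationError, ValueError, KeyError, TypeError) as exc:
            if errors == "raise":
                if isinstance(exc, ValidationError):
                    raise
                raise ValidationError(f"row {idx} ({rid}): {exc}") from exc
            rejected.append({"row": int(idx), "survey_id": rid, "reason": str(exc)})
            continue
        records.append(rec)
    provenance = {
        "path": str(path),
        "loaded_at": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "percent_schema": percent,
    }
    if rejected:
        provenance["rejected"] = rejected
    return SurveyDatabase(records=records, provenance=provenance)


def write_survey_table(db: SurveyDatabase, path: str | Path) -> None:
    """Write a database back to the CSV dialect ``load_survey_table`` reads."""
    rows = []
    all_variants = sorted({v for r in db.records for v in r.variants_tested})
    for r in db.records:
        row = {
            "survey_id": r.survey_id,
            "source_id": r.source_id,
            "country": r.country,
            "location_name": r.location_name,
            "latitude": r.latitude,
            "longitude": r.longitude,
            "national_level": r.national_level,
            "year": r.year,
            "group": r.group,
            "n_individuals": r.n_individuals,
        }
        for form in FORMS:
            row[_FREQ_COLS[form]] = r.freq.get(form)
        for v in all_variants:
            row[f"var:{v}"] = r.variant_chromosomes.get(v, 0) if v in r.variants_tested else None
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def to_geojson(db: SurveyDatabase, path: str | Path | None = None) -> dict:
    """Export point-located surveys as a GeoJSON FeatureCollection."""
    features = []
    for r in db.records:
        if not r.has_point:
            continue
        props = {
            "survey_id": r.survey_id,
            "country": r.country,
            "n_individuals": r.n_individuals,
        }
        props.update({_FREQ_COLS[f]: r.freq[f] for f in FORMS if f in r.freq})
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [r.longitude, r.latitude]},
                "properties": props,
            }
        )
    fc = {"type": "FeatureCollection", "features": features}
    if path is not None:
        Path(path).write_text(json.dumps(fc, indent=1))
    return fc
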