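"""CSV readers/writers, model bundles and the end-to-end pipeline.

All tabular interchange is CSV (UTF-8, one header row, ISO-8601 dates);
numeric outputs carry explicit units in their column names (rate_per_10k,
person_years, p10).  Schema validation reports the first offending row and
column rather than silently coercing.

Table schemas
-------------
cases        case_id, person_id, sex, age_years, event_date, resident,
             mechanism, pathological, site, hospitalized, source
population   band_lower, band_upper (empty = open band), sex, count
rates        band_lower, band_upper, sex, n_cases, person_years,
             rate_per_10k, ci_low, ci_high
mortality    band_lower, band_upper, sex, death_rate_per_10k
ratios       band_lower, band_upper, sex, mof_to_hip_ratio
standard     band_lower, band_upper, weight
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .bands import SEXES
from .frax import CountryModel, probability_table
from .incidence import compute_incidence, estimate_burden, person_years, standardize_rates
from .registry import (
    MECHANISM_VALUES,
    SITE_VALUES,
    SOURCE_VALUES,
    FilterRules,
    FractureCase,
    ascertainment_summary,
    filter_cases,
)


class SchemaError(ValueError):
    """A table failed validation; the message names the row and column."""


_REQUIRED = {
    "cases": ["case_id", "person_id", "sex", "age_years", "event_date", "resident",
              "mechanism", "pathological", "site", "hospitalized", "source"],
    "population": ["band_lower", "band_upper", "sex", "count"],
    "rates": ["band_lower", "band_upper", "sex", "n_cases", "person_years",
              "rate_per_10k", "ci_low", "ci_high"],
    "mortality": ["band_lower", "band_upper", "sex", "death_rate_per_10k"],
    "ratios": ["band_lower", "band_upper", "sex", "mof_to_hip_ratio"],
    "standard": ["band_lower", "band_upper", "weight"],
}

_ENUMS = {"sex": SEXES, "mechanism": MECHANISM_VALUES, "site": SITE_VALUES,
          "source": SOURCE_VALUES}
_NONNEG = {"count", "rate_per_10k", "death_rate_per_10k", "weight",
           "person_years", "n_cases", "age_years"}


def _check_columns(df: pd.DataFrame, schema_name: str, path) -> None:
    missing = [c for c in _REQUIRED[schema_name] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)} "
                          f"for schema {schema_name!r}")


def read_table(path, schema_name: str) -> pd.DataFrame:
    """Read and validate one CSV against a named schema.

    Row numbers in error messages are 1-based data rows (header excluded).
    """
    if schema_name not in _REQUIRED:
        raise ValueError(f"unknown schema {schema_name!r}")
    df = pd.read_csv(path)
    _check_columns(df, schema_name, path)
    for col, allowed in _ENUMS.items():
        if col in _REQUIRED[schema_name]:
            bad = df.index[~df[col].isin(allowed)]
            if len(bad):
                i = int(bad[0])
                raise SchemaError(
                    f"{path}: row {i + 1}, column {col!r}: value {df.at[i, col]!r} "
                    f"not in {allowed}"
                )
    for col in _NONNEG & set(df.columns):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals < 0]
        if len(bad):
            i = int(bad[0])
            raise SchemaError(f"{path}: row {i + 1}, column {col!r}: negative value")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


_BOOL = {"0": False, "1": True, "false": False, "true": True,
         False: False, True: True, 0: False, 1: True}


def read_cases(path) -> list[FractureCase]:
    """Load a cases CSV into FractureCase records with row-level errors."""
    df = read_table(path, "cases")
    cases = []
    for i, row in df.iterrows():
        try:
            date = _dt.date.fromisoformat(str(row["event_date"]))
        except ValueError as exc:
            raise SchemaError(f"{path}: row {int(i) + 1}, column 'event_date': "
                              f"{row['event_date']!r} is not an ISO-8601 date") from exc
        try:
            cases.append(FractureCase(
                case_id=str(row["case_id"]), person_id=str(row["person_id"]),
                sex=str(row["sex"]), age_years=int(row["age_years"]), event_date=date,
                resident=_BOOL[row["resident"] if not isinstance(row["resident"], str)
                               else row["resident"].lower()],
                mechanism=str(row["mechanism"]),
                pathological=_BOOL[row["pathological"] if not isinstance(row["pathological"], str)
                                   else row["pathological"].lower()],
                site=str(row["site"]),
                hospitalized=_BOOL[row["hospitalized"] if not isinstance(row["hospitalized"], str)
                                   else row["hospitalized"].lower()],
                source=str(row["source"]),
            ))
        except (KeyError, ValueError) as exc:
            raise SchemaError(f"{path}: row {int(i) + 1}: {exc}") from exc
    return cases


def cases_to_frame(cases) -> pd.DataFrame:
    rows = []
    for c in cases:
        d = dataclasses.asdict(c)
        d["event_date"] = c.event_date.isoformat()
        for col in ("resident", "pathological", "hospitalized"):
            d[col] = int(d[col])
        rows.append(d)
    return pd.DataFrame(rows, columns=_REQUIRED["cases"])


def write_cases(cases, path) -> None:
    write_table(cases_to_frame(cases), path)


def read_rules(path) -> FilterRules:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for key in ("window_start", "window_end"):
        if key not in raw:
            raise SchemaError(f"{path}: rules file must define {key}")
        raw[key] = _dt.date.fromisoformat(str(raw[key]))
    return FilterRules(**raw)


def read_model_bundle(path) -> CountryModel:
    """Load a model bundle (YAML mapping table names to CSV paths relative
    to the bundle file, plus a scenario map and engine options)."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    base = path.parent

    def resolve(p):
        p = Path(p)
        return p if p.is_absolute() else base / p

    hip = read_table(resolve(raw["hip_rates"]), "rates")
    mort = read_table(resolve(raw["mortality"]), "mortality")
    ratios = read_table(resolve(raw["ratios"]), "ratios") if raw.get("ratios") else None
    return CountryModel(
        name=raw.get("name", path.stem),
        hip_rates=hip, mortality=mort, ratios=ratios,
        scenarios=raw.get("scenarios", {"prior_fracture": 2.0}),
        interpolation=raw.get("interpolation", "midpoint_linear"),
        a_max=int(raw.get("a_max", 100)),
    )


def bundled_data_path(name: str) -> Path:
    """Path to a table shipped with the package (synthetic stand-ins)."""
    return Path(resources.files("hipfrax") / "data" / name)


@dataclass
class RunConfig:
    """Everything the end-to-end pipeline needs."""

    cases_path: Path
    population_path: Path
    rules_path: Path
    standard_path: Path
    target_population_path: Path
    mortality_path: Path
    ratios_path: Optional[Path]
    out_dir: Path
    observation_years: float = 2.0
    ci_level: float = 0.95
    interpolation: str = "midpoint_linear"
    a_max: int = 100
    horizon_years: int = 10
    ages: tuple[int, ...] = (50, 55, 60, 65, 70, 75, 80, 85, 90)
    scenarios: dict = dataclasses.field(default_factory=lambda: {"prior_fracture": 2.0})
    seed: int = 0


def run_pipeline(config: RunConfig) -> dict:
    """Filter -> incidence -> standardize -> burden -> probabilities.

    Writes the five output tables plus a machine-readable run log to the
    output directory and returns the in-memory objects. Deterministic for
    fixed inputs; any stage failure is re-raised naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "read inputs"
    try:
        cases = read_cases(config.cases_path)
        rules = read_rules(config.rules_path)
        pop = read_table(config.population_path, "population")
        std = read_table(config.standard_path, "standard")
        target = read_table(config.target_population_path, "population")
        mort = read_table(config.mortality_path, "mortality")
        ratios = (read_table(config.ratios_path, "ratios")
                  if config.ratios_path else None)

        stage = "filter"
        report = filter_cases(cases, rules)
        write_cases(report.included, out / "included.csv")
        excl = cases_to_frame([c for c, _ in report.excluded])
        excl["reason"] = [r for _, r in report.excluded]
        write_table(excl, out / "exclusions.csv")
        summary = ascertainment_summary(report)

        stage = "incidence"
        py = person_years(pop, config.observation_years)
        rates = compute_incidence(report, py, config.ci_level)
        write_table(rates, out / "rates.csv")

        stage = "standardize"
        asr = standardize_rates(rates, std, config.ci_level)
        asr_df = pd.DataFrame([dataclasses.asdict(v) for v in asr.values()])
        write_table(asr_df, out / "standardized.csv")

        stage = "burden"
        burden = estimate_burden(rates, target)
        burden_df = pd.DataFrame(
            [{"sex": s, "expected_fractures_per_year": round(v, 1),
              "expected_fractures_per_year_int": int(round(v))}
             for s, v in burden.by_sex.items()]
            + [{"sex": "total", "expected_fractures_per_year": round(burden.total, 1),
                "expected_fractures_per_year_int": int(round(burden.total))}]
        )
        write_table(burden_df, out / "burden.csv")

        stage = "probability"
        model = CountryModel(
            name="run", hip_rates=rates, mortality=mort, ratios=ratios,
            scenarios=config.scenarios, interpolation=config.interpolation,
            a_max=config.a_max,
        )
        outcomes = ("hip", "mof") if ratios is not None else ("hip",)
        scen_names = ("baseline",) + tuple(config.scenarios)
        probs = probability_table(model, config.ages, outcomes, scen_names,
                                  config.horizon_years)
        write_table(probs, out / "probabilities.csv")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    log = {
        "package_version": __version__,
        "seed": config.seed,
        "stages": ["filter", "incidence", "standardize", "burden", "probability"],
        "inputs": {k: str(getattr(config, k)) for k in
                   ("cases_path", "population_path", "rules_path", "standard_path",
                    "target_population_path", "mortality_path", "ratios_path")},
        "options": {"observation_years": config.observation_years,
                    "ci_level": config.ci_level,
                    "interpolation": config.interpolation,
                    "a_max": config.a_max,
                    "horizon_years": config.horizon_years,
                    "ages": list(config.ages),
                    "scenarios": dict(config.scenarios)},
        "ascertainment": dataclasses.asdict(summary),
        "outputs": ["included.csv", "exclusions.csv", "rates.csv",
                    "standardized.csv", "burden.csv", "probabilities.csv"],
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2)
    return {"report": report, "summary": summary, "rates": rates,
            "standardized": asr, "burden": burden, "probabilities": probs}
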