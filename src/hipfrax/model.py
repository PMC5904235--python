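"""Model/Results surface over the registry, incidence and risk engines.

Two modelling objects organise the package, in the style of statsmodels:

``HipFractureIncidenceModel``
    built from raw case records plus a census pyramid; ``fit()`` filters
    the registry, estimates band x sex Poisson rates with exact
    confidence limits, and returns ``IncidenceResults`` carrying the
    rate table, the filter audit, ascertainment statistics, and methods
    for direct standardization and burden projection.

``FractureRiskModel``
    built from band-level incidence and mortality tables (optionally a
    MOF:hip ratio table and clinical-risk-factor scenarios); ``fit()``
    expands the bands into annual hazard curves and returns
    ``FractureRiskResults`` with 10-year competing-risk probabilities,
    probability tables, plotting, and a Monte-Carlo cross-check.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import pandas as pd

from . import frax, incidence as _inc, io as _io, registry as _reg
from .frax import CountryModel, HazardCurve
from .registry import FilterReport, FilterRules


class HipFractureIncidenceModel:
    """Age/sex-specific fracture incidence from a registry and a pyramid.

    Parameters
    ----------
    cases : list of FractureCase
        Candidate registry events (pre-filter).
    population : DataFrame
        Census pyramid with columns band_lower, band_upper, sex, count.
    rules : FilterRules
        Inclusion/exclusion rules; defines the observation window.
    observation_years : float, optional
        Duration of the survey; defaults to the rules window length in
        days / 365.25.
    """

    def __init__(self, cases, population: pd.DataFrame, rules: FilterRules,
                 observation_years: Optional[float] = None):
        self.cases = list(cases)
        self.population = population
        self.rules = rules
        if observation_years is None:
            observation_years = ((rules.window_end - rules.window_start).days + 1) / 365.25
        self.observation_years = float(observation_years)

    @classmethod
    def from_csv(cls, cases_path, population_path, rules_path,
                 observation_years: Optional[float] = None) -> "HipFractureIncidenceModel":
        return cls(_io.read_cases(cases_path),
                   _io.read_table(population_path, "population"),
                   _io.read_rules(rules_path), observation_years)

    def fit(self, ci_level: float = 0.95) -> "IncidenceResults":
        report = _reg.filter_cases(self.cases, self.rules)
        py = _inc.person_years(self.population, self.observation_years)
        rates = _inc.compute_incidence(report, py, ci_level)
        return IncidenceResults(self, report, rates, ci_level)


class IncidenceResults:
    """Fitted incidence estimates with their audit trail."""

    def __init__(self, model: HipFractureIncidenceModel, report: FilterReport,
                 rates: pd.DataFrame, ci_level: float):
        self.model = model
        self.filter_report = report
        self.rates = rates
        self.ci_level = ci_level
        self.ascertainment = _reg.ascertainment_summary(report)

    def standardized(self, standard: pd.DataFrame) -> dict[str, _inc.StandardizedRate]:
        """Directly standardized rate per sex against a weight table."""
        return _inc.standardize_rates(self.rates, standard, self.ci_level)

    def project_burden(self, target_population: pd.DataFrame) -> _inc.BurdenEstimate:
        """Expected annual fracture counts in a target pyramid."""
        return _inc.estimate_burden(self.rates, target_population)

    def summary(self) -> str:
        a = self.ascertainment
        lines = ["Hip-fracture incidence estimates",
                 "=" * 56,
                 f"Candidate cases:     {self.filter_report.n_input}",
                 f"Included:            {a.n_total} "
                 f"(female {a.n_female}, male {a.n_male})"]
        counts = self.filter_report.counts
        excl = ", ".join(f"{k}={v}" for k, v in counts.items() if v)
        lines.append(f"Excluded:            {len(self.filter_report.excluded)}"
                     + (f" ({excl})" if excl else ""))
        lines.append(f"Hospitalized:        {a.pct_hospitalized}% "
                     f"(not hospitalized {a.pct_not_hospitalized}%)")
        ratio = "undefined" if a.female_male_ratio is None else a.female_male_ratio
        lines.append(f"Female:male ratio:   {ratio}")
        lines.append(f"Observation:         {self.model.observation_years:g} years; "
                     f"CI level {self.ci_level:g} (exact Poisson)")
        lines.append("")
        tab = self.rates.copy()
        tab["band"] = [f"{int(lo)}+" if pd.isna(up) else f"{int(lo)}-{int(up) - 1}"
                       for lo, up in zip(tab["band_lower"], tab["band_upper"])]
        lines.append(tab[["band", "sex", "n_cases", "person_years",
                          "rate_per_10k", "ci_low", "ci_high"]]
                     .to_string(index=False,
                                float_format=lambda v: f"{v:.1f}"))
        return "\n".join(lines)


class FractureRiskModel:
    """FRAX-style 10-year fracture-probability model for one country.

    Wraps a :class:`~hipfrax.frax.CountryModel` bundle: band-level hip
    incidence, band-level mortality (both per 10,000 person-years), an
    optional MOF:hip ratio table, and named multiplicative risk-factor
    scenarios.
    """

    def __init__(self, hip_rates: pd.DataFrame, mortality: pd.DataFrame,
                 ratios: Optional[pd.DataFrame] = None,
                 scenarios: Optional[Mapping[str, float]] = None,
                 name: str = "model", interpolation: str = "midpoint_linear",
                 a_max: int = 100):
        self.country = CountryModel(
            name=name, hip_rates=hip_rates, mortality=mortality, ratios=ratios,
            scenarios=dict(scenarios) if scenarios else {"prior_fracture": 2.0},
            interpolation=interpolation, a_max=a_max,
        )

    @classmethod
    def from_incidence(cls, results: IncidenceResults, mortality: pd.DataFrame,
                       **kwargs) -> "FractureRiskModel":
        return cls(results.rates, mortality, **kwargs)

    @classmethod
    def from_bundle(cls, path) -> "FractureRiskModel":
        m = _io.read_model_bundle(path)
        obj = cls.__new__(cls)
        obj.country = m
        return obj

    def fit(self) -> "FractureRiskResults":
        curves = {"hip": self.country.hazard_curve("hip")}
        if self.country.ratios is not None:
            curves["mof"] = self.country.hazard_curve("mof")
        return FractureRiskResults(self, curves)


class FractureRiskResults:
    """Hazard curves and the probabilities derived from them."""

    def __init__(self, model: FractureRiskModel, curves: dict[str, HazardCurve]):
        self.model = model
        self.curves = curves
        self.outcomes = tuple(curves)

    def ten_year_probability(self, sex: str, age: int, outcome: str = "hip",
                             scenario: str = "baseline",
                             horizon_years: int = 10) -> float:
        rr = self.model.country.scenario_rr(scenario)
        return frax.ten_year_probability(self.curves[outcome], sex, age, rr,
                                         horizon_years)

    def probability_table(self, ages: Sequence[int],
                          outcomes: Optional[Sequence[str]] = None,
                          scenarios: Sequence[str] = ("baseline",),
                          horizon_years: int = 10) -> pd.DataFrame:
        return frax.probability_table(self.model.country, ages,
                                      outcomes or self.outcomes,
                                      scenarios, horizon_years)

    def mc_check(self, sex: str, age: int, outcome: str = "hip",
                 scenario: str = "baseline", n: int = 100_000,
                 seed: int = 0) -> tuple[float, float]:
        """Monte-Carlo estimate and SE for one cell (independent oracle)."""
        rr = self.model.country.scenario_rr(scenario)
        return frax.mc_probability_oracle(self.curves[outcome], sex, age, rr,
                                          n=n, seed=seed)

    def summary(self, ages: Sequence[int] = (50, 55, 60, 65, 70, 75, 80, 85, 90)) -> str:
        name = self.model.country.name
        scen = ("baseline",) + tuple(self.model.country.scenarios)
        tab = self.probability_table(ages, scenarios=scen)
        wide = tab.pivot_table(index="age", columns=["outcome", "scenario", "sex"],
                               values="p10_pct")
        lines = [f"10-year fracture probabilities (%) — {name}",
                 "=" * 56,
                 f"Outcomes: {', '.join(self.outcomes)}; "
                 f"scenarios: {', '.join(scen)}",
                 f"Interpolation: {self.model.country.interpolation}; "
                 f"terminal hazard held constant to age {self.model.country.a_max}",
                 "",
                 wide.to_string(float_format=lambda v: f"{v:.1f}")]
        return "\n".join(lines)

    def plot_probability(self, ages: Sequence[int], outcome: str = "hip",
                         scenario: str = "baseline", ax=None):
        """Probability-by-age curves, one line per sex."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        tab = self.probability_table(ages, outcomes=(outcome,), scenarios=(scenario,))
        for sex, grp in tab.groupby("sex"):
            ax.plot(grp["age"], 100 * grp["p10"], marker="o", label=sex)
        ax.set_xlabel("Age (years)")
        ax.set_ylabel(f"10-year {outcome} fracture probability (%)")
        ax.set_title(f"{self.model.country.name}: {scenario}")
        ax.legend()
        return ax


def compare_risk_models(results: Sequence[FractureRiskResults],
                        ages: Sequence[int],
                        outcomes: Sequence[str] = ("hip",)) -> pd.DataFrame:
    """Long cross-country table of baseline probabilities by age and sex."""
    return frax.compare_models([r.model.country for r in results], ages, outcomes)
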