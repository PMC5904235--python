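"""Synthetic fracture registries with known ground truth.

The generator emulates a two-year, single-city prospective hip-fracture
survey of the kind run in Eastern-European FRAX calibration studies: a
catchment population of ~35,000 persons aged 50+ (21,069 women, 14,380
men), a Gompertz (exponential-in-age) fracture hazard per sex, hospital
ascertainment that falls with age and is lower in women, and contaminant
records (high-energy, pathological, non-resident, under-age, repeat
admissions) that the registry filter must remove.  Every registry carries
a SimTruth with the generating parameters, the true band-level rates and
per-case labels, so rate recovery and filter exactness are testable
without external data.

The default preset is calibrated so the expected qualifying-case count is
76 women and 41 men over two years, with male incidence exceeding female
below age ~70 and the reverse at older ages.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
import numpy as np
import pandas as pd

from .bands import DEFAULT_BANDS, AgeBand, SEXES
from .incidence import RATE_SCALE
from .registry import FractureCase

QUALIFYING = "qualifying"
CONTAMINANT_TYPES = ("high_energy", "pathological", "nonresident", "under50", "duplicate")

#: Default Mozyr-like population pyramid (persons per 5-year band, 50-54 ... 85+).
DEFAULT_POPULATION = {
    "female": (4951, 4530, 3371, 2212, 2107, 1896, 1159, 843),   # 21,069
    "male": (3883, 3451, 2445, 1582, 1294, 1007, 503, 215),      # 14,380
}


@dataclass(frozen=True)
class GompertzIncidence:
    """h(a) = h0 * exp(gamma * (a - 50)), per person-year."""

    h0: float
    gamma: float

    def hazard(self, age: float) -> float:
        if self.h0 < 0:
            raise ValueError("h0 must be non-negative")
        return self.h0 * float(np.exp(self.gamma * (age - 50.0)))


@dataclass(frozen=True)
class HospitalizationModel:
    """Logistic probability of in-patient treatment given age and sex.

    logit p = intercept + age_slope * (age - 70) + female_offset * 1[female].
    Negative slope and offset reproduce the pattern that non-hospitalized
    patients are older and more often female.
    """

    intercept: float = 1.65
    age_slope: float = -0.09
    female_offset: float = -0.4

    def probability(self, age: float, sex: str) -> float:
        x = self.intercept + self.age_slope * (age - 70.0)
        if sex == "female":
            x += self.female_offset
        return float(1.0 / (1.0 + np.exp(-x)))


@dataclass(frozen=True)
class SimulationParams:
    """Generating parameters of a synthetic registry."""

    population: dict[str, tuple[int, ...]] = field(
        default_factory=lambda: dict(DEFAULT_POPULATION)
    )
    bands: tuple[AgeBand, ...] = DEFAULT_BANDS
    observation_years: float = 2.0
    window_start: _dt.date = _dt.date(2011, 1, 1)
    window_end: _dt.date = _dt.date(2012, 12, 31)
    incidence: dict[str, GompertzIncidence] = field(
        default_factory=lambda: {
            "female": GompertzIncidence(h0=1.2374e-4, gamma=0.125),
            "male": GompertzIncidence(h0=2.6778e-4, gamma=0.098),
        }
    )
    hospitalization: HospitalizationModel = HospitalizationModel()
    p_high_energy: float = 0.10
    p_pathological: float = 0.04
    p_nonresident: float = 0.06
    p_under50: float = 0.05
    p_duplicate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_high_energy", "p_pathological", "p_nonresident",
                     "p_under50", "p_duplicate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.observation_years <= 0:
            raise ValueError("observation_years must be positive")
        for sex in SEXES:
            if self.incidence[sex].h0 < 0:
                raise ValueError("Gompertz h0 must be non-negative")

    def population_frame(self) -> pd.DataFrame:
        rows = [{"band_lower": b.lower, "band_upper": b.upper, "sex": sex, "count": n}
                for sex in SEXES
                for b, n in zip(self.bands, self.population[sex])]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of one simulated registry: the parameters, the implied
    band-level rates (band-midpoint evaluation of the Gompertz curve), the
    expected counts per cell, and per-case labels."""

    params: SimulationParams
    rates: pd.DataFrame  # band_lower, band_upper, sex, true_rate_per_10k, person_years, expected_count
    labels: dict[str, str]  # case_id -> "qualifying" or contaminant type

    def qualifying_ids(self) -> set[str]:
        return {cid for cid, lab in self.labels.items() if lab == QUALIFYING}


def true_rate_table(params: SimulationParams) -> pd.DataFrame:
    rows = []
    for sex in SEXES:
        model = params.incidence[sex]
        for band, pop in zip(params.bands, params.population[sex]):
            h = model.hazard(band.midpoint)
            py = pop * params.observation_years
            rows.append({"band_lower": band.lower, "band_upper": band.upper,
                         "sex": sex, "true_rate_per_10k": h * RATE_SCALE,
                         "person_years": py, "expected_count": h * py})
    return pd.DataFrame(rows)


def _random_date(rng: np.random.Generator, start: _dt.date, end: _dt.date) -> _dt.date:
    span = (end - start).days
    return start + _dt.timedelta(days=int(rng.integers(0, span + 1)))


def _uniform_age(rng: np.random.Generator, band: AgeBand) -> int:
    upper = band.upper if band.upper is not None else band.lower + 10
    return int(rng.integers(band.lower, upper))


def simulate_registry(params: SimulationParams) -> tuple[list[FractureCase], SimTruth]:
    """Draw one registry: Poisson qualifying counts per (band, sex) cell at
    the band-midpoint hazard, then contaminant records.

    A single RNG stream seeded from ``params.seed`` is used, with the
    qualifying cases drawn first, so changing contamination probabilities
    never perturbs the qualifying sample at a fixed seed.  Each contaminant
    violates exactly one filter rule and is labeled in the truth.
    """
    rng = np.random.default_rng(params.seed)
    truth_rates = true_rate_table(params)
    cases: list[FractureCase] = []
    labels: dict[str, str] = {}
    next_id = 0

    def fresh_ids() -> tuple[str, str]:
        nonlocal next_id
        next_id += 1
        return f"C{next_id:06d}", f"P{next_id:06d}"

    sides = ("hip_left", "hip_right")
    for _, row in truth_rates.iterrows():
        band = AgeBand(int(row["band_lower"]),
                       None if pd.isna(row["band_upper"]) else int(row["band_upper"]))
        sex = row["sex"]
        n = int(rng.poisson(row["expected_count"]))
        for _ in range(n):
            case_id, person_id = fresh_ids()
            age = _uniform_age(rng, band)
            hosp = rng.random() < params.hospitalization.probability(age, sex)
            cases.append(FractureCase(
                case_id=case_id, person_id=person_id, sex=sex, age_years=age,
                event_date=_random_date(rng, params.window_start, params.window_end),
                resident=True, mechanism="low_energy", pathological=False,
                site=sides[int(rng.integers(0, 2))], hospitalized=bool(hosp),
                source="hospital" if hosp else "primary_care",
            ))
            labels[case_id] = QUALIFYING

    n_qual = len(cases)
    qualifying = list(cases)

    def base_contaminant(label: str, **overrides) -> None:
        """Append a contaminant that is eligible except for one rule."""
        case_id, person_id = fresh_ids()
        sex = SEXES[int(rng.integers(0, 2))]
        fields = dict(
            case_id=case_id, person_id=person_id, sex=sex,
            age_years=int(rng.integers(50, 95)),
            event_date=_random_date(rng, params.window_start, params.window_end),
            resident=True, mechanism="low_energy", pathological=False,
            site=sides[int(rng.integers(0, 2))], hospitalized=True, source="hospital",
        )
        fields.update(overrides)
        cases.append(FractureCase(**fields))
        labels[case_id] = label

    for label, p in (("high_energy", params.p_high_energy),
                     ("pathological", params.p_pathological),
                     ("nonresident", params.p_nonresident),
                     ("under50", params.p_under50)):
        for _ in range(int(rng.poisson(p * max(n_qual, 1)))):
            if label == "high_energy":
                base_contaminant(label, mechanism="high_energy")
            elif label == "pathological":
                base_contaminant(label, pathological=True)
            elif label == "nonresident":
                base_contaminant(label, resident=False)
            else:
                base_contaminant(label, age_years=int(rng.integers(35, 50)))

    if qualifying:
        for _ in range(int(rng.poisson(params.p_duplicate * n_qual))):
            orig = qualifying[int(rng.integers(0, n_qual))]
            case_id, _ = fresh_ids()
            days_left = (params.window_end - orig.event_date).days
            offset = int(rng.integers(1, days_left + 1)) if days_left > 0 else 0
            cases.append(replace(
                orig, case_id=case_id,
                event_date=orig.event_date + _dt.timedelta(days=offset),
                source="hospital",
            ))
            labels[case_id] = "duplicate"

    return cases, SimTruth(params=params, rates=truth_rates, labels=labels)


@dataclass(frozen=True)
class RecoveryReport:
    """Cell-wise comparison of estimated against generating rates."""

    table: pd.DataFrame  # adds z columns to the truth table
    share_within_3se: float  # over cells with expected_count >= min_expected
    min_expected: float


def recovery_report(
    truth: SimTruth,
    estimated: pd.DataFrame,
    min_expected: float = 5.0,
) -> RecoveryReport:
    """z-score per cell: (estimated - true) / Poisson SE at the true rate,
    SE(rate) = sqrt(true_rate / PY) on the per-10,000 scale."""
    est_map = {(int(lo), None if pd.isna(up) else int(up), s): float(r)
               for lo, up, s, r in zip(estimated["band_lower"], estimated["band_upper"],
                                       estimated["sex"], estimated["rate_per_10k"])}
    tab = truth.rates.copy()
    est, zs = [], []
    for _, row in tab.iterrows():
        key = (int(row["band_lower"]),
               None if pd.isna(row["band_upper"]) else int(row["band_upper"]),
               row["sex"])
        if key not in est_map:
            raise ValueError(f"estimated rate table missing cell {key}")
        e = est_map[key]
        se = np.sqrt(row["true_rate_per_10k"] * RATE_SCALE / row["person_years"])
        z = 0.0 if se == 0 and e == row["true_rate_per_10k"] else (
            np.inf if se == 0 else (e - row["true_rate_per_10k"]) / se
        )
        est.append(e)
        zs.append(z)
    tab["estimated_rate_per_10k"] = est
    tab["z"] = zs
    mask = tab["expected_count"] >= min_expected
    share = float((tab.loc[mask, "z"].abs() <= 3).mean()) if mask.any() else 1.0
    return RecoveryReport(table=tab, share_within_3se=share, min_expected=min_expected)
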