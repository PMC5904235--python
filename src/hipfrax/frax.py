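"""Competing-risk 10-year fracture probabilities from band-level hazards.

The engine follows the multi-decrement life-table logic behind FRAX-style
risk calculators: per-sex annual hazards of fracture and of death are built
from band-level incidence and mortality tables, and the 10-year probability
of a first fracture is the cause-specific cumulative incidence under
piecewise-constant one-year hazards,

    p = sum_i S_i * (lam_i / tau_i) * (1 - exp(-tau_i)),
    tau_i = lam_i + mu_i,   S_{i+1} = S_i * exp(-tau_i),

where lam_i is the (scenario-scaled) fracture hazard in year i and mu_i the
death hazard; death before fracture removes an individual from risk. Major
osteoporotic fracture (MOF: hip, clinical spine, forearm, humerus) incidence
is imputed from hip incidence via age/sex-specific MOF:hip ratio tables, the
standard device for countries where only hip rates are observed. Clinical
risk factors enter as named multiplicative scenarios on the fracture hazard
(e.g. prior fragility fracture, rr = 2 by default); the proprietary FRAX
regression coefficients are out of scope.

An independent Monte-Carlo oracle (``mc_probability_oracle``) simulates
individual year-by-year competing exponentials and is used to cross-check
the deterministic engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .bands import AgeBand, SEXES, bands_from_frame, same_ladder
from .incidence import RATE_SCALE, BandMismatchError

MIN_AGE = 50
OUTCOMES = ("hip", "mof")


def impute_mof(hip: pd.DataFrame, ratios: pd.DataFrame) -> pd.DataFrame:
    """MOF incidence imputed cell-wise: mof_rate = hip_rate x ratio.

    ``ratios`` needs columns band_lower, band_upper, sex, mof_to_hip_ratio
    (each >= 1 since MOF includes hip). Counts and confidence limits are not
    propagated; the output carries an ``imputed`` flag instead.
    """
    if not same_ladder(bands_from_frame(hip), bands_from_frame(ratios)):
        raise BandMismatchError("ratio table band ladder differs from hip rates")
    r_map = {(int(lo), None if pd.isna(up) else int(up), s): float(r)
             for lo, up, s, r in zip(ratios["band_lower"], ratios["band_upper"],
                                     ratios["sex"], ratios["mof_to_hip_ratio"])}
    if any(v < 1.0 for v in r_map.values()):
        raise ValueError("mof_to_hip_ratio must be >= 1 (MOF includes hip)")
    rows = []
    for _, row in hip.iterrows():
        key = (int(row["band_lower"]),
               None if pd.isna(row["band_upper"]) else int(row["band_upper"]),
               row["sex"])
        if key not in r_map:
            raise ValueError(f"missing MOF:hip ratio for cell {key}")
        rows.append({"band_lower": key[0], "band_upper": key[1], "sex": key[2],
                     "rate_per_10k": row["rate_per_10k"] * r_map[key],
                     "imputed": True})
    return pd.DataFrame(rows)


@dataclass
class HazardCurve:
    """Per-sex piecewise-constant annual hazards on integer ages 50..a_max."""

    ages: np.ndarray
    h_frac: dict[str, np.ndarray]
    h_death: dict[str, np.ndarray]

    @property
    def a_max(self) -> int:
        return int(self.ages[-1])

    def _at(self, table: dict[str, np.ndarray], sex: str, age: int) -> float:
        if sex not in table:
            raise KeyError(f"no hazards for sex {sex!r}")
        idx = min(max(age, MIN_AGE), self.a_max) - MIN_AGE
        return float(table[sex][idx])

    def frac(self, sex: str, age: int) -> float:
        return self._at(self.h_frac, sex, age)

    def death(self, sex: str, age: int) -> float:
        return self._at(self.h_death, sex, age)


def _band_values(df: pd.DataFrame, sex: str, value_col: str) -> tuple[list[AgeBand], np.ndarray]:
    sub = df[df["sex"] == sex]
    pairs = sorted(
        (AgeBand(int(lo), None if pd.isna(up) else int(up)), float(v))
        for lo, up, v in zip(sub["band_lower"], sub["band_upper"], sub[value_col])
    )
    bands = [p[0] for p in pairs]
    vals = np.array([p[1] for p in pairs])
    if np.any(vals < 0):
        raise ValueError(f"negative {value_col} for sex {sex}")
    return bands, vals


def _expand(bands: list[AgeBand], per10k: np.ndarray, ages: np.ndarray, mode: str) -> np.ndarray:
    hazards = per10k / RATE_SCALE
    if mode == "step":
        out = np.empty_like(ages, dtype=float)
        for i, age in enumerate(ages):
            idx = None
            for j, b in enumerate(bands):
                if b.contains(int(age)):
                    idx = j
                    break
            out[i] = hazards[idx if idx is not None else -1]  # beyond ladder: hold last
        return out
    if mode == "midpoint_linear":
        mids = np.array([b.midpoint for b in bands])
        # np.interp extends with the edge values below the first and above
        # the last midpoint, which is exactly the constant extension wanted.
        return np.interp(ages.astype(float), mids, hazards)
    raise ValueError(f"unknown interpolation mode {mode!r}")


def build_hazard_curves(
    rates: pd.DataFrame,
    mortality: pd.DataFrame,
    mode: str = "midpoint_linear",
    a_max: int = 100,
) -> HazardCurve:
    """Expand band-level tables (per 10,000 PY) to annual per-person hazards.

    ``mode='step'`` assigns each band's rate to every integer age in the
    band; ``'midpoint_linear'`` interpolates between band midpoints (52.5,
    57.5, ..., terminal open band at lower + 2.5) with constant extension at
    both ends. Ages beyond the ladder hold the terminal value.
    """
    if a_max < 99:
        raise ValueError("a_max must be at least 99")
    ages = np.arange(MIN_AGE, a_max + 1)
    h_frac: dict[str, np.ndarray] = {}
    h_death: dict[str, np.ndarray] = {}
    for sex in SEXES:
        fb, fv = _band_values(rates, sex, "rate_per_10k")
        db, dv = _band_values(mortality, sex, "death_rate_per_10k")
        if not fb or not db:
            raise ValueError(f"no band coverage for sex {sex}")
        h_frac[sex] = _expand(fb, fv, ages, mode)
        h_death[sex] = _expand(db, dv, ages, mode)
    return HazardCurve(ages=ages, h_frac=h_frac, h_death=h_death)


def ten_year_probability(
    hz: HazardCurve,
    sex: str,
    age: int,
    rr: float = 1.0,
    horizon_years: int = 10,
) -> float:
    """Cause-specific cumulative incidence of first fracture over the horizon.

    Deterministic life-table sum with one-year piecewise-constant hazards;
    ``rr`` scales the fracture hazard only (a clinical-risk-factor scenario).
    """
    if rr < 0:
        raise ValueError("relative risk must be non-negative")
    if horizon_years <= 0:
        raise ValueError("horizon must be positive")
    if age + horizon_years > hz.a_max + 1:
        raise ValueError(
            f"age {age} + horizon {horizon_years} exceeds the hazard grid (a_max={hz.a_max})"
        )
    surv = 1.0
    p = 0.0
    for i in range(horizon_years):
        lam = rr * hz.frac(sex, age + i)
        mu = hz.death(sex, age + i)
        tau = lam + mu
        if tau > 0.0:
            p += surv * (lam / tau) * (1.0 - math.exp(-tau))
            surv *= math.exp(-tau)
    return p


@dataclass
class CountryModel:
    """Bundle of the tables a country-specific risk model is built from."""

    name: str
    hip_rates: pd.DataFrame
    mortality: pd.DataFrame
    ratios: Optional[pd.DataFrame] = None
    scenarios: Mapping[str, float] = field(default_factory=dict)
    interpolation: str = "midpoint_linear"
    a_max: int = 100

    def __post_init__(self) -> None:
        ladders = [bands_from_frame(self.hip_rates), bands_from_frame(self.mortality)]
        if self.ratios is not None:
            ladders.append(bands_from_frame(self.ratios))
        if not all(same_ladder(ladders[0], l) for l in ladders[1:]):
            raise BandMismatchError(f"model {self.name!r}: component tables do not share one band ladder")
        self._curves: dict[str, HazardCurve] = {}

    def scenario_rr(self, scenario: str) -> float:
        if scenario == "baseline":
            return 1.0
        if scenario not in self.scenarios:
            raise KeyError(f"unknown scenario {scenario!r} for model {self.name!r}")
        return float(self.scenarios[scenario])

    def hazard_curve(self, outcome: str = "hip") -> HazardCurve:
        if outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {outcome!r}")
        if outcome not in self._curves:
            if outcome == "hip":
                rates = self.hip_rates
            else:
                if self.ratios is None:
                    raise ValueError(f"model {self.name!r} has no MOF:hip ratio table")
                rates = impute_mof(self.hip_rates, self.ratios)
            self._curves[outcome] = build_hazard_curves(
                rates, self.mortality, mode=self.interpolation, a_max=self.a_max
            )
        return self._curves[outcome]


def probability_table(
    model: CountryModel,
    ages: Sequence[int],
    outcomes: Sequence[str] = ("hip",),
    scenarios: Sequence[str] = ("baseline",),
    horizon_years: int = 10,
) -> pd.DataFrame:
    """Long table of 10-year probabilities, one row per
    (age, sex, outcome, scenario), with ``p10_pct`` at one decimal for
    report output."""
    rows = []
    for outcome in outcomes:
        hz = model.hazard_curve(outcome)
        for scenario in scenarios:
            rr = model.scenario_rr(scenario)
            for age in ages:
                for sex in SEXES:
                    p = ten_year_probability(hz, sex, int(age), rr, horizon_years)
                    rows.append({"age": int(age), "sex": sex, "outcome": outcome,
                                 "scenario": scenario, "p10": p,
                                 "p10_pct": round(100.0 * p, 1)})
    return pd.DataFrame(rows, columns=["age", "sex", "outcome", "scenario", "p10", "p10_pct"])


def compare_models(
    models: Iterable[CountryModel],
    ages: Sequence[int],
    outcomes: Sequence[str] = ("hip",),
    horizon_years: int = 10,
) -> pd.DataFrame:
    """Concatenated baseline probability tables keyed by model name,
    suitable for plotting cross-country probability-by-age curves."""
    models = list(models)
    if not models:
        raise ValueError("need at least one model")
    names = [m.name for m in models]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate model names: {names}")
    frames = []
    for m in models:
        tab = probability_table(m, ages, outcomes, ("baseline",), horizon_years)
        tab.insert(0, "model", m.name)
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)


def mc_probability_oracle(
    hz: HazardCurve,
    sex: str,
    age: int,
    rr: float = 1.0,
    n: int = 100_000,
    seed: int = 0,
    horizon_years: int = 10,
) -> tuple[float, float]:
    """Monte-Carlo estimate of the 10-year first-fracture probability.

    Simulates n individuals year by year, drawing competing exponential
    times to fracture and death with that year's hazards; returns the
    fraction fracturing within the horizon and its binomial standard error.
    Kept deliberately independent of the life-table engine.
    """
    if n < 1_000:
        raise ValueError("n must be at least 1,000")
    rng = np.random.default_rng(seed)
    alive = np.ones(n, dtype=bool)
    fractured = np.zeros(n, dtype=bool)
    for i in range(horizon_years):
        lam = rr * hz.frac(sex, age + i)
        mu = hz.death(sex, age + i)
        idx = np.flatnonzero(alive)
        if idx.size == 0:
            break
        t_frac = (rng.exponential(1.0 / lam, idx.size) if lam > 0
                  else np.full(idx.size, np.inf))
        t_death = (rng.exponential(1.0 / mu, idx.size) if mu > 0
                   else np.full(idx.size, np.inf))
        frac_now = (t_frac < 1.0) & (t_frac < t_death)
        death_now = (t_death < 1.0) & ~frac_now
        fractured[idx[frac_now]] = True
        alive[idx[frac_now | death_now]] = False
    p = fractured.mean()
    se = math.sqrt(p * (1.0 - p) / n)
    return float(p), float(se)
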