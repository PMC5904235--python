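"""Age/sex-specific incidence, direct standardization and burden projection.

Rates are expressed per 10,000 person-years throughout, the customary unit
for hip-fracture incidence. Person-years come from the static-population
approximation (census count x observation duration); confidence limits for
cell rates are exact Poisson (Garwood) limits, which remain valid for
zero-count cells. Standardized rates use direct standardization against a
user-supplied standard-population weight table, with a delta-method CI from
the weighted Poisson cell variances. Burden projection applies band rates
to a target pyramid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .bands import AgeBand, SEXES, assign_band, bands_from_frame, same_ladder
from .registry import FilterReport

RATE_SCALE = 10_000.0


class BandMismatchError(ValueError):
    """Two tables do not share the same band ladder."""


def _require_same_ladder(a: pd.DataFrame, b: pd.DataFrame, what: str) -> None:
    la, lb = bands_from_frame(a), bands_from_frame(b)
    if not same_ladder(la, lb):
        raise BandMismatchError(
            f"band ladders differ between rates and {what}: "
            f"{[b_.label for b_ in la]} vs {[b_.label for b_ in lb]}"
        )


def _band_cols(band: AgeBand) -> dict:
    return {"band_lower": band.lower, "band_upper": band.upper}


def person_years(pop: pd.DataFrame, observation_years: float) -> pd.DataFrame:
    """Person-years per (band, sex): census count x observation duration.

    ``pop`` needs columns band_lower, band_upper, sex, count, with every
    (band, sex) cell present for both sexes.
    """
    if observation_years <= 0:
        raise ValueError("observation_years must be positive")
    bands = bands_from_frame(pop)
    missing = []
    keyed = {(int(lo), None if pd.isna(up) else int(up), s): c
             for lo, up, s, c in zip(pop["band_lower"], pop["band_upper"],
                                     pop["sex"], pop["count"])}
    rows = []
    for band in bands:
        for sex in SEXES:
            key = (band.lower, band.upper, sex)
            if key not in keyed:
                missing.append(f"{band.label}/{sex}")
                continue
            count = keyed[key]
            if count < 0:
                raise ValueError(f"negative population count in cell {band.label}/{sex}")
            rows.append({**_band_cols(band), "sex": sex,
                         "person_years": float(count) * observation_years})
    if missing:
        raise ValueError(f"population table is missing cells: {', '.join(missing)}")
    return pd.DataFrame(rows)


def poisson_ci(n: int, level: float = 0.95) -> tuple[float, float]:
    """Garwood exact confidence limits for a Poisson count."""
    if not 0 < level < 1:
        raise ValueError("ci level must be in (0, 1)")
    alpha = 1.0 - level
    low = 0.0 if n == 0 else stats.chi2.ppf(alpha / 2, 2 * n) / 2.0
    high = stats.chi2.ppf(1 - alpha / 2, 2 * n + 2) / 2.0
    return float(low), float(high)


def compute_incidence(
    report: FilterReport | list,
    py: pd.DataFrame,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Band x sex rate table from filtered cases and a person-years table.

    Returns columns band_lower, band_upper, sex, n_cases, person_years,
    rate_per_10k, ci_low, ci_high (rate-scale Garwood limits).
    """
    cases = report.included if isinstance(report, FilterReport) else list(report)
    bands = bands_from_frame(py)
    counts: dict[tuple[AgeBand, str], int] = {}
    for c in cases:
        band = assign_band(c.age_years, bands)  # raises below-ladder
        counts[(band, c.sex)] = counts.get((band, c.sex), 0) + 1

    py_map = {(AgeBand(int(lo), None if pd.isna(up) else int(up)), s): v
              for lo, up, s, v in zip(py["band_lower"], py["band_upper"],
                                      py["sex"], py["person_years"])}
    rows = []
    for band in bands:
        for sex in SEXES:
            pys = py_map.get((band, sex))
            if pys is None:
                raise ValueError(f"person-years missing for cell {band.label}/{sex}")
            if pys <= 0:
                raise ValueError(f"non-positive person-years in cell {band.label}/{sex}")
            n = counts.get((band, sex), 0)
            lo, hi = poisson_ci(n, ci_level)
            rows.append({**_band_cols(band), "sex": sex, "n_cases": n,
                         "person_years": pys,
                         "rate_per_10k": n / pys * RATE_SCALE,
                         "ci_low": lo / pys * RATE_SCALE,
                         "ci_high": hi / pys * RATE_SCALE})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class StandardizedRate:
    sex: str
    asr_per_10k: float
    ci_low: float
    ci_high: float


def standardize_rates(
    rates: pd.DataFrame,
    std: pd.DataFrame,
    ci_level: float = 0.95,
) -> dict[str, StandardizedRate]:
    """Directly standardized rate per sex: ASR = sum_b w_b r_b with the
    standard weights normalized to 1.

    ``std`` needs columns band_lower, band_upper, weight covering every band
    in ``rates``. The CI is a normal approximation using the delta-method
    variance sum_b w_b^2 var(r_b), var(r_b) = n_b / PY_b^2 on the rate scale.
    """
    rate_bands = bands_from_frame(rates)
    std_bands = bands_from_frame(std)
    missing = [b.label for b in rate_bands if b not in std_bands]
    if missing:
        raise BandMismatchError(
            f"standard population lacks weights for bands: {', '.join(missing)}"
        )
    w_map = {AgeBand(int(lo), None if pd.isna(up) else int(up)): float(w)
             for lo, up, w in zip(std["band_lower"], std["band_upper"], std["weight"])}
    if any(w < 0 for w in w_map.values()):
        raise ValueError("standard-population weights must be non-negative")
    total_w = sum(w_map[b] for b in rate_bands)
    if total_w <= 0:
        raise ValueError("standard-population weights sum to zero over the ladder")
    z = stats.norm.ppf(0.5 + ci_level / 2.0)

    out: dict[str, StandardizedRate] = {}
    for sex, grp in rates.groupby("sex"):
        asr = 0.0
        var = 0.0
        for _, row in grp.iterrows():
            band = AgeBand(int(row["band_lower"]),
                           None if pd.isna(row["band_upper"]) else int(row["band_upper"]))
            w = w_map[band] / total_w
            asr += w * row["rate_per_10k"]
            var += (w ** 2) * row["n_cases"] / row["person_years"] ** 2 * RATE_SCALE ** 2
        se = np.sqrt(var)
        out[str(sex)] = StandardizedRate(
            sex=str(sex), asr_per_10k=asr,
            ci_low=max(0.0, asr - z * se), ci_high=asr + z * se,
        )
    return out


@dataclass(frozen=True)
class BurdenEstimate:
    """Expected annual fracture counts in a target population."""

    by_sex: dict[str, float]
    total: float

    def rounded(self) -> dict[str, int]:
        out = {s: int(round(v)) for s, v in self.by_sex.items()}
        out["total"] = int(round(self.total))
        return out


def estimate_burden(rates: pd.DataFrame, target_pop: pd.DataFrame) -> BurdenEstimate:
    """Expected annual fractures: sum_b pop_b x rate_b / 10,000 per sex."""
    _require_same_ladder(rates, target_pop, "target population")
    pop_map = {(int(lo), None if pd.isna(up) else int(up), s): float(c)
               for lo, up, s, c in zip(target_pop["band_lower"], target_pop["band_upper"],
                                       target_pop["sex"], target_pop["count"])}
    by_sex: dict[str, float] = {}
    for _, row in rates.iterrows():
        key = (int(row["band_lower"]),
               None if pd.isna(row["band_upper"]) else int(row["band_upper"]),
               row["sex"])
        if key not in pop_map:
            raise BandMismatchError(f"target population missing cell {key}")
        by_sex[row["sex"]] = by_sex.get(row["sex"], 0.0) + (
            pop_map[key] * row["rate_per_10k"] / RATE_SCALE
        )
    return BurdenEstimate(by_sex=by_sex, total=sum(by_sex.values()))
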