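"""Hazard curves, competing-risk probabilities, MOF imputation, oracles."""

import math

import numpy as np
import pandas as pd
import pytest

import hipfrax as hf
from hipfrax.frax import HazardCurve
from hipfrax.incidence import BandMismatchError


def band_table(values, sexes=("female", "male"), value_col="rate_per_10k"):
    """Eight-band table (50-54 ... 85+) with given per-sex values."""
    rows = []
    for sex in sexes:
        vals = values[sex] if isinstance(values, dict) else values
        for i, lo in enumerate(range(50, 90, 5)):
            rows.append({"band_lower": lo,
                         "band_upper": None if lo == 85 else lo + 5,
                         "sex": sex, value_col: vals[i]})
    return pd.DataFrame(rows)


def constant_curve(lam, mu, a_max=100):
    ages = np.arange(50, a_max + 1)
    n = ages.size
    return HazardCurve(ages=ages,
                       h_frac={s: np.full(n, lam) for s in ("female", "male")},
                       h_death={s: np.full(n, mu) for s in ("female", "male")})


def random_curve(rng, a_max=100):
    ages = np.arange(50, a_max + 1)
    n = ages.size
    def grow(lo, hi, g):  # noisy, age-increasing hazards
        base = lo * np.exp(np.linspace(0, g, n))
        return np.clip(base * rng.uniform(0.6, 1.4, n), 0, hi)
    return HazardCurve(
        ages=ages,
        h_frac={s: grow(rng.uniform(1e-4, 2e-3), 0.15, rng.uniform(2, 4))
                for s in ("female", "male")},
        h_death={s: grow(rng.uniform(1e-3, 8e-3), 0.5, rng.uniform(2, 4))
                 for s in ("female", "male")},
    )


class TestImputeMof:
    def test_unit_ratio_is_identity(self):
        hip = band_table([10.0] * 8)
        ratios = band_table([1.0] * 8, value_col="mof_to_hip_ratio")
        mof = hf.impute_mof(hip, ratios)
        assert np.allclose(mof["rate_per_10k"], 10.0)
        assert mof["imputed"].all()

    def test_cellwise_product_and_zero_preserved(self):
        hip = band_table([10.0, 0.0] + [10.0] * 6)
        ratios = band_table([4.0] * 8, value_col="mof_to_hip_ratio")
        mof = hf.impute_mof(hip, ratios)
        female = mof[mof.sex == "female"].sort_values("band_lower")
        assert female["rate_per_10k"].tolist()[:2] == [40.0, 0.0]

    def test_ratio_below_one_rejected(self):
        hip = band_table([10.0] * 8)
        ratios = band_table([0.5] * 8, value_col="mof_to_hip_ratio")
        with pytest.raises(ValueError, match=">= 1"):
            hf.impute_mof(hip, ratios)

    def test_ladder_mismatch_rejected(self):
        hip = band_table([10.0] * 8)
        ratios = band_table([2.0] * 8, value_col="mof_to_hip_ratio")
        ratios = ratios[ratios.band_lower != 60]
        with pytest.raises(BandMismatchError):
            hf.impute_mof(hip, ratios)


class TestBuildHazardCurves:
    def test_constant_input_identity_in_both_modes(self):
        rates = band_table([20.0] * 8)
        mort = band_table([100.0] * 8, value_col="death_rate_per_10k")
        for mode in ("step", "midpoint_linear"):
            hz = hf.build_hazard_curves(rates, mort, mode=mode)
            assert np.allclose(hz.h_frac["female"], 0.002)
            assert np.allclose(hz.h_death["male"], 0.01)

    def test_step_mode_band_edges(self):
        vals = [10.0, 30.0] + [30.0] * 6
        hz = hf.build_hazard_curves(
            band_table(vals), band_table([0.0] * 8, value_col="death_rate_per_10k"),
            mode="step")
        assert hz.frac("female", 54) == pytest.approx(0.001)
        assert hz.frac("female", 55) == pytest.approx(0.003)

    def test_midpoint_linear_interpolates_between_midpoints(self):
        # bands 50-54 (mid 52.5) at 10 and 55-59 (mid 57.5) at 30: the
        # halfway age 55 sits at the mean hazard 0.002.
        vals = [10.0, 30.0] + [30.0] * 6
        hz = hf.build_hazard_curves(
            band_table(vals), band_table([0.0] * 8, value_col="death_rate_per_10k"),
            mode="midpoint_linear")
        assert hz.frac("female", 55) == pytest.approx(0.002)
        # constant extension below the first midpoint and above the last
        assert hz.frac("female", 50) == pytest.approx(0.001)
        assert hz.frac("female", 100) == pytest.approx(0.003)

    def test_negative_rate_rejected(self):
        rates = band_table([10.0] * 7 + [-1.0])
        mort = band_table([0.0] * 8, value_col="death_rate_per_10k")
        with pytest.raises(ValueError, match="negative"):
            hf.build_hazard_curves(rates, mort)


class TestTenYearProbability:
    def test_null_fracture_hazard_gives_zero(self):
        hz = constant_curve(0.0, 0.05)
        assert hf.ten_year_probability(hz, "female", 60) == 0.0

    def test_constant_hazard_closed_form(self):
        """lam=0.01, mu=0.02: p10 = (1/3)(1 - e^-0.3) ~ 0.086394."""
        hz = constant_curve(0.01, 0.02)
        expected = (0.01 / 0.03) * (1 - math.exp(-0.3))
        p = hf.ten_year_probability(hz, "female", 60)
        assert abs(p - expected) / expected < 1e-12

    def test_zero_mortality_single_decrement_limit(self):
        hz = constant_curve(0.01, 0.0)
        expected = 1 - math.exp(-0.1)
        p = hf.ten_year_probability(hz, "male", 60)
        assert abs(p - expected) / expected < 1e-12

    @pytest.mark.parametrize("kwargs", [dict(rr=-0.1), dict(horizon_years=0),
                                        dict(age=95)])
    def test_invalid_arguments_rejected(self, kwargs):
        hz = constant_curve(0.01, 0.02)
        args = dict(sex="female", age=60, rr=1.0, horizon_years=10)
        args.update(kwargs)
        with pytest.raises(ValueError):
            hf.ten_year_probability(hz, **args)

    def test_monotone_in_rr_and_bounded(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            hz = random_curve(rng)
            age = int(rng.integers(50, 85))
            p1 = hf.ten_year_probability(hz, "female", age, rr=1.0)
            p2 = hf.ten_year_probability(hz, "female", age, rr=2.0)
            p4 = hf.ten_year_probability(hz, "female", age, rr=4.0)
            assert 0 <= p1 <= p2 <= p4 <= 1
            assert p2 <= 2 * p1 and p4 <= 4 * p1  # sub-multiplicativity

    def test_higher_mortality_lowers_probability(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            hz = random_curve(rng)
            bumped = HazardCurve(ages=hz.ages, h_frac=hz.h_frac,
                                 h_death={s: v + 0.05 for s, v in hz.h_death.items()})
            for age in (55, 70, 85):
                assert (hf.ten_year_probability(bumped, "male", age)
                        <= hf.ten_year_probability(hz, "male", age))


class TestMonteCarloOracle:
    def test_zero_hazard_estimates_zero(self):
        hz = constant_curve(0.0, 0.02)
        est, se = hf.mc_probability_oracle(hz, "female", 60, n=2_000, seed=1)
        assert est == 0.0

    def test_seed_reproducibility(self):
        hz = constant_curve(0.01, 0.02)
        a = hf.mc_probability_oracle(hz, "female", 60, n=5_000, seed=9)
        b = hf.mc_probability_oracle(hz, "female", 60, n=5_000, seed=9)
        assert a == b

    def test_agrees_with_closed_form(self):
        hz = constant_curve(0.01, 0.02)
        expected = (0.01 / 0.03) * (1 - math.exp(-0.3))
        est, se = hf.mc_probability_oracle(hz, "female", 60, n=200_000, seed=5)
        assert abs(est - expected) <= 3 * se

    def test_engine_matches_oracle_on_random_curves(self):
        rng = np.random.default_rng(2024)
        for _ in range(5):
            hz = random_curve(rng)
            age = int(rng.integers(50, 85))
            rr = float(rng.uniform(0.5, 3.0))
            p = hf.ten_year_probability(hz, "male", age, rr)
            est, se = hf.mc_probability_oracle(hz, "male", age, rr, n=40_000,
                                               seed=int(rng.integers(2**31)))
            assert abs(p - est) <= max(3 * se, 1e-4)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            hf.mc_probability_oracle(constant_curve(0.01, 0.0), "female", 60, n=10)


@pytest.fixture(scope="module")
def toy_model():
    rates = band_table({"female": [3, 5, 9, 15, 24, 38, 61, 98],
                        "male": [7, 9, 12, 17, 22, 30, 41, 55]})
    mort = band_table({"female": [55, 80, 120, 190, 320, 560, 1000, 2000],
                       "male": [150, 220, 320, 450, 650, 950, 1450, 2400]},
                      value_col="death_rate_per_10k")
    ratios = band_table({"female": [7.5, 6.5, 5.5, 4.5, 3.4, 2.6, 2.0, 1.6],
                         "male": [4.5, 4.0, 3.5, 3.0, 2.5, 2.0, 1.7, 1.4]},
                        value_col="mof_to_hip_ratio")
    return hf.CountryModel(name="toy", hip_rates=rates, mortality=mort,
                           ratios=ratios, scenarios={"prior_fracture": 2.0})


class TestProbabilityTable:
    def test_baseline_matches_engine_cellwise(self, toy_model):
        tab = hf.probability_table(toy_model, ages=(55, 70, 85), outcomes=("hip",))
        hz = toy_model.hazard_curve("hip")
        for _, row in tab.iterrows():
            assert row["p10"] == pytest.approx(
                hf.ten_year_probability(hz, row["sex"], row["age"]))

    def test_scenario_doubles_hazard_not_probability(self, toy_model):
        base = hf.probability_table(toy_model, ages=(60, 75), scenarios=("baseline",))
        prior = hf.probability_table(toy_model, ages=(60, 75),
                                     scenarios=("prior_fracture",))
        assert (prior["p10"].values > base["p10"].values).all()
        assert (prior["p10"].values <= 2 * base["p10"].values + 1e-12).all()

    def test_empty_ages_gives_empty_table(self, toy_model):
        assert hf.probability_table(toy_model, ages=()).empty

    def test_unknown_scenario_rejected(self, toy_model):
        with pytest.raises(KeyError):
            hf.probability_table(toy_model, ages=(60,), scenarios=("smoking",))

    def test_mof_exceeds_hip_probability(self, toy_model):
        tab = hf.probability_table(toy_model, ages=(60, 75),
                                   outcomes=("hip", "mof"))
        wide = tab.pivot_table(index=["age", "sex"], columns="outcome", values="p10")
        assert (wide["mof"] >= wide["hip"]).all()


class TestCompareModels:
    def test_single_model_identity(self, toy_model):
        tab = hf.compare_models([toy_model], ages=(60, 80))
        ref = hf.probability_table(toy_model, ages=(60, 80))
        assert np.allclose(tab["p10"].values, ref["p10"].values)
        assert (tab["model"] == "toy").all()

    def test_uniform_mortality_increase_lowers_probabilities(self, toy_model):
        heavier = hf.CountryModel(
            name="heavier",
            hip_rates=toy_model.hip_rates,
            mortality=toy_model.mortality.assign(
                death_rate_per_10k=toy_model.mortality["death_rate_per_10k"] + 500),
            ratios=toy_model.ratios)
        tab = hf.compare_models([toy_model, heavier], ages=(55, 70, 85))
        wide = tab.pivot_table(index=["age", "sex"], columns="model", values="p10")
        assert (wide["heavier"] <= wide["toy"]).all()

    def test_identical_models_give_identical_columns(self, toy_model):
        clone = hf.CountryModel(name="clone", hip_rates=toy_model.hip_rates,
                                mortality=toy_model.mortality, ratios=toy_model.ratios)
        tab = hf.compare_models([toy_model, clone], ages=(60, 80))
        wide = tab.pivot_table(index=["age", "sex"], columns="model", values="p10")
        assert np.allclose(wide["toy"], wide["clone"])

    def test_duplicate_names_rejected(self, toy_model):
        with pytest.raises(ValueError, match="duplicate"):
            hf.compare_models([toy_model, toy_model], ages=(60,))
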