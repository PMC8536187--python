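import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
from scipy.special import expit

from repleteaudit.cohort import build_cohort
from repleteaudit.errors import ConfigError
from repleteaudit.linkage import link_episodes
from repleteaudit.model import default_error_bounds
from repleteaudit.synth import (
    ElectrolyteParams,
    GeneratorParams,
    generate_cohort,
    planted_truth,
)


def _one_elec_params(**overrides):
    """Potassium-only settings for focused checks."""
    from repleteaudit.synth import _default_electrolytes

    ep = _default_electrolytes()["potassium"]
    for k, v in overrides.pop("potassium", {}).items():
        ep = ElectrolyteParams(**{**ep.__dict__, k: v})
    return GeneratorParams(electrolytes={"potassium": ep}, **overrides)


class TestDeterminismAndShape:
    def test_same_seed_is_byte_identical(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_cohort(GeneratorParams(n_stays=50, seed=42), out_dir=d1)
        generate_cohort(GeneratorParams(n_stays=50, seed=42), out_dir=d2)
        for name in ("stays", "labs", "repletions", "diagnoses"):
            assert (d1 / f"{name}.csv").read_bytes() == (d2 / f"{name}.csv").read_bytes()

    def test_different_seeds_differ(self):
        t1, _ = generate_cohort(GeneratorParams(n_stays=50, seed=1))
        t2, _ = generate_cohort(GeneratorParams(n_stays=50, seed=2))
        assert not t1["labs"]["value"].equals(t2["labs"]["value"])

    def test_zero_base_probability_means_no_repletions(self):
        params = _one_elec_params(n_stays=80, seed=3, potassium={"base_prob": 0.0})
        tables, truth = generate_cohort(params)
        assert tables["repletions"].empty
        assert truth.trigger_prob["potassium"] == 0.0

    def test_events_fall_inside_stay_bounds(self):
        tables, _ = generate_cohort(GeneratorParams(n_stays=60, seed=4))
        stays = tables["stays"].set_index("stay_id")
        labs = tables["labs"].join(stays[["intime", "outtime"]], on="stay_id")
        assert (labs["charttime"] >= labs["intime"]).all()
        assert (labs["charttime"] <= labs["outtime"]).all()

    def test_infeasible_spacing_is_hard_error(self):
        with pytest.raises(ConfigError, match="spacing"):
            GeneratorParams(slot_spacing_hours=30.0)


class TestPlantedProbabilities:
    def test_flat_rule_recovers_base_probability(self):
        # a very soft logistic (huge slope scale) makes the rule value-free:
        # the per-cluster trigger probability is base/2 at the threshold
        params = _one_elec_params(
            n_stays=4000, seed=5,
            scenario_mix=0.0, minor_fraction=0.0, excluded_dx_fraction=0.0,
            error_value_fraction=0.0,
            potassium={"base_prob": 0.2, "slope": 1e6},
        )
        tables, truth = generate_cohort(params)
        n_primary_est = params.n_stays * params.labs_per_stay_mean
        p_hat = len(tables["repletions"]) / n_primary_est
        assert truth.trigger_prob["potassium"] == pytest.approx(0.1, rel=1e-3)
        se = np.sqrt(0.1 * 0.9 / n_primary_est)
        assert abs(p_hat - 0.1) < 4 * se

    def test_monte_carlo_matches_quadrature(self):
        params = _one_elec_params(n_stays=6000, seed=6, minor_fraction=0.0,
                                  excluded_dx_fraction=0.0, error_value_fraction=0.0)
        tables, truth = generate_cohort(params)
        labs = tables["labs"]
        # primary draws are the ones that can trigger; reconstruct their
        # count from the planted structure: primaries = labs - extras - followups
        n_rep = len(tables["repletions"])
        # MC trigger estimate vs quadrature expectation
        ep = params.electrolytes["potassium"]
        low, high = default_error_bounds()["potassium"]
        a, b = (low - ep.mean) / ep.sd, (high - ep.mean) / ep.sd
        rng = np.random.default_rng(123)
        v = sps.truncnorm.rvs(a, b, loc=ep.mean, scale=ep.sd, size=200_000, random_state=rng)
        p_mc = float(np.mean(ep.base_prob * expit((ep.threshold - v) / ep.slope)))
        assert p_mc == pytest.approx(truth.trigger_prob["potassium"], abs=3 * 2e-4)

    def test_delta_zero_gives_near_zero_expected_d(self):
        # not exactly zero: the physiologic-bounds truncation of the
        # follow-up noise leaves an O(1e-4) asymmetry near the bounds
        params = _one_elec_params(potassium={"post_shift": 0.0})
        truth = planted_truth(params)
        assert truth.d_expected["potassium"] == pytest.approx(0.0, abs=1e-3)

    def test_values_within_range_give_within_proportion_one(self):
        from repleteaudit.model import ReferenceRange

        params = _one_elec_params(potassium={"mean": 4.5, "sd": 0.1})
        wide = {"potassium": ReferenceRange("potassium", 2.5, 6.9)}
        truth = planted_truth(params, ranges=wide)
        assert truth.cell_proportions[("potassium", "repletion", "within")] == pytest.approx(
            1.0, abs=1e-6
        )
        assert truth.cell_proportions[("potassium", "non_repletion", "within")] == pytest.approx(
            1.0, abs=1e-6
        )


@pytest.fixture(scope="module")
def run():
    params = GeneratorParams(n_stays=2500, seed=17)
    tables, truth = generate_cohort(params)
    cohort, log = build_cohort(tables)
    res = link_episodes(cohort["labs"], cohort["repletions"])
    return params, truth, log, res


class TestEndToEndRecovery:
    """One replicate of the full pipeline against the planted truth."""

    def test_attrition_is_exact(self, run):
        params, truth, log, _ = run
        assert log.removed("age_under_minimum") == truth.n_minor_stays
        n_err = sum(
            log.removed(f"value_error_{e}") for e in ("potassium", "magnesium", "phosphate")
        )
        assert n_err == truth.n_error_values

    def test_repletion_fraction_recovered(self, run):
        from repleteaudit.classify import repletion_fraction

        _, truth, _, res = run
        frac = repletion_fraction(res.episodes).set_index("electrolyte")
        for elec, expected in truth.repletion_fraction.items():
            n = frac.loc[elec, "n_episodes"]
            se = np.sqrt(expected * (1 - expected) / n)
            assert abs(frac.loc[elec, "fraction"] - expected) < 3.5 * se, elec

    def test_effect_size_recovered(self, run):
        from repleteaudit.stats import pre_post_effect

        _, truth, _, res = run
        eff = pre_post_effect(res.episodes).set_index("electrolyte")
        for elec, d_exp in truth.d_expected.items():
            n = eff.loc[elec, "n"]
            se_d = np.sqrt(2 / n + d_exp**2 / (4 * n))
            assert abs(eff.loc[elec, "d_cohen"] - d_exp) < 3.5 * se_d, elec

    def test_latency_mean_recovered(self, run):
        from repleteaudit.temporal import latency_summary

        _, truth, _, res = run
        summ = latency_summary(res.episodes).set_index(["electrolyte", "kind"])
        for elec, lat_exp in truth.latency_mean.items():
            row = summ.loc[(elec, "lab_to_order")]
            se = row["sd_minutes"] / np.sqrt(row["n"])
            assert abs(row["mean_minutes"] - lat_exp) < 3.5 * se, elec

    def test_circadian_peak_recovered(self, run):
        from repleteaudit.temporal import hour_histogram

        _, truth, _, res = run
        hist = hour_histogram(res.episodes, "index_time")
        assert hist.peak_hour == truth.peak_hour
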