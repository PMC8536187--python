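import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from repleteaudit.linkage import (
    LinkageConfig,
    classify_scenario,
    link_episodes,
    scenario_frequencies,
)
from repleteaudit.model import SCENARIO_1L1R, SCENARIO_ML1R, SCENARIO_NR

from tests.conftest import make_labs, make_repletions, random_event_streams
from tests.oracle import (
    brute_force_link,
    episodes_to_tuples,
    tuples_count_ignored,
)

H = 60  # minutes per hour


class TestScenarioExamples:
    def test_lone_lab_is_nr(self):
        res = link_episodes(make_labs([("s1", "potassium", 0, 3.4)]), make_repletions([]))
        assert res.episodes["scenario"].tolist() == [SCENARIO_NR]
        assert res.unanchored_repletions.empty and res.orphan_labs.empty

    def test_multiple_labs_closest_used_others_ignored(self):
        labs = make_labs(
            [("s1", "potassium", 0, 3.4), ("s1", "potassium", 2 * H, 3.1)]
        )
        reps = make_repletions([("s1", "potassium", 3 * H)])
        res = link_episodes(labs, reps)
        ep = res.episodes
        assert len(ep) == 1
        assert ep["scenario"].iloc[0] == SCENARIO_ML1R
        assert ep["index_value"].iloc[0] == 3.1  # the 2 h draw, closest to the order
        assert ep["lab_to_order_minutes"].iloc[0] == 60.0
        assert res.ignored_labs["value"].tolist() == [3.4]

    def test_order_outside_window_leaves_nr_and_unanchored(self):
        labs = make_labs([("s1", "potassium", 0, 3.4)])
        reps = make_repletions([("s1", "potassium", 25 * H)])
        res = link_episodes(labs, reps)
        assert res.episodes["scenario"].tolist() == [SCENARIO_NR]
        assert len(res.unanchored_repletions) == 1

    def test_lab_at_exactly_ordertime_counts_as_preceding(self):
        labs = make_labs([("s1", "potassium", 100, 3.4)])
        reps = make_repletions([("s1", "potassium", 100)])
        res = link_episodes(labs, reps)
        ep = res.episodes
        assert ep["scenario"].tolist() == [SCENARIO_1L1R]
        assert ep["lab_to_order_minutes"].iloc[0] == 0.0

    def test_followup_is_earliest_after_order(self):
        labs = make_labs(
            [
                ("s1", "magnesium", 0, 1.5),
                ("s1", "magnesium", 4 * H, 2.0),  # +3 h after order
                ("s1", "magnesium", 10 * H, 2.2),  # +9 h, not chosen
            ]
        )
        reps = make_repletions([("s1", "magnesium", 1 * H)])
        res = link_episodes(labs, reps)
        rep_ep = res.episodes.loc[res.episodes["scenario"] != SCENARIO_NR].iloc[0]
        assert rep_ep["followup_value"] == 2.0
        assert rep_ep["order_to_followup_minutes"] == 3 * H

    def test_no_followup_within_window(self):
        labs = make_labs(
            [("s1", "potassium", 0, 3.0), ("s1", "potassium", 26 * H, 3.9)]
        )
        reps = make_repletions([("s1", "potassium", 1 * H)])
        res = link_episodes(labs, reps)
        rep_ep = res.episodes.loc[res.episodes["scenario"] != SCENARIO_NR].iloc[0]
        assert pd.isna(rep_ep["followup_time"])

    def test_followup_may_also_serve_as_later_index(self):
        # the +6 h draw is follow-up of the first order AND index of the second
        labs = make_labs(
            [("s1", "potassium", 0, 3.0), ("s1", "potassium", 6 * H, 3.2)]
        )
        reps = make_repletions(
            [("s1", "potassium", 1 * H), ("s1", "potassium", 7 * H)]
        )
        res = link_episodes(labs, reps)
        ep = res.episodes
        assert len(ep) == 2
        assert ep["followup_value"].iloc[0] == 3.2
        assert ep["index_value"].iloc[1] == 3.2


class TestClassifyScenario:
    @pytest.mark.parametrize(
        "order_time, n_ignored, expected",
        [
            (pd.NaT, 0, SCENARIO_NR),
            (pd.Timestamp("2140-01-01"), 0, SCENARIO_1L1R),
            (pd.Timestamp("2140-01-01"), 2, SCENARIO_ML1R),
        ],
    )
    def test_total_function(self, order_time, n_ignored, expected):
        assert classify_scenario({"order_time": order_time, "n_ignored": n_ignored}) == expected


class TestOracleEquivalence:
    def test_random_instances_match_brute_force(self, rng):
        for _ in range(150):
            labs, reps = random_event_streams(rng, int(rng.integers(0, 40)))
            res = link_episodes(labs, reps)
            oracle_eps, oracle_unanchored, oracle_orphans = brute_force_link(labs, reps)
            assert episodes_to_tuples(res.episodes) == tuples_count_ignored(oracle_eps)
            assert len(res.unanchored_repletions) == len(oracle_unanchored)
            assert len(res.orphan_labs) == len(oracle_orphans) == 0

    def test_conservation_every_lab_has_exactly_one_role(self, rng):
        for _ in range(30):
            labs, reps = random_event_streams(rng, int(rng.integers(5, 60)))
            res = link_episodes(labs, reps)
            n_roles = len(res.episodes) + len(res.ignored_labs) + len(res.orphan_labs)
            assert n_roles == len(labs)


class TestProperties:
    def test_window_monotonicity_nr_never_increases(self, rng):
        for _ in range(25):
            labs, reps = random_event_streams(rng, 30)
            nr_counts = []
            for w in (6 * H, 24 * H, 48 * H):
                res = link_episodes(labs, reps, LinkageConfig(window_minutes=w))
                nr_counts.append((res.episodes["scenario"] == SCENARIO_NR).sum())
            assert nr_counts[0] >= nr_counts[1] >= nr_counts[2]

    def test_row_order_invariance(self, rng):
        # distinct timestamps: with identical-minute draws the tie-break is
        # input-sequence based by design
        times = rng.choice(5000, size=20, replace=False)
        labs = make_labs(
            [("s1", "potassium", int(t), float(v)) for t, v in zip(times, rng.uniform(3, 5, 20))]
        )
        reps = make_repletions([("s1", "potassium", 900), ("s1", "potassium", 3000)])
        base = link_episodes(labs, reps)
        shuffled = link_episodes(
            labs.sample(frac=1, random_state=1).reset_index(drop=True),
            reps.sample(frac=1, random_state=2).reset_index(drop=True),
        )
        assert episodes_to_tuples(base.episodes) == episodes_to_tuples(shuffled.episodes)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        lab_times=st.lists(st.integers(0, 4000), max_size=12),
        rep_times=st.lists(st.integers(0, 4000), max_size=5),
    )
    def test_hypothesis_streams_match_oracle(self, lab_times, rep_times):
        labs = make_labs([("s1", "potassium", t, 3.5) for t in lab_times])
        reps = make_repletions([("s1", "potassium", t) for t in rep_times])
        res = link_episodes(labs, reps)
        oracle_eps, oracle_un, oracle_orph = brute_force_link(labs, reps)
        assert episodes_to_tuples(res.episodes) == tuples_count_ignored(oracle_eps)
        assert len(res.unanchored_repletions) == len(oracle_un)
        assert len(res.orphan_labs) == len(oracle_orph)


class TestScenarioFrequencies:
    def test_even_split(self):
        labs = make_labs(
            [
                ("s1", "potassium", 0, 3.0),
                ("s2", "potassium", 0, 3.0),
                ("s2", "potassium", 60, 3.1),
            ]
        )
        reps = make_repletions(
            [("s1", "potassium", 60), ("s2", "potassium", 120)]
        )
        freq = scenario_frequencies(link_episodes(labs, reps).episodes)
        rep_rows = freq.loc[freq["scenario"] != SCENARIO_NR]
        assert rep_rows["pct_of_repletions"].tolist() == [50.0, 50.0]
        assert rep_rows["pct_of_repletions"].sum() == 100.0

    def test_all_nr_gives_undefined_percentages(self):
        labs = make_labs([("s1", "potassium", 0, 3.0)])
        freq = scenario_frequencies(link_episodes(labs, make_repletions([])).episodes)
        assert freq["pct_of_repletions"].isna().all()

    def test_planted_mix_recovered(self):
        from repleteaudit.synth import GeneratorParams, generate_cohort
        from repleteaudit.cohort import build_cohort

        params = GeneratorParams(n_stays=800, seed=21)
        tables, truth = generate_cohort(params)
        cohort, _ = build_cohort(tables)
        res = link_episodes(cohort["labs"], cohort["repletions"])
        freq = scenario_frequencies(res.episodes)
        for elec in ("magnesium", "phosphate"):  # enough repletions at this n
            sub = freq.loc[freq["electrolyte"] == elec]
            ml = sub.loc[sub["scenario"] == SCENARIO_ML1R].iloc[0]
            n_rep = sub.loc[sub["scenario"] != SCENARIO_NR, "n"].sum()
            expected = truth.ml_fraction[elec]
            se = np.sqrt(expected * (1 - expected) / n_rep)
            assert abs(ml["pct_of_repletions"] / 100 - expected) < 4 * se
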