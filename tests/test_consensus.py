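"""Informative-probe filtering and the dose-consistent consensus."""

import numpy as np
import pandas as pd
import pytest

from crconsensus.call_engine import ChangeResult, DetectionResult
from crconsensus.consensus import (
    CallRecord,
    DirectionMatrix,
    build_direction_matrix,
    count_informative,
    cr_responsive,
    informative_counts_table,
    informative_direction,
)
from crconsensus.design import ConditionKey, condition_columns, tissue_conditions
from crconsensus.synthetic import planted_responsive


def record(
    tissue="liver",
    duration="1w",
    level=5,
    probe="p1",
    rep=0,
    det=("present", "present"),
    change="increase",
):
    return CallRecord(
        probe_set_id=probe,
        condition=ConditionKey(tissue, duration, level),
        replicate_index=rep,
        baseline_detection=DetectionResult(0.01, det[0]),
        experiment_detection=DetectionResult(0.01, det[1]),
        change=ChangeResult(0.001, change, 1.0),
    )


class TestInformativeDirection:
    def test_firm_increase_is_up(self):
        assert informative_direction([record()]) == "up"

    def test_firm_decrease_is_down(self):
        assert informative_direction([record(change="decrease")]) == "down"

    def test_absent_on_either_chip_excludes(self):
        assert informative_direction([record(det=("present", "absent"))]) == "none"
        assert informative_direction([record(det=("absent", "present"))]) == "none"

    def test_marginal_detection_is_not_excluded(self):
        assert informative_direction([record(det=("marginal", "present"))]) == "up"

    @pytest.mark.parametrize("call", ["no_change", "marginal_increase", "marginal_decrease"])
    def test_soft_change_calls_excluded(self, call):
        assert informative_direction([record(change=call)]) == "none"

    def test_adipose_requires_agreement(self):
        a = record(tissue="adipose", rep=0)
        b_agree = record(tissue="adipose", rep=1)
        b_nc = record(tissue="adipose", rep=1, change="no_change")
        b_down = record(tissue="adipose", rep=1, change="decrease")
        assert informative_direction([a, b_agree]) == "up"
        assert informative_direction([a, b_nc]) == "none"
        assert informative_direction([a, b_down]) == "none"

    def test_replicate_count_enforced(self):
        with pytest.raises(ValueError):
            informative_direction([record(tissue="adipose")])
        with pytest.raises(ValueError):
            informative_direction([record(), record(rep=1)])


class TestBuildDirectionMatrix:
    def test_empty_records_give_empty_matrix(self):
        assert build_direction_matrix([]).frame.empty

    def test_single_informative_entry(self):
        m = build_direction_matrix([record()])
        assert m.frame.shape == (1, 1)
        assert m.frame.at["p1", "liver_1w_5"] == "up"

    def test_uninformative_probe_kept_as_none_row(self):
        m = build_direction_matrix([record(), record(probe="p2", change="no_change")])
        assert list(m.frame.loc["p2"]) == ["none"]

    def test_duplicate_records_rejected(self):
        with pytest.raises(ValueError):
            build_direction_matrix([record(), record()])


def full_matrix(entries):
    """Matrix over all 36 conditions, defaulting to 'none'."""
    probes = sorted(entries)
    frame = pd.DataFrame("none", index=probes, columns=condition_columns(), dtype=object)
    for probe, cols in entries.items():
        for col, val in cols.items():
            frame.at[probe, col] = val
    return DirectionMatrix(frame)


class TestCountInformative:
    def test_counts_non_none_entries(self):
        m = full_matrix(
            {
                "a": {"liver_1w_5": "up"},
                "b": {"liver_1w_5": "down"},
                "c": {},
                "d": {"liver_1w_5": "up"},
            }
        )
        assert count_informative(m, ConditionKey("liver", "1w", 5)) == 3
        assert count_informative(m, ConditionKey("liver", "1w", 10)) == 0

    def test_recovers_planted_count_from_simulation(self, small_sim, small_sim_matrix):
        config, result = small_sim
        _, matrix = small_sim_matrix
        cond = ConditionKey("muscle", "1m", 30)
        planted = (
            config.n_responsive_up
            + config.n_responsive_down
            + config.n_common_up
            + config.n_common_down
        )
        # low noise: every planted probe is informative at the strongest dose
        assert count_informative(matrix, cond) >= planted


class TestCrResponsive:
    def test_up_in_all_conditions_is_responsive(self):
        cols = {c.column: "up" for c in tissue_conditions("liver")}
        up, down = cr_responsive(full_matrix({"a": cols}), "liver")
        assert up == {"a"} and down == set()

    def test_one_missing_condition_excludes(self):
        cols = {c.column: "up" for c in tissue_conditions("liver")}
        cols["liver_1m_30"] = "none"
        up, _ = cr_responsive(full_matrix({"a": cols}), "liver")
        assert up == set()

    def test_per_duration_reading_is_weaker(self):
        cols = {c.column: "up" for c in tissue_conditions("liver") if c.duration == "1w"}
        m = full_matrix({"a": cols})
        assert cr_responsive(m, "liver")[0] == set()
        assert cr_responsive(m, "liver", duration="1w")[0] == {"a"}

    def test_sets_disjoint_and_subset_of_informative(self, small_sim_matrix):
        _, matrix = small_sim_matrix
        for tissue in ("liver", "adipose", "intestine"):
            up, down = cr_responsive(matrix, tissue)
            assert not (up & down)
            for cond in tissue_conditions(tissue):
                informative = set(
                    matrix.frame.index[matrix.frame[cond.column] != "none"]
                )
                assert up <= informative and down <= informative

    def test_dropping_a_condition_grows_or_preserves(self, small_sim_matrix):
        _, matrix = small_sim_matrix
        full_up, full_down = cr_responsive(matrix, "liver")
        for duration in ("1w", "1m"):
            part_up, part_down = cr_responsive(matrix, "liver", duration=duration)
            assert full_up <= part_up and full_down <= part_down

    def test_recovers_planted_truth(self, small_sim, small_sim_matrix):
        _, result = small_sim
        _, matrix = small_sim_matrix
        for tissue in ("liver", "adipose", "muscle", "brain", "intestine"):
            up, down = cr_responsive(matrix, tissue)
            true_up, true_down = planted_responsive(result.truth, tissue)
            assert up == true_up and down == true_down


def test_informative_counts_table_layout(small_sim_matrix):
    _, matrix = small_sim_matrix
    table = informative_counts_table(matrix)
    assert set(table["tissue"]) == {"liver", "adipose", "muscle", "brain", "intestine"}
    assert table.shape[0] == 9  # tissue x duration rows (intestine 1m only)
    assert {5, 10, 20, 30} <= set(table.columns)
    # overlap equals |up| + |down| of the consensus sets
    up, down = cr_responsive(matrix, "liver")
    assert table.loc[table["tissue"] == "liver", "overlap"].unique().tolist() == [
        len(up) + len(down)
    ]
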