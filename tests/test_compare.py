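import numpy as np
import pytest
from scipy.stats import wilcoxon as scipy_wilcoxon

from refassess.compare import (
    cherry_pick,
    head_to_head_counts,
    load_printed_mr_table,
    model1_identification_rate,
    mr_viability,
    pooled_zrecords,
    wilcoxon_one_tailed,
)
from refassess.ranking import METRICS, ModelRecord


class TestWilcoxon:
    def test_identical_vectors_give_p_one(self):
        a = np.arange(10.0)
        res = wilcoxon_one_tailed(a, a)
        assert res.p_value == 1.0
        assert not res.significant

    def test_ten_uniform_wins_exact(self):
        res = wilcoxon_one_tailed(np.arange(1, 11.0), np.zeros(10))
        assert res.p_value == pytest.approx(1 / 1024)
        assert res.significant

    def test_threshold_is_strict(self):
        # 6 uniform wins: p = 1/64 ≈ 0.0156 > 0.01
        res = wilcoxon_one_tailed(np.arange(1, 7.0), np.zeros(6), alpha=0.01)
        assert res.p_value == pytest.approx(1 / 64)
        assert not res.significant

    def test_matches_scipy_exact_on_small_fixtures(self):
        rng = np.random.default_rng(10)
        for _ in range(25):
            n = int(rng.integers(5, 13))
            a, b = rng.normal(size=n), rng.normal(size=n)
            mine = wilcoxon_one_tailed(a, b).p_value
            ref = scipy_wilcoxon(a - b, alternative="greater", mode="exact").pvalue
            assert mine == pytest.approx(ref, abs=1e-12)

    def test_handles_tied_magnitudes_with_average_ranks(self):
        a = np.array([1.0, 1.0, 2.0, -1.0, 3.0])
        b = np.zeros(5)
        res = wilcoxon_one_tailed(a, b)
        assert 0 < res.p_value <= 1

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0.8, 1.0, size=40)
        b = np.zeros(40)
        res = wilcoxon_one_tailed(a, b)
        ref = scipy_wilcoxon(a - b, alternative="greater", mode="approx", correction=True).pvalue
        assert res.p_value == pytest.approx(ref, rel=0.05)


class TestHeadToHead:
    def _records(self, offsets, n_targets=25, seed=0):
        rng = np.random.default_rng(seed)
        records = []
        for t in range(n_targets):
            for g, off in offsets.items():
                delta = {q: 0.0 for q in METRICS}
                delta["gdt_ha"] = off + rng.normal(0, 0.5)
                records.append(ModelRecord(f"T{t}", g, 1, delta))
        return records

    def test_identical_groups_count_zero(self):
        records = self._records({"a": 0.0, "b": 0.0})
        df = head_to_head_counts(["a", "b"], records).set_index("group")
        assert df.loc["a", "gdt_ha"] == 0
        assert df.loc["b", "gdt_ha"] == 0

    def test_planted_dominant_group_beats_all_five(self):
        offsets = {"top": 5.0, **{f"g{i}": 0.0 for i in range(5)}}
        records = self._records(offsets, seed=3)
        df = head_to_head_counts(list(offsets), records).set_index("group")
        assert df.loc["top", "gdt_ha"] == 5

    def test_groups_outside_list_never_counted(self):
        offsets = {"top": 5.0, "in": 0.0, "out": -5.0}
        records = self._records(offsets, seed=4)
        df = head_to_head_counts(["top", "in"], records)
        assert set(df.group) == {"top", "in"}
        assert df.set_index("group").loc["top", "gdt_ha"] <= 1


def records_for_target(values_by_group_index, target="T1"):
    records = []
    for (g, idx), v in values_by_group_index.items():
        delta = {q: 0.0 for q in METRICS}
        delta["gdt_ha"] = v
        records.append(ModelRecord(target, g, idx, delta))
    return records


class TestCherryPick:
    def test_identical_models_tie_break_to_index_one(self):
        vals = {("g", i): 1.0 for i in range(1, 6)}
        vals.update({("h", i): float(-i) for i in range(1, 6)})
        picks = cherry_pick(pooled_zrecords(records_for_target(vals)))
        pick_g = next(p for p in picks if p.group == "g")
        assert pick_g.chosen_index == 1
        assert pick_g.was_model1

    def test_planted_best_at_index_three_found(self):
        vals = {("g", i): (5.0 if i == 3 else 1.0) for i in range(1, 6)}
        vals.update({("h", i): 0.0 + 0.1 * i for i in range(1, 6)})
        picks = cherry_pick(pooled_zrecords(records_for_target(vals)))
        pick_g = next(p for p in picks if p.group == "g")
        assert pick_g.chosen_index == 3
        assert not pick_g.was_model1

    def test_single_submission_group(self):
        vals = {("solo", 2): 1.0}
        vals.update({("h", i): float(i) for i in range(1, 6)})
        picks = cherry_pick(pooled_zrecords(records_for_target(vals)))
        solo = next(p for p in picks if p.group == "solo")
        assert solo.chosen_index == 2
        assert not solo.was_model1

    def test_pick_never_below_model1(self):
        rng = np.random.default_rng(11)
        vals = {(g, i): float(rng.normal()) for g in "abc" for i in range(1, 6)}
        picks = cherry_pick(pooled_zrecords(records_for_target(vals)))
        for p in picks:
            assert p.pooled_sp >= p.model1_pooled_sp


class TestModel1Rate:
    def _picks(self, flags, group="g"):
        from refassess.compare import CherryPick

        return [
            CherryPick(f"T{i}", group, 1 if f else 3, 1.0, f) for i, f in enumerate(flags)
        ]

    def test_always_right_is_100(self):
        assert model1_identification_rate(self._picks([True] * 10), "g") == 100.0

    def test_half_right(self):
        assert model1_identification_rate(self._picks([True] * 12 + [False] * 12), "g") == 50.0

    def test_no_qualifying_target_is_error(self):
        with pytest.raises(ValueError):
            model1_identification_rate([], "g")


class TestMrViability:
    def test_printed_table_examples(self):
        df = load_printed_mr_table()
        starting = dict(zip(df.target, df.starting_llg))
        records = [
            {"target": r.target, "group": "best", "model_id": r.best_model_id, "llg": r.best_llg}
            for r in df.itertuples()
        ]
        per_target, _ = mr_viability(starting, records)
        byt = per_target.set_index("target")
        assert bool(byt.loc["TR704", "starting_viable"])  # 62.07 > 60
        assert not bool(byt.loc["TR679", "rescued"])  # 29.68 → 54.35 stays short
        assert bool(byt.loc["TR663", "rescued"])

    def test_llg_exactly_60_not_viable(self):
        per_target, _ = mr_viability(
            {"T1": 60.0}, [{"target": "T1", "group": "g", "model_id": "m", "llg": 60.0}]
        )
        row = per_target.iloc[0]
        assert not row.starting_viable
        assert not row.best_viable

    def test_missing_starting_llg_skips_target(self):
        per_target, _ = mr_viability(
            {"T1": 50.0},
            [
                {"target": "T1", "group": "g", "model_id": "m1", "llg": 70.0},
                {"target": "T2", "group": "g", "model_id": "m2", "llg": 70.0},
            ],
        )
        assert list(per_target.target) == ["T1"]
        assert per_target.attrs["skipped_targets"] == ["T2"]

    def test_group_summary_counts_targets(self):
        starting = {"T1": 50.0, "T2": 80.0}
        records = [
            {"target": "T1", "group": "g", "model_id": "a", "llg": 65.0},
            {"target": "T1", "group": "g", "model_id": "b", "llg": 40.0},
            {"target": "T2", "group": "g", "model_id": "c", "llg": 90.0},
        ]
        _, per_group = mr_viability(starting, records)
        row = per_group.iloc[0]
        assert row.n_viable_targets == 2
        assert row.mean_delta_llg == pytest.approx(((65 - 50) + (90 - 80)) / 2)
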