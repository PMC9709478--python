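"""Four-step read-through screen."""

import numpy as np
import pandas as pd
import pytest

from trtscreen.annotation import enumerate_adjacent_pairs, pairs_to_frame
from trtscreen.screen import (
    ScreenParams,
    call_trt,
    control_baseline,
    recurrent_pairs,
    step2_expressed_upstream,
    step3_intergenic_fc,
    step4_downstream_effect,
)

from conftest import gm, make_expr


def two_pair_setup():
    """g1->g2 and g3->g4 cis pairs on separate chromosomes."""
    genes = [
        gm("g1", "chr1", 100, 300, "+"),
        gm("g2", "chr1", 500, 800, "+"),
        gm("g3", "chr2", 1000, 1300, "+"),
        gm("g4", "chr2", 1500, 1900, "+"),
    ]
    return genes, enumerate_adjacent_pairs(genes)


class TestControlBaseline:
    def test_mean_over_controls(self):
        expr = make_expr({"c1": [2.0], "c2": [4.0]}, ["f"])
        assert control_baseline(expr, ["c1", "c2"])["f"] == 3.0

    def test_single_control_is_identity(self):
        expr = make_expr({"c1": [2.5]}, ["f"])
        assert control_baseline(expr, ["c1"])["f"] == 2.5

    def test_empty_control_set_is_error(self):
        expr = make_expr({"c1": [2.5]}, ["f"])
        with pytest.raises(ValueError):
            control_baseline(expr, [])


class TestStep2:
    params = ScreenParams()

    def make(self, upstream_values):
        n = len(upstream_values)
        genes, index = [], []
        rows = {}
        for i, v in enumerate(upstream_values):
            rows[f"u{i}"] = v
        frame = pd.DataFrame(
            {
                "pair_id": [f"u{i}__d{i}" for i in range(n)],
                "upstream_gene": [f"u{i}" for i in range(n)],
                "downstream_gene": [f"d{i}" for i in range(n)],
            }
        )
        feats = list(rows) + [f"d{i}" for i in range(n)]
        vals = list(upstream_values) + [0.0] * n
        expr = make_expr({"p": vals}, feats)
        return frame, expr

    def test_strictly_above_linear_interpolation_percentile(self):
        frame, expr = self.make([0.0, 1.0, 2.0, 3.0])
        kept = step2_expressed_upstream(frame, expr, "p", self.params)
        threshold = np.percentile([0.0, 1.0, 2.0, 3.0], 25)  # 0.75
        expected = [f"u{i}__d{i}" for i, v in enumerate([0, 1, 2, 3]) if v > threshold]
        assert kept == expected

    def test_all_equal_upstream_yields_empty(self):
        frame, expr = self.make([5.0, 5.0, 5.0])
        assert step2_expressed_upstream(frame, expr, "p", self.params) == []

    def test_single_pair_yields_empty(self):
        frame, expr = self.make([7.0])
        assert step2_expressed_upstream(frame, expr, "p", self.params) == []


class TestStep3:
    params = ScreenParams()

    def run(self, patient, mean, fallback=None, params=None):
        expr = make_expr({"p": [patient]}, ["u__d"])
        baseline = pd.Series({"u__d": mean})
        pair = pd.Series({"pair_id": "u__d", "upstream_gene": "u", "downstream_gene": "d"})
        return step3_intergenic_fc(pair, expr, "p", baseline, params or self.params, fallback)

    def test_fold_change_above_threshold_passes(self):
        passed, fc = self.run(12.0, 2.0)
        assert passed and fc == 6.0

    def test_fold_change_below_threshold_fails(self):
        passed, fc = self.run(9.0, 2.0)
        assert not passed and fc == 4.5

    def test_no_signal_fails(self):
        passed, _ = self.run(0.0, 0.0)
        assert not passed

    def test_zero_control_mean_uses_fallback_unit(self):
        assert self.run(1.1, 0.0, fallback=0.2)[0]  # 1.1 > 5 * 0.2
        assert not self.run(0.9, 0.0, fallback=0.2)[0]
        assert not self.run(0.9, 0.0, fallback=None)[0]

    def test_epsilon_policy_replaces_fallback(self):
        params = ScreenParams(zero_mean_epsilon=0.1)
        passed, fc = self.run(1.0, 0.0, params=params)
        assert passed and fc == pytest.approx(10.0)


class TestStep4:
    params = ScreenParams()

    def run(self, patient, mean):
        expr = make_expr({"p": [0.0, patient]}, ["u__d", "d"])
        baseline = pd.Series({"u__d": 0.0, "d": mean})
        pair = pd.Series({"pair_id": "u__d", "upstream_gene": "u", "downstream_gene": "d"})
        return step4_downstream_effect(pair, expr, "p", baseline, self.params)

    def test_absolute_branch_when_control_mean_zero(self):
        passed, value, branch = self.run(2.0, 0.0)
        assert passed and branch == "absolute" and value == 2.0

    def test_fold_branch_failure(self):
        passed, value, branch = self.run(1.4, 1.0)
        assert not passed and branch == "fold" and value == pytest.approx(1.4)

    def test_fold_branch_pass(self):
        passed, value, branch = self.run(4.0, 2.0)
        assert passed and branch == "fold" and value == pytest.approx(2.0)


class TestCallTrt:
    def test_all_zero_expression_gives_all_false(self):
        genes, pairs = two_pair_setup()
        feats = [g.gene_id for g in genes] + [p.pair_id for p in pairs]
        expr = make_expr(
            {s: [0.0] * len(feats) for s in ["p1", "p2", "c1"]}, feats
        )
        res = call_trt(pairs, expr, ["p1", "p2"], ["c1"])
        assert not res.calls.to_numpy().any()

    def planted_expr(self):
        """Pair g1__g2 passes all steps in p1 only; g3__g4 never does."""
        feats = ["g1", "g2", "g3", "g4", "g1__g2", "g3__g4"]
        data = {
            # g1 high in p1, intergenic FC 12 vs control mean 1, downstream FC 4
            "p1": [100.0, 8.0, 1.0, 1.0, 12.0, 0.5],
            "p2": [100.0, 2.0, 1.0, 1.0, 2.0, 0.5],
            "c1": [50.0, 2.0, 1.0, 1.0, 1.0, 0.5],
            "c2": [50.0, 2.0, 1.0, 1.0, 1.0, 0.5],
        }
        return make_expr(data, feats)

    def test_single_planted_cell_called(self):
        genes, pairs = two_pair_setup()
        expr = self.planted_expr()
        res = call_trt(pairs, expr, ["p1", "p2"], ["c1", "c2"])
        assert res.calls.loc["g1__g2", "p1"]
        assert res.calls.to_numpy().sum() == 1
        # cell agrees with independent step-by-step evaluation
        frame = pairs_to_frame(pairs)
        baseline = control_baseline(expr, ["c1", "c2"])
        row = frame.iloc[0]
        assert "g1__g2" in step2_expressed_upstream(frame, expr, "p1", res.params)
        assert step3_intergenic_fc(row, expr, "p1", baseline, res.params)[0]
        assert step4_downstream_effect(row, expr, "p1", baseline, res.params)[0]

    def test_diagnostics_record_failing_cells_too(self):
        genes, pairs = two_pair_setup()
        res = call_trt(pairs, self.planted_expr(), ["p1", "p2"], ["c1", "c2"])
        assert len(res.diagnostics) == 2 * 2
        cell = res.diagnostics.set_index(["pair_id", "patient_id"]).loc[("g3__g4", "p2")]
        assert not cell["call"]
        assert cell["step_passed"] in (1, 2, 3)

    def test_unknown_sample_is_error(self):
        genes, pairs = two_pair_setup()
        with pytest.raises(KeyError):
            call_trt(pairs, self.planted_expr(), ["p1", "nope"], ["c1"])

    def test_overlapping_patient_and_control_sets_rejected(self):
        genes, pairs = two_pair_setup()
        with pytest.raises(ValueError, match="overlap"):
            call_trt(pairs, self.planted_expr(), ["p1"], ["p1", "c1"])

    def test_patient_permutation_permutes_columns_only(self):
        genes, pairs = two_pair_setup()
        expr = self.planted_expr()
        a = call_trt(pairs, expr, ["p1", "p2"], ["c1", "c2"]).calls
        b = call_trt(pairs, expr, ["p2", "p1"], ["c1", "c2"]).calls
        pd.testing.assert_frame_equal(a, b[a.columns])

    def test_threshold_monotonicity_on_simulated_cohort(self, default_cohort):
        c = default_cohort
        calls = {}
        for fc_min in (2.0, 5.0, 10.0):
            params = ScreenParams(intergenic_fc_min=fc_min)
            calls[fc_min] = call_trt(c.pairs, c.expr, c.patient_ids, c.control_ids, params).calls
        assert (calls[5.0] <= calls[2.0]).all().all()
        assert (calls[10.0] <= calls[5.0]).all().all()

    def test_controls_are_not_called_under_the_null(self, default_cohort):
        # screening half the controls against the other half yields ~no calls
        c = default_cohort
        ctl = c.control_ids
        res = call_trt(c.pairs, c.expr, ctl[: len(ctl) // 2], ctl[len(ctl) // 2 :])
        assert res.calls.to_numpy().mean() < 0.005


class TestRecurrentPairs:
    def make_calls(self, true_counts, n_patients=10):
        data = {
            f"pair{i}": [j < k for j in range(n_patients)]
            for i, k in enumerate(true_counts)
        }
        return pd.DataFrame(data).T.set_axis([f"p{j}" for j in range(n_patients)], axis=1)

    def test_strictly_above_threshold_kept(self):
        calls = self.make_calls([4, 3, 0])
        assert recurrent_pairs(calls, ScreenParams()) == ["pair0"]

    def test_empty_matrix_gives_empty_set(self):
        assert recurrent_pairs(pd.DataFrame(), ScreenParams()) == []

    def test_recurrence_threshold_monotonicity(self, default_screen):
        sets = [
            set(recurrent_pairs(default_screen.calls, ScreenParams(recurrence_min_frac=f)))
            for f in (0.1, 0.3, 0.6)
        ]
        assert sets[2] <= sets[1] <= sets[0]


class TestScreenParams:
    def test_invalid_ranges_rejected(self):
        with pytest.raises(ValueError, match="recurrence_min_frac"):
            ScreenParams(recurrence_min_frac=1.5)
        with pytest.raises(ValueError, match="upstream_percentile"):
            ScreenParams(upstream_percentile=150)
        with pytest.raises(ValueError, match="intergenic_fc_min"):
            ScreenParams(intergenic_fc_min=0)
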