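"""Subtype machinery: expression truth, array conversion, window selection,
sequential cutoffs and the gated call rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cfmethyl.containers import CalibrationTable
from cfmethyl.subtyping import (array_to_counts,
                                assign_subtype_from_expression, call_subtype,
                                derive_sequential_cutoffs,
                                select_subtype_dmrs)


class TestExpressionAssignment:
    @pytest.mark.parametrize("expr,context,expected", [
        ({"ASCL1": 10, "NEUROD1": 3, "POU2F3": 3, "YAP1": 3}, "cell_line", "ASCL1"),
        ({"ASCL1": 3, "NEUROD1": 10, "POU2F3": 3, "YAP1": 3}, "cell_line", "NEUROD1"),
        ({"ASCL1": 10, "NEUROD1": 10, "POU2F3": 3, "YAP1": 3}, "cell_line", "excluded"),
        ({"ASCL1": 10, "NEUROD1": 10, "POU2F3": 3, "YAP1": 3}, "model", "NEUROD1"),
        ({"ASCL1": 3, "NEUROD1": 3, "POU2F3": 3, "YAP1": 10}, "cell_line", "double_negative"),
        ({"ASCL1": 3, "NEUROD1": 3, "POU2F3": 10, "YAP1": 3}, "cell_line", "double_negative"),
        ({"ASCL1": 3, "NEUROD1": 3, "POU2F3": 3, "YAP1": 3}, "cell_line", "unclassified"),
        ({"ASCL1": 5, "NEUROD1": 4, "POU2F3": 8, "YAP1": 2}, "model", "double_negative"),
        ({"ASCL1": 9.5, "NEUROD1": 4, "POU2F3": 8, "YAP1": 2}, "model", "ASCL1"),
    ])
    def test_threshold_and_argmax_rules(self, expr, context, expected):
        assert assign_subtype_from_expression(expr, context=context) == expected

    def test_missing_gene_rejected(self):
        with pytest.raises(ValueError, match="YAP1"):
            assign_subtype_from_expression({"ASCL1": 1, "NEUROD1": 1, "POU2F3": 1})

    def test_cohort_expression_reproduces_generator_truth(self, cohort_small):
        expr = cohort_small.expression
        for sid, row in expr.iterrows():
            got = assign_subtype_from_expression(
                row[["ASCL1", "NEUROD1", "POU2F3", "YAP1"]].to_dict(),
                context="cell_line" if row["context"] == "cell_line" else "model")
            want = {"ASCL1": "ASCL1", "NEUROD1": "NEUROD1",
                    "DN": "double_negative"}[row["subtype_truth"]]
            assert got == want


@pytest.fixture
def flat_setup():
    windows = pd.DataFrame({
        "contig": "c", "start": np.arange(4) * 300,
        "end": np.arange(1, 5) * 300, "cpg_count": [10, 10, 10, 10],
        "excluded": [False, False, False, True],
        "qc_always_methylated": False, "cgi": False})
    cal = CalibrationTable(pd.DataFrame(
        {"d_min": [10], "d_max": [10], "d_mean": [10.0],
         "bg": [20.0], "full": [120.0], "n": [50]}))
    return windows, cal


class TestArrayConversion:
    def test_beta_endpoints_map_to_background_and_full(self, flat_setup):
        windows, cal = flat_setup
        prof = pd.DataFrame({"window": [0, 1], "beta": [0.0, 1.0]})
        counts, covered, dropped = array_to_counts(prof, cal, windows,
                                                   target_library_size=1_000_000)
        assert counts[0] == 20 and counts[1] == 120
        assert covered.tolist() == [True, True, False, False]
        assert dropped == 0

    def test_multiple_probes_use_the_maximum(self, flat_setup):
        windows, cal = flat_setup
        prof = pd.DataFrame({"window": [0, 0], "beta": [0.3, 0.8]})
        counts, _, _ = array_to_counts(prof, cal, windows,
                                       target_library_size=1_000_000)
        assert counts[0] == 100  # 20 + 0.8 * 100

    def test_probes_on_excluded_windows_dropped_with_tally(self, flat_setup):
        windows, cal = flat_setup
        prof = pd.DataFrame({"window": [0, 3], "beta": [0.5, 0.5]})
        counts, covered, dropped = array_to_counts(prof, cal, windows,
                                                   target_library_size=1_000_000)
        assert dropped == 1 and not covered[3] and counts[3] == 0

    def test_out_of_range_probe_rejected(self, flat_setup):
        windows, cal = flat_setup
        prof = pd.DataFrame({"window": [99], "beta": [0.5]})
        with pytest.raises(ValueError, match="outside"):
            array_to_counts(prof, cal, windows)


def _contrast(windows, deltas, q=1e-6):
    return pd.DataFrame({"window": windows,
                         "delta_beta": deltas,
                         "q_value": q})


class TestSubtypeWindowSelection:
    def test_disjoint_contrasts_give_exactly_300(self):
        contrasts = {}
        for c in range(3):
            wins = np.arange(c * 1000, c * 1000 + 200)
            deltas = np.linspace(-0.9, 0.9, 200)
            contrasts[f"c{c}"] = _contrast(wins, deltas)
        out = select_subtype_dmrs(contrasts, n_per_direction=50)
        assert len(out) == 300

    def test_shared_windows_deduplicate(self):
        # two contrasts sharing every top window collapse to one copy each
        wins = np.arange(200)
        deltas = np.linspace(-0.9, 0.9, 200)
        contrasts = {"a": _contrast(wins, deltas), "b": _contrast(wins, deltas)}
        out = select_subtype_dmrs(contrasts, n_per_direction=50)
        assert len(out) == 100
        assert len(set(out)) == len(out)

    def test_short_contrast_takes_all_available_with_warning(self):
        contrasts = {"a": _contrast(np.arange(30), np.linspace(0.5, 0.9, 30))}
        with pytest.warns(UserWarning, match="fewer than"):
            out = select_subtype_dmrs(contrasts, n_per_direction=50)
        assert len(out) == 30

    def test_insignificant_windows_never_selected(self):
        table = pd.concat([
            _contrast(np.arange(100), np.linspace(-0.9, 0.9, 100), q=1e-6),
            _contrast(np.arange(100, 140), 0.95, q=0.5)])
        out = select_subtype_dmrs({"a": table}, n_per_direction=50)
        assert set(out) <= set(range(100))


class TestSequentialCutoffs:
    def test_perfect_separation_attains_unit_objective(self):
        truth = np.array(["NEUROD1"] * 5 + ["ASCL1"] * 5 + ["DN"] * 5)
        s_n = np.r_[np.full(5, 0.9), np.full(10, 0.05)]
        s_a = np.r_[np.full(5, 0.1), np.full(5, 0.9), np.full(5, 0.1)]
        res = derive_sequential_cutoffs(truth, s_n, s_a)
        assert res.avg_balanced_accuracy == pytest.approx(1.0)
        # smallest grid pair attaining the optimum
        assert res.neurod1_cutoff <= 0.9 and res.ascl1_cutoff <= 0.9
        calls_n = s_n >= res.neurod1_cutoff
        assert calls_n.sum() == 5

    def test_matches_brute_force_grid_oracle(self):
        rng = np.random.default_rng(3)
        grid = np.round(np.arange(0, 1.001, 0.01), 10)
        for _ in range(10):
            n = 24
            truth = rng.choice(["NEUROD1", "ASCL1", "DN"], n)
            s_n, s_a = rng.random(n), rng.random(n)
            res = derive_sequential_cutoffs(truth, s_n, s_a)
            best = -1.0
            best_pair = None
            is_n, is_a = truth == "NEUROD1", truth == "ASCL1"
            for cn in grid:
                call_n = s_n >= cn
                ba_n = ((call_n[is_n].mean() if is_n.any() else np.nan)
                        + ((~call_n[~is_n]).mean() if (~is_n).any() else np.nan)) / 2
                if np.isnan(ba_n):
                    continue
                elig = ~call_n
                for ca in grid:
                    pos, neg = elig & is_a, elig & ~is_a
                    if not pos.any() or not neg.any():
                        continue
                    ba_a = ((s_a[pos] >= ca).mean() + (s_a[neg] < ca).mean()) / 2
                    obj = (ba_n + ba_a) / 2
                    if obj > best + 1e-12:
                        best, best_pair = obj, (cn, ca)
            assert res.avg_balanced_accuracy == pytest.approx(best)
            assert (res.neurod1_cutoff, res.ascl1_cutoff) == pytest.approx(best_pair)


class TestCallRule:
    CUT = dict(neurod1_cutoff=0.16, ascl1_cutoff=0.76)

    @pytest.mark.parametrize("s_n,s_a,expected", [
        (0.20, 0.10, "NEUROD1"),
        (0.05, 0.80, "ASCL1"),
        (0.05, 0.30, "double_negative"),
        (0.90, 0.90, "NEUROD1"),  # NEUROD1 never consults the ASCL1 score
    ])
    def test_sequential_rule(self, s_n, s_a, expected):
        call = call_subtype("s", s_n, s_a, tumor_fraction=0.2, **self.CUT)
        assert call.call == expected

    def test_low_tumor_fraction_not_evaluable(self):
        call = call_subtype("s", 0.99, 0.99, tumor_fraction=0.03, **self.CUT)
        assert call.call == "not_evaluable"

    def test_missing_tumor_fraction_is_an_error(self):
        with pytest.raises(ValueError, match="tumor fraction"):
            call_subtype("s", 0.5, 0.5, tumor_fraction=float("nan"), **self.CUT)

    @settings(max_examples=50)
    @given(st.floats(0, 1), st.floats(0, 1), st.floats(0, 1),
           st.floats(0, 0.2), st.floats(0, 0.2))
    def test_lowering_the_gate_only_unlocks_calls(self, s_n, s_a, tf, g_hi, g_lo):
        g_lo, g_hi = sorted((g_lo, g_hi))
        hi = call_subtype("s", s_n, s_a, tf, gate=g_hi, **self.CUT)
        lo = call_subtype("s", s_n, s_a, tf, gate=g_lo, **self.CUT)
        if hi.call != "not_evaluable":
            assert lo.call == hi.call


class TestUndersampling:
    def test_members_balance_ascl1_against_the_other_pools(self, subtype_run):
        truth = subtype_run.source_subtypes
        for model in (subtype_run.bundle.neurod1_model,
                      subtype_run.bundle.ascl1_model):
            for src in model.member_sources:
                kinds = pd.Series([truth[t] for t in src["tumor"]]).value_counts()
                basis = kinds.get("NEUROD1", 0) + kinds.get("DN", 0)
                assert abs(kinds.get("ASCL1", 0) - basis) <= 1
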