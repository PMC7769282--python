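"""Predictor selection: AUROC oracle, CI calibration, effects, rule, permutation FDR."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pe_triage import select, synthcohort as sc
from pe_triage.errors import DataError


def brute_force_auroc(cases, controls):
    """Oracle: exhaustive pair counting with ties at one half."""
    wins = sum(
        1.0 if c > k else 0.5 if c == k else 0.0 for c in cases for k in controls
    )
    return wins / (len(cases) * len(controls))


class TestAuroc:
    def test_small_example(self):
        # cases {3,5} vs controls {1,2,4}: 5 of 6 pairs won
        vals = np.array([3, 5, 1, 2, 4], dtype=float)
        case = np.array([1, 1, 0, 0, 0], dtype=bool)
        assert select.estimate_auroc(vals, case).auroc == pytest.approx(5 / 6)

    def test_perfect_separation(self):
        vals = np.r_[np.ones(5) + 10, np.ones(5)]
        case = np.r_[np.ones(5, bool), np.zeros(5, bool)]
        r = select.estimate_auroc(vals, case)
        assert r.auroc == 1.0 and r.direction == "up"

    @given(
        st.lists(st.integers(0, 9), min_size=1, max_size=25),
        st.lists(st.integers(0, 9), min_size=1, max_size=25),
    )
    @settings(max_examples=150, deadline=None)
    def test_matches_brute_force_pair_counting(self, cases, controls):
        vals = np.array(cases + controls, dtype=float)
        case = np.r_[np.ones(len(cases), bool), np.zeros(len(controls), bool)]
        r = select.estimate_auroc(vals, case)
        raw = brute_force_auroc(cases, controls)
        assert max(raw, 1 - raw) == pytest.approx(r.auroc, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.normal(size=40)
        case = rng.random(40) < 0.4
        if case.all() or not case.any():
            return
        a = select.estimate_auroc(vals, case)
        b = select.estimate_auroc(np.exp(vals), case)  # strictly monotone
        assert a.auroc == pytest.approx(b.auroc, abs=1e-12)
        assert a.direction == b.direction

    def test_all_tied_degenerate(self):
        r = select.estimate_auroc(np.ones(10), np.r_[np.ones(4, bool), np.zeros(6, bool)])
        assert r.auroc == 0.5 and r.degenerate

    def test_one_class_empty(self):
        with pytest.raises(DataError):
            select.estimate_auroc(np.arange(5.0), np.zeros(5, bool))

    def test_down_direction_folded(self):
        spec = sc.BiomarkerSpec("p", control_location=0.04,
                                effects={"preterm_pe": sc.OutcomeEffect(0.43, 0.73)})
        cases, ctrl = sc.draw_calibrated(spec, "preterm_pe", 20000, 20000, seed=2)
        r = select.estimate_auroc(np.r_[cases, ctrl],
                                  np.r_[np.ones(20000, bool), np.zeros(20000, bool)])
        assert r.direction == "down"
        assert r.auroc == pytest.approx(0.73, abs=0.01)

    def test_type_one_rate_of_ci_rule_under_null(self):
        """P(lower CI bound >= 0.50) stays near the nominal 5% under the null."""
        rng = np.random.default_rng(7)
        n_cases, n_ctrl = 97, 335
        hits = 0
        reps = 800
        for _ in range(reps):
            vals = rng.normal(size=n_cases + n_ctrl)
            case = np.r_[np.ones(n_cases, bool), np.zeros(n_ctrl, bool)]
            hits += select.estimate_auroc(vals, case).ci_low >= 0.50
        # one-sided binomial allowance (~2.5 sigma) around 0.05
        assert hits / reps <= 0.05 + 2.5 * np.sqrt(0.05 * 0.95 / reps)


class TestEffect:
    def test_fold_change_arithmetic(self):
        vals = np.array([2.9, 2.9, 2.9, 2.0, 2.0, 2.0])
        case = np.array([1, 1, 1, 0, 0, 0], bool)
        r = select.estimate_effect(vals, case, "fold-change", B_boot=50, seed=0)
        assert r.effect == pytest.approx(1.45)

    def test_identical_groups_cover_null(self):
        rng = np.random.default_rng(3)
        vals = rng.lognormal(size=120)
        case = np.r_[np.ones(60, bool), np.zeros(60, bool)]
        vals[case] = vals[~case]
        r = select.estimate_effect(vals, case, "fold-change", B_boot=400, seed=1)
        assert r.ci_low <= 1.0 <= r.ci_high

    def test_map_difference_recovery(self):
        spec = sc.BiomarkerSpec("MAP", family="normal", control_location=79.2,
                                effects={"any_pe": sc.OutcomeEffect(4.7, 0.67)})
        cases, ctrl = sc.draw_calibrated(spec, "any_pe", 5000, 5000, seed=4)
        vals = np.r_[cases, ctrl]
        case = np.r_[np.ones(5000, bool), np.zeros(5000, bool)]
        r = select.estimate_effect(vals, case, "difference", B_boot=200, seed=2)
        assert r.effect == pytest.approx(4.7, abs=0.3)

    def test_zero_control_median(self):
        vals = np.array([1.0, 2.0, 0.0, 0.0, 0.0])
        case = np.array([1, 1, 0, 0, 0], bool)
        with pytest.raises(DataError):
            select.estimate_effect(vals, case, "fold-change", B_boot=10, seed=0)


class TestSelectionRule:
    @pytest.mark.parametrize(
        "auroc,ci_low,expect",
        [
            (0.61, 0.50, True),   # boundary: inclusive on the CI floor
            (0.60, 0.55, False),  # strict > on the AUROC floor
            (0.72, 0.49, False),  # CI rule
            (0.601, 0.501, True),
        ],
    )
    def test_rule(self, auroc, ci_low, expect):
        assert select.passes_selection(auroc, ci_low) is expect

    def test_modelling_set_is_any_pe_selection(self, default_cc):
        rep = select.build_predictor_report(
            default_cc, ["PlGF", "DLG", "MAP"], B_boot=50, with_fdr=False
        )
        assert rep.modelling_set == rep.selected("any_pe")
        assert set(rep.table["outcome"]) == {"preterm_pe", "term_pe", "any_pe"}


def enumeration_fdr(values, case, pi0=1.0):
    """Oracle: exact label-permutation FDR by full enumeration."""
    n, k = len(case), int(case.sum())

    def count(mask):
        c = 0
        for j in range(values.shape[1]):
            r = select.estimate_auroc(values[:, j], mask)
            c += select.passes_selection(r.auroc, r.ci_low)
        return c

    observed = count(case)
    if observed == 0:
        return float("nan")
    total, m = 0, 0
    for pos in combinations(range(n), k):
        mask = np.zeros(n, bool)
        mask[list(pos)] = True
        total += count(mask)
        m += 1
    return min(1.0, pi0 * total / m / observed)


class TestPermutationFDR:
    def _toy(self):
        rng = np.random.default_rng(5)
        t = pd.DataFrame(
            {
                "outcome": ["preterm_pe"] * 3 + ["none"] * 5,
                "a": [9.0, 8.0, 7.0, 1.0, 2.0, 3.0, 4.0, 0.5],
                "b": rng.normal(size=8),
            }
        )
        return t

    def test_exact_mode_matches_enumeration_oracle(self):
        t = self._toy()
        est = select.estimate_fdr_permutation(t, ["a", "b"], "preterm_pe", exact=True)
        case, _ = select.outcome_mask(t["outcome"], "preterm_pe")
        oracle = enumeration_fdr(t[["a", "b"]].to_numpy(), case)
        assert est == pytest.approx(oracle, abs=1e-12)

    def test_sampled_converges_to_exact(self):
        t = self._toy()
        exact = select.estimate_fdr_permutation(t, ["a", "b"], "preterm_pe", exact=True)
        sampled = select.estimate_fdr_permutation(t, ["a", "b"], "preterm_pe", B=4000, seed=0)
        assert sampled == pytest.approx(exact, abs=0.05)

    def test_all_null_panel_fdr_near_one(self):
        rng = np.random.default_rng(6)
        n = 200
        t = pd.DataFrame(rng.normal(size=(n, 20)), columns=[f"v{i}" for i in range(20)])
        t["outcome"] = ["preterm_pe"] * 40 + ["none"] * (n - 40)
        fdr = select.estimate_fdr_permutation(
            t, [f"v{i}" for i in range(20)], "preterm_pe", B=150, seed=1
        )
        assert np.isnan(fdr) or fdr > 0.5

    def test_strong_signal_low_fdr(self):
        rng = np.random.default_rng(8)
        n = 300
        t = pd.DataFrame(rng.normal(size=(n, 10)), columns=[f"v{i}" for i in range(10)])
        t["outcome"] = ["preterm_pe"] * 60 + ["none"] * (n - 60)
        t.loc[t.outcome == "preterm_pe", "v0"] += 2.5  # overwhelming predictor
        fdr = select.estimate_fdr_permutation(
            t, [f"v{i}" for i in range(10)], "preterm_pe", B=200, seed=2
        )
        assert fdr < 0.5

    def test_conservative_vs_realised_fdp(self):
        """With pi0 = 1 the estimate dominates the realised FDP in most panels."""
        rng = np.random.default_rng(9)
        n, n_case = 260, 50
        dominated = 0
        reps = 10
        for i in range(reps):
            x = rng.normal(size=(n, 16))
            case = np.zeros(n, bool)
            case[:n_case] = True
            x[case, :4] += 0.55  # four real effects, twelve nulls
            t = pd.DataFrame(x, columns=[f"v{j}" for j in range(16)])
            t["outcome"] = np.where(case, "preterm_pe", "none")
            names = [f"v{j}" for j in range(16)]
            discoveries = [
                v
                for v in names
                if select.passes_selection(
                    *(lambda r: (r.auroc, r.ci_low))(
                        select.estimate_auroc(t[v].to_numpy(), case)
                    )
                )
            ]
            if not discoveries:
                dominated += 1
                continue
            realised = sum(1 for v in discoveries if int(v[1:]) >= 4) / len(discoveries)
            est = select.estimate_fdr_permutation(t, names, "preterm_pe", B=120, seed=i)
            dominated += est >= realised
        assert dominated >= 0.9 * reps
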