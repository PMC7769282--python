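"""Model construction: PLS-DA, high-PlGF threshold, constrained partitioning."""

from itertools import product

import numpy as np
import pandas as pd
import pytest

from pe_triage import models, select
from pe_triage.errors import ConfigurationError, DataError


def make_table(rng, n=60, seed_effect=1.0):
    t = pd.DataFrame(
        {
            "PlGF": rng.normal(0.0, 1.0, n),
            "DLG": rng.normal(0.0, 1.0, n),
            "1-HGP": rng.normal(0.0, 1.0, n),
        }
    )
    risk = -seed_effect * t["PlGF"] + seed_effect * t["DLG"] - seed_effect * t["1-HGP"]
    labels = (risk + rng.normal(0, 1.5, n)) > np.quantile(risk, 0.7)
    return t, labels.to_numpy()


class TestPLSDA:
    def test_single_predictor_preserves_auroc(self):
        rng = np.random.default_rng(0)
        t, y = make_table(rng)
        m = models.fit_plsda(t, ["DLG"], y, n_components=1)
        s = m.score(t)
        a1 = select.estimate_auroc(s, y)
        a2 = select.estimate_auroc(t["DLG"].to_numpy(), y)
        assert a1.auroc == pytest.approx(a2.auroc, abs=1e-12)

    def test_symmetric_predictors_equal_weights(self):
        rng = np.random.default_rng(1)
        n = 4000
        y = rng.random(n) < 0.5
        # two independent standardized predictors with equal class covariance
        a = rng.normal(size=n) + 0.5 * y
        b = rng.normal(size=n) + 0.5 * y
        t = pd.DataFrame({"a": a, "b": b})
        m = models.fit_plsda(t, ["a", "b"], y, n_components=1)
        w = m.x_weights[:, 0]
        assert abs(w[0]) == pytest.approx(abs(w[1]), rel=0.1)

    def test_one_component_score_is_class_covariance_direction(self):
        rng = np.random.default_rng(2)
        t, y = make_table(rng, n=200)
        m = models.fit_plsda(t, ["PlGF", "DLG", "1-HGP"], y, n_components=1)
        x = t[m.predictors].to_numpy()
        xs = (x - x.mean(0)) / x.std(0, ddof=1)
        yc = np.where(y, 1.0, -1.0) - np.where(y, 1.0, -1.0).mean()
        direct = xs @ (xs.T @ yc)  # covariance-direction score
        r = np.corrcoef(m.score(t), direct)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-10)

    def test_orientation_cases_higher(self):
        rng = np.random.default_rng(3)
        t, y = make_table(rng, n=300)
        m = models.fit_plsda(t, ["PlGF", "DLG"], y)
        s = m.score(t)
        assert s[y].mean() > s[~y].mean()

    def test_constant_predictor_dropped(self):
        rng = np.random.default_rng(4)
        t, y = make_table(rng)
        t["flat"] = 1.0
        with pytest.warns(UserWarning):
            m = models.fit_plsda(t, ["DLG", "flat"], y)
        assert m.predictors == ["DLG"]


class TestHighPlGF:
    def test_separable_toy(self):
        # low PlGF = PE; threshold lands on the smallest perfect cut
        plgf = np.array([1.0, 2.0, 3.0, 4.0])
        labels = np.array([1, 1, 0, 0], bool)
        r = models.find_high_plgf_threshold(plgf, labels)
        assert r.threshold == 3.0 and r.accuracy == 1.0 and not r.degenerate

    def test_null_labels_degenerate(self):
        rng = np.random.default_rng(5)
        plgf = rng.normal(size=200)
        labels = rng.random(200) < 0.3
        r = models.find_high_plgf_threshold(plgf, labels)
        assert r.accuracy >= max(labels.mean(), 1 - labels.mean()) - 1e-12

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(6)
        plgf = rng.normal(size=30)
        labels = (plgf + rng.normal(0, 1, 30)) < 0
        r = models.find_high_plgf_threshold(plgf, labels)
        best = max(
            ((plgf < t) == labels).mean()
            for t in np.r_[np.unique(plgf), np.inf]
        )
        assert r.accuracy == pytest.approx(best, abs=1e-12)


def brute_force_search(scores, directions, labels, w, objective, pv_target):
    """Oracle: full enumeration over all observed cut-offs per step.

    Returns the best feasible objective value (None if infeasible). The
    final positive set of a step-wise model is the union of per-step tails,
    which this oracle exploits directly.
    """
    wc, wk = w * labels, w * (~labels)
    cand = [[None] + list(np.unique(s)) for s in scores]
    best = None
    for combo in product(*cand):
        flag = np.zeros(len(labels), bool)
        for s, d, c in zip(scores, directions, combo):
            if c is not None:
                flag |= (s >= c) if d == "up" else (s <= c)
        tp, fp = wc[flag].sum(), wk[flag].sum()
        fn, tn = wc[~flag].sum(), wk[~flag].sum()
        if objective == "rule-in":
            con = tp / (tp + fp) if tp + fp > 0 else np.nan
            obj = tp / (tp + fn)
        else:
            con = tn / (tn + fn) if tn + fn > 0 else np.nan
            obj = tn / (tn + fp)
        if pv_target > 0 and (np.isnan(con) or con < pv_target):
            continue
        if best is None or obj > best:
            best = obj
    return best


def small_fixture(seed, n=14):
    rng = np.random.default_rng(seed)
    t = pd.DataFrame(
        {
            "PlGF": np.round(rng.normal(size=n), 2),
            "DLG": np.round(rng.normal(size=n), 2),
        }
    )
    labels = (-t["PlGF"] + t["DLG"] + rng.normal(0, 1, n)) > 0.5
    w = np.where(labels, 1.0, 3.0)
    return t, labels.to_numpy(), w


class TestPartitionSearch:
    @pytest.mark.parametrize("objective,pv_target", [("rule-in", 0.4), ("rule-in", 0.0), ("rule-out", 0.8)])
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_default_search_matches_enumeration_oracle(self, objective, pv_target, seed):
        t, labels, w = small_fixture(seed)
        if labels.all() or not labels.any():
            return
        model = models.build_partition_model(
            t, labels, objective, [["PlGF"], ["DLG"]], weights=w, pv_target=pv_target
        )
        scores = [t["PlGF"].to_numpy(), t["DLG"].to_numpy()]
        oracle = brute_force_search(scores, ["down", "up"], labels, w, objective, pv_target)
        if oracle is None:
            assert not model.feasible
        else:
            key = "sensitivity" if objective == "rule-in" else "specificity"
            assert model.feasible
            assert model.training_metrics[key] == pytest.approx(oracle, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_greedy_matches_exhaustive_rule_in(self, seed):
        t, labels, w = small_fixture(seed, n=18)
        if labels.all() or not labels.any():
            return
        kw = dict(weights=w, pv_target=0.4)
        ex = models.build_partition_model(t, labels, "rule-in", [["PlGF"], ["DLG"]],
                                          search="exhaustive", **kw)
        gr = models.build_partition_model(t, labels, "rule-in", [["PlGF"], ["DLG"]],
                                          search="greedy", **kw)
        assert ex.feasible == gr.feasible
        if ex.feasible:
            assert gr.training_metrics["sensitivity"] == pytest.approx(
                ex.training_metrics["sensitivity"], abs=1e-12
            )

    def test_unconstrained_rule_in_flags_everything(self):
        t, labels, w = small_fixture(7)
        m = models.build_partition_model(t, labels, "rule-in", [["PlGF"]], weights=w, pv_target=0.0)
        assert m.training_metrics["sensitivity"] == 1.0

    def test_pv_target_monotonicity(self, model_matrix):
        """Relaxing the PPV floor never decreases achieved training sensitivity."""
        m = model_matrix
        labels = (m["outcome"] == "preterm_pe").to_numpy()
        w = m["weight"].to_numpy()
        sens = []
        for pv in (0.08, 0.05, 0.02, 0.0):
            mod = models.build_partition_model(
                m, labels, "rule-in", [["PlGF"], ["DLG"]], weights=w, pv_target=pv
            )
            sens.append(mod.training_metrics["sensitivity"] if mod.feasible else -1.0)
        assert sens == sorted(sens)

    def test_first_step_must_be_plgf(self, model_matrix):
        labels = (model_matrix["outcome"] != "none").to_numpy()
        with pytest.raises(ConfigurationError):
            models.build_partition_model(model_matrix, labels, "rule-in", [["DLG"], ["PlGF"]])

    def test_infeasibility_is_first_class(self):
        # one case buried among controls at 50% PPV demand: no cut works
        t = pd.DataFrame({"PlGF": [1.0, 2.0, 3.0, 4.0], "DLG": [1.0, 1.0, 1.0, 1.0]})
        labels = np.array([0, 1, 0, 0], bool)
        w = np.array([1.0, 1.0, 9.0, 9.0])
        m = models.build_partition_model(
            t, labels, "rule-in", [["PlGF"], ["DLG"]], weights=w, pv_target=0.9
        )
        assert not m.feasible and "no cut-off" in m.reason


class TestPredictPartition:
    def _model(self):
        s1 = models.PartitionStep(["PlGF"], "down", 0.0)
        s2 = models.PartitionStep(["DLG"], "up", 1.0)
        return models.PartitionModel([s1, s2], "rule-in", 0.05)

    def test_truth_table(self):
        t = pd.DataFrame(
            {
                "PlGF": [-1.0, -1.0, 1.0, 1.0, 0.0, 2.0, -5.0, 3.0],
                "DLG": [2.0, 0.0, 2.0, 0.0, 5.0, 0.5, 0.9, 1.0],
            }
        )
        pred = self._model().predict(t)
        # hand-traced: PlGF <= 0 exits at step 1; else DLG >= 1 exits at step 2
        assert pred["flag"].tolist() == [1, 1, 1, 0, 1, 0, 1, 1]
        assert pred["step"].tolist() == [1, 1, 2, 0, 1, 0, 1, 2]

    def test_short_circuit_ignores_later_steps(self):
        t = pd.DataFrame({"PlGF": [-1.0], "DLG": [-99.0]})
        pred = self._model().predict(t)
        assert pred["flag"].iloc[0] == 1 and pred["step"].iloc[0] == 1

    def test_missing_predictor_unclassifiable(self):
        t = pd.DataFrame({"PlGF": [np.nan, 1.0], "DLG": [1.0, 2.0]})
        pred = self._model().predict(t)
        assert np.isnan(pred["flag"].iloc[0]) and pred["step"].iloc[0] == -1
        with pytest.raises(DataError):
            self._model().flags(t)


class TestEnumerate:
    def test_combination_count(self):
        pool = ["PlGF", "DLG", "1-HGP", "MAP", "BMI"]
        suite = models.enumerate_models(pool, methods=("score",))
        assert len(suite) == 25  # C(5,1)+C(5,2)+C(5,3)

    def test_partition_requires_plgf(self):
        suite = models.enumerate_models(["DLG", "MAP"], methods=("partition",))
        assert suite == []

    def test_comparator_tagging(self):
        suite = models.enumerate_models(["PlGF", "MAP", "BMI", "DLG"], methods=("score",))
        by_name = {s.name: s for s in suite}
        assert by_name["PlGF+MAP"].comparator
        assert not by_name["PlGF+DLG"].comparator

    def test_named_headline_suite_has_eight_models(self):
        assert len(models.table3_models()) == 8


class TestOptimismUnderPermutedLabels:
    def test_held_out_ppv_near_prevalence(self, model_matrix):
        """Cut-offs tuned on permuted labels carry no signal to new data."""
        m = model_matrix
        w = m["weight"].to_numpy()
        labels = (m["outcome"] == "preterm_pe").to_numpy()
        rng = np.random.default_rng(10)
        half = len(m) // 2
        heldout_ppvs = []
        null_prevs = []
        for _ in range(15):
            perm = rng.permutation(labels)
            mod = models.build_partition_model(
                m.iloc[:half], perm[:half], "rule-in", [["PlGF"], ["DLG"]],
                weights=w[:half], pv_target=0.05,
            )
            if not mod.feasible:
                continue
            fl = mod.flags(m.iloc[half:])
            tp = w[half:][fl & perm[half:]].sum()
            fp = w[half:][fl & ~perm[half:]].sum()
            if tp + fp > 0:
                heldout_ppvs.append(tp / (tp + fp))
                # null reference: weighted prevalence of the permuted labels
                null_prevs.append(w[half:][perm[half:]].sum() / w[half:].sum())
        if heldout_ppvs:  # permuted fits are often infeasible, which is itself honest
            assert abs(np.mean(heldout_ppvs) - np.mean(null_prevs)) < 0.04
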