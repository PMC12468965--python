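"""Confusion-matrix metrics, grouped splits, curves, and bootstrap CIs."""

import numpy as np
import pandas as pd
import pytest

from pleuradx.evaluation import (ConfusionMatrix, bootstrap_ci,
                                 calibration_bins, check_no_leakage,
                                 confusion, decision_curve,
                                 evaluate_predictions, grouped_split,
                                 macro_metrics, roc_pr_curves)


def brute_force_metrics(cm):
    """Independent evaluation of the five confusion-matrix formulas."""
    tp, tn, fp, fn = cm.tp, cm.tn, cm.fp, cm.fn

    def div(a, b):
        return a / b if b else 0.0

    return {
        "se": div(tp, fn + tp),
        "sp": div(tn, fp + tn),
        "pre": div(tp, fp + tp),
        "f_scr": div(2 * tp, 2 * tp + fn + fp),
        "acc": div(tn + tp, tn + tp + fn + fp),
    }


class TestConfusion:
    def test_all_correct(self):
        y = ["p"] * 5 + ["n"] * 5
        cm = confusion(y, y, "p")
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (5, 5, 0, 0)

    def test_all_inverted(self):
        y = ["p"] * 5 + ["n"] * 5
        pred = ["n"] * 5 + ["p"] * 5
        cm = confusion(y, pred, "p")
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (0, 0, 5, 5)

    def test_matches_pairwise_counting(self, rng):
        y = rng.choice(["p", "n"], 50).tolist()
        pred = rng.choice(["p", "n"], 50).tolist()
        cm = confusion(y, pred, "p")
        assert cm.tp == sum(t == "p" and q == "p" for t, q in zip(y, pred))
        assert cm.fn == sum(t == "p" and q == "n" for t, q in zip(y, pred))
        assert cm.fp == sum(t == "n" and q == "p" for t, q in zip(y, pred))
        assert cm.total == 50

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion(["p"], [], "p")


class TestMacroMetrics:
    def test_perfect_predictions(self):
        cms = {"a": ConfusionMatrix(tp=5, tn=5),
               "b": ConfusionMatrix(tp=5, tn=5)}
        rep = macro_metrics(cms)
        assert all(v == 1.0 for v in rep.macro.values())

    def test_worked_example(self):
        rep = macro_metrics([ConfusionMatrix(tp=3, fn=1, fp=0, tn=4)])
        vals = rep.per_class[0]
        assert vals["se"] == 0.75
        assert vals["sp"] == 1.0
        assert vals["pre"] == 1.0
        assert vals["f_scr"] == pytest.approx(6 / 7)
        assert vals["acc"] == 0.875

    def test_symmetric_matrices_equal_macro(self):
        cm = ConfusionMatrix(tp=4, tn=4, fp=1, fn=1)
        rep = macro_metrics({"a": cm, "b": cm})
        assert rep.macro == rep.per_class["a"]

    def test_against_brute_force_on_random_matrices(self, rng):
        for _ in range(100):
            cm = ConfusionMatrix(*(int(v) for v in rng.integers(0, 30, 4)))
            rep = macro_metrics([cm])
            expected = brute_force_metrics(cm)
            for k, v in expected.items():
                assert abs(rep.per_class[0][k] - v) < 1e-12

    def test_zero_denominator_warns_not_raises(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING):
            rep = macro_metrics([ConfusionMatrix(tp=0, fn=0, fp=0, tn=5)])
        assert rep.per_class[0]["se"] == 0.0
        assert any("zero denominator" in r.message for r in caplog.records)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            macro_metrics({})


def _table(n_per_class=10, slices=3):
    rows = []
    for cls in ("pos", "neg"):
        for p in range(n_per_class):
            for s in range(slices):
                rows.append((f"{cls}{p}_s{s}", f"{cls}{p}", cls))
    return pd.DataFrame(rows, columns=["image_id", "patient_id", "label"])


class TestGroupedSplit:
    def test_holdout_patient_arithmetic(self):
        df = _table(10)
        plan = grouped_split(df, "holdout", 0.7, seed=1)
        pat = dict(zip(df.image_id, df.patient_id))
        train_p = {pat[i] for i in plan.train_ids}
        test_p = {pat[i] for i in plan.test_ids}
        assert not train_p & test_p
        for cls in ("pos", "neg"):
            assert sum(p.startswith(cls) for p in train_p) == 7
            assert sum(p.startswith(cls) for p in test_p) == 3
        check_no_leakage(plan, df)

    def test_kfold_partition(self):
        df = _table(10)
        plan = grouped_split(df, "kfold", 5, seed=2)
        assert len(plan.folds) == 5
        all_test = [i for _, te in plan.folds for i in te]
        assert sorted(all_test) == sorted(df.image_id)
        pat = dict(zip(df.image_id, df.patient_id))
        for _, te in plan.folds:
            test_p = {pat[i] for i in te}
            assert sum(p.startswith("pos") for p in test_p) == 2
            assert sum(p.startswith("neg") for p in test_p) == 2
        check_no_leakage(plan, df)

    def test_too_few_patients_raises(self):
        with pytest.raises(ValueError):
            grouped_split(_table(3), "kfold", 5, seed=0)

    def test_mixed_label_patient_rejected(self):
        df = _table(4)
        df.loc[0, "label"] = "neg"
        with pytest.raises(ValueError):
            grouped_split(df, "holdout", 0.7, seed=0)

    def test_deterministic(self):
        df = _table(8)
        a = grouped_split(df, "holdout", 0.7, seed=9)
        b = grouped_split(df, "holdout", 0.7, seed=9)
        assert a.train_ids == b.train_ids and a.test_ids == b.test_ids


class TestCurves:
    def test_perfect_and_tied_scores(self):
        y = [0, 0, 1, 1]
        assert roc_pr_curves(y, [0.1, 0.2, 0.8, 0.9])["auc"] == 1.0
        assert roc_pr_curves(y, [0.5] * 4)["auc"] == 0.5

    def test_auc_matches_concordant_pair_fraction(self, rng):
        y = np.array([0] * 10 + [1] * 10)
        s = rng.normal(size=20)
        res = roc_pr_curves(y, s)
        pos, neg = s[y == 1], s[y == 0]
        conc = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert res["auc"] == pytest.approx(conc / 100.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_pr_curves([1, 1, 1], [0.1, 0.5, 0.9])


class TestCalibration:
    def test_constant_half_probability(self):
        tab = calibration_bins([0, 1] * 10, [0.5] * 20)
        occupied = tab[tab["count"] > 0]
        assert len(occupied) == 1
        row = occupied.iloc[0]
        assert row["observed_frequency"] == pytest.approx(0.5)
        assert abs(row["mean_predicted"] - row["observed_frequency"]) < 1e-12

    def test_oracle_probabilities(self):
        y = [0] * 5 + [1] * 5
        tab = calibration_bins(y, [0.0] * 5 + [1.0] * 5)
        occ = tab[tab["count"] > 0]
        assert len(occ) == 2
        assert np.allclose(occ["mean_predicted"], occ["observed_frequency"])

    def test_matches_brute_force_bins(self, rng):
        y = rng.integers(0, 2, 200)
        p = rng.uniform(0, 1, 200)
        tab = calibration_bins(y, p, n_bins=10)
        for b in range(10):
            lo, hi = b / 10, (b + 1) / 10
            sel = (p >= lo) & (p < hi) if b < 9 else (p >= lo) & (p <= hi)
            if sel.sum():
                assert tab.loc[b, "mean_predicted"] == \
                    pytest.approx(p[sel].mean())
                assert tab.loc[b, "observed_frequency"] == \
                    pytest.approx(y[sel].mean())

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            calibration_bins([1], [1.2])


class TestDecisionCurve:
    def test_treat_none_is_zero_and_boundaries_excluded(self):
        tab = decision_curve([0, 1] * 5, [0.6] * 10, [0.0, 0.3, 1.0])
        assert len(tab) == 1
        assert (tab["net_benefit_treat_none"] == 0).all()

    def test_symmetric_cancellation(self):
        # everyone predicted positive, prevalence 0.5, pt = 0.5 -> NB = 0
        tab = decision_curve([0, 1] * 10, [0.9] * 20, [0.5])
        assert tab["net_benefit_model"].iloc[0] == pytest.approx(0.0)
        assert tab["net_benefit_treat_all"].iloc[0] == pytest.approx(0.0)

    def test_formula_example(self):
        # TP=50, FP=10, N=100 at pt=0.1
        y = [1] * 50 + [0] * 10 + [0] * 40
        p = [0.9] * 60 + [0.01] * 40
        tab = decision_curve(y, p, [0.1])
        assert tab["net_benefit_model"].iloc[0] == \
            pytest.approx(0.5 - 0.1 * (0.1 / 0.9))


class TestBootstrap:
    def test_constant_metric_zero_width(self):
        lo, hi = bootstrap_ci(lambda t, p: 1.0, np.zeros(50), np.zeros(50),
                              b=200, seed=0)
        assert lo == hi == 1.0

    def test_seeded_determinism(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 100)
        p = rng.integers(0, 2, 100)
        acc = lambda t, q: float(np.mean(t == q))  # noqa: E731
        assert bootstrap_ci(acc, y, p, b=300, seed=7) == \
            bootstrap_ci(acc, y, p, b=300, seed=7)

    def test_small_b_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci(lambda t, p: 1.0, np.zeros(5), np.zeros(5), b=50)

    def test_coverage_of_true_accuracy(self):
        """95% percentile intervals cover the true accuracy of a
        Bernoulli(0.8) predictor at n=200 close to nominally."""
        rng = np.random.default_rng(11)
        acc = lambda t, q: float(np.mean(t == q))  # noqa: E731
        hits = 0
        reps = 150
        for r in range(reps):
            y = np.zeros(200, dtype=int)
            pred = (rng.uniform(size=200) > 0.8).astype(int)
            lo, hi = bootstrap_ci(acc, y, pred, b=200, seed=r)
            hits += lo <= 0.8 <= hi
        assert 0.88 <= hits / reps <= 1.0


class TestEvaluatePredictions:
    def test_full_report_assembly(self, rng):
        y = ["pos"] * 30 + ["neg"] * 30
        scores = np.concatenate([rng.normal(1, 0.5, 30),
                                 rng.normal(-1, 0.5, 30)])
        probs = 1 / (1 + np.exp(-scores))
        pred = np.where(probs > 0.5, "pos", "neg").tolist()
        rep = evaluate_predictions(y, pred, scores=scores, probs=probs,
                                   positive_label="pos", bootstrap=150)
        assert 0 <= rep.macro["acc"] <= 1
        assert rep.auc is not None and rep.auc > 0.9
        assert "acc" in rep.confidence_intervals
        assert "decision" in rep.curves and "calibration" in rep.curves
        d = rep.to_dict()
        assert isinstance(d["macro"]["acc"], float)

    def test_per_fold_matrices_sum_to_pooled(self, rng):
        folds = []
        all_t, all_p = [], []
        for _ in range(4):
            t = rng.choice(["pos", "neg"], 30).tolist()
            p = rng.choice(["pos", "neg"], 30).tolist()
            folds.append(confusion(t, p, "pos"))
            all_t.extend(t)
            all_p.extend(p)
        pooled = confusion(all_t, all_p, "pos")
        summed = folds[0]
        for f in folds[1:]:
            summed = summed + f
        assert vars(summed) == vars(pooled)
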