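import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from compoda.benchmark import (
    PowerModel,
    aggregate_records,
    alr_ttest,
    classification_metrics,
    fit_power_model,
    pooled_roc_pr,
    records_frame,
    required_sample_size,
    roc_pr,
    run_grid,
)
from compoda.datacore import apply_zero_pseudocount
from compoda.simulate import SimulationConfig, generate_dataset


class TestClassificationMetrics:
    def test_perfect_agreement(self):
        t = np.array([1, 0, 0, 1, 0], dtype=bool)
        assert classification_metrics(t, t) == (1.0, 1.0, 0.0)

    def test_no_discoveries_convention(self):
        t = np.array([1, 0, 1], dtype=bool)
        d = np.zeros(3, dtype=bool)
        assert classification_metrics(t, d) == (0.0, 0.0, 0.0)

    def test_mixed_confusion_matrix(self):
        truth = np.array([1, 1, 0, 0, 0], dtype=bool)      # TP=1, FN=1, FP=1, TN=2
        decision = np.array([1, 0, 1, 0, 0], dtype=bool)
        mcc, tpr, fdr = classification_metrics(truth, decision)
        assert mcc == pytest.approx(1 / 6)
        assert tpr == pytest.approx(0.5)
        assert fdr == pytest.approx(0.5)

    def test_mcc_symmetric_under_label_swap(self, rng):
        for _ in range(20):
            t = rng.uniform(size=8) > 0.5
            d = rng.uniform(size=8) > 0.5
            mcc1, _, _ = classification_metrics(t, d)
            mcc2, _, _ = classification_metrics(~t, ~d)
            assert mcc1 == pytest.approx(mcc2)


class TestRocPr:
    def test_perfect_separation(self):
        auc, ap = roc_pr([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0 and ap == 1.0

    def test_constant_scores_give_half_auc(self):
        auc, _ = roc_pr([0.5] * 6, [1, 0, 1, 0, 0, 1])
        assert auc == pytest.approx(0.5)

    def test_six_item_worked_set_matches_enumeration(self):
        scores = np.array([0.9, 0.8, 0.7, 0.6, 0.5, 0.4])
        truth = np.array([1, 1, 0, 1, 0, 0], dtype=bool)
        auc, ap = roc_pr(scores, truth)
        # brute-force over all thresholds (one per distinct score)
        pts = []
        for c in np.concatenate([[np.inf], np.sort(scores)[::-1]]):
            called = scores >= c
            tp, fp = (called & truth).sum(), (called & ~truth).sum()
            pts.append((fp / 3, tp / 3, tp / max(called.sum(), 1)))
        auc_bf = np.trapezoid([p[1] for p in pts], [p[0] for p in pts])
        recalls = np.array([p[1] for p in pts])
        precisions = np.array([p[2] for p in pts])
        ap_bf = np.sum(np.diff(recalls) * precisions[1:])
        assert auc == pytest.approx(auc_bf)
        assert ap == pytest.approx(ap_bf)

    def test_auc_equals_normalized_mannwhitney(self, rng):
        for _ in range(10):
            truth = np.concatenate([np.ones(6, bool), np.zeros(9, bool)])
            scores = rng.standard_normal(15)
            auc, _ = roc_pr(scores, truth)
            u = mannwhitneyu(scores[truth], scores[~truth]).statistic
            assert auc == pytest.approx(u / (6 * 9))

    def test_degenerate_truth_rejected(self):
        with pytest.raises(ValueError):
            roc_pr([0.1, 0.2], [1, 1])


class TestAlrTtest:
    def _sim(self, effect, seed):
        cfg = SimulationConfig(n_cell_types=5, n_control=5, n_case=5, total=5000,
                               base_count=1000.0, effect=effect, seed=seed)
        return generate_dataset(cfg)

    def test_reference_coordinate_never_called(self):
        ds, _ = self._sim(500.0, 1)
        decisions, scores = alr_ttest(ds, reference=4)
        assert not decisions[4] and scores[4] == 0.0
        assert decisions.shape == (5,)

    def test_identical_groups_yield_no_rejections(self):
        counts = np.tile([100.0, 200.0, 300.0], (6, 1))
        from compoda.datacore import CompositionalDataset
        ds = CompositionalDataset(
            counts=counts, sample_ids=[f"s{i}" for i in range(6)],
            cell_types=list("abc"),
            covariates=np.array([0.0] * 3 + [1.0] * 3)[:, None],
            covariate_names=["condition"],
        )
        decisions, _ = alr_ttest(ds, reference=2)
        assert not decisions.any()

    def test_single_sample_groups_flagged_negative(self):
        ds, _ = generate_dataset(SimulationConfig(
            n_cell_types=5, n_control=1, n_case=1, total=5000, effect=2000.0, seed=2))
        decisions, scores = alr_ttest(ds, reference=4)
        assert not decisions.any() and not scores.any()

    def test_strong_effect_detected_in_most_seeds(self):
        hits = 0
        for i in range(20):
            ds, truth = self._sim(2000.0, 300 + i)
            decisions, _ = alr_ttest(ds, reference=4)
            hits += bool(decisions[0])
        assert hits >= 18


class TestRunGrid:
    def _configs(self):
        return [SimulationConfig(n_cell_types=5, n_control=3, n_case=3, total=5000,
                                 base_count=1000.0, effect=(0.0, 1000.0), seed=s)
                for s in (11, 22, 33)]

    def test_cardinality_and_config_echo(self):
        records = run_grid(self._configs(), method="alr_ttest")
        assert len(records) == 3
        assert [r.config.seed for r in records] == [11, 22, 33]

    def test_aggregate_equals_hand_average(self):
        records = run_grid(self._configs(), method="alr_ttest")
        agg = aggregate_records(records)
        assert agg.loc[0, "mcc"] == pytest.approx(np.mean([r.mcc for r in records]))

    def test_degenerate_grid_cell_flagged_failed(self):
        bad = SimulationConfig(n_cell_types=5, n_control=2, n_case=2, total=5000,
                               base_count=1000.0, effect=(1000.0, 2000.0), seed=1)
        records = run_grid([bad], method="alr_ttest")
        assert records[0].failed and "generation" in records[0].note
        assert aggregate_records(records).empty

    def test_pooling_excludes_single_sample_groups(self):
        configs = self._configs() + [SimulationConfig(
            n_cell_types=5, n_control=1, n_case=1, total=5000,
            base_count=1000.0, effect=(0.0, 1000.0), seed=44)]
        records = run_grid(configs, method="alr_ttest")
        scores, truth = [], []
        for r in records[:3]:
            scores.append(r.score)
            truth.append(r.truth)
        expected = roc_pr(np.concatenate(scores), np.concatenate(truth))
        assert pooled_roc_pr(records, min_group_size=2) == expected


class TestPowerModel:
    def _synthetic_frame(self, coefs, rng, n=120):
        x_ss = rng.uniform(np.log(2), np.log(20), n)
        x_fc = rng.uniform(0.1, 3.0, n)
        x_cc = rng.uniform(np.log(10), np.log(1000), n)
        lin = (coefs[0] + coefs[1] * x_ss + coefs[2] * x_fc
               + coefs[3] * x_fc * x_cc + coefs[4] * x_ss * x_cc)
        return pd.DataFrame({"tpr": np.exp(lin), "x_ss": x_ss, "x_fc": x_fc,
                             "x_cc": x_cc})

    def test_parameter_recovery_from_exact_link_data(self, rng):
        coefs = np.array([-2.0, 0.25, 0.2, 0.01, 0.02])
        frame = self._synthetic_frame(coefs, rng)
        assert (frame["tpr"] < 1).all()
        model = fit_power_model(frame)
        np.testing.assert_allclose(model.coefficients, coefs, atol=1e-3)

    def test_constant_tpr_gives_zero_slopes(self, rng):
        frame = self._synthetic_frame(np.array([-1.5, 0, 0, 0, 0]), rng)
        model = fit_power_model(frame)
        np.testing.assert_allclose(model.coefficients[1:], 0.0, atol=1e-6)
        assert model.intercept == pytest.approx(-1.5, abs=1e-6)

    def test_design_has_five_columns(self, rng):
        frame = self._synthetic_frame(np.array([-2.0, 0.3, 0.1, 0.0, 0.01]), rng)
        model = fit_power_model(frame)
        assert model.result.params.shape == (5,)

    def test_too_few_points_rejected(self):
        frame = pd.DataFrame({"tpr": [0.5] * 5, "x_ss": [1.0] * 5,
                              "x_fc": [1.0] * 5, "x_cc": [1.0] * 5})
        with pytest.raises(ValueError):
            fit_power_model(frame)


class TestRequiredSampleSize:
    def test_pure_slope_model_inverts_link(self):
        model = PowerModel(intercept=0.0, b_ss=1.0, b_fc=0.0, b_fc_cc=0.0, b_ss_cc=0.0)
        assert required_sample_size(model, 0.8, 1.0, 1.0) == pytest.approx(np.log(0.8))

    def test_round_trip_for_random_coefficients(self, rng):
        for _ in range(100):
            coefs = rng.standard_normal(5)
            if abs(coefs[1] + coefs[4] * 2.0) < 1e-3:
                continue
            model = PowerModel(intercept=coefs[0], b_ss=coefs[1], b_fc=coefs[2],
                               b_fc_cc=coefs[3], b_ss_cc=coefs[4])
            target = rng.uniform(0.1, 0.95)
            x_ss = required_sample_size(model, target, x_fc=1.5, x_cc=2.0)
            assert model.predict_tpr(x_ss, 1.5, 2.0) == pytest.approx(target, abs=1e-10)

    def test_zero_denominator_rejected(self):
        model = PowerModel(intercept=0.0, b_ss=0.0, b_fc=0.1, b_fc_cc=0.0, b_ss_cc=0.0)
        with pytest.raises(ZeroDivisionError):
            required_sample_size(model, 0.8, 1.0, 1.0)
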