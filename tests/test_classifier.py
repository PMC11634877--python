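"""Random-forest classifier, ROC/Youden cutoff, bulk and single-cell calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import brute_force_youden
from ovuln.classifier import (
    BRCAnessClassifier,
    ROCRecord,
    classify_bulk,
    classify_single_cell_sample,
    load_model,
    save_model,
    train_model,
    youden_cutoff,
)
from ovuln.matrix import ExpressionMatrix
from ovuln.simulate import CohortSpec, generate_cohort


class TestYoudenCutoff:
    def test_worked_example(self):
        y = [True, True, True, False, False, False]
        s = [0.9, 0.8, 0.4, 0.7, 0.3, 0.2]
        roc = ROCRecord.from_scores(y, s)
        expected_t, expected_j = brute_force_youden(y, s)
        got = youden_cutoff(roc)
        assert got == pytest.approx(expected_t)
        i = int(np.flatnonzero(roc.thresholds == got)[0])
        assert roc.sensitivities[i] + roc.specificities[i] - 1 == pytest.approx(expected_j)

    def test_perfect_separation_lowest_tie(self):
        y = [True, True, False, False]
        s = [0.8, 0.9, 0.1, 0.2]
        # J = 1 anywhere in the gap; the lowest candidate threshold is 0.2
        assert youden_cutoff(ROCRecord.from_scores(y, s)) == pytest.approx(0.2)

    def test_degenerate_equal_scores(self):
        y = [True, False, True, False]
        s = [0.5, 0.5, 0.5, 0.5]
        assert youden_cutoff(ROCRecord.from_scores(y, s)) == pytest.approx(0.5)

    def test_empty_scores_rejected(self):
        with pytest.raises(ValueError):
            ROCRecord.from_scores([], [])

    @given(st.data())
    @settings(derandomize=True, max_examples=100)
    def test_matches_brute_force_on_random_rocs(self, data):
        n_pos = data.draw(st.integers(2, 12))
        n_neg = data.draw(st.integers(2, 12))
        scores = data.draw(
            st.lists(
                st.floats(0, 1, allow_nan=False),
                min_size=n_pos + n_neg, max_size=n_pos + n_neg,
            )
        )
        y = [True] * n_pos + [False] * n_neg
        expected_t, _ = brute_force_youden(y, scores)
        assert youden_cutoff(ROCRecord.from_scores(y, scores)) == pytest.approx(expected_t)


class TestTraining:
    def test_separable_cohort_high_auc(self, small_cohort, trained_model):
        assert trained_model.cv_auc_mean_ >= 0.99
        assert 0 < trained_model.cutoff_ < 1

    def test_determinism_same_seed(self, small_cohort):
        genes = [g for g in small_cohort.expr.gene_ids if g.startswith("DEG")]
        kwargs = dict(n_folds=5, seed=7, n_estimators=50)
        a = train_model(small_cohort.expr, small_cohort.labels, genes, **kwargs)
        b = train_model(small_cohort.expr, small_cohort.labels, genes, **kwargs)
        assert a.cv_auc_mean_ == b.cv_auc_mean_
        assert a.cutoff_ == b.cutoff_
        np.testing.assert_array_equal(
            a.brcaness_probability(small_cohort.expr.values[: len(genes)].T),
            b.brcaness_probability(small_cohort.expr.values[: len(genes)].T),
        )

    def test_small_class_rejected_with_fold_message(self):
        cohort = generate_cohort(
            CohortSpec(n_samples=30, n_genes=50, n_informative=5, class_fraction=0.2, seed=8)
        )
        genes = cohort.informative_genes
        with pytest.raises(ValueError, match="n_folds"):
            train_model(cohort.expr, cohort.labels, genes, n_folds=20, seed=0)

    def test_fixed_cutoff_override(self, small_cohort):
        genes = [g for g in small_cohort.expr.gene_ids if g.startswith("DEG")]
        m = train_model(
            small_cohort.expr, small_cohort.labels, genes,
            n_folds=5, seed=1, cutoff=0.5266, n_estimators=30,
        )
        assert m.cutoff_ == 0.5266

    def test_save_load_round_trip(self, trained_model, small_cohort, tmp_path):
        path = tmp_path / "model.ovuln"
        save_model(trained_model, path)
        back = load_model(path)
        a = classify_bulk(trained_model, small_cohort.expr)
        b = classify_bulk(back, small_cohort.expr)
        pd.testing.assert_frame_equal(a, b)


class TestClassifyBulk:
    def test_label_is_strict_step_function_of_probability(self, trained_model, monkeypatch):
        grid = np.round(np.arange(0.0, 1.0001, 0.0001), 4)
        monkeypatch.setattr(trained_model, "cutoff_", 0.5266)
        monkeypatch.setattr(
            type(trained_model), "brcaness_probability", lambda self, X: grid
        )
        genes = [str(g) for g in trained_model.feature_names_in_]
        expr = ExpressionMatrix(
            pd.DataFrame(
                np.zeros((len(genes), grid.size)),
                index=genes,
                columns=[f"P{i}" for i in range(grid.size)],
            ),
            "log2tpm1",
        )
        out = classify_bulk(trained_model, expr)
        neg = out.loc[out["brcaness_label"] == "noBRCAness", "brcaness_probability"]
        assert neg.max() == pytest.approx(0.5266)  # exactly-at-cutoff is negative
        pos = out.loc[out["brcaness_label"] == "BRCAness", "brcaness_probability"]
        assert pos.min() > 0.5266

    def test_training_samples_classified_correctly(self, trained_model, small_cohort):
        out = classify_bulk(trained_model, small_cohort.expr)
        truth = small_cohort.classes
        agree = (out["brcaness_label"] == truth).mean()
        assert agree >= 0.95

    def test_missing_signature_gene_errors(self, trained_model, small_cohort):
        reduced = small_cohort.expr.subset_genes(small_cohort.expr.gene_ids[1:])
        with pytest.raises(KeyError, match="missing"):
            classify_bulk(trained_model, reduced)

    def test_impute_zero_warns(self, trained_model, small_cohort):
        reduced = small_cohort.expr.subset_genes(small_cohort.expr.gene_ids[1:])
        with pytest.warns(UserWarning, match="imputing"):
            out = classify_bulk(trained_model, reduced, impute_missing="zero")
        assert len(out) == small_cohort.expr.n_samples


class TestSingleCell:
    def _stub_model(self, trained_model, monkeypatch, probs):
        monkeypatch.setattr(
            type(trained_model), "brcaness_probability", lambda self, X: np.asarray(probs)
        )
        return trained_model

    def _cells(self, trained_model, n, sample="SA"):
        genes = [str(g) for g in trained_model.feature_names_in_]
        expr = ExpressionMatrix(
            pd.DataFrame(
                np.zeros((len(genes), n)), index=genes,
                columns=[f"{sample}_c{i}" for i in range(n)],
            ),
            "log2tpm1",
        )
        return expr, {f"{sample}_c{i}": sample for i in range(n)}

    def test_majority_positive(self, trained_model, monkeypatch):
        expr, mapping = self._cells(trained_model, 10)
        m = self._stub_model(trained_model, monkeypatch, [0.9] * 6 + [0.1] * 4)
        out = classify_single_cell_sample(m, expr, mapping)
        assert out.loc["SA", "brcaness_label"] == "BRCAness"

    def test_exact_half_is_negative(self, trained_model, monkeypatch):
        expr, mapping = self._cells(trained_model, 10)
        m = self._stub_model(trained_model, monkeypatch, [0.9] * 5 + [0.1] * 5)
        out = classify_single_cell_sample(m, expr, mapping)
        assert out.loc["SA", "brcaness_label"] == "noBRCAness"

    def test_cell_cutoff_strict(self, trained_model, monkeypatch):
        expr, mapping = self._cells(trained_model, 3)
        m = self._stub_model(trained_model, monkeypatch, [0.45, 0.45, 0.45])
        out = classify_single_cell_sample(m, expr, mapping, cell_cutoff=0.45)
        assert out.loc["SA", "n_brcaness_cells"] == 0

    def test_unmapped_cell_rejected(self, trained_model):
        expr, mapping = self._cells(trained_model, 3)
        del mapping["SA_c0"]
        with pytest.raises(ValueError, match="no sample assignment"):
            classify_single_cell_sample(trained_model, expr, mapping)
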