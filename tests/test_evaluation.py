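"""LOSO evaluation, Cohen's d, model summaries, importance aggregation."""

import numpy as np
import pandas as pd
import pytest

from eegflavor import search
from eegflavor.dataset import FeatureTable
from eegflavor.evaluation import (
    CVResult,
    EffectSize,
    ModelResult,
    SearchSpace,
    aggregate_importance,
    antilog_mae,
    bayes_optimize,
    cohens_d,
    cv_mae,
    loso_splits,
    summarize_models,
)
from eegflavor.models import LSBoostHyperParams


def _table(y_by_subject, trials=1, n_feats=3, seed=0):
    rng = np.random.default_rng(seed)
    sids = list(y_by_subject)
    meta = pd.DataFrame(
        {
            "subject_id": np.repeat(sids, trials),
            "phase": "Be",
            "trial": np.tile(np.arange(1, trials + 1), len(sids)),
        }
    )
    X = pd.DataFrame(
        rng.normal(size=(len(sids) * trials, n_feats)),
        columns=[f"f{i}" for i in range(n_feats)],
    )
    y = pd.DataFrame({"bitter": np.repeat([y_by_subject[s] for s in sids], trials)})
    return FeatureTable(meta=meta, X=X, y=y, tag="Be")


class TestLosoSplits:
    def test_partition_property(self):
        ids = [f"S{i}" for i in range(15) for _ in range(4)]
        splits = loso_splits(ids)
        assert len(splits) == 15
        tested = [test for _, test in splits]
        assert sorted(tested) == sorted(set(ids))
        for train, test in splits:
            assert test not in train
            assert set(train) | {test} == set(ids)
            # the study design: 14 training subjects × 4 trials = 56 rows
            assert sum(ids.count(s) for s in train) == 56

    def test_duplicates_keyed_by_subject(self):
        splits = loso_splits(["a", "a", "a", "b"])
        assert len(splits) == 2

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError, match="2 distinct subjects"):
            loso_splits(["only", "only"])


class TestCvMae:
    def test_mean_benchmark_constant_targets(self):
        table = _table({"a": 2.0, "b": 2.0, "c": 2.0}, trials=2)
        result = cv_mae("mean", table, "bitter")
        assert np.allclose(result.fold_maes, 0.0)
        assert result.n_folds == 3

    def test_mean_benchmark_hand_enumerated(self):
        """Targets 1, 2, 3 per subject: fold errors are |mean(rest) − y|."""
        table = _table({"a": 1.0, "b": 2.0, "c": 3.0}, trials=1)
        result = cv_mae("mean", table, "bitter")
        assert result.fold_maes == pytest.approx([1.5, 0.0, 1.5])
        assert result.mean == pytest.approx(1.0)

    def test_fold_maes_invariant_to_trial_order(self, rng):
        table = _table({"a": 1.0, "b": 2.0, "c": 3.0, "d": 1.5}, trials=3, seed=4)
        # shuffle rows within each subject
        order = np.arange(table.n_rows)
        for sid in ("a", "b", "c", "d"):
            rows = table.rows_of(sid)
            order[rows] = rng.permutation(order[rows])
        shuffled = FeatureTable(
            meta=table.meta.iloc[order].reset_index(drop=True),
            X=table.X.iloc[order].reset_index(drop=True),
            y=table.y.iloc[order].reset_index(drop=True),
            tag="Be",
        )
        hp = LSBoostHyperParams(n=5, rho=0.5, leaf_size=1, max_splits=3)
        for kind in ("mean", "lsboost"):
            a = cv_mae(kind, table, "bitter", seed=0, hp=hp)
            b = cv_mae(kind, shuffled, "bitter", seed=0, hp=hp)
            assert a.fold_maes == pytest.approx(b.fold_maes)

    def test_unknown_target_rejected(self):
        table = _table({"a": 1.0, "b": 2.0})
        with pytest.raises(KeyError, match="sweet"):
            cv_mae("mean", table, "sweet")


class TestCohensD:
    def test_identical_samples_zero(self):
        es = cohens_d([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert es.d == 0.0
        assert not es.significant

    def test_published_cell_arithmetic(self):
        """Summary stats 0.604±0.165 vs 0.459±0.178 give d ≈ 0.845."""
        es = cohens_d((0.604, 0.165), (0.459, 0.178), n_folds=15)
        assert es.d == pytest.approx(0.8449, abs=5e-4)
        assert es.d == pytest.approx(0.844, abs=1e-3)  # printed value
        assert es.significant  # CI excludes zero at 15 folds

    def test_antisymmetry(self, rng):
        a, b = rng.random(10), rng.random(10) + 0.3
        assert cohens_d(a, b).d == pytest.approx(-cohens_d(b, a).d)

    def test_scale_invariance(self, rng):
        a, b = rng.random(10), rng.random(10) + 0.3
        assert cohens_d(3.7 * a, 3.7 * b).d == pytest.approx(cohens_d(a, b).d)

    def test_degenerate_constant_samples(self):
        es = cohens_d([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert es.d == 0.0 and es.ci95 == (0.0, 0.0) and not es.significant

    def test_significance_matches_ci(self):
        es_small = cohens_d((0.50, 0.20), (0.48, 0.20), n_folds=15)
        assert not es_small.significant
        assert es_small.ci95[0] <= 0.0 <= es_small.ci95[1]


class TestAntilog:
    def test_examples(self):
        assert antilog_mae(0.0) == 0.0
        assert antilog_mae(np.log(2.0)) == pytest.approx(1.0)
        assert antilog_mae(0.490) == pytest.approx(0.6323, abs=1e-4)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            antilog_mae(-0.1)


def _result(dataset, target, mae, d_me, d_lr, significant=True):
    ci = (0.1, 2.0) if significant else (-0.5, 2.0)
    return ModelResult(
        dataset=dataset, target=target,
        lsboost=(mae, 0.15), me=(mae + 0.1, 0.15), lr=(mae + 0.1, 0.15),
        d_me=EffectSize(d_me, ci, significant),
        d_lr=EffectSize(d_lr, ci, significant),
    )


class TestSummarize:
    def test_published_aggregates(self):
        """The four significant models' printed per-model statistics
        aggregate to the published overall MAE, anti-log MAE and mean
        d-scores."""
        results = [
            _result("Be", "bitter", 0.490, 1.344, 1.372),
            _result("Be", "sweet", 0.600, 0.651, 0.660),
            _result("Co", "acid", 0.459, 0.844, 0.841),
            _result("BeCo", "astringent", 0.598, 0.595, 0.717),
        ]
        rep = summarize_models(results)
        assert rep.n_significant == 4
        assert rep.overall_mae[0] == pytest.approx(0.537, abs=5e-4)
        assert rep.overall_mae[1] == pytest.approx(0.073, abs=5e-4)
        assert rep.overall_mae_antilog[0] == pytest.approx(0.714, abs=5e-4)
        assert rep.overall_mae_antilog[1] == pytest.approx(0.124, abs=1e-3)
        assert rep.d_me[0] == pytest.approx(0.858, abs=1e-3)
        assert rep.d_me[1] == pytest.approx(0.341, abs=5e-4)
        assert rep.d_lr[0] == pytest.approx(0.897, abs=1e-3)
        assert rep.d_lr[1] == pytest.approx(0.326, abs=1e-3)

    def test_insignificant_models_filtered(self):
        results = [
            _result("Be", "bitter", 0.5, 1.0, 1.0),
            _result("Co", "sweet", 0.4, 0.2, 0.2, significant=False),
        ]
        rep = summarize_models(results)
        assert rep.n_significant == 1
        assert rep.overall_mae[0] == pytest.approx(0.5)

    def test_no_significant_model_flags_empty(self):
        rep = summarize_models([_result("Be", "b", 0.5, 0.1, 0.1, significant=False)])
        assert rep.empty and rep.n_significant == 0


class TestAggregateImportance:
    def _names(self):
        from eegflavor.dataset import feature_names
        from eegflavor.montage import CHANNELS_38

        return feature_names(CHANNELS_38)

    def test_concentrated_importance(self):
        names = self._names()
        imp = np.zeros(len(names))
        imp[names.index("Cz.p_alpha")] = 1.0
        summary = aggregate_importance([("Be", "bitter", imp, names)])
        row = summary.class_table.iloc[0]
        assert row["p_alpha"] == pytest.approx(1.0)
        assert row[["Age", "Group", "p_delta", "A", "M", "C"]].sum() == 0.0
        topo = summary.topography.set_index("channel")["score"]
        assert topo["Cz"] == pytest.approx(1.0)
        assert topo.drop("Cz").sum() == 0.0

    def test_uniform_importance(self):
        names = self._names()
        imp = np.full(len(names), 1.0 / len(names))
        summary = aggregate_importance([("Be", "bitter", imp, names)])
        row = summary.class_table.iloc[0]
        for band in ("p_delta", "p_theta", "p_alpha", "p_beta", "p_gamma",
                     "A", "M", "C"):
            assert row[band] == pytest.approx(38.0 / 306.0)
        assert row["Age"] == pytest.approx(1.0 / 306.0)
        assert row["Group"] == pytest.approx(1.0 / 306.0)

    def test_class_scores_partition_unit_mass(self):
        names = self._names()
        rng = np.random.default_rng(0)
        imp = rng.random(len(names))
        imp /= imp.sum()
        summary = aggregate_importance([("Co", "acid", imp, names)])
        row = summary.class_table.iloc[0].drop(["dataset", "target"])
        assert row.sum() == pytest.approx(1.0, abs=1e-9)

    def test_unnormalized_vector_rejected(self):
        names = self._names()
        with pytest.raises(ValueError, match="not normalized"):
            aggregate_importance([("Be", "bitter", np.ones(len(names)), names)])


class TestBayesOptimizeIntegration:
    def test_degenerate_space_single_evaluation(self):
        table = _table({"a": 1.0, "b": 2.0, "c": 1.5}, trials=4, n_feats=4)
        space = SearchSpace(
            n=(3, 3), rho=(0.5, 0.5), leaf_size=(1, 1), max_splits=(2, 2),
            standardizers=("none",), max_evaluations=1, seed=0,
        )
        best, log = bayes_optimize(table, "bitter", space)
        assert log.n_trials == 1
        assert best == {
            "n": 3, "rho": 0.5, "leaf_size": 1, "max_splits": 2,
            "standardizer": "none",
        }
        assert log.best_value == min(t.value for t in log.trials)
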