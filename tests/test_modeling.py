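"""Outlier gate, ensemble training/normalization contracts, CV behaviour,
and recovery of the configured LVEDP effect by the risk score."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from pulsewave.errors import (ConfigurationError, EmptyStratumError,
                              SchemaError)
from pulsewave.features import featurize_cohort
from pulsewave.modeling import (ModelSpec, cross_validate,
                                default_model_specs, detect_outliers,
                                ensemble_predict, labels_for_spec,
                                train_ensemble)
from pulsewave.synthetic import (CohortConfig, SignalConfig, generate_cohort,
                                 generate_cohort_signals)


def _gaussian_features(n, p=8, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(rng.normal(size=(n, p)),
                        index=[f"S{i:04d}" for i in range(n)],
                        columns=[f"f{j}" for j in range(p)])


class TestOutliers:
    def test_gross_outlier_flagged_duplicate_not(self):
        feats = _gaussian_features(150)
        feats.iloc[0] = 50.0                       # 10x beyond the cohort range
        feats.iloc[1] = feats.iloc[2]              # duplicate of an inlier
        flags = detect_outliers(feats, contamination=0.05, seed=0)
        assert flags.iloc[0]
        assert not flags.iloc[1] and not flags.iloc[2]

    def test_contamination_sets_flag_count(self):
        flags = detect_outliers(_gaussian_features(200), 0.05, seed=1)
        assert abs(int(flags.sum()) - 10) <= 3
        assert detect_outliers(_gaussian_features(200), 0.05, seed=1).equals(flags)

    def test_invalid_contamination(self):
        with pytest.raises(ConfigurationError):
            detect_outliers(_gaussian_features(50), 0.0)
        with pytest.raises(ConfigurationError):
            detect_outliers(_gaussian_features(50), 0.6)

    def test_nonfinite_features_rejected(self):
        feats = _gaussian_features(50)
        feats.iloc[0, 0] = np.nan
        with pytest.raises(SchemaError):
            detect_outliers(feats, 0.05)


class TestSpecs:
    def test_thirteen_default_specs(self):
        specs = default_model_specs([f"f{i}" for i in range(200)], seed=0)
        assert len(specs) == 13
        fam = [s.family for s in specs]
        assert fam.count("random_forest") == 4
        assert fam.count("xgboost") == 5
        assert fam.count("elastic_net") == 4
        for s in specs:
            assert 89 <= len(s.feature_subset) <= 194
            d = s.hyperparameters.get("max_depth")
            if s.family in ("random_forest", "xgboost"):
                assert 3 <= d <= 7

    def test_subset_range_clips_to_narrow_tables(self):
        specs = default_model_specs([f"f{i}" for i in range(20)], seed=0)
        assert all(1 <= len(s.feature_subset) <= 20 for s in specs)

    def test_depth_limit_enforced(self):
        with pytest.raises(ConfigurationError):
            ModelSpec(1, "random_forest", ["f0"], hyperparameters={"max_depth": 9})

    def test_label_thresholds(self):
        subj = pd.DataFrame({"lvedp": [5.0, 14.0, 30.0, 12.0, 25.0]},
                            index=list("abcde"))
        spec = ModelSpec(1, "elastic_net", ["f0"], label_threshold=(25.0, 12.0))
        y = labels_for_spec(subj, spec)
        assert y.to_dict() == {"a": 0, "c": 1, "d": 0, "e": 1}


class TestEnsemble:
    def test_training_aucs_above_chance(self, modeling_cohort):
        subj, feats = modeling_cohort
        model = train_ensemble(feats, subj, seed=0)
        assert len(model.constituents) == 13
        for fc in model.constituents:
            y = labels_for_spec(subj.loc[feats.index], fc.spec)
            out = fc.normalized_output(
                feats.loc[y.index, fc.spec.feature_subset].to_numpy(float))
            assert roc_auc_score(y, out) > 0.5

    def test_deterministic_predictions(self, modeling_cohort):
        subj, feats = modeling_cohort
        tr, te = feats.iloc[:90], feats.iloc[90:]
        p1 = train_ensemble(tr, subj, seed=5).predict(te)
        p2 = train_ensemble(tr, subj, seed=5).predict(te)
        assert p1.equals(p2)
        assert p1.between(0.0, 1.0).all()

    def test_ensemble_equals_mean_of_normalized_outputs(self, modeling_cohort):
        subj, feats = modeling_cohort
        model = train_ensemble(feats, subj, seed=1)
        manual = np.mean([
            fc.normalized_output(feats[fc.spec.feature_subset].to_numpy(float))
            for fc in model.constituents], axis=0)
        assert np.allclose(ensemble_predict(model, feats).to_numpy(), manual)

    def test_missing_feature_column_rejected(self, modeling_cohort):
        subj, feats = modeling_cohort
        model = train_ensemble(feats, subj, seed=2)
        with pytest.raises(SchemaError):
            model.predict(feats.drop(columns=feats.columns[:3]))

    def test_empty_stratum_rejected(self, modeling_cohort):
        subj, feats = modeling_cohort
        low = subj.loc[feats.index, "lvedp"] <= 12
        with pytest.raises(EmptyStratumError):
            train_ensemble(feats.loc[low], subj, seed=0)

    def test_permuted_labels_give_chance_auc(self, modeling_cohort):
        """With lvedp shuffled across subjects, held-out ensemble AUC
        averages to ~0.5 (mean over 5 permutations)."""
        subj, feats = modeling_cohort
        rng = np.random.default_rng(0)
        aucs = []
        for _ in range(5):
            perm = subj.loc[feats.index].copy()
            perm["lvedp"] = rng.permutation(perm["lvedp"].to_numpy())
            tr, te = feats.iloc[::2], feats.iloc[1::2]
            model = train_ensemble(tr, perm, seed=3)
            score = model.predict(te)
            y = (perm.loc[te.index, "lvedp"] >= 25).astype(int)
            aucs.append(roc_auc_score(y, score))
        assert abs(np.mean(aucs) - 0.5) <= 0.08

    def test_ensemble_not_much_worse_than_constituents(self, modeling_cohort):
        """Held-out ensemble AUC >= mean constituent AUC - 0.02."""
        subj, feats = modeling_cohort
        tr, te = feats.iloc[:80], feats.iloc[80:]
        model = train_ensemble(tr, subj, seed=4)
        y = (subj.loc[te.index, "lvedp"] >= 25).astype(int)
        ens_auc = roc_auc_score(y, model.predict(te))
        cons = [roc_auc_score(
            y, fc.normalized_output(te[fc.spec.feature_subset].to_numpy(float)))
            for fc in model.constituents]
        assert ens_auc >= np.mean(cons) - 0.02

    def test_effect_size_drives_heldout_auc_monotonically(self):
        """Scaling all LVEDP effect slopes up from zero increases held-out
        ensemble AUC (Spearman rho > 0.9 over the grid, fixed seeds).

        The noiseless generator has a steep dose-response — at the default
        slopes the score separates the strata perfectly — so the grid spans
        the transition region between chance and saturation.
        """
        from scipy.stats import spearmanr
        cohort_cfg = CohortConfig(stratum_proportions=(0.5, 0.0, 0.5))
        subjects = generate_cohort(90, cohort_cfg, seed=31)
        subj_df = pd.DataFrame(
            [{"subject_id": s.subject_id, "lvedp": s.lvedp} for s in subjects]
        ).set_index("subject_id")
        grid = (0.0, 0.003, 0.01, 1.0)
        aucs = []
        for mult in grid:
            sig = SignalConfig(duration=12.0,
                               atrial_jitter_slope_ms=6.0 * mult,
                               repol_dispersion_slope=0.15 * mult,
                               ppg_base_slope=80.0 * mult)
            records = generate_cohort_signals(subjects, sig, seed=32)
            feats = featurize_cohort(records)
            tr, te = feats.iloc[::2], feats.iloc[1::2]
            model = train_ensemble(tr, subj_df, seed=33)
            y = (subj_df.loc[te.index, "lvedp"] >= 25).astype(int)
            aucs.append(roc_auc_score(y, model.predict(te)))
        assert spearmanr(grid, aucs).statistic > 0.9
        assert aucs[-1] > 0.9


class TestCrossValidate:
    def test_perfect_feature(self):
        n = 100
        rng = np.random.default_rng(0)
        lvedp = np.r_[np.full(n // 2, 8.0), np.full(n // 2, 30.0)]
        feats = pd.DataFrame({
            "good": lvedp + rng.normal(0, 0.1, n),
            "noise": rng.normal(size=n)},
            index=[f"S{i:04d}" for i in range(n)])
        subj = pd.DataFrame({"lvedp": lvedp}, index=feats.index)
        spec = ModelSpec(1, "random_forest", ["good", "noise"],
                         hyperparameters={"max_depth": 3})
        aucs = cross_validate(spec, feats, subj, folds=5, iterations=2, seed=0)
        assert aucs.shape == (10,)
        assert aucs.mean() > 0.99

    def test_pure_noise_features(self):
        n = 200
        rng = np.random.default_rng(1)
        feats = _gaussian_features(n, p=6, seed=1)
        subj = pd.DataFrame(
            {"lvedp": np.where(rng.random(n) < 0.5, 8.0, 30.0)},
            index=feats.index)
        spec = ModelSpec(1, "random_forest", list(feats.columns),
                         hyperparameters={"max_depth": 3})
        aucs = cross_validate(spec, feats, subj, folds=5, iterations=10, seed=2)
        assert 0.42 <= aucs.mean() <= 0.58

    def test_single_iteration_is_plain_kfold(self, modeling_cohort):
        subj, feats = modeling_cohort
        spec = ModelSpec(1, "elastic_net", list(feats.columns[:5]))
        aucs = cross_validate(spec, feats, subj, folds=5, iterations=1, seed=0)
        assert aucs.shape == (5,)
        again = cross_validate(spec, feats, subj, folds=5, iterations=1, seed=0)
        assert np.array_equal(aucs, again)

    def test_small_class_rejected(self):
        feats = _gaussian_features(20)
        subj = pd.DataFrame({"lvedp": [30.0] * 3 + [8.0] * 17}, index=feats.index)
        spec = ModelSpec(1, "elastic_net", list(feats.columns))
        with pytest.raises(ConfigurationError):
            cross_validate(spec, feats, subj, folds=5, iterations=1, seed=0)
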