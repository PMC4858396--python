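import numpy as np
import pandas as pd
import pytest

from toxprofiler import qsar, synthetic
from toxprofiler.qsar import (
    ConsensusBundle,
    DescriptorMatrix,
    ModelSpec,
    RangeScaler,
    TrainingError,
    cpt_classify,
    default_specs,
    downsample,
    external_cv,
    train_consensus,
)


def _dm(X, prefix="d"):
    n, p = X.shape
    return DescriptorMatrix(
        tuple(f"c{i}" for i in range(n)), tuple(f"{prefix}{j}" for j in range(p)), X
    )


FAST_SPECS = default_specs(seed=0, rf_trees=30)


def _separable(n=120, seed=0):
    rng = np.random.default_rng(seed)
    y = np.arange(n) % 2
    a = rng.normal(size=(n, 8)) + y[:, None] * 6.0
    b = rng.normal(size=(n, 12)) + y[:, None] * 6.0
    desc = {"setA": _dm(a), "setB": _dm(b, "e")}
    labels = pd.Series(y, index=list(desc["setA"].ids))
    return desc, labels


class TestRangeScaler:
    def test_training_values_in_unit_interval(self, rng):
        dm = _dm(rng.normal(size=(50, 6)) * 10)
        scaled = RangeScaler().fit_transform(dm)
        assert scaled.min() >= 0.0 and scaled.max() <= 1.0

    def test_idempotent_on_training_data(self, rng):
        dm = _dm(rng.normal(size=(50, 6)))
        scaler = RangeScaler()
        first = scaler.fit_transform(dm)
        second = scaler.transform(dm)
        np.testing.assert_array_equal(first, second)

    def test_constant_descriptor_dropped(self, rng):
        X = rng.normal(size=(20, 3))
        X[:, 1] = 7.0
        dm = _dm(X)
        scaler = RangeScaler()
        out = scaler.fit_transform(dm)
        assert out.shape[1] == 2
        assert scaler.dropped_features == ("d1",)

    def test_external_values_clipped(self, rng):
        dm = _dm(rng.uniform(size=(30, 4)))
        scaler = RangeScaler().fit(dm)
        query = _dm(np.full((2, 4), 99.0))
        out = scaler.transform(query)
        assert out.max() <= 1.0

    def test_dimension_mismatch(self, rng):
        scaler = RangeScaler().fit(_dm(rng.uniform(size=(10, 4))))
        with pytest.raises(ValueError):
            scaler.transform(_dm(rng.uniform(size=(3, 5))))


class TestDownsample:
    def test_count_contract(self, rng):
        actives = [f"a{i}" for i in range(10)]
        inactives = [f"i{i}" for i in range(1000)]
        feats = {c: rng.integers(0, 2, size=32).astype(float) for c in actives + inactives}
        modeling, leftout = downsample(actives, inactives, feats, ratio=(1, 1), seed=0)
        assert len(modeling) == 20
        assert len(leftout) == 990
        assert set(modeling) | set(leftout) == set(actives + inactives)

    def test_deterministic(self, rng):
        actives = [f"a{i}" for i in range(5)]
        inactives = [f"i{i}" for i in range(50)]
        feats = {c: rng.integers(0, 2, size=16).astype(float) for c in actives + inactives}
        m1, _ = downsample(actives, inactives, feats, ratio=(1, 2), seed=7)
        m2, _ = downsample(actives, inactives, feats, ratio=(1, 2), seed=7)
        assert m1 == m2

    def test_selected_more_similar_than_random(self):
        """Similarity-guided picks beat random draws on mean Tanimoto to the
        active set (Monte-Carlo baseline)."""
        rng = np.random.default_rng(0)
        actives = [f"a{i}" for i in range(8)]
        inactives = [f"i{i}" for i in range(300)]
        proto = rng.integers(0, 2, size=64).astype(float)
        feats = {}
        for c in actives:
            v = proto.copy()
            flip = rng.choice(64, 5, replace=False)
            v[flip] = 1 - v[flip]
            feats[c] = v
        for c in inactives:
            feats[c] = rng.integers(0, 2, size=64).astype(float)
        # a few inactives resemble the actives
        for c in inactives[:20]:
            v = proto.copy()
            flip = rng.choice(64, 8, replace=False)
            v[flip] = 1 - v[flip]
            feats[c] = v
        modeling, _ = downsample(actives, inactives, feats, ratio=(1, 2), seed=1)
        chosen = [c for c in modeling if c.startswith("i")]
        A = np.vstack([feats[c] for c in actives])

        def mean_sim(ids):
            B = np.vstack([feats[c] for c in ids])
            return qsar._tanimoto_sim(A, B).mean()

        random_means = []
        for s in range(100):
            r = np.random.default_rng(s)
            random_means.append(mean_sim(list(r.choice(inactives, size=len(chosen), replace=False))))
        assert mean_sim(chosen) > np.mean(random_means)

    def test_shortfall_warns_and_uses_all(self):
        feats = {c: np.ones(8) for c in ["a0", "a1", "i0"]}
        with pytest.warns(UserWarning):
            modeling, leftout = downsample(["a0", "a1"], ["i0"], feats, ratio=(1, 2), seed=0)
        assert sorted(modeling) == ["a0", "a1", "i0"]
        assert leftout == []


class TestCptClassify:
    @pytest.mark.parametrize(
        "score,c1,c2",
        [
            (0.5, "active", "inconclusive"),
            (0.8, "active", "active"),
            (0.3, "inactive", "inactive"),
            (0.75, "active", "inconclusive"),
            (0.49999, "inactive", "inconclusive"),
            (0.0, "inactive", "inactive"),
            (1.0, "active", "active"),
        ],
    )
    def test_thresholds(self, score, c1, c2):
        assert cpt_classify(score) == (c1, c2)

    @pytest.mark.parametrize("score", [-0.1, 1.1])
    def test_out_of_range(self, score):
        with pytest.raises(ValueError):
            cpt_classify(score)


class TestConsensus:
    def test_separable_data_near_perfect_cv(self):
        desc, labels = _separable()
        report = external_cv(desc, labels, folds=5, seed=0, specs=FAST_SPECS, balance=False)
        folds = report.folds
        cpt1 = folds[(folds.cpt == "cpt1") & (~folds.ad)]
        assert cpt1.ccr.mean() >= 0.95

    def test_shuffled_labels_chance_level(self):
        desc, labels = _separable(n=160, seed=1)
        bad = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            shuffled = pd.Series(
                rng.permutation(labels.to_numpy()), index=labels.index
            )
            report = external_cv(
                desc, shuffled, folds=5, seed=seed, specs=FAST_SPECS, balance=False
            )
            folds = report.folds
            ccr = folds[(folds.cpt == "cpt1") & (~folds.ad)].ccr.mean()
            if not 0.4 <= ccr <= 0.6:
                bad += 1
        assert bad <= 1

    def test_scores_bounded(self, rng):
        desc, labels = _separable()
        bundle = train_consensus(desc, labels, specs=FAST_SPECS)
        q = {
            "setA": _dm(rng.normal(size=(1000, 8)) * 3),
            "setB": _dm(rng.normal(size=(1000, 12)) * 3, "e"),
        }
        scores = bundle.predict_scores(q)
        assert ((scores >= 0) & (scores <= 1)).all().all()

    def test_consensus_is_mean_of_models(self):
        desc, labels = _separable()
        bundle = train_consensus(desc, labels, specs=FAST_SPECS)
        scores = bundle.predict_scores(desc)
        model_cols = [s.name for s in FAST_SPECS]
        np.testing.assert_allclose(
            scores["consensus"], scores[model_cols].mean(axis=1)
        )
        # removing one model shifts the mean by at most max deviation/(m-1)
        m = len(model_cols)
        for col in model_cols:
            reduced = scores[[c for c in model_cols if c != col]].mean(axis=1)
            max_dev = (scores[model_cols].sub(scores["consensus"], axis=0)).abs().max(axis=1)
            assert (np.abs(reduced - scores["consensus"]) <= max_dev / (m - 1) + 1e-12).all()

    def test_single_class_error(self):
        desc, labels = _separable()
        with pytest.raises(TrainingError):
            train_consensus(desc, labels * 0, specs=FAST_SPECS)

    def test_six_default_specs(self):
        specs = default_specs()
        assert len(specs) == 6
        assert {(s.descriptor_set, s.algorithm) for s in specs} == {
            (d, a) for d in ("setA", "setB") for a in ("random_forest", "svm", "knn")
        }


class TestApplicabilityDomain:
    def _bundle(self, z=0.5):
        desc, labels = _separable(n=200, seed=3)
        return desc, train_consensus(desc, labels, specs=FAST_SPECS, ad_z=z)

    def test_self_consistency(self):
        # at the default z=0.5 the cutoff sits half a standard deviation
        # above the mean training-point neighbour distance, so the majority
        # (but, by construction, not >=95%) of training points are in-AD;
        # a wide cutoff admits essentially all of them
        desc, bundle = self._bundle()
        in_ad = bundle.ad_check(desc, exclude_self=True)
        assert in_ad.mean() >= 0.6
        desc2, wide = self._bundle(z=3.0)
        assert wide.ad_check(desc2, exclude_self=True).mean() >= 0.95

    def test_extreme_outlier_rejected(self):
        desc, bundle = self._bundle()
        far = {
            "setA": _dm(np.full((1, 8), 1000.0)),
            "setB": _dm(np.full((1, 12), 1000.0), "e"),
        }
        # clipped to the corner of descriptor space; still far from the data
        assert not bundle.ad_check(far)[0]

    def test_coverage_monotone_in_z(self):
        desc, labels = _separable(n=200, seed=3)
        covs = []
        for z in (-50.0, 0.0, 0.5, 2.0, 50.0):
            bundle = train_consensus(desc, labels, specs=FAST_SPECS, ad_z=z)
            covs.append(bundle.coverage(desc))
        assert covs == sorted(covs)
        assert covs[-1] == 1.0
        assert covs[0] <= 0.05


class TestExternalCV:
    def test_fold_sizes_balanced(self):
        desc, labels = _separable(n=123, seed=4)
        report = external_cv(desc, labels, folds=5, seed=0, specs=FAST_SPECS, balance=False)
        folds = report.folds
        n_per_fold = folds[(folds.cpt == "cpt1") & (~folds.ad)]["n"]
        assert n_per_fold.max() - n_per_fold.min() <= 1

    def test_cpt2_coverage_never_exceeds_cpt1(self):
        desc, labels = _separable(n=150, seed=5)
        report = external_cv(desc, labels, folds=5, seed=0, specs=FAST_SPECS, balance=False)
        folds = report.folds
        for ad_flag in (False, True):
            c1 = folds[(folds.cpt == "cpt1") & (folds.ad == ad_flag)].set_index("fold")
            c2 = folds[(folds.cpt == "cpt2") & (folds.ad == ad_flag)].set_index("fold")
            assert (c2.coverage <= c1.coverage).all()

    def test_too_few_per_class(self):
        desc, labels = _separable(n=120)
        few = labels.copy()
        few.iloc[:] = 0
        few.iloc[:3] = 1
        with pytest.raises(TrainingError):
            external_cv(desc, few, folds=5, specs=FAST_SPECS, balance=False)

    def test_report_csv(self, tmp_path):
        desc, labels = _separable()
        report = external_cv(desc, labels, folds=5, seed=0, specs=FAST_SPECS, balance=False)
        report.to_csv(tmp_path / "cv.csv")
        assert (tmp_path / "cv.csv").read_text().startswith("fold,")
        summary = report.summary()
        assert set(summary.columns) >= {"cpt", "ad", "ccr", "coverage"}


def test_bundle_persistence_round_trip(tmp_path):
    desc, labels = _separable()
    bundle = train_consensus(desc, labels, specs=FAST_SPECS)
    qsar.save_bundle(bundle, tmp_path / "bundle")
    assert (tmp_path / "bundle" / "manifest.json").exists()
    restored = qsar.load_bundle(tmp_path / "bundle")
    np.testing.assert_allclose(
        restored.predict_scores(desc)["consensus"],
        bundle.predict_scores(desc)["consensus"],
    )
    np.testing.assert_array_equal(restored.ad_check(desc), bundle.ad_check(desc))
    assert restored.ad_threshold_ == bundle.ad_threshold_


def test_descriptors_from_smiles(small_library):
    smiles = [r.smiles for r in small_library[:40]]
    ids = [r.compound_id for r in small_library[:40]]
    desc = qsar.descriptor_sets_from_smiles(smiles, ids, n_bits=128)
    assert desc["setA"].values.shape[0] == 40
    assert desc["setB"].values.shape == (40, 128)
    assert np.isfinite(desc["setA"].values).all()
    fps = qsar.fingerprint_features(smiles, ids, n_bits=128)
    assert set(fps) == set(ids)
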