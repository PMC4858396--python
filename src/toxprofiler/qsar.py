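"""Consensus QSAR engine for pathway-activation modeling.

Two descriptor sets x three algorithms (random forest, SVM, k-NN) give six
individual models whose [0,1] scores are averaged into a consensus.  The
modeling set is balanced by similarity-guided down-sampling of inactives,
validated by stratified 5-fold external cross-validation (scalers, sampler
and models re-fit inside each training fold), classified under two
consensus prediction thresholds (split at 0.5; and >=0.8 / <=0.3 with an
inconclusive band), and gated by a k-NN distance applicability domain.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors
from sklearn.svm import SVC

DESCRIPTOR_SETS = ("setA", "setB")
ALGORITHMS = ("random_forest", "svm", "knn")

CPT1_THRESHOLD = 0.5
CPT2_ACTIVE = 0.8
CPT2_INACTIVE = 0.3
DEFAULT_RATIO = (750, 800)
DEFAULT_AD_K = 5
DEFAULT_AD_Z = 0.5


class TrainingError(ValueError):
    pass


@dataclass(frozen=True)
class DescriptorMatrix:
    """Compound x descriptor value block (raw scale; scaling is separate)."""

    ids: tuple[str, ...]
    features: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (len(self.ids), len(self.features)):
            raise ValueError("descriptor matrix shape mismatch")

    def subset(self, ids: Sequence[str]) -> "DescriptorMatrix":
        pos = {cid: i for i, cid in enumerate(self.ids)}
        rows = [pos[c] for c in ids]
        return DescriptorMatrix(tuple(ids), self.features, self.values[rows])


class RangeScaler:
    """Per-descriptor min/max scaling to [0,1] fit on training data.

    Constant descriptors are dropped and recorded.  Out-of-range values of
    external compounds are clipped to [0,1] so distances stay bounded.
    """

    def __init__(self) -> None:
        self.min_: np.ndarray | None = None
        self.max_: np.ndarray | None = None
        self.keep_: np.ndarray | None = None
        self.dropped_features: tuple[str, ...] = ()

    def fit(self, dm: DescriptorMatrix) -> "RangeScaler":
        X = dm.values
        self.min_ = X.min(axis=0)
        self.max_ = X.max(axis=0)
        self.keep_ = self.max_ > self.min_
        self.dropped_features = tuple(
            f for f, k in zip(dm.features, self.keep_) if not k
        )
        return self

    def transform(self, dm: DescriptorMatrix, clip: bool = True) -> np.ndarray:
        if self.min_ is None:
            raise TrainingError("scaler is not fitted")
        X = dm.values
        if X.shape[1] != self.min_.size:
            raise ValueError("descriptor dimension mismatch")
        denom = np.where(self.keep_, self.max_ - self.min_, 1.0)
        out = (X - self.min_) / denom
        out = out[:, self.keep_]
        if clip:
            out = np.clip(out, 0.0, 1.0)
        return out

    def fit_transform(self, dm: DescriptorMatrix) -> np.ndarray:
        return self.fit(dm).transform(dm)


@dataclass(frozen=True)
class ModelSpec:
    descriptor_set: str
    algorithm: str
    hyperparameters: tuple[tuple[str, object], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.descriptor_set not in DESCRIPTOR_SETS:
            raise ValueError(f"unknown descriptor set: {self.descriptor_set}")
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm: {self.algorithm}")

    @property
    def name(self) -> str:
        return f"{self.descriptor_set}-{self.algorithm}"

    def params(self) -> dict:
        return dict(self.hyperparameters)


def default_specs(
    seed: int = 0, rf_trees: int = 500, knn_k: int = 5, svm_c: float = 1.0
) -> tuple[ModelSpec, ...]:
    """The six descriptor-set x algorithm combinations of the consensus."""
    specs = []
    for ds in DESCRIPTOR_SETS:
        specs.append(ModelSpec(ds, "random_forest", (("n_estimators", rf_trees),), seed))
        specs.append(ModelSpec(ds, "svm", (("C", svm_c),), seed))
        specs.append(ModelSpec(ds, "knn", (("n_neighbors", knn_k),), seed))
    return tuple(specs)


def _make_estimator(spec: ModelSpec):
    p = spec.params()
    if spec.algorithm == "random_forest":
        return RandomForestClassifier(
            n_estimators=int(p.get("n_estimators", 500)),
            random_state=spec.seed,
            n_jobs=1,
        )
    if spec.algorithm == "svm":
        return SVC(kernel=p.get("kernel", "rbf"), C=float(p.get("C", 1.0)), gamma="scale")
    return KNeighborsClassifier(
        n_neighbors=int(p.get("n_neighbors", 5)), weights="distance"
    )


def _model_scores(est, spec: ModelSpec, X: np.ndarray) -> np.ndarray:
    """Individual-model scores on a common [0,1] scale: tree-vote fraction
    for forests, distance-weighted neighbor fraction for k-NN, a logistic
    link on the margin for SVMs."""
    if spec.algorithm == "svm":
        margin = est.decision_function(X)
        return 1.0 / (1.0 + np.exp(-margin))
    proba = est.predict_proba(X)
    active_col = list(est.classes_).index(1)
    return proba[:, active_col]


def cpt_classify(
    score: float,
    cpt1_threshold: float = CPT1_THRESHOLD,
    cpt2_active: float = CPT2_ACTIVE,
    cpt2_inactive: float = CPT2_INACTIVE,
) -> tuple[str, str]:
    """Classify a consensus score under both thresholds.

    CPT-1: >= 0.5 active, < 0.5 inactive.  CPT-2: >= 0.8 active, <= 0.3
    inactive, strictly between the two inconclusive.
    """
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"score outside [0,1]: {score}")
    c1 = "active" if score >= cpt1_threshold else "inactive"
    if score >= cpt2_active:
        c2 = "active"
    elif score <= cpt2_inactive:
        c2 = "inactive"
    else:
        c2 = "inconclusive"
    return c1, c2


@dataclass(frozen=True)
class ConsensusPrediction:
    compound_id: str
    score: float
    class_cpt1: str
    class_cpt2: str
    in_ad: bool


def _tanimoto_sim(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise Tanimoto similarity between binary row vectors."""
    A = (np.asarray(A) > 0).astype(float)
    B = (np.asarray(B) > 0).astype(float)
    inter = A @ B.T
    union = A.sum(axis=1)[:, None] + B.sum(axis=1)[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / union, 0.0)
    return sim


def downsample(
    active_ids: Sequence[str],
    inactive_ids: Sequence[str],
    features: Mapping[str, np.ndarray] | DescriptorMatrix,
    ratio: tuple[int, int] = DEFAULT_RATIO,
    seed: int = 0,
    metric: str = "tanimoto",
    max_actives: int | None = None,
) -> tuple[list[str], list[str]]:
    """Similarity-guided balancing of the modeling set.

    All actives are retained (up to ``max_actives``); inactives nearest to
    the actives are drawn round-robin without replacement until the
    configured active:inactive ratio is met.  Everything left out forms the
    external pool.  ``metric`` is "tanimoto" for binary fingerprints or
    "euclidean" for dense descriptors.
    """
    if len(active_ids) == 0 or len(inactive_ids) == 0:
        raise TrainingError("both actives and inactives are required")
    rng = np.random.default_rng(seed)
    actives = list(active_ids)
    if max_actives is not None and len(actives) > max_actives:
        keep = rng.choice(len(actives), size=max_actives, replace=False)
        actives = [actives[i] for i in sorted(keep)]
    inactives = list(inactive_ids)

    if isinstance(features, DescriptorMatrix):
        feat = {cid: features.values[i] for i, cid in enumerate(features.ids)}
    else:
        feat = features
    A = np.vstack([feat[c] for c in actives])
    B = np.vstack([feat[c] for c in inactives])
    if metric == "tanimoto":
        sim = _tanimoto_sim(A, B)
    elif metric == "euclidean":
        from scipy.spatial.distance import cdist

        sim = -cdist(A, B)
    else:
        raise ValueError(f"unknown metric: {metric}")

    n_target = int(round(len(actives) * ratio[1] / ratio[0]))
    if n_target > len(inactives):
        warnings.warn(
            f"only {len(inactives)} inactives available for a target of {n_target}; using all"
        )
        n_target = len(inactives)
    order = np.argsort(-sim, axis=1, kind="stable")
    taken: list[int] = []
    taken_mask = np.zeros(len(inactives), dtype=bool)
    cursor = [0] * len(actives)
    while len(taken) < n_target:
        progressed = False
        for ai in range(len(actives)):
            if len(taken) >= n_target:
                break
            while cursor[ai] < len(inactives) and taken_mask[order[ai, cursor[ai]]]:
                cursor[ai] += 1
            if cursor[ai] < len(inactives):
                j = order[ai, cursor[ai]]
                taken_mask[j] = True
                taken.append(j)
                cursor[ai] += 1
                progressed = True
        if not progressed:
            break
    modeling = actives + [inactives[j] for j in sorted(taken)]
    chosen = set(modeling)
    leftout = [c for c in list(active_ids) + inactives if c not in chosen]
    return modeling, leftout


class ConsensusBundle:
    """Trained consensus model: per-spec scaler+estimator pairs, the scaled
    training matrices for the applicability domain, and the AD cutoff."""

    def __init__(
        self,
        specs: Sequence[ModelSpec],
        ad_k: int = DEFAULT_AD_K,
        ad_z: float = DEFAULT_AD_Z,
        ad_descriptor_set: str = "setA",
    ) -> None:
        self.specs = tuple(specs)
        self.ad_k = ad_k
        self.ad_z = ad_z
        self.ad_descriptor_set = ad_descriptor_set
        self.scalers: dict[str, RangeScaler] = {}
        self.models: dict[str, object] = {}
        self.train_scaled: dict[str, np.ndarray] = {}
        self.train_ids: tuple[str, ...] = ()
        self.ad_threshold_: float | None = None
        self._ad_nn: NearestNeighbors | None = None
        self._ad_k_eff: int = ad_k

    # -- training ----------------------------------------------------------
    def fit(
        self, descriptors: Mapping[str, DescriptorMatrix], labels: Mapping[str, int] | pd.Series
    ) -> "ConsensusBundle":
        labels = pd.Series(labels)
        ids = tuple(descriptors[self.specs[0].descriptor_set].ids)
        y = labels.loc[list(ids)].to_numpy(dtype=int)
        if len(np.unique(y)) < 2:
            raise TrainingError("training labels contain a single class")
        self.train_ids = ids
        for ds in {s.descriptor_set for s in self.specs}:
            scaler = RangeScaler()
            self.train_scaled[ds] = scaler.fit_transform(descriptors[ds])
            self.scalers[ds] = scaler
        for spec in self.specs:
            est = _make_estimator(spec)
            est.fit(self.train_scaled[spec.descriptor_set], y)
            self.models[spec.name] = est
        self._fit_ad()
        return self

    def _fit_ad(self) -> None:
        X = self.train_scaled[self.ad_descriptor_set]
        k = min(self.ad_k, X.shape[0] - 1)
        if k < 1:
            raise TrainingError("too few training compounds for the applicability domain")
        nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
        dist, _ = nn.kneighbors(X)
        mean_dist = dist[:, 1:].mean(axis=1)  # exclude self
        self.ad_threshold_ = float(mean_dist.mean() + self.ad_z * mean_dist.std())
        self._ad_k_eff = k
        self._ad_nn = NearestNeighbors(n_neighbors=k).fit(X)

    # -- inference ---------------------------------------------------------
    def _scaled(self, descriptors: Mapping[str, DescriptorMatrix]) -> dict[str, np.ndarray]:
        return {
            ds: self.scalers[ds].transform(descriptors[ds])
            for ds in self.scalers
        }

    def predict_scores(self, descriptors: Mapping[str, DescriptorMatrix]) -> pd.DataFrame:
        """Per-model and consensus scores for the query compounds."""
        scaled = self._scaled(descriptors)
        ids = descriptors[self.specs[0].descriptor_set].ids
        out = pd.DataFrame(index=list(ids))
        for spec in self.specs:
            out[spec.name] = _model_scores(
                self.models[spec.name], spec, scaled[spec.descriptor_set]
            )
        out["consensus"] = out[[s.name for s in self.specs]].mean(axis=1)
        return out

    def ad_check(
        self, descriptors: Mapping[str, DescriptorMatrix], exclude_self: bool = False
    ) -> np.ndarray:
        """True where the query's mean distance to its k nearest modeling-set
        neighbours is within the trained cutoff.

        ``exclude_self`` drops the nearest neighbour (use when querying
        modeling-set compounds against their own bundle).
        """
        if self._ad_nn is None or self.ad_threshold_ is None:
            raise TrainingError("bundle is not fitted")
        Xq = self.scalers[self.ad_descriptor_set].transform(
            descriptors[self.ad_descriptor_set]
        )
        dist, _ = self._ad_nn.kneighbors(Xq, n_neighbors=self._ad_k_eff + int(exclude_self))
        if exclude_self:
            dist = dist[:, 1:]
        return dist.mean(axis=1) <= self.ad_threshold_

    def coverage(self, descriptors: Mapping[str, DescriptorMatrix]) -> float:
        in_ad = self.ad_check(descriptors)
        return float(in_ad.mean()) if in_ad.size else float("nan")

    def predict(self, descriptors: Mapping[str, DescriptorMatrix]) -> list[ConsensusPrediction]:
        scores = self.predict_scores(descriptors)
        in_ad = self.ad_check(descriptors)
        out = []
        for (cid, row), ad_flag in zip(scores.iterrows(), in_ad):
            c1, c2 = cpt_classify(float(row["consensus"]))
            out.append(
                ConsensusPrediction(str(cid), float(row["consensus"]), c1, c2, bool(ad_flag))
            )
        return out


def save_bundle(bundle: ConsensusBundle, directory) -> None:
    """Persist a trained bundle: scaler CSVs, model binaries (joblib), and a
    manifest JSON with specs and AD parameters."""
    import json
    from pathlib import Path

    import joblib

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    manifest = {
        "specs": [
            {
                "descriptor_set": s.descriptor_set,
                "algorithm": s.algorithm,
                "hyperparameters": dict(s.hyperparameters),
                "seed": s.seed,
            }
            for s in bundle.specs
        ],
        "ad_k": bundle.ad_k,
        "ad_z": bundle.ad_z,
        "ad_descriptor_set": bundle.ad_descriptor_set,
        "ad_threshold": bundle.ad_threshold_,
        "train_ids": list(bundle.train_ids),
    }
    (d / "manifest.json").write_text(json.dumps(manifest, indent=2))
    for ds, scaler in bundle.scalers.items():
        pd.DataFrame(
            {"min": scaler.min_, "max": scaler.max_, "keep": scaler.keep_}
        ).to_csv(d / f"scaler_{ds}.csv", index_label="feature_index")
        np.savetxt(d / f"train_scaled_{ds}.csv", bundle.train_scaled[ds], delimiter=",")
    for name, model in bundle.models.items():
        joblib.dump(model, d / f"model_{name}.joblib")


def load_bundle(directory) -> ConsensusBundle:
    import json
    from pathlib import Path

    import joblib

    d = Path(directory)
    manifest = json.loads((d / "manifest.json").read_text())
    specs = tuple(
        ModelSpec(
            s["descriptor_set"],
            s["algorithm"],
            tuple(s["hyperparameters"].items()),
            s["seed"],
        )
        for s in manifest["specs"]
    )
    bundle = ConsensusBundle(
        specs,
        ad_k=manifest["ad_k"],
        ad_z=manifest["ad_z"],
        ad_descriptor_set=manifest["ad_descriptor_set"],
    )
    bundle.train_ids = tuple(manifest["train_ids"])
    for ds in {s.descriptor_set for s in specs}:
        table = pd.read_csv(d / f"scaler_{ds}.csv", index_col="feature_index")
        scaler = RangeScaler()
        scaler.min_ = table["min"].to_numpy()
        scaler.max_ = table["max"].to_numpy()
        scaler.keep_ = table["keep"].to_numpy(dtype=bool)
        bundle.scalers[ds] = scaler
        bundle.train_scaled[ds] = np.loadtxt(
            d / f"train_scaled_{ds}.csv", delimiter=","
        ).reshape(len(bundle.train_ids), -1)
    for spec in specs:
        bundle.models[spec.name] = joblib.load(d / f"model_{spec.name}.joblib")
    bundle._fit_ad()
    bundle.ad_threshold_ = manifest["ad_threshold"]
    return bundle


def train_consensus(
    descriptors: Mapping[str, DescriptorMatrix],
    labels: Mapping[str, int] | pd.Series,
    specs: Sequence[ModelSpec] | None = None,
    ad_k: int = DEFAULT_AD_K,
    ad_z: float = DEFAULT_AD_Z,
) -> ConsensusBundle:
    specs = tuple(specs) if specs is not None else default_specs()
    return ConsensusBundle(specs, ad_k=ad_k, ad_z=ad_z).fit(descriptors, labels)


def _binary_metrics(y_true: np.ndarray, y_pred_active: np.ndarray) -> tuple[float, float, float]:
    pos = y_true == 1
    tp = int(np.count_nonzero(y_pred_active & pos))
    fn = int(np.count_nonzero(~y_pred_active & pos))
    fp = int(np.count_nonzero(y_pred_active & ~pos))
    tn = int(np.count_nonzero(~y_pred_active & ~pos))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    return sens, spec, (sens + spec) / 2.0


@dataclass
class CVReport:
    """Per-fold external-validation metrics, Table-row style."""

    folds: pd.DataFrame  # fold, cpt, ad, sensitivity, specificity, ccr, coverage, n

    def summary(self) -> pd.DataFrame:
        return (
            self.folds.groupby(["cpt", "ad"])[
                ["sensitivity", "specificity", "ccr", "coverage"]
            ]
            .mean()
            .reset_index()
        )

    def to_csv(self, path) -> None:
        self.folds.to_csv(path, index=False)


def external_cv(
    descriptors: Mapping[str, DescriptorMatrix],
    labels: Mapping[str, int] | pd.Series,
    folds: int = 5,
    seed: int = 0,
    specs: Sequence[ModelSpec] | None = None,
    ad_k: int = DEFAULT_AD_K,
    ad_z: float = DEFAULT_AD_Z,
    balance: bool = True,
    ratio: tuple[int, int] = DEFAULT_RATIO,
    similarity_metric: str = "euclidean",
    similarity_set: str = "setB",
) -> CVReport:
    """Stratified k-fold external cross-validation (80/20 at k=5).

    Down-sampling, scaling and model fitting happen inside each training
    fold only; external-fold compounds are never seen during fitting.
    """
    labels = pd.Series(labels)
    specs = tuple(specs) if specs is not None else default_specs(seed=seed)
    base_ids = list(descriptors["setA"].ids)
    y_all = labels.loc[base_ids].to_numpy(dtype=int)
    counts = np.bincount(y_all, minlength=2)
    if counts.min() < folds:
        raise TrainingError(f"need at least {folds} compounds per class")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    records = []
    for fold_no, (train_pos, test_pos) in enumerate(skf.split(base_ids, y_all), start=1):
        train_ids = [base_ids[i] for i in train_pos]
        test_ids = [base_ids[i] for i in test_pos]
        if balance:
            tr_labels = labels.loc[train_ids]
            act = [c for c in train_ids if tr_labels[c] == 1]
            inact = [c for c in train_ids if tr_labels[c] == 0]
            sim_features = descriptors[similarity_set].subset(train_ids)
            modeling_ids, _ = downsample(
                act, inact, sim_features, ratio=ratio, seed=seed + fold_no,
                metric=similarity_metric,
            )
        else:
            modeling_ids = train_ids
        train_desc = {ds: descriptors[ds].subset(modeling_ids) for ds in descriptors}
        test_desc = {ds: descriptors[ds].subset(test_ids) for ds in descriptors}
        bundle = ConsensusBundle(specs, ad_k=ad_k, ad_z=ad_z).fit(
            train_desc, labels.loc[modeling_ids]
        )
        scores = bundle.predict_scores(test_desc)["consensus"].to_numpy()
        in_ad = bundle.ad_check(test_desc)
        y_test = labels.loc[test_ids].to_numpy(dtype=int)
        n_test = len(test_ids)
        for cpt in ("cpt1", "cpt2"):
            if cpt == "cpt1":
                definite = np.ones(n_test, dtype=bool)
                pred_active = scores >= CPT1_THRESHOLD
            else:
                definite = (scores >= CPT2_ACTIVE) | (scores <= CPT2_INACTIVE)
                pred_active = scores >= CPT2_ACTIVE
            for use_ad in (False, True):
                mask = definite & in_ad if use_ad else definite
                if mask.any():
                    sens, spec, ccr = _binary_metrics(y_test[mask], pred_active[mask])
                else:
                    sens = spec = ccr = float("nan")
                records.append(
                    {
                        "fold": fold_no,
                        "cpt": cpt,
                        "ad": use_ad,
                        "sensitivity": sens,
                        "specificity": spec,
                        "ccr": ccr,
                        "coverage": float(mask.mean()),
                        "n": int(mask.sum()),
                    }
                )
    return CVReport(folds=pd.DataFrame(records))


# ---------------------------------------------------------------------------
# descriptor providers for real molecules

def descriptor_sets_from_smiles(
    smiles: Sequence[str], ids: Sequence[str], n_bits: int = 512, radius: int = 2
) -> dict[str, DescriptorMatrix]:
    """Open 2-D descriptor stand-ins: a physicochemical block (setA) and a
    hashed circular-fingerprint block (setB)."""
    from rdkit import Chem
    from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

    physchem = (
        ("MolWt", Descriptors.MolWt),
        ("HeavyAtomCount", Descriptors.HeavyAtomCount),
        ("MolLogP", Crippen.MolLogP),
        ("MolMR", Crippen.MolMR),
        ("TPSA", rdMolDescriptors.CalcTPSA),
        ("NumHDonors", rdMolDescriptors.CalcNumHBD),
        ("NumHAcceptors", rdMolDescriptors.CalcNumHBA),
        ("NumRotatableBonds", rdMolDescriptors.CalcNumRotatableBonds),
        ("NumAromaticRings", rdMolDescriptors.CalcNumAromaticRings),
        ("NumAliphaticRings", rdMolDescriptors.CalcNumAliphaticRings),
        ("FractionCSP3", rdMolDescriptors.CalcFractionCSP3),
        ("NumHeteroatoms", rdMolDescriptors.CalcNumHeteroatoms),
        ("RingCount", Descriptors.RingCount),
        ("NHOHCount", Descriptors.NHOHCount),
        ("NOCount", Descriptors.NOCount),
        ("NumValenceElectrons", Descriptors.NumValenceElectrons),
        ("BalabanJ", Descriptors.BalabanJ),
        ("BertzCT", Descriptors.BertzCT),
        ("Chi0v", Descriptors.Chi0v),
        ("Chi1v", Descriptors.Chi1v),
        ("Kappa1", Descriptors.Kappa1),
        ("Kappa2", Descriptors.Kappa2),
        ("LabuteASA", Descriptors.LabuteASA),
        ("MaxPartialCharge", Descriptors.MaxPartialCharge),
        ("MinPartialCharge", Descriptors.MinPartialCharge),
    )
    mols = []
    for s in smiles:
        mol = Chem.MolFromSmiles(s)
        if mol is None:
            raise ValueError(f"unparseable SMILES for descriptors: {s}")
        mols.append(mol)
    a = np.array([[float(fn(m)) for _, fn in physchem] for m in mols])
    a = np.nan_to_num(a, nan=0.0, posinf=0.0, neginf=0.0)
    fps = np.array(
        [
            np.asarray(
                rdMolDescriptors.GetMorganFingerprintAsBitVect(m, radius, nBits=n_bits),
                dtype=float,
            )
            for m in mols
        ]
    )
    ids = tuple(str(c) for c in ids)
    return {
        "setA": DescriptorMatrix(ids, tuple(n for n, _ in physchem), a),
        "setB": DescriptorMatrix(
            ids, tuple(f"morgan_{j}" for j in range(n_bits)), fps
        ),
    }


def fingerprint_features(smiles: Sequence[str], ids: Sequence[str], n_bits: int = 512):
    """Binary fingerprints keyed by id, for Tanimoto down-sampling."""
    from rdkit import Chem
    from rdkit.Chem import rdMolDescriptors

    out = {}
    for cid, s in zip(ids, smiles):
        mol = Chem.MolFromSmiles(s)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {s}")
        out[str(cid)] = np.asarray(
            rdMolDescriptors.GetMorganFingerprintAsBitVect(mol, 2, nBits=n_bits), dtype=float
        )
    return out
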