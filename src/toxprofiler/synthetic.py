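"""Synthetic compound libraries, qHTS curves, assay matrices and labels.

Generates data with the statistical structure the analysis assumes: valid
structures built from a small scaffold vocabulary decorated with planted
substructure fragments, a logistic latent model linking carried fragments
to pathway activation and organ toxicity, Hill-shaped active curves with
Gaussian noise, and a sparse categorical assay matrix in which a planted
assay subset is associated with the latent labels.  Latent truth fields are
never consumed by analysis stages - they exist for recovery tests.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from rdkit import Chem, RDLogger

from .bioprofile import ACTIVE, INACTIVE, INCONCLUSIVE, UNTESTED, AssayResponseMatrix
from .curves import CurveSeries

RDLogger.DisableLog("rdApp.*")


class ConfigurationError(ValueError):
    pass


#: scaffold SMILES; fragments and decorations attach at carbons with free valence
DEFAULT_SCAFFOLDS = (
    "c1ccccc1",          # benzene
    "c1ccncc1",          # pyridine
    "C1CCCCC1",          # cyclohexane
    "CCCCCC",            # hexane
    "c1ccc2ccccc2c1",    # naphthalene
    "C1CCOC1",           # tetrahydrofuran
)

#: small substituents used for diversity; chosen so they can never create a
#: planted fragment by accident
DECORATIONS = ("C", "O", "Cl")


@dataclass(frozen=True)
class PlantedFragment:
    """A substructure planted at a fixed prevalence whose carriage multiplies
    the odds of latent pathway activity and of in vivo toxicity."""

    fragment_id: str
    smiles: str
    prevalence: float
    activity_odds: float = 1.0
    toxicity_odds: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise ConfigurationError(f"prevalence out of [0,1]: {self.prevalence}")
        if self.activity_odds < 1.0 or self.toxicity_odds < 1.0:
            raise ConfigurationError("odds multipliers must be >= 1")
        if Chem.MolFromSmiles(self.smiles) is None:
            raise ConfigurationError(f"invalid fragment SMILES: {self.smiles}")


DEFAULT_FRAGMENTS = (
    PlantedFragment("frag_cf3", "C(F)(F)F", 0.10, 6.0, 6.0),
    PlantedFragment("frag_methylamide", "N(C)C=O", 0.10, 12.0, 12.0),
    PlantedFragment("frag_sulfonamide", "S(=O)(=O)N", 0.10, 8.0, 8.0),
    PlantedFragment("frag_nitrile", "C#N", 0.12, 4.0, 4.0),
)


@dataclass(frozen=True)
class LatentTruth:
    is_are_active: bool
    is_liver_toxic: bool
    carries_fragment: dict[str, bool]


@dataclass(frozen=True)
class CompoundRecord:
    compound_id: str
    smiles: str
    truth: LatentTruth


@dataclass(frozen=True)
class SimulationConfig:
    n_compounds: int = 500
    fragment_specs: tuple[PlantedFragment, ...] = DEFAULT_FRAGMENTS
    scaffolds: tuple[str, ...] = DEFAULT_SCAFFOLDS
    n_assays: int = 40
    n_relevant_assays: int = 4
    association_odds: float = 8.0
    are_association_odds: float = 1.0
    assay_base_active_rate: float = 0.2
    assay_inconclusive_rate: float = 0.0
    missing_rate: float = 0.0
    curve_noise_sd: float = 5.0
    target_active_rate: float = 0.15
    target_toxic_rate: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds < 0:
            raise ConfigurationError("n_compounds must be >= 0")
        if len(self.scaffolds) == 0:
            raise ConfigurationError("scaffold set must be nonempty")
        if self.n_relevant_assays > self.n_assays:
            raise ConfigurationError("n_relevant_assays must be <= n_assays")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError("missing_rate must be in [0,1)")
        if self.association_odds <= 0 or self.are_association_odds <= 0:
            raise ConfigurationError("association odds must be positive")
        for rate in (self.assay_base_active_rate, self.target_active_rate, self.target_toxic_rate):
            if not 0.0 < rate < 1.0:
                raise ConfigurationError("rates must lie strictly inside (0,1)")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationConfig":
        raw = dict(raw)
        frags = raw.pop("fragment_specs", None)
        if frags is not None:
            raw["fragment_specs"] = tuple(
                f if isinstance(f, PlantedFragment) else PlantedFragment(**f) for f in frags
            )
        scaffolds = raw.pop("scaffolds", None)
        if scaffolds is not None:
            raw["scaffolds"] = tuple(scaffolds)
        return cls(**raw)


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _solve_intercept(
    fragments: Sequence[PlantedFragment], odds_attr: str, target_rate: float
) -> float:
    """Intercept of the logistic latent model such that the *marginal* event
    rate equals ``target_rate``, by exact enumeration of fragment carriage
    patterns and bisection on the intercept."""
    betas = [math.log(getattr(f, odds_attr)) for f in fragments]
    prevs = [f.prevalence for f in fragments]
    k = len(fragments)

    def marginal(b0: float) -> float:
        total = 0.0
        for mask in range(1 << k):
            p_combo, shift = 1.0, 0.0
            for i in range(k):
                if mask >> i & 1:
                    p_combo *= prevs[i]
                    shift += betas[i]
                else:
                    p_combo *= 1.0 - prevs[i]
            total += p_combo * _sigmoid(b0 + shift)
        return total

    lo, hi = -30.0, 30.0
    for _ in range(100):
        mid = (lo + hi) / 2.0
        if marginal(mid) < target_rate:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def _attach(core: Chem.Mol, fragment_smiles: str, rng: np.random.Generator) -> Chem.Mol:
    """Bond atom 0 of the fragment to a random carbon of the core that still
    has a free valence."""
    frag = Chem.MolFromSmiles(fragment_smiles)
    candidates = [
        a.GetIdx()
        for a in core.GetAtoms()
        if a.GetAtomicNum() == 6 and a.GetTotalNumHs() > 0
    ]
    if not candidates:
        return core  # saturated; skip attachment rather than fail
    idx = int(candidates[int(rng.integers(len(candidates)))])
    combo = Chem.RWMol(Chem.CombineMols(core, frag))
    combo.AddBond(idx, core.GetNumAtoms(), Chem.BondType.SINGLE)
    mol = combo.GetMol()
    Chem.SanitizeMol(mol)
    return mol


def generate_library(config: SimulationConfig) -> list[CompoundRecord]:
    """Generate ``n_compounds`` structurally valid compounds with latent truth.

    Fragment carriage is Bernoulli at each fragment's prevalence; latent
    activity/toxicity are drawn from logistic models over carried fragments
    whose intercepts are solved so the marginal rates match the configured
    targets.  Identical config (including seed) gives identical output.
    """
    rng = np.random.default_rng((config.seed, 0))
    b0_act = _solve_intercept(config.fragment_specs, "activity_odds", config.target_active_rate)
    b0_tox = _solve_intercept(config.fragment_specs, "toxicity_odds", config.target_toxic_rate)
    width = max(4, len(str(max(config.n_compounds, 1))))
    library: list[CompoundRecord] = []
    for i in range(config.n_compounds):
        carries = {
            f.fragment_id: bool(rng.random() < f.prevalence) for f in config.fragment_specs
        }
        scaffold = config.scaffolds[int(rng.integers(len(config.scaffolds)))]
        mol = Chem.MolFromSmiles(scaffold)
        if mol is None:
            raise ConfigurationError(f"invalid scaffold SMILES: {scaffold}")
        for f in config.fragment_specs:
            if carries[f.fragment_id]:
                mol = _attach(mol, f.smiles, rng)
        for _ in range(int(rng.integers(0, 3))):
            mol = _attach(mol, DECORATIONS[int(rng.integers(len(DECORATIONS)))], rng)
        act_logodds = b0_act + sum(
            math.log(f.activity_odds) for f in config.fragment_specs if carries[f.fragment_id]
        )
        tox_logodds = b0_tox + sum(
            math.log(f.toxicity_odds) for f in config.fragment_specs if carries[f.fragment_id]
        )
        is_active = bool(rng.random() < _sigmoid(act_logodds))
        is_toxic = bool(rng.random() < _sigmoid(tox_logodds))
        library.append(
            CompoundRecord(
                compound_id=f"CMP{i:0{width}d}",
                smiles=Chem.MolToSmiles(mol),
                truth=LatentTruth(is_active, is_toxic, carries),
            )
        )
    return library


N_CONCENTRATIONS = 15
N_REPLICATES = 3
#: 15 points log-spaced over 4 decades
CONCENTRATIONS_M = np.logspace(-9.0, -5.0, N_CONCENTRATIONS)


def generate_curves(
    library: Sequence[CompoundRecord], config: SimulationConfig
) -> list[CurveSeries]:
    """Triplicate 15-point curves: Hill-shaped for latent actives (top in
    [25, 100], midpoint inside the tested range, positive slope, rescaled so
    the top is attained at the highest tested concentration), pure noise
    around zero for inactives."""
    if len(library) == 0:
        raise ConfigurationError("library must be nonempty")
    rng = np.random.default_rng((config.seed, 1))
    conc = CONCENTRATIONS_M
    curves: list[CurveSeries] = []
    for rec in library:
        if rec.truth.is_are_active:
            top = rng.uniform(25.0, 100.0)
            ac50 = 10.0 ** rng.uniform(-8.0, -6.0)
            slope = rng.uniform(1.0, 3.0)
            hill = 1.0 / (1.0 + (ac50 / conc) ** slope)
            base = top * hill / hill[-1]
        else:
            base = np.zeros(N_CONCENTRATIONS)
        for rep in range(1, N_REPLICATES + 1):
            noise = (
                rng.normal(0.0, config.curve_noise_sd, N_CONCENTRATIONS)
                if config.curve_noise_sd > 0
                else 0.0
            )
            curves.append(
                CurveSeries(
                    compound_id=rec.compound_id,
                    replicate=rep,
                    concentrations=conc,
                    responses=base + noise,
                )
            )
    return curves


def generate_assay_matrix(
    library: Sequence[CompoundRecord], config: SimulationConfig
) -> AssayResponseMatrix:
    """Sparse categorical compound x assay matrix.

    A planted subset of ``n_relevant_assays`` assays has its active-call odds
    multiplied by ``association_odds`` for latently toxic compounds (and by
    ``are_association_odds`` for latently pathway-active compounds; defaults
    to 1, i.e. off).  All other assays are independent of the labels.  Cells
    are independently masked untested with probability ``missing_rate``.
    The planted flag is recorded in the metadata for recovery tests only.
    """
    if len(library) == 0:
        raise ConfigurationError("library must be nonempty")
    rng = np.random.default_rng((config.seed, 2))
    n, m = len(library), config.n_assays
    assay_ids = [f"A{j:03d}" for j in range(m)]
    planted_idx = np.sort(rng.choice(m, size=config.n_relevant_assays, replace=False))
    planted = np.zeros(m, dtype=bool)
    planted[planted_idx] = True

    toxic = np.array([rec.truth.is_liver_toxic for rec in library])
    are = np.array([rec.truth.is_are_active for rec in library])
    base_odds = config.assay_base_active_rate / (1.0 - config.assay_base_active_rate)
    odds = np.full((n, m), base_odds)
    odds[:, planted] *= np.where(toxic, config.association_odds, 1.0)[:, None]
    odds[:, planted] *= np.where(are, config.are_association_odds, 1.0)[:, None]
    p_active = odds / (1.0 + odds)

    cells = np.where(rng.random((n, m)) < p_active, ACTIVE, INACTIVE).astype(object)
    if config.assay_inconclusive_rate > 0:
        cells[rng.random((n, m)) < config.assay_inconclusive_rate] = INCONCLUSIVE
    if config.missing_rate > 0:
        cells[rng.random((n, m)) < config.missing_rate] = UNTESTED

    calls = pd.DataFrame(cells, index=[rec.compound_id for rec in library], columns=assay_ids)
    in_vitro = rng.random(m) >= 0.1  # a few in vivo assays among the irrelevant ones
    in_vitro[planted] = True
    metadata = pd.DataFrame(
        {
            "in_vitro": in_vitro,
            "planted": planted,
            "description": [
                ("planted reporter assay" if planted[j] else "unrelated screen")
                for j in range(m)
            ],
        },
        index=assay_ids,
    )
    return AssayResponseMatrix(calls=calls, metadata=metadata)


def liver_labels(library: Sequence[CompoundRecord]) -> pd.Series:
    """Binary in vivo liver-damage labels (from latent truth)."""
    return pd.Series(
        {rec.compound_id: int(rec.truth.is_liver_toxic) for rec in library}, name="liver_damage"
    )


def are_truth_labels(library: Sequence[CompoundRecord]) -> pd.Series:
    return pd.Series(
        {rec.compound_id: int(rec.truth.is_are_active) for rec in library}, name="are_active"
    )


def generate_descriptor_sets(
    labels: Sequence[int] | np.ndarray,
    seed: int = 0,
    n_features: tuple[int, int] = (40, 300),
    n_informative: tuple[int, int] = (10, 30),
    separation: float = 1.0,
):
    """Two synthetic descriptor blocks with a planted class signal.

    Informative columns get a class-conditional mean shift of
    ``separation * w`` (w ~ U[0.5, 1.5]); the rest are standard normal
    noise.  Returns ``{"setA": (ids, names, X), "setB": ...}`` raw values
    (scaling is the modeling engine's job).
    """
    from .qsar import DescriptorMatrix

    y = np.asarray(labels, dtype=int)
    rng = np.random.default_rng((seed, 3))
    n = y.size
    ids = tuple(f"CMP{i:04d}" for i in range(n))
    out = {}
    for set_name, p, k in (
        ("setA", n_features[0], n_informative[0]),
        ("setB", n_features[1], n_informative[1]),
    ):
        X = rng.normal(size=(n, p))
        info = rng.choice(p, size=min(k, p), replace=False)
        w = rng.uniform(0.5, 1.5, size=info.size) * rng.choice([-1.0, 1.0], size=info.size)
        X[:, info] += np.outer(y, separation * w)
        names = tuple(f"{set_name}_d{j:04d}" for j in range(p))
        out[set_name] = DescriptorMatrix(ids=ids, features=names, values=X)
    return out


# ---------------------------------------------------------------------------
# writers

def write_smiles(library: Sequence[CompoundRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in library:
            fh.write(f"{rec.smiles}\t{rec.compound_id}\n")


def write_sdf(library: Sequence[CompoundRecord], path) -> None:
    writer = Chem.SDWriter(str(path))
    try:
        for rec in library:
            mol = Chem.MolFromSmiles(rec.smiles)
            mol.SetProp("_Name", rec.compound_id)
            writer.write(mol)
    finally:
        writer.close()


def write_curves_csv(curves: Sequence[CurveSeries], path) -> None:
    rows = []
    for c in curves:
        for k in range(len(c.concentrations)):
            rows.append(
                (c.compound_id, c.replicate, k, c.concentrations[k], c.responses[k])
            )
    pd.DataFrame(
        rows, columns=["compound_id", "replicate", "conc_index", "concentration_M", "response"]
    ).to_csv(path, index=False)


def write_labels_csv(labels: pd.Series, path) -> None:
    labels.rename("liver_damage").to_csv(path, index_label="compound_id")


def write_truth_csv(library: Sequence[CompoundRecord], path) -> None:
    rows = []
    for rec in library:
        row = {
            "compound_id": rec.compound_id,
            "is_are_active": int(rec.truth.is_are_active),
            "is_liver_toxic": int(rec.truth.is_liver_toxic),
        }
        row.update({k: int(v) for k, v in rec.truth.carries_fragment.items()})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
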