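"""Toxicophore matching, fragment-level IVIVC, and enrichment ranking.

User-supplied substructure patterns are matched against compound sets; the
compound subset carrying a fragment is evaluated for in vitro / in vivo
agreement (2x2 confusion and chi-squared).  A transparent, simplified
circular-fragment enumeration ranks candidate fragments by their odds ratio
of occurrence in dual-active compounds versus the rest (this is an openly
labeled simplification, not a reconstruction of commercial fragment-mining
tools).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger

from .bioprofile import ACTIVE, INACTIVE, AssayStats

RDLogger.DisableLog("rdApp.*")


class FragmentPatternError(ValueError):
    pass


@dataclass(frozen=True)
class FragmentSpec:
    fragment_id: str
    pattern: str  # SMILES/SMARTS substructure query
    provenance: str = "user_supplied"  # or "enumerated"


def _query_mol(pattern: str, fragment_id: str = "") -> Chem.Mol:
    q = Chem.MolFromSmarts(pattern)
    if q is None or q.GetNumAtoms() == 0:
        q = Chem.MolFromSmiles(pattern, sanitize=False)
        if q is not None:
            try:
                q.UpdatePropertyCache(strict=False)
                Chem.FastFindRings(q)
            except Exception:
                q = None
    if q is None or q.GetNumAtoms() == 0:
        raise FragmentPatternError(
            f"invalid substructure pattern for fragment {fragment_id or pattern!r}"
        )
    return q


def match(
    fragment: FragmentSpec, compounds: Sequence[tuple[str, str | Chem.Mol]]
) -> list[str]:
    """Compound ids containing the fragment (subgraph-isomorphism semantics).

    Output follows input order, so it is deterministic.
    """
    query = _query_mol(fragment.pattern, fragment.fragment_id)
    out = []
    for cid, structure in compounds:
        mol = Chem.MolFromSmiles(structure) if isinstance(structure, str) else structure
        if mol is not None and mol.HasSubstructMatch(query):
            out.append(cid)
    return out


@dataclass(frozen=True)
class FragmentIVIVC:
    fragment_id: str
    n_matched: int
    n_indeterminate: int  # matched but lacking a definite call or a label
    stats: AssayStats
    source: str  # experimental | predicted | mixed


def fragment_ivivc(
    matched_ids: Sequence[str],
    invitro_calls: Mapping[str, str] | pd.Series,
    invivo_labels: Mapping[str, int] | pd.Series,
    fragment_id: str = "",
    source: str = "experimental",
) -> FragmentIVIVC:
    """2x2 in vitro call vs in vivo label over the matched compounds.

    Compounds with inconclusive/untested calls or without a label count as
    indeterminate and stay out of the table.
    """
    if len(matched_ids) == 0:
        raise ValueError("matched compound set is empty")
    calls = pd.Series(invitro_calls)
    labels = pd.Series(invivo_labels)
    tp = tn = fp = fn = 0
    indeterminate = 0
    for cid in matched_ids:
        call = calls.get(cid)
        label = labels.get(cid)
        if call not in (ACTIVE, INACTIVE) or label is None or pd.isna(label):
            indeterminate += 1
            continue
        pos = int(label) == 1
        if call == ACTIVE:
            tp, fp = (tp + 1, fp) if pos else (tp, fp + 1)
        else:
            fn, tn = (fn + 1, tn) if pos else (fn, tn + 1)
    stats = AssayStats.from_counts(tp, tn, fp, fn)
    return FragmentIVIVC(
        fragment_id=fragment_id,
        n_matched=len(matched_ids),
        n_indeterminate=indeterminate,
        stats=stats,
        source=source,
    )


@dataclass(frozen=True)
class RankedFragment:
    spec: FragmentSpec
    odds_ratio: float
    n_dual: int
    n_other: int
    matched_ids: tuple[str, ...]


def enumerate_fragments(
    compounds: Sequence[tuple[str, str | Chem.Mol]],
    radius: int = 2,
    min_support: int = 5,
) -> dict[str, set[str]]:
    """Circular fragments (radius 0..``radius``) and the compounds carrying
    them, keyed by fragment SMILES."""
    occurrence: dict[str, set[str]] = {}
    for cid, structure in compounds:
        mol = Chem.MolFromSmiles(structure) if isinstance(structure, str) else structure
        if mol is None:
            continue
        seen: set[str] = set()
        for atom in mol.GetAtoms():
            for r in range(radius + 1):
                if r == 0:
                    sub_smiles = atom.GetSmarts()
                else:
                    env = Chem.FindAtomEnvironmentOfRadiusN(mol, r, atom.GetIdx())
                    if not env:
                        continue
                    amap: dict[int, int] = {}
                    sub = Chem.PathToSubmol(mol, env, atomMap=amap)
                    if sub.GetNumAtoms() == 0:
                        continue
                    sub_smiles = Chem.MolToSmiles(sub, canonical=True)
                if sub_smiles:
                    seen.add(sub_smiles)
        for s in seen:
            occurrence.setdefault(s, set()).add(cid)
    return {s: ids for s, ids in occurrence.items() if len(ids) >= min_support}


def rank_fragments(
    compounds: Sequence[tuple[str, str | Chem.Mol]],
    dual_activity_flags: Mapping[str, bool] | pd.Series,
    radius: int = 2,
    min_support: int = 5,
) -> list[RankedFragment]:
    """Rank enumerated circular fragments by enrichment in dual-active
    compounds (in vitro active AND in vivo toxic) versus the rest.

    Odds ratios use a 0.5 Haldane correction; descending order with the
    fragment pattern as tiebreak.  Requires both flag classes present.
    """
    flags = pd.Series(dual_activity_flags).astype(bool)
    ids = [cid for cid, _ in compounds]
    flags = flags.loc[[c for c in ids if c in flags.index]]
    n_dual_total = int(flags.sum())
    n_other_total = int((~flags).sum())
    if n_dual_total < 2 or n_other_total < 2:
        return []
    occurrence = enumerate_fragments(compounds, radius=radius, min_support=min_support)
    if not occurrence:
        warnings.warn("no fragment meets the minimum support")
        return []
    dual_ids = set(flags.index[flags])
    ranked = []
    for i, (smiles, carrier_ids) in enumerate(sorted(occurrence.items())):
        n_dual = len(carrier_ids & dual_ids)
        n_other = len(carrier_ids) - n_dual
        a, b = n_dual + 0.5, n_other + 0.5
        c, d = (n_dual_total - n_dual) + 0.5, (n_other_total - n_other) + 0.5
        odds_ratio = (a / c) / (b / d)
        ranked.append(
            RankedFragment(
                spec=FragmentSpec(f"enum_{smiles}", smiles, "enumerated"),
                odds_ratio=float(odds_ratio),
                n_dual=n_dual,
                n_other=n_other,
                matched_ids=tuple(sorted(carrier_ids)),
            )
        )
    ranked.sort(key=lambda rf: (-rf.odds_ratio, rf.spec.pattern))
    return ranked


def read_fragments_csv(path) -> list[FragmentSpec]:
    df = pd.read_csv(path)
    return [
        FragmentSpec(
            str(row["fragment_id"]),
            str(row["pattern"]),
            str(row.get("provenance", "user_supplied")),
        )
        for _, row in df.iterrows()
    ]


def write_ivivc_csv(results: Sequence[FragmentIVIVC], path) -> None:
    rows = []
    for r in results:
        s = r.stats
        rows.append(
            {
                "fragment_id": r.fragment_id,
                "n_matched": r.n_matched,
                "n_indeterminate": r.n_indeterminate,
                "TP": s.tp, "TN": s.tn, "FP": s.fp, "FN": s.fn,
                "sensitivity": s.sensitivity, "specificity": s.specificity,
                "ccr_pct": s.ccr_pct, "chi2_p": s.chi2_p,
                "source": r.source,
                "note": "simplified enrichment ranking" if r.source == "predicted" else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
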