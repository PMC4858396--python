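"""Chemical structure standardisation and deduplication.

Rules: desalt to the largest covalent component, reject metalorganics
(carbon-metal bond) and very large molecules (MW > 2000), neutralise
charges where a proton transfer suffices, strip stereochemistry, and
canonicalise.  Stereoisomers of the same constitution share one identity
key.  Every input ends up as exactly one CuratedCompound or Rejection.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors

RDLogger.DisableLog("rdApp.*")

log = logging.getLogger(__name__)

MW_LIMIT = 2000.0

#: elements whose bonds to carbon do NOT make a compound metalorganic
_NONMETAL_PARTNERS = frozenset(
    (1, 5, 6, 7, 8, 9, 14, 15, 16, 17, 34, 35, 53)  # H B C N O F Si P S Cl Se Br I
)

REASON_NO_STRUCTURE = "no_structure"
REASON_MW = "mw_gt_2000"
REASON_METALORGANIC = "metalorganic"
REASON_UNPARSEABLE = "unparseable"


@dataclass(frozen=True)
class CuratedCompound:
    canonical_structure: str
    identity_key: str
    provenance: tuple[str, ...] = ()


@dataclass(frozen=True)
class Rejection:
    original_id: str
    reason: str


def _largest_component(mol: Chem.Mol) -> tuple[Chem.Mol, bool]:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return mol, False
    # largest by heavy atoms; canonical SMILES breaks ties deterministically
    best = max(frags, key=lambda f: (f.GetNumHeavyAtoms(), Chem.MolToSmiles(f)))
    return best, True


def _is_metalorganic(mol: Chem.Mol) -> bool:
    for bond in mol.GetBonds():
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        nums = {a.GetAtomicNum(), b.GetAtomicNum()}
        if 6 in nums and not nums.issubset(_NONMETAL_PARTNERS):
            return True
    return False


def _neutralize(mol: Chem.Mol) -> Chem.Mol:
    """Neutralise formal charges where adding/removing a proton suffices.

    Quaternary nitrogens and other charges not fixable by proton transfer
    are left as-is.
    """
    mol = Chem.RWMol(mol)
    for atom in mol.GetAtoms():
        q = atom.GetFormalCharge()
        if q == 0:
            continue
        # charges balanced by an adjacent opposite charge (e.g. nitro groups
        # written charge-separated) are not proton-transfer fixable
        if any(n.GetFormalCharge() * q < 0 for n in atom.GetNeighbors()):
            continue
        if q > 0 and atom.GetTotalNumHs() >= q:
            atom.SetFormalCharge(0)
            atom.SetNumExplicitHs(max(atom.GetNumExplicitHs() - q, 0))
        elif q < 0:
            atom.SetFormalCharge(0)
            atom.SetNumExplicitHs(atom.GetNumExplicitHs() - q)
        atom.UpdatePropertyCache(strict=False)
    out = mol.GetMol()
    Chem.SanitizeMol(out)
    return out


def curate(structure, original_id: str = "") -> CuratedCompound | Rejection:
    """Standardise one structure (SMILES string or RDKit Mol).

    Returns a :class:`CuratedCompound` or a :class:`Rejection`; never raises
    on bad input.
    """
    oid = original_id or ""
    if structure is None:
        return Rejection(oid, REASON_NO_STRUCTURE)
    if isinstance(structure, str):
        if not structure.strip():
            return Rejection(oid, REASON_NO_STRUCTURE)
        mol = Chem.MolFromSmiles(structure)
        if mol is None:
            return Rejection(oid, REASON_UNPARSEABLE)
    elif isinstance(structure, Chem.Mol):
        mol = structure
    else:
        return Rejection(oid, REASON_UNPARSEABLE)
    if mol.GetNumAtoms() == 0:
        return Rejection(oid, REASON_NO_STRUCTURE)

    mol, was_mixture = _largest_component(mol)
    if was_mixture:
        log.info("mixture %s: retained largest component", oid or "<anon>")
    if _is_metalorganic(mol):
        return Rejection(oid, REASON_METALORGANIC)
    try:
        mol = _neutralize(mol)
    except Exception:
        return Rejection(oid, REASON_UNPARSEABLE)
    if Descriptors.MolWt(mol) > MW_LIMIT:
        return Rejection(oid, REASON_MW)
    Chem.RemoveStereochemistry(mol)
    canonical = Chem.MolToSmiles(mol)
    return CuratedCompound(
        canonical_structure=canonical,
        identity_key=canonical,
        provenance=(oid,) if oid else (),
    )


def curate_many(
    items: Iterable[tuple[str, object]]
) -> tuple[list[CuratedCompound], list[Rejection]]:
    """Curate (id, structure) pairs; totality: every input lands in one list."""
    curated: list[CuratedCompound] = []
    rejected: list[Rejection] = []
    for oid, structure in items:
        result = curate(structure, original_id=str(oid))
        if isinstance(result, CuratedCompound):
            curated.append(result)
        else:
            rejected.append(result)
    return curated, rejected


def deduplicate(
    records: Sequence[tuple[CuratedCompound, str]]
) -> list[tuple[CuratedCompound, str]]:
    """Merge records sharing an identity key; labels resolved by majority.

    Ties resolve to "inconclusive".  Provenance lists are concatenated.
    Output ordered by first appearance.
    """
    groups: dict[str, list[tuple[CuratedCompound, str]]] = {}
    order: list[str] = []
    for rec, label in records:
        if rec.identity_key not in groups:
            order.append(rec.identity_key)
        groups.setdefault(rec.identity_key, []).append((rec, label))
    out = []
    for key in order:
        members = groups[key]
        counts: dict[str, int] = {}
        for _, label in members:
            counts[label] = counts.get(label, 0) + 1
        top = max(counts.values())
        winners = sorted(lbl for lbl, c in counts.items() if c == top)
        resolved = winners[0] if len(winners) == 1 else "inconclusive"
        if len(members) > 1:
            log.info("deduplicated %d records for %s -> %s", len(members), key, resolved)
        provenance = tuple(p for rec, _ in members for p in rec.provenance)
        merged = CuratedCompound(members[0][0].canonical_structure, key, provenance)
        out.append((merged, resolved))
    return out


def read_smi(path) -> list[tuple[str, str]]:
    """Read 'structure<TAB>id' lines; returns (id, smiles) pairs."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            smiles = parts[0]
            cid = parts[1] if len(parts) > 1 else f"line{i + 1}"
            out.append((cid, smiles))
    return out


def read_sdf(path) -> list[tuple[str, Chem.Mol]]:
    out = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for i, mol in enumerate(supplier):
        name = mol.GetProp("_Name") if mol is not None and mol.HasProp("_Name") else f"sdf{i + 1}"
        out.append((name, mol))
    return out


def write_smi(curated: Sequence[CuratedCompound], path) -> None:
    with open(path, "w") as fh:
        for rec in curated:
            cid = rec.provenance[0] if rec.provenance else rec.identity_key
            fh.write(f"{rec.canonical_structure}\t{cid}\n")


def write_rejections_csv(rejections: Sequence[Rejection], path) -> None:
    with open(path, "w") as fh:
        fh.write("original_id,reason\n")
        for r in rejections:
            fh.write(f"{r.original_id},{r.reason}\n")
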