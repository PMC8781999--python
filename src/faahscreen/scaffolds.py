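"""Scaffold decomposition: Murcko frameworks, generic skeletons, plain rings.

Three scaffold notions drive the enrichment analysis:

* **MF** (Murcko framework): rings plus the linker atoms connecting them,
  all side chains removed; atom types and bond orders are preserved, and
  exocyclic multi-bonded atoms (e.g. a carbonyl O on a ring) are retained.
* **BM** (Bemis-Murcko generic skeleton): the MF with every atom relabelled
  to carbon and every bond set to single order — a pure connectivity
  scaffold. An acyclic molecule maps to the *null* skeleton.
* **PR** (plain ring): one fragment per ring system (rings sharing an atom
  or a bond, spiro included, form one system) with every single-bonded
  substituent erased; only double-bonded heteroatoms attached directly to
  a ring atom are kept.

Side-chain statistics (SC = MW(molecule) - MW(framework), plus counts of
the major substitution groups) complement the framework profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit.Chem import Descriptors
from rdkit.Chem.Scaffolds import MurckoScaffold

from .chem_io import CompoundRecord

log = logging.getLogger(__name__)

KINDS = ("MF", "BM", "PR")


@dataclass(frozen=True)
class ScaffoldKey:
    """A canonical scaffold of a given kind; hashable for counting."""

    kind: str
    canonical: str
    is_null: bool = False

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown scaffold kind {self.kind!r}")
        if self.is_null != (self.canonical == ""):
            raise ValueError("null scaffolds must have empty canonical SMILES")


def _null_key(kind: str) -> ScaffoldKey:
    return ScaffoldKey(kind=kind, canonical="", is_null=True)


def murcko_framework(record: CompoundRecord) -> ScaffoldKey:
    """Murcko framework of a molecule; acyclic molecules yield the null key."""
    mol = record.mol
    if mol.GetRingInfo().NumRings() == 0:
        return _null_key("MF")
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    return ScaffoldKey(kind="MF", canonical=Chem.MolToSmiles(scaffold))


def _make_generic(mol: Chem.Mol) -> Chem.Mol:
    """Relabel every atom to carbon and every bond to single order."""
    rw = Chem.RWMol(mol)
    for atom in rw.GetAtoms():
        atom.SetAtomicNum(6)
        atom.SetFormalCharge(0)
        atom.SetIsAromatic(False)
        atom.SetIsotope(0)
        atom.SetNoImplicit(False)
        atom.SetNumExplicitHs(0)
        atom.SetNumRadicalElectrons(0)
        atom.SetChiralTag(Chem.ChiralType.CHI_UNSPECIFIED)
    for bond in rw.GetBonds():
        bond.SetBondType(Chem.BondType.SINGLE)
        bond.SetIsAromatic(False)
        bond.SetStereo(Chem.BondStereo.STEREONONE)
    generic = rw.GetMol()
    Chem.SanitizeMol(generic)
    return generic


def bm_skeleton(record: CompoundRecord) -> ScaffoldKey:
    """Generic Bemis-Murcko skeleton (framework, atoms -> C, bonds -> single).

    Flattening bond orders turns the framework's exocyclic double-bonded
    atoms (e.g. a ring carbonyl O) into ordinary terminal side-chain atoms,
    so a final framework pass prunes them; this keeps the transformation
    idempotent.
    """
    mf = murcko_framework(record)
    if mf.is_null:
        return _null_key("BM")
    generic = _make_generic(Chem.MolFromSmiles(mf.canonical))
    generic = MurckoScaffold.GetScaffoldForMol(generic)
    return ScaffoldKey(kind="BM", canonical=Chem.MolToSmiles(generic))


def _ring_systems(mol: Chem.Mol) -> list[set[int]]:
    """Atom-index sets of fused ring systems (shared atom or bond merges)."""
    rings = [set(r) for r in mol.GetRingInfo().AtomRings()]
    systems: list[set[int]] = []
    for ring in rings:
        merged = set(ring)
        rest = []
        for system in systems:
            if system & merged:
                merged |= system
            else:
                rest.append(system)
        rest.append(merged)
        systems = rest
    return systems


def _extract_fragment(mol: Chem.Mol, keep: set[int]) -> Chem.Mol | None:
    """Submolecule on ``keep`` atom indices, with valences repaired.

    Atoms that lose substituents regain implicit hydrogens; an aromatic
    nitrogen that loses its exocyclic single bond gets an explicit H when
    needed to keep the ring kekulizable (N-methylpyrrole ring -> pyrrole).
    """
    # aromatic N atoms whose single-bonded substituent is being erased; only
    # these may need re-protonation (protonating every bare aromatic N would
    # break rings like imidazole that also hold a pyridine-type N)
    lost_sub = set()
    for idx in keep:
        atom = mol.GetAtomWithIdx(idx)
        if atom.GetAtomicNum() == 7 and atom.GetIsAromatic():
            for bond in atom.GetBonds():
                if (
                    bond.GetOtherAtom(atom).GetIdx() not in keep
                    and bond.GetBondType() == Chem.BondType.SINGLE
                ):
                    lost_sub.add(idx)
    new_index = {old: rank for rank, old in enumerate(sorted(keep))}

    rw = Chem.RWMol(mol)
    for idx in sorted(range(mol.GetNumAtoms()), reverse=True):
        if idx not in keep:
            rw.RemoveAtom(idx)
    frag = rw.GetMol()
    for atom in frag.GetAtoms():
        atom.SetNoImplicit(False)
        atom.SetChiralTag(Chem.ChiralType.CHI_UNSPECIFIED)

    # a failed sanitize can leave the molecule partially modified, so each
    # attempt runs on its own copy
    attempt = Chem.Mol(frag)
    try:
        Chem.SanitizeMol(attempt)
        return attempt
    except (Chem.KekulizeException, Chem.AtomValenceException, ValueError):
        pass
    # second chance: re-protonate the aromatic nitrogens that lost their
    # substituent (N-methylpyrrole ring -> pyrrole needs its N-H back)
    attempt = Chem.Mol(frag)
    for old_idx in lost_sub:
        atom = attempt.GetAtomWithIdx(new_index[old_idx])
        if atom.GetNumExplicitHs() == 0 and atom.GetFormalCharge() == 0:
            atom.SetNumExplicitHs(1)
    try:
        Chem.SanitizeMol(attempt)
        return attempt
    except (Chem.KekulizeException, Chem.AtomValenceException, ValueError):
        log.warning("plain-ring fragment could not be sanitized; dropped")
        return None


def plain_rings(record: CompoundRecord) -> set[ScaffoldKey]:
    """Plain-ring fragments: ring systems plus attached =X heteroatoms.

    Every single-bonded substituent is erased; double-bonded heteroatoms
    directly attached to a ring atom are retained (2-pyridone keeps its
    exocyclic =O). Duplicate fragments within one molecule collapse.
    Acyclic molecules yield the empty set.
    """
    mol = record.mol
    keys: set[ScaffoldKey] = set()
    for system in _ring_systems(mol):
        keep = set(system)
        for idx in system:
            atom = mol.GetAtomWithIdx(idx)
            for bond in atom.GetBonds():
                other = bond.GetOtherAtom(atom)
                if other.GetIdx() in keep:
                    continue
                if (
                    bond.GetBondTypeAsDouble() >= 2.0
                    and other.GetAtomicNum() not in (1, 6)
                ):
                    keep.add(other.GetIdx())
        frag = _extract_fragment(mol, keep)
        if frag is not None:
            keys.add(ScaffoldKey(kind="PR", canonical=Chem.MolToSmiles(frag)))
    return keys


def assign_scaffolds(
    records: Sequence[CompoundRecord], kind: str
) -> dict[str, set[ScaffoldKey]]:
    """Scaffold set per compound id.

    For MF/BM the set holds exactly one key (possibly the null key, so that
    acyclic compounds are counted in null-skeleton statistics); for PR it
    holds one key per distinct ring system, empty for acyclic molecules.
    """
    if kind not in KINDS:
        raise ValueError(f"unknown scaffold kind {kind!r}")
    fn = {"MF": murcko_framework, "BM": bm_skeleton}.get(kind)
    assignment: dict[str, set[ScaffoldKey]] = {}
    for rec in records:
        if kind == "PR":
            assignment[rec.id] = plain_rings(rec)
        else:
            assignment[rec.id] = {fn(rec)}
    return assignment


# ---------------------------------------------------------------------------
# Side-chain statistics

# Substructure definitions for the major substitution groups. The hydroxyl
# pattern excludes carboxylic OH, and the primary-amine pattern excludes
# primary amides, so the four overlapping groups stay disjoint.
_SUBSTITUTION_SMARTS = {
    "nF": "[F]",
    "nCl": "[Cl]",
    "nBr": "[Br]",
    "nI": "[I]",
    "nOH": "[OX2H;!$([OX2H][CX3]=[OX1])]",
    "nCOOH": "[CX3](=[OX1])[OX2H1]",
    "nCONH2": "[CX3](=[OX1])[NX3H2]",
    "nNH2": "[NX3H2;!$([NX3H2][CX3]=[OX1])]",
    "nNO2": "[$([NX3](=O)=O),$([NX3+](=O)[O-])]",
}
_SUBSTITUTION_QUERIES = {
    name: Chem.MolFromSmarts(smarts) for name, smarts in _SUBSTITUTION_SMARTS.items()
}


@dataclass
class SideChainProfile:
    """Side-chain size and substitution-group counts for one compound."""

    sc: float  # g/mol; MW(molecule) - MW(framework)
    sc_heavy: int
    nF: int = 0
    nCl: int = 0
    nBr: int = 0
    nI: int = 0
    nOH: int = 0
    nCOOH: int = 0
    nCONH2: int = 0
    nNH2: int = 0
    nNO2: int = 0
    acyclic: bool = False

    @property
    def nX(self) -> int:
        return self.nF + self.nCl + self.nBr + self.nI


def count_substitutions(record: CompoundRecord) -> dict[str, int]:
    mol = record.mol
    return {
        name: len(mol.GetSubstructMatches(query))
        for name, query in _SUBSTITUTION_QUERIES.items()
    }


def side_chain_stats(record: CompoundRecord) -> SideChainProfile:
    """SC size (mass and heavy atoms) plus substitution-group counts.

    For acyclic molecules the framework is null; SC is reported as the whole
    molecular weight with the ``acyclic`` flag set, and such compounds are
    excluded from SC summaries by default.
    """
    mf = murcko_framework(record)
    counts = count_substitutions(record)
    if mf.is_null:
        return SideChainProfile(
            sc=record.mw, sc_heavy=record.n_heavy, acyclic=True, **counts
        )
    mf_mol = Chem.MolFromSmiles(mf.canonical)
    sc = max(0.0, record.mw - Descriptors.MolWt(mf_mol))
    sc_heavy = record.n_heavy - mf_mol.GetNumHeavyAtoms()
    return SideChainProfile(sc=sc, sc_heavy=sc_heavy, **counts)


_HALOGENS = ("nF", "nCl", "nBr", "nI")


def side_chain_summary(profiles: Sequence[SideChainProfile]) -> dict[str, float]:
    """Library-level side-chain statistics over cyclic compounds.

    Reports the count and percentage of scaffold-only compounds (no
    side-chain heavy atoms) and of compounds whose side chains consist of
    halogen atoms only, plus SC range and mean. Percentages are relative to
    the full profile list.
    """
    if not profiles:
        raise ValueError("no profiles")
    n = len(profiles)
    cyclic = [p for p in profiles if not p.acyclic]
    no_side = [p for p in cyclic if p.sc_heavy == 0]
    halogen_only = [
        p for p in cyclic if p.sc_heavy > 0 and p.sc_heavy == p.nX
    ]
    sc_values = [p.sc for p in cyclic]
    return {
        "n": n,
        "n_no_sidechain": len(no_side),
        "pct_no_sidechain": 100.0 * len(no_side) / n,
        "n_halogen_only": len(halogen_only),
        "pct_halogen_only": 100.0 * len(halogen_only) / n,
        "sc_min": min(sc_values) if sc_values else float("nan"),
        "sc_max": max(sc_values) if sc_values else float("nan"),
        "sc_mean": sum(sc_values) / len(sc_values) if sc_values else float("nan"),
    }
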