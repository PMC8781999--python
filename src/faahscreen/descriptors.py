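"""The descriptor panel consumed by the activity classifier.

Eleven descriptors: Crippen logP, two topological/Burden 2D descriptors,
five WHIM total-size indices, one radial-distribution-function descriptor
and two charge-weighted surface areas. The 3D descriptors operate on a
single deterministic conformer (distance-geometry embedding plus force-field
minimization) with Gasteiger partial charges, hydrogen contributions folded
onto their heavy atoms.

All 3D descriptors are invariant under rigid motion of the conformer and
all descriptors are invariant under atom renumbering; identical input and
seed give bit-identical values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem, Crippen
from rdkit.Chem.EState import EStateIndices

from . import _elements
from .chem_io import CompoundRecord

log = logging.getLogger(__name__)

DESCRIPTOR_NAMES = [
    "CrippenLogP", "SpMAD_D", "SpMax5_Bhi",
    "Au", "Ae", "Ai", "As", "Av",
    "RDF85m", "WPSA1", "WPSA2",
]


@dataclass
class Conformer:
    """Heavy-atom geometry with per-atom charges, masses and weights.

    ``charges`` are Gasteiger partial charges with each hydrogen's charge
    added to its heavy neighbour; ``estate`` holds electrotopological-state
    indices (used as WHIM I-state weights). ``embedded_3d`` is False when
    distance-geometry embedding failed and planar fallback coordinates were
    used (flagged so such rows can be excluded downstream).
    """

    coords: np.ndarray  # (n_heavy, 3), Angstrom, centered
    charges: np.ndarray
    masses: np.ndarray
    elements: np.ndarray  # atomic numbers
    estate: np.ndarray
    seed: int
    embedded_3d: bool = True

    def __post_init__(self) -> None:
        n = len(self.coords)
        if not all(len(a) == n for a in (self.charges, self.masses, self.elements, self.estate)):
            raise ValueError("per-atom arrays must have equal length")
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite coordinates")


def embed_3d(record: CompoundRecord, seed: int = 0) -> Conformer:
    """Deterministic single-conformer 3D embedding with partial charges.

    Distance-geometry (ETKDG) embedding of the hydrogen-completed molecule,
    MMFF94 minimization (UFF fallback), Gasteiger charges. When embedding
    fails the 2D depiction coordinates with z = 0 are used and the conformer
    is flagged.
    """
    mol = Chem.AddHs(record.mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2**31 - 1)
    embedded = AllChem.EmbedMolecule(mol, params) == 0
    if embedded:
        try:
            if AllChem.MMFFHasAllMoleculeParams(mol):
                AllChem.MMFFOptimizeMolecule(mol, maxIters=500)
            else:
                AllChem.UFFOptimizeMolecule(mol, maxIters=500)
        except Exception:  # minimization failure leaves the raw embedding
            log.warning("%s: force-field minimization failed", record.id)
    else:
        log.warning("%s: 3D embedding failed; planar fallback", record.id)
        AllChem.Compute2DCoords(mol)

    AllChem.ComputeGasteigerCharges(mol)
    conf = mol.GetConformer()

    heavy = [a for a in mol.GetAtoms() if a.GetAtomicNum() != 1]
    coords = np.array([list(conf.GetAtomPosition(a.GetIdx())) for a in heavy])
    coords = coords - coords.mean(axis=0)
    charges = np.zeros(len(heavy))
    for i, atom in enumerate(heavy):
        q = float(atom.GetDoubleProp("_GasteigerCharge"))
        for nb in atom.GetNeighbors():
            if nb.GetAtomicNum() == 1:
                q += float(nb.GetDoubleProp("_GasteigerCharge"))
        charges[i] = q
    masses = np.array([a.GetMass() for a in heavy])
    elements = np.array([a.GetAtomicNum() for a in heavy])
    estate = np.asarray(EStateIndices(record.mol), dtype=float)
    return Conformer(
        coords=coords, charges=charges, masses=masses, elements=elements,
        estate=estate, seed=int(seed), embedded_3d=embedded,
    )


# ---------------------------------------------------------------------------
# 2D descriptors


def crippen_logp(record: CompoundRecord) -> float:
    """Wildman-Crippen atomic-contribution logP."""
    return float(Crippen.MolLogP(record.mol))


def spmad_distance(record: CompoundRecord) -> float:
    """Spectral mean absolute deviation of the topological distance matrix.

    Eigenvalues of the heavy-atom graph distance matrix; the descriptor is
    the mean absolute deviation of the spectrum from its mean. Single-atom
    molecules return 0.
    """
    mol = record.mol
    if mol.GetNumHeavyAtoms() < 2:
        return 0.0
    dist = Chem.GetDistanceMatrix(mol)
    eig = np.linalg.eigvalsh(dist)
    return float(np.mean(np.abs(eig - eig.mean())))


def burden_matrix(record: CompoundRecord, diagonal: np.ndarray) -> np.ndarray:
    """Burden connectivity matrix with a caller-supplied diagonal weighting.

    Off-diagonal entries follow Burden's convention: 0.1 x conventional bond
    order for bonded pairs (0.15 for aromatic bonds), +0.01 when either atom
    is terminal, and 0.001 for non-bonded pairs.
    """
    mol = record.mol
    n = mol.GetNumHeavyAtoms()
    b = np.full((n, n), 0.001)
    np.fill_diagonal(b, diagonal)
    degrees = [a.GetDegree() for a in mol.GetAtoms()]
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if bond.GetIsAromatic():
            v = 0.15
        else:
            v = 0.1 * bond.GetBondTypeAsDouble()
        if degrees[i] == 1 or degrees[j] == 1:
            v += 0.01
        b[i, j] = b[j, i] = v
    return b


def burden_spmax5(record: CompoundRecord) -> float:
    """5th largest absolute eigenvalue of the ionization-weighted Burden matrix.

    The diagonal carries first ionization energies relative to carbon.
    Molecules with fewer than five heavy atoms return the smallest available
    absolute eigenvalue (a flagged degenerate value).
    """
    diag = np.array(
        [_elements.relative_ionization(a.GetAtomicNum()) for a in record.mol.GetAtoms()]
    )
    eig = np.sort(np.abs(np.linalg.eigvalsh(burden_matrix(record, diag))))[::-1]
    if len(eig) < 5:
        log.debug("%s: fewer than 5 heavy atoms; SpMax5 degenerate", record.id)
        return float(eig[-1])
    return float(eig[4])


# ---------------------------------------------------------------------------
# 3D descriptors

WHIM_WEIGHTINGS = ("unweighted", "sanderson_en", "ionization", "istate", "vdw_volume")
_WHIM_NAME = {
    "unweighted": "Au", "sanderson_en": "Ae", "ionization": "Ai",
    "istate": "As", "vdw_volume": "Av",
}


def _whim_weights(conformer: Conformer, weighting: str) -> np.ndarray:
    if weighting == "unweighted":
        return np.ones(len(conformer.coords))
    if weighting == "sanderson_en":
        return np.array([_elements.relative_en(z) for z in conformer.elements])
    if weighting == "ionization":
        return np.array([_elements.relative_ionization(z) for z in conformer.elements])
    if weighting == "istate":
        # E-state indices can be slightly negative for buried atoms; clip at
        # zero so the weighted covariance stays positive semidefinite.
        return np.clip(conformer.estate, 0.0, None)
    if weighting == "vdw_volume":
        return np.array([_elements.relative_vdw_volume(z) for z in conformer.elements])
    raise ValueError(f"unknown WHIM weighting {weighting!r}")


def whim_size(conformer: Conformer, weighting: str = "unweighted") -> float:
    """WHIM total size index A: second symmetric function of the eigenvalues.

    The weighted covariance matrix of the centered coordinates has
    eigenvalues l1 >= l2 >= l3; A = l1*l2 + l1*l3 + l2*l3. Planar or linear
    geometries are allowed (l3 = 0).
    """
    w = _whim_weights(conformer, weighting)
    total = w.sum()
    if total <= 0 or len(conformer.coords) < 2:
        return 0.0
    center = (w[:, None] * conformer.coords).sum(axis=0) / total
    x = conformer.coords - center
    cov = (w[:, None] * x).T @ x / total
    l1, l2, l3 = np.sort(np.linalg.eigvalsh(cov))[::-1]
    return float(l1 * l2 + l1 * l3 + l2 * l3)


def rdf_descriptor(
    conformer: Conformer, r: float = 8.5, beta: float = 100.0,
    weighting: str = "mass",
) -> float:
    """Radial distribution function at radius ``r``, mass-weighted.

    g(r) = sum over atom pairs i<j of w_i * w_j * exp(-beta (r - r_ij)^2)
    with w the atomic mass relative to carbon; ``beta`` (per Angstrom^2)
    controls the Gaussian smoothing. Single atoms return 0.
    """
    n = len(conformer.coords)
    if n < 2:
        return 0.0
    if weighting == "mass":
        w = conformer.masses / _elements.CARBON_MASS
    elif weighting == "unweighted":
        w = np.ones(n)
    else:
        raise ValueError(f"unknown RDF weighting {weighting!r}")
    diff = conformer.coords[:, None, :] - conformer.coords[None, :, :]
    dists = np.sqrt((diff**2).sum(axis=-1))
    iu = np.triu_indices(n, k=1)
    return float(np.sum(w[iu[0]] * w[iu[1]] * np.exp(-beta * (r - dists[iu]) ** 2)))


def shrake_rupley_sasa(
    coords: np.ndarray, radii: np.ndarray, probe: float = 1.4, n_points: int = 960
) -> np.ndarray:
    """Per-atom solvent-accessible surface area by Shrake-Rupley sampling.

    Deterministic golden-spiral sphere points; each atom's accessible
    fraction is the share of its (radius + probe) sphere points outside all
    neighbouring spheres.
    """
    n = len(coords)
    k = np.arange(n_points)
    # golden-spiral unit sphere
    z = 1.0 - 2.0 * (k + 0.5) / n_points
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    rho = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    sphere = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])

    extended = radii + probe
    sasa = np.zeros(n)
    for i in range(n):
        points = coords[i] + extended[i] * sphere
        accessible = np.ones(n_points, dtype=bool)
        for j in range(n):
            if j == i:
                continue
            d2 = ((points - coords[j]) ** 2).sum(axis=1)
            accessible &= d2 > extended[j] ** 2
        sasa[i] = 4.0 * np.pi * extended[i] ** 2 * accessible.mean()
    return sasa


def wpsa_from_sasa(sasa: np.ndarray, charges: np.ndarray) -> tuple[float, float]:
    """WPSA-1/WPSA-2 from per-atom surface areas and partial charges.

    PPSA1 is the summed surface of positively charged atoms; PPSA2 is PPSA1
    times the total positive charge; each is multiplied by the total surface
    and divided by 1000.
    """
    sasa = np.asarray(sasa, dtype=float)
    charges = np.asarray(charges, dtype=float)
    positive = charges > 0
    ppsa1 = float(sasa[positive].sum())
    ppsa2 = float(charges[positive].sum()) * ppsa1
    tmsa = float(sasa.sum())
    return ppsa1 * tmsa / 1000.0, ppsa2 * tmsa / 1000.0


def cpsa_wpsa(conformer: Conformer, probe: float = 1.4) -> tuple[float, float]:
    """Surface-weighted charged partial surface areas (WPSA-1, WPSA-2)."""
    if not np.isfinite(conformer.charges).all():
        raise ValueError("missing or non-finite partial charges")
    radii = np.array([_elements.VDW_RADIUS[z] for z in conformer.elements])
    sasa = shrake_rupley_sasa(conformer.coords, radii, probe=probe)
    return wpsa_from_sasa(sasa, conformer.charges)


# ---------------------------------------------------------------------------
# Panel assembly


def compute_descriptors(record: CompoundRecord, seed: int = 0) -> dict[str, float]:
    """The full 11-descriptor vector for one compound."""
    conformer = embed_3d(record, seed=seed)
    wpsa1, wpsa2 = cpsa_wpsa(conformer)
    values = {
        "CrippenLogP": crippen_logp(record),
        "SpMAD_D": spmad_distance(record),
        "SpMax5_Bhi": burden_spmax5(record),
        "RDF85m": rdf_descriptor(conformer),
        "WPSA1": wpsa1,
        "WPSA2": wpsa2,
    }
    for weighting in WHIM_WEIGHTINGS:
        values[_WHIM_NAME[weighting]] = whim_size(conformer, weighting)
    return values


def descriptor_table(
    records, seed: int = 0, id_column: str = "id"
) -> pd.DataFrame:
    """Descriptor panel for a record list, indexed by compound id."""
    rows = []
    for rec in records:
        row = {id_column: rec.id}
        row.update(compute_descriptors(rec, seed=seed))
        rows.append(row)
    return pd.DataFrame(rows, columns=[id_column] + DESCRIPTOR_NAMES)
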