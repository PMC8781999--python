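"""Synthetic libraries with the statistical structure the pipeline assumes.

The generator emulates the shape of a curated inhibitor/decoy study without
any database download: actives are built by decorating ring scaffolds drawn
with enrichment odds (an over-weighted scaffold appears more often among
actives than decoys), potency follows the scaffold class, every structure
passes the standard property window, and docking scores are drawn so that
the strong/weak class means match the reported -9.71 / -8.12 kcal/mol.
Ground truth (which scaffold seeded each compound) is recorded so scaffold
recovery can be checked exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from .chem_io import CompoundRecord
from .curation import PropertyWindow

log = logging.getLogger(__name__)

#: Ring systems prominent among known FAAH inhibitors (benzene, piperazine,
#: pyridine, piperidine) plus common background rings, with default
#: enrichment odds: the relative weight of the scaffold among actives versus
#: decoys.
DEFAULT_SCAFFOLDS: tuple[tuple[str, float], ...] = (
    ("c1ccccc1", 2.0),        # benzene
    ("C1CNCCN1", 8.0),        # piperazine
    ("c1ccncc1", 4.0),        # pyridine
    ("C1CCNCC1", 6.0),        # piperidine
    ("C1CCCCC1", 1.0),        # cyclohexane
    ("C1COCCN1", 1.0),        # morpholine
    ("c1ccsc1", 1.0),         # thiophene
    ("c1ccoc1", 1.0),         # furan
)

#: Acyclic substituents only, so the ring-system landscape of a generated
#: library is exactly the scaffold pool.
DEFAULT_SUBSTITUENTS: tuple[str, ...] = (
    "C", "CC", "CCC", "CC(C)C", "CCCC", "OC", "OCC", "N(C)C",
    "F", "Cl", "C(F)(F)F", "C#N", "C(=O)N", "C(=O)OC", "S(=O)(=O)C",
    "CCO", "CCN", "C(=O)C",
)


@dataclass
class SyntheticConfig:
    """Generator parameters for planted-enrichment libraries.

    Potency defaults keep the strong/weak thresholds (8/5) well inside each
    class: enriched-scaffold compounds draw pIC50 from N(8.5, 0.6), others
    from N(4.5, 0.4). Docking defaults reproduce the reported class means
    (weak -8.12, strong -9.71 kcal/mol, i.e. slope -1.59).
    """

    n_fi: int = 200
    decoy_ratio: int = 10
    enriched_scaffolds: tuple[tuple[str, float], ...] = DEFAULT_SCAFFOLDS
    substituent_pool: tuple[str, ...] = DEFAULT_SUBSTITUENTS
    pic50_active_mean: float = 8.5
    pic50_active_sd: float = 0.6
    pic50_inactive_mean: float = 4.5
    pic50_inactive_sd: float = 0.4
    docking_intercept: float = -8.12  # kcal/mol, weak-class mean
    docking_slope: float = -1.59  # kcal/mol shift for the strong class
    docking_noise_sd: float = 1.2  # kcal/mol
    seed: int = 0
    window: PropertyWindow = field(default_factory=PropertyWindow)

    def __post_init__(self) -> None:
        if self.n_fi < 50:
            raise ValueError("n_fi >= 50 required for stable scoring tests")
        if any(odds <= 0 for _, odds in self.enriched_scaffolds):
            raise ValueError("enrichment odds must be positive")
        if min(self.pic50_active_sd, self.pic50_inactive_sd) <= 0:
            raise ValueError("pIC50 standard deviations must be positive")
        if self.docking_noise_sd < 0:
            raise ValueError("docking noise must be non-negative")


def _attachment_points(mol: Chem.Mol) -> list[int]:
    return [a.GetIdx() for a in mol.GetAtoms() if a.GetTotalNumHs() > 0]


def _attach(core: Chem.Mol, substituent: str, atom_idx: int) -> Chem.Mol | None:
    frag = Chem.MolFromSmiles(substituent)
    if frag is None:
        return None
    combo = Chem.RWMol(Chem.CombineMols(core, frag))
    combo.AddBond(atom_idx, core.GetNumAtoms(), Chem.BondType.SINGLE)
    mol = combo.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return mol


def _decorate(
    scaffold: str, substituents: tuple[str, ...], rng: np.random.Generator,
    window: PropertyWindow, max_attempts: int = 30,
) -> str | None:
    """Random window-passing decoration of a scaffold; canonical SMILES."""
    base = Chem.MolFromSmiles(scaffold)
    if base is None:
        raise ValueError(f"unparsable scaffold SMILES {scaffold!r}")
    for _ in range(max_attempts):
        mol = Chem.Mol(base)
        n_sub = int(rng.integers(2, 6))
        for _ in range(n_sub):
            points = _attachment_points(mol)
            if not points:
                break
            candidate = _attach(
                mol,
                str(rng.choice(substituents)),
                int(rng.choice(points)),
            )
            if candidate is not None:
                mol = candidate
        rec = CompoundRecord.from_smiles(Chem.MolToSmiles(mol), id="probe")
        if rec is not None and window.contains(rec):
            return rec.smiles_canonical
    return None


def generate_library(
    config: SyntheticConfig,
) -> tuple[list[CompoundRecord], list[CompoundRecord], pd.DataFrame]:
    """Generate an active set, a decoy set and the ground-truth table.

    Actives draw their scaffold proportionally to the enrichment odds and
    their pIC50 from the scaffold-class potency distribution; decoys draw
    scaffolds with inverted weights (1/odds). All structures pass the
    property window, actives and decoys are disjoint by canonical SMILES,
    and the whole library is reproducible from the seed.
    """
    rng = np.random.default_rng(config.seed)
    scaffolds = [s for s, _ in config.enriched_scaffolds]
    odds = np.array([o for _, o in config.enriched_scaffolds])
    w_active = odds / odds.sum()
    w_decoy = (1.0 / odds) / (1.0 / odds).sum()

    seen: set[str] = set()
    truth_rows = []

    def _build(n: int, weights: np.ndarray, tag: str) -> list[CompoundRecord]:
        out: list[CompoundRecord] = []
        attempts = 0
        while len(out) < n:
            attempts += 1
            # allow a handful of failures per success; a pool that cannot
            # produce window-passing unique structures aborts quickly
            if attempts > 8 * len(out) + 100:
                raise RuntimeError(
                    "scaffold/substituent pools produce too few window-passing "
                    f"unique structures for the {tag} set"
                )
            s_idx = int(rng.choice(len(scaffolds), p=weights))
            smiles = _decorate(
                scaffolds[s_idx], config.substituent_pool, rng, config.window
            )
            if smiles is None or smiles in seen:
                continue
            seen.add(smiles)
            cid = f"{tag}{len(out) + 1:05d}"
            enriched = odds[s_idx] > 1.0
            pic50 = None
            if tag == "FI":
                if enriched:
                    pic50 = float(rng.normal(config.pic50_active_mean, config.pic50_active_sd))
                else:
                    pic50 = float(rng.normal(config.pic50_inactive_mean, config.pic50_inactive_sd))
            rec = CompoundRecord.from_smiles(smiles, id=cid, pic50=pic50, set_tag=tag)
            out.append(rec)
            truth_rows.append(
                {
                    "id": cid, "set_tag": tag, "scaffold": scaffolds[s_idx],
                    "odds": float(odds[s_idx]), "enriched": enriched,
                }
            )
        return out

    fi = _build(config.n_fi, w_active, "FI")
    dcy = _build(config.n_fi * config.decoy_ratio, w_decoy, "DCY")
    return fi, dcy, pd.DataFrame(truth_rows)


def simulate_docking(
    records: list[CompoundRecord], config: SyntheticConfig, seed: int | None = None
) -> pd.DataFrame:
    """Gaussian docking scores with an activity-class shift.

    dG = intercept + slope * shift + noise, with shift 1 for strong
    compounds (pIC50 > 8), 0 for weak (pIC50 < 5), and 0.5 for mid-range or
    unscored compounds. Defaults reproduce the reported class means.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rows = []
    for rec in records:
        if rec.pic50 is None:
            shift = 0.5
        elif rec.pic50 > 8.0:
            shift = 1.0
        elif rec.pic50 < 5.0:
            shift = 0.0
        else:
            shift = 0.5
        dg = config.docking_intercept + config.docking_slope * shift
        if config.docking_noise_sd > 0:
            dg += float(rng.normal(0.0, config.docking_noise_sd))
        rows.append(
            {
                "id": rec.id, "dg": dg, "n_heavy": rec.n_heavy,
                "le": abs(dg) / rec.n_heavy, "covalent": False,
            }
        )
    return pd.DataFrame(rows)


def generate_flag_fixture(
    n: int,
    coefficients: dict[str, float] | None = None,
    intercept: float | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Bernoulli flag table with labels drawn from a flag logistic model.

    Flags are independent Bernoulli(0.5); labels are Bernoulli(P) with P
    from the supplied (default: published) coefficients. Used for
    parameter-recovery checks of the logistic refit.
    """
    from .classifier import PUBLISHED_COEFFICIENTS, PUBLISHED_INTERCEPT

    if n < 100:
        raise ValueError("n >= 100 required for a usable fixture")
    coefficients = dict(PUBLISHED_COEFFICIENTS) if coefficients is None else coefficients
    intercept = PUBLISHED_INTERCEPT if intercept is None else intercept
    rng = np.random.default_rng(seed)
    flags = pd.DataFrame(
        rng.integers(0, 2, size=(n, len(coefficients))),
        columns=list(coefficients),
    )
    logit = intercept + flags.to_numpy() @ np.array(list(coefficients.values()))
    proba = 1.0 / (1.0 + np.exp(-logit))
    labels = (rng.random(n) < proba).astype(int)
    return flags, labels
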