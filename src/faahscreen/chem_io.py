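"""Molecule and table input/output.

Reads structure libraries (SMILES, SDF, CSV activity tables) into
:class:`CompoundRecord` objects carrying canonical SMILES and the four
physicochemical properties the screening protocol filters on (MW, Crippen
logP, Lipinski HBA/HBD), and writes tabular results back to CSV.

Conventions
-----------
* Salts/mixtures: the largest organic fragment is kept before
  canonicalization.
* HBA = number of N + O atoms; HBD = number of N-H and O-H hydrogens
  (Lipinski-style counts).
* logP is the Wildman-Crippen atomic-contribution estimate throughout, so
  the curation filter and the descriptor panel agree with each other.
"""

from __future__ import annotations

import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, Lipinski

log = logging.getLogger(__name__)

# RDKit is chatty about every unparsable SMILES; we report skips ourselves.
RDLogger.DisableLog("rdApp.error")

#: Elements considered "organic" for this pipeline. Anything outside this set
#: marks the compound as organometallic (removed during curation because such
#: structures break descriptor computation and never occur among the actives).
ALLOWED_ELEMENTS = frozenset(
    {1, 5, 6, 7, 8, 9, 14, 15, 16, 17, 34, 35, 53}
)  # H B C N O F Si P S Cl Se Br I


@dataclass
class CompoundRecord:
    """One molecule with identity, properties and optional activity.

    ``label`` is ``"strong"`` (pIC50 > 8), ``"weak"`` (pIC50 < 5) or
    ``"unlabeled"``; ``set_tag`` marks provenance (``FI`` actives, ``DCY``
    decoys, or ``candidate``).
    """

    id: str
    smiles_input: str
    smiles_canonical: str
    mw: float
    logp: float
    hba: int
    hbd: int
    n_heavy: int
    pic50: float | None = None
    label: str = "unlabeled"
    set_tag: str = "candidate"

    _mol: Chem.Mol | None = field(default=None, repr=False, compare=False)

    @property
    def mol(self) -> Chem.Mol:
        """RDKit molecule, rebuilt from the canonical SMILES on demand."""
        if self._mol is None:
            self._mol = Chem.MolFromSmiles(self.smiles_canonical)
        return self._mol

    @classmethod
    def from_smiles(
        cls, smiles: str, id: str, pic50: float | None = None, set_tag: str = "candidate"
    ) -> "CompoundRecord | None":
        """Build a record from a SMILES string, or ``None`` if unparsable."""
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            return None
        mol = largest_organic_fragment(mol)
        if mol is None or mol.GetNumHeavyAtoms() == 0:
            return None
        canonical = Chem.MolToSmiles(mol)
        return cls(
            id=id,
            smiles_input=smiles,
            smiles_canonical=canonical,
            mw=Descriptors.MolWt(mol),
            logp=Crippen.MolLogP(mol),
            hba=Lipinski.NOCount(mol),
            hbd=Lipinski.NHOHCount(mol),
            n_heavy=mol.GetNumHeavyAtoms(),
            pic50=pic50,
            set_tag=set_tag,
            _mol=mol,
        )


def largest_organic_fragment(mol: Chem.Mol) -> Chem.Mol | None:
    """Largest fragment (by heavy-atom count) that contains carbon.

    Falls back to the overall largest fragment when no fragment contains
    carbon, so purely inorganic inputs still yield a molecule (they are
    flagged later by :func:`is_organometallic`).
    """
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if not frags:
        return None
    organic = [f for f in frags if any(a.GetAtomicNum() == 6 for a in f.GetAtoms())]
    pool = organic if organic else list(frags)
    best = max(pool, key=lambda f: (f.GetNumHeavyAtoms(), Descriptors.MolWt(f)))
    Chem.SanitizeMol(best)
    return best


def is_organometallic(record: CompoundRecord) -> bool:
    """True iff any atom falls outside the allowed organic element set."""
    return any(
        atom.GetAtomicNum() not in ALLOWED_ELEMENTS for atom in record.mol.GetAtoms()
    )


def _pic50_from_ic50(raw: object) -> float | None:
    """pIC50 from a numeric molar IC50; qualified or non-positive -> None."""
    try:
        value = float(raw)  # rejects ">1e-6", "~2e-8", "" etc.
    except (TypeError, ValueError):
        return None
    if not math.isfinite(value) or value <= 0:
        return None
    return -math.log10(value)


def parse_structures(path: str | Path, format: str | None = None) -> list[CompoundRecord]:
    """Read molecules from ``.smi``, SDF or CSV into compound records.

    Unparsable entries are logged with their line/row number and skipped;
    a file from which nothing parses is an error.

    CSV files need ``id`` and ``smiles`` columns; an optional ``ic50`` column
    (molar) is converted to pIC50. Qualified IC50 strings (">1e-6", "~2e-8")
    are not numeric and leave pIC50 unset, which downstream curation treats
    as "approximate value: drop before duplicate merging".
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {".smi": "smiles", ".sdf": "sdf", ".csv": "csv", ".tsv": "csv"}.get(
            path.suffix.lower(), "smiles"
        )

    records: list[CompoundRecord] = []
    n_skipped = 0
    if format == "smiles":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split(None, 1)
                smiles = parts[0]
                mol_id = parts[1].strip() if len(parts) > 1 else f"mol{lineno}"
                rec = CompoundRecord.from_smiles(smiles, id=mol_id)
                if rec is None:
                    log.warning("%s line %d: unparsable SMILES %r, skipped", path, lineno, smiles)
                    n_skipped += 1
                else:
                    records.append(rec)
    elif format == "sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        for i, mol in enumerate(supplier, start=1):
            if mol is None:
                log.warning("%s entry %d: unparsable SDF record, skipped", path, i)
                n_skipped += 1
                continue
            mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol{i}"
            rec = CompoundRecord.from_smiles(Chem.MolToSmiles(mol), id=mol_id)
            if rec is None:
                n_skipped += 1
            else:
                records.append(rec)
    elif format == "csv":
        sep = "\t" if path.suffix.lower() == ".tsv" else ","
        frame = pd.read_csv(path, sep=sep, dtype={"id": str})
        missing = {"id", "smiles"} - set(frame.columns)
        if missing:
            raise ValueError(f"{path}: missing required columns {sorted(missing)}")
        for row_idx, row in frame.iterrows():
            pic50 = None
            if "pic50" in frame.columns and pd.notna(row["pic50"]):
                pic50 = float(row["pic50"])
            elif "ic50" in frame.columns:
                pic50 = _pic50_from_ic50(row["ic50"])
                if pic50 is None and pd.notna(row["ic50"]):
                    log.warning(
                        "%s row %d: qualified or non-positive IC50 %r, activity dropped",
                        path, row_idx + 2, row["ic50"],
                    )
            rec = CompoundRecord.from_smiles(str(row["smiles"]), id=str(row["id"]), pic50=pic50)
            if rec is None:
                log.warning("%s row %d: unparsable SMILES %r, skipped", path, row_idx + 2, row["smiles"])
                n_skipped += 1
            else:
                records.append(rec)
    else:
        raise ValueError(f"unknown format {format!r}")

    if not records:
        raise ValueError(f"{path}: no parsable structures (skipped {n_skipped})")
    if n_skipped:
        log.info("%s: parsed %d structures, skipped %d", path, len(records), n_skipped)
    return records


#: Stable column order for record tables.
RECORD_COLUMNS = [
    "id", "smiles_input", "smiles_canonical", "mw", "logp", "hba", "hbd",
    "n_heavy", "pic50", "label", "set_tag",
]


def records_to_frame(records: Sequence[CompoundRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        row = asdict(rec)
        row.pop("_mol", None)
        rows.append(row)
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[CompoundRecord]:
    records = []
    for _, row in frame.iterrows():
        records.append(
            CompoundRecord(
                id=str(row["id"]),
                smiles_input=str(row["smiles_input"]),
                smiles_canonical=str(row["smiles_canonical"]),
                mw=float(row["mw"]),
                logp=float(row["logp"]),
                hba=int(row["hba"]),
                hbd=int(row["hbd"]),
                n_heavy=int(row["n_heavy"]),
                pic50=float(row["pic50"]) if pd.notna(row["pic50"]) else None,
                label=str(row["label"]),
                set_tag=str(row["set_tag"]),
            )
        )
    return records


def write_table(
    records: "Sequence[CompoundRecord] | pd.DataFrame", path: str | Path
) -> Path:
    """Write records (or any score table) to CSV with stable column order.

    Floats are written with full round-trip precision so re-reading the file
    reproduces values bit-identically. An empty input is an error and no file
    is created.
    """
    if isinstance(records, pd.DataFrame):
        frame = records
    else:
        frame = records_to_frame(list(records))
    if frame.empty:
        raise ValueError("refusing to write an empty table")
    path = Path(path)
    frame.to_csv(path, index=False, float_format="%.17g")  # bit-exact round trip
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    # the default C float parser is lossy; round_trip preserves written values
    return pd.read_csv(path, dtype={"id": str}, float_precision="round_trip")
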