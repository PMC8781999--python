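"""The candidate-screening cascade and docking-result post-filters.

Candidates pass, in order: (1) the physicochemical property window with
organometallic removal, (2) the halogen substitution filter (the ranges
observed across the inhibitor set), (3) a repurposing-score threshold
(default 5.17, strict), (4) the published logistic model at probability
> 0.7, and (5), when a docking table is supplied, ligand-efficiency and
binding-energy thresholds (0.25 <= LE <= 0.4, dG <= -6 kcal/mol). A
compound failing a stage leaves later stages unevaluated.

Docking is consumed, never executed: binding energies arrive as a CSV from
any engine; heavy-atom counts for ligand efficiency come from the
structure, not from the docking file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .chem_io import CompoundRecord, is_organometallic
from .classifier import (
    HIGHLY_ACTIVE_PROBABILITY,
    PUBLISHED_MODEL,
    LogisticModel,
    flagize_table,
)
from .curation import PropertyWindow
from .scaffolds import ScaffoldKey, bm_skeleton, count_substitutions, plain_rings
from .scoring import repurposing_score

log = logging.getLogger(__name__)

DEFAULT_RPS_THRESHOLD = 5.17

#: Halogen-count ranges observed across the inhibitor set; candidates
#: outside them are filtered out.
FI_SUBSTITUTION_RANGES = {
    "nF": (0, 8),
    "nCl": (0, 3),
    "nBr": (0, 2),
    "nI": (0, 1),
}


def substitution_filter(
    counts: dict[str, int],
    ranges: dict[str, tuple[int, int]] | None = None,
) -> bool:
    """True iff every substitution count lies inside its closed range."""
    ranges = ranges or FI_SUBSTITUTION_RANGES
    return all(lo <= counts[name] <= hi for name, (lo, hi) in ranges.items())


def ligand_efficiency(dg: float, n_heavy: int) -> float:
    """Absolute binding energy per heavy atom (kcal/mol per atom)."""
    if n_heavy < 1:
        raise ValueError("ligand efficiency needs n_heavy >= 1")
    return abs(dg) / n_heavy


@dataclass
class DockingRecord:
    """One ligand's docking outcome with the derived efficiency."""

    ligand_id: str
    dg: float  # kcal/mol; negative for binders
    n_heavy: int
    covalent: bool = False
    le: float = None  # type: ignore[assignment]
    pass_docking: bool | None = None

    def __post_init__(self) -> None:
        if self.le is None:
            self.le = ligand_efficiency(self.dg, self.n_heavy)


def docking_filter(
    records: list[DockingRecord],
    le_low: float = 0.25,
    le_high: float = 0.4,
    dg_max: float = -6.0,
    exempt_covalent: bool = False,
) -> list[DockingRecord]:
    """Apply the efficiency and binding-energy thresholds in place.

    Pass iff ``le_low <= LE <= le_high`` and ``dG <= dg_max``. Poses flagged
    covalent can optionally be exempted from the energy threshold (their
    reported dG is not comparable to non-covalent scores); the exemption is
    off by default.
    """
    for rec in records:
        energy_ok = rec.dg <= dg_max or (exempt_covalent and rec.covalent)
        rec.pass_docking = bool(le_low <= rec.le <= le_high and energy_ok)
    return records


def read_docking_table(frame: pd.DataFrame, n_heavy: dict[str, int]) -> list[DockingRecord]:
    """Docking records from a (ligand id, dg) table plus structure sizes."""
    records = []
    for _, row in frame.iterrows():
        lid = str(row["id"])
        if lid not in n_heavy:
            log.warning("docking row %s has no matching structure; skipped", lid)
            continue
        records.append(
            DockingRecord(
                ligand_id=lid,
                dg=float(row["dg"]),
                n_heavy=n_heavy[lid],
                covalent=bool(row.get("covalent", False)),
            )
        )
    return records


@dataclass
class ScreeningResult:
    """Per-candidate cascade outcome; unevaluated stages stay None."""

    id: str
    pass_property: bool
    pass_substitution: bool | None = None
    rps: float | None = None
    pass_rps: bool | None = None
    prob: float | None = None
    pass_prob: bool | None = None
    pass_docking: bool | None = None
    final: bool = False


def screen_library(
    candidates: list[CompoundRecord],
    pr_iscores: dict[ScaffoldKey, float],
    bm_iscores: dict[ScaffoldKey, float],
    model: LogisticModel = PUBLISHED_MODEL,
    descriptor_flags: pd.DataFrame | None = None,
    window: PropertyWindow | None = None,
    rps_threshold: float = DEFAULT_RPS_THRESHOLD,
    prob_threshold: float = HIGHLY_ACTIVE_PROBABILITY,
    docking: list[DockingRecord] | None = None,
    descriptor_seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Run the full screening cascade over a candidate library.

    ``descriptor_flags`` (indexed by candidate id, columns ``flg<name>``)
    may be precomputed; otherwise descriptors are computed on the compounds
    that reach the probability stage and discretized with the published
    cutoffs. Returns the per-candidate result table sorted by RpS
    descending (then id) and the per-stage survivor counts.
    """
    window = window or PropertyWindow()
    docking_by_id = {d.ligand_id: d for d in (docking or [])}
    results: dict[str, ScreeningResult] = {}

    # stage 1: property window + organometallic removal
    stage1 = []
    for rec in candidates:
        ok = window.contains(rec) and not is_organometallic(rec)
        results[rec.id] = ScreeningResult(id=rec.id, pass_property=ok)
        if ok:
            stage1.append(rec)

    # stage 2: substitution ranges
    stage2 = []
    for rec in stage1:
        ok = substitution_filter(count_substitutions(rec))
        results[rec.id].pass_substitution = ok
        if ok:
            stage2.append(rec)

    # stage 3: repurposing score
    stage3 = []
    for rec in stage2:
        rps = repurposing_score(
            plain_rings(rec), bm_skeleton(rec), pr_iscores, bm_iscores
        )
        results[rec.id].rps = rps
        results[rec.id].pass_rps = rps > rps_threshold
        if results[rec.id].pass_rps:
            stage3.append(rec)

    # stage 4: published-model probability
    stage4 = []
    if stage3:
        if descriptor_flags is None:
            from .descriptors import descriptor_table  # deferred: 3D embedding is heavy

            desc = descriptor_table(stage3, seed=descriptor_seed).set_index("id")
            flags = flagize_table(desc)
        else:
            flags = descriptor_flags
        for rec in stage3:
            prob = model.predict_proba(flags.loc[rec.id])
            results[rec.id].prob = float(prob)
            results[rec.id].pass_prob = prob > prob_threshold
            if results[rec.id].pass_prob:
                stage4.append(rec)

    # stage 5: docking post-filter (only when a table was supplied)
    stage5 = []
    for rec in stage4:
        if not docking_by_id:
            stage5.append(rec)
            continue
        dock = docking_by_id.get(rec.id)
        if dock is None:
            log.warning("candidate %s has no docking record; fails docking stage", rec.id)
            results[rec.id].pass_docking = False
            continue
        if dock.pass_docking is None:
            docking_filter([dock])
        results[rec.id].pass_docking = dock.pass_docking
        if dock.pass_docking:
            stage5.append(rec)

    for res in results.values():
        stages = [
            res.pass_property, res.pass_substitution, res.pass_rps, res.pass_prob,
        ]
        if docking_by_id:
            stages.append(res.pass_docking)
        res.final = all(s is True for s in stages if s is not None) and all(
            s is not None for s in stages
        )

    counts = {
        "input": len(candidates),
        "property": len(stage1),
        "substitution": len(stage2),
        "rps": len(stage3),
        "probability": len(stage4),
        "docking": len(stage5) if docking_by_id else len(stage4),
    }
    log.info("screening cascade survivors: %s", counts)

    frame = pd.DataFrame([vars(r) for r in results.values()])
    frame = frame.sort_values(
        by=["rps", "id"], ascending=[False, True], na_position="last"
    ).reset_index(drop=True)
    return frame, counts
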