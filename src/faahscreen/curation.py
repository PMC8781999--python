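"""Dataset curation: building the FI / FI-S / FI-W / DCY sets.

The screening protocol starts from a curated inhibitor table (FI), two
potency-labelled subsets (FI-S strong, pIC50 > 8; FI-W weak, pIC50 < 5) and
a property-matched decoy set (DCY) sampled at a 10:1 ratio so that the prior
probability of drawing an inhibitor from the pooled set is
1/(1+10) = 0.0909...

Potency thresholds are strict inequalities ("above 8" / "under 5");
boundary compounds stay unlabeled. Property windows are closed intervals.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, replace

import numpy as np

from .chem_io import CompoundRecord, is_organometallic

log = logging.getLogger(__name__)

STRONG_ABOVE = 8.0  # pIC50 threshold for the strong class, strict
WEAK_BELOW = 5.0  # pIC50 threshold for the weak class, strict


@dataclass(frozen=True)
class PropertyWindow:
    """Closed physicochemical intervals for compound filtering.

    Defaults are the windows used both to select decoys and to pre-filter
    candidate libraries: MW 150-620 g/mol, logP -0.8-9.2, HBA 1-12, HBD 0-4.
    """

    mw_min: float = 150.0
    mw_max: float = 620.0
    logp_min: float = -0.8
    logp_max: float = 9.2
    hba_min: int = 1
    hba_max: int = 12
    hbd_min: int = 0
    hbd_max: int = 4

    def __post_init__(self) -> None:
        for lo, hi in (
            (self.mw_min, self.mw_max),
            (self.logp_min, self.logp_max),
            (self.hba_min, self.hba_max),
            (self.hbd_min, self.hbd_max),
        ):
            if lo > hi:
                raise ValueError(f"window bound {lo} > {hi}")

    def contains(self, record: CompoundRecord) -> bool:
        return (
            self.mw_min <= record.mw <= self.mw_max
            and self.logp_min <= record.logp <= self.logp_max
            and self.hba_min <= record.hba <= self.hba_max
            and self.hbd_min <= record.hbd <= self.hbd_max
        )

    def violated_rules(self, record: CompoundRecord) -> list[str]:
        rules = []
        if not self.mw_min <= record.mw <= self.mw_max:
            rules.append("mw")
        if not self.logp_min <= record.logp <= self.logp_max:
            rules.append("logp")
        if not self.hba_min <= record.hba <= self.hba_max:
            rules.append("hba")
        if not self.hbd_min <= record.hbd <= self.hbd_max:
            rules.append("hbd")
        return rules


def merge_duplicates(records: list[CompoundRecord]) -> list[CompoundRecord]:
    """Merge duplicate structures (same canonical SMILES) into one entry.

    The merged IC50 is the arithmetic mean of the member IC50 values
    (pIC50 is then -log10 of that mean, not the mean of the pIC50s).
    Records without a usable pIC50 — including those whose IC50 was only
    approximate — are removed before merging.
    """
    usable = [r for r in records if r.pic50 is not None]
    n_dropped = len(records) - len(usable)
    if n_dropped:
        log.warning("merge_duplicates: dropped %d records without precise IC50", n_dropped)

    by_smiles: dict[str, list[CompoundRecord]] = {}
    for rec in usable:
        by_smiles.setdefault(rec.smiles_canonical, []).append(rec)

    merged: list[CompoundRecord] = []
    for members in by_smiles.values():
        if len(members) == 1:
            merged.append(members[0])
            continue
        mean_ic50 = float(np.mean([10.0 ** (-m.pic50) for m in members]))
        merged.append(replace(members[0], pic50=-math.log10(mean_ic50)))
    return merged


def label_activity(
    records: list[CompoundRecord],
    strong_above: float = STRONG_ABOVE,
    weak_below: float = WEAK_BELOW,
) -> tuple[list[CompoundRecord], list[CompoundRecord]]:
    """Split records into strong (FI-S) and weak (FI-W) inhibitor subsets.

    Strong iff pIC50 > ``strong_above``; weak iff pIC50 < ``weak_below``
    (both strict); everything else, including records without pIC50, stays
    unlabeled. Labels are written onto the records in place.
    """
    strong, weak = [], []
    for rec in records:
        if rec.pic50 is not None and rec.pic50 > strong_above:
            rec.label = "strong"
            strong.append(rec)
        elif rec.pic50 is not None and rec.pic50 < weak_below:
            rec.label = "weak"
            weak.append(rec)
        else:
            rec.label = "unlabeled"
    return strong, weak


def property_filter(
    records: list[CompoundRecord],
    window: PropertyWindow | None = None,
    drop_organometallic: bool = True,
) -> tuple[list[CompoundRecord], dict[str, int]]:
    """Keep records inside the property window (and optionally organic only).

    Returns the retained records and a per-rule rejection count
    (a record violating several rules increments each of them).
    """
    window = window or PropertyWindow()
    kept: list[CompoundRecord] = []
    rejections: Counter[str] = Counter()
    for rec in records:
        rules = window.violated_rules(rec)
        if drop_organometallic and is_organometallic(rec):
            rules.append("organometallic")
        if rules:
            rejections.update(rules)
        else:
            kept.append(rec)
    if rejections:
        log.info("property_filter rejections: %s", dict(rejections))
    return kept, dict(rejections)


def sample_decoys(
    pool: list[CompoundRecord],
    fi: list[CompoundRecord],
    ratio: int = 10,
    seed: int = 0,
) -> list[CompoundRecord]:
    """Uniform random decoy sample, ``ratio`` times the size of FI.

    The pool is assumed to be already property-filtered to FI's windows;
    structures also present in FI (by canonical SMILES) are excluded before
    sampling. Sampling is without replacement and reproducible per seed.
    """
    fi_smiles = {r.smiles_canonical for r in fi}
    eligible = [r for r in pool if r.smiles_canonical not in fi_smiles]
    n_needed = ratio * len(fi)
    if len(eligible) < n_needed:
        raise ValueError(
            f"decoy pool too small: need {n_needed} structures disjoint from FI, "
            f"have {len(eligible)}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(eligible), size=n_needed, replace=False)
    decoys = [replace(eligible[i], set_tag="DCY") for i in sorted(idx)]
    return decoys


def prior_probability(n_fi: int, n_dcy: int) -> float:
    """Probability that a compound drawn from the pooled set is an inhibitor."""
    if n_fi <= 0 or n_dcy < 0:
        raise ValueError("need n_fi > 0 and n_dcy >= 0")
    return n_fi / (n_fi + n_dcy)
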