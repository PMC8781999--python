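"""Scaffold enrichment and potency scoring, filters, and the repurposing score.

For every scaffold the pipeline counts how many inhibitors (FI) and decoys
(DCY) contain it — each compound contributes at most once per distinct
scaffold — and converts the counts into an enrichment score

    P = (count_fi / (count_fi + count_dcy)) / prior,

where ``prior`` is the probability of drawing an inhibitor from the pooled
set (0.0909... at the standard 10:1 decoy ratio). P = 1 is random
expectation; the maximum, reached by inhibitor-exclusive scaffolds, is
1/prior. Significance of the FI/DCY frequency difference comes from a
Pearson chi-square test on the 2x2 containment table (no continuity
correction). The potency score I is the mean pIC50 of the inhibitors
containing the scaffold.

The repurposing score of a compound is

    RpS = mean(I-PR over contained filter ring systems) + I-BM(skeleton),

with a missing term contributing zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .roc import ThresholdReport, threshold_at_sensitivity
from .scaffolds import ScaffoldKey

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentContext:
    """Set sizes and the implied prior inhibitor probability."""

    n_fi: int
    n_dcy: int

    def __post_init__(self) -> None:
        if self.n_fi <= 0 or self.n_dcy <= 0:
            raise ValueError("need positive FI and DCY sizes")

    @property
    def prior(self) -> float:
        return self.n_fi / (self.n_fi + self.n_dcy)


@dataclass
class ScaffoldScore:
    """Enrichment and potency scores for one scaffold."""

    key: ScaffoldKey
    count_fi: int
    count_dcy: int
    p_score: float
    chi2_p: float
    i_score: float | None  # mean pIC50 of FI members; None when count_fi == 0


def p_score(count_fi: int, count_dcy: int, prior: float) -> float:
    """Enrichment of a scaffold relative to the prior inhibitor probability."""
    if count_fi < 0 or count_dcy < 0 or count_fi + count_dcy == 0:
        raise ValueError("counts must be non-negative with a positive total")
    return (count_fi / (count_fi + count_dcy)) / prior


def containment_chi2_p(
    count_fi: int, count_dcy: int, ctx: EnrichmentContext
) -> float:
    """Pearson chi-square p-value for the 2x2 scaffold-containment table."""
    table = np.array(
        [
            [count_fi, ctx.n_fi - count_fi],
            [count_dcy, ctx.n_dcy - count_dcy],
        ]
    )
    if (table < 0).any():
        raise ValueError("containment counts exceed set sizes")
    if table.sum(axis=0).min() == 0:  # scaffold in every or in no compound
        return 1.0
    result = chi2_contingency(table, correction=False)
    return float(result.pvalue)


def score_scaffolds(
    fi_assign: dict[str, set[ScaffoldKey]],
    dcy_assign: dict[str, set[ScaffoldKey]],
    ctx: EnrichmentContext,
    pic50: dict[str, float] | None = None,
) -> list[ScaffoldScore]:
    """Score every scaffold occurring in FI or DCY, sorted by P descending.

    ``fi_assign``/``dcy_assign`` map compound id to its set of scaffold keys
    (one element for MF/BM, possibly several for PR). ``pic50`` supplies the
    FI potencies for the I-score.
    """
    pic50 = pic50 or {}
    fi_members: dict[ScaffoldKey, list[str]] = {}
    for cid, keys in fi_assign.items():
        for key in keys:
            fi_members.setdefault(key, []).append(cid)
    dcy_counts: dict[ScaffoldKey, int] = {}
    for keys in dcy_assign.values():
        for key in keys:
            dcy_counts[key] = dcy_counts.get(key, 0) + 1

    scores = []
    for key in set(fi_members) | set(dcy_counts):
        cf = len(fi_members.get(key, []))
        cd = dcy_counts.get(key, 0)
        member_pic50 = [pic50[c] for c in fi_members.get(key, []) if c in pic50]
        scores.append(
            ScaffoldScore(
                key=key,
                count_fi=cf,
                count_dcy=cd,
                p_score=p_score(cf, cd, ctx.prior),
                chi2_p=containment_chi2_p(cf, cd, ctx),
                i_score=float(np.mean(member_pic50)) if member_pic50 else None,
            )
        )
    scores.sort(key=lambda s: (-s.p_score, -s.count_fi, s.key.canonical))
    return scores


@dataclass(frozen=True)
class FilterReport:
    sensitivity: float
    specificity: float
    hits_fi: int
    hits_dcy: int


def evaluate_filter(
    filter_scaffolds: set[ScaffoldKey],
    fi_assign: dict[str, set[ScaffoldKey]],
    dcy_assign: dict[str, set[ScaffoldKey]],
) -> FilterReport:
    """Sensitivity/specificity of "contains at least one filter scaffold"."""
    if not filter_scaffolds:
        log.warning("empty filter scaffold set: sensitivity 0, specificity 1")
        return FilterReport(0.0, 1.0, 0, 0)
    hits_fi = sum(1 for keys in fi_assign.values() if keys & filter_scaffolds)
    hits_dcy = sum(1 for keys in dcy_assign.values() if keys & filter_scaffolds)
    return FilterReport(
        sensitivity=hits_fi / len(fi_assign),
        specificity=1.0 - hits_dcy / len(dcy_assign),
        hits_fi=hits_fi,
        hits_dcy=hits_dcy,
    )


def select_filter_scaffolds(
    scores: list[ScaffoldScore],
    mode: str = "significance",
    threshold: float | None = None,
    alpha: float = 0.05,
) -> set[ScaffoldKey]:
    """Choose filter scaffolds from their scores.

    ``significance`` (skeleton-style): P > 1 and chi-square p < alpha.
    ``p_threshold`` (plain-ring-style): P >= threshold.
    """
    if mode == "significance":
        return {s.key for s in scores if s.p_score > 1.0 and s.chi2_p < alpha}
    if mode == "p_threshold":
        if threshold is None:
            raise ValueError("p_threshold mode needs a threshold")
        return {s.key for s in scores if s.p_score >= threshold}
    raise ValueError(f"unknown mode {mode!r}")


def i_score_table(scores: list[ScaffoldScore]) -> dict[ScaffoldKey, float]:
    """Scaffold -> I-score lookup, skipping scaffolds without FI members."""
    return {s.key: s.i_score for s in scores if s.i_score is not None}


def repurposing_score(
    compound_pr: set[ScaffoldKey],
    compound_bm: ScaffoldKey | None,
    pr_iscores: dict[ScaffoldKey, float],
    bm_iscores: dict[ScaffoldKey, float],
) -> float:
    """RpS: mean I-PR over contained filter ring systems plus the skeleton I-BM.

    Only ring systems present in the filter I-PR table contribute; a missing
    PR or BM term contributes zero.
    """
    contained = [pr_iscores[k] for k in compound_pr if k in pr_iscores]
    rps = float(np.mean(contained)) if contained else 0.0
    if compound_bm is not None and compound_bm in bm_iscores:
        rps += bm_iscores[compound_bm]
    return rps


def rps_threshold(
    rps_values, labels, target_sensitivity: float = 0.9
) -> ThresholdReport:
    """ROC threshold on the repurposing score at a target sensitivity.

    Returns the largest threshold (positive iff RpS strictly above it) whose
    sensitivity meets the target, together with AUC and the resulting
    specificity.
    """
    return threshold_at_sensitivity(rps_values, labels, target_sensitivity)


# ---------------------------------------------------------------------------
# Library-level framework statistics


def null_fraction(assign: dict[str, set[ScaffoldKey]]) -> float:
    """Fraction of compounds mapping to the null scaffold (acyclic)."""
    if not assign:
        raise ValueError("empty assignment")
    n_null = sum(
        1 for keys in assign.values() if not keys or all(k.is_null for k in keys)
    )
    return n_null / len(assign)


def exclusive_coverage(
    fi_assign: dict[str, set[ScaffoldKey]],
    dcy_assign: dict[str, set[ScaffoldKey]],
) -> dict[str, float]:
    """Coverage of FI by the scaffolds it does not share with DCY.

    Returns the number of FI-exclusive (non-null) scaffolds, the number and
    percentage of FI compounds containing at least one of them, and the
    number of shared scaffolds.
    """
    fi_keys = {k for keys in fi_assign.values() for k in keys if not k.is_null}
    dcy_keys = {k for keys in dcy_assign.values() for k in keys if not k.is_null}
    exclusive = fi_keys - dcy_keys
    covered = sum(1 for keys in fi_assign.values() if keys & exclusive)
    return {
        "n_scaffolds_fi": len(fi_keys),
        "n_exclusive": len(exclusive),
        "n_shared": len(fi_keys & dcy_keys),
        "n_covered": covered,
        "pct_covered": 100.0 * covered / len(fi_assign),
    }


def scores_to_frame(scores: list[ScaffoldScore]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "kind": [s.key.kind for s in scores],
            "scaffold": [s.key.canonical for s in scores],
            "is_null": [s.key.is_null for s in scores],
            "count_fi": [s.count_fi for s in scores],
            "count_dcy": [s.count_dcy for s in scores],
            "p_score": [s.p_score for s in scores],
            "chi2_p": [s.chi2_p for s in scores],
            "i_score": [s.i_score for s in scores],
        }
    )
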