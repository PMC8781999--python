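"""Flag-discretized logistic activity classifier.

Descriptors are screened by an independent-samples t-test (strong vs weak
inhibitors), discretized against ROC-derived cutoffs into binary flags
(flag = 1 iff descriptor >= cutoff) and combined by a binary logistic
regression. The published four-flag model is

    logit(P) = 1.323*flgWPSA1 + 0.736*flgSpMAD_D + 1.709*flgRDF85m
               + 1.076*flgCrippenLogP - 2.103,

with a compound called "highly active" when P > 0.7. The published
coefficients and descriptor cutoffs ship verbatim, independent of the
refitting machinery, so the reference model never depends on our selection
heuristics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .roc import ThresholdReport, rank_auc, sens_spec_at, youden_cutoff

log = logging.getLogger(__name__)

#: ROC cutoffs of the retained descriptor panel, applied as value >= cutoff
#: (all are "greater is active"). These were derived on the original
#: training data; applied to descriptor values from other implementations
#: they are approximate (different conformers and charge models shift the
#: 3D descriptor scales).
PUBLISHED_CUTOFFS = {
    "CrippenLogP": 4.582,
    "SpMAD_D": 12.569,
    "SpMax5_Bhi": 3.333,
    "Au": 98.038,
    "Ae": 96.826,
    "Ai": 100.252,
    "As": 97.668,
    "Av": 81.277,
    "RDF85m": 5.699,
    "WPSA1": 382.111,
    "WPSA2": 767.505,
}

#: Coefficients of the published four-flag logistic model.
PUBLISHED_COEFFICIENTS = {
    "flgWPSA1": 1.323,
    "flgSpMAD_D": 0.736,
    "flgRDF85m": 1.709,
    "flgCrippenLogP": 1.076,
}
PUBLISHED_INTERCEPT = -2.103
HIGHLY_ACTIVE_PROBABILITY = 0.7


@dataclass(frozen=True)
class CutoffRule:
    """A descriptor discretization rule derived from ROC analysis."""

    descriptor: str
    cutoff: float
    orientation: str = "greater_is_active"
    auc: float = float("nan")
    sens: float = float("nan")
    spec: float = float("nan")

    def __post_init__(self) -> None:
        if self.orientation not in ("greater_is_active", "less_is_active"):
            raise ValueError(f"unknown orientation {self.orientation!r}")


class SeparationError(RuntimeError):
    """Raised when a flag perfectly separates the classes."""


def univariate_screen(
    table: pd.DataFrame, labels, alpha: float = 0.05
) -> pd.DataFrame:
    """Two-sided pooled-variance t-test per descriptor column.

    Returns a frame with t statistic, p-value and a ``retained`` column
    (p < alpha). Descriptors with zero variance in both classes are dropped
    with a warning (their p-value is undefined).
    """
    labels = np.asarray(labels, dtype=int)
    if min((labels == 1).sum(), (labels == 0).sum()) < 2:
        raise ValueError("need at least 2 samples per class")
    rows = []
    for name in table.columns:
        values = table[name].to_numpy(dtype=float)
        a, b = values[labels == 1], values[labels == 0]
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            if a.mean() == b.mean():
                # no within-class variance and no mean difference: p undefined
                log.warning("descriptor %s constant within both classes; dropped", name)
                continue
            t, p = math.inf if a.mean() > b.mean() else -math.inf, 0.0
        else:
            t, p = stats.ttest_ind(a, b, equal_var=True)
        rows.append({"descriptor": name, "t": float(t), "p": float(p), "retained": p < alpha})
    if not rows:
        return pd.DataFrame(columns=["t", "p", "retained"])
    return pd.DataFrame(rows).set_index("descriptor")


def roc_cutoff(
    values, labels,
    min_sens: float = 0.75, min_spec: float = 0.75, min_auc: float = 0.8,
    descriptor: str = "",
) -> CutoffRule | None:
    """ROC-derived discretization cutoff, or None when the descriptor fails.

    The orientation is chosen so that AUC >= 0.5 (descriptors where smaller
    values mark actives are negated). Among cutoffs with sensitivity and
    specificity both at least the floors, the one maximizing their sum
    (Youden) wins; descriptors with AUC below ``min_auc`` or no feasible
    cutoff yield None.
    """
    values = np.asarray(values, dtype=float)
    auc = rank_auc(values, labels)
    orientation = "greater_is_active"
    oriented = values
    if auc < 0.5:
        orientation = "less_is_active"
        oriented = -values
        auc = 1.0 - auc
    if auc < min_auc:
        return None
    best = youden_cutoff(oriented, labels, min_sens=min_sens, min_spec=min_spec)
    if best is None:
        return None
    cutoff = best.threshold if orientation == "greater_is_active" else -best.threshold
    return CutoffRule(
        descriptor=descriptor, cutoff=float(cutoff), orientation=orientation,
        auc=auc, sens=best.sensitivity, spec=best.specificity,
    )


def flagize(value: float, rule: CutoffRule) -> int:
    """Binary flag: 1 iff the (orientation-aligned) value meets the cutoff."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        raise ValueError(f"missing value for descriptor {rule.descriptor}")
    if rule.orientation == "less_is_active":
        return int(-value >= -rule.cutoff)
    return int(value >= rule.cutoff)


def flagize_table(
    table: pd.DataFrame, rules: "dict[str, CutoffRule] | dict[str, float] | None" = None
) -> pd.DataFrame:
    """Flag columns ``flg<descriptor>`` for every rule with a table column.

    ``rules`` may map descriptor names to :class:`CutoffRule` or to bare
    cutoffs (greater-is-active); the default is the published cutoff table.
    """
    if rules is None:
        rules = PUBLISHED_CUTOFFS
    out = {}
    for name, rule in rules.items():
        if name not in table.columns:
            continue
        if not isinstance(rule, CutoffRule):
            rule = CutoffRule(descriptor=name, cutoff=float(rule))
        out[f"flg{name}"] = [flagize(v, rule) for v in table[name].to_numpy(dtype=float)]
    return pd.DataFrame(out, index=table.index)


@dataclass
class LogisticModel:
    """A flag logistic model: coefficients, intercept and fit diagnostics."""

    coefficients: dict[str, float]
    intercept: float
    std_errors: dict[str, float] = field(default_factory=dict)
    p_values: dict[str, float] = field(default_factory=dict)
    sensitivity: float | None = None
    specificity: float | None = None

    def logit(self, flags: "dict[str, int] | pd.Series") -> float:
        z = self.intercept
        for name, coef in self.coefficients.items():
            if name not in flags:
                raise ValueError(f"missing flag {name}")
            z += coef * float(flags[name])
        return z

    def predict_proba(self, flags) -> float:
        return 1.0 / (1.0 + math.exp(-self.logit(flags)))

    def predict_table(self, flags: pd.DataFrame) -> np.ndarray:
        z = np.full(len(flags), self.intercept)
        for name, coef in self.coefficients.items():
            z = z + coef * flags[name].to_numpy(dtype=float)
        return 1.0 / (1.0 + np.exp(-z))


#: The published four-flag model, shipped verbatim.
PUBLISHED_MODEL = LogisticModel(
    coefficients=dict(PUBLISHED_COEFFICIENTS), intercept=PUBLISHED_INTERCEPT
)


def predict_published(flags) -> float:
    """Probability of high activity under the published four-flag model."""
    return PUBLISHED_MODEL.predict_proba(flags)


def is_highly_active(
    probability: float, threshold: float = HIGHLY_ACTIVE_PROBABILITY
) -> bool:
    """Strictly-above classification rule on the predicted probability."""
    return probability > threshold


def fit_flag_logistic(
    flags: pd.DataFrame, labels, selection: str = "none", alpha: float = 0.05
) -> LogisticModel:
    """Maximum-likelihood logistic fit on binary flags, no regularization.

    ``selection="backward_p05"`` repeatedly drops the slope with the largest
    p-value until every remaining slope has p < alpha (possibly leaving an
    intercept-only model). Constant flags are dropped with a warning; a flag
    that perfectly separates the classes raises :class:`SeparationError`
    naming it.
    """
    if selection not in ("none", "backward_p05"):
        raise ValueError(f"unknown selection {selection!r}")
    labels = np.asarray(labels, dtype=float)
    flags = flags.copy()
    for name in list(flags.columns):
        if flags[name].nunique() < 2:
            log.warning("flag %s is constant; dropped from the fit", name)
            flags = flags.drop(columns=name)

    def _fit(columns: list[str]):
        x = sm.add_constant(
            flags[columns].to_numpy(dtype=float), has_constant="add"
        )
        try:
            result = sm.Logit(labels, x).fit(disp=0, maxiter=200)
        except Exception as exc:  # statsmodels raises on perfect separation
            raise SeparationError(str(exc)) from exc
        if np.abs(result.params[1:]).max(initial=0.0) > 20:
            worst = columns[int(np.abs(result.params[1:]).argmax())]
            raise SeparationError(f"flag {worst} (quasi-)separates the classes")
        return result

    columns = list(flags.columns)
    result = _fit(columns)
    if selection == "backward_p05":
        while columns:
            slope_p = result.pvalues[1:]
            worst = int(np.argmax(slope_p))
            if slope_p[worst] < alpha:
                break
            dropped = columns.pop(worst)
            log.info("backward elimination: dropped %s (p=%.3g)", dropped, slope_p[worst])
            result = _fit(columns)

    coefficients = {c: float(result.params[i + 1]) for i, c in enumerate(columns)}
    model = LogisticModel(
        coefficients=coefficients,
        intercept=float(result.params[0]),
        std_errors={c: float(result.bse[i + 1]) for i, c in enumerate(columns)}
        | {"intercept": float(result.bse[0])},
        p_values={c: float(result.pvalues[i + 1]) for i, c in enumerate(columns)}
        | {"intercept": float(result.pvalues[0])},
    )
    if columns:
        proba = model.predict_table(flags)
    else:
        proba = np.full(len(flags), 1.0 / (1.0 + math.exp(-model.intercept)))
    sens, spec = sens_spec_at(proba, labels.astype(int), 0.5, strict=False)
    model.sensitivity, model.specificity = sens, spec
    return model
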