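"""Validation statistics: binomial CIs, partition tables, kappa, summaries.

Malignancy frequencies per class (and per risk group / simplified label) are
reported as binomial proportions with 95% confidence intervals.  Two interval
methods are provided because with handfuls of events they differ visibly:

* Wilson score interval — inversion of the score test; well-behaved at zero
  events (used for the 0/7, 0/68, 0/23, 7/11, 0/93 style cells);
* Clopper–Pearson — exact beta-quantile interval, conservative; at zero
  events its upper bound is ``1 - (alpha/2)**(1/n)``.

Inter-reader agreement of the ordinal score uses Cohen's kappa with linear
weights ``w_ij = 1 - |i - j| / (K - 1)`` over category ranks, so near-miss
disagreements receive partial credit; with two categories this reduces to the
unweighted kappa.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .engine import ORADS_CLASSES, ClassifiedRecord
from .simplified import RiskGroup, SimplifiedLabel, classify_simplified, dichotomize_orads

__all__ = [
    "ProportionCI",
    "ClassSummaryRow",
    "KappaResult",
    "wilson_interval",
    "clopper_pearson_interval",
    "proportion_interval",
    "malignancy_by_class",
    "risk_group_summary",
    "weighted_kappa",
    "summarize_continuous",
]


@dataclass(frozen=True)
class ProportionCI:
    """A binomial proportion with its confidence interval."""

    events: int
    trials: int
    point: float
    lower: float
    upper: float
    method: str
    level: float


@dataclass(frozen=True)
class ClassSummaryRow:
    """One cell of a cohort partition: label, size, malignancies, CI."""

    label: str
    n: int
    malignant: int
    proportion_ci: ProportionCI


@dataclass(frozen=True)
class KappaResult:
    kappa: Optional[float]  # None when chance agreement is total (Pe_w = 1)
    weighting: str
    n: int
    categories: tuple


def _check_counts(events: int, trials: int, level: float) -> None:
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if not 0 <= events <= trials:
        raise ValueError("events must lie in [0, trials]")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")


def _clip_bounds(events: int, trials: int, lower: float, upper: float) -> tuple[float, float]:
    # boundary cells are exact: 0 events pins the lower bound at 0, all
    # events pins the upper at 1 (backends can leave 1e-17-size residue)
    lower = 0.0 if events == 0 else min(max(float(lower), 0.0), 1.0)
    upper = 1.0 if events == trials else min(max(float(upper), 0.0), 1.0)
    return lower, upper


def wilson_interval(events: int, trials: int, level: float = 0.95) -> ProportionCI:
    """Wilson score interval for ``events / trials`` at the given level."""
    _check_counts(events, trials, level)
    lower, upper = proportion_confint(events, trials, alpha=1 - level, method="wilson")
    lower, upper = _clip_bounds(events, trials, lower, upper)
    return ProportionCI(events, trials, events / trials, lower, upper, "wilson", level)


def clopper_pearson_interval(events: int, trials: int, level: float = 0.95) -> ProportionCI:
    """Exact (Clopper–Pearson) beta-quantile interval."""
    _check_counts(events, trials, level)
    lower, upper = proportion_confint(events, trials, alpha=1 - level, method="beta")
    lower, upper = _clip_bounds(events, trials, lower, upper)
    return ProportionCI(
        events, trials, events / trials, lower, upper, "clopper_pearson", level
    )


_METHODS = {"wilson": wilson_interval, "clopper_pearson": clopper_pearson_interval}


def proportion_interval(
    events: int, trials: int, level: float = 0.95, method: str = "wilson"
) -> ProportionCI:
    try:
        fn = _METHODS[method]
    except KeyError:
        raise ValueError(f"unknown CI method: {method!r}") from None
    return fn(events, trials, level)


def _require_outcomes(classified: Sequence[ClassifiedRecord]) -> None:
    for cr in classified:
        if cr.record.malignant is None:
            raise ValueError(f"record {cr.record.id}: malignant status missing")


def malignancy_by_class(
    classified: Sequence[ClassifiedRecord],
    method: str = "wilson",
    level: float = 0.95,
) -> list[ClassSummaryRow]:
    """Per-class malignancy table (one row per O-RADS class 1-5).

    Classes with no records get an ``n = 0`` row with no interval (a CI of a
    zero-trial cell is undefined); counts across rows sum to the cohort size.
    """
    _require_outcomes(classified)
    rows = []
    for cls in ORADS_CLASSES:
        members = [cr for cr in classified if cr.orads_class == cls]
        n = len(members)
        mal = sum(bool(cr.record.malignant) for cr in members)
        ci = proportion_interval(mal, n, level, method) if n else None
        rows.append(ClassSummaryRow(f"orads_{cls}", n, mal, ci))
    return rows


def risk_group_summary(
    classified: Sequence[ClassifiedRecord],
    method: str = "wilson",
    level: float = 0.95,
) -> list[ClassSummaryRow]:
    """Low/high-risk rows plus likely-benign/likely-malignant rows.

    Risk group comes from dichotomizing the engine class; the simplified label
    is recomputed from the lesion descriptors.  Raises on an empty cohort or
    missing outcome.
    """
    if not classified:
        raise ValueError("empty cohort")
    _require_outcomes(classified)
    rows = []
    for group in (RiskGroup.low, RiskGroup.high):
        members = [cr for cr in classified if dichotomize_orads(cr.orads_class) is group]
        n = len(members)
        mal = sum(bool(cr.record.malignant) for cr in members)
        ci = proportion_interval(mal, n, level, method) if n else None
        rows.append(ClassSummaryRow(f"risk_{group.value}", n, mal, ci))
    for label in (SimplifiedLabel.likely_benign, SimplifiedLabel.likely_malignant):
        members = [
            cr for cr in classified if classify_simplified(cr.record.features) is label
        ]
        n = len(members)
        mal = sum(bool(cr.record.malignant) for cr in members)
        ci = proportion_interval(mal, n, level, method) if n else None
        rows.append(ClassSummaryRow(label.value, n, mal, ci))
    return rows


def weighted_kappa(
    a: Sequence, b: Sequence, categories: Sequence, weighting: str = "linear"
) -> KappaResult:
    """Cohen's kappa with linear weights over ordered categories.

    ``kappa = (Po_w - Pe_w) / (1 - Pe_w)`` with observed weighted agreement
    Po_w and chance agreement Pe_w from the product of the two raters'
    marginals.  When ``Pe_w = 1`` (both raters constant on the same category)
    kappa is undefined and reported as ``None``.
    """
    if weighting != "linear":
        raise ValueError("only linear weighting is supported")
    if len(a) != len(b):
        raise ValueError("rating sequences must have equal length")
    if len(a) == 0:
        raise ValueError("rating sequences must be non-empty")
    cats = list(categories)
    index = {c: i for i, c in enumerate(cats)}
    k = len(cats)
    obs = np.zeros((k, k))
    for x, y in zip(a, b):
        obs[index[x], index[y]] += 1
    obs /= obs.sum()
    ranks = np.arange(k)
    if k > 1:
        weights = 1.0 - np.abs(np.subtract.outer(ranks, ranks)) / (k - 1)
    else:
        weights = np.ones((1, 1))
    po = float((weights * obs).sum())
    pe = float((weights * np.outer(obs.sum(axis=1), obs.sum(axis=0))).sum())
    if np.isclose(pe, 1.0):
        # both raters constant on the same category: chance agreement is
        # total and kappa is undefined
        kappa = None
    else:
        kappa = (po - pe) / (1.0 - pe)
    return KappaResult(kappa, "linear", len(a), tuple(cats))


def _has_solid_component(f) -> bool:
    # composition: purely cystic vs lesion with a solid component; an
    # enhancing component inside a fatty lesion and peritoneal spread both
    # count as non-cystic composition
    if f.solid_tissue_present or f.peritoneal_disease:
        return True
    if f.fat_present and (f.enhancing_component_diameter or 0.0) > 0.0:
        return True
    return False


#: predictor name -> record-level extractor (lesion-bearing records only)
PREDICTOR_EXTRACTORS = {
    "peritoneal_disease": lambda r: float(r.features.peritoneal_disease),
    "composition": lambda r: float(_has_solid_component(r.features)),
    "fat_present": lambda r: float(r.features.fat_present),
    "age": lambda r: float(r.age),
    "max_diameter": lambda r: float(r.features.max_diameter or 0.0),
    "septa": lambda r: float(r.features.locularity is not None
                             and r.features.locularity.value == "multilocular"),
    "nonsimple_fluid": lambda r: float(r.features.fluid_type is not None
                                       and r.features.fluid_type.value != "simple"),
}

#: the seven clinical/imaging variables screened for malignancy prediction
DEFAULT_PREDICTORS = (
    "peritoneal_disease",
    "composition",
    "fat_present",
    "age",
    "max_diameter",
    "septa",
    "nonsimple_fluid",
)


def screen_predictors(records, predictors: Sequence[str] = DEFAULT_PREDICTORS):
    """Multivariable Firth-penalized screen of malignancy predictors.

    Fits one penalized logistic model of the malignancy outcome on all named
    predictors jointly, over lesion-bearing records (composition is undefined
    without a mass), and returns one :class:`~orads.firth.PredictorEffect`
    per predictor with a penalized likelihood-ratio p-value.  Raises if any
    outcome is missing or the outcome is constant.
    """
    from .firth import firth_effects

    lesion_records = [r for r in records if r.features.mass_present]
    if not lesion_records:
        raise ValueError("no lesion-bearing records")
    for r in lesion_records:
        if r.malignant is None:
            raise ValueError(f"record {r.id}: malignant status missing")
    unknown = [p for p in predictors if p not in PREDICTOR_EXTRACTORS]
    if unknown:
        raise ValueError(f"unknown predictors: {unknown}")
    X = np.array(
        [[PREDICTOR_EXTRACTORS[p](r) for p in predictors] for r in lesion_records]
    )
    y = np.array([float(r.malignant) for r in lesion_records])
    return firth_effects(X, y, list(predictors))


def summarize_continuous(values: Iterable[float]) -> dict[str, float]:
    """Median and IQR (25th/75th percentiles, linear interpolation)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("no values to summarize")
    if not np.all(np.isfinite(arr)):
        raise ValueError("values must be finite")
    q25, q50, q75 = np.percentile(arr, [25, 50, 75])  # linear interpolation
    return {"median": float(q50), "q25": float(q25), "q75": float(q75)}
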