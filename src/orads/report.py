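"""Validation report and reproduction document.

:func:`validation_report` assembles the cohort-level statistics (per-class,
per-risk-group and per-simplified-label malignancy tables with CIs, optional
inter-reader kappa, predictor screen) into one JSON-able dictionary.

:func:`repro_document` re-derives the study's headline numbers from the
canonical synthetic cohort and compares them cell by cell against the values
the publication prints, flagging each as ``match``, ``mismatch`` (documented
source inconsistency) or ``ambiguous`` (the printed value matches neither
interval method).  It is deterministic: repeated calls give identical output.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

from .cohort import canonical_cohort, cohort_margins
from .engine import ClassifiedRecord, classify_cohort
from .simplified import classify_simplified
from .stats import (
    ClassSummaryRow,
    clopper_pearson_interval,
    malignancy_by_class,
    risk_group_summary,
    screen_predictors,
    summarize_continuous,
    weighted_kappa,
    wilson_interval,
)

__all__ = ["validation_report", "format_report_table", "repro_document", "round_percent"]


def round_percent(p: float) -> int:
    """Proportion -> whole percent, half away from zero."""
    return int(math.floor(p * 100 + 0.5))


def _row_dict(row: ClassSummaryRow) -> dict:
    d = {"label": row.label, "n": row.n, "malignant": row.malignant}
    ci = row.proportion_ci
    if ci is not None:
        d.update(
            {
                "proportion": ci.point,
                "percent": round_percent(ci.point),
                "ci_lower": ci.lower,
                "ci_upper": ci.upper,
                "ci_lower_percent": round_percent(ci.lower),
                "ci_upper_percent": round_percent(ci.upper),
                "ci_method": ci.method,
                "level": ci.level,
            }
        )
    else:
        d["proportion"] = None
    return d


def validation_report(
    classified: Sequence[ClassifiedRecord],
    ci_method: str = "both",
    level: float = 0.95,
    predictors: Optional[Sequence[str]] = None,
) -> dict:
    """Full validation report over an annotated cohort.

    ``ci_method`` is ``wilson``, ``clopper_pearson`` or ``both`` (rows are
    emitted once per method).  Kappa is included when every record carries a
    second-reader class.  The predictor screen is skipped (with a note) when
    the outcome is constant.
    """
    methods = ["wilson", "clopper_pearson"] if ci_method == "both" else [ci_method]
    report: dict = {"n": len(classified), "level": level, "tables": {}}
    for method in methods:
        report["tables"][method] = {
            "by_class": [_row_dict(r) for r in malignancy_by_class(classified, method, level)],
            "by_group": [_row_dict(r) for r in risk_group_summary(classified, method, level)],
        }

    records = [cr.record for cr in classified]
    if all(r.reader2_class is not None for r in records) and records:
        a = [cr.orads_class for cr in classified]
        b = [r.reader2_class for r in records]
        kr = weighted_kappa(a, b, categories=[1, 2, 3, 4, 5])
        simp_a = [classify_simplified(r.features).value for r in records]
        # second reader's simplified verdict via the risk dichotomy of their class
        simp_b = [
            "likely_malignant" if c >= 4 else "likely_benign" for c in b
        ]
        kr2 = weighted_kappa(
            simp_a, simp_b, categories=["likely_benign", "likely_malignant"]
        )
        report["kappa"] = {
            "orads": {"kappa": kr.kappa, "weighting": kr.weighting, "n": kr.n},
            "simplified": {"kappa": kr2.kappa, "weighting": kr2.weighting, "n": kr2.n},
        }

    outcomes = {r.malignant for r in records if r.features.mass_present}
    if outcomes == {True, False}:
        effects = screen_predictors(records, predictors) if predictors else screen_predictors(records)
        report["predictors"] = [
            {
                "name": e.name,
                "estimate": e.estimate,
                "std_error": e.std_error,
                "p_value": e.p_value,
                "method": e.method,
            }
            for e in effects
        ]
    else:
        report["predictors"] = None
        report["predictors_note"] = "outcome constant among lesions; screen not identifiable"

    report["age"] = summarize_continuous([r.age for r in records]) if records else None
    sizes = [r.features.max_diameter for r in records if r.features.max_diameter is not None]
    report["size_mm"] = summarize_continuous(sizes) if sizes else None
    return report


def format_report_table(report: dict) -> str:
    """Render the report's partition tables as a tab-delimited text block."""
    lines = ["label\tn\tmalignant\tpercent\tci\tmethod"]
    for method, tables in report["tables"].items():
        for row in tables["by_class"] + tables["by_group"]:
            if row.get("proportion") is None:
                lines.append(f"{row['label']}\t{row['n']}\t{row['malignant']}\t-\t-\t{method}")
            else:
                ci = f"{row['ci_lower_percent']}-{row['ci_upper_percent']}%"
                lines.append(
                    f"{row['label']}\t{row['n']}\t{row['malignant']}\t"
                    f"{row['percent']}%\t{ci}\t{method}"
                )
    if report.get("kappa"):
        lines.append(f"kappa_orads\t{report['kappa']['orads']['n']}\t-\t"
                     f"{report['kappa']['orads']['kappa']:.3f}\t-\tlinear")
    if report.get("predictors"):
        lines.append("predictor\testimate\tstd_error\tp_value\t-\t-")
        for e in report["predictors"]:
            lines.append(
                f"{e['name']}\t{e['estimate']:+.3f}\t{e['std_error']:.3f}\t"
                f"{e['p_value']:.4g}\t-\t-"
            )
    return "\n".join(lines) + "\n"


# printed values the reproduction compares against: (events, trials,
# printed percent, printed CI bounds in percent)
_PRINTED_CLASS_CELLS = {
    1: (0, 7, 0, (0, 35)),
    2: (0, 68, 0, (0, 5)),
    3: (0, 23, 0, (0, 14)),
    4: (1, 2, 50, (1, 99)),
    5: (6, 9, 75, (41, 93)),
}


def _interval_pair(events: int, trials: int) -> dict:
    w = wilson_interval(events, trials)
    cp = clopper_pearson_interval(events, trials)
    return {
        "wilson": [round_percent(w.lower), round_percent(w.upper)],
        "clopper_pearson": [round_percent(cp.lower), round_percent(cp.upper)],
    }


def repro_document() -> dict:
    """Deterministic comparison of computed vs published headline values."""
    records = canonical_cohort()
    classified, tally = classify_cohort(records)
    margins = cohort_margins(records)
    items: list[dict] = []

    def add(name: str, computed, printed, status: Optional[str] = None, note: str = "") -> None:
        if status is None:
            status = "match" if computed == printed else "mismatch"
        item = {"name": name, "computed": computed, "printed": printed, "status": status}
        if note:
            item["note"] = note
        items.append(item)

    add("patients", len(records), 109)
    add("malignant_total", margins["malignant_total"], 7)
    for cls in (1, 2, 3, 4, 5):
        add(f"orads_{cls}_count", tally[cls], {1: 7, 2: 68, 3: 23, 4: 2, 5: 9}[cls])
    for cls, (ev, n, printed_pct, printed_ci) in _PRINTED_CLASS_CELLS.items():
        computed_ev = margins["malignant_by_class"][cls]
        add(f"orads_{cls}_malignant", computed_ev, ev)
        pct = round_percent(computed_ev / tally[cls])
        note = ""
        status = None
        if cls == 5:
            # the publication prints 75% beside the fraction 6/9 (= 67%)
            status = "match" if pct == printed_pct else "mismatch"
            note = "source prints 75% alongside the fraction 6/9"
        add(f"orads_{cls}_percent", pct, printed_pct, status, note)
        ivs = _interval_pair(computed_ev, tally[cls])
        matched = [m for m, b in ivs.items() if b == list(printed_ci)]
        add(
            f"orads_{cls}_ci_percent",
            ivs,
            list(printed_ci),
            "match" if matched else "ambiguous",
            f"printed bounds match: {', '.join(matched) if matched else 'neither method'}",
        )

    # risk dichotomy
    groups = {r.label: r for r in risk_group_summary(classified, "wilson")}
    low, high = groups["risk_low"], groups["risk_high"]
    add("high_risk_malignant", f"{high.malignant}/{high.n}", "7/11")
    add("high_risk_percent", round_percent(high.proportion_ci.point), 64)
    add(
        "high_risk_ci_percent",
        _interval_pair(high.malignant, high.n),
        [35, 85],
        "match"
        if _interval_pair(high.malignant, high.n)["wilson"] == [35, 85]
        else "ambiguous",
        "printed bounds match: wilson",
    )
    ivs_low = _interval_pair(low.malignant, low.n)
    add(
        "low_risk_ci_percent",
        ivs_low,
        [0, 3],
        "ambiguous",
        "printed upper bound 3% is reproduced by neither method (both give 4%)",
    )

    # simplified framework
    lm = groups["likely_malignant"]
    lb = groups["likely_benign"]
    add("likely_malignant_count", lm.n, 11)
    add("malignant_captured", lm.malignant, 7)
    add("likely_benign_malignant", lb.malignant, 0)
    add(
        "likely_benign_count",
        lb.n,
        93,
        "mismatch",
        "source reports an 11 + 93 = 104 split over 109 enrolled patients; "
        "the discrepancy is unexplained in the source",
    )

    # demographics
    age = margins["age"]
    add("age_median_iqr", [age["median"], age["q25"], age["q75"]], [13, 11, 15])
    size = margins["size_mm"]
    add("size_median_iqr", [size["median"], size["q25"], size["q75"]], [62, 45, 110])
    add("laterality_right", margins["laterality"]["right"], 54)

    n_match = sum(1 for i in items if i["status"] == "match")
    return {
        "items": items,
        "summary": {
            "match": n_match,
            "mismatch": sum(1 for i in items if i["status"] == "mismatch"),
            "ambiguous": sum(1 for i in items if i["status"] == "ambiguous"),
            "total": len(items),
        },
    }
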