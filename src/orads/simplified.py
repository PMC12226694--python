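"""Simplified pediatric reading framework and the low/high-risk dichotomy.

In the pediatric cohort the three lowest O-RADS classes carried essentially no
malignancy, so the ordinal score collapses naturally into a binary one.  Two
binary views are provided:

* :func:`dichotomize_orads` — the risk grouping of the ordinal score itself
  (classes 1-3 low risk, 4-5 high risk);
* :func:`classify_simplified` — a short decision tree over only the three
  descriptors that predicted malignancy (peritoneal disease, lesion
  composition, intralesional fat), skipping the full reading algorithm.

The two agree everywhere except for the "dark-dark" solid pattern, which the
full algorithm treats as benign (class 2) while the simplified tree — which
looks at composition only — flags as likely malignant.  No such lesion
occurred in the study cohort.
"""

from __future__ import annotations

from enum import Enum

from .engine import InvalidFeaturesError
from .features import LARGE_ENHANCING_THRESHOLD, LesionFeatures, validate_features

__all__ = ["RiskGroup", "SimplifiedLabel", "dichotomize_orads", "classify_simplified"]


class RiskGroup(str, Enum):
    low = "low"
    high = "high"


class SimplifiedLabel(str, Enum):
    likely_benign = "likely_benign"
    likely_malignant = "likely_malignant"


def dichotomize_orads(orads_class: int) -> RiskGroup:
    """Map an O-RADS class to low (1-3) or high (4-5) malignancy risk."""
    if orads_class in (1, 2, 3):
        return RiskGroup.low
    if orads_class in (4, 5):
        return RiskGroup.high
    raise ValueError(f"not an O-RADS class: {orads_class!r}")


def classify_simplified(f: LesionFeatures) -> SimplifiedLabel:
    """Label a lesion likely-benign or likely-malignant from three descriptors.

    Ordered rules: no mass -> benign; peritoneal disease -> malignant; purely
    cystic -> benign; fat-containing -> malignant only when the enhancing
    component is large (>= 80 mm); any other solid tissue -> malignant.
    """
    violations = validate_features(f)
    if violations:
        raise InvalidFeaturesError(violations[0])

    if not f.mass_present:
        return SimplifiedLabel.likely_benign
    if f.peritoneal_disease:
        return SimplifiedLabel.likely_malignant
    if f.is_cystic:
        return SimplifiedLabel.likely_benign
    if f.fat_present:
        assert f.enhancing_component_diameter is not None
        if f.enhancing_component_diameter >= LARGE_ENHANCING_THRESHOLD:
            return SimplifiedLabel.likely_malignant
        return SimplifiedLabel.likely_benign
    # non-fatty lesion with solid tissue
    return SimplifiedLabel.likely_malignant
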