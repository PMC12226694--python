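"""Deterministic O-RADS MRI decision tree over structured lesion descriptors.

The classifier walks an ordered tree:

1. no ovarian mass                        -> O-RADS 1
2. peritoneal/mesenteric/omental disease  -> O-RADS 5
3. intralesional fat                      -> O-RADS 5 if the enhancing
   component is large (>= 80 mm), else O-RADS 2
4. solid tissue (lexicon definition)      -> O-RADS 2 if "dark-dark"
   (homogeneously T2-hypointense AND homogeneously without diffusion
   restriction), else O-RADS 4 if hypo/iso-enhancing relative to the
   myometrium, else O-RADS 5
5. cystic lesion                          -> O-RADS 3 if multilocular; a
   unilocular cyst is O-RADS 2 for simple or endometriotic fluid, and for
   other non-simple fluid O-RADS 3 with wall enhancement, O-RADS 2 without.

Branch precedence is part of the contract: peritoneal disease dominates
everything else, and fat short-circuits the solid/cystic branches.  Routing
fat-containing lesions with a large enhancing component to class 5 (rather
than 4) follows the pediatric reading algorithm implemented here; other
published variants of the parent framework differ on this point.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable

from .features import (
    LARGE_ENHANCING_THRESHOLD,
    EnhancementGrade,
    FluidType,
    LesionFeatures,
    Locularity,
    PatientRecord,
    validate_features,
)

__all__ = [
    "ORADS_CLASSES",
    "InvalidFeaturesError",
    "ClassifiedRecord",
    "classify_orads",
    "classify_cohort",
]

ORADS_CLASSES: tuple[int, ...] = (1, 2, 3, 4, 5)


class InvalidFeaturesError(ValueError):
    """Raised when lesion descriptors violate a validity invariant."""


def classify_orads(f: LesionFeatures) -> int:
    """Assign the O-RADS MRI class (1-5) for one set of lesion descriptors.

    Raises :class:`InvalidFeaturesError` naming the first violation if the
    descriptors are incoherent.  Equal inputs give equal outputs.
    """
    violations = validate_features(f)
    if violations:
        raise InvalidFeaturesError(violations[0])

    if not f.mass_present:
        return 1
    if f.peritoneal_disease:
        return 5
    if f.fat_present:
        assert f.enhancing_component_diameter is not None
        if f.enhancing_component_diameter >= LARGE_ENHANCING_THRESHOLD:
            return 5
        return 2
    if f.solid_tissue_present:
        if f.is_dark_dark:
            return 2
        if f.enhancement_grade is EnhancementGrade.hypo_or_iso:
            return 4
        return 5
    # cystic: mass without fat and without solid tissue
    if f.locularity is Locularity.multilocular:
        return 3
    if f.fluid_type in (FluidType.simple, FluidType.endometriotic):
        return 2
    return 3 if f.wall_enhancement else 2


@dataclass(frozen=True)
class ClassifiedRecord:
    """A patient record together with its engine-assigned O-RADS class."""

    record: PatientRecord
    orads_class: int


def classify_cohort(
    records: Iterable[PatientRecord],
) -> tuple[list[ClassifiedRecord], dict[int, int]]:
    """Classify every record and tally classes 1-5.

    Returns ``(classified, tally)`` where ``tally`` maps each class to its
    count (zero-filled) and sums to the number of records.  An invalid record
    raises :class:`InvalidFeaturesError` naming the record id.
    """
    classified: list[ClassifiedRecord] = []
    counts: Counter[int] = Counter()
    for rec in records:
        try:
            cls = classify_orads(rec.features)
        except InvalidFeaturesError as err:
            raise InvalidFeaturesError(f"record {rec.id}: {err}") from None
        classified.append(ClassifiedRecord(rec, cls))
        counts[cls] += 1
    tally = {c: counts.get(c, 0) for c in ORADS_CLASSES}
    return classified, tally
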