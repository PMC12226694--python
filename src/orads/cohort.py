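"""Synthetic pediatric cohort: canonical fixture and seeded generator.

The study cohort (109 girls referred to pelvic MRI for suspected ovarian
masses) is not deposited anywhere; only its margins are printed.  This module
provides two substitutes, both entirely synthetic:

* :func:`canonical_cohort` — a fixed, deterministic 109-record table that
  reproduces every printed margin simultaneously: class counts 7/68/23/2/9,
  per-class malignancies 0/0/0/1/6 (total 7, with the published histologies),
  the class-2 fat (46) / cystic (63) overlap (41), the class-5 composition
  (3 peritoneal, 1 large-enhancing fatty lesion, 5 hyperenhancing solid),
  age median 13 (IQR 11-15), lesion size median 62 mm (IQR 45-110 mm), and
  laterality 54 right / 48 left.
* :func:`generate_cohort` — a seeded sampler whose parameters default to the
  canonical frequencies, for scaling experiments and parameter-recovery
  tests.  Features are drawn from class-conditional archetypes built so the
  rule engine returns the intended class with probability one.

Known source inconsistencies are resolved as follows: the class-5 malignant
count is 6 (the per-class totals 1 + 6 must sum to the authoritative 7
malignancies, although one table cell prints 7), and the class-5
hyperenhancing-solid count is 5 = 9 - 3 peritoneal - 1 large-fatty (one table
cell prints 4; overlapping rows cannot all hold at n = 9).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .engine import ORADS_CLASSES, classify_cohort
from .features import (
    EnhancementGrade,
    FluidType,
    Laterality,
    LesionFeatures,
    Locularity,
    PatientRecord,
)
from .stats import summarize_continuous

__all__ = [
    "CohortParams",
    "canonical_cohort",
    "default_params",
    "generate_cohort",
    "sample_cohort",
    "cohort_margins",
]

# ---------------------------------------------------------------------------
# canonical fixture
# ---------------------------------------------------------------------------

#: age -> patient count; 109 total, median 13, IQR 11-15 under linear
#: interpolation of order statistics
_AGE_COUNTS: dict[int, int] = {
    4: 2, 5: 2, 6: 3, 7: 3, 8: 4, 9: 5, 10: 5,
    11: 12, 12: 15, 13: 16, 14: 12, 15: 14,
    16: 7, 17: 5, 18: 4,
}

_MALIGNANT_HISTOLOGIES = (
    "dysgerminoma",
    "dysgerminoma",
    "malignant teratoma",
    "mucinous borderline tumor with intraepithelial carcinoma",
    "malignant granulosa cell tumor",
    "rhabdoid tumor",
    "burkitt lymphoma",
)


def _canonical_sizes() -> np.ndarray:
    """102 lesion sizes (mm), sorted: median 62, IQR 45-110."""
    below = 20.0 + np.arange(25)                    # 20..44
    q1 = np.array([45.0, 45.0])
    low_mid = np.linspace(45.5, 61.5, 23)
    med = np.array([62.0, 62.0])
    high_mid = np.linspace(63.0, 109.0, 23)
    q3 = np.array([110.0, 110.0])
    above = np.linspace(112.0, 200.0, 25)
    sizes = np.concatenate([below, q1, low_mid, med, high_mid, q3, above])
    assert sizes.size == 102
    return sizes


def _canonical_ages() -> list[int]:
    ages: list[int] = []
    for age, count in _AGE_COUNTS.items():
        ages.extend([age] * count)
    assert len(ages) == 109
    return ages


def _cystic(locularity: Locularity, fluid: FluidType, wall: Optional[bool]) -> LesionFeatures:
    return LesionFeatures(
        mass_present=True,
        locularity=locularity,
        fluid_type=fluid,
        wall_enhancement=wall,
    )


def _solid(grade: EnhancementGrade) -> LesionFeatures:
    return LesionFeatures(
        mass_present=True,
        solid_tissue_present=True,
        t2_homogeneous_hypointense=False,
        dwi_homogeneous_no_restriction=False,
        enhancement_grade=grade,
    )


def _lesion_archetypes() -> list[tuple[LesionFeatures, int, bool, Optional[str]]]:
    """(features, intended class, malignant, histology) for the 102 lesions."""
    out: list[tuple[LesionFeatures, int, bool, Optional[str]]] = []

    # --- O-RADS 2: 68 lesions, none malignant -----------------------------
    # 41 fat-containing with coexisting cystic spaces (dermoid pattern)
    for i in range(41):
        out.append((
            LesionFeatures(
                mass_present=True,
                fat_present=True,
                enhancing_component_diameter=10.0,
                locularity=Locularity.unilocular if i % 2 else Locularity.multilocular,
                fluid_type=FluidType.proteinaceous,
                wall_enhancement=False,
            ),
            2, False, "mature teratoma",
        ))
    # 5 fat-containing without cystic descriptors
    for _ in range(5):
        out.append((
            LesionFeatures(
                mass_present=True, fat_present=True, enhancing_component_diameter=15.0
            ),
            2, False, "mature teratoma",
        ))
    # 18 unilocular simple cysts (functional)
    for _ in range(18):
        out.append((
            _cystic(Locularity.unilocular, FluidType.simple, None),
            2, False, "functional cyst",
        ))
    # 4 unilocular non-simple cysts without wall enhancement
    for i in range(4):
        fluid = FluidType.hemorrhagic if i % 2 else FluidType.proteinaceous
        out.append((
            _cystic(Locularity.unilocular, fluid, False),
            2, False, "hemorrhagic cyst",
        ))

    # --- O-RADS 3: 23 cystic lesions, none malignant ----------------------
    for _ in range(12):
        out.append((
            _cystic(Locularity.multilocular, FluidType.simple, None),
            3, False, "serous cystadenoma",
        ))
    for _ in range(11):
        out.append((
            _cystic(Locularity.unilocular, FluidType.hemorrhagic, True),
            3, False, "hemorrhagic cyst",
        ))

    # --- O-RADS 4: 2 hypo/iso-enhancing solid lesions, 1 malignant --------
    out.append((_solid(EnhancementGrade.hypo_or_iso), 4, True, "dysgerminoma"))
    out.append((_solid(EnhancementGrade.hypo_or_iso), 4, False, "serous papillary cystadenoma"))

    # --- O-RADS 5: 9 lesions, 6 malignant ---------------------------------
    # 3 with peritoneal disease (one also fat-containing), all malignant
    out.append((
        LesionFeatures(mass_present=True, peritoneal_disease=True),
        5, True, "mucinous borderline tumor with intraepithelial carcinoma",
    ))
    out.append((
        LesionFeatures(
            mass_present=True,
            peritoneal_disease=True,
            fat_present=True,
            enhancing_component_diameter=30.0,
        ),
        5, True, "rhabdoid tumor",
    ))
    out.append((
        LesionFeatures(mass_present=True, peritoneal_disease=True),
        5, True, "burkitt lymphoma",
    ))
    # 1 fat-containing lesion with a large (>= 80 mm) enhancing component
    out.append((
        LesionFeatures(
            mass_present=True, fat_present=True, enhancing_component_diameter=95.0
        ),
        5, True, "malignant teratoma",
    ))
    # 5 hyperenhancing solid lesions: 2 malignant, 3 benign
    out.append((_solid(EnhancementGrade.hyper), 5, True, "dysgerminoma"))
    out.append((_solid(EnhancementGrade.hyper), 5, True, "malignant granulosa cell tumor"))
    out.append((_solid(EnhancementGrade.hyper), 5, False, "fibroma"))
    out.append((_solid(EnhancementGrade.hyper), 5, False, "fibroma"))
    out.append((_solid(EnhancementGrade.hyper), 5, False, "benign lesion, unspecified"))

    assert len(out) == 102
    return out


def canonical_cohort() -> list[PatientRecord]:
    """The fixed 109-record synthetic cohort reproducing the printed margins.

    Deterministic: every call returns identical records.  Record ids are
    ``P001`` to ``P109``; the 7 no-mass records come first.
    """
    lesions = _lesion_archetypes()

    # Age and lesion size carried no malignancy signal in the study, so the
    # fixture realizes that null by balanced assignment: the 7 malignant
    # lesions take sizes at evenly spread quantiles of the size distribution
    # (their median equals the cohort median) and representative ages, with
    # the large-enhancing teratoma taking the largest of those slots.
    sorted_sizes = _canonical_sizes()
    highrisk_idx = [i for i, (_, cls, _, _) in enumerate(lesions) if cls >= 4]
    # interleave malignant and benign high-risk lesions across evenly spread
    # order-statistic slots of the size distribution; the large-enhancing
    # teratoma (95 mm component) takes the top slot
    large_fatty = next(
        i for i in highrisk_idx
        if lesions[i][0].fat_present
        and (lesions[i][0].enhancing_component_diameter or 0) >= 80
    )
    mal_hr = [i for i in highrisk_idx if lesions[i][2] and i != large_fatty]
    ben_hr = [i for i in highrisk_idx if not lesions[i][2]]
    slots = [int(round(s)) for s in np.linspace(5, 96, 11)]
    slot_order = [
        mal_hr[0], ben_hr[0], mal_hr[1], mal_hr[2], ben_hr[1], mal_hr[3],
        ben_hr[2], mal_hr[4], mal_hr[5], ben_hr[3], large_fatty,
    ]
    sizes = [0.0] * 102
    taken = set()
    for i, slot in zip(slot_order, slots):
        sizes[i] = float(sorted_sizes[slot])
        taken.add(slot)
    rest = [float(sorted_sizes[k]) for k in range(102) if k not in taken]
    shuffle = np.random.default_rng(20120109)
    rest = list(shuffle.permutation(rest))
    low_idx = [i for i in range(102) if i not in highrisk_idx]
    for i, size in zip(low_idx, rest):
        sizes[i] = size

    # ages likewise: high-risk lesions get representative ages (median 13 in
    # both outcome groups), everyone else a permuted draw from the remainder
    highrisk_ages = [9, 10, 11, 12, 12, 13, 13, 14, 15, 16, 17]
    age_pool = _canonical_ages()
    for a in highrisk_ages:
        age_pool.remove(a)
    age_pool = [int(a) for a in shuffle.permutation(age_pool)]
    ages = [0] * 109
    for i, a in zip(slot_order, highrisk_ages):
        ages[7 + i] = a
    other_positions = [k for k in range(109) if k not in {7 + i for i in highrisk_idx}]
    for pos, a in zip(other_positions, age_pool):
        ages[pos] = a

    records: list[PatientRecord] = []
    for i in range(7):
        records.append(
            PatientRecord(
                id=f"P{i + 1:03d}",
                age=ages[i],
                features=LesionFeatures(mass_present=False),
                laterality=None,
                malignant=False,
            )
        )
    for j, (feats, _cls, malignant, histology) in enumerate(lesions):
        side = Laterality.right if (j < 6 or j % 2 == 0) else Laterality.left
        feats = replace(feats, max_diameter=float(sizes[j]))
        records.append(
            PatientRecord(
                id=f"P{j + 8:03d}",
                age=ages[7 + j],
                features=feats,
                laterality=side,
                malignant=malignant,
                histology=histology,
            )
        )
    return records


# ---------------------------------------------------------------------------
# seeded generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortParams:
    """Generative description of a synthetic cohort.

    Probability vectors must each sum to one (tolerance 1e-9).  Ages are
    drawn from a rounded normal clipped to 4-18 years; lesion sizes from a
    log-normal; both parameterized to match the study's medians and IQRs.
    """

    n: int = 109
    class_probabilities: tuple[float, ...] = (7 / 109, 68 / 109, 23 / 109, 2 / 109, 9 / 109)
    malignancy_probability: tuple[float, ...] = (0.0, 0.0, 0.0, 0.5, 6 / 9)
    class5_mixture: tuple[float, float, float] = (3 / 9, 1 / 9, 5 / 9)  # peritoneal, fat_large, hyper_solid
    class2_mixture: tuple[float, float, float] = (46 / 68, 18 / 68, 4 / 68)  # fatty, cystic_simple, cystic_nonsimple_no_wall
    class3_mixture: tuple[float, float] = (12 / 23, 11 / 23)  # multilocular, unilocular_nonsimple_enhancing_wall
    age_loc: float = 13.0
    age_scale: float = 2.97  # IQR 4 years / 1.349
    size_log_loc: float = float(np.log(62.0))  # median 62 mm
    size_log_scale: float = 0.66  # log(110/45) / 1.349
    laterality_probability: float = 54 / 102  # P(right)
    seed: int = 0

    def validate(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        for name in ("class_probabilities", "class5_mixture", "class2_mixture", "class3_mixture"):
            vec = np.asarray(getattr(self, name), dtype=float)
            if np.any(vec < 0) or abs(vec.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must be a probability vector summing to 1")
        mal = np.asarray(self.malignancy_probability, dtype=float)
        if mal.shape != (5,) or np.any((mal < 0) | (mal > 1)):
            raise ValueError("malignancy_probability must be 5 probabilities")


def default_params(seed: int = 0) -> CohortParams:
    """Parameters whose expectations equal the canonical cohort's margins."""
    return CohortParams(seed=seed)


_FAT_CYSTIC_OVERLAP = 41 / 46  # P(cystic spaces | fatty class-2 lesion)


def _sample_features(cls: int, params: CohortParams, rng: np.random.Generator) -> LesionFeatures:
    if cls == 1:
        return LesionFeatures(mass_present=False)
    if cls == 2:
        arm = rng.choice(3, p=params.class2_mixture)
        if arm == 0:  # fatty, enhancing component below 80 mm
            feats = LesionFeatures(
                mass_present=True,
                fat_present=True,
                enhancing_component_diameter=float(rng.uniform(5.0, 75.0)),
            )
            if rng.random() < _FAT_CYSTIC_OVERLAP:
                feats = replace(
                    feats,
                    locularity=Locularity(rng.choice(["unilocular", "multilocular"])),
                    fluid_type=FluidType.proteinaceous,
                    wall_enhancement=False,
                )
            return feats
        if arm == 1:
            return _cystic(Locularity.unilocular, FluidType.simple, None)
        fluid = FluidType(rng.choice(["hemorrhagic", "proteinaceous"]))
        return _cystic(Locularity.unilocular, fluid, False)
    if cls == 3:
        arm = rng.choice(2, p=params.class3_mixture)
        if arm == 0:
            return _cystic(Locularity.multilocular, FluidType.simple, None)
        return _cystic(Locularity.unilocular, FluidType.hemorrhagic, True)
    if cls == 4:
        return _solid(EnhancementGrade.hypo_or_iso)
    arm = rng.choice(3, p=params.class5_mixture)
    if arm == 0:
        feats = LesionFeatures(mass_present=True, peritoneal_disease=True)
        if rng.random() < 1 / 3:  # one of three peritoneal lesions was fatty
            feats = replace(
                feats,
                fat_present=True,
                enhancing_component_diameter=float(rng.uniform(5.0, 75.0)),
            )
        return feats
    if arm == 1:
        return LesionFeatures(
            mass_present=True,
            fat_present=True,
            enhancing_component_diameter=float(rng.uniform(80.0, 150.0)),
        )
    return _solid(EnhancementGrade.hyper)


def sample_cohort(params: CohortParams) -> list[tuple[PatientRecord, int]]:
    """Sample records with their intended O-RADS class.

    The archetypes are built so the rule engine reproduces the intended class
    exactly (round-trip guarantee); the pairing is returned so that guarantee
    is testable.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    out: list[tuple[PatientRecord, int]] = []
    for i in range(params.n):
        cls = int(rng.choice(ORADS_CLASSES, p=params.class_probabilities))
        feats = _sample_features(cls, params, rng)
        age = int(np.clip(np.rint(rng.normal(params.age_loc, params.age_scale)), 4, 18))
        malignant = bool(rng.random() < params.malignancy_probability[cls - 1])
        if cls == 1:
            record = PatientRecord(
                id=f"S{i + 1:05d}", age=age, features=feats, malignant=malignant
            )
        else:
            size = float(rng.lognormal(params.size_log_loc, params.size_log_scale))
            if feats.enhancing_component_diameter is not None:
                size = max(size, feats.enhancing_component_diameter)
            side = (
                Laterality.right
                if rng.random() < params.laterality_probability
                else Laterality.left
            )
            record = PatientRecord(
                id=f"S{i + 1:05d}",
                age=age,
                features=replace(feats, max_diameter=size),
                laterality=side,
                malignant=malignant,
            )
        out.append((record, cls))
    return out


def generate_cohort(params: CohortParams) -> list[PatientRecord]:
    """Seeded, reproducible synthetic cohort (records only)."""
    return [record for record, _ in sample_cohort(params)]


# ---------------------------------------------------------------------------
# margins
# ---------------------------------------------------------------------------


def cohort_margins(records: Sequence[PatientRecord]) -> dict:
    """Summary margins mirroring the study's descriptive tables.

    Classifies the records with the rule engine and reports class counts,
    malignancies per class, per-class feature-row counts, age and size
    summaries, and the laterality split among lesions.
    """
    classified, tally = classify_cohort(records)

    def per_class(predicate) -> dict[int, int]:
        counts = {c: 0 for c in ORADS_CLASSES}
        for cr in classified:
            f = cr.record.features
            if f.mass_present and predicate(f):
                counts[cr.orads_class] += 1
        return counts

    malignant_by_class = {c: 0 for c in ORADS_CLASSES}
    for cr in classified:
        if cr.record.malignant:
            malignant_by_class[cr.orads_class] += 1

    feature_rows = {
        "peritoneal_thickening_or_nodules": per_class(lambda f: f.peritoneal_disease),
        "fat_component": per_class(lambda f: f.fat_present),
        "large_enhancing_component": per_class(
            lambda f: f.fat_present
            and (f.enhancing_component_diameter or 0.0) >= 80.0
        ),
        "dark_dark_solid": per_class(lambda f: f.is_dark_dark),
        "solid_enhancement_graded": per_class(
            lambda f: f.solid_tissue_present and not f.is_dark_dark
        ),
        "cystic_lesions": per_class(
            lambda f: f.locularity is not None and not f.solid_tissue_present
        ),
    }

    ages = [r.age for r in records]
    sizes = [
        r.features.max_diameter
        for r in records
        if r.features.max_diameter is not None
    ]
    laterality = {
        "right": sum(1 for r in records if r.laterality is Laterality.right),
        "left": sum(1 for r in records if r.laterality is Laterality.left),
    }
    return {
        "n": len(records),
        "class_counts": tally,
        "malignant_by_class": malignant_by_class,
        "malignant_total": sum(malignant_by_class.values()),
        "feature_rows": feature_rows,
        "age": summarize_continuous(ages) if ages else None,
        "size_mm": summarize_continuous(sizes) if sizes else None,
        "laterality": laterality,
    }
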