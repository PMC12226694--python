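"""Structured MRI descriptors of an adnexal lesion and their validity rules.

The O-RADS MRI rule engine operates on categorical/measured descriptors that a
radiologist records while reading a pelvic MRI — not on images.  A lesion is
described by whether a mass is present at all, whether there is peritoneal
disease (nodularity or irregular thickening of peritoneum, mesentery or
omentum, with or without ascites), whether it contains macroscopic fat on
T1-based sequences, the descriptors of any solid tissue (T2 signal relative to
iliopsoas, diffusion restriction, enhancement relative to the outer
myometrium), and — for purely cystic lesions — locularity, fluid type and
parietal (wall) enhancement.

Fields that are meaningless for a given lesion (e.g. locularity of a fatty
mass) are optional; :func:`validate_features` enforces exactly the conditional
requirements the reading algorithm needs and nothing more.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

__all__ = [
    "EnhancementGrade",
    "Locularity",
    "FluidType",
    "Laterality",
    "LesionFeatures",
    "PatientRecord",
    "validate_features",
    "LARGE_ENHANCING_THRESHOLD",
]

#: Enhancing tissue inside a fat-containing lesion at or above this diameter
#: (millimetres) counts as a "large" enhancing component.
LARGE_ENHANCING_THRESHOLD: float = 80.0


class EnhancementGrade(str, Enum):
    """Solid-tissue contrast enhancement relative to the outer myometrium."""

    hypo_or_iso = "hypo_or_iso"
    hyper = "hyper"


class Locularity(str, Enum):
    unilocular = "unilocular"
    multilocular = "multilocular"


class FluidType(str, Enum):
    """Cyst content signal pattern.

    ``simple`` is urine-like (T2-hyperintense, T1-hypointense); endometriotic,
    hemorrhagic and proteinaceous contents are the non-simple types.
    """

    simple = "simple"
    endometriotic = "endometriotic"
    hemorrhagic = "hemorrhagic"
    proteinaceous = "proteinaceous"


class Laterality(str, Enum):
    left = "left"
    right = "right"


NON_SIMPLE_FLUIDS = frozenset(
    {FluidType.endometriotic, FluidType.hemorrhagic, FluidType.proteinaceous}
)


@dataclass(frozen=True)
class LesionFeatures:
    """Imaging descriptors of one adnexal lesion (or its absence)."""

    mass_present: bool = False
    peritoneal_disease: bool = False
    fat_present: bool = False
    enhancing_component_diameter: Optional[float] = None
    solid_tissue_present: bool = False
    t2_homogeneous_hypointense: Optional[bool] = None
    dwi_homogeneous_no_restriction: Optional[bool] = None
    enhancement_grade: Optional[EnhancementGrade] = None
    locularity: Optional[Locularity] = None
    fluid_type: Optional[FluidType] = None
    wall_enhancement: Optional[bool] = None
    max_diameter: Optional[float] = None

    @property
    def is_cystic(self) -> bool:
        """Purely cystic lesion: a mass whose composition branch is cystic.

        Lesions with peritoneal disease are classified before composition is
        assessed, so they are not required to carry cystic descriptors.
        """
        return (
            self.mass_present
            and not self.peritoneal_disease
            and not self.fat_present
            and not self.solid_tissue_present
        )

    @property
    def is_dark_dark(self) -> bool:
        """Solid tissue homogeneously T2-hypointense AND without restriction."""
        return (
            self.solid_tissue_present
            and self.t2_homogeneous_hypointense is True
            and self.dwi_homogeneous_no_restriction is True
        )


@dataclass(frozen=True)
class PatientRecord:
    """One patient of the cohort: demographics, lesion descriptors, outcome."""

    id: str
    age: float
    features: LesionFeatures
    laterality: Optional[Laterality] = None
    malignant: Optional[bool] = None
    histology: Optional[str] = None
    reader2_class: Optional[int] = None


def validate_features(f: LesionFeatures) -> list[str]:
    """Check the conditional-requirement invariants of ``f``.

    Returns a list of human-readable violation descriptions, each naming the
    offending field; an empty list means the descriptor set is coherent.
    Never raises.
    """
    violations: list[str] = []

    if not f.mass_present:
        lesion_fields = {
            "peritoneal_disease": f.peritoneal_disease,
            "fat_present": f.fat_present,
            "enhancing_component_diameter": f.enhancing_component_diameter,
            "solid_tissue_present": f.solid_tissue_present,
            "t2_homogeneous_hypointense": f.t2_homogeneous_hypointense,
            "dwi_homogeneous_no_restriction": f.dwi_homogeneous_no_restriction,
            "enhancement_grade": f.enhancement_grade,
            "locularity": f.locularity,
            "fluid_type": f.fluid_type,
            "wall_enhancement": f.wall_enhancement,
            "max_diameter": f.max_diameter,
        }
        for name, value in lesion_fields.items():
            if value not in (None, False):
                violations.append(
                    f"{name}: must be absent when mass_present is false"
                )
        return violations

    if f.fat_present:
        if f.enhancing_component_diameter is None:
            violations.append(
                "enhancing_component_diameter: required when fat_present is true"
            )
        elif f.enhancing_component_diameter < 0:
            violations.append("enhancing_component_diameter: must be >= 0")
    elif f.enhancing_component_diameter is not None:
        violations.append(
            "enhancing_component_diameter: only meaningful for fat-containing lesions"
        )

    if f.solid_tissue_present:
        if f.t2_homogeneous_hypointense is None:
            violations.append(
                "t2_homogeneous_hypointense: required when solid_tissue_present"
            )
        if f.dwi_homogeneous_no_restriction is None:
            violations.append(
                "dwi_homogeneous_no_restriction: required when solid_tissue_present"
            )
        if not f.is_dark_dark and f.enhancement_grade is None and None not in (
            f.t2_homogeneous_hypointense,
            f.dwi_homogeneous_no_restriction,
        ):
            violations.append(
                "enhancement_grade: required for solid tissue that is not dark-dark"
            )

    if f.is_cystic:
        if f.locularity is None:
            violations.append("locularity: required for cystic lesions")
        if f.fluid_type is None:
            violations.append("fluid_type: required for cystic lesions")
        elif f.fluid_type in NON_SIMPLE_FLUIDS and f.wall_enhancement is None:
            violations.append(
                "wall_enhancement: required for cystic lesions with non-simple fluid"
            )

    if f.max_diameter is not None and f.max_diameter < 0:
        violations.append("max_diameter: must be >= 0")
    if (
        f.max_diameter is not None
        and f.enhancing_component_diameter is not None
        and f.max_diameter < f.enhancing_component_diameter
    ):
        violations.append(
            "max_diameter: must be >= enhancing_component_diameter"
        )

    return violations
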