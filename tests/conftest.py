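import itertools

import pytest

from orads.features import (
    EnhancementGrade,
    FluidType,
    LesionFeatures,
    Locularity,
    validate_features,
)
from orads.cohort import canonical_cohort
from orads.engine import classify_cohort

DIAMETERS = (0.0, 79.0, 80.0, 81.0, 200.0)


def enumerate_valid_features() -> list[LesionFeatures]:
    """Exhaustive grid of valid descriptor combinations.

    Booleans and enums range over all values consistent with the validity
    invariants; diameters range over values straddling the 80 mm threshold.
    """
    grid: list[LesionFeatures] = [LesionFeatures(mass_present=False)]
    for peritoneal in (False, True):
        # fat-containing
        for diam in DIAMETERS:
            grid.append(
                LesionFeatures(
                    mass_present=True,
                    peritoneal_disease=peritoneal,
                    fat_present=True,
                    enhancing_component_diameter=diam,
                    max_diameter=max(diam, 200.0),
                )
            )
        # solid tissue
        for t2, dwi in itertools.product((False, True), repeat=2):
            grades = list(EnhancementGrade)
            if t2 and dwi:  # dark-dark: grade not required
                grades = grades + [None]
            for grade in grades:
                grid.append(
                    LesionFeatures(
                        mass_present=True,
                        peritoneal_disease=peritoneal,
                        solid_tissue_present=True,
                        t2_homogeneous_hypointense=t2,
                        dwi_homogeneous_no_restriction=dwi,
                        enhancement_grade=grade,
                    )
                )
        # cystic
        for loc, fluid in itertools.product(Locularity, FluidType):
            walls = (None,) if fluid is FluidType.simple else (False, True)
            for wall in walls:
                grid.append(
                    LesionFeatures(
                        mass_present=True,
                        peritoneal_disease=peritoneal,
                        locularity=loc,
                        fluid_type=fluid,
                        wall_enhancement=wall,
                    )
                )
        # peritoneal disease with no composition descriptors at all
        if peritoneal:
            grid.append(LesionFeatures(mass_present=True, peritoneal_disease=True))
    assert all(validate_features(f) == [] for f in grid)
    return grid


@pytest.fixture(scope="session")
def valid_grid():
    return enumerate_valid_features()


@pytest.fixture(scope="session")
def cohort():
    return canonical_cohort()


@pytest.fixture(scope="session")
def classified_cohort(cohort):
    classified, tally = classify_cohort(cohort)
    return classified, tally
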