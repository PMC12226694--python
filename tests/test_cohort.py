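import collections
import dataclasses

import numpy as np
import pytest

from orads.cohort import (
    canonical_cohort,
    cohort_margins,
    default_params,
    generate_cohort,
    sample_cohort,
)
from orads.engine import classify_orads
from orads.features import validate_features
from orads.simplified import SimplifiedLabel, classify_simplified


class TestCanonicalCohort:
    def test_is_deterministic(self, cohort):
        assert canonical_cohort() == cohort
        assert len(cohort) == 109

    def test_every_record_is_valid(self, cohort):
        for r in cohort:
            assert validate_features(r.features) == [], r.id

    def test_headline_counts(self, cohort, classified_cohort):
        _, tally = classified_cohort
        assert sum(1 for r in cohort if not r.features.mass_present) == 7
        assert tally == {1: 7, 2: 68, 3: 23, 4: 2, 5: 9}
        assert sum(1 for r in cohort if r.malignant) == 7

    def test_malignancies_by_class_and_histology(self, cohort, classified_cohort):
        classified, _ = classified_cohort
        by_class = collections.Counter(
            cr.orads_class for cr in classified if cr.record.malignant
        )
        assert by_class == {4: 1, 5: 6}
        histologies = sorted(r.histology for r in cohort if r.malignant)
        assert histologies == sorted(
            [
                "dysgerminoma",
                "dysgerminoma",
                "malignant teratoma",
                "mucinous borderline tumor with intraepithelial carcinoma",
                "malignant granulosa cell tumor",
                "rhabdoid tumor",
                "burkitt lymphoma",
            ]
        )

    def test_class2_fat_and_cystic_margins(self, cohort, classified_cohort):
        classified, _ = classified_cohort
        class2 = [cr.record.features for cr in classified if cr.orads_class == 2]
        fatty = [f for f in class2 if f.fat_present]
        cystic = [f for f in class2 if f.locularity is not None and not f.solid_tissue_present]
        assert len(fatty) == 46
        assert len(cystic) == 63
        assert sum(1 for f in class2 if f.fat_present and f.locularity is not None) == 41
        assert all(f.enhancing_component_diameter < 80 for f in fatty)

    def test_class5_composition(self, classified_cohort):
        classified, _ = classified_cohort
        class5 = [cr.record for cr in classified if cr.orads_class == 5]
        assert sum(1 for r in class5 if r.features.peritoneal_disease) == 3
        assert sum(1 for r in class5 if r.features.fat_present) == 2
        large = [
            r for r in class5
            if r.features.fat_present
            and r.features.enhancing_component_diameter >= 80
        ]
        assert len(large) == 1 and large[0].malignant
        assert large[0].histology == "malignant teratoma"
        solid = [r for r in class5 if r.features.solid_tissue_present]
        assert len(solid) == 5
        assert sorted(r.histology for r in solid if not r.malignant) == [
            "benign lesion, unspecified", "fibroma", "fibroma",
        ]

    def test_class4_histologies(self, classified_cohort):
        classified, _ = classified_cohort
        class4 = [cr.record for cr in classified if cr.orads_class == 4]
        assert {r.histology for r in class4} == {
            "dysgerminoma", "serous papillary cystadenoma",
        }
        assert sum(1 for r in class4 if r.malignant) == 1

    def test_demographic_margins(self, cohort):
        m = cohort_margins(cohort)
        assert m["age"] == {"median": 13.0, "q25": 11.0, "q75": 15.0}
        assert m["size_mm"] == {"median": 62.0, "q25": 45.0, "q75": 110.0}
        assert m["laterality"] == {"right": 54, "left": 48}

    def test_feature_row_margins(self, cohort):
        rows = cohort_margins(cohort)["feature_rows"]
        assert rows["peritoneal_thickening_or_nodules"][5] == 3
        assert rows["fat_component"][2] == 46
        assert rows["fat_component"][5] == 2
        assert rows["large_enhancing_component"][5] == 1
        assert rows["dark_dark_solid"] == {1: 0, 2: 0, 3: 0, 4: 0, 5: 0}
        assert rows["solid_enhancement_graded"][4] == 2
        assert rows["solid_enhancement_graded"][5] == 5
        assert rows["cystic_lesions"][2] == 63
        assert rows["cystic_lesions"][3] == 23

    def test_simplified_split(self, cohort):
        labels = [classify_simplified(r.features) for r in cohort]
        assert sum(l is SimplifiedLabel.likely_malignant for l in labels) == 11


class TestGenerator:
    def test_empty_cohort(self):
        assert generate_cohort(dataclasses.replace(default_params(), n=0)) == []

    def test_same_seed_reproduces(self):
        p = dataclasses.replace(default_params(seed=99), n=200)
        assert generate_cohort(p) == generate_cohort(p)

    def test_different_seeds_differ(self):
        a = generate_cohort(dataclasses.replace(default_params(seed=1), n=200))
        b = generate_cohort(dataclasses.replace(default_params(seed=2), n=200))
        assert a != b

    def test_invalid_probability_vectors_raise(self):
        bad = dataclasses.replace(default_params(), class_probabilities=(0.5, 0.5, 0.2, 0, 0))
        with pytest.raises(ValueError):
            bad.validate()
        with pytest.raises(ValueError):
            generate_cohort(dataclasses.replace(default_params(), n=-1))

    def test_round_trip_class_fidelity(self):
        """Every generated record classifies to its intended class."""
        pairs = sample_cohort(dataclasses.replace(default_params(seed=1234), n=10_000))
        assert all(classify_orads(r.features) == cls for r, cls in pairs)

    def test_generated_records_valid(self):
        for r in generate_cohort(dataclasses.replace(default_params(seed=5), n=2000)):
            assert validate_features(r.features) == []

    def test_empirical_margins_match_parameters(self):
        """Class and malignancy frequencies of a large seeded cohort are
        consistent with the generator parameters (goodness-of-fit tests,
        which bound all margins jointly without stacking marginal checks)."""
        from scipy import stats as sps

        n = 50_000
        params = dataclasses.replace(default_params(seed=777), n=n)
        pairs = sample_cohort(params)
        cls = np.array([c for _, c in pairs])
        mal = np.array([bool(r.malignant) for r, _ in pairs])
        observed = np.array([(cls == c).sum() for c in range(1, 6)])
        expected = np.array(params.class_probabilities) * n
        gof = sps.chisquare(observed, expected)
        assert gof.pvalue > 1e-3
        for c, p in zip(range(1, 6), params.malignancy_probability):
            sub = mal[cls == c]
            if p in (0.0, 1.0):
                assert sub.mean() == p
            else:
                test = sps.binomtest(int(sub.sum()), sub.size, p)
                assert test.pvalue > 1e-3

    def test_demographics_track_targets(self):
        recs = generate_cohort(dataclasses.replace(default_params(seed=42), n=20_000))
        ages = np.array([r.age for r in recs])
        sizes = np.array(
            [r.features.max_diameter for r in recs if r.features.max_diameter]
        )
        assert abs(np.median(ages) - 13) <= 1
        assert abs(np.median(sizes) - 62) <= 5
        right = np.mean([r.laterality.value == "right" for r in recs if r.laterality])
        assert abs(right - 54 / 102) < 0.02


def test_cohort_margins_empty():
    m = cohort_margins([])
    assert m["n"] == 0
    assert all(v == 0 for v in m["class_counts"].values())
    assert m["age"] is None
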