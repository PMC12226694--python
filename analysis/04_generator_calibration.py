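#!/usr/bin/env python
"""Calibration of the seeded synthetic-cohort generator.

Two checks at scale: (1) round-trip fidelity — every generated record must be
assigned its intended O-RADS class by the rule engine (10,000 records); and
(2) margin calibration — class frequencies, per-class malignancy rates and
demographic medians of a 50,000-record cohort against the generator
parameters, reported with binomial standard errors.
"""

import dataclasses
import json
from pathlib import Path

import numpy as np

from orads.cohort import default_params, sample_cohort
from orads.engine import classify_orads

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 20260101


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    pairs = sample_cohort(dataclasses.replace(default_params(seed=SEED), n=10_000))
    mismatches = sum(classify_orads(r.features) != c for r, c in pairs)
    print(f"round-trip: {len(pairs) - mismatches}/{len(pairs)} records "
          f"classify to their intended class")

    n = 50_000
    params = dataclasses.replace(default_params(seed=SEED + 1), n=n)
    big = sample_cohort(params)
    cls = np.array([c for _, c in big])
    mal = np.array([bool(r.malignant) for r, _ in big])
    ages = np.array([r.age for r, _ in big])
    sizes = np.array([r.features.max_diameter for r, _ in big if r.features.max_diameter])

    out = {"n": n, "seed": SEED, "round_trip_mismatches": mismatches, "classes": {}}
    print(f"margins at n = {n}:")
    for c, p, pm in zip(range(1, 6), params.class_probabilities, params.malignancy_probability):
        freq = float((cls == c).mean())
        se = float(np.sqrt(p * (1 - p) / n))
        sub = mal[cls == c]
        out["classes"][c] = {
            "frequency": freq, "expected": p, "se": se,
            "malignancy": float(sub.mean()), "malignancy_expected": pm,
        }
        print(f"  class {c}: freq {freq:.4f} (expected {p:.4f}, SE {se:.4f}); "
              f"malignancy {sub.mean():.3f} (expected {pm:.3f})")
    out["age_median"] = float(np.median(ages))
    out["size_median_mm"] = float(np.median(sizes))
    print(f"  age median {out['age_median']:.0f} (target 13); "
          f"size median {out['size_median_mm']:.0f} mm (target 62)")
    (RESULTS / "generator_calibration.json").write_text(
        json.dumps(out, indent=2) + "\n", encoding="utf-8"
    )


if __name__ == "__main__":
    main()
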