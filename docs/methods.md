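# Methods

## The reading algorithm

The engine consumes structured descriptors a radiologist records while
reading a pelvic MRI — it performs no image processing. The descriptor model
(`LesionFeatures`) makes conditional requirements explicit: an
enhancing-component diameter is required exactly when the lesion contains
fat; T2 and DWI homogeneity assessments exactly when solid tissue is
present; locularity and fluid type exactly when the cystic branch of the
tree can be reached (a mass with neither peritoneal disease, fat, nor solid
tissue). Descriptors irrelevant to the branch actually taken are ignored,
not rejected, so a fatty lesion may also carry cystic descriptors — as
dermoids usually do.

Classification is an ordered tree with strict precedence:

1. no mass → class 1;
2. peritoneal, mesenteric or omental nodularity and/or irregular thickening
   (with or without ascites — ascites alone does not trigger this branch) →
   class 5;
3. intralesional fat → class 5 when the enhancing component is **≥ 80 mm**,
   else class 2;
4. solid tissue (lexicon definition; smooth enhancing walls/septa do not
   count) → class 2 for the dark-dark pattern, class 4 when
   hypo/iso-enhancing versus the outer myometrium, class 5 when
   hyperenhancing;
5. cystic → class 3 if multilocular; unilocular cysts are class 2 for simple
   or endometriotic fluid, and for hemorrhagic/proteinaceous fluid class 3
   with parietal enhancement, class 2 without.

Choices worth stating because the parent framework and its published
variants differ:

* **Fat + large enhancing component → class 5, not 4.** The 80 mm threshold
  is inclusive. This routing is required to reproduce the class tallies this
  implementation validates against; variants that route such lesions to
  class 4 exist, and the constant (`LARGE_ENHANCING_THRESHOLD`) together
  with the single branch line makes the alternative a one-line change.
* **Dark-dark solid tissue → class 2.** No lesion with this pattern occurs
  in the validation cohort, so the assignment follows the parent framework
  and is untested by cohort data.
* **Endometriotic fluid → class 2 regardless of wall enhancement.** Wall
  enhancement is assessed only where it can change the class
  (hemorrhagic/proteinaceous unilocular cysts).
* **No class 0.** Incomplete examinations are an inclusion matter, not an
  engine output.

## The simplified framework and the risk dichotomy

Classes 1–3 versus 4–5 form the low/high-risk dichotomy. The simplified
tree reproduces the dichotomy from the three descriptors that carry the
malignancy signal: peritoneal disease → likely malignant; purely cystic →
likely benign; fat-containing → likely malignant only with a large (≥ 80 mm)
enhancing component; any other solid lesion → likely malignant; no mass →
likely benign. The two views agree everywhere except dark-dark solid
lesions, which the full algorithm calls class 2 (benign pattern) while the
simplified tree — seeing only "solid" — flags them. The conservative,
sensitivity-first choice is deliberate and is exercised by a property test
over the full descriptor grid.

The simplified split is reported over all 109 records (11 likely malignant /
98 likely benign). The source this cohort emulates prints an 11 + 93 = 104
split without explaining the five missing patients; the reproduction
document flags this as a source inconsistency rather than forcing agreement.

## Confidence intervals

Two binomial interval methods are provided because, with single-digit event
counts, they differ visibly and the emulated tables evidently mix them: the
zero-event cells and the 7/11 cell round to the **Wilson** score interval,
while the 1/2 cell (50%, CI 1–99%) is **Clopper–Pearson**. The validation
report therefore prints both, and the reproduction document marks which
method matches each printed cell. Two printed bounds match neither method
(the low-risk 0/98 upper bound of 3% — both methods give 4% — and the
class-5 interval printed beside an internally inconsistent percentage);
these stay flagged `ambiguous`. Bounds are clipped exactly at boundary cells
(zero events → lower bound exactly 0).

Coverage facts the tests assert: Clopper–Pearson empirical coverage is at or
above the nominal 95% everywhere on the seeded grid p ∈ {0.05, 0.3, 0.7},
n ∈ {10, 50}; Wilson tracks nominal within two points at n = 50 but is
mildly anti-conservative at n = 10 (exact coverage 0.914–0.924 on this
grid — a property of the interval, not of this implementation), so the test
asserts ≥ 0.90 there.

## Inter-reader agreement

Cohen's kappa with linear weights `w_ij = 1 − |i − j|/(K − 1)` over the
ordinal class ranks; with two categories this degenerates to unweighted
kappa (cross-checked against scikit-learn). When both raters are constant on
the same category, chance agreement is total and kappa is reported as
undefined rather than 1. The published agreement values (κ = 0.766 / 0.771)
depend on the second reader's unpublished per-case labels and therefore
cannot be recomputed; the implementation is instead validated against a
hand-computed contingency oracle (κ = 5/7 on a worked four-pair example) and
the perfect-agreement identity.

## Predictor screening

With 7 malignancies in 109 patients and predictors that separate the
outcome perfectly (every peritoneal-disease lesion is malignant), ordinary
maximum-likelihood logistic regression has no finite optimum. The screen
therefore maximizes the Firth-penalized likelihood
`ℓ(β) + ½ log det I(β)` (Jeffreys prior), via damped Newton steps on the
modified score `U*_j = Σ_i (y_i − p_i + h_i(½ − p_i)) x_ij` with
step-halving on the penalized likelihood. P-values are penalized
likelihood-ratio tests in which the reduced model constrains the tested
coefficient to zero **while keeping the full-design penalty** — dropping the
column instead would change the penalty's dimension and make the test
depend on covariate units (a millimetre-scaled covariate would inflate its
own determinant term). Scale invariance is asserted by test.

The default screen uses the seven variables the emulated analysis assessed:
peritoneal disease; composition (purely cystic versus any solid component,
where an enhancing component inside a fatty lesion and peritoneal spread
both count as non-cystic); intralesional fat; age; maximum lesion diameter;
multilocularity (septa); and non-simple fluid. It runs over lesion-bearing
records only, composition being undefined without a mass. On the canonical
cohort, composition and peritoneal disease carry the two smallest p-values
(0.0099 and 0.035), fat is protective but weaker (0.26), and the remaining
four are null — the qualitative pattern the package validates. Exact
published p-values are not reproducible: they depend on unstated model
details, and the published borderline p for fat (0.051) is unreachable on
these margins, where fat is necessarily a strong conditional predictor
(2/48 versus 5/9 malignant within the solid-component stratum).

## The synthetic cohort

`canonical_cohort()` is a fixed, deterministic 109-record table satisfying
simultaneously: 7 no-mass records; engine class counts 7/68/23/2/9;
malignancies 0/0/0/1/6 by class with the seven published histologies;
class-2 composition 46 fat-containing (all enhancing components < 80 mm) and
63 cystic with overlap 41; class-3 all cystic (12 multilocular, 11
unilocular non-simple with wall enhancement — the split is unpublished and
chosen arbitrarily); class 5 as 3 peritoneal-disease lesions (one also
fat-containing), 1 fatty lesion with a 95 mm enhancing component, and 5
hyperenhancing solid lesions; age median 13 (IQR 11–15) years; lesion size
median 62 (IQR 45–110) mm; 54 right / 48 left. Where the emulated tables are
internally inconsistent (a class-5 malignant cell of 7 beside the fraction
6/9; feature rows that cannot sum to the class total of 9), class totals and
the malignancy count of 7 take precedence, and the reproduction document
flags the residue.

Ages and sizes are assigned so the printed medians and IQRs hold exactly
under the linear-interpolation percentile convention, with one deliberate
design property: the 11 high-risk lesions take ages and sizes at evenly
spread order-statistic slots, interleaving malignant and benign records, so
the fixture realizes by construction the null association of age and size
with malignancy that the emulated analysis reports. Leaving this to a random
permutation lets chance correlations with only 7 events distort the
predictor screen. Remaining records receive a fixed-seed permutation of the
leftover values.

`generate_cohort(params)` is a seeded sampler whose defaults equal the
canonical frequencies: class from the 7/68/23/2/9 mixture; class-conditional
feature archetypes constructed so the engine returns the intended class with
probability one (asserted over 10,000 records); malignancy as a
class-conditional Bernoulli (0, 0, 0, ½, 6⁄9); ages from a rounded normal
(location 13, scale 2.97 ≈ 4/1.349) clipped to 4–18; sizes from a log-normal
(log-location ln 62, log-scale 0.66 ≈ ln(110/45)/1.349, truncated below at
the lesion's enhancing-component diameter); laterality right with
probability 54/102. The generator emulates the *margins* of a referral
cohort, not its clinical texture: descriptors are drawn independently within
archetypes, so it reproduces none of the real-world correlation between,
say, lesion size and composition, and passing margin tests says nothing
about performance on real images.

## Numerical and interface conventions

Percentiles use linear interpolation between order statistics; display
rounding is to whole percent, half away from zero. Records travel as CSV or
JSON-lines with a fixed 18-column schema (booleans `true`/`false`, absent
optionals empty, enums lowercase, diameters in millimetres, ages in years);
reading is strict and a malformed cell names its row and column. CLI exit
codes: 0 success, 2 input/schema error, 3 internal failure. All randomness
flows through a single integer seed per run.

## Problem sizes

The test suite and drivers use the 109-record canonical cohort for all
exact reproductions, 10,000 records for round-trip fidelity, 50,000 for
generator calibration, 10,000 replicates per cell for interval coverage,
and n = 2,000 for logistic parameter recovery — sizes at which the binomial
standard errors asserted by the tests are decisive for the properties under
test.

## Known limitations

* The engine covers ovarian/adnexal masses as described; tubal or
  paraovarian lesions and torsion-compromised examinations are out of scope.
* Dark-dark solid routing and the class assignment of endometriotic cysts
  with enhancing walls follow the parent framework but are unconstrained by
  the validation cohort (zero such lesions).
* Published kappa values and exact regression p-values are not reproducible
  from published information; the package validates those components against
  independent oracles instead.
* The synthetic cohort matches printed margins, not patient-level reality;
  conclusions about real diagnostic performance require real data.
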