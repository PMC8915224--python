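# Methods

## The measurement model

A CT volume is a 3D grid of integer Hounsfield units (HU) with voxel
spacing in cm. The analysis assumes three attenuation populations
inside the body — fat (≈ −100 HU), lean soft tissue (≈ +60 HU), and
bone (≥ 350 HU) — plus excludable contents that would otherwise
contaminate the counts: the scanner table and other external objects,
non-aerated lung, GI/stomach contents and bladder urine, and dense
non-skeletal objects (implants, microchips, mineralization, calculi).
Excluded regions are set to the air sentinel −1024 HU so they fall out
of every window. Masks are inputs: no automated organ segmentation is
attempted, mirroring practice where such regions are contoured by hand.

Soft tissue is quantified in the window [−250, 250] HU (inclusive at
both ends). The fat/lean boundary is not a fixed HU value but the
midpoint of the two tissue peaks of each subject's histogram, which
adapts to subject-specific attenuation shifts. The fat interval is
closed at the midpoint: fat = [−250, midpoint], lean = (midpoint, 250].
With integer bins and a half-integer midpoint, the bin just below the
midpoint is the last fat bin. Bone is voxels ≥ 350 HU after
bone-purpose exclusions.

Volumes follow from the voxel volume VV = pixel width × pixel length ×
slice thickness (cm³), which assumes non-overlapping slice
reconstruction (increment = thickness). For overlapping
reconstructions, pass the effective slice spacing as the third spacing
component instead. nBFV = BFV/TBBV is computed as the voxel-count ratio
fat/bone, so it is exactly invariant to any voxel-spacing change.

## Peak detection

How tissue peaks are "identified" is a genuinely open design point; we
fix a deterministic rule: smooth the integer-binned counts with an
11-HU moving average, find local maxima with prominence ≥ 0.5% of the
total in-window count and mutual separation ≥ 30 HU, and take the two
largest (lower = fat, higher = lean). All three parameters are
arguments.

The prominence floor is calibrated to the noise model: a Gaussian fat
compartment with HU standard deviation σ and fraction f of soft tissue
has peak height ≈ f/(σ√2π) of the total, i.e. ≈ 0.040·f at the default
σ = 10. A floor of 0.005 therefore admits fat fractions down to
roughly 13% and rejects leaner histograms with an explicit
`UndefinedFatPeakError` (carrying the number of peaks found) — the
analogue of excluding underweight subjects that lack a defined fat
peak. A floor of 1% would reject everything below ~25% fat at this σ,
which would misclassify clearly measurable subjects; 0.5% keeps the
error mode confined to the genuinely underweight while still requiring
a real mode, not a noise wiggle.

Whether the midpoint should be rounded to an integer HU before
thresholding is unstated in the field; we keep it at half-integer
precision and document the tie rule above.

## FFR and records

FFR = FFPW/FL with FL first rounded to its 2-decimal (cm) recording
precision. FFPW below scale resolution is stored as 0 g, kept in the
cohort (FFR 0), and flagged `below_scale`; it is excluded only from
ln-scale fits, where 0 is undefined. When postmortem FL is missing, a
CT-measured femur length substitutes and the source is recorded. FFR
is reported to 1 decimal; classification against cutoffs always uses
full precision, and the boundary FFR = 1.6 classifies as overweight
(half-open bands [1.6, 3.5) overweight, [3.5, ∞) obese).

## Cutoff derivation and diagnostics

The nBFV overweight cutoff is (median_normal + median_overweight)/2 and
the obese cutoff (median_overweight + median_obese)/2; medians of
even-length samples average the two central order statistics. Cutoffs
are mapped to other scales by evaluating fitted regressions:
exp(a + b·ln(x)) for the ln-ln FFR fit, a + b·x for the linear %BF fit.
Reported cutoffs are rounded to 1 decimal; chaining and classification
use full precision. Note that cutoffs derived this way are
cohort-dependent — they inherit the adiposity distribution of the
population whose medians produced them.

Diagnostic evaluation treats the visual fat category as the reference:
for obesity, disease-positive = visually obese, test-positive =
FFR ≥ obese cutoff; for overweight, disease-positive = visually
overweight, test-positive = FFR in the overweight band (both leaner and
obese test results count as negative). Sensitivity and specificity
carry two-sided Clopper–Pearson exact binomial CIs (statsmodels'
beta-quantile implementation; lower bound 0 at zero successes, upper
bound 1 at all successes), reported to 2 decimals with half-away
rounding, and banded <0.5 low, 0.5–0.69 moderate, 0.7–0.89 high,
0.9–1 very high (left-closed edges).

## Cohort statistics

Correlations are simple OLS with Pearson r and its two-sided p. The
`auto` policy refits on ln-ln scales when a Shapiro–Wilk test rejects
residual normality at α = 0.05 and both variables are positive,
recording the transform used. Group differences use the Kruskal–Wallis
test with tie correction; groups below a configurable size floor
(default 4) are dropped with a warning before testing. Pairwise
comparisons are Dunn z-tests on pooled mean ranks with the tie-corrected
variance and Bonferroni family adjustment — implemented here because no
installed package provides them; the variant of the multiplicity
adjustment is a declared choice.

A caution on power: with Bonferroni-adjusted Dunn tests, realistic
effect sizes (nBFV 2.8 ± 0.7, 5.7 ± 1.7, 10.1 ± 3.0) and realistic
category sizes (8/17/11), the probability that *all three* pairwise
comparisons reach p ≤ 0.05 is only ≈ 0.6 (measured by the Monte-Carlo
check in the test suite); the extreme normal-vs-obese pair is detected
essentially always. Single-study all-pairs significance at this scale
is therefore partly fortunate, and the test suite asserts the measured
regime rather than near-certain success.

## The phantom generator

Each phantom is an ellipsoidal body (semi-axes 0.42 of each extent) of
soft tissue with an embedded skeleton proxy (an axial spine rod plus
two transverse limb rods), optional lung (−400 HU), GI/bladder contents
(+20 HU), metal implant (3000 HU), and an external table slab (0 HU)
outside the body. Fat voxels are chosen by a seeded permutation of the
soft-tissue voxels, so the requested fat fraction is hit exactly at
voxel resolution and growing the target only grows the fat set
(truth nBFV is monotone in the target). HU values are tissue means plus
Gaussian noise (σ = 10 HU), rounded half away from zero to integers —
CT data are integer HU — with background exactly −1024. Generation is
bitwise deterministic in (spec, seed).

Default geometry is 64³ voxels at (0.05, 0.05, 0.06) cm spacing —
deliberately far smaller than a real whole-body scan (~10⁸ voxels) so
that cohort-scale simulation is cheap; all statistics of interest are
ratios or correlations that do not depend on absolute volume.

Cohorts spread target fat fractions evenly over a requested range
(default 0.10–0.60) with ±10% body-size variation. Necropsy records
emulate the structure the analysis assumes: FFPW = 5 g/cm³ × true BFV
plus Gaussian noise (σ = 4.5 g), floored at 0 and rounded to whole
grams (a 0-g reading is kept and flagged, as real below-scale fat pads
are); FL = 11.4 cm scaled by relative body size, rounded to 2 decimals.
The slope puts FFPW in the tens of grams at phantom-scale BFV, and the
noise targets the strong FFPW–BFV correlation regime (analytically
r ≈ 0.89 over the default fraction range). Visual fat categories are
assigned from the true soft-tissue fat fraction by fixed bands
(<0.15 underweight, <0.27 normal, <0.40 overweight, else obese) —
arbitrary but fixed, and used only to exercise agreement machinery.
Muscle grades are drawn at 20% atrophic / 2% hypertrophic.

What the phantom does *not* emulate: anatomically realistic geometry,
beam hardening, partial-volume blur, spatially correlated noise, or
evaluator disagreement in visual categories. Passing tests therefore
demonstrate the correctness of the measurement and statistics chain
under the stated noise model, not robustness to scanner physics.

## Degenerate inputs and numerical conventions

- Peak separation below 6σ must be explicitly allowed
  (`allow_degenerate=True`); bone mean must be ≥ 350 + 3σ.
- Zero soft-tissue or zero bone counts raise errors rather than
  producing NaN ratios.
- An empty disease margin in a generated cohort (e.g. no visually obese
  animal) is reported as "sensitivity/specificity undefined" rather
  than aborting the run.
- All reported decimals round half away from zero (matching printed
  clinical values); internal computation keeps full precision, and
  rounding happens only at the report layer.
- Every random step in a pipeline run derives from the single seed in
  `RunConfig`; per-animal streams are spawned from it, so runs are
  bitwise reproducible.

## Known limitations

- Derived cutoffs depend on the cohort's category composition; they are
  not portable constants.
- The %BF cutoffs obtained by chaining the linear %BF-on-nBFV fit are
  only as good as that fit's linearity over the cutoff region.
- The exclusion masks are trusted as given; labeling errors propagate
  directly into the counts.
- FFR cannot separate normal from underweight animals; the classifier
  deliberately returns a single `not_overweight` class below the
  overweight cutoff.
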