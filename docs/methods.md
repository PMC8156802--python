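# Methods

This note documents the models and procedures implemented in `gaitfuse`,
the assumptions behind them, the parameter defaults, and the package's own
design choices where the procedure left room for judgement.

## Problem setting and data model

A recognition session consists of per-subject recordings of T consecutive
motion frames, each holding the 3-D positions (meters) of 10 lower-body
markers (thigh, shank, ankle ×2, tiptoe; both sides), sampled at 5 Hz
(τ = 0.2 s). Training uses a few gait cycles per subject (order 100
frames); identification fuses the per-frame decisions of a shorter test
recording. Marker ordering is an arbitrary but fixed convention
(`gaitfuse.trajectory.MARKER_NAMES`); any consistent ordering works as long
as training and test agree. The exchange format is a documented plain-text
CSV dialect; binary mocap formats (C3D/TRC) are out of scope.

## Features

Per frame: the 45 strictly-upper-triangle pairwise marker distances
(row-major order) and the 10 signed forward (x-axis) marker velocities by
forward difference. The last frame of a recording has no forward
difference, so a T-frame recording contributes T−1 feature rows; this is
the natural end-of-sequence convention for a forward-difference velocity.
Distances capture body proportions plus momentary limb configuration and
are invariant to rigid motion of the whole marker set; velocities add
walking speed, a known biometric correlate, and are invariant to
translation only.

Features are z-scored per column with statistics fitted on the training
split (sample n−1 standard deviation; zero-variance columns get unit scale
and a warning). The scale-sensitive RBF kernel downstream is why
normalization is required; z-scoring is the standard choice. Calibration is
applied to raw features *before* normalization, since outlier screening is
defined on the physical feature values.

## Unreliable-feature calibration

Each feature's pooled training values are smoothed with a Gaussian KDE
using Silverman's bandwidth ρ = σ·(4/(3L))^{1/5}. Values outside
[Φ⁻¹(1−P_th), Φ⁻¹(P_th)] of the KDE CDF are deemed unreliable; default
P_th = 0.999. The default action clamps them to the violated bound; a
`mean` strategy (replace with the feature's training mean) and `off` are
selectable. No frame is ever deleted — a partly corrupted frame still
carries usable soft evidence for fusion. Bounds are fitted once on the
pooled training split (a single distribution per feature, not per subject)
and applied unchanged to test data.

Numerical choices: the KDE kernel is the *normalized* Gaussian with
standard deviation ρ and its CDF integrates from −∞, so that Φ is a proper
distribution function and the bound equations have unique solutions; the
quantiles are found by bisection (`brentq`) on a bracket spanning the data
range padded by multiples of ρ, widened automatically for extreme P_th.
Constant features signal a degenerate distribution and are skipped
(infinite bounds). Fitted bounds serialize to JSON.

## Kernel extreme learning machine

A kernel ridge classifier trained in one closed-form solve: RBF Gram matrix
K_ij = exp(−‖zᵢ−zⱼ‖²/h) (note: h divides the squared distance directly),
one-vs-rest label matrix C with +1 in the true-class column and −1
elsewhere, and output weights β = (K + I/λ)⁻¹C. The ridge term (1/λ)·I
makes the system symmetric positive definite for any finite λ; it is solved
by Cholesky factorization, never explicit inversion. Scores for a query
frame are o = k(z, Z)β; the hard decision is the arg-max class (ties to the
lowest class index, deterministically).

Defaults h = 2³ and λ = 10⁴, with the usual search grids h ∈ {2⁻⁹…2⁹},
λ ∈ {10⁻⁹…10⁹}; both parameters are plain config values and an alternative
pairing (h = 2⁴, λ = 10⁵) is equally legitimate — accuracy is not very
sensitive between the two on the synthetic benchmark. As λ → ∞ training
outputs converge to C (interpolation limit; property-tested at λ = 10⁹).

## Fuzzy decisions and fusion

Scores map to memberships μᵢ = exp(−(oᵢ/(ō + γσ))²) with ō the mean, σ the
sample (n−1) standard deviation of the score vector, and γ = 0.5. This
exact reading (sample σ, square of the ratio) is pinned by a hand-verified
worked example in the test suite. Two properties of the transform worth
knowing:

* it is **even** in its argument, so scores +c and −c get equal membership;
  with the typical negative denominator the *least negative / smallest
  magnitude* score wins the membership arg-max, not necessarily the largest
  score. In the saturated regime (all scores near the ±1 label values) the
  membership arg-max can systematically disagree with the classifier's own
  hard decision. This follows the defining formula and is documented, not
  altered;
* a constant score vector maps to uniform memberships e⁻¹; a vanishing
  denominator falls back to uniform memberships with a warning.

Because of the first property, the majority-vote baseline counts the
*classifier's* hard decisions (arg-max of o), which the evaluation harness
passes to `baseline_fuse` explicitly; standalone calls without score
information fall back to the membership arg-max.

**RWS rule.** Consistency matrix A_tk = ⟨μᵗ, μᵏ⟩ (a Gram matrix: symmetric,
nonnegative, PSD; diagonal included). Its unit-norm principal eigenvector,
oriented nonnegative (Perron–Frobenius guarantees this orientation exists
for nonnegative A), scores each frame's agreement with the rest and is
rescaled affinely onto [a, a+b]. Degenerate case w_max = w_min (mutually
identical frames): all reliabilities a+b, since identical frames are
maximally mutually consistent. Global membership μ_g = (1/T)Σ r_t μᵗ,
winner by arg-max; a single frame gets reliability a+b.

Defaults a = 0.6, b = 0.4. The package's worked example and its
documentation use a = 0.3, b = 0.7, which maps that example's reliabilities
onto [0.3, 1.0]; both parameterizations are plain config values
(`--rel-lower`, `--rel-span`) and the winner is typically insensitive to
the choice because the rescaling is monotone.

**Baselines.** Sum (mean membership), product Π(μᵢᵗ+δ), belief
Π 1/(1−μᵢᵗ+δ), reliability-weighted belief Π 1/(1−r_t μᵢᵗ+δ) (reliabilities
as in RWS), majority vote (ties: larger mean membership, then lowest
index). δ = 10⁻³ keeps the product-type rules finite near membership 0/1;
δ also breaks their invariance to a common positive rescaling of all
memberships, which sum/RWS/majority retain (property-tested).

## Synthetic cohort generator

The generator provides the statistical structure the pipeline needs —
distinguishable subjects, realistic frame counts, occasional gross
outliers — not biomechanical fidelity. Each subject is a planar two-link
(thigh–shank) chain per leg: hips advance along x at the walking speed;
thigh angle and knee flexion follow sinusoids at the gait frequency (knee
with a quarter-cycle lead, never hyperextended); legs in antiphase; five
markers per side placed along the chain at a fixed lateral offset.

Population defaults (drawn per subject, seeded): height uniform on
1.44–1.78 m with standard segment-length fractions (thigh 0.245, shank
0.246, foot 0.152 of height) plus 2% individual scatter; walking speed
U(0.9, 1.3) m/s; cadence U(0.7, 1.1) strides/s; phase uniform on the
circle. Marker noise default σ = 0.02 m — deliberately the soft-tissue-
artefact scale rather than the camera noise scale, so single-frame
classification is imperfect and fusion has measurable headroom. Outlier
injection displaces each marker-frame by ±0.5 m along one random axis with
probability p (default 0 in the config; the robustness benchmark uses
p = 0.01), emulating marker swaps/reflections. Everything is deterministic
given the seed, to the point of byte-identical output files.

What the generator does **not** emulate: ground contact and double-support
kinematics, soft-tissue artefact correlation structure, marker occlusion
patterns (outliers here are i.i.d.), within-subject day-to-day variation,
and footwear/clothing effects. Passing tests therefore demonstrate the
pipeline's mechanics and the fusion rules' comparative behaviour, not
field-condition recognition accuracy.

## Evaluation design

The benchmark uses 10 subjects, one 120-frame training recording and three
60-frame test recordings per subject (test ≈ half the training frames,
mirroring a realistic session design); these sizes keep the full suite fast
while leaving accuracy usefully below 1. Accuracy-vs-ratio curves fuse the
leading ⌈ρT⌉ frames of each test recording for ρ = 0.1…1.0 (a seeded
random-subset mode is also provided). Single-frame accuracy is the
frame-level hard-decision accuracy. The 6-marker configuration (thigh,
shank, ankle per side) is available via `tracker_subset`, giving
6·5/2 + 6 = 21 features.

On the fixed-seed benchmark, single-frame accuracy is ≈ 0.44 (chance 0.1)
and every fusion rule beats it at full ratio (RWS ≈ 0.93), with accuracy
increasing in the number of fused frames.

## Known limitations

* **Calibration effect size.** On this generator, KDE-tail clamping has no
  detectable effect on mean accuracy under injected 0.5 m glitches
  (paired across 10 seeds): such gross outliers sit 10–20σ out, so the
  0.1% tail bound of the contaminated pooled distribution lands near or
  inside the outlier cloud, and a clamped value is still extreme for the
  saturating RBF kernel. The acceptance check therefore verifies "does not
  significantly reduce accuracy" (one-sided paired t-test, α = 0.05) rather
  than a positive benefit. Calibration's value on real capture data, where
  glitch geometry differs, may well be larger; the mechanism to watch is
  the ratio of contamination rate to the 2(1−P_th) tail band.
* The membership transform's evenness (above) means soft-rule fusion can
  underperform when the single-frame classifier is already near-perfect;
  in that regime majority vote is the safe rule.
* Bounds, normalizer and classifier all assume the test markers follow the
  same placement convention and preprocessing as training; there is no
  domain adaptation.
* The eigenvector reliability assumes the consistency matrix is
  irreducible enough for a unique principal direction; exactly orthogonal
  membership sets (measure zero in practice) would make the choice
  arbitrary, and ties are broken by the first returned eigenvector.
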