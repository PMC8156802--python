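# gaitfuse

Gait recognition from marker-based optical motion capture, built around
single-frame classification plus multi-frame decision fusion.

Optical capture systems record the 3-D positions of body-mounted markers
with millimetre precision, which makes the *shape and motion* of a walking
person — rather than their face or fingerprint — usable as a biometric.
`gaitfuse` identifies a walker from short recordings (a few gait cycles) of
10 lower-body markers sampled at 5 Hz: thigh, shank, two ankle markers and
tiptoe on each side. It is aimed at researchers in gait biometrics and
human-movement analysis who want a tested, scriptable reference pipeline
for first-classify-then-fuse recognition.

## Method

For each motion frame *t* the feature vector is
**z**ᵗ = {**d**ᵗ; **v**ᵗ} ∈ ℝ⁵⁵: the 45 pairwise Euclidean marker distances
d⁽ᵗ⁾ᵢⱼ (upper triangle of the symmetric 10×10 distance matrix) and the 10
forward velocities vᵢᵗ = (xᵢᵗ⁺¹ − xᵢᵗ)/τ, τ = 0.2 s.

1. **Calibration.** Each feature's training distribution is smoothed with a
   Gaussian KDE (Silverman bandwidth ρ = σ(4/3L)^⅕); values outside the
   central band [Φ⁻¹(1−P_th), Φ⁻¹(P_th)] (default P_th = 0.999) are deemed
   unreliable and clamped to the bound (no frame is discarded).
2. **Single-frame classification** with a kernel extreme learning machine:
   RBF Gram matrix K_ij = exp(−‖zᵢ−zⱼ‖²/h), one-vs-rest ±1 label matrix C,
   closed-form weights β = (K + I/λ)⁻¹C, scores **o**ᵗ = k(zᵗ, Z)β
   (defaults h = 2³, λ = 10⁴).
3. **Fuzzy decisions.** μᵢᵗ = exp(−(oᵢᵗ/(ō + γσ(**o**ᵗ)))²), γ = 0.5.
4. **Reliability-weighted-sum (RWS) fusion.** The T×T consistency matrix
   A_tk = ⟨**μ**ᵗ, **μ**ᵏ⟩ scores how much each frame agrees with the rest;
   its principal eigenvector (nonnegative by Perron–Frobenius), rescaled
   into [a, a+b], gives per-frame reliabilities r_t. The global decision is
   **μ**_g = (1/T) Σ_t r_t **μ**ᵗ, winner = arg-max class.

Five baseline fusion rules (sum, product, majority vote, belief,
reliability-weighted belief) are included for comparison, as is a synthetic
cohort generator (planar two-link gait kinematics with per-subject
anthropometry) so the whole pipeline can be exercised end to end without
access to capture hardware.

## Worked example

The fusion chain on a hand-sized example — ten five-class fuzzy decisions,
mostly but not unanimously favouring class 2:

```python
>>> import numpy as np, gaitfuse as gf
>>> from gaitfuse.datasets import example_memberships
>>> M = example_memberships()          # 10 frames x 5 classes
>>> A = gf.consistency_matrix(M)
>>> round(A[0, 1], 2)                  # agreement of frames 1 and 2
0.53
>>> dec = gf.rws_fuse(M, a=0.3, b=0.7)
>>> np.round(dec.reliabilities, 2)     # frames 1, 3, 6 are down-weighted
array([0.38, 1.  , 0.3 , 0.7 , 0.48, 0.39, 0.67, 0.36, 0.4 , 0.76])
>>> np.round(dec.membership, 2)
array([0.12, 0.27, 0.16, 0.14, 0.14])
>>> dec.class_index + 1
2
```

Frames whose memberships disagree with the consensus (frames 1, 3 and 6,
whose top class is not class 2) receive the smallest reliabilities, and the
fused decision picks class 2 with a clear margin.

A full synthetic experiment from the shell:

```sh
gaitfuse evaluate --subjects 10 --train-frames 120 --test-frames 60 \
    --test-recordings 3 --seed 1 --out curve.csv
```

prints the single-frame accuracy (`0.4446` for this seed — chance is 0.1
for 10 subjects) and a table of subject-level accuracy per fusion rule as
the fraction of fused test frames grows from 0.1 to 1.0 (RWS rises from
0.67 at ratio 0.1 to 0.93 at ratio 1.0 here). `gaitfuse simulate | extract |
calibrate | train | predict` expose the individual stages.

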