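# Methods

`aladdin_acbv` quantifies arterial cerebral blood volume (aCBV) from
multiphase, inter-slice-labeled balanced-SSFP ASL data acquired with the
alternate ascending/descending (ALADDIN) scheme.  This note documents the
models, the numerical choices, and what the synthetic-data validation does
and does not establish.

## Signal physics

A bSSFP readout applies alternating ±FA hard pulses every TR.  On
resonance, after an FA/2 catalyzation, the transverse signal sampled once
per TR relaxes from `M0·sin(FA/2)` toward the steady state

    M_ss = M0·sin(FA)·(1−E1) / (1 − (E1−E2)·cos(FA) − E1·E2),
    E_i = exp(−TR/T_i),

with per-pulse decay factor

    ρ = E2·sin²(FA/2) + E1·cos²(FA/2).

`M_ss` is the *exact* fixed point of the alternating-pulse Bloch recursion
sampled immediately after a pulse (we derived and verified this; the
TR/2 echo differs only by the constant `exp(−TR/2T2)`, which cancels in all
normalized quantities, so the simulator reports post-pulse magnitudes).
`ρ`, in contrast, is a first-order approximation to the exact per-TR
eigenvalue `λ₊ = [(E1−E2)cosFA + √((E1−E2)²cos²FA + 4E1E2)]/2`.  For blood
and tissue at TR = 4.15 ms the discrepancy is tiny per pulse but compounds
through the transient: the closed form deviates from the Bloch simulation
by at most ~0.9% (relative) for arterial blood (T2 = 120 ms) and by ~2%
for venous blood (T2 = 54 ms).  In absolute terms the deviation never
exceeds 1% of M0 for any of the three compartments at any pulse 1–500,
which is the agreement level the tests assert.  Consumers needing exact
per-pulse physics should use the simulator, not the closed form.

## Kinetic models

Time zero is the start of the imaging slice's own acquisition.  Because
every prior slice labels inflowing arterial blood, delivery to a voxel is a
constant `2·α·M0·F'·exp(−ATT/T1b)` that ends at `t = ATT` (the last labeled
blood needs the transit time ATT to cover the gap).  `F` is stored in
mL/100 mL/min and converted internally to a volume fraction per ms
(`F' = F/100/60000`); this is the convention under which
`aCBV = F·δ/60000` (mL/100 mL) is dimensionally consistent and under which
the fitted gray-matter values produce realistic (~0.5%) fractional signal
changes.  Labeled signal is removed by

1. washout through the arterial compartment — exponential residue function
   `R(t) = exp(−t/δ)`;
2. T1 recovery `m(t) = exp(−t/T1b)`;
3. once the readout runs, the RF train, modeled as the continuous envelope
   `ρ^(t/TR)`.

The **T1 model** ignores (3): a plateau
`2αF'·δT1b/(δ+T1b)·e^(−ATT/T1b)` for `t ≤ ATT`, then an extra
`e^(−(t−ATT)(T1b+δ)/(δT1b))`.

The **bSSFP model** splits arrivals at t = 0.  Label present before the
readout starts decays under washout and the RF envelope
(`term1 = δT1b/(δ+T1b)·e^(−t/δ)·ρ^(t/TR)`); label arriving during `[0, ATT]`
contributes the closed-form convolution of the rectangular delivery with
`e^(−s/δ)·ρ^(s/TR)` (`term2`, with rate `k₂ = 1/δ − ln ρ/TR`).  This
"physical" reading — T1 recovery acts only before arrival — is the default
because it is the only reading that reduces exactly to the T1 model as
FA → 0 (verified to 1e-9).  The literal convolution, in which T1 decay also
continues during the readout, is available behind `literal_mode=True`; the
two are deliberately not merged.

The closed forms treat the 2-s labeling duration as semi-infinite; the
truncation error is `exp(−(L−ATT)(1/δ+1/T1b))` relative, ≈0.3% at
δ = 661 ms and ~8% only at the extreme δ = 1000 ms corner of the validation
grid (the Bloch simulator honors the finite window, so that corner is also
where model and simulation legitimately part ways).

## Venous (SSS) labeling model

The ascending−descending difference in the superior sagittal sinus carries
two mechanisms: *labeling from vein* (fast venous blood directly saturated
by `n = slice_thickness/(v·TR)` prior-slice pulses; visible until the bolus
clears the gap at `ε = gap/v`, ~280 ms for a 36-mm gap at 13 cm/s) and
*labeling from tissue* (prior-slice tissue water at its bSSFP steady state
drains into the vein; `M_b,in = M_ss,t/λ` with λ = 0.9 mL/g).  Both decay
with venous T1.  Only inverse proportionality of the tissue component to
the gap is physically constrained; its reference gap defaults to 100% of
slice thickness, chosen so the default simulated curves reproduce the
observed temporal structure (an early vein plateau that stands above the
tissue tail and drops at ε).  The labeling efficiency α is estimated as the
mean normalized difference over the phases with `t + TD ≤ ε` — the first
two phases for a 450% gap at TD = 0 — and is flagged invalid when no phase
qualifies (e.g. TD = 500 ms), reproducing the "no vein labeling detected"
behavior.  The estimate normalizes by the ascending SSS signal and is
reported as defined, without correcting the known ~`sin(FA/2)`-related
underestimation.

## Bloch simulator and Monte Carlo validation

The simulator is a transparent isochromat scheme: instantaneous
alternating-phase hard pulses, on-resonance, free relaxation between
pulses.  Difference magnetization (control − label) obeys homogeneous Bloch
dynamics, so each labeled spin is propagated by a shared 2×2 per-TR
operator; spins differ in arrival time (stratified over the 2-s delivery
window ending at ATT), exponential residence time (mean δ — after which the
spin joins the capillary pool, is driven to the common steady state and
contributes zero difference), and initial amplitude
`2αM0·e^(−ATT/T1b)` (pre-readout arrivals decay further with T1 until
t = 0).  Signals are read at the center-of-segment pulse of each of the
nine phases and normalized by `M0·sin(FA/2)`.

Entering difference magnetization is, by default, captured onto the
FA/2-tilted slow-decay axis ("catalyzed" entry).  This idealization stands
in for the ramped startup pulses and the averaging over pulse parity and
off-resonance that smooths real inflowing magnetization, and it keeps the
ensemble consistent with the kinetic model to <5% at the curve peak for
moderate transit times.  The physically abrupt alternative
(`entry_state="longitudinal"`, with adjacent-pulse averaging) is provided
for comparison; it projects ~12% less amplitude onto the slow axis
(`2cos(FA/2)·E1/(λ₊−λ₋)`), a real effect of mid-train entry that the
closed-form model does not capture.

The Monte Carlo study follows the stated grid — F = 100–300 step 50
mL/100 mL/min, δ = 200–1000 step 200 ms, 3-cm gap, vessel velocity 6–15
step 3 cm/s, vessel angle 0–80° step 20°, ATT = gap/(v·cos φ), peak-signal
SNR 5–20 step 5 with real additive Gaussian noise on the difference
curves.  Each noisy curve is fitted with the bSSFP model; accuracy is the
error percentage of the fitted mean (|mean − truth|/truth × 100) and
precision the coefficient of variation (SD/mean × 100), aggregated over
cells by unweighted mean (the aggregation rule is recorded in the output
metadata).  Cells whose geometric ATT exceeds the last phase time
(~1170 ms; the φ = 80° column except v = 15 cm/s) are unidentifiable and
are excluded with a logged count.  Each cell's noiseless curve uses a
2000-spin ensemble.  One property of this design deserves emphasis: the
simulator's own sampling error (residence-time survival is Bernoulli) is a
per-cell shift that does *not* average out over noise repetitions, so it
enters the accuracy metric alongside genuine estimator bias.  A
convergence sweep of the noiseless full grid quantifies it — the aggregate
(ATT, F, δ) errors fall from (2.3, 8.1, 12.0)% at 2000 spins to
(1.8, 5.4, 9.3)% at 8000 and (1.6, 4.1, 7.2)% at 32000, i.e. roughly
1/√n_spins — so at the study's ensemble size a substantial share of the
reported "error" is simulator sampling, not fit bias.  The ensemble size
is configurable (`McGrid(n_spins=...)`) for users who want the converged
estimator-only figures.  Repetitions default to 1000 but the
shipped validation runs use 100 per cell (30 in the SNR-sweep test on a
moderate-transit subgrid), which keeps the full study within minutes on
one CPU; at these sizes the mean-estimation jitter still inflates the
reported error percentages slightly relative to a 1000-rep run.

## Voxel-wise fitting

Bounded trust-region least squares (`scipy.optimize.least_squares`, trf)
on `dS(t)/S0` with analytic Jacobians.  α is fixed, not fitted — α and F
enter only as a product and are not jointly identifiable from one curve;
the SSS measurement supplies α.  `S0` is a single global value per dataset
(mean ascending-order SSS signal).  Bounds default to F ∈ [0, 600]
mL/100 mL/min, δ ∈ [50, 3000] ms, ATT ∈ [0, 3000] ms — wide brackets
around literature values.  Map fitting multi-starts from a 3×3×3 grid over
the bounds interior; the Monte Carlo engine uses a cheaper four-point
data-driven start set (transit from the curve peak, amplitude from the
plateau).  Convergence tolerances are 1e-10 on the cost and 1e-8 on the
parameters; ties across starts are broken by lowest residual, then lowest
ATT.  Exactly flat zero curves are flagged "non-perfused" without
optimization.  True ATT below the first phase time (~108 ms) is
unidentifiable (every sample is post-transit and F trades off exactly
against ATT); such voxels fit perfectly but with arbitrary F/ATT split,
which is why validation grids start at ATT = 200 ms.  Non-converged voxels
are excluded from ROI statistics and counted in the diagnostics.

## Digital phantom

A 2D 64×64 (configurable) slice: GM ribbon with the measured GM kinetics
for the 450%-gap/0-ms-delay condition (F = 197 mL/100 mL/min, δ = 661 ms,
ATT = 628 ms), a weakly perfused WM core (F = 60, δ = 500, ATT = 900 —
round placeholder values), arteries at 3× GM flow, an SSS cluster following
the venous model, baselines GM 1.0 / WM 0.8 / SSS 0.5 (arbitrary units),
α = 0.208.  Ascending images lose the arterial labeling signal (arterial
flow accompanies the ascending order), descending images lose the venous
signal; MT-asymmetry and eddy-current confounds are additive offsets
flipping sign with gradient sign and readout polarity; noise is Gaussian
per image type *before* combination, so combining reduces it as in real
data.  The phantom emulates the signal model, disjoint-compartment
geometry and confound structure — not partial-volume mixing, vascular-tree
geometry, motion, or off-resonance banding.  Passing round trips therefore
establish the *internal consistency* of combination, normalization,
fitting and aCBV computation, not robustness to those real-data effects.

## Known limitations

* On-resonance only; no slice-profile, off-resonance or T2* effects.
* Single-exponential residue; no dispersion or water-exchange modeling.
* The closed-form ρ is ~2% optimistic for short-T2 (venous) blood.
* The Bloch reconstruction of the validation study is this package's own
  (the original framework is not fully specified); headline accuracy
  figures should be read with the generous tolerances used in the tests.
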