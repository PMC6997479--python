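# Methods

## Scope and model

`renoquant` implements the quantitative layer of comparative renography:
estimating split renal function (SRF) and grading drainage from dynamic
renal imaging, by two modalities that are routinely compared in pediatric
uropathy work-ups — dynamic contrast-enhanced MR urography (fMRU) and
⁹⁹ᵐTc-MAG3 dynamic renal scintigraphy (DRS) — together with the
method-agreement statistics used to decide whether the two modalities can
be used interchangeably. Because no patient images ship with the package,
a digital phantom generates paired studies with known ground truth; every
pipeline claim the test suite makes is a claim about recovery of that
ground truth.

### Tracer-kinetic forward model

The aortic input is a gamma-variate first pass
`P₁(t) = A·(t−t₀)^α·exp(−(t−t₀)/β)` plus a recirculation term equal to
the first pass convolved with a unit step, scaled to plateau at a fraction
*f* of the first-pass peak (closed form: the regularized lower incomplete
gamma function). Defaults: peak at 40 s, α = 2.5, β = 12 s, *f* = 0.1,
peak amplitude 1 a.u. MR signal is assumed proportional to concentration
(reasonable for a gadolinium micro-bolus; no T1-relaxivity nonlinearity is
modelled).

Parenchymal enhancement follows the irreversible-uptake (Rutland-Patlak)
model: per unit parenchymal volume,

```
q(t) = K·∫_{t−T}^{t} P dτ + V_b·P(t)
```

where `K` (s⁻¹, default 0.004) is the uptake constant, `V_b` (default
0.04) the apparent blood-volume fraction, and `T` (default 180 s) a pure
transit delay after which tracer passes to the collecting system. The
pelvis compartment obeys `z′ = K·P(t−T) − k_out·z` and the whole-kidney
(drainage) curve is `q + z`. `T = 180 s` places the whole default Patlak
window (aortic peak + 20 s … + 120 s) inside the pure-uptake phase, and is
a plausible parenchymal transit time.

Drainage regimes are realized purely through `k_out`:

* **normal** — `k_out = 0.02 s⁻¹`, fast enough that the late curve falls
  well below the renogram peak;
* **accumulation** — `k_out = 0`; the whole-kidney curve is then exactly
  `K∫P + V_b·P`, which is non-decreasing provided `K·β ≥ V_b` (the
  gamma-variate log-derivative is bounded by 1/β). The defaults satisfy
  `K·β = 0.048 > V_b = 0.04`; configurations violating the inequality can
  produce a slight dip after the vascular peak, which is physical (blood
  pool washout) but breaks the textbook "ever-increasing" description;
* **borderline** — `k_out = 0.0024 s⁻¹`, chosen so the pelvis equilibrium
  level `K·p∞/k_out` (with `p∞` the recirculation plateau) sits just
  below the bolus deposit `K·∫P₁`: the curve then shows a mild interior
  maximum followed by a plateau at ≥ 90% of peak on both the 10-min fMRU
  and 20-min DRS schedules (end-to-peak ratios 0.95 and 0.91). The
  borderline band is intrinsically narrow — roughly
  `k_out ∈ [0.0021, 0.0027] s⁻¹ `under the default input function — which
  mirrors the genuine ambiguity of plateau-pattern reading between human
  observers.

### Study synthesis

* **fMRU**: 4D series on a 96×48×40 grid, 2×2×4 mm voxels (4 mm slices),
  70 frames — 60 × 5 s then 10 × 30 s. Kidneys are 2:1:1 prolate
  ellipsoids at ±55 mm from the midline (x increases toward the patient's
  left), each with a small medial pelvis ellipsoid (4 mL); the aorta is a
  6 mm-radius vertical cylinder. Parenchymal voxels carry `q(t)`, pelvis
  voxels `z(t)` times the parenchyma-to-pelvis volume ratio, aortic
  voxels `P(t)`, other tissue a low slowly-enhancing baseline. Additive
  Gaussian noise (default sd: 1% of the parenchymal peak via the paired
  spec factory); a static T2-like volume (parenchyma 1.0, pelvis 0.3,
  background 0.05, sd 0.02) supports threshold segmentation.
* **DRS**: posterior 2D projection, 96×96 pixels of 4 mm, 120 × 10 s
  frames. Pixel rates are path-length integrals through the ellipsoids, so
  ROI count sums are exactly proportional to whole-organ activity; a
  cardiac blood-pool disc provides the input function, and a uniform body
  slab adds background at 10% of peak parenchymal density following the
  blood time course — corrected by C-shaped perirenal ROIs (annulus
  1.15–1.6× the kidney ellipse, open medially) with ROI-size-ratio
  scaling. Counts are Poisson with the larger kidney's noise-free peak
  calibrated to 10 000 counts/frame.

Everything is reproducible from `PhantomSpec.seed` (separate child streams
for the two modalities).

### What the phantom does *not* emulate

No respiratory or bulk motion, no partial-volume blur or point-spread
function, no attenuation or scatter asymmetry, no T1 saturation, no
furosemide pharmacokinetics (F-0 vs F+20 timing is a label, not a model),
no pelvic peristalsis, and kidneys are geometric ellipsoids segmentable
almost perfectly. Passing recovery tests therefore demonstrates the
correctness and internal consistency of the estimators — not their
robustness to the artifacts that dominate failed clinical acquisitions.

## Estimators

* **AUC SRF** — trapezoid integrals of background-corrected parenchymal
  curves over the uptake window, ratioed to percent.
* **Rutland-Patlak** — OLS of `Q/P` on `(∫₀ᵗP)/P` (cumulative trapezoid
  from acquisition start) over the window; frames with non-positive input
  are dropped with a warning, < 3 usable frames is an error; negative
  slopes are floored at zero with a warning before SRF formation.
* **Volumetric SRF** — `100·V_L·k_L/(V_L·k_L + V_R·k_R)` with `k` the
  ROI-mean Patlak slope (already per unit volume for MR signal curves)
  and `V` from threshold (0.5 × max) + largest-two 26-connected-component
  segmentation of the volumetric frame. For DRS count curves the kidney
  total already weights by volume, so the count-based Patlak SRF is
  volumetric by construction; this is what makes the two paths directly
  comparable.
* **Drainage**: with `t_peak` the 5-frame moving-average global maximum
  (ties earliest) and `r` the mean of the final 60 s over the peak value,
  classify *accumulation* if `t_peak` falls in the final 60 s, else
  *normal* if `r ≤ 0.90`, else *borderline*. NORA is the activity at 20
  min (or study end) over the 1–2-min mean; output efficiency is
  `100·(1 − R(t)/U(t))` with `U(t) = K·∫₀ᵗP dτ` the Patlak-modelled
  cumulative input (capped at 100, negative values flagged); Tmax is the
  smoothed peak time. Traditional scintigraphic reading labels map
  {normal, borderline, poor} → {normal, borderline, accumulation}.
* **Agreement**: Bland-Altman with n−1 SD, limits mean ± 1.96 SD, CI of
  the mean ± 1.96 SD/√n and of each limit ± 1.96 SD·√(3/n); unweighted
  Cohen's kappa (linear/quadratic weights optional) with the simple
  large-sample SE `√(Po(1−Po)/(N(1−Pe)²))`; diagnostic effectiveness =
  table trace / N; Spearman ρ with average ranks and `r² = ρ²`.

## Numerical choices

The forward model runs on an internal 2.5 s uniform grid; the pelvis ODE
uses an exact exponential-integrator step (stable for any `k_out·Δt`),
and curves are sampled back to frame midpoints. Conservation (zero
outflow, zero noise) holds to < 0.5% at the default resolution. Curve
resampling is linear (no overshoot); endpoint times are preserved exactly.
Peak finding uses nearest-edge moving-average smoothing so monotone curves
peak at the last frame. SRF pairs are renormalized to sum to exactly 100;
`r²` is clipped into [0, 1]; a flat Patlak response (`Q ∝ P`) reports
`r² = 1` since the fit is exact. A flat drainage curve is reported as
borderline with a flag; an all-zero curve is an error, as is a kidney pair
with non-positive combined signal (undefined SRF rather than a crash).

## Problem sizes

The bundled validation runs 20 paired phantom studies (full 4D MR + planar
DRS synthesis and both analysis paths, ~10 s total), 100 noisy curves per
drainage pattern for classifier recovery, 20–100-seed Monte-Carlo checks
for peak/SRF recovery, and 10 000 synthetic pairs for Bland-Altman
coverage. These sizes give binomial/Monte-Carlo margins comfortably tighter
than the asserted thresholds while keeping the whole suite interactive.

## Known limitations

* The peak of a normal renogram is broad: at 2% noise the smoothed Tmax
  is reproducible to about ±10 s, not ±1 frame of the 5 s MR sampling.
* The kappa confidence interval uses the simple large-sample SE; other
  common formulas (e.g. the Fleiss-Cohen-Everitt exact SE) differ in the
  second decimal, so CI bounds should not be over-interpreted.
* The volumetric-combination formula (volume-weighted slope density) is
  one reasonable convention; clinical packages do not always publish
  theirs, and alternatives (AUC-density weighting) are supported via the
  same interface.
* Borderline-pattern classification is threshold-sensitive by nature; the
  (0.10, 60 s) defaults are configurable and should be tuned per protocol
  length if applied to other acquisition schedules.
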