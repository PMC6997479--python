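# renoquant

Quantitative renography in Python: split renal function, drainage-curve
grading and method-agreement statistics for dynamic MR urography (fMRU)
and ⁹⁹ᵐTc-MAG3 renal scintigraphy (DRS), with a paired digital phantom
for validation.

## Who this is for

Children with obstructive congenital anomalies of the kidney and urinary
tract (CAKUT) are followed with functional imaging to decide whether a
dilated system is truly obstructed and how function is split between the
two kidneys. DRS is the clinical reference; fMRU is its radiation-free
challenger. This package implements, in one tested codebase, the numbers
both modalities produce and the statistics used to compare them —
for imaging scientists validating protocols, and for anyone who needs a
reproducible software phantom of a renography study.

## What it computes

**Split renal function (SRF).** For background-corrected kidney curves
`Q(t)` and an arterial input `P(t)`:

- *AUC method*: `SRF_L = 100·∫Q_L / (∫Q_L + ∫Q_R)` over the uptake window;
- *Rutland-Patlak*: OLS on `Q(t)/P(t) = K·(∫₀ᵗP dτ)/P(t) + V₀`; SRF is
  the ratio of uptake slopes `K`;
- *Volumetric SRF*: `100·V_L·k_L/(V_L·k_L + V_R·k_R)`, combining
  per-unit-volume slopes with segmented parenchymal volumes.

**Drainage.** Whole-kidney curves are classified as **normal** (decline
after the filtration peak), **borderline** (post-peak plateau) or
**accumulation** (ever-increasing), and quantified by NORA (late/early
activity ratio), renal output efficiency `100·(1 − R(t)/K∫₀ᵗP)` and Tmax.

**Agreement.** Bland-Altman limits `mean ± 1.96·SD` with confidence
intervals, Cohen's kappa `κ = (Po − Pe)/(1 − Pe)` with interpretation
bands, diagnostic effectiveness / misclassification from a 3×3 table, and
Spearman correlation.

**Phantom.** `simulate_mru` / `simulate_drs` generate paired 4D MR and
planar scintigraphy studies from one ground-truth spec (gamma-variate
input, Patlak uptake, collecting-system compartment, Gaussian/Poisson
noise, C-shaped background), so every estimator can be validated against
known truth. See `docs/methods.md` for the model.

## Worked example

```python
from renoquant import PhantomSpec, simulate_mru, simulate_drs
from renoquant.pipeline import analyze_mru, analyze_drs, make_phantom_spec

spec = make_phantom_spec(65.0, 120.0, 100.0, "normal", "accumulation", seed=7)
mru = analyze_mru(simulate_mru(spec))
drs = analyze_drs(simulate_drs(spec))
print(f"true left SRF     : {spec.true_srf_left:.1f}")
print(f"fMRU volumetric   : {mru.srf.volumetric_srf_left:.1f}"
      f"  (volumes {mru.srf.volume_left:.0f}/{mru.srf.volume_right:.0f} mL)")
print(f"DRS  volumetric   : {drs.srf.volumetric_srf_left:.1f}")
print(f"patterns (fMRU)   : {mru.drainage['left'].pattern} / "
      f"{mru.drainage['right'].pattern}")
print(f"DRS left NORA/ROE : {drs.drainage['left'].nora:.2f} / "
      f"{drs.drainage['left'].roe:.0f}%")
```

prints

```
true left SRF     : 65.0
fMRU volumetric   : 64.8  (volumes 119/100 mL)
DRS  volumetric   : 65.3
patterns (fMRU)   : normal / accumulation
DRS left NORA/ROE : 0.48 / 85%
```

The two analysis paths agree within half a point of SRF on this phantom,
both recover the generating drainage patterns, and the draining kidney
shows low residual activity (NORA < 1) with high output efficiency.

A `renoquant` CLI wraps the same functions (`simulate`, `srf`,
`drainage`, `agree kappa`, `agree bland-altman`); curves travel as
`time_s,duration_s,value` CSV, volumes as NIfTI, results as JSON.

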