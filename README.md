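# nanotrans

Quantitative analysis chain for in vitro nanoparticle translocation
studies across a gastrointestinal barrier model: compartmental
translocation kinetics with non-linear mixed-effects estimation and
simulation envelopes, single-particle ICP-MS (spICP-MS) data reduction,
electrical asymmetrical flow field-flow fractionation (EAF4)
ζ-potential analysis, and the supporting assay statistics.

It is written for researchers who quantify how engineered nanomaterials
cross cell barriers in Transwell-type systems and want the entire
numerical pipeline — from raw dwell-resolved ICP-MS intensities to
population kinetic parameters with prediction intervals — reproducible,
tested, and runnable on synthetic data that emulates the study design.

## The models

**Translocation kinetics.** Fractions of the applied particle dose in the
apical (a), cellular (c) and basolateral (b) compartments follow a linear
three-compartment system,

```
dAa/dt = -k12·Aa + k21·Ac
dAc/dt =  k12·Aa - (k21 + k23)·Ac + k32·Ab
dAb/dt =  k23·Ac - k32·Ab,        Aa(t0) = φ + ηᵢ
```

where φ is the population mean fraction available for translocation,
ηᵢ ~ N(0, ω²) is the between-species deviation, and observed fractions
carry combined proportional + additive error Y = A(1+ε₁) + ε₂.
Estimation maximises a Laplace/FOCE-I-style marginal likelihood (with a
Gauss–Hermite quadrature cross-check built in), reports empirical Bayes
estimates, η-shrinkage, and a collapse decision for uninformative random
effects. Fitted models feed 2000-replicate stochastic simulations giving
95% confidence and 68% prediction envelopes, with Savitzky–Golay
post-smoothing of the prediction limits.

**spICP-MS reduction.** Event detection at the first minimum of the
intensity-frequency histogram; transport efficiency by the size method
from a 58 nm gold reference (η = m_true/m_apparent); particle number
concentration n/(η·flow·duration) with the 10-event detection limit
(≈ 4.98×10⁵ particles/L at η = 5.8%); mass ↔ equivalent spherical
diameter d = (6m/πρ)^⅓; translocated fraction from basolateral vs applied
particle numbers.

**EAF4 ζ-potential.** Peak retention shifts under applied fields give the
electrophoretic mobility via t_r(E)/t_r(0) = 1 + sμE/u_cf (linear least
squares); ζ = 3ημ/(2ε₀εᵣ·f(κa)) with Henry's function f(κa) = 1.5.

**Assay statistics.** alamarBlue viability normalised to untreated
controls, qPCR 2^(−ΔΔCT) fold changes with a two-fold upregulation
threshold, Welch's t-tests with star categories, and per-time-point
one-way species ANOVA with Holm adjustment.

## Worked example

```python
import numpy as np
from nanotrans import (generate_translocation, fit, simulate_ensemble,
                       envelope, zeta_from_mobility, lod_conc,
                       AcquisitionConfig)

# simulate the study design (3 gold species x {10,30,60,240} min x 3 reps)
data = generate_translocation(seed=1)
res = fit(data, seed=1)
print(f"phi = {100*res.params.phi:.1f}%  collapsed={res.collapsed}")

env = envelope(simulate_ensemble(res, np.linspace(0, 240, 60), n=2000,
                                 seed=1), compartment="basolateral")
print(f"basolateral at 240 min: {env.mean[-1]:.3f} "
      f"(95% CI {env.ci_lo[-1]:.3f}-{env.ci_hi[-1]:.3f})")

print(f"{zeta_from_mobility(-2.74e-8).zeta_mv:.1f} mV")
print(f"{lod_conc(AcquisitionConfig(neb_efficiency=0.058)):.3g} particles/L")
```

prints (values from this exact invocation):

```
phi = 69.2%  collapsed=False
basolateral at 240 min: 0.088 (95% CI 0.068-0.107)
-35.0 mV
4.98e+05 particles/L
```

φ is the estimated fraction of the applied dose available for
translocation (69.2% of applied particles); `collapsed=False` means the
between-species variance survived the likelihood-ratio drop test for this
dataset (which was generated with a real species effect — on data
without one the fit reports `collapsed=True` and the parsimonious model
has no species-level random effect); the basolateral fraction reaches
~8.8% of the applied
dose after 4 h with its simulation-based confidence band; −35.0 mV is the
ζ-potential of a particle with mobility −2.74×10⁻⁸ m²/(V·s); and
4.98×10⁵ particles/L is the spICP-MS concentration detection limit under
the stated acquisition settings.

## The analysis, step by step

Numbered drivers under `analysis/` run the chain and write their tables
to `results/` (pass a seed as the only argument):

```sh
python analysis/01_simulate_study.py 1     # synthetic study inputs
python analysis/02_fit_translocation.py 1  # mixed-effects fit + ANOVA
python analysis/03_prediction_envelopes.py 1
python analysis/04_spicpms_reduction.py 1
python analysis/05_eaf4_zeta.py 1
python analysis/06_assay_stats.py 1
```

A thin CLI exposes the same operations on files
(`nanotrans synth|fit|simulate`, `nanotrans spicpms reduce`,
`nanotrans eaf4 mobility|zeta`, `nanotrans assays viability|rq`,
`nanotrans report`).

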