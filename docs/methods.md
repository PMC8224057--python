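# Methods

## The system being modelled

An in vitro gastrointestinal barrier (a triple co-culture on a Transwell
insert) is exposed apically to metallic nanoparticles — gold spheres of two
sizes, gold nanorods, and silver spheres as a comparison arm. Medium
sampled from the apical and basolateral chambers at fixed times is
quantified by single-particle ICP-MS, and the fraction of the applied
particle number found in each chamber is the observable. The package
implements the full quantitative chain of such a study: translocation
kinetics with population-level inference, the spICP-MS data reduction that
produces the fractions in the first place, the EAF4 electrokinetic
characterisation of the particles, the supporting assay statistics, and
seeded generators that emulate the study design so every stage is testable
without access to the original raw data (which were not deposited).

## Translocation kinetics

Three well-mixed compartments — apical medium, a lumped cellular
compartment (cells plus the supporting filter membrane), basolateral
medium — exchange by first-order transfer:

    dAa/dt = -k12 Aa + k21 Ac
    dAc/dt =  k12 Aa - (k21 + k23) Ac + k32 Ab
    dAb/dt =  k23 Ac - k32 Ab

with A* fractions of the applied dose (0–1) and rates in 1/min. Mechanism
(endocytosis, membrane wrapping) is deliberately collapsed into the four
rate constants. The system is linear; `solve` uses the eigendecomposition
of the 3x3 rate matrix (matrix exponential), falling back to `expm` when
the eigenvalue gap is below 1e-9 relative. Mass is conserved to 1e-10
along every trajectory and the analytic solution agrees with an adaptive
Runge–Kutta integration to better than 1e-8.

Only a fraction φ of the applied dose is available for translocation at
t0 (the rest is lost to incomplete recovery, surface adhesion and similar
non-kinetic sinks), so the initial state is (φ + η_i, 0, 0) where η_i is a
normally distributed species-level deviation, η_i ~ N(0, ω²). Observed
fractions carry combined proportional + additive residual error,

    Y_ij = A_ij (1 + ε1_ij) + ε2_ij,   ε1 ~ N(0, σ1²), ε2 ~ N(0, σ2²).

## Estimation

The marginal likelihood integrates η out per species. The integral is
approximated by a Laplace expansion about each species' conditional mode,
with residual variances evaluated at the conditional prediction — the
interaction refinement of first-order conditional estimation. Because the
kinetics are linear in the initial state, predictions factor as
(φ + η)·b(t) with b the unit-initial-fraction response; the inner
optimisation is a one-dimensional safeguarded Newton on the analytic
derivative, making the objective cheap enough for simulation studies.
A 41-node adaptive Gauss–Hermite quadrature implementation of the same
marginal likelihood is included for validation; the two agree within 0.1
in -2LL across the physically sensible parameter region (φ + 2ω ≤ 1 —
beyond it the (0,1] bound on φ + η truncates the random-effect
distribution, which the Laplace expansion ignores; this is a known
limitation, irrelevant at the fractions this assay produces).

Zero observations are left-censored. A measured fraction cannot be
negative, and concentrations below the spICP-MS detection limit are
reported as zero by the reduction rules, so the likelihood uses a Tobit
term Φ(-A/σ) for zero observations and the Gaussian density otherwise.
Without this, near-zero basolateral predictions at early times bias the
cellular-to-basolateral rate upward by around 10%; with it, all fixed
effects are recovered with ≤ 3% relative bias at an information-rich
design.

Fitting transforms parameters to an unconstrained scale (logit φ, log
rates, log σ, log ω), explores with adaptive Nelder–Mead from jittered
starts (5 by default; the simulation studies use 1, which the pilot runs
showed reaches the same optimum on these designs) and polishes with
L-BFGS-B. Standard errors come from the numerical curvature of -2LL.
Empirical Bayes estimates are the per-species conditional modes;
η-shrinkage is 1 − SD(η̂)/ω with the n−1 sample SD, clipped to [0, 1].

**Random-effect collapse.** A species-level effect is reported as
collapsed when ω̂² < 1e-6, or when it fails a boundary likelihood-ratio
comparison against the fixed-effects model (ΔOFV < 3.84, the 5% χ²₁
criterion standard in pharmacometric model building). The second arm is
needed because the boundary mixture distribution of ω̂² leaves roughly
half of all null-data estimates strictly positive; the LRT arm reproduces
the model-development decision path (an uninformative effect is dropped)
in ≥ 90% of null simulations while retaining genuinely present effects at
well-powered designs.

Species differences at each observation time are screened by classical
one-way ANOVA with Holm adjustment across the four time points (the
adjustment method is a package choice; the source analysis reported
adjusted p-values without naming one).

## Simulation envelopes

`simulate_ensemble` draws, per replicate: population parameters from the
estimated sampling distribution (multivariate normal on the unconstrained
scale — a documented switch can disable this), a species effect η
(truncated so φ + η ∈ (0, 1], by resampling), and residual errors per the
combined model (observations truncated at zero). The 95% confidence band
is the percentile interval of the noise-free replicate trajectories
(parameter/η uncertainty only); the 68% prediction band is the percentile
interval of the simulated observations. Linear-interpolation empirical
quantiles are used throughout; 2000 replicates by default.

Prediction-interval limits can be post-processed by a Savitzky–Golay
smoother of polynomial degree 2 whose window is a fraction (default 0.75)
of the series length, rounded to the nearest odd integer ≥ 5. The window
fraction generalises the filter's usual fixed window; near the boundaries
the window shrinks symmetrically and the polynomial is refit, so no
padding artefacts arise and any global polynomial of order ≤ 2 is
reproduced exactly. Only the PI limits are smoothed — means and confidence
bands are not. Envelope bands on real 4-point designs should be computed
on a densified (≥ 50-point) grid before filtering.

## spICP-MS reduction

Per-dwell intensities (100 µs dwells, 60 s acquisitions, 0.346 mL/min)
are split into ionic background and particle events at the first minimum
of the intensity-frequency histogram. Binning uses the Freedman–Diaconis
rule on the sub-99th-percentile intensities with a 1-count floor
(intensities are integrated counts; sub-unit bins fragment the discrete
background into spurious minima); the first interior valley or empty bin
after the background mode is accepted only if at least 10 dwells — the
detection-limit event count — lie beyond it. This automates the
published manual split reproducibly.

The ionic calibration (counts per dwell per µg/L) converts a net event
intensity to an apparent mass at 100% transport,
m_app = (I/slope)·flow·dwell. The "size method" for transport efficiency
uses a 58 nm gold reference: η_neb = m_true/m_app with
m_true = ρ(π/6)d³. Particle number concentration is
n/(η_neb·flow·duration), dilution-corrected; 10 events per acquisition
defines LOD_conc (≈ 4.98e5 particles/L at η_neb = 5.8%), below which
results are reported as zero with a flag. Per-event masses scaled by
η_neb give equivalent spherical diameters; events below LOD_size (15 nm
default, configurable — its derivation is instrument-specific and not
modelled) are counted as ionic, and fewer than 10 usable events is a
below-LOD condition. Ionic concentrations come from the mean
sub-threshold intensity, with element reporting limits (150 ng/L Au,
100 µg/L Ag) applied on the dilution-corrected scale. The translocated
fraction is 100·(C_baso·V_baso)/(C_applied·V_apical) with per-experiment
applied concentrations (0.75/1.5 mL chamber volumes).

Events are single dwells above threshold: at 100 µs dwells split events
are rare and no reconstitution is attempted (the vendor integration
algorithm is proprietary). Particle coincidence (> 1 expected particle
per dwell) triggers a warning in the generator.

## EAF4 electrokinetics

In the high-retention limit of flow field-flow fractionation, retention
time is proportional to the total transverse drift velocity. With an
electrical field superimposed, t_r(E)/t_r(0) = 1 + s·μE/u_cf, with u_cf
the mean cross-flow velocity (cross-flow rate over effective accumulation
wall area), μ the electrophoretic mobility, and s the electrode polarity
sign (default −1: negative mobility increases retention). Ordinary least
squares of t_r on E yields μ = s·b·u_cf/a from slope b and intercept a,
with the slope's regression SE propagated to μ. This relative-shift model
is an explicit simplification of full EAF4 retention theory (no electrode
polarisation correction — effective field equals applied field; no steric
or membrane-interaction effects). Fractogram peak maxima are located
after void-peak exclusion, with parabolic three-point refinement.

ζ follows from Henry's equation in the Smoluchowski limit:
ζ = 3ημ/(2ε0εr·f(κa)) with f(κa) = 1.5, which reduces to the
Helmholtz–Smoluchowski form ζ = ημ/(ε0εr). Medium constants are fixed at
T = 298.15 K, εr = 78.4, η = 8.872e-4 Pa·s (thermostatted channel at
25 °C; these constants reproduce all eight published mobility→ζ pairs
within 0.15 mV). Uncertainty scales linearly with the mobility
uncertainty.

## Assay statistics

alamarBlue viability is the treated-well mean as a percentage of the
untreated-control mean (defined as 100%), with the SD propagated from
replicate wells of both groups (well-level and experiment-level SDs are
both available — the source data's convention is ambiguous). qPCR fold
change is 2^(−ΔΔCT) with replicate CTs averaged before ΔCT (the common
workflow; no amplification-efficiency correction), HPRT1 as reference and
an untreated control as calibrator; RQ ≥ 2 flags upregulation. Group
comparisons use Welch's unequal-variance t-test with Welch–Satterthwaite
degrees of freedom and strict star thresholds (* < 0.05, ** < 0.01,
*** < 0.001).

## Synthetic-data generators

The generators define the study conditions the tests exercise:

- **Translocation**: 3 gold species at {10, 30, 60, 240} min, triplicate,
  apical + basolateral observed (the cellular compartment is latent);
  silver arm at {120, 1440} min with applied concentration 2.70e14
  particles/L. Applied concentrations 6.91e9 (rods), 3.80e12 (30 nm),
  9.22e9 (200 nm) particles/L. Defaults: φ = 0.69; ω = 0.08 (reproducing
  the reported species spread of the available fraction, 74/73/59% around
  69%); rates k12 = 0.002, k21 = 0.005, k23 = 0.007, k32 = 0.003 1/min —
  scenario constants chosen so the basolateral fraction rises from
  ~0.05% at 10 min to ~9% at 240 min, matching the reported translocation
  range (the fitted rate estimates themselves were not published in the
  available text); σ1 = 0.15, σ2 = 0.01 (unreported; set to the relative
  scatter visible in the published means ± SDs). Observed fractions are
  truncated at zero — which is why the estimator carries the censored
  term.
- **Event streams**: per-dwell particle counts are Poisson with mean
  C·η_neb·flow·dwell/dilution; diameters log-normal (median, geometric
  SD); per-particle counts Poisson around the calibration-implied
  intensity; ionic background Poisson with mean slope·C_ion. Calibration
  slope 20 counts/dwell per µg/L.
- **Field series**: t_r(E) from the relative-shift model with
  multiplicative Gaussian timing noise. Defaults: fields 0–10 V/m in 1
  V/m steps, 8 replicate fractionations per field, cross-flow
  0.15 mL/min over a 31.6 cm² effective channel area, t_r(0) = 12 min,
  1% timing noise. This design puts the worst-case regression SE at
  ~1.5% of μ across the published mobility range, so the 5% recovery
  requirement holds with a 3σ margin; it is a measurement design for the
  mobility regression, not a fractionation method (the study's separation
  cross-flows were 0.8–1.2 mL/min).

What the generators do **not** emulate: protein-corona growth, AgNP
dissolution kinetics, particle agglomeration, instrument drift, split
events, or correlations between compartments beyond the shared η. Passing
round trips therefore demonstrate the internal consistency of the
reduction and estimation chain under the stated model, not robustness to
those real-data effects.

## Numerical choices and problem sizes

Simulation studies use 200 replicate studies (fits) per question — the
phi-recovery study at the 3x4x3 design, the bias study at a 6x8x10
design, the bootstrap-coverage study at the 3x4x3 design — and 1000
null simulations per calibration check; envelopes use 2000 replicates.
Tie-breaks and degenerate inputs: identical constant ANOVA groups give
p = 1 (p = 0 if means differ with zero within-group variance); Welch on
two constant equal groups gives p = 1; the SG smoother returns boundary
points unchanged when fewer symmetric neighbours than the polynomial
order remain; envelope bounds are clipped to bracket the simulated mean.
All randomness flows through `numpy.random.default_rng` seeds; identical
seeds give bitwise-identical outputs.

## Known limitations

- The Laplace objective ignores the (0, 1] bound on φ + η (see above).
- The cellular compartment is latent; its occupancy is inferred only
  through the rate structure.
- k21 and k32 are weakly identified at the 4-time-point triplicate design;
  their standard errors are honest about this, and species-level random
  effects on rates (available behind `ModelSpec.eta_rates`) are
  essentially unidentifiable there.
- The EAF4 mobility model is first-order in E and ignores electrode
  polarisation; the effective-field assumption is a stated simplification.
- spICP-MS reduction assumes single-particle events and a linear ionic
  response; coincidence and detector dead-time are out of scope.
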