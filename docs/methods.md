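# Methods

## The constitutive model

The arterial wall is modeled as an incompressible, hyperelastic,
axisymmetric membrane-like tube with a four-fiber-family strain energy

    W = c/2 (I_C − 3) + Σᵢ c1ᵢ/(4 c2ᵢ) { exp[ c2ᵢ (IV_Cᵢ − 1)² ] − 1 },

where `c` (kPa) is an isotropic neo-Hookean ground-matrix modulus and each
fiber family i contributes an exponentially stiffening term governed by a
stress-like modulus `c1ᵢ` (kPa) and a dimensionless exponent `c2ᵢ`.
`I_C = λr² + λθ² + λz²` and `IV_Cᵢ = λθ² sin²αᵢ + λz² cos²αᵢ` are invariants
of the right Cauchy–Green tensor, with fiber angles measured from the axial
direction in the traction-free reference configuration.  Four families are
used: axial (α = 0), circumferential (α = π/2) and two symmetric diagonals
at ±α₀ that share one (c1, c2) pair — eight independent parameters in all.
The model is phenomenological: the "fibers" absorb cross-link and
entanglement effects and are not literal histological structures.  Fibers
under compression (IV < 1) contribute energy exactly as written; no
tension-only switch is applied.

Incompressibility (det F = 1) eliminates the radial stretch,
λr = 1/(λθ λz), and the hydrostatic reaction pressure is eliminated from
load predictions by working with Cauchy stress differences:

    σθθ − σrr = c (λθ² − λr²) + λθ² Σᵢ mᵢ c1ᵢ eᵢ exp(c2ᵢ eᵢ²) sin²αᵢ,

with eᵢ = IV_Cᵢ − 1 and analogously for the axial difference; mᵢ = 2 for
the diagonal pair.  W ≥ 0 on all incompressible states because I_C ≥ 3 by
AM–GM under λr λθ λz = 1 and each exponential term is nonnegative.

### Kinematics and equilibrium

The traction-free configuration is described by the unloaded outer radius
R_o and thickness H (µm); the residual-stress opening angle is not modeled
(the reference map starts from the near traction-free state).  Given the
axial stretch λz and a measured deformed outer radius r_o,
incompressibility of the wall gives the inner radius
a = √(r_o² − (R_o² − R_i²)/λz), and the mid-wall circumferential stretch is
the ratio of deformed to unloaded mid-wall radii,
λθ = (a + h/2)/(R_i + H/2).

Loads are predicted by a mean-wall (mid-wall single-point) treatment of
equilibrium:

    P̂ = (σθθ − σrr) · h / r_mid,
    f̂ = π h (2a + h) (σzz − σrr − P̂/2) − π a² P̂,

where f̂ is the force read by an in-line transducer on a cannulated,
capped vessel (the −π a² P̂ term removes the pressure force on the closed
end, and −P̂/2 is the mid-wall radial stress).  Units are internally
consistent: kPa·mm² = mN; pressures cross the API in mmHg
(1 mmHg = 0.133322 kPa).

**Accuracy of the mean-wall rule.**  Against transmural integration
(P = ∫ (σθθ−σrr)/r dr with radially resolved incompressible kinematics),
the mid-point rule's relative error grows as roughly (Δ ln σ)²/24, where
Δ ln σ is the transmural variation of the log stress.  That variation is
set jointly by the relative wall thickness *in the reference configuration*
and by the material's exponential gain d ln σ/d λθ ≈ 4 c2 e λθ, which is
amplified at large stretch (the transmural stretch gradient scales with
|1 − λz λθ²|).  For thin-walled vessels (H/R_o ≲ 1/20) at stretches
λθ ≤ 1.5 with moderate exponents (c2 ≲ 1.2) the two agree within 2% — the
regime asserted in the test suite.  For the thick-walled perimorbid wall or
for steep exponents the mean-wall rule deviates from the integral by tens
of percent and is used as a *convention*, not an approximation: generator
and fitter use the same forward model, matching standard practice in
ex vivo vessel biomechanics where mean-wall quantities are the reported
phenotype.

### Linearized stiffness

The circumferential and axial components of the stiffness tensor
linearized about a finitely deformed configuration reduce, for diagonal F,
to

    C_θθθθ = 4 λθ² ∂W/∂C_θθ + 4 λθ⁴ ∂²W/∂C_θθ²,

and analogously for C_zzzz, evaluated analytically with the C components
treated as independent.  A central-finite-difference construction
(λθ · dσ̂θθ/dλθ at fixed λz) agrees to better than 1e−4 relative error and
is kept as a test oracle.  The evaluation configuration for a given
(pressure, λz) is found by bisection on the outer diameter over
(zero-lumen, 3 R_o], tolerance 1e−3 mmHg; predicted pressure is monotone in
diameter over the physiologic range, and configurations where no
equilibrium exists (low pressure demanded of a strongly axially stretched,
diagonally reinforced wall) raise a specific error.

## Parameter estimation

Per specimen, the eight parameters minimize

    J = Σₖ [ (P̂ₖ − Pₖ)²/P̄² + (f̂ₖ − fₖ)²/f̄² ]

over the pooled last-unloading-curve points of all seven quasi-static
protocols (three pressure–diameter sweeps at fixed axial stretch
{0.95, 1, 1.05}·λiv; four force–length sweeps at fixed pressure), with
P̄ the mean measured pressure and f̄ the mean measured |force| (floored at
1 mN with a warning for degenerate data).  Minimization is
Levenberg–Marquardt from three random starts, keeping the lowest converged
objective.  Non-negativity is enforced by a softplus reparameterization
(c, c1ᵢ, c2ᵢ) and α₀ by a scaled logistic onto (0, π/2), so the LM
iteration itself is unconstrained.  Starts are drawn uniformly:
c ~ U(1, 50) kPa, c1 ~ U(0.1, 30) kPa, c2 ~ U(0.01, 3),
α₀ ~ U(20°, 70°); each start is the best of 50 candidate draws screened by
a single objective evaluation.  Screening matters: the reparameterized
landscape has a broad high-objective basin (degenerate fiber geometry,
c1 → 0) that captures 30–50% of raw random starts on muscular-artery
datasets; screened starts reach the global optimum in >95% of seeds while
preserving the random multi-start character.  Convergence: relative
objective change < 1e−10 or 4000 residual evaluations.

Raw parameters of this model class trade off (notably c1 vs c2 and the
circumferential vs diagonal families); identifiability is therefore
asserted on derived metrics — stiffness, stored energy, pulse wave
velocity — never on raw parameters.

## Derived hemodynamic metrics

At the working point (100 mmHg for the thoracic aorta, 60 mmHg for the
mesenteric artery, both at the specimen's in vivo axial stretch):

- mean wall stresses σθ = P a/h and σz = (f + π a² P)/(π h (2a + h));
- C_θθθθ and C_zzzz (reported in MPa);
- stored energy density W (kPa);
- Moens–Korteweg PWV = √(E h / (2 ρ a)) with E = C_θθθθ and
  ρ = 1050 kg/m³ (configurable);
- distensibility D = (d_sys − d_dias)/((P_sys − P_dias) d_dias) from the
  model-predicted *inner* diameters at 120/80 mmHg (defaults; the study
  could not measure blood pressure) and Bramwell–Hill PWV = √(1/(ρ D)).

The two PWV routes are computed from independent ingredients (a local
linearization vs a finite pressure–diameter excursion) and agree within
15% on all aortic groups (max ≈ 12%, driven by wall nonlinearity between
100 mmHg and the 80–120 mmHg window).  For the mesenteric artery the
80–120 mmHg window lies far above the 60 mmHg working point and the routes
diverge by ~45%; the internal-validation check is therefore an aortic
statement.

## Vasoactive, cardiac and histological quantification

KCl/phenylephrine constriction is the percent diameter reduction from the
t = 0 baseline to the steady state at 10 min (trailing 30 s median to
suppress noise), plus the time to half response; responses below 1% of
baseline are flagged `no_response` with an undefined half-time.
Acetylcholine dilation is the percent of the phenylephrine pre-constriction
recovered and is undefined (flagged) when pre-constriction is below 1% of
baseline — a vessel that cannot contract provides no information about
endothelium-dependent dilation.

LV volumes use the Teichholz formula V(D) = 7.0/(2.4 + D) · D³ (D in cm),
with the plain cube method behind a switch; EF ≥ FS holds for Teichholz on
any valid dimensions (volume cubing amplifies shortening).  Technical
replicates are averaged before indices (EF, FS, SV, CO, E/A, E/e′, DT) are
computed.

Movat pentachrome sections are segmented by fixed HSV rules: bright
desaturated pixels (S ≤ 0.15, V ≥ 0.85) are background; dark pixels
(V ≤ 0.25) are elastin; remaining pixels with S ≥ 0.15 fall to hue bands —
red ±20° cytoplasm, 35–70° collagen, 190–260° proteoglycans; everything
else is unclassified.  The saturation floor exists because hue is
meaningless for near-achromatic pixels.  Alizarin-red calcification is a
single positive class (red hue, S ≥ 0.40, V ≤ 0.65), monotone in its
thresholds.  Area fractions always use tissue pixels (optionally restricted
to a provided media mask) as the denominator.  Segmentation is
deterministic and orientation-invariant.  Three replicate sections per
specimen are averaged, with a dispersion flag at a 0.05 range.

## The synthetic study

The generator forward-solves the constitutive model along the
vessel-specific protocol paths (aorta: pressure 10–140 mmHg, force–length
at {10, 60, 100, 140} mmHg; mesenteric: 10–90 and {10, 30, 60, 90}), with
400 points per protocol (2800 per specimen) on the unloading pass.
Measured diameters get multiplicative Gaussian noise (CV 1% default),
measured forces additive Gaussian noise (SD 0.1 mN); controlled variables
(pressure set-point, stretch) are recorded exactly.  Specimens vary around
their group by one lognormal scale factor on all stress-like parameters
(CV 8%), a lognormal size factor on geometry (CV 2%) and Gaussian jitter on
λiv (SD 0.015); metrics are generated independently within specimen — true
biological covariance between, e.g., stiffness and contractility is not
modeled.  A single global seed fans out to per-item streams via
`SeedSequence` keyed by a CRC32 of the item label, so any specimen
regenerates identically regardless of cohort composition.

Ground-truth parameter sets per group/age/vessel are fixed constants,
solved once from a 4×4 linear system in (c, c1_axial, c1_circ, c1_diag) at
the group's working configuration for four targets — pressure equilibrium,
stored energy and both stiffness components — over a small grid of
(c2, α₀) choices, and frozen in `vesselmech/calibration.py`.  Working-point
targets equal the published group means where printed (wild-type
1.13 MPa / ~201 kPa / 60 kPa; untreated progeria P42 0.84 MPa with
h = 39 µm, a = 474 µm; P168 1.69 MPa with h = 115 µm, a = 371 µm and
W = 2 kPa; lonafarnib-from-weaning h = 95 µm, σθ = 59 kPa, W = 6 kPa);
axial stiffness, mesenteric-artery values and intermediate ages are
interpolated or field-plausible choices made once.  Active responses are
mono-exponential approaches to plateau (τ = 60 s) with group amplitudes
encoding the progressive loss of aortic contractility and its mesenteric
rescue by lonafarnib; echo records are drawn around group means with the
E wave generated through a per-animal E/e′ ratio; histology images are
annuli with exact painted class quotas (media and adventitia painted
separately) plus small color jitter, returning ground-truth masks;
survival tables encode the study's published counts.

### What the synthetic study does and does not show

Passing tests demonstrate that the pipeline is internally correct: exact
round-trip IO, equilibrium and stiffness agreeing with independent oracles,
recovery of known ground truth, and reproduction of the calibrated group
means.  They do not validate the constitutive model against real tissue,
nor the HSV thresholds against real stain variability (real sections have
stain gradients, layer intergrowth and imaging artifacts the painted annuli
lack), nor the noise model against a real test rig (drift and hysteresis
are not simulated).

### An identifiability limit, documented deliberately

The perimorbid untreated-progeria aorta is nearly rigid: its printed
working-point targets imply d ln P/d ln d ≈ 34 near 100 mmHg, i.e. ~0.03%
diameter change per mmHg.  With 1% multiplicative diameter noise
(the generator default), the prescribed objective — pressure residuals
evaluated at measured diameters — suffers errors-in-variables attenuation:
the least-squares optimum genuinely lies below the truth (the fitted
objective is ~3× smaller than the objective at the true parameters), the
fitted stiffness of this group is biased low by ~45% and its fitted cohort
PWV is ~11.6 m/s against the 16.2 m/s target.  A noise sweep shows the
group is recoverable to within 5% only for diameter CV ≤ 0.2%.  The
pipeline therefore reports both fitted metrics and the generator-truth
cohort surface (clearly labeled), and the corresponding fitted-PWV
acceptance check is left failing rather than silently re-tuned; compliant
vessels (wild-type, young progeria) are unaffected (noisy recovery within
2%).

## Statistics and reporting

Group comparisons use one-way ANOVA (or a two-way OLS fit with type-II
sums of squares; the factor pair is a config choice) with Bonferroni
adjustment over all group pairs within a metric, stars at 0.05/0.01/0.001,
and mean ± SEM descriptives.  Survival is reported as raw alive/total
fractions (no Kaplan–Meier inference), rounded to the printed convention:
nearest integer at ≥ 50%, one decimal below.  Fold changes round half-up to
one decimal and percent reductions to integers; by direct arithmetic the
medial collagen change 0.094 → 0.046 is a 51% reduction.  Headline numbers
are rounded only at the reporting boundary; all internal values stay at
full precision.

## Problem sizes

Defaults used throughout: 400 points per protocol (2800 per specimen);
cohorts of 4–5 vessels per group matching the study design (53 fitted
specimens in the default study); 6 echo animals per group with 6 technical
replicates; 5 specimens × 3 replicate sections per histology group at
256×256 px; 3 Levenberg–Marquardt starts × 50 screened candidates per fit.
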