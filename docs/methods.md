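# Methods

This note documents the models implemented in `spu`, the choices made
where the design was genuinely open, and what the synthetic-data tests
do and do not demonstrate.

## Spectral preprocessing and band selection

Spectra live on a canonical 1 nm grid; off-grid inputs are linearly
interpolated at load time. The first-derivative default is a
Savitzky–Golay filter (window 15 nm, polynomial order 2) — a common
compromise for field spectra that suppresses baseline offsets without
destroying the red-edge shape; plain central differences are available
for exactness checks.

2DCOS follows the generalized formulation: spectra are ordered by the
perturbation trait (ascending, ties broken by sample id), mean-centered,
and correlated with normalization 1/(m−1); the asynchronous map uses the
Hilbert–Noda transform. Autopeaks are strictly interior local maxima of
the synchronous diagonal at ≥ 10 % of its maximum, merged within 10 nm
(ties keep the lower wavelength). Grid endpoints are excluded: one-sided
derivative windows inflate edge variance and produce spurious boundary
autopeaks. Band-selection stability is assessed by re-running the
selection on trait-quantile-stratified subsamples (default 10 draws,
stable = selected ≥ 8 times). Because the synchronous diagonal is a
per-band variance, it is invariant to the sample ordering; stability
across subsamples therefore probes the variance structure of the data,
not the trait ordering.

The two-trace variant correlates the filling- and milk-stage spectrum
of each plot; bands supported by strictly more than half of the plot
pairs are retained.

## Forward radiative transfer

The leaf model is an N-layer plate system (generalized plate model):
per-wavelength absorption is the concentration-weighted sum of
chlorophyll, carotenoid, brown-pigment, water and dry-matter
coefficients divided by the structure parameter N; interface
transmissivities are angle-averaged Fresnel integrals (40° incidence
cone on top, isotropic inside), evaluated by 128-point Gauss–Legendre
quadrature rather than the closed-form Stern average.
**The optical constants are synthetic**: smooth Gaussian-mixture stand-ins
with the peak positions and magnitudes of the well-known leaf absorption
features (chlorophyll 430/670 nm, water 1450/1940 nm, dry matter
1730/2100/2300 nm), shipped in `spu.rtm.optical_synthetic`. They produce
realistic maize canopy spectra but are not the measured PROSPECT-5B
tables, so absolute reflectances differ from any real instrument and
cross-comparison against reference leaf-model implementations is out of
scope. What remains testable — and tested — are the physical contracts:
energy conservation of the canopy solution under conservative scattering
(reflectance = 1 to 1e-6), the LAI→0 soil limit (exact), pigment/water
absorption monotonicity, and [0, 1] bounds everywhere.

The canopy model is a four-stream SAIL-type turbid medium with an
ellipsoidal leaf-angle distribution (Campbell χ from the mean leaf
angle, 13 inclination classes), the analytic two-stream solution for
diffuse fluxes, analytic bidirectional terms, and the finite-sunfleck
hot-spot integral on the single-scattering term. Geometry defaults to
sza 30°, vza 0°, raa 0°; output mixes the direct and diffuse-sky
reflectance factors with a 10 % diffuse fraction.

Leaf biomass is defined as 100·LAI·Cm (g/cm² × m²/m² → t/ha) — the
retrieval target of the hybrid branch.

Maize-typical free-parameter ranges (editable via config): Cab 20–70
µg/cm², Car 5–18 µg/cm², Cw 0.008–0.025 cm, Cm 0.003–0.010 g/cm², LAI
0.5–7, ALA 40–70°, hot-spot 0.05–0.5; fixed: N 1.5, Cbrown 0.1, psoil
0.7. The 400–615 and 765–990 nm regions are excluded from hybrid
modeling (the simulation is least trustworthy there); the working grid
is 615–765 + 990–2500 nm (1662 bands).

## Sensitivity analysis and calibration

eFAST assigns each parameter in turn a high driver frequency along a
space-filling search curve (interference factor M = 4, ≥ 65 points per
curve); Si sums the spectrum at the driver harmonics, STi is one minus
the low-frequency (complementary) variance. Closed-form checks: an
additive 2:1 model splits 0.8/0.2; the Ishigami function reproduces
S1 = 0.314, ST1 = 0.557 within 0.05. Parameters exceeding the 0.1
threshold in any spectral region (visible/NIR/SWIR mean reflectance)
stay free; dry matter is always kept free because the retrieval target
is proportional to it. Fixed parameters are calibrated by minimizing
the RMSE between the forward spectrum and the measured mean spectrum
with the sparrow-search hybrid.

## Optimizers

NRBO: population of 30, Newton–Raphson search rule built from the
current best and worst individuals (secant-like step with a guarded
denominator), a δ schedule (1 − 2t/T)⁵, and a trap-avoidance jump
applied with deciding factor 0.6; greedy per-individual replacement.
Sparrow-search hybrid: logistic-map chaotic initialization, sine–cosine
producer moves with amplitude decay 2(1 − t/T), Lévy-flight scrounger
steps (Mantegna, β = 1.5), 10 % scouts. Both clamp to bounds, evaluate
exactly once per individual per iteration (archive size pop·(iters+1)),
and are deterministic under a seed. Benchmarks: sphere < 1e-3 in
≥ 9/10 seeds at pop 30 × 200 iterations for both; NRBO solves 2-D
Rosenbrock and the sparrow hybrid 2-D Rastrigin at the same budget.

## Active learning

Representatives are chosen by Kennard–Stone (max–min coverage; SPXY and
random available). The candidate pool comes from the archives of
several short NRBO runs (pop 20, 8 iterations each, restarted until the
pool target is met) minimizing the distance between the simulated
spectrum and the representative centroid — short restarts keep the
trajectory diversity that a single long run would collapse away.

Filters use strict inequalities. The spectral threshold defaults to the
1st percentile of candidate-to-representative minimum distances and the
response threshold to 0.25 × SD of the representative responses. These
are deliberately tight: admitting more than a fraction of a percent of
the pool lets simulations through whose responses disagree with the
measured relation by more than the representative regression's own
error, and such samples measurably degrade the retrieval. The linear
model f of the response filter is OLS on the ≤ 10 highest-variance
bands (capped below the representative count; ridge 1e-3 fallback when
ill-conditioned). The greedy loop adds the measured sample whose
inclusion most reduces f's RMSE over all measured samples, refits, and
re-applies the response filter, stopping at floor(0.10·N) additions or
when no sample helps. Zero surviving simulations is a valid outcome —
training then degrades gracefully to the measured side of the pool
(the spec'd error fires only if the whole training set is empty).

The hybrid biomass model trains an ELM on the selected pool with three
stabilizers, chosen because a plain full-spectrum ELM at these sample
sizes (tens of samples, 1662 collinear bands) is erratic: features are
reduced to the 30 most important bands of a random forest fit to the
training pool (mirroring the top-30 band workflow of the LUT
benchmark); the ELM uses 40 hidden units with ridge 1e-3 on the output
weights; and the noise-free simulated rows are augmented with the
nominal sensor-noise model (1 % multiplicative, 0.002 additive) so
their feature distribution matches field spectra.

## Organ composition

The LPC model is a GBRT over derivative features at 1Der-2DCOS-selected
bands, trained per stage — pooling jointing and filling samples, as one
would with real data, confounds the regressor at this sample size
because the two stages place the same LPC at very different LAI. Leaf
uptake is LPC × hybrid leaf biomass. The stem link is a degree-2
least-squares polynomial from leaf to stem uptake (negative predictions
clipped to zero). The grain branch multiplies a milk-stage
grain-biomass model by the mature-leaf P concentration; in the default
"predicted" mode that concentration is the mean of the jointing- and
filling-stage LPC predictions, matching the layer set that defines
mature leaves (jointing upper+middle, filling upper+middle+lower). A
single-stage whole-plant spectral model serves as the empirical
baseline.

## Synthetic campaign

The generator emulates a randomized-block P trial: 7 rates
(0–120 kg P₂O₅/ha) × 4 replicates, three stages. Traits respond to the
P rate through a saturating curve (half-saturation 40 kg/ha) with a
per-plot latent vigor deviate (SD 6 %) shared across traits and 3 %
idiosyncratic jitter; Cab is linear in LPC (13·LPC + 3), senescence
lowers Cab and raises brown pigment at milk. P bookkeeping: leaf and
stem uptakes are the filling-stage (pre-remobilization) pools; grain P
is f_leaf·leaf_P + f_stem·stem_P with remobilized fractions drawn from
the physiological ranges [0.50, 0.85] and [0.15, 0.50]; grain biomass
follows as grain P divided by the grain concentration (= mature-leaf
concentration × a configurable ratio, 1 by default, which makes the
leaf-for-grain substitution exact and its bias analytic when the ratio
differs from 1). Spectra are forward-simulated and degraded with 1 %
multiplicative noise, 0.002 additive noise and a low-order polynomial
baseline wiggle (SD 0.0015) to exercise the derivative preprocessing.

What passing recovery tests show: the pipeline's machinery — band
selection, filtering, composition — reconstructs known truth through
the same forward model that generated it (an "inverse-crime" setting
with realistic noise). What they do not show: robustness to real
instrument artifacts, canopy heterogeneity, atmospheric effects, or a
mismatch between the radiative-transfer model and actual maize optics.

## Problem sizes and numerics

Default study sizes used by the test suite and acceptance script: a
20,000-row Latin-hypercube LUT for the biomass benchmark and the
AL-vs-random comparison; NRBO candidate pools of ~2,400 for the
campaign pipeline; 10 seeds for every stochastic claim. Degenerate
inputs: zero-variance responses yield constant predictors with a
warning; RPD is reported as infinity at zero RMSE; MAPE is undefined
when all observations are zero; all-zero synchronous diagonals yield
empty band sets.

## Known limitations

Stem uptake is only reachable through the leaf-uptake link, so its
errors are correlated with the leaf branch. The mature-leaf/grain
concentration substitution biases grain uptake by 1 − 1/ρ when the true
concentration ratio ρ ≠ 1. The synthetic optical constants preclude
quantitative comparison with measured reflectance. The eFAST regional
summary (mean reflectance per region) is one of several defensible
scalarizations; indices shift modestly under other choices.
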