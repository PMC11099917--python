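# Methods

## Equilibrium model

Each fibril polymorph is modelled as a set of independent binding-site
populations. A population has a site class (BS1 or BS2), a
concentration in nM, and a map of ligand → dissociation constant K_d
(absent entry = no binding). BS1 is accessible to both the reporter L0
and the dark competitor L1; BS2 binds L0 only. Ligands occupying the
same population are mutually exclusive (competitive binding): the
displacement behaviour of the assays implies competition rather than
allostery, and no cooperativity is modelled because every observed
titration is described by a 1:1 isotherm. Concentrations are nM
throughout; intensities are arbitrary units; anisotropy is
dimensionless.

For one ligand and one site pool, the bound concentration is the
physical root of `b² − (L+S+K)b + LS = 0`, evaluated in the numerically
stable form `b = 2LS/(p + √(p² − 4LS))`, `p = L+S+K`, which avoids
cancellation when binding is very tight or very weak.

The coupled two-ligand system is solved by a nested root-find on the two
free concentrations: at fixed free L1 the L0 mass balance is strictly
increasing in free L0 and is solved by bisection (Brent) on
`[0, L0_total]`; the outer L1 balance is likewise monotone and bracketed
on `[0, L1_total]`. Both residuals are driven to machine precision and
the solution is verified against conservation to a relative tolerance of
1e-10; the solver therefore needs no initial guess and is independent of
any starting point. (A damped-Newton path was considered but the
bracketed monotone formulation is both faster at this problem size and
unconditionally convergent, so it is the only path.)

Observed signals: intensity
`F = Σ_reporters (brightness_bound·bound + brightness_free·free)`, with
dark competitors contributing nothing and a single `brightness_bound`
shared by BS1 and BS2 — the endpoint calculation of %BS1 implicitly
assumes equal bound-state brightness, and the simulator treats unequal
brightness only as a non-default stress option. Anisotropy follows the
equal-quantum-yield mixing rule `r = r_free + (r_bound − r_free)·f_bound`
with `f_bound = bound/(bound+free)`.

## Assay geometry and isotherm fitting

Direct titrations add fibril binding sites (titrant, in site-equivalent
nM) to a fixed reporter concentration; the signal is
`baseline + amplitude·θ(titrant; K_d)` where θ is the exact
ligand-depletion-aware quadratic bound fraction of the reporter. This
geometry makes the fit family exact and fully identifiable from the
curve metadata alone (the reporter total is a known fixed
concentration), for intensity and anisotropy assays alike; for
titrant ≫ reporter the quadratic coincides with the free-ligand
hyperbola. Because the sites-per-monomer stoichiometry of a fibril is
unknown, direct-titration concentrations (and hence fitted K_d values on
real data) are in apparent site-equivalent units.

Competition titrations add the dark competitor to a pre-equilibrated
mixture of fibril (500 nM monomer-equivalent) and reporter (1000 nM, the
panel defaults). The fitted model is
`signal = f_end + (f_start − f_end)(1 − θ(l1; K_d,app))` with θ the 1:1
bound fraction of L1 computed in the free≈total limit: at the default
site density the shared sites (≈ 35–95 nM) are dilute relative to the
apparent K_d (≳ 500 nM), so competitor depletion is negligible and the
fitted constant is the conventional apparent K_d (the true K_d scaled by
the reporter competition factor `1 + f0/K0`). The shared-site
percentage is `%BS1 = 100(f_start − f_end)/(f_start − f_background)`.

`f_background` defaults to the measured no-fibril blank shipped with the
curve; when absent, the baseline of a paired direct fit of the reporter
(or zero) may be supplied. Whether free-reporter fluorescence is
subtracted or fitted is left open by the assay description, so the model
exposes `brightness_free` and the fitter always treats the baseline as a
parameter.

Fitting is nonlinear least squares with the two linear coefficients
profiled out exactly at every K_d, leaving a 1-D optimization over
log10 K_d started from three deterministic points spanning the titrant
range (ties broken by lowest residual). Confidence intervals come from
the linearized covariance at the optimum with Student-t quantiles
(df = n − 3). Non-convergence is reported via `converged=False`, never
an exception. A fit whose maximum titrant is below K_d/2 is flagged
`low_confidence` rather than silently reported.

A competition curve is called "no displacement" when an
extra-sum-of-squares F-test (α = 0.05) cannot reject the constant model
— the profile-likelihood form of "the displacement CI includes 0", and
robust against the unbounded `f_end` extrapolation that flat curves
otherwise produce — or when the fitted |f_start − f_end| is below three
residual SDs. Such fits report `%BS1 = 0` and an undefined K_d.

Replicates are fitted per curve and pooled as
`mean ± t(0.975, n−1)·sd/√n` (per-replicate fitting, then t-based
aggregation, mirroring the averaging of at least three experimental
measurements; no global multi-curve fit).

## Statistics and profiling

Binding calls require all of: pooled amplitude/displacement 95% CI
excluding zero, magnitude ≥ 3 pooled residual SDs, and the physical
sign. The sign requirement makes extreme noise degrade to a no-call
rather than an opposite-direction call, and the 3-SD requirement keeps
the false-positive rate on flat assays far below the nominal 5% of the
CI rule alone.

Pairwise comparisons use the two-sided paired t-test,
`t = mean(d)/(sd(d)/√n)`, df = n − 1, paired by replicate index (what
exactly is paired — replicate batch or plate — is not specified by the
protocol; replicate index is the documented assumption). Zero-variance
differences with nonzero mean are flagged degenerate with p floored at
1e-12, never NaN. α = 0.05 throughout (the PD/S5H contrast is typically
far below 0.01, but the decision threshold stays 0.05). No
multiple-testing correction is applied by default, matching the raw
paired-t protocol; a Holm step-down option is provided.

Ordinal features assert only significance-backed orderings: within a
binary group, `s5h_kd_rank='lowest'` requires a significant paired win
against every other member; the remaining members are ranked on the AAR
direct K_d the same way; unsupported orderings are left unset, and
classification then returns an ambiguity set instead of a guess. The
OXI %BS1 class is 'low'/'high' only when the pooled CI is entirely on
one side of 70% — the split between partial displacement (≈ 35–45%) and
almost-complete displacement (≳ 85%).

## Decision tree and minimal panel

The fixed tree tests, in order: AAR binding (splitting off {R, f91},
resolved by S5H binding); S5H binding (PMCA polymorphs vs de novo); for
de novo binders, BTA binding (F) and the OXI %BS1 class (f110 vs f65);
for PMCA polymorphs, the lowest S5H K_d (PD) and the AAR K_d order
(MSA vs DLB). Profiles missing a feature stop at that node and return
the set of labels below it, matching the two-stage binary→quantitative
protocol (binary-only profiles yield exactly the five categories).

The shipped reference profile table records only discriminations with
recorded evidence, each cell tagged `stated`, `implied` (e.g. BTA
displacement for f91 and the PMCA polymorphs, entailed by the statement
that only F and R show none) or `stated-significant`; pairs without
evidence are treated as not separable by that assay, and the ThT/ThR and
AAR/ThT assays are registered as candidates carrying no separations.
The minimal-panel search enumerates subsets exhaustively by increasing
size, lexicographically in registry order (AAR-direct first), so the
first feasible subset is a proven minimum with a deterministic
tie-break; its separation certificate lists the pairs each assay
separates and is re-verified independently in the tests.

## Synthetic data generator

The generator emulates the study conditions: eight fibril models, four
protocol assays (optionally the confirmatory ThT/ThR, AAR/ThT and
BTA-direct assays), fibril 500 nM and reporter 1000 nM for competition
assays, ≥ 12-point log-spaced titrant grids, three replicates, and
multiplicative Gaussian noise of 2% (an absolute-noise floor defaults to
0; plate-reader noise at these signal levels is near-Gaussian, so no
Poisson component is modelled). Each fibril carries one BS1 and one BS2
population with a common reporter K_d, so the ground-truth %BS1 equals
the BS1 fraction exactly and is also recomputed independently through
the equilibrium solver.

Absolute K_d magnitudes are not constrained by the reference system —
only binary calls and orderings are — so nominal values are placed in
the 0.25–2.5 μM range and jittered per seed by a factor of e^±0.15,
which preserves every ordinal constraint (all constrained ratios are
≥ 4×). The BS1 fraction is 0.35–0.45 for the low-%BS1 polymorphs
(R, f110) and 0.86–0.93 otherwise, jittered by ±0.03. The site density
is 0.2 reporter sites per monomer-equivalent (100 nM sites at 500 nM
fibril): real per-ligand stoichiometries and brightness ratios are not
available to constrain it, and this density keeps the re-equilibration
bias of the endpoint %BS1 estimator (reporter freed from BS1 re-binding
BS2) below about one percentage point while leaving strong, easily
quantified signals. Reporter brightness values are nominal
(bound ≫ free), with the solvatochromic free-ligand contribution small
but nonzero so that no-binding curves still carry a realistic baseline.

What the generator does not emulate: instrument drift, plate effects,
pipetting (titrant-axis) error, aggregation kinetics, fibril
heterogeneity within a sample, and inner-filter effects. Passing tests
therefore demonstrate the correctness and calibration of the analysis
under its stated statistical assumptions, not robustness of the wet-lab
assay itself.

## Problem sizes and numerical choices

The stochastic validation runs use 50 pipeline seeds (full
simulate→fit→profile→classify on all eight fibrils) and 1000 simulated
twin panels for the type-I calibration, sizes at which the binomial
uncertainty of the measured rates is a fraction of the acceptance bands.
Degenerate inputs are handled explicitly: zero ligand or zero sites give
zero bound; an anisotropy readout with no ligand is an error; a
competition curve whose start signal does not exceed the background
raises a degenerate-assay error (the reporter never bound); missing
protocol assays raise an incomplete-profile error naming the assay.

## Known limitations

* Fitted K_d values from direct titrations are in site-equivalent
  units; comparing them across fibrils assumes comparable site
  stoichiometry.
* The competition fit returns an apparent K_d; converting to a true
  competitor K_d requires the reporter occupancy correction.
* The decision tree is fixed by the reference system; it is not learned
  from data and does not handle mixtures of polymorphs.
* Ordinal ranks depend on panel context (which fibrils are profiled
  together); a lone profile classifies only to its binary category.
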