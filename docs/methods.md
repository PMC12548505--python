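# Methods

## Model and assumptions

The competitive-binding model treats adhesion between two peptide-coated
surfaces as governed solely by the concentration of inter-surface dimers:
direct pairs P₂ (π–π / native cation–π pairing) and cation-bridged pairs P₂T
(π-cation-π). Two assumptions are built in:

1. all adsorbed peptides are available for inter-plane pairing (the base
   model neglects intra-plane pairing; the K6 extension relaxes this for the
   salt-free grafting-density series);
2. adhesion has no contribution from hydrogen bonding, van der Waals or
   double-layer forces — only the π-mediated interactions above.

Consequences worth keeping in mind: the model underestimates adhesion at
high ionic strength for multivalent ions (intra-plane pairs act as a
reservoir that can convert to inter-plane bridges as ions are added, a
redistribution the model does not describe), and divalent cations have no
species of their own — `divalent_as_trivalent=True` maps them onto the T
role as an explicitly labelled extension, off by default.

## Units and identifiability

Bath concentrations are mM. The adsorbed peptide total `p_total` is an
*effective* surface concentration with arbitrary units; K3–K6 carry the
matching inverse units. This is deliberate: experimentally the curves are
normalized to their salt-free value, and the normalized isotherm

E(I)/E(0) = (1 + (K4/K5)[T]) / (1 + K1[M] + K2[T])²

depends only on K1 (1/mM), K2 (1/mM) and the ratio K4/K5 (1/mM). Those are
the quantities `fit_constants` estimates; absolute K5·p_total² or K6·p_total
products are only accessible through the grafting-density series, where the
reported "k5" is the effective prefactor of adhesion against density in
whatever units the densities were supplied.

A parameter is reported as identifiable only if the supplied curves actually
probe it: K1 requires points with [M] > 0, K2 and K4/K5 require points with
[T] > 0. Unconstrained parameters come back as `None`, never as a silent
boundary value.

## Mixed-electrolyte convention

The ionic-strength axis is the **total** ionic strength I = ½Σcᵢzᵢ². For a
1:1 salt [M] = I; for a 3:1 salt [T] = I/6. In a mixed series with the
trivalent concentration held at t, the trivalent salt contributes 6t of
ionic strength, so points with I > 0 are interpreted as [T] = t,
[M] = I − 6t; the I = 0 point is the salt-free baseline used for
normalization, and points with 0 < I < 6t are rejected as inconsistent.
This is the only reading under which a mixed curve, its baseline, and the
single-salt curves share one axis.

## Solvers

`solve_closed_form` implements the dimer-neglecting closed form (the default
everywhere, since it is what the normalized isotherm is derived from).
`solve_exact` substitutes the mass-action laws into the full conservation
sum, giving a·p + 2b·p² = p_total with a = 1 + K1[M] + K2[T] and
b = K4[T] + K5 (+ K6·K5 with `include_intra=True`); the unique non-negative
root is evaluated as p = 2·p_total/(a + √(a² + 8b·p_total)), which is
algebraically identical to the quadratic formula but immune to the
cancellation that form suffers when a dominates. b = 0 falls back to the
linear limit rather than a 0/0. Conservation holds to 1e-9 relative for the
exact solver; the closed form converges to it at first order in
b·p_total/a² (relative error ≈ 4·b·p_total/a² in the dilute regime).

The `include_intra` branch uses p₂,intra = K6·K5·p², which makes the
ion-free exact model self-consistent with one more pairing channel. The
grafting-density closed form K5·ρ²/(1 + 2K6·ρ)² is a distinct
approximation fitted directly to data; K6 there is treated as an effective
inverse-density constant because that is how the operative formula uses it.

## Fitting

Weighted least squares (1/SD weights when per-point uncertainties exist,
unweighted otherwise — no fitting criterion is canonical for these data).
Constants span decades and have no natural starting values, so parameters
are optimized as log10 values bounded in [−6, 6] (wider, [−14, 8], for the
grafting fit, whose constants scale with inverse squared density), from 20
Latin-hypercube starts seeded by the user's seed; refits with the same seed
are bit-reproducible. Tight tolerances (1e-15) make noise-free recovery
exact to ≲1e-6 relative. Uncertainty comes from a seeded residual bootstrap
(`bootstrap_constants`, 500 resamples by default), kept out of the core fit
path so simulation studies stay fast; a Gauss–Newton covariance in log
space is attached to every fit when the Jacobian is invertible.

The sequestered-fraction estimate reads the shortfall of measured adhesion
below the anchored quadratic as F ∝ [P_available]², giving
fraction = 1 − √(observed/predicted). That square-root availability reading
is an interpretation of the deviation, and outputs label it as such.

## Synthetic data

The adhesion generator emulates the study design: ionic-strength grid
{0, 1, 3, 6, 10, 30, 60, 100} mM, a monovalent (KNO₃) and a trivalent
(Y(NO₃)₃) series, mixed series with Y³⁺ held at 1 and 5 mM, 3 replicates,
and multiplicative Gaussian noise (5% SD) on a 10 mJ/m² salt-free baseline
— error bars in force measurements grow with the signal, hence
multiplicative rather than additive noise. Generating constants are
k1 = 0.5/mM, k2 = 0.2/mM, k4/k5 = 1.0/mM, chosen so the monovalent decay,
the trivalent overshoot (peak at 3 mM Y³⁺) and the mixed-series attenuation
are all expressed inside the sampled grid. Replicates are independent
draws; the generator does not model day/surface random effects, drift,
force–distance hysteresis, or any double-layer contribution, so passing
recovery tests demonstrate correctness of the estimation machinery under
the stated noise model, not robustness to structured experimental error.

Geometry fixtures are regular hexagons of radius 1.39 Å (benzene C–C bond;
hydrogens omitted) in T-shaped, parallel-stacked and cation-bridged motifs
plus a random-gas control, with per-atom Gaussian jitter. Rings that jitter
beyond 0.5 Å out of plane carry a warning flag (hard error above 1.5 Å).

## Geometry conventions

Ring normals are the smallest principal component of the centered six
atoms, signed to +z (ties to +x, then +y). Both contact cutoffs are strict
inequalities ("less than 4.5 Å" / "less than 10 Å"); the 10 Å cation–π
criterion is generous compared with common ≤ 6 Å definitions and is kept
configurable. The NH₃⁺ group is represented by its nitrogen position, and
"distance to the ring" means distance to the ring centroid. A cation not
assigned to a layer (bath) labels its contacts by the ring's layer;
bridging across layers is reported separately by `bridging_motifs`.
Coordinates are treated as unwrapped — no periodic-boundary handling.

The 2D stacking KDE uses a product Gaussian kernel with Scott's rule per
axis (σ·n^(−1/6), floors 0.25 Å and 2.5° for degenerate axes, both recorded
in the output metadata) and reflects kernel mass at the angle boundaries
(0°, 90°) and at distance 0, so the density integrates to 1 over the folded
domain on any grid covering the data ± 3 bandwidths. A hand-rolled KDE was
chosen over a generic one so that point-mass inputs, the folded domain and
the per-axis bandwidth rule are all handled exactly as stated.

## Problem sizes

The test suite and acceptance script use: 1000 random parameter draws for
the solver/bisection and overshoot cross-checks, 100 simulated studies for
the noisy recovery benchmark (median relative error ≈ 7%, specification
≤ 15%), 200 random instances (up to 30 rings, 50 cations) for the detector
oracles, and 435 ring pairs for the KDE normalization check. These sizes
give stable medians and exhaust the combinatorics the detectors can
encounter while keeping the full run under a minute.

## Known limitations

- [M] and [T] are taken as bulk reservoir concentrations; confinement
  corrections between contacting surfaces are not modelled.
- Whether the closed-form isotherm is exact under an extra assumption or
  purely a dilute approximation cannot be settled from the available
  derivation; here it is treated as the approximation the exact solver
  quantifies.
- Per-curve versus joint fitting across salts is a user choice; the default
  is joint (all curves share one constant set).
- No ring perception: rings are declared via the sidecar index, never
  inferred from connectivity.
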