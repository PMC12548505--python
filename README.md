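# pibridge

Tools for analysing **cation-modulated adhesion between aromatic-peptide-coated
surfaces**. Adhesive peptides rich in phenylalanine and lysine stick to each
other through π–π stacking, NH₃⁺–π and cation–π interactions; free cations in
the bath compete for the aromatic rings, so adhesion depends strongly on ionic
strength and on cation valency. Monovalent ions (K⁺) cap the rings with
complexes that cannot bridge two surfaces and kill adhesion; trivalent ions
(Y³⁺) can coordinate two rings at once, forming π-cation-π bridges that
preserve — and at low concentration even enhance — adhesion.

The package is aimed at people who measure adhesion with a surface forces
apparatus (SFA) or analyse peptide-brush simulation snapshots and want a
quantitative, testable version of that competitive-binding picture.

## The model

Surface-bound peptides P equilibrate with bath cations M (monovalent) and T
(trivalent):

```
P + M  ⇌ PM        K1 = [PM]/([P][M])
P + T  ⇌ PT        K2 = [PT]/([P][T])
P + PT ⇌ P₂T       K3;  K4 = K2·K3
P + P  ⇌ P₂        K5 = [P₂]/[P]²
```

with the conservation law `[P]T = [P] + [PM] + [PT] + 2[P₂T] + 2[P₂]`.
Adhesion is carried by the inter-surface dimers, `[P₂] + [P₂T]`. Dropping the
dimer terms from the conservation sum gives the closed form

```
[P₂T] + [P₂] = (K4[T] + K5) [P]T² / (1 + K1[M] + K2[T])²
```

whose limits predict an inverse-square decay in [M] (monovalent-only), an
adhesion *overshoot* in [T] whenever K4/K5 > 2·K2 (trivalent-only, peak at
T\* = (K4/K5 − 2K2)/(K2·K4/K5)), and a quadratic dependence K5·[P]T² on
grafting density with no salt. A crowded-surface extension
`K5[P]T²/(1 + 2K6[P]T)²` accounts for intra-plane pairing that sequesters
peptides at high grafting density. `solve_exact` solves the *full*
conservation law (a quadratic in [P]) and serves as the internal oracle for
the closed-form approximation.

Normalized adhesion curves, `E(I)/E(0)`, depend only on K1, K2 and K4/K5;
`fit_constants` recovers exactly those ratios by weighted least squares in
log space with a seeded multi-start, and flags whatever the data cannot
identify.

The geometry module implements the matching trajectory-analysis conventions:
π–π contacts are any-atom pairs < 4.5 Å, cation–π contacts are
cation-to-ring-centroid distances < 10 Å, normal–normal angles are folded to
[0°, 90°], and the 2D (centroid distance, angle) distribution is a
boundary-reflected Gaussian KDE with Scott's-rule bandwidths.

## Worked example

Simulate a full study (monovalent, trivalent, and two mixed-electrolyte
series at held 1 and 5 mM Y³⁺; 8 ionic strengths, 3 replicates, 5%
multiplicative noise) from known constants, then fit them back:

```python
from pibridge import (AdhesionSimSpec, simulate_adhesion_curves, normalize_curve,
                      fit_constants, overshoot_diagnostic, BindingConstants)

spec = AdhesionSimSpec(seed=42)           # truth: k1=0.5, k2=0.2, k4/k5=1.0
curves = [normalize_curve(c) for c in simulate_adhesion_curves(spec)]
fit = fit_constants(curves, seed=42)
print("fitted constants:", fit.constants)

diag = overshoot_diagnostic(BindingConstants(k2=fit.constants["k2"],
                                             k4=fit.constants["k4_over_k5"], k5=1.0))
print("overshoot:", diag.has_overshoot, "peak at", round(diag.t_peak, 3), "mM Y3+")
```

prints

```
fitted constants: {'k1': 0.5139, 'k2': 0.1989, 'k4_over_k5': 1.0119}
overshoot: True peak at 3.051 mM Y3+
```

i.e. the three identifiable constants come back within a few percent of the
generating values at the study's noise level, and the fitted trivalent
isotherm is diagnosed as overshooting, with its maximum near 3 mM Y³⁺ —
adhesion there exceeds the salt-free value before ionic screening takes over.

The same workflow is available from the shell:

```sh
pibridge simulate-adhesion --config sim.yaml --seed 42 --out data/
pibridge fit-adhesion      --config fit.yaml --seed 42 --out fit/
pibridge make-fixtures     --config fix.yaml --out fixtures/
pibridge analyze-contacts  --config ana.yaml --out contacts/
```

Every output embeds the seed and the resolved configuration, and reruns with
the same seed are byte-identical.

## Documentation

`docs/methods.md` describes the model assumptions, the units convention, the
synthetic-data generator and what it does and does not emulate, and the
numerical choices (solver form, optimizer hygiene, KDE boundary handling).
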