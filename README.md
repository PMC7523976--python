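# plaquestress

Factor screening for computed peak stresses in atherosclerotic carotid
plaque cross-sections.

Finite-element stress analysis is the standard way to estimate the rupture
risk of a carotid plaque: the peak first principal stress in the fibrous
cap (PCS) — the thin tissue layer separating the lipid core from the blood
— is the usual vulnerability indicator, with the peak stress over the whole
plaque (PPS) alongside it. Every such model, however, is built from
uncertain inputs: imaging resolution limits the reconstructed geometry,
plaque tissue stiffnesses span orders of magnitude, and models built from
endarterectomy samples or in vivo imaging often lack the media and
adventitia entirely. This package quantifies how much those modelling
choices move the computed peaks, on a fully synthetic, reproducible
phantom, using a designed experiment:

| factor | range | meaning |
|---|---|---|
| WT | 0 – 0.5 mm | wall thickness carrying real media/adventitia properties (0 = wall treated as plaque tissue) |
| ST | 0.25 – 1.5 mm | imaging slice thickness the geometry is reconstructed from |
| LC | 0.1 – 50 kPa | lipid-core stiffness (neo-Hookean c10) |
| FT | 2.7 – 342.1 kPa | fibrous-tissue initial stiffness (2nd-order Yeoh c10, c20 = 20 kPa fixed) |
| MB | isotropic / anisotropic | media constitutive behaviour |

The pipeline: build an idealized eccentric-plaque vessel segment with a
large lipid core and a locally thin fibrous cap → degrade its contours to
the requested slice thickness → partition the 0.5 mm outer wall annulus by
WT → solve each cross-section as a nearly incompressible plane-strain
hyperelastic problem under 13 kPa luminal follower pressure (Yeoh tissues;
fiber-reinforced anisotropic media with two collagen families at ±6.9°,
Ψ = μ/2(I₁−3) + k₁/(2k₂)(exp[k₂((1−ρ)(I₁−3)² + ρ(I₄−1)²)]−1)) → extract
PPS and PCS per station → fit full quadratic response surfaces on the
face-centred central composite design (25 runs per media behaviour) and
screen term significance by ANOVA at the 95% confidence level, with a
paired t-test for the media factor. See `docs/methods.md` for the science
and the numerical choices.

## Worked example

Solve one design point from the shell (a soft plaque with the wall treated
as fibrous tissue, the common "wall-omitted" shortcut):

```
$ plaquestress solve-one --wt 0.0 --st 0.25 --lc 25.05 --ft 2.7
PPS = 317.58 kPa at z = 2.00 mm
PCS = 9.66 kPa at z = 0.60 mm
...
$ plaquestress solve-one --wt 0.5 --st 0.25 --lc 25.05 --ft 2.7
PPS = 43.11 kPa at z = 2.00 mm
PCS = -7.40 kPa at z = 0.60 mm
```

Assigning fibrous-tissue properties to the wall instead of real
media/adventitia stiffness raises the computed peak plaque stress about
sevenfold here (318 vs 43 kPa) — wall omission is the dominant modelling
error for soft plaques (with the full wall the soft cushion is in
near-hydrostatic compression, hence the small, even negative, cap stress).
With hard fibrous tissue (`--ft 342.1`) the ordering reverses
(PPS 65 vs 80 kPa): once the plaque is as stiff as the wall, omitting the
wall layers mildly *lowers* the peaks. The plaque peak localizes at
z = 2.0 mm, the station of the local cap-thickness minimum.

The numbered scripts under `analysis/` run the full study: phantom
generation and slice-thickness degradation (`01`), solver verification
against the semi-analytic tube-inflation oracle (`02` — hoop-stress error
0.07% at the 128×16 mesh, second-order convergence), the wall-contrast
corner models with exported stress fields (`03`), the 50-run screening
campaign (`04`), and the ANOVA/cube-plot report (`05`). On the campaign
(seed 1) the fitted surfaces give R² = 0.90 (PPS) and 0.82 (PCS); the WT
main effect and the WT×FT interaction are significant for both responses,
LC and its interactions additionally for PCS, while the paired
isotropic-vs-anisotropic media difference is about 1 kPa in PPS and
0.3 kPa in PCS — under 2% of the mean response, i.e. media anisotropy is a
minor factor compared to wall handling and tissue stiffness.

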