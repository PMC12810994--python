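# Methods

## Scope and data model

`aneuprep` implements the classical-image-processing support stack for
deep aneurysm segmentation on 3D TOF-MRA: vessel enhancement, automatic
vessel-based ROI cropping, construction of a vessel-enhanced-attention
(VEA) training modality, a family of hybrid segmentation losses, and
evaluation/cross-validation statistics. Network training itself (the
3D U-Net, its schedule and augmentation) is deliberately out of scope;
the package prepares inputs for and evaluates outputs of such a model.

All geometry uses per-axis voxel spacing in mm. World orientation
(affine direction cosines) is read from NIfTI headers and carried as
opaque metadata but never used in computation: the pipeline is
intensity- and geometry-based, not atlas-registered. Voxel indices are
0-based; boxes are half-open `[lo, hi)`, which makes crop composition
unambiguous. Masks binarize at value > 0 on load to tolerate label
files storing 1 or 255. Bias-field correction and resampling are
upstream of this toolkit.

## Vessel enhancement

Tubularity is the Frangi measure on the eigenvalues of the
σ²-normalised Gaussian-derivative Hessian, bright-tube convention only
(TOF-MRA vessels are hyperintense; voxels with λ₂ > 0 or λ₃ > 0 score
zero). Defaults:

| parameter | default | meaning |
|---|---|---|
| `scales_mm` | 0.5, 1, 2, 3 | σ in mm; covers perforator-to-basilar calibres |
| `prefilter_sigma_mm` | 0.5 | one Gaussian prefilter pass before all scales |
| `alpha`, `beta` | 0.5, 0.5 | plate/line and blob discriminators (standard values) |
| `c` | `"auto"` | half the max Hessian Frobenius norm over the volume |

The prefilter is applied once, not per scale; per-scale smoothing is
already provided by the derivative kernels, and a single pass keeps the
response maximum across scales comparable. σ in mm is converted
per axis to voxel units and derivatives are divided by the spacing per
order, so eigenvalues are in mm⁻² and anisotropic grids are handled
without resampling.

Numerical choices. Derivative kernels are truncated Gaussians with
corrected discrete moments: the order-2 kernel is made exactly
zero-sum with unit response to x²/2, and the order-1 kernel has unit
response to x. Without the zero-sum correction, truncation leaks
curvature of order 10⁻⁴ into constant regions, which the auto-`c` rule
would then amplify into spurious response on structure-free volumes.
Boundary handling is reflect padding everywhere, avoiding rim
artifacts that would otherwise distort the Otsu histogram. Where
λ₃ = 0 the voxel has no structure and the response is 0; a small floor
(10⁻¹²) protects the square root in R_B.

Maximum composition across scales makes the response monotone in the
scale set, and eigenvalue rotation invariance makes the response
exactly equivariant under 90° grid rotations on isotropic spacing —
both are tested properties.

## ROI extraction

The response is binarized with a single global Otsu threshold computed
from the histogram of the entire 3D volume (256 bins by default) and
applied voxelwise — full-3D rather than slice-wise thresholding
preserves inter-slice vessel continuity. Thresholding the vesselness
response is the default; a `threshold_on="weighted_intensity"` switch
thresholds the response-weighted intensity image instead. Connected
components use 26-connectivity by default (faces, edges and corners
connected — the most permissive neighbourhood, fitting tortuous
vessels), and components under `min_voxels = 500` are removed as
spurious. Both numbers are configuration, not constants; 500 voxels is
an empirical default. The crop is the minimum axis-aligned bounding
box over the surviving mask — the componentwise extrema, not an
equal-sided cube, since equal sides would not be minimal; an optional
`cube` flag expands it symmetrically for consumers that want cubes.
Default `pad_voxels = 0`.

If every component falls below the size minimum, the pipeline falls
back to the largest component with a warning rather than failing a
batch; `strict=True` turns this into an error with the component-size
diagnostic.

## VEA modality

The second training channel is the voxelwise product of the original
image with the min–max-normalised response. Min–max (rather than
z-scoring) is used because the product acts as a multiplicative
attention mask and must stay in [0, 1]; a constant response maps to all
zeros so that "no detectable structure" suppresses everything rather
than passing a constant through. The VEA channel is computed on the
full volume and cropped afterwards — multiplication and cropping
commute, so channel values never depend on the box. Channel files
follow the nnU-Net suffix convention; any further intensity
normalisation is the downstream trainer's business.

## Loss family

Terms operate on a predicted foreground-probability volume and a
binary target, volume-level (not per-patch):

- **CE**: voxel mean of −[y log ŷ + (1−y) log(1−ŷ)].
- **Dice**: 1 − 2Σyŷ/Σ(y²+ŷ²), the squared-denominator soft form,
  with smoothing ε = 10⁻⁵ in numerator and denominator (leaves
  volume-sized worked values unchanged to ≥ 6 decimals, stabilises
  empty foreground).
- **TopK**: `threshold` mode averages CE over voxels whose true-class
  probability is below t (the indicator form; empty selection → 0);
  `fraction` mode (default, k = 10%) averages the ⌈kN/100⌉ largest
  per-voxel CE values and reduces to CE at k = 100.
- **Focal**: the default `squared` variant evaluates
  −[α(1−ŷ)^γ y log ŷ + (1+α)ŷ²(1−y) log(1−ŷ)] exactly as this loss
  family defines it — note the background term's fixed square and
  (1+α) weight; a `canonical` variant with (1−α)ŷ^γ is kept because
  that form deviates from the wider object-detection literature. Defaults
  α = 0.25, γ = 2.
- **Tversky**: 1 − Σp₀g₀/(Σp₀g₀ + αΣp₀g₁ + βΣp₁g₀), foreground-only by
  default, α = 0.3 / β = 0.7 (penalising false negatives, the usual
  imbalance choice); at α = β = 0.5 on binary input it reduces to the
  linear-denominator Dice complement.

Probabilities are clipped to [10⁻⁷, 1] inside logarithms: the lower
clip keeps confident mistakes finite while log 1 = 0 stays exact, so
every loss is exactly zero at a perfect binary prediction. CE-family
terms reduce by unweighted voxel mean; Dice/Tversky use volume-global
sums, as their defining formulas do. Compounds are Σ wᵢ·termᵢ and
linear in the weights. The eight studied combinations are exposed as
presets L1–L8; the per-term weights of the *weighted* variants L7/L8
were never published, so those presets require explicit weights.

## Evaluation statistics

DSC = 2TP/(2TP+FP+FN), sensitivity = TP/(TP+FN), precision =
TP/(TP+FP). Empty-mask conventions follow common challenge practice:
two empty masks give DSC 1; a zero denominator makes
sensitivity/precision NaN, excluded from fold means with a warning.
HD95 takes boundary voxels (true voxels with a false 6-neighbour, the
volume border counting as false), collects voxel-centre nearest-surface
distances in mm each way with anisotropic spacing, and returns the
larger of the two directed 95th percentiles; it is undefined for empty
masks. Fold summaries use the sample SD (k−1) and the
normal-approximation interval mean ± 1.96·sd/√k with the multiplier
fixed at 1.96, not a t-quantile — this reproduces, at their printed
3-decimal precision, three of the four published five-fold intervals;
the fourth ([0.529, 0.564] for mean 0.5467, sd 0.019) is inconsistent
with its own formula, which gives [0.530, 0.563], so the formula's
value is what the package computes and tests.

## Phantom generator

Phantoms are bright tubes around polylines with Gaussian radial
profile peak·exp(−d²/2r²) (d = mm distance to the centreline, sampled
at ≤ 0.25·min-spacing for bounded geometric error), mask d ≤ r; saccular
aneurysms are spheres placed tangent to a tube surface, their masks
excluded from tube interiors so the two ground truths are disjoint but
adjacent; noise is seeded additive Gaussian by default (a Rician
magnitude model is available as a config enum, since real MR magnitude
noise is Rician; Gaussian is sufficient at the contrast regimes tested
and simpler to reason about). Identical spec and seed give
bit-identical cases. Fusiform dilations exist as a local radius bulge
on a tube but are not used by the default presets.

Presets emulate two aneurysm-size regimes: `adam_like` (0.5 mm
isotropic, diameters 1.0/3.6/15.9 mm — minimum/median/maximum of the
public-challenge cohort) and `renji_like` (0.8 mm isotropic, diameters
2.0/9.35/18.0 mm around the clinical cohort's 9.35 mm median).
Background 0.1, structure peak 1.0, noise SD 0.05 — a tube-to-
background contrast of 18 noise SDs, comfortably inside the ≥ 3σ
regime where ROI extraction is guaranteed.

`random_network_spec` builds the seeded phantoms used for the
end-to-end ROI guarantee: three thick trunk tubes (radii U(2, 3) mm),
one spanning the volume along each axis, plus one or two thin interior
connectors (radii U(0.5, 2) mm), and one aneurysm with diameter
log-uniform over 1–16 mm attached to the z trunk (the grid grows to
64³ for diameters above 8 mm so the sphere always fits interior).
Trunks are mutually offset so they never cross: Hessian-based
vesselness is suppressed at junctions, where the local geometry is
blob- rather than tube-like, and a trunk split at a crossing could
fall under the 500-voxel suppression floor. With axis-spanning,
non-crossing trunks, every ground-truth extremum lies on a volume face
where reflect-padded filtering keeps the response high, and each trunk
alone survives suppression, so 100% box containment follows from
geometry. A far-field bright blob (3 voxels across, far below the
500-voxel floor) is seeded near a corner to exercise suppression.

What passing phantom tests do **not** show about real data: phantoms
have no flow artifacts, no intensity inhomogeneity, no intra-aneurysmal
dark signal, no skull or tissue background, and straight rather than
tortuous vessels; junction suppression in particular means that on real
vasculature the component-size floor interacts with bifurcations, which
the non-crossing trunk design sidesteps rather than solves. The
guarantees demonstrated are therefore about the pipeline's logic and
numerics, not its clinical accuracy.

## Problem sizes

The test suite and acceptance script run phantoms at 48³–64³ voxels
with 2–4 filter scales — sizes at which every stage's behaviour
(thresholding statistics, connectivity, containment) is already
representative while the whole suite stays fast; clinical volumes are
larger but change nothing structurally, since every operation is
linear or near-linear in voxel count.

## Known limitations

- Otsu assumes a meaningfully bimodal response histogram; a volume with
  no vessels raises a degenerate-histogram or empty-ROI error rather
  than guessing.
- The auto-`c` rule adapts the structureness weight to each volume, so
  responses are not comparable across volumes unless `c` is fixed.
- Losses are binary foreground/background only; no gradients are
  provided (the functions are for analysis and verification, not
  training loops).
- HD95 is voxel-centre based; sub-voxel surface positioning is out of
  scope.
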