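# Methods

This note documents the models and procedures `prolifatlas` implements, the
parameters that matter, what the synthetic cohorts do and do not emulate,
and the numerical choices made where the design was genuinely open.

## Data model and conventions

Volumes are dense 3D arrays indexed `(x, y, z)` — x left→right,
y posterior→anterior, z inferior→superior — with world coordinates in µm at
voxel centres (`origin + index·spacing`, 0-based, NIfTI-style). Tissue
labels are fixed small integers: 0 background, 1 mesenchyme, 2 neural
ectoderm; majority voting and masking rely on this stable encoding. TIFF
stacks carry spacing in a `<name>.spacing.json` sidecar because TIFF
z-spacing tags are unreliable across writers.

Anisotropic→isotropic conversion emulates light-sheet acquisition geometry
(e.g. 5 µm slice interval at 0.9 µm in-plane). The output depth is
`ceil(extent / target_spacing)` — never truncating tissue — and the default
isotropic target is the in-plane spacing.

## Phantom cohorts

The generator produces the study design the pipeline expects: four
half-day age groups, five specimens each, staged by tail-somite count, with
per-specimen pose variation (±3° rotation, 2% size s.d., small shifts),
label-boundary jitter, and landmark jitter.

Geometry is a superellipsoid head (exponent 2.5) with an interior
neural-ectoderm core and three spheroid prominence lobes — a midline
frontonasal analog and a mirrored maxillary pair. Growth is analytic:
each lobe's radius scales by a per-stage factor (default 1.15) about a
fixed centre, so the added-voxel shell, the expanding region (the lobe
interiors, where the analytic volume-change factor is `g³ > 1`) and the
per-stage landmark positions are all known in closed form and serve as
oracles for registration, VBM and correlation recovery.

Nuclei are a thinned hard-core point process: a 3-voxel lattice with
±0.5-voxel jitter, 90% retention, stamped as 7-voxel blobs inside tissue.
Proliferating cells are whole nuclei selected with probability
`base_prolif_fraction` (default 0.16, inside the reported 14–18% range),
elevated by Gaussian hotspot fields anchored to the growing prominences
(default peak excess 0.10–0.12; enrichment experiments use 0.16, i.e.
double the base rate). All random draws are made on one half-grid and
reflected, so a phantom with zero jitter and identity pose is exactly
midplane-symmetric — including the stochastic cell maps — which the mirror
invariants test. One subtlety this forces: the site lattice is offset half
a step from the midplane, since an even grid has no centre voxel to hold a
midplane site.

What the phantom does **not** emulate: imaging artifacts (blur, signal
loss, refraction), nucleus texture, segmentation errors, or biological
asymmetries. Passing tests therefore demonstrate that the *pipeline*
recovers known spatial statistics from segmented maps, not that any
segmenter would produce such maps from raw light-sheet data.

## Registration

Landmark rigid and similarity transforms use the closed-form SVD
absolute-orientation solution (the similarity variant adds one uniform
scale); noiseless fixtures are recovered to RMS < 1e−9 µm. Head (5-point)
landmarks drive the rigid within-group alignment; face (37-point)
landmarks drive the similarity (size-removing) alignment used for
bulk/differential analyses. Size is removed only in the similarity chain
and in GPA — the atlas-stage chain is rigid+affine without explicit
scaling — so size is never removed twice.

Groupwise affine registration is an iterated-mean scheme: the mean starts
as the reference specimen; each volume is registered to it by
multi-resolution (4 levels) mean-squared optimization of the float-cast
label image with linear interpolation, resampled nearest-neighbour, and the
mean is recomputed by per-voxel majority vote, until the mean's
label-change fraction falls below 1e−3 (≤10 outer rounds). The optimizer is
regular-step gradient descent (learning rate 8, minimum step 1e−8,
relaxation 0.8, scales from physical shift); on the known-affine recovery
experiment (one 64³ phantom under 10 random affines, scale 0.9–1.1,
rotation ≤10°) this restores pairwise label Dice ≥ 0.95. Iteration counts
are desk-scale (hundreds per level, not tens of thousands) and
configurable.

Nonlinear registration is symmetric-forces demons on the smoothed label
floats over a 3-level pyramid with Gaussian field regularization. The
smoothing σ is **2 voxels** (ITK interprets the demons standard deviation
in voxel units): on the scaled-sphere oracle (sphere → 1.1× sphere,
analytic mean J = 1.331) σ=2 recovers 1.296 and σ=3 only 1.273, so 2 is
the default; larger σ trades volumetric accuracy for smoothness. A
diagnostic warns when J > 0 on fewer than 99% of tissue voxels.

Jacobian fields are computed in-package as `J = det(I + ∇u)` with central
differences in the interior and one-sided stencils at borders; tests check
the uniform-scale closed form (s³ to 1e−6), an independently assembled
finite-difference oracle (1e−10), and SimpleITK's
`DisplacementFieldJacobianDeterminant` as a third opinion.

## Atlases and heatmaps

Per-age tissue atlases are per-voxel majority votes; ties break to the
highest label code, making atlases deterministic and order-invariant.
Proliferation heatmaps are centred box-filter means of the binary
proliferating map with shrinking windows at borders (values remain true
in-grid means), normalized by clipped linear rescaling between the 1st and
99th in-tissue percentiles (so P1→0, P99→1, invariant to positive affine
rescaling of the raw densities; a constant map degenerates to zeros). Group
atlases average each specimen with its mirrored copy, making them
left–right symmetric by construction.

The density window is 0.15 mm for real-scale volumes (the acquisition
protocol's scale). The phantom head is ~0.5 mm across — roughly a fifth of
a real embryo head — so phantom experiments use a proportionally scaled
40 µm window; at 0.15 mm the window would span an entire phantom prominence
and average the hotspot signal away.

The face mask keeps voxels labeled mesenchyme in strictly more than 30% of
the registered segmentations, restricted to a 0.39 mm surface shell
(distance to the primary mask's own boundary, with out-of-grid treated as
background); an optional ROI file replaces the interactive manual
refinement step. The mutant-prominence mask votes first, then closes with
a 40³-voxel cubic element (implemented as padded separable max/min filters
with the erosion origin reflected for even sizes — verified against
`binary_closing` — so closing is idempotent and exact), then applies the
same shell rule.

## Voxel statistics

Differential volumes code, per voxel, +1 where a (size-removed,
similarity-registered) specimen has mesenchyme and the previous-age atlas
does not, −1 for the reverse, 0 for agreement. The shape–proliferation
association is the Pearson correlation of these codes with the
previous-age proliferation atlas inside the face mask, reported per
specimen with |r| for group summaries.

VBM t-maps are one-sample t statistics of log J against 0 (df = n−1;
positive t = expansion; a two-group Welch option exists). The log makes
expansion and contraction symmetric; raw-J mode is available. The analysed
domain is the union of the two stages' tissue, so voxels a stage grows
*into* participate. The default significance threshold is the one-sided
Student quantile at α=0.05; a direct `t_crit` override is exposed because
printed thresholds in the source analyses are not derivable from the
stated degrees of freedom. Zero-variance voxels are masked, not NaN-ed.

The random-mask null draws R=100 equal-size voxel sets uniformly without
replacement from the universe mask, records their mean proliferation, and
reports the empirical p with the +1 correction plus an "outside the null
range" flag (observed above every null mean). Sampling is voxel-wise, not
contiguity-preserving, mirroring a null of randomly sampled t-values. Under
zero hotspot excess the p-values are calibrated (super-uniform); at double
excess the expanding-prominence mean exceeds every null draw in ≥90% of
specimens.

A caveat on the demons-based t-map: with field smoothing σ the top-|t|
band straddles the previous-stage boundary with width ~2σ, while the
analytic added-voxel shell is only 1–2 voxels thick at the test
resolution, so top-|t| concentration is asserted against the
smoothing-matched (2-voxel-dilated) shell (≥70%, versus a ~3% chance
level) rather than the raw shell.

## Morphometrics

GPA centres, scales to unit centroid size, and rotates configurations to an
evolving mean (convergence 1e−8); alignment is reflection-free. PCA is a
centred SVD with each component's largest-magnitude loading forced
positive, removing sign ambiguity. Two-block PLS takes the SVD of
`X'Y/(n−1)` between the column-centred proliferation block (X) and shape
block (Y); the reported r is the Pearson correlation of the first latent
pair. The permutation test shuffles specimen rows of the proliferation
block with the shape block fixed (the geometric-morphometrics convention),
one-tailed, with p = (#{stat_perm ≥ stat_obs}+1)/(n_perm+1) and z the
normal-theory standardization against the permuted distribution; an
exhaustive mode enumerates all n! permutations for small n and then
reports the exact enumeration p. The default permutation statistic is the
leading cross-covariance (first singular value), not the latent r: with
far more voxel features than specimens the latent correlation of *any*
two blocks saturates near 1, so an r-based permutation test has
essentially no power in the voxel-block regime, while the singular value
carries the signal. An r-based variant remains available
(`perm_stat="correlation"`); both are exact permutation tests and type-I
calibrated. PLS r is deliberately *not* claimed
invariant to column rescaling (covariance-based PLS is scale-sensitive);
it is invariant to global rotations of the shape block, which is tested.

The SVM genotype test z-scores the first five PC scores, fits a linear SVM
(hinge loss, C=1, ≤10,000 iterations; the dual formulation, since liblinear
supports hinge only in the dual) with the wild-type class as positive, and
evaluates accuracy and F1 on the training task — deliberately optimistic,
matching the small-cohort design it reproduces, and stated as such. The
permutation test refits under shuffled labels; with 1000 permutations the
smallest attainable p is 1/1001.

Stage residualization regresses each feature column on tail-somite count
(OLS) and returns residuals; the somite-14 boundary splits cohorts into
the younger (≤14) and older (≥15) groups used for within-group analyses.

## Problem sizes and tolerances

Tests run phantoms at 64³ (8 µm voxels; same 0.5 mm world extent as the
128³/4 µm default) with 3–5 specimens per group, chosen as desk-scale
sizes that keep every statistical check well-powered; the reproduction
script runs the full 4-stage × 5-specimen cohort at 96³. Monte-Carlo
assertions use seeded generators with tolerances set from binomial/normal
error at the simulated sizes (e.g. rejection-rate bands of ±2 Monte-Carlo
s.e.). Known limitations: the groupwise mean is voxelized (majority vote),
bounding achievable Dice at coarse grids; demons accuracy is limited by
its smoothing scale; and percentile equalization is undefined on constant
maps (mapped to zero by rule).
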