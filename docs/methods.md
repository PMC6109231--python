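# Methods

This note records the models, conventions, numerical choices, and known
limitations behind `shotgunem`, in the order data flows through the package.

## Complexome mapping and the similarity hierarchy

A complex database is a list of named subunit sets over an opaque accession
namespace (no identifier resolution is attempted).  Candidate filtering keeps
complexes whose identified-subunit fraction is at least `min_coverage`
(default 0.5, inclusive).  Relatedness between complexes A and B uses the
directed overlap score S(A, B) = |A ∩ B| / |A|; the score is asymmetric by
design — a sub-complex scores 1 toward any complex containing it while the
parent scores |A|/|B| back — which is what lets thresholding recover
subset-into-superset hierarchies.  The grouping rule connects a pair when
**either** direction reaches the threshold (default 0.9, inclusive), then
takes undirected connected components; components of size ≥ 2 are groups,
singletons are "unique".  Nothing in the directed-edge set forces a
particular direction convention for grouping, so the either-direction rule is
a package decision: it is the weakest rule that never splits a
subset/superset pair.  All orderings are lexicographic by complex id so
outputs are byte-stable.

## Label-free quantification

NSAF_i = (SpC_i/L_i) / Σ_j (SpC_j/L_j): spectral count over protein length,
normalised to sum to one across identified proteins.  Top-3 abundance is the
mean of a protein's three largest peptide areas; with fewer than three
peptides the available areas are averaged, and a protein with none scores 0 —
both choices consistent with the zero-imputation rule below.  Complex
abundance is the mean of a per-protein measure over **all** defined subunits,
with subunits not identified contributing zero; this deliberately couples
abundance to coverage, since a complex missing half its subunits should rank
below a fully observed one of equal intensity.  The two methods are compared
by Pearson correlation on raw (not log) abundances; a log option exists but
is off by default.  Stoichiometry between two assemblies is the ratio of
mean per-protein abundance over their subunit sets, again with zero
imputation.

## Synthetic data: what it emulates and what it does not

The generators define the study conditions for every test in the package.

**Complex databases.** `make_complex_db` draws base complexes from disjoint
accession pools, so inter-group similarity is exactly zero and group recovery
has an unambiguous ground truth.  Variants remove at most 10% of a parent's
subunits or add one pool subunit, guaranteeing a ≥ 0.9 similarity in at least
one direction.  True abundances are log-normal (location 0, scale 0.5) —
a generic heavy-tailed choice — and protein lengths uniform in 150–1200
residues.

**MS observation.** Expected spectral count per protein is
`count_scale × (summed abundance of complexes containing it) × length/1000`;
observed counts are Poisson; a protein is reported only if its count exceeds
`detection_floor`; peptide areas are log-normal with location log(expected
count) and scale `peptide_area_sigma`.  This reproduces the qualitative
features the pipeline must cope with — length- and abundance-dependent
counts, detection dropout, heavy-tailed areas, shared subunits — but no
spectrum-level physics (no ionisation efficiency, missed cleavages, or
peptide-specific response), so quantitative MS biases are out of scope of
what passing tests show.

**Phantoms.** Four parametric shapes at a stated diameter: a uniform ball; a
barrel of two stacked annular rings with a central channel; the same barrel
with a substantial off-axis rectangular cap on one end (~25% of particle
mass, echoing a regulatory particle docked on a protease core — large enough
that side and top views are distinguishable at 30 Å scale, and breaking both
the z-mirror and the axial rotational symmetry); and seven Gaussian blobs on
a circle, exactly C7 about z.  Shapes are smoothed with a 1.2-voxel Gaussian
so that trilinear interpolation of rotations is well behaved.

**Rendering.** Particle orientations are uniform over SO(3) (uniform in-plane
and azimuth angles, cos(tilt) uniform in [−1, 1]); shifts are integer pixels
in a square window; noise is i.i.d. Gaussian.  Protein is high intensity on a
dark background throughout the package (negative-stain appearance after
standard display inversion).  Micrographs place particles by rejection
sampling with a minimum-distance constraint and a hard 10,000-attempt cap.
No CTF, stain depth, or detector model is simulated; SNR in tests is defined
as mean noiseless-projection variance over noise variance.

**Pseudo-atomic rings.** `make_ring_structure` builds Cn rings of uniformly
scattered point atoms with a stated outer diameter, standing in for
ring-forming oligomers at chaperonin (135 Å) and protease-ring (115 Å)
scales where real crystal structures are not bundled; it exercises the
rasterize → low-pass → measure chain with a known answer.

## Volume numerics

Volumes are cubic, even-sided, indexed (z, y, x), rotation centre at voxel
N/2.  Euler angles (rot, tilt, psi) are intrinsic ZYZ in degrees, rotating
reference into particle frame; with this convention the first angle is an
in-plane rotation of the projection, and the (tilt, psi) pair fixes the
viewing direction.  Shifts (dx, dy) displace the projected image.  MRC I/O
goes through gemmi and writes mode 2 (float32) with the fast axis x.

* **Rasterization**: every non-hydrogen atom contributes a unit-weight 3D
  Gaussian of σ = 2 Å (splat + sum-preserving blur); the σ is immaterial in
  shape terms once maps are filtered to tens of Å and is stated for
  reproducibility.
* **Low-pass**: raised-cosine Fourier edge, gain 1 below f_c − w and 0 above
  f_c + w with f_c = 1/resolution and w = two Fourier-pixel widths; DC is
  untouched so means are preserved; resolutions at or below Nyquist are
  rejected.
* **Projection**: trilinear rotation then z-sum; mass is conserved to
  interpolation tolerance (≤ 0.5%).
* **Back-projection**: un-shift, smear along the viewing axis, trilinear
  accumulation, voxelwise normalisation by an identically smeared weight
  volume clamped at 1e-6 of its maximum.  Deliberately unfiltered — adequate
  for consistency scoring and toy fidelity (a ball reconstructs at cc ≈ 0.91
  from 200 projections), not for resolution claims.
* **Rigid alignment**: exhaustive ZYZ grid (poles collapse the degenerate
  angle), translations solved per rotation by FFT cross-correlation at
  integer voxels; sub-voxel refinement is out of scope at 30 Å.  The reported
  score is the masked map-to-map correlation at the optimum.
* **Masked correlation**: the comparison mask is taken from whichever map has
  the larger support — more voxels above 3× its MAD-based robust σ — so the
  region of computation always covers the bigger structure.
* **Ring diameter**: circularly averaged radial profile of the top view;
  diameter = 2 × the largest radius where the profile still reaches 20% of
  its maximum.  The 20% rule is a package decision (no field-standard rule
  exists); after a 30 Å low-pass it biases outward by roughly one smoothing
  half-width (~8 Å on a sharp annulus), which is why diameter-based
  identification is quoted at ±10 Å.

## 2D classification and identification

The classifier is a deterministic multireference-alignment / k-means hybrid:
seeded random partition; per iteration, every particle is aligned to every
class average over a grid of in-plane rotations and integer shifts (circular
FFT cross-correlation, normalised after mask-weighted mean subtraction so
scores are invariant to affine intensity rescaling), assigned to its best
class, and averages are recomputed from the aligned members; empty classes
are reseeded from the worst-fitting particles; ties go to the lowest class
index.  This is **not** a regularized-likelihood (Bayesian) classifier as
used by the mainstream packages — there is no noise model, no marginalisation
over poses, and no resolution control — but it is adequate in the noise
regimes of the synthetic data (purity 1.0 noiseless, ≥ 0.99 at SNR 1 on
two-shape mixtures).

Class identification matches each average against a reprojection library
under a soft circular mask (radius 0.45 × box, cosine edge).  Identification
works on distinctive views: a flat ring seen down its axis or a capped
barrel from the side.  Side views of a ring and of a barrel are both
elongated stripes at 30 Å scale and are not claimed separable; counting by
state therefore keys on caller-supplied class labels (e.g. from matched
side-view classes), mirroring practice of counting side views only.
State-count ratios come with exact Clopper–Pearson 95% intervals.

The DoG picker band-passes with σ = r/√2 at the two radii, keeps local
maxima above `threshold` × response σ, and suppresses weaker peaks within
`min_distance`.  Junk filtering beyond an optional correlation floor is not
modelled.

## Model-error scoring

E = 2/(1/R + 1/T) combines quantities in different units (degrees, pixels)
literally; the subsequent min–max normalisation onto [1, 2] (order-
preserving, endpoints pinned) is what should be interpreted.  Real and null
scores are normalised jointly; the KS statistic is invariant to any shared
monotone transform, so this choice cannot affect D.

R and T are estimated by **split-half, noise-perturbed realignment**: split
the model's particles into seeded random halves, back-project each half with
the model's orientations, then realign every particle to both half-volumes
by exhaustive projection matching — each realignment on an independently
re-noised copy of the particle (noise σ = per-image background standard
deviation outside the central 0.45-box disc).  R is the median geodesic
angle between the two recovered rotations (optionally minimised over a
declared Cn point group, since poses differing by a symmetry operator are
equivalent); T is the median shift distance.  Both are floored at the search
grid's resolution (half the angular step; half a pixel).

The noise perturbation is essential and is the package's own refinement of a
plain split-half comparison: without it the statistic measures
reproducibility, and a featureless model whose two half-maps are
near-identical realigns "consistently" through the particle's own noise —
random-particle null models then score as well as real ones.  Re-noising
decorrelates the two realignments exactly when the alignment landscape is
flat, which is what "poor accuracy" means; the procedure is operationally
close to accuracy estimation by probing alignment stability under noise in
the mainstream refinement packages.  The definition is validated by its
discrimination property (real vs null KS D = 0.9–1.0, p < 0.001 at 10
models per side under the default study conditions), not claimed to
reproduce any package's numerical accuracies.

Null models sample particles without replacement (fresh seeded sample per
model), refine from a supplied reference (default: a soft-edged sphere) for
a fixed 3 iterations of projection matching and back-projection, and are
scored identically to real models.

## Problem sizes

Tests and the acceptance script run at deliberately small scale, chosen so
the full pipeline remains exhaustive-search exact: 32-px boxes at 6 Å/px
(128-px at 3.6 Å/px for pseudo-atomic rasterization), 30° angular grids for
3D work and 10–15° in-plane for 2D, stacks of 120–1,000 particles, 10 + 10
models of 60 particles for the KS comparison, and 200-replicate Monte-Carlo
checks on the MS side.  At these sizes the whole test suite and the
acceptance script each complete in minutes on one CPU.

## Known limitations

* No CTF, no Fourier-space (gridding) reconstruction, no FSC/resolution
  estimation, no B-factor handling; reconstruction quality statements are
  correlation-based and toy-scale.
* The 2D classifier and the projection-matching refiner are grid-exhaustive
  and deterministic; they do not marginalise over poses and will not match
  likelihood-based tools on hard (low-SNR) data.
* Euler-space accuracy comparison is identifiable only up to the particle's
  point group; continuous symmetries (the plain barrel about z) make R
  meaningless, and a Cn register finer than the angular grid (C7 on a 30°
  grid) degrades it — the discrimination experiments therefore use the
  asymmetric capped-barrel phantom for same-structure model sets.
* MS simulation is generative plumbing, not an instrument model; conclusions
  about real spectra require real data.
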