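# Methods

This note documents the models, parameter choices, and numerical decisions
behind `packfrac`, in the spirit of a methods supplement: what is computed,
under which assumptions, and what the synthetic validation does and does not
establish about real data.

## Coordinate and image conventions

Physical coordinates are right-handed, in micrometers, with z = 0 at the
glass substratum.  Image arrays are indexed `[z, y, x]`; voxel `(k, j, i)`
covers the half-open box `[i·dx, (i+1)·dx) × [j·dy, (j+1)·dy) × [k·dz,
(k+1)·dz)` and is represented by its center.  The default analysis voxel is
0.2 × 0.2 × 0.5 µm — a typical 40× confocal sampling with axial anisotropy;
it is a package default, not a measured constant, and every operation takes
the voxel geometry explicitly.  All distances, ball discretizations, and
EDTs use physical spacings, never voxel counts.

## Synthetic scenes

Cells are spherocylinders (capsules): endpoints p0, p1 and radius r, volume
πr²·|p1−p0| + (4/3)πr³.  Rods are the generic bacterial shape and exercise
anisotropy in every downstream metric; the two default species differ in
size (a short 0.35 × 1.2 µm *Vibrio*-like rod, modeled straight, and a
0.40 × 2.0 µm *E. coli*-like rod).  Scenes are static snapshots — no growth,
hydrodynamics, or phage diffusion is simulated; time courses are built as
sequences of scenes.

Regions of a scene carry a target biovolume (packing) fraction, realized by
two placement modes:

- **Loose (target ≤ 0.55): overlap-tolerant random sequential addition.**
  Candidate cells are drawn with uniform random position and isotropic
  orientation, constrained to lie fully inside the domain.  The minimum
  axis–axis separation starts at r₁ + r₂ (hard non-overlap) and relaxes in
  stages (× 0.9, 0.8, … 0.5) whenever 300 consecutive candidates are
  rejected.  Strict RSA jams near fraction 0.38 for rods, well below the
  packing of real segmented biomass, where touching and partially merged
  cells are the norm; bounded overlap is therefore a model of segmentation
  unions, not a numerical shortcut.  The realized union fraction is tracked
  on an occupancy grid of pitch r/3 and placement stops at the target, so
  the realized fraction matches the target to within one cell increment.
- **Dense (target > 0.55): jittered hexagonal lines.**  Lines of
  pole-to-pole cells (consecutive cells share an axis endpoint, keeping the
  union a continuous capsule) run along the region's longest axis and are
  hexagonally packed in the orthogonal cross-section.  The lattice spacing is
  solved by bisection of a coverage model (2D disc-union coverage of the
  finite cross-section, integrated along the line with end-cap correction)
  so that the union fraction hits the target.  Per-line lateral jitter is
  ≤ 0.1 r.  This is the only way static particles reach the > 0.9 packing
  regime of matrix-compacted clusters; random placement cannot, which is why
  requesting placement `rsa` above 0.74 is rejected with a pointer to the
  lattice mode.

The **embedded_basal_layer** architecture places the basal species in the
bottom layer (default 2 µm, capped at 4 µm) and fills the region above with
the overlay species at the region target.  A slab thinner than a few cell
diameters cannot itself reach 0.9 — its feasible maximum is used instead —
but the 6 µm neighborhood of a basal cell is dominated by the overlay, so
basal-cell local packing still lands at the overlay regime (≈ 0.88 median at
overlay target 0.9).

**Rasterization and noise.**  Occupancy (voxel center inside any cell of a
species) is blurred with a per-axis Gaussian PSF, scaled, offset, and
corrupted: intensity = blur(occupancy)·photon_scale + background, then
Poisson, then additive Gaussian read noise.  Defaults: σ = (0.10, 0.10,
0.25) µm, photon_scale 150, background 5, read σ 2.  These emulate
*post-deconvolution* stacks — deconvolution before export is standard
practice in biofilm confocal pipelines — and deliver segmentation recovery
of Jaccard ≥ 0.99 noise-free and ≥ 0.9 under default noise on loose scenes.
Seeding: one `SeedSequence` per stack, spawned per channel, so channels are
independently noisy and the stack is bit-reproducible.

**Ground-truth oracles.**  `true_local_fraction` evaluates the occupied
fraction of a ball (clipped to the domain) by point-in-spherocylinder tests
on a supersampling grid, default pitch 0.1 µm — five times finer than the
axial analysis voxel and the reference for the cube metric (agreement
required within ±0.03).  Phage placement (`excluded_from_dense`) and the
phage-survival filter (`remove_unprotected`) instead use a convolution-based
local-packing field on a 0.25 µm grid, which is orders of magnitude cheaper;
the pointwise oracle cross-checks it in the tests.

## Segmentation

Per-channel thresholding is Otsu by default (parameter-free, reproducible)
or a fixed value; a constant channel raises with advice to use a fixed
threshold.  Cleanup removes 26-connected components below a volume floor and
optionally fills enclosed cavities.  Where several channels exceed threshold
at one voxel, per-species masks are made exclusive by higher
background-normalized intensity, keeping species biovolumes additive; the
joint (merged) mask is the OR of the raw masks, so occupied space is never
double-counted in packing metrics.  No deconvolution is implemented; no
single-cell instance segmentation is attempted (all metrics are mask- and
cube-based).

## Architecture metrics

- **Grid dissection**: foreground voxels binned by floor(center/ℓ) per axis,
  ℓ = 0.8 µm ("node" is read as non-overlapping cube edge, the most literal
  interpretation).  Cubes partition the foreground exactly; ℓ below the
  largest voxel spacing is rejected as unresolvable.
- **Neighborhood fraction**: one value per cube, ball centered at the voxel
  containing the cube centroid.  The ball is discretized once per geometry
  as the set of integer offsets whose center-to-center physical distance is
  ≤ r; counting is integer, so equality with brute-force enumeration is
  exact, not approximate.  The denominator is the in-bounds ball volume by
  default: biofilms touch the glass, and zero-padding would systematically
  depress basal packing — the regime of interest.  `zero_padding` is kept as
  an option for sensitivity analysis.  Fractions are evaluated at the cubes
  of one (focal) species but always against the joint mask.
- **Distances** are surface-gap distances: the minimum EDT value of the
  partner mask over a cube's or object's member voxels, 0 when touching.
  Sub-µm median inter-species distances are only meaningful under this
  definition (centroid distances cannot fall below one cell radius).  An
  empty partner mask yields +inf sentinels, which summaries exclude and
  count.  Both median (mean-of-middle-two for even n) and mean summaries are
  computed, since either convention is defensible for per-image summaries.
- **Shell fluorescence**: mean intensity over the band 0 < EDT ≤ 2 µm
  outside the focal mask; interior voxels are excluded so focal-channel
  bleed-through does not contaminate the partner signal.  Raw intensities
  are used.
- **Mander's coefficients**: M1 = ΣA over {B > t} / ΣA, M2 symmetric, R the
  intensity cross-correlation; the partner threshold defaults to Otsu.  M1
  with the focal segmentation as A and the phage channel as B is the default
  infection/association readout; all three variants are exposed.

## Population dynamics and statistics

Trajectory normalization divides by the biovolume at an explicit baseline
time (the last pre-phage timepoint), with the baseline sample mapped to
exactly 1; a zero baseline is an error, not a NaN.  Titer = count × dilution
/ plated volume (mL); zero counts are flagged with the one-colony detection
limit rather than treated as true zeros.  Resistance frequency
resistant/total distinguishes architectural protection (frequency stays at
the ~10⁻⁵ mutation-supply level) from resistance sweeps.  Adsorption curves
are classified on log10(PFU/inoculum) with a ±0.3 band: within-band
everywhere → no adsorption; leaves the band but never rises > 0.3 above the
running minimum (which includes the implicit unity start) → adsorption only;
otherwise → adsorption then amplification.  The three rules partition all
trajectories.

Technical replicates (separate stacks at randomized chamber locations) are
averaged into one value per chamber; chambers are the n of all tests.
Mann–Whitney U is exact (full labeling enumeration, via scipy's exact
method) for combined n ≤ 16 without ties, otherwise the tie-corrected
normal approximation with continuity correction; Wilcoxon signed-rank drops
zero differences (count reported) and is exact for n ≤ 20 via the full 2ⁿ
sign-flip distribution computed by convolution over midranks — midranks keep
the exact path valid under tied |differences|.  All p values are two-sided;
Bonferroni multiplies by an explicitly stated family size and caps at 1.
Under the null (n = m = 8), the exact test rejects at α = 0.05 with
probability 0.0499 — slightly conservative, as expected for a discrete test.

## What the synthetic validation shows — and does not

Passing tests establish that the measurement chain recovers known ground
truth: generator targets 0.45 / 0.9 re-emerge as cube-fraction regimes
0.3–0.6 and ≥ 0.85; removing unsheltered focal cells shifts median
inter-species distances in the expected directions; colocalization of
sheltered cells with excluded phage puncta is ≈ 0.  The generator does not
emulate real optics in full (no depth-dependent attenuation, no spherical
aberration, straight rods only, no matrix autofluorescence), so these
results validate the *measurements*, not any biological claim about a
particular imaging system.  Problem sizes in tests and the acceptance script
(chambers of 12–22 µm, stacks up to 120 × 80 × 16 voxels, 10⁴ null
simulations) were chosen to exercise every regime at desk scale.

## Known limitations

- Dense placement produces locally aligned cell groups; real dense clusters
  show radial order.  The packing fractions are faithful; the orientation
  field is not modeled.
- Loose placement's overlap tolerance means cell counts at high loose
  targets slightly exceed what hard particles would allow.
- The EDT distance between two masks is voxel-center based; sub-voxel
  surface localization is not attempted.
- OME-TIFF I/O covers single-series CZYX/ZYX stacks, not multi-position or
  multi-timepoint files; time courses are handled as one file per timepoint.
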