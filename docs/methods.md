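# Methods

## Problem

A brain lesion (here, a glioma core `T` or core-plus-oedema `T+O`)
disrupts the white-matter pathways that pass through it.  A *structural
disconnection* (SD) map estimates, voxel by voxel, which territories
lose connectivity because their fibres traverse the lesion.  Two
families of methods exist:

* **Direct (dSD)** — use the patient's own tractogram.  Select the
  streamlines with non-null overlap with the lesion; the dSD value of a
  voxel is the number of selected streamlines passing through it.
* **Indirect (iSD)** — use a population of N normative control
  tractograms.  For each control, mark the voxels visited by control
  streamlines that cross the lesion (a binary visitation map); the iSD
  value of a voxel is the percentage of controls visiting it, a 0-100%
  disconnection probability.

This package implements both, the binarisation rules that make them
comparable, a three-metric comparison framework, cohort statistics and
a threshold-sensitivity analysis, exercised end to end on synthetic
phantoms.

## Geometry and traversal

Volumes live on a `VoxelGrid` (dims, 4x4 voxel-to-world affine, a
left-right axis and a midsagittal plane given as a continuous voxel
coordinate).  Voxel `i` spans the half-open interval `[i-0.5, i+0.5)`
in continuous voxel coordinates; boundary ties belong to the
larger-index voxel.  Streamlines are polylines in world mm (TCK/TRK
files are loaded through nibabel, which normalises the TRK voxel-mm
convention to RAS mm).

The visited-voxel set of a streamline is computed *exactly*: for every
segment, the parameters at which it crosses a lattice plane are
enumerated and each inter-crossing interval is assigned to the cell
containing its midpoint.  This is algebraically an Amanatides-Woo grid
walk, vectorised over all segments of a tractogram, and is
sampling-independent — corner-clipped voxels with arbitrarily short
chords are found.  A streamline counts at most once per voxel no matter
how many of its segments re-enter the voxel.  Portions outside the grid
are clipped silently.  The test suite checks the traversal against two
independent oracles: an exact per-voxel Liang-Barsky interval clip
(set equality) and dense point-sampling at 0.01 voxel steps (which is
one-sided — it can miss sub-step corner chords — and must therefore be
contained in, not equal to, the exact result).

## Direct significance threshold

dSD counts are not comparable across brains without a normaliser.  The
pipeline builds `AvgDensity`: per subject a whole-tractogram track
density map, averaged across the population *excluding each subject's
lesioned voxels from their own contribution* (per-voxel denominator =
number of contributing subjects; voxels lesioned in everyone are set to
0 and flagged), then left-right symmetrised, `out(v) = (in(v) +
in(mirror(v)))/2`, to balance lesion laterality.  A voxel is
significantly disconnected when

    dSD(v) / AvgDensity(v) > t,     t = 0.10 by default,
    grid {0.05, 0.10, 0.15, 0.20, 0.25}

with a strict inequality.  Where `AvgDensity = 0`, any positive dSD is
significant (the ratio is +inf — evidence where the normative density
is null); `0/0` is not.  The indirect threshold is `iSD(v) > 100*t`
with `t = 0.5` by default, grid `{0.3, 0.5, 0.7}`, strict as well.

Instead of seeding a new tractography inside the lesion, the indirect
method filters each control's precomputed whole-brain tractogram to the
streamlines intersecting the lesion and takes their visited voxels; for
a fixed tractogram the supports coincide and the computation is
deterministic.  Registration between template and control spaces is an
affine contract (identity in the synthetic cohort); nonlinear warps are
out of scope, and resampling uses nearest-neighbour for binary data and
trilinear interpolation for continuous maps.

## Comparison framework

Before any comparison an SD map is masked with the lesion that
generated it — lesion voxels are zeroed, i.e. disconnection is measured
outside the causative lesion.  Three metrics are computed per map pair:

* `ΔVol` (cm^3): signed difference of binarised-map volumes,
  `(|A| - |B|) * voxel volume`; antisymmetric in the pair order.
* `Dice = 2|A∩B| / (|A| + |B|)` on the binarised maps; undefined when
  both are empty.
* `Corr`: Pearson correlation of the thresholded *continuous* values
  over the intersection of the two significance supports; missing when
  the intersection has < 2 voxels or either side is constant.

Four pairs are evaluated per patient: two intra-method (`X_T+O` vs
`X_T` for X = iSD, dSD) and two inter-method (iSD vs dSD at fixed
lesion role).  ΔVol and Dice are additionally split into ipsilateral /
contralateral components relative to the tumour side; voxels whose
centre lies exactly on the midplane belong to neither hemisphere (the
conservation check is explicit in the tests), and bilateral tumours are
excluded from the hemispheric analysis.

## Cohort statistics

Metrics are summarised as median [p25, p75] with linear-interpolation
quantiles (recorded in output metadata; missing values excluded
listwise per metric).  Volume contrasts use the unpaired two-sample
Wilcoxon rank-sum test — exact enumeration when the smaller sample has
<= 8 values without ties, tie-corrected normal approximation otherwise
— and metric-vs-lesion-volume relationships the Spearman rank
correlation (Pearson on mid-ranks, t-approximation p).  All tests are
two-sided at alpha = 0.05 with raw p-values; no multiplicity
correction.  The underlying design is within-subject, but the rank-sum
(unpaired) test is used deliberately to match the named procedure.

Threshold sensitivity over the 5x3 `(t_dSD, t_iSD)` grid is quantified
by the normalised range of variation of a metric's median k:

    nRV(k) = 100 * |max k - min k| / |max k|

undefined when the maximal median is zero.  The denominator uses the
absolute value so that nRV is non-negative even when every median is
negative (ΔVol between methods routinely is); for positive maxima this
is the plain max.

## Synthetic phantoms

The generator emulates the data regime the pipeline consumes, not the
MRI physics.  A cohort shares one bundle anatomy — one left-right
crossing bundle plus 2-5 others drawn along the anterior-posterior or
inferior-superior axes, 3-6 bundles in total, each with 200-1000
streamlines as smooth polylines around its centerline with Gaussian
lateral offsets (spread 2-4 mm, optional sagittal bow).  Every subject
(patient or control) instantiates the anatomy with 1.5 mm endpoint
jitter.  The default grid is 48^3 at 2 mm isotropic, symmetric about
the world origin.

Patients additionally receive nested ellipsoidal lesions: core radii
6-12 mm, oedema radii 4-10 mm larger, with the side label (left /
right / bilateral) derived from the core centre's hemisphere (~10% of
tumours are placed on the midline).  Tumour centres are offset from a
bundle core by 0.5-1.5 core radii, so the core clips part of a bundle
and the oedema shell recruits additional streamlines — the regime in
which including the oedema enlarges the detected disconnection, as the
intra-method comparisons assume.

Optional mass displacement pushes streamline points radially away from
the tumour centre with a cosine-ramp decay (maximum 4-8 mm at the
centre, zero at twice the maximal core radius), preserving
connectivity.  Because lesions are segmented on the patient's displaced
anatomy, the oedema mask is carried through the same displacement field
(T+O = core ∪ oedema ∪ displaced oedema, rasterised with 2x
supersampling); displaced peritumoural fibres therefore still traverse
the T+O mask, and the direct map sees the displaced corridor outside
the lesion while the normative atlas cannot — which is what drives the
negative inter-method ΔVol on displaced cohorts.

Ground truth per lesion role is the union of visited voxels of the
bundles that intersect the lesion, with the lesion itself excluded.
All randomness flows through one seeded generator, so cohorts are
bit-reproducible.

What the phantoms do *not* model: dMRI signal formation, tracking
errors (false positives/negatives), infiltrative tumour growth,
Wallerian degeneration, irregular oedema geometry, and nonlinear
registration error.  Passing tests therefore demonstrate the
correctness and internal consistency of the mapping and comparison
machinery under known geometry — not the clinical accuracy of either
method on real data.

## Problem sizes and numerical choices

The reference cohort is 20 patients and 10 controls on the 48^3 grid —
large enough for stable medians and majority votes, small enough that
the full analysis (four maps per patient, four comparisons per scope,
rank-sum/Spearman tables and the 15-cell sensitivity grid) completes in
well under a minute.  The displacement experiment uses cohorts of 6
displaced patients and summarises each with the cohort median of
ΔVol(iSD_T+O, dSD_T+O), sized so the median's sampling noise is small
against the displacement effect.  Ties at threshold boundaries are
resolved by the strict inequalities above; iSD percentages are computed
as `count * (100/N)` so discretisation to multiples of 100/N is exact
in floating point; degenerate statistics (empty overlap, constant
values, all-tied samples) are reported as missing rather than imputed,
and missing values never enter medians or nRV.

## Known limitations

* The indirect method reimplements the disconnectome logic as
  streamline filtering; it is not a bit-level reproduction of
  TrackVis-based seeded tracking.
* Only affine (by default identity) spatial transforms are supported.
* `AvgDensity` is built from the cohort itself, as in the source
  procedure; with very small cohorts it is noisy and the symmetrisation
  halves densities at laterally unbalanced locations.
* Hemisphere decomposition assumes the left-right voxel axis maps
  dominantly onto a single world axis (RAS-like affines).
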