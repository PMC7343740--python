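# Methods

## Image model

An SUV volume is a 3D float32 grid with anisotropic voxel spacing
(dx, dy, dz) in mm; index order (i, j, k) maps to (x, y, z) and the voxel
volume is dx·dy·dz / 1000 ml. SUV values are body-weight normalized and
required to be finite and non-negative; negative voxels in input NIfTI
files (reconstruction/interpolation artifacts) are clipped to zero with a
warning. Masks are binary grids on the same lattice; every operation that
combines a mask with a volume or another mask verifies shape and spacing
and rejects mismatches. Voxel coordinates are 0-based throughout, and
axial crops use half-open slice intervals [z_lo, z_hi) — a deliberate
choice to remove the off-by-one ambiguity a GUI "slider" leaves open.
Volumes in ml are reported to 2 decimals in formatted outputs. DICOM
conversion and SUV computation from injected dose/weight/decay are
upstream of this package: input is reconstructed SUV NIfTI only.

## Segmentation operators

All region growing and component labeling uses 26-connectivity by default
(the standard choice for PET hot spots; 6-connectivity is available for
sensitivity checks). Thresholds compare with ≥, so a voxel exactly at the
threshold is included, and the ≥ 3 ml preselection filter is likewise
inclusive. Ties for a maximum break to the smallest lexicographic index,
which makes every operator deterministic.

**Robust local maximum.** A click with SUV c is grown once at threshold
0.7·c (a single pass on the clicked value, not iteratively re-thresholded
on the running maximum) and the hottest voxel of the grown region becomes
the seed. Consequently two clicks anywhere in a lesion part that is
connected above 70 % of its peak refine to the same seed; clicks in a part
separated from the global maximum by a valley deeper than 70 % of the
clicked value do *not* reach it — the behavior that makes
percentage-of-maximum thresholds sensitive to where a heterogeneous lesion
is clicked.

**SUVpeak.** The paper tradition defines SUVpeak loosely; here it is the
PERCIST-style quantity: the maximal mean SUV in a 1.0 ml sphere whose
center ranges over lesion voxels, sphere membership decided by
voxel-center distance ≤ r(1 ml) ≈ 6.204 mm. The sphere may extend beyond
the lesion (it averages the surroundings of small lesions, so SUVpeak of a
sub-1 ml lesion is well below its SUVmax, and can also fall below its
SUVmean); voxels outside the grid are excluded from the mean. Implemented
by convolution over a crop, which equals the exhaustive all-centers
evaluation.

**Adaptive A50%P.** The background-corrected 50 %-of-peak method iterates

    T = 0.5 · (SUVpeak(mask) − BG) + BG

with BG the mean SUV in a 2-voxel-thick shell starting 1 voxel outside the
current mask (an exclusion mask can remove other lesions from the shell),
and the mask regrown as the connected component of {SUV ≥ T} containing
the seed, starting from a provisional grow at half the seed SUV, until a
fixed point or 10 iterations. The exact background-correction formula of
the original interactive tool is not public; this formula is an explicit,
documented policy and is the natural reading of "50 % of SUVpeak with
local background correction". Non-convergence (the threshold can
oscillate between two masks on strongly heterogeneous lesions) returns
the last mask with a warning note instead of failing, mirroring how an
interactive tool would simply display its current contour.

**Majority vote.** MV(k) is the voxel set selected by ≥ k of the input
masks; MV(1) is the union, MV(#masks) the intersection, and MV2 ⊇ MV3 by
construction. In Workflow A the vote is taken per lesion over the four
base-method masks and the per-lesion consensus masks are then unioned —
the alternative (voting on the total volumes) gives the same voxel set
because the per-lesion masks of one method are unioned anyway; a failed
base segmentation contributes an empty vote.

**Automated preselection.** All 26-connected components of {SUV ≥ 4.0}
with volume ≥ 3.0 ml, ordered by descending volume (ties by lexicographic
centroid) and assigned stable ids; each carries SUVmax, SUVpeak, SUVmean,
volume and TLG. A *region* is any such component; whether it is tumor is
an observer decision.

## Workflows and totals

Totals are always computed on the union of the current masks, so MTV is
invariant to how a voxel set is partitioned into lesions and overlapping
selections are never double-counted. TLG of the union is
SUVmean(union) × MTV(union), identical to the per-voxel SUV sum times the
voxel volume — equal to summing per-lesion TLGs for disjoint lesions and
well-defined for overlapping ones. Failed per-lesion segmentations (click
in background, lesion below a fixed threshold) are retained as failure
records in the result rather than silently dropped.

Interactive editing is replaced by declarative edit scripts (clear region,
crop axial range, add lesion by A50%P seed or manual mask, erase voxels)
applied strictly in order. Workflow C starts from the Workflow B result;
an empty script reproduces it exactly, and the physician check (C2) is a
second script over the C1 state, not a distinct algorithm. Erasing is
idempotent, and adding a mask then erasing it restores the previous
totals.

## Reliability statistics

ICC form is the single-rater two-way random-effects model for absolute
agreement, ICC(2,1) — each MTV comes from one observer — computed from
the two-way ANOVA mean squares, with the F-distribution confidence
interval of McGraw & Wong. If the data carry no variance at all, or the
rater and residual mean squares both vanish (identical observers),
agreement is perfect by definition: the estimate is 1.0 with CI (1, 1)
and a degenerate flag, since the F-based interval is undefined at r = 1.
CI endpoints are interpreted as poor (< 0.5), moderate (0.5–0.75), good
(0.75–0.9) and excellent (> 0.9), reported as a range ("good to
excellent") when the endpoints fall in different bands.

CoV per patient is the sample SD (ddof = 1, configurable) over the k
observer values divided by their mean, in percent; study CoV is the
unweighted mean over patients. In report tables a patient on whom every
observer measured exactly 0 counts as CoV 0 (perfect agreement); a zero
mean with disagreement leaves the row flagged.

Bland-Altman limits use the conventional fixed 1.96 multiplier (not a
t-quantile). Outlier exclusion is never automatic: an explicit list of
pair indices triggers a *second* set of limits reported alongside the
originals. "Shapiro-Wilk" is the normality test applied to the
differences (3 ≤ n ≤ 5000; constant vectors are rejected as degenerate).
Note the test's nominal 5 % type-I error: truly normal differences fail
it about 5 % of the time.

## Digital phantoms

The generator emulates a body-like scan on a 64×64×48 grid with 4 mm
isotropic voxels (≈ 25 × 25 × 19 cm field of view) — sizes chosen so a
full 12-patient × 3-observer study with every method runs in seconds.
Spacing, grid and all levels are parameters; nothing in the algorithms
assumes these defaults. A uniform background (SUV 0.5) carries:

* **uniform ellipsoidal lesions** (SUV 5–20, volumes ~0.5–58 ml),
* **core+rim lesions** (hot core at 60 % of the radii inside a cooler
  SUV 4.5–7 rim),
* **dumbbell lesions**: a small very hot focus (SUV 14–26, r 5–8 mm)
  joined to a larger moderately avid mass (SUV 8–12, r 14–24 mm) by a thin
  bridge at SUV 4.2–5. The bridge keeps the lesion one preselected region,
  but a click on the mass cannot cross it at 70 % of the clicked value, so
  the refined maximum — and hence the 41 % threshold — depends on where
  the lesion is clicked. This is the minimal geometry that reproduces the
  clinical failure mode of percentage-of-maximum thresholds on
  heterogeneous lesions,
* **physiological structures**: brain (SUV 8), bladder (SUV 12) and liver
  (SUV 5) analogues that the preselection picks up and observers must
  clear.

Structures must lie inside the grid and may not overlap (ground truth
stays unambiguous). Noise is additive Gaussian on SUV (SD 0.1), truncated
at 0 — controllable and sufficient to randomize maxima; PET Poisson-like
noise, scanner PSF/partial-volume blur, scatter and anatomical realism
are deliberately **not** modeled. Two consequences for interpreting
passing tests: fixed thresholds (2.5 vs 4.0) behave near-identically here
because there is no blur-driven halo between background and lesion, and
absolute volume recovery is limited only by voxelization, not by the
partial-volume effects that dominate small-lesion accuracy on real
scanners.

## Observer model

Per lesion, the simulated observer clicks the hottest voxel, except that
with probability 0.3 the click targets a random visually avid voxel
(SUV ≥ 4) of the lesion — the "clicked a different part of a
heterogeneous lesion" behavior, set to the rough rate at which commonly
selected lesions showed non-identical segmentations in practice. Isotropic
Gaussian jitter (SD 4 mm) is added and redrawn until the click lands
inside the lesion (100 tries, then the lesion counts as missed). Lesions
below 3 ml are missed outright with probability 0.2. In Workflow B each
preselected region is classified by its dominant ground-truth overlap;
a physiological region is erroneously kept with probability 0.02 (nobody
mistakes the brain for tumor) and a tumor region erroneously cleared with
probability 0.02 (a judgment-call error). For Workflow C the
observer adds, per clicked lesion not covered by the preselection, an
adaptive segmentation from their click. All rates are order-of-magnitude
choices, not calibrated values — no quantitative observer-error rates are
available to fit them.

Click-related draws and edit-decision draws come from two independent
child streams of the observer seed, so Workflow B results are invariant
to the click parameters by construction. A zero-jitter, zero-error model
reproduces the ground-truth decisions exactly, which pins the analytic
upper bound ICC = 1, CoV = 0 for every workflow.

Jitter degrades agreement monotonically only while it stays below the
lesion scale: because clicks are truncated to the lesion interior, very
large jitter makes every observer's click effectively uniform over the
lesion and disagreement saturates and then declines. The monotonicity
property is therefore tested at 0/4/8 mm.

## Study design and seeds

The default simulated study mirrors the reference design: 12 patients,
3 observers, Workflow A with methods {41max, a50p, suv25, suv40, mv2,
mv3}, automated preselection (SUV ≥ 4.0, ≥ 3 ml) for Workflow B, and
manual modification (C1). One master seed spawns per-patient and
per-observer child seeds via numpy's SeedSequence, so any single cell is
reproducible in isolation. Replicate directional experiments restrict to
the methods under comparison (41max, suv40, preselection) to keep 50
replicates within a couple of minutes of CPU time.

## Known limitations

* No partial-volume/PSF modeling: SUV 2.5 vs 4.0 fixed thresholds are
  nearly indistinguishable on these phantoms, unlike on clinical images.
* SUVpeak's sphere definition is configurable but fixed to the 1 ml
  center-distance convention; other conventions (corner-touching voxels,
  fractional weights) will differ near lesion boundaries.
* The A50%P background formula is a documented policy, not a reproduction
  of any proprietary implementation.
* ICC values depend on the between-patient MTV spread of the simulated
  cohort, exactly as they do across clinical cohorts; absolute ICC levels
  from the simulator are therefore not comparable to any particular
  clinical study — directional comparisons between methods on the same
  simulated cohort are the meaningful output.
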