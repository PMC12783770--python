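# Methods

## Phantom SBEM volumes

The phantom emulates what a membrane-targeted peroxidase label looks
like in a backscatter EM stack of inner retina. The array is
section-major `(z, y, x)`; z walks from the ganglion cell layer (GCL)
through the inner plexiform layer (IPL) into the inner nuclear layer
(INL). Each structure is stamped into an 8-bit intensity volume (dark =
labeled) and, in parallel, into a 16-bit label volume that constitutes
exact ground truth (id → class, id → parent neuron).

**Geometry.** Default stack: 240 × 256 × 256 voxels at 150 nm
isotropic (36 µm deep, 38.4 µm field), with GCL/IPL/INL boundaries at
sections 60 and 200. This is a deliberately scaled-down stand-in for a
full acquisition (which runs to ~10³ sections of 20k × 20k pixels at
~5.7 nm in-plane / 50 nm section pitch); the package's physical
bookkeeping (`stack_physical_volume_um3`) is exercised at full scale
analytically, while rendering and segmentation run at phantom scale.
All sizes are configurable.

**Neurons.** Somas are rendered as dark spherical *shells* (membrane
label only, ~0.3 µm thick, padded to stay watertight at the voxel
size); dendrites as filled dark tubes, 0.8 µm radius at the trunk
tapering to 0.3 µm, with varicosities (1.6× local radius) every few
micrometres — mirroring the labeling pattern in which somas show a
darkened membrane while dendrites appear almost completely dark and
carry periodic mitochondria-bearing swellings. Arbors are seeded
recursive random trees: a trunk descends from the soma shell to the
target IPL depth, then branches laterally with angular jitter,
bifurcating `branch_depth` times. Target depths: OFF stratum 0.2,
ON stratum 0.7 (normalized IPL depth, see below); bistratified cells
alternate initial dendrites between both. No biological growth model is
claimed.

**Intensity model.** Background mean 180, strong label 40, weak label
110 (all 8-bit), Gaussian noise of configurable SD (default 12) added
to background and structures alike, clipped to [0, 255]. The weak-label
mean sits midway between strong label and background by design: weakly
labeled dendrites are visibly dark but sit *above* the default
segmentation threshold, reproducing the observed failure mode in which
weakly labeled dendrites escape automatic detection. The ordering
strong < weak < background is enforced.

**Distractors.** Four classes of electron-dense confounders:
lysosomes (spheres, r ≈ 0.25–0.45 µm), mitochondria (in-plane
ellipsoids), nucleoli (spheres, GCL only) — all sized so their z-extent
stays strictly below the section filter (`filter_sections`, default 15)
at whatever section thickness is configured — and Müller-glia-like
processes: thin tubes running along z through the IPL, always spanning
at least `filter_sections` sections, i.e. designed false positives.
Distractors are rejection-sampled with ≥ 2 voxels of clearance from
everything already rendered so they never bridge structures; this keeps
the ground-truth connectivity interpretable.

**Determinism.** One `numpy` generator seeded from the config drives
all placement and noise; identical configs give byte-identical volumes
and truth.

## Segmentation

The chain is threshold → link → filter:

1. `threshold_section`: 4-connected components of pixels strictly
   below `intensity_threshold`, kept if ≥ `min_contour_area` pixels.
   The strict inequality matters for noiseless fixtures: a pixel *at*
   the threshold is background.
2. `link_contours`: contours on consecutive sections (Δz = 1 only) are
   linked iff their (row, col) pixel sets share ≥ `min_overlap`
   pixels; objects are connected components of the link graph
   (union-find). Duplicate pixel claims within a section are an error.
3. `filter_by_extent`: keep objects occupying ≥ `min_sections`
   *distinct* sections. z-extent is the count of occupied sections, not
   `max − min + 1`: it is an object-size criterion, and the linking
   rule cannot produce internal gaps anyway.

Defaults: `intensity_threshold` 80 — between the phantom's strong-label
mean (40) and weak-label mean (110), so strong label segments and weak
label does not; on real data, `calibrate_threshold` sets it to the mean
gray value of user-supplied seed pixels on labeled dendrites (the
fixed-threshold rule), and everything is overridable.
`min_contour_area` 50 px matches nanometre-scale pixels; at phantom
scale (150 nm pixels) a matched value is ~5 px. `min_overlap` 1,
`min_sections` 15.

With `min_contour_area = min_overlap = min_sections = 1` the object
partition equals face-adjacency (6-connected) 3D connected-component
labeling — per-section 4-connectivity plus Δz = 1 overlap *is* face
adjacency. The test suite checks this equivalence against
`scipy.ndimage.label` on 100 seeded binary-noise volumes.

A note on parameter monotonicity: the object count is non-increasing in
`min_sections`, and the contour count in `min_contour_area`, but
raising `min_overlap` removes links and therefore *refines* the
partition — the pre-filter object count is non-decreasing in it.

**Layer assignment and FPR.** An object's layer is that of its z-median
occupied section; for an even section count the lower-z of the two
middle sections decides (documented, arbitrary tie-break). Against
ground truth, an object is a true positive iff ≥ `match_fraction`
(default 0.5) of its voxels fall on dendrite or soma truth voxels;
FPR = FP / (FP + TP) per layer, with empty layers flagged rather than
reported as 0.

Because a soma shell and its dendrites touch, a correct segmentation
returns one object per *connected group* of truth structures; recovery
is therefore scored against connected components of the truth
foreground, not against individual truth ids.

## Morphometry

**Depth convention.** Normalized IPL depth is 0 at the INL border and
1 at the GCL border. The OFF sublamina is depth < 0.4 and ON is
≥ 0.4 — the boundary is configurable; the 2:3 outer/inner split follows
standard IPL stratification conventions, since no numeric boundary is
universal. A cell is called OFF (or ON) when > 0.8 of its IPL dendrite
voxels fall in that sublamina, otherwise ON-OFF; the 0.8 dominance
level is a package choice for a call that is qualitative in practice.

**Sholl (top view).** Dendrite voxels are projected along z; for each
ring radius (default spacing 5 µm) the intersection count is the number
of 8-connected runs of projected-mask pixels on a thin annulus
(half-width 0.75 pixel — wide enough that a digital curve cannot step
across it). Each branch crossing contributes one run; a re-entrant
crossing of one branch still counts once. Profiles are computed on
in-volume voxels only, so arbors leaving the volume give partial
profiles, as they would in a real reconstruction.

**Coverage.** `coverage_fraction` is the fraction of region pixels
covered by the raw binary x-y projection of dendrite voxels — no
dilation; whether published coverage figures used dilated masks is
generally unstated, so the conservative raw projection is used.
`grid_box_coverage` partitions the field into an equal 5 × 5 grid,
excludes boxes whose projection contains any soma voxel, and samples 5
of the eligible boxes without replacement with a fixed seed.

**Soma metrics.** Soma diameter is the equivalent-circle diameter
2·√(A/π) of the largest single-section cross-section (the underlying
published metric is typically unstated; this one is robust for
half-visible somas). Composition metrics are voxel-volume percentages
(nucleus, mitochondria of soma volume) and mitochondria instances per
µm³; organelle voxels must lie within the soma. Phantom somas carry no
organelles (peroxidase does not label them), so composition is
exercised on constructed voxel sets.

**Synapses.** Each synapse must lie within one voxel (Chebyshev) of a
dendrite voxel; offenders are listed in the error. The per-bin synapse
counts over IPL depth are compared with the dendrite depth profile of
the same region by Spearman rank correlation (NaN when either profile
is constant, where ranks are meaningless).

## MEA simulation

Cells are inhomogeneous Poisson processes: constant baseline rate plus,
for responders, a stimulus-locked elevation lasting
`evoked_duration_s` from onset. The elevation follows a Hill-type
saturating function of log10 irradiance
(`max / (1 + 10^(−slope·(log I − log EC50)))`) — a standard
photoreceptor dose-response shape; the exact functional form is a
package choice. Baseline and evoked spikes are drawn as independent
homogeneous processes and merged (superposition), so the generator is
exact, not an approximation. Built-in protocols mirror the two
experimental designs: four 30-s 365-nm flashes (1.17×10¹¹ –
1.02×10¹⁴ photons/cm²/s) and five 30-s 470-nm flashes (4.82×10¹¹ –
9.01×10¹⁵), onsets 120 s apart — inter-stimulus spacing is rarely
published; 90 s of recovery between flashes is typical for slow
melanopsin-range responses. `generate_population` fixes the responder
count to `round(n_cells × fraction)` exactly and records per-cell truth
in generation metadata.

## Response detection

Rates are binned in non-overlapping 1-s bins aligned to stimulus onset;
1 s makes both the 3-s termination rule and the 30-s baseline integral
numbers of bins. The baseline SD is the sample SD (ddof 1) across the
30 baseline bin rates; what the published "+2·SD" is taken over is
ambiguous, and per-bin rates are the only quantity with a meaningful
spread here. Detection: first bin strictly above threshold starts the
response; the response is over at the first run of 3 consecutive bins
at or below threshold (the run is excluded); duration is the
suprathreshold time inside the span, so brief dips neither terminate
nor count; responder ⇔ duration > 1 s. The discharge rate averages the
suprathreshold bins and subtracts baseline.

Two windows bound the scan. The response may *extend* to the next
stimulus onset minus the baseline window (or the recording end). The
response may only *start* within the stimulus window: light-evoked
responses are stimulus-locked, and without this bound the detector's
false-responder rate on baseline-only Poisson cells rises to ~12%
(any chance suprathreshold bin in a 90-s scan can seed a "response"),
which we judged an unacceptable specificity for a detector whose point
is to separate responders from active-but-unresponsive cells. With the
start bounded, specificity loss on baseline-only cells at 1/5/20 Hz is
~9% — inherent to a +2·SD threshold estimated from 30 bins, and the
measured operating point of the published rule rather than a target.

Cell-level dose dependence: Spearman correlation of discharge rate
vs log10 irradiance > 0 with at least 2 responding stimuli. Strict
monotonicity is deliberately not required — Poisson noise breaks it
even for true responders.

## Statistics

Mann-Whitney U: exact enumeration p (via `scipy`'s exact method) when
the combined sample is ≤ 14 with no ties, otherwise the tie-corrected
normal approximation *without* continuity correction, which makes the
two-group case agree with the Kruskal-Wallis chi-square p. Midranks
everywhere. Kruskal-Wallis returns (0, 1) when every observation is
identical (the tie-corrected statistic is undefined there).
Benjamini-Hochberg is the step-up adjustment (via `statsmodels`),
checked in tests against the bare definition. Significance is called at
adjusted p < 0.05.

## Problem sizes and runtime

Defaults keep everything desk-scale: phantoms of ~15M voxels render and
segment in seconds; the oracle-equivalence check uses 100 volumes of
64³; detector calibration uses 200 responder and 1000 baseline-only
cells on 630-s recordings. All are configuration, not limits of the
method.

## What the phantom does and does not show

The phantom has the *statistical structure* the pipeline assumes —
dark connected tubes vs. lighter neuropil, distractors below/above the
section filter, Poisson spiking with stimulus-locked elevations — so
passing tests demonstrate the correctness of the segmentation relation,
the filters, the morphometric estimators and the detector's operating
characteristics. It does not emulate real EM texture (membranes,
vesicles, staining gradients), section artifacts, registration error,
spike-sorting contamination, or biological arbor statistics; absolute
FPR or coverage numbers measured on phantoms characterize the designed
scene, not any real tissue. Known limitations: no gap-tolerant linking
(a fully missing section splits objects); soma truncation at the volume
face is not modeled, so composition percentages are for the rendered
(full) soma; the Sholl annulus method reports crossings, not the
classical distinct-segment count, though the two agree on arbors
without retrograde branches.
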