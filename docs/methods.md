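# Methods

This note records the models, defaults and numerical choices behind
`artseqfish`, and what the synthetic test bed does and does not establish
about behaviour on real microscope data.

## Barcode model and codebook

A barcode is a set of (round, channel) presences with at most one colour per
round and 1–4 slots, one per bridge-probe readout flank. The number of
distinct barcodes over R rounds, C colours and at most S slots is
`Σ_{j=1..S} C(R,j)·C^j`; `codebook.capacity` computes this closed form and is
tested against exhaustive enumeration on all small cases.

`generate_codebook` draws a seeded random permutation of the full barcode
space and keeps candidates greedily subject to a pairwise symmetric set
difference of at least `min_set_difference` (default 2). The margin of 2 has
a decoding consequence used below: no codeword can be another codeword plus
one slot, so a signature missing one slot can never collide with a
*different* target's exact codeword.

The stock synthetic codebook (`default_codebook`) uses 12 targets over
4 rounds × (ATTO488, TAMRA, CY5) with 2–3 slots per target. Channel order is
fixed to green, red, far-red everywhere.

## Probe designer

Lengths are structural constants of the chemistry: padlock probe
84 nt = 18 + 28 + 20 + 18; bridge probe 108 nt = 4·18 + 28 + 4·2; antibody
oligo 46 nt = 10 + 36. Choices the chemistry leaves open:

- **Arm orientation.** The 5′ arm reverse-complements the 3′ half of the
  36-nt target window and the 3′ arm the 5′ half, so the ligation junction
  sits mid-target; this matches standard padlock hybridisation geometry.
  Equivalently `revcomp(arm5 + arm3) == target36`, which is the round-trip
  property tested.
- **GC bounds are inclusive** (45% and 65% both pass); the window search
  returns the leftmost 36-nt window whose two 18-nt halves each pass,
  deterministically.
- **Off-target check** is exact-substring based: the longest substring of
  the probe whose reverse complement occurs in any off-target transcript,
  computed by binary search over shared-substring length and verified
  against an O(n·m·L) exhaustive oracle. Pass means < 13 nt. No melting
  temperature model is attempted; the < 13 nt rule on an 18-nt readout
  is a length cutoff, not a thermodynamic quantity.
- The 28-nt unique sequences, RCA primer and 18-nt readouts come from an
  orthogonal-sequence generator outside this package's scope; the designer
  accepts them as inputs and validates the assembled products.

## Synthetic experiment generator

The generator is the package's test bed and defines the conditions under
which every downstream claim is measured.

**Geometry.** Field of view: 10 z-slices of 256×256 px at 0.325 µm/px and
0.5 µm z-step (larger for benchmark configs). Nuclei are axis-aligned
ellipsoids, lateral radius 3.0–4.5 µm, axial 1.5–2.1 µm, centred mid-stack,
rejection-placed with an 8 µm surface gap. The generous gap guarantees that
every molecule (placed within 1.8 nucleus radii laterally) is strictly
nearest to its own nucleus, so cell-assignment ground truth is unambiguous.
Colony-scale structure (the 750-µm disc) is not rendered as pixels; cell
positions on the full pattern and radially varying counts are generated
separately (`simulate_cell_positions`, `simulate_counts`) without imagery.

**Molecules.** Counts per (cell, target) are Poisson with mean 4.5 by
default (checked by a chi-square goodness-of-fit test at 1000 cells).
Positions are uniform laterally within 1.8 nucleus radii and uniform in
depth. A minimum pairwise 3D spacing of 2.5 px is enforced by rejection
sampling (hash grid; a molecule that cannot be placed after 200 tries is
placed anyway so Poisson counts are never truncated). This models the
amplified rolling-circle products as optically resolvable objects —
empirically the preprocessing chain resolves two equal spots at ≥ 2.4–2.5 px
in any direction — and is the single most consequential idealisation: real
data contain stacked signals that this package handles only through the
one-dropout rescue, not through explicit deconvolution. Passing tests
therefore demonstrate correctness of the decoding logic, not robustness to
heavy optical crowding.

**Optics and noise.** Spots are 3D Gaussians with σ = (0.95, 0.9) px
(axial, lateral) — at 0.325 µm/px the lateral figure slightly exceeds the
diffraction limit, i.e. marginally conservative — amplitude uniform in
400–800 counts on a background of 100, with Poisson shot noise on
signal+background plus Gaussian read noise (σ = 2). The nuclear stain is
rendered per round, drifting with the readout channels, so nuclei are usable
as registration fiducials.

**Negative controls.** `render_negative_control` produces nuclei, noise and
spurious PSF-shaped spots at a configurable per-cell rate per channel, each
in one random round. The default benchmark rate (0.3/cell in the noisiest
channel) sits inside the 0.03–0.5 spots/cell range real negative controls
show. Spurious spots are rendered as genuine PSFs deliberately: a detector
cannot distinguish them morphologically, so false-positive suppression in a
merged stack must come from dilution by true signal — which is the effect
being measured.

**Merging** of two stacks is voxelwise maximum (robust for spot imagery;
addition would double the background).

## Spot detection

The six preprocessing steps (count fixed by contract, content configurable):

1. selective hot-pixel removal — replace a pixel by its per-slice 3×3 median
   only when it exceeds 2.5× that median. A plain median filter flattens PSF
   tops and degrades two-point resolution from ~2.4 px to ~3 px, which is
   why the filter is conditional; the ratio test keeps the step invariant to
   global intensity scaling;
2. per-slice grey top-hat (11 px) background subtraction;
3. lateral Gaussian denoise, σ = 0.5 px (kept small for the same resolution
   reason);
4. Laplacian sharpening `v − 0.6·∇²v`, clipped at zero — empirically sharper
   than a Laplacian-of-Gaussian band-pass at these PSF widths;
5. per-slice median subtraction (background to ~0);
6. rescale by the volume maximum (to [0, 1]).

Steps 5–6 make the candidate threshold (`min_prominence`, default 0.1)
a *relative* quantity: no fixed intensity threshold exists anywhere, and
doubling all input intensities provably leaves the accepted spot set
unchanged (tested). Maxima use a 3×3×3 footprint (`min_distance=1`) with
3-point parabolic subpixel refinement, lateral only — the 0.5-µm z-step is
too coarse to justify axial fitting.

Patch features for the classifier: the peak-normalized 7×7×7 patch, the
lateral radial mean profile at the peak slice, a second-moment width and the
log signal-to-background ratio (351 values). Peak normalization is what
makes classification scale-free. The SVM (RBF kernel, C=10, sigmoid-
calibrated for probabilistic scores) trains on synthetic patches: positives
are jittered rendered PSFs, negatives are noise volumes re-centred on their
own brightest voxel — exactly the maxima that fool a detector. Accuracy is
reported on a stratified 25% hold-out; the model is fit on the training
portion only, so the number is honest.

## Nucleus segmentation and 3D reconstruction

The filter bank crosses {Otsu, triangle} thresholds × Gaussian σ ∈ {1, 2, 4}
px × optional distance-transform watershed (12 combinations; minimum label
area 60 px²). Every label from every combination becomes a candidate with
mask-shape features: log-area, solidity, eccentricity, circularity, extent,
axis ratio and the IoU between the mask and its own second-moment ellipse.
The moment-ellipse IoU is the workhorse — merged, clipped and speckle masks
all deviate from their moment ellipse even when they remain convex. The
quality SVM trains on synthetic ellipse masks vs programmatic corruptions
(merged pairs, clipped halves, dilated speckle, slivers). Intensity
statistics are deliberately absent from the feature set so the model carries
no dependence on staining levels.

Deduplication keeps the best-scoring representative per nucleus per slice,
treating two masks as duplicates when IoU ≥ 0.5 *or* when the intersection
covers ≥ 0.8 of the smaller mask: heavy smoothing in the sweep produces halo
masks that nest the tight mask of the same nucleus at low IoU, and the
containment test is what catches them. Ordering and tie-breaks (score, then
area, then provenance index, then centroid) are fully deterministic.

Reconstruction links labels on slices ≤ 2 apart whose lateral centroid
distance is at most half the equivalent radius of the larger label — a
size-adaptive rule, so no pixel constant needs retuning with magnification.
Components spanning < 3 slices are debris. Missing slices are filled by
linear interpolation of signed distance maps (the interpolation of two
circles of different radii is an intermediate circle, which is the tested
property). Single-nucleus QC uses derived features — slice count, bbox fill
fraction, per-slice circularity/solidity (on slices with ≥ 25% of the peak
area, so erratic pole slices don't drown the body), area-profile valley
depth (targets axially stacked doublets), maximum centroid jump (lateral
fusions and fragments) and axial aspect. On rendered fields the QC accepts
~85% of true single nuclei while the reconstruction count itself is exact;
the rejected cells still claim their own spots in the assignment volume so
their molecules are excluded rather than leaked to neighbours.

## Registration

The global per-round shift maximizes the full zero-padded cross-correlation
of the Otsu-binarized nuclear max-projections. Zero padding matters: plain
FFT phase correlation wraps periodically and aliases large drifts in small
fields. Refinement scans integer shifts in ±3 px and maximizes the number
of round spots within 1 px of a reference-round spot (ties: smaller norm,
then lexicographic); refinement can never reduce the matched count because
(0,0) is in the search set. Registration is 2D-lateral; axial drift is
assumed negligible at a 0.5-µm z-step. Round 0 is the reference.

## Decoding and assignment

Collocation is greedy and brightest-first: each seed collects the nearest
unclaimed detection per (round, channel) within 1.5 px (Euclidean, voxel
units — the axial PSF spans about one slice, so no anisotropy correction is
applied). Every detection lands in exactly one cluster; consensus positions
are intensity-weighted.

Exact signature matches win. A signature that matches no codeword is rescued
as a one-dropout match when *exactly one* codeword is the signature plus one
slot. With the codebook's set-difference ≥ 2 guarantee a dropped signature
can never equal a different codeword, and the rescue declines on ambiguity,
so it cannot misdecode between codewords; it is therefore enabled by
default. This rescue is the package's answer to resolution-limited slot
loss: without it, zero-noise end-to-end recovery saturates near 99%, with it
99.8–100%.

Cytoplasmic assignment uses the distance from the spot to the nearest
nucleus *surface* (via a sampled Euclidean distance transform of the label
volume, anisotropy-aware), not to centroids — centroid distance would
penalize large nuclei. The cutoff is 15 µm; beyond it a molecule is reported
unassigned, never dropped silently. The count-matrix total equals the number
of decoded-and-assigned molecules by construction, with undecoded and
unassigned tallies carried alongside.

## Spatial statistics

The pattern centre is the minimum enclosing circle of the cell centroids
(shapely); the radius defaults to the known fabrication value 375 µm, with
the fitted radius only as a fallback (flagged degenerate when the cells sit
in one clump). Distance-to-edge is clamped at 0 for fit jitter. A cell is
"centre" iff strictly more than 125 µm from the edge; the partition is
exact. Radial profiles use equal-width distance-to-edge bins (default 7)
with empty bins reported as missing, not zero; fold change is
mean(edge)/mean(centre) per target with an explicit "inf" sentinel when the
centre mean is zero. Radial intensity profiles average pixels over the disc
per bin; `normalize=True` divides by the profile maximum.

## Pipeline, seeding and problem sizes

One seed in the run configuration feeds everything, including the synthetic
training material for the three SVMs, so reruns are bit-identical (tested).
The stacks manifest is an explicit JSON map (round, channel) → TIFF file —
no microscope filename parsing. The run manifest records per-stage counts
(monotone along the candidate → accepted → decoded → assigned funnel) and is
written even on failure, naming the failed stage.

Test and benchmark problem sizes are deliberate package choices: unit and
property tests run on 128–256 px fields with 3–10 cells; the drift benchmark
uses 20 trials of ±10 px; the cell-count benchmark 20 seeded fields; the
merged negative-control benchmark a 640-px field with ~100 cells, 0.3
spurious spots/cell in the noisiest channel, averaged over five seeds. These
sizes put the full suite at a few minutes on one CPU while keeping every
statistical claim testable.

## Known limitations

- No explicit PSF deconvolution: stacked signals closer than ~2.4 px merge,
  and the one-dropout rescue is the only mitigation. Quantification in
  heavily crowded real images will undercount.
- The six-step chain and SVM feature sets are this package's own defaults,
  chosen for the synthetic optics; they are configurable but not claimed to
  reproduce any particular production pipeline bit-for-bit.
- Nuclei are ellipsoids with smooth texture; segmentation performance on
  irregular chromatin, mitotic figures or apoptotic morphology is untested.
- Registration is rigid and lateral; chromatic aberration between channels
  and non-rigid tissue deformation are out of scope.
- Detection efficiency against an absolute standard (e.g. single-molecule
  FISH) requires real chemistry and is not simulated; counts are relative.
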