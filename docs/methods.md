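# Methods

`nichemetry` analyzes how a micro-fabricated scaffold's geometry shapes the
spatial arrangement and motility of cells growing in it.  Because no imaging
data is redistributable, every analysis runs on a synthetic phantom with
fully known ground truth; this note describes the models, the conventions
chosen where several were defensible, and what the synthetic results do and
do not establish about real acquisitions.

## Scaffold geometry

The scaffold is a planar array of thin vertical walls extruded 24 µm in Z.
A *unit wall* is 210 µm long, divided by 15 µm cross walls (7.5 µm on each
side of the wall) into seven niche sections: three of 10 µm, two of 30 µm,
one of 50 µm and one of 70 µm.  Four units joined end to end form an 840 µm
wall; the last two units mirror the first two.  Sixteen walls are arranged
in four sets of four with wall separations of 20, 25, 35 and 55 µm,
spanning 520 µm in total.  All dimensions are measured between traced-line
centers; the fabricated line itself is 2 µm thick.

Derived closed forms used throughout:

- chamber footprint = niche size x wall separation (200 µm² for the 10x20
  chamber up to 3850 µm² for 70x55);
- chamber opening = separation − 15 µm (5 µm to 40 µm);
- isotropic niche ratio = min(1, 2 x 7.5 / separation): the fraction of
  *uniformly distributed* material expected within the 7.5 µm contact zone
  of a wall — 0.75, 0.60, 0.43, 0.27 for the four separations.  This is the
  null curve against which wall-contact enrichment is judged.

Conventions the design leaves open, fixed here and configurable in
`ScaffoldParams`:

- the in-wall order of niche sections is (10, 10, 10, 30, 30, 50, 70);
- the twelve in-set gaps account for 405 µm of the 520 µm depth; the
  remaining 115 µm is split equally over the three inter-set gaps
  (≈38.33 µm each);
- chambers are enumerated over the canonical unit (x in [0, 210) µm): one
  chamber per niche section per inter-wall gap, 84 in total.  The other
  units repeat or mirror the same (niche, separation) classes, so analyses
  over the enumerated chambers sample every class; the rasterizer still
  draws the full 840 µm walls.

`rasterize` produces an integer label mask (0 free space, 1 wall material,
2 niche zone) plus an exact per-pixel wall-coverage field (axis-aligned
rectangle overlap), so material areas are available to machine precision
even at coarse pixels where the 0/1 labels quantize.  Pixel (0, 0) is
top-left; pixel centers sit at (i + 0.5) x pixel size.

## Spectra and UV quenching

Lambda-mode acquisition is modelled on two channel grids: 32 channels over
416–687 nm (405 nm excitation) and 23 channels over 494–687 nm (488 nm
excitation).  The nominal 9 nm bin width is inconsistent with those ranges
and counts (32 x 9 = 288 nm ≠ 271 nm), so the actual bin width is derived
from range and count (8.47 and 8.39 nm) with 9 nm kept as metadata.

Endmember spectra are unit-sum weight vectors obtained by integrating a
line shape over the bin edges:

| endmember  | shape                  | default      | rationale |
|------------|------------------------|--------------|-----------|
| scaffold   | wide Gaussian          | 480/220 nm   | broadband photo-initiator autofluorescence spanning all channels |
| nuclei     | Gaussian               | 461/50 nm    | Hoechst-like |
| cytoplasm  | Gaussian               | 515/40 nm    | CF488-like |
| background | flat                   | —            | stray light / medium |

The stain shapes are generator conventions with known ground truth, not
claims about the real dyes.  A wide Gaussian was chosen over a tilted flat
profile for the scaffold because it is physically more plausible and keeps
the endmember matrix well conditioned against the flat background
(cond ≈ 11).

Scaffold autofluorescence quenches under UV as a single exponential
I(t) = I0·exp(−k·t).  The default rate k = ln(1/0.22)/150 ≈ 0.0101 min⁻¹
maps the start intensity to 22% after 150 min of treatment.  `fit_quench`
fits the model by linear regression on log-intensity — the decay is linear
on a log scale, and the closed form makes parameter recovery exactly
testable — rather than by nonlinear least squares.

## Synthetic phantom

`render_stack` renders cells and scaffold into (Z, C, Y, X) stacks matching
the acquisition geometry: 12 slices at 2 µm step, 1.66 µm/pixel, field of
view up to 630 x 520 µm (analyses default to a 210 x 520 µm crop — the
canonical unit — which covers all chamber classes at native resolution).
Cells are 15 µm spheres with concentric 8 µm nuclei; per-slice occupancy is
exact slab integration of the sphere along Z and center-sampled in XY.
Per-voxel expected photon counts are endmember-weighted sums of the source
amplitudes (scaffold 5000/0.22 before quenching, so ~5x the 1000-count
stain brightness after the standard 150 min treatment; background 50);
noise is Poisson shot noise plus Gaussian read noise (sd 2).  Optional
full-well clipping emulates saturation and is off by default.

`place_cells` draws each cell's chamber with probability proportional to
footprint, then makes it a *contact* cell with probability `niche_bias`:
contact centers are uniform over the niche zone eroded by the nucleus
radius (so the nucleus — the compact marker scored downstream — lies wholly
inside the 7.5 µm zone), interior centers are uniform over the whole
chamber.  Three details matter for unbiased statistics and were chosen
deliberately: the chamber and the contact decision are kept fixed across
rejection retries (otherwise crowding converts contact draws into interior
ones, class-dependently); non-overlap is a 3-D nucleus-center distance of
8 µm (an XY-only exclusion depletes interior cells near crowded wall
strips); z is uniform over [r_nuc, height − r_nuc].

`simulate_timelapse` moves cells in fixed-length, uniformly directed steps
per 65 min interval (6 timepoints ≈ 5 h 25 min), with region-dependent step
scales if requested.  Steps whose straight path touches wall material are
redrawn (up to 25 times, then the cell stays), so walls are never crossed;
the per-interval displacement equals the step scale exactly in free space,
which makes motility recovery testable.  The default 5 µm/interval is of
the order of reported epithelial cell motility (~10 µm/h) after confinement.

What the phantom does *not* model: optical point-spread and confocal
sectioning physics, excitation cross-talk between the 405 and 488 stacks,
cell deformation, division or death, Z-directed migration, and detector
saturation artefacts.  Passing tests therefore establish that the analysis
chain is correct and unbiased on geometrically faithful data, not that it
is robust to every optical artefact of a real microscope.

## Spectral unmixing

Per voxel, the measured spectrum y is decomposed as y = E·a with E the
(channels x 4) endmember matrix.  `unmix` offers ordinary least squares
(exact on noiseless mixtures; used by oracle tests) and non-negative least
squares (the default — abundances are material amounts).  The NNLS solver
exploits the small fixed endmember count: in normal-equation form it
enumerates all 2⁴−1 candidate active sets, solves each restricted system
for every voxel simultaneously with dense linear algebra, and selects per
voxel the support satisfying the KKT conditions.  It matches
`scipy.optimize.nnls` to 1e-7 voxel-by-voxel and unmixes ~500k voxels per
second.  No spatial regularization and no per-slice rescaling is applied;
unmixing is strictly per-voxel, so voxel order is irrelevant.

Endmember estimation averages the spectrum over user-supplied ROIs and
normalizes to unit sum.  An ROI drawn over cells yields a stain + cytoplasm
+ background mixture — documented behaviour, flagged when it drives the
endmember matrix toward ill-conditioning (condition number > 1e3).

## Packing statistics

Per chamber and per cell endmember, abundance is summed over the full
12-slice height, normalized to the 200 µm² reference chamber
(density = total x 200 / footprint), and split into contact material (pixel
center within 7.5 µm of a bounding wall centerline) versus free space.
Abundance on wall pixels counts as contact material in both numerator and
denominator: signal overlapping the traced line is material pressed against
the wall, and excluding it systematically deflates measured ratios by up to
the full tolerance of the parameter-recovery checks.  Replicate chambers of
one class aggregate abundance-weighted (pooled niche / pooled total).

Non-negative unmixing leaves zero-truncated noise on empty voxels; summed
over the large free areas of wide chambers it biases ratios toward the
plain area fraction.  `sum_per_chamber(threshold="auto")` therefore zeroes
voxels below a robust noise floor (median + 5 x MAD of the positive
values) before summation; the default `threshold=0` keeps sums exact for
noiseless or ground-truth input.

With these conventions the full chain (place → render → unmix → pack)
recovers the analytic mixture b + (1−b) x isotropic ratio of the seeded
niche bias b to within 0.05 per separation class (200 cells, 10 seeds,
nuclei endmember).  The residual systematic error is real physics of
extended emitters: an 8 µm nucleus whose center is excluded from the 2 µm
wall line cannot reproduce a point statistic exactly.

## Tracking and motility maps

Each time-lapse stack is split into a bottom partition (first 7 slices,
14 µm — one cell height above the substrate) and a top partition (last 5
slices, 10 µm), each reduced by maximum-intensity projection (mean
available).  Nuclei are detected by Gaussian smoothing (σ = 1 px), Otsu
thresholding, an area gate of 0.25–4x the nominal nucleus cross-section,
and intensity-weighted centroids.

Linking is the single-parameter greedy tracker: each track's next position
is the nearest unclaimed detection within N pixels (default N = 10 =
16.6 µm at 1.66 µm/px, about one cell diameter); each detection feeds at
most one track; a track with no candidate ends.  Pass 1 seeds from the t=0
detections in input order and advances tracks timepoint-major in seeding
order (deterministic conflict resolution; ties break to the lowest
detection index).  Pass 2 re-seeds from the earliest detections left
unclaimed.  Tracks spanning fewer than 5 consecutive timepoints are
discarded.  On configurations where cells stay more than 2N apart the
greedy result provably coincides with the exhaustive minimum-total-distance
matching, which the tests verify against a brute-force oracle.

Gradient maps deposit each track's total path length as Gaussian bumps
(σ = 5 px, truncated at 3σ) around its positions; overlapping deposits
combine by maximum and the field is clipped at a display maximum of 30 µm.
The kernel shape is a rendering convention; tests assert field maxima, not
shapes.  Frame alignment against the scaffold channel is integer-pixel
phase correlation (`estimate_shift`/`apply_shift`); the generator emits
pre-aligned frames, so registration is exercised with injected shifts.

Motility summaries assign each track to the wall set containing its t=0
position (elsewhere: the planar control region) and report track counts,
mean/max total distance and the fraction starting in a niche zone, which
for uniform seeding matches the isotropic expectation within binomial
uncertainty.

## Problem sizes and numerical notes

- Analyses and tests run on the 210 x 520 µm unit-1 crop (127 x 313 px,
  12 x 32-channel slices ≈ 16M voxel-channels per stack); a full render +
  unmix + pack cycle takes a few seconds, and the parameter-recovery study
  (30 runs) a couple of minutes.
- Abundances are solved and stored in float64; rendered stacks are float32
  photon counts.
- NNLS feasibility tolerances scale with the data magnitude
  (1e-9 x (1 + max|y|)); degenerate voxels (ties) fall back to
  scipy.optimize.nnls.
- The tracker is deterministic given detection order; detections come out
  of `skimage.measure.regionprops` in raster-scan order.

## Known limitations

- Geometry is extruded 2-D; no STL/GWL export, no fabrication voxel shape.
- The mapping from design niche size to *effective* niche size (−2 µm line
  thickness) is reported by the geometry but analyses use design
  dimensions, as the figures of record do.
- Cytoplasm-based niche ratios are systematically below the point-statistic
  expectation (a 15 µm sphere cannot sit wholly inside a 7.5 µm zone);
  quantitative recovery targets use the nuclei endmember.
- Vertical (Z) motion is not tracked; cells spanning the partition boundary
  appear in both projections.
- With N = 10 and 6 timepoints the maximum recordable path is
  5 x 16.6 = 83 µm.
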