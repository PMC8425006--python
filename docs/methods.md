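# Methods

This note documents the models, algorithms and numerical choices behind
`ermorph`, what its synthetic-data generator does and does not emulate,
and the known limitations of both.

## Imaging model and projection

Input fields carry up to three channels — DNA counterstain (nucleus),
plasma-membrane counterstain (membrane, optional) and an ER marker —
each a single optical plane or a z-stack. Adherent cells are nearly
two-dimensional but have enough depth that a single confocal slice can
miss continuous tubules; all analysis therefore runs on the per-pixel
maximum-intensity projection over z. Projection is idempotent and
commutes with any monotone intensity transform applied uniformly to all
planes.

Intensities are carried in arbitrary detector units and never
renormalised: every downstream threshold is defined relative to
per-cell or per-ROI statistics, so bit depth and detector gain cancel
(this is asserted by the scale-invariance tests). The xy pixel size is
read from OME/TIFF metadata; when absent, 0.28 µm/px is assumed with a
warning — the effective resolution of a 63×/1.15 NA water-immersion
confocal at which peripheral tubules are resolvable.

## Segmentation

Nuclei are the primary objects: the nucleus channel is smoothed at
`smoothing_scale_um` (default 1 µm), thresholded (Otsu by default;
fixed or percentile thresholds are configurable), and touching nuclei
are split by a watershed seeded at maxima of the Euclidean distance
transform. The distance map is smoothed before peak picking so that
rasterisation bumps along the medial axis of an elongated nucleus do
not seed spurious splits; minimum seed separation is
0.5·√(min_area)/pixel_size. Because Gaussian smoothing dilates the
thresholded support and would dilute area and mean-intensity
measurements, the labelled mask is trimmed against a threshold of the
*raw* image. The segmentation-stage size floor (default 20 µm²) only
removes debris; it is deliberately below the QC stage's nuclear-area
cut (60 µm²) so that small mitotic nuclei survive segmentation and can
be flagged rather than silently vanish.

Cells are grown from nucleus seeds by a watershed over the gradient
magnitude (Sobel) of the membrane channel, with one extra seed covering
the image background. Letting background compete places the
nucleus/background watershed line on the strongest intensity edge — the
cell boundary — rather than on the blurred threshold contour, which
overshoots by roughly the smoothing radius. Claimed pixels below the
raw-image threshold are then released, each cell is reduced to the
connected component containing its seed nucleus (so foreground annexed
across flat background, e.g. a footprint whose nucleus was filtered
out, is dropped), and holes are refilled. When no membrane channel was
acquired (marker-only experiments), the ER channel takes its place.

Seeded growth yields exactly one cell per nucleus, so a genuinely
binucleated cell emerges split in two. Adjacent cells are re-merged
when the mean membrane intensity along their shared border is below
`merge_ridge_factor` (default 1.2) times the mean of their interiors,
i.e. when no actual membrane separates them. Cells with any pixel on
the image border are deleted (their metrics would be truncated), and
cytoplasm is the per-cell set difference cell − assigned nuclei.
Conventions fixed once and used everywhere: row-major (y, x) arrays,
8-connected labelling, every pixel belongs to at most one object.

## Population QC

The filters express intent (remove dividing, apoptotic, multinucleated
and non-expressing cells) through proxy rules on measured features,
since the commercial building blocks they mirror do not publish
formulas:

* dividing — nuclear mean intensity above `max_mean_intensity` *and*
  area below `min_area_um2` (condensed mitotic chromatin);
* apoptotic — area below `min_area_um2` *and* roundness
  (4π·area/perimeter², capped at 1.1 for pixelated objects) below
  `min_roundness`;
* multinucleated — more than `max_nuclei_per_cell` (default 1) nuclei;
* low_expression — cytoplasmic mean ER intensity strictly below an
  absolute cut, or below a percentile (default 25th) of the per-image
  population of cell means.

All comparisons are strict so boundary behaviour is testable; flags are
additive and never removed, which makes filtering monotone (tightening
any threshold can only discard more cells) and order-independent. When
`max_mean_intensity` is not set it resolves to 1.5× the per-image
median of nuclear means: intensities are arbitrary units, so a fixed
absolute default would be meaningless across detectors. Note that the
percentile expression rule by construction flags the dimmest quartile
even in a fully expressing population; use an absolute cut when that is
not wanted.

## ER metrics

**Peripheral ROI.** For cytoplasm pixels, let D_n be the distance to
the nucleus border and D_p the distance to the cell perimeter. The ROI
keeps pixels with D_n/(D_n+D_p) ≥ f, so its inner border sits a
fraction f of the local nucleus-to-perimeter distance from the nucleus;
f = 0 returns the whole cytoplasm. The pipeline default is f = 0.25,
which excludes most of the perinuclear dense region from polygon
analysis while keeping the tubule-bearing periphery.

**Tubule mask.** The default automatic threshold is Otsu computed on
log-transformed ROI intensities (`log(v − min + δ)`, δ = 10⁻⁶ of the
range), mapped back and scaled by a configurable multiplier. The log
domain matters: the ROI histogram is typically trimodal (lumen, tubule,
a residual tail of bright dense ER), and linear Otsu can place the cut
*above* the tubule class when the bright tail is heavy, which collapses
the polygon count to zero; in log space the lumen/tubule split
dominates. The construction is exactly equivariant under uniform
intensity scaling. Percentile and fixed thresholds are available.

**Polygons.** The 8-connected components of (ROI − tubule mask) are
candidate polygons. Components adjacent — within a one-pixel dilation —
to the cell's one-pixel inner perimeter band are open to the cell
exterior, not tubule-bounded, and are discarded; so are components
below `min_polygon_area_um2` (default 4 pixels, noise suppression).
The per-cell readout is the mean area of the survivors; a cell with no
surviving polygon carries an explicit undefined value (NaN) and is
excluded from well means — a missing mean is not a zero area. The
implementation is verified against an independent brute-force flood
fill with border-adjacency check on every small fixture.

**Dense ER.** Pixels above k × the lower-median cytoplasmic ER
intensity (default k = 2) form the dense mask; the readout is
100·|dense|/|cytoplasm|. The lower median (rather than the
interpolated one) makes the exactly-50/50 bimodal case cut between the
classes. The denominator is cytoplasm by default and switchable to
whole-cell area; both readings of "cell area" appear in common usage
and the two differ only by the nuclear footprint.

**Aggregation.** Per-well mean ± SEM over passed cells; SEM is defined
only for n ≥ 2. Wells with fewer than 50 analysed cells are flagged,
since population variability in cultured cells is only averaged out at
that scale. Outputs are tidy CSVs with fixed float formatting
(byte-identical across reruns); significance testing is deliberately
left to external stats tools.

## Synthetic data generator

The generator renders what the analysis assumes: well-separated,
convex-ish elliptical cells (radius 13–16 µm) with ovoid nuclei
(5–7 µm), a perinuclear dense region grown radially from the nucleus to
a designed fraction of the cytoplasm (default 0.20, hit to within
rasterisation error, ±2 pp), and a peripheral tubule mesh. The mesh is
the edge set of a planar partition whose seeds sit on a square lattice
of pitch `mesh_pitch_um` (default 3 µm) jittered by 8% of the pitch;
a pixel is tubule when its two nearest seeds are nearly equidistant,
giving edges of width `tubule_width_um` (default 0.5 µm). Zero jitter
gives the regular-grid mode used for exact-count oracle fixtures. For
this construction the designed mean gap area is approximately
(pitch − width)²; the generator also records the empirically true
polygon areas (same component rule as the analysis, including the
perimeter exclusion and the 4-px floor) per cell.

Intensity levels (a.u.): background 50, ER lumen 600, tubule 1100,
dense 3300, nucleus 3000, membrane fill 800 with a brighter outline
1600. Two constraints shaped these defaults: the dense region is ≈3×
the tubule intensity, mirroring the perinuclear/peripheral contrast of
real ER markers; and 2 × median(cytoplasm) must land between the tubule
and dense levels whether the median falls in the lumen class
(2×600 = 1200) or the tubule class (2×1100 = 2200), so the default
dense threshold is a valid separator by construction. Noise is Poisson
shot noise (gain 0.5 photons per unit) followed by Gaussian read noise
(sd 20), applied to the 2-D render; z-stacks are emitted by giving each
pixel its full value in one plane (cycling by position) and a reduced
copy elsewhere, so max-projection recovers the 2-D render exactly.
Geometry and noise use split seeds: noise-robustness tests can redraw
noise over fixed geometry. Defect presets inject the QC classes: dark
(ER scaled to 5% above background), mitotic (30 µm² round nucleus at
2× intensity), binucleate (two nuclei in one footprint), border
(footprint crossing an image edge).

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: point-spread-function blur and
partial-volume effects at tubule edges (tubules are rendered as hard
binary bands), out-of-focus haze, illumination gradients across the
field, touching or overlapping cells, irregular (non-convex) cell
shapes, ER sheets outside the perinuclear region, and intensity
variation along tubules. Recovery numbers on synthetic data are
accordingly an upper bound on real-image performance; the
configuration surface (threshold methods, multipliers, ROI fraction)
exists precisely because real markers need per-experiment adjustment.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run on 320–512 px fields with
3–5 cells each, 1–2 fields per condition — enough for ≥100 polygons at
the default mesh and stable well means, while keeping the whole suite
around half a minute. Larger plates are generated the same way by
turning up `image_size_px`, `n_cells` and `--n-fields`.

## Known limitations

* The watershed-based cell boundary assumes a membrane (or ER)
  intensity edge at the perimeter; cells in confluent contact with no
  ridge between them would be merged by the multinucleate rule.
* The dividing/apoptotic rules are morphological proxies; they do not
  use chromatin texture and will miss phenotypes that preserve nuclear
  size and brightness.
* Polygon areas near the ROI inner border are measured as clipped by
  whatever bounds them there (dense ER or the ROI edge); with very
  small shrink fractions and no dense region, gaps adjacent to the
  nucleus are bounded in part by the nuclear border rather than by
  tubules.
* Metrics are 2-D by construction; genuinely 3-D ER architecture is
  collapsed by the projection.
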