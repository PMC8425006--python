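# ermorph

Per-cell quantification of endoplasmic-reticulum (ER) morphology from
high-content fluorescence microscopy.

The ER of adherent cultured cells has two visually distinct
subcompartments at confocal resolution: a peripheral network of smooth-ER
(SER) tubules that meet at three-way junctions and enclose polygonal
"gaps", and a perinuclear region of markedly brighter ER-marker signal
that largely corresponds to the sheet-like rough ER (RER). `ermorph`
turns multiwell plates of multi-channel fluorescence images (nucleus
counterstain, optional plasma-membrane counterstain, ER marker such as
Sec61β-mEmerald) into two per-cell readouts:

* **mean SER polygon area (µm²)** — the average area of the closed
  regions enclosed by tubules in a peripheral ring of the cytoplasm.
  A denser network (more three-way junctions) gives smaller polygons;
  a loosened network gives larger ones.
* **dense-ER percent** — the percentage of the cytoplasm covered by
  pixels whose ER intensity exceeds a multiple of the cytoplasmic
  median, an RER proxy.

It is aimed at screening labs that want an open, scriptable equivalent
of commercial high-content analysis pipelines: drug panels, siRNA/ORF
screens, or marker-validation experiments where ER network density and
RER expansion are the phenotypes of interest.

## Method

For each field: optional z-stacks are reduced by maximum-intensity
projection; nuclei are segmented (smoothing, Otsu threshold,
distance-transform seeded watershed); cells are grown from nucleus
seeds over the membrane channel by a gradient watershed in which the
image background competes as an extra seed; cells touching the image
border are discarded and seed-split fragments of multinucleated cells
are re-merged when no membrane ridge separates them. Population QC
removes dividing cells (small, very bright nuclei), apoptotic cells
(small, irregular nuclei), multinucleated cells, and cells expressing
little or no ER marker (cytoplasmic mean below an absolute cut or a
population percentile).

For each passed cell, a ring-shaped peripheral ROI is cut from the
cytoplasm: with D_n the distance of a pixel to the nucleus border and
D_p its distance to the cell perimeter, the ROI keeps pixels with
D_n / (D_n + D_p) ≥ f (default f = 0.25). ER tubules are masked by an
automatic threshold of the ER signal inside the ROI; the mask is
inverted; 8-connected components of the complement that do not touch
the cell perimeter and exceed a minimum area are the SER polygons.
Separately, pixels above k × median cytoplasmic ER intensity (default
k = 2) form the dense-ER mask, reported as a percentage of the
cytoplasm. Results are aggregated per well (mean ± SEM over passed
cells; wells analysing fewer than 50 cells are flagged).

All default thresholds are relative to per-cell statistics, so both
metrics are invariant under uniform intensity rescaling and independent
of detector bit depth.

A built-in synthetic-image generator renders fields of elliptical cells
with nuclei, a perinuclear dense region of designed areal fraction, and
a peripheral tubule mesh of designed pitch and width, plus
non-transfected / mitotic / binucleated / border cells and shot + read
noise — with full ground truth, so every pipeline stage is testable
without real images.

## Worked example

Simulate a three-condition plate in which the mesh pitch of the tubule
network is scaled 0.7× / 1.0× / 1.5× (the analogue of drugs that
condense or loosen the SER network), then analyse it:

```
$ ermorph simulate --out plate --seed 2 --n-fields 2 --no-noise \
      --pitch-multipliers 0.7,1.0,1.5
wrote 6 field(s) to plate
$ ermorph init-config --out config.yaml
$ ermorph run --config config.yaml --input plate --out results
analysed 24 passed cells across 3 well(s); outputs in results
```

`results/per_well.csv` (wells are conditions; abridged):

```
well,n_cells_analysed,mean_polygon_area_um2,sem_polygon_area_um2,mean_dense_er_percent,...
r01c01,8,2.55712,0.033408,20.0138,...
r01c02,8,6.00543,0.109488,20.0039,...
r01c03,8,13.2251,0.769601,20.0074,...
```

Reading the numbers: at the base pitch of 3 µm and tubule width 0.5 µm
the designed lattice gap is (3 − 0.5)² = 6.25 µm², and the measured
mean polygon area in well r01c02 is 6.01 ± 0.11 µm²; shrinking the
pitch 0.7× roughly halves the polygon area (2.56 µm²) and enlarging it
1.5× more than doubles it (13.23 µm²), while the dense-ER percentage
stays at its designed 20% in all three conditions. `per_cell.csv`
carries one row per cell with its QC flags, `per_object.csv` one row
per detected polygon, and `qc_report.json` the per-field discard
counts. (Each simulated well holds 2 fields ≈ 8 cells, so every well
also carries the low-cell-count flag that real ≥50-cell wells would
not.)

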