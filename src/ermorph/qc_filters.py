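"""Population QC: drop dividing, apoptotic, multinucleated and
non-expressing cells before any ER measurement.

Dividing and apoptotic cells are proxied by nuclear morphology and
intensity: mitotic chromatin condenses into a small, very bright
nucleus; apoptotic nuclei fragment into small, irregular pieces.
Cells that lost the ER-marker transgene (or express it weakly) are
removed by their cytoplasmic ER-marker mean intensity, either against
an absolute cut-off or against a percentile of the per-image cell
population.

All comparisons at thresholds are strict (<, >) so boundary behaviour
is well defined; flags are additive and never removed, which makes
filtering monotone: tightening any threshold can only discard more.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from skimage.measure import regionprops

from .segmentation import LabelMap

#: recognised QC flags
QC_FLAGS = ("dividing", "apoptotic", "multinucleated", "low_expression", "border")

#: slack on roundness for heavily pixelated objects (a rasterised disc
#: can exceed 1 slightly; single pixels are capped here)
ROUNDNESS_CAP = 1.1


@dataclass
class NuclearFeatures:
    """Morphology and intensity of one segmented nucleus."""

    label: int
    area_um2: float
    roundness: float  # 4*pi*area/perimeter^2, capped at ROUNDNESS_CAP
    mean_intensity: float
    integrated_intensity: float


@dataclass
class CellRecord:
    """One segmented cell with its nuclei, expression level and QC fate."""

    cell_label: int
    nucleus_labels: list[int]
    nuclear_features: list[NuclearFeatures]
    cytoplasm_mean_er: float = float("nan")
    qc_flags: set[str] = dc_field(default_factory=set)

    @property
    def passed(self) -> bool:
        return not self.qc_flags


def compute_nuclear_features(nuclei: LabelMap, nucleus_channel: np.ndarray) -> list[NuclearFeatures]:
    """Area (µm²), roundness, mean and integrated intensity per nucleus.

    Perimeter is measured on the object boundary as estimated by
    ``skimage.measure.regionprops`` (8-connected objects).
    """
    px = nuclei.pixel_size_um
    feats = []
    for rp in regionprops(nuclei.labels, intensity_image=np.asarray(nucleus_channel, float)):
        perim = rp.perimeter
        if perim > 0:
            roundness = 4.0 * np.pi * rp.area / perim**2
        else:  # single pixel or degenerate object
            roundness = ROUNDNESS_CAP
        feats.append(
            NuclearFeatures(
                label=int(rp.label),
                area_um2=float(rp.area) * px**2,
                roundness=float(min(roundness, ROUNDNESS_CAP)),
                mean_intensity=float(rp.intensity_mean),
                integrated_intensity=float(rp.intensity_mean * rp.area),
            )
        )
    return feats


def flag_by_nucleus(
    records: list[CellRecord],
    min_area_um2: float = 60.0,
    max_area_um2: float = 600.0,
    min_roundness: float = 0.5,
    max_mean_intensity: float | None = None,
    max_nuclei_per_cell: int = 1,
) -> list[CellRecord]:
    """Add nuclear-morphology QC flags (in place; records returned).

    * dividing: nucleus brighter than ``max_mean_intensity`` AND smaller
      than ``min_area_um2`` (condensed mitotic chromatin);
    * apoptotic: smaller than ``min_area_um2`` AND rounder-than-allowed
      below ``min_roundness`` (fragmented nucleus);
    * multinucleated: more than ``max_nuclei_per_cell`` nuclei assigned.

    ``max_mean_intensity=None`` resolves to 1.5× the median nuclear mean
    intensity over the records (intensities are arbitrary units, so an
    absolute default would be meaningless).
    """
    if not (0 < min_area_um2 < max_area_um2):
        raise ValueError("need 0 < min_area_um2 < max_area_um2")
    if not (0 < min_roundness <= ROUNDNESS_CAP):
        raise ValueError("min_roundness out of range")
    if max_mean_intensity is not None and max_mean_intensity <= 0:
        raise ValueError("max_mean_intensity must be positive")

    if max_mean_intensity is None:
        means = [f.mean_intensity for r in records for f in r.nuclear_features]
        max_mean_intensity = 1.5 * float(np.median(means)) if means else float("inf")

    for rec in records:
        if len(rec.nucleus_labels) > max_nuclei_per_cell:
            rec.qc_flags.add("multinucleated")
        for f in rec.nuclear_features:
            if f.mean_intensity > max_mean_intensity and f.area_um2 < min_area_um2:
                rec.qc_flags.add("dividing")
            if f.area_um2 < min_area_um2 and f.roundness < min_roundness:
                rec.qc_flags.add("apoptotic")
    return records


def flag_by_er_expression(
    records: list[CellRecord],
    cytoplasm: LabelMap,
    er_channel: np.ndarray,
    min_mean_er_intensity: float | None = None,
    percentile: float | None = 25.0,
) -> list[CellRecord]:
    """Flag weakly expressing / non-transfected cells.

    Each record's ``cytoplasm_mean_er`` is filled in, then compared
    (strict <) against either the absolute ``min_mean_er_intensity`` or,
    when that is None, the given ``percentile`` of the per-image
    population of cytoplasmic means.
    """
    img = np.asarray(er_channel, float)
    for rec in records:
        mask = cytoplasm.labels == rec.cell_label
        if not mask.any():
            warnings.warn(f"cell {rec.cell_label} has empty cytoplasm", stacklevel=2)
            rec.qc_flags.add("low_expression")
            rec.cytoplasm_mean_er = float("nan")
        else:
            rec.cytoplasm_mean_er = float(img[mask].mean())

    if min_mean_er_intensity is None:
        if percentile is None:
            raise ValueError("need an absolute threshold or a percentile")
        pop = [r.cytoplasm_mean_er for r in records if np.isfinite(r.cytoplasm_mean_er)]
        if not pop:
            return records
        min_mean_er_intensity = float(np.percentile(pop, percentile))

    for rec in records:
        if np.isfinite(rec.cytoplasm_mean_er) and rec.cytoplasm_mean_er < min_mean_er_intensity:
            rec.qc_flags.add("low_expression")
    return records


def apply_filters(records: list[CellRecord]) -> tuple[list[CellRecord], dict[str, int]]:
    """Split records into the passed population and a per-flag count report."""
    passed = [r for r in records if r.passed]
    report = {flag: 0 for flag in QC_FLAGS}
    for rec in records:
        for flag in rec.qc_flags:
            report[flag] = report.get(flag, 0) + 1
    report["n_total"] = len(records)
    report["n_passed"] = len(passed)
    return passed, report


def build_cell_records(segmentation, nucleus_channel: np.ndarray) -> list[CellRecord]:
    """Assemble one CellRecord per segmented cell from a SegmentationResult."""
    feats = {f.label: f for f in compute_nuclear_features(segmentation.nuclei, nucleus_channel)}
    records = []
    for c in segmentation.cells.ids:
        nlabels = sorted(segmentation.nuclei_of_cell(int(c)))
        records.append(
            CellRecord(
                cell_label=int(c),
                nucleus_labels=nlabels,
                nuclear_features=[feats[n] for n in nlabels if n in feats],
            )
        )
    return records
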