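"""Nuclear:cytoplasmic ratio quantification from two-channel micrographs.

Re-implements a threshold-based high-content readout of transcription-factor
translocation: nuclei are detected by grey thresholding of the nuclear-stain
channel, the immunostain channel is averaged over each nucleus and over a
fixed-width cytoplasmic annulus around it, and each cell is summarised by
the ratio nucleus mean / cytoplasm mean.  A cell counts as positively
stained (nuclear-translocated) when its nuclear mean is strictly greater
than 1.25x its cytoplasmic mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from skimage import measure, morphology
from skimage.filters import threshold_otsu

__all__ = [
    "CellMeasure",
    "FieldSummary",
    "POSITIVITY_FACTOR",
    "segment_nuclei",
    "measure_cells",
    "summarize_condition",
    "compare_conditions",
]

logger = logging.getLogger(__name__)

POSITIVITY_FACTOR = 1.25
"""A nucleus is called positive when nuc_mean > POSITIVITY_FACTOR * cyt_mean (strict)."""


@dataclass(frozen=True)
class CellMeasure:
    """Per-cell intensity readout on the immunostain channel."""

    cell_id: int
    nuc_mean: float
    cyt_mean: float
    ratio: float
    positive: bool


@dataclass(frozen=True)
class FieldSummary:
    """Per-condition summary of per-cell ratios (mean ± SEM, positive count)."""

    condition: str
    n_cells: int
    mean_ratio: float
    sem_ratio: float
    n_positive: int


def segment_nuclei(nuclear_channel: np.ndarray, threshold: float | None = 40.0,
                   min_area_px: int = 20) -> np.ndarray:
    """Label nuclei as connected components of the above-threshold pixel set.

    ``threshold`` is a fixed grey level (strictly-above rule); pass ``None``
    to pick it automatically by Otsu's method.  Components smaller than
    ``min_area_px`` are discarded.  Labels are assigned in raster order, so
    the labelling is deterministic; an empty result (no nuclei) is valid.
    """
    img = np.asarray(nuclear_channel)
    if img.ndim != 2:
        raise ValueError("expected a 2-D intensity image")
    if threshold is None:
        thr = float(threshold_otsu(img))
    else:
        if not (0 <= threshold <= 255):
            raise ValueError("fixed threshold must lie in [0, 255]")
        thr = float(threshold)
    mask = img > thr
    labels = measure.label(mask, connectivity=2)
    if min_area_px > 1 and labels.max() > 0:
        counts = np.bincount(labels.ravel())
        small = np.flatnonzero(counts < min_area_px)
        labels[np.isin(labels, small)] = 0
        labels = measure.label(labels > 0, connectivity=2)
    return labels


def measure_cells(stain_channel: np.ndarray, nucleus_labels: np.ndarray,
                  ring_width_px: int = 5) -> list[CellMeasure]:
    """Mean nuclear and annular-cytoplasm stain intensity per detected cell.

    The cytoplasm of a cell is a ``ring_width_px``-wide annulus obtained by
    dilating its nucleus mask, minus the nucleus pixels of *all* cells.
    Cells whose annulus would extend past the image border are excluded
    (an incomplete annulus biases the cytoplasmic mean), as are cells whose
    annulus ends up empty; both exclusions are logged.
    """
    stain = np.asarray(stain_channel, dtype=float)
    labels = np.asarray(nucleus_labels)
    if stain.shape != labels.shape:
        raise ValueError("stain and label images must share a shape")
    if ring_width_px < 1:
        raise ValueError("ring_width_px must be >= 1")
    selem = morphology.disk(ring_width_px)
    out: list[CellMeasure] = []
    for region in measure.regionprops(labels):
        lab = region.label
        minr, minc, maxr, maxc = region.bbox
        pad = ring_width_px + 1
        r0, c0 = minr - pad, minc - pad
        r1, c1 = maxr + pad, maxc + pad
        if r0 < 0 or c0 < 0 or r1 > labels.shape[0] or c1 > labels.shape[1]:
            logger.info("cell %d touches the image border; excluded", lab)
            continue
        win = labels[r0:r1, c0:c1]
        nuc = win == lab
        ring = morphology.dilation(nuc, footprint=selem) & ~(win > 0)
        # the window is padded by ring_width+1, so the dilation cannot clip
        if not ring.any():
            logger.info("cell %d has an empty cytoplasmic annulus; excluded", lab)
            continue
        stain_win = stain[r0:r1, c0:c1]
        nuc_mean = float(stain_win[nuc].mean())
        cyt_mean = float(stain_win[ring].mean())
        ratio = nuc_mean / cyt_mean
        out.append(CellMeasure(
            cell_id=lab, nuc_mean=nuc_mean, cyt_mean=cyt_mean,
            ratio=ratio, positive=bool(nuc_mean > POSITIVITY_FACTOR * cyt_mean),
        ))
    return out


def summarize_condition(measures: list[CellMeasure], condition: str) -> FieldSummary:
    """Mean ratio, SEM (sd/sqrt(n), sample sd) and positive count."""
    if not measures:
        raise ValueError("cannot summarise an empty measurement list")
    ratios = np.array([m.ratio for m in measures])
    n = len(ratios)
    sem = float(np.std(ratios, ddof=1) / np.sqrt(n)) if n >= 2 else float("nan")
    return FieldSummary(
        condition=condition,
        n_cells=n,
        mean_ratio=float(ratios.mean()),
        sem_ratio=sem,
        n_positive=int(sum(m.positive for m in measures)),
    )


def compare_conditions(a, b) -> tuple[float, float]:
    """Welch two-sample test on per-cell ratios; returns (statistic, p).

    Degenerate zero-variance inputs short-circuit to (0, 1) when the means
    are equal and (inf, 0) otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 ratios")
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        return (0.0, 1.0) if np.mean(a) == np.mean(b) else (float("inf"), 0.0)
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)
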