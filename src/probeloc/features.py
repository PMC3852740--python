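"""Per-image staining-pattern quantification.

The pipeline mirrors standard high-content-screening practice: nuclei are
segmented from the Hoechst channel, the nuclear mask is dilated by 10 pixels
(Euclidean disk) to define the cell-associated region, the three probe
channels are summed into a total-intensity image, the median intensity of
the background (complement of the cell mask) is subtracted and negatives
truncated at zero, images without probe signal or with extensive saturation
are excluded, and three features are computed on the rest:

1. cell/background ratio  — mean cell-associated intensity over the median
   background intensity, both pre-subtraction;
2. cytoplasm/nucleus ratio — mean background-corrected intensity over the
   cell mask minus the nucleus, over the mean within the nucleus;
3. CV of cell-associated pixels — sd/mean of the corrected intensities over
   the cell mask (high for punctate staining).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .render import MAX_INTENSITY, PROBE_CHANNELS, ImageSet

QC_PASS = "pass"
QC_NO_SIGNAL = "excluded_no_signal"
QC_SATURATED = "excluded_saturated"

DEFAULT_MIN_NUCLEUS_AREA = 50
DEFAULT_SIGNAL_MARGIN = 0.10
DEFAULT_SATURATION_LIMIT = 0.05


@dataclass
class SegmentationResult:
    nuclear_mask: np.ndarray
    cell_mask: np.ndarray

    @property
    def background_mask(self) -> np.ndarray:
        return ~self.cell_mask


@dataclass
class FeatureRecord:
    compound_id: str
    qc_status: str
    cell_background_ratio: float = np.nan
    cyto_nuc_ratio: float = np.nan
    cv_cell: float = np.nan
    observed_class: str = "unscored"
    image_index: int = 0
    timepoint: str = "incubation"
    flags: tuple = ()


def segment_nuclei(
    hoechst: np.ndarray, min_area: int = DEFAULT_MIN_NUCLEUS_AREA
) -> np.ndarray:
    """Nuclear mask from the Hoechst channel by Otsu thresholding.

    Holes are filled and connected components below ``min_area`` pixels are
    removed.  A blank (constant) channel yields an empty mask with a warning.
    """
    hoechst = np.asarray(hoechst)
    if hoechst.min() == hoechst.max():
        warnings.warn("blank Hoechst channel: returning empty nuclear mask")
        return np.zeros(hoechst.shape, dtype=bool)
    mask = hoechst > threshold_otsu(hoechst)
    mask = ndimage.binary_fill_holes(mask)
    labels, n = ndimage.label(mask)
    if n == 0:
        return mask
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    return np.isin(labels, np.nonzero(sizes >= min_area)[0])


def dilate_mask(mask: np.ndarray, radius: float = 10.0) -> np.ndarray:
    """Dilate a boolean mask by a Euclidean disk of the given radius.

    Implemented via the exact Euclidean distance transform: every pixel
    within distance ``radius`` of a set pixel is turned on, so the result
    always contains the input.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return mask.copy()
    return ndimage.distance_transform_edt(~mask) <= radius


def combine_probe_channels(
    fitc: np.ndarray, tritc: np.ndarray, cy5: np.ndarray
) -> np.ndarray:
    """Pixel-wise sum of the three probe channels, without re-clipping."""
    arrays = [np.asarray(a, dtype=np.int64) for a in (fitc, tritc, cy5)]
    if len({a.shape for a in arrays}) != 1:
        raise ValueError("probe channels must share a shape")
    return arrays[0] + arrays[1] + arrays[2]


def subtract_background(total: np.ndarray, background_mask: np.ndarray) -> np.ndarray:
    """Subtract the median background intensity and truncate at zero."""
    background_mask = np.asarray(background_mask, dtype=bool)
    if not background_mask.any():
        raise ValueError("empty background mask: image not interpretable")
    med = np.median(np.asarray(total, dtype=float)[background_mask])
    return np.clip(np.asarray(total, dtype=float) - med, 0.0, None)


def qc_image(
    total: np.ndarray,
    segmentation: SegmentationResult,
    probe_channels: dict | None = None,
    saturation_fraction_limit: float = DEFAULT_SATURATION_LIMIT,
    signal_margin: float = DEFAULT_SIGNAL_MARGIN,
) -> str:
    """Classify an image as pass / no-signal / saturated.

    No-signal: mean cell-mask intensity at or below the background median
    times ``1 + signal_margin`` (or no cells found at all).  Saturated: more
    than ``saturation_fraction_limit`` of cell pixels at the 12-bit ceiling
    in any single probe channel.
    """
    cell = segmentation.cell_mask
    bg = segmentation.background_mask
    if not cell.any() or not bg.any():
        return QC_NO_SIGNAL
    total = np.asarray(total, dtype=float)
    if total[cell].mean() <= np.median(total[bg]) * (1.0 + signal_margin):
        return QC_NO_SIGNAL
    if probe_channels:
        for name in PROBE_CHANNELS:
            frac = np.mean(np.asarray(probe_channels[name])[cell] >= MAX_INTENSITY)
            if frac > saturation_fraction_limit:
                return QC_SATURATED
    return QC_PASS


def compute_features(
    corrected: np.ndarray,
    nuclear_mask: np.ndarray,
    cell_mask: np.ndarray,
    raw_total: np.ndarray,
    background_mask: np.ndarray,
) -> dict:
    """The three staining-pattern features over the pooled cell mask.

    The cell/background ratio uses the pre-subtraction image (the corrected
    background median is ~0 by construction); the other two features use the
    background-corrected image.  A zero nuclear mean yields an ``inf``
    cytoplasm/nucleus ratio with a flag rather than an error.
    """
    corrected = np.asarray(corrected, dtype=float)
    raw_total = np.asarray(raw_total, dtype=float)
    cyto = cell_mask & ~nuclear_mask
    if not nuclear_mask.any() or not cyto.any():
        raise ValueError("need non-empty nuclear and cytoplasmic regions")
    if not np.asarray(background_mask, dtype=bool).any():
        raise ValueError("empty background mask")

    cell_mean = corrected[cell_mask].mean()
    if cell_mean <= 0:
        raise ValueError("zero mean cell-associated intensity after correction")
    flags = []
    nuc_mean = corrected[nuclear_mask].mean()
    if nuc_mean > 0:
        cyto_nuc = corrected[cyto].mean() / nuc_mean
    else:
        cyto_nuc = np.inf
        flags.append("zero_nuclear_mean")
    return {
        "cell_background_ratio": raw_total[cell_mask].mean()
        / np.median(raw_total[background_mask]),
        "cyto_nuc_ratio": cyto_nuc,
        "cv_cell": corrected[cell_mask].std() / cell_mean,
        "flags": tuple(flags),
    }


def extract_features(
    image_set: ImageSet,
    dilation_radius: float = 10.0,
    min_nucleus_area: int = DEFAULT_MIN_NUCLEUS_AREA,
    signal_margin: float = DEFAULT_SIGNAL_MARGIN,
    saturation_fraction_limit: float = DEFAULT_SATURATION_LIMIT,
    image_index: int = 0,
) -> FeatureRecord:
    """Full pipeline for one image set: segment, QC, measure.

    Returns a :class:`FeatureRecord`; features are populated only when QC
    passes.  The pipeline is deterministic given the pixels.
    """
    nuclear = segment_nuclei(image_set.channels["Hoechst"], min_area=min_nucleus_area)
    seg = SegmentationResult(nuclear, dilate_mask(nuclear, dilation_radius))
    total = combine_probe_channels(
        *(image_set.channels[c] for c in PROBE_CHANNELS)
    )
    status = qc_image(
        total,
        seg,
        probe_channels=image_set.channels,
        saturation_fraction_limit=saturation_fraction_limit,
        signal_margin=signal_margin,
    )
    record = FeatureRecord(
        compound_id=image_set.compound_id,
        qc_status=status,
        image_index=image_index,
        timepoint=image_set.timepoint,
    )
    if status != QC_PASS:
        return record
    corrected = subtract_background(total, seg.background_mask)
    feats = compute_features(
        corrected, seg.nuclear_mask, seg.cell_mask, total, seg.background_mask
    )
    record.cell_background_ratio = feats["cell_background_ratio"]
    record.cyto_nuc_ratio = feats["cyto_nuc_ratio"]
    record.cv_cell = feats["cv_cell"]
    record.flags = feats["flags"]
    return record
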