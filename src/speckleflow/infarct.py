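"""Infarct segmentation and volumetry on coronal section stacks.

Regions of neuron-stain loss ("unstained" areas) are the infarct; the
volume is the rectangular sum over sections

    V_infarct = sum_i S_i * h,

with S_i the infarct area of slice i (mm^2) and h the slice thickness
(100 um by default), i.e. no interpolation between slices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage.measure import label as cc_label

from .phantom import SectionStack

__all__ = ["InfarctMeasurement", "segment_infarct", "infarct_volume"]

#: connected components smaller than this area (mm^2) are treated as noise
MIN_COMPONENT_AREA_MM2 = 0.01


@dataclass
class InfarctMeasurement:
    per_slice_area_mm2: list[float]
    slice_spacing_h_um: float
    volume_mm3: float

    def __post_init__(self) -> None:
        expect = sum(self.per_slice_area_mm2) * self.slice_spacing_h_um / 1000.0
        assert abs(self.volume_mm3 - expect) < 1e-12 * max(1.0, expect)


def segment_infarct(
    neuron_image: np.ndarray,
    tissue_mask: np.ndarray | None = None,
    threshold_fraction: float = 0.5,
    pixel_size: float | None = None,
) -> np.ndarray:
    """Segment the unstained (infarct) region of one neuron-stain slice.

    A tissue pixel is a candidate when its intensity falls below
    ``threshold_fraction`` times the median intensity of stained tissue;
    the largest connected component is kept (plus any component above the
    noise floor when ``pixel_size`` is given, components below 0.01 mm^2
    are dropped).  Returns an all-False mask for a uniformly stained slice.
    """
    img = np.asarray(neuron_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D slice image")
    tissue = np.ones_like(img, dtype=bool) if tissue_mask is None else np.asarray(tissue_mask, dtype=bool)
    if not tissue.any():
        raise ValueError("empty tissue mask")
    if not (0.0 < threshold_fraction < 1.0):
        raise ValueError("threshold_fraction must be in (0, 1)")
    stained_median = float(np.median(img[tissue]))
    candidates = tissue & (img < threshold_fraction * stained_median)
    if not candidates.any():
        return np.zeros_like(img, dtype=bool)
    labels = cc_label(candidates, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    if pixel_size is not None:
        floor_px = MIN_COMPONENT_AREA_MM2 / pixel_size**2
        keep = np.flatnonzero(counts >= max(floor_px, 1))
        if keep.size == 0:
            keep = np.array([int(counts.argmax())])
    else:
        keep = np.array([int(counts.argmax())])
    return np.isin(labels, keep)


def infarct_volume(
    sections: SectionStack,
    masks: Sequence[np.ndarray] | None = None,
    threshold_fraction: float = 0.5,
) -> InfarctMeasurement:
    """Measure per-slice infarct areas and the summed volume of a stack.

    ``masks`` may supply per-slice infarct masks directly (e.g. manual
    tracings); otherwise each neuron-channel slice is segmented with
    segment_infarct.  Area = pixel count x (mm/px)^2; volume = sum(area) x h.
    """
    if sections.pixel_size is None or sections.pixel_size <= 0:
        raise ValueError("section stack is missing a pixel-size calibration")
    if masks is None:
        masks = [
            segment_infarct(
                img, threshold_fraction=threshold_fraction, pixel_size=sections.pixel_size
            )
            for img in sections.neuron_channel
        ]
    elif len(masks) != sections.n_slices:
        raise ValueError("one mask per slice required")
    px_area = sections.pixel_size**2
    areas = [float(np.asarray(m, dtype=bool).sum()) * px_area for m in masks]
    h_mm = sections.slice_spacing_h / 1000.0
    return InfarctMeasurement(areas, sections.slice_spacing_h, sum(areas) * h_mm)
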