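"""Organoid segmentation from single-channel brightfield images."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import gaussian, threshold_otsu


@dataclass
class SegmentationMask:
    """Binary organoid mask with pixel calibration."""

    mask: np.ndarray  # bool raster
    pixel_size_um: float
    n_components: int
    largest_component_only: bool = False

    @property
    def area_um2(self) -> float:
        return float(self.mask.sum()) * self.pixel_size_um ** 2

    @property
    def empty(self) -> bool:
        return not bool(self.mask.any())


def segment(
    image: np.ndarray,
    pixel_size_um: float,
    min_object_area_um2: float = 30.0,
    keep_largest: bool = False,
    threshold: float | None = None,
    blur_sigma_px: float = 1.0,
) -> SegmentationMask:
    """Threshold a dark-organoid / bright-background image.

    Otsu's threshold on the blurred image by default (``threshold``
    overrides it); foreground is the dark phase.  Objects smaller than
    ``min_object_area_um2`` are removed.  A blank (constant) image yields
    an empty mask rather than an exception.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a single-channel image")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    sm = gaussian(img, sigma=blur_sigma_px, preserve_range=True) if blur_sigma_px > 0 else img
    if threshold is None:
        if np.ptp(sm) < 1e-9:
            return SegmentationMask(np.zeros_like(sm, bool), pixel_size_um, 0, keep_largest)
        threshold = float(threshold_otsu(sm))
    fg = sm < threshold

    lab, n = ndi.label(fg, structure=np.ones((3, 3), int))
    if n == 0:
        return SegmentationMask(fg, pixel_size_um, 0, keep_largest)
    min_px = max(1, int(round(min_object_area_um2 / pixel_size_um ** 2)))
    sizes = ndi.sum_labels(fg, lab, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= min_px) + 1
    if keep.size == 0:
        return SegmentationMask(np.zeros_like(fg), pixel_size_um, 0, keep_largest)
    if keep_largest:
        keep = np.array([keep[np.argmax(sizes[keep - 1])]])
    fg = np.isin(lab, keep)
    return SegmentationMask(fg, pixel_size_um, int(keep.size), keep_largest)
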