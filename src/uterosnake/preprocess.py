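"""Specular-highlight removal and two-class ROI thresholding.

Laparoscopic images carry small saturated specular blobs where the light
source reflects off the wet organ surface. They are detected by a saturation
cutoff, grown by one pixel, and filled by smooth (biharmonic) inpainting so
the surrounding speckle statistics are disturbed as little as possible.

The region of interest is then obtained by a two-class histogram split
(Otsu's between-class-variance criterion) followed by selection of the
connected component closest to the seed-point centroid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import disk
from skimage.restoration import inpaint_biharmonic

from .image_io import BinaryMask, GrayImage, SeedPoints, ValidationError

__all__ = ["PreprocessResult", "remove_specular", "threshold_two_class", "preprocess"]

logger = logging.getLogger("uterosnake")

DEFAULT_SATURATION_CUTOFF = 250.0


@dataclass
class PreprocessResult:
    """Products of the preprocessing stage."""

    cleaned: GrayImage
    roi_mask: BinaryMask
    threshold: float


def remove_specular(
    img: GrayImage, saturation_cutoff: float = DEFAULT_SATURATION_CUTOFF
) -> GrayImage:
    """Detect and inpaint saturated specular highlights.

    Pixels at or above ``saturation_cutoff`` form the detection mask, which is
    dilated by one pixel so the bright halo around each highlight is also
    replaced. Masked pixels are filled by biharmonic inpainting from the mask
    boundary; every other pixel is returned unchanged. The output is clipped
    below the cutoff, which also makes the operation idempotent.
    """
    if not (0 < saturation_cutoff <= 255):
        raise ValidationError("saturation_cutoff must lie in (0, 255]")
    pixels = img.pixels
    hot = pixels >= saturation_cutoff
    if not hot.any():
        return GrayImage(pixels.copy(), source_id=img.source_id)
    frac = hot.mean()
    if frac > 0.5:
        logger.warning(
            "more than half the image (%.0f%%) is saturated; inpainting anyway",
            100 * frac,
        )
    mask = ndimage.binary_dilation(hot, structure=np.ones((3, 3), bool))
    filled = inpaint_biharmonic(pixels / 255.0, mask) * 255.0
    out = pixels.copy()
    out[mask] = np.clip(filled[mask], 0.0, np.nextafter(saturation_cutoff, 0.0))
    return GrayImage(out, source_id=img.source_id)


def threshold_two_class(
    img: GrayImage,
    seeds: SeedPoints | None = None,
    roi_polarity: str = "bright",
    presmooth_sigma: float = 0.0,
) -> tuple[float, BinaryMask]:
    """Split the image into two intensity classes and extract the ROI.

    The threshold maximizes the between-class variance of the 256-bin
    histogram (Otsu's criterion). With ``roi_polarity="bright"`` the
    foreground is pixels above the threshold; ``"dark"`` selects pixels at
    or below it. ``presmooth_sigma`` > 0 applies a Gaussian filter before
    thresholding — on speckled ultrasound the raw histogram classes overlap
    too much for a meaningful split, so the pipeline smooths at roughly the
    speckle correlation scale first. Foreground is tidied by a small
    morphological closing and hole filling, and reduced to the connected
    component containing — or, failing that, nearest to — the seed-point
    centroid (the largest component when no seeds are given).

    Returns ``(threshold, roi_mask)``.
    """
    pixels = img.pixels
    if presmooth_sigma > 0:
        pixels = ndimage.gaussian_filter(pixels, presmooth_sigma)
    if np.ptp(pixels) == 0:
        raise ValidationError("degenerate histogram: image is constant")
    if roi_polarity not in ("bright", "dark"):
        raise ValidationError(f"unknown roi_polarity {roi_polarity!r}")
    t = float(threshold_otsu(np.clip(np.rint(pixels), 0, 255).astype(np.uint8), nbins=256))
    fg = pixels > t if roi_polarity == "bright" else pixels <= t
    # tidy the speckle-fragmented foreground before component selection
    # closing with erosion border_value=1 so foreground touching the image
    # border is not stripped
    fg = ndimage.binary_dilation(fg, structure=disk(3))
    fg = ndimage.binary_erosion(fg, structure=disk(3), border_value=1)
    fg = ndimage.binary_fill_holes(fg)
    labels, n = ndimage.label(fg)
    if n == 0:
        raise ValidationError("thresholding produced an empty foreground")
    roi = _select_component(labels, n, seeds)
    return t, BinaryMask(roi)


def _select_component(
    labels: np.ndarray, n: int, seeds: SeedPoints | None
) -> np.ndarray:
    if seeds is None:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
        return labels == (int(np.argmax(sizes)) + 1)
    cr, cc = seeds.points.mean(axis=0)
    r = int(round(np.clip(cr, 0, labels.shape[0] - 1)))
    c = int(round(np.clip(cc, 0, labels.shape[1] - 1)))
    if labels[r, c] > 0:
        return labels == labels[r, c]
    # centroid fell on background: pick the component with the nearest pixel
    best, best_d = 1, np.inf
    rows, cols = np.nonzero(labels)
    d2 = (rows - cr) ** 2 + (cols - cc) ** 2
    idx = int(np.argmin(d2))
    best = labels[rows[idx], cols[idx]]
    return labels == best


def preprocess(
    img: GrayImage,
    seeds: SeedPoints | None = None,
    saturation_cutoff: float = DEFAULT_SATURATION_CUTOFF,
    roi_polarity: str = "bright",
    presmooth_sigma: float = 3.0,
) -> PreprocessResult:
    """Run highlight removal followed by ROI thresholding.

    The default ``presmooth_sigma`` of 3 px suits fully developed speckle;
    pass 0 for images that are already smooth.
    """
    cleaned = remove_specular(img, saturation_cutoff)
    t, roi = threshold_two_class(
        cleaned, seeds=seeds, roi_polarity=roi_polarity,
        presmooth_sigma=presmooth_sigma,
    )
    return PreprocessResult(cleaned=cleaned, roi_mask=roi, threshold=t)
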