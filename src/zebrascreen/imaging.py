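"""Fluorescence tumor-area quantification and segmentation-consistency scores.

Tumor area (TA) is the number of pixels whose intensity strictly exceeds
an autofluorescence-removal threshold (default 7000 on the 16-bit scale),
optionally restricted to a region-of-interest mask and scaled by a
per-pixel area.  ROI summaries (Area / Mean / IntDen), Z-score correction
against non-injected controls, and the Dice similarity coefficient for
intra-observer delineation variability live here too.

Images are single-channel 2-D grids, 0-based and row-major; masks are
boolean grids of the same shape.  On disk, images are 16-bit grayscale
TIFF (PNG also accepted) and masks are 8-bit images where nonzero means
inside the ROI.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data_model import ZScoreParams

#: Default intensity threshold removing embryo autofluorescence.
DEFAULT_THRESHOLD = 7000.0

#: A pairwise delineation is successful when Dice strictly exceeds this.
DICE_SUCCESS_CUTOFF = 0.60

MAX_INTENSITY = 65535


def as_intensity_image(pixels) -> np.ndarray:
    """Validate and return a 2-D nonnegative intensity grid (<= 65535)."""
    arr = np.asarray(pixels)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("image must be a nonempty 2-D grid")
    if np.any(arr < 0) or np.any(arr > MAX_INTENSITY):
        raise ValueError("intensities must lie in [0, 65535]")
    return arr


def as_mask(pixels, like: np.ndarray | None = None) -> np.ndarray:
    """Validate a boolean ROI mask, optionally against a paired image shape."""
    mask = np.asarray(pixels)
    if mask.ndim != 2 or mask.size == 0:
        raise ValueError("mask must be a nonempty 2-D grid")
    mask = mask.astype(bool)
    if like is not None and mask.shape != like.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match image shape {like.shape}"
        )
    return mask


def tumor_area(
    image,
    threshold: float = DEFAULT_THRESHOLD,
    mask=None,
    pixel_area: float = 1.0,
) -> float:
    """Fluorescent tumor area: ``pixel_area`` x count of pixels > threshold.

    The comparison is strict — pixels at exactly the threshold are treated
    as autofluorescence and not counted.  ``mask`` restricts the counted
    region.  Returns 0 when no pixel exceeds the threshold.
    """
    img = as_intensity_image(image)
    if not (0 <= threshold <= MAX_INTENSITY):
        raise ValueError(f"threshold must lie in [0, 65535], got {threshold}")
    above = img > threshold
    if mask is not None:
        above &= as_mask(mask, like=img)
    return float(pixel_area) * int(np.count_nonzero(above))


@dataclass(frozen=True)
class RoiMetrics:
    """Area (pixel count), Mean (average intensity) and IntDen (summed
    intensity) over a region of interest; IntDen == Mean x Area."""

    area: int
    mean: float
    int_den: float


def roi_metrics(image, mask) -> RoiMetrics:
    """Compute Area / Mean / IntDen of ``image`` within ``mask``."""
    img = as_intensity_image(image)
    m = as_mask(mask, like=img)
    area = int(np.count_nonzero(m))
    if area == 0:
        raise ValueError("empty ROI mask: mean intensity is undefined")
    int_den = float(np.sum(img[m], dtype=np.float64))
    return RoiMetrics(area=area, mean=int_den / area, int_den=int_den)


def zscore(x: float, params: ZScoreParams) -> float:
    """Z-score of a measurement against the negative-control distribution."""
    return (x - params.mu_neg_ctrl) / params.sigma_neg_ctrl


def dice(a, b) -> float:
    """Dice similarity coefficient 2|a∩b| / (|a| + |b|) between two masks.

    Symmetric in its arguments; 1 for identical nonempty masks, 0 for
    disjoint ones.  Undefined (error) when both masks are empty.
    """
    ma = as_mask(a)
    mb = as_mask(b, like=ma)
    na = int(np.count_nonzero(ma))
    nb = int(np.count_nonzero(mb))
    if na + nb == 0:
        raise ValueError("Dice coefficient is undefined for two empty masks")
    inter = int(np.count_nonzero(ma & mb))
    return 2.0 * inter / (na + nb)


@dataclass(frozen=True)
class DiceTriplet:
    """The three pairwise Dice coefficients of a segmentation triplet.

    ``labels`` names the pairs (S1&S2, S1&S3, S2&S3); ``successes`` marks
    values strictly above the success cutoff.
    """

    values: tuple[float, float, float]
    successes: tuple[bool, bool, bool]
    cutoff: float = DICE_SUCCESS_CUTOFF
    labels: tuple[str, str, str] = ("S1&S2", "S1&S3", "S2&S3")


def dice_triplet(s1, s2, s3, cutoff: float = DICE_SUCCESS_CUTOFF) -> DiceTriplet:
    """Pairwise Dice values of three repeated delineations of one region.

    A pair is successful when its coefficient is strictly higher than
    ``cutoff`` (default 0.60); a value exactly at the cutoff fails.
    """
    values = (dice(s1, s2), dice(s1, s3), dice(s2, s3))
    return DiceTriplet(
        values=values,
        successes=tuple(v > cutoff for v in values),  # type: ignore[arg-type]
        cutoff=cutoff,
    )


def load_image(path: str | Path) -> np.ndarray:
    """Load a single-channel intensity image (TIFF preferred, PNG accepted)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[-1] == 1:
        arr = arr[..., 0]
    return as_intensity_image(arr)


def save_image(image, path: str | Path) -> None:
    """Write a 16-bit grayscale image (TIFF or PNG by extension)."""
    arr = as_intensity_image(image).astype(np.uint16)
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, arr)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, arr)


def load_roi_mask(path: str | Path) -> np.ndarray:
    """Load an 8-bit mask image; nonzero pixels are inside the ROI."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[-1] == 1:
        arr = arr[..., 0]
    return as_mask(arr != 0)
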