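"""The collagen-quality quantification pipeline.

For each SHG sample, in order: maximum intensity z-projection, background
subtraction, 500x500 ROI extraction, mean intensity (native units, comparable
across samples only under constant acquisition settings), histogram
equalization, first-order Shannon entropy plus GLCM texture features of the
equalized ROI, Otsu binarization, and percent area of positive pixels as a
collagen-amount proxy.

Intensity comparability contract
--------------------------------
``mean_intensity`` is reported in native intensity units with NO per-image
normalization of any kind.  Cross-sample intensity comparisons are only
meaningful when laser power, gain and dwell time were held constant across
the cohort — the acquisition protocol this pipeline mirrors fixes them on the
first sample of a series.  Equalization happens strictly *after* the mean is
taken, because it deliberately destroys absolute intensity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .config import PipelineConfig
from .exceptions import (
    BoundsError,
    DegenerateImageError,
    ParameterError,
    PipelineStageError,
)
from .image_io import Image2D, ImageStack, max_projection, single_slice

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RoiSpec:
    """Rectangular ROI, row-major, 0-based, origin top-left.

    Covers the half-open window ``[row0, row0+height) x [col0, col0+width)``.
    """

    row0: int
    col0: int
    height: int = 500
    width: int = 500

    def __post_init__(self) -> None:
        if self.row0 < 0 or self.col0 < 0:
            raise ParameterError("ROI origin must be nonnegative")
        if self.height <= 0 or self.width <= 0:
            raise ParameterError("ROI dimensions must be > 0")


@dataclass
class QuantResult:
    """All pipeline outputs for one sample."""

    sample_id: str
    group_factors: dict[str, str] = field(default_factory=dict)
    mean_intensity: float = float("nan")
    entropy_bits: float = float("nan")
    glcm_features: dict[str, float] = field(default_factory=dict)
    otsu_threshold: int | None = None
    percent_area: float = float("nan")
    chp_mean_intensity: float | None = None
    acquisition_batch: str = "default"

    def to_row(self) -> dict[str, object]:
        """Flatten into the CSV result schema."""
        row: dict[str, object] = {"sample_id": self.sample_id}
        row.update(self.group_factors)
        row.update(
            mean_intensity=self.mean_intensity,
            entropy_bits=self.entropy_bits,
            glcm_entropy=self.glcm_features.get("entropy", float("nan")),
            glcm_energy=self.glcm_features.get("energy", float("nan")),
            glcm_inertia=self.glcm_features.get("inertia", float("nan")),
            glcm_idm=self.glcm_features.get("idm", float("nan")),
            glcm_correlation=self.glcm_features.get("correlation", float("nan")),
            otsu_threshold=self.otsu_threshold,
            percent_area=self.percent_area,
            chp_mean_intensity=self.chp_mean_intensity,
            acquisition_batch=self.acquisition_batch,
        )
        return row


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def subtract_background(
    image: Image2D, method: str = "mode", param: float | None = None
) -> Image2D:
    """Subtract a scalar background estimate and clamp at zero.

    ``method`` selects the estimate *b*: ``"mode"`` = modal gray value of the
    image histogram, ``"percentile"`` = the given percentile of the pixel
    values (``param`` in [0, 100]), ``"constant"`` = ``param`` itself.  Output
    is ``clamp(round(image - b), 0, max)``.
    """
    pix = image.pixels.astype(np.int64)
    if method == "mode":
        counts = np.bincount(pix.ravel(), minlength=image.max_value + 1)
        b: float = float(np.argmax(counts))
    elif method == "percentile":
        if param is None or not 0 <= param <= 100:
            raise ParameterError(f"percentile must be in [0, 100], got {param}")
        b = float(np.percentile(pix, param))
    elif method == "constant":
        if param is None:
            raise ParameterError("constant background subtraction needs a value")
        b = float(param)
    else:
        raise ParameterError(f"unknown background method {method!r}")
    out = np.clip(np.rint(pix - b), 0, image.max_value).astype(np.int64)
    return Image2D(out, bit_depth=image.bit_depth, provenance="background-subtracted")


def extract_roi(image: Image2D, roi: RoiSpec) -> Image2D:
    """Return the ROI sub-image; never crops silently."""
    h, w = image.shape
    if roi.row0 + roi.height > h or roi.col0 + roi.width > w:
        raise BoundsError(
            f"ROI {roi} exceeds image bounds {h}x{w}"
        )
    sub = image.pixels[roi.row0:roi.row0 + roi.height, roi.col0:roi.col0 + roi.width]
    return Image2D(sub.copy(), bit_depth=image.bit_depth, provenance=image.provenance)


def auto_roi(image: Image2D, height: int = 500, width: int = 500) -> RoiSpec:
    """Center an ROI on the intensity-weighted centroid of the foreground.

    Foreground = pixels above the image's Otsu threshold (for a constant image
    the geometric center is used).  The origin is clipped so the ROI fits.
    Stand-in for the manual selection of the central anterior AF region.
    """
    h, w = image.shape
    if h < height or w < width:
        raise BoundsError(f"image {h}x{w} smaller than requested ROI {height}x{width}")
    pix = image.pixels.astype(np.float64)
    try:
        t = otsu_threshold(image)
        weights = np.where(pix > t, pix, 0.0)
        if weights.sum() == 0:  # pathological: nothing above threshold
            weights = pix
    except DegenerateImageError:
        weights = np.ones_like(pix)
    total = weights.sum()
    if total == 0:
        cr, cc = (h - 1) / 2.0, (w - 1) / 2.0
    else:
        rows = np.arange(h, dtype=np.float64)
        cols = np.arange(w, dtype=np.float64)
        cr = float((weights.sum(axis=1) * rows).sum() / total)
        cc = float((weights.sum(axis=0) * cols).sum() / total)
    row0 = int(np.clip(round(cr - (height - 1) / 2.0), 0, h - height))
    col0 = int(np.clip(round(cc - (width - 1) / 2.0), 0, w - width))
    return RoiSpec(row0=row0, col0=col0, height=height, width=width)


def mean_intensity(image: Image2D) -> float:
    """Arithmetic mean of all pixels, native intensity units."""
    return float(image.pixels.mean())


def equalize(image: Image2D, levels: int = 256) -> Image2D:
    """Histogram equalization by the classic CDF mapping.

    ``out(v) = round((levels-1) * (cdf(v) - cdf_min) / (1 - cdf_min))`` where
    ``cdf`` is the empirical cumulative histogram and ``cdf_min`` its value at
    the lowest occupied bin.  A constant image is degenerate (``cdf_min = 1``):
    all pixels map to ``levels - 1`` and a warning is logged.
    """
    if levels < 2:
        raise ParameterError("equalize needs levels >= 2")
    pix = image.pixels.astype(np.int64)
    counts = np.bincount(pix.ravel(), minlength=image.max_value + 1)
    cdf = np.cumsum(counts)
    total = int(cdf[-1])
    cdf_min = int(counts[np.nonzero(counts)[0][0]])
    out_depth = max(1, int(levels - 1).bit_length())
    if cdf_min == total:
        logger.warning("equalize: constant image (degenerate CDF); mapping to %d", levels - 1)
        out = np.full_like(pix, levels - 1)
    else:
        lut = np.rint((levels - 1) * (cdf - cdf_min) / (total - cdf_min))
        lut = np.clip(lut, 0, levels - 1).astype(np.int64)
        out = lut[pix]
    return Image2D(out, bit_depth=out_depth, provenance="equalized")


def shannon_entropy(image: Image2D, bins: int = 256) -> float:
    """First-order Shannon entropy in bits of the gray-level histogram.

    ``H = -sum_i p_i log2 p_i`` over a ``bins``-bin histogram of the container
    range, with ``0 * log 0 := 0``.  Lower values indicate a loss of
    structural complexity of the collagen network.
    """
    if bins < 1:
        raise ParameterError("bins must be >= 1")
    v = image.pixels.ravel().astype(np.int64)
    n_levels = image.max_value + 1
    idx = v if bins >= n_levels else (v * bins) // n_levels
    counts = np.bincount(idx, minlength=bins)
    p = counts[counts > 0] / v.size
    return float(-(p * np.log2(p)).sum())


def otsu_threshold(image: Image2D) -> int:
    """Otsu's automatic threshold.

    Returns the ``t`` maximizing the between-class variance
    ``sigma_B^2(t) = w0(t) w1(t) (mu0(t) - mu1(t))^2`` with classes
    ``{<= t}`` and ``{> t}``; ties broken toward the smallest maximizing t.
    """
    v = image.pixels.ravel().astype(np.int64)
    n_levels = image.max_value + 1
    counts = np.bincount(v, minlength=n_levels).astype(np.float64)
    if np.count_nonzero(counts) < 2:
        raise DegenerateImageError("Otsu threshold undefined for a constant image")
    p = counts / counts.sum()
    levels = np.arange(n_levels, dtype=np.float64)
    omega = np.cumsum(p)[:-1]           # class-0 mass for t = 0 .. L-2
    mu = np.cumsum(p * levels)[:-1]     # class-0 mean mass
    mu_total = float((p * levels).sum())
    sigma_b = np.zeros(n_levels - 1)
    valid = (omega > 0) & (omega < 1)
    sigma_b[valid] = (mu_total * omega[valid] - mu[valid]) ** 2 / (
        omega[valid] * (1.0 - omega[valid])
    )
    return int(np.argmax(sigma_b))  # argmax returns the first (smallest) maximizer


def percent_area(image: Image2D, threshold: int) -> float:
    """Percent of pixels strictly above ``threshold`` (positive-pixel area)."""
    if not 0 <= threshold <= image.max_value - 1:
        raise ParameterError(
            f"threshold {threshold} outside [0, {image.max_value - 1}]"
        )
    return float(100.0 * np.mean(image.pixels > threshold))


def binarize(image: Image2D, threshold: int) -> Image2D:
    """Binary {0,1} mask of pixels strictly above ``threshold``."""
    return Image2D(
        (image.pixels > threshold).astype(np.uint8), bit_depth=1, provenance="binary"
    )


# ---------------------------------------------------------------------------
# the composed pipeline
# ---------------------------------------------------------------------------

def quantify_sample(
    stack: ImageStack,
    roi: RoiSpec | str = "auto",
    config: PipelineConfig | None = None,
    sample_id: str = "",
    group_factors: Mapping[str, str] | None = None,
    acquisition_batch: str = "default",
) -> QuantResult:
    """Run the full quantification pipeline on one SHG stack.

    Stage order: projection -> background subtraction -> ROI ->
    mean intensity; then equalization -> first-order entropy and GLCM
    features; then Otsu threshold -> percent area.  Stage errors are wrapped
    in :class:`PipelineStageError` carrying the stage name.  Identical stack
    and config always give a bitwise-identical result.
    """
    from .texture import glcm, glcm_features  # local import avoids a cycle

    cfg = config or PipelineConfig()
    result = QuantResult(
        sample_id=sample_id,
        group_factors=dict(group_factors or {}),
        acquisition_batch=acquisition_batch,
    )

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineStageError(name, exc) from exc

    if cfg.projection == "max":
        proj = _stage("projection", max_projection, stack)
    else:
        proj = _stage("projection", single_slice, stack)
    sub = _stage(
        "background-subtraction",
        subtract_background, proj, cfg.background_method, cfg.background_param,
    )
    if roi == "auto":
        # clamp the configured window to the image so small fields of view
        # still quantify; explicit RoiSpecs stay strict
        rh = min(cfg.roi_height, sub.shape[0])
        rw = min(cfg.roi_width, sub.shape[1])
        if cfg.roi_mode == "full" or sub.shape == (rh, rw):
            roi_spec = RoiSpec(0, 0, sub.shape[0], sub.shape[1])
        else:
            roi_spec = _stage("auto-roi", auto_roi, sub, rh, rw)
    elif isinstance(roi, RoiSpec):
        roi_spec = roi
    else:
        raise ParameterError(f"roi must be an RoiSpec or 'auto', got {roi!r}")
    roi_img = _stage("roi-extraction", extract_roi, sub, roi_spec)

    result.mean_intensity = _stage("mean-intensity", mean_intensity, roi_img)

    eq = _stage("equalization", equalize, roi_img, cfg.equalize_levels)
    result.entropy_bits = _stage("entropy", shannon_entropy, eq, cfg.entropy_bins)
    try:
        g = glcm(
            eq,
            levels=cfg.glcm_levels,
            distance=cfg.glcm_distance,
            angles=cfg.glcm_angles,
            symmetric=cfg.glcm_symmetric,
        )
        result.glcm_features = glcm_features(g)
    except Exception as exc:
        raise PipelineStageError("glcm", exc) from exc

    thr_img = roi_img if cfg.threshold_on == "subtracted" else eq
    try:
        t = otsu_threshold(thr_img)
    except DegenerateImageError:
        logger.warning(
            "sample %s: constant %s image, Otsu threshold undefined; "
            "percent_area reported as NaN", sample_id, cfg.threshold_on,
        )
        result.otsu_threshold = None
        result.percent_area = float("nan")
    else:
        result.otsu_threshold = t
        result.percent_area = _stage("percent-area", percent_area, thr_img, t)
    return result
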