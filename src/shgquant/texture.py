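"""Second-order (gray-level co-occurrence) texture statistics.

The GLCM is the normalized joint histogram of gray-level pairs at a fixed
spatial offset; its scalar summaries — entropy, energy, inertia (contrast),
inverse difference moment (homogeneity) and correlation — describe how
intensity varies between neighboring pixels and are sensitive to
fibril-level disorganization that first-order statistics miss.

Conventions: gray levels are quantized uniformly over the full container
range ``[0, 2**bit_depth - 1]`` (not per-image min-max) so features inherit
the pipeline's cross-sample comparability contract; defaults are 64 levels,
distance 1, the four standard angles accumulated, symmetric. All logarithms
are base 2 so first-order and GLCM entropies share units (bits).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.feature import graycomatrix

from .exceptions import DegenerateImageError, ParameterError
from .image_io import Image2D

#: angle in degrees -> skimage angle in radians; 0 deg pairs along columns
#: (horizontal), 90 deg along rows (vertical)
_ANGLE_RAD = {0.0: 0.0, 45.0: math.pi / 4, 90.0: math.pi / 2, 135.0: 3 * math.pi / 4}

DEFAULT_ANGLES = (0.0, 45.0, 90.0, 135.0)


@dataclass
class Glcm:
    """A normalized co-occurrence matrix and the parameters that built it."""

    P: np.ndarray
    levels: int = 64
    distance: int = 1
    angles: tuple[float, ...] = DEFAULT_ANGLES
    symmetric: bool = True

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=np.float64)
        if self.P.ndim != 2 or self.P.shape[0] != self.P.shape[1]:
            raise ParameterError("P must be square")
        if np.any(self.P < 0) or not np.isclose(self.P.sum(), 1.0):
            raise ParameterError("P must be nonnegative and sum to 1")
        if self.symmetric and not np.allclose(self.P, self.P.T):
            raise ParameterError("symmetric GLCM must equal its transpose")


def quantize(image: Image2D, levels: int) -> np.ndarray:
    """Uniformly bin the container range ``[0, 2**bit_depth - 1]`` to ``levels``."""
    if levels < 2:
        raise ParameterError("levels must be >= 2")
    v = image.pixels.astype(np.int64)
    n_in = image.max_value + 1
    if levels >= n_in:
        return v
    return np.minimum((v * levels) // n_in, levels - 1)


def glcm(
    image: Image2D,
    levels: int = 64,
    distance: int = 1,
    angles: tuple[float, ...] = DEFAULT_ANGLES,
    symmetric: bool = True,
) -> Glcm:
    """Build the co-occurrence matrix, accumulated over the requested angles.

    Pair counts at each offset come from :func:`skimage.feature.graycomatrix`;
    they are summed over angles, symmetrized on request, and normalized to a
    probability matrix.
    """
    if distance < 1:
        raise ParameterError("distance must be >= 1")
    unknown = set(angles) - set(_ANGLE_RAD)
    if unknown:
        raise ParameterError(f"unsupported angles {sorted(unknown)}; use 0/45/90/135")
    if min(image.shape) <= distance:
        raise DegenerateImageError(
            f"image {image.shape} too small for co-occurrence distance {distance}"
        )
    q = quantize(image, levels)
    if q.max() >= levels:
        raise ParameterError("quantized image exceeds requested levels")
    dtype = np.uint8 if levels <= 256 else np.uint16
    counts = graycomatrix(
        q.astype(dtype),
        distances=[distance],
        angles=[_ANGLE_RAD[a] for a in angles],
        levels=levels,
        symmetric=symmetric,
        normed=False,
    )
    total = counts[:, :, 0, :].sum(axis=-1).astype(np.float64)
    if total.sum() == 0:
        raise DegenerateImageError("no co-occurring pairs at the requested offsets")
    return Glcm(
        P=total / total.sum(),
        levels=levels,
        distance=distance,
        angles=tuple(angles),
        symmetric=symmetric,
    )


def glcm_features(g: Glcm) -> dict[str, float]:
    """The five scalar GLCM summaries.

    entropy = -sum P log2 P;  energy = sum P^2;  inertia = sum (i-j)^2 P;
    idm = sum P / (1 + (i-j)^2);  correlation = sum (i-mu_i)(j-mu_j) P /
    (sigma_i sigma_j) with marginal means/SDs.  Correlation is NaN when either
    marginal SD is zero (single occupied level); the other features are still
    returned.
    """
    P = g.P
    n = P.shape[0]
    i = np.arange(n, dtype=np.float64)[:, None]
    j = np.arange(n, dtype=np.float64)[None, :]
    nz = P[P > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    energy = float((P ** 2).sum())
    diff2 = (i - j) ** 2
    inertia = float((diff2 * P).sum())
    idm = float((P / (1.0 + diff2)).sum())
    p_i = P.sum(axis=1)
    p_j = P.sum(axis=0)
    mu_i = float((i.ravel() * p_i).sum())
    mu_j = float((j.ravel() * p_j).sum())
    var_i = float(((i.ravel() - mu_i) ** 2 * p_i).sum())
    var_j = float(((j.ravel() - mu_j) ** 2 * p_j).sum())
    if var_i <= 0 or var_j <= 0:
        correlation = float("nan")
    else:
        correlation = float(
            (((i - mu_i) * (j - mu_j) * P).sum()) / math.sqrt(var_i * var_j)
        )
    return {
        "entropy": entropy,
        "energy": energy,
        "inertia": inertia,
        "idm": idm,
        "correlation": correlation,
    }
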