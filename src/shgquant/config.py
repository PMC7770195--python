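"""Pipeline configuration.

Every tunable default of the quantification pipeline lives here so a run can
be reproduced from a single config snapshot.  Values can be overridden from a
YAML file with the same keys.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from os import PathLike

import yaml

from .exceptions import ParameterError


@dataclass(frozen=True)
class PipelineConfig:
    """Defaults for :func:`shgquant.quantify.quantify_sample`.

    Attributes
    ----------
    roi_mode
        ``"auto"`` centers a ``roi_height x roi_width`` window on the
        intensity-weighted foreground centroid; ``"full"`` uses the whole
        image; an explicit :class:`~shgquant.quantify.RoiSpec` can be passed
        per call.
    background_method, background_param
        ``"mode"`` (subtract the modal gray value; robust when background
        dominates), ``"percentile"`` (param = percentile in [0, 100]) or
        ``"constant"`` (param = value).
    threshold_on
        Which image the Otsu threshold and percent-area are computed on:
        ``"subtracted"`` (background-subtracted ROI; default — preserves the
        background/fiber separation that makes percent area a collagen-amount
        measure) or ``"equalized"`` (sensitivity mode; equalization
        rank-flattens the foreground histogram and compresses percent-area
        differences between groups).
    projection
        ``"max"`` for maximum intensity z-projection, ``"single-slice"`` for
        one focal plane (middle slice).
    """

    roi_mode: str = "auto"
    roi_height: int = 500
    roi_width: int = 500
    background_method: str = "mode"
    background_param: float | None = None
    equalize_levels: int = 256
    entropy_bins: int = 256
    glcm_levels: int = 64
    glcm_distance: int = 1
    glcm_angles: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
    glcm_symmetric: bool = True
    threshold_on: str = "subtracted"
    projection: str = "max"
    detect_12bit: bool = False

    def __post_init__(self) -> None:
        if self.roi_mode not in ("auto", "full"):
            raise ParameterError(f"roi_mode must be 'auto' or 'full', got {self.roi_mode!r}")
        if self.threshold_on not in ("subtracted", "equalized"):
            raise ParameterError(
                f"threshold_on must be 'subtracted' or 'equalized', got {self.threshold_on!r}"
            )
        if self.projection not in ("max", "single-slice"):
            raise ParameterError(
                f"projection must be 'max' or 'single-slice', got {self.projection!r}"
            )
        if self.roi_height <= 0 or self.roi_width <= 0:
            raise ParameterError("ROI dimensions must be > 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["glcm_angles"] = list(d["glcm_angles"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "glcm_angles" in d:
            d["glcm_angles"] = tuple(d["glcm_angles"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | PathLike) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def replace(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)
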