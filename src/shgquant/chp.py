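"""Collagen-hybridizing-peptide (CHP) damage quantification.

CHP hybridizes to unfolded collagen triple helices, so the mean green-channel
fluorescence in an annulus-fibrosus region reports molecular-level collagen
damage.  Only intensity is quantified (no entropy or area), mirroring the SHG
mean-intensity contract: background-subtracted, no per-image normalization.

Because CHP acquisition settings typically differ between experiments (e.g.
thin-section vs in situ series), every result carries an acquisition-batch
tag and group comparisons refuse cross-batch contrasts — CHP intensity is
relative within an experiment, never an absolute value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .exceptions import BatchMismatchError, ParameterError
from .image_io import Image2D


@dataclass
class ChpImage:
    """A two-channel CHP acquisition: green = CHP, blue = nuclear counterstain."""

    green: Image2D
    blue: Image2D | None = None
    batch: str = "default"

    def __post_init__(self) -> None:
        if self.blue is not None and self.blue.shape != self.green.shape:
            raise ParameterError(
                f"channel shapes differ: green {self.green.shape} vs blue {self.blue.shape}"
            )


def chp_mean_intensity(
    img: ChpImage,
    roi,
    background_method: str = "mode",
    background_param: float | None = None,
) -> float:
    """Mean background-subtracted green intensity within the ROI.

    Re-uses the SHG subtraction operators and ROI geometry; ``roi`` is a
    :class:`~shgquant.quantify.RoiSpec` or ``"auto"``.
    """
    from .quantify import auto_roi, extract_roi, mean_intensity, subtract_background

    sub = subtract_background(img.green, background_method, background_param)
    if roi == "auto":
        roi = auto_roi(sub, *(min(500, s) for s in sub.shape))
    return mean_intensity(extract_roi(sub, roi))


def chp_cohort_compare(
    results: Sequence,
    mode: str = "aim1",
    alpha: float = 0.05,
    **kwargs,
):
    """Group comparison of CHP intensity (delegates to the stats layer).

    ``results`` are :class:`~shgquant.quantify.QuantResult` records with
    ``chp_mean_intensity`` and ``acquisition_batch`` populated.  Refuses to
    contrast results from different acquisition batches.
    """
    from .stats import run_study

    batches = {getattr(r, "acquisition_batch", "default") for r in results}
    if len(batches) > 1:
        raise BatchMismatchError(
            f"CHP intensities span acquisition batches {sorted(batches)}; "
            "intensity is only comparable within one batch"
        )
    tables = run_study(
        results, mode=mode, metrics=["chp_mean_intensity"], alpha=alpha, **kwargs
    )
    return tables["chp_mean_intensity"]
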