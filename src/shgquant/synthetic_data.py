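"""Synthetic SHG / CHP phantoms of annulus-fibrosus collagen with ground truth.

The generator emulates the features of the real imaging data the pipeline was
built for: lamellar crimped collagen texture (alternating ±orientation per
z-slice), a tunable fibril-disruption level ``d`` (smooth phase noise plus
ablation of an exact fraction ``d`` of fiber pixels), a tunable overall SHG
intensity scale ``s``, an exact collagen area fraction ``f`` (binary mask from
quantile-thresholded smoothed noise), photon-limited Poisson noise with
Gaussian read noise, and a low-frequency background surface.  CHP phantoms
carry a ``damage`` parameter that linearly scales the expected green signal,
plus a scattered-nuclei blue counterstain channel.

The clean per-slice pattern is::

    C(x, y) = M(x, y) * A(x, y) * (c0 + (1 - c0) * 0.5 * (1 + cos(
        2*pi*nu*u + crimp * sin(2*pi*nu*v) + phi_d(x, y) + phi_slice)))

with ``(u, v)`` coordinates rotated by ±orientation (sign alternating by
slice to mimic lamellae), ``M`` the exact-coverage collagen mask, ``A`` the
ablation keep-mask and ``phi_d`` smooth phase noise of amplitude ``pi*d``.
``c0`` is a fiber baseline brightness: intact fibers emit everywhere, with
the cosine term modelling crimp contrast on top.  Observed intensity is
``Poisson(gain * s * C) + N(0, read_noise_sd) + background`` clipped to the
container range.

Everything is deterministic given the seed; cohort per-sample seeds are
derived by hashing ``(master_seed, group, index)`` so adding groups never
reshuffles existing samples.
"""

from __future__ import annotations

import hashlib
import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .chp import ChpImage
from .exceptions import DesignError, ParameterError
from .image_io import Image2D, ImageStack

# correlation lengths (pixels) of the seeded noise fields
_MASK_SIGMA = 15.0      # collagen-region blobs, lamellar scale
_PHASE_SIGMA = 25.0     # disruption phase noise
_ABLATION_SIGMA = 8.0   # fibril-scale ablation patches
_BACKGROUND_SIGMA = 60.0


@dataclass
class PhantomParams:
    """Full parameterization of one synthetic SHG/CHP sample.

    ``disruption`` and ``collagen_fraction`` are in [0, 1]; ``photon_gain``
    is the expected photon count of a unit-intensity pixel at scale 1, so the
    noise regime is photon-limited like PMT acquisition.
    """

    seed: int = 0
    shape: tuple[int, int, int] = (10, 600, 600)
    fiber_frequency: float = 0.05      # cycles / pixel
    orientation_deg: float = 30.0
    crimp_amplitude: float = 1.0
    disruption: float = 0.0
    intensity_scale: float = 1.0
    collagen_fraction: float = 0.5
    fiber_baseline: float = 0.35
    photon_gain: float = 120.0
    read_noise_sd: float = 1.0
    background_amplitude: float = 2.0
    damage: float = 0.0
    bit_depth: int = 16
    pixel_size_um: float = 1.0
    z_step_um: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.disruption <= 1.0:
            raise ParameterError(f"disruption must be in [0, 1], got {self.disruption}")
        if not 0.0 <= self.collagen_fraction <= 1.0:
            raise ParameterError(
                f"collagen_fraction must be in [0, 1], got {self.collagen_fraction}"
            )
        if not 0.0 <= self.fiber_baseline < 1.0:
            raise ParameterError("fiber_baseline must be in [0, 1)")
        for name in ("intensity_scale", "read_noise_sd", "background_amplitude",
                     "damage", "crimp_amplitude"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.photon_gain <= 0:
            raise ParameterError("photon_gain must be > 0")
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ParameterError(f"shape must be (slices, rows, cols) >= 1, got {self.shape}")


def _exact_top_fraction_mask(field_: np.ndarray, count: int) -> np.ndarray:
    """Boolean mask selecting exactly ``count`` pixels with the largest values."""
    mask = np.zeros(field_.size, dtype=bool)
    if count > 0:
        order = np.argsort(field_.ravel(), kind="stable")
        mask[order[-count:]] = True
    return mask.reshape(field_.shape)


def clean_shg_volume(p: PhantomParams) -> np.ndarray:
    """Noise-free clean pattern ``C`` in [0, 1], shape (slices, rows, cols).

    This is the ground truth the Poisson draw is taken around; exposed so
    tests and calibration can compute closed-form expectations.
    """
    n_slices, rows, cols = p.shape
    rng = np.random.default_rng([p.seed, 0])

    mask_field = gaussian_filter(rng.standard_normal((rows, cols)), _MASK_SIGMA)
    n_collagen = int(round(p.collagen_fraction * rows * cols))
    mask = _exact_top_fraction_mask(mask_field, n_collagen)

    phase_field = gaussian_filter(rng.standard_normal((rows, cols)), _PHASE_SIGMA)
    sd = phase_field.std()
    if p.disruption > 0 and sd > 0:
        phi_d = math.pi * p.disruption * (phase_field / sd)
    else:
        phi_d = np.zeros((rows, cols))

    ablation_field = gaussian_filter(rng.standard_normal((rows, cols)), _ABLATION_SIGMA)
    keep = mask.copy()
    n_fiber = int(mask.sum())
    n_ablate = int(round(p.disruption * n_fiber))
    if n_ablate > 0:
        fiber_vals = ablation_field[mask]
        order = np.argsort(fiber_vals, kind="stable")
        fiber_idx = np.flatnonzero(mask.ravel())
        keep.ravel()[fiber_idx[order[:n_ablate]]] = False

    y, x = np.mgrid[0:rows, 0:cols].astype(np.float32)
    phi_d = phi_d.astype(np.float32)
    out = np.empty((n_slices, rows, cols), dtype=np.float32)
    c0 = np.float32(p.fiber_baseline)
    two_pi_nu = 2.0 * math.pi * p.fiber_frequency
    # the two lamellar orientations alternate by slice; precompute both
    # stripe-phase fields (carrier + crimp modulation + disruption phase)
    base_phase = {}
    for sign in (1.0, -1.0):
        alpha = math.radians(sign * p.orientation_deg)
        u = np.float32(math.cos(alpha)) * x + np.float32(math.sin(alpha)) * y
        v = np.float32(-math.sin(alpha)) * x + np.float32(math.cos(alpha)) * y
        base_phase[sign] = (
            np.float32(two_pi_nu) * u
            + np.float32(p.crimp_amplitude) * np.sin(np.float32(two_pi_nu) * v)
            + phi_d
        )
    for s in range(n_slices):
        sign = 1.0 if s % 2 == 0 else -1.0
        phi_s = np.float32(rng.uniform(0.0, 2.0 * math.pi))
        w = 0.5 * (1.0 + np.cos(base_phase[sign] + phi_s))
        out[s] = np.where(keep, c0 + (np.float32(1.0) - c0) * w, np.float32(0.0))
    return out


def _background_surface(p: PhantomParams, rows: int, cols: int, stream: int) -> np.ndarray:
    """Low-frequency background in [0, 1], shared across slices."""
    rng = np.random.default_rng([p.seed, stream])
    surf = gaussian_filter(rng.standard_normal((rows, cols)), _BACKGROUND_SIGMA)
    lo, hi = surf.min(), surf.max()
    if hi > lo:
        surf = (surf - lo) / (hi - lo)
    else:
        surf = np.zeros((rows, cols))
    return surf


def _observe(lam: np.ndarray, p: PhantomParams, noise_stream: int,
             bg_stream: int) -> np.ndarray:
    """Apply the Poisson + read-noise + background observation model."""
    rng = np.random.default_rng([p.seed, noise_stream])
    img = np.zeros(lam.shape, dtype=np.float32)
    pos = lam > 0  # Poisson(0) is identically 0; draw only where the rate is positive
    img[pos] = rng.poisson(lam[pos])
    if p.read_noise_sd > 0:
        img += np.float32(p.read_noise_sd) * rng.standard_normal(
            lam.shape, dtype=np.float32
        )
    if p.background_amplitude > 0:
        surf = _background_surface(p, lam.shape[-2], lam.shape[-1], bg_stream)
        img += np.float32(p.background_amplitude) * surf.astype(np.float32)
    max_val = (1 << p.bit_depth) - 1
    np.rint(img, out=img)
    np.clip(img, 0, max_val, out=img)
    return img.astype(np.uint8 if p.bit_depth == 8 else np.uint16)


def generate_shg_stack(p: PhantomParams) -> ImageStack:
    """Generate one SHG z-stack; deterministic given ``p.seed``."""
    clean = clean_shg_volume(p)
    lam = p.photon_gain * p.intensity_scale * clean
    voxels = _observe(lam, p, noise_stream=1, bg_stream=2)
    return ImageStack(
        voxels=voxels,
        pixel_size_um=p.pixel_size_um,
        z_step_um=p.z_step_um,
        bit_depth=p.bit_depth,
        channel_label="SHG",
    )


def clean_chp_pattern(p: PhantomParams) -> np.ndarray:
    """Noise-free 2-D fibrous pattern (single slice) for the CHP green channel.

    Disruption is *not* applied here: SHG reports intact fibrils (disruption
    ablates them), whereas CHP hybridizes to unfolded collagen wherever
    fibrous tissue is present — damaged regions bind more peptide, not less.
    The expected green signal therefore scales only with ``damage`` (and the
    collagen footprint ``f``).
    """
    p2 = replace(p, shape=(1, p.shape[1], p.shape[2]), disruption=0.0)
    return clean_shg_volume(p2)[0]


def generate_chp_image(p: PhantomParams, n_nuclei: int = 150,
                       batch: str = "default") -> ChpImage:
    """Generate a two-channel CHP image.

    Green channel: expected signal ``photon_gain * damage * C(x, y)`` (damage
    scales the mean linearly) observed under the same noise model as SHG.
    Blue channel: scattered Gaussian nuclei blobs as a counterstain stand-in.
    """
    rows, cols = p.shape[1], p.shape[2]
    clean = clean_chp_pattern(p)
    lam = p.photon_gain * p.damage * clean
    green = _observe(lam, p, noise_stream=3, bg_stream=4)

    rng = np.random.default_rng([p.seed, 5])
    impulses = np.zeros((rows, cols))
    rr = rng.integers(0, rows, size=n_nuclei)
    cc = rng.integers(0, cols, size=n_nuclei)
    np.add.at(impulses, (rr, cc), 60.0 * p.photon_gain)
    blobs = gaussian_filter(impulses, 2.5)
    max_val = (1 << p.bit_depth) - 1
    blue = np.clip(np.rint(blobs), 0, max_val).astype(
        np.uint8 if p.bit_depth == 8 else np.uint16
    )
    return ChpImage(
        green=Image2D(green, bit_depth=p.bit_depth, provenance="raw-projection"),
        blue=Image2D(blue, bit_depth=p.bit_depth, provenance="raw-projection"),
        batch=batch,
    )


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortDesign:
    """A factorial study design mapped onto phantom parameters.

    ``factors`` is an ordered mapping factor name -> levels; cells are the
    cartesian product.  ``n_per_group`` is either one integer for all cells
    or a mapping cell tuple -> n.  ``effects`` maps a cell tuple — or a single
    level name, applying to every cell containing that level — to parameter
    overrides applied on top of ``base_params``.
    """

    factors: dict[str, tuple[str, ...]]
    n_per_group: int | Mapping[tuple[str, ...], int]
    base_params: PhantomParams = field(default_factory=PhantomParams)
    effects: dict = field(default_factory=dict)
    master_seed: int = 0
    modality: str = "both"  # "shg" | "chp" | "both"
    batch: str = "default"

    def __post_init__(self) -> None:
        if not self.factors:
            raise DesignError("design needs at least one factor")
        for name, levels in self.factors.items():
            if len(levels) == 0:
                raise DesignError(f"factor {name!r} has no levels")
        if self.modality not in ("shg", "chp", "both"):
            raise DesignError(f"unknown modality {self.modality!r}")

    def cells(self) -> list[tuple[str, ...]]:
        return list(itertools.product(*self.factors.values()))

    def n_for(self, cell: tuple[str, ...]) -> int:
        if isinstance(self.n_per_group, int):
            return self.n_per_group
        try:
            return int(self.n_per_group[cell])
        except KeyError:
            raise DesignError(f"n_per_group missing cell {cell}")

    def params_for(self, cell: tuple[str, ...]) -> PhantomParams:
        overrides: dict = {}
        for key, delta in self.effects.items():
            if isinstance(key, str):
                if key in cell:
                    overrides.update(delta)
            elif tuple(key) == cell:
                overrides.update(delta)
        return replace(self.base_params, **overrides)


@dataclass
class CohortSample:
    sample_id: str
    group_factors: dict[str, str]
    params: PhantomParams
    stack: ImageStack | None
    chp: ChpImage | None


def sample_seed(master_seed: int, group_label: str, index: int) -> int:
    """Stable per-sample seed: hashing keeps existing samples fixed when
    groups are added."""
    digest = hashlib.blake2b(
        f"{master_seed}|{group_label}|{index}".encode(), digest_size=8
    ).digest()
    return int.from_bytes(digest[:4], "big") & 0x7FFFFFFF


def generate_cohort(design: CohortDesign) -> tuple[list[CohortSample], pd.DataFrame]:
    """Generate all samples of a design plus the ground-truth table."""
    samples: list[CohortSample] = []
    truth_rows: list[dict] = []
    factor_names = list(design.factors)
    for cell in design.cells():
        n = design.n_for(cell)
        if n < 2:
            raise DesignError(f"cell {cell} has n={n}; every group needs n >= 2")
        cell_label = ":".join(cell)
        cell_params = design.params_for(cell)
        for i in range(n):
            seed = sample_seed(design.master_seed, cell_label, i)
            p = replace(cell_params, seed=seed)
            sid = f"{cell_label}_{i:02d}"
            stack = generate_shg_stack(p) if design.modality in ("shg", "both") else None
            chp = (
                generate_chp_image(p, batch=design.batch)
                if design.modality in ("chp", "both") else None
            )
            samples.append(CohortSample(
                sample_id=sid,
                group_factors=dict(zip(factor_names, cell)),
                params=p,
                stack=stack,
                chp=chp,
            ))
            truth_rows.append({
                "sample_id": sid,
                **dict(zip(factor_names, cell)),
                "seed": seed,
                "disruption": p.disruption,
                "intensity_scale": p.intensity_scale,
                "collagen_fraction": p.collagen_fraction,
                "damage": p.damage,
            })
    return samples, pd.DataFrame(truth_rows)


# study-design presets -------------------------------------------------------

#: control-arm phantom state shared by both presets: mild baseline disruption
#: and unit intensity/damage scales
_BASE_CONTROL = dict(disruption=0.15, intensity_scale=1.0,
                     collagen_fraction=0.5, damage=1.0)

#: dietary-challenge arm: dimmer, more disrupted, slightly less collagen,
#: more molecular damage (effect sizes several-fold the within-group spread)
AIM1_HIGH_AGE_EFFECT = dict(
    intensity_scale=0.72, disruption=0.45, collagen_fraction=0.46, damage=1.8,
)

#: AGE-challenged wild-type organ-culture cell; the other three cells stay at
#: the control state (the knockout is protective)
AIM2_WT_AGE_EFFECT = dict(intensity_scale=0.35, disruption=0.45, damage=1.6)


def aim1_design(master_seed: int = 0, null: bool = False,
                base_params: PhantomParams | None = None,
                effects: dict | None = None) -> CohortDesign:
    """In-vivo-style dietary design: sex x diet, n = 12 low / 11 high.

    Thin-section geometry: ~10 µm depth at 1.5 µm steps (7 optical slices).
    """
    base = base_params or PhantomParams(
        shape=(7, 600, 600), z_step_um=1.5, **_BASE_CONTROL,
    )
    if effects is None:
        effects = {} if null else {"H-AGE": dict(AIM1_HIGH_AGE_EFFECT)}
    return CohortDesign(
        factors={"sex": ("F", "M"), "diet": ("L-AGE", "H-AGE")},
        n_per_group={
            ("F", "L-AGE"): 6, ("M", "L-AGE"): 6,
            ("F", "H-AGE"): 6, ("M", "H-AGE"): 5,
        },
        base_params=base,
        effects=effects,
        master_seed=master_seed,
        modality="both",
        batch="in-vivo",
    )


def aim2_design(master_seed: int = 0, null: bool = False,
                base_params: PhantomParams | None = None,
                effects: dict | None = None, n: int = 5) -> CohortDesign:
    """Organ-culture design: genotype x treatment, n = 5 per cell.

    In situ geometry: 100 µm depth at 10 µm steps (10 optical slices).
    """
    base = base_params or PhantomParams(
        shape=(10, 600, 600), z_step_um=10.0, **_BASE_CONTROL,
    )
    if effects is None:
        effects = {} if null else {("WT", "AGE-BSA"): dict(AIM2_WT_AGE_EFFECT)}
    return CohortDesign(
        factors={"genotype": ("WT", "RAGE-KO"), "treatment": ("Control", "AGE-BSA")},
        n_per_group=n,
        base_params=base,
        effects=effects,
        master_seed=master_seed,
        modality="both",
        batch="ex-vivo",
    )
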