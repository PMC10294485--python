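"""Reinhard color-transfer stain normalization (fast variant).

Tile colors are mapped into Ruderman's decorrelated log-opponent lαβ space
(RGB -> LMS via a fixed matrix, elementwise log, then a fixed orthogonal
transform), where each channel of the tile is affinely rescaled so its mean
and standard deviation match a stored target, and mapped back to RGB with
gamut clipping.  The "fast" variant applies no separate percentile-based
brightness standardization before the transfer; the luminance channel l is
normalized by the same affine map as the opponent channels.

The log is taken as log(LMS + 1) with LMS computed from RGB scaled to
[0, 1], which guards log(0) on black pixels; the log base cancels inside
the affine transfer, so this choice only affects the stored constants, not
the normalized images.
"""

from __future__ import annotations

import json
import logging
import functools
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, ZeroVarianceError

logger = logging.getLogger(__name__)

SPACE_TAG = "ruderman-lab-log1p"

# Reinhard et al. color transfer matrices.
_RGB2LMS = np.array(
    [
        [0.3811, 0.5783, 0.0402],
        [0.1967, 0.7244, 0.0782],
        [0.0241, 0.1288, 0.8444],
    ]
)
_LMS2RGB = np.linalg.inv(_RGB2LMS)

_D = np.diag([1.0 / np.sqrt(3.0), 1.0 / np.sqrt(6.0), 1.0 / np.sqrt(2.0)])
_B = np.array([[1.0, 1.0, 1.0], [1.0, 1.0, -2.0], [1.0, -1.0, 0.0]])
_LOG2LAB = _D @ _B
_LAB2LOG = np.linalg.inv(_LOG2LAB)


@dataclass(frozen=True)
class ReinhardFit:
    """Target per-channel mean and standard deviation in lαβ space."""

    target_mean: tuple[float, float, float]
    target_std: tuple[float, float, float]
    space_tag: str = SPACE_TAG

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.target_std):
            raise ParameterError("target_std must be positive componentwise")

    def to_json(self) -> str:
        return json.dumps(
            {
                "space_tag": self.space_tag,
                "target_mean": list(self.target_mean),
                "target_std": list(self.target_std),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ReinhardFit":
        d = json.loads(text)
        return cls(
            target_mean=tuple(d["target_mean"]),
            target_std=tuple(d["target_std"]),
            space_tag=d.get("space_tag", SPACE_TAG),
        )

    def key(self) -> tuple:
        return (self.space_tag, tuple(self.target_mean), tuple(self.target_std))


def rgb_to_lab(image: np.ndarray) -> np.ndarray:
    """8-bit (or [0,255] float) RGB -> float lαβ image."""
    x = np.asarray(image, dtype=np.float64) / 255.0
    lms = x @ _RGB2LMS.T
    log_lms = np.log(np.maximum(lms, 0.0) + 1.0)
    return log_lms @ _LOG2LAB.T


def lab_to_rgb(lab: np.ndarray) -> np.ndarray:
    """Inverse map with clipping to the 8-bit gamut; returns uint8."""
    log_lms = np.asarray(lab, dtype=np.float64) @ _LAB2LOG.T
    lms = np.expm1(log_lms)
    x = np.maximum(lms, 0.0) @ _LMS2RGB.T
    return np.clip(np.round(x * 255.0), 0, 255).astype(np.uint8)


def rgb_lab_roundtrip(image: np.ndarray, direction: str) -> np.ndarray:
    """Spec-style single entry point: direction in {'to_lab', 'to_rgb'}."""
    if direction == "to_lab":
        return rgb_to_lab(image)
    if direction == "to_rgb":
        return lab_to_rgb(image)
    raise ParameterError(f"unknown direction {direction!r}")


def fit_reinhard(reference: np.ndarray | None = None, preset: bool = False) -> ReinhardFit:
    """Fit targets from a reference image, or return the shipped preset.

    With an image, targets are the per-channel mean and standard deviation
    of its lαβ representation.  A constant image has zero variance and is
    rejected.
    """
    if preset:
        return preset_fit()
    if reference is None:
        raise ParameterError("provide a reference image or preset=True")
    lab = rgb_to_lab(reference)
    mean = lab.reshape(-1, 3).mean(axis=0)
    std = lab.reshape(-1, 3).std(axis=0)
    if np.any(std <= 1e-12):
        raise ZeroVarianceError("reference image has a zero-variance lαβ channel")
    return ReinhardFit(target_mean=tuple(mean), target_std=tuple(std))


def transfer_lab(lab: np.ndarray, fit: ReinhardFit) -> np.ndarray:
    """Affine moment transfer in lαβ (no gamut clipping).

    The output's per-channel mean and std equal the fit targets exactly.
    Raises if a channel of the input has (numerically) zero variance.
    """
    flat = lab.reshape(-1, 3)
    mu = flat.mean(axis=0)
    sd = flat.std(axis=0)
    if np.any(sd <= 1e-12):
        raise ZeroVarianceError("tile has a zero-variance lαβ channel")
    return (lab - mu) / sd * np.asarray(fit.target_std) + np.asarray(fit.target_mean)


def apply_reinhard(tile: np.ndarray, fit: ReinhardFit) -> np.ndarray:
    """Normalize one 8-bit RGB tile against the fit; returns uint8 RGB.

    A tile with a zero-variance lαβ channel (blank tile) is returned
    unchanged with a logged warning: such tiles should already have been
    removed by the low-contrast filter.
    """
    lab = rgb_to_lab(tile)
    try:
        lab_out = transfer_lab(lab, fit)
    except ZeroVarianceError:
        logger.warning("zero-variance tile passed through stain normalization unchanged")
        return np.asarray(tile, dtype=np.uint8)
    return lab_to_rgb(lab_out)


# --- shipped preset -----------------------------------------------------


def reference_tile() -> np.ndarray:
    """Synthetic 256x256 H&E-like reference tile (deterministic).

    A synthetic stand-in for a real stained-tissue reference: pink base,
    purple nuclei-like spots and a small bright strip, generated from a
    fixed seed so the preset fit is a package constant.
    """
    from .synthetic import (
        CohortSpec, DatasetSpec, IDENTITY_CAST, render_slide_image,
    )

    spec = CohortSpec(
        datasets=(DatasetSpec("REF", 1, 1),),
        slide_size=(256, 256),
        tissue_fraction=0.9,
        seed=0,
    )
    rng = np.random.default_rng(np.random.SeedSequence([20230626]))
    img, _, _ = render_slide_image("tumor", spec, IDENTITY_CAST, rng)
    return img


@functools.lru_cache(maxsize=1)
def preset_fit() -> ReinhardFit:
    """The package's fixed normalization target (lαβ stats of the reference tile)."""
    return fit_reinhard(reference_tile())
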