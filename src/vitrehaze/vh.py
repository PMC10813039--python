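"""Vitreous haze (VH) scoring.

The VH score of an eye is the ratio of the mean raw intensity of all
vitreous pixels (strictly above the segmented ILM) to the mean raw
intensity of all pixels at or below the ILM, pooled over every
non-failed A-scan of the macular volume.  Because it is a ratio of
means, the score is invariant to a global intensity gain, and it is
deliberately computed on raw data: display contrast transforms inflate
the relative vitreous signal and would bias the score upward.

All downstream modelling uses the natural-log-transformed score,
``log(ratio + eps)`` with a small epsilon so a zero ratio stays finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContrastStateError, UndefinedScoreError, VitrehazeError
from .ilm import IlmSurface
from .phantom import RawOctVolume

DEFAULT_LOG_EPS = 1e-6


@dataclass(frozen=True)
class VhScore:
    """Haze ratio of one volume plus the pixel accounting behind it."""

    ratio: float
    log_ratio: float
    n_vitreous_px: int
    n_below_px: int
    n_excluded_ascans: int


def log_transform(ratio: float, eps: float = DEFAULT_LOG_EPS) -> float:
    """Natural log of ``ratio + eps``; strictly increasing in ratio.

    The epsilon keeps a zero ratio finite at ``log(eps)``; with the
    default 1e-6 a ratio of 1 maps to ~0.
    """
    if ratio < 0:
        raise VitrehazeError("haze ratio cannot be negative")
    if eps <= 0:
        raise VitrehazeError("eps must be positive")
    return float(np.log(ratio + eps))


def compute_vh(
    volume: RawOctVolume,
    surface: IlmSurface,
    eps: float = DEFAULT_LOG_EPS,
    denominator: str = "below_ilm",
    allow_contrast_adjusted: bool = False,
) -> VhScore:
    """Compute the haze score of a volume given its ILM surface.

    Pixels are pooled across the whole volume (grand means, not
    per-B-scan averages).  Failed A-scans contribute to neither mean.

    Parameters
    ----------
    denominator : ``"below_ilm"`` uses every pixel at or below the ILM
        (the complement of the vitreous); ``"retina_only"`` restricts it
        to a fixed-thickness band below the ILM for sensitivity
        analysis (half the remaining depth).
    allow_contrast_adjusted : the score is defined on raw data; set this
        only to demonstrate the inflation caused by display transforms.
    """
    if volume.is_contrast_adjusted and not allow_contrast_adjusted:
        raise ContrastStateError("haze is defined on raw data, not display-adjusted data")
    d = surface.depth_index
    if d.shape != volume.intensities.shape[:2]:
        raise VitrehazeError("surface dimensions do not match the volume")
    nb, na, nd = volume.intensities.shape
    valid = (d >= 0) & (d < nd)
    n_excluded = int((~valid).sum())
    if not valid.any():
        raise UndefinedScoreError("all A-scans failed segmentation")

    depth = np.arange(nd)[None, None, :]
    ilm = np.where(valid, d, nd)[..., None]  # failed A-scans: no vitreous pixels
    above = (depth < ilm) & valid[..., None]
    if denominator == "below_ilm":
        below = (depth >= ilm) & valid[..., None]
    elif denominator == "retina_only":
        band = np.minimum(nd, ilm + (nd - ilm) // 2)
        below = (depth >= ilm) & (depth < band) & valid[..., None]
    else:
        raise VitrehazeError(f"unknown denominator policy {denominator!r}")

    n_vit = int(above.sum())
    n_below = int(below.sum())
    if n_vit == 0:
        raise UndefinedScoreError("no vitreous pixels (ILM at the top of every A-scan)")
    if n_below == 0:
        raise UndefinedScoreError("no pixels below the ILM")
    num = float(volume.intensities[above].mean())
    den = float(volume.intensities[below].mean())
    if den <= np.finfo(float).eps:
        raise UndefinedScoreError("sub-ILM mean intensity is numerically zero")
    ratio = num / den
    return VhScore(
        ratio=ratio,
        log_ratio=log_transform(ratio, eps),
        n_vitreous_px=n_vit,
        n_below_px=n_below,
        n_excluded_ascans=n_excluded,
    )


def average_log_vh(scores) -> float:
    """Average multiple volumes of the same eye on the log scale."""
    scores = list(scores)
    if not scores:
        raise VitrehazeError("no scores to average")
    return float(np.mean([s.log_ratio for s in scores]))
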