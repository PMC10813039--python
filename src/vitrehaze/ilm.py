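"""Internal limiting membrane (ILM) detection on raw OCT volumes.

The ILM separates the dark vitreous from the bright inner retina, so
each A-scan shows a sharp intensity rise at the ILM.  The detector is a
running-baseline rule: intensities are median-smoothed along depth, a
robust vitreous baseline (median) and spread (scaled MAD) are tracked in
a trailing window, and the ILM is the first depth whose smoothed
intensity exceeds ``baseline + k * robust_sd``.  The resulting surface
is median-filtered across neighbouring A-scans.  A-scans with no
qualifying rise are flagged failed (depth -1) and excluded downstream
rather than interpolated.

The threshold is relative to the data, so detection is invariant to a
global intensity gain, and exact on noiseless step profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter

from .errors import ConfigError, ContrastStateError
from .phantom import RawOctVolume

#: failure fraction above which a whole volume is considered unusable
VOLUME_FAILURE_THRESHOLD = 0.5


@dataclass(eq=False)
class IlmSurface:
    """Per-A-scan ILM depth indices; -1 marks a failed A-scan."""

    depth_index: np.ndarray  # int, shape (n_bscans, n_ascans)

    def __post_init__(self):
        self.depth_index = np.asarray(self.depth_index, dtype=np.int64)
        if self.depth_index.ndim != 2:
            raise ConfigError("depth_index must be 2-D (b_scan, a_scan)")

    @property
    def failed(self) -> np.ndarray:
        return self.depth_index < 0

    @property
    def n_failed(self) -> int:
        return int(self.failed.sum())

    @property
    def failure_fraction(self) -> float:
        return self.n_failed / self.depth_index.size

    @property
    def volume_failed(self) -> bool:
        """Whole-volume segmentation failure signal (QC rejection)."""
        return self.failure_fraction > VOLUME_FAILURE_THRESHOLD


def segment_ilm(
    volume: RawOctVolume,
    k: float = 4.0,
    axial_window: int = 3,
    lateral_window: int = 5,
    baseline_window: int = 16,
    min_lead: int = 8,
    sd_floor_frac: float = 0.05,
    persist: int = 2,
) -> IlmSurface:
    """Detect the ILM surface in a raw volume.

    Parameters
    ----------
    k : threshold in robust SDs above the running vitreous baseline.
    axial_window : depth median-smoothing window (odd).
    lateral_window : across-A-scan median filter applied to the surface.
    baseline_window : trailing window for the running baseline/MAD.
    min_lead : minimum number of vitreous pixels required above the ILM;
        boundaries shallower than this cannot be detected and the A-scan
        is flagged failed.
    sd_floor_frac : floor on the robust SD as a fraction of the baseline,
        guarding against MAD underestimation in small windows (relative,
        so gain invariance is preserved).
    persist : number of consecutive depths that must exceed the
        threshold; rejects isolated speckle spikes without shifting the
        detected boundary.

    Haze scoring is defined on raw data, so contrast-adjusted input is
    refused.
    """
    if volume.is_contrast_adjusted:
        raise ContrastStateError("ILM segmentation requires raw (unadjusted) data")
    if axial_window < 1 or axial_window % 2 == 0:
        raise ConfigError("axial_window must be odd and >= 1")
    nb, na, nd = volume.intensities.shape
    sm = median_filter(volume.intensities, size=(1, 1, axial_window), mode="nearest")

    flat = sm.reshape(nb * na, nd)
    depth = np.full(nb * na, -1, dtype=np.int64)
    found = np.zeros(nb * na, dtype=bool)
    gmax = float(flat.max())
    for j in range(min_lead, nd):
        lo = max(0, j - baseline_window)
        window = flat[:, lo:j]
        base = np.median(window, axis=1)
        mad = np.median(np.abs(window - base[:, None]), axis=1)
        sd = 1.4826 * mad
        # relative floor keeps the rule scale-invariant while rejecting
        # numerically flat profiles
        floor = np.maximum(sd_floor_frac * np.abs(base), 1e-12 * gmax)
        thresh = base + k * np.maximum(sd, floor)
        hit = flat[:, j] > thresh
        for step in range(1, persist):
            if j + step < nd:
                hit &= flat[:, j + step] > thresh
        hit &= ~found
        depth[hit] = j
        found |= hit
        if found.all():
            break

    surface = IlmSurface(depth.reshape(nb, na))
    if lateral_window > 1:
        surface = surface_smooth(surface, lateral_window)
    return surface


def surface_smooth(surface: IlmSurface, window: int = 5) -> IlmSurface:
    """2-D median filter of the surface, ignoring failed A-scans.

    Each non-failed entry is replaced by the median of the non-failed
    entries in its ``window x window`` neighbourhood; failed entries
    stay failed.  Idempotent on flat surfaces.
    """
    if window < 1 or window % 2 == 0:
        raise ConfigError("window must be odd and >= 1")
    if window == 1:
        return IlmSurface(surface.depth_index.copy())
    d = surface.depth_index
    nb, na = d.shape
    half = window // 2
    padded = np.pad(d.astype(np.float64), half, mode="edge")
    padded[padded < 0] = np.nan
    sw = np.lib.stride_tricks.sliding_window_view(padded, (window, window))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(sw.reshape(nb, na, -1), axis=-1)
    out = np.where(d < 0, -1, np.rint(np.nan_to_num(med, nan=-1.0))).astype(np.int64)
    return IlmSurface(out)
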