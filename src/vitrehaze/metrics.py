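"""Retinal layer thickness summaries.

Macular layer thicknesses (mGCIPL, mINL) are summarised on an
ETDRS-style grid centred on the fovea: concentric circles of 1.0, 2.22
and 3.4 mm diameter divide the macula into a central circle plus four
inner-ring and four outer-ring quadrant sectors.  The summary is the
unweighted mean of the 8 sector means, excluding the central 1.0 mm
circle.  Peripapillary RNFL (pRNFL) thickness is the global mean over a
circular scan around the optic nerve head.

Quadrants are split along the 45 degree diagonals; the nasal/temporal
orientation mirrors with eye laterality (OD/OS).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import VitrehazeError

#: ETDRS grid radii in mm: central exclusion, inner ring, outer ring.
GRID_RADII_MM = (0.5, 1.11, 1.7)

SECTOR_NAMES = (
    "inner_superior",
    "inner_nasal",
    "inner_inferior",
    "inner_temporal",
    "outer_superior",
    "outer_nasal",
    "outer_inferior",
    "outer_temporal",
)


@dataclass(eq=False)
class ThicknessMap:
    """Per-A-scan layer thickness (µm) on the macular raster.

    ``fovea_center`` is the (b_scan, a_scan) coordinate of the foveal
    centre; spacings convert raster indices to retinal mm.
    """

    thickness_um: np.ndarray  # (n_bscans, n_ascans)
    lateral_spacing_um: float  # along A-scans
    bscan_spacing_um: float  # between B-scans
    fovea_center: tuple  # (b_scan, a_scan), may be fractional

    def __post_init__(self):
        self.thickness_um = np.asarray(self.thickness_um, dtype=np.float64)
        if self.thickness_um.ndim != 2:
            raise VitrehazeError("thickness map must be 2-D")
        if np.any(self.thickness_um < 0):
            raise VitrehazeError("thickness must be non-negative")
        b, a = self.fovea_center
        nb, na = self.thickness_um.shape
        if not (0 <= b < nb and 0 <= a < na):
            raise VitrehazeError("fovea centre outside the map")


@dataclass(frozen=True)
class SectorSummary:
    """Means of the 8 ETDRS quadrant sectors and their grand mean."""

    sector_means_um: dict
    grand_mean_um: float


def _sector_labels(map_: ThicknessMap, eye: str) -> np.ndarray:
    """Per-pixel sector index 0..7 (order = SECTOR_NAMES) or -1 if excluded."""
    if eye not in ("OD", "OS"):
        raise VitrehazeError("eye must be 'OD' or 'OS'")
    nb, na = map_.thickness_um.shape
    fb, fa = map_.fovea_center
    y = -(np.arange(nb)[:, None] - fb) * map_.bscan_spacing_um / 1000.0  # +y = superior
    x = (np.arange(na)[None, :] - fa) * map_.lateral_spacing_um / 1000.0
    if eye == "OD":
        x = -x  # nasal side of an OD scan lies at decreasing a-scan index
    # now +x = nasal for either eye
    x = np.broadcast_to(x, (nb, na))
    y = np.broadcast_to(y, (nb, na))
    r = np.hypot(x, y)

    ring = np.full((nb, na), -1, dtype=np.int64)
    ring[(r > GRID_RADII_MM[0]) & (r <= GRID_RADII_MM[1])] = 0
    ring[(r > GRID_RADII_MM[1]) & (r <= GRID_RADII_MM[2])] = 1

    ang = np.degrees(np.arctan2(y, x))  # 0 = nasal, 90 = superior
    quad = np.full((nb, na), 0, dtype=np.int64)
    quad[(ang > 45) & (ang <= 135)] = 0  # superior
    quad[(ang > -45) & (ang <= 45)] = 1  # nasal
    quad[(ang > -135) & (ang <= -45)] = 2  # inferior
    quad[(ang <= -135) | (ang > 135)] = 3  # temporal

    sector = np.where(ring < 0, -1, ring * 4 + quad)
    return sector


def sector_average(map_: ThicknessMap, eye: str = "OD") -> SectorSummary:
    """ETDRS sector means and their unweighted grand mean.

    Raises if the 3.4 mm circle extends beyond the scanned raster or if
    any sector contains no pixels.
    """
    nb, na = map_.thickness_um.shape
    fb, fa = map_.fovea_center
    half_b = (nb - 1) * map_.bscan_spacing_um / 2000.0
    half_a = (na - 1) * map_.lateral_spacing_um / 2000.0
    # the outer circle must fit inside the raster around the fovea
    reach_b = min(fb, nb - 1 - fb) * map_.bscan_spacing_um / 1000.0
    reach_a = min(fa, na - 1 - fa) * map_.lateral_spacing_um / 1000.0
    if min(reach_b, reach_a) < GRID_RADII_MM[2]:
        raise VitrehazeError(
            "the 3.4 mm ETDRS circle extends beyond the thickness map "
            f"(reach {reach_b:.2f} x {reach_a:.2f} mm around the fovea)"
        )
    sector = _sector_labels(map_, eye)
    means = {}
    for idx, name in enumerate(SECTOR_NAMES):
        mask = sector == idx
        if not mask.any():
            raise VitrehazeError(f"sector {name} contains no pixels")
        means[name] = float(map_.thickness_um[mask].mean())
    grand = float(np.mean(list(means.values())))
    return SectorSummary(sector_means_um=means, grand_mean_um=grand)


def prnfl_mean(circular_scan_thickness_um, valid=None) -> float:
    """Global mean pRNFL thickness over the valid A-scans of a circle scan."""
    t = np.asarray(circular_scan_thickness_um, dtype=np.float64)
    if t.ndim != 1 or t.size == 0:
        raise VitrehazeError("need a non-empty 1-D thickness vector")
    if valid is None:
        valid = np.isfinite(t)
    else:
        valid = np.asarray(valid, dtype=bool) & np.isfinite(t)
    if not valid.any():
        raise VitrehazeError("no valid A-scans on the circular scan")
    return float(t[valid].mean())
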