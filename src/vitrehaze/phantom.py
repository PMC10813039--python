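"""Synthetic OCT macular-volume phantoms with known ground truth.

A phantom volume mimics the raw A-scan intensity structure of a
spectral-domain OCT macular scan: a dark vitreous compartment above the
internal limiting membrane (ILM), piecewise-constant retinal layers
(RNFL, GCIPL, INL, ONL), narrow high-intensity peaks at the inner/outer
segment (IS/OS) junction and the retinal pigment epithelium (RPE), and a
moderately reflective choroid below.  Vitreous haze is modelled as a
non-negative intensity offset added to the vitreous baseline, so the
expected haze ratio of a phantom is known in closed form.

Noise is multiplicative log-normal speckle (mean 1, so expected
intensities are unchanged) plus optional additive Gaussian read noise;
intensities are clipped at zero.

The depth axis convention throughout the package: index 0 is the top of
the image (vitreous side), increasing toward the choroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError, ContrastStateError, InvalidGeometryError

#: Conversion used to map the 20 degree scan field to retinal distance.
MICRONS_PER_DEGREE = 300.0

#: Ordered layer segments rendered below the ILM.  Each entry is
#: (name, reference thickness in pixels at a 128-pixel depth axis,
#: intensity).  The last segment ("choroid") extends to the bottom of
#: the scan regardless of its nominal thickness.
DEFAULT_LAYER_STACK = (
    ("rnfl", 10, 0.75),
    ("gcipl", 12, 0.55),
    ("inl", 8, 0.40),
    ("onl", 16, 0.20),
    ("isos", 2, 1.00),
    ("os", 4, 0.30),
    ("rpe", 2, 0.95),
    ("choroid", 0, 0.35),
)

DEFAULT_VITREOUS_BASELINE = 0.05


@dataclass(eq=False)
class RawOctVolume:
    """A 3-D OCT intensity stack with geometry metadata.

    ``intensities`` is indexed (b_scan, a_scan, depth); depth index 0 is
    the vitreous side.  ``is_contrast_adjusted`` distinguishes raw
    acquisition data (on which haze is defined) from display-transformed
    data.
    """

    intensities: np.ndarray
    axial_spacing_um: float
    lateral_spacing_um: float
    bscan_spacing_um: float
    is_contrast_adjusted: bool = False

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 3:
            raise InvalidGeometryError("intensities must be 3-D (b_scan, a_scan, depth)")
        if np.any(self.intensities < 0):
            raise InvalidGeometryError("intensities must be non-negative")
        for name in ("axial_spacing_um", "lateral_spacing_um", "bscan_spacing_um"):
            if getattr(self, name) <= 0:
                raise InvalidGeometryError(f"{name} must be positive")

    @property
    def n_bscans(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_ascans(self) -> int:
        return self.intensities.shape[1]

    @property
    def n_depth(self) -> int:
        return self.intensities.shape[2]


@dataclass(eq=False)
class PhantomTruth:
    """Ground-truth sidecar for a generated phantom volume.

    ``layer_boundaries`` has shape (n_bscans, n_ascans, n_boundaries);
    boundary ``i`` is the first depth index of segment
    ``boundary_names[i]``.  The ILM is the first boundary.
    """

    layer_boundaries: np.ndarray
    boundary_names: tuple
    layer_intensities: np.ndarray
    vitreous_baseline: float
    vitreous_haze_level: float
    noise_sigma: float

    def __post_init__(self):
        self.layer_boundaries = np.asarray(self.layer_boundaries, dtype=np.int64)
        self.layer_intensities = np.asarray(self.layer_intensities, dtype=np.float64)
        if np.any(np.diff(self.layer_boundaries, axis=-1) <= 0):
            raise InvalidGeometryError("layer boundaries must be strictly increasing")
        if self.vitreous_haze_level < 0 or self.noise_sigma < 0:
            raise ConfigError("haze level and noise sigma must be non-negative")

    @property
    def ilm_depth(self) -> np.ndarray:
        return self.layer_boundaries[..., 0]

    def thickness_um(self, top: str, bottom: str, axial_spacing_um: float) -> np.ndarray:
        """Thickness map (µm) between two named boundaries."""
        names = list(self.boundary_names)
        i, j = names.index(top), names.index(bottom)
        if j <= i:
            raise InvalidGeometryError(f"boundary {bottom!r} is not below {top!r}")
        diff = self.layer_boundaries[..., j] - self.layer_boundaries[..., i]
        return diff.astype(np.float64) * axial_spacing_um


@dataclass
class PhantomSpec:
    """Parameters for :func:`generate_volume`.

    The defaults render a reduced-size analogue of a 20x20 degree
    macular volume scan (the clinical protocol is 49 B-scans of 512
    A-scans); the raster is downsampled but the lateral spacings keep
    the full ~6 mm field (20 degrees at 300 µm/degree), so the ETDRS
    grid fits and a volume renders in milliseconds.
    """

    n_bscans: int = 12
    n_ascans: int = 64
    n_depth: int = 128
    axial_spacing_um: float = 3.87
    lateral_spacing_um: float = 20 * MICRONS_PER_DEGREE / 64
    bscan_spacing_um: float = 20 * MICRONS_PER_DEGREE / 12
    ilm_base_depth_frac: float = 0.25
    pit_depth_px: float = 8.0
    pit_radius_frac: float = 0.15
    vitreous_baseline: float = DEFAULT_VITREOUS_BASELINE
    haze_level: float = 0.01
    noise_sigma: float = 0.05
    read_noise_sigma: float = 0.0
    layer_stack: tuple = DEFAULT_LAYER_STACK
    ilm_depth_map: np.ndarray | None = None  # explicit override, shape (n_bscans, n_ascans)

    def __post_init__(self):
        if min(self.n_bscans, self.n_ascans) < 1 or self.n_depth < 8:
            raise ConfigError("volume must have >=1 B-scan/A-scan and >=8 depth pixels")
        if self.haze_level < 0 or self.noise_sigma < 0 or self.read_noise_sigma < 0:
            raise ConfigError("noise and haze parameters must be non-negative")


def generate_ascan_profile(
    boundaries,
    intensities,
    n_depth: int,
    vitreous_baseline: float = DEFAULT_VITREOUS_BASELINE,
    haze_level: float = 0.0,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
    read_noise_sigma: float = 0.0,
):
    """Render one A-scan intensity profile.

    ``boundaries`` are strictly increasing depth indices; segment ``i``
    spans ``[boundaries[i], boundaries[i+1])`` with intensity
    ``intensities[i]`` (the last segment extends to the bottom).  The
    vitreous above the first boundary gets ``vitreous_baseline +
    haze_level``.  Speckle is multiplicative log-normal with unit mean,
    so the expected profile equals the noiseless one before clipping.
    """
    boundaries = np.asarray(boundaries, dtype=np.int64)
    intensities = np.asarray(intensities, dtype=np.float64)
    if boundaries.ndim != 1 or boundaries.size != intensities.size:
        raise InvalidGeometryError("need one intensity per boundary segment")
    if np.any(np.diff(boundaries) <= 0):
        raise InvalidGeometryError("boundaries must be strictly increasing")
    if boundaries[0] < 0 or boundaries[-1] >= n_depth:
        raise InvalidGeometryError("boundaries fall outside the depth range")

    profile = np.empty(n_depth, dtype=np.float64)
    profile[: boundaries[0]] = vitreous_baseline + haze_level
    for i, start in enumerate(boundaries):
        stop = boundaries[i + 1] if i + 1 < boundaries.size else n_depth
        profile[start:stop] = intensities[i]

    if noise_sigma > 0 or read_noise_sigma > 0:
        if rng is None:
            raise ConfigError("an rng is required when noise is requested")
        if noise_sigma > 0:
            profile = profile * rng.lognormal(
                -0.5 * noise_sigma**2, noise_sigma, size=n_depth
            )
        if read_noise_sigma > 0:
            profile = profile + rng.normal(0.0, read_noise_sigma, size=n_depth)
        profile = np.clip(profile, 0.0, None)
    return profile


def _build_boundaries(spec: PhantomSpec) -> tuple[np.ndarray, tuple, np.ndarray]:
    """Boundary depth array (nb, na, K), names and segment intensities."""
    nb, na, nd = spec.n_bscans, spec.n_ascans, spec.n_depth
    if spec.ilm_depth_map is not None:
        ilm = np.asarray(spec.ilm_depth_map, dtype=np.float64)
        if ilm.shape != (nb, na):
            raise InvalidGeometryError("ilm_depth_map shape mismatch")
    else:
        # Foveal pit: the ILM dips toward the RPE near the scan centre.
        b = np.arange(nb)[:, None] - (nb - 1) / 2.0
        a = np.arange(na)[None, :] - (na - 1) / 2.0
        r2 = (b / max(nb, 2)) ** 2 + (a / max(na, 2)) ** 2
        pit = spec.pit_depth_px * np.exp(-r2 / (2 * spec.pit_radius_frac**2))
        ilm = spec.ilm_base_depth_frac * nd + pit

    scale = nd / 128.0
    thick = []
    intens = []
    for _name, ref_px, intensity in spec.layer_stack:
        thick.append(max(1, round(ref_px * scale)) if ref_px > 0 else 0)
        intens.append(intensity)
    # boundary i starts segment i; boundary 0 is the ILM (top of the RNFL)
    names = ("ilm",) + tuple(name for name, _t, _i in spec.layer_stack[1:])
    offsets = np.concatenate([[0], np.cumsum(thick[:-1])])
    bounds = np.rint(ilm)[..., None] + offsets[None, None, :]
    bounds = bounds.astype(np.int64)
    if np.any(bounds[..., 0] < 1):
        raise InvalidGeometryError("ILM reaches the top of the scan (no vitreous)")
    if np.any(bounds[..., -1] >= nd):
        raise InvalidGeometryError("layer stack extends beyond the depth range")
    return bounds, names, np.asarray(intens)


def generate_volume(
    spec: PhantomSpec, seed: int | np.random.Generator
) -> tuple[RawOctVolume, PhantomTruth]:
    """Render a phantom volume and its ground-truth sidecar.

    Reproducible: the same spec and integer seed yield bit-identical
    volumes.  The rendered ILM equals the sidecar truth exactly (noise
    perturbs intensities, never geometry).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bounds, names, intens = _build_boundaries(spec)
    nb, na, nd = spec.n_bscans, spec.n_ascans, spec.n_depth

    depth = np.arange(nd)[None, None, :]
    vol = np.full((nb, na, nd), spec.vitreous_baseline + spec.haze_level)
    n_seg = bounds.shape[-1]
    for i in range(n_seg):
        lo = bounds[..., i][..., None]
        if i + 1 < n_seg:
            hi = bounds[..., i + 1][..., None]
            mask = (depth >= lo) & (depth < hi)
        else:
            mask = depth >= lo
        vol = np.where(mask, intens[i], vol)

    if spec.noise_sigma > 0:
        vol = vol * rng.lognormal(-0.5 * spec.noise_sigma**2, spec.noise_sigma, vol.shape)
    if spec.read_noise_sigma > 0:
        vol = vol + rng.normal(0.0, spec.read_noise_sigma, vol.shape)
    vol = np.clip(vol, 0.0, None)

    volume = RawOctVolume(
        vol,
        axial_spacing_um=spec.axial_spacing_um,
        lateral_spacing_um=spec.lateral_spacing_um,
        bscan_spacing_um=spec.bscan_spacing_um,
        is_contrast_adjusted=False,
    )
    truth = PhantomTruth(
        layer_boundaries=bounds,
        boundary_names=names,
        layer_intensities=intens,
        vitreous_baseline=spec.vitreous_baseline,
        vitreous_haze_level=spec.haze_level,
        noise_sigma=spec.noise_sigma,
    )
    return volume, truth


def contrast_adjust(volume: RawOctVolume, gamma: float = 0.5) -> RawOctVolume:
    """Display transform: max-normalised gamma map (gamma < 1 brightens).

    ``x -> vmax * (x / vmax) ** gamma`` is monotone and concave for
    gamma < 1, which raises the relative vitreous signal of any volume
    whose vitreous is darker than its retina — the reason haze must be
    scored on raw data.
    """
    if volume.is_contrast_adjusted:
        raise ContrastStateError("volume is already contrast-adjusted")
    if not 0 < gamma:
        raise ConfigError("gamma must be positive")
    vmax = float(volume.intensities.max())
    if vmax == 0:
        adjusted = volume.intensities.copy()
    else:
        adjusted = vmax * (volume.intensities / vmax) ** gamma
    return replace(volume, intensities=adjusted, is_contrast_adjusted=True)


def expected_haze_ratio(spec: PhantomSpec) -> float:
    """Closed-form expected haze ratio of a phantom (noise-free geometry).

    Computed by rendering the noiseless volume once and pooling means
    above/below the true ILM — the same pooling the scorer uses.
    """
    quiet = replace(spec, noise_sigma=0.0, read_noise_sigma=0.0)
    vol, truth = generate_volume(quiet, 0)
    depth = np.arange(quiet.n_depth)[None, None, :]
    above = depth < truth.ilm_depth[..., None]
    return float(vol.intensities[above].mean() / vol.intensities[~above].mean())


def haze_for_target_ratio(spec: PhantomSpec, target_ratio: float) -> float:
    """Haze level that gives a phantom the requested expected haze ratio."""
    if target_ratio < 0:
        raise ConfigError("target ratio must be non-negative")
    quiet = replace(spec, haze_level=0.0, noise_sigma=0.0, read_noise_sigma=0.0)
    vol, truth = generate_volume(quiet, 0)
    depth = np.arange(quiet.n_depth)[None, None, :]
    above = depth < truth.ilm_depth[..., None]
    below_mean = float(vol.intensities[~above].mean())
    haze = target_ratio * below_mean - spec.vitreous_baseline
    if haze < 0:
        raise ConfigError(
            f"target ratio {target_ratio} is below the baseline ratio of this phantom"
        )
    return haze


def generate_circular_rnfl_profile(
    mean_um: float,
    rng: np.random.Generator,
    n_ascans: int = 1536,
    bundle_amplitude_um: float = 20.0,
    noise_sd_um: float = 2.0,
) -> np.ndarray:
    """Per-A-scan thickness on a circular peripapillary scan.

    The superior/inferior fibre bundles give the classic double-hump
    profile, modelled as a zero-mean ``cos(2*theta)`` modulation so the
    circular mean stays at ``mean_um``.
    """
    theta = np.linspace(0, 2 * np.pi, n_ascans, endpoint=False)
    prof = mean_um - bundle_amplitude_um * np.cos(2 * theta)
    prof = prof + rng.normal(0.0, noise_sd_um, n_ascans)
    return np.clip(prof, 0.0, None)
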