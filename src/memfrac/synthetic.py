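"""Ground-truth synthetic cells for validating the unmixing pipeline.

A cell is modeled as a disk of uniform cytoplasmic fluorophore density with
an excluded nucleus, bounded by a plasma membrane treated as an infinitely
thin circular line source (real membranes are far below optical
resolution). Each channel has its own cytoplasm density (photons/um^2),
membrane surface density (photons/um), Gaussian PSF width, translation
shift, and additive background; photon shot noise is Poisson. The source
distribution is rendered at 5x supersampling (so the thin membrane is laid
down without gridding artifacts), convolved with the PSF, and then sampled
at the final pixel centers, matching how a point-scanning confocal records
the convolved field at discrete scan positions.

For a locally planar membrane the noiseless profile perpendicular to the
membrane has a closed form: the cytoplasm edge blurs to a complementary-
error-function step c * Phi(-x/sigma) and the membrane line to a Gaussian
m / (sqrt(2 pi) sigma) * exp(-x^2 / 2 sigma^2). The ratio of the membrane
peak to the cytoplasm plateau is therefore known exactly, which is the
ground truth the pipeline must recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.special import ndtr

from .imaging_io import ChannelStack, DEFAULT_PIXEL_SIZE_UM, ROLES
from .profiles import Profile
from .roiset import LineRoi

SQRT_2PI = float(np.sqrt(2.0 * np.pi))

# Study-like defaults: cytoplasm plateau ~100 counts/px, membrane marker
# peaking at ~300% of its cytoplasm level, protein of interest at 20%.
# The cytoplasm-marker PSF is slightly wider than the others, which
# reproduces the small artifactual membrane residual seen in negative
# controls when marker and protein PSFs differ.
_DEFAULT_CYTO = {"PM_marker": 5000.0, "CP_marker": 5000.0, "POI": 5000.0}
_DEFAULT_SIGMA = {"PM_marker": 0.18, "CP_marker": 0.21, "POI": 0.18}
_DEFAULT_BG = {"PM_marker": 10.0, "CP_marker": 10.0, "POI": 10.0}


def membrane_density_for_peak(
    peak_percent: float, cyto_density: float, psf_sigma_um: float
) -> float:
    """Membrane surface density (photons/um) giving the requested peak, in
    percent of the cytoplasm plateau, under a Gaussian PSF."""
    return peak_percent / 100.0 * SQRT_2PI * psf_sigma_um * cyto_density


def _default_membrane() -> dict[str, float]:
    return {
        "PM_marker": membrane_density_for_peak(300.0, 5000.0, 0.18),
        "CP_marker": 0.0,
        "POI": membrane_density_for_peak(20.0, 5000.0, 0.18),
    }


@dataclass
class SyntheticSpec:
    """Complete ground-truth description of a simulated three-channel cell."""

    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    fov_px: int = 144
    radius_um: float = 6.0
    nucleus_radius_um: float = 2.0
    membrane_thickness_um: float = 0.0
    center_um: tuple[float, float] | None = None
    cyto_density: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_CYTO))
    membrane_density: dict[str, float] = field(default_factory=_default_membrane)
    psf_sigma_um: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_SIGMA))
    shift_px: dict[str, tuple[float, float]] = field(default_factory=dict)
    background: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_BG))
    frames: int = 8
    poisson: bool = True
    seed: int = 0
    supersample: int = 5

    def __post_init__(self) -> None:
        if self.radius_um <= self.nucleus_radius_um:
            raise ValueError("cell radius must exceed nucleus radius")
        if self.membrane_thickness_um >= self.pixel_size:
            raise ValueError("membrane is modeled as a line source (< pixel)")
        for role in ROLES:
            if self.psf_sigma_um[role] <= 0:
                raise ValueError("PSF sigma must be > 0")
            if self.cyto_density[role] < 0 or self.membrane_density[role] < 0:
                raise ValueError("densities must be >= 0")
        if self.center_um is None:
            half = self.fov_px * self.pixel_size / 2.0
            self.center_um = (half, half)

    def with_pm_peak(self, role: str, peak_percent: float) -> "SyntheticSpec":
        """Copy with the membrane density of one channel set so its
        ground-truth peak equals ``peak_percent`` of the cytoplasm level."""
        dens = dict(self.membrane_density)
        dens[role] = membrane_density_for_peak(
            peak_percent, self.cyto_density[role], self.psf_sigma_um[role]
        )
        return replace(self, membrane_density=dens)

    def matched_psfs(self, sigma_um: float = 0.18) -> "SyntheticSpec":
        return replace(self, psf_sigma_um={r: sigma_um for r in ROLES})


def expected_pm_peak(spec: SyntheticSpec, role: str) -> float:
    """Ground-truth membrane peak as percent of the cytoplasm plateau:
    100 * (m / (sqrt(2 pi) sigma)) / c for that channel's PSF."""
    c = spec.cyto_density[role]
    if c <= 0:
        raise ValueError("cytoplasm density must be > 0 for a relative peak")
    m = spec.membrane_density[role]
    sigma = spec.psf_sigma_um[role]
    return 100.0 * (m / (SQRT_2PI * sigma)) / c


def expected_cyto_counts(spec: SyntheticSpec, role: str) -> float:
    """Expected counts per pixel in the cytoplasm plateau (no background)."""
    return spec.cyto_density[role] * spec.pixel_size**2


def analytic_profiles(
    spec: SyntheticSpec, role: str, positions_um: np.ndarray | None = None
) -> Profile:
    """Closed-form noiseless profile perpendicular to the membrane
    (locally planar approximation), in counts per pixel; membrane at 0,
    cytoplasm at negative positions."""
    if positions_um is None:
        positions_um = np.arange(-25, 26) * spec.pixel_size
    x = np.asarray(positions_um, dtype=float)
    sigma = spec.psf_sigma_um[role]
    area = spec.pixel_size**2
    cyto = spec.cyto_density[role] * ndtr(-x / sigma) * area
    mem = (
        spec.membrane_density[role]
        / (SQRT_2PI * sigma)
        * np.exp(-0.5 * (x / sigma) ** 2)
        * area
    )
    return Profile(x, cyto + mem + spec.background[role], role)


def _render_channel(spec: SyntheticSpec, role: str) -> np.ndarray:
    """Noiseless expected counts per pixel for one channel."""
    s = spec.supersample
    n = spec.fov_px * s
    a = spec.pixel_size / s  # supersampled pixel size, um
    cx, cy = spec.center_um
    extent = spec.radius_um + 4 * spec.psf_sigma_um[role] + 2 * spec.pixel_size
    fov_um = spec.fov_px * spec.pixel_size
    if cx - extent < 0 or cy - extent < 0 or cx + extent > fov_um or cy + extent > fov_um:
        raise ValueError("cell (plus PSF support) exceeds the field of view")
    coords = (np.arange(n) + 0.5) * a
    yy = coords[:, None] - cy
    xx = coords[None, :] - cx
    r2 = xx * xx + yy * yy
    density = np.zeros((n, n))
    density[(r2 < spec.radius_um**2) & (r2 > spec.nucleus_radius_um**2)] = (
        spec.cyto_density[role]
    )
    m = spec.membrane_density[role]
    if m > 0:
        # deposit the circular line source bilinearly at ~a/4 arc steps
        n_pts = int(np.ceil(2 * np.pi * spec.radius_um / (a / 4)))
        theta = np.linspace(0, 2 * np.pi, n_pts, endpoint=False)
        ds = 2 * np.pi * spec.radius_um / n_pts
        px = (cx + spec.radius_um * np.cos(theta)) / a - 0.5
        py = (cy + spec.radius_um * np.sin(theta)) / a - 0.5
        w = m * ds / (a * a)  # photons per supersampled-pixel area
        ix, iy = np.floor(px).astype(int), np.floor(py).astype(int)
        fx, fy = px - ix, py - iy
        for ox, oy, wt in (
            (0, 0, (1 - fx) * (1 - fy)),
            (1, 0, fx * (1 - fy)),
            (0, 1, (1 - fx) * fy),
            (1, 1, fx * fy),
        ):
            np.add.at(density, (iy + oy, ix + ox), w * wt)
    blurred = ndimage.gaussian_filter(density, spec.psf_sigma_um[role] / a)
    # point-scanning confocal: the pixel value samples the PSF-convolved
    # field at the scan position (pixel center), it does not integrate a
    # detector aperture. With odd supersampling a sample sits exactly on
    # each final-pixel center; with even supersampling the central 2x2 mean
    # is the closest equivalent.
    if s % 2 == 1:
        c0 = (s - 1) // 2
        sampled = blurred[c0::s, c0::s]
    else:
        half = blurred.reshape(spec.fov_px, s, spec.fov_px, s)
        c0 = s // 2 - 1
        sampled = half[:, c0 : c0 + 2, :, c0 : c0 + 2].mean(axis=(1, 3))
    expected = sampled * spec.pixel_size**2
    dx, dy = spec.shift_px.get(role, (0.0, 0.0))
    if dx or dy:
        expected = ndimage.shift(expected, (dy, dx), order=1, mode="nearest")
    return expected + spec.background[role]


def make_cell_stack(spec: SyntheticSpec) -> tuple[ChannelStack, dict]:
    """Render the three channels of a synthetic cell.

    Returns the stack (frames of Poisson draws if ``spec.poisson``) plus a
    ground-truth record with the spec and the expected membrane peak and
    cytoplasm plateau per channel.
    """
    rng = np.random.default_rng(spec.seed)
    channels = {}
    for role in ROLES:
        expected = _render_channel(spec, role)
        if spec.poisson:
            frames = rng.poisson(expected, size=(spec.frames, *expected.shape))
            channels[role] = frames.astype(float)
        else:
            channels[role] = np.broadcast_to(
                expected, (spec.frames, *expected.shape)
            ).copy()
    truth = {
        "spec": spec,
        "expected_pm_peak": {
            role: (
                expected_pm_peak(spec, role) if spec.cyto_density[role] > 0 else None
            )
            for role in ROLES
        },
        "expected_cyto_counts": {role: expected_cyto_counts(spec, role) for role in ROLES},
    }
    stack = ChannelStack(channels, pixel_size=spec.pixel_size)
    return stack, truth


def radial_line_rois(
    spec: SyntheticSpec,
    n: int = 20,
    seed: int | None = None,
    inner_um: float = 3.6,
    outer_um: float = 3.0,
    width: int = 10,
) -> list[LineRoi]:
    """Line ROIs crossing the membrane radially, evenly spread in angle
    (with a random rotation if ``seed`` is given), running from the
    cytoplasm side outward."""
    rng = np.random.default_rng(seed)
    offset = rng.uniform(0, 2 * np.pi) if seed is not None else 0.0
    cx, cy = spec.center_um
    rois = []
    for k in range(n):
        theta = offset + 2 * np.pi * k / n
        ux, uy = np.cos(theta), np.sin(theta)
        r0 = spec.radius_um - inner_um
        r1 = spec.radius_um + outer_um
        rois.append(
            LineRoi(
                x1=(cx + r0 * ux) / spec.pixel_size,
                y1=(cy + r0 * uy) / spec.pixel_size,
                x2=(cx + r1 * ux) / spec.pixel_size,
                y2=(cy + r1 * uy) / spec.pixel_size,
                width=width,
                name=f"radial-{k:03d}",
            )
        )
    return rois
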