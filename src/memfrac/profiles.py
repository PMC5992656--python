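"""Line-profile extraction, alignment, normalization and linear unmixing.

This is the heart of the membrane-fraction method. Width-averaged intensity
profiles are scanned perpendicular to the plasma membrane in three channels
(membrane marker f_CFP, cytoplasm marker f_RFP, protein of interest f_YFP),
aligned on the membrane-marker peak, oriented with the cytoplasm at negative
positions, and normalized so the cytoplasmic plateau is 1. Because the
membrane marker also has a cytoplasmic pool, the pure-membrane basis is
f_corr = f_CFP - f_RFP. The protein-of-interest profile is then decomposed
by non-negative least squares,

    f_YFP(x) = a_CP * f_RFP(x) + a_PM * f_corr(x),

inside a window around the membrane. The peak of the membrane component
a_PM * f_corr, expressed in percent of the cytoplasmic level, is the
reported plasma-membrane association. Confidence bands come from a
line-level bootstrap that repeats normalization and unmixing on each
resampled set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, optimize, signal

from .imaging_io import ChannelStack, ROLES
from .roiset import LineRoi

_IDX = {role: i for i, role in enumerate(ROLES)}

DEFAULT_WINDOW_UM = (-2.25, 2.25)
EXTRACELLULAR_FROM_UM = 2.0
CYTO_WINDOW_UM = (-2.5, -1.5)


class AlignmentError(ValueError):
    """No usable membrane peak in a line's PM-marker profile."""


class NormalizationError(ValueError):
    """Cytoplasm-window mean is non-positive; normalization is degenerate."""


class UnmixError(ValueError):
    """The unmixing design is rank-deficient or empty."""


@dataclass(frozen=True)
class Profile:
    """A 1-D intensity trace on a calibrated position axis (um).

    By convention the membrane sits at 0 and the cytoplasm extends to
    negative positions once the profile has been aligned and oriented.
    """

    positions: np.ndarray
    intensities: np.ndarray
    channel_role: str
    source: tuple | None = None

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        val = np.asarray(self.intensities, dtype=float)
        if pos.shape != val.shape or pos.ndim != 1:
            raise ValueError("positions and intensities must be matching 1-D arrays")
        d = np.diff(pos)
        if pos.size > 1 and (np.any(d <= 0) or not np.allclose(d, d[0], rtol=1e-6)):
            raise ValueError("positions must be strictly increasing and uniform")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "intensities", val)

    @property
    def step(self) -> float:
        return float(self.positions[1] - self.positions[0])


@dataclass
class ProfileSet:
    """Per-line aligned profiles of all three channels on one common axis.

    ``aligned`` has shape (n_lines, 3, len(axis)) with channel order
    (PM_marker, CP_marker, POI) and NaN where a line has no data.
    """

    axis: np.ndarray
    aligned: np.ndarray
    averages: np.ndarray | None = None
    norm_record: dict | None = None
    line_shifts: np.ndarray | None = None
    line_flipped: np.ndarray | None = None
    rejected: list[int] = field(default_factory=list)
    source_triples: list[dict[str, Profile]] | None = None
    extra_shift: float = 0.0

    @property
    def n_lines(self) -> int:
        return self.aligned.shape[0]

    def average_profile(self, role: str) -> Profile:
        if self.averages is None:
            raise ValueError("averages not computed yet")
        return Profile(self.axis, self.averages[_IDX[role]], role)


@dataclass(frozen=True)
class CiBands:
    """Bootstrap 95% bands for the unmixed components and the PM peak."""

    cp_lo: np.ndarray
    cp_hi: np.ndarray
    pm_lo: np.ndarray
    pm_hi: np.ndarray
    pm_peak_lo: float
    pm_peak_hi: float
    pm_peak_sd: float
    n_boot: int
    seed: int | None
    method: str = "sem"


@dataclass
class UnmixResult:
    """Outcome of the non-negative unmixing of the protein-of-interest
    profile into cytoplasmic (CP) and plasma-membrane (PM) components."""

    a_cp: float
    a_pm: float
    axis: np.ndarray
    cp_component: np.ndarray
    pm_component: np.ndarray
    pm_peak_percent: float
    residual: float
    window: tuple[float, float] = DEFAULT_WINDOW_UM
    n_lines: int | None = None
    n_cells: int | None = None
    seed: int | None = None
    ci: CiBands | None = None
    realigned: bool = False
    degenerate_pm: bool = False


# ---------------------------------------------------------------------------
# line scanning


def line_scan(
    image: np.ndarray,
    roi: LineRoi,
    pixel_size: float,
    step_px: float = 1.0,
    mask: np.ndarray | None = None,
    channel_role: str = "POI",
    source: tuple | None = None,
) -> Profile:
    """Width-averaged bilinear line scan along a ROI.

    At each axial sample, ``roi.width`` bilinear samples spaced 1 px apart
    are taken perpendicular to the line and averaged. Positions are in um
    from the line start.
    """
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    p0 = np.array([roi.x1, roi.y1], dtype=float)
    p1 = np.array([roi.x2, roi.y2], dtype=float)
    length = float(np.linalg.norm(p1 - p0))
    u = (p1 - p0) / length
    perp = np.array([-u[1], u[0]])
    t = np.arange(0.0, length + 1e-9, step_px)
    offsets = (np.arange(roi.width) - (roi.width - 1) / 2.0)[:, None]
    xs = p0[0] + t[None, :] * u[0] + offsets * perp[0]
    ys = p0[1] + t[None, :] * u[1] + offsets * perp[1]
    inside = (xs >= 0) & (xs <= w - 1) & (ys >= 0) & (ys <= h - 1)
    if not np.all(inside):
        raise ValueError(
            f"ROI {roi.name or roi} exits the image "
            f"(endpoints ({roi.x1:.1f},{roi.y1:.1f})-({roi.x2:.1f},{roi.y2:.1f}), "
            f"width {roi.width})"
        )
    samples = ndimage.map_coordinates(img, [ys, xs], order=1, mode="nearest")
    if mask is not None:
        valid = ndimage.map_coordinates(
            mask.astype(float), [ys, xs], order=0, mode="constant", cval=0.0
        )
        if np.any(valid < 1):
            raise ValueError(
                f"ROI {roi.name or roi} samples registration-invalid pixels"
            )
    return Profile(t * pixel_size, samples.mean(axis=0), channel_role, source)


# ---------------------------------------------------------------------------
# alignment


def _peak_position(
    positions: np.ndarray, values: np.ndarray, min_prominence_frac: float = 0.05
) -> float | None:
    """Subpixel peak location: 3-sample moving average, most prominent peak,
    parabolic refinement. Ties break toward the profile midpoint."""
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(values)
    if ok.sum() < 3:
        return None
    # restrict to the contiguous finite segment (grid edges can lack data)
    first, last = np.nonzero(ok)[0][[0, -1]]
    if not ok[first : last + 1].all():
        return None
    positions = positions[first : last + 1]
    y = ndimage.uniform_filter1d(values[first : last + 1], 3, mode="nearest")
    span = float(np.ptp(y))
    if span <= 0:
        return None
    peaks, props = signal.find_peaks(y, prominence=min_prominence_frac * span)
    if peaks.size == 0:
        return None
    prom = props["prominences"]
    best = prom.max()
    candidates = peaks[prom >= best * (1 - 1e-12)]
    mid = (len(y) - 1) / 2.0
    i = int(candidates[np.argmin(np.abs(candidates - mid))])
    x = positions[i]
    if 0 < i < len(y) - 1:
        denom = y[i - 1] - 2 * y[i] + y[i + 1]
        if denom < 0:
            offset = 0.5 * (y[i - 1] - y[i + 1]) / denom
            x = x + offset * (positions[1] - positions[0])
    return float(x)


def default_axis(step_um: float, half_extent_um: float = 3.5) -> np.ndarray:
    n = int(round(half_extent_um / step_um))
    return np.arange(-n, n + 1) * step_um


def align_and_average(
    line_profiles: list[dict[str, Profile]],
    axis: np.ndarray | None = None,
    min_prominence_frac: float = 0.05,
    orient_window_um: tuple[float, float] = (1.0, 2.5),
    extra_shift: float = 0.0,
) -> ProfileSet:
    """Center each line on its PM-marker peak, orient cytoplasm-left, and
    resample all channels of all lines onto a common axis; lines whose
    PM-marker profile has no sufficiently prominent peak are rejected."""
    if not line_profiles:
        raise ValueError("no line profiles given")
    step = line_profiles[0][ROLES[0]].step
    if axis is None:
        axis = default_axis(step)
    lo, hi = orient_window_um
    rows, shifts, flipped, rejected = [], [], [], []
    for li, triple in enumerate(line_profiles):
        missing = [r for r in ROLES if r not in triple]
        if missing:
            raise ValueError(f"line {li} missing channels {missing}")
        pm = triple[ROLES[0]]
        peak = _peak_position(pm.positions, pm.intensities, min_prominence_frac)
        if peak is None:
            rejected.append(li)
            warnings.warn(f"line {li}: no PM-marker peak; rejected", stacklevel=2)
            continue
        pos = pm.positions - peak
        cp_vals = triple[ROLES[1]].intensities
        left = cp_vals[(pos >= -hi) & (pos <= -lo)]
        right = cp_vals[(pos >= lo) & (pos <= hi)]
        flip = np.nanmean(right) > np.nanmean(left) if left.size and right.size else False
        row = np.full((3, axis.size), np.nan)
        for role in ROLES:
            p = pos
            v = triple[role].intensities
            if flip:
                p, v = -p[::-1], v[::-1]
            # extra_shift recenters in the oriented frame (realignment pass)
            row[_IDX[role]] = np.interp(
                axis, p - extra_shift, v, left=np.nan, right=np.nan
            )
        rows.append(row)
        shifts.append(peak)
        flipped.append(flip)
    if not rows:
        raise AlignmentError("all lines rejected: no detectable PM-marker peaks")
    aligned = np.stack(rows)
    pset = ProfileSet(
        axis=np.asarray(axis, dtype=float),
        aligned=aligned,
        line_shifts=np.asarray(shifts),
        line_flipped=np.asarray(flipped),
        rejected=rejected,
        source_triples=list(line_profiles),
        extra_shift=extra_shift,
    )
    pset.averages = _nanmean_lines(aligned)
    return pset


def _nanmean_lines(aligned: np.ndarray) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(aligned, axis=0)


# ---------------------------------------------------------------------------
# normalization and basis correction


def _normalize_arrays(means: np.ndarray, axis: np.ndarray) -> tuple[np.ndarray, dict]:
    ext = axis > EXTRACELLULAR_FROM_UM
    cyt = (axis >= CYTO_WINDOW_UM[0]) & (axis <= CYTO_WINDOW_UM[1])
    if not ext.any() or not cyt.any():
        raise NormalizationError("axis does not cover the normalization windows")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        bg = np.nanmean(means[..., ext], axis=-1)
        out = means - bg[..., None]
        cyto = np.nanmean(out[..., cyt], axis=-1)
    if np.any(~np.isfinite(cyto)) or np.any(cyto <= 0):
        raise NormalizationError(
            f"non-positive cytoplasm-window mean after background removal: {cyto}"
        )
    out = out / cyto[..., None]
    record = {
        role: {"background": float(bg[_IDX[role]]), "cyto_mean": float(cyto[_IDX[role]])}
        for role in ROLES
    }
    return out, record


def normalize_profiles(pset: ProfileSet) -> ProfileSet:
    """Subtract residual extracellular background (x > 2 um) and scale each
    channel average so its cytoplasm-window ([-2.5, -1.5] um) mean is 1."""
    if pset.averages is None:
        pset.averages = _nanmean_lines(pset.aligned)
    normed, record = _normalize_arrays(pset.averages, pset.axis)
    return replace(pset, averages=normed, norm_record=record)


def correct_pm_marker(pm_profile: Profile, cp_profile: Profile) -> Profile:
    """Pure-membrane basis: subtract the cytoplasm-marker profile from the
    membrane-marker profile (both normalized, common axis)."""
    if not np.array_equal(pm_profile.positions, cp_profile.positions):
        raise ValueError("profiles must share an axis")
    return Profile(
        pm_profile.positions,
        pm_profile.intensities - cp_profile.intensities,
        "PM_basis",
        pm_profile.source,
    )


# ---------------------------------------------------------------------------
# unmixing


def _nnls2(
    g11: np.ndarray, g12: np.ndarray, g22: np.ndarray, h1: np.ndarray, h2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Exact non-negative least squares for two regressors, vectorized.

    Solves min ||b - a1 x1 - a2 x2|| with a1, a2 >= 0 from the Gram entries
    g_ij = <x_i, x_j>, h_i = <x_i, b>. If the unconstrained solution leaves
    the quadrant, the best single-axis solution is taken (exact for 2-D)."""
    det = g11 * g22 - g12 * g12
    with np.errstate(divide="ignore", invalid="ignore"):
        a1 = (g22 * h1 - g12 * h2) / det
        a2 = (g11 * h2 - g12 * h1) / det
        interior = (det > 0) & (a1 >= 0) & (a2 >= 0)
        c1 = np.clip(h1 / g11, 0, None)
        c2 = np.clip(h2 / g22, 0, None)
    # objective (up to const): -2 a.h + a.G a ; evaluate both edge candidates
    obj1 = c1 * c1 * g11 - 2 * c1 * h1
    obj2 = c2 * c2 * g22 - 2 * c2 * h2
    edge1 = obj1 <= obj2
    a1_out = np.where(interior, a1, np.where(edge1, c1, 0.0))
    a2_out = np.where(interior, a2, np.where(edge1, 0.0, c2))
    return a1_out, a2_out


def unmix_profile(
    poi: Profile,
    cp_basis: Profile,
    pm_basis: Profile,
    window: tuple[float, float] = DEFAULT_WINDOW_UM,
) -> UnmixResult:
    """Non-negative decomposition of the protein-of-interest profile into
    the cytoplasm basis and the corrected membrane basis within ``window``."""
    axis = poi.positions
    if not (
        np.array_equal(axis, cp_basis.positions)
        and np.array_equal(axis, pm_basis.positions)
    ):
        raise ValueError("profiles must share an axis")
    m = (
        (axis >= window[0])
        & (axis <= window[1])
        & np.isfinite(poi.intensities)
        & np.isfinite(cp_basis.intensities)
        & np.isfinite(pm_basis.intensities)
    )
    if m.sum() < 3:
        raise UnmixError("unmixing window contains fewer than 3 valid samples")
    a_mat = np.column_stack([cp_basis.intensities[m], pm_basis.intensities[m]])
    norms = np.linalg.norm(a_mat, axis=0)
    if norms[1] == 0:
        raise UnmixError("membrane basis is identically zero inside the window")
    if norms[0] == 0 or abs(a_mat[:, 0] @ a_mat[:, 1]) >= (1 - 1e-12) * norms[0] * norms[1]:
        raise UnmixError("rank-deficient design: bases are collinear in the window")
    coef, rnorm = optimize.nnls(a_mat, poi.intensities[m])
    a_cp, a_pm = float(coef[0]), float(coef[1])
    cp_comp = a_cp * cp_basis.intensities
    pm_comp = a_pm * pm_basis.intensities
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        pm_peak = float(np.nanmax(pm_comp)) * 100.0
    return UnmixResult(
        a_cp=a_cp,
        a_pm=a_pm,
        axis=axis,
        cp_component=cp_comp,
        pm_component=pm_comp,
        pm_peak_percent=max(pm_peak, 0.0) if a_pm == 0 else pm_peak,
        residual=float(rnorm),
        window=window,
    )


def estimate_from_set(
    pset: ProfileSet, window: tuple[float, float] = DEFAULT_WINDOW_UM
) -> tuple[ProfileSet, UnmixResult]:
    """Normalize the set's averages and unmix the POI channel."""
    pset = normalize_profiles(pset)
    f_cfp = pset.average_profile("PM_marker")
    f_rfp = pset.average_profile("CP_marker")
    f_yfp = pset.average_profile("POI")
    f_corr = correct_pm_marker(f_cfp, f_rfp)
    result = unmix_profile(f_yfp, f_rfp, f_corr, window)
    result.n_lines = pset.n_lines
    return pset, result


def realign_on_pm(
    pset: ProfileSet,
    result: UnmixResult,
    window: tuple[float, float] = DEFAULT_WINDOW_UM,
    min_prominence_frac: float = 0.05,
) -> tuple[ProfileSet, UnmixResult]:
    """Recenter the common axis on the peak of the unmixed PM component and
    redo averaging, normalization and unmixing once.

    If the PM component has no usable peak (cytoplasm-only protein), the
    inputs are returned unchanged with ``degenerate_pm`` set.
    """
    peak = None
    if result.a_pm > 0:
        peak = _peak_position(result.axis, result.pm_component, min_prominence_frac)
    if peak is None:
        out = replace(result, degenerate_pm=True)
        return pset, out
    if abs(peak) < 1e-12:
        return pset, replace(result, realigned=True)
    if pset.source_triples is not None:
        # regrid once from the raw line scans with the extra recentering
        # shift, so interpolation passes do not compound
        new_set = align_and_average(
            pset.source_triples,
            axis=pset.axis,
            min_prominence_frac=min_prominence_frac,
            extra_shift=pset.extra_shift + peak,
        )
    else:
        # fall back to shifting the gridded rows: value at x comes from x + peak
        shifted = np.full_like(pset.aligned, np.nan)
        for li in range(pset.n_lines):
            for ci in range(3):
                row = pset.aligned[li, ci]
                ok = np.isfinite(row)
                if ok.sum() >= 2:
                    shifted[li, ci] = np.interp(
                        pset.axis + peak,
                        pset.axis[ok],
                        row[ok],
                        left=np.nan,
                        right=np.nan,
                    )
        new_set = replace(
            pset,
            aligned=shifted,
            averages=_nanmean_lines(shifted),
            line_shifts=None if pset.line_shifts is None else pset.line_shifts + peak,
        )
    new_set, new_result = estimate_from_set(new_set, window)
    new_result.realigned = True
    return new_set, new_result


# ---------------------------------------------------------------------------
# bootstrap


def _replicate_estimates(
    aligned: np.ndarray,
    axis: np.ndarray,
    idx: np.ndarray,
    window: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized normalization + 2-basis NNLS for bootstrap replicates.

    Returns (a_cp, a_pm, f_cp, f_corr) per replicate; degenerate replicates
    (non-positive cytoplasm mean) come back NaN.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(aligned[idx], axis=1)  # (B, 3, L)
        ext = axis > EXTRACELLULAR_FROM_UM
        cyt = (axis >= CYTO_WINDOW_UM[0]) & (axis <= CYTO_WINDOW_UM[1])
        bg = np.nanmean(means[..., ext], axis=-1)
        means = means - bg[..., None]
        cyto = np.nanmean(means[..., cyt], axis=-1)
        bad = ~np.isfinite(cyto) | (cyto <= 0)
        cyto = np.where(bad, np.nan, cyto)
        means = means / cyto[..., None]
        f_cfp, f_cp, f_poi = means[:, 0], means[:, 1], means[:, 2]
        f_corr = f_cfp - f_cp
        m = (axis >= window[0]) & (axis <= window[1])
        x1 = np.nan_to_num(f_cp[:, m])
        x2 = np.nan_to_num(f_corr[:, m])
        b = np.nan_to_num(f_poi[:, m])
        g11 = np.sum(x1 * x1, axis=1)
        g12 = np.sum(x1 * x2, axis=1)
        g22 = np.sum(x2 * x2, axis=1)
        h1 = np.sum(x1 * b, axis=1)
        h2 = np.sum(x2 * b, axis=1)
        a_cp, a_pm = _nnls2(g11, g12, g22, h1, h2)
        degen = bad.any(axis=1)
        a_cp = np.where(degen, np.nan, a_cp)
        a_pm = np.where(degen, np.nan, a_pm)
    return a_cp, a_pm, f_cp, f_corr


def bootstrap_ci(
    pset: ProfileSet,
    result: UnmixResult,
    n_boot: int = 1000,
    seed: int | None = None,
    window: tuple[float, float] = DEFAULT_WINDOW_UM,
    method: str = "sem",
    chunk: int = 250,
) -> CiBands:
    """Line-level bootstrap of the full normalization + unmixing.

    Lines are resampled with replacement; each replicate recomputes channel
    averages, normalization, basis correction and the non-negative fit. The
    95% interval is the point estimate +/- 1.96 x the bootstrap SD
    (``method='sem'``), or the 2.5/97.5 percentiles (``method='percentile'``).
    """
    n = pset.n_lines
    if n < 2:
        raise ValueError("bootstrap needs at least 2 lines")
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small; CI will be noisy", stacklevel=2)
    rng = np.random.default_rng(seed)
    a_cp_all, a_pm_all, peaks = [], [], []
    cp_comps, pm_comps = [], []
    for start in range(0, n_boot, chunk):
        b = min(chunk, n_boot - start)
        idx = rng.integers(0, n, size=(b, n))
        a_cp, a_pm, f_cp, f_corr = _replicate_estimates(
            pset.aligned, pset.axis, idx, window
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            peaks.append(100.0 * a_pm * np.nanmax(f_corr, axis=1))
            cp_comps.append(a_cp[:, None] * f_cp)
            pm_comps.append(a_pm[:, None] * f_corr)
        a_cp_all.append(a_cp)
        a_pm_all.append(a_pm)
    peaks = np.concatenate(peaks)
    cp_comps = np.concatenate(cp_comps)
    pm_comps = np.concatenate(pm_comps)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if method == "sem":
            peak_sd = float(np.nanstd(peaks))
            cp_sd = np.nanstd(cp_comps, axis=0)
            pm_sd = np.nanstd(pm_comps, axis=0)
            ci = CiBands(
                cp_lo=result.cp_component - 1.96 * cp_sd,
                cp_hi=result.cp_component + 1.96 * cp_sd,
                pm_lo=result.pm_component - 1.96 * pm_sd,
                pm_hi=result.pm_component + 1.96 * pm_sd,
                pm_peak_lo=result.pm_peak_percent - 1.96 * peak_sd,
                pm_peak_hi=result.pm_peak_percent + 1.96 * peak_sd,
                pm_peak_sd=peak_sd,
                n_boot=n_boot,
                seed=seed,
                method=method,
            )
        elif method == "percentile":
            ci = CiBands(
                cp_lo=np.nanpercentile(cp_comps, 2.5, axis=0),
                cp_hi=np.nanpercentile(cp_comps, 97.5, axis=0),
                pm_lo=np.nanpercentile(pm_comps, 2.5, axis=0),
                pm_hi=np.nanpercentile(pm_comps, 97.5, axis=0),
                pm_peak_lo=float(np.nanpercentile(peaks, 2.5)),
                pm_peak_hi=float(np.nanpercentile(peaks, 97.5)),
                pm_peak_sd=float(np.nanstd(peaks)),
                n_boot=n_boot,
                seed=seed,
                method=method,
            )
        else:
            raise ValueError(f"unknown CI method {method!r}")
    return ci


# ---------------------------------------------------------------------------
# end-to-end


def pm_association(
    stack: ChannelStack,
    rois: list[LineRoi],
    window: tuple[float, float] = DEFAULT_WINDOW_UM,
    n_boot: int = 1000,
    seed: int | None = 0,
    n_cells: int | None = None,
    min_prominence_frac: float = 0.05,
    ci_method: str = "sem",
    step_px: float = 0.5,
) -> UnmixResult:
    """Full pipeline: line scans -> align -> normalize -> correct ->
    unmix -> single realignment on the PM component -> bootstrap CI.

    Line scans default to a half-pixel axial step so that regridding the
    per-line profiles onto the common axis adds negligible broadening on
    top of the bilinear image interpolation.
    """
    if not rois:
        raise ValueError("at least one line ROI is required")
    if not stack.registered or not stack.background_corrected:
        raise ValueError("stack must be registered and background-corrected")
    images = {role: stack.image(role) for role in ROLES}
    triples = []
    for ri, roi in enumerate(rois):
        triples.append(
            {
                role: line_scan(
                    images[role],
                    roi,
                    stack.pixel_size,
                    step_px=step_px,
                    mask=stack.valid_mask,
                    channel_role=role,
                    source=(role, ri),
                )
                for role in ROLES
            }
        )
    pset = align_and_average(
        triples,
        axis=default_axis(stack.pixel_size),
        min_prominence_frac=min_prominence_frac,
    )
    pset, result = estimate_from_set(pset, window)
    pset, result = realign_on_pm(pset, result, window, min_prominence_frac)
    result.ci = bootstrap_ci(
        pset, result, n_boot=n_boot, seed=seed, window=window, method=ci_method
    )
    result.n_lines = pset.n_lines
    result.n_cells = n_cells
    result.seed = seed
    return result
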