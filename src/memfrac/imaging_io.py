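"""Image stack I/O, frame averaging, channel registration and background.

The analysis expects three confocal channels per acquisition: a plasma
membrane marker (e.g. Lck-CFP), a cytoplasm marker (soluble RFP) and the
protein of interest (YFP fusion). Stacks are stored as frames x height x
width per channel; a short time series is averaged before analysis.
Channels are registered to each other by a translation-only Lucas-Kanade
estimate, and a scalar background is subtracted per channel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage

from .roiset import LineRoi, read_roiset

ROLES = ("PM_marker", "CP_marker", "POI")

DEFAULT_PIXEL_SIZE_UM = 0.14


class RegistrationError(RuntimeError):
    """Raised when shift estimation fails or exceeds the sanity bound."""


@dataclass(frozen=True)
class RegistrationShift:
    """Subpixel translation (in pixels) that maps a moving image onto a
    reference: ``apply_shift(moving, shift) ~= reference``."""

    dx: float
    dy: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.dx) and np.isfinite(self.dy)):
            raise ValueError("shift components must be finite")

    @property
    def magnitude(self) -> float:
        return float(np.hypot(self.dx, self.dy))

    def __neg__(self) -> "RegistrationShift":
        return RegistrationShift(-self.dx, -self.dy)


@dataclass
class ChannelStack:
    """Multi-channel image data with pixel calibration.

    channels maps each role in ROLES to a float array of shape
    (frames, height, width). ``valid_mask`` marks pixels with data in every
    channel after registration (shifted-in borders are excluded).
    """

    channels: dict[str, np.ndarray]
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    registered: bool = False
    background_corrected: bool = False
    valid_mask: np.ndarray | None = None
    background: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [r for r in ROLES if r not in self.channels]
        if missing:
            raise ValueError(f"missing channel roles: {missing}")
        shapes = {self.channels[r].shape for r in ROLES}
        if len(shapes) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        shape = shapes.pop()
        if len(shape) != 3:
            raise ValueError("channels must be (frames, height, width)")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        for r in ROLES:
            arr = np.asarray(self.channels[r], dtype=float)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite intensities in channel {r}")
            self.channels[r] = arr

    @property
    def n_frames(self) -> int:
        return self.channels[ROLES[0]].shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.channels[ROLES[0]].shape[1:]

    def image(self, role: str) -> np.ndarray:
        """2-D image for a role; frames are averaged if more than one."""
        arr = self.channels[role]
        return arr[0] if arr.shape[0] == 1 else arr.mean(axis=0)


def load_stack(
    path: str | Path,
    channel_map: dict[str, int],
    axes: str = "CTYX",
    pixel_size: float | None = None,
) -> ChannelStack:
    """Read a multi-channel TIFF into a ChannelStack.

    ``channel_map`` maps the three roles to channel indices; ``axes`` gives
    the on-disk axis order using C (channel), T (frame), Y, X. A missing T
    axis means a single frame.
    """
    missing = [r for r in ROLES if r not in channel_map]
    if missing:
        raise ValueError(f"channel_map missing roles: {missing}")
    try:
        data = tifffile.imread(str(path))
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read TIFF {path}: {exc}") from exc
    axes = axes.upper()
    if data.ndim != len(axes):
        raise ValueError(f"data has {data.ndim} axes but axes={axes!r}")
    order = [axes.index(a) for a in "CTYX" if a in axes]
    data = np.transpose(data, order)
    if "T" not in axes:
        data = data[:, None]
    channels = {role: data[idx].astype(float) for role, idx in channel_map.items()}
    return ChannelStack(channels, pixel_size=pixel_size or DEFAULT_PIXEL_SIZE_UM)


def save_stack(stack: ChannelStack, path: str | Path) -> None:
    """Write a ChannelStack as a (C, T, Y, X) float32 TIFF."""
    data = np.stack([stack.channels[r] for r in ROLES]).astype(np.float32)
    tifffile.imwrite(str(path), data)


def average_frames(stack: ChannelStack) -> ChannelStack:
    """Arithmetic mean over the time series, per channel."""
    channels = {r: stack.channels[r].mean(axis=0, keepdims=True) for r in ROLES}
    return replace(stack, channels=channels)


def _integer_shift_xcorr(reference: np.ndarray, moving: np.ndarray) -> tuple[float, float]:
    # coarse init: integer-pixel peak of the FFT cross-correlation
    f_ref = np.fft.fft2(reference - reference.mean())
    f_mov = np.fft.fft2(moving - moving.mean())
    corr = np.fft.ifft2(f_ref * np.conj(f_mov)).real
    peak = np.unravel_index(np.argmax(corr), corr.shape)
    dy, dx = peak
    h, w = corr.shape
    if dy > h // 2:
        dy -= h
    if dx > w // 2:
        dx -= w
    return float(dx), float(dy)


def estimate_shift(
    reference: np.ndarray,
    moving: np.ndarray,
    *,
    max_shift: float = 20.0,
    max_iter: int = 100,
    tol: float = 1e-4,
    smooth_sigma: float = 1.0,
    coarse_init: bool = True,
) -> RegistrationShift:
    """Translation between two images by iterative Lucas-Kanade.

    Gauss-Newton on a pure-translation warp: at each iterate the moving
    image is bilinearly resampled, and the update solves the 2x2 normal
    equations built from its spatial gradients. An integer-pixel FFT
    cross-correlation seed (``coarse_init``) extends the convergence basin
    well beyond the gradient correlation length.
    """
    ref = np.asarray(reference, dtype=float)
    mov = np.asarray(moving, dtype=float)
    if ref.shape != mov.shape:
        raise ValueError("images must share a shape")
    if np.ptp(ref) == 0 or np.ptp(mov) == 0:
        raise RegistrationError("constant image: shift is undefined")
    if smooth_sigma > 0:
        ref = ndimage.gaussian_filter(ref, smooth_sigma)
        mov = ndimage.gaussian_filter(mov, smooth_sigma)

    dx, dy = _integer_shift_xcorr(ref, mov) if coarse_init else (0.0, 0.0)
    for _ in range(max_iter):
        warped = ndimage.shift(mov, (dy, dx), order=1, mode="nearest")
        margin = int(np.ceil(max(abs(dx), abs(dy)))) + 2
        sl = (slice(margin, ref.shape[0] - margin), slice(margin, ref.shape[1] - margin))
        if sl[0].start >= sl[0].stop or sl[1].start >= sl[1].stop:
            raise RegistrationError(
                f"shift ({dx:.2f}, {dy:.2f}) leaves no overlap to match"
            )
        err = (ref - warped)[sl]
        gy, gx = np.gradient(warped)
        gx, gy = gx[sl], gy[sl]
        a11 = np.sum(gx * gx)
        a12 = np.sum(gx * gy)
        a22 = np.sum(gy * gy)
        det = a11 * a22 - a12 * a12
        if det <= 0 or not np.isfinite(det):
            raise RegistrationError("degenerate gradient structure tensor")
        b1 = np.sum(gx * err)
        b2 = np.sum(gy * err)
        # minimize ||err + G.delta||: delta = -(G'G)^-1 G'err
        ddx = -(a22 * b1 - a12 * b2) / det
        ddy = -(a11 * b2 - a12 * b1) / det
        dx += ddx
        dy += ddy
        if np.hypot(dx, dy) > max_shift:
            raise RegistrationError(
                f"estimated shift ({dx:.2f}, {dy:.2f}) px exceeds sanity bound "
                f"{max_shift} px"
            )
        if np.hypot(ddx, ddy) < tol:
            return RegistrationShift(dx, dy)
    raise RegistrationError(
        f"Lucas-Kanade did not converge; last iterate ({dx:.3f}, {dy:.3f}) px"
    )


def apply_shift(image: np.ndarray, shift: RegistrationShift) -> np.ndarray:
    """Bilinearly resample an image by a subpixel translation.

    Pixels shifted in from outside the field are NaN so that downstream ROI
    sampling can reject them.
    """
    if shift.dx == 0 and shift.dy == 0:
        return np.asarray(image, dtype=float).copy()
    return ndimage.shift(
        np.asarray(image, dtype=float),
        (shift.dy, shift.dx),
        order=1,
        mode="constant",
        cval=np.nan,
    )


def register_stack(
    stack: ChannelStack,
    shifts: dict[str, RegistrationShift],
    reference_role: str = "POI",
) -> ChannelStack:
    """Apply per-channel shifts mapping each channel onto the reference.

    Border pixels without data in every channel after shifting are recorded
    in ``valid_mask`` and set to 0 so the stack stays finite.
    """
    channels: dict[str, np.ndarray] = {}
    valid = np.ones(stack.frame_shape, dtype=bool)
    for role in ROLES:
        arr = stack.channels[role]
        s = shifts.get(role)
        if role == reference_role or s is None or (s.dx == 0 and s.dy == 0):
            channels[role] = arr.copy()
            continue
        shifted = np.stack([apply_shift(frame, s) for frame in arr])
        chan_valid = np.all(np.isfinite(shifted), axis=0)
        valid &= chan_valid
        shifted[~np.isfinite(shifted)] = 0.0
        channels[role] = shifted
    return replace(stack, channels=channels, registered=True, valid_mask=valid)


def shifts_from_controls(
    positive: ChannelStack, negative: ChannelStack
) -> dict[str, RegistrationShift]:
    """Per-channel registration shifts estimated from control acquisitions.

    The PM-marker -> POI shift comes from a positive control in which both
    the marker and the protein of interest are membrane-localized (shared
    structure); the CP-marker -> POI shift comes from a negative control in
    which both are soluble. The returned shifts are then applied to every
    experimental stack acquired with the same configuration.
    """
    pos = average_frames(positive)
    neg = average_frames(negative)
    return {
        "PM_marker": estimate_shift(pos.image("POI"), pos.image("PM_marker")),
        "CP_marker": estimate_shift(neg.image("POI"), neg.image("CP_marker")),
    }


def subtract_background(
    image: np.ndarray,
    bg_roi: np.ndarray | tuple[slice, slice] | None = None,
    percentile: float = 5.0,
) -> tuple[np.ndarray, float]:
    """Subtract a scalar background; returns (corrected image, background).

    With ``bg_roi`` (boolean mask or slice pair over an empty region) the
    background is its mean; otherwise a low-percentile estimate of the whole
    frame is used, which is robust when most of the field is extracellular.
    Negative values are retained to keep the downstream unmixing unbiased.
    """
    img = np.asarray(image, dtype=float)
    if bg_roi is not None:
        region = img[bg_roi]
        if region.size == 0:
            raise ValueError("background ROI selects no pixels")
        bg = float(np.mean(region))
    else:
        bg = float(np.nanpercentile(img, percentile))
    return img - bg, bg


def preprocess(
    stack: ChannelStack,
    shifts: dict[str, RegistrationShift] | None = None,
    bg_roi: np.ndarray | tuple[slice, slice] | None = None,
    percentile: float = 5.0,
    reference_role: str = "POI",
) -> ChannelStack:
    """Frame-average, register and background-correct a raw stack."""
    out = average_frames(stack)
    if shifts:
        out = register_stack(out, shifts, reference_role=reference_role)
    else:
        out = replace(out, registered=True, valid_mask=None)
    channels = {}
    background = {}
    for role in ROLES:
        corrected, bg = subtract_background(out.channels[role][0], bg_roi, percentile)
        channels[role] = corrected[None]
        background[role] = bg
    return replace(
        out, channels=channels, background_corrected=True, background=background
    )


def import_roiset(
    path: str | Path,
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM,
    length_bounds_um: tuple[float, float] = (6.0, 10.0),
) -> list[LineRoi]:
    """Load line ROIs from an ImageJ RoiSet, warning on unusual lengths."""
    rois = read_roiset(path)
    lo, hi = length_bounds_um
    for roi in rois:
        length = roi.length_um(pixel_size)
        if not lo <= length <= hi:
            warnings.warn(
                f"line ROI {roi.name or '?'} is {length:.2f} um long "
                f"(expected {lo}-{hi} um)",
                stacklevel=2,
            )
    return rois
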