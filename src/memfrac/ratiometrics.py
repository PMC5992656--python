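"""Ratiometric quantifications: FRET ratios, translocation ratios,
fold-change over untransfected controls, and notched boxplot summaries."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class FretTrace:
    """Background-subtracted CFP/YFP intensity time series of one cell.

    ``beta`` is the donor bleedthrough: the fraction of CFP emission
    detected in the YFP channel (about 0.55 for the filter sets used with
    CFP/YFP pairs). ``stimulus_time`` marks an agonist addition for
    baseline normalization.
    """

    time: np.ndarray
    i_cfp: np.ndarray
    i_yfp: np.ndarray
    beta: float = 0.55
    stimulus_time: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        c = np.asarray(self.i_cfp, dtype=float)
        y = np.asarray(self.i_yfp, dtype=float)
        if not (t.shape == c.shape == y.shape) or t.ndim != 1:
            raise ValueError("time, i_cfp and i_yfp must be matching 1-D arrays")
        if not 0 <= self.beta < 1:
            raise ValueError("bleedthrough beta must be in [0, 1)")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "i_cfp", c)
        object.__setattr__(self, "i_yfp", y)


@dataclass(frozen=True)
class CellMeasure:
    """One scalar per cell: a ratio or normalized intensity, with its
    experimental group and (optionally) the field of view it came from."""

    cell_id: str
    value: float
    group: str = ""
    fov: str | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise ValueError("cell measure must be finite")


def fret_ratio_trace(trace: FretTrace) -> dict[str, np.ndarray]:
    """Bleedthrough-corrected YFP/CFP ratio per timepoint.

    ratio(t) = (I_YFP - beta * I_CFP) / I_CFP. Timepoints with
    non-positive CFP are masked NaN with a warning. If a stimulus time is
    set, a per-cell baseline-normalized trace (ratio / pre-stimulus mean)
    is returned as well.
    """
    bad = trace.i_cfp <= 0
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} timepoints with non-positive CFP masked", stacklevel=2
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (trace.i_yfp - trace.beta * trace.i_cfp) / trace.i_cfp
    ratio = np.where(bad, np.nan, ratio)
    out = {"time": trace.time, "ratio": ratio}
    if trace.stimulus_time is not None:
        pre = ratio[(trace.time < trace.stimulus_time) & np.isfinite(ratio)]
        if pre.size == 0:
            raise ValueError("no finite pre-stimulus timepoints for baseline")
        out["normalized"] = ratio / pre.mean()
    return out


def nuc_cyto_ratio(
    image: np.ndarray,
    nucleus_mask: np.ndarray,
    cytoplasm_mask: np.ndarray,
    cell_id: str = "",
    group: str = "",
) -> CellMeasure:
    """Mean nuclear over mean cytoplasmic intensity of a background-
    subtracted image, given disjoint user-supplied masks."""
    img = np.asarray(image, dtype=float)
    nuc = np.asarray(nucleus_mask, dtype=bool)
    cyt = np.asarray(cytoplasm_mask, dtype=bool)
    if nuc.shape != img.shape or cyt.shape != img.shape:
        raise ValueError("masks must match the image shape")
    if not nuc.any() or not cyt.any():
        raise ValueError("masks must be non-empty")
    if (nuc & cyt).any():
        raise ValueError("nucleus and cytoplasm masks overlap")
    return CellMeasure(
        cell_id, float(img[nuc].mean() / img[cyt].mean()), group=group
    )


def fold_over_control(
    values: list[CellMeasure], controls: list[CellMeasure]
) -> list[CellMeasure]:
    """Normalize each transfected cell to the mean of the untransfected
    controls in the same field of view; fields without controls are
    excluded with a warning."""
    control_by_fov: dict[str | None, list[float]] = {}
    for c in controls:
        control_by_fov.setdefault(c.fov, []).append(c.value)
    control_mean = {fov: float(np.mean(v)) for fov, v in control_by_fov.items()}
    out = []
    skipped = set()
    for v in values:
        if v.fov not in control_mean:
            skipped.add(v.fov)
            continue
        out.append(
            CellMeasure(v.cell_id, v.value / control_mean[v.fov], v.group, v.fov)
        )
    if skipped:
        warnings.warn(
            f"fields without controls excluded: {sorted(map(str, skipped))}",
            stacklevel=2,
        )
    return out


@dataclass(frozen=True)
class NotchedSummary:
    """Notched-boxplot statistics of one group."""

    n: int
    median: float
    q1: float
    q3: float
    iqr: float
    whisker_lo: float
    whisker_hi: float
    notch_lo: float
    notch_hi: float


def notched_summary(values: np.ndarray | list[float]) -> NotchedSummary:
    """Median, type-7 quartiles, 1.5 x IQR whiskers (clipped to the most
    extreme data inside), and the median notch median +/- 1.58 IQR / sqrt(n),
    which approximates a 95% CI on the median."""
    v = np.asarray(values, dtype=float)
    if v.size < 1 or not np.all(np.isfinite(v)):
        raise ValueError("values must be non-empty and finite")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    half_notch = 1.58 * iqr / np.sqrt(v.size)
    return NotchedSummary(
        n=int(v.size),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        iqr=float(iqr),
        whisker_lo=float(inside.min()),
        whisker_hi=float(inside.max()),
        notch_lo=float(med - half_notch),
        notch_hi=float(med + half_notch),
    )
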