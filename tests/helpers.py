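"""Shared independent oracles for the test suite."""

import numpy as np


def grid_search_nnls(
    basis1: np.ndarray, basis2: np.ndarray, target: np.ndarray, step: float = 1e-3
) -> tuple[float, float]:
    """Dense non-negative grid search for the 2-coefficient least squares,
    independent of any solver: exhaustively evaluates the residual on a
    grid around the unconstrained solution (clipped to >= 0)."""
    a_mat = np.column_stack([basis1, basis2])
    unc, *_ = np.linalg.lstsq(a_mat, target, rcond=None)
    lo1 = 0.0
    hi1 = max(unc[0] + 0.5, 0.5)
    lo2 = 0.0
    hi2 = max(unc[1] + 0.5, 0.5)
    a1 = np.arange(lo1, hi1 + step, step)
    a2 = np.arange(lo2, hi2 + step, step)
    g11 = basis1 @ basis1
    g12 = basis1 @ basis2
    g22 = basis2 @ basis2
    h1 = basis1 @ target
    h2 = basis2 @ target
    # residual^2 (up to a constant) on the full outer grid
    obj = (
        g11 * a1[:, None] ** 2
        + g22 * a2[None, :] ** 2
        + 2 * g12 * a1[:, None] * a2[None, :]
        - 2 * h1 * a1[:, None]
        - 2 * h2 * a2[None, :]
    )
    i, j = np.unravel_index(np.argmin(obj), obj.shape)
    return float(a1[i]), float(a2[j])
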