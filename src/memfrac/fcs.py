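"""FCS autocorrelation model, global fitting and diffusion calibration.

The autocorrelation of confocal fluorescence fluctuations is fit with the
standard 3-D Gaussian observation-volume model with a triplet-state term
and two diffusing components:

    G(tau) = (1/N) * (1 + T/(1-T) * exp(-tau/tau_T))
             * sum_i f_i * (1 + tau/tau_Di)^-1 * (1 + tau/(s^2 tau_Di))^-1/2

with mean particle number N, triplet fraction T and time tau_T (bounded to
0-50 us), diffusion times tau_D1 < tau_D2, fast fraction f1 (f2 = 1 - f1),
and the volume shape factor s (axial/lateral ratio) fixed from
calibration. Across measurements of one species the diffusion times are
globally linked: a single (tau_D1, tau_D2) pair is shared while N, T,
tau_T and f1 stay per-curve. Diffusion times convert to coefficients via a
reference measurement of a dye/protein of known D on the same day, so the
beam waist cancels: D = D_ref * tau_ref / tau_D.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

TAU_T_MAX_S = 50e-6


class FcsFitError(RuntimeError):
    """Global ACF fit failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_iterate: np.ndarray | None = None):
        super().__init__(message)
        self.last_iterate = last_iterate


@dataclass(frozen=True)
class AcfCurve:
    """One autocorrelation curve: lag times (s) vs amplitudes G."""

    lag: np.ndarray
    g: np.ndarray
    weights: np.ndarray | None = None
    measurement_id: str | None = None
    duration_s: float | None = None

    def __post_init__(self) -> None:
        lag = np.asarray(self.lag, dtype=float)
        g = np.asarray(self.g, dtype=float)
        if lag.shape != g.shape or lag.ndim != 1:
            raise ValueError("lag and G must be matching 1-D arrays")
        if np.any(lag <= 0) or np.any(np.diff(lag) <= 0):
            raise ValueError("lag times must be positive and strictly increasing")
        if not np.all(np.isfinite(g)):
            raise ValueError("G must be finite")
        object.__setattr__(self, "lag", lag)
        object.__setattr__(self, "g", g)


@dataclass(frozen=True)
class AcfModelParams:
    """Triplet + two-component diffusion parameters."""

    n_particles: float
    triplet_fraction: float
    tau_triplet: float
    tau_d1: float
    tau_d2: float
    f1: float
    shape_factor: float = 5.0

    def __post_init__(self) -> None:
        if self.n_particles <= 0:
            raise ValueError("N must be > 0")
        if not 0 <= self.triplet_fraction < 1:
            raise ValueError("triplet fraction must be in [0, 1)")
        if not 0 <= self.tau_triplet <= TAU_T_MAX_S:
            raise ValueError(f"triplet time must be in [0, {TAU_T_MAX_S}] s")
        if self.tau_d1 <= 0 or self.tau_d2 <= 0:
            raise ValueError("diffusion times must be > 0")
        if self.tau_d1 > self.tau_d2:
            raise ValueError("convention: tau_d1 <= tau_d2 (fast component first)")
        if not 0 <= self.f1 <= 1:
            raise ValueError("f1 must be in [0, 1]")
        if self.shape_factor <= 0:
            raise ValueError("shape factor must be > 0")


@dataclass(frozen=True)
class Calibration:
    """Reference diffusion time and known coefficient (e.g. a free
    fluorescent protein with D = 90 um^2/s in PBS)."""

    tau_ref: float
    d_ref: float = 90.0

    def __post_init__(self) -> None:
        if self.tau_ref <= 0 or self.d_ref <= 0:
            raise ValueError("calibration values must be > 0")


def model_acf(params: AcfModelParams, lag: np.ndarray) -> np.ndarray:
    """Evaluate the triplet x two-component diffusion ACF."""
    tau = np.asarray(lag, dtype=float)
    s2 = params.shape_factor**2
    t = params.triplet_fraction
    if params.tau_triplet > 0 and t > 0:
        trip = 1.0 + t / (1.0 - t) * np.exp(-tau / params.tau_triplet)
    else:
        trip = np.ones_like(tau)
    diff = 0.0
    for f, tau_d in ((params.f1, params.tau_d1), (1.0 - params.f1, params.tau_d2)):
        diff = diff + f / ((1.0 + tau / tau_d) * np.sqrt(1.0 + tau / (s2 * tau_d)))
    return trip * diff / params.n_particles


def simulate_acf(
    params: AcfModelParams,
    lag: np.ndarray | None = None,
    noise_fraction: float = 0.02,
    noise_floor: float = 1e-4,
    seed: int | None = 0,
    measurement_id: str | None = None,
) -> AcfCurve:
    """Model curve plus heteroscedastic Gaussian noise with
    SD = noise_fraction * G(tau) + noise_floor."""
    if lag is None:
        lag = np.logspace(-6, 0, 120)
    g = model_acf(params, lag)
    if noise_fraction or noise_floor:
        rng = np.random.default_rng(seed)
        g = g + rng.normal(0.0, noise_fraction * np.abs(g) + noise_floor)
    return AcfCurve(lag, g, measurement_id=measurement_id)


@dataclass
class GlobalFitResult:
    """Shared diffusion times plus per-curve photophysics parameters."""

    per_curve: list[AcfModelParams]
    tau_d1: float
    tau_d2: float
    stderr: dict = field(default_factory=dict)
    cost: float = np.nan
    residuals: np.ndarray | None = None
    tau_t_at_bound: list[bool] = field(default_factory=list)
    success: bool = True


def _initial_guess(curve: AcfCurve) -> tuple[float, float]:
    g0 = max(float(curve.g[: max(3, curve.g.size // 20)].mean()), 1e-6)
    n0 = 1.0 / g0
    half = g0 / 2.0
    below = np.nonzero(curve.g <= half)[0]
    tau_half = float(curve.lag[below[0]]) if below.size else float(curve.lag[-1] / 10)
    return n0, tau_half


def fit_acf_global(
    curves: list[AcfCurve],
    init: AcfModelParams | None = None,
    max_nfev: int = 20000,
) -> GlobalFitResult:
    """Joint bounded least squares over all curves.

    tau_D1 and tau_D2 are shared (globally linked); N, T, tau_T and f1 are
    per-curve; the shape factor is fixed at its init value. Ordering
    tau_D1 < tau_D2 is enforced by fitting log10(tau_D1) and the log10 of
    the ratio tau_D2/tau_D1 (bounded > 1). Standard errors come from the
    Jacobian at the solution.
    """
    if not curves:
        raise ValueError("at least one curve is required")
    if init is None:
        n0, tau_half = _initial_guess(curves[0])
        init = AcfModelParams(n0, 0.1, 5e-6, tau_half / 2, tau_half * 4, 0.5)
    s_fixed = init.shape_factor
    nc = len(curves)

    # x = [log10 tau_d1, log10 ratio] + per curve [log10 N, T, tau_T, f1]
    x0 = [np.log10(init.tau_d1), np.log10(max(init.tau_d2 / init.tau_d1, 1.05))]
    lo = [-8.0, np.log10(1.01)]
    hi = [1.0, 4.0]
    for _ in range(nc):
        x0 += [np.log10(init.n_particles), init.triplet_fraction,
               max(init.tau_triplet, 1e-7), init.f1]
        lo += [-6.0, 0.0, 0.0, 0.0]
        hi += [9.0, 0.99, TAU_T_MAX_S, 1.0]

    def unpack(x: np.ndarray) -> tuple[float, float, list[AcfModelParams]]:
        tau_d1 = 10.0 ** x[0]
        tau_d2 = tau_d1 * 10.0 ** x[1]
        per = []
        for i in range(nc):
            b = 2 + 4 * i
            per.append(
                AcfModelParams(
                    n_particles=10.0 ** x[b],
                    triplet_fraction=float(x[b + 1]),
                    tau_triplet=float(x[b + 2]),
                    tau_d1=tau_d1,
                    tau_d2=tau_d2,
                    f1=float(x[b + 3]),
                    shape_factor=s_fixed,
                )
            )
        return tau_d1, tau_d2, per

    def residuals(x: np.ndarray) -> np.ndarray:
        _, _, per = unpack(x)
        res = []
        for curve, p in zip(curves, per):
            r = model_acf(p, curve.lag) - curve.g
            if curve.weights is not None:
                r = r * curve.weights
            res.append(r)
        return np.concatenate(res)

    sol = optimize.least_squares(
        residuals, np.asarray(x0), bounds=(np.asarray(lo), np.asarray(hi)),
        max_nfev=max_nfev, method="trf",
    )
    if not sol.success:
        raise FcsFitError(f"global fit did not converge: {sol.message}", sol.x)
    tau_d1, tau_d2, per = unpack(sol.x)

    ndata = sol.fun.size
    npar = sol.x.size
    stderr: dict = {}
    if ndata > npar:
        try:
            jtj = sol.jac.T @ sol.jac
            cov = np.linalg.pinv(jtj) * 2.0 * sol.cost / (ndata - npar)
            sd = np.sqrt(np.clip(np.diag(cov), 0, None))
            ln10 = np.log(10.0)
            stderr["tau_d1"] = sd[0] * ln10 * tau_d1
            # tau_d2 depends on both shared params; first-order propagation
            g_vec = np.zeros(npar)
            g_vec[0] = ln10 * tau_d2
            g_vec[1] = ln10 * tau_d2
            stderr["tau_d2"] = float(np.sqrt(g_vec @ cov @ g_vec))
            stderr["per_curve"] = []
            for i, p in enumerate(per):
                b = 2 + 4 * i
                stderr["per_curve"].append(
                    {
                        "n_particles": sd[b] * ln10 * p.n_particles,
                        "triplet_fraction": sd[b + 1],
                        "tau_triplet": sd[b + 2],
                        "f1": sd[b + 3],
                    }
                )
        except np.linalg.LinAlgError:  # pragma: no cover
            warnings.warn("singular Jacobian; uncertainties unavailable", stacklevel=2)
    at_bound = [
        abs(p.tau_triplet - TAU_T_MAX_S) < 1e-9 or p.tau_triplet < 1e-9 for p in per
    ]
    if any(at_bound):
        warnings.warn("triplet time pinned at a bound for some curves", stacklevel=2)
    return GlobalFitResult(
        per_curve=per,
        tau_d1=tau_d1,
        tau_d2=tau_d2,
        stderr=stderr,
        cost=float(sol.cost),
        residuals=sol.fun,
        tau_t_at_bound=at_bound,
        success=True,
    )


def diffusion_coefficient(tau_d: float, cal: Calibration) -> float:
    """Convert a diffusion time to a coefficient via the same-day
    calibration: D = D_ref * tau_ref / tau_D (the beam waist cancels)."""
    if tau_d <= 0:
        raise ValueError("tau_D must be > 0")
    return cal.d_ref * cal.tau_ref / tau_d


def mean_diffusion(f1: float, d1: float, d2: float) -> float:
    """Fraction-weighted average diffusion coefficient."""
    if not 0 <= f1 <= 1:
        raise ValueError("f1 must be in [0, 1]")
    if d1 <= 0 or d2 <= 0:
        raise ValueError("coefficients must be > 0")
    return f1 * d1 + (1.0 - f1) * d2
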