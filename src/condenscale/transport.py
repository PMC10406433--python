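"""Translational diffusion and shear viscosity from simulation observables.

Diffusion: the centre-of-mass mean-square displacement is fitted in a
linear regime (MSD = c + 6 D_PBC tau), the finite-size periodic-boundary
artefact is removed with the cubic-lattice correction
D_t = D_PBC + k_B T xi / (6 pi eta L) with xi = 2.837297, and the result
may be rescaled by the ratio of simulated to experimental solvent
viscosity (D_pred = D_t * eta_sim / eta_expt).

Viscosity: the Green-Kubo relation eta_ij = V/(k_B T) integral C_ij(t) dt
over the autocorrelation of the five independent (six recorded) deviatoric
pressure-tensor components; the integral is evaluated numerically to
``t_numeric`` and analytically beyond it from a double-exponential fit of
the ACF tail, then averaged over components.

Units: lag times ns and MSD nm^2 for diffusion (D reported in um^2/s);
time ps, pressure bar, volume nm^3 for viscosity (eta in mPa s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "KB",
    "XI_CUBIC",
    "MSDSeries",
    "PressureSeries",
    "ViscosityFit",
    "fit_msd_diffusion",
    "pbc_correct_diffusion",
    "autocorrelation",
    "green_kubo_viscosity",
    "rescale_diffusion",
]

KB = 1.380649e-23        # Boltzmann constant, J/K (exact, SI)
XI_CUBIC = 2.837297      # cubic-lattice self-interaction term

#: conversion of bar^2 * nm^3 * ps to mPa s after division by k_B T [J]
_GK_UNIT = 1e10 * 1e-27 * 1e-12 * 1e3  # (Pa^2 m^3 s) per (bar^2 nm^3 ps), in mPa


@dataclass
class MSDSeries:
    """Mean-square displacement curve: lag in ns, msd in nm^2."""

    lag: np.ndarray
    msd: np.ndarray
    window: tuple[float, float] = (20.0, 40.0)  # fit window, ns

    def __post_init__(self) -> None:
        self.lag = np.asarray(self.lag, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        if self.lag.ndim != 1 or len(self.lag) != len(self.msd):
            raise ValueError("lag and msd must be 1D arrays of equal length")
        if np.any(np.diff(self.lag) <= 0):
            raise ValueError("lags must be strictly increasing")
        if np.any(self.msd < 0):
            raise ValueError("msd values must be non-negative")


@dataclass
class PressureSeries:
    """Deviatoric pressure-tensor time series for Green-Kubo viscosity.

    ``components`` holds six columns in bar: P_xy, P_xz, P_yz,
    (P_xx - P_yy)/2, (P_xx - P_zz)/2, (P_yy - P_zz)/2; time in ps must be
    uniformly sampled.  ``volume`` in nm^3, ``temperature`` in K.
    """

    time: np.ndarray
    components: np.ndarray
    volume: float
    temperature: float

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.components = np.atleast_2d(np.asarray(self.components, dtype=float))
        if self.components.shape[0] == len(self.time) and self.components.shape[1] == 6:
            self.components = self.components.T
        if self.components.shape != (6, len(self.time)):
            raise ValueError("expected six pressure components")
        dt = np.diff(self.time)
        if len(dt) == 0 or not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError("time step must be uniform")
        if self.volume <= 0 or self.temperature <= 0:
            raise ValueError("volume and temperature must be positive")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])


@dataclass
class ViscosityFit:
    """Per-component Green-Kubo results with ACF tail-fit parameters
    (a e^{-t/b} + c e^{-t/d})."""

    eta: float                       # mean over components, mPa s
    eta_components: np.ndarray       # (6,), mPa s
    tail_params: np.ndarray          # (6, 4): a, b, c, d (bar^2, ps)
    acf: np.ndarray = field(repr=False, default=None)   # (6, n_lags), bar^2
    lags: np.ndarray = field(repr=False, default=None)  # ps


def fit_msd_diffusion(series: MSDSeries) -> tuple[float, float]:
    """Fit MSD = c + 6 D tau inside the series' linear window.

    Returns ``(D, c)`` with the diffusion coefficient in um^2/s and the
    intercept in nm^2.
    """
    lo, hi = series.window
    mask = (series.lag >= lo) & (series.lag <= hi)
    if mask.sum() < 3:
        raise ValueError(
            f"fewer than 3 MSD points inside the fit window [{lo}, {hi}] ns"
        )
    slope, intercept = np.polyfit(series.lag[mask], series.msd[mask], 1)
    d_nm2_per_ns = slope / 6.0
    return d_nm2_per_ns * 1e3, float(intercept)  # nm^2/ns -> um^2/s


def pbc_correct_diffusion(D_pbc: float, T: float, eta: float, L: float) -> float:
    """Finite-size correction for diffusion under cubic periodic boundaries.

    D_t = D_PBC + k_B T xi / (6 pi eta L), with T in K, eta in mPa s, L in
    nm and D in um^2/s.  The correction is strictly positive and vanishes
    as L -> infinity.
    """
    if T <= 0 or eta <= 0 or L <= 0:
        raise ValueError("T, eta and L must be positive")
    corr_m2_s = KB * T * XI_CUBIC / (6.0 * np.pi * (eta * 1e-3) * (L * 1e-9))
    return D_pbc + corr_m2_s * 1e12  # m^2/s -> um^2/s


def autocorrelation(x: np.ndarray, n_lags: int) -> np.ndarray:
    """Unbiased FFT-based autocorrelation <x(t) x(0)> for lags 0..n_lags-1."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n_lags > n:
        raise ValueError("series shorter than requested lag range")
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    fx = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(fx * np.conj(fx), nfft)[:n_lags]
    return acov / (n - np.arange(n_lags))


def _double_exp(t, a, b, c, d):
    return a * np.exp(-t / b) + c * np.exp(-t / d)


def _fit_tail(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Double-exponential fit of an ACF tail with a log-linear two-segment
    initialisation; falls back across several starts before giving up.

    Decay constants are bounded by twice the fit-window end and amplitudes
    by the observed tail magnitude: the extrapolated integral must be
    supported by decays the window can actually resolve, otherwise noise
    with a near-flat long-time component dominates the continuation.
    """
    scale = max(float(np.max(np.abs(y))), 1e-30)
    span = t[-1] - t[0]
    starts = [
        (0.7 * y[0], span / 4, 0.3 * y[0], span),
        (0.5 * y[0], span / 10, 0.5 * y[0], span / 2),
        (y[0], span / 2, 0.0, span),
    ]
    # log-linear heuristic on the positive part of each half of the tail
    half = len(t) // 2
    for seg, (t_s, y_s) in enumerate(((t[:half], y[:half]), (t[half:], y[half:]))):
        pos = y_s > 0
        if pos.sum() >= 2:
            sl, ic = np.polyfit(t_s[pos], np.log(y_s[pos]), 1)
            if sl < 0:
                amp, tau = float(np.exp(ic)), float(-1.0 / sl)
                starts.insert(0, (amp, tau, 0.1 * amp, 3 * tau)
                              if seg == 0 else (0.1 * amp, tau / 3, amp, tau))
    tau_max = t[-1]
    amp_max = 3.0 * scale * math.exp(t[0] / max(span / 4, 1e-6))
    bounds = ([-amp_max, 1e-3, -amp_max, 1e-3],
              [amp_max, tau_max, amp_max, tau_max])
    best, best_res = None, np.inf
    for p0 in starts:
        p0 = np.clip(p0, bounds[0], bounds[1])
        try:
            popt, _ = curve_fit(_double_exp, t, y, p0=p0, bounds=bounds,
                                maxfev=20000)
        except RuntimeError:
            continue
        res = float(np.sum((y - _double_exp(t, *popt)) ** 2))
        if res < best_res:
            best, best_res = popt, res
    if best is None:
        raise RuntimeError(
            "ACF tail fit did not converge for any start "
            f"(tail range {t[0]:g}-{t[-1]:g} ps, C(t0) = {y[0]:g} bar^2)"
        )
    return np.asarray(best)


def integrate_acf(
    lags: np.ndarray,
    acf: np.ndarray,
    volume: float,
    temperature: float,
    t_numeric: float = 1.0,
    t_fit: tuple[float, float] = (1.0, 5.0),
) -> tuple[float, np.ndarray]:
    """Green-Kubo integral of a single pressure-component ACF.

    Trapezoid on [0, t_numeric] ps plus the analytic continuation of the
    double-exponential tail fitted on ``t_fit``
    (a b e^{-t1/b} + c d e^{-t1/d}); returns (eta_component in mPa s,
    tail parameters).
    """
    lags = np.asarray(lags, dtype=float)
    acf = np.asarray(acf, dtype=float)
    dt = lags[1] - lags[0]
    n_num = int(round(t_numeric / dt))
    tail_mask = (lags >= t_fit[0]) & (lags <= t_fit[1])
    if tail_mask.sum() < 8:
        raise ValueError("fewer than 8 ACF points inside the tail fit window")
    numeric = float(np.trapezoid(acf[: n_num + 1], dx=dt))
    a, b, c, d = _fit_tail(lags[tail_mask], acf[tail_mask])
    tail = a * b * math.exp(-t_numeric / b) + c * d * math.exp(-t_numeric / d)
    prefactor = volume / (KB * temperature) * _GK_UNIT
    return prefactor * (numeric + tail), np.array([a, b, c, d])


def green_kubo_viscosity(
    series: PressureSeries,
    t_numeric: float = 1.0,
    t_fit: tuple[float, float] = (1.0, 5.0),
    max_lag: float | None = None,
) -> ViscosityFit:
    """Shear viscosity from pressure-tensor autocorrelations (mPa s).

    Per component: the ACF is integrated by the trapezoid rule on
    [0, t_numeric] ps and analytically beyond it using the fitted
    double-exponential tail (a b e^{-t1/b} + c d e^{-t1/d}); eta_ij =
    V/(k_B T) times the integral, and eta is the mean over the six
    components.
    """
    if t_fit[1] <= t_fit[0]:
        raise ValueError("invalid tail fit window")
    if series.time[-1] - series.time[0] < t_fit[1]:
        raise ValueError("series shorter than the tail fit window")
    dt = series.dt
    if max_lag is None:
        max_lag = 2.0 * t_fit[1]
    n_lags = min(int(round(max_lag / dt)) + 1, series.components.shape[1])
    lags = dt * np.arange(n_lags)

    acfs = np.empty((6, n_lags))
    etas = np.empty(6)
    params = np.empty((6, 4))
    errors = []
    for k in range(6):
        acf = autocorrelation(series.components[k], n_lags)
        acfs[k] = acf
        try:
            etas[k], params[k] = integrate_acf(
                lags, acf, series.volume, series.temperature,
                t_numeric=t_numeric, t_fit=t_fit)
        except (RuntimeError, ValueError) as exc:
            errors.append(f"component {k}: {exc}")
            params[k] = np.nan
            etas[k] = np.nan
    if errors:
        raise RuntimeError("Green-Kubo tail fits failed:\n" + "\n".join(errors))
    return ViscosityFit(eta=float(etas.mean()), eta_components=etas,
                        tail_params=params, acf=acfs, lags=lags)


def rescale_diffusion(D_t: float, eta_sim: float, eta_expt: float = 0.69) -> float:
    """Rescale a corrected diffusion coefficient by the simulated-to-
    experimental solvent viscosity ratio: D_pred = D_t * eta_sim / eta_expt."""
    if eta_sim <= 0 or eta_expt <= 0:
        raise ValueError("viscosities must be positive")
    return D_t * eta_sim / eta_expt
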