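"""Analytical fractal scaling model of condensate architecture.

A condensate is modelled as an iterative, self-similar assembly process:
molecules of compactness (volume fraction) ``phi`` associate with average
valency ``n`` into clusters, clusters associate into larger clusters with
the same valency, and at every level the sub-clusters occupy the same
volume fraction ``phi`` of the apparent cluster volume.  The recursion
yields exact closed forms for every iteration ``i`` (``i = 0`` is the
monomer)::

    N_i = (n+1)^i
    V_i = V_0 ((n+1)/phi)^i          V_0 = (4/3) pi R_0^3
    R_i = R_0 ((n+1)/phi)^(i/3)
    M_i = M_0 (n+1)^i
    C_i = C_0 phi^i                  C_0 = 1/(N_A V_0)

so mass and size obey ``M ∝ R^d_f`` with fractal dimension

    d_f = 3 ln(n+1) / ln((n+1)/phi)

and fractal prefactor ``k_f = 1`` (``N_i = (R_i/R_0)^{d_f}`` exactly).

Units are fixed throughout: nm, kDa, mM; regressions use log base 10.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "AVOGADRO",
    "ScalingParams",
    "IterationState",
    "PowerLawFit",
    "PercolationThreshold",
    "fractal_dimension",
    "iterate_assembly",
    "fit_mass_size",
    "invert_fit",
    "concentration_at_size",
    "isocurve_phi_of_n",
    "percolation_threshold",
]

AVOGADRO = 6.02214076e23  # 1/mol

#: Partial specific volume of a typical protein, expressed as van der Waals
#: volume per unit mass: 0.73 cm^3/g == 1.2124 nm^3/kDa.
VDW_VOLUME_PER_KDA = 0.73 * 1e21 / AVOGADRO * 1e3  # nm^3 per kDa


def _sphere_volume(radius: float) -> float:
    return 4.0 / 3.0 * math.pi * radius**3


def _molar_concentration_mM(n_molecules: float, volume_nm3: float) -> float:
    """Molar concentration of ``n_molecules`` in ``volume_nm3`` nm^3, in mM."""
    litres = volume_nm3 * 1e-24
    return n_molecules / (AVOGADRO * litres) * 1e3


@dataclass(frozen=True)
class ScalingParams:
    """Monomer-level parameters of the fractal model.

    Attributes
    ----------
    phi : float
        Compactness (volume fraction): ratio of the van der Waals to the
        hydrodynamic (apparent) volume of one molecule, in (0, 1].
    n : float
        Interaction valency: average number of bound partners per molecule.
        May be non-integer (it is an ensemble average).
    R0 : float
        Apparent (hydrodynamic) radius of the monomer, nm.  Typically the
        ensemble-average Rg of the chain in the crowded phase.
    M0 : float
        Monomer mass, kDa.
    """

    phi: float
    n: float
    R0: float = 1.60
    M0: float = 9.06

    def __post_init__(self) -> None:
        if not (0.0 < self.phi <= 1.0):
            raise ValueError(f"phi must be in (0, 1], got {self.phi}")
        if self.n <= 0:
            raise ValueError(f"valency n must be > 0, got {self.n}")
        if self.R0 <= 0:
            raise ValueError(f"R0 must be > 0, got {self.R0}")
        if self.M0 <= 0:
            raise ValueError(f"M0 must be > 0, got {self.M0}")

    @property
    def V0(self) -> float:
        """Apparent monomer volume (4/3) pi R0^3, nm^3."""
        return _sphere_volume(self.R0)

    @property
    def C0(self) -> float:
        """Effective molar concentration of one molecule in V0, mM."""
        return _molar_concentration_mM(1.0, self.V0)


@dataclass(frozen=True)
class IterationState:
    """State of the assembly recursion at iteration ``i`` (0 = monomer)."""

    i: int
    N: float  #: number of molecules, (n+1)^i
    V: float  #: apparent volume, nm^3
    R: float  #: apparent radius, nm
    M: float  #: mass, kDa
    C: float  #: effective molar concentration, mM


class PowerLawFit(NamedTuple):
    """log10(M) = B + A*log10(R); the slope A equals the fractal dimension."""

    A: float
    B: float
    r2: float


class PercolationThreshold(NamedTuple):
    p_crit: float
    clipped: bool  #: True when 1/(n-1) exceeds 1 (threshold not reachable)


def fractal_dimension(params: ScalingParams) -> float:
    """Fractal dimension d_f = 3 ln(n+1) / ln((n+1)/phi).

    Completely determined by the monomer compactness and valency; equals 3
    exactly in the space-filling limit phi = 1.
    """
    ratio = (params.n + 1.0) / params.phi
    if ratio <= 1.0:
        raise ValueError(
            f"degenerate parameters: (n+1)/phi = {ratio} <= 1 (log argument)"
        )
    return 3.0 * math.log(params.n + 1.0) / math.log(ratio)


def iterate_assembly(params: ScalingParams, i_max: int) -> list[IterationState]:
    """Evaluate the assembly recursion for iterations 0..i_max.

    Molecule counts are generally non-integer because ``n`` is an ensemble
    average; use :func:`round` only for display.
    """
    if i_max < 0:
        raise ValueError("i_max must be >= 0")
    growth_N = params.n + 1.0
    growth_V = growth_N / params.phi
    states = []
    for i in range(i_max + 1):
        N = growth_N**i
        V = params.V0 * growth_V**i
        R = params.R0 * growth_V ** (i / 3.0)
        M = params.M0 * N
        C = params.C0 * params.phi**i
        states.append(IterationState(i=i, N=N, V=V, R=R, M=M, C=C))
    return states


def fit_mass_size(points: Sequence[tuple[float, float]]) -> PowerLawFit:
    """Least-squares power-law fit of mass (kDa) against size (nm).

    Fits log10(M) = B + A*log10(R); on model-generated points the fit is
    exact and A equals the fractal dimension.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValueError("need at least 2 (R, M) points")
    if np.any(pts <= 0):
        raise ValueError("R and M must all be positive")
    logR = np.log10(pts[:, 0])
    logM = np.log10(pts[:, 1])
    if np.ptp(logR) == 0:
        raise ValueError("need at least 2 distinct R values")
    A, B = np.polyfit(logR, logM, 1)
    resid = logM - (B + A * logR)
    ss_tot = float(np.sum((logM - logM.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return PowerLawFit(A=float(A), B=float(B), r2=r2)


def invert_fit(fit: PowerLawFit, M0: float, V_vdw: float) -> ScalingParams:
    """Recover (phi, n, R0) from a mass-size regression.

    Exact inverse of the forward map: R0 = 10^((log10 M0 - B)/A);
    phi = V_vdw / ((4/3) pi R0^3); n = exp(A ln(1/phi)/(3 - A)) - 1.

    Parameters
    ----------
    fit : PowerLawFit
        Slope/intercept of the log10 M vs log10 R regression.
    M0 : float
        Monomer mass, kDa.
    V_vdw : float
        Monomer van der Waals volume, nm^3 (sets phi given the apparent
        monomer volume implied by the regression).
    """
    if not (0.0 < fit.A < 3.0):
        raise ValueError(f"slope A must be in (0, 3), got {fit.A}")
    R0 = 10.0 ** ((math.log10(M0) - fit.B) / fit.A)
    phi = V_vdw / _sphere_volume(R0)
    if not (0.0 < phi <= 1.0 + 1e-12):
        raise ValueError(
            f"inconsistent inversion: recovered phi = {phi:.6g} outside (0, 1] "
            f"(R0 = {R0:.6g} nm, V_vdw = {V_vdw:.6g} nm^3)"
        )
    phi = min(phi, 1.0)
    n = math.exp(fit.A * math.log(1.0 / phi) / (3.0 - fit.A)) - 1.0
    return ScalingParams(phi=phi, n=n, R0=R0, M0=M0)


def concentration_at_size(params: ScalingParams, R: float) -> float:
    """Effective molar concentration (mM) of a cluster of apparent radius R.

    C(R) = C0 * (R/R0)^(d_f - 3): the density of a fractal decreases as a
    power of the length scale with exponent d_f - d (d = 3 here).
    """
    if R < params.R0 * (1.0 - 1e-12):
        raise ValueError(f"R = {R} nm below monomer radius R0 = {params.R0} nm")
    d_f = fractal_dimension(params)
    return params.C0 * (R / params.R0) ** (d_f - 3.0)


def isocurve_phi_of_n(
    R: float,
    C: float,
    M0: float,
    n_grid: Sequence[float],
    V_vdw: float | None = None,
) -> list[tuple[float, float]]:
    """Compactness phi required at each valency n to realise a condensate of
    fixed size R (nm) and concentration C (mM).

    For each n the equation C(R; phi, n) = C is solved for phi by bracketed
    bisection on (1e-4, 1].  The monomer apparent radius depends on phi
    through the molecule's van der Waals volume, R0(phi) = (3 V_vdw /
    (4 pi phi))^{1/3}; by default V_vdw is estimated from the monomer mass
    with a standard protein partial specific volume of 0.73 cm^3/g.

    Grid points with no solution in (0, 1] are returned with phi = nan.
    """
    if R <= 0 or C <= 0 or M0 <= 0:
        raise ValueError("R, C and M0 must be positive")
    if V_vdw is None:
        V_vdw = M0 * VDW_VOLUME_PER_KDA

    def conc(phi: float, n: float) -> float:
        R0 = (V_vdw / phi / (4.0 / 3.0 * math.pi)) ** (1.0 / 3.0)
        p = ScalingParams(phi=phi, n=n, R0=R0, M0=M0)
        if R < R0:
            return math.nan
        return concentration_at_size(p, R)

    out: list[tuple[float, float]] = []
    lo, hi = 1e-4, 1.0
    for n in n_grid:
        if n <= 0:
            raise ValueError("n_grid entries must be positive")
        f_lo = conc(lo, n) - C
        f_hi = conc(hi, n) - C
        if math.isnan(f_lo) or math.isnan(f_hi) or f_lo * f_hi > 0:
            out.append((float(n), math.nan))
            continue
        phi = brentq(lambda p: conc(p, n) - C, lo, hi, rtol=1e-8)
        out.append((float(n), float(phi)))
    return out


def percolation_threshold(n: float) -> PercolationThreshold:
    """Flory-Stockmayer critical bond probability p_crit = 1/(n-1).

    ``clipped`` flags valencies 1 < n < 2 for which the nominal threshold
    exceeds 1 (no percolation possible at any bond probability).
    """
    if n <= 1.0:
        raise ValueError(f"percolation threshold requires n > 1, got {n}")
    p = 1.0 / (n - 1.0)
    return PercolationThreshold(p_crit=p, clipped=p > 1.0)
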