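"""Synthetic inputs with known ground truth for every analysis path.

These generators emulate the data the descriptor, transport and FRAP
modules consume — crowded multi-chain scenes with planted contact graphs,
polymer conformers of tunable compactness, recovery curves with known
double-exponential parameters, MSD series with a planted diffusion
coefficient, and pressure-tensor series whose autocorrelation integral
yields a planted viscosity — without any molecular dynamics or microscopy.

Polymers are pseudo-atomic (4 carbon-radius atoms per residue): enough to
exercise the contact, volume and Rg code paths while keeping generation
fast.  Every generator is deterministic under its seed and returns its
ground truth alongside the generated object.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np
from scipy.signal import lfilter

from .descriptors import random_coil_rg
from .ensemble import Chain, ChainEnsemble
from .frap import RecoveryCurve
from .transport import KB, MSDSeries, PressureSeries

__all__ = [
    "gen_polymer",
    "gen_scene",
    "gen_frap",
    "gen_msd",
    "gen_pressure",
]

BOND_LENGTH = 0.38      # nm, residue-residue spacing of the bead walk
AVOID_DIST = 0.30       # nm, self-avoidance distance between beads
SIDE_OFFSET = 0.12      # nm, placement of the 3 pseudo side atoms

#: offsets of the three side pseudo-atoms relative to the backbone bead
_SIDE_DIRS = np.array([[1.0, 0.0, 0.0], [-0.5, 0.866, 0.0], [-0.5, -0.866, 0.0]])


def _random_unit(rng: np.random.Generator, n: int = 1) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _walk(n: int, rng: np.random.Generator, *, confine: float | None,
          persistence: float) -> np.ndarray | None:
    """Self-avoiding bead walk; confined to a sphere (compact) or with
    directional persistence (extended).  Returns None on failure."""
    beads = np.zeros((n, 3))
    direction = _random_unit(rng)[0]
    for k in range(1, n):
        for _ in range(120):
            if persistence > 0:
                step = direction + persistence * rng.normal(size=3)
            else:
                step = rng.normal(size=3)
            step /= np.linalg.norm(step)
            cand = beads[k - 1] + BOND_LENGTH * step
            if confine is not None and np.linalg.norm(cand) > confine:
                continue
            if k > 1 and np.min(
                np.linalg.norm(beads[: k - 1] - cand, axis=1)
            ) < AVOID_DIST:
                continue
            beads[k] = cand
            direction = step
            break
        else:
            return None
    return beads


def gen_polymer(
    n_res: int,
    compactness_mode: str = "compact",
    seed: int = 0,
    rg_target: float | None = None,
    sequence: str | None = None,
) -> tuple[Chain, np.ndarray]:
    """Single-chain pseudo-atomic conformer of tunable compactness.

    ``compact`` confines the walk to a sphere sized so the chain Rg falls
    below the random-coil reference for that length (``rg_target``
    overrides the default 0.6 x coil); ``extended`` uses a persistent walk
    whose Rg exceeds the coil value.  4 pseudo-atoms per residue, carbon
    radii; identical seeds give identical coordinates.
    """
    if n_res < 2:
        raise ValueError("need at least 2 residues")
    if sequence is None:
        sequence = "G" * n_res
    if len(sequence) != n_res:
        raise ValueError("sequence length must equal n_res")
    rng = np.random.default_rng(seed)
    if compactness_mode == "compact":
        target = rg_target if rg_target is not None else 0.6 * random_coil_rg(n_res)
        confine, persistence = target / math.sqrt(3.0 / 5.0), 0.0
    elif compactness_mode == "extended":
        confine, persistence = None, 0.4
    else:
        raise ValueError(f"unknown compactness_mode {compactness_mode!r}")

    beads = None
    for _ in range(50):
        beads = _walk(n_res, rng, confine=confine, persistence=persistence)
        if beads is not None:
            break
    if beads is None:
        raise RuntimeError(
            f"self-avoiding walk failed for n_res = {n_res} "
            f"({compactness_mode}); loosen rg_target"
        )
    coords = (beads[:, None, :]
              + SIDE_OFFSET * np.vstack([np.zeros(3), _SIDE_DIRS])[None, :, :]
              ).reshape(-1, 3)
    chain = Chain(
        elements=np.array(["C"] * (4 * n_res), dtype=object),
        residue_index=np.repeat(np.arange(n_res), 4),
        sequence=sequence,
    )
    return chain, coords


def _blob(rng: np.random.Generator, n_core: int, rho: float) -> np.ndarray:
    """Points inside a ball of radius rho (core of a scene chain)."""
    pts = rng.normal(size=(n_core, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    return pts * (rho * rng.uniform(0.0, 0.7, size=(n_core, 1)) ** (1 / 3))


def _layout_centers(n, L, edges, d_on, d_off, rng, margin, n_iter=2000):
    """Chain-centre layout honouring a planted contact graph.

    Nodes are seeded along a BFS tree of the graph (each child at distance
    d_on from its parent, random orientation) and refined by damped stress
    relaxation: planted edges relax to distance d_on, all other pairs to
    >= d_off, everything inside the box margins.  Per-iteration steps are
    capped to keep hubs from being catapulted by summed spring forces.
    """
    edge_set = {tuple(sorted(e)) for e in edges}
    neighbours: dict[int, list[int]] = {k: [] for k in range(n)}
    for i, j in edge_set:
        neighbours[i].append(j)
        neighbours[j].append(i)

    pos = np.full((n, 3), np.nan)
    for root in range(n):
        if not np.isnan(pos[root, 0]):
            continue
        pos[root] = rng.uniform(margin, L - margin, size=3)
        queue = [root]
        while queue:
            cur = queue.pop(0)
            for nb in neighbours[cur]:
                if np.isnan(pos[nb, 0]):
                    pos[nb] = np.clip(pos[cur] + d_on * _random_unit(rng)[0],
                                      margin, L - margin)
                    queue.append(nb)

    max_step = 0.25 * d_on
    for _ in range(n_iter):
        shift = np.zeros_like(pos)
        worst = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                d = pos[j] - pos[i]
                dist = np.linalg.norm(d)
                if dist < 1e-9:
                    d = _random_unit(rng)[0] * 1e-3
                    dist = 1e-3
                if (i, j) in edge_set:
                    err = dist - d_on
                    worst = max(worst, abs(err))
                    corr = 0.3 * err * d / dist
                    shift[i] += corr
                    shift[j] -= corr
                elif dist < d_off:
                    err = d_off - dist
                    worst = max(worst, err)
                    corr = 0.4 * err * d / dist
                    shift[i] -= corr
                    shift[j] += corr
        norms = np.linalg.norm(shift, axis=1, keepdims=True)
        scale = np.minimum(1.0, max_step / np.maximum(norms, 1e-12))
        pos = np.clip(pos + shift * scale, margin, L - margin)
        if worst < 0.02:
            return pos
    return None


def gen_scene(
    n_chains: int,
    L: float,
    planted_adjacency: Iterable[tuple[int, int]] | np.ndarray | None = None,
    seed: int = 0,
    n_frames: int = 1,
    atoms_per_chain: int = 12,
) -> tuple[ChainEnsemble, np.ndarray]:
    """Crowded multi-chain scene in a periodic cubic box of edge L nm.

    With a planted contact graph, chain pairs joined by an edge are placed
    with minimum interatomic distance <= 0.3 nm and all other pairs at
    >= 0.6 nm — margins on either side of the 0.35 nm contact cutoff, so
    descriptor results are robust to cutoff choices in [0.33, 0.40] nm.
    With ``planted_adjacency=None`` chains are dropped uniformly at random
    (for oracle-equivalence testing); the returned adjacency is then empty.

    Returns ``(ensemble, planted_adjacency_matrix)``.
    """
    if n_chains < 1:
        raise ValueError("n_chains must be >= 1")
    rng = np.random.default_rng(seed)
    rho = 0.35  # blob radius, nm
    planted = np.zeros((n_chains, n_chains), dtype=bool)

    if planted_adjacency is None:
        centers = rng.uniform(0.0, L, size=(n_chains, 3))
        edges: list[tuple[int, int]] = []
    else:
        adj = np.asarray(planted_adjacency)
        if adj.ndim == 2 and adj.shape == (n_chains, n_chains):
            edges = [tuple(e) for e in np.argwhere(np.triu(adj, 1))]
        else:
            edges = [tuple(sorted(map(int, e))) for e in planted_adjacency]
        for i, j in edges:
            planted[i, j] = planted[j, i] = True
        d_on = 2 * rho + 0.25   # min atom distance ~0.25 via surface anchors
        d_off = 2 * rho + 0.70  # non-edges: min atom distance >= 0.70
        margin = rho + 0.5
        if L < 2 * margin + d_off:
            raise ValueError(f"box L = {L} nm too small for {n_chains} chains")
        centers = None
        for attempt in range(20):
            centers = _layout_centers(
                n_chains, L, edges, d_on, d_off,
                np.random.default_rng(rng.integers(2**31)), margin)
            if centers is not None:
                break
        if centers is None:
            raise RuntimeError(
                f"packing failed for the planted graph ({len(edges)} edges "
                f"on {n_chains} chains in L = {L} nm)"
            )

    n_res = max(1, atoms_per_chain // 4)
    per_res = int(np.ceil(atoms_per_chain / n_res))
    n_atoms = n_res * per_res
    seq = ("GYR" * n_res)[:n_res]
    chains = []
    base_coords = []
    for c in range(n_chains):
        core = _blob(rng, n_atoms, rho)
        if planted_adjacency is not None:
            # surface anchors toward each planted partner guarantee the
            # <= 0.3 nm contact margin
            partners = np.flatnonzero(planted[c])
            for k, p in enumerate(partners[: n_atoms]):
                d = centers[p] - centers[c]
                core[k] = rho * d / np.linalg.norm(d)
        base_coords.append(core + centers[c])
        chains.append(Chain(
            elements=np.array(["C"] * n_atoms, dtype=object),
            residue_index=np.repeat(np.arange(n_res), per_res),
            sequence=seq,
            label=str(c),
        ))

    frames = []
    for f in range(n_frames):
        jitter = rng.normal(scale=0.005, size=(n_chains, n_atoms, 3)) if f else 0.0
        frames.append([
            base_coords[c] + (jitter[c] if f else 0.0) for c in range(n_chains)
        ])
    ensemble = ChainEnsemble(chains=chains, frames=frames,
                             times=np.arange(n_frames, dtype=float),
                             box=L, periodic=True)
    return ensemble, planted


def gen_frap(
    a: float, b: float, tau_a: float, tau_b: float,
    noise_sigma: float = 0.0, n_points: int = 32, seed: int = 0,
    t_max: float = 1200.0,
) -> RecoveryCurve:
    """Recovery curve sampled from the double-exponential model on a
    log-spaced grid out to ``t_max`` s (20 min), with additive Gaussian
    noise of standard deviation ``noise_sigma``."""
    if min(a, b) < 0 or min(tau_a, tau_b) <= 0:
        raise ValueError("amplitudes must be >= 0 and times > 0")
    rng = np.random.default_rng(seed)
    t = np.concatenate([[0.0], np.geomspace(t_max / 300.0, t_max, n_points - 1)])
    y = 1.0 - a * np.exp(-t / tau_a) - b * np.exp(-t / tau_b)
    if noise_sigma > 0:
        y = y + rng.normal(scale=noise_sigma, size=len(t))
    return RecoveryCurve(time=t, intensity=y)


def gen_msd(
    D: float, c: float = 0.0, t_max: float = 50.0,
    noise_sigma: float = 0.0, seed: int = 0, n_points: int = 200,
    window: tuple[float, float] = (20.0, 40.0),
) -> MSDSeries:
    """MSD series msd = c + 6 D tau with planted D (um^2/s), lag in ns and
    msd in nm^2, plus optional additive Gaussian noise (nm^2)."""
    if D < 0 or t_max <= 0:
        raise ValueError("D must be >= 0 and t_max positive")
    rng = np.random.default_rng(seed)
    lag = np.linspace(t_max / n_points, t_max, n_points)
    d_nm2_ns = D * 1e-3  # um^2/s -> nm^2/ns
    msd = c + 6.0 * d_nm2_ns * lag
    if noise_sigma > 0:
        msd = np.maximum(msd + rng.normal(scale=noise_sigma, size=len(lag)), 0.0)
    return MSDSeries(lag=lag, msd=msd, window=window)


def gen_pressure(
    eta_target: float, V: float = 729.0, T: float = 310.0,
    dt: float = 0.01, length: int = 4_000_000, seed: int = 0,
    tau_c: float = 1.5,
) -> PressureSeries:
    """Pressure-tensor series with a planted Green-Kubo viscosity.

    Each of the six components is an independent Ornstein-Uhlenbeck process
    with autocorrelation C(t) = sigma^2 exp(-t/tau_c); the variance is
    chosen so that V/(k_B T) * sigma^2 tau_c equals ``eta_target`` mPa s.
    ``dt`` and ``tau_c`` in ps, V in nm^3.  The defaults mirror an
    equilibrium run sampled every 10 fs with a ~ps pressure decorrelation
    time, long enough (40 ns) for the tail fit of the autocorrelation to
    be statistically converged, as Green-Kubo estimates require.
    """
    if eta_target <= 0 or V <= 0 or T <= 0 or dt <= 0 or tau_c <= 0:
        raise ValueError("all parameters must be positive")
    rng = np.random.default_rng(seed)
    # eta [mPa s] = V/(kB T) * sigma^2 tau_c * unit  =>  sigma^2 in bar^2
    unit = 1e10 * 1e-27 * 1e-12 * 1e3  # bar^2 nm^3 ps / J -> mPa s
    sigma2 = eta_target * KB * T / (V * tau_c * unit)
    decay = math.exp(-dt / tau_c)
    innov = math.sqrt(sigma2 * (1.0 - decay**2))
    comps = np.empty((6, length))
    for k in range(6):
        noise = rng.normal(scale=innov, size=length)
        noise[0] = rng.normal(scale=math.sqrt(sigma2))
        # AR(1) recursion x_i = decay * x_{i-1} + noise_i
        comps[k] = lfilter([1.0], [1.0, -decay], noise)
    time = dt * np.arange(length)
    return PressureSeries(time=time, components=comps, volume=V, temperature=T)
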