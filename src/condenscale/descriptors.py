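"""Per-chain and per-ensemble descriptors of crowded multi-chain systems.

Implements the descriptor layer that turns multi-chain coordinate sets into
the quantities the fractal model consumes: chain-chain contacts under a
minimum-image cutoff (0.35 nm by default, all atoms), interaction valency,
contact probability, single-linkage chain clusters, residue-type contact
enrichment, 1D interaction profiles and their representative mode, radius
of gyration, compactness (van der Waals / hydrodynamic volume ratio), box
concentration, and the size-normalised configurational-entropy difference
used to compare mutants.

Residue indices are 0-based internally and 1-based in any report output.
Analysis windows default to the trailing 30% of frames.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .ensemble import ATOMIC_MASSES, BONDI_RADII, Chain, ChainEnsemble
from .scaling import AVOGADRO

__all__ = [
    "ContactStats",
    "ClusterPartition",
    "CompactnessResult",
    "ValencySeries",
    "EnrichmentTable",
    "RepresentativeMode",
    "chain_contacts",
    "valency_series",
    "contact_probability",
    "cluster_chains",
    "enrichment_from_counts",
    "contact_enrichment",
    "interaction_profiles",
    "representative_mode",
    "radius_of_gyration",
    "random_coil_rg",
    "compactness",
    "box_concentration",
    "entropy_mutation_difference",
]

DEFAULT_CUTOFF = 0.35      # nm, all-atom minimum-distance contact cutoff
DEFAULT_WINDOW = 0.3       # trailing fraction of frames used for averages


def _window_start(n_frames: int, window: float) -> int:
    """Index of the first frame inside a trailing window fraction."""
    if not (0.0 < window <= 1.0):
        raise ValueError("window fraction must be in (0, 1]")
    return n_frames - max(1, int(math.ceil(window * n_frames)))


@dataclass
class ContactStats:
    """Frame-resolved contact statistics of a multi-chain ensemble.

    ``adjacency[f, i, j]`` is True when the minimum interatomic distance
    between chains i and j in frame f is at or below the cutoff (minimum
    image under the periodic box).  Residue-pair events are deduplicated:
    one event per residue pair per frame regardless of how many atom pairs
    qualify.
    """

    adjacency: np.ndarray        # (F, C, C) bool
    min_dist: np.ndarray         # (F, C, C) float, nm
    inter_counts: np.ndarray     # (F, T, T) residue-type pair events, upper-symmetric
    intra_counts: np.ndarray     # (F, T, T)
    inter_profiles: np.ndarray   # (F, C, L) per-position inter-chain events
    intra_profiles: np.ndarray   # (F, C, L)
    types: list[str]
    composition: pd.Series       # f_A over the chain sequences, sums to 1
    sequences: list[str]
    times: np.ndarray
    cutoff: float

    @property
    def n_frames(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_chains(self) -> int:
        return self.adjacency.shape[1]


class ValencySeries(NamedTuple):
    degrees: np.ndarray        # (F, C) partner counts per chain per frame
    mean_per_frame: np.ndarray  # (F,)
    window_mean: float         # mean over the trailing analysis window


@dataclass
class ClusterPartition:
    """Per-frame single-linkage partition of chains (connected components
    of the contact graph, equivalent to hierarchical clustering of the
    chain-chain minimum-distance matrix cut at the contact cutoff)."""

    partitions: list[list[list[int]]]
    largest_size: np.ndarray            # (F,)
    largest_rg: np.ndarray | None = None  # (F,) nm, if coordinates supplied


class EnrichmentTable(NamedTuple):
    observed: pd.DataFrame   # unordered-pair frequencies, sum to 1
    expected: pd.DataFrame   # f_A^2 (A == B) and 2 f_A f_B (A != B)
    enrichment: pd.DataFrame  # observed/expected; NaN where expected == 0


class RepresentativeMode(NamedTuple):
    profile: np.ndarray   # (L,) mean of the selected chains' profiles
    members: tuple[int, ...]
    qc_pearson: float     # correlation with the all-chain average profile
    passed: bool          # qc_pearson > 0.6


def _chain_trees(frame: list[np.ndarray], box: float | None):
    """KD-trees per chain; coordinates wrapped into [0, L) when periodic."""
    trees = []
    for xyz in frame:
        pts = np.mod(xyz, box) if box is not None else xyz
        trees.append(cKDTree(pts, boxsize=box))
    return trees


def chain_contacts(
    ensemble: ChainEnsemble,
    cutoff: float = DEFAULT_CUTOFF,
    min_sequence_separation: int = 2,
) -> ContactStats:
    """All-atom contact statistics under a minimum-image distance cutoff.

    Two chains are in contact in a frame iff their minimum interatomic
    distance is <= ``cutoff``.  Intra-chain residue contacts exclude pairs
    closer in sequence than ``min_sequence_separation`` (bonded and
    next-neighbour positions carry no interaction information).
    """
    if ensemble.n_frames < 1:
        raise ValueError("ensemble has no frames")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    box = ensemble.box if ensemble.periodic else None
    if ensemble.periodic and box is None:
        raise ValueError("periodic flag set without a cubic box")
    if not ensemble.homogeneous:
        raise ValueError("contact statistics require homogeneous chain lengths")

    C = ensemble.n_chains
    L = ensemble.sequence_length()
    sequences = [c.sequence for c in ensemble.chains]
    types = sorted(set("".join(sequences)))
    if not types:
        raise ValueError("chains carry empty sequences")
    t_index = {t: k for k, t in enumerate(types)}
    T = len(types)
    F = ensemble.n_frames

    adjacency = np.zeros((F, C, C), dtype=bool)
    min_dist = np.full((F, C, C), np.inf)
    inter_counts = np.zeros((F, T, T))
    intra_counts = np.zeros((F, T, T))
    inter_profiles = np.zeros((F, C, L))
    intra_profiles = np.zeros((F, C, L))

    res_idx = [c.residue_index for c in ensemble.chains]
    seq_codes = [np.array([t_index[s] for s in seq]) for seq in sequences]

    for f, frame in enumerate(ensemble.frames):
        trees = _chain_trees(frame, box)
        wrapped = [t.data for t in trees]
        for i in range(C):
            # intra-chain residue pairs
            pairs = trees[i].query_pairs(cutoff, output_type="ndarray")
            if len(pairs):
                ri = res_idx[i][pairs[:, 0]]
                rj = res_idx[i][pairs[:, 1]]
                keep = np.abs(ri - rj) >= min_sequence_separation
                respairs = {tuple(sorted(p)) for p in zip(ri[keep], rj[keep])}
                for ra, rb in respairs:
                    ta, tb = sorted((seq_codes[i][ra], seq_codes[i][rb]))
                    intra_counts[f, ta, tb] += 1
                    intra_profiles[f, i, ra] += 1
                    intra_profiles[f, i, rb] += 1
            for j in range(i + 1, C):
                d, _ = trees[j].query(wrapped[i], k=1)
                dmin = float(np.min(d))
                min_dist[f, i, j] = min_dist[f, j, i] = dmin
                if dmin > cutoff:
                    continue
                adjacency[f, i, j] = adjacency[f, j, i] = True
                neigh = trees[i].query_ball_tree(trees[j], cutoff)
                respairs = set()
                for ai, a_js in enumerate(neigh):
                    for aj in a_js:
                        respairs.add((res_idx[i][ai], res_idx[j][aj]))
                for ra, rb in respairs:
                    ta, tb = sorted((seq_codes[i][ra], seq_codes[j][rb]))
                    inter_counts[f, ta, tb] += 1
                    inter_profiles[f, i, ra] += 1
                    inter_profiles[f, j, rb] += 1

    comp = pd.Series(
        {t: sum(seq.count(t) for seq in sequences) for t in types}, dtype=float
    )
    comp /= comp.sum()
    return ContactStats(
        adjacency=adjacency,
        min_dist=min_dist,
        inter_counts=inter_counts,
        intra_counts=intra_counts,
        inter_profiles=inter_profiles,
        intra_profiles=intra_profiles,
        types=types,
        composition=comp,
        sequences=sequences,
        times=ensemble.times.copy(),
        cutoff=cutoff,
    )


def valency_series(stats: ContactStats, window: float = DEFAULT_WINDOW) -> ValencySeries:
    """Interaction valency: number of bound partner chains per chain."""
    degrees = stats.adjacency.sum(axis=2).astype(float)
    mean_per_frame = degrees.mean(axis=1)
    start = _window_start(stats.n_frames, window)
    return ValencySeries(
        degrees=degrees,
        mean_per_frame=mean_per_frame,
        window_mean=float(mean_per_frame[start:].mean()),
    )


def contact_probability(stats: ContactStats, n_chains: int | None = None) -> np.ndarray:
    """Per-frame contact probability p = mean valency / (n_chains - 1),
    assuming a well-mixed system where every chain can reach every other."""
    if n_chains is None:
        n_chains = stats.n_chains
    if n_chains < 2:
        raise ValueError("contact probability needs at least 2 chains")
    return valency_series(stats).mean_per_frame / (n_chains - 1)


def cluster_chains(
    stats: ContactStats, ensemble: ChainEnsemble | None = None
) -> ClusterPartition:
    """Single-linkage chain clusters per frame.

    Cutting a single-linkage dendrogram of the chain-chain minimum-distance
    matrix at the contact cutoff yields exactly the connected components of
    the contact graph, which is what is computed here.  When the source
    ensemble is supplied, the radius of gyration of the largest cluster is
    reported per frame (chains unwrapped by minimum image along a spanning
    tree of the cluster's contact graph).
    """
    partitions = []
    largest = np.zeros(stats.n_frames, dtype=int)
    largest_rg = np.zeros(stats.n_frames) if ensemble is not None else None
    for f in range(stats.n_frames):
        graph = csr_matrix(stats.adjacency[f].astype(int))
        n_comp, labels = connected_components(graph, directed=False)
        blocks = [sorted(np.flatnonzero(labels == k).tolist()) for k in range(n_comp)]
        blocks.sort(key=len, reverse=True)
        partitions.append(blocks)
        largest[f] = len(blocks[0])
        if ensemble is not None:
            members = blocks[0]
            coords, masses = _unwrap_cluster(ensemble, f, members, stats.adjacency[f])
            largest_rg[f] = radius_of_gyration(coords, masses)
    return ClusterPartition(partitions=partitions, largest_size=largest,
                            largest_rg=largest_rg)


def _unwrap_cluster(ensemble, f, members, adjacency):
    """Concatenate member-chain coordinates, shifting each chain by whole
    box vectors so the cluster is contiguous (BFS over the contact graph)."""
    L = ensemble.box if ensemble.periodic else None
    frame = ensemble.frames[f]
    centers = {c: frame[c].mean(axis=0) for c in members}
    shift = {members[0]: np.zeros(3)}
    queue = [members[0]]
    while queue:
        c = queue.pop(0)
        for d in members:
            if d in shift or not adjacency[c, d]:
                continue
            delta = np.zeros(3)
            if L is not None:
                gap = (centers[c] + shift[c]) - centers[d]
                delta = np.round(gap / L) * L
            shift[d] = delta
            queue.append(d)
    for c in members:  # disconnected safety net (should not happen)
        shift.setdefault(c, np.zeros(3))
    coords = np.vstack([frame[c] + shift[c] for c in members])
    masses = np.concatenate([ensemble.chains[c].masses() for c in members])
    return coords, masses


def enrichment_from_counts(
    counts: np.ndarray, types: list[str], composition: pd.Series
) -> EnrichmentTable:
    """Residue-type pair enrichment ENR(A,B) = f_obs(A,B) / f_exp(A,B).

    Observed frequencies are normalised over unordered type pairs; the
    random expectation from sequence composition is f_A^2 for homotypic and
    2 f_A f_B for heterotypic pairs, so both tables sum to 1.
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("contact counts must be non-negative")
    # fold ordered counts onto unordered pairs, presented as a symmetric table
    unordered = counts + counts.T - np.diag(np.diag(counts))
    total = np.triu(unordered).sum()
    if total <= 0:
        raise ValueError("no contact events to compute enrichment from")
    f = composition.reindex(types).to_numpy(dtype=float)
    if np.any(np.isnan(f)) or f.sum() <= 0:
        raise ValueError("invalid sequence composition")
    obs = unordered / total
    exp = 2.0 * np.outer(f, f)
    np.fill_diagonal(exp, f**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        enr = np.where(exp > 0, obs / exp, np.nan)
    idx = pd.Index(types)

    def as_df(m: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(m, index=idx, columns=idx)

    return EnrichmentTable(observed=as_df(obs), expected=as_df(exp),
                           enrichment=as_df(enr))


def contact_enrichment(
    stats: ContactStats, window: float = DEFAULT_WINDOW
) -> dict[str, EnrichmentTable]:
    """Enrichment tables for intra- and inter-chain contacts over the
    trailing analysis window."""
    start = _window_start(stats.n_frames, window)
    out = {}
    for scope, counts in (("intra", stats.intra_counts), ("inter", stats.inter_counts)):
        total = counts[start:].sum(axis=0)
        if total.sum() > 0:
            out[scope] = enrichment_from_counts(total, stats.types, stats.composition)
    if not out:
        raise ValueError("no contact events in the analysis window")
    return out


def interaction_profiles(
    stats: ContactStats, scope: str = "inter", window: float = DEFAULT_WINDOW
) -> np.ndarray:
    """Per-chain 1D interaction profiles (dynamic interaction modes).

    Returns a (n_chains, seq_len) array of per-position contact event
    frequencies averaged over the trailing analysis window.
    """
    if scope == "inter":
        prof = stats.inter_profiles
    elif scope == "intra":
        prof = stats.intra_profiles
    else:
        raise ValueError(f"scope must be 'intra' or 'inter', got {scope!r}")
    start = _window_start(stats.n_frames, window)
    return prof[start:].mean(axis=0)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = np.std(x), np.std(y)
    if sx == 0 or sy == 0:
        return 1.0 if np.allclose(x - x.mean(), y - y.mean()) else 0.0
    return float(np.corrcoef(x, y)[0, 1])


def representative_mode(
    profiles: np.ndarray,
    valencies: np.ndarray,
    n_select: int = 4,
    qc_threshold: float = 0.6,
    max_exhaustive: int = 20,
) -> RepresentativeMode:
    """Representative interaction mode of the ensemble.

    Chains whose mean valency rounds (half-to-even) to the rounded system
    mean are eligible; among them the ``n_select`` profiles maximising the
    sum of pairwise Pearson correlations are averaged.  Selection is
    exhaustive for up to ``max_exhaustive`` eligible chains, greedy beyond
    (start from the best pair, add the chain maximising the summed
    correlation to the current set).  QC reports the Pearson correlation of
    the representative with the all-chain average profile.
    """
    profiles = np.asarray(profiles, dtype=float)
    valencies = np.asarray(valencies, dtype=float)
    target = np.round(valencies.mean())
    eligible = np.flatnonzero(np.round(valencies) == target)
    if len(eligible) < n_select:
        raise ValueError(
            f"only {len(eligible)} chains have rounded valency {target:g}; "
            f"need {n_select} — fall back to the all-chain average profile"
        )
    corr = np.ones((len(eligible), len(eligible)))
    for a, b in itertools.combinations(range(len(eligible)), 2):
        corr[a, b] = corr[b, a] = _pearson(profiles[eligible[a]], profiles[eligible[b]])

    def score(idx: tuple[int, ...]) -> float:
        return sum(corr[a, b] for a, b in itertools.combinations(idx, 2))

    if len(eligible) <= max_exhaustive:
        best = max(itertools.combinations(range(len(eligible)), n_select), key=score)
    else:
        a, b = max(itertools.combinations(range(len(eligible)), 2),
                   key=lambda p: corr[p])
        chosen = [a, b]
        while len(chosen) < n_select:
            rest = [k for k in range(len(eligible)) if k not in chosen]
            chosen.append(max(rest, key=lambda k: sum(corr[k, c] for c in chosen)))
        best = tuple(chosen)
    members = tuple(int(eligible[k]) for k in best)
    rep = profiles[list(members)].mean(axis=0)
    qc = _pearson(rep, profiles.mean(axis=0))
    return RepresentativeMode(profile=rep, members=members, qc_pearson=qc,
                              passed=qc > qc_threshold)


def radius_of_gyration(coords: np.ndarray, masses: np.ndarray | None = None) -> float:
    """Mass-weighted radius of gyration about the centre of mass, nm."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 1:
        raise ValueError("need at least one atom")
    if masses is None:
        masses = np.ones(len(coords))
    masses = np.asarray(masses, dtype=float)
    total = masses.sum()
    if total <= 0:
        raise ValueError("total mass must be positive")
    com = (masses[:, None] * coords).sum(axis=0) / total
    return float(np.sqrt((masses * ((coords - com) ** 2).sum(axis=1)).sum() / total))


def random_coil_rg(n_residues: int, r0: float = 0.254, nu: float = 0.522) -> float:
    """Random-coil Rg from the IDP scaling law Rg = r0 * N^nu (nm)."""
    if n_residues < 1:
        raise ValueError("residue count must be >= 1")
    return r0 * n_residues**nu


@dataclass
class CompactnessResult:
    V_vdw: float   # union-of-spheres van der Waals volume, nm^3
    V_h: float     # hydrodynamic (apparent) volume (4/3) pi Rh^3, nm^3
    phi: float     # V_vdw / V_h
    Rg: float      # nm
    Rh: float      # nm


def _union_of_spheres_volume(
    coords: np.ndarray, radii: np.ndarray, grid_spacing: float
) -> float:
    """Volume of the union of atomic spheres by grid voxelisation."""
    lo = (coords - radii[:, None]).min(axis=0) - grid_spacing
    hi = (coords + radii[:, None]).max(axis=0) + grid_spacing
    dims = np.maximum(np.ceil((hi - lo) / grid_spacing).astype(int) + 1, 1)
    occupied = np.zeros(dims, dtype=bool)
    axes = [lo[k] + grid_spacing * np.arange(dims[k]) for k in range(3)]
    for xyz, r in zip(coords, radii):
        i0 = np.maximum(np.floor((xyz - r - lo) / grid_spacing).astype(int), 0)
        i1 = np.minimum(np.ceil((xyz - lo + r) / grid_spacing).astype(int) + 1, dims)
        sub = [axes[k][i0[k]:i1[k]] - xyz[k] for k in range(3)]
        dx2 = sub[0][:, None, None] ** 2 + sub[1][None, :, None] ** 2 \
            + sub[2][None, None, :] ** 2
        occupied[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]] |= dx2 <= r * r
    return float(occupied.sum()) * grid_spacing**3


def _kirkwood_rh(coords: np.ndarray) -> float:
    """Kirkwood double-sum hydrodynamic radius: Rh^-1 = N^-2 sum_{i!=j} 1/r_ij."""
    n = len(coords)
    if n == 1:
        raise ValueError("Kirkwood Rh undefined for a single atom")
    diff = coords[:, None, :] - coords[None, :, :]
    r = np.sqrt((diff**2).sum(axis=-1))
    inv = np.zeros_like(r)
    mask = ~np.eye(n, dtype=bool)
    inv[mask] = 1.0 / r[mask]
    return float(n * n / inv.sum())


def compactness(
    coords: np.ndarray,
    elements: np.ndarray,
    grid_spacing: float = 0.05,
    rh_method: str = "kirkwood",
    masses: np.ndarray | None = None,
    radii_override: dict[str, float] | None = None,
    rh_override: float | None = None,
) -> CompactnessResult:
    """Compactness phi = V_vdw / V_h of a single chain conformer.

    V_vdw is the union-of-spheres volume with Bondi radii (voxelised at
    ``grid_spacing`` nm); V_h = (4/3) pi Rh^3 with Rh from the Kirkwood
    double sum (default) or the compact-sphere mapping Rh = sqrt(5/3) Rg
    (``rh_method='empirical'``), or an explicit ``rh_override``.
    """
    coords = np.asarray(coords, dtype=float)
    if len(coords) < 1:
        raise ValueError("need at least one atom")
    table = dict(BONDI_RADII)
    if radii_override:
        table.update({k.upper(): v for k, v in radii_override.items()})
    try:
        radii = np.array([table[str(e).upper()] for e in elements])
    except KeyError as exc:
        raise ValueError(f"unknown element {exc}: supply radii_override") from exc
    if masses is None:
        masses = np.array([ATOMIC_MASSES.get(str(e).upper(), 12.011) for e in elements])
    rg = radius_of_gyration(coords, masses)
    v_vdw = _union_of_spheres_volume(coords, radii, grid_spacing)
    if rh_override is not None:
        rh = rh_override
    elif len(coords) == 1:
        rh = float(radii[0])
    elif rh_method == "kirkwood":
        rh = _kirkwood_rh(coords)
    elif rh_method == "empirical":
        rh = math.sqrt(5.0 / 3.0) * rg
    else:
        raise ValueError(f"unknown rh_method {rh_method!r}")
    v_h = 4.0 / 3.0 * math.pi * rh**3
    phi = v_vdw / v_h
    if phi > 1.0:
        warnings.warn(
            f"compactness estimator yielded phi = {phi:.3f} > 1 "
            "(hydrodynamic volume smaller than van der Waals volume)",
            stacklevel=2,
        )
    return CompactnessResult(V_vdw=v_vdw, V_h=v_h, phi=phi, Rg=rg, Rh=rh)


def box_concentration(n_chains: int, L: float) -> float:
    """Molar concentration (mM) of ``n_chains`` molecules in a cubic box of
    edge L nm: C = N / (N_A L^3)."""
    if n_chains < 1:
        raise ValueError("n_chains must be >= 1")
    if L <= 0:
        raise ValueError("box edge must be positive")
    return n_chains / (AVOGADRO * L**3 * 1e-24) * 1e3


def entropy_mutation_difference(
    S_mut: float, N_mut: int, S_wt: float, N_wt: int, T: float = 310.0
) -> float:
    """Size-normalised configurational-entropy difference between a mutant
    and the wild type, returned as T*dS.

    dS = [S_mut/(3 N_mut - 6) - S_wt/(3 N_wt - 6)] * (3 N_mut - 6), where N
    are atom counts and 3N - 6 the internal degrees of freedom; normalising
    per degree of freedom makes chains of different size comparable.  With
    entropies in kcal/mol/K and T in K the result is kcal/mol.
    """
    if N_mut < 3 or N_wt < 3:
        raise ValueError("atom counts must be >= 3")
    dof_mut = 3 * N_mut - 6
    dof_wt = 3 * N_wt - 6
    dS = (S_mut / dof_mut - S_wt / dof_wt) * dof_mut
    return dS * T
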