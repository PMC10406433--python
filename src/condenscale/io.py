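"""Structure readers/writers and delimited-table I/O.

Coordinate formats (PDB, GRO, XYZ) are parsed and written through
MDAnalysis; everything is converted to the package's internal units (nm)
at this boundary.  Chains are resolved from PDB segment/chain identifiers,
from residue-numbering restarts in GRO files, and from a JSON sidecar
(``<file>.chains.json``) for XYZ.  Aggregates whose coordinates overflow
the fixed-width PDB fields are transparently written as XYZ instead.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import MDAnalysis as mda

from Bio.Data.IUPACData import protein_letters_1to3, protein_letters_3to1

from .ensemble import Chain, ChainEnsemble
from .transport import MSDSeries, PressureSeries
from .frap import RecoveryCurve

__all__ = [
    "read_structure",
    "write_structure",
    "read_msd_table",
    "read_pressure_table",
    "read_frap_table",
]

_ONE_TO_THREE = {k: v.upper() for k, v in protein_letters_1to3.items()}
_THREE_TO_ONE = {k.upper(): v for k, v in protein_letters_3to1.items()}
_CHAIN_ID_POOL = (
    "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
)
PDB_COORD_LIMIT = 9999.999  # Angstrom, fixed-width field maximum


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt:
        return fmt.lower()
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("pdb", "gro", "xyz"):
        return suffix
    raise ValueError(f"cannot infer structure format from {path.name!r}")


def _element_of(atom) -> str:
    try:
        el = atom.element.strip()
        if el:
            return el.capitalize()
    except mda.exceptions.NoDataError:
        pass
    name = atom.name.strip()
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "C"


def _sequence_of(resnames) -> str:
    return "".join(_THREE_TO_ONE.get(str(r).upper(), "X") for r in resnames)


def _chain_boundaries(universe, fmt: str) -> list[np.ndarray]:
    """Atom-index groups, one per chain."""
    atoms = universe.atoms
    if fmt == "gro":
        # chains delimited by residue-number restarts
        resids = atoms.resids
        starts = [0]
        prev = resids[0]
        for k in range(1, len(atoms)):
            if resids[k] < prev:
                starts.append(k)
            prev = resids[k]
        bounds = starts + [len(atoms)]
        return [np.arange(bounds[i], bounds[i + 1]) for i in range(len(starts))]
    segids = getattr(atoms, "segids", None)
    chainids = None
    try:
        chainids = atoms.chainIDs
    except mda.exceptions.NoDataError:
        pass
    use = None
    if segids is not None and len(set(segids)) > 1:
        use = segids
    elif chainids is not None and len(set(chainids)) > 1:
        use = chainids
    if use is None:
        return [np.arange(len(atoms))]
    groups: dict[str, list[int]] = {}
    order: list[str] = []
    for k, key in enumerate(use):
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(k)
    return [np.asarray(groups[key]) for key in order]


def read_structure(path: str | Path, fmt: str | None = None,
                   dt_ns: float = 1.0) -> ChainEnsemble:
    """Read a (multi-frame) structure file into a :class:`ChainEnsemble`.

    Coordinates are converted to nm regardless of the source convention;
    a cubic box is taken from CRYST1/the GRO box line when present.  XYZ
    files require a ``<file>.chains.json`` sidecar carrying chain lengths,
    sequences and (optionally) the box.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, fmt)
    sidecar = None
    if fmt == "xyz":
        sc_path = path.with_suffix(path.suffix + ".chains.json")
        if not sc_path.exists():
            raise ValueError(
                f"XYZ input needs a chain-map sidecar at {sc_path.name}"
            )
        sidecar = json.loads(sc_path.read_text())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        universe = mda.Universe(str(path))

    atoms = universe.atoms
    if fmt == "xyz":
        lengths = sidecar["chain_atoms"]
        if sum(lengths) != len(atoms):
            raise ValueError("sidecar chain_atoms do not sum to the atom count")
        bounds = np.cumsum([0] + list(lengths))
        groups = [np.arange(bounds[i], bounds[i + 1]) for i in range(len(lengths))]
    else:
        groups = _chain_boundaries(universe, fmt)

    chains = []
    for c, idx in enumerate(groups):
        sub = atoms[idx]
        elements = np.array([_element_of(a) for a in sub], dtype=object)
        if fmt == "xyz":
            res_per = np.asarray(sidecar["residue_index"][c], dtype=int)
            seq = sidecar["sequences"][c]
        else:
            resids = sub.resids
            _, res_per = np.unique(resids, return_inverse=True)
            first = np.concatenate([[True], np.diff(res_per) != 0])
            seq = _sequence_of(sub.resnames[first])
        chains.append(Chain(elements=elements, residue_index=res_per,
                            sequence=seq, label=str(c)))

    frames, times = [], []
    for ts in universe.trajectory:
        pos = atoms.positions / 10.0  # A -> nm
        frames.append([pos[idx].copy() for idx in groups])
        times.append(ts.frame * dt_ns)

    box = None
    periodic = False
    if fmt == "xyz":
        box = sidecar.get("box")
        periodic = bool(sidecar.get("periodic", box is not None))
    else:
        dims = universe.dimensions
        if dims is not None and dims[0] > 0:
            lx, ly, lz = dims[:3] / 10.0
            if not np.allclose([lx, ly], lz, rtol=1e-3):
                raise ValueError(
                    f"non-cubic box {lx:.3f} x {ly:.3f} x {lz:.3f} nm unsupported"
                )
            box, periodic = float(lx), True
    return ChainEnsemble(chains=chains, frames=frames,
                         times=np.asarray(times, dtype=float),
                         box=box, periodic=periodic)


def _build_universe(ensemble: ChainEnsemble) -> mda.Universe:
    n_atoms = sum(c.n_atoms for c in ensemble.chains)
    n_res = sum(c.n_residues for c in ensemble.chains)
    atom_res = []
    res_seg = []
    names, resnames, resids, segids, chainids, elements = [], [], [], [], [], []
    res_offset = 0
    for c, chain in enumerate(ensemble.chains):
        atom_res.extend((chain.residue_index + res_offset).tolist())
        res_seg.extend([c] * chain.n_residues)
        for r, letter in enumerate(chain.sequence):
            resnames.append(_ONE_TO_THREE.get(letter.upper(), "UNK"))
            resids.append(r + 1)
        counts = np.zeros(chain.n_residues, dtype=int)
        for e, r in zip(chain.elements, chain.residue_index):
            counts[r] += 1
            names.append(f"{str(e).upper()}{counts[r]}"[:4])
            elements.append(str(e).capitalize())
        segids.append(f"{c:04d}")
        chainids.extend([_CHAIN_ID_POOL[c % len(_CHAIN_ID_POOL)]] * chain.n_atoms)
    u = mda.Universe.empty(
        n_atoms, n_residues=n_res, n_segments=ensemble.n_chains,
        atom_resindex=np.asarray(atom_res), residue_segindex=np.asarray(res_seg),
        trajectory=True,
    )
    u.add_TopologyAttr("names", names)
    u.add_TopologyAttr("elements", elements)
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("resids", resids)
    u.add_TopologyAttr("segids", segids)
    u.add_TopologyAttr("chainIDs", chainids)
    coords = np.stack([
        np.vstack(frame) * 10.0 for frame in ensemble.frames  # nm -> A
    ])
    u.load_new(coords, format="memory", order="fac")
    if ensemble.periodic and ensemble.box:
        L = ensemble.box * 10.0
        for ts in u.trajectory:
            ts.dimensions = [L, L, L, 90.0, 90.0, 90.0]
        u.trajectory[0]
    return u


def write_structure(ensemble: ChainEnsemble, path: str | Path,
                    fmt: str | None = None) -> Path:
    """Write a :class:`ChainEnsemble` (or decorated aggregate) to disk.

    Returns the path actually written: PDB output whose coordinates exceed
    the fixed-width field limit is diverted to XYZ with a warning.  XYZ
    output always carries a ``<file>.chains.json`` sidecar so it can be
    read back with full chain information.
    """
    path = Path(path)
    if ensemble.n_chains == 0 or ensemble.n_frames == 0:
        raise ValueError("refusing to write an empty ensemble")
    fmt = _infer_format(path, fmt)
    if fmt == "pdb":
        flat = np.concatenate([np.vstack(fr).ravel() for fr in ensemble.frames])
        if np.max(np.abs(flat)) * 10.0 > PDB_COORD_LIMIT:
            warnings.warn(
                "coordinates overflow PDB fixed-width fields; writing XYZ instead",
                stacklevel=2,
            )
            return write_structure(ensemble, path.with_suffix(".xyz"), "xyz")
    universe = _build_universe(ensemble)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if fmt == "gro":
            if ensemble.n_frames != 1:
                raise ValueError("GRO output supports a single frame")
            universe.atoms.write(str(path))
        else:
            multi = ensemble.n_frames > 1
            with mda.Writer(str(path), universe.atoms.n_atoms,
                            multiframe=multi) as w:
                for _ in universe.trajectory:
                    w.write(universe.atoms)
    if fmt == "xyz":
        sidecar = {
            "chain_atoms": [c.n_atoms for c in ensemble.chains],
            "residue_index": [c.residue_index.tolist() for c in ensemble.chains],
            "sequences": [c.sequence for c in ensemble.chains],
            "box": ensemble.box,
            "periodic": ensemble.periodic,
        }
        path.with_suffix(path.suffix + ".chains.json").write_text(
            json.dumps(sidecar))
    return path


def read_msd_table(path: str | Path,
                   window: tuple[float, float] = (20.0, 40.0)) -> MSDSeries:
    """Two-column TSV (lag ns, msd nm^2), '#' comments allowed."""
    df = pd.read_csv(path, sep=r"\s+", comment="#", header=None)
    if df.shape[1] < 2:
        raise ValueError("expected two columns: lag_ns, msd_nm2")
    return MSDSeries(lag=df.iloc[:, 0].to_numpy(),
                     msd=df.iloc[:, 1].to_numpy(), window=window)


def _header_json(path: Path) -> dict:
    with open(path) as fh:
        first = fh.readline().strip()
    if first.startswith("#"):
        body = first.lstrip("#").strip()
        if body.startswith("{"):
            return json.loads(body)
    return {}


def read_pressure_table(path: str | Path, volume: float | None = None,
                        temperature: float | None = None) -> PressureSeries:
    """Seven-column TSV (time ps + six pressure components, bar) with a
    JSON header line ``# {"volume_nm3": ..., "temperature_K": ...}``;
    explicit arguments override the header."""
    path = Path(path)
    header = _header_json(path)
    volume = volume if volume is not None else header.get("volume_nm3")
    temperature = (temperature if temperature is not None
                   else header.get("temperature_K"))
    if volume is None or temperature is None:
        raise ValueError("volume_nm3 and temperature_K required "
                         "(header JSON or arguments)")
    df = pd.read_csv(path, sep=r"\s+", comment="#", header=None)
    if df.shape[1] != 7:
        raise ValueError("expected 7 columns: time_ps + six pressure components")
    return PressureSeries(time=df.iloc[:, 0].to_numpy(),
                          components=df.iloc[:, 1:].to_numpy().T,
                          volume=float(volume), temperature=float(temperature))


def read_frap_table(path: str | Path, geometry: str = "whole") -> RecoveryCurve:
    """Two-column TSV (time s, normalised intensity)."""
    df = pd.read_csv(path, sep=r"\s+", comment="#", header=None)
    if df.shape[1] < 2:
        raise ValueError("expected two columns: time_s, intensity")
    return RecoveryCurve(time=df.iloc[:, 0].to_numpy(),
                         intensity=df.iloc[:, 1].to_numpy(), geometry=geometry)
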