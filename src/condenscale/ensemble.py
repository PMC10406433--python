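"""In-memory container for multi-chain, multi-frame atomic coordinate sets.

Coordinates are stored in nm.  A :class:`ChainEnsemble` holds a static
per-chain topology (elements, residue indices, one-letter sequence) plus a
list of frames, each frame being a list of per-chain ``(n_atoms, 3)``
coordinate arrays.  The box, when periodic, is cubic with edge length L nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Chain", "ChainEnsemble", "ATOMIC_MASSES", "BONDI_RADII"]

#: Standard atomic masses (Da) for the elements that occur in protein models.
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
    "S": 32.06, "P": 30.974, "SE": 78.971,
}

#: Bondi van der Waals radii, nm.
BONDI_RADII = {
    "H": 0.120, "C": 0.170, "N": 0.155, "O": 0.152,
    "S": 0.180, "P": 0.180, "SE": 0.190,
}


@dataclass
class Chain:
    """Static topology of a single chain.

    ``residue_index`` maps each atom to its 0-based residue position;
    ``sequence`` is the one-letter residue string of the chain.
    """

    elements: np.ndarray          # (n_atoms,) str
    residue_index: np.ndarray     # (n_atoms,) int, 0-based, contiguous
    sequence: str
    label: str = ""

    def __post_init__(self) -> None:
        self.elements = np.asarray(self.elements, dtype=object)
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        if len(self.elements) != len(self.residue_index):
            raise ValueError("elements and residue_index length mismatch")
        if len(self.residue_index):
            uniq = np.unique(self.residue_index)
            if uniq[0] != 0 or uniq[-1] != len(uniq) - 1:
                raise ValueError("residue indices must be contiguous from 0")
            if self.sequence and len(self.sequence) != len(uniq):
                raise ValueError("sequence length does not match residues")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def n_residues(self) -> int:
        return int(self.residue_index.max()) + 1 if self.n_atoms else 0

    def masses(self) -> np.ndarray:
        try:
            return np.array([ATOMIC_MASSES[str(e).upper()] for e in self.elements])
        except KeyError as exc:
            raise ValueError(f"unknown element {exc} (no mass available)") from exc


@dataclass
class ChainEnsemble:
    """frames x chains x atoms coordinate set with a periodic cubic box.

    ``frames[f][c]`` is the ``(n_atoms_c, 3)`` nm coordinate array of chain
    ``c`` at frame ``f``; ``times`` carries per-frame timestamps in ns.
    """

    chains: list[Chain]
    frames: list[list[np.ndarray]]
    times: np.ndarray = field(default_factory=lambda: np.zeros(0))
    box: float | None = None      # cubic edge length L, nm
    periodic: bool = False

    def __post_init__(self) -> None:
        if self.periodic and (self.box is None or self.box <= 0):
            raise ValueError("periodic flag set but no positive cubic box given")
        for f, frame in enumerate(self.frames):
            if len(frame) != len(self.chains):
                raise ValueError(f"frame {f}: chain count mismatch")
            for c, (xyz, chain) in enumerate(zip(frame, self.chains)):
                xyz = np.asarray(xyz, dtype=float)
                if xyz.shape != (chain.n_atoms, 3):
                    raise ValueError(f"frame {f} chain {c}: bad coordinate shape")
                if not np.all(np.isfinite(xyz)):
                    raise ValueError(f"frame {f} chain {c}: non-finite coordinates")
                frame[c] = xyz
        times = np.asarray(self.times, dtype=float)
        if times.size == 0:
            times = np.arange(len(self.frames), dtype=float)
        if len(times) != len(self.frames):
            raise ValueError("times length must match number of frames")
        self.times = times

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def homogeneous(self) -> bool:
        """True when all chains share one sequence length."""
        lengths = {c.n_residues for c in self.chains}
        return len(lengths) <= 1

    def sequence_length(self) -> int:
        if not self.homogeneous:
            raise ValueError("heterogeneous ensemble has no single sequence length")
        return self.chains[0].n_residues if self.chains else 0
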