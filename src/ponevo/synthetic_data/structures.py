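"""Pseudo protein structures with planted residue clusters.

Backbone C-alpha positions follow a self-avoiding random walk with ~3.8 A
steps (the canonical C-alpha--C-alpha distance); a subset of residues can
be re-placed inside a sphere of chosen radius to plant a spatial cluster.
The emitted text is standard PDB ATOM records (C-alpha only), plus a
truth set of the clustered residue indices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .._rng import child_rng
from ..phylo_engine.alignment import AMINO_ACIDS

__all__ = ["StructureSpec", "simulate_structure"]

CA_STEP = 3.8  # Angstrom
_MIN_SELF_DISTANCE = 3.5
_MAX_ATTEMPTS = 200

_THREE_LETTER = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


@dataclass
class StructureSpec:
    n_residues: int
    cluster: tuple[int, float] | None = None  # (n_clustered_sites, radius A)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 1:
            raise ValueError("n_residues must be >= 1")
        if self.cluster is not None:
            n, radius = self.cluster
            if n > self.n_residues:
                raise ValueError("cluster larger than the structure")
            if n < 1 or radius <= 0:
                raise ValueError("invalid cluster geometry")
            # sphere packing sanity: ~2 A minimum spacing inside the sphere
            if n > max(1, int((radius / 2.0 + 1) ** 3)):
                raise ValueError(
                    f"cluster_radius {radius} A too small for {n} residues"
                )


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def simulate_structure(spec: StructureSpec) -> tuple[str, set[int]]:
    """Emit (pdb_text, clustered_residue_numbers).

    Residue numbers are 1-based and match the ATOM records.  The walk is
    self-avoiding (no two C-alphas closer than 3.5 A); clustered residues
    are drawn uniformly inside a sphere of the requested radius around a
    point near the walk's centroid.  Identical specs give identical text.
    """
    rng = child_rng(spec.seed, "simulate_structure")
    n = spec.n_residues
    coords = np.zeros((n, 3))
    for i in range(1, n):
        placed = False
        for _ in range(_MAX_ATTEMPTS):
            cand = coords[i - 1] + CA_STEP * _random_unit(rng)
            if i < 2 or np.min(np.linalg.norm(coords[: i - 1] - cand, axis=1)) >= _MIN_SELF_DISTANCE:
                coords[i] = cand
                placed = True
                break
        if not placed:
            raise RuntimeError("self-avoiding walk stalled; try another seed")

    truth: set[int] = set()
    if spec.cluster is not None:
        k, radius = spec.cluster
        members = rng.choice(n, size=k, replace=False)
        center = coords.mean(axis=0) + rng.normal(scale=2.0, size=3)
        for idx in members:
            # uniform in the sphere, repelled to >= 2 A from other members
            for _ in range(_MAX_ATTEMPTS):
                u = rng.random() ** (1 / 3)
                cand = center + radius * u * _random_unit(rng)
                others = [j for j in truth if j - 1 != idx]
                if not others or np.min(
                    np.linalg.norm(coords[[j - 1 for j in others]] - cand, axis=1)
                ) >= 2.0:
                    break
            coords[idx] = cand
            truth.add(int(idx) + 1)

    resnames = [
        _THREE_LETTER[AMINO_ACIDS[i]]
        for i in child_rng(spec.seed, "structure_resnames").integers(0, 20, size=n)
    ]
    lines = []
    for i in range(n):
        x, y, z = coords[i]
        lines.append(
            f"ATOM  {i + 1:>5}  CA  {resnames[i]} A{i + 1:>4}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    return "\n".join(lines) + "\n", truth
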