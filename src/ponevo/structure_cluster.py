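"""Structural clustering of selected residues.

Parses PDB coordinates, computes per-residue accessible surface area
(Shrake-Rupley sphere sampling with a deterministic golden-spiral point
set), classifies exposed residues against reference maximum ASA values,
maps alignment columns onto structure residues, and runs a permutation
test asking whether a set of residues (e.g. positively selected sites)
sits closer together in space than random same-sized draws from the
candidate pool.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import protein_letters_3to1
from scipy.spatial import cKDTree

from ._rng import child_rng
from .phylo_engine.alignment import Alignment

logger = logging.getLogger(__name__)

__all__ = [
    "StructureResidue",
    "ClusterTestResult",
    "parse_structure",
    "compute_asa",
    "classify_exposed",
    "map_alignment_to_structure",
    "clustering_permutation_test",
]

PROBE_RADIUS = 1.4  # water probe, Angstrom

# van der Waals radii by element (Angstrom)
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "P": 1.80}
_DEFAULT_RADIUS = 1.70

# Theoretical maximum ASA per residue type (Tien et al. 2013), Angstrom^2.
MAX_ASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}


@dataclass
class StructureResidue:
    chain: str
    resnum: int
    resname: str
    elements: list[str]
    coords: np.ndarray  # (n_atoms, 3)
    radii: np.ndarray  # (n_atoms,)
    ca: np.ndarray | None  # C-alpha coordinates or None if unresolved
    asa: float | None = None
    exposed: bool | None = None

    @property
    def one_letter(self) -> str:
        return protein_letters_3to1.get(self.resname, "X")


@dataclass
class ClusterTestResult:
    observed: float  # statistic value, Angstrom
    n_permutations: int
    n_at_most_observed: int  # b = #{null <= observed}
    p_value: float  # (b + 1) / (N + 1)
    seed: int
    statistic: str = "mean_pairwise_ca_distance"
    pool_size: int = 0
    n_selected: int = 0


# ----------------------------------------------------------------------
def parse_structure(pdb_text: str) -> list[StructureResidue]:
    """Parse ATOM records into :class:`StructureResidue` entries.

    Residues are keyed by (chain, residue number); HETATM-only input is
    an error.  Alternate locations resolve to the highest-occupancy
    conformer (first seen on ties, the Bio.PDB convention).  A residue
    without a C-alpha is retained but excluded from distance statistics.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", io.StringIO(pdb_text))
    residues: list[StructureResidue] = []
    for model in structure:
        for chain in model:
            for res in chain:
                if res.id[0] != " ":
                    continue  # skip HETATM / water
                elements, coords, radii = [], [], []
                ca = None
                for atom in res:  # disordered atoms yield the selected altloc
                    el = (atom.element or atom.get_name()[:1]).upper()
                    elements.append(el)
                    coords.append(atom.coord.astype(float))
                    radii.append(VDW_RADII.get(el, _DEFAULT_RADIUS))
                    if atom.get_name() == "CA":
                        ca = atom.coord.astype(float)
                if not coords:
                    continue
                if ca is None:
                    logger.warning(
                        "residue %s%s %s has no C-alpha; excluded from "
                        "distance statistics", chain.id, res.id[1], res.resname,
                    )
                residues.append(
                    StructureResidue(
                        chain=chain.id,
                        resnum=int(res.id[1]),
                        resname=res.resname,
                        elements=elements,
                        coords=np.asarray(coords),
                        radii=np.asarray(radii),
                        ca=ca,
                    )
                )
        break  # first model only
    if not residues:
        raise ValueError("no ATOM records (standard residues) in input")
    return residues


def _golden_spiral(n: int) -> np.ndarray:
    """n deterministic, nearly uniform points on the unit sphere."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5**0.5) * k
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def compute_asa(
    residues: list[StructureResidue],
    probe_radius: float = PROBE_RADIUS,
    n_points: int = 960,
) -> list[StructureResidue]:
    """Fill per-residue accessible surface area (Shrake-Rupley).

    Each atom's expanded sphere (vdW + probe) is sampled at ``n_points``
    golden-spiral points; points inside any neighboring expanded sphere
    are buried.  Deterministic for a given point count.
    """
    if n_points < 10:
        raise ValueError("n_points must be >= 10")
    pts = _golden_spiral(n_points)
    all_coords = np.concatenate([r.coords for r in residues])
    all_radii = np.concatenate([r.radii for r in residues])
    owner = np.concatenate(
        [np.full(len(r.coords), i) for i, r in enumerate(residues)]
    )
    expanded = all_radii + probe_radius
    tree = cKDTree(all_coords)
    max_reach = expanded.max() * 2
    asa = np.zeros(len(residues))
    for a in range(len(all_coords)):
        r_exp = expanded[a]
        sphere = all_coords[a] + r_exp * pts
        accessible = np.ones(n_points, dtype=bool)
        for b in tree.query_ball_point(all_coords[a], r_exp + expanded.max()):
            if b == a:
                continue
            d = np.linalg.norm(all_coords[b] - all_coords[a])
            if d >= r_exp + expanded[b]:
                continue
            # points exactly on the shared surface belong to the
            # lower-indexed atom, so coincident spheres count once
            tol = 1e-9 if b > a else -1e-9
            accessible &= (
                np.linalg.norm(sphere - all_coords[b], axis=1) >= expanded[b] + tol
            )
            if not accessible.any():
                break
        asa[owner[a]] += accessible.mean() * 4 * np.pi * r_exp**2
    for i, r in enumerate(residues):
        r.asa = float(asa[i])
    return residues


def classify_exposed(
    residues: list[StructureResidue], ratio_threshold: float = 0.2
) -> list[StructureResidue]:
    """Flag residues whose ASA reaches ``ratio_threshold`` of the
    residue-type maximum (inclusive).  Unknown residue types are treated
    as exposed and logged."""
    for r in residues:
        if r.asa is None:
            raise ValueError("run compute_asa before classify_exposed")
        ref = MAX_ASA.get(r.resname)
        if ref is None:
            logger.warning("unknown residue type %s: treated as exposed", r.resname)
            r.exposed = True
        else:
            r.exposed = (r.asa / ref) >= ratio_threshold
    return residues


# ----------------------------------------------------------------------
def map_alignment_to_structure(
    msa: Alignment,
    query_name: str,
    structure_seq: str,
    residue_numbers: list[int] | None = None,
    max_mismatch: float = 0.05,
) -> dict[int, int]:
    """Map alignment columns of the query row to structure residue numbers.

    The query row's ungapped sequence is laid against ``structure_seq``
    position by position; each non-gap column maps to the corresponding
    residue number (1-based by default, or ``residue_numbers``).  Columns
    where the query is gapped map to nothing.  More than ``max_mismatch``
    disagreement raises an error.
    """
    if query_name not in msa.names:
        raise ValueError(f"query {query_name!r} not in alignment")
    row = msa.rows[msa.names.index(query_name)]
    ungapped = [(col, ch) for col, ch in enumerate(row) if ch not in "-."]
    if len(ungapped) != len(structure_seq):
        raise ValueError(
            f"query has {len(ungapped)} residues but structure sequence has "
            f"{len(structure_seq)}"
        )
    if residue_numbers is None:
        residue_numbers = list(range(1, len(structure_seq) + 1))
    if len(residue_numbers) != len(structure_seq):
        raise ValueError("residue_numbers length mismatch")
    mismatches = sum(
        1
        for (_, ch), s in zip(ungapped, structure_seq.upper())
        if ch != s and ch != "X" and s != "X"
    )
    if len(structure_seq) and mismatches / len(structure_seq) > max_mismatch:
        raise ValueError(
            f"{mismatches}/{len(structure_seq)} mismatches between query and "
            "structure sequence exceed the tolerance"
        )
    return {col: residue_numbers[i] for i, (col, _) in enumerate(ungapped)}


# ----------------------------------------------------------------------
def _mean_pairwise(D: np.ndarray) -> float:
    n = D.shape[0]
    return float(D[np.triu_indices(n, 1)].mean())


def clustering_permutation_test(
    selected: set[int],
    residues: list[StructureResidue],
    restrict_to_exposed: bool = True,
    n_permutations: int = 1_000_000,
    seed: int = 0,
    statistic: str = "mean_pairwise",
) -> ClusterTestResult:
    """Permutation test for spatial clustering of ``selected`` residues.

    The observed statistic (mean pairwise C-alpha distance by default,
    mean nearest-neighbor distance with ``statistic='mean_nn'``) is
    compared against the same statistic for ``n_permutations`` uniform
    same-size draws (without replacement) from the candidate pool: the
    exposed residues when ``restrict_to_exposed``, else all residues
    with a C-alpha.  p = (b + 1) / (N + 1) where b counts null draws
    with a statistic <= observed, so p is never below 1/(N+1).
    """
    pool = [
        r for r in residues
        if r.ca is not None and (not restrict_to_exposed or r.exposed)
    ]
    pool_nums = [r.resnum for r in pool]
    index_of = {num: i for i, num in enumerate(pool_nums)}
    dropped = [s for s in selected if s not in index_of]
    if dropped:
        logger.warning(
            "%d selected residues outside the candidate pool dropped: %s",
            len(dropped), sorted(dropped),
        )
    kept = sorted(s for s in selected if s in index_of)
    k = len(kept)
    if k < 2:
        raise ValueError("need >= 2 selected residues inside the candidate pool")
    if len(pool) < k:
        raise ValueError("candidate pool smaller than the selected set")
    coords = np.asarray([r.ca for r in pool])
    D = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)

    sel_idx = np.asarray([index_of[s] for s in kept])

    def stat_many(idx: np.ndarray) -> np.ndarray:
        # idx: (m, k) index matrix into the pool
        sub = D[idx[:, :, None], idx[:, None, :]]
        if statistic == "mean_pairwise":
            return sub.sum(axis=(1, 2)) / (k * (k - 1))
        if statistic == "mean_nn":
            sub = sub + np.eye(k)[None, :, :] * 1e9
            return sub.min(axis=2).mean(axis=1)
        raise ValueError(f"unknown statistic {statistic!r}")

    observed = float(stat_many(sel_idx[None, :])[0])
    rng = child_rng(seed, "clustering_permutation_test")
    n_permutations = int(n_permutations)
    b = 0
    chunk = 20_000
    done = 0
    npool = len(pool)
    while done < n_permutations:
        m = min(chunk, n_permutations - done)
        keys = rng.random((m, npool))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
        stats = stat_many(idx)
        b += int((stats <= observed + 1e-12).sum())
        done += m
    p = (b + 1) / (n_permutations + 1)
    return ClusterTestResult(
        observed=observed,
        n_permutations=n_permutations,
        n_at_most_observed=b,
        p_value=float(p),
        seed=int(seed),
        statistic="mean_pairwise_ca_distance" if statistic == "mean_pairwise"
        else "mean_nn_ca_distance",
        pool_size=npool,
        n_selected=k,
    )
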