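"""Synthetic gene-locus tables and matching domain-hit text.

Plants tandem arrays (consecutive loci on one scaffold with a chosen
inter-gene gap), per-group family absences, and intron-loss (retrocopy)
genes, then emits the coordinate table and a domtblout-dialect hit file
whose e-values optionally straddle the 1e-6 inclusion cutoff.  Every
planted feature is returned in a truth table so the scan stage can be
checked against it exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .._rng import child_rng

__all__ = ["PlantedArray", "LocusTableSpec", "simulate_locus_table"]

# separation between distinct planted arrays on a shared scaffold; must
# exceed the 100-kb tandem window so planted arrays never merge
_ARRAY_SEPARATION_BP = 400_000
_GENE_LENGTH_RANGE = (2_000, 20_000)


@dataclass(frozen=True)
class PlantedArray:
    species: str
    scaffold: str
    n_genes: int
    gap_bp: int
    family: str = "fam1"
    retro_indices: tuple[int, ...] = ()  # genes planted with one exon

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.gap_bp < 0:
            raise ValueError("gap must be >= 0")


@dataclass
class LocusTableSpec:
    species: list[str]
    arrays: list[PlantedArray]
    seed: int
    scaffold_count: dict[str, int] = field(default_factory=dict)
    absences: dict[str, set[str]] = field(default_factory=dict)  # family -> species
    straddle_evalues: bool = False  # if set, ~half the hits fail the cutoff

    def __post_init__(self) -> None:
        for arr in self.arrays:
            if arr.species not in self.species:
                raise ValueError(f"array species {arr.species!r} not listed")
            if arr.species in self.absences.get(arr.family, set()):
                raise ValueError(
                    f"family {arr.family!r} planted in {arr.species!r} but "
                    "also declared absent there"
                )
        for sp, n in self.scaffold_count.items():
            if n < 1:
                raise ValueError("scaffold counts must be >= 1")


def simulate_locus_table(
    spec: LocusTableSpec,
) -> tuple[pd.DataFrame, str, dict]:
    """Emit (locus table, domtblout text, truth) for a planted family layout.

    The locus table has columns species, gene_id, scaffold, start, end,
    strand, exon_count.  Every planted gene gets one or two domain-hit
    lines; species declared absent for a family get none.  With
    ``straddle_evalues`` a coin decides per gene whether its e-values
    pass the 1e-6 cutoff (both must pass to count as retained); the
    decision is stored in the truth table.
    """
    rng = child_rng(spec.seed, "simulate_locus_table")
    rows = []
    hit_lines = [
        "# target name        accession   tlen query name           accession   "
        "qlen   E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias  "
        "from    to  from    to  from    to  acc description of target",
        "#------------------- ----------",
    ]
    truth_genes = []
    cursor: dict[tuple[str, str], int] = {}  # (species, scaffold) -> next free bp
    for ai, arr in enumerate(spec.arrays):
        key = (arr.species, arr.scaffold)
        pos = cursor.get(key, 0)
        if pos > 0:
            pos += _ARRAY_SEPARATION_BP
        members = []
        for g in range(arr.n_genes):
            length = int(rng.integers(*_GENE_LENGTH_RANGE))
            start = pos + 1
            end = start + length - 1
            pos = end + arr.gap_bp + 1 - 1  # next start = end + gap + 1
            gene_id = f"{arr.species}_{arr.family}_a{ai}_g{g}"
            strand = "+" if rng.random() < 0.5 else "-"
            exon_count = 1 if g in arr.retro_indices else int(rng.integers(4, 12))
            rows.append(
                dict(
                    species=arr.species,
                    gene_id=gene_id,
                    scaffold=arr.scaffold,
                    start=start,
                    end=end,
                    strand=strand,
                    exon_count=exon_count,
                )
            )
            passes = True
            if spec.straddle_evalues:
                passes = bool(rng.random() < 0.5)
            if passes:
                full_e = 10.0 ** rng.uniform(-30, np.log10(1e-6))
                dom_e = min(full_e * 10.0 ** rng.uniform(0, 2), 1e-6)
            else:
                # fail on one or both criteria
                which = rng.integers(3)
                full_e = (
                    10.0 ** rng.uniform(-5, -2) if which in (0, 2)
                    else 10.0 ** rng.uniform(-30, -7)
                )
                dom_e = (
                    10.0 ** rng.uniform(-5, -2) if which in (1, 2)
                    else 10.0 ** rng.uniform(-30, -7)
                )
            n_domains = int(rng.integers(1, 3))
            target = f"{arr.species}|{gene_id}"
            for d in range(n_domains):
                # extra domain lines carry worse independent e-values so the
                # per-gene best is the planted one
                dom_e_line = dom_e if d == 0 else min(dom_e * 10 ** rng.uniform(1, 4), 10.0)
                hit_lines.append(
                    f"{target} - 400 arylesterase PF01731.21 330 {full_e:.3g} "
                    f"55.0 0.1 {d + 1} {n_domains} {dom_e_line:.3g} {dom_e_line:.3g} "
                    f"50.0 0.1 5 320 10 380 5 390 0.95 -"
                )
            members.append(gene_id)
            truth_genes.append(
                dict(
                    gene_id=gene_id,
                    species=arr.species,
                    family=arr.family,
                    array_index=ai,
                    member_index=g,
                    retro=g in arr.retro_indices,
                    evalue_pass=passes,
                    full_seq_evalue=full_e,
                    best_domain_evalue=dom_e,
                    n_domains=n_domains,
                )
            )
        cursor[key] = pos if arr.n_genes == 0 else rows[-1]["end"]
    loci = pd.DataFrame(
        rows,
        columns=[
            "species", "gene_id", "scaffold", "start", "end", "strand", "exon_count",
        ],
    )
    # overlap guard: planted genes on one scaffold must not collide
    for (sp, sc), block in loci.groupby(["species", "scaffold"]):
        b = block.sort_values("start")
        if (b["start"].values[1:] <= b["end"].values[:-1]).any():
            raise ValueError(f"planted genes overlap on {sp}/{sc}")
    families = sorted({a.family for a in spec.arrays} | set(spec.absences))
    truth = {
        "genes": truth_genes,
        "arrays": [
            dict(
                species=a.species, scaffold=a.scaffold, n_genes=a.n_genes,
                gap_bp=a.gap_bp, family=a.family,
            )
            for a in spec.arrays
        ],
        "absences": {fam: sorted(sp) for fam, sp in spec.absences.items()},
        "families": families,
        "n_hit_genes": len(truth_genes),
    }
    return loci, "\n".join(hit_lines) + "\n", truth
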