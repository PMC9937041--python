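#!/usr/bin/env python
"""Generate the synthetic study inputs every later stage consumes.

Emits, under results/simulated/:
  - a protein alignment simulated under JTT+G on the topology where gene 1
    diverged first (the truth the topology stage should recover),
  - a codon alignment with planted branch-site selection on a marked
    foreground clade (truth for the selection stage),
  - a locus table + domain-hit text with planted tandem arrays, a planted
    whole-group absence and one retrocopy (truth for the scan stage),
  - a 150-residue pseudo-structure with a planted 8-residue cluster
    (truth for the clustering stage),
plus JSON truth tables for each.
"""

import json
from pathlib import Path

from ponevo.phylo_engine import AAModel, PhyloTree, write_fasta
from ponevo.selection_tests import SiteClassModel
from ponevo.synthetic_data import SimulationSpec, simulate_alignment
from ponevo.synthetic_data.loci import (
    LocusTableSpec,
    PlantedArray,
    simulate_locus_table,
)
from ponevo.synthetic_data.structures import StructureSpec, simulate_structure

SEED = 2023
OUT = Path(__file__).resolve().parent.parent / "results" / "simulated"

T1 = "(out:0.3,(p1:0.25,(p2:0.2,p3:0.2):0.1):0.15);"
MARKED = "(((a#1:0.2,b#1:0.2)#1:0.1,c:0.3):0.1,(d:0.2,e:0.2):0.15,f:0.4);"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    # protein alignment on the "gene 1 first" topology
    tree = PhyloTree.from_newick(T1)
    aln, truth = simulate_alignment(
        SimulationSpec(tree, AAModel("JTT", gamma_shape=1.29), 2_000, SEED)
    )
    write_fasta(aln, OUT / "tetrapod_like.fasta")
    (OUT / "tetrapod_like_truth.json").write_text(
        json.dumps({"generating_tree": T1, **truth})
    )
    print(f"protein alignment: {aln.n_sites} sites on {tree.n_leaves} taxa")

    # codon alignment with planted branch-site selection
    marked = PhyloTree.from_newick(MARKED)
    model = SiteClassModel(
        "BranchSiteA", kappa=2.0, p0=0.66, p1=0.22, omega0=0.2, omega2=5.0
    )
    codon_aln, codon_truth = simulate_alignment(
        SimulationSpec(marked, model, 500, SEED + 1)
    )
    write_fasta(codon_aln, OUT / "foreground_selection.fasta")
    (OUT / "foreground_selection_truth.json").write_text(json.dumps(codon_truth))
    (OUT / "marked_tree.nwk").write_text(MARKED + "\n")
    n_sel = len(codon_truth["selected_sites"])
    print(
        f"codon alignment: {codon_aln.n_sites} codons, "
        f"{n_sel} sites planted in the selected classes "
        f"({100 * n_sel / codon_aln.n_sites:.1f}%)"
    )

    # locus table with planted arrays, an absence and a retrocopy
    spec = LocusTableSpec(
        species=["possum", "wallaby", "opossum", "platypus"],
        arrays=[
            PlantedArray("possum", "chr3", 4, 50_000, retro_indices=(3,)),
            PlantedArray("wallaby", "chr3", 3, 60_000),
            PlantedArray("opossum", "chr1", 3, 40_000),
            PlantedArray("opossum", "chr5", 1, 0),
        ],
        absences={"fam1": {"platypus"}},
        seed=SEED + 2,
    )
    loci, hits_text, loci_truth = simulate_locus_table(spec)
    loci.to_csv(OUT / "loci.tsv", sep="\t", index=False)
    (OUT / "hits.domtblout").write_text(hits_text)
    (OUT / "loci_truth.json").write_text(json.dumps(loci_truth))
    (OUT / "groups.tsv").write_text(
        "species\tgroup\npossum\tmarsupial\nwallaby\tmarsupial\n"
        "opossum\tmarsupial\nplatypus\tmonotreme\n"
    )
    print(
        f"locus table: {len(loci)} genes in {len(spec.arrays)} planted arrays; "
        "family absent from platypus"
    )

    # pseudo-structure with a planted surface cluster
    pdb_text, cluster_truth = simulate_structure(
        StructureSpec(n_residues=150, cluster=(8, 6.0), seed=SEED + 3)
    )
    (OUT / "structure.pdb").write_text(pdb_text)
    (OUT / "structure_truth.json").write_text(json.dumps(sorted(cluster_truth)))
    print(f"pseudo-structure: 150 residues, cluster at {sorted(cluster_truth)}")


if __name__ == "__main__":
    main()
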