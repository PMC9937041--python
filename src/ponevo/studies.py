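"""Replicated validation studies over the package's own machinery.

Each function runs one self-contained study — simulate under known truth,
run the method, measure recovery / error rates — and returns plain
numbers.  The test suite asserts on them and the acceptance script
reports them; both consume the same code so the measured quantities are
identical by construction.  Every study takes an explicit seed and is
deterministic given it.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.linalg import expm
from scipy.stats import kstest

from ._rng import child_rng, child_seed
from .family_scan import (
    GeneLocus,
    assign_names,
    filter_hits,
    flag_retroduplication,
    parse_domtblout,
)
from .phylo_engine import (
    AAModel,
    Alignment,
    PhyloTree,
    build_rate_matrix,
    optimize_branch_lengths,
    tree_log_likelihood,
)
from .phylo_engine.alignment import AMINO_ACIDS
from .selection_tests import (
    SiteClassModel,
    branch_site_lrt,
    fit_branch_site,
    fit_site_model,
)
from .structure_cluster import (
    clustering_permutation_test,
    compute_asa,
    parse_structure,
)
from .synthetic_data import SimulationSpec, simulate_alignment
from .synthetic_data.loci import LocusTableSpec, PlantedArray, simulate_locus_table
from .synthetic_data.structures import StructureSpec, simulate_structure
from .topology_tests import lrt_pvalue

__all__ = [
    "enumeration_log_likelihood",
    "reported_topology_lrts",
    "pruning_oracle_max_deviation",
    "jc_branch_length_max_error",
    "m0_omega_recovery",
    "branch_site_power",
    "branch_site_type1_error",
    "family_scan_recovery",
    "planted_cluster_pvalue",
    "cluster_null_uniformity",
    "single_atom_asa_relative_error",
]

# printed log-likelihoods of the three constrained duplication-order
# models (inputs to the topology LRT stage)
REPORTED_LOGL = {"PON1_first": -8410.56, "PON2_first": -8413.77,
                 "PON3_first": -8411.31}

SIX_TAXON_NEWICK = "(((a:0.2,b:0.2):0.1,c:0.3):0.1,(d:0.2,e:0.2):0.15,f:0.4);"
MARKED_SIX_TAXON_NEWICK = (
    "(((a#1:0.2,b#1:0.2)#1:0.1,c:0.3):0.1,(d:0.2,e:0.2):0.15,f:0.4);"
)


# ----------------------------------------------------------------------
def enumeration_log_likelihood(aln: Alignment, tree: PhyloTree, model) -> float:
    """Independent likelihood oracle: exhaustive interior-state enumeration.

    Uses scipy's expm rather than the engine's spectral decomposition and
    sums the joint probability over every assignment of states to
    interior nodes; exponential in the interior-node count, so only for
    small trees.
    """
    Q, pi = build_rate_matrix(model)
    rates, probs = model.rate_mixture()
    S = len(pi)
    mat = aln.state_matrix()
    row_of = {n: i for i, n in enumerate(aln.names)}
    interior = [i for i in range(tree.n_nodes) if tree.children[i]]
    pos = {n: k for k, n in enumerate(interior)}
    grids = np.indices((S,) * len(interior)).reshape(len(interior), -1)
    total = 0.0
    for site in range(aln.n_sites):
        site_lik = 0.0
        for r, w in zip(rates, probs):
            P = {
                i: (np.eye(S) if r == 0 else expm(Q * r * tree.lengths[i]))
                for i in range(tree.n_nodes - 1)
            }
            term = pi[grids[pos[tree.root]]]
            for i in range(tree.n_nodes - 1):
                parent_states = grids[pos[tree.parent[i]]]
                if tree.children[i]:
                    term = term * P[i][parent_states, grids[pos[i]]]
                else:
                    s = mat[row_of[tree.labels[i]], site]
                    if s >= 0:
                        term = term * P[i][parent_states, s]
            site_lik += w * term.sum()
        total += np.log(site_lik)
    return float(total)


def _random_small_tree(rng: np.random.Generator, n_leaves: int) -> PhyloTree:
    nodes = [f"t{i}:{rng.uniform(0.01, 0.8):.4f}" for i in range(n_leaves)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):{rng.uniform(0.01, 0.5):.4f}")
    return PhyloTree.from_newick(f"({nodes[0]},{nodes[1]});")


# ----------------------------------------------------------------------
def reported_topology_lrts() -> dict[str, float]:
    """P-values of the duplication-order contrasts from the reported
    log-likelihoods (treated as inputs)."""
    l1 = REPORTED_LOGL["PON1_first"]
    l2 = REPORTED_LOGL["PON2_first"]
    l3 = REPORTED_LOGL["PON3_first"]
    return {
        "p_pon2_vs_pon1": lrt_pvalue(l2, l1, 1).p_value,
        "p_pon3_vs_pon1": lrt_pvalue(l3, l1, 1).p_value,
        "p_pon2_vs_pon3": lrt_pvalue(l2, l3, 1).p_value,
    }


def pruning_oracle_max_deviation(n_trees: int = 100, seed: int = 0) -> float:
    """Max |pruning - enumeration| over random small trees/alignments."""
    rng = child_rng(seed, "pruning_oracle")
    worst = 0.0
    chars = list(AMINO_ACIDS) + ["-"]
    p = [0.9 / 20] * 20 + [0.1]
    for i in range(n_trees):
        tree = _random_small_tree(rng, int(rng.integers(2, 6)))
        n_sites = int(rng.integers(1, 11))
        rows = ["".join(rng.choice(chars, n_sites, p=p)) for _ in tree.leaf_names]
        aln = Alignment(list(tree.leaf_names), rows)
        model = (
            AAModel("JTT", gamma_shape=0.8, n_rate_categories=2)
            if i % 3 == 0
            else AAModel("Poisson")
        )
        exact = enumeration_log_likelihood(aln, tree, model)
        fast = tree_log_likelihood(aln, tree, model).log_likelihood
        worst = max(worst, abs(fast - exact))
    return worst


def jc_branch_length_max_error(n_pairs: int = 20, seed: int = 0) -> float:
    """Max |optimized - analytic| two-taxon Poisson distance."""
    rng = child_rng(seed, "jc_mle")
    worst = 0.0
    for _ in range(n_pairs):
        n = int(rng.integers(30, 500))
        d = int(rng.integers(1, int(n * 0.75)))
        aln = Alignment(["x", "y"], ["A" * n, "R" * d + "A" * (n - d)])
        tree = PhyloTree.from_newick("(x:0.1,y:0.1);")
        out_tree, _ = optimize_branch_lengths(aln, tree, AAModel("Poisson"))
        est = float(out_tree.lengths[:2].sum())
        analytic = -(19 / 20) * math.log(1 - (20 / 19) * (d / n))
        worst = max(worst, abs(est - analytic))
    return worst


# ----------------------------------------------------------------------
def m0_omega_recovery(
    omegas: tuple[float, ...] = (0.2, 1.0, 3.0),
    n_replicates: int = 20,
    n_codons: int = 2_000,
    kappa: float = 4.0,
    seed: int = 0,
    rel_tol: float = 0.2,
) -> dict:
    """Fraction of M0 fits recovering the generating omega within
    ``rel_tol`` relative error (six-taxon tree)."""
    tree = PhyloTree.from_newick(SIX_TAXON_NEWICK)
    ok = 0
    estimates = []
    for rep in range(n_replicates):
        omega = omegas[rep % len(omegas)]
        truth = SiteClassModel("M0", kappa=kappa, omega=omega)
        sseed = child_seed(seed, f"m0_recovery_{rep}")
        aln, _ = simulate_alignment(SimulationSpec(tree, truth, n_codons, sseed))
        fit = fit_site_model(aln, tree, "M0", tol=1e-3, xatol=3e-3, max_rounds=3)
        est = fit.model.omega
        estimates.append((omega, est))
        if abs(est - omega) / omega <= rel_tol:
            ok += 1
    return {
        "n_within_tolerance": ok,
        "n_replicates": n_replicates,
        "fraction": ok / n_replicates,
        "estimates": estimates,
    }


def _branch_site_replicate(aln, tree) -> float:
    """One LRT p-value: M0 branch lengths shared by null and alternative."""
    m0 = fit_site_model(aln, tree, "M0", tol=1e-2, xatol=1e-2, max_rounds=2)
    null = fit_branch_site(
        aln, tree, null=True, fixed_branch_lengths=m0.tree.lengths,
        tol=1e-2, xatol=1e-2, max_rounds=5,
    )
    alt = fit_branch_site(
        aln, tree, null=False, fixed_branch_lengths=m0.tree.lengths,
        tol=1e-2, xatol=1e-2, max_rounds=5, init_model=null.model,
    )
    return branch_site_lrt(null, alt).p_value


def branch_site_power(
    n_replicates: int = 50,
    n_codons: int = 400,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Rejection rate under planted selection (p2 = 0.12, omega2 = 5)."""
    tree = PhyloTree.from_newick(MARKED_SIX_TAXON_NEWICK)
    truth = SiteClassModel(
        "BranchSiteA", kappa=2.0, p0=0.66, p1=0.22, omega0=0.2, omega2=5.0
    )
    rejections = 0
    for rep in range(n_replicates):
        sseed = child_seed(seed, f"bs_power_{rep}")
        aln, _ = simulate_alignment(SimulationSpec(tree, truth, n_codons, sseed))
        if _branch_site_replicate(aln, tree) < alpha:
            rejections += 1
    return {
        "n_rejections": rejections,
        "n_replicates": n_replicates,
        "fraction": rejections / n_replicates,
    }


def branch_site_type1_error(
    n_replicates: int = 200,
    n_codons: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Rejection rate when the generating model is the branch-site null."""
    tree = PhyloTree.from_newick(MARKED_SIX_TAXON_NEWICK)
    truth = SiteClassModel(
        "BranchSiteA_null", kappa=2.0, p0=0.66, p1=0.22, omega0=0.2
    )
    rejections = 0
    for rep in range(n_replicates):
        sseed = child_seed(seed, f"bs_null_{rep}")
        aln, _ = simulate_alignment(SimulationSpec(tree, truth, n_codons, sseed))
        if _branch_site_replicate(aln, tree) < alpha:
            rejections += 1
    return {
        "n_rejections": rejections,
        "n_replicates": n_replicates,
        "fraction": rejections / n_replicates,
    }


# ----------------------------------------------------------------------
def family_scan_recovery(n_tables: int = 200, seed: int = 0) -> dict:
    """Exact recovery of planted arrays, absences and retro flags, plus
    agreement of the e-value filter with a brute-force comprehension."""
    rng = child_rng(seed, "family_scan_recovery")
    tables_ok = 0
    filters_ok = 0
    for t in range(n_tables):
        species = ["s1", "s2", "s3", "s4"]
        arrays = []
        for ai in range(int(rng.integers(1, 4))):
            n_genes = int(rng.integers(1, 5))
            retro = (
                tuple(int(x) for x in rng.choice(n_genes, 1))
                if n_genes >= 2 and rng.random() < 0.4
                else ()
            )
            arrays.append(
                PlantedArray(
                    species=species[int(rng.integers(3))],
                    scaffold=f"sc{int(rng.integers(2))}",
                    n_genes=n_genes,
                    gap_bp=int(rng.integers(0, 95_000)),
                    retro_indices=retro,
                )
            )
        straddle = bool(t % 2)
        spec = LocusTableSpec(
            species=species,
            arrays=arrays,
            absences={"fam1": {"s4"}},
            straddle_evalues=straddle,
            seed=int(rng.integers(2**31)),
        )
        loci, text, truth = simulate_locus_table(spec)
        hits = parse_domtblout(text)
        kept = filter_hits(hits)

        # filter equals the brute-force set comprehension
        brute = [
            h for h in hits
            if h.full_seq_evalue <= 1e-6 and h.best_domain_evalue <= 1e-6
        ]
        expected_pass = {g["gene_id"] for g in truth["genes"] if g["evalue_pass"]}
        if kept == brute and {h.gene_id for h in kept} == expected_pass:
            filters_ok += 1

        # planted structure recovered exactly (on the full locus table)
        ok = True
        if any(g["species"] == "s4" for g in truth["genes"]):
            ok = False
        by_species: dict[str, list[GeneLocus]] = {}
        for row in loci.to_dict("records"):
            by_species.setdefault(row["species"], []).append(GeneLocus(**row))
        planted = {}
        for g in truth["genes"]:
            planted.setdefault((g["species"], g["array_index"]), set()).add(
                g["gene_id"]
            )
        for sp, sp_loci in by_species.items():
            names = assign_names(sp_loci)
            recovered: dict[str, set] = {}
            for gid, name in names.items():
                recovered.setdefault(name.rstrip("0123456789"), set()).add(gid)
            want = {
                frozenset(v) for (s, _), v in planted.items() if s == sp
            }
            if {frozenset(v) for v in recovered.values()} != want:
                ok = False
        for (sp, ai), members in planted.items():
            if len(members) < 2:
                continue
            sub = [l for l in by_species[sp] if l.gene_id in members]
            expected_retro = sorted(
                g["gene_id"] for g in truth["genes"]
                if g["array_index"] == ai and g["retro"]
            )
            if sorted(flag_retroduplication(sub)) != expected_retro:
                ok = False
        tables_ok += ok
    return {
        "n_tables": n_tables,
        "tables_recovered": tables_ok,
        "filters_exact": filters_ok,
        "fraction_recovered": tables_ok / n_tables,
        "fraction_filters_exact": filters_ok / n_tables,
    }


# ----------------------------------------------------------------------
def planted_cluster_pvalue(
    n_residues: int = 150,
    cluster: tuple[int, float] = (8, 6.0),
    n_permutations: int = 10_000,
    seed: int = 0,
) -> float:
    """Permutation p-value for a planted cluster in a pseudo-structure."""
    pdb, truth = simulate_structure(
        StructureSpec(n_residues=n_residues, cluster=cluster,
                      seed=child_seed(seed, "planted_cluster_structure"))
    )
    residues = parse_structure(pdb)
    res = clustering_permutation_test(
        truth, residues, restrict_to_exposed=False,
        n_permutations=n_permutations,
        seed=child_seed(seed, "planted_cluster_perm"),
    )
    return res.p_value


def cluster_null_uniformity(
    n_replicates: int = 200,
    n_residues: int = 150,
    n_selected: int = 8,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> dict:
    """KS test of permutation p-values for randomly selected residue sets."""
    pdb, _ = simulate_structure(
        StructureSpec(n_residues=n_residues,
                      seed=child_seed(seed, "null_structure"))
    )
    residues = parse_structure(pdb)
    pool = [r.resnum for r in residues]
    rng = child_rng(seed, "null_selection")
    pvals = []
    for rep in range(n_replicates):
        selected = set(rng.choice(pool, size=n_selected, replace=False).tolist())
        res = clustering_permutation_test(
            selected, residues, restrict_to_exposed=False,
            n_permutations=n_permutations,
            seed=child_seed(seed, f"null_perm_{rep}"),
        )
        pvals.append(res.p_value)
    stat, ks_p = kstest(pvals, "uniform")
    return {"ks_statistic": float(stat), "ks_p_value": float(ks_p),
            "n_replicates": n_replicates, "p_values": pvals}


def single_atom_asa_relative_error() -> float:
    """Relative error of sampled vs analytic area for an isolated atom."""
    text = (
        "ATOM      1  CA  ALA A   1       0.000   0.000   0.000"
        "  1.00  0.00           C\nEND\n"
    )
    res = compute_asa(parse_structure(text))
    expected = 4 * math.pi * (1.70 + 1.4) ** 2
    return abs(res[0].asa - expected) / expected
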