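"""End-to-end pipeline orchestration from a single declarative config.

A config (TOML) holds one block per stage — simulate, scan, topotest,
seltest, structcluster — plus a global seed, output directory and log
level.  Stages run in dependency order, every stochastic operation logs
the seed it consumed, each stage's JSON-serializable result is embedded
in one consolidated report, and a rerun with the same config reproduces
deterministic stages byte for byte.  CLI flags override config values.
"""

from __future__ import annotations

import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import child_seed
from .family_scan import (
    GeneLocus,
    assign_names,
    filter_hits,
    flag_retroduplication,
    infer_loss,
    parse_domtblout,
)
from .phylo_engine.alignment import read_fasta, write_fasta
from .phylo_engine.models import AAModel, CodonModel
from .phylo_engine.trees import PhyloTree
from .selection_tests import (
    MULTINUC_CAVEAT,
    SiteClassModel,
    branch_site_lrt,
    fit_branch_site,
    fit_site_model,
    identify_selected_sites,
    site_model_lrt,
)
from .structure_cluster import (
    classify_exposed,
    clustering_permutation_test,
    compute_asa,
    parse_structure,
)
from .synthetic_data.loci import LocusTableSpec, PlantedArray, simulate_locus_table
from .synthetic_data.sequences import SimulationSpec, simulate_alignment
from .synthetic_data.structures import StructureSpec, simulate_structure
from .topology_tests import compare_fixed_topologies

logger = logging.getLogger("ponevo.workflow")

__all__ = ["PipelineConfig", "run_pipeline", "render_report", "parse_model_string"]

_STAGE_ORDER = ("simulate", "scan", "topotest", "seltest", "structcluster")
_GLOBAL_KEYS = {"seed", "out_dir", "log_level"}
_STAGE_KEYS = {
    "simulate": {"alignment", "loci", "structure"},
    "scan": {"hits", "loci", "groups", "window", "evalue"},
    "topotest": {"aln", "trees", "model", "df"},
    "seltest": {"aln", "tree", "test", "fix_branch_lengths"},
    "structcluster": {
        "pdb", "sites", "sites_file", "nperm", "restrict_to_exposed", "statistic",
    },
}
_PATH_KEYS = {
    ("scan", "hits"), ("scan", "loci"), ("scan", "groups"),
    ("topotest", "aln"), ("seltest", "aln"), ("seltest", "tree"),
    ("structcluster", "pdb"), ("structcluster", "sites_file"),
}


def parse_model_string(text: str) -> tuple[AAModel, set[str]]:
    """'JTT+G+I' -> (AAModel, free parameter names to optimize)."""
    parts = text.split("+")
    name = parts[0]
    free: set[str] = set()
    kwargs: dict = {}
    for p in parts[1:]:
        if p == "G":
            kwargs["gamma_shape"] = 1.0
            free.add("gamma_shape")
        elif p == "I":
            kwargs["p_invariant"] = 0.1
            free.add("p_invariant")
        else:
            raise ValueError(f"unknown model suffix {p!r} in {text!r}")
    return AAModel(name, **kwargs), free


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: Path = Path("ponevo_out")
    log_level: str = "INFO"
    stages: dict = field(default_factory=dict)

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        return cls.from_dict(raw, base_dir=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base_dir: Path = Path(".")) -> "PipelineConfig":
        unknown = set(raw) - _GLOBAL_KEYS - set(_STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        stages = {}
        for stage in _STAGE_ORDER:
            if stage not in raw:
                continue
            block = dict(raw[stage])
            bad = set(block) - _STAGE_KEYS[stage]
            if bad:
                raise ValueError(f"unknown keys in [{stage}]: {sorted(bad)}")
            for key in list(block):
                if (stage, key) in _PATH_KEYS:
                    block[key] = (base_dir / block[key]).resolve()
            stages[stage] = block
        cfg = cls(
            seed=int(raw.get("seed", 0)),
            out_dir=(base_dir / raw.get("out_dir", "ponevo_out")).resolve(),
            log_level=str(raw.get("log_level", "INFO")),
            stages=stages,
        )
        cfg.validate_paths()
        return cfg

    def validate_paths(self) -> None:
        """Every input path must exist before any stage runs."""
        missing = []
        for stage, block in self.stages.items():
            for key, value in block.items():
                if (stage, key) in _PATH_KEYS and not Path(value).exists():
                    missing.append(f"[{stage}] {key} = {value}")
        if stage_trees := self.stages.get("topotest", {}).get("trees"):
            for t in stage_trees:
                if not Path(t).exists():
                    missing.append(f"[topotest] tree {t}")
        if missing:
            raise FileNotFoundError(
                "missing input path(s): " + "; ".join(missing)
            )


# ----------------------------------------------------------------------
def _stage_simulate(block: dict, seed: int, out: Path) -> dict:
    out.mkdir(parents=True, exist_ok=True)
    result: dict = {}
    if "alignment" in block:
        sub = dict(block["alignment"])
        tree = PhyloTree.from_newick(sub["tree"])
        model = _model_from_dict(sub["model"])
        sseed = child_seed(seed, "simulate.alignment")
        logger.info("simulate.alignment seed=%d", sseed)
        aln, truth = simulate_alignment(
            SimulationSpec(tree, model, int(sub["n_sites"]), sseed)
        )
        write_fasta(aln, out / "alignment.fasta")
        (out / "alignment_truth.json").write_text(json.dumps(truth, indent=1))
        result["alignment"] = {
            "fasta": str(out / "alignment.fasta"),
            "truth": str(out / "alignment_truth.json"),
            "n_sites": aln.n_sites,
            "seed": sseed,
        }
    if "loci" in block:
        sub = dict(block["loci"])
        arrays = [PlantedArray(**a) for a in sub["arrays"]]
        sseed = child_seed(seed, "simulate.loci")
        logger.info("simulate.loci seed=%d", sseed)
        spec = LocusTableSpec(
            species=list(sub["species"]),
            arrays=arrays,
            absences={k: set(v) for k, v in sub.get("absences", {}).items()},
            straddle_evalues=bool(sub.get("straddle_evalues", False)),
            seed=sseed,
        )
        loci, hits_text, truth = simulate_locus_table(spec)
        loci.to_csv(out / "loci.tsv", sep="\t", index=False)
        (out / "hits.domtblout").write_text(hits_text)
        (out / "loci_truth.json").write_text(json.dumps(truth, indent=1))
        result["loci"] = {
            "table": str(out / "loci.tsv"),
            "hits": str(out / "hits.domtblout"),
            "truth": str(out / "loci_truth.json"),
            "seed": sseed,
        }
    if "structure" in block:
        sub = dict(block["structure"])
        cluster = None
        if "cluster_n" in sub:
            cluster = (int(sub["cluster_n"]), float(sub["cluster_radius"]))
        sseed = child_seed(seed, "simulate.structure")
        logger.info("simulate.structure seed=%d", sseed)
        pdb_text, truth = simulate_structure(
            StructureSpec(int(sub["n_residues"]), cluster, sseed)
        )
        (out / "structure.pdb").write_text(pdb_text)
        (out / "structure_truth.json").write_text(json.dumps(sorted(truth)))
        result["structure"] = {
            "pdb": str(out / "structure.pdb"),
            "truth": str(out / "structure_truth.json"),
            "seed": sseed,
        }
    return result


def _model_from_dict(d: dict):
    d = dict(d)
    kind = d.pop("type")
    if kind == "AAModel":
        return AAModel(**d)
    if kind == "CodonModel":
        return CodonModel(**d)
    if kind == "SiteClassModel":
        return SiteClassModel(**d)
    raise ValueError(f"unknown model type {kind!r}")


def _stage_scan(block: dict, out: Path) -> dict:
    out.mkdir(parents=True, exist_ok=True)
    hits = parse_domtblout(Path(block["hits"]).read_text())
    kept = filter_hits(
        hits,
        float(block.get("evalue", 1e-6)),
        float(block.get("evalue", 1e-6)),
    )
    loci = pd.read_csv(block["loci"], sep="\t")
    window = int(block.get("window", 100_000))
    kept_ids = {(h.species, h.gene_id) for h in kept}
    names_rows = []
    for species, sp_block in loci.groupby("species"):
        sp_loci = [
            GeneLocus(**row)
            for row in sp_block.to_dict("records")
            if (row["species"], row["gene_id"]) in kept_ids
        ]
        names = assign_names(sp_loci, window=window)
        for loc in sp_loci:
            names_rows.append(
                dict(
                    species=species,
                    gene_id=loc.gene_id,
                    name=names[loc.gene_id],
                    scaffold=loc.scaffold,
                    start=loc.start,
                    end=loc.end,
                )
            )
    assignment = pd.DataFrame(names_rows)
    assignment.to_csv(out / "assignments.tsv", sep="\t", index=False)
    result = {
        "n_hits": len(hits),
        "n_retained": len(kept),
        "assignments": str(out / "assignments.tsv"),
    }
    if "groups" in block:
        groups = pd.read_csv(block["groups"], sep="\t")
        group_of = dict(zip(groups["species"], groups["group"]))
        species_list = sorted(set(loci["species"]) | set(group_of))
        present_species = {h.species for h in kept}
        presence = pd.DataFrame(
            {"family": [sp in present_species for sp in species_list]},
            index=species_list,
        )
        claims = infer_loss(presence, group_of)
        pd.DataFrame(claims, columns=["group", "family"]).to_csv(
            out / "loss_claims.tsv", sep="\t", index=False
        )
        result["loss_claims"] = [list(c) for c in claims]
    # retroduplication flags per (species, scaffold-family proxy): use the
    # full locus table within each species
    retro = []
    for species, sp_block in loci.groupby("species"):
        sp_loci = [GeneLocus(**row) for row in sp_block.to_dict("records")]
        if len(sp_loci) >= 2:
            retro.extend(flag_retroduplication(sp_loci))
    result["retroduplication_flags"] = sorted(retro)
    return result


def _stage_topotest(block: dict, seed: int, out: Path) -> dict:
    out.mkdir(parents=True, exist_ok=True)
    aln = read_fasta(block["aln"], flavor="protein")
    model, free = parse_model_string(str(block.get("model", "JTT+G")))
    trees = []
    for i, tpath in enumerate(block["trees"]):
        trees.append(
            (Path(tpath).stem or f"tree{i}", PhyloTree.from_newick(Path(tpath).read_text()))
        )
    comp = compare_fixed_topologies(
        aln, trees, model, free, df=int(block.get("df", 1))
    )
    report = {
        "ranking": comp.ranking,
        "best": comp.best,
        "log_likelihoods": {
            lab: fit.log_likelihood for lab, fit in comp.fits.items()
        },
        "pairwise": {
            f"{a} vs {b}": {
                "statistic": r.statistic, "df": r.df, "p_value": r.p_value,
            }
            for (a, b), r in comp.pairwise.items()
        },
    }
    (out / "topotest.json").write_text(json.dumps(report, indent=1))
    return report


def _stage_seltest(block: dict, seed: int, out: Path) -> dict:
    out.mkdir(parents=True, exist_ok=True)
    aln = read_fasta(block["aln"], flavor="codon")
    tree = PhyloTree.from_newick(Path(block["tree"]).read_text())
    test = str(block.get("test", "branch-site"))
    fixed_bl = None
    if bool(block.get("fix_branch_lengths", True)):
        m0 = fit_site_model(aln, tree, "M0")
        fixed_bl = m0.tree.lengths
    if test == "sites":
        report: dict = {"test": "sites"}
        fits = {
            fam: fit_site_model(aln, tree, fam, fixed_branch_lengths=fixed_bl)
            for fam in ("M1a", "M2a", "M7", "M8")
        }
        for null_fam, alt_fam in (("M1a", "M2a"), ("M7", "M8")):
            rec = site_model_lrt(fits[null_fam], fits[alt_fam])
            report[f"{null_fam}_vs_{alt_fam}"] = {
                "null_logL": rec.null_log_likelihood,
                "alt_logL": rec.alt_log_likelihood,
                "statistic": rec.statistic,
                "df": rec.df,
                "p_value": rec.p_value,
            }
        sites = identify_selected_sites(fits["M8"], 0.5, "BEB")
        report["selected_sites_M8_BEB"] = sites
    elif test == "branch-site":
        null = fit_branch_site(aln, tree, null=True, fixed_branch_lengths=fixed_bl)
        alt = fit_branch_site(
            aln, tree, null=False, fixed_branch_lengths=fixed_bl,
            init_model=null.model,
        )
        rec = branch_site_lrt(null, alt)
        sites = identify_selected_sites(alt, 0.5, "BEB")
        report = {
            "test": "branch-site",
            "null_logL": rec.null_log_likelihood,
            "alt_logL": rec.alt_log_likelihood,
            "statistic": rec.statistic,
            "df": rec.df,
            "p_value": rec.p_value,
            "proportion_under_selection": alt.proportion_under_selection,
            "selected_sites_BEB": sites,
            "caveat": MULTINUC_CAVEAT,
        }
    else:
        raise ValueError(f"unknown seltest {test!r}")
    (out / "seltest.json").write_text(json.dumps(report, indent=1))
    return report


def _stage_structcluster(block: dict, seed: int, out: Path) -> dict:
    out.mkdir(parents=True, exist_ok=True)
    residues = parse_structure(Path(block["pdb"]).read_text())
    compute_asa(residues)
    classify_exposed(residues)
    if "sites" in block:
        selected = {int(s) for s in block["sites"]}
    else:
        sites_df = pd.read_csv(block["sites_file"], sep="\t")
        selected = {int(s) for s in sites_df["resnum"]}
    sseed = child_seed(seed, "structcluster")
    logger.info("structcluster seed=%d", sseed)
    res = clustering_permutation_test(
        selected,
        residues,
        restrict_to_exposed=bool(block.get("restrict_to_exposed", True)),
        n_permutations=int(block.get("nperm", 1_000_000)),
        seed=sseed,
        statistic=str(block.get("statistic", "mean_pairwise")),
    )
    per_res = pd.DataFrame(
        [
            dict(
                resnum=r.resnum, resname=r.resname,
                asa=round(r.asa, 2), exposed=bool(r.exposed),
                selected=r.resnum in selected,
            )
            for r in residues
        ]
    )
    per_res.to_csv(out / "residues.tsv", sep="\t", index=False)
    report = {
        "observed": res.observed,
        "statistic": res.statistic,
        "n_permutations": res.n_permutations,
        "p_value": res.p_value,
        "pool_size": res.pool_size,
        "n_selected": res.n_selected,
        "seed": res.seed,
    }
    (out / "structcluster.json").write_text(json.dumps(report, indent=1))
    return report


def run_pipeline(config: PipelineConfig) -> dict:
    """Run configured stages in dependency order; return the consolidated
    report (also written to ``out_dir/report.json``)."""
    logging.basicConfig(
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}}
    for stage in _STAGE_ORDER:
        if stage not in config.stages:
            continue
        block = config.stages[stage]
        logger.info("stage %s starting", stage)
        try:
            if stage == "simulate":
                res = _stage_simulate(block, config.seed, out / "simulate")
            elif stage == "scan":
                res = _stage_scan(block, out / "scan")
            elif stage == "topotest":
                res = _stage_topotest(block, config.seed, out / "topotest")
            elif stage == "seltest":
                res = _stage_seltest(block, config.seed, out / "seltest")
            else:
                res = _stage_structcluster(block, config.seed, out / "structcluster")
        except Exception as exc:
            (out / "report.json").write_text(json.dumps(report, indent=1))
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        report["stages"][stage] = res
        logger.info("stage %s done", stage)
    (out / "report.json").write_text(json.dumps(report, indent=1))
    return report


# ----------------------------------------------------------------------
def render_report(report: dict) -> str:
    """Human-readable summary of a pipeline report."""
    lines = ["ponevo pipeline report", "=" * 22, f"seed: {report.get('seed')}", ""]
    stages = report.get("stages", {})
    if "scan" in stages:
        s = stages["scan"]
        lines += [
            "family scan",
            "-----------",
            f"hits parsed: {s.get('n_hits')}, retained after e-value filter: "
            f"{s.get('n_retained')}",
            f"loss claims: {s.get('loss_claims', [])}",
            f"retroduplication flags: {s.get('retroduplication_flags', [])}",
            "",
        ]
    if "topotest" in stages:
        t = stages["topotest"]
        lines += ["topology comparison", "-------------------"]
        lls = t.get("log_likelihoods", {})
        best = t.get("best")
        lines.append(f"{'model':<16}{'logL':>14}  best")
        for lab in t.get("ranking", sorted(lls)):
            mark = "  *" if lab == best else ""
            lines.append(f"{lab:<16}{lls[lab]:>14.2f}{mark}")
        for pair, rec in t.get("pairwise", {}).items():
            lines.append(
                f"  {pair}: 2dL = {rec['statistic']:.3f}, "
                f"p = {rec['p_value']:.4g} (df={rec['df']})"
            )
        lines.append("")
    if "seltest" in stages:
        s = stages["seltest"]
        lines += ["selection tests", "---------------"]
        if s.get("test") == "branch-site":
            lines.append(
                f"branch-site A vs null: 2dL = {s['statistic']:.3f}, "
                f"p = {s['p_value']:.4g}"
            )
            lines.append(
                "proportion under selection: "
                f"{100 * s['proportion_under_selection']:.1f}%"
            )
            lines.append(
                f"BEB sites (> 0.5): {[i for i, _ in s['selected_sites_BEB']]}"
            )
        else:
            for key in ("M1a_vs_M2a", "M7_vs_M8"):
                if key in s:
                    lines.append(
                        f"{key}: 2dL = {s[key]['statistic']:.3f}, "
                        f"p = {s[key]['p_value']:.4g}"
                    )
        lines.append("")
    if "structcluster" in stages:
        s = stages["structcluster"]
        lines += [
            "structural clustering",
            "---------------------",
            f"observed {s['statistic']}: {s['observed']:.2f} A",
            f"permutations: {s['n_permutations']}, p = {s['p_value']:.3g}",
            "",
        ]
    return "\n".join(lines)
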