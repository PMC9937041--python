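"""Gene-family identification and annotation rules.

Implements the scan stage of the pipeline: parsing per-domain hit tables
(the whitespace-separated domtblout dialect emitted by profile-HMM
search), e-value filtering, naming of tandem arrays from genomic
coordinates (same scaffold, gap at most 100 kb, single-linkage), BLAST
coverage/identity inclusion filtering with longest-isoform selection,
conservative per-group loss calls, retroduplication flagging from exon
counts, and duplication-node labeling on gene trees by the
species-overlap rule.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .phylo_engine.trees import PhyloTree

__all__ = [
    "DomainHit",
    "GeneLocus",
    "BlastHit",
    "parse_domtblout",
    "filter_hits",
    "assign_names",
    "infer_loss",
    "flag_retroduplication",
    "filter_blast_hits",
    "label_duplication_nodes",
]

EVALUE_THRESHOLD = 1e-6
TANDEM_WINDOW_BP = 100_000
MIN_QUERY_COVERAGE = 90.0
MIN_PERCENT_IDENTITY = 50.0


@dataclass(frozen=True)
class DomainHit:
    """Per-gene aggregate of profile-HMM domain matches."""

    species: str
    gene_id: str
    full_seq_evalue: float
    best_domain_evalue: float
    n_domains: int

    def __post_init__(self) -> None:
        if self.full_seq_evalue < 0 or self.best_domain_evalue < 0:
            raise ValueError("e-values must be non-negative")
        if self.n_domains < 1:
            raise ValueError("n_domains must be >= 1")


@dataclass(frozen=True)
class GeneLocus:
    species: str
    gene_id: str
    scaffold: str
    start: int
    end: int
    strand: str
    exon_count: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"locus {self.gene_id}: start > end")
        if self.exon_count < 1:
            raise ValueError("exon_count must be >= 1")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")


@dataclass(frozen=True)
class BlastHit:
    query_id: str
    subject_id: str
    percent_identity: float
    query_coverage: float
    alignment_length: int = 0
    evalue: float = 0.0
    bitscore: float = 0.0
    subject_length: int = 0  # for longest-isoform selection
    subject_locus: str | None = None  # isoforms share a locus id

    def __post_init__(self) -> None:
        if not (0 <= self.percent_identity <= 100):
            raise ValueError("percent_identity outside [0, 100]")
        if not (0 <= self.query_coverage <= 100):
            raise ValueError("query_coverage outside [0, 100]")


# ----------------------------------------------------------------------
def parse_domtblout(text: str, species: str = "") -> list[DomainHit]:
    """Parse domtblout-dialect text into per-gene :class:`DomainHit` records.

    Domain lines for the same gene are aggregated: ``best_domain_evalue``
    is the minimum per-domain independent e-value and ``n_domains``
    counts the lines.  Lines starting with '#' are comments.  A malformed
    line raises a parse error naming its line number.

    Standard column order is assumed: target name (0), full-sequence
    e-value (6), per-domain independent e-value (12).  The species is
    taken from ``species`` if given, else from a ``species|gene`` target
    name, else left empty.
    """
    per_gene: dict[tuple[str, str], dict] = {}
    order: list[tuple[str, str]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 13:
            raise ValueError(
                f"malformed domtblout line {lineno}: expected >= 13 columns, "
                f"got {len(fields)}"
            )
        target = fields[0]
        if species:
            sp = species
            gene = target
        elif "|" in target:
            sp, gene = target.split("|", 1)
        else:
            sp, gene = "", target
        try:
            full_e = float(fields[6])
            dom_e = float(fields[12])
        except ValueError as exc:
            raise ValueError(f"malformed domtblout line {lineno}: {exc}") from None
        key = (sp, gene)
        rec = per_gene.get(key)
        if rec is None:
            per_gene[key] = {"full": full_e, "best": dom_e, "n": 1}
            order.append(key)
        else:
            rec["best"] = min(rec["best"], dom_e)
            rec["n"] += 1
    return [
        DomainHit(
            species=sp,
            gene_id=gene,
            full_seq_evalue=per_gene[(sp, gene)]["full"],
            best_domain_evalue=per_gene[(sp, gene)]["best"],
            n_domains=per_gene[(sp, gene)]["n"],
        )
        for sp, gene in order
    ]


def filter_hits(
    hits: Iterable[DomainHit],
    full_thresh: float = EVALUE_THRESHOLD,
    dom_thresh: float = EVALUE_THRESHOLD,
) -> list[DomainHit]:
    """Keep hits passing BOTH e-value cutoffs (inclusive bounds).

    The number of domains is never considered: a gene qualifies on its
    full-sequence and best-domain e-values alone.
    """
    if full_thresh <= 0 or dom_thresh <= 0:
        raise ValueError("thresholds must be > 0")
    return [
        h
        for h in hits
        if h.full_seq_evalue <= full_thresh and h.best_domain_evalue <= dom_thresh
    ]


# ----------------------------------------------------------------------
def _letters() -> list[str]:
    """A, B, ..., Z, AA, AB, ... — enough letters for any scan."""
    single = list(string.ascii_uppercase)
    return single + [a + b for a in single for b in single]


def assign_names(
    loci: Sequence[GeneLocus], window: int = TANDEM_WINDOW_BP
) -> dict[str, str]:
    """Name loci of one species by the tandem-array convention.

    Loci are chained into arrays by single linkage: two loci link iff
    they share a scaffold and the gap between their nearest ends is at
    most ``window`` (overlapping loci have gap 0).  Arrays are ordered by
    (scaffold, leftmost start) and lettered A, B, ...; a singleton array
    keeps the bare letter while members of a multi-gene array are
    numbered 1..k by start coordinate.
    """
    if not loci:
        return {}
    species = {l.species for l in loci}
    if len(species) > 1:
        raise ValueError("assign_names expects loci from a single species")
    ids = [l.gene_id for l in loci]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate gene_id in loci")
    ordered = sorted(loci, key=lambda l: (l.scaffold, l.start, l.end, l.gene_id))
    arrays: list[list[GeneLocus]] = []
    for loc in ordered:
        cur = arrays[-1] if arrays else None
        if cur is not None and cur[-1].scaffold == loc.scaffold:
            # single-linkage on sorted loci reduces to chaining consecutive
            # gaps; gap = distance between nearest ends, 0 when overlapping
            right_end = max(l.end for l in cur)
            gap = max(0, loc.start - right_end - 1)
            if gap <= window:
                cur.append(loc)
                continue
        arrays.append([loc])
    letters = _letters()
    names: dict[str, str] = {}
    for ai, arr in enumerate(arrays):
        letter = letters[ai]
        if len(arr) == 1:
            names[arr[0].gene_id] = letter
        else:
            for k, loc in enumerate(sorted(arr, key=lambda l: (l.start, l.end)), 1):
                names[loc.gene_id] = f"{letter}{k}"
    return names


def infer_loss(
    presence: pd.DataFrame, groups: Mapping[str, str]
) -> list[tuple[str, str]]:
    """Conservative loss claims: (group, family) lost iff absent in every
    species of the group.

    ``presence`` is a boolean species x family table; ``groups`` maps
    every species to exactly one group.
    """
    missing = set(presence.index) - set(groups)
    if missing:
        raise ValueError(f"species without a group: {sorted(missing)}")
    claims: list[tuple[str, str]] = []
    group_of = pd.Series({sp: groups[sp] for sp in presence.index})
    for group, block in presence.groupby(group_of):
        if block.empty:
            raise ValueError(f"empty group {group!r}")
        for family in presence.columns:
            if not block[family].any():
                claims.append((str(group), str(family)))
    return sorted(claims)


def flag_retroduplication(loci: Sequence[GeneLocus]) -> list[str]:
    """Flag single-exon loci whose clade siblings retain introns.

    A locus is flagged iff its exon_count is 1 while the median
    exon_count of the other clade members is >= 2 — the intron-loss
    signature of a retrocopy.
    """
    if len(loci) < 2:
        raise ValueError("need >= 2 loci to assess retroduplication")
    flagged = []
    for i, loc in enumerate(loci):
        if loc.exon_count != 1:
            continue
        others = [l.exon_count for j, l in enumerate(loci) if j != i]
        if np.median(others) >= 2:
            flagged.append(loc.gene_id)
    return flagged


def filter_blast_hits(
    hits: Sequence[BlastHit],
    min_qcov: float = MIN_QUERY_COVERAGE,
    min_pid: float = MIN_PERCENT_IDENTITY,
) -> list[BlastHit]:
    """Coverage/identity filter with longest-isoform selection.

    Keeps hits with query_coverage >= min_qcov AND percent_identity >=
    min_pid (inclusive).  When several passing subjects are isoforms of
    one locus (same ``subject_locus``), only the longest subject sequence
    is retained; order is otherwise preserved.
    """
    if not (0 <= min_qcov <= 100 and 0 <= min_pid <= 100):
        raise ValueError("thresholds must lie in [0, 100]")
    passing = [
        h
        for h in hits
        if h.query_coverage >= min_qcov and h.percent_identity >= min_pid
    ]
    best_by_locus: dict[str, BlastHit] = {}
    for h in passing:
        if h.subject_locus is None:
            continue
        cur = best_by_locus.get(h.subject_locus)
        if cur is None or h.subject_length > cur.subject_length:
            best_by_locus[h.subject_locus] = h
    out = []
    for h in passing:
        if h.subject_locus is not None and best_by_locus[h.subject_locus] is not h:
            continue
        out.append(h)
    return out


# ----------------------------------------------------------------------
def label_duplication_nodes(
    gene_tree: PhyloTree, species_of: Mapping[str, str]
) -> dict[int, str]:
    """Label internal nodes duplication/speciation by species overlap.

    An internal node is a duplication iff the species sets of its child
    subtrees intersect.  Multifurcations are first resolved
    deterministically (left fold, zero-length branches).
    """
    missing = set(gene_tree.leaf_names) - set(species_of)
    if missing:
        raise ValueError(f"leaves without a species: {sorted(missing)}")
    tree = gene_tree.resolved_binary()
    species_sets: list[set[str]] = [set() for _ in range(tree.n_nodes)]
    labels: dict[int, str] = {}
    for i in range(tree.n_nodes):
        ch = tree.children[i]
        if not ch:
            species_sets[i] = {species_of[tree.labels[i]]}
            continue
        sets = [species_sets[c] for c in ch]
        overlap = False
        for a in range(len(sets)):
            for b in range(a + 1, len(sets)):
                if sets[a] & sets[b]:
                    overlap = True
        labels[i] = "duplication" if overlap else "speciation"
        species_sets[i] = set().union(*sets)
    return labels
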