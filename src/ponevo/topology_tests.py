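"""Constrained-topology comparison and substitution-model selection.

Candidate topologies (each encoding one hypothesis about which gene
duplicated first) are scored by maximizing the likelihood independently
per tree, then contrasted with chi-square likelihood-ratio tests with one
degree of freedom.  These topology contrasts are not nested in the usual
sense; applying the plain chi-square is the convention this module
reproduces, and the raw 2*delta-log-likelihood is always reported so a
different calibration can be applied downstream.  Model selection among
fitted substitution models uses AIC = 2k - 2logL.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import chi2

from .phylo_engine.alignment import Alignment
from .phylo_engine.likelihood import LikelihoodResult
from .phylo_engine.optimize import fit_model
from .phylo_engine.trees import PhyloTree

__all__ = [
    "LRTResult",
    "TopologyComparison",
    "lrt_pvalue",
    "compare_fixed_topologies",
    "aic_select",
]


@dataclass
class LRTResult:
    statistic: float
    df: int
    p_value: float


@dataclass
class TopologyComparison:
    labels: list[str]
    fits: dict  # label -> LikelihoodResult
    ranking: list[str]  # labels ordered best (highest logL) first
    pairwise: dict  # (label_better, label_worse) -> LRTResult

    @property
    def best(self) -> str:
        return self.ranking[0]


def lrt_pvalue(logL0: float, logL1: float, df: int) -> LRTResult:
    """Likelihood-ratio statistic 2(logL1 - logL0) against chi-square(df).

    The statistic is clamped at zero when the 'alternative' likelihood is
    the smaller one, in which case p = 1.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    stat = max(0.0, 2.0 * (logL1 - logL0))
    return LRTResult(statistic=stat, df=int(df), p_value=float(chi2.sf(stat, df)))


def compare_fixed_topologies(
    aln: Alignment,
    trees: list[tuple[str, PhyloTree]],
    model,
    free_params: set[str] | frozenset[str] = frozenset(),
    df: int = 1,
    **fit_kwargs,
) -> TopologyComparison:
    """Optimize each labeled candidate tree independently and test all pairs.

    Branch lengths and the requested free model parameters are
    re-optimized per topology.  Pairwise LRTs use ``df`` degrees of
    freedom (1 by convention for these contrasts) with the better tree as
    the alternative.
    """
    if len(trees) < 2:
        raise ValueError("need at least two candidate topologies")
    leaf_set = set(aln.names)
    for label, tree in trees:
        if set(tree.leaf_names) != leaf_set:
            raise ValueError(f"tree {label!r} does not span the alignment's taxa")
    fits: dict[str, LikelihoodResult] = {}
    for label, tree in trees:
        fits[label] = fit_model(aln, tree, model, free_params, **fit_kwargs)
    labels = [lab for lab, _ in trees]
    ranking = sorted(labels, key=lambda l: (-fits[l].log_likelihood, l))
    pairwise = {}
    for i, la in enumerate(labels):
        for lb in labels[i + 1 :]:
            better, worse = (
                (la, lb)
                if fits[la].log_likelihood >= fits[lb].log_likelihood
                else (lb, la)
            )
            pairwise[(better, worse)] = lrt_pvalue(
                fits[worse].log_likelihood, fits[better].log_likelihood, df
            )
    return TopologyComparison(labels=labels, fits=fits, ranking=ranking,
                              pairwise=pairwise)


def aic_select(fits: list[tuple[str, float, int]]) -> list[tuple[str, float]]:
    """Rank models by AIC = 2k - 2logL, ascending.

    ``fits`` holds (label, log_likelihood, n_free_params) triples.  Ties
    break toward fewer parameters, then label order.
    """
    if not fits:
        raise ValueError("need at least one fit")
    scored = [
        (label, 2.0 * k - 2.0 * logL, k) for label, logL, k in fits
    ]
    scored.sort(key=lambda t: (t[1], t[2], t[0]))
    return [(label, aic) for label, aic, _ in scored]
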