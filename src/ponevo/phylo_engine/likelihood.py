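"""Exact alignment log-likelihoods on fixed topologies (Felsenstein pruning).

The engine works on compressed site patterns, treats gaps and ambiguity
codes as missing data (all-ones partial likelihoods), mixes over discrete
rate categories / site classes in linear space per pattern, and rescales
partial likelihoods at every internal node so long trees do not
underflow.  Branch transition matrices come from the symmetric spectral
decomposition of the reversible rate matrix, computed once per parameter
set and shared across branches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import Alignment
from .models import AAModel, CodonModel, SpectralQ, build_rate_matrix
from .trees import PhyloTree

__all__ = ["LikelihoodResult", "tree_log_likelihood", "PatternData"]

_LOG_FLOOR = -1e300


@dataclass
class LikelihoodResult:
    """Log-likelihood plus per-site values and optimizer diagnostics."""

    log_likelihood: float
    per_site_log_likelihood: np.ndarray
    parameters: dict
    diagnostics: dict = field(default_factory=dict)
    tree: PhyloTree | None = None
    site_posteriors: np.ndarray | None = None  # (n_components, n_sites)


class PatternData:
    """Alignment compressed to site patterns, row-ordered to match a tree."""

    def __init__(self, aln: Alignment, tree: PhyloTree):
        tree_names = tree.leaf_names
        if set(tree_names) != set(aln.names):
            raise ValueError("tree leaves and alignment names differ")
        order = [aln.names.index(n) for n in tree_names]
        pats, weights, site_to_pat = aln.patterns()
        self.patterns = pats[order]  # (n_leaves, n_patterns), tree leaf order
        self.weights = weights
        self.site_to_pattern = site_to_pat
        self.n_states = aln.n_states
        self.n_sites = aln.n_sites
        self.leaf_order = tree_names


def _leaf_partial(Pt: np.ndarray, states: np.ndarray) -> np.ndarray:
    """(n_patterns, n_states) partial for a leaf given the transposed
    branch matrix: row ``Pt[s] = P[:, s]`` per observed state, ones where
    the state is missing."""
    npat, n_states = states.shape[0], Pt.shape[0]
    missing = states < 0
    if not missing.any():
        return Pt[states]
    out = np.empty((npat, n_states))
    out[missing] = 1.0
    obs = ~missing
    out[obs] = Pt[states[obs]]
    return out


def pruning_log_likelihood(
    tree: PhyloTree,
    data: PatternData,
    P_per_node: list[np.ndarray | None],
    pi: np.ndarray,
) -> np.ndarray:
    """Per-pattern log-likelihood for one set of branch matrices.

    ``P_per_node[i]`` is the transition matrix for the branch above node
    ``i`` (ignored for the root).  Partials are kept in (pattern, state)
    orientation and rescaled at every internal node.
    """
    npat = data.patterns.shape[1]
    partial: list[np.ndarray | None] = [None] * tree.n_nodes
    log_scale = np.zeros(npat)
    leaf_row = {idx: r for r, idx in enumerate(tree.leaf_indices)}
    for i in range(tree.n_nodes):
        ch = tree.children[i]
        if not ch:
            continue
        acc = None
        for c in ch:
            if tree.children[c]:
                contrib = partial[c] @ P_per_node[c].T
                partial[c] = None
            else:
                Pt = np.ascontiguousarray(P_per_node[c].T)
                contrib = _leaf_partial(Pt, data.patterns[leaf_row[c]])
            acc = contrib if acc is None else acc * contrib
        scale = acc.max(axis=1)
        nz = scale > 0
        acc[nz] /= scale[nz, None]
        with np.errstate(divide="ignore"):
            log_scale += np.where(nz, np.log(np.where(nz, scale, 1.0)), _LOG_FLOOR)
        partial[i] = acc
    site_lik = partial[tree.root] @ pi
    with np.errstate(divide="ignore"):
        return np.where(site_lik > 0, np.log(np.maximum(site_lik, 1e-320)), _LOG_FLOOR) + log_scale


def mixture_log_likelihood(
    tree: PhyloTree,
    data: PatternData,
    components: list[tuple[float, list[np.ndarray | None]]],
    pi: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Log-likelihood per pattern for a mixture of branch-matrix sets.

    ``components`` is a list of (weight, P_per_node).  Returns
    ``(per_pattern_loglik, per_component_log_joint)`` where the latter is
    the (n_components, n_patterns) array of log(weight * L_component),
    from which class posteriors follow by normalization.
    """
    logs = []
    for w, P in components:
        if w <= 0:
            logs.append(np.full(data.patterns.shape[1], _LOG_FLOOR))
            continue
        logs.append(np.log(w) + pruning_log_likelihood(tree, data, P, pi))
    logm = np.vstack(logs)
    top = logm.max(axis=0)
    safe_top = np.where(np.isfinite(top), top, 0.0)
    tot = safe_top + np.log(np.exp(logm - safe_top[None, :]).sum(axis=0))
    return np.where(np.isfinite(top), tot, _LOG_FLOOR), logm


def _identity_like(pi: np.ndarray) -> np.ndarray:
    return np.eye(pi.shape[0])


def tree_log_likelihood(
    aln: Alignment, tree: PhyloTree, model
) -> LikelihoodResult:
    """Exact pruning log-likelihood of ``aln`` on ``tree`` under ``model``.

    ``model`` is an :class:`AAModel` or :class:`CodonModel`; rate-mixture
    models (+G, +I) are averaged per site over their categories.
    """
    tree.validate()
    data = PatternData(aln, tree)
    if data.n_states != model.n_states:
        raise ValueError("alignment flavor does not match model state space")
    Q, pi = build_rate_matrix(model)
    spec = SpectralQ(Q, pi)
    rates, probs = model.rate_mixture()
    components = []
    for r, w in zip(rates, probs):
        if r == 0.0:
            P = [_identity_like(pi)] * tree.n_nodes
        else:
            P = [spec.transition(r * t) for t in tree.lengths]
        components.append((float(w), P))
    per_pattern, logm = mixture_log_likelihood(tree, data, components, pi)
    total = float(per_pattern @ data.weights)
    per_site = per_pattern[data.site_to_pattern]
    with np.errstate(invalid="ignore"):
        post = np.exp(logm - per_pattern[None, :])
    posteriors = post[:, data.site_to_pattern]
    params = {"model": type(model).__name__}
    if isinstance(model, AAModel):
        params.update(
            name=model.name,
            gamma_shape=model.gamma_shape,
            p_invariant=model.p_invariant,
        )
    else:
        params.update(kappa=model.kappa, omega=model.omega)
    return LikelihoodResult(
        log_likelihood=total,
        per_site_log_likelihood=per_site,
        parameters=params,
        diagnostics={"n_patterns": int(data.patterns.shape[1])},
        tree=tree,
        site_posteriors=posteriors,
    )
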