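"""Alignment simulation under the engine's own substitution models.

The root state is drawn from the model's stationary frequencies and each
branch applies the matrix exponential of the scaled rate matrix, so the
simulator samples from exactly the process the likelihood engine scores.
Mixture models (discrete-Gamma rates, site classes, branch-site classes)
first assign each site a latent component, which is returned in a truth
table so downstream tests can check recovery against the planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .._rng import child_rng
from ..phylo_engine.alignment import AMINO_ACIDS, SENSE_CODONS, Alignment
from ..phylo_engine.models import (
    AAModel,
    CodonModel,
    SpectralQ,
    build_rate_matrix,
    codon_rate_matrix,
    mean_rate,
)
from ..phylo_engine.trees import PhyloTree
from ..selection_tests import SiteClassModel

__all__ = ["SimulationSpec", "simulate_alignment"]


@dataclass
class SimulationSpec:
    """Everything that determines a simulated alignment, seed included."""

    tree: PhyloTree
    model: object  # AAModel | CodonModel | SiteClassModel
    n_sites: int
    seed: int

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.tree.n_leaves < 2:
            raise ValueError("tree must have at least 2 leaves")
        self.tree.validate()


def _components(model, tree: PhyloTree):
    """(weights, [(bg_spectral, fg_spectral)], pi, labels) for the mixture."""
    if isinstance(model, (AAModel, CodonModel)):
        Q, pi = build_rate_matrix(model)
        spec = SpectralQ(Q, pi)
        rates, probs = model.rate_mixture()
        comps = []
        for r in rates:
            if r == 0.0:
                comps.append((None, None))  # identity: no change
            else:
                rq = SpectralQ(Q * r, pi)
                comps.append((rq, rq))
        labels = [f"rate={r:.6g}" for r in rates]
        return probs, comps, pi, labels
    if isinstance(model, SiteClassModel):
        pi = model.frequencies()
        props = model.class_proportions()
        bg, fg = model.class_omegas()
        mu = sum(
            w * mean_rate(codon_rate_matrix(model.kappa, om, pi, scale=False), pi)
            for w, om in zip(props, bg)
        )
        cache: dict[float, SpectralQ] = {}

        def spectral(om: float) -> SpectralQ:
            if om not in cache:
                cache[om] = SpectralQ(
                    codon_rate_matrix(model.kappa, om, pi, scale=False) / mu, pi
                )
            return cache[om]

        comps = [(spectral(b), spectral(f)) for b, f in zip(bg, fg)]
        labels = [f"class={c}" for c in range(len(props))]
        return props, comps, pi, labels
    raise TypeError(f"cannot simulate under {type(model).__name__}")


def _sample_markov(
    P: np.ndarray, parent_states: np.ndarray, u: np.ndarray
) -> np.ndarray:
    """Vectorized categorical draw of child states given parent states."""
    cdf = np.cumsum(P, axis=1)
    rows = cdf[parent_states]
    return (rows > u[:, None]).argmax(axis=1)


def simulate_alignment(spec: SimulationSpec) -> tuple[Alignment, dict]:
    """Simulate one alignment; returns (alignment, truth_table).

    The truth table records each site's latent mixture component
    (``site_component``) plus the component labels, and for codon
    mixtures the per-class omega values.  Identical specs (seed included)
    yield byte-identical output.
    """
    tree, model = spec.tree, spec.model
    rng = child_rng(spec.seed, "simulate_alignment")
    probs, comps, pi, labels = _components(model, tree)
    n_sites = spec.n_sites
    site_comp = rng.choice(len(probs), size=n_sites, p=np.asarray(probs) / np.sum(probs))

    states = np.empty((tree.n_nodes, n_sites), dtype=np.int64)
    states[tree.root] = rng.choice(len(pi), size=n_sites, p=pi / pi.sum())
    # walk the tree root-to-tips (reverse postorder)
    for i in range(tree.n_nodes - 2, -1, -1):
        par = tree.parent[i]
        u = rng.random(n_sites)
        child = np.empty(n_sites, dtype=np.int64)
        fg = bool(tree.foreground[i])
        for c in range(len(probs)):
            mask = site_comp == c
            if not mask.any():
                continue
            bg_spec, fg_spec = comps[c]
            sp = fg_spec if fg else bg_spec
            if sp is None:  # invariant class
                child[mask] = states[par][mask]
            else:
                P = sp.transition(tree.lengths[i])
                child[mask] = _sample_markov(P, states[par][mask], u[mask])
        states[i] = child

    flavor = "codon" if len(pi) == 61 else "protein"
    alphabet = SENSE_CODONS if flavor == "codon" else AMINO_ACIDS
    names, rows = [], []
    for idx in tree.leaf_indices:
        names.append(tree.labels[idx])
        rows.append("".join(alphabet[s] for s in states[idx]))
    aln = Alignment(names, rows, flavor=flavor)

    truth: dict = {
        "site_component": site_comp.tolist(),
        "component_labels": labels,
        "component_probs": np.asarray(probs, dtype=float).tolist(),
    }
    if isinstance(model, SiteClassModel):
        bg, fg = model.class_omegas()
        truth["background_omega"] = bg.tolist()
        truth["foreground_omega"] = fg.tolist()
        truth["selection_classes"] = model.selection_class_indices
        truth["selected_sites"] = [
            int(i)
            for i in range(n_sites)
            if site_comp[i] in model.selection_class_indices
        ]
    return aln, truth
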