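"""Branch-length and model-parameter optimization.

Branch lengths are optimized one at a time by bounded scalar search on a
log-length scale, cycled over the tree until a full sweep improves the
log-likelihood by less than a tolerance; model parameters (gamma shape,
invariant proportion, kappa, omega) alternate with branch sweeps until
joint convergence.  Everything is deterministic: fixed starting values,
no randomness.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
from scipy.optimize import minimize_scalar

from .alignment import Alignment
from .likelihood import (
    LikelihoodResult,
    PatternData,
    mixture_log_likelihood,
)
from .models import AAModel, SpectralQ, build_rate_matrix
from .trees import PhyloTree

__all__ = ["optimize_branch_lengths", "fit_model"]

BRANCH_BOUNDS = (1e-8, 50.0)
DEFAULT_SWEEP_TOL = 1e-6


def bounded_min(fun, lo: float, hi: float, xatol: float = 1e-8):
    """Bounded scalar minimization; returns (x, f(x))."""
    res = minimize_scalar(
        fun, bounds=(lo, hi), method="bounded", options={"xatol": xatol}
    )
    return float(res.x), float(res.fun)


class _Evaluator:
    """Caches pattern data and spectral decompositions across objective calls."""

    def __init__(self, aln: Alignment, tree: PhyloTree, model):
        self.data = PatternData(aln, tree)
        if self.data.n_states != model.n_states:
            raise ValueError("alignment flavor does not match model state space")
        self.tree = tree.copy()
        self._cache_key = None
        self._spec = None
        self._mixture = None
        self.model = model

    def _prepare(self, model) -> None:
        key = self._model_key(model)
        if key == self._cache_key:
            return
        Q, pi = build_rate_matrix(model)
        self._spec = SpectralQ(Q, pi)
        self._mixture = model.rate_mixture()
        self._pi = pi
        self._cache_key = key

    @staticmethod
    def _model_key(model):
        if isinstance(model, AAModel):
            return (model.name, model.gamma_shape, model.n_rate_categories,
                    model.p_invariant)
        return (model.kappa, model.omega)

    def loglik(self, lengths: np.ndarray, model) -> float:
        self._prepare(model)
        rates, probs = self._mixture
        components = []
        eye = np.eye(self.data.n_states)
        for r, w in zip(rates, probs):
            if r == 0.0:
                P = [eye] * self.tree.n_nodes
            else:
                P = [self._spec.transition(r * t) for t in lengths]
            components.append((float(w), P))
        per_pattern, _ = mixture_log_likelihood(
            self.tree, self.data, components, self._pi
        )
        return float(per_pattern @ self.data.weights)


def _branch_sweeps(
    ev: _Evaluator,
    lengths: np.ndarray,
    model,
    *,
    sweep_tol: float,
    max_sweeps: int,
    xatol: float = 1e-8,
    window: float | None = None,
) -> tuple[np.ndarray, float, int, bool]:
    """Cycle bounded searches over every branch until a sweep stalls.

    ``window`` restricts each univariate search to +/- that many log
    units around the branch's current value; the window re-centers every
    sweep, so the optimum can still be reached by walking, at a fraction
    of the function evaluations a full-range search costs.
    """
    glo, ghi = math.log(BRANCH_BOUNDS[0]), math.log(BRANCH_BOUNDS[1])
    current = ev.loglik(lengths, model)
    branch_ids = [i for i in range(ev.tree.n_nodes) if i != ev.tree.root]
    sweeps = 0
    converged = False
    for sweeps in range(1, max_sweeps + 1):
        before = current
        for b in branch_ids:
            old = lengths[b]
            if window is None:
                lo, hi = glo, ghi
            else:
                center = math.log(max(lengths[b], BRANCH_BOUNDS[0]))
                lo = max(glo, center - window)
                hi = min(ghi, center + window)

            def neg(logt, b=b):
                lengths[b] = math.exp(logt)
                return -ev.loglik(lengths, model)

            x, f = bounded_min(neg, lo, hi, xatol=xatol)
            if -f >= current:
                lengths[b] = math.exp(x)
                current = -f
            else:  # keep the previous value if the search did not improve
                lengths[b] = old
        if current - before < sweep_tol:
            converged = True
            break
    return lengths, current, sweeps, converged


def optimize_branch_lengths(
    aln: Alignment,
    tree: PhyloTree,
    model,
    *,
    sweep_tol: float = DEFAULT_SWEEP_TOL,
    max_sweeps: int = 30,
    xatol: float = 1e-8,
    window: float | None = None,
) -> tuple[PhyloTree, LikelihoodResult]:
    """Optimize every branch length; model parameters stay fixed.

    Returns the optimized tree and a :class:`LikelihoodResult`; when the
    sweep limit is hit without convergence the best-so-far tree is
    returned with ``converged=False`` in the diagnostics.
    """
    from .likelihood import tree_log_likelihood

    ev = _Evaluator(aln, tree, model)
    lengths = tree.lengths.copy()
    lengths[tree.root] = 0.0
    lengths, current, sweeps, converged = _branch_sweeps(
        ev, lengths, model, sweep_tol=sweep_tol, max_sweeps=max_sweeps,
        xatol=xatol, window=window,
    )
    out_tree = tree.with_lengths(lengths)
    result = tree_log_likelihood(aln, out_tree, model)
    result.diagnostics.update(sweeps=sweeps, converged=converged)
    return out_tree, result


_PARAM_BOUNDS = {
    "gamma_shape": (0.02, 100.0, "log"),
    "p_invariant": (0.0, 0.99, "linear"),
    "kappa": (0.05, 100.0, "log"),
    "omega": (1e-4, 50.0, "log"),
}
_INITIALS = {"gamma_shape": 1.0, "p_invariant": 0.1, "kappa": 2.0, "omega": 0.5}


def _get_param(model, name):
    return getattr(model, name)


def _set_param(model, name, value):
    return replace(model, **{name: value})


def fit_model(
    aln: Alignment,
    tree: PhyloTree,
    model,
    free_params: set[str] | frozenset[str] = frozenset(),
    *,
    optimize_branches: bool = True,
    sweep_tol: float = DEFAULT_SWEEP_TOL,
    max_rounds: int = 12,
    max_sweeps: int = 8,
    xatol: float = 1e-8,
    branch_window: float | None = 3.0,
) -> LikelihoodResult:
    """Alternating optimization of free model parameters and branch lengths.

    ``free_params`` must name continuous parameters of ``model``
    (``gamma_shape``, ``p_invariant`` for amino-acid models; ``kappa``,
    ``omega`` for codon models).  Deterministic given its inputs.
    """
    from .likelihood import tree_log_likelihood

    allowed = set(model.free_parameter_names())
    unknown = set(free_params) - allowed
    if unknown:
        raise ValueError(f"not free parameters of this model: {sorted(unknown)}")

    # fixed deterministic starting values for the freed parameters
    for name in free_params:
        model = _set_param(model, name, _INITIALS[name])

    ev = _Evaluator(aln, tree, model)
    lengths = tree.lengths.copy()
    lengths[tree.root] = 0.0
    current = ev.loglik(lengths, model)
    at_bound: list[str] = []
    rounds = 0
    converged = False
    for rounds in range(1, max_rounds + 1):
        before = current
        for name in sorted(free_params):
            lo, hi, scale = _PARAM_BOUNDS[name]
            if scale == "log":
                tlo, thi = math.log(lo), math.log(hi)
                inv = math.exp
            else:
                tlo, thi = lo, hi
                inv = lambda x: x

            def neg(x, name=name, inv=inv):
                return -ev.loglik(lengths, _set_param(model, name, inv(x)))

            x, f = bounded_min(neg, tlo, thi, xatol=max(xatol, 1e-6))
            if -f >= current:
                model = _set_param(model, name, inv(x))
                current = -f
        if optimize_branches:
            lengths, current, _, _ = _branch_sweeps(
                ev, lengths, model,
                sweep_tol=sweep_tol, max_sweeps=max_sweeps,
                xatol=max(xatol, 1e-6), window=branch_window,
            )
        if current - before < sweep_tol:
            converged = True
            break
    for name in sorted(free_params):
        lo, hi, scale = _PARAM_BOUNDS[name]
        v = _get_param(model, name)
        rel = (hi - lo) * 1e-4 if scale == "linear" else None
        if scale == "log" and (v <= lo * 1.001 or v >= hi * 0.999):
            at_bound.append(name)
        elif scale == "linear" and (v <= lo + rel or v >= hi - rel):
            at_bound.append(name)

    out_tree = tree.with_lengths(lengths)
    result = tree_log_likelihood(aln, out_tree, model)
    result.diagnostics.update(
        rounds=rounds, converged=converged, at_bound=at_bound
    )
    result.parameters["free_params"] = sorted(free_params)
    result.parameters["fitted_model"] = model
    return result
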