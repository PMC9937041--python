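"""Codon-model positive-selection inference.

Site models let the nonsynonymous/synonymous rate ratio omega vary across
sites as a finite mixture: M0 (one ratio), M1a (nearly-neutral: omega0 < 1
and omega1 = 1), M2a (adds a selection class omega2 >= 1), M7 (beta-
distributed omega on (0,1), discretized), and M8 (beta plus a selection
class).  The branch-site model A additionally lets the selection class
apply only on designated foreground branches; its null fixes omega2 = 1.
Nested pairs are compared by chi-square likelihood-ratio tests, and
selected sites are identified by naive empirical Bayes (NEB) at the MLEs
or by Bayes empirical Bayes (BEB), which averages the class posteriors
over a discrete prior grid on the mixture proportions and omega2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import chi2

from .phylo_engine.alignment import Alignment
from .phylo_engine.likelihood import PatternData, pruning_log_likelihood
from .phylo_engine.models import SpectralQ, codon_rate_matrix, discretize_beta, mean_rate
from .phylo_engine.optimize import BRANCH_BOUNDS, bounded_min
from .phylo_engine.trees import PhyloTree

__all__ = [
    "SiteClassModel",
    "ModelFit",
    "LRTRecord",
    "fit_site_model",
    "site_model_lrt",
    "fit_branch_site",
    "branch_site_lrt",
    "identify_selected_sites",
]

SITE_FAMILIES = ("M0", "M1a", "M2a", "M7", "M8")
BRANCH_SITE_FAMILIES = ("BranchSiteA", "BranchSiteA_null")

OMEGA_BOUNDS = (1e-4, 50.0)
MULTINUC_CAVEAT = (
    "Branch-site tests assume single-nucleotide codon changes; multinucleotide "
    "substitutions and synonymous rate variation (cf. BUSTED) can produce "
    "false positives and are not modeled here."
)


@dataclass
class SiteClassModel:
    """Descriptor for a codon site-class (or branch-site) mixture model."""

    family: str
    kappa: float = 2.0
    codon_frequencies: np.ndarray | None = None
    # mixture parameters; which are meaningful depends on the family
    p0: float = 0.5
    p1: float = 0.25
    omega0: float = 0.2
    omega: float = 0.5  # M0 only
    omega2: float = 2.0  # M2a / M8 (omega_s) / branch-site alternative
    beta_p: float = 0.5
    beta_q: float = 1.0
    k_beta: int = 10

    def __post_init__(self) -> None:
        if self.family not in SITE_FAMILIES + BRANCH_SITE_FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        props = self.class_proportions()
        if np.any(props < -1e-12) or abs(props.sum() - 1) > 1e-9:
            raise ValueError("class proportions must be in [0,1] and sum to 1")
        if self.family in ("M1a", "M2a", "BranchSiteA", "BranchSiteA_null"):
            if not (0 < self.omega0 < 1):
                raise ValueError("omega0 must lie in (0, 1)")
        if self.family in ("M2a", "M8", "BranchSiteA"):
            if self.omega2 < 1:
                raise ValueError("omega2 must be >= 1 in the alternative model")

    # ------------------------------------------------------------------
    def frequencies(self) -> np.ndarray:
        if self.codon_frequencies is None:
            return np.full(61, 1 / 61)
        return np.asarray(self.codon_frequencies, dtype=float)

    def class_proportions(self) -> np.ndarray:
        f = self.family
        if f == "M0":
            return np.array([1.0])
        if f == "M1a":
            return np.array([self.p0, 1 - self.p0])
        if f == "M2a":
            return np.array([self.p0, self.p1, 1 - self.p0 - self.p1])
        if f == "M7":
            return np.full(self.k_beta, 1 / self.k_beta)
        if f == "M8":
            return np.concatenate(
                [np.full(self.k_beta, self.p0 / self.k_beta), [1 - self.p0]]
            )
        # branch-site A: 2a/2b split the selection mass proportionally to p0:p1
        p0, p1 = self.p0, self.p1
        if p0 + p1 <= 0:
            raise ValueError("p0 + p1 must be > 0 for branch-site models")
        p2 = 1 - p0 - p1
        return np.array(
            [p0, p1, p2 * p0 / (p0 + p1), p2 * p1 / (p0 + p1)]
        )

    def class_omegas(self) -> tuple[np.ndarray, np.ndarray]:
        """(background, foreground) omega per class; equal for site models."""
        f = self.family
        if f == "M0":
            bg = np.array([self.omega])
        elif f == "M1a":
            bg = np.array([self.omega0, 1.0])
        elif f == "M2a":
            bg = np.array([self.omega0, 1.0, self.omega2])
        elif f == "M7":
            bg = discretize_beta(self.beta_p, self.beta_q, self.k_beta)
        elif f == "M8":
            bg = np.concatenate(
                [discretize_beta(self.beta_p, self.beta_q, self.k_beta), [self.omega2]]
            )
        else:
            w2 = 1.0 if f == "BranchSiteA_null" else self.omega2
            bg = np.array([self.omega0, 1.0, self.omega0, 1.0])
            fg = np.array([self.omega0, 1.0, w2, w2])
            return bg, fg
        return bg, bg.copy()

    @property
    def selection_class_indices(self) -> list[int]:
        """Indices of classes that can carry omega > 1 (positive selection)."""
        f = self.family
        if f == "M2a":
            return [2]
        if f == "M8":
            return [self.k_beta]
        if f in BRANCH_SITE_FAMILIES:
            return [2, 3]
        return []

    @property
    def proportion_under_selection(self) -> float:
        props = self.class_proportions()
        return float(sum(props[i] for i in self.selection_class_indices))


@dataclass
class ModelFit:
    """Optimized site-class model with everything BEB needs downstream."""

    model: SiteClassModel
    log_likelihood: float
    tree: PhyloTree
    aln: Alignment
    class_log_likelihoods: np.ndarray  # (n_classes, n_sites), at the MLEs
    site_posteriors: np.ndarray  # (n_classes, n_sites), NEB
    per_site_log_likelihood: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    @property
    def proportion_under_selection(self) -> float:
        return self.model.proportion_under_selection


@dataclass
class LRTRecord:
    statistic: float
    df: int
    p_value: float
    null_log_likelihood: float
    alt_log_likelihood: float
    caveat: str = MULTINUC_CAVEAT


# ----------------------------------------------------------------------
class _CodonMixtureEvaluator:
    """Likelihood of a codon site-class mixture on a fixed topology.

    Caches spectral decompositions keyed by the omega value (kappa and
    frequencies are fixed per evaluator instance refresh), and chooses the
    foreground matrix on marked branches.  All class matrices share one
    scale factor: the mean background rate of the mixture, so one unit of
    branch length is one expected substitution per codon on background
    branches.
    """

    def __init__(self, aln: Alignment, tree: PhyloTree):
        if aln.flavor != "codon":
            raise ValueError("selection tests require a codon alignment")
        self.tree = tree.copy()
        self.data = PatternData(aln, tree)
        self.aln = aln
        self._kappa = None
        self._pi = None
        self._specs: dict[float, SpectralQ] = {}

    def _spectral(self, omega: float, kappa: float, pi: np.ndarray, scale: float):
        key = (round(float(omega), 12), round(float(kappa), 12), round(scale, 12))
        if self._kappa != kappa:
            self._specs.clear()
            self._kappa = kappa
        spec = self._specs.get(key)
        if spec is None:
            Q = codon_rate_matrix(kappa, omega, pi, scale=False) / scale
            spec = SpectralQ(Q, pi)
            if len(self._specs) > 256:
                self._specs.clear()
            self._specs[key] = spec
        return spec

    def components(
        self, model: SiteClassModel, lengths: np.ndarray
    ) -> tuple[list, np.ndarray]:
        """(weight, P_per_node) per class; matrices are batch-built per
        distinct omega and shared between classes."""
        pi = model.frequencies()
        props = model.class_proportions()
        bg, fg = model.class_omegas()
        scale = self._mixture_scale(model, pi)
        distinct = sorted({*bg, *fg})
        P_by_omega = {
            om: self._spectral(om, model.kappa, pi, scale).transitions(lengths)
            for om in distinct
        }
        fg_mask = self.tree.foreground
        comps = []
        for c, w in enumerate(props):
            Pb, Pf = P_by_omega[bg[c]], P_by_omega[fg[c]]
            P = [Pf[i] if fg_mask[i] else Pb[i] for i in range(self.tree.n_nodes)]
            comps.append((float(w), P))
        return comps, pi

    def _mixture_scale(self, model: SiteClassModel, pi: np.ndarray) -> float:
        props = model.class_proportions()
        bg, _ = model.class_omegas()
        mu = 0.0
        for w, om in zip(props, bg):
            mu += w * mean_rate(codon_rate_matrix(model.kappa, om, pi, scale=False), pi)
        return mu

    def loglik(
        self, model: SiteClassModel, lengths: np.ndarray, return_classes: bool = False
    ):
        pi = model.frequencies()
        props = model.class_proportions()
        bg, fg = model.class_omegas()
        scale = self._mixture_scale(model, pi)
        distinct = sorted({*bg, *fg})
        P_by_omega = {
            om: self._spectral(om, model.kappa, pi, scale).transitions(lengths)
            for om in distinct
        }
        fg_mask = self.tree.foreground
        # classes whose per-branch matrix assignment coincides (e.g. the
        # branch-site null's 2b class equals its neutral class) are pruned once
        keys = [
            tuple(fg[c] if fg_mask[i] else bg[c] for i in range(self.tree.n_nodes))
            for c in range(len(props))
        ]
        unique_ll: dict[tuple, np.ndarray] = {}
        for c, key in enumerate(keys):
            if key not in unique_ll:
                Pb, Pf = P_by_omega[bg[c]], P_by_omega[fg[c]]
                P = [
                    Pf[i] if fg_mask[i] else Pb[i]
                    for i in range(self.tree.n_nodes)
                ]
                unique_ll[key] = pruning_log_likelihood(
                    self.tree, self.data, P, pi
                )
        rows = []
        for c, key in enumerate(keys):
            w = props[c]
            if w <= 0:
                rows.append(np.full(self.data.patterns.shape[1], -1e300))
            else:
                rows.append(np.log(w) + unique_ll[key])
        logm = np.vstack(rows)
        top = logm.max(axis=0)
        per_pattern = top + np.log(np.exp(logm - top[None, :]).sum(axis=0))
        total = float(per_pattern @ self.data.weights)
        if not return_classes:
            return total
        return total, per_pattern, logm


# ----------------------------------------------------------------------
# Free-parameter schedules per family: (attr, lo, hi, transform)
_FREE = {
    "M0": [("kappa", 0.05, 100, "log"), ("omega", *OMEGA_BOUNDS, "log")],
    "M1a": [
        ("kappa", 0.05, 100, "log"),
        ("omega0", 1e-4, 1 - 1e-6, "logit"),
        ("p0", 1e-6, 1 - 1e-6, "logit"),
    ],
    "M2a": [
        ("kappa", 0.05, 100, "log"),
        ("omega0", 1e-4, 1 - 1e-6, "logit"),
        ("omega2", 1.0, OMEGA_BOUNDS[1], "log"),
        ("p0", None, None, "simplex"),
        ("p1", None, None, "simplex"),
    ],
    "M7": [
        ("kappa", 0.05, 100, "log"),
        ("beta_p", 0.005, 99, "log"),
        ("beta_q", 0.005, 99, "log"),
    ],
    "M8": [
        ("kappa", 0.05, 100, "log"),
        ("beta_p", 0.005, 99, "log"),
        ("beta_q", 0.005, 99, "log"),
        ("p0", 1e-6, 1 - 1e-6, "logit"),
        ("omega2", 1.0, OMEGA_BOUNDS[1], "log"),
    ],
    "BranchSiteA": [
        ("kappa", 0.05, 100, "log"),
        ("omega0", 1e-4, 1 - 1e-6, "logit"),
        ("omega2", 1.0, OMEGA_BOUNDS[1], "log"),
        ("p0", None, None, "simplex"),
        ("p1", None, None, "simplex"),
    ],
    "BranchSiteA_null": [
        ("kappa", 0.05, 100, "log"),
        ("omega0", 1e-4, 1 - 1e-6, "logit"),
        ("p0", None, None, "simplex"),
        ("p1", None, None, "simplex"),
    ],
}

# Deterministic multi-starts to mitigate the multimodality of the
# M2a/M8/branch-site likelihood surfaces.
_RESTART_OMEGA2 = (2.0, 5.0)
_RESTART_P = (0.85, 0.6)


def _optimize_mixture(
    ev: _CodonMixtureEvaluator,
    model: SiteClassModel,
    *,
    optimize_branches: bool = True,
    max_rounds: int = 10,
    tol: float = 1e-4,
    xatol: float = 1e-3,
    max_sweeps: int = 4,
    n_restarts: int = 2,
) -> tuple[SiteClassModel, np.ndarray, float, dict]:
    """Alternating bounded scalar searches over the family's free
    parameters and (optionally) branch lengths."""
    schedule = _FREE[model.family]
    best = None
    starts = []
    base = model
    for s in range(max(1, n_restarts)):
        m = base
        if model.family in ("M2a", "M8", "BranchSiteA") and s > 0:
            p0 = _RESTART_P[min(s - 1, len(_RESTART_P) - 1)]
            changes = {
                "omega2": _RESTART_OMEGA2[min(s - 1, len(_RESTART_OMEGA2) - 1)],
                "p0": p0,
            }
            if m.family != "M8":
                changes["p1"] = 0.5 * (1 - p0)
            starts.append(replace(m, **changes))
        else:
            starts.append(m)
    for m in starts:
        lengths = ev.tree.lengths.copy()
        lengths[ev.tree.root] = 0.0
        current = ev.loglik(m, lengths)
        rounds = 0
        converged = False
        for rounds in range(1, max_rounds + 1):
            before = current
            for attr, lo, hi, tf in schedule:
                m, current = _opt_scalar(ev, m, lengths, current, attr, lo, hi, tf, xatol)
            if optimize_branches:
                lengths, current = _opt_branches(
                    ev, m, lengths, current, xatol=xatol, max_sweeps=max_sweeps, tol=tol
                )
            if current - before < tol:
                converged = True
                break
        if best is None or current > best[2]:
            best = (m, lengths.copy(), current, {"rounds": rounds, "converged": converged})
    m, lengths, current, diag = best
    diag["at_bound"] = _bound_flags(m)
    return m, lengths, current, diag


def _opt_scalar(ev, model, lengths, current, attr, lo, hi, tf, xatol):
    if tf == "simplex":
        return _opt_simplex_coord(ev, model, lengths, current, attr, xatol)
    if tf == "log":
        tlo, thi, fwd, inv = math.log(lo), math.log(hi), math.log, math.exp
    elif tf == "logit":
        def fwd(x):
            return math.log(x / (1 - x))

        def inv(y):
            return 1 / (1 + math.exp(-y))

        tlo, thi = fwd(lo), fwd(hi)
    else:  # linear
        tlo, thi = lo, hi
        inv = lambda y: y

    def neg(y):
        return -ev.loglik(replace(model, **{attr: inv(y)}), lengths)

    x, f = bounded_min(neg, tlo, thi, xatol=xatol)
    if -f > current:
        return replace(model, **{attr: inv(x)}), -f
    return model, current


def _opt_simplex_coord(ev, model, lengths, current, attr, xatol):
    """Optimize one proportion holding the relative split of the rest."""
    props = {"p0": model.p0, "p1": model.p1}
    other = "p1" if attr == "p0" else "p0"
    rest = 1 - props[attr] - props[other]
    lo, hi = 1e-6, 1 - 1e-6

    def neg(y):
        v = 1 / (1 + math.exp(-y))
        # rescale the two remaining masses to keep the simplex closed
        total_other = props[other] + rest
        if total_other <= 0:
            frac = 0.5
        else:
            frac = props[other] / total_other
        new_other = (1 - v) * frac
        return -ev.loglik(
            replace(model, **{attr: v, other: new_other}), lengths
        )

    def fwd(x):
        x = min(max(x, lo), hi)
        return math.log(x / (1 - x))

    x, f = bounded_min(neg, fwd(lo), fwd(hi), xatol=xatol)
    if -f > current:
        v = 1 / (1 + math.exp(-x))
        total_other = props[other] + rest
        frac = props[other] / total_other if total_other > 0 else 0.5
        return replace(model, **{attr: v, other: (1 - v) * frac}), -f
    return model, current


def _opt_branches(ev, model, lengths, current, *, xatol, max_sweeps, tol,
                  window: float = 2.5):
    glo, ghi = math.log(BRANCH_BOUNDS[0]), math.log(BRANCH_BOUNDS[1])
    ids = [i for i in range(ev.tree.n_nodes) if i != ev.tree.root]
    for _ in range(max_sweeps):
        before = current
        for b in ids:
            old = lengths[b]
            center = math.log(max(lengths[b], BRANCH_BOUNDS[0]))
            lo = max(glo, center - window)
            hi = min(ghi, center + window)

            def neg(logt, b=b):
                lengths[b] = math.exp(logt)
                return -ev.loglik(model, lengths)

            x, f = bounded_min(neg, lo, hi, xatol=xatol)
            if -f >= current:
                lengths[b] = math.exp(x)
                current = -f
            else:
                lengths[b] = old
        if current - before < tol:
            break
    return lengths, current


def _bound_flags(model: SiteClassModel) -> list[str]:
    flags = []
    for attr, lo, hi, tf in _FREE[model.family]:
        if tf == "simplex":
            v = getattr(model, attr)
            if v <= 2e-6 or v >= 1 - 2e-6:
                flags.append(attr)
            continue
        v = getattr(model, attr)
        if v <= lo * 1.001 + 1e-12 or v >= hi * 0.999:
            flags.append(attr)
    return flags


def _finalize_fit(ev, model, lengths, loglik, diag) -> ModelFit:
    total, per_pattern, logm = ev.loglik(model, lengths, return_classes=True)
    s2p = ev.data.site_to_pattern
    with np.errstate(invalid="ignore"):
        post = np.exp(logm - per_pattern[None, :])
    class_ll = logm - np.log(model.class_proportions())[:, None]
    return ModelFit(
        model=model,
        log_likelihood=loglik,
        tree=ev.tree.with_lengths(lengths),
        aln=ev.aln,
        class_log_likelihoods=class_ll[:, s2p],
        site_posteriors=post[:, s2p],
        per_site_log_likelihood=per_pattern[s2p],
        diagnostics=diag,
    )


# ----------------------------------------------------------------------
def fit_site_model(
    codon_aln: Alignment,
    tree: PhyloTree,
    family: str,
    k_beta: int = 10,
    *,
    codon_freq: str = "F3x4",
    optimize_branches: bool = True,
    fixed_branch_lengths: np.ndarray | None = None,
    tol: float = 1e-4,
    xatol: float = 1e-3,
    max_rounds: int = 10,
    n_restarts: int | None = None,
) -> ModelFit:
    """Fit one of the site models M0/M1a/M2a/M7/M8 by maximum likelihood.

    Branch lengths are optimized jointly unless ``fixed_branch_lengths``
    is given (a common speed-up is to estimate them once under M0 and
    share them across the model family).
    """
    if family not in SITE_FAMILIES:
        raise ValueError(f"not a site-model family: {family!r}")
    freqs = codon_aln.empirical_codon_frequencies(codon_freq)
    model = SiteClassModel(family=family, kappa=2.0, codon_frequencies=freqs,
                           k_beta=k_beta, omega0=0.5, p0=0.7, p1=0.2, omega2=2.0)
    use_tree = tree.copy()
    if fixed_branch_lengths is not None:
        use_tree.lengths = np.asarray(fixed_branch_lengths, dtype=float).copy()
        optimize_branches = False
    ev = _CodonMixtureEvaluator(codon_aln, use_tree)
    if n_restarts is None:
        n_restarts = 2 if family in ("M2a", "M8") else 1
    model, lengths, loglik, diag = _optimize_mixture(
        ev, model, optimize_branches=optimize_branches, tol=tol, xatol=xatol,
        max_rounds=max_rounds, n_restarts=n_restarts,
    )
    return _finalize_fit(ev, model, lengths, loglik, diag)


def fit_branch_site(
    codon_aln: Alignment,
    tree: PhyloTree,
    null: bool = False,
    *,
    codon_freq: str = "F3x4",
    optimize_branches: bool = True,
    fixed_branch_lengths: np.ndarray | None = None,
    tol: float = 1e-4,
    xatol: float = 1e-3,
    max_rounds: int = 10,
    n_restarts: int | None = None,
    init_model: SiteClassModel | None = None,
) -> ModelFit:
    """Fit branch-site model A (or its null with omega2 = 1).

    The tree must carry at least one foreground branch mark (``#1`` in the
    newick).  Initial kappa is 2 and the initial selection-class omega is
    1, the conventional starting point for this test.
    """
    if not tree.foreground.any():
        raise ValueError("branch-site models need >= 1 foreground branch mark")
    freqs = codon_aln.empirical_codon_frequencies(codon_freq)
    family = "BranchSiteA_null" if null else "BranchSiteA"
    if init_model is not None:
        model = replace(
            init_model, family=family, codon_frequencies=freqs,
            omega2=max(1.0, init_model.omega2 if not null else 1.0),
        )
    else:
        model = SiteClassModel(
            family=family, kappa=2.0, codon_frequencies=freqs,
            p0=0.7, p1=0.2, omega0=0.5, omega2=1.0,
        )
    use_tree = tree.copy()
    if fixed_branch_lengths is not None:
        use_tree.lengths = np.asarray(fixed_branch_lengths, dtype=float).copy()
        optimize_branches = False
    ev = _CodonMixtureEvaluator(codon_aln, use_tree)
    if n_restarts is None:
        n_restarts = 1 if (null or init_model is not None) else 2
    model, lengths, loglik, diag = _optimize_mixture(
        ev, model, optimize_branches=optimize_branches, tol=tol, xatol=xatol,
        max_rounds=max_rounds, n_restarts=n_restarts,
    )
    fit = _finalize_fit(ev, model, lengths, loglik, diag)
    fit.diagnostics["proportion_under_selection"] = fit.proportion_under_selection
    return fit


# ----------------------------------------------------------------------
_NESTED_SITE_PAIRS = {("M1a", "M2a"), ("M7", "M8")}


def site_model_lrt(null_fit: ModelFit, alt_fit: ModelFit) -> LRTRecord:
    """Chi-square(2) LRT for the nested pairs (M1a, M2a) and (M7, M8)."""
    pair = (null_fit.model.family, alt_fit.model.family)
    if pair not in _NESTED_SITE_PAIRS:
        raise ValueError(f"not a supported nested site-model pair: {pair}")
    return _lrt(null_fit, alt_fit, df=2)


def branch_site_lrt(null_fit: ModelFit, alt_fit: ModelFit) -> LRTRecord:
    """Chi-square(1) LRT of branch-site model A against its omega2=1 null."""
    pair = (null_fit.model.family, alt_fit.model.family)
    if pair != ("BranchSiteA_null", "BranchSiteA"):
        raise ValueError(f"mismatched branch-site pair: {pair}")
    return _lrt(null_fit, alt_fit, df=1)


def _lrt(null_fit: ModelFit, alt_fit: ModelFit, df: int) -> LRTRecord:
    stat = max(0.0, 2 * (alt_fit.log_likelihood - null_fit.log_likelihood))
    return LRTRecord(
        statistic=stat,
        df=df,
        p_value=float(chi2.sf(stat, df)),
        null_log_likelihood=null_fit.log_likelihood,
        alt_log_likelihood=alt_fit.log_likelihood,
    )


# ----------------------------------------------------------------------
def identify_selected_sites(
    fit: ModelFit,
    threshold: float = 0.5,
    method: str = "BEB",
    grid_points: int = 10,
) -> list[tuple[int, float]]:
    """Sites whose positive-selection-class posterior exceeds ``threshold``.

    Returns ``[(site_index, posterior), ...]`` in alignment (codon)
    coordinates, 0-based.  NEB evaluates the Bayes rule at the MLEs; BEB
    averages over a uniform discrete prior grid on the class proportions
    and, for models with a free selection omega, on omega2
    (Yang-Wong-Nielsen-style; numerical agreement with other BEB
    implementations is not claimed).
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie in (0, 1)")
    sel = fit.model.selection_class_indices
    if not sel:
        return []
    if method == "NEB":
        post = fit.site_posteriors[sel].sum(axis=0)
    elif method == "BEB":
        post = _beb_posteriors(fit, grid_points)
    else:
        raise ValueError(f"unknown method {method!r}")
    return [(int(i), float(p)) for i, p in enumerate(post) if p > threshold]


def _beb_posteriors(fit: ModelFit, d: int) -> np.ndarray:
    """Selection-class posterior per site, integrating over a prior grid.

    The grid covers the mixture proportions (triangle grid for 3+-class
    models) and omega2; kappa, omega0/beta parameters and branch lengths
    stay at their MLEs, as in the published scheme.
    """
    model = fit.model
    family = model.family
    ev = _CodonMixtureEvaluator(fit.aln, fit.tree)
    lengths = fit.tree.lengths

    # class log-likelihood matrices for each omega2 grid value
    def classes_for(m: SiteClassModel) -> np.ndarray:
        _, per_pattern, logm = ev.loglik(m, lengths, return_classes=True)
        del per_pattern
        return logm - np.log(m.class_proportions())[:, None]

    w2_grid = None
    if family in ("M2a", "M8", "BranchSiteA"):
        w2_grid = 1.0 + 10.0 * (np.arange(d) + 0.5) / d  # midpoints of (1, 11)
    base_cll = None
    cll_by_w2 = []
    if w2_grid is None:
        base_cll = classes_for(model)[:, ev.data.site_to_pattern]
    else:
        for w2 in w2_grid:
            cll_by_w2.append(
                classes_for(replace(model, omega2=float(w2)))[:, ev.data.site_to_pattern]
            )

    # proportion grids (uniform prior over grid points)
    mids = (np.arange(d) + 0.5) / d
    prop_grid: list[np.ndarray] = []
    if family == "M1a":
        prop_grid = [np.array([p, 1 - p]) for p in mids]
    elif family == "M8":
        prop_grid = [
            np.concatenate([np.full(model.k_beta, p / model.k_beta), [1 - p]])
            for p in mids
        ]
    elif family in ("M2a", "BranchSiteA", "BranchSiteA_null"):
        for p0 in mids:
            for p1 in mids:
                if p0 + p1 >= 1:
                    continue
                if family == "M2a":
                    prop_grid.append(np.array([p0, p1, 1 - p0 - p1]))
                else:
                    p2 = 1 - p0 - p1
                    prop_grid.append(
                        np.array(
                            [p0, p1, p2 * p0 / (p0 + p1), p2 * p1 / (p0 + p1)]
                        )
                    )
    else:  # M0/M7 have no selection class; handled by caller
        return np.zeros(fit.aln.n_sites)

    sel = model.selection_class_indices
    n_sites = fit.aln.n_sites
    log_marg = []  # log f(X | theta) per grid point
    sel_post = []  # selection-class posterior per site per grid point
    cll_list = cll_by_w2 if w2_grid is not None else [base_cll]
    for cll in cll_list:
        for props in prop_grid:
            with np.errstate(divide="ignore"):
                logw = np.where(props > 0, np.log(np.maximum(props, 1e-300)), -np.inf)
            joint = logw[:, None] + cll
            top = joint.max(axis=0)
            site_ll = top + np.log(np.exp(joint - top[None, :]).sum(axis=0))
            log_marg.append(site_ll.sum())
            sel_post.append(np.exp(joint[sel] - site_ll[None, :]).sum(axis=0))
    log_marg = np.asarray(log_marg)
    weights = np.exp(log_marg - log_marg.max())
    weights /= weights.sum()
    sel_post = np.asarray(sel_post)  # (n_grid, n_sites)
    return weights @ sel_post
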