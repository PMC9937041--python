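"""Substitution models: empirical amino-acid matrices and codon models.

Amino-acid models are time-reversible GTR-form matrices built from a
symmetric exchangeability matrix S and stationary frequencies pi,
Q_ij = S_ij pi_j, optionally mixed over k discrete-Gamma rate categories
and an invariant-sites class.  Codon models follow the Goldman-Yang
parameterization: substitutions touching more than one codon position are
forbidden, transitions are scaled by kappa and nonsynonymous changes by
omega, and the target-codon frequency multiplies every rate.

All matrices are scaled so that one unit of branch length equals one
expected substitution per site under the model's own rate mixture.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.stats import gamma as gamma_dist

from .alignment import AMINO_ACIDS, SENSE_CODONS, translate_codon

__all__ = [
    "AAModel",
    "CodonModel",
    "SpectralQ",
    "discretize_gamma",
    "discretize_beta",
    "build_rate_matrix",
    "load_empirical_model",
]

def _data_text(fname: str) -> str:
    return resources.files("ponevo.phylo_engine").joinpath("data", fname).read_text()


def _load_manifest() -> dict:
    return json.loads(_data_text("manifest.json"))


def load_empirical_model(name: str) -> tuple[np.ndarray, np.ndarray]:
    """Return (S, pi) for an empirical amino-acid model ('JTT' or 'LG')."""
    fname = f"{name.lower()}.json"
    text = _data_text(fname)
    manifest = _load_manifest()
    digest = hashlib.sha256(text.encode()).hexdigest()
    if manifest[fname] != digest:
        raise ValueError(f"checksum mismatch for shipped model table {fname}")
    d = json.loads(text)
    if d["order"] != AMINO_ACIDS:
        raise ValueError("model table residue order mismatch")
    S = np.zeros((20, 20))
    tri = iter(d["exchangeabilities_lower_triangle"])
    for i in range(1, 20):
        for j in range(i):
            S[i, j] = S[j, i] = next(tri)
    pi = np.asarray(d["frequencies"], dtype=float)
    return S, pi / pi.sum()


# ----------------------------------------------------------------------
@dataclass
class AAModel:
    """Empirical (or Poisson) amino-acid model, optionally +G and/or +I."""

    name: str = "Poisson"  # Poisson | JTT | LG
    gamma_shape: float | None = None
    n_rate_categories: int = 4
    p_invariant: float | None = None
    frequencies: np.ndarray | None = None  # override stationary frequencies

    def __post_init__(self) -> None:
        if self.name not in ("Poisson", "JTT", "LG"):
            raise ValueError(f"unknown amino-acid model {self.name!r}")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma shape must be > 0")
        if self.n_rate_categories < 1:
            raise ValueError("need at least one rate category")
        if self.p_invariant is not None and not (0 <= self.p_invariant < 1):
            raise ValueError("p_invariant must lie in [0, 1)")

    @property
    def n_states(self) -> int:
        return 20

    def exchangeabilities(self) -> tuple[np.ndarray, np.ndarray]:
        if self.name == "Poisson":
            S = np.ones((20, 20)) - np.eye(20)
            pi = np.full(20, 1 / 20)
        else:
            S, pi = load_empirical_model(self.name)
        if self.frequencies is not None:
            pi = np.asarray(self.frequencies, dtype=float)
        return S, pi

    def rate_mixture(self) -> tuple[np.ndarray, np.ndarray]:
        """(rates, probs) including the invariant class when present.

        Gamma rates are rescaled by 1/(1 - p_inv) so the full mixture has
        mean rate exactly 1.
        """
        if self.gamma_shape is None:
            rates = np.array([1.0])
            probs = np.array([1.0])
        else:
            rates = discretize_gamma(self.gamma_shape, self.n_rate_categories)
            probs = np.full(self.n_rate_categories, 1 / self.n_rate_categories)
        if self.p_invariant:
            p = self.p_invariant
            rates = np.concatenate([[0.0], rates / (1 - p)])
            probs = np.concatenate([[p], probs * (1 - p)])
        return rates, probs

    def free_parameter_names(self) -> list[str]:
        names = []
        if self.gamma_shape is not None:
            names.append("gamma_shape")
        if self.p_invariant is not None:
            names.append("p_invariant")
        return names


@dataclass
class CodonModel:
    """Goldman-Yang codon model (single omega; the M0 model)."""

    kappa: float = 2.0
    omega: float = 0.5
    codon_frequencies: np.ndarray | None = None  # (61,); uniform if None

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.omega < 0:
            raise ValueError("omega must be >= 0")
        if self.codon_frequencies is not None:
            f = np.asarray(self.codon_frequencies, dtype=float)
            if f.shape != (61,):
                raise ValueError("codon frequencies must have length 61")
            if abs(f.sum() - 1) > 1e-9:
                raise ValueError("codon frequencies must sum to 1")

    @property
    def n_states(self) -> int:
        return 61

    def frequencies(self) -> np.ndarray:
        if self.codon_frequencies is None:
            return np.full(61, 1 / 61)
        return np.asarray(self.codon_frequencies, dtype=float)

    def rate_mixture(self) -> tuple[np.ndarray, np.ndarray]:
        return np.array([1.0]), np.array([1.0])

    def free_parameter_names(self) -> list[str]:
        return ["kappa", "omega"]


# ----------------------------------------------------------------------
def discretize_gamma(alpha: float, k: int) -> np.ndarray:
    """Means of the k equal-probability bins of Gamma(alpha, alpha).

    The returned rates average exactly 1.  Bin means use the identity
    E[X; a<X<b] = F_{alpha+1}(b) - F_{alpha+1}(a) for Gamma(alpha, alpha).
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        return np.array([1.0])
    edges = gamma_dist.ppf(np.arange(1, k) / k, a=alpha, scale=1 / alpha)
    upper = gamma_dist.cdf(edges, a=alpha + 1, scale=1 / alpha)
    cum = np.concatenate([[0.0], upper, [1.0]])
    rates = k * np.diff(cum)
    return rates / rates.mean()  # remove last-digit drift; exact mean 1


def discretize_beta(p: float, q: float, k: int) -> np.ndarray:
    """Means of the k equal-probability bins of Beta(p, q) on (0, 1)."""
    from scipy.stats import beta as beta_dist

    if p <= 0 or q <= 0:
        raise ValueError("beta parameters must be > 0")
    edges = beta_dist.ppf(np.arange(1, k) / k, p, q)
    # E[X; a<X<b] for Beta(p,q) = mean * (F_{p+1,q}(b) - F_{p+1,q}(a))
    upper = beta_dist.cdf(edges, p + 1, q)
    cum = np.concatenate([[0.0], upper, [1.0]])
    means = (p / (p + q)) * np.diff(cum) * k
    return np.clip(means, 1e-9, 1 - 1e-9)


# ----------------------------------------------------------------------
class SpectralQ:
    """Reversible rate matrix with its symmetric eigendecomposition.

    P(t) = D^{-1/2} U exp(L t) U' D^{1/2} with D = diag(pi); exact and
    stable, and the decomposition is reused across branches.
    """

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        self.Q = Q
        self.pi = pi
        sqrt_pi = np.sqrt(pi)
        A = (Q * sqrt_pi[:, None]) / sqrt_pi[None, :]
        A = 0.5 * (A + A.T)  # symmetrize numerical noise
        lam, U = np.linalg.eigh(A)
        self._lam = lam
        self._left = U / sqrt_pi[:, None]  # D^{-1/2} U
        self._right = (U * sqrt_pi[:, None]).T  # U' D^{1/2}

    def transition(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("negative branch length")
        P = (self._left * np.exp(self._lam * t)) @ self._right
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def transitions(self, ts: np.ndarray) -> np.ndarray:
        """Batched transition matrices, shape (len(ts), n, n)."""
        ts = np.asarray(ts, dtype=float)
        if np.any(ts < 0):
            raise ValueError("negative branch length")
        E = np.exp(np.outer(ts, self._lam))
        P = (self._left[None, :, :] * E[:, None, :]) @ self._right
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=2, keepdims=True)
        return P


def _gtr_rate_matrix(S: np.ndarray, pi: np.ndarray) -> np.ndarray:
    Q = S * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


_CODON_ARRAYS: dict[str, np.ndarray] = {}


def _codon_change_arrays() -> dict[str, np.ndarray]:
    """Precomputed masks over the 61x61 codon grid: single-nt changes,
    transitions, and nonsynonymous changes."""
    if _CODON_ARRAYS:
        return _CODON_ARRAYS
    n = len(SENSE_CODONS)
    single = np.zeros((n, n), dtype=bool)
    transition = np.zeros((n, n), dtype=bool)
    nonsyn = np.zeros((n, n), dtype=bool)
    ts_pairs = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            single[i, j] = True
            if diffs[0] in ts_pairs:
                transition[i, j] = True
            if translate_codon(ci) != translate_codon(cj):
                nonsyn[i, j] = True
    _CODON_ARRAYS.update(single=single, transition=transition, nonsyn=nonsyn)
    return _CODON_ARRAYS


def codon_rate_matrix(
    kappa: float, omega: float, pi: np.ndarray, scale: bool = True
) -> np.ndarray:
    """Goldman-Yang Q; if ``scale``, normalized to mean rate 1 under pi."""
    masks = _codon_change_arrays()
    Q = np.where(masks["single"], pi[None, :], 0.0)
    Q = Q * np.where(masks["transition"], kappa, 1.0)
    Q = Q * np.where(masks["nonsyn"], omega, 1.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    if scale:
        mu = -float(pi @ np.diag(Q))
        if mu > 0:
            Q = Q / mu
    return Q


def mean_rate(Q: np.ndarray, pi: np.ndarray) -> float:
    return -float(pi @ np.diag(Q))


def build_rate_matrix(model) -> tuple[np.ndarray, np.ndarray]:
    """Scaled rate matrix and stationary frequencies for a model.

    The matrix is normalized so that, averaged over the model's rate
    mixture (Gamma categories and invariant class), one unit of branch
    length is one expected substitution per site.
    """
    if isinstance(model, AAModel):
        S, pi = model.exchangeabilities()
        if abs(pi.sum() - 1) > 1e-9:
            raise ValueError("frequencies must sum to 1")
        Q = _gtr_rate_matrix(S, pi)
        Q /= mean_rate(Q, pi)
        # rate_mixture() already has mean 1, so QL averaged over the
        # mixture has unit mean rate.
        return Q, pi
    if isinstance(model, CodonModel):
        pi = model.frequencies()
        if abs(pi.sum() - 1) > 1e-9:
            raise ValueError("frequencies must sum to 1")
        return codon_rate_matrix(model.kappa, model.omega, pi), pi
    raise TypeError(f"unsupported model type {type(model).__name__}")
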