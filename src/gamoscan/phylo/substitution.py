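"""Reversible amino-acid substitution models and discrete-gamma rates.

The WAG model ships with the package (exchangeabilities S and equilibrium
frequencies π).  The rate matrix is Q_ij = S_ij π_j with the diagonal set so
rows sum to zero, scaled so the expected substitution rate -Σ π_i Q_ii is 1
(branch lengths are then expected substitutions per site).  Transition
matrices come from the symmetric eigendecomposition of
B = Π^{1/2} Q Π^{-1/2}, computed once and reused for every branch length.

Among-site rate variation uses Yang's discrete gamma: k equal-probability
categories, each represented by its bin mean, normalised to mean one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from ..codec import AMINO_ACIDS, _data_path

AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


@dataclass
class SubstitutionModel:
    exchangeabilities: np.ndarray  # symmetric (20, 20), zero diagonal
    equilibrium_freqs: np.ndarray  # (20,), sums to 1
    name: str = "custom"

    def __post_init__(self) -> None:
        S = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.equilibrium_freqs, dtype=float)
        if S.shape != (20, 20) or not np.allclose(S, S.T):
            raise ValueError("exchangeabilities must be a symmetric 20x20 matrix")
        if pi.shape != (20,) or not np.isclose(pi.sum(), 1.0, atol=1e-6):
            raise ValueError("equilibrium frequencies must be a 20-vector summing to 1")
        pi = pi / pi.sum()
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        scale = -np.sum(pi * np.diag(Q))
        Q /= scale
        self.exchangeabilities = S
        self.equilibrium_freqs = pi
        self.rate_matrix = Q
        # symmetric eigendecomposition, exact and reusable across branch lengths
        sqrt_pi = np.sqrt(pi)
        B = (Q * sqrt_pi[:, None]) / sqrt_pi[None, :]
        evals, evecs = np.linalg.eigh((B + B.T) / 2.0)
        self._evals = evals
        self._left = evecs / sqrt_pi[:, None]   # Π^{-1/2} U
        self._right = (evecs * sqrt_pi[:, None]).T  # U^T Π^{1/2}

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) with P[i, j] = Pr(j at the child | i at the parent)."""
        if t < 0:
            raise ValueError("branch length must be non-negative")
        P = (self._left * np.exp(self._evals * t)) @ self._right
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def transition_matrices(self, ts: np.ndarray) -> np.ndarray:
        """Stacked P(t) for a vector of branch lengths, shape (len(ts), 20, 20)."""
        ts = np.asarray(ts, dtype=float)
        expd = np.exp(self._evals[None, :] * ts[:, None])  # (m, 20)
        P = (self._left[None, :, :] * expd[:, None, :]) @ self._right
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=2, keepdims=True)
        return P

    @classmethod
    def wag(cls) -> "SubstitutionModel":
        exch = _read_matrix(_data_path("wag_exchangeabilities.tsv"))
        freqs = _read_freqs(_data_path("wag_frequencies.tsv"))
        return cls(exch, freqs, name="WAG")


def _read_matrix(path: Path) -> np.ndarray:
    rows: dict[str, dict[str, float]] = {}
    header: list[str] = []
    for line in path.read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if parts[0] == "aa":
            header = parts[1:]
            continue
        rows[parts[0]] = dict(zip(header, map(float, parts[1:])))
    M = np.zeros((20, 20))
    for a, i in AA_INDEX.items():
        for b, j in AA_INDEX.items():
            M[i, j] = rows[a][b]
    return M


def _read_freqs(path: Path) -> np.ndarray:
    vals = {}
    for line in path.read_text().splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("aa\t"):
            continue
        a, v = line.split("\t")
        vals[a] = float(v)
    return np.array([vals[a] for a in AMINO_ACIDS])


@dataclass
class GammaRates:
    """Discrete-gamma among-site rate categories (mean method)."""

    alpha: float
    k: int
    rates: np.ndarray = field(default=None)  # type: ignore[assignment]
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.k < 1:
            raise ValueError("need at least one rate category")
        if self.rates is None:
            self.rates = discrete_gamma(self.alpha, self.k)
        if self.weights is None:
            self.weights = np.full(self.k, 1.0 / self.k)
        if not np.isclose(float(self.weights @ self.rates), 1.0, atol=1e-8):
            raise ValueError("rates must be normalised to mean one")


def discrete_gamma(alpha: float, k: int) -> np.ndarray:
    """Category rates: means of k equal-probability bins of Gamma(alpha, 1/alpha).

    For X ~ Gamma(a, scale=1/a) and bin [b0, b1),
    E[X | bin] * (1/k) = I(a+1, a*b1) - I(a+1, a*b0) with I the regularised
    lower incomplete gamma function, so the bin-mean rate is k times that
    difference.  Mean-one normalisation holds exactly.
    """
    if k == 1:
        return np.ones(1)
    edges = gamma_dist.ppf(np.arange(1, k) / k, a=alpha, scale=1.0 / alpha)
    upper = np.concatenate([gammainc(alpha + 1.0, alpha * edges), [1.0]])
    lower = np.concatenate([[0.0], gammainc(alpha + 1.0, alpha * edges)])
    rates = k * (upper - lower)
    return rates / (rates.mean())  # guard tiny numerical drift
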