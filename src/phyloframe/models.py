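"""Time-reversible substitution models (JC through GTR, binary for RY data).

A model is parameterized by exchangeabilities, stationary base frequencies,
a discrete-gamma shape (alpha) and a proportion of invariant sites.  The rate
matrix is always rescaled to one expected substitution per site per unit
branch length; among-site rate variation enters as a finite mixture of rate
categories (gamma mean-category rates, plus a zero-rate category for p_inv).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

STATES_DNA = "ACGT"
STATES_RY = "RY"
# exchangeability order for DNA: AC, AG, AT, CG, CT, GT
EXCH_PAIRS = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]


@dataclass(frozen=True)
class SubstitutionModel:
    name: str = "GTR"
    exchangeabilities: tuple = (1.0,) * 6
    base_frequencies: tuple = (0.25,) * 4
    gamma_shape: float | None = None
    p_inv: float | None = None
    n_categories: int = 4

    def __post_init__(self):
        f = np.asarray(self.base_frequencies, float)
        if not np.isclose(f.sum(), 1.0, atol=1e-8):
            raise ValueError("base frequencies must sum to 1")
        if np.any(np.asarray(self.exchangeabilities) <= 0):
            raise ValueError("exchangeabilities must be positive")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma shape must be positive")
        if self.p_inv is not None and not (0 <= self.p_inv < 1):
            raise ValueError("p_inv must lie in [0, 1)")

    # -------------------------------------------------------------- matrices
    @property
    def n_states(self) -> int:
        return len(self.base_frequencies)

    @property
    def states(self) -> str:
        return STATES_DNA if self.n_states == 4 else STATES_RY

    def rate_matrix(self) -> np.ndarray:
        """Q scaled so that -sum_i pi_i Q_ii = 1."""
        k = self.n_states
        pi = np.asarray(self.base_frequencies, float)
        Q = np.zeros((k, k))
        if k == 4:
            for r, (i, j) in zip(self.exchangeabilities, EXCH_PAIRS):
                Q[i, j] = r * pi[j]
                Q[j, i] = r * pi[i]
        else:  # binary
            r = self.exchangeabilities[0]
            Q[0, 1] = r * pi[1]
            Q[1, 0] = r * pi[0]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -(pi * np.diag(Q)).sum()
        return Q / mu

    def _eigen(self):
        """Symmetric-form eigendecomposition of the reversible Q."""
        pi = np.asarray(self.base_frequencies, float)
        sq = np.sqrt(pi)
        Q = self.rate_matrix()
        S = (Q / sq[None, :]) * sq[:, None]   # diag(√π) Q diag(1/√π), symmetric
        S = (S + S.T) / 2
        w, U = np.linalg.eigh(S)
        left = U.T * sq[None, :]       # rows: U^T diag(sqrt pi)
        right = (U.T / sq[None, :]).T  # diag(1/sqrt pi) U
        return w, right, left

    def transition_matrices(self, lengths: np.ndarray) -> np.ndarray:
        """P(t) for an array of branch lengths → shape (..., k, k)."""
        w, right, left = self._eigen()
        t = np.asarray(lengths, float)
        # Q eigenvalues are <= 0; clip the tiny positive numerical noise
        e = np.exp(np.minimum(np.multiply.outer(t, w), 0.0))  # (..., k)
        P = np.einsum("ik,...k,kj->...ij", right, e, left)
        return np.clip(P, 0.0, 1.0)

    # --------------------------------------------------- rate heterogeneity
    def category_rates(self) -> tuple[np.ndarray, np.ndarray]:
        """(rates, weights) of the finite site-rate mixture, mean rate 1."""
        rates, weights = [], []
        pinv = self.p_inv or 0.0
        if pinv > 0:
            rates.append(0.0)
            weights.append(pinv)
        if self.gamma_shape is not None:
            a, k = self.gamma_shape, self.n_categories
            qs = gamma_dist.ppf(np.arange(k + 1) / k, a, scale=1.0 / a)
            # mean rate within each quantile slice (mean-category discretization)
            cum = gammainc(a + 1, a * qs)
            cat = k * np.diff(cum)
            cat = cat / (cat.mean())
            for r in cat:
                rates.append(r / (1 - pinv))
                weights.append((1 - pinv) / k)
        else:
            rates.append(1.0 / (1 - pinv) if pinv > 0 else 1.0)
            weights.append(1 - pinv)
        return np.asarray(rates), np.asarray(weights)

    def with_rates(self, **kw) -> "SubstitutionModel":
        return replace(self, **kw)

    # ------------------------------------------------------------- factories
    @classmethod
    def jc(cls, **kw) -> "SubstitutionModel":
        return cls(name="JC", **kw)

    @classmethod
    def k80(cls, kappa: float = 2.0, **kw) -> "SubstitutionModel":
        return cls(name="K80", exchangeabilities=(1, kappa, 1, 1, kappa, 1), **kw)

    @classmethod
    def hky(cls, kappa: float = 2.0, base_frequencies=(0.25,) * 4, **kw) -> "SubstitutionModel":
        return cls(name="HKY", exchangeabilities=(1, kappa, 1, 1, kappa, 1),
                   base_frequencies=tuple(base_frequencies), **kw)

    @classmethod
    def tim(cls, a: float = 1.0, b: float = 2.0, c: float = 1.0, d: float = 2.0,
            base_frequencies=(0.25,) * 4, **kw) -> "SubstitutionModel":
        """Transitional model: AC=GT=a, AG=b, AT=CG=c, CT=d."""
        return cls(name="TIM", exchangeabilities=(a, b, c, c, d, a),
                   base_frequencies=tuple(base_frequencies), **kw)

    @classmethod
    def gtr(cls, exchangeabilities=(1.0,) * 6, base_frequencies=(0.25,) * 4,
            **kw) -> "SubstitutionModel":
        return cls(name="GTR", exchangeabilities=tuple(exchangeabilities),
                   base_frequencies=tuple(base_frequencies), **kw)

    @classmethod
    def binary(cls, freq_r: float = 0.5, **kw) -> "SubstitutionModel":
        """Two-state model for RY-recoded data."""
        return cls(name="BIN", exchangeabilities=(1.0,),
                   base_frequencies=(freq_r, 1 - freq_r), **kw)
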