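"""The GTR+Gamma substitution model.

The general time-reversible rate matrix is parameterised by six symmetric
exchangeabilities (order AC, AG, AT, CG, CT, GT with GT fixed to 1) and the
stationary base frequencies pi.  Q is scaled so that the expected number of
substitutions per unit branch length is 1.  Among-site rate variation uses
the discrete-gamma approximation: k equal-probability categories, each
represented by its category mean under Gamma(alpha, alpha) (mean 1).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

__all__ = ["GTRGamma", "discretize_gamma", "JC_LIKE"]

_RATE_ORDER = ("AC", "AG", "AT", "CG", "CT", "GT")


def discretize_gamma(alpha: float, k: int) -> np.ndarray:
    """Mean rates of k equal-probability classes of Gamma(alpha, alpha).

    Category i spans the (i/k, (i+1)/k) quantile interval; its rate is the
    conditional mean over that interval, so the rates average exactly 1
    (renormalised to kill residual quadrature error).
    """
    if alpha <= 0:
        raise ValueError("gamma shape alpha must be > 0")
    if k < 1:
        raise ValueError("need at least one rate category")
    if k == 1:
        return np.ones(1)
    edges = gamma_dist.ppf(np.linspace(0.0, 1.0, k + 1), a=alpha, scale=1.0 / alpha)
    edges[0], edges[-1] = 0.0, np.inf
    # E[X ; X in (lo, hi)] for Gamma(a, rate=a) is P(a+1, a*hi) - P(a+1, a*lo)
    # with P the regularised lower incomplete gamma (mean of the dist is 1).
    upper = np.where(np.isinf(edges), 1.0, gammainc(alpha + 1.0, alpha * edges))
    rates = k * np.diff(upper)
    return rates / rates.mean()


@dataclass(frozen=True)
class GTRGamma:
    """GTR+Gamma model parameters (also covers JC69 as a special case)."""

    rates: Sequence[float] = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    freqs: Sequence[float] = (0.25, 0.25, 0.25, 0.25)
    alpha: float = 1.0
    ncat: int = 4

    def __post_init__(self):
        r = np.asarray(self.rates, dtype=float)
        f = np.asarray(self.freqs, dtype=float)
        if r.shape != (6,) or np.any(r <= 0):
            raise ValueError("need 6 positive exchangeabilities (AC,AG,AT,CG,CT,GT)")
        if f.shape != (4,) or np.any(f <= 0) or abs(f.sum() - 1.0) > 1e-12:
            raise ValueError("base frequencies must be positive and sum to 1")
        if self.alpha <= 0 or self.ncat < 1:
            raise ValueError("alpha must be > 0 and ncat >= 1")
        object.__setattr__(self, "rates", tuple(r / r[5]))  # GT == 1
        object.__setattr__(self, "freqs", tuple(f))

    # -- derived quantities ---------------------------------------------
    @property
    def category_rates(self) -> np.ndarray:
        return discretize_gamma(self.alpha, self.ncat)

    @property
    def q_matrix(self) -> np.ndarray:
        """Scaled rate matrix Q with sum_i pi_i * (-Q_ii) = 1."""
        ac, ag, at, cg, ct, gt = self.rates
        s = np.array([[0, ac, ag, at],
                      [ac, 0, cg, ct],
                      [ag, cg, 0, gt],
                      [at, ct, gt, 0]], dtype=float)
        pi = np.asarray(self.freqs)
        q = s * pi[None, :]
        np.fill_diagonal(q, -q.sum(axis=1))
        scale = -(pi * np.diag(q)).sum()
        return q / scale

    def _eigensystem(self):
        cached = getattr(self, "_eig_cache", None)
        if cached is not None:
            return cached
        pi = np.asarray(self.freqs)
        sqrt_pi = np.sqrt(pi)
        b = (sqrt_pi[:, None] * self.q_matrix) / sqrt_pi[None, :]
        w, u = np.linalg.eigh((b + b.T) / 2.0)
        left = u.T * sqrt_pi[None, :]          # U' diag(sqrt pi)
        right = (1.0 / sqrt_pi)[:, None] * u   # diag(1/sqrt pi) U
        object.__setattr__(self, "_eig_cache", (w, right, left))
        return w, right, left

    def transition_matrices(self, lengths: np.ndarray) -> np.ndarray:
        """P(t) for an array of branch length * rate products.

        Returns an array of shape ``lengths.shape + (4, 4)``; rows of every
        matrix sum to 1.
        """
        t = np.asarray(lengths, dtype=float)
        if np.any(t < 0):
            raise ValueError("negative branch length")
        w, right, left = self._eigensystem()
        expwt = np.exp(np.multiply.outer(t, w))           # (..., 4)
        p = np.einsum("ik,...k,kj->...ij", right, expwt, left)
        return np.clip(p, 0.0, None)

    def transition_matrix(self, t: float) -> np.ndarray:
        return self.transition_matrices(np.asarray(t))

    def with_(self, **kw) -> "GTRGamma":
        return replace(self, **kw)


#: Jukes-Cantor-like instance (equal rates/frequencies, one rate category).
JC_LIKE = GTRGamma(ncat=1)
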