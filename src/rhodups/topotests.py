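"""Topology tests from per-site log-likelihoods: RELL bootstrap
probabilities and the approximately-unbiased (AU) test.

RELL ("resampling estimated log-likelihoods") re-weights the per-site
log-likelihood columns instead of re-optimising trees: a replicate draws
``round(n * r)`` sites with replacement, sums the sampled site values per
tree and credits the tree with the highest sum (ties split equally).

The AU test runs RELL at several scales r (default 0.5..1.4), transforms
each bootstrap proportion via z = Phi^-1(1 - BP), fits the multiscale
model z(r) ~ d*sqrt(r) + c/sqrt(r) by weighted least squares (weights from
the binomial variance of BP), and reports au = 1 - Phi(d - c).  ``np`` is
the plain RELL proportion at scale 1.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = ["rell_bp", "au_test", "AUResult", "AUTestReport", "DEFAULT_SCALES",
           "read_site_loglik_matrix"]

DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.45, 0.1), 1))


def _weighted_site_sums(matrix: np.ndarray, m: int, B: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Replicate log-likelihood sums via multinomial site weights."""
    n = matrix.shape[0]
    weights = rng.multinomial(m, np.full(n, 1.0 / n), size=B)
    return weights @ matrix                     # (B, n_trees)


def rell_bp(matrix: np.ndarray, scale: float = 1.0, B: int = 1000,
            seed: Optional[int] = None,
            rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """RELL bootstrap proportions at one scale.

    ``matrix`` is sites x trees.  Each of the B replicates resamples
    ``round(n * scale)`` sites with replacement; the argmax tree gets the
    credit, split equally on ties.  Returns per-tree proportions summing
    to 1.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[1] < 2:
        raise ValueError("need a sites x trees matrix with >= 2 trees")
    if B < 1 or scale <= 0:
        raise ValueError("need B >= 1 and scale > 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    m = max(int(round(matrix.shape[0] * scale)), 1)
    sums = _weighted_site_sums(matrix, m, B, rng)
    best = sums.max(axis=1, keepdims=True)
    wins = np.isclose(sums, best, rtol=0.0, atol=1e-9)
    credit = wins / wins.sum(axis=1, keepdims=True)
    return credit.sum(axis=0) / B


@dataclass
class AUResult:
    """AU/np outcome for one candidate tree."""
    tree: str
    loglik: float
    rank: int
    au: float
    np_value: float
    d: float                                   # signed distance
    c: float                                   # curvature
    bp_by_scale: np.ndarray = field(repr=False, default=None)
    residuals: np.ndarray = field(repr=False, default=None)
    flag: Optional[str] = None


@dataclass
class AUTestReport:
    results: List[AUResult]
    scales: np.ndarray

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"tree": r.tree, "loglik": r.loglik, "rank": r.rank,
              "au": r.au, "np": r.np_value, "d": r.d, "c": r.c,
              "flag": r.flag} for r in self.results])

    def __iter__(self):
        return iter(self.results)


def au_test(matrix: np.ndarray, tree_labels: Optional[Sequence[str]] = None,
            scales: Optional[Sequence[float]] = None, B: int = 1000,
            seed: int = 0) -> AUTestReport:
    """Multiscale-bootstrap AU test over a candidate tree set.

    The scale list always receives 1.0 (np is read off that scale exactly).
    Bootstrap proportions are clamped to [1/(2B), 1 - 1/(2B)] before the
    normal-quantile transform; a tree pinned at the clamp on every scale is
    reported at the implied bound and flagged ``degenerate``.
    """
    matrix = np.asarray(matrix, dtype=float)
    ntrees = matrix.shape[1]
    scales = np.array(sorted(set([*(scales if scales is not None
                                    else DEFAULT_SCALES), 1.0])), dtype=float)
    if len(scales) < 2:
        raise ValueError("need at least two distinct scales")
    labels = (list(tree_labels) if tree_labels is not None
              else [f"tree{i+1}" for i in range(ntrees)])
    master = np.random.default_rng(np.random.SeedSequence(seed))
    bp = np.stack([rell_bp(matrix, scale=r, B=B, rng=master) for r in scales])
    eps = 1.0 / (2.0 * B)
    bp_cl = np.clip(bp, eps, 1.0 - eps)
    z = norm.isf(bp_cl)                         # Phi^-1(1 - BP)
    # WLS design: z ~ d*sqrt(r) + c/sqrt(r)
    x = np.column_stack([np.sqrt(scales), 1.0 / np.sqrt(scales)])
    totals = matrix.sum(axis=0)
    order = np.argsort(-totals, kind="stable")
    ranks = np.empty(ntrees, dtype=int)
    ranks[order] = np.arange(1, ntrees + 1)
    i_np = int(np.argmin(np.abs(scales - 1.0)))
    results: List[AUResult] = []
    for j in range(ntrees):
        pinned = np.all((bp[:, j] <= eps) | (bp[:, j] >= 1 - eps))
        var = bp_cl[:, j] * (1 - bp_cl[:, j]) / (B * norm.pdf(z[:, j]) ** 2)
        w = 1.0 / var
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(x * sw[:, None], z[:, j] * sw, rcond=None)
        d, c = float(coef[0]), float(coef[1])
        fitted = x @ coef
        au = float(norm.sf(d - c))
        flag = None
        if pinned:
            au = 1.0 - eps if bp[i_np, j] >= 1 - eps else eps
            flag = "degenerate"
        results.append(AUResult(labels[j], float(totals[j]), int(ranks[j]),
                                au, float(bp[i_np, j]), d, c,
                                bp_by_scale=bp[:, j].copy(),
                                residuals=z[:, j] - fitted, flag=flag))
    return AUTestReport(results, scales)


def read_site_loglik_matrix(path):
    """Read the columnar site log-likelihood table written by the
    likelihood layer; returns ``(matrix, tree_labels)``."""
    with open(path) as fh:
        header = fh.readline().split("\t")
        if header[0] != "site":
            raise ValueError("not a site log-likelihood table")
        labels = [h.strip() for h in header[1:]]
        rows = [[float(x) for x in line.split("\t")[1:]] for line in fh if line.strip()]
    matrix = np.asarray(rows, dtype=float)
    if matrix.shape[1] != len(labels):
        raise ValueError("ragged site log-likelihood table")
    return matrix, labels
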