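"""Phylogenetic signal: ML Pagel's lambda (continuous) and Fritz–Purvis D
(binary).

Pagel's lambda is estimated by maximizing the multivariate-normal
log-likelihood of the trait with mean mu*1 and covariance sigma^2*C(lambda),
profiling mu and sigma^2 analytically; lambda = 0 means phylogenetic
independence, lambda = 1 pure Brownian covariance.

The D statistic scales the observed sum of sister-clade differences d_obs of
a 0/1 trait between two reference distributions obtained on the same tree:

    D = (d_obs - mean d_Brownian) / (mean d_random - mean d_Brownian)

so D = 1 matches random tip shuffles and D = 0 matches a Brownian threshold
model at the observed prevalence; negative D indicates stronger-than-
Brownian phylogenetic clumping.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .trees import Phylogeny, covariance
from .pgls import profile_lambda, _ml_loglik

logger = logging.getLogger(__name__)

__all__ = ["LambdaEstimate", "DStatResult", "estimate_lambda", "d_statistic"]


@dataclass(frozen=True)
class LambdaEstimate:
    lambda_hat: float
    loglik: float
    loglik_lambda0: float
    loglik_lambda1: float
    degenerate: bool = False  # star tree: likelihood flat in lambda


def estimate_lambda(tree: Phylogeny, x) -> LambdaEstimate:
    """ML Pagel's lambda for a continuous trait.

    ``x`` is a mapping tip label -> value, or an array in tip order.
    """
    y = _tip_vector(tree, x)
    if tree.n_tips < 4:
        raise ValueError("lambda estimation needs at least 4 tips")
    if np.ptp(y) == 0:
        raise ValueError("constant trait: lambda undefined")
    X = np.ones((len(y), 1))
    C, _ = covariance(tree, 1.0)
    diag = np.diag(np.diag(C))
    ll0 = _ml_loglik(y, X, diag)[0]
    ll1 = _ml_loglik(y, X, C)[0]
    if np.max(np.abs(C - diag)) == 0.0:
        warnings.warn("star tree: likelihood is constant in lambda; returning 0",
                      RuntimeWarning, stacklevel=2)
        return LambdaEstimate(0.0, ll0, ll0, ll1, degenerate=True)
    lam, ll = profile_lambda(y, X, C)
    return LambdaEstimate(lam, ll, ll0, ll1)


@dataclass(frozen=True)
class DStatResult:
    d_obs: float
    mean_d_random: float
    mean_d_brownian: float
    D: float
    n_permutations: int
    seed: int


def _tip_vector(tree: Phylogeny, x) -> np.ndarray:
    if isinstance(x, dict):
        return np.array([float(x[t]) for t in tree.tip_labels])
    x = np.asarray(x, dtype=float)
    if len(x) != tree.n_tips:
        raise ValueError("trait vector length does not match tip count")
    return x


def _node_pass_arrays(tree: Phylogeny):
    """Precompute (internal nodes in postorder, their children) as arrays."""
    kids = tree.children()
    order = [int(i) for i in tree.postorder if not tree.is_tip[i]]
    return order, kids


def sister_clade_d(tree: Phylogeny, states: np.ndarray,
                   _cache=None) -> np.ndarray:
    """Sum of sister-clade differences of nodal estimates, vectorized.

    ``states`` has tips in tip order along axis 0 and may carry extra
    columns (one d per column). Each internal node's estimate is the mean of
    its children's estimates; d adds |node - child| over all children.
    """
    order, kids = _cache if _cache is not None else _node_pass_arrays(tree)
    states = np.atleast_2d(np.asarray(states, dtype=float).T).T  # (n_tips, m)
    m = states.shape[1]
    est = np.zeros((tree.n_nodes, m))
    tip_rank = {int(t): r for r, t in enumerate(tree.tip_indices)}
    for i in tree.tip_indices:
        est[i] = states[tip_rank[int(i)]]
    d = np.zeros(m)
    for i in order:
        ch = kids[i]
        vals = est[ch]                       # (n_children, m)
        est[i] = vals.mean(axis=0)
        d += np.abs(vals - est[i]).sum(axis=0)
    return d


def rank_threshold(sim: np.ndarray, n_ones: int) -> np.ndarray:
    """Binarize columns of ``sim`` so exactly ``n_ones`` largest entries are 1."""
    sim = np.atleast_2d(sim.T).T
    n = sim.shape[0]
    order = np.argsort(sim, axis=0, kind="stable")
    out = np.zeros_like(sim)
    rows = order[n - n_ones:, :]
    np.put_along_axis(out, rows, 1.0, axis=0)
    return out


def d_statistic(tree: Phylogeny, states, n_permutations: int = 1000,
                n_simulations: int | None = None, seed: int = 0) -> DStatResult:
    """Fritz–Purvis D for a binary trait.

    ``states`` maps tip label -> {0, 1} (or an array in tip order). The
    random reference shuffles tip states; the Brownian reference simulates
    Brownian motion on the tree and rank-thresholds each replicate at the
    observed prevalence. Fully deterministic given ``seed``.
    """
    s = _tip_vector(tree, states)
    if not set(np.unique(s)) <= {0.0, 1.0}:
        raise ValueError("states must be binary 0/1")
    n_ones = int(s.sum())
    n = len(s)
    if n_ones in (0, n):
        raise ValueError("monomorphic trait: D undefined")
    if n_permutations < 1:
        raise ValueError("need at least 1 permutation")
    n_simulations = n_permutations if n_simulations is None else n_simulations

    cache = _node_pass_arrays(tree)
    d_obs = float(sister_clade_d(tree, s, _cache=cache)[0])

    rng = np.random.default_rng(seed)
    perms = np.empty((n, n_permutations))
    for j in range(n_permutations):
        perms[:, j] = rng.permutation(s)
    mean_d_random = float(sister_clade_d(tree, perms, _cache=cache).mean())

    C, _ = covariance(tree, 1.0)
    L = np.linalg.cholesky(C + 1e-12 * np.mean(np.diag(C)) * np.eye(n))
    sims = L @ rng.standard_normal((n, n_simulations))
    binary = rank_threshold(sims, n_ones)
    mean_d_brownian = float(sister_clade_d(tree, binary, _cache=cache).mean())

    denom = mean_d_random - mean_d_brownian
    if denom == 0:
        raise ValueError("degenerate references: random and Brownian d coincide")
    D = (d_obs - mean_d_brownian) / denom
    return DStatResult(d_obs=d_obs, mean_d_random=mean_d_random,
                       mean_d_brownian=mean_d_brownian, D=float(D),
                       n_permutations=n_permutations, seed=seed)
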