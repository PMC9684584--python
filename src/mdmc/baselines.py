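"""Baseline pervasive-community detectors.

Three reference methods fit the same Poisson link-generation model
``A_nm ~ Poisson(sum_k theta_nk theta_mk)`` on symmetric adjacency
matrices:

* :func:`bkn_em` — the Ball–Karrer–Newman stochastic block model EM on the
  node-community propensities theta.  MDMC at alpha = 0 is equivalent to it
  under the mapping ``theta_nk = sqrt(2L pi(k)) p(n|k)``, which is used as a
  cross-check oracle in the tests.
* :func:`nmf_em` — non-negative matrix factorization A ≈ WH under the
  generalized Kullback–Leibler divergence (Lee–Seung multiplicative
  updates).
* :func:`bayesian_nmf_em` — NMF with half-normal shrinkage priors on W, H
  and gamma hyper-priors on the per-community precisions beta_k (Psorakis
  et al.); redundant communities are driven to zero automatically.

All three report communities through the same (p(n|k), pi(k)) mapping
``p(n|k) = W_nk / W_k`` and ``pi(k) = W_k^2 / sum_k W_k^2`` with
``W_k = sum_n W_nk``, so the evaluation layer is detector-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from mdmc.graph_io import Network

__all__ = ["PropensityModel", "BayesNMFState", "bkn_em", "nmf_em", "bayesian_nmf_em"]

EPS = 1e-12  # floor on multiplicative-update denominators
BETA_CAP = 1e12


@dataclass
class PropensityModel:
    """Non-negative propensities theta plus the derived (p, pi) readout."""

    theta: np.ndarray  # (N, K)
    p: np.ndarray  # (K, N), rows normalized where the community is alive
    pi: np.ndarray  # (K,)
    objective: np.ndarray = field(default_factory=lambda: np.empty(0))
    seed: int | None = None

    @property
    def K(self) -> int:
        return self.theta.shape[1]


@dataclass
class BayesNMFState:
    """Bayesian NMF state: symmetric factors and per-community precisions."""

    W: np.ndarray  # (N, K)
    H: np.ndarray  # (K, N)
    beta: np.ndarray  # (K,)
    hyper_a: float
    hyper_b: float
    p: np.ndarray = None  # (K, N) derived over surviving columns
    pi: np.ndarray = None  # (K,)
    survived: np.ndarray = None
    objective: np.ndarray = field(default_factory=lambda: np.empty(0))
    seed: int | None = None


def _require_symmetric(net: Network) -> np.ndarray:
    if net.directed:
        raise ValueError("baseline detectors require an undirected network")
    return net.adjacency(sparse=False)


def _derive_p_pi(W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    Wk = W.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(Wk > 0, W / np.where(Wk > 0, Wk, 1.0), 0.0).T
    sq = Wk**2
    tot = sq.sum()
    pi = sq / tot if tot > 0 else np.full(Wk.size, 1.0 / Wk.size)
    return p, pi


def _poisson_loglik(A_data, links_to, theta: np.ndarray) -> float:
    """Variable part of log p(A) for the Poisson model, over ordered pairs
    (the constant -log A_nm! is dropped)."""
    lam_links = np.einsum("lk,lk->l", theta[links_to[0]], theta[links_to[1]])
    lam_links = np.maximum(lam_links, EPS)
    total_rate = float((theta.sum(axis=0) ** 2).sum())
    return float((A_data * np.log(lam_links)).sum()) - total_rate


def bkn_em(
    net: Network, K: int, n_iter: int = 200, seed: int | None = 0
) -> PropensityModel:
    """Ball–Karrer–Newman EM for the propensities theta_nk.

    E-step: per stored link, q_l(k) ∝ theta[from,k] theta[to,k].
    M-step: theta_nk = sum_m A_nm q_nm(k) / sqrt(sum_{n,m} A_nm q_nm(k)).
    Tracks the Poisson log-likelihood (without the constant factorial term).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    _require_symmetric(net)  # validates symmetry/directedness
    N = net.n_nodes
    lf, lt, w = net.links_from, net.links_to, net.weights
    rng = np.random.default_rng(seed)
    theta = rng.random((N, K)) + 0.1
    # scale so the model's expected total weight matches the observed one
    scale = net.total_weight / max((theta.sum(axis=0) ** 2).sum(), EPS)
    theta *= np.sqrt(scale)
    dead_rows = np.flatnonzero(
        np.bincount(lf, weights=w, minlength=N) + np.bincount(lt, weights=w, minlength=N) == 0
    )
    theta[dead_rows] = 0.0
    inc_to = sp.coo_matrix(
        (np.ones(lt.size), (lt, np.arange(lt.size))), shape=(N, lt.size)
    ).tocsr()
    ll = np.empty(n_iter)
    for it in range(n_iter):
        num = theta[lf] * theta[lt]  # (L, K)
        tot = num.sum(axis=1, keepdims=True)
        q = np.where(tot > 0, num / np.where(tot > 0, tot, 1.0), 1.0 / K)
        wq = w[:, None] * q
        node_sum = inc_to @ wq  # (N, K): sum_m A_nm q_nm(k), A[n,m] over links m->n
        denom = wq.sum(axis=0)  # sum over ordered pairs
        theta = np.where(denom > 0, node_sum / np.sqrt(np.maximum(denom, EPS)), 0.0)
        ll[it] = _poisson_loglik(w, (lf, lt), theta)
    p, pi = _derive_p_pi(theta)
    return PropensityModel(theta=theta, p=p, pi=pi, objective=ll, seed=seed)


def _gkl_divergence(A: np.ndarray, WH: np.ndarray) -> float:
    """Generalized KL divergence D(A || WH) with 0 log 0 = 0."""
    mask = A > 0
    WHm = np.maximum(WH, EPS)
    return float((A[mask] * np.log(A[mask] / WHm[mask])).sum() - A.sum() + WH.sum())


def nmf_em(
    net: Network, K: int, n_iter: int = 200, seed: int | None = 0
) -> PropensityModel:
    """Symmetric NMF of the adjacency matrix under generalized KL.

    Alternating Lee–Seung multiplicative updates on (W, H); each half-step
    is non-increasing in D(A||WH) by construction.  Starting from the
    symmetric tie H = Wᵀ on a symmetric A the factors stay numerically
    near-symmetric; the reported propensity is (W + Hᵀ)/2.
    """
    A = _require_symmetric(net)
    N = net.n_nodes
    rng = np.random.default_rng(seed)
    W = rng.random((N, K)) + 0.1
    W *= np.sqrt(A.sum() / max((W.sum(axis=0) ** 2).sum(), EPS))
    H = W.T.copy()
    obj = np.empty(n_iter)
    for it in range(n_iter):
        WH = np.maximum(W @ H, EPS)
        W *= (A / WH) @ H.T / np.maximum(H.sum(axis=1)[None, :], EPS)
        WH = np.maximum(W @ H, EPS)
        H *= W.T @ (A / WH) / np.maximum(W.sum(axis=0)[:, None], EPS)
        obj[it] = _gkl_divergence(A, W @ H)
    theta = 0.5 * (W + H.T)
    p, pi = _derive_p_pi(theta)
    return PropensityModel(theta=theta, p=p, pi=pi, objective=obj, seed=seed)


def bayesian_nmf_em(
    net: Network,
    K: int,
    a: float = 5.0,
    b: float = 2.0,
    n_iter: int = 500,
    seed: int | None = 0,
    survival_rel_tol: float = 1e-6,
) -> BayesNMFState:
    """Bayesian NMF with half-normal priors and automatic community removal.

    Multiplicative updates damped by the precisions beta_k; beta_k follows
    its gamma posterior mode ``(N + a - 1) / (0.5 [sum W^2 + sum H^2] + b)``.
    Large b keeps the precisions small, making the shrinkage (and hence the
    vanishing of redundant communities) ineffective.  A community whose W
    column L1 norm drops below ``survival_rel_tol`` times the mean column
    norm counts as vanished.
    """
    if a <= 0 or b < 0:
        raise ValueError("need a > 0 and b >= 0")
    A = _require_symmetric(net)
    N = net.n_nodes
    rng = np.random.default_rng(seed)
    W = rng.random((N, K)) + 0.1
    W *= np.sqrt(A.sum() / max((W.sum(axis=0) ** 2).sum(), EPS))
    H = W.T.copy()
    beta = np.full(K, 1.0)
    obj = np.empty(n_iter)
    for it in range(n_iter):
        WH = np.maximum(W @ H, EPS)
        W *= (A / WH) @ H.T / np.maximum(H.sum(axis=1)[None, :] + beta[None, :] * W, EPS)
        WH = np.maximum(W @ H, EPS)
        H *= W.T @ (A / WH) / np.maximum(W.sum(axis=0)[:, None] + beta[:, None] * H, EPS)
        beta = (N + a - 1.0) / np.maximum(
            0.5 * ((W**2).sum(axis=0) + (H**2).sum(axis=1)) + b, EPS
        )
        beta = np.minimum(beta, BETA_CAP)
        obj[it] = _gkl_divergence(A, W @ H)
    col = np.abs(W).sum(axis=0)
    survived = np.flatnonzero(col >= survival_rel_tol * max(col.mean(), EPS))
    theta = 0.5 * (W + H.T)
    theta_surv = np.zeros_like(theta)
    theta_surv[:, survived] = theta[:, survived]
    p, pi = _derive_p_pi(theta_surv)
    return BayesNMFState(
        W=W, H=H, beta=beta, hyper_a=a, hyper_b=b,
        p=p, pi=pi, survived=survived, objective=obj, seed=seed,
    )
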