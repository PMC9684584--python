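"""Network containers, transition matrices and stationary distributions.

A network is stored as a directed link list: an undirected input edge
``{n, m}`` becomes the two directed links ``n -> m`` and ``m -> n`` with
equal weight, so the link count ``L`` always refers to directed links.
The random walker moves according to the column-stochastic transition
matrix ``T_nm = A_nm / sum_n' A_n'm`` (rate for the move ``m -> n``),
optionally mixed with PageRank-style teleportation to restore ergodicity
on directed networks with dangling nodes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Network",
    "TransitionModel",
    "load_edge_list",
    "build_transition_model",
    "karate_club_network",
    "karate_club_split",
]

DEFAULT_TELEPORT = 0.15


@dataclass
class Network:
    """A weighted, possibly directed network as an ordered directed-link list.

    Node indices are 0-based internally; edge-list files are 1-based by
    default and original labels are kept in ``node_labels``.
    """

    n_nodes: int
    links_from: np.ndarray  # (L,) int
    links_to: np.ndarray  # (L,) int
    weights: np.ndarray  # (L,) float, non-negative
    directed: bool = False
    node_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.links_from = np.asarray(self.links_from, dtype=np.int64)
        self.links_to = np.asarray(self.links_to, dtype=np.int64)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if np.any(self.weights < 0):
            raise ValueError("link weights must be non-negative")
        for arr in (self.links_from, self.links_to):
            if arr.size and (arr.min() < 0 or arr.max() >= self.n_nodes):
                raise ValueError("node indices out of range")

    @property
    def n_links(self) -> int:
        """Number of directed links L (an undirected edge counts twice)."""
        return self.links_from.size

    @property
    def total_weight(self) -> float:
        """Sum of all directed link weights (= 2 L_w for undirected input)."""
        return float(self.weights.sum())

    def adjacency(self, sparse: bool = True):
        """Adjacency with the walker convention A[n, m] = weight of m -> n."""
        A = sp.coo_matrix(
            (self.weights, (self.links_to, self.links_from)),
            shape=(self.n_nodes, self.n_nodes),
        ).tocsr()
        A.sum_duplicates()
        return A if sparse else np.asarray(A.todense())

    @classmethod
    def from_arrays(
        cls,
        src: np.ndarray,
        dst: np.ndarray,
        weights: np.ndarray | None = None,
        *,
        n_nodes: int | None = None,
        directed: bool = False,
        node_labels: list[str] | None = None,
    ) -> "Network":
        """Build from parallel edge arrays, expanding undirected edges and
        summing duplicates."""
        src = np.asarray(src, dtype=np.int64)
        dst = np.asarray(dst, dtype=np.int64)
        w = np.ones(src.size) if weights is None else np.asarray(weights, dtype=np.float64)
        if n_nodes is None:
            n_nodes = int(max(src.max(initial=-1), dst.max(initial=-1))) + 1
        if not directed:
            loops = src == dst
            src2 = np.concatenate([src, dst[~loops]])
            dst2 = np.concatenate([dst, src[~loops]])
            w = np.concatenate([w, w[~loops]])
            src, dst = src2, dst2
        # merge duplicate (src, dst) pairs by summing their weights
        key = src * n_nodes + dst
        order = np.argsort(key, kind="stable")
        key, src, dst, w = key[order], src[order], dst[order], w[order]
        uniq, start = np.unique(key, return_index=True)
        wsum = np.add.reduceat(w, start) if key.size else w
        return cls(
            n_nodes=n_nodes,
            links_from=src[start],
            links_to=dst[start],
            weights=wsum,
            directed=directed,
            node_labels=node_labels,
        )

    @classmethod
    def from_adjacency(cls, A, directed: bool = False) -> "Network":
        """Build from a dense or sparse adjacency matrix A[n, m] (m -> n).

        For undirected networks A must be symmetric; both link directions
        are stored.
        """
        A = sp.csr_matrix(A)
        if not directed and abs(A - A.T).max() > 1e-12:
            raise ValueError("undirected network requires a symmetric adjacency matrix")
        coo = A.tocoo()
        return cls(
            n_nodes=A.shape[0],
            links_from=coo.col,
            links_to=coo.row,
            weights=coo.data,
            directed=directed,
        )

    def to_edge_list(self, path, one_based: bool = True) -> None:
        """Write a whitespace edge list (undirected edges written once)."""
        off = 1 if one_based else 0
        with open(path, "w") as fh:
            fh.write(f"# nodes={self.n_nodes} directed={int(self.directed)}\n")
            for s, t, w in zip(self.links_from, self.links_to, self.weights):
                if not self.directed and s > t:
                    continue  # each undirected edge once
                fh.write(f"{s + off} {t + off} {w:.12g}\n")

    def to_json_header(self, path) -> None:
        meta = {
            "n_nodes": self.n_nodes,
            "n_links": self.n_links,
            "directed": self.directed,
            "node_labels": self.node_labels,
        }
        with open(path, "w") as fh:
            json.dump(meta, fh, indent=1)


def load_edge_list(
    path,
    directed: bool = False,
    weighted: bool | None = None,
    one_based: bool = True,
) -> Network:
    """Read a whitespace/TSV edge list ``from to [weight]``.

    Lines starting with ``#`` are comments.  Node labels are arbitrary
    strings; integer labels are mapped preserving numeric order (1-based by
    default), any other labels in order of first appearance.  Duplicate
    edges are summed; negative weights are rejected with their line number.
    """
    srcs: list[str] = []
    dsts: list[str] = []
    ws: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#")[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"line {lineno}: expected 'from to [weight]'")
            w = 1.0
            if len(parts) >= 3 and weighted is not False:
                w = float(parts[2])
                if w < 0:
                    raise ValueError(f"line {lineno}: negative weight {w}")
            srcs.append(parts[0])
            dsts.append(parts[1])
            ws.append(w)
    labels = srcs + dsts
    if all(lab.lstrip("-").isdigit() for lab in labels):
        nums = sorted({int(lab) for lab in labels})
        if one_based and nums and nums[0] >= 1:
            n_nodes = max(nums)
            index = {str(v): v - 1 for v in range(1, n_nodes + 1)}
            node_labels = [str(v) for v in range(1, n_nodes + 1)]
        else:
            index = {str(v): i for i, v in enumerate(nums)}
            n_nodes = len(nums)
            node_labels = [str(v) for v in nums]
    else:
        seen: dict[str, int] = {}
        for lab in labels:
            seen.setdefault(lab, len(seen))
        index, n_nodes, node_labels = seen, len(seen), list(seen)
    src = np.array([index[s] for s in srcs], dtype=np.int64)
    dst = np.array([index[d] for d in dsts], dtype=np.int64)
    net = Network.from_arrays(
        src, dst, np.array(ws), n_nodes=n_nodes, directed=directed, node_labels=node_labels
    )
    deg = np.bincount(net.links_from, weights=net.weights, minlength=n_nodes)
    deg += np.bincount(net.links_to, weights=net.weights, minlength=n_nodes)
    if np.any(deg == 0):
        warnings.warn(f"{int((deg == 0).sum())} isolated node(s) with zero incident weight")
    return net


@dataclass
class TransitionModel:
    """Column-stochastic transition rates plus stationary node/link weights.

    ``T`` holds the raw rates ``A_nm / sum_n' A_n'm`` (dangling columns are
    zero); teleportation with probability ``rho`` is applied on the fly by
    :meth:`propagate`, mixing in a uniform jump and redistributing the mass
    absorbed by dangling nodes.  ``p_st_link`` carries the stationary
    probability of observing the walker on each original link; teleport
    moves are unobservable, so the link probabilities are renormalized to
    sum to one.
    """

    network: Network
    T: sp.csr_matrix
    teleport_rho: float
    dangling_flags: np.ndarray  # (N,) bool
    p_st_node: np.ndarray  # (N,)
    p_st_link: np.ndarray  # (L,)
    residual: float = 0.0
    n_power_steps: int = 0
    _Tcsr: sp.csr_matrix = field(init=False, repr=False, default=None)

    def __post_init__(self) -> None:
        self._Tcsr = sp.csr_matrix(self.T)

    @property
    def n_nodes(self) -> int:
        return self.network.n_nodes

    def propagate(self, P: np.ndarray) -> np.ndarray:
        """One step of the (teleport-adjusted) Markov chain.

        ``P`` is either a length-N distribution or a (K, N) stack of
        distributions over nodes; returns the same shape.
        """
        P = np.asarray(P, dtype=np.float64)
        out = (self._Tcsr @ P.T).T
        rho = self.teleport_rho
        if rho > 0 or self.dangling_flags.any():
            dang = P[..., self.dangling_flags].sum(axis=-1)
            mix = ((1.0 - rho) * dang + rho * P.sum(axis=-1)) / self.n_nodes
            out = (1.0 - rho) * out + np.expand_dims(mix, -1)
        return out


def build_transition_model(
    net: Network,
    rho: float = 0.0,
    tol: float = 1e-12,
    max_steps: int = 10_000,
    rng: np.random.Generator | None = None,
) -> TransitionModel:
    """Build T, find the stationary state by power iteration, and assign
    per-link stationary probabilities.

    For ``rho = 0`` the network must be ergodic; dangling nodes then raise
    an error suggesting teleportation.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError("teleportation probability rho must lie in [0, 1]")
    if net.n_nodes == 0:
        raise ValueError("empty network")
    A = net.adjacency()
    col = np.asarray(A.sum(axis=0)).ravel()  # total out-weight of each node
    dangling = col == 0
    if rho == 0.0 and dangling.any():
        raise ValueError(
            f"{int(dangling.sum())} dangling node(s): the Markov chain is not "
            "ergodic; rerun with teleportation (rho > 0, e.g. rho=0.15)"
        )
    inv = np.where(dangling, 0.0, 1.0 / np.where(dangling, 1.0, col))
    T = (A @ sp.diags(inv)).tocsr()
    model = TransitionModel(
        network=net,
        T=T,
        teleport_rho=rho,
        dangling_flags=dangling,
        p_st_node=np.full(net.n_nodes, 1.0 / net.n_nodes),
        p_st_link=np.zeros(net.n_links),
    )
    if not net.directed and rho == 0.0:
        # symmetric A: the stationary state is the weighted degree profile
        p = np.asarray(A.sum(axis=1)).ravel() / A.sum()
        model.p_st_node = p
        model.residual = float(np.abs(model.propagate(p) - p).sum())
        model.n_power_steps = 0
    else:
        if rng is None:
            p = np.full(net.n_nodes, 1.0 / net.n_nodes)
        else:
            p = rng.random(net.n_nodes) + 1e-3
            p /= p.sum()
        resid = np.inf
        for step in range(1, max_steps + 1):
            p_one = model.propagate(p)
            resid = float(np.abs(p_one - p).sum())  # fixed-point residual of T
            # lazy half-step: same fixed point, robust to (near-)periodic chains
            p = 0.5 * (p_one + p)
            if resid <= tol:
                break
        else:
            raise ValueError(
                f"power iteration did not converge in {max_steps} steps "
                f"(L1 residual {resid:.3e})"
            )
        model.p_st_node = p
        model.residual = resid
        model.n_power_steps = step
    # probability of observing the walker traversing each original link;
    # the teleport fraction is unobservable, hence renormalization
    t_link = np.asarray(T[net.links_to, net.links_from]).ravel()
    raw = (1.0 - rho) * t_link * p[net.links_from] if rho > 0 else t_link * p[net.links_from]
    total = raw.sum()
    if total <= 0:
        raise ValueError("all link probabilities vanished; network has no usable links")
    model.p_st_link = raw / total
    return model


def karate_club_network() -> Network:
    """Zachary's karate club (34 nodes, unweighted, undirected)."""
    import networkx as nx

    g = nx.karate_club_graph()
    edges = np.array(g.edges(), dtype=np.int64)
    return Network.from_arrays(
        edges[:, 0],
        edges[:, 1],
        n_nodes=g.number_of_nodes(),
        directed=False,
        node_labels=[str(n + 1) for n in range(g.number_of_nodes())],
    )


def karate_club_split() -> np.ndarray:
    """The club's historical two-faction split (0 = Mr. Hi, 1 = Officer)."""
    import networkx as nx

    g = nx.karate_club_graph()
    return np.array([0 if g.nodes[n]["club"] == "Mr. Hi" else 1 for n in g.nodes()])
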