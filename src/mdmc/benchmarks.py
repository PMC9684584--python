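"""Synthetic networks with planted community structure.

Two families:

* Poisson (Ball–Karrer–Newman) networks planted with pervasive communities
  whose membership profiles p*(n|k*) and sizes pi*(k*) follow truncated
  power laws — the benchmark used for the MaxSim/NMI comparative study
  (base setting: N = 1000 nodes, K* = 10 communities, exponents gamma = 3
  for memberships, beta = 2 for sizes, expected L = 20000 links).
* Two nested toy networks with known two-layer hierarchies of definite
  communities: a block-of-blocks-of-blocks (5 x 5 x 40 nodes of nested
  Erdős–Rényi blocks) and a ring-of-rings-of-rings (nested rings, strongly
  non-cohesive modules).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from mdmc.graph_io import Network

__all__ = [
    "PlantedCommunities",
    "HierarchyGroundTruth",
    "sample_planted_communities",
    "generate_bkn_network",
    "generate_block_hierarchy",
    "generate_ring_hierarchy",
    "BENCHMARK_CLASSES",
]

# (N, expected L) of the five benchmark classes; density D = L/N
BENCHMARK_CLASSES = {
    1: (1000, 20_000),
    2: (500, 20_000),
    3: (2000, 20_000),
    4: (1000, 10_000),
    5: (1000, 40_000),
}


@dataclass
class PlantedCommunities:
    """Ground-truth pervasive communities for Poisson network generation."""

    p_star: np.ndarray  # (K*, N), rows normalized
    pi_star: np.ndarray  # (K*,)
    gamma: float
    beta: float
    ratio_cap_p: float
    ratio_cap_pi: float
    seed: int | None = None

    @property
    def K_star(self) -> int:
        return self.pi_star.size

    @property
    def n_nodes(self) -> int:
        return self.p_star.shape[1]

    def partition(self) -> np.ndarray:
        """Hard planted labels: argmax_k* of the belonging pi* p* per node."""
        return np.argmax(self.pi_star[:, None] * self.p_star, axis=0)

    def to_json(self, path) -> None:
        import json

        doc = {
            "K_star": self.K_star,
            "n_nodes": self.n_nodes,
            "gamma": self.gamma,
            "beta": self.beta,
            "pi_star": self.pi_star.tolist(),
            "p_star": self.p_star.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)


@dataclass
class HierarchyGroundTruth:
    """Nested layer partitions of a planted two-layer hierarchy."""

    labels_fine: np.ndarray  # e.g. 25-way leaf labels
    labels_coarse: np.ndarray  # e.g. 5-way top labels
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        # nestedness: each fine block must sit inside exactly one coarse block
        for lab in np.unique(self.labels_fine):
            parents = np.unique(self.labels_coarse[self.labels_fine == lab])
            if parents.size != 1:
                raise ValueError("layer partitions are not nested")


def _truncated_power_law(
    rng: np.random.Generator, exponent: float, ratio_cap: float, size: int
) -> np.ndarray:
    """Inverse-CDF draws with density ∝ x^-exponent on [1, ratio_cap]."""
    if exponent <= 1:
        raise ValueError("power-law exponent must exceed 1")
    if ratio_cap < 1:
        raise ValueError("ratio cap must be >= 1")
    if ratio_cap == 1.0:
        return np.ones(size)
    u = rng.random(size)
    g = 1.0 - exponent
    return (1.0 + u * (ratio_cap**g - 1.0)) ** (1.0 / g)


def sample_planted_communities(
    N: int = 1000,
    K_star: int = 10,
    gamma: float = 3.0,
    beta: float = 2.0,
    ratio_cap_p: float = 100.0,
    ratio_cap_pi: float = 20.0,
    seed: int | None = 0,
    max_resamples: int = 1000,
) -> PlantedCommunities:
    """Draw planted memberships and sizes from truncated power laws.

    Each p*(.|k*) is N i.i.d. draws with tail exponent gamma, normalized;
    pi* likewise with exponent beta.  The truncation bounds enforce the
    moderate max/min ratio caps; draws are rejection-resampled should a
    degenerate draw break them.
    """
    rng = np.random.default_rng(seed)
    for _ in range(max_resamples):
        p_raw = _truncated_power_law(rng, gamma, ratio_cap_p, (K_star, N))
        pi_raw = _truncated_power_law(rng, beta, ratio_cap_pi, K_star)
        ok_p = all(
            row.max() / row.min() <= ratio_cap_p * (1 + 1e-12) for row in p_raw
        )
        ok_pi = pi_raw.max() / pi_raw.min() <= ratio_cap_pi * (1 + 1e-12)
        if ok_p and ok_pi:
            return PlantedCommunities(
                p_star=p_raw / p_raw.sum(axis=1, keepdims=True),
                pi_star=pi_raw / pi_raw.sum(),
                gamma=gamma,
                beta=beta,
                ratio_cap_p=ratio_cap_p,
                ratio_cap_pi=ratio_cap_pi,
                seed=seed,
            )
    raise RuntimeError(
        f"ratio caps unreachable in {max_resamples} resamples; widen the caps"
    )


def generate_bkn_network(
    planted: PlantedCommunities, target_L: float, seed: int | None = 0
) -> Network:
    """Poisson multigraph with pairwise rate 2 L sum_k pi* p*(n) p*(m).

    Rates are applied once per unordered pair n < m (no self-loops); the
    expected total undirected link weight is then ≈ target_L.  Multi-edges
    are kept as integer weights.
    """
    if target_L <= 0:
        raise ValueError("target_L must be positive")
    rng = np.random.default_rng(seed)
    P = planted.p_star  # (K*, N)
    rate = 2.0 * target_L * np.einsum("k,kn,km->nm", planted.pi_star, P, P)
    iu, ju = np.triu_indices(planted.n_nodes, k=1)
    counts = rng.poisson(rate[iu, ju])
    nz = counts > 0
    return Network.from_arrays(
        iu[nz], ju[nz], counts[nz].astype(float),
        n_nodes=planted.n_nodes, directed=False,
    )


def _is_connected(net: Network) -> bool:
    n_comp, _ = sp.csgraph.connected_components(net.adjacency(), directed=False)
    return n_comp == 1


def generate_block_hierarchy(
    n_top: int = 5,
    n_mid: int = 5,
    leaf_size: int = 40,
    p_within: float = 0.25,
    p_mid: float = 0.05,
    p_top: float = 0.005,
    seed: int | None = 0,
    max_resamples: int = 20,
) -> tuple[Network, HierarchyGroundTruth]:
    """Block-of-blocks-of-blocks: nested Erdős–Rényi communities.

    n_top top-level blocks, each of n_mid leaf blocks of leaf_size nodes.
    Edge probabilities: p_within inside a leaf, p_mid between leaves of the
    same top block, p_top across top blocks (must decrease in that order
    for a three-scale separation).  Resamples on a disconnected draw.
    """
    if not p_within > p_mid > p_top > 0:
        raise ValueError("need p_within > p_mid > p_top > 0")
    N = n_top * n_mid * leaf_size
    leaf = np.arange(N) // leaf_size
    top = np.arange(N) // (n_mid * leaf_size)
    prob = np.where(
        leaf[:, None] == leaf[None, :],
        p_within,
        np.where(top[:, None] == top[None, :], p_mid, p_top),
    )
    rng = np.random.default_rng(seed)
    for attempt in range(max_resamples):
        iu, ju = np.triu_indices(N, k=1)
        edges = rng.random(iu.size) < prob[iu, ju]
        net = Network.from_arrays(iu[edges], ju[edges], n_nodes=N, directed=False)
        if _is_connected(net):
            break
        import warnings

        warnings.warn(f"disconnected draw (attempt {attempt + 1}); resampling")
    else:
        raise RuntimeError("could not draw a connected block hierarchy")
    truth = HierarchyGroundTruth(
        labels_fine=leaf,
        labels_coarse=top,
        params={
            "kind": "block", "n_top": n_top, "n_mid": n_mid, "leaf_size": leaf_size,
            "p_within": p_within, "p_mid": p_mid, "p_top": p_top, "seed": seed,
        },
    )
    return net, truth


def generate_ring_hierarchy(
    n_top: int = 5,
    n_mid: int = 5,
    leaf_size: int = 40,
    inter_ring_links: int = 1,
    seed: int | None = None,
) -> tuple[Network, HierarchyGroundTruth]:
    """Ring-of-rings-of-rings: nested non-cohesive communities.

    Each leaf is a cycle of leaf_size nodes; the n_mid leaves of a mid-level
    module are joined into a ring by ``inter_ring_links`` links between
    deterministic port nodes at the cycle seams, and the n_top mid-level
    modules are joined into a ring the same way through one middle leaf per
    module.  Weak (single-link) coupling keeps every ring a strong
    diffusion trap, which lets annealed community detection resolve the
    fine 25-ring layer exactly; stronger coupling moves the ring-merging
    transitions down the resolution axis at the cost of blurring the ring
    boundaries.  The construction is deterministic; ``seed`` is accepted
    for API symmetry only.
    """
    N = n_top * n_mid * leaf_size
    c = int(inter_ring_links)
    if not 1 <= c <= leaf_size:
        raise ValueError("inter_ring_links must be in [1, leaf_size]")
    src: list[int] = []
    dst: list[int] = []

    def node(t: int, m: int, i: int) -> int:
        return (t * n_mid + m) * leaf_size + i

    for t in range(n_top):
        for m in range(n_mid):
            for i in range(leaf_size):  # leaf cycle
                src.append(node(t, m, i))
                dst.append(node(t, m, (i + 1) % leaf_size))
        for m in range(n_mid):  # ring of leaves: c seam links between adjacent cycles
            for j in range(c):
                src.append(node(t, m, leaf_size - 1 - j))
                dst.append(node(t, (m + 1) % n_mid, j))
    for t in range(n_top):  # ring of mid modules: c seam links via a middle leaf
        for j in range(c):
            src.append(node(t, n_mid // 2, leaf_size // 2 - j))
            dst.append(node((t + 1) % n_top, n_mid // 2, leaf_size // 2 + 1 + j))
    net = Network.from_arrays(
        np.array(src), np.array(dst), n_nodes=N, directed=False
    )
    leaf = np.arange(N) // leaf_size
    top = np.arange(N) // (n_mid * leaf_size)
    truth = HierarchyGroundTruth(
        labels_fine=leaf,
        labels_coarse=top,
        params={
            "kind": "ring", "n_top": n_top, "n_mid": n_mid,
            "leaf_size": leaf_size, "inter_ring_links": c, "seed": seed,
        },
    )
    return net, truth
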