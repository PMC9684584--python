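"""Hierarchy extraction by quasi-static annealing of the resolution alpha.

Starting from a consensus fit at a small alpha_ini (many small communities),
alpha is increased geometrically while the EM iteration continues.  The
mixture weights pi(k) stay almost constant within each layer of the hierarchy
and reorganize sharply at discrete phase transitions where small communities
merge into larger ones.  Stable phases are detected from the per-step change
of pi; each layer's node belongings p(k|n) are evaluated at the centre of its
alpha range, and probability flows between belongings of adjacent layers give
the (generally non-tree) parent-child structure, exportable as a Sankey
diagram.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from mdmc.core import (
    MDMCResult,
    MDMCState,
    default_survival_threshold,
    count_surviving,
    em_iteration,
    q_lower_bound,
    run_em,
)
from mdmc.graph_io import TransitionModel

__all__ = [
    "AnnealSchedule",
    "HierarchyTrace",
    "Layer",
    "FlowMatrix",
    "make_schedule",
    "consensus_init",
    "run_quasi_static",
    "detect_layers",
    "layer_flows",
    "sankey_export",
    "extract_hierarchy",
]


@dataclass
class AnnealSchedule:
    """Geometric alpha schedule: alpha(t) = alpha_ini * (alpha_fin/alpha_ini)^s
    with s = (t - t_ini)/(t_fin - t_ini)."""

    alpha_ini: float
    alpha_fin: float
    t_ini: int
    t_fin: int
    values: np.ndarray  # alpha at t_ini .. t_fin inclusive

    @property
    def n_steps(self) -> int:
        return self.t_fin - self.t_ini

    def alpha(self, t: int) -> float:
        return float(self.values[t - self.t_ini])


def make_schedule(
    alpha_ini: float, alpha_fin: float, t_ini: int = 0, t_fin: int = 2000
) -> AnnealSchedule:
    """Geometric interpolation between alpha_ini and alpha_fin.

    The per-step ratio is constant; the midpoint sits at the geometric mean
    sqrt(alpha_ini * alpha_fin).  alpha_fin = alpha_ini gives a constant
    schedule.
    """
    if alpha_ini <= 0 or alpha_fin <= 0:
        raise ValueError("alpha bounds must be positive")
    if alpha_fin < alpha_ini:
        raise ValueError("annealing increases alpha: need alpha_fin >= alpha_ini")
    if t_fin <= t_ini:
        raise ValueError("need t_fin > t_ini")
    s = np.arange(t_fin - t_ini + 1) / (t_fin - t_ini)
    values = alpha_ini * (alpha_fin / alpha_ini) ** s
    return AnnealSchedule(alpha_ini, alpha_fin, t_ini, t_fin, values)


@dataclass
class HierarchyTrace:
    """Record of the annealing run: alpha and pi at every step, plus
    membership snapshots at requested steps."""

    schedule: AnnealSchedule
    steps: np.ndarray  # (T+1,)
    alphas: np.ndarray  # (T+1,)
    pis: np.ndarray  # (T+1, K)
    snapshots: dict[int, MDMCState] = field(default_factory=dict)
    checkpoints: dict[int, MDMCState] = field(default_factory=dict)
    survival_threshold: float = 1e-5

    @property
    def K(self) -> int:
        return self.pis.shape[1]

    def save_tsv(self, path) -> None:
        header = "t\talpha\t" + "\t".join(f"pi{k + 1}" for k in range(self.K))
        data = np.column_stack([self.steps, self.alphas, self.pis])
        np.savetxt(path, data, delimiter="\t", header=header, comments="", fmt="%.10g")


@dataclass
class Layer:
    """A stable phase of the annealing trajectory."""

    h: int
    alpha_range: tuple[float, float]
    alpha_center: float
    t_center: int  # schedule step at which the layer is evaluated
    pi: np.ndarray  # (K,)
    n_survived: int
    belonging: np.ndarray | None = None  # (K, N) p(k|n), filled by extract pass
    membership: np.ndarray | None = None  # (K, N) p(n|k)
    p_node: np.ndarray | None = None

    def partition(self, survival_threshold: float | None = None) -> np.ndarray:
        """Hard labels by argmax belonging over surviving communities."""
        if self.belonging is None:
            raise ValueError("layer has no belonging snapshot")
        thr = (
            default_survival_threshold(self.pi.size)
            if survival_threshold is None
            else survival_threshold
        )
        survived = np.flatnonzero(self.pi >= thr)
        if survived.size == 0:
            survived = np.array([int(np.argmax(self.pi))])
        return survived[np.argmax(self.belonging[survived], axis=0)]


@dataclass
class FlowMatrix:
    """Probability flows f(pi^(h)(k') -> pi^(h+1)(k)) between adjacent layers."""

    source_layer: int
    target_layer: int
    flows: np.ndarray  # (K, K), [k_child, k_parent]


def consensus_init(
    model: TransitionModel,
    K: int,
    alpha_ini: float,
    n_restarts: int = 24,
    n_iter: int = 500,
    seeds: list[int] | None = None,
    base_seed: int = 0,
    tol: float = 1e-10,
) -> MDMCResult:
    """Fit at fixed alpha_ini from several random starts and keep the fit
    whose converged Q̃ is largest (ties broken by the earlier seed)."""
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    if seeds is None:
        seeds = [base_seed + i for i in range(n_restarts)]
    if len(seeds) != n_restarts:
        raise ValueError("len(seeds) must equal n_restarts")
    best: MDMCResult | None = None
    for s in seeds:
        res = run_em(model, K, alpha_ini, n_iter=n_iter, seed=s, tol=tol, track_q=False)
        if best is None or res.state.q_tilde > best.state.q_tilde:
            best = res
    return best


def run_quasi_static(
    model: TransitionModel,
    K: int,
    schedule: AnnealSchedule,
    init_state: MDMCState,
    em_steps_per_alpha: int = 1,
    snapshot_steps: set[int] | None = None,
    checkpoint_every: int | None = None,
) -> HierarchyTrace:
    """Continue the EM iteration while alpha follows the schedule.

    Fully deterministic given ``init_state``.  pi is recorded at every
    schedule step; full states are kept at ``snapshot_steps`` and (as
    replay checkpoints) every ``checkpoint_every`` steps.
    """
    state = init_state.copy()
    snapshot_steps = set() if snapshot_steps is None else set(snapshot_steps)
    steps = np.arange(schedule.t_ini, schedule.t_fin + 1)
    pis = np.empty((steps.size, K))
    pis[0] = state.pi
    snaps: dict[int, MDMCState] = {}
    checks: dict[int, MDMCState] = {schedule.t_ini: init_state.copy()}
    if schedule.t_ini in snapshot_steps:
        snaps[schedule.t_ini] = state.copy()
    for i, t in enumerate(steps[1:], start=1):
        state.alpha = schedule.alpha(int(t))
        for _ in range(em_steps_per_alpha):
            resp, pi_new, P_new = em_iteration(state, model)
            if not (np.all(np.isfinite(pi_new)) and np.all(np.isfinite(P_new))):
                raise FloatingPointError(f"non-finite state at annealing step t={t}")
            state.resp, state.pi, state.membership = resp, pi_new, P_new
        pis[i] = state.pi
        if int(t) in snapshot_steps:
            state.q_tilde = q_lower_bound(state, model)
            snaps[int(t)] = state.copy()
        if checkpoint_every and i % checkpoint_every == 0:
            checks[int(t)] = state.copy()
    return HierarchyTrace(
        schedule=schedule,
        steps=steps,
        alphas=schedule.values.copy(),
        pis=pis,
        snapshots=snaps,
        checkpoints=checks,
        survival_threshold=default_survival_threshold(K),
    )


def detect_layers(
    trace: HierarchyTrace,
    stability_threshold: float = 0.05,
    min_width: float = 0.1,
) -> list[Layer]:
    """Locate stable phases of the pi trajectory.

    The change rate d(t) = max_k |pi_t(k) - pi_{t-1}(k)| per unit log alpha
    must stay below ``stability_threshold`` — and the surviving-community
    count must stay constant — over a contiguous interval spanning at least
    ``min_width`` in log alpha to count as a layer.  (Rates per log alpha
    make the criterion independent of how many schedule steps resolve the
    same alpha range.)  Adjacent layers are separated at the geometric
    midpoint of the transition interval between them; each layer is
    evaluated at the step whose alpha is closest to the centre of its alpha
    range (clamped into the stable run).
    """
    alphas = trace.alphas
    dlog = np.diff(np.log(alphas))
    if np.any(dlog <= 0):  # constant schedule: rate undefined, use per step
        dlog = np.ones_like(dlog)
    d = np.max(np.abs(np.diff(trace.pis, axis=0)), axis=1) / dlog
    n_surv = np.array(
        [count_surviving(p, trace.survival_threshold) for p in trace.pis]
    )
    stable = (d < stability_threshold) & (n_surv[1:] == n_surv[:-1])
    runs: list[tuple[int, int]] = []  # index ranges into trace.steps (inclusive)
    i = 0
    while i < stable.size:
        if stable[i]:
            j = i
            while j + 1 < stable.size and stable[j + 1]:
                j += 1
            width = np.log(alphas[j + 1]) - np.log(alphas[i])
            if width >= min_width or (trace.schedule.alpha_fin == trace.schedule.alpha_ini):
                runs.append((i, j + 1))  # steps i .. j+1 share a stable phase
            i = j + 1
        else:
            i += 1
    if not runs:
        import warnings

        warnings.warn("no stable interval found; returning an empty layer list")
        return []
    # a noise blip can split one phase in two: merge adjacent runs whose pi
    # configurations are essentially the same state
    merged: list[tuple[int, int]] = [runs[0]]
    for s, e in runs[1:]:
        ps, pe = merged[-1]
        if (
            n_surv[s] == n_surv[pe]
            and np.max(np.abs(trace.pis[s] - trace.pis[pe])) < 0.05
        ):
            merged[-1] = (ps, e)
        else:
            merged.append((s, e))
    runs = merged
    # boundaries between consecutive layers: geometric midpoint of the
    # transition interval; outer boundaries at the schedule ends
    bounds = [float(alphas[0])]
    for (_, e0), (s1, _) in zip(runs[:-1], runs[1:]):
        bounds.append(float(np.sqrt(alphas[e0] * alphas[s1])))
    bounds.append(float(alphas[-1]))
    layers: list[Layer] = []
    for h, (s, e) in enumerate(runs, start=1):
        lo, hi = bounds[h - 1], bounds[h]
        center = 0.5 * (lo + hi)
        idx = int(np.argmin(np.abs(alphas - center)))
        idx = min(max(idx, s), e)
        pi_at = trace.pis[idx]
        layers.append(
            Layer(
                h=h,
                alpha_range=(lo, hi),
                alpha_center=center,
                t_center=int(trace.steps[idx]),
                pi=pi_at.copy(),
                n_survived=count_surviving(pi_at, trace.survival_threshold),
            )
        )
    return layers


def layer_flows(layer_h: Layer, layer_h1: Layer, p_node: np.ndarray) -> FlowMatrix:
    """Probability flow between the belongings of two adjacent layers.

    Per node, the belonging mass lost by shrinking communities is
    distributed over growing ones in proportion to their gains; the net
    community-to-community flow marginalizes the per-node flows with weight
    p(n).  Nodes with no flow contribute zero (0/0 -> 0).
    """
    if layer_h.belonging is None or layer_h1.belonging is None:
        raise ValueError("both layers need belonging snapshots")
    B0, B1 = layer_h.belonging, layer_h1.belonging
    if B0.shape != B1.shape:
        raise ValueError("layers must share the same (K, N) shape")
    p_node = np.asarray(p_node, dtype=np.float64)
    delta = B1 - B0
    gain = np.maximum(delta, 0.0)  # flow-in of community k at node n
    loss = np.maximum(-delta, 0.0)  # flow-out of community k' at node n
    out_tot = loss.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac_out = np.where(out_tot > 0, loss / out_tot, 0.0)
    flows = (frac_out * p_node) @ gain.T  # (K_child, K_parent)
    return FlowMatrix(source_layer=layer_h.h, target_layer=layer_h1.h, flows=flows)


def sankey_export(
    layers: list[Layer],
    flow_matrices: list[FlowMatrix],
    path,
    min_flow: float = 0.0,
) -> dict:
    """Serialize layers and inter-layer flows as Sankey JSON.

    Nodes carry (layer, community, pi); links carry the flow value, which
    sets the band width.  Flows at or below ``min_flow`` are omitted.
    Returns the written document.
    """
    if len(flow_matrices) != max(len(layers) - 1, 0):
        raise ValueError("need one flow matrix per adjacent layer pair")
    doc: dict = {"layers": [], "links": []}
    for layer in layers:
        doc["layers"].append(
            {
                "h": layer.h,
                "alpha_center": layer.alpha_center,
                "alpha_range": list(layer.alpha_range),
                "communities": [
                    {"k": k + 1, "pi": float(layer.pi[k])} for k in range(layer.pi.size)
                ],
            }
        )
    for fm in flow_matrices:
        K_child, K_parent = fm.flows.shape
        for kc in range(K_child):
            for kp in range(K_parent):
                v = float(fm.flows[kc, kp])
                if v > min_flow:
                    doc["links"].append(
                        {
                            "source_layer": fm.source_layer,
                            "target_layer": fm.target_layer,
                            "source_k": kc + 1,
                            "target_k": kp + 1,
                            "value": v,
                        }
                    )
    if path is not None:
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)
    return doc


def extract_hierarchy(
    model: TransitionModel,
    K: int,
    alpha_ini: float,
    alpha_fin: float,
    n_steps: int = 2000,
    n_restarts: int = 24,
    init_iters: int = 500,
    base_seed: int = 0,
    em_steps_per_alpha: int = 1,
    stability_threshold: float = 0.05,
    min_width: float = 0.1,
) -> tuple[HierarchyTrace, list[Layer], list[FlowMatrix]]:
    """Full pipeline: consensus fit at alpha_ini, one annealing pass with
    periodic replay checkpoints, layer detection, deterministic replay to
    each layer's evaluation step to capture its belongings, and flows
    between adjacent layers."""
    best = consensus_init(
        model, K, alpha_ini, n_restarts=n_restarts, n_iter=init_iters, base_seed=base_seed
    )
    schedule = make_schedule(alpha_ini, alpha_fin, t_ini=0, t_fin=n_steps)
    trace = run_quasi_static(
        model, K, schedule, best.state,
        em_steps_per_alpha=em_steps_per_alpha,
        checkpoint_every=max(1, n_steps // 50),
    )
    layers = detect_layers(
        trace, stability_threshold=stability_threshold, min_width=min_width
    )
    for layer in layers:
        st = _replay_to_step(model, schedule, trace, layer.t_center, em_steps_per_alpha)
        trace.snapshots[layer.t_center] = st
        pi, P = st.pi, st.membership
        p_node = pi @ P
        with np.errstate(divide="ignore", invalid="ignore"):
            layer.belonging = np.where(p_node > 0, pi[:, None] * P / p_node, 0.0)
        layer.membership = P
        layer.p_node = p_node
    flows = [
        layer_flows(layers[i], layers[i + 1], layers[i + 1].p_node)
        for i in range(len(layers) - 1)
    ]
    return trace, layers, flows


def _replay_to_step(
    model: TransitionModel,
    schedule: AnnealSchedule,
    trace: HierarchyTrace,
    t_target: int,
    em_steps_per_alpha: int,
) -> MDMCState:
    """Rerun the (deterministic) annealing from the nearest checkpoint at
    or before ``t_target``; returns the full state at that step."""
    starts = [t for t in trace.checkpoints if t <= t_target]
    if not starts:
        raise ValueError(f"no checkpoint at or before step {t_target}")
    t0 = max(starts)
    state = trace.checkpoints[t0].copy()
    for t in range(t0 + 1, t_target + 1):
        state.alpha = schedule.alpha(t)
        for _ in range(em_steps_per_alpha):
            resp, pi_new, P_new = em_iteration(state, model)
            state.resp, state.pi, state.membership = resp, pi_new, P_new
    state.q_tilde = q_lower_bound(state, model)
    return state
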