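"""Expression-weighted Markov chain over the signalling interactome.

A candidate niche signal performs a random walk on the interactome. The
probability of hopping from node i to an out-neighbour j is proportional to
an expression weight w_ij (by default the product E_i * E_j, so flux vanishes
through unexpressed nodes and the walk follows out-neighbour expression
share when E_i > 0). The long-run visit probabilities — the stationary
distribution pi — rank each node's likelihood of mediating sustained
niche-induced signalling; high-pi intermediates are the signalling hotspots.

Edge signs play no role here: activation vs inhibition only matters for the
downstream compatibility scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .network_io import SignalingNetwork

logger = logging.getLogger("nichespotter")

#: pluggable edge-weight functions w_ij = f(E_i, E_j)
WEIGHT_FUNCTIONS = {
    "product": lambda ei, ej: ei * ej,
    "target": lambda ei, ej: 0.0 * ei + ej,  # broadcast E_j across rows
    "min": np.minimum,
}

DEFAULT_DAMPING = 0.01


class ConvergenceError(RuntimeError):
    """Power iteration failed to reach the requested tolerance."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


@dataclass
class TransitionMatrix:
    """Row-stochastic per-sample state transition matrix P over network nodes."""

    node_order: list[str]
    P: np.ndarray
    sample_id: str = ""

    @property
    def n(self) -> int:
        return len(self.node_order)

    def validate(self, tol: float = 1e-10) -> None:
        if not np.allclose(self.P.sum(axis=1), 1.0, atol=tol, rtol=0):
            raise ValueError("transition matrix rows do not sum to 1")
        if (self.P < 0).any() or (self.P > 1).any():
            raise ValueError("transition probabilities outside [0, 1]")


@dataclass
class StationaryDistribution:
    """Stationary probability vector pi with convergence metadata."""

    node_order: list[str]
    pi: np.ndarray
    sample_id: str = ""
    method: str = ""
    iterations: int = 0
    residual: float = 0.0
    dispersion: np.ndarray | None = None  # per-node std across samples, if aggregated

    def as_series(self) -> pd.Series:
        return pd.Series(self.pi, index=self.node_order, name="pi")

    def as_mapping(self) -> dict[str, float]:
        return dict(zip(self.node_order, self.pi.tolist()))


def build_transition_matrix(
    network: SignalingNetwork,
    expression: Mapping[str, float] | pd.Series,
    sample_id: str = "",
    weight: str = "product",
) -> TransitionMatrix:
    """Build the per-sample transition matrix P from one expression vector.

    For node i with out-neighbours N(i), the unnormalised weight of edge
    i -> j is w_ij = f(E_i, E_j); rows are normalised to probabilities.
    Rows with zero total weight — dangling nodes and zero-expression hubs —
    jump uniformly to all nodes (the standard dangling-node convention):
    a self-loop would make every transiently unexpressed node absorbing,
    so that in single-cell data the aggregated pi would track dropout
    patterns rather than signalling flux. Expression missing for a node is
    treated as 0.
    """
    if weight not in WEIGHT_FUNCTIONS:
        raise ValueError(f"unknown weight function {weight!r}")
    nodes = network.nodes
    n = len(nodes)
    idx = {node: i for i, node in enumerate(nodes)}
    e = np.zeros(n)
    for node in nodes:
        val = expression.get(node, 0.0) if hasattr(expression, "get") else expression[node]
        e[idx[node]] = float(val)
    if (e < 0).any():
        raise ValueError("expression values must be non-negative")
    if not (e > 0).any():
        raise ValueError("no expressed nodes: all-zero expression vector")

    adj = np.zeros((n, n), dtype=bool)
    for u, v in network.graph.edges:
        adj[idx[u], idx[v]] = True
    W = WEIGHT_FUNCTIONS[weight](e[:, None], e[None, :]) * adj
    row_sums = W.sum(axis=1)
    P = np.zeros((n, n))
    pos = row_sums > 0
    P[pos] = W[pos] / row_sums[pos, None]
    # dangling / zero-weight rows: uniform jump
    P[~pos] = 1.0 / n
    return TransitionMatrix(node_order=nodes, P=P, sample_id=sample_id)


def _damped(P: np.ndarray, damping: float) -> np.ndarray:
    """Uniform teleportation P' = (1 - beta) P + beta J / n, ensuring a unique pi."""
    n = P.shape[0]
    if damping == 0.0:
        return P
    return (1.0 - damping) * P + damping / n


def stationary_distribution(
    tm: TransitionMatrix,
    method: str = "power",
    damping: float = DEFAULT_DAMPING,
    tol: float = 1e-10,
    max_iter: int = 100_000,
    seed: int = 0,
    mc_steps: int = 1_000_000,
) -> StationaryDistribution:
    """Compute the stationary distribution pi of the (damped) chain.

    Methods: ``power`` iterates x <- x P' from a uniform start until the L1
    change drops below ``tol``; ``linear_solve`` solves pi P' = pi with
    sum(pi) = 1 directly; ``monte_carlo`` counts visit frequencies of a
    seeded simulated walk with teleport restarts (``mc_steps`` steps).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if not 0.0 <= damping <= 1.0:
        raise ValueError("damping must lie in [0, 1]")
    n = tm.n
    Pd = _damped(tm.P, damping)

    if method == "power":
        x = np.full(n, 1.0 / n)
        for it in range(1, max_iter + 1):
            x_new = x @ Pd
            delta = float(np.abs(x_new - x).sum())
            x = x_new
            if delta < tol:
                break
        else:
            raise ConvergenceError(
                f"power iteration did not converge in {max_iter} iterations "
                f"(last residual {delta:.3e})",
                residual=delta,
            )
        pi, iters = x / x.sum(), it
    elif method == "linear_solve":
        # pi (P' - I) = 0 with the normalisation constraint replacing one equation
        A = Pd.T - np.eye(n)
        A[-1, :] = 1.0
        b = np.zeros(n)
        b[-1] = 1.0
        pi = np.linalg.solve(A, b)
        pi = np.clip(pi, 0.0, None)
        pi = pi / pi.sum()
        iters = 1
    elif method == "monte_carlo":
        rng = np.random.default_rng(seed)
        cum = np.cumsum(Pd, axis=1)
        counts = np.zeros(n, dtype=np.int64)
        state = int(rng.integers(n))
        chunk = 65_536
        done = 0
        while done < mc_steps:
            m = min(chunk, mc_steps - done)
            draws = rng.random(m)
            for r in draws:
                state = int(np.searchsorted(cum[state], r, side="right"))
                if state >= n:  # guard against cum[-1] < r by rounding
                    state = n - 1
                counts[state] += 1
            done += m
        pi, iters = counts / counts.sum(), mc_steps
    else:
        raise ValueError(f"unknown method {method!r}")

    residual = float(np.abs(pi @ Pd - pi).sum())
    return StationaryDistribution(
        node_order=tm.node_order,
        pi=pi,
        sample_id=tm.sample_id,
        method=method,
        iterations=iters,
        residual=residual,
    )


def condition_pi(
    pis: Sequence[StationaryDistribution], aggregation: str = "mean"
) -> StationaryDistribution:
    """Aggregate per-sample stationary distributions to one condition-level pi.

    Element-wise mean (or median) renormalised to sum 1; the per-node std
    across samples is kept for the single-cell heterogeneity report.
    """
    if not pis:
        raise ValueError("need at least one per-sample distribution")
    order = pis[0].node_order
    for p in pis[1:]:
        if p.node_order != order:
            raise ValueError("mismatched node orders across samples")
    M = np.vstack([p.pi for p in pis])
    if aggregation == "mean":
        agg = M.mean(axis=0)
    elif aggregation == "median":
        agg = np.median(M, axis=0)
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    agg = agg / agg.sum()
    return StationaryDistribution(
        node_order=list(order),
        pi=agg,
        sample_id=f"aggregate[{len(pis)}]",
        method=f"{aggregation} of {len(pis)} sample(s)",
        dispersion=M.std(axis=0),
    )


def select_hotspots(
    network: SignalingNetwork,
    stationary: StationaryDistribution,
    percentile: float = 90.0,
) -> pd.DataFrame:
    """Rank intermediate-layer nodes whose pi reaches the given percentile.

    Only intermediates are hotspot candidates — receptors and TFs are ranked
    separately by the caller. All nodes tied at the threshold are included;
    ordering is deterministic by (-pi, node id).
    """
    if not 0.0 < percentile < 100.0:
        raise ValueError("percentile must lie in (0, 100)")
    pi = stationary.as_series()
    inter = [n for n in stationary.node_order if network.layer.get(n) == "intermediate"]
    if not inter:
        logger.warning("no intermediate-layer nodes; hotspot set is empty")
        return pd.DataFrame(columns=["node", "layer", "pi", "rank"])
    values = pi.loc[inter]
    thr = float(np.percentile(values.to_numpy(), percentile))
    hits = sorted(
        ((node, float(values[node])) for node in inter if values[node] >= thr),
        key=lambda t: (-t[1], t[0]),
    )
    return pd.DataFrame(
        {
            "node": [n for n, _ in hits],
            "layer": "intermediate",
            "pi": [v for _, v in hits],
            "rank": np.arange(1, len(hits) + 1),
        }
    )


def pi_table(network: SignalingNetwork, stationary: StationaryDistribution) -> pd.DataFrame:
    """Full per-node pi table (node, layer, pi) sorted by descending pi."""
    df = pd.DataFrame(
        {
            "node": stationary.node_order,
            "layer": [network.layer.get(n, "?") for n in stationary.node_order],
            "pi": stationary.pi,
        }
    )
    if stationary.dispersion is not None:
        df["pi_std"] = stationary.dispersion
    return df.sort_values(["pi", "node"], ascending=[False, True], ignore_index=True)
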