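"""Compatibility of signalling hotspots with a differential-TF signature.

A hotspot node explains a TF's differential expression if the signal it
relays reaches the TF with the right net effect: every directed shortest
path from the node to the TF carries a sign (the product of its edge signs,
activation +1 / inhibition -1) and a relative contribution Omega derived
from the stationary probabilities of the nodes it traverses. The
compatibility score of a (node, TF) pair is the Omega-weighted fraction of
shortest paths whose net sign matches the TF's direction — interpretable as
the probability that the node activates (direction up) or represses
(direction down) the TF. Averaging over the differential-TF set and
thresholding at 0.5 classifies each node as active or inactive in the
condition of interest.

Signature TFs that are absent from the interactome are scored through
interactome TFs that regulate them via exactly one GRN edge; the GRN edge
sign multiplies the path sign.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .network_io import (
    ExpressionMatrix,
    GeneRegulatoryNetwork,
    SignalingNetwork,
    TFSignature,
    align_expression,
)
from .markov_core import (
    StationaryDistribution,
    build_transition_matrix,
    condition_pi,
    pi_table,
    select_hotspots,
    stationary_distribution,
)

logger = logging.getLogger("nichespotter")

DEFAULT_MAX_PATHS = 10_000
DEFAULT_ACTIVITY_THRESHOLD = 0.5

OMEGA_VARIANTS = ("geometric", "product", "mean")


@dataclass
class SignedPath:
    """One directed shortest path with its net sign and relative contribution."""

    nodes: tuple[str, ...]
    sign: int | None = None
    omega: float | None = None

    def __len__(self) -> int:
        return len(self.nodes) - 1  # hop count


def enumerate_shortest_paths(
    network: SignalingNetwork,
    source: str,
    target: str,
    max_paths: int = DEFAULT_MAX_PATHS,
) -> list[SignedPath]:
    """All directed shortest (minimum-hop) paths from source to target.

    BFS assigns distance labels from the source; paths are then enumerated
    backwards from the target over the shortest-path DAG (predecessors whose
    distance is exactly one less). An unreachable target yields an empty
    list. Enumeration is truncated at ``max_paths`` with a warning; the
    returned list is sorted canonically by node sequence.
    """
    if source == target:
        raise ValueError("source and target must differ")
    g = network.graph
    if source not in g or target not in g:
        raise KeyError(f"node not in network: {source if source not in g else target!r}")

    dist = {source: 0}
    frontier = [source]
    while frontier and target not in dist:
        nxt = []
        for u in frontier:
            for v in g.successors(u):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    if target not in dist:
        return []

    paths: list[tuple[str, ...]] = []
    truncated = False

    def backtrack(node: str, suffix: tuple[str, ...]) -> None:
        nonlocal truncated
        if truncated:
            return
        if node == source:
            paths.append((source,) + suffix)
            if len(paths) >= max_paths:
                truncated = True
            return
        for u in g.predecessors(node):
            if dist.get(u) == dist[node] - 1:
                backtrack(u, (node,) + suffix)

    backtrack(target, ())
    if truncated:
        logger.warning(
            "shortest-path enumeration for %s->%s truncated at %d paths",
            source,
            target,
            max_paths,
        )
    return [SignedPath(nodes=p) for p in sorted(paths)]


def path_sign(path: SignedPath, network: SignalingNetwork) -> int:
    """Net regulatory effect: the product of edge signs along the path."""
    s = 1
    for u, v in zip(path.nodes, path.nodes[1:]):
        s *= network.sign(u, v)
    return s


def path_omega(
    paths: Sequence[SignedPath],
    pi: Mapping[str, float],
    variant: str = "geometric",
) -> list[SignedPath]:
    """Assign each path its relative contribution Omega from stationary probabilities.

    The raw weight of a path is the geometric mean of pi over its interior
    nodes (source and target excluded; direct edges get raw weight 1), then
    weights are normalised to sum 1 within the (source, target) pair. The
    geometric mean does not penalise longer paths among equal-length shortest
    paths and is stable under rescaling; ``product`` and arithmetic ``mean``
    variants are available.
    """
    if variant not in OMEGA_VARIANTS:
        raise ValueError(f"unknown omega variant {variant!r}")
    if not paths:
        raise ValueError("need at least one path")
    raws = []
    for p in paths:
        interior = p.nodes[1:-1]
        if not interior:
            raws.append(1.0)
            continue
        vals = [float(pi[n]) for n in interior]
        if variant == "geometric":
            raws.append(math.prod(vals) ** (1.0 / len(vals)))
        elif variant == "product":
            raws.append(math.prod(vals))
        else:
            raws.append(sum(vals) / len(vals))
    total = sum(raws)
    if total == 0.0:
        logger.warning("all path weights are zero; using uniform Omega")
        raws = [1.0] * len(paths)
        total = float(len(paths))
    return [
        SignedPath(nodes=p.nodes, sign=p.sign, omega=r / total)
        for p, r in zip(paths, raws)
    ]


@dataclass
class PairScore:
    node: str
    tf: str
    score: float
    n_paths: int
    n_compatible: int


def _activation_mass(
    network: SignalingNetwork,
    source: str,
    target: str,
    pi: Mapping[str, float],
    extra_sign: int = 1,
    max_paths: int = DEFAULT_MAX_PATHS,
    omega_variant: str = "geometric",
) -> tuple[float, int, int] | None:
    """Omega mass of net-activating paths source -> target, or None if no path.

    Returns (activating mass, n paths, n activating paths); ``extra_sign``
    multiplies each path sign (used for the GRN edge onto an off-network TF).
    """
    paths = enumerate_shortest_paths(network, source, target, max_paths=max_paths)
    if not paths:
        return None
    for p in paths:
        p.sign = path_sign(p, network) * extra_sign
    paths = path_omega(paths, pi, variant=omega_variant)
    plus_mass = sum(p.omega for p in paths if p.sign > 0)
    n_plus = sum(1 for p in paths if p.sign > 0)
    return plus_mass, len(paths), n_plus


def pair_compatibility(
    node: str,
    tf: str,
    direction: int,
    network: SignalingNetwork,
    pi: Mapping[str, float] | StationaryDistribution,
    grn: GeneRegulatoryNetwork | None = None,
    max_paths: int = DEFAULT_MAX_PATHS,
    omega_variant: str = "geometric",
) -> PairScore | None:
    """Compatibility score of one (signalling node, TF) pair, or None if no path.

    A shortest path is compatible iff its net sign matches the TF direction
    (+1 with up, -1 with down); the score is the Omega mass of compatible
    paths. The two sign classes partition the path set, so
    score(up) + score(down) = 1 exactly for any reachable pair.
    """
    if isinstance(pi, StationaryDistribution):
        pi = pi.as_mapping()
    if tf in network.graph:
        masses = [
            _activation_mass(
                network, node, tf, pi, 1, max_paths=max_paths, omega_variant=omega_variant
            )
        ]
    elif grn is not None:
        masses = [
            _activation_mass(
                network, node, reg, pi, gsign,
                max_paths=max_paths, omega_variant=omega_variant,
            )
            for reg, gsign in grn.regulators_of(tf)
            if reg in network.graph
        ]
    else:
        return None
    masses = [m for m in masses if m is not None]
    if not masses:
        return None
    # per-route scores averaged; for an in-network TF there is a single route
    scores, n_paths, n_compat = [], 0, 0
    for plus_mass, n_p, n_plus in masses:
        scores.append(plus_mass if direction > 0 else 1.0 - plus_mass)
        n_paths += n_p
        n_compat += n_plus if direction > 0 else n_p - n_plus
    return PairScore(
        node=node,
        tf=tf,
        score=float(np.mean(scores)),
        n_paths=n_paths,
        n_compatible=n_compat,
    )


@dataclass
class NodeScore:
    node: str
    mean_score: float  # NaN when no signature TF is reachable
    n_tfs_used: int
    call: str  # active / inactive / indeterminate / unreachable
    pair_scores: list[PairScore] = field(default_factory=list)


def node_compatibility(
    node: str,
    signature: TFSignature,
    network: SignalingNetwork,
    pi: Mapping[str, float] | StationaryDistribution,
    grn: GeneRegulatoryNetwork | None = None,
    threshold: float = DEFAULT_ACTIVITY_THRESHOLD,
    max_paths: int = DEFAULT_MAX_PATHS,
    omega_variant: str = "geometric",
) -> NodeScore:
    """Average compatibility of a node over the differential-TF signature.

    Unreachable TFs are excluded from the average rather than scored 0 —
    no path means no evidence, not contradiction. The activity call is
    active above the threshold, inactive below, indeterminate at a tie,
    and unreachable when no signature TF has a path.
    """
    pairs: list[PairScore] = []
    n_dropped = 0
    for tf, direction in signature.entries:
        ps = pair_compatibility(
            node, tf, direction, network, pi, grn,
            max_paths=max_paths, omega_variant=omega_variant,
        )
        if ps is None:
            n_dropped += 1
        else:
            pairs.append(ps)
    if n_dropped:
        logger.info("node %s: %d unreachable signature TF(s) dropped", node, n_dropped)
    if not pairs:
        return NodeScore(node=node, mean_score=float("nan"), n_tfs_used=0, call="unreachable")
    mean = float(np.mean([p.score for p in pairs]))
    if mean > threshold:
        call = "active"
    elif mean < threshold:
        call = "inactive"
    else:
        call = "indeterminate"
    return NodeScore(node=node, mean_score=mean, n_tfs_used=len(pairs), call=call, pair_scores=pairs)


def compatibility_table(
    nodes: Sequence[str],
    signature: TFSignature,
    network: SignalingNetwork,
    pi: Mapping[str, float] | StationaryDistribution,
    grn: GeneRegulatoryNetwork | None = None,
    condition: str = "",
    **kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pair-level and node-level compatibility tables for a set of nodes."""
    pair_rows, node_rows = [], []
    for node in nodes:
        ns = node_compatibility(node, signature, network, pi, grn, **kwargs)
        node_rows.append(
            {
                "node": node,
                "mean_score": ns.mean_score,
                "n_tfs_used": ns.n_tfs_used,
                "call": ns.call,
                "condition": condition,
            }
        )
        for p in ns.pair_scores:
            pair_rows.append(
                {
                    "node": p.node,
                    "tf": p.tf,
                    "score": p.score,
                    "n_paths": p.n_paths,
                    "n_compatible": p.n_compatible,
                    "condition": condition,
                }
            )
    pair_cols = ["node", "tf", "score", "n_paths", "n_compatible", "condition"]
    node_cols = ["node", "mean_score", "n_tfs_used", "call", "condition"]
    return (
        pd.DataFrame(pair_rows, columns=pair_cols),
        pd.DataFrame(node_rows, columns=node_cols),
    )


@dataclass
class ConditionResult:
    """Per-condition pipeline products."""

    condition: str
    sample_pis: list[StationaryDistribution]
    pi: StationaryDistribution
    hotspots: pd.DataFrame
    pi_table: pd.DataFrame
    pairs: pd.DataFrame
    nodes: pd.DataFrame


@dataclass
class ConditionComparison:
    a: ConditionResult
    b: ConditionResult
    diff: pd.DataFrame  # per-node score_a, score_b, score_diff


def _condition_stationary(
    expr: ExpressionMatrix,
    network: SignalingNetwork,
    *,
    weight: str,
    method: str,
    damping: float,
    tol: float,
    max_iter: int,
    seed: int,
    aggregation: str,
) -> tuple[list[StationaryDistribution], StationaryDistribution]:
    aligned = align_expression(network, expr)
    pis = []
    for i, sample in enumerate(aligned.columns):
        tm = build_transition_matrix(network, aligned[sample], sample_id=str(sample), weight=weight)
        pis.append(
            stationary_distribution(
                tm, method=method, damping=damping, tol=tol,
                max_iter=max_iter, seed=seed + i,
            )
        )
    return pis, condition_pi(pis, aggregation=aggregation)


def compare_conditions(
    expr_a: ExpressionMatrix,
    expr_b: ExpressionMatrix,
    network: SignalingNetwork,
    signature: TFSignature,
    grn: GeneRegulatoryNetwork | None = None,
    *,
    weight: str = "product",
    method: str = "linear_solve",
    damping: float = 0.01,
    tol: float = 1e-10,
    max_iter: int = 100_000,
    seed: int = 0,
    aggregation: str = "mean",
    percentile: float = 90.0,
    omega_variant: str = "geometric",
    threshold: float = DEFAULT_ACTIVITY_THRESHOLD,
    max_paths: int = DEFAULT_MAX_PATHS,
) -> ConditionComparison:
    """Run the full two-condition pipeline and return paired reports.

    Per condition: per-sample transition matrices -> per-sample pi ->
    aggregated condition pi -> hotspot selection -> compatibility scoring.
    The signature directions describe condition A relative to B, so they are
    flipped for condition B. Both conditions' hotspot sets are pooled and
    every pooled node is scored under each condition's own pi, giving a
    joint table of score differences.
    """
    results = {}
    for label, expr, sig in (
        ("A", expr_a, signature),
        ("B", expr_b, signature.flipped()),
    ):
        cond = expr.condition or label
        sample_pis, cpi = _condition_stationary(
            expr, network,
            weight=weight, method=method, damping=damping, tol=tol,
            max_iter=max_iter, seed=seed, aggregation=aggregation,
        )
        hotspots = select_hotspots(network, cpi, percentile=percentile)
        results[label] = dict(
            condition=cond, sample_pis=sample_pis, pi=cpi, hotspots=hotspots, sig=sig
        )

    scored_nodes = sorted(
        set(results["A"]["hotspots"]["node"]) | set(results["B"]["hotspots"]["node"])
    )
    if not scored_nodes:
        logger.warning("empty hotspot set in both conditions; reports are empty")

    finished: dict[str, ConditionResult] = {}
    for label, r in results.items():
        pairs, nodes = compatibility_table(
            scored_nodes, r["sig"], network, r["pi"], grn,
            condition=r["condition"], threshold=threshold,
            max_paths=max_paths, omega_variant=omega_variant,
        )
        finished[label] = ConditionResult(
            condition=r["condition"],
            sample_pis=r["sample_pis"],
            pi=r["pi"],
            hotspots=r["hotspots"],
            pi_table=pi_table(network, r["pi"]),
            pairs=pairs,
            nodes=nodes,
        )

    na, nb = finished["A"].nodes, finished["B"].nodes
    diff = pd.merge(
        na[["node", "mean_score", "call"]].rename(
            columns={"mean_score": "score_a", "call": "call_a"}
        ),
        nb[["node", "mean_score", "call"]].rename(
            columns={"mean_score": "score_b", "call": "call_b"}
        ),
        on="node",
        how="outer",
    )
    diff["score_diff"] = diff["score_a"] - diff["score_b"]
    return ConditionComparison(a=finished["A"], b=finished["B"], diff=diff)
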