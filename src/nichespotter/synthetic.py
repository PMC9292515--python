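"""Synthetic layered interactomes with planted signalling cascades.

Generates everything the pipeline consumes — a signed layered interactome,
a small GRN layer, two-condition expression (bulk or single-cell with
dropout) and a differential-TF signature — together with a ground truth:

* a planted *driver* cascade receptor -> ... -> TF whose edges are all
  activating and whose TF is up in condition A, so the driver intermediate
  should be called active;
* a planted *decoy* cascade that is equally highly expressed in condition A
  but whose final edge is inhibitory while its TF is up — its paths
  contradict the signature by construction, so the decoy intermediate
  should be called inactive;
* one GRN-only TF regulated by the planted TF, exercising the one-edge
  GRN scoring route.

Condition A expresses both cascades at ``fold_change`` times baseline;
condition B expresses everything at baseline. Everything is reproducible
from the seed (numpy PCG64).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .network_io import (
    ExpressionMatrix,
    GeneRegulatoryNetwork,
    SignalingNetwork,
    TFSignature,
    write_expression_mtx,
    write_expression_tsv,
    write_grn,
    write_interactome,
    write_node_layers,
    write_tf_signature,
)

import networkx as nx

GRN_TF = "TFG01"  # signature TF living only in the GRN layer


@dataclass
class SyntheticScenario:
    network: SignalingNetwork
    grn: GeneRegulatoryNetwork
    expression: dict[str, ExpressionMatrix]  # condition label -> matrix
    signature: TFSignature
    truth: dict
    seed: int
    params: dict = field(default_factory=dict)


def _layer_sizes(n_nodes: int, n_layers: int) -> list[int]:
    """Node counts per layer: receptors, intermediate layer(s), TFs."""
    n_receptors = max(2, n_nodes // 6)
    n_tfs = max(3, n_nodes // 6)
    n_inter = n_nodes - n_receptors - n_tfs
    n_inter_layers = n_layers - 2
    if n_inter < n_inter_layers:
        raise ValueError("impossible topology: too few nodes for the requested layers")
    base, extra = divmod(n_inter, n_inter_layers)
    sizes = [n_receptors] + [base + (1 if i < extra else 0) for i in range(n_inter_layers)]
    return sizes + [n_tfs]


def generate_scenario(
    n_nodes: int = 60,
    n_layers: int = 4,
    edge_density: float = 0.3,
    n_cells: int = 100,
    dropout: float = 0.3,
    noise_cv: float = 0.2,
    seed: int = 0,
    fold_change: float = 10.0,
    baseline_mean: float = 5.0,
    assay: str = "single_cell",
) -> SyntheticScenario:
    """Generate a reproducible two-condition scenario with planted truth.

    The interactome is a strictly layered DAG (edges only between
    consecutive layers); every node is on at least one receptor -> TF
    route, extra edges are added with probability ``edge_density``, and
    edge signs are random except along the planted cascades. Bulk assay:
    mean-preserving log-normal values around the condition means
    (``noise_cv`` is the coefficient of variation). Single-cell assay:
    Poisson counts with log-normal rate heterogeneity, thinned by Bernoulli
    dropout.
    """
    if n_nodes < 6:
        raise ValueError("need at least 6 nodes")
    if n_layers < 3:
        raise ValueError("need at least 3 layers (receptor, intermediate, tf)")
    if not 0.0 <= dropout < 1.0:
        raise ValueError("dropout must lie in [0, 1)")
    if assay not in ("bulk", "single_cell"):
        raise ValueError(f"unknown assay {assay!r}")
    rng = np.random.default_rng(seed)

    sizes = _layer_sizes(n_nodes, n_layers)
    layers: list[list[str]] = []
    layers.append([f"R{i:02d}" for i in range(sizes[0])])
    for k, sz in enumerate(sizes[1:-1], start=1):
        layers.append([f"S{k}_{i:02d}" for i in range(sz)])
    layers.append([f"TF{i:02d}" for i in range(sizes[-1])])

    # planted cascade and decoy: one node per layer, disjoint
    cascade = [layers[k][int(rng.integers(len(layers[k])))] for k in range(len(layers))]
    decoy = []
    for k in range(len(layers)):
        choices = [n for n in layers[k] if n != cascade[k]]
        decoy.append(choices[int(rng.integers(len(choices)))])
    driver, planted_tf = cascade[-2], cascade[-1]
    decoy_node, decoy_tf = decoy[-2], decoy[-1]

    edge_sign: dict[tuple[str, str], int] = {}

    def add(u: str, v: str, sign: int) -> None:
        edge_sign[(u, v)] = sign

    for k in range(len(layers) - 1):
        src_layer, tgt_layer = layers[k], layers[k + 1]
        # backbone: every target has a parent, every source has a child
        for v in tgt_layer:
            u = src_layer[int(rng.integers(len(src_layer)))]
            add(u, v, 1 if rng.random() < 0.5 else -1)
        for u in src_layer:
            v = tgt_layer[int(rng.integers(len(tgt_layer)))]
            if (u, v) not in edge_sign:
                add(u, v, 1 if rng.random() < 0.5 else -1)
        for u in src_layer:
            for v in tgt_layer:
                if (u, v) not in edge_sign and rng.random() < edge_density:
                    add(u, v, 1 if rng.random() < 0.5 else -1)

    # plant the cascades: driver cascade all-activating; decoy cascade
    # activating except an inhibitory final edge into its up-regulated TF
    for u, v in zip(cascade, cascade[1:]):
        add(u, v, 1)
    for u, v in zip(decoy, decoy[1:]):
        add(u, v, 1)
    add(decoy[-2], decoy[-1], -1)
    # the planted truth requires these cross edges to be absent
    edge_sign.pop((driver, decoy_tf), None)
    edge_sign.pop((decoy_node, planted_tf), None)

    graph = nx.DiGraph()
    for (u, v), s in edge_sign.items():
        graph.add_edge(u, v, sign=s)
    layer_of = {}
    for n in layers[0]:
        layer_of[n] = "receptor"
    for lay in layers[1:-1]:
        for n in lay:
            layer_of[n] = "intermediate"
    for n in layers[-1]:
        layer_of[n] = "tf"
    # drop isolated nodes (possible only if a layer node got no edge; backbone prevents it)
    network = SignalingNetwork(graph=graph, layer={n: layer_of[n] for n in graph.nodes})
    network.validate()

    grn = GeneRegulatoryNetwork(edges=[(planted_tf, GRN_TF, 1)])

    signature = TFSignature({planted_tf: 1, decoy_tf: 1, GRN_TF: 1})

    genes = sorted(graph.nodes) + [GRN_TF]
    high = set(cascade) | set(decoy)
    means_a = np.array(
        [baseline_mean * (fold_change if g in high or g == GRN_TF else 1.0) for g in genes]
    )
    means_b = np.full(len(genes), baseline_mean)

    def draw(means: np.ndarray, label: str) -> ExpressionMatrix:
        cols = [f"cell{i:03d}" for i in range(n_cells)]
        if noise_cv > 0:
            sigma = np.sqrt(np.log1p(noise_cv**2))
            factors = rng.lognormal(-(sigma**2) / 2.0, sigma, size=(len(genes), n_cells))
        else:
            factors = np.ones((len(genes), n_cells))
        rates = means[:, None] * factors
        if assay == "bulk":
            values = rates
        else:
            values = rng.poisson(rates).astype(float)
            if dropout > 0:
                keep = rng.random(values.shape) >= dropout
                values = values * keep
        df = pd.DataFrame(values, index=genes, columns=cols)
        return ExpressionMatrix(values=df, condition=label)

    expr_a = draw(means_a, "A")
    expr_b = draw(means_b, "B")

    truth = {
        "driver": driver,
        "driver_call": "active",
        "decoy": decoy_node,
        "decoy_call": "inactive",
        "cascade": cascade,
        "decoy_cascade": decoy,
        "planted_tf": planted_tf,
        "decoy_tf": decoy_tf,
        "grn_tf": GRN_TF,
    }
    params = dict(
        n_nodes=n_nodes, n_layers=n_layers, edge_density=edge_density,
        n_cells=n_cells, dropout=dropout, noise_cv=noise_cv,
        fold_change=fold_change, baseline_mean=baseline_mean, assay=assay,
        rng="PCG64",
    )
    return SyntheticScenario(
        network=network, grn=grn, expression={"A": expr_a, "B": expr_b},
        signature=signature, truth=truth, seed=seed, params=params,
    )


def write_scenario(scenario: SyntheticScenario, directory: str | Path) -> dict[str, Path]:
    """Write a scenario in the exact dialects the loaders read.

    Emits interactome + node layers, GRN, per-condition expression (TSV
    always; additionally MatrixMarket triplets in single-cell mode), the
    signature, and a truth/metadata JSON. Returns the path of each artifact.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["interactome"] = d / "interactome.tsv"
    write_interactome(scenario.network, paths["interactome"])
    paths["layers"] = d / "node_layers.tsv"
    write_node_layers(scenario.network, paths["layers"])
    paths["grn"] = d / "grn.tsv"
    write_grn(scenario.grn, paths["grn"])
    for label, expr in scenario.expression.items():
        key = f"expression_{label}"
        paths[key] = d / f"expression_{label}.tsv"
        write_expression_tsv(expr, paths[key])
        if scenario.params.get("assay") == "single_cell":
            mtx_dir = d / f"expression_{label}_mtx"
            write_expression_mtx(expr, mtx_dir)
            paths[f"{key}_mtx"] = mtx_dir
    paths["signature"] = d / "signature.tsv"
    write_tf_signature(scenario.signature, paths["signature"])
    paths["truth"] = d / "truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump(
            {"seed": scenario.seed, "params": scenario.params, "truth": scenario.truth},
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    return paths
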