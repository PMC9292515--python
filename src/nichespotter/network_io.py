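"""I/O and validation for signalling interactomes, expression matrices and TF signatures.

The interactome is a signed directed graph: nodes are signalling molecules
(gene symbols), an edge ``u -> v`` with sign +1 means u activates v, sign -1
means u inhibits v. Each node carries a layer label — ``receptor`` (niche
input), ``intermediate`` (kinases, phosphatases, adaptors, ...) or ``tf``
(transcription factor, the terminal layer). An optional gene regulatory
network (GRN) adds signed TF -> TF edges for signature TFs that have no
direct interactome connection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger("nichespotter")

ACTIVATION = 1
INHIBITION = -1

#: recognised sign tokens in interactome / GRN tables
SIGN_TOKENS = {
    "+": ACTIVATION,
    "1": ACTIVATION,
    "+1": ACTIVATION,
    "activation": ACTIVATION,
    "-": INHIBITION,
    "-1": INHIBITION,
    "inhibition": INHIBITION,
}

#: recognised TF-signature direction tokens (+1 = up in condition A vs B)
DIRECTION_TOKENS = {"up": 1, "+1": 1, "down": -1, "-1": -1}

LAYERS = ("receptor", "intermediate", "tf")


class NetworkValidationError(ValueError):
    """Raised when an input table violates a structural contract."""


@dataclass
class SignalingNetwork:
    """Signed directed signalling network with per-node layer labels.

    Backed by a :class:`networkx.DiGraph` whose edges carry a ``sign``
    attribute in {+1, -1}.
    """

    graph: nx.DiGraph
    layer: dict[str, str]

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, int]]:
        return sorted((u, v, d["sign"]) for u, v, d in self.graph.edges(data=True))

    def sign(self, u: str, v: str) -> int:
        return self.graph.edges[u, v]["sign"]

    def nodes_in_layer(self, layer: str) -> list[str]:
        return sorted(n for n, l in self.layer.items() if l == layer)

    def validate(self) -> None:
        for u, v, d in self.graph.edges(data=True):
            if d.get("sign") not in (ACTIVATION, INHIBITION):
                raise NetworkValidationError(f"edge {u}->{v} has invalid sign {d.get('sign')!r}")
        missing = set(self.graph.nodes) - set(self.layer)
        if missing:
            raise NetworkValidationError(f"nodes without layer label: {sorted(missing)[:5]}")
        bad = set(self.layer.values()) - set(LAYERS)
        if bad:
            raise NetworkValidationError(f"unknown layer labels: {sorted(bad)}")
        for n, l in self.layer.items():
            if l == "tf" and self.graph.in_degree(n) == 0:
                raise NetworkValidationError(f"tf node {n!r} has no incoming edge")


@dataclass
class GeneRegulatoryNetwork:
    """Signed TF -> TF edges linking interactome-terminal TFs to signature TFs."""

    edges: list[tuple[str, str, int]] = field(default_factory=list)

    def regulators_of(self, tf: str) -> list[tuple[str, int]]:
        """(regulator, sign) pairs with a direct GRN edge onto ``tf``."""
        return sorted((r, s) for r, t, s in self.edges if t == tf)


@dataclass
class ExpressionMatrix:
    """Genes x samples non-negative expression matrix for one condition."""

    values: pd.DataFrame  # genes in rows, samples in columns
    condition: str = ""

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class TFSignature:
    """Differential-TF signature: direction (+1 up / -1 down) of each TF in
    condition A relative to condition B. Magnitudes are deliberately not kept."""

    directions: dict[str, int]

    @property
    def entries(self) -> list[tuple[str, int]]:
        return sorted(self.directions.items())

    @property
    def tfs(self) -> list[str]:
        return sorted(self.directions)

    def flipped(self) -> "TFSignature":
        """The same signature seen from condition B (all directions reversed)."""
        return TFSignature({tf: -d for tf, d in self.directions.items()})


# ---------------------------------------------------------------------------
# parsing helpers


def parse_sign(token: str, line_no: int | None = None) -> int:
    tok = token.strip().lower()
    if tok not in SIGN_TOKENS:
        where = f" at line {line_no}" if line_no is not None else ""
        raise NetworkValidationError(f"unknown sign token {token!r}{where}")
    return SIGN_TOKENS[tok]


def _read_edge_rows(path: str | Path, dialect: str) -> list[tuple[int, list[str]]]:
    path = Path(path)
    if dialect not in ("sif", "tsv3col"):
        raise ValueError(f"unknown dialect {dialect!r}")
    rows: list[tuple[int, list[str]]] = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split() if dialect == "sif" else line.split("\t")
            if dialect == "tsv3col" and i == 1:
                # header row
                continue
            if len(fields) < 3:
                raise NetworkValidationError(
                    f"{path.name}: line {i} has {len(fields)} fields, expected >= 3"
                )
            rows.append((i, fields))
    return rows


def load_interactome(
    path: str | Path,
    dialect: str = "tsv3col",
    tf_catalogue: str | Path | Iterable[str] | None = None,
    layer_file: str | Path | None = None,
) -> SignalingNetwork:
    """Read a signed interactome from a SIF or 3/4-column TSV file.

    Duplicate edges with the same sign are collapsed silently; contradictory
    duplicates keep the inhibitory sign (conservative for compatibility
    scoring) with a logged warning. Layers come from, in order of precedence:
    the optional 4th column (labels the *target* node of each row), an
    explicit ``layer_file`` (node<TAB>layer), then inference — receptors are
    nodes with no incoming edge; TFs are catalogue members (or, without a
    catalogue, nodes with no outgoing edge); everything else is intermediate.
    """
    rows = _read_edge_rows(path, dialect)
    edge_sign: dict[tuple[str, str], int] = {}
    explicit_layer: dict[str, str] = {}
    n_conflicts = 0
    for line_no, fields in rows:
        src, tok, tgt = fields[0].strip(), fields[1], fields[2].strip()
        sign = parse_sign(tok, line_no)
        key = (src, tgt)
        if key in edge_sign and edge_sign[key] != sign:
            n_conflicts += 1
            edge_sign[key] = INHIBITION  # inhibition wins on conflict
        else:
            edge_sign[key] = sign
        if len(fields) >= 4 and fields[3].strip():
            lab = fields[3].strip().lower()
            if lab not in LAYERS:
                raise NetworkValidationError(
                    f"unknown layer label {fields[3]!r} at line {line_no}"
                )
            prev = explicit_layer.get(tgt)
            if prev is not None and prev != lab:
                raise NetworkValidationError(
                    f"conflicting layer labels for node {tgt!r}"
                )
            explicit_layer[tgt] = lab
    if n_conflicts:
        logger.warning(
            "%d contradictory duplicate edge(s); kept the inhibitory sign", n_conflicts
        )

    if layer_file is not None:
        for node, lab in _read_layer_file(layer_file).items():
            explicit_layer.setdefault(node, lab)

    graph = nx.DiGraph()
    for (src, tgt), sign in edge_sign.items():
        graph.add_edge(src, tgt, sign=sign)

    catalogue: set[str] | None = None
    if tf_catalogue is not None:
        if isinstance(tf_catalogue, (str, Path)):
            catalogue = {
                ln.strip() for ln in open(tf_catalogue) if ln.strip()
            }
        else:
            catalogue = set(tf_catalogue)

    layer = dict(explicit_layer)
    for n in graph.nodes:
        if n in layer:
            continue
        if catalogue is not None and n in catalogue:
            layer[n] = "tf"
        elif graph.in_degree(n) == 0:
            layer[n] = "receptor"
        elif catalogue is None and graph.out_degree(n) == 0:
            layer[n] = "tf"
        else:
            layer[n] = "intermediate"
    # a declared TF without any incoming edge cannot receive signal: demote
    for n, l in list(layer.items()):
        if l == "tf" and graph.in_degree(n) == 0:
            logger.warning("declared TF %r has no incoming edge; treated as receptor", n)
            layer[n] = "receptor"

    net = SignalingNetwork(graph=graph, layer=layer)
    net.validate()
    return net


def _read_layer_file(path: str | Path) -> dict[str, str]:
    layers: dict[str, str] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if i == 1 and fields[-1].strip().lower() not in LAYERS:
                continue  # header
            if len(fields) < 2:
                raise NetworkValidationError(f"layer file line {i}: expected node<TAB>layer")
            lab = fields[1].strip().lower()
            if lab not in LAYERS:
                raise NetworkValidationError(f"unknown layer label {fields[1]!r} at line {i}")
            layers[fields[0].strip()] = lab
    return layers


def write_interactome(network: SignalingNetwork, path: str | Path) -> None:
    """Write the edge list as a 3-column TSV (header: source, sign, target)."""
    with open(path, "w") as fh:
        fh.write("source\tsign\ttarget\n")
        for u, v, s in network.edges:
            fh.write(f"{u}\t{'+' if s > 0 else '-'}\t{v}\n")


def write_node_layers(network: SignalingNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("node\tlayer\n")
        for n in network.nodes:
            fh.write(f"{n}\t{network.layer[n]}\n")


def load_grn(
    path: str | Path,
    network: SignalingNetwork | None = None,
    dialect: str = "tsv3col",
) -> GeneRegulatoryNetwork:
    """Read signed TF->TF regulatory edges; regulators must be interactome TFs."""
    rows = _read_edge_rows(path, dialect)
    edges: list[tuple[str, str, int]] = []
    seen: dict[tuple[str, str], int] = {}
    for line_no, fields in rows:
        reg, tok, tgt = fields[0].strip(), fields[1], fields[2].strip()
        sign = parse_sign(tok, line_no)
        key = (reg, tgt)
        if key in seen:
            if seen[key] != sign:
                logger.warning("conflicting GRN edge %s->%s; kept inhibition", reg, tgt)
                seen[key] = INHIBITION
            continue
        seen[key] = sign
    for (reg, tgt), sign in seen.items():
        if network is not None and network.layer.get(reg) != "tf":
            raise NetworkValidationError(
                f"GRN regulator {reg!r} is not a tf-layer node of the interactome"
            )
        edges.append((reg, tgt, sign))
    return GeneRegulatoryNetwork(edges=sorted(edges))


def write_grn(grn: GeneRegulatoryNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("regulator\tsign\ttarget\n")
        for r, t, s in sorted(grn.edges):
            fh.write(f"{r}\t{'+' if s > 0 else '-'}\t{t}\n")


# ---------------------------------------------------------------------------
# expression


def load_expression(
    path: str | Path, format: str = "tsv", condition: str = ""
) -> ExpressionMatrix:
    """Read a genes x samples expression matrix.

    ``tsv``: tab-separated, gene identifiers in the first column, sample names
    in the header row. ``mtx_triplet``: a MatrixMarket coordinate file with
    ``genes.tsv`` and ``barcodes.tsv`` sidecars in the same directory
    (CellRanger-style triplet).

    Values must be non-negative (any pre-normalised scale); missing entries
    become 0 with a warning; duplicate gene rows are summed.
    """
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
    elif format == "mtx_triplet":
        mtx_path = path / "matrix.mtx" if path.is_dir() else path
        d = mtx_path.parent
        mat = scipy.io.mmread(mtx_path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        genes = [ln.split("\t")[0].strip() for ln in open(d / "genes.tsv") if ln.strip()]
        cells = [ln.strip() for ln in open(d / "barcodes.tsv") if ln.strip()]
        df = pd.DataFrame(np.asarray(mat, dtype=float), index=genes, columns=cells)
    else:
        raise ValueError(f"unknown expression format {format!r}")

    if df.size == 0:
        raise NetworkValidationError(f"{path}: empty expression matrix")
    df = df.astype(float)
    n_missing = int(df.isna().sum().sum())
    if n_missing:
        logger.warning("%d missing expression value(s) set to 0", n_missing)
        df = df.fillna(0.0)
    if (df.values < 0).any():
        g, s = np.argwhere(df.values < 0)[0]
        raise NetworkValidationError(
            f"negative expression value at gene {df.index[g]!r}, sample {df.columns[s]!r}"
        )
    if df.index.duplicated().any():
        n_dup = int(df.index.duplicated().sum())
        logger.warning("%d duplicate gene row(s) collapsed by summation", n_dup)
        df = df.groupby(level=0, sort=False).sum()
    df.index = df.index.astype(str)
    return ExpressionMatrix(values=df, condition=condition)


def write_expression_tsv(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene")


def write_expression_mtx(expr: ExpressionMatrix, directory: str | Path) -> None:
    """Write a MatrixMarket triplet (matrix.mtx + genes.tsv + barcodes.tsv)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    sp = scipy.sparse.coo_matrix(expr.values.values)
    scipy.io.mmwrite(str(d / "matrix.mtx"), sp)
    (d / "genes.tsv").write_text("".join(f"{g}\n" for g in expr.genes))
    (d / "barcodes.tsv").write_text("".join(f"{s}\n" for s in expr.samples))


def align_expression(network: SignalingNetwork, expr: ExpressionMatrix) -> pd.DataFrame:
    """Expression restricted to network nodes (rows = nodes, sorted).

    Matching is exact but case-insensitive on gene symbols; network nodes
    without a matching gene get expression 0 everywhere (they become
    unreachable in the walk) and their count is logged.
    """
    by_upper: dict[str, np.ndarray] = {}
    for gene in expr.genes:
        key = gene.upper()
        row = expr.values.loc[gene].to_numpy(dtype=float)
        if row.ndim > 1:  # duplicate symbols after case folding
            row = row.sum(axis=0)
        if key in by_upper:
            by_upper[key] = by_upper[key] + row
        else:
            by_upper[key] = row
    nodes = network.nodes
    out = np.zeros((len(nodes), expr.n_samples))
    n_unmatched = 0
    for i, node in enumerate(nodes):
        row = by_upper.get(node.upper())
        if row is None:
            n_unmatched += 1
        else:
            out[i] = row
    if n_unmatched:
        logger.warning(
            "%d of %d network node(s) have no matching gene; expression set to 0",
            n_unmatched,
            len(nodes),
        )
    return pd.DataFrame(out, index=nodes, columns=expr.samples)


# ---------------------------------------------------------------------------
# TF signature


def load_tf_signature(path: str | Path) -> TFSignature:
    """Read a 2-column (tf, direction) table; direction in {up, down, +1, -1}."""
    directions: dict[str, int] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise NetworkValidationError(
                    f"signature line {i}: expected tf<TAB>direction"
                )
            tf, tok = fields[0].strip(), fields[1].strip().lower()
            if i == 1 and tok not in DIRECTION_TOKENS:
                continue  # header
            if tok not in DIRECTION_TOKENS:
                raise NetworkValidationError(
                    f"unknown direction token {fields[1]!r} at line {i}"
                )
            d = DIRECTION_TOKENS[tok]
            if tf in directions:
                if directions[tf] != d:
                    raise NetworkValidationError(
                        f"TF {tf!r} listed with conflicting directions"
                    )
                logger.warning("duplicate signature entry for %r", tf)
            directions[tf] = d
    if not directions:
        raise NetworkValidationError("signature must contain >=1 TF")
    return TFSignature(directions=directions)


def write_tf_signature(signature: TFSignature, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("tf\tdirection\n")
        for tf, d in signature.entries:
            fh.write(f"{tf}\t{'up' if d > 0 else 'down'}\n")
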