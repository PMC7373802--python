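"""Domain types and I/O for multilayer lncRNA–splicing-gene networks.

The model distinguishes two sides of the node universe: non-coding
regulators (lncRNAs and pseudogenes) and the gene side (alternatively
spliced genes together with their co-effectors: transcription factors,
splicing factors and miRNAs). Evidence layers connect the two sides
(co-expression, epigenetic regulation) or run within the gene side
(splicing-pathway protein–protein interactions); no layer may connect two
non-coding regulators to each other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

NODE_CLASSES = frozenset({"lncRNA", "pseudogene", "miRNA", "TF", "ASF", "AS_gene"})

#: classes treated as the non-coding regulator side of bipartite layers
LNC_SIDE = frozenset({"lncRNA", "pseudogene"})

#: classes treated as the gene side (AS genes plus co-effectors)
GENE_SIDE = frozenset({"miRNA", "TF", "ASF", "AS_gene"})

LAYER_NAMES = ("coexpression", "epigenetic", "ppi")


class NetworkConstraintError(ValueError):
    """An edge or layer violates the structural rules of the model."""


@dataclass(frozen=True)
class NodeMeta:
    """A node identity with its class in the regulatory model."""

    id: str
    node_class: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("node id must be non-empty")
        if self.node_class not in NODE_CLASSES:
            raise ValueError(
                f"unknown node_class {self.node_class!r}; "
                f"expected one of {sorted(NODE_CLASSES)}"
            )


def _canonical_pair(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u < v else (v, u)


@dataclass
class Layer:
    """One named evidence layer: an undirected weighted edge set.

    Edges are stored once per unordered pair with endpoints in
    lexicographic order; weights live in (0, 1].
    """

    name: str
    edges: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        canon: dict[tuple[str, str], float] = {}
        for (u, v), w in self.edges.items():
            key = _canonical_pair(u, v)
            if u == v:
                raise NetworkConstraintError(f"self-loop on node {u!r} in layer {self.name}")
            if not (0.0 < w <= 1.0) or not math.isfinite(w):
                raise ValueError(
                    f"edge weight {w} for {key} in layer {self.name} outside (0, 1]"
                )
            if key in canon and canon[key] != w:
                raise ValueError(
                    f"duplicate edge {key} in layer {self.name} with conflicting "
                    f"weights {canon[key]} and {w}"
                )
            canon[key] = w
        self.edges = canon

    def node_ids(self) -> set[str]:
        out: set[str] = set()
        for u, v in self.edges:
            out.add(u)
            out.add(v)
        return out

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class MultiGraph:
    """A shared node universe with K evidence layers over it."""

    nodes: list[NodeMeta]
    layers: list[Layer]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def node_class_of(self) -> dict[str, str]:
        return {n.id: n.node_class for n in self.nodes}

    def to_networkx(self) -> nx.MultiGraph:
        """Export as a networkx multigraph with a ``layer`` edge attribute."""
        g = nx.MultiGraph()
        for n in self.nodes:
            g.add_node(n.id, node_class=n.node_class)
        for layer in self.layers:
            for (u, v), w in layer.edges.items():
                g.add_edge(u, v, layer=layer.name, weight=w)
        return g


def read_edge_list(path: str | Path, layer_name: str) -> Layer:
    """Read a TSV edge list (node_a, node_b[, weight]) into a canonical Layer.

    A missing third column defaults every weight to 1.0. Opposite orderings
    of the same pair deduplicate; conflicting duplicate weights are an error.
    """
    path = Path(path)
    edges: dict[tuple[str, str], float] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 1:  # tolerate whitespace-separated input
                parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: malformed edge line {line!r}")
            u, v = parts[0].strip(), parts[1].strip()
            if not u or not v:
                raise ValueError(f"{path}:{lineno}: empty node id in {line!r}")
            if u == v:
                raise NetworkConstraintError(f"{path}:{lineno}: self-loop on node {u!r}")
            if len(parts) >= 3 and parts[2].strip():
                try:
                    w = float(parts[2])
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: unparseable weight {parts[2]!r}"
                    ) from exc
            else:
                w = 1.0
            if not (0.0 < w <= 1.0):
                raise ValueError(f"{path}:{lineno}: weight {w} outside (0, 1]")
            key = _canonical_pair(u, v)
            if key in edges and edges[key] != w:
                raise ValueError(
                    f"{path}:{lineno}: duplicate edge {key} with conflicting weight"
                )
            edges[key] = w
    return Layer(name=layer_name, edges=edges)


def write_edge_list(layer: Layer, path: str | Path) -> None:
    """Write a Layer as a 3-column TSV in canonical (u < v) order."""
    path = Path(path)
    with path.open("w") as fh:
        for (u, v), w in sorted(layer.edges.items()):
            fh.write(f"{u}\t{v}\t{w!r}\n")  # repr round-trips floats exactly


def read_node_table(path: str | Path) -> list[NodeMeta]:
    """Read node metadata TSV with columns id, node_class."""
    df = pd.read_csv(path, sep="\t", header=None, names=["id", "node_class"], comment="#")
    if df["id"].duplicated().any():
        dupes = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate node ids: {dupes}")
    return [NodeMeta(str(r.id), str(r.node_class)) for r in df.itertuples()]


def write_node_table(nodes: Sequence[NodeMeta], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for n in nodes:
            fh.write(f"{n.id}\t{n.node_class}\n")


def _validate_layer_sides(layer: Layer, class_of: Mapping[str, str]) -> None:
    for u, v in layer.edges:
        cu, cv = class_of[u], class_of[v]
        if cu in LNC_SIDE and cv in LNC_SIDE:
            raise NetworkConstraintError(
                f"layer {layer.name}: edge ({u}, {v}) connects two non-coding "
                "regulators; no lncRNA–lncRNA interactions are admitted"
            )
        if layer.name == "ppi" and (cu in LNC_SIDE or cv in LNC_SIDE):
            raise NetworkConstraintError(
                f"ppi layer edge ({u}, {v}) must have gene-side endpoints only"
            )
        if layer.name in ("coexpression", "epigenetic"):
            sides = {cu in LNC_SIDE, cv in LNC_SIDE}
            if sides != {True, False}:
                raise NetworkConstraintError(
                    f"layer {layer.name}: edge ({u}, {v}) is not bipartite "
                    "(one non-coding endpoint and one gene-side endpoint required)"
                )


def build_multigraph(layers: Sequence[Layer], nodes: Sequence[NodeMeta]) -> MultiGraph:
    """Assemble and validate the multilayer graph over a declared node universe.

    Raises if a layer references an undeclared node, if any layer contains a
    lncRNA–lncRNA edge, or if bipartite/PPI side constraints are violated.
    """
    if len(layers) == 0:
        raise ValueError("at least one layer is required")
    node_list = list(nodes)
    ids = [n.id for n in node_list]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate node ids in node table")
    class_of = {n.id: n.node_class for n in node_list}
    for layer in layers:
        missing = layer.node_ids() - class_of.keys()
        if missing:
            raise ValueError(
                f"layer {layer.name} references undeclared nodes: {sorted(missing)}"
            )
        _validate_layer_sides(layer, class_of)
    return MultiGraph(nodes=node_list, layers=list(layers))


def write_ranking(ranked: pd.DataFrame, path: str | Path) -> None:
    """Write a ranking table as TSV with columns id, rank, score, node_class."""
    cols = ["id", "rank", "score", "node_class"]
    out = ranked.loc[:, cols] if len(ranked) else pd.DataFrame(columns=cols)
    if len(out) and not out["score"].map(math.isfinite).all():
        raise ValueError("ranking contains non-finite scores")
    out.to_csv(path, sep="\t", index=False)


def read_ranking(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_id_list(path: str | Path) -> list[str]:
    """Read a plain-text list of ids, one per line, ignoring blanks/comments."""
    out = []
    for line in Path(path).read_text().splitlines():
        s = line.strip()
        if s and not s.startswith("#"):
            out.append(s)
    return out
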