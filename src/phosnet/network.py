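"""Impact networks and layer decomposition of the kinase hierarchy.

An *impact network* is a directed graph in which an edge k -> t records
that inactivating enzyme k changed the phosphorylation of protein t in a
phospho-proteomic screen. Restricted to kinase-kinase edges, the network
admits a natural three-layer decomposition: kinases that impact other
kinases without being targeted sit on top, kinases that are targeted but
impact none sit at the bottom, and kinases doing both form the middle.
Kinases with no kinase-kinase relationship at all form an outgroup.

Two layering schemes are provided. The *simple* scheme classifies by the
mere presence of outgoing/incoming kinase-kinase edges. The *stringent*
scheme demands at least two supporting relationships per assignment, so
that no layer membership rests on a single (possibly spurious) edge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TOP",
    "MID",
    "BOT",
    "OUTGROUP",
    "LAYERS",
    "ImpactNetwork",
    "LayerAssignment",
    "build_network",
    "subnetwork_by_class",
    "assign_layers_simple",
    "assign_layers_stringent",
    "restrict_to_measured",
    "phosphatase_placement",
    "layer_recovery",
    "export_attributed_network",
]

TOP = "TOP"
MID = "MID"
BOT = "BOT"
OUTGROUP = "OUTGROUP"
LAYERS = (TOP, MID, BOT, OUTGROUP)


@dataclass
class ImpactNetwork:
    """Directed impact graph: deduplicated, self-loop-free.

    Wraps a :class:`networkx.DiGraph`; build through :func:`build_network`
    so the invariants (no parallel edges, no self-loops, every endpoint a
    node) hold by construction.
    """

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)
    n_self_loops_dropped: int = 0
    n_duplicates_dropped: int = 0

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return list(self.graph.edges)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def out_degree(self, node: str) -> int:
        return int(self.graph.out_degree(node))

    def in_degree(self, node: str) -> int:
        return int(self.graph.in_degree(node))

    def __contains__(self, node: str) -> bool:
        return node in self.graph

    def copy(self) -> "ImpactNetwork":
        return ImpactNetwork(
            self.graph.copy(), self.n_self_loops_dropped, self.n_duplicates_dropped
        )


@dataclass(frozen=True)
class LayerAssignment:
    """Total partition of a node set into TOP/MID/BOT/OUTGROUP.

    ``scheme`` records how the labels were produced (``"simple"``,
    ``"stringent"`` or ``"planted"`` for synthetic ground truth).
    """

    labels: Mapping[str, str]
    scheme: str

    def __post_init__(self) -> None:
        bad = {v for v in self.labels.values() if v not in LAYERS}
        if bad:
            raise ValueError(f"unknown layer labels: {sorted(bad)}")

    def __getitem__(self, node: str) -> str:
        return self.labels[node]

    def __len__(self) -> int:
        return len(self.labels)

    def members(self, layer: str) -> list[str]:
        if layer not in LAYERS:
            raise ValueError(f"unknown layer {layer!r}")
        return sorted(n for n, l in self.labels.items() if l == layer)

    def counts(self) -> dict[str, int]:
        c = {layer: 0 for layer in LAYERS}
        for l in self.labels.values():
            c[l] += 1
        return c

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": sorted(self.labels),
                "layer": [self.labels[n] for n in sorted(self.labels)],
                "scheme": self.scheme,
            }
        )


def build_network(
    edges: Iterable[tuple],
    node_universe: Iterable[str] | None = None,
) -> ImpactNetwork:
    """Assemble an :class:`ImpactNetwork` from raw (source, target) pairs.

    Duplicate edges collapse to a single relationship, self-loops are
    dropped (and counted), and any node listed in ``node_universe`` is
    retained even when isolated — isolated enzymes become OUTGROUP members
    downstream rather than silently disappearing.

    Edges may carry a third element (a provenance tag) which is stored as
    the edge attribute ``provenance``.
    """
    edges = list(edges)
    universe = list(node_universe) if node_universe is not None else []
    if not edges and not universe:
        raise ValueError("no edges given and no node universe declared")

    g = nx.DiGraph()
    g.add_nodes_from(universe)
    n_loops = 0
    n_dups = 0
    for i, edge in enumerate(edges):
        if len(edge) not in (2, 3):
            raise ValueError(f"edge {i}: expected (source, target[, provenance]), got {edge!r}")
        src, dst = edge[0], edge[1]
        if src is None or dst is None or str(src) == "" or str(dst) == "":
            raise ValueError(f"edge {i}: missing endpoint in {edge!r}")
        src, dst = str(src), str(dst)
        if src == dst:
            n_loops += 1
            g.add_node(src)
            continue
        if g.has_edge(src, dst):
            n_dups += 1
            continue
        attrs = {"provenance": edge[2]} if len(edge) == 3 else {}
        g.add_edge(src, dst, **attrs)
    if n_loops:
        logger.info("dropped %d self-loop edge(s)", n_loops)
    if n_dups:
        logger.info("collapsed %d duplicate edge(s)", n_dups)
    return ImpactNetwork(g, n_self_loops_dropped=n_loops, n_duplicates_dropped=n_dups)


def _class_of(records: pd.DataFrame) -> dict[str, str]:
    if "id" not in records.columns or "enzyme_class" not in records.columns:
        raise ValueError("records must have 'id' and 'enzyme_class' columns")
    dup = records["id"][records["id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate enzyme ids in records: {sorted(set(dup))}")
    return dict(zip(records["id"].astype(str), records["enzyme_class"].astype(str)))


def subnetwork_by_class(
    net: ImpactNetwork, records: pd.DataFrame, enzyme_class: str
) -> ImpactNetwork:
    """Restrict the network to edges within one enzyme class.

    The node set is every class member present in the input network, so
    class members that lose all their edges stay in as isolated nodes
    (future OUTGROUP). Unknown class labels raise.
    """
    cls = _class_of(records)
    if enzyme_class not in set(cls.values()):
        raise ValueError(f"class {enzyme_class!r} not present in records")
    members = {n for n, c in cls.items() if c == enzyme_class}
    g = nx.DiGraph()
    g.add_nodes_from(n for n in net.nodes if n in members)
    g.add_edges_from(
        (u, v, net.graph.edges[u, v])
        for u, v in net.edges
        if u in members and v in members
    )
    return ImpactNetwork(g)


def assign_layers_simple(net: ImpactNetwork) -> LayerAssignment:
    """Layer each node by the presence of outgoing/incoming impact edges.

    TOP: impacts others, targeted by none (out > 0, in = 0).
    MID: both (out > 0, in > 0).
    BOT: targeted only (out = 0, in > 0).
    OUTGROUP: isolated (out = 0, in = 0).
    """
    labels: dict[str, str] = {}
    for node in net.nodes:
        out_d, in_d = net.out_degree(node), net.in_degree(node)
        if out_d > 0 and in_d == 0:
            labels[node] = TOP
        elif out_d > 0:
            labels[node] = MID
        elif in_d > 0:
            labels[node] = BOT
        else:
            labels[node] = OUTGROUP
    return LayerAssignment(labels, "simple")


def assign_layers_stringent(net: ImpactNetwork) -> LayerAssignment:
    """Layer each node requiring >= 2 supporting relationships.

    TOP: impacts >= 2, targeted by <= 1 (the one allowed incoming edge
    could be noise). MID: impacts >= 2 and targeted by >= 2. BOT: impacts
    <= 1 and targeted by >= 2. Nodes matching none of the rules (out <= 1
    and in <= 1) fall to OUTGROUP, so no assignment rests on a single
    edge.
    """
    labels: dict[str, str] = {}
    for node in net.nodes:
        out_d, in_d = net.out_degree(node), net.in_degree(node)
        if out_d >= 2 and in_d <= 1:
            labels[node] = TOP
        elif out_d >= 2 and in_d >= 2:
            labels[node] = MID
        elif out_d <= 1 and in_d >= 2:
            labels[node] = BOT
        else:
            labels[node] = OUTGROUP
    return LayerAssignment(labels, "stringent")


def restrict_to_measured(obj, measured_ids: Iterable[str]):
    """Drop nodes outside the measured set before layering or profiling.

    Profiling only genes/proteins that were actually measured avoids
    treating absence of evidence as evidence of absence. Works on either
    an :class:`ImpactNetwork` (returns the induced subnetwork) or a
    :class:`LayerAssignment` (returns the filtered mapping). An empty
    intersection raises.
    """
    measured = {str(m) for m in measured_ids}
    if not measured:
        raise ValueError("measured_ids is empty")
    if isinstance(obj, ImpactNetwork):
        keep = [n for n in obj.nodes if n in measured]
        if not keep:
            raise ValueError("no network node is in measured_ids")
        dropped = obj.n_nodes - len(keep)
        if dropped:
            logger.info("restrict_to_measured: dropped %d unmeasured node(s)", dropped)
        return ImpactNetwork(obj.graph.subgraph(keep).copy())
    if isinstance(obj, LayerAssignment):
        kept = {n: l for n, l in obj.labels.items() if n in measured}
        if not kept:
            raise ValueError("no assigned node is in measured_ids")
        dropped = len(obj) - len(kept)
        if dropped:
            logger.info("restrict_to_measured: dropped %d unmeasured node(s)", dropped)
        return LayerAssignment(kept, obj.scheme)
    raise TypeError(f"cannot restrict object of type {type(obj).__name__}")


def phosphatase_placement(
    full_net: ImpactNetwork,
    kinase_layers: LayerAssignment,
    records: pd.DataFrame,
) -> pd.DataFrame:
    """Place phosphatases relative to the kinase hierarchy.

    Phosphatases are not layered themselves (they show no layered
    architecture); instead each is profiled by which kinase layers its
    impact edges reach, how many phosphatase-phosphatase relationships it
    participates in, and how often kinases impact it. A phosphatase with
    no impact relationship to any kinase or phosphatase is flagged
    ``outgroup`` (drawn as a grid member beside the hierarchy).

    Returns a DataFrame indexed by phosphatase id with columns
    ``to_TOP, to_MID, to_BOT, to_OUTGROUP`` (impacted kinases per layer),
    ``pp_out, pp_in`` (phosphatase-phosphatase edges), ``from_kinase``
    (incoming edges from kinases) and ``outgroup`` (bool).
    """
    cls = _class_of(records)
    kinases = {n for n, c in cls.items() if c == "kinase"}
    phosphatases = sorted(n for n, c in cls.items() if c == "phosphatase")
    both = kinases & set(phosphatases)
    if both:
        raise ValueError(f"ids annotated as both kinase and phosphatase: {sorted(both)}")
    if not phosphatases:
        raise ValueError("no phosphatase records")

    rows = []
    for p in phosphatases:
        row = {"id": p, "to_TOP": 0, "to_MID": 0, "to_BOT": 0, "to_OUTGROUP": 0,
               "pp_out": 0, "pp_in": 0, "from_kinase": 0}
        if p in full_net:
            for _, tgt in full_net.graph.out_edges(p):
                if tgt in kinases:
                    layer = kinase_layers.labels.get(tgt, OUTGROUP)
                    row[f"to_{layer}"] += 1
                elif cls.get(tgt) == "phosphatase":
                    row["pp_out"] += 1
            for src, _ in full_net.graph.in_edges(p):
                if src in kinases:
                    row["from_kinase"] += 1
                elif cls.get(src) == "phosphatase":
                    row["pp_in"] += 1
        row["outgroup"] = (
            row["to_TOP"] + row["to_MID"] + row["to_BOT"] + row["to_OUTGROUP"]
            + row["pp_out"] + row["pp_in"] + row["from_kinase"]
        ) == 0
        rows.append(row)
    return pd.DataFrame(rows).set_index("id")


def layer_recovery(truth: LayerAssignment, inferred: LayerAssignment) -> float:
    """Fraction of nodes whose inferred layer matches the planted layer."""
    if set(truth.labels) != set(inferred.labels):
        raise ValueError("truth and inferred assignments cover different node sets")
    if len(truth) == 0:
        raise ValueError("empty assignments")
    n_match = sum(1 for n, l in truth.labels.items() if inferred.labels[n] == l)
    return n_match / len(truth)


def export_attributed_network(
    net: ImpactNetwork,
    layers: LayerAssignment,
    breadth: Mapping[str, int],
    edge_path,
    node_path,
    records: pd.DataFrame | None = None,
) -> None:
    """Write the network as an edge TSV plus a node-attribute TSV.

    The node table carries layer, enzyme class (when ``records`` given)
    and impact breadth — everything an external renderer needs to draw
    the hierarchy (node size by breadth, color by layer/class).
    """
    edge_rows = [
        {"source": u, "target": v,
         "provenance": net.graph.edges[u, v].get("provenance", "")}
        for u, v in sorted(net.edges)
    ]
    pd.DataFrame(edge_rows, columns=["source", "target", "provenance"]).to_csv(
        edge_path, sep="\t", index=False
    )
    cls = _class_of(records) if records is not None else {}
    node_rows = [
        {"id": n,
         "layer": layers.labels.get(n, ""),
         "enzyme_class": cls.get(n, ""),
         "impact_breadth": int(breadth.get(n, 0))}
        for n in sorted(net.nodes)
    ]
    pd.DataFrame(
        node_rows, columns=["id", "layer", "enzyme_class", "impact_breadth"]
    ).to_csv(node_path, sep="\t", index=False)
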