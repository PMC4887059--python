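"""Readers and writers for the gene-set and network formats the pipeline touches.

Gene identity throughout the package is the uppercased HGNC-style symbol
string; no alias resolution is attempted.  Gene-set carriers are GMT files
(driver calls, GO annotations) and plain one-gene-per-line lists (census,
background).  Networks travel as 2-4 column edge-list TSV or SIF on the way
in, GraphML on the way out, and Cytoscape-dialect XGMML for externally
produced stage networks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from lxml import etree

__all__ = [
    "FormatError",
    "GeneSetCollection",
    "Graph",
    "LoadReport",
    "INTERACTION_TYPES",
    "normalize_symbol",
    "read_gmt",
    "write_gmt",
    "read_gene_list",
    "write_gene_list",
    "read_edge_list",
    "write_edge_list",
    "read_sif",
    "read_xgmml",
    "write_xgmml",
    "read_graphml",
    "write_graphml",
]

#: Edge provenance labels accepted on interactome edges.
INTERACTION_TYPES = ("physical", "ppi", "predicted", "unknown")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def normalize_symbol(symbol: str) -> str:
    """Return the canonical (uppercased, stripped) form of a gene symbol.

    Raises :class:`FormatError` for empty or whitespace-containing symbols.
    """
    sym = symbol.strip().upper()
    if not sym or any(c.isspace() for c in sym):
        raise FormatError(f"invalid gene symbol: {symbol!r}")
    return sym


class GeneSetCollection(dict):
    """Mapping of set name -> set of uppercased gene symbols.

    A thin ``dict`` subclass; construction helpers enforce symbol
    normalization and set semantics (duplicates collapse).
    """

    @classmethod
    def from_items(cls, items: Mapping[str, Iterable[str]]) -> "GeneSetCollection":
        coll = cls()
        for name, genes in items.items():
            coll[name] = {normalize_symbol(g) for g in genes}
        return coll

    def all_genes(self) -> set[str]:
        """Union of every member set (the annotation universe for GMT input)."""
        out: set[str] = set()
        for genes in self.values():
            out |= genes
        return out


@dataclass
class LoadReport:
    """Per-file account of lines skipped or repaired while reading."""

    self_loops_skipped: int = 0
    comment_lines: int = 0
    duplicate_edges_merged: int = 0
    warnings: list[str] = field(default_factory=list)


class Graph:
    """Undirected gene graph: no self-loops, no parallel edges.

    Edges carry a positive weight (default 1.0) and an interaction-type
    label.  Adding an edge that already exists collapses the duplicate by
    summing weights; the first non-"unknown" type label wins.
    """

    def __init__(self) -> None:
        self._adj: dict[str, dict[str, list]] = {}
        #: populated by :func:`read_xgmml` / readers that carry attributes
        self.node_attributes: dict[str, dict[str, str]] = {}
        self.load_report: LoadReport = LoadReport()

    # -- construction -------------------------------------------------

    def add_node(self, node: str) -> None:
        node = normalize_symbol(node)
        self._adj.setdefault(node, {})

    def add_edge(self, u: str, v: str, weight: float = 1.0,
                 etype: str = "unknown") -> None:
        u, v = normalize_symbol(u), normalize_symbol(v)
        if u == v:
            raise FormatError(f"self-loop on {u!r} not allowed")
        if weight <= 0:
            raise FormatError(f"edge weight must be > 0, got {weight}")
        if etype not in INTERACTION_TYPES:
            raise FormatError(f"unknown interaction type {etype!r}")
        self._adj.setdefault(u, {})
        self._adj.setdefault(v, {})
        if v in self._adj[u]:
            data = self._adj[u][v]
            data[0] += weight
            if data[1] == "unknown" and etype != "unknown":
                data[1] = etype
            self.load_report.duplicate_edges_merged += 1
        else:
            data = [float(weight), etype]
            self._adj[u][v] = data
            self._adj[v][u] = data

    # -- queries ------------------------------------------------------

    @property
    def nodes(self) -> set[str]:
        return set(self._adj)

    def sorted_nodes(self) -> list[str]:
        return sorted(self._adj)

    def edges(self) -> Iterator[tuple[str, str, float, str]]:
        """Yield each undirected edge once as (u, v, weight, type), u < v."""
        for u in sorted(self._adj):
            for v in sorted(self._adj[u]):
                if u < v:
                    w, t = self._adj[u][v]
                    yield u, v, w, t

    def number_of_nodes(self) -> int:
        return len(self._adj)

    def number_of_edges(self) -> int:
        return sum(len(nbrs) for nbrs in self._adj.values()) // 2

    def has_node(self, node: str) -> bool:
        return node in self._adj

    def has_edge(self, u: str, v: str) -> bool:
        return u in self._adj and v in self._adj[u]

    def edge_weight(self, u: str, v: str) -> float:
        return self._adj[u][v][0]

    def edge_type(self, u: str, v: str) -> str:
        return self._adj[u][v][1]

    def neighbors(self, node: str) -> set[str]:
        return set(self._adj[node])

    def degree(self, node: str) -> int:
        return len(self._adj[node])

    def subgraph(self, nodes: Iterable[str]) -> "Graph":
        """Induced subgraph on ``nodes`` (members absent from the graph ignored)."""
        keep = {normalize_symbol(n) for n in nodes} & self.nodes
        sub = Graph()
        for n in keep:
            sub.add_node(n)
        for u, v, w, t in self.edges():
            if u in keep and v in keep:
                sub.add_edge(u, v, w, t)
        return sub

    def connected_components(self) -> list[set[str]]:
        """Components as node sets, largest first (ties by smallest label)."""
        seen: set[str] = set()
        comps: list[set[str]] = []
        for start in sorted(self._adj):
            if start in seen:
                continue
            comp = {start}
            stack = [start]
            while stack:
                cur = stack.pop()
                for nbr in self._adj[cur]:
                    if nbr not in comp:
                        comp.add(nbr)
                        stack.append(nbr)
            seen |= comp
            comps.append(comp)
        comps.sort(key=lambda c: (-len(c), min(c)))
        return comps

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Graph):
            return NotImplemented
        if self.nodes != other.nodes:
            return False
        mine = {(u, v): (w, t) for u, v, w, t in self.edges()}
        theirs = {(u, v): (w, t) for u, v, w, t in other.edges()}
        if mine.keys() != theirs.keys():
            return False
        return all(
            abs(mine[k][0] - theirs[k][0]) < 1e-9 and mine[k][1] == theirs[k][1]
            for k in mine
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<Graph nodes={self.number_of_nodes()} "
                f"edges={self.number_of_edges()}>")


# ---------------------------------------------------------------------------
# GMT and plain gene lists
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one named gene set per tab-separated line.

    Each line is ``name<TAB>description<TAB>gene1<TAB>gene2...``; gene
    symbols are uppercased and deduplicated.
    """
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected >=3 tab-separated "
                    f"fields, got {len(fields)}")
            name = fields[0].strip()
            coll[name] = {normalize_symbol(g) for g in fields[2:] if g.strip()}
    return coll


def write_gmt(collection: Mapping[str, Iterable[str]], path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection):
            desc = (descriptions or {}).get(name, "na")
            genes = sorted({normalize_symbol(g) for g in collection[name]})
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_gene_list(path: str | Path) -> set[str]:
    """One gene symbol per line; blank lines and ``#`` comments skipped."""
    genes: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.add(normalize_symbol(line))
    return genes


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted({normalize_symbol(x) for x in genes}):
            fh.write(g + "\n")


# ---------------------------------------------------------------------------
# Edge lists / SIF
# ---------------------------------------------------------------------------

def read_edge_list(path: str | Path) -> Graph:
    """Read a 2-4 column TSV edge list: ``A<TAB>B[<TAB>weight[<TAB>type]]``.

    Comment lines (``#``) are skipped; self-loop lines are skipped with a
    warning counted in ``graph.load_report``.
    """
    g = Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.lstrip().startswith("#"):
                g.load_report.comment_lines += 1
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                # single-column line declares an isolated node
                g.add_node(fields[0])
                continue
            u, v = normalize_symbol(fields[0]), normalize_symbol(fields[1])
            if u == v:
                g.load_report.self_loops_skipped += 1
                g.load_report.warnings.append(
                    f"line {lineno}: self-loop on {u} skipped")
                g.add_node(u)
                continue
            weight = 1.0
            etype = "unknown"
            if len(fields) >= 3 and fields[2].strip():
                try:
                    weight = float(fields[2])
                except ValueError as exc:
                    raise FormatError(
                        f"{path}: line {lineno}: non-numeric weight "
                        f"{fields[2]!r}") from exc
            if len(fields) >= 4 and fields[3].strip():
                etype = fields[3].strip().lower()
            g.add_edge(u, v, weight, etype)
    return g


def write_edge_list(graph: Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for u, v, w, t in graph.edges():
            fh.write(f"{u}\t{v}\t{w:g}\t{t}\n")
        # isolated nodes survive as single-column records
        for n in graph.sorted_nodes():
            if graph.degree(n) == 0:
                fh.write(f"{n}\n")


def read_sif(path: str | Path) -> Graph:
    """Read a Cytoscape SIF file (``source relation target1 target2 ...``)."""
    g = Graph()
    with open(path) as fh:
        for line in fh:
            fields = line.split()
            if not fields or fields[0].startswith("#"):
                continue
            if len(fields) == 1:
                g.add_node(fields[0])
                continue
            src, rel = fields[0], fields[1].lower()
            etype = rel if rel in INTERACTION_TYPES else "unknown"
            for tgt in fields[2:]:
                if normalize_symbol(src) == normalize_symbol(tgt):
                    g.load_report.self_loops_skipped += 1
                    g.add_node(src)
                    continue
                g.add_edge(src, tgt, 1.0, etype)
    return g


# ---------------------------------------------------------------------------
# XGMML (Cytoscape dialect, input) and GraphML (output + read-back)
# ---------------------------------------------------------------------------

def _local(tag) -> str:
    """Local element name without XML namespace."""
    if isinstance(tag, str):
        return tag.rsplit("}", 1)[-1]
    return ""


def read_xgmml(path: str | Path) -> Graph:
    """Read a Cytoscape-dialect XGMML network.

    Only the features needed here are interpreted: ``<node>`` elements with a
    ``label`` (falling back to ``id``), ``<edge>`` elements with ``source``
    and ``target`` referencing node ids or labels, and flat ``<att>`` children
    whose name/value pairs are preserved in ``graph.node_attributes`` keyed by
    the node label.  Other constructs are ignored with a warning in the load
    report.
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"{path}: XML parse failure: {exc}") from exc
    root = tree.getroot()
    g = Graph()
    id_to_label: dict[str, str] = {}
    for el in root.iter():
        name = _local(el.tag)
        if name == "node":
            label = el.get("label") or el.get("id")
            if label is None:
                raise FormatError(f"{path}: node element without label or id")
            label = normalize_symbol(label)
            node_id = el.get("id")
            if node_id is not None:
                id_to_label[node_id] = label
            id_to_label[label] = label
            g.add_node(label)
            atts = {}
            for att in el:
                if _local(att.tag) == "att" and att.get("name") is not None:
                    atts[att.get("name")] = att.get("value", "")
            if atts:
                g.node_attributes[label] = atts
        elif name == "edge":
            src, tgt = el.get("source"), el.get("target")
            if src is None or tgt is None:
                raise FormatError(f"{path}: edge element without source/target")
            try:
                u, v = id_to_label[src], id_to_label[tgt]
            except KeyError as exc:
                raise FormatError(
                    f"{path}: edge references unknown node id {exc}") from exc
            weight = 1.0
            etype = "unknown"
            for att in el:
                if _local(att.tag) != "att":
                    continue
                att_name = (att.get("name") or "").lower()
                if att_name == "weight":
                    try:
                        weight = float(att.get("value", "1"))
                    except ValueError:
                        pass
                elif att_name in ("interaction", "type"):
                    val = (att.get("value") or "").lower()
                    if val in INTERACTION_TYPES:
                        etype = val
            if u == v:
                g.load_report.self_loops_skipped += 1
                continue
            g.add_edge(u, v, weight, etype)
        elif name not in ("graph", "att"):
            g.load_report.warnings.append(f"ignored XGMML element <{name}>")
    return g


def write_xgmml(graph: Graph, path: str | Path, label: str = "network") -> None:
    """Write a minimal Cytoscape-dialect XGMML document."""
    root = etree.Element("graph", label=label, directed="0")
    ids = {n: str(i) for i, n in enumerate(graph.sorted_nodes())}
    for n in graph.sorted_nodes():
        el = etree.SubElement(root, "node", id=ids[n], label=n)
        for k, v in graph.node_attributes.get(n, {}).items():
            etree.SubElement(el, "att", name=k, value=str(v))
    for u, v, w, t in graph.edges():
        el = etree.SubElement(root, "edge", source=ids[u], target=ids[v],
                              label=f"{u} ({t}) {v}")
        etree.SubElement(el, "att", name="weight", value=repr(w))
        etree.SubElement(el, "att", name="interaction", value=t)
    etree.ElementTree(root).write(str(path), pretty_print=True,
                                  xml_declaration=True, encoding="UTF-8")


_GRAPHML_NS = "http://graphml.graphdrawing.org/xmlns"


def write_graphml(graph: Graph, path: str | Path) -> None:
    """Write standard GraphML with ``weight`` and ``type`` edge attributes."""
    root = etree.Element(f"{{{_GRAPHML_NS}}}graphml", nsmap={None: _GRAPHML_NS})
    for key_id, attr, typ in (("w", "weight", "double"), ("t", "type", "string")):
        etree.SubElement(root, f"{{{_GRAPHML_NS}}}key", id=key_id,
                         **{"for": "edge", "attr.name": attr, "attr.type": typ})
    gel = etree.SubElement(root, f"{{{_GRAPHML_NS}}}graph",
                           edgedefault="undirected")
    for n in graph.sorted_nodes():
        etree.SubElement(gel, f"{{{_GRAPHML_NS}}}node", id=n)
    for u, v, w, t in graph.edges():
        eel = etree.SubElement(gel, f"{{{_GRAPHML_NS}}}edge", source=u, target=v)
        d = etree.SubElement(eel, f"{{{_GRAPHML_NS}}}data", key="w")
        d.text = repr(w)
        d = etree.SubElement(eel, f"{{{_GRAPHML_NS}}}data", key="t")
        d.text = t
    etree.ElementTree(root).write(str(path), pretty_print=True,
                                  xml_declaration=True, encoding="UTF-8")


def read_graphml(path: str | Path) -> Graph:
    """Read GraphML written by :func:`write_graphml` (round-trip partner)."""
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"{path}: XML parse failure: {exc}") from exc
    g = Graph()
    key_names: dict[str, str] = {}
    for el in tree.getroot().iter():
        name = _local(el.tag)
        if name == "key":
            key_names[el.get("id", "")] = el.get("attr.name", "")
        elif name == "node":
            g.add_node(el.get("id"))
        elif name == "edge":
            u, v = el.get("source"), el.get("target")
            weight, etype = 1.0, "unknown"
            for data in el:
                if _local(data.tag) != "data":
                    continue
                attr = key_names.get(data.get("key", ""), data.get("key", ""))
                if attr in ("weight", "w"):
                    weight = float(data.text or "1")
                elif attr in ("type", "t"):
                    if (data.text or "") in INTERACTION_TYPES:
                        etype = data.text
            g.add_edge(u, v, weight, etype)
    return g


def _warn(msg: str) -> None:  # small indirection so tests can capture it
    warnings.warn(msg, stacklevel=3)
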