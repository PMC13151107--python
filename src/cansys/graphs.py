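"""Typed pathway graphs: OBO parsing, KEGG relations, significant subgraphs.

GO biological-process terms form a DAG with child -> parent edges of five
relation types (is_a, part_of, regulates, positively_regulates,
negatively_regulates) rooted at GO:0008150. KEGG pathways form a flat
undirected "related" graph. The visualization subgraph keeps significant
nodes and, for GO, the non-significant connectors lying on a path from a
significant node to the root.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from typing import Iterable, Mapping, Optional

import networkx as nx

logger = logging.getLogger(__name__)

GO_ROOT = "GO:0008150"
GO_RELATIONS = ("is_a", "part_of", "regulates",
                "positively_regulates", "negatively_regulates")
KEGG_RELATION = "related"


def _parse_obo_stanzas(path: Path):
    """Yield (lineno, dict of key -> list of values) per [Term] stanza."""
    stanza: Optional[dict] = None
    start = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if line.startswith("["):
                if stanza is not None:
                    yield start, stanza
                stanza = {} if line == "[Term]" else None
                start = lineno
                continue
            if stanza is None or not line or line.startswith("!"):
                continue
            if ":" not in line:
                logger.warning("%s:%d: malformed line skipped", path, lineno)
                continue
            key, _, value = line.partition(":")
            value = value.split("!")[0].strip()
            stanza.setdefault(key.strip(), []).append(value)
    if stanza is not None:
        yield start, stanza


def parse_obo(path: str | Path, namespace: str = "biological_process",
              root: str = GO_ROOT,
              relations: Iterable[str] = GO_RELATIONS) -> nx.MultiDiGraph:
    """Parse OBO 1.2/1.4 term stanzas into a typed child -> parent graph.

    Only non-obsolete terms of the requested namespace are kept; edges to
    terms outside the namespace are dropped. The root must be present.
    """
    path = Path(path)
    relations = set(relations)
    graph = nx.MultiDiGraph()
    parents: list[tuple[str, str, str]] = []
    for lineno, stanza in _parse_obo_stanzas(path):
        ids = stanza.get("id")
        if not ids:
            logger.warning("%s: stanza at line %d lacks an id, skipped", path, lineno)
            continue
        term_id = ids[0]
        if stanza.get("is_obsolete", ["false"])[0] == "true":
            continue
        ns = stanza.get("namespace", [namespace])[0]
        if ns != namespace:
            continue
        name = stanza.get("name", [term_id])[0]
        graph.add_node(term_id, name=name, namespace=ns)
        for target in stanza.get("is_a", []):
            parents.append((term_id, target, "is_a"))
        for rel in stanza.get("relationship", []):
            parts = rel.split()
            if len(parts) < 2:
                logger.warning("%s: malformed relationship %r in %s", path, rel, term_id)
                continue
            rtype, target = parts[0], parts[1]
            if rtype in relations:
                parents.append((term_id, target, rtype))
    for child, parent, rtype in parents:
        if child == parent:
            continue
        if parent in graph:
            graph.add_edge(child, parent, relation=rtype)
    if root not in graph:
        raise ValueError(f"root term {root} missing from {path}")
    graph.graph["root"] = root
    graph.graph["source"] = "GO"
    return graph


def parse_kegg_relations(path: str | Path,
                         names: Optional[Mapping[str, str]] = None) -> nx.Graph:
    """Two-column tab-separated pathway edge list -> undirected graph.

    Duplicate (and reversed-duplicate) edges collapse; self-edges drop.
    Edges naming unknown pathways keep a placeholder name with a warning.
    """
    names = dict(names or {})
    graph = nx.Graph(source="KEGG")
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                logger.warning("%s:%d: malformed edge skipped", path, lineno)
                continue
            a, b = fields[0], fields[1]
            for node in (a, b):
                if node not in names:
                    logger.warning("%s:%d: unknown pathway %s", path, lineno, node)
                graph.add_node(node, name=names.get(node, node))
            if a == b:
                continue
            graph.add_edge(a, b, relation=KEGG_RELATION)
    return graph


def load_pathway_names(path: str | Path) -> dict[str, str]:
    """Two-column id -> name table."""
    out = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) >= 2:
                out[fields[0]] = fields[1]
    return out


def set_gene_counts(graph: nx.Graph, gene_sets: Mapping[str, "object"]) -> None:
    """Attach gene_count and ln-gene-count size attributes from a GMT map."""
    for node in graph.nodes:
        gs = gene_sets.get(node)
        if gs is not None and len(gs.genes) >= 1:
            graph.nodes[node]["gene_count"] = len(gs.genes)
            graph.nodes[node]["size"] = math.log(len(gs.genes))


def significant_subgraph(graph: nx.Graph | nx.MultiDiGraph,
                         significant_ids: Iterable[str],
                         scores: Optional[Mapping[str, float]] = None) -> nx.Graph:
    """Extract the visualization subgraph around significant pathways.

    GO (directed): BFS over child -> parent edges from every significant
    node; an ancestor is kept only if the root is reachable from it, so
    every non-significant connector lies on a significant-to-root path.
    Significant nodes disconnected from the root stay as isolated
    components with a warning. An empty significant set yields the root
    alone. KEGG (undirected): significant nodes plus their one-hop
    neighbors and induced edges.

    Nodes carry ``significant`` flags and, when ``scores`` gives a pathway
    disturbance score, a ``score`` attribute.
    """
    scores = dict(scores or {})
    significant = set(significant_ids)
    missing = significant - set(graph.nodes)
    if missing:
        logger.warning("%d significant ids absent from the graph: %s",
                       len(missing), sorted(missing)[:5])
        significant -= missing

    if graph.is_directed():
        root = graph.graph.get("root", GO_ROOT)
        reaches_root = {root} | nx.ancestors(graph, root)
        keep: set[str] = set(significant) | ({root} if root in graph else set())
        for node in significant:
            ancestors = nx.descendants(graph, node)  # parent direction
            if root not in ancestors and node != root:
                logger.warning("significant node %s has no path to root %s",
                               node, root)
            keep |= {a for a in ancestors if a in reaches_root}
        sub = graph.subgraph(keep).copy()
    else:
        keep = set(significant)
        for node in significant:
            keep |= set(graph.neighbors(node))
        sub = graph.subgraph(keep).copy()

    for node in sub.nodes:
        sub.nodes[node]["significant"] = node in significant
        if node in scores:
            sub.nodes[node]["score"] = float(scores[node])
    return sub


def export_subgraph(subgraph: nx.Graph, edges_path: str | Path,
                    nodes_path: str | Path) -> None:
    """Write a tab-separated edge list and a JSON node table, stably ordered."""
    edges_path, nodes_path = Path(edges_path), Path(nodes_path)
    edge_rows = []
    if subgraph.is_multigraph():
        it = subgraph.edges(keys=True, data=True)
        for u, v, _k, data in it:
            edge_rows.append((u, v, data.get("relation", "")))
    else:
        for u, v, data in subgraph.edges(data=True):
            a, b = sorted((u, v))
            edge_rows.append((a, b, data.get("relation", "")))
    edge_rows = sorted(set(edge_rows))
    with open(edges_path, "w") as fh:
        fh.write("source\ttarget\trelation\n")
        for u, v, rel in edge_rows:
            fh.write(f"{u}\t{v}\t{rel}\n")

    nodes = []
    for node in sorted(subgraph.nodes):
        data = subgraph.nodes[node]
        nodes.append({
            "id": node,
            "name": data.get("name", node),
            "significant": bool(data.get("significant", False)),
            "score": data.get("score"),
            "gene_count": data.get("gene_count"),
            "size": data.get("size"),
        })
    meta = {"directed": subgraph.is_directed(),
            "root": subgraph.graph.get("root"),
            "source": subgraph.graph.get("source")}
    with open(nodes_path, "w") as fh:
        json.dump({"meta": meta, "nodes": nodes}, fh, indent=1, sort_keys=True)


def import_subgraph(edges_path: str | Path, nodes_path: str | Path) -> nx.Graph:
    """Re-load an exported subgraph (inverse of `export_subgraph`)."""
    with open(nodes_path) as fh:
        payload = json.load(fh)
    meta = payload.get("meta", {})
    graph: nx.Graph
    graph = nx.MultiDiGraph() if meta.get("directed") else nx.Graph()
    graph.graph["root"] = meta.get("root")
    graph.graph["source"] = meta.get("source")
    for node in payload["nodes"]:
        attrs = {k: v for k, v in node.items() if k != "id" and v is not None}
        graph.add_node(node["id"], **attrs)
    with open(edges_path) as fh:
        header = fh.readline()
        for line in fh:
            u, v, rel = line.rstrip("\n").split("\t")
            graph.add_edge(u, v, relation=rel)
    return graph
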