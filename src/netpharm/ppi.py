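"""Background PPI network construction from STRING-dialect edge lists.

The background network is read from a ``protein.links``-style file
(whitespace-separated, header ``protein1 protein2 combined_score``, ids
prefixed with an NCBI taxon such as ``10090.`` for mouse), filtered at a
confidence threshold, standardized to Entrez gene ids via an alias table,
and reduced to its largest connected component so the random-walk
transition operator is well defined (no dangling nodes).

Edges are undirected and unweighted for propagation; combined scores are
kept only for confidence filtering.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .exceptions import ConfigurationError, FormatError, InputDataError

logger = logging.getLogger(__name__)

STRING_HEADER = ("protein1", "protein2", "combined_score")
DEFAULT_SCORE_THRESHOLD = 400  # STRING "medium confidence"

#: canonical edge key: unordered pair stored as a sorted tuple
EdgeKey = tuple[str, str]


def _edge_key(a: str, b: str) -> EdgeKey:
    return (a, b) if a <= b else (b, a)


class Network:
    """Undirected, connected background network over string gene ids.

    Node ordering is canonical (lexicographic) and shared by every score
    vector computed on the network, so vectors from different seedings
    are directly comparable position by position.
    """

    def __init__(self, graph: nx.Graph):
        if graph.number_of_nodes() == 0:
            raise InputDataError("network has no nodes")
        self.graph = graph
        self.node_order: tuple[str, ...] = tuple(sorted(graph.nodes))
        self._index = {n: i for i, n in enumerate(self.node_order)}

    # -- construction -------------------------------------------------

    @classmethod
    def from_edges(
        cls, edges: Mapping[EdgeKey, int] | Iterable[EdgeKey]
    ) -> "Network":
        """Build a network, removing self-loops and keeping only the LCC.

        ``edges`` may be a mapping pair -> confidence score or a plain
        iterable of pairs (scores then default to None).
        """
        g = nx.Graph()
        if isinstance(edges, Mapping):
            items = edges.items()
        else:
            items = ((e, None) for e in edges)
        for (a, b), score in items:
            if a == b:
                continue
            if g.has_edge(a, b):
                prev = g.edges[a, b].get("score")
                if score is not None and (prev is None or score > prev):
                    g.edges[a, b]["score"] = score
            else:
                g.add_edge(a, b, score=score)
        if g.number_of_nodes() == 0:
            raise InputDataError("no edges left after cleanup")
        components = list(nx.connected_components(g))
        if len(components) > 1:
            lcc = max(components, key=lambda c: (len(c), min(c)))
            dropped = g.number_of_nodes() - len(lcc)
            logger.info(
                "keeping largest connected component: %d nodes kept, %d dropped",
                len(lcc),
                dropped,
            )
            g = g.subgraph(lcc).copy()
        return cls(g)

    # -- queries ------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def __contains__(self, node: str) -> bool:
        return node in self.graph

    def index_of(self, node: str) -> int:
        return self._index[node]

    def edge_dict(self) -> dict[EdgeKey, int | None]:
        return {
            _edge_key(a, b): data.get("score")
            for a, b, data in self.graph.edges(data=True)
        }

    # -- export -------------------------------------------------------

    def write(self, path: str | Path, stats_extra: dict | None = None) -> None:
        """Write an edge-list TSV plus a JSON stats sidecar."""
        path = Path(path)
        lines = ["node1\tnode2\tscore"]
        for (a, b), score in sorted(self.edge_dict().items()):
            lines.append(f"{a}\t{b}\t{'' if score is None else score}")
        path.write_text("\n".join(lines) + "\n")
        stats = {"nodes": self.n_nodes, "edges": self.n_edges}
        if stats_extra:
            stats.update(stats_extra)
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(stats, sort_keys=True, indent=2) + "\n"
        )


@dataclass
class SeedSet:
    """A requested gene list restricted to the network's node set."""

    requested: list[str]
    mapped: list[str]
    label: str = ""

    @property
    def overlap(self) -> int:
        return len(self.mapped)


def read_string_links(
    source: str | Path, score_threshold: int = DEFAULT_SCORE_THRESHOLD
) -> dict[EdgeKey, int]:
    """Parse a STRING protein.links file into an undirected edge map.

    Edges with ``combined_score >= score_threshold`` are kept (the
    threshold is inclusive).  STRING lists both orientations of each
    pair; they collapse to a single undirected edge keeping the maximum
    score.  Surviving zero edges is an explicit error — an empty
    background network is never accepted silently.
    """
    source = Path(source)
    edges: dict[EdgeKey, int] = {}
    with source.open() as fh:
        header = fh.readline().split()
        if [h.strip() for h in header[:3]] != list(STRING_HEADER):
            raise FormatError(
                f"{source}: expected header {' '.join(STRING_HEADER)!r}, "
                f"got {' '.join(header)!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 3:
                raise FormatError(f"{source} line {lineno}: expected 3 fields")
            try:
                score = int(parts[2])
            except ValueError as exc:
                raise FormatError(
                    f"{source} line {lineno}: non-integer combined_score "
                    f"{parts[2]!r}"
                ) from exc
            if score < score_threshold:
                continue
            key = _edge_key(parts[0], parts[1])
            if key[0] == key[1]:
                continue
            prev = edges.get(key)
            if prev is None or score > prev:
                edges[key] = score
    if not edges:
        raise InputDataError(
            f"{source}: no edges with combined_score >= {score_threshold}"
        )
    return edges


def write_string_links(edges: Mapping[EdgeKey, int], path: str | Path) -> None:
    """Write an edge map in the STRING protein.links dialect."""
    path = Path(path)
    lines = [" ".join(STRING_HEADER)]
    for (a, b), score in sorted(edges.items()):
        lines.append(f"{a} {b} {score}")
    path.write_text("\n".join(lines) + "\n")


def load_alias_map(source: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping protein ids to Entrez gene ids.

    A protein may map to at most one gene; conflicting rows are an error.
    """
    aliases: dict[str, str] = {}
    for lineno, line in enumerate(Path(source).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2 or not parts[1].strip():
            raise FormatError(f"{source} line {lineno}: expected 2 tab-separated fields")
        protein, gene = parts[0].strip(), parts[1].strip()
        if protein in aliases and aliases[protein] != gene:
            raise InputDataError(
                f"{source}: protein {protein!r} maps to both "
                f"{aliases[protein]!r} and {gene!r}"
            )
        aliases[protein] = gene
    if not aliases:
        raise InputDataError(f"{source}: empty alias map")
    return aliases


def write_alias_map(aliases: Mapping[str, str], path: str | Path) -> None:
    path = Path(path)
    lines = [f"{p}\t{g}" for p, g in sorted(aliases.items())]
    path.write_text("\n".join(lines) + "\n")


def apply_alias_map(
    edges: Mapping[EdgeKey, int], aliases: Mapping[str, str]
) -> Network:
    """Translate protein-id edges to gene ids and build the network.

    Edges with an unmapped endpoint are dropped (counted and logged);
    parallel edges created by many-to-one mapping collapse keeping the
    max score; self-loops created by mapping are removed; finally the
    largest connected component is extracted.
    """
    if not aliases:
        raise InputDataError("alias map is empty")
    mapped: dict[EdgeKey, int] = {}
    n_unmapped = 0
    for (a, b), score in edges.items():
        ga, gb = aliases.get(a), aliases.get(b)
        if ga is None or gb is None:
            n_unmapped += 1
            continue
        if ga == gb:
            continue  # mapping collapsed the edge to a self-loop
        key = _edge_key(ga, gb)
        prev = mapped.get(key)
        if prev is None or (score is not None and score > prev):
            mapped[key] = score
    if n_unmapped:
        logger.info("dropped %d edge(s) with unmapped endpoints", n_unmapped)
    if not mapped:
        raise InputDataError("no edges survived alias mapping")
    return Network.from_edges(mapped)


def restrict_seeds(genes: Sequence[str], network: Network, label: str = "") -> SeedSet:
    """Intersect a gene list with the network nodes, preserving order.

    The size of the intersection is the "overlap" reported for each seed
    list.  An empty intersection is an error: propagation cannot be
    seeded.
    """
    if not genes:
        raise InputDataError(f"seed list {label!r} is empty")
    seen: set[str] = set()
    mapped = []
    for g in genes:
        if g in network and g not in seen:
            mapped.append(g)
            seen.add(g)
    if not mapped:
        raise InputDataError(
            f"none of the {len(genes)} genes in seed list {label!r} "
            "are present in the network"
        )
    return SeedSet(requested=list(genes), mapped=mapped, label=label)
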