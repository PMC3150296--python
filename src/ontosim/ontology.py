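"""Ontology DAG: OBO parsing, validation and structural queries.

The ontology is a rooted directed acyclic graph whose edges are ``is-a``
(subtype) relations pointing from the more specific term (child) to the more
general one (parent).  Every similarity measure, the annotation propagation
and the enrichment depth criterion are defined on this structure, so parsing
normalises aggressively: obsolete terms are retained but carry no edges, any
non-``is_a`` relationship is dropped with a warning, and a synthetic root is
inserted when the file contains several parentless terms so that a common
ancestor always exists.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

#: accession of the synthetic root inserted above multi-root ontologies
SYNTHETIC_ROOT = "SYN:0000000"

_RELATIONS = ("parents", "children", "siblings")


class OntologyError(Exception):
    """Structural problem in an ontology file (cycle, dangling edge...)."""


class LookupError_(KeyError):
    """Unknown or unusable accession."""


@dataclass(frozen=True)
class OntologyTerm:
    """A single ontology term.

    ``parents`` holds the accessions one ``is-a`` edge up; obsolete terms
    keep an empty parent set.
    """

    accession: str
    name: str = ""
    parents: frozenset[str] = field(default_factory=frozenset)
    obsolete: bool = False


class OntologyDAG:
    """Rooted DAG of ontology terms connected by ``is-a`` edges.

    Parameters
    ----------
    terms
        Iterable of :class:`OntologyTerm`.  Parent accessions must resolve
        to terms of the iterable; edges from/to obsolete terms are rejected.
    alt_ids
        Optional mapping from alternative accession to canonical accession.

    Internally the live (non-obsolete) part is a :class:`networkx.DiGraph`
    with edges child → parent.
    """

    def __init__(self, terms: Iterable[OntologyTerm], alt_ids: dict[str, str] | None = None):
        self.terms: dict[str, OntologyTerm] = {}
        self.alt_ids: dict[str, str] = dict(alt_ids or {})
        g = nx.DiGraph()
        for t in terms:
            if not t.accession:
                raise OntologyError("empty accession")
            if t.accession in self.terms:
                raise OntologyError(f"duplicate accession {t.accession!r}")
            self.terms[t.accession] = t
            if not t.obsolete:
                g.add_node(t.accession, name=t.name)
        for t in self.terms.values():
            if t.obsolete:
                continue
            for p in t.parents:
                if p not in self.terms:
                    raise OntologyError(f"dangling is_a target {p!r} (child {t.accession!r})")
                if self.terms[p].obsolete:
                    raise OntologyError(f"is_a target {p!r} is obsolete (child {t.accession!r})")
                g.add_edge(t.accession, p)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            pass
        else:
            a, b = cycle[0][:2]
            raise OntologyError(f"cycle detected through edge {a!r} -> {b!r}")
        roots = sorted(n for n in g.nodes if g.out_degree(n) == 0)
        if not roots:
            raise OntologyError("ontology has no terms")
        if len(roots) > 1:
            logger.info("inserting synthetic root %s above %d parentless terms",
                        SYNTHETIC_ROOT, len(roots))
            self.terms[SYNTHETIC_ROOT] = OntologyTerm(SYNTHETIC_ROOT, "synthetic root")
            g.add_node(SYNTHETIC_ROOT, name="synthetic root")
            for r in roots:
                g.add_edge(r, SYNTHETIC_ROOT)
                self.terms[r] = OntologyTerm(
                    r, self.terms[r].name, frozenset({SYNTHETIC_ROOT}), False)
            roots = [SYNTHETIC_ROOT]
        self.root: str = roots[0]
        self.graph: nx.DiGraph = g
        self._depths: dict[str, int] | None = None

    # -- basic introspection -------------------------------------------------

    def __contains__(self, accession: str) -> bool:
        return accession in self.terms

    def __len__(self) -> int:
        return len(self.graph)

    def live_terms(self) -> list[str]:
        """Accessions of all non-obsolete terms."""
        return list(self.graph.nodes)

    def resolve(self, accession: str) -> str:
        """Map an alt_id to its canonical accession (identity otherwise)."""
        return self.alt_ids.get(accession, accession)

    def _check(self, t: str) -> str:
        t = self.resolve(t)
        if t not in self.terms:
            raise LookupError_(f"unknown accession {t!r}")
        if self.terms[t].obsolete:
            raise LookupError_(f"accession {t!r} is obsolete")
        return t

    # -- structural queries --------------------------------------------------

    def ancestors(self, t: str, include_self: bool = True) -> set[str]:
        """Transitive closure over parent edges (the ``is-a`` sub-DAG above t)."""
        t = self._check(t)
        anc = nx.descendants(self.graph, t)  # edges run child -> parent
        if include_self:
            anc.add(t)
        return anc

    def descendants(self, t: str, include_self: bool = True) -> set[str]:
        """Transitive closure over child edges."""
        t = self._check(t)
        des = nx.ancestors(self.graph, t)
        if include_self:
            des.add(t)
        return des

    def depth(self, t: str) -> int:
        """Minimum number of edges from the root down to ``t`` (root = 0)."""
        t = self._check(t)
        if self._depths is None:
            self._depths = nx.single_source_shortest_path_length(
                self.graph.reverse(copy=False), self.root)
        if t not in self._depths:
            raise LookupError_(f"term {t!r} not reachable from root {self.root!r}")
        return self._depths[t]

    def related_terms(self, t: str, relation: str) -> set[str]:
        """One-step neighbours: ``parents``, ``children`` or ``siblings``."""
        t = self._check(t)
        if relation == "parents":
            return set(self.graph.successors(t))
        if relation == "children":
            return set(self.graph.predecessors(t))
        if relation == "siblings":
            sibs: set[str] = set()
            for p in self.graph.successors(t):
                sibs.update(self.graph.predecessors(p))
            sibs.discard(t)
            return sibs
        raise ValueError(f"unknown relation {relation!r}; expected one of {_RELATIONS}")

    def induced_graph(self, leaves: Iterable[str]) -> "OntologyDAG":
        """Sub-DAG on the union of the ancestor closures of ``leaves``.

        The given terms become leaves of the extracted graph unless the
        closure of another leaf passes through them.
        """
        leaves = [self._check(t) for t in leaves]
        if not leaves:
            raise ValueError("empty leaf set")
        keep: set[str] = set()
        for t in leaves:
            keep |= self.ancestors(t, include_self=True)
        sub_terms = []
        for acc in keep:
            t = self.terms[acc]
            sub_terms.append(OntologyTerm(acc, t.name, frozenset(t.parents & keep)))
        return OntologyDAG(sub_terms)

    # -- leaves --------------------------------------------------------------

    def leaves(self) -> list[str]:
        """Terms without children."""
        return [n for n in self.graph.nodes if self.graph.in_degree(n) == 0]

    # -- serialization -------------------------------------------------------

    def to_obo(self) -> str:
        """Serialize as a minimal OBO 1.2 flat file (``is_a`` edges only)."""
        out = ["format-version: 1.2", "ontology: ontosim-export", ""]
        for acc in sorted(self.terms):
            t = self.terms[acc]
            out.append("[Term]")
            out.append(f"id: {acc}")
            if t.name:
                out.append(f"name: {t.name}")
            for alt, canon in sorted(self.alt_ids.items()):
                if canon == acc:
                    out.append(f"alt_id: {alt}")
            for p in sorted(t.parents):
                out.append(f"is_a: {p} ! {self.terms[p].name}")
            if t.obsolete:
                out.append("is_obsolete: true")
            out.append("")
        return "\n".join(out) + "\n"

    def to_edge_list(self) -> str:
        """Two-column TSV of child → parent edges."""
        lines = ["#child\tparent"]
        lines += [f"{c}\t{p}" for c, p in sorted(self.graph.edges)]
        return "\n".join(lines) + "\n"

    def to_dot(self) -> str:
        """Graphviz DOT, edge direction child → parent."""
        def q(s: str) -> str:
            return '"' + s.replace('"', r'\"') + '"'
        lines = ["digraph ontology {"]
        for n in sorted(self.graph.nodes):
            lines.append(f"  {q(n)} [label={q(self.terms[n].name or n)}];")
        for c, p in sorted(self.graph.edges):
            lines.append(f"  {q(c)} -> {q(p)};")
        lines.append("}")
        return "\n".join(lines) + "\n"

    def write_graphml(self, path: str) -> None:
        nx.write_graphml(self.graph, path)


def parse_obo(source) -> OntologyDAG:
    """Parse an OBO 1.2 flat file into a validated :class:`OntologyDAG`.

    Parameters
    ----------
    source
        Path, file-like object, or the OBO text itself (detected by the
        presence of a ``[Term]`` stanza and a newline).

    Only ``is_a`` edges are kept; other relationship types are discarded
    with a logged warning.  Obsolete terms are retained but carry no edges.
    Multiple parentless terms are normalised under a synthetic root.
    """
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    graph = obonet.read_obo(source, ignore_obsolete=False)

    dropped_rel: set[str] = set()
    terms: dict[str, OntologyTerm] = {}
    alt_ids: dict[str, str] = {}
    for acc, data in graph.nodes(data=True):
        if "name" not in data and graph.degree(acc) > 0 and not data:
            # node materialised only because an is_a line pointed at it
            raise OntologyError(f"dangling is_a target {acc!r}")
        obsolete = str(data.get("is_obsolete", "false")).lower() == "true"
        parents: set[str] = set()
        if not obsolete:
            for _, parent, rel in graph.out_edges(acc, keys=True):
                if rel != "is_a":
                    dropped_rel.add(rel)
                    continue
                parents.add(parent)
        terms[acc] = OntologyTerm(acc, data.get("name", ""), frozenset(parents), obsolete)
        for alt in data.get("alt_id", []):
            alt_ids[alt] = acc
    if dropped_rel:
        logger.warning("ignored non-is_a relationship types: %s", sorted(dropped_rel))
    # parents referencing obsolete or unknown targets surface in the constructor
    live_parents = {p for t in terms.values() for p in t.parents}
    for p in live_parents:
        if p not in terms:
            raise OntologyError(f"dangling is_a target {p!r}")
    return OntologyDAG(terms.values(), alt_ids)
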