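"""Ontology graph handling: OBO parsing, annotation reading and propagation.

Terms form a DAG with ``is_a`` and ``part_of`` edges pointing child -> parent.
Annotation propagation applies the true-path rule over both edge kinds: a gene
annotated to a term is annotated to every ancestor of that term.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import IO, Iterable, Optional

import networkx as nx

from .errors import ParseError, ValidationError

NAMESPACES = ("biological_process", "molecular_function", "cellular_component")


@dataclass(frozen=True)
class OntologyTerm:
    term_id: str
    name: str = ""
    namespace: str = "biological_process"
    # (parent_id, relation) with relation in {"is_a", "part_of"}
    parents: tuple[tuple[str, str], ...] = ()
    obsolete: bool = False


class OntologyDAG:
    """Directed acyclic term graph; edges run child -> parent."""

    def __init__(self, terms: Iterable[OntologyTerm]) -> None:
        self.terms: dict[str, OntologyTerm] = {}
        graph = nx.DiGraph()
        for term in terms:
            if term.term_id in self.terms:
                raise ParseError(f"duplicate term id {term.term_id}")
            if term.obsolete:
                continue
            self.terms[term.term_id] = term
            graph.add_node(term.term_id)
        for term in self.terms.values():
            for parent_id, rel in term.parents:
                if parent_id not in self.terms:
                    raise ParseError(
                        f"term {term.term_id} references undeclared parent {parent_id}"
                    )
                graph.add_edge(term.term_id, parent_id, rel=rel)
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            path = " -> ".join(str(a) for a, _ in cycle)
            raise ParseError(f"ontology contains a cycle: {path}")
        self.graph = graph
        self._ancestor_cache: dict[str, frozenset[str]] = {}
        self._validate_roots()

    def _validate_roots(self) -> None:
        roots_by_ns: dict[str, list[str]] = {}
        for tid in self.graph.nodes:
            if self.graph.out_degree(tid) == 0:
                roots_by_ns.setdefault(self.terms[tid].namespace, []).append(tid)
        for ns, roots in roots_by_ns.items():
            if len(roots) != 1:
                raise ParseError(
                    f"namespace {ns} has {len(roots)} roots ({sorted(roots)}); expected 1"
                )
        self.roots: dict[str, str] = {ns: r[0] for ns, r in roots_by_ns.items()}

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def ancestors(self, term_id: str) -> frozenset[str]:
        """All ancestors of a term via is_a/part_of edges (excluding itself)."""
        if term_id not in self.terms:
            raise ValidationError(f"unknown term {term_id}")
        cached = self._ancestor_cache.get(term_id)
        if cached is None:
            cached = frozenset(nx.descendants(self.graph, term_id))
            self._ancestor_cache[term_id] = cached
        return cached

    def edges(self) -> list[tuple[str, str, str]]:
        """(child, parent, relation) triples, sorted."""
        return sorted(
            (c, p, d["rel"]) for c, p, d in self.graph.edges(data=True)
        )


@dataclass
class AnnotationSet:
    """gene_id -> set of term ids; ``closed`` marks ancestor closure applied."""

    mapping: dict[str, set[str]] = field(default_factory=dict)
    closed: bool = False

    def genes(self) -> set[str]:
        return set(self.mapping)

    def terms_for(self, gene_id: str) -> set[str]:
        return self.mapping.get(gene_id, set())


def parse_obo(stream: IO[str]) -> OntologyDAG:
    """Parse an OBO 1.2 document into an OntologyDAG.

    Only ``[Term]`` stanzas are read; obsolete terms are dropped before graph
    construction.  ``is_a`` and ``relationship: part_of`` lines become edges.
    """
    terms: list[OntologyTerm] = []
    stanza: Optional[dict] = None

    def flush() -> None:
        if stanza is None or "id" not in stanza:
            return
        terms.append(
            OntologyTerm(
                term_id=stanza["id"],
                name=stanza.get("name", ""),
                namespace=stanza.get("namespace", "biological_process"),
                parents=tuple(stanza.get("parents", [])),
                obsolete=stanza.get("obsolete", False),
            )
        )

    in_term = False
    for raw in stream:
        line = raw.split("!")[0].strip()
        if not line:
            continue
        if line.startswith("["):
            flush()
            stanza = {} if line == "[Term]" else None
            in_term = line == "[Term]"
            continue
        if not in_term or stanza is None or ":" not in line:
            continue
        key, value = line.split(":", 1)
        key, value = key.strip(), value.strip()
        if key == "id":
            stanza["id"] = value
        elif key == "name":
            stanza["name"] = value
        elif key == "namespace":
            stanza["namespace"] = value
        elif key == "is_a":
            stanza.setdefault("parents", []).append((value.split()[0], "is_a"))
        elif key == "relationship":
            parts = value.split()
            if len(parts) >= 2 and parts[0] == "part_of":
                stanza.setdefault("parents", []).append((parts[1], "part_of"))
        elif key == "is_obsolete":
            stanza["obsolete"] = value.lower() == "true"
    flush()
    return OntologyDAG(terms)


def write_obo(dag: OntologyDAG, stream: IO[str]) -> None:
    """Serialize a DAG back to minimal OBO 1.2 text."""
    stream.write("format-version: 1.2\n")
    for tid in sorted(dag.terms):
        term = dag.terms[tid]
        stream.write(f"\n[Term]\nid: {term.term_id}\nname: {term.name}\n")
        stream.write(f"namespace: {term.namespace}\n")
        for parent, rel in term.parents:
            if rel == "is_a":
                stream.write(f"is_a: {parent}\n")
            else:
                stream.write(f"relationship: part_of {parent}\n")


def read_gaf(stream: IO[str], exclude_evidence: Optional[set[str]] = None) -> AnnotationSet:
    """Read GAF 2.x annotations (columns 2 = object id, 5 = term, 7 = evidence).

    No evidence-code filter is applied by default; pass ``exclude_evidence``
    to drop codes such as IEA.
    """
    exclude = exclude_evidence or set()
    mapping: dict[str, set[str]] = {}
    for raw in stream:
        if not raw.strip() or raw.startswith("!"):
            continue
        cols = raw.rstrip("\n").split("\t")
        if len(cols) < 5:
            raise ParseError(f"GAF line has {len(cols)} columns, expected >= 5")
        gene, term = cols[1].strip(), cols[4].strip()
        evidence = cols[6].strip() if len(cols) > 6 else ""
        if evidence in exclude:
            continue
        mapping.setdefault(gene, set()).add(term)
    return AnnotationSet(mapping=mapping, closed=False)


def read_annotations_tsv(stream: IO[str]) -> AnnotationSet:
    """Read the minimal two-column dialect: gene <tab> term per line."""
    mapping: dict[str, set[str]] = {}
    reader = csv.reader(stream, delimiter="\t")
    for i, row in enumerate(reader, start=1):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if row[0].strip().lower() in {"gene", "gene_id"}:  # tolerate a header
            continue
        if len(row) < 2:
            raise ParseError(f"line {i}: expected 'gene<TAB>term'")
        mapping.setdefault(row[0].strip(), set()).add(row[1].strip())
    return AnnotationSet(mapping=mapping, closed=False)


def write_annotations_tsv(annots: AnnotationSet, stream: IO[str]) -> None:
    for gene in sorted(annots.mapping):
        for term in sorted(annots.mapping[gene]):
            stream.write(f"{gene}\t{term}\n")


def propagate_annotations(dag: OntologyDAG, raw: AnnotationSet) -> AnnotationSet:
    """Close an annotation set under the true-path rule (is_a and part_of).

    Annotation to a term absent from the DAG is an error listing the
    offending (gene, term) pairs.  Idempotent on already-closed sets.
    """
    bad = sorted(
        (gene, term)
        for gene, terms in raw.mapping.items()
        for term in terms
        if term not in dag
    )
    if bad:
        shown = ", ".join(f"({g}, {t})" for g, t in bad[:10])
        raise ValidationError(
            f"{len(bad)} annotation(s) to unknown terms: {shown}"
            + ("..." if len(bad) > 10 else "")
        )
    closed: dict[str, set[str]] = {}
    for gene, terms in raw.mapping.items():
        full = set(terms)
        for term in terms:
            full |= dag.ancestors(term)
        closed[gene] = full
    return AnnotationSet(mapping=closed, closed=True)
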