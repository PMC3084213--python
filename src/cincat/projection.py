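"""Cross-species candidate gene sets: orthology projection and term membership.

Two partially overlapping human candidate lists are produced: the direct
orthologs of catalogue genes, and the human genes annotated to strongly
enriched terms (fold >= 3 by default, inclusive).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import IO, Iterable, Optional

from .catalogue import CINCatalogue
from .enrichment import EnrichmentResult
from .errors import ParseError, ValidationError
from .ontology import AnnotationSet

ORTHOLOGY_KINDS = frozenset({"SEQUENCE", "FUNCTIONAL"})


def normalize_symbol(symbol: str) -> str:
    return symbol.strip().upper()


@dataclass(frozen=True)
class OrthologyRecord:
    yeast_orf: str
    human_symbol: str
    kind: str = "SEQUENCE"

    def __post_init__(self) -> None:
        if self.kind not in ORTHOLOGY_KINDS:
            raise ValidationError(
                f"orthology kind {self.kind!r} not in {sorted(ORTHOLOGY_KINDS)}"
            )


@dataclass
class OrthologyMap:
    records: list[OrthologyRecord] = field(default_factory=list)

    def by_yeast(self) -> dict[str, list[OrthologyRecord]]:
        out: dict[str, list[OrthologyRecord]] = {}
        for rec in self.records:
            out.setdefault(rec.yeast_orf, []).append(rec)
        return out


@dataclass
class CandidateSet:
    """Human candidates plus per-gene supporting evidence.

    ``evidence`` maps each human symbol to supporting yeast genes (ORTHOLOGY
    method) or supporting term ids (GO_TERM method).
    """

    method: str  # ORTHOLOGY or GO_TERM
    evidence: dict[str, set[str]] = field(default_factory=dict)
    n_terms_contributing: int = 0
    unmapped_genes: set[str] = field(default_factory=set)

    def genes(self) -> set[str]:
        return set(self.evidence)

    def __len__(self) -> int:
        return len(self.evidence)

    @property
    def association_count(self) -> int:
        if self.method != "GO_TERM":
            return 0
        return sum(len(v) for v in self.evidence.values())


@dataclass(frozen=True)
class OverlapSummary:
    size_a: int
    size_b: int
    intersection: int
    union: int
    jaccard: float


def read_orthology(stream: IO[str]) -> OrthologyMap:
    """Read orthology TSV (yeast_orf, human_symbol, kind); duplicates collapse."""
    reader = csv.DictReader(stream, delimiter="\t")
    if reader.fieldnames is None or not {"yeast_orf", "human_symbol"} <= set(reader.fieldnames):
        raise ParseError("orthology table needs columns yeast_orf, human_symbol[, kind]")
    seen: set[OrthologyRecord] = set()
    records: list[OrthologyRecord] = []
    for row in reader:
        rec = OrthologyRecord(
            yeast_orf=(row["yeast_orf"] or "").strip(),
            human_symbol=normalize_symbol(row["human_symbol"] or ""),
            kind=((row.get("kind") or "SEQUENCE").strip().upper() or "SEQUENCE"),
        )
        if not rec.yeast_orf or not rec.human_symbol:
            raise ParseError(f"line {reader.line_num}: empty yeast_orf or human_symbol")
        if rec not in seen:
            seen.add(rec)
            records.append(rec)
    return OrthologyMap(records=records)


def project_orthologs(catalogue: CINCatalogue, orthology: OrthologyMap) -> CandidateSet:
    """Human candidates = union of ortholog symbols over catalogue genes.

    Catalogue genes without any ortholog row are reported in
    ``unmapped_genes``; orthology rows for genes outside the catalogue are
    ignored.
    """
    by_yeast = orthology.by_yeast()
    evidence: dict[str, set[str]] = {}
    unmapped: set[str] = set()
    for gene in sorted(catalogue.genes()):
        recs = by_yeast.get(gene)
        if not recs:
            unmapped.add(gene)
            continue
        for rec in recs:
            evidence.setdefault(rec.human_symbol, set()).add(gene)
    return CandidateSet(method="ORTHOLOGY", evidence=evidence, unmapped_genes=unmapped)


def project_go_terms(
    enrichments: Iterable[EnrichmentResult],
    human_annots: AnnotationSet,
    fold_min: float = 3.0,
) -> CandidateSet:
    """Human candidates annotated to >=1 enriched term with fold >= fold_min.

    The fold cutoff is inclusive.  ``association_count`` counts gene-term
    pairs over the selected terms; ``n_terms_contributing`` counts selected
    terms that contributed at least one human gene.
    """
    if fold_min < 0:
        raise ValidationError(f"fold_min must be >= 0, got {fold_min}")
    if not human_annots.closed:
        raise ValidationError("human annotations must be closed before projection")
    selected = {r.term_id for r in enrichments if r.enriched and r.fold >= fold_min}
    evidence: dict[str, set[str]] = {}
    contributing: set[str] = set()
    for gene, terms in human_annots.mapping.items():
        hit = terms & selected
        if hit:
            evidence[normalize_symbol(gene)] = hit
            contributing |= hit
    return CandidateSet(
        method="GO_TERM",
        evidence=evidence,
        n_terms_contributing=len(contributing),
    )


def overlap_summary(a: CandidateSet, b: CandidateSet) -> OverlapSummary:
    ga, gb = a.genes(), b.genes()
    inter = len(ga & gb)
    union = len(ga | gb)
    return OverlapSummary(
        size_a=len(ga),
        size_b=len(gb),
        intersection=inter,
        union=union,
        jaccard=(inter / union) if union else 0.0,
    )


def write_candidates(candidates: CandidateSet, stream: IO[str]) -> None:
    writer = csv.writer(stream, delimiter="\t", lineterminator="\n")
    writer.writerow(["human_gene", "method", "evidence", "n_terms"])
    for gene in sorted(candidates.evidence):
        support = sorted(candidates.evidence[gene])
        n_terms = len(support) if candidates.method == "GO_TERM" else 0
        writer.writerow([gene, candidates.method, ";".join(support), n_terms])


def read_candidates(stream: IO[str]) -> CandidateSet:
    reader = csv.DictReader(stream, delimiter="\t")
    method: Optional[str] = None
    evidence: dict[str, set[str]] = {}
    terms: set[str] = set()
    for row in reader:
        method = row["method"]
        support = set(filter(None, (row["evidence"] or "").split(";")))
        evidence[row["human_gene"]] = support
        if method == "GO_TERM":
            terms |= support
    return CandidateSet(
        method=method or "ORTHOLOGY",
        evidence=evidence,
        n_terms_contributing=len(terms),
    )
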