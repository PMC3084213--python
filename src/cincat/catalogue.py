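"""Screen-hit ingestion and integration into a confidence-scored CIN catalogue.

The catalogue holds one record per gene, pooling evidence (assay, strength,
source) across any number of screen-hit tables plus literature-derived hit
lists.  Confidence is a two-level call: a gene is HIGH confidence when it was
reported by at least two independent sources or carries at least one STRONG
hit; everything else is LOW.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Optional

from .errors import ParseError, ValidationError

ASSAYS = frozenset({"CTF", "ALF", "GCR", "BIM", "LOH"})
STRENGTHS = frozenset({"STRONG", "WEAK"})

HIGH = "HIGH"
LOW = "LOW"


@dataclass(frozen=True)
class ScreenHit:
    """One hit of one gene in one assay reported by one source."""

    gene_id: str
    assay: str
    strength: str
    source: str
    allele: Optional[str] = None
    temperature: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValidationError("ScreenHit requires a non-empty gene_id")
        if self.assay not in ASSAYS:
            raise ValidationError(
                f"unknown assay {self.assay!r}; expected one of {sorted(ASSAYS)}"
            )
        if self.strength not in STRENGTHS:
            raise ValidationError(
                f"unknown strength {self.strength!r}; expected one of {sorted(STRENGTHS)}"
            )


@dataclass(frozen=True)
class GeneMeta:
    """Static per-gene annotation used for catalogue stratification."""

    gene_id: str
    essential: Optional[bool] = None
    nuclear: Optional[bool] = None
    verified_orf: bool = True
    functional_group: str = ""


@dataclass
class CatalogueRecord:
    gene_id: str
    evidence: list[ScreenHit] = field(default_factory=list)
    confidence: Optional[str] = None
    meta: Optional[GeneMeta] = None

    @property
    def assays(self) -> set[str]:
        return {h.assay for h in self.evidence}

    @property
    def sources(self) -> set[str]:
        return {h.source for h in self.evidence}

    @property
    def strengths(self) -> set[str]:
        return {h.strength for h in self.evidence}


class CINCatalogue:
    """Mapping of gene_id -> CatalogueRecord with set-like convenience."""

    def __init__(self, records: Iterable[CatalogueRecord] = ()) -> None:
        self._records: dict[str, CatalogueRecord] = {}
        for rec in records:
            if rec.gene_id in self._records:
                raise ValidationError(f"duplicate catalogue record for {rec.gene_id}")
            self._records[rec.gene_id] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[CatalogueRecord]:
        return iter(self._records.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._records

    def __getitem__(self, gene_id: str) -> CatalogueRecord:
        return self._records[gene_id]

    def genes(self) -> set[str]:
        return set(self._records)

    def records(self) -> list[CatalogueRecord]:
        return list(self._records.values())


@dataclass
class CatalogueSummary:
    total_genes: int
    essential_cin: int
    essential_universe: int
    nonessential_cin: int
    nonessential_universe: int
    unknown_essentiality: int
    essential_pct: Optional[float]
    nonessential_pct: Optional[float]
    high_confidence_fraction: Optional[float]
    per_assay_counts: dict[str, int]
    nuclear_breakdown: dict[str, dict[str, int]]


def _parse_bool(token: str, line_no: int, column: str) -> Optional[bool]:
    t = token.strip().lower()
    if t in {"", "na", "nan", "none"}:
        return None
    if t in {"1", "true", "t", "yes", "y"}:
        return True
    if t in {"0", "false", "f", "no", "n"}:
        return False
    raise ParseError(f"line {line_no}: cannot parse boolean {token!r} in column {column!r}")


def read_screen_table(stream: IO[str]) -> list[ScreenHit]:
    """Parse a tab-delimited screen-hit table into validated ScreenHit rows.

    The header must name at least ``gene``, ``assay``, ``strength`` and
    ``source``; ``allele`` and ``temperature`` are optional.  Row order is
    preserved.  A repeated (gene, assay, source) triple is a parse error.
    """
    reader = csv.DictReader(stream, delimiter="\t")
    if reader.fieldnames is None:
        return []
    required = {"gene", "assay", "strength", "source"}
    missing = required - set(reader.fieldnames)
    if missing:
        raise ParseError(f"screen table header missing column(s): {sorted(missing)}")

    hits: list[ScreenHit] = []
    seen: set[tuple[str, str, str]] = set()
    for row in reader:
        line_no = reader.line_num
        gene = (row["gene"] or "").strip()
        assay = (row["assay"] or "").strip().upper()
        strength = (row["strength"] or "").strip().upper()
        source = (row["source"] or "").strip()
        if not gene:
            raise ParseError(f"line {line_no}: empty gene id")
        if assay not in ASSAYS:
            raise ParseError(
                f"line {line_no}: unknown assay {row['assay']!r} "
                f"(expected one of {sorted(ASSAYS)})"
            )
        if strength not in STRENGTHS:
            raise ParseError(
                f"line {line_no}: unknown strength {row['strength']!r} "
                f"(expected one of {sorted(STRENGTHS)})"
            )
        key = (gene, assay, source)
        if key in seen:
            raise ParseError(f"line {line_no}: duplicate (gene, assay, source) {key}")
        seen.add(key)
        temp_raw = (row.get("temperature") or "").strip()
        temperature = float(temp_raw) if temp_raw else None
        allele = (row.get("allele") or "").strip() or None
        hits.append(ScreenHit(gene, assay, strength, source, allele, temperature))
    return hits


def read_gene_meta(stream: IO[str]) -> list[GeneMeta]:
    """Parse a gene-metadata TSV (gene, essential, nuclear, verified_orf, ...)."""
    reader = csv.DictReader(stream, delimiter="\t")
    if reader.fieldnames is None or "gene" not in reader.fieldnames:
        raise ParseError("gene metadata table must have a header with a 'gene' column")
    out: list[GeneMeta] = []
    seen: set[str] = set()
    for row in reader:
        line_no = reader.line_num
        gene = (row["gene"] or "").strip()
        if not gene:
            raise ParseError(f"line {line_no}: empty gene id")
        if gene in seen:
            raise ParseError(f"line {line_no}: duplicate gene metadata for {gene}")
        seen.add(gene)
        verified = _parse_bool(row.get("verified_orf", "1") or "1", line_no, "verified_orf")
        out.append(
            GeneMeta(
                gene_id=gene,
                essential=_parse_bool(row.get("essential", "") or "", line_no, "essential"),
                nuclear=_parse_bool(row.get("nuclear", "") or "", line_no, "nuclear"),
                verified_orf=True if verified is None else verified,
                functional_group=(row.get("functional_group") or "").strip(),
            )
        )
    return out


def integrate_screens(
    hit_tables: list[list[ScreenHit]], meta: Iterable[GeneMeta]
) -> CINCatalogue:
    """Union screen-hit tables into one deduplicated catalogue.

    Evidence is pooled per gene across all tables.  Genes absent from the
    metadata table raise a warning and get a null-meta record; genes whose
    metadata marks them unverified are retained but flagged through their
    attached GeneMeta.
    """
    if not hit_tables:
        raise ValidationError("integrate_screens requires at least one hit table")
    meta_by_gene = {m.gene_id: m for m in meta}
    records: dict[str, CatalogueRecord] = {}
    for table in hit_tables:
        for hit in table:
            rec = records.get(hit.gene_id)
            if rec is None:
                rec = CatalogueRecord(gene_id=hit.gene_id)
                records[hit.gene_id] = rec
            if hit not in rec.evidence:
                rec.evidence.append(hit)
    unknown = sorted(g for g in records if g not in meta_by_gene)
    if unknown:
        warnings.warn(
            f"{len(unknown)} gene(s) missing from metadata: {', '.join(unknown[:10])}"
            + ("..." if len(unknown) > 10 else ""),
            stacklevel=2,
        )
    for gene, rec in records.items():
        rec.meta = meta_by_gene.get(gene)
    catalogue = CINCatalogue(records[g] for g in sorted(records))
    return classify_confidence(catalogue)


def classify_confidence(catalogue: CINCatalogue) -> CINCatalogue:
    """Assign HIGH/LOW confidence in place and return the catalogue.

    HIGH iff the gene has >= 2 distinct sources or any STRONG hit.
    """
    for rec in catalogue:
        if not rec.evidence:
            raise ValidationError(f"catalogue record {rec.gene_id} has no evidence")
        rec.confidence = (
            HIGH if len(rec.sources) >= 2 or "STRONG" in rec.strengths else LOW
        )
    return catalogue


def _pct(count: int, universe: int) -> Optional[float]:
    """Percentage rounded in the reporting style: integer at >=10%, one decimal below."""
    if universe == 0:
        return None
    pct = 100.0 * count / universe
    if pct >= 10.0:
        return float(round(pct))
    return round(pct, 1)


def summarize(catalogue: CINCatalogue, universe: Iterable[GeneMeta]) -> CatalogueSummary:
    """Compute catalogue-level counts and essential/non-essential proportions.

    The universe supplies essentiality flags; genes with unknown essentiality
    are excluded from both proportion denominators and reported separately.
    """
    universe = list(universe)
    essential_universe = sum(1 for m in universe if m.essential is True)
    nonessential_universe = sum(1 for m in universe if m.essential is False)
    meta_by_gene = {m.gene_id: m for m in universe}

    essential_cin = 0
    nonessential_cin = 0
    unknown = 0
    high = 0
    per_assay: dict[str, int] = {a: 0 for a in sorted(ASSAYS)}
    nuclear_breakdown = {
        loc: {HIGH: 0, LOW: 0} for loc in ("nuclear", "other", "unknown")
    }
    for rec in catalogue:
        m = rec.meta if rec.meta is not None else meta_by_gene.get(rec.gene_id)
        ess = m.essential if m is not None else None
        if ess is True:
            essential_cin += 1
        elif ess is False:
            nonessential_cin += 1
        else:
            unknown += 1
        if rec.confidence == HIGH:
            high += 1
        for assay in rec.assays:
            per_assay[assay] += 1
        if rec.confidence in (HIGH, LOW):
            nuc = m.nuclear if m is not None else None
            loc = "nuclear" if nuc is True else ("other" if nuc is False else "unknown")
            nuclear_breakdown[loc][rec.confidence] += 1

    total = len(catalogue)
    return CatalogueSummary(
        total_genes=total,
        essential_cin=essential_cin,
        essential_universe=essential_universe,
        nonessential_cin=nonessential_cin,
        nonessential_universe=nonessential_universe,
        unknown_essentiality=unknown,
        essential_pct=_pct(essential_cin, essential_universe),
        nonessential_pct=_pct(nonessential_cin, nonessential_universe),
        high_confidence_fraction=(high / total) if total else None,
        per_assay_counts=per_assay,
        nuclear_breakdown=nuclear_breakdown,
    )


def write_catalogue(catalogue: CINCatalogue, stream: IO[str]) -> None:
    """Write one row per gene with semicolon-joined evidence triples."""
    writer = csv.writer(stream, delimiter="\t", lineterminator="\n")
    writer.writerow(
        ["gene", "assays", "sources", "confidence", "evidence",
         "essential", "nuclear", "verified_orf"]
    )
    for rec in sorted(catalogue, key=lambda r: r.gene_id):
        ev = ";".join(
            f"{h.assay}:{h.strength}:{h.source}" for h in rec.evidence
        )
        m = rec.meta
        fmt = lambda v: "" if v is None else ("1" if v else "0")  # noqa: E731
        writer.writerow(
            [
                rec.gene_id,
                ";".join(sorted(rec.assays)),
                ";".join(sorted(rec.sources)),
                rec.confidence or "",
                ev,
                fmt(m.essential if m else None),
                fmt(m.nuclear if m else None),
                fmt(m.verified_orf if m else None),
            ]
        )


def read_catalogue(stream: IO[str]) -> CINCatalogue:
    """Read a catalogue written by :func:`write_catalogue`."""
    reader = csv.DictReader(stream, delimiter="\t")
    records = []
    for row in reader:
        evidence = []
        for triple in (row["evidence"] or "").split(";"):
            if not triple:
                continue
            assay, strength, source = triple.split(":", 2)
            evidence.append(ScreenHit(row["gene"], assay, strength, source))
        parse = lambda v: None if v == "" else v == "1"  # noqa: E731
        meta = GeneMeta(
            gene_id=row["gene"],
            essential=parse(row.get("essential", "")),
            nuclear=parse(row.get("nuclear", "")),
            verified_orf=parse(row.get("verified_orf", "")) is not False,
        )
        records.append(
            CatalogueRecord(
                gene_id=row["gene"],
                evidence=evidence,
                confidence=row.get("confidence") or None,
                meta=meta,
            )
        )
    return CINCatalogue(records)
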