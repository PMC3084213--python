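"""Somatic-mutation cross-reference and the pooled two-proportion z-test."""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import IO, Optional

from .errors import ParseError, ValidationError
from .projection import CandidateSet, normalize_symbol

MUTATION_SOURCES = frozenset({"COSMIC", "CENSUS"})


@dataclass
class MutationGeneTable:
    """Human symbols tagged with the mutation source(s) listing them."""

    sources_by_gene: dict[str, set[str]] = field(default_factory=dict)
    version: str = ""

    def genes(self) -> set[str]:
        return set(self.sources_by_gene)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.sources_by_gene


@dataclass
class CrossRefResult:
    mutated: set[str]
    per_source: dict[str, set[str]]

    @property
    def per_source_counts(self) -> dict[str, int]:
        return {s: len(g) for s, g in self.per_source.items()}


@dataclass
class ProportionTest:
    k1: int
    n1: int
    k2: int
    n2: int
    p1: float
    p2: float
    pooled: float
    z: float
    p_two_sided: float
    p_one_sided: Optional[float] = None
    degenerate: bool = False


def read_mutation_table(stream: IO[str]) -> MutationGeneTable:
    """Read a mutation TSV with columns symbol, source[, version]."""
    reader = csv.DictReader(stream, delimiter="\t")
    if reader.fieldnames is None or not {"symbol", "source"} <= set(reader.fieldnames):
        raise ParseError("mutation table needs columns symbol, source[, version]")
    table = MutationGeneTable()
    for row in reader:
        symbol = normalize_symbol(row["symbol"] or "")
        source = (row["source"] or "").strip().upper()
        if not symbol:
            raise ParseError(f"line {reader.line_num}: empty symbol")
        if source not in MUTATION_SOURCES:
            raise ParseError(
                f"line {reader.line_num}: unknown source {row['source']!r} "
                f"(expected one of {sorted(MUTATION_SOURCES)})"
            )
        table.sources_by_gene.setdefault(symbol, set()).add(source)
        version = (row.get("version") or "").strip()
        if version:
            table.version = version
    return table


def read_gene_list(stream: IO[str]) -> set[str]:
    """One symbol per line (or first TSV column); normalized; header tolerated."""
    out: set[str] = set()
    for line in stream:
        token = line.split("\t")[0].strip()
        if not token or token.lower() in {"gene", "symbol", "human_gene"}:
            continue
        out.add(normalize_symbol(token))
    return out


def crossref(candidates: CandidateSet, table: MutationGeneTable) -> CrossRefResult:
    """Intersect candidate symbols with the mutation table, per source tag."""
    cand = candidates.genes()
    mutated = cand & table.genes()
    per_source = {
        s: {g for g in mutated if s in table.sources_by_gene[g]}
        for s in sorted(MUTATION_SOURCES)
    }
    return CrossRefResult(mutated=mutated, per_source=per_source)


def two_proportion_ztest(k1: int, n1: int, k2: int, n2: int) -> ProportionTest:
    """Pooled two-proportion z-test, no continuity correction.

    z = (p1 - p2) / sqrt(pooled (1 - pooled) (1/n1 + 1/n2)).  When the pooled
    proportion is 0 or 1 the statistic is undefined; the result is flagged
    degenerate with p = 1.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValidationError("both sample sizes must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValidationError("counts must satisfy 0 <= k_i <= n_i")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return ProportionTest(
            k1=k1, n1=n1, k2=k2, n2=n2, p1=p1, p2=p2, pooled=pooled,
            z=0.0, p_two_sided=1.0, p_one_sided=1.0, degenerate=True,
        )
    se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (p1 - p2) / se
    p_two = math.erfc(abs(z) / math.sqrt(2.0))
    p_one = 0.5 * math.erfc(z / math.sqrt(2.0))  # upper tail: H1 p1 > p2
    return ProportionTest(
        k1=k1, n1=n1, k2=k2, n2=n2, p1=p1, p2=p2, pooled=pooled,
        z=z, p_two_sided=min(1.0, p_two), p_one_sided=min(1.0, p_one),
    )
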