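"""Term over-representation: exact hypergeometric upper tail with Bonferroni.

The study set is tested against an explicit background (all genes screened),
one upper-tail hypergeometric test per term with at least one study
annotation.  Bonferroni multiplies each raw p by the number of terms tested,
capped at 1.  Fold enrichment is (k/n)/(K/N).

The background size N counts every background gene, annotated or not: each
gene is implicitly annotated to its namespace root, so N does not depend on
annotation sparsity.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import IO, Iterable, Optional

import numpy as np
from scipy.special import gammaln

from .errors import ValidationError
from .ontology import AnnotationSet, OntologyDAG


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    k: int          # study genes annotated to the term
    n: int          # study-set size
    K: int          # background genes annotated to the term
    N: int          # background size
    p_raw: float
    p_bonf: float
    fold: float
    enriched: bool
    name: str = ""
    namespace: str = ""


@lru_cache(maxsize=64)
def _log_factorials(n: int) -> np.ndarray:
    # entry x holds log(x!) for x in 0..n
    return gammaln(np.arange(1, n + 2, dtype=np.float64))


def hypergeometric_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail probability P(X >= k) for X ~ Hypergeometric(N, K, n).

    Computed as a log-space sum of exact pmf terms; the sum has only positive
    terms, so relative error stays near machine precision.
    """
    if min(k, K, n, N) < 0:
        raise ValidationError("hypergeometric counts must be non-negative")
    if K > N or n > N:
        raise ValidationError(f"K={K} and n={n} must not exceed N={N}")
    if k > min(n, K):
        raise ValidationError(f"k={k} exceeds min(n, K)={min(n, K)}")
    if k == 0:
        return 1.0
    lf = _log_factorials(N)
    i = np.arange(k, min(n, K) + 1)
    log_terms = (
        lf[K] - lf[i] - lf[K - i]
        + lf[N - K] - lf[n - i] - lf[N - K - n + i]
        + lf[n] + lf[N - n] - lf[N]
    )
    m = log_terms.max()
    total = math.exp(m) * float(np.exp(log_terms - m).sum())
    return min(1.0, total)


def count_annotations(genes: Iterable[str], annots: AnnotationSet) -> dict[str, int]:
    """Number of genes (from ``genes``) annotated to each term."""
    counts: dict[str, int] = {}
    for gene in genes:
        for term in annots.terms_for(gene):
            counts[term] = counts.get(term, 0) + 1
    return counts


def compute_enrichment(
    study: Iterable[str],
    background: Iterable[str],
    dag: OntologyDAG,
    annots: AnnotationSet,
    alpha: float = 0.05,
    background_counts: Optional[dict[str, int]] = None,
) -> list[EnrichmentResult]:
    """Test every term hit by the study set against the background.

    Requires ``study`` to be a subset of ``background`` and a closed
    annotation set.  Results are sorted by raw p ascending, ties broken by
    term id.  ``background_counts`` (term -> K) may be supplied to avoid
    recounting an unchanged background across many study sets; it must have
    been produced by :func:`count_annotations` on the same background.
    """
    study_set = set(study)
    background_set = set(background)
    extra = sorted(study_set - background_set)
    if extra:
        raise ValidationError(
            f"study genes absent from background: {', '.join(extra[:10])}"
            + ("..." if len(extra) > 10 else "")
        )
    if not annots.closed:
        raise ValidationError("annotations must be propagated (closed) before testing")
    if not study_set:
        return []

    n = len(study_set)
    N = len(background_set)
    K_counts = (
        background_counts
        if background_counts is not None
        else count_annotations(background_set, annots)
    )
    k_counts = count_annotations(study_set, annots)

    tested = sorted(k_counts)
    T = len(tested)
    results = []
    for term in tested:
        k = k_counts[term]
        K = K_counts[term]
        p_raw = hypergeometric_tail(k, K, n, N)
        p_bonf = min(1.0, p_raw * T)
        fold = (k / n) / (K / N)
        meta = dag.terms.get(term)
        results.append(
            EnrichmentResult(
                term_id=term,
                k=k, n=n, K=K, N=N,
                p_raw=p_raw,
                p_bonf=p_bonf,
                fold=fold,
                enriched=p_bonf < alpha,
                name=meta.name if meta else "",
                namespace=meta.namespace if meta else "",
            )
        )
    results.sort(key=lambda r: (r.p_raw, r.term_id))
    return results


def write_enrichment(results: Iterable[EnrichmentResult], stream: IO[str]) -> None:
    writer = csv.writer(stream, delimiter="\t", lineterminator="\n")
    writer.writerow(
        ["term", "name", "namespace", "k", "n", "K", "N",
         "p_raw", "p_bonf", "fold", "enriched"]
    )
    for r in results:
        writer.writerow(
            [r.term_id, r.name, r.namespace, r.k, r.n, r.K, r.N,
             f"{r.p_raw:.6e}", f"{r.p_bonf:.6e}", f"{r.fold:.6f}",
             "1" if r.enriched else "0"]
        )


def read_enrichment(stream: IO[str]) -> list[EnrichmentResult]:
    reader = csv.DictReader(stream, delimiter="\t")
    out = []
    for row in reader:
        out.append(
            EnrichmentResult(
                term_id=row["term"],
                name=row.get("name", ""),
                namespace=row.get("namespace", ""),
                k=int(row["k"]), n=int(row["n"]),
                K=int(row["K"]), N=int(row["N"]),
                p_raw=float(row["p_raw"]),
                p_bonf=float(row["p_bonf"]),
                fold=float(row["fold"]),
                enriched=row["enriched"] == "1",
            )
        )
    return out


def write_edge_list(dag: OntologyDAG, stream: IO[str]) -> None:
    """Export (child, parent, relation) for external network plotting."""
    stream.write("child\tparent\trelation\n")
    for child, parent, rel in dag.edges():
        stream.write(f"{child}\t{parent}\t{rel}\n")


def per_namespace_counts(results: Iterable[EnrichmentResult]) -> dict[str, int]:
    """Enriched-term counts per namespace (joint testing, split reporting)."""
    counts: dict[str, int] = {}
    for r in results:
        if r.enriched:
            counts[r.namespace] = counts.get(r.namespace, 0) + 1
    return counts
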