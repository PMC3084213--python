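"""End-to-end orchestration: integrate -> enrich -> project -> xref [-> cluster].

Stages communicate through files only; each stage's outputs are sufficient to
re-run any downstream stage in isolation.  The run report contains input and
output digests and the headline numbers of every stage, and is byte-stable
for identical inputs and config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

from . import __version__
from .catalogue import (
    integrate_screens,
    read_gene_meta,
    read_screen_table,
    summarize,
    write_catalogue,
)
from .cluster import (
    average_linkage,
    cocluster,
    correlation_distance,
    read_matrix,
    shared_hits,
    to_newick,
)
from .enrichment import compute_enrichment, per_namespace_counts, write_enrichment
from .errors import ValidationError
from .mutation import crossref, read_gene_list, read_mutation_table, two_proportion_ztest
from .ontology import parse_obo, propagate_annotations, read_annotations_tsv, read_gaf
from .projection import (
    overlap_summary,
    project_go_terms,
    project_orthologs,
    read_orthology,
    write_candidates,
)

log = logging.getLogger("cincat.pipeline")

_REQUIRED_KEYS = (
    "screens", "meta", "obo", "annotations", "background",
    "orthology", "human_annotations", "mutations", "human_universe", "out_dir",
)


def read_pipeline_config(path: str | Path) -> dict[str, str]:
    """Flat ``key = value`` pipeline configuration."""
    config: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#")[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValidationError(f"bad config line (expected key = value): {line!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        config[key] = value
    return config


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _timed(name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc_type is None:
                log.info("stage %s: done in %.2fs", name, dt)
            else:
                log.error("stage %s: failed after %.2fs: %s", name, dt, exc)
            return False

    return _Timer()


def run_pipeline(config: dict[str, str]) -> dict:
    """Execute all stages; returns the run report (also written to disk).

    A missing input path aborts before any stage runs; a failure inside a
    stage propagates with the stage name attached.
    """
    missing = [k for k in _REQUIRED_KEYS if k not in config]
    if missing:
        raise ValidationError(f"pipeline config missing key(s): {missing}")

    input_paths: dict[str, list[Path]] = {
        "screens": [Path(p) for p in config["screens"].split(",") if p],
    }
    for key in ("meta", "obo", "annotations", "background", "orthology",
                "human_annotations", "mutations", "human_universe"):
        input_paths[key] = [Path(config[key])]
    if config.get("literature"):
        input_paths["literature"] = [Path(p) for p in config["literature"].split(",") if p]
    has_matrix = bool(config.get("matrix"))
    if has_matrix:
        input_paths["matrix"] = [Path(config["matrix"])]
    absent = [str(p) for paths in input_paths.values() for p in paths if not p.exists()]
    if absent:
        raise ValidationError(f"missing input file(s): {absent}")

    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    alpha = float(config.get("alpha", "0.05"))
    fold_min = float(config.get("fold_min", "3.0"))
    report: dict = {
        "version": __version__,
        "config": dict(sorted(config.items())),
        "inputs": {
            k: {str(p): _digest(p) for p in paths}
            for k, paths in sorted(input_paths.items())
        },
        "stages": {},
    }

    try:
        with _timed("integrate"):
            tables = []
            for path in input_paths["screens"] + input_paths.get("literature", []):
                with open(path) as fh:
                    tables.append(read_screen_table(fh))
            with open(input_paths["meta"][0]) as fh:
                meta = read_gene_meta(fh)
            catalogue = integrate_screens(tables, meta)
            summary = summarize(catalogue, meta)
            catalogue_path = out_dir / "catalogue.tsv"
            with open(catalogue_path, "w") as fh:
                write_catalogue(catalogue, fh)
            report["stages"]["integrate"] = {
                "n_genes": len(catalogue),
                "summary": asdict(summary),
            }
    except Exception as exc:
        raise ValidationError(f"stage integrate failed: {exc}") from exc

    try:
        with _timed("enrich"):
            with open(input_paths["obo"][0]) as fh:
                dag = parse_obo(fh)
            annot_path = input_paths["annotations"][0]
            with open(annot_path) as fh:
                if annot_path.suffix == ".gaf":
                    raw = read_gaf(fh)
                else:
                    raw = read_annotations_tsv(fh)
            annots = propagate_annotations(dag, raw)
            with open(input_paths["background"][0]) as fh:
                background = {line.strip() for line in fh if line.strip()}
            study = catalogue.genes() & background
            results = compute_enrichment(study, background, dag, annots, alpha=alpha)
            enrichment_path = out_dir / "enrichment.tsv"
            with open(enrichment_path, "w") as fh:
                write_enrichment(results, fh)
            n_enriched = sum(r.enriched for r in results)
            report["stages"]["enrich"] = {
                "n_terms_tested": len(results),
                "n_enriched": n_enriched,
                "per_namespace": per_namespace_counts(results),
            }
    except Exception as exc:
        raise ValidationError(f"stage enrich failed: {exc}") from exc

    try:
        with _timed("project"):
            with open(input_paths["orthology"][0]) as fh:
                orthology = read_orthology(fh)
            ortho_set = project_orthologs(catalogue, orthology)
            hpath = input_paths["human_annotations"][0]
            with open(hpath) as fh:
                if hpath.suffix == ".gaf":
                    human_raw = read_gaf(fh)
                else:
                    human_raw = read_annotations_tsv(fh)
            human_annots = propagate_annotations(dag, human_raw)
            go_set = project_go_terms(results, human_annots, fold_min=fold_min)
            overlap = overlap_summary(ortho_set, go_set)
            with open(out_dir / "candidates_orthology.tsv", "w") as fh:
                write_candidates(ortho_set, fh)
            with open(out_dir / "candidates_go.tsv", "w") as fh:
                write_candidates(go_set, fh)
            report["stages"]["project"] = {
                "orthology_candidates": len(ortho_set),
                "go_candidates": len(go_set),
                "go_terms_contributing": go_set.n_terms_contributing,
                "association_count": go_set.association_count,
                "unmapped_catalogue_genes": len(ortho_set.unmapped_genes),
                "overlap": asdict(overlap),
            }
    except Exception as exc:
        raise ValidationError(f"stage project failed: {exc}") from exc

    try:
        with _timed("xref"):
            with open(input_paths["mutations"][0]) as fh:
                mutations = read_mutation_table(fh)
            with open(input_paths["human_universe"][0]) as fh:
                universe = read_gene_list(fh)
            xref_report = {}
            for name, cand in (("orthology", ortho_set), ("go_term", go_set)):
                result = crossref(cand, mutations)
                background_genes = universe - cand.genes()
                k2 = len(background_genes & mutations.genes())
                n2 = len(background_genes)
                if len(cand) and n2:
                    test = two_proportion_ztest(
                        len(result.mutated), len(cand), k2, n2
                    )
                    test_dict = asdict(test)
                else:
                    test_dict = None
                xref_report[name] = {
                    "n_candidates": len(cand),
                    "n_mutated": len(result.mutated),
                    "per_source": result.per_source_counts,
                    "test": test_dict,
                }
            with open(out_dir / "xref.json", "w") as fh:
                json.dump(xref_report, fh, indent=1, sort_keys=True)
                fh.write("\n")
            report["stages"]["xref"] = xref_report
    except Exception as exc:
        raise ValidationError(f"stage xref failed: {exc}") from exc

    if has_matrix:
        try:
            with _timed("cluster"):
                with open(input_paths["matrix"][0]) as fh:
                    matrix = read_matrix(fh)
                metric = config.get("metric", "centered")
                dist = correlation_distance(matrix, metric=metric)
                tree = average_linkage(dist, matrix.rows)
                n_clusters = int(config.get("n_clusters", "5"))
                queries = [q for q in config.get("queries", "").split(",") if q]
                cluster_report: dict = {"n_leaves": len(matrix.rows)}
                if queries:
                    together, assignment = cocluster(tree, queries, n_clusters)
                    cluster_report["queries_cocluster"] = together
                    cluster_report["n_clusters"] = n_clusters
                cutoff = float(config.get("score_cutoff", "2.0"))
                hits = shared_hits(matrix, cutoff)
                cluster_report["n_shared_interactions"] = hits.n_shared
                with open(out_dir / "dendrogram.nwk", "w") as fh:
                    fh.write(to_newick(tree) + "\n")
                report["stages"]["cluster"] = cluster_report
        except Exception as exc:
            raise ValidationError(f"stage cluster failed: {exc}") from exc
    else:
        report["stages"]["cluster"] = {"skipped": True}

    report["outputs"] = {
        p.name: _digest(p)
        for p in sorted(out_dir.iterdir())
        if p.is_file() and p.name != "report.json"
    }
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return report
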