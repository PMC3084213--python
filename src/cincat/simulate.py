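"""Seeded synthetic inputs with planted ground truth.

Generators emulate the structure of the real inputs: multi-assay screen-hit
tables with partial overlap, an ontology DAG with planted enriched terms,
one-to-many orthology fan-out, a mutation table enriched for true
candidates, and an interaction matrix containing a co-functional query
group.  Every generator is a pure function of (config, seed); the random
stream is partitioned per generator so one stage's config cannot perturb
another stage's draws.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .catalogue import GeneMeta, ScreenHit
from .cluster import InteractionMatrix, write_matrix
from .errors import ValidationError
from .ontology import (
    AnnotationSet,
    OntologyDAG,
    OntologyTerm,
    write_annotations_tsv,
    write_obo,
)
from .projection import OrthologyMap, OrthologyRecord

ASSAY_ORDER = ("CTF", "ALF", "GCR", "BIM", "LOH")
_STREAMS = ("truth", "ontology", "screens", "downstream")


@dataclass
class SimulationConfig:
    seed: int = 0
    # universe
    n_genes: int = 2000
    frac_essential: float = 0.3
    # ontology shape
    n_terms: int = 300
    dag_depth: int = 5
    mean_children: float = 3.0
    annotation_rate: float = 6.0        # mean raw terms per gene
    part_of_fraction: float = 0.2
    # planted CIN signal
    n_cin_genes: int = 200
    n_planted_terms: int = 5
    planted_multiplier: float = 8.0
    planted_terms: Optional[tuple[tuple[str, float], ...]] = None
    # screens
    assay_sensitivity: float = 0.8
    assay_fpr: float = 0.002
    n_sources: int = 3
    strong_prob: float = 0.3
    # orthology / human side
    ortholog_coverage: float = 0.6
    ortholog_fanout_mean: float = 1.3   # >= 1; extra targets ~ Poisson(mean - 1)
    functional_fraction: float = 0.1
    n_human_extra: int = 500
    # mutation table
    mutation_base_rate: float = 0.1
    candidate_mutation_multiplier: float = 3.0
    census_fraction: float = 0.3
    mutation_enriched: bool = True
    # interaction matrix
    n_array_genes: int = 200
    n_query_group: int = 4
    n_query_unrelated: int = 20
    template_sd: float = 3.0
    noise_sd: float = 1.0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "frac_essential", "assay_sensitivity", "assay_fpr", "strong_prob",
            "ortholog_coverage", "functional_fraction", "mutation_base_rate",
            "census_fraction", "missing_rate", "part_of_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        for name in ("planted_multiplier", "candidate_mutation_multiplier",
                     "ortholog_fanout_mean"):
            if getattr(self, name) < 1.0:
                raise ValidationError(f"{name} must be >= 1")
        if self.n_terms < 3:
            raise ValidationError("need at least 3 terms to build an ontology")
        if self.n_cin_genes > self.n_genes:
            raise ValidationError("n_cin_genes cannot exceed n_genes")
        if self.n_query_group > self.n_cin_genes:
            raise ValidationError("n_query_group cannot exceed n_cin_genes")


@dataclass
class PlantedTruth:
    cin_genes: tuple[str, ...]
    planted_terms: tuple[tuple[str, float], ...]
    query_group: tuple[str, ...]
    mutation_enriched: bool


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    seq = np.random.SeedSequence(config.seed, spawn_key=(_STREAMS.index(stream),))
    return np.random.default_rng(seq)


def gene_ids(config: SimulationConfig) -> list[str]:
    return [f"G{i:04d}" for i in range(config.n_genes)]


def term_ids(config: SimulationConfig) -> list[str]:
    return [f"SYN:{i:07d}" for i in range(config.n_terms)]


def _term_levels(config: SimulationConfig) -> list[int]:
    """Deterministic DAG level per term; term 0 is the root at level 0."""
    depth = max(1, config.dag_depth)
    levels = [0]
    for idx in range(1, config.n_terms):
        levels.append(1 + min(depth - 1, int((idx - 1) * depth / max(1, config.n_terms - 1))))
    return levels


def plant_truth(config: SimulationConfig) -> PlantedTruth:
    """Choose CIN genes, enriched terms and the co-functional query group.

    Planted terms are drawn from the deepest DAG level; parents always sit
    at shallower levels, so these terms are leaves and annotation closure
    cannot dilute their fold enrichment with descendant annotations.
    """
    rng = _rng(config, "truth")
    genes = gene_ids(config)
    cin = tuple(sorted(rng.choice(genes, size=config.n_cin_genes, replace=False)))
    if config.planted_terms is not None:
        planted = tuple(config.planted_terms)
    else:
        levels = _term_levels(config)
        deepest = max(levels)
        pool = [t for t, lv in zip(term_ids(config), levels) if lv == deepest]
        if len(pool) < config.n_planted_terms:
            raise ValidationError(
                f"only {len(pool)} deepest-level terms available for "
                f"{config.n_planted_terms} planted terms; increase n_terms"
            )
        chosen = rng.choice(pool, size=config.n_planted_terms, replace=False)
        planted = tuple((t, config.planted_multiplier) for t in sorted(chosen))
    group = cin[: config.n_query_group]
    return PlantedTruth(
        cin_genes=cin,
        planted_terms=planted,
        query_group=tuple(group),
        mutation_enriched=config.mutation_enriched,
    )


def simulate_ontology(
    config: SimulationConfig, truth: PlantedTruth
) -> tuple[OntologyDAG, AnnotationSet]:
    """Random single-namespace DAG plus raw (unpropagated) annotations.

    Each non-root term draws 1-2 parents from strictly shallower levels.  A
    gene is annotated to each non-root term with probability
    annotation_rate / n_terms; for planted terms, CIN genes get that
    probability multiplied by the planted multiplier.
    """
    if config.n_terms < 3:
        raise ValidationError("need at least 3 terms to build an ontology")
    rng = _rng(config, "ontology")
    tids = term_ids(config)
    root = tids[0]
    level_of = _term_levels(config)
    terms = [OntologyTerm(term_id=root, name="root", namespace="biological_process")]
    by_level: dict[int, list[str]] = {0: [root]}
    for idx, tid in enumerate(tids[1:], start=1):
        level = level_of[idx]
        shallower = [t for lv in range(level) for t in by_level.get(lv, [])]
        n_parents = int(rng.integers(1, 3)) if len(shallower) > 1 else 1
        n_parents = min(n_parents, len(shallower))
        parents = rng.choice(shallower, size=n_parents, replace=False)
        rels = tuple(
            (p, "part_of" if rng.random() < config.part_of_fraction else "is_a")
            for p in sorted(parents)
        )
        terms.append(
            OntologyTerm(
                term_id=tid,
                name=f"synthetic term {idx}",
                namespace="biological_process",
                parents=rels,
            )
        )
        by_level.setdefault(level, []).append(tid)
    dag = OntologyDAG(terms)

    genes = gene_ids(config)
    cin_mask = np.isin(genes, truth.cin_genes)
    base_q = min(1.0, config.annotation_rate / config.n_terms)
    probs = np.full((config.n_genes, config.n_terms), base_q)
    probs[:, 0] = 0.0  # root annotations arise only via closure
    mult_by_term = dict(truth.planted_terms)
    for j, tid in enumerate(tids):
        mult = mult_by_term.get(tid)
        if mult is not None:
            probs[cin_mask, j] = min(1.0, base_q * mult)
    draws = rng.random(probs.shape) < probs
    mapping: dict[str, set[str]] = {}
    for gi, tj in zip(*np.nonzero(draws)):
        mapping.setdefault(genes[gi], set()).add(tids[tj])
    return dag, AnnotationSet(mapping=mapping, closed=False)


def simulate_screens(
    config: SimulationConfig, truth: PlantedTruth
) -> tuple[list[list[ScreenHit]], list[GeneMeta]]:
    """Per-assay hit tables plus the gene-metadata table.

    Planted CIN genes are reported by each assay with the configured
    sensitivity; other genes appear at the false-positive rate.  Sources are
    assigned round-robin over the configured source labels; strengths are
    STRONG with the configured probability.
    """
    rng = _rng(config, "screens")
    genes = gene_ids(config)
    cin = set(truth.cin_genes)
    sources = [f"source_{i:02d}" for i in range(config.n_sources)]
    tables: list[list[ScreenHit]] = []
    for a_idx, assay in enumerate(ASSAY_ORDER):
        source = sources[a_idx % len(sources)]
        table: list[ScreenHit] = []
        u = rng.random(config.n_genes)
        s = rng.random(config.n_genes)
        for gi, gene in enumerate(genes):
            p = config.assay_sensitivity if gene in cin else config.assay_fpr
            if u[gi] < p:
                strength = "STRONG" if s[gi] < config.strong_prob else "WEAK"
                table.append(ScreenHit(gene, assay, strength, source))
        tables.append(table)

    ess = rng.random(config.n_genes) < config.frac_essential
    nuc = rng.random(config.n_genes)
    meta = [
        GeneMeta(
            gene_id=g,
            essential=bool(ess[i]),
            nuclear=bool(nuc[i] < (0.7 if g in cin else 0.3)),
            verified_orf=True,
            functional_group="",
        )
        for i, g in enumerate(genes)
    ]
    return tables, meta


def simulate_downstream(
    config: SimulationConfig,
    truth: PlantedTruth,
    yeast_annots: AnnotationSet,
) -> tuple[OrthologyMap, AnnotationSet, dict[str, set[str]], InteractionMatrix, list[str]]:
    """Orthology map, human annotations, mutation table and interaction matrix.

    Human orthologs inherit their yeast source gene's raw term annotations;
    extra human-only genes are annotated independently at the base rate.
    The mutation table (returned as symbol -> source set) marks genes at the
    base rate, multiplied for orthologs of planted CIN genes when the
    enrichment flag is set.  The interaction matrix contains the planted
    query group built from one shared template plus noise, among unrelated
    rows.
    """
    rng = _rng(config, "downstream")
    genes = gene_ids(config)
    tids = term_ids(config)

    records: list[OrthologyRecord] = []
    human_map: dict[str, set[str]] = {}
    for gene in genes:
        if rng.random() >= config.ortholog_coverage:
            continue
        fanout = 1 + int(rng.poisson(config.ortholog_fanout_mean - 1.0))
        for j in range(fanout):
            symbol = f"H{gene}_{j}"
            kind = "FUNCTIONAL" if rng.random() < config.functional_fraction else "SEQUENCE"
            records.append(OrthologyRecord(gene, symbol, kind))
            human_map.setdefault(symbol, set()).add(gene)
    orthology = OrthologyMap(records=records)

    mapping: dict[str, set[str]] = {}
    for symbol, yeast_sources in human_map.items():
        terms: set[str] = set()
        for yg in yeast_sources:
            terms |= yeast_annots.terms_for(yg)
        if terms:
            mapping[symbol] = set(terms)
    base_q = min(1.0, config.annotation_rate / config.n_terms)
    for i in range(config.n_human_extra):
        symbol = f"HX{i:04d}"
        draws = np.nonzero(rng.random(config.n_terms - 1) < base_q)[0]
        if draws.size:
            mapping[symbol] = {tids[j + 1] for j in draws}
    human_annots = AnnotationSet(mapping=mapping, closed=False)

    planted_cin = set(truth.cin_genes)
    candidate_symbols = {
        s for s, ys in human_map.items() if ys & planted_cin
    }
    mutations: dict[str, set[str]] = {}
    all_humans = sorted(set(human_map) | {f"HX{i:04d}" for i in range(config.n_human_extra)})
    for symbol in all_humans:
        rate = config.mutation_base_rate
        if truth.mutation_enriched and symbol in candidate_symbols:
            rate = min(1.0, rate * config.candidate_mutation_multiplier)
        if rng.random() < rate:
            sources = {"COSMIC"}
            if rng.random() < config.census_fraction:
                sources.add("CENSUS")
            mutations[symbol] = sources

    cols = [f"A{i:04d}" for i in range(config.n_array_genes)]
    template = rng.normal(0.0, config.template_sd, size=config.n_array_genes)
    rows: list[str] = []
    data: list[np.ndarray] = []
    for gene in truth.query_group:
        rows.append(gene)
        data.append(template + rng.normal(0.0, config.noise_sd, size=config.n_array_genes))
    total_sd = math.hypot(config.template_sd, config.noise_sd)
    for i in range(config.n_query_unrelated):
        rows.append(f"Q{i:03d}")
        data.append(rng.normal(0.0, total_sd, size=config.n_array_genes))
    values = np.vstack(data)
    if config.missing_rate > 0:
        mask = rng.random(values.shape) < config.missing_rate
        values = values.copy()
        values[mask] = np.nan
    matrix = InteractionMatrix(rows=rows, cols=cols, values=values)
    return orthology, human_annots, mutations, matrix, all_humans


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    truth: PlantedTruth
    dag: OntologyDAG
    yeast_annotations: AnnotationSet
    screen_tables: list[list[ScreenHit]]
    gene_meta: list[GeneMeta]
    orthology: OrthologyMap
    human_annotations: AnnotationSet
    mutations: dict[str, set[str]]
    matrix: InteractionMatrix
    human_universe: list[str]


def simulate_all(config: SimulationConfig) -> SyntheticDataset:
    truth = plant_truth(config)
    dag, yeast_annots = simulate_ontology(config, truth)
    tables, meta = simulate_screens(config, truth)
    orthology, human_annots, mutations, matrix, human_universe = simulate_downstream(
        config, truth, yeast_annots
    )
    return SyntheticDataset(
        config=config,
        truth=truth,
        dag=dag,
        yeast_annotations=yeast_annots,
        screen_tables=tables,
        gene_meta=meta,
        orthology=orthology,
        human_annotations=human_annots,
        mutations=mutations,
        matrix=matrix,
        human_universe=human_universe,
    )


def write_fixture_dir(config: SimulationConfig, out_dir: str | Path) -> Path:
    """Materialize one synthetic dataset as the text files the CLI consumes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds = simulate_all(config)

    for assay, table in zip(ASSAY_ORDER, ds.screen_tables):
        with open(out / f"screens_{assay}.tsv", "w") as fh:
            fh.write("gene\tassay\tstrength\tsource\n")
            for hit in table:
                fh.write(f"{hit.gene_id}\t{hit.assay}\t{hit.strength}\t{hit.source}\n")
    with open(out / "meta.tsv", "w") as fh:
        fh.write("gene\tessential\tnuclear\tverified_orf\tfunctional_group\n")
        for m in ds.gene_meta:
            fh.write(
                f"{m.gene_id}\t{int(bool(m.essential))}\t{int(bool(m.nuclear))}\t"
                f"{int(m.verified_orf)}\t{m.functional_group}\n"
            )
    with open(out / "ontology.obo", "w") as fh:
        write_obo(ds.dag, fh)
    with open(out / "annotations_yeast.tsv", "w") as fh:
        write_annotations_tsv(ds.yeast_annotations, fh)
    with open(out / "annotations_human.tsv", "w") as fh:
        write_annotations_tsv(ds.human_annotations, fh)
    with open(out / "background.tsv", "w") as fh:
        for g in gene_ids(config):
            fh.write(g + "\n")
    with open(out / "orthology.tsv", "w") as fh:
        fh.write("yeast_orf\thuman_symbol\tkind\n")
        for rec in ds.orthology.records:
            fh.write(f"{rec.yeast_orf}\t{rec.human_symbol}\t{rec.kind}\n")
    with open(out / "mutations.tsv", "w") as fh:
        fh.write("symbol\tsource\tversion\n")
        for symbol in sorted(ds.mutations):
            for source in sorted(ds.mutations[symbol]):
                fh.write(f"{symbol}\t{source}\tsim-v1\n")
    with open(out / "human_universe.tsv", "w") as fh:
        for symbol in ds.human_universe:
            fh.write(symbol + "\n")
    with open(out / "matrix.tsv", "w") as fh:
        write_matrix(ds.matrix, fh)
    with open(out / "truth.json", "w") as fh:
        json.dump(
            {
                "cin_genes": list(ds.truth.cin_genes),
                "planted_terms": [[t, m] for t, m in ds.truth.planted_terms],
                "query_group": list(ds.truth.query_group),
                "mutation_enriched": ds.truth.mutation_enriched,
            },
            fh,
            indent=1,
            sort_keys=True,
        )
        fh.write("\n")
    with open(out / "sim.cfg", "w") as fh:
        for key, value in asdict(config).items():
            if value is None:
                continue
            fh.write(f"{key} = {value}\n")
    with open(out / "pipeline.cfg", "w") as fh:
        screens = ",".join(str(out / f"screens_{a}.tsv") for a in ASSAY_ORDER)
        fh.write(f"screens = {screens}\n")
        fh.write(f"meta = {out / 'meta.tsv'}\n")
        fh.write(f"obo = {out / 'ontology.obo'}\n")
        fh.write(f"annotations = {out / 'annotations_yeast.tsv'}\n")
        fh.write(f"background = {out / 'background.tsv'}\n")
        fh.write(f"orthology = {out / 'orthology.tsv'}\n")
        fh.write(f"human_annotations = {out / 'annotations_human.tsv'}\n")
        fh.write(f"mutations = {out / 'mutations.tsv'}\n")
        fh.write(f"human_universe = {out / 'human_universe.tsv'}\n")
        fh.write(f"matrix = {out / 'matrix.tsv'}\n")
        fh.write(f"queries = {','.join(ds.truth.query_group)}\n")
        fh.write("fold_min = 3.0\nalpha = 0.05\nn_clusters = 5\nscore_cutoff = 2.0\n")
        fh.write(f"out_dir = {out / 'results'}\n")
    return out


def load_config(path: str | Path) -> SimulationConfig:
    """Read a flat ``key = value`` config file into a SimulationConfig."""
    raw: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#")[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValidationError(f"bad config line (expected key = value): {line!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        raw[key] = value
    kwargs: dict = {}
    defaults = SimulationConfig()
    for key, value in raw.items():
        if not hasattr(defaults, key):
            raise ValidationError(f"unknown simulation config key {key!r}")
        current = getattr(defaults, key)
        if isinstance(current, bool):
            kwargs[key] = value.lower() in {"1", "true", "yes"}
        elif isinstance(current, int):
            kwargs[key] = int(value)
        elif isinstance(current, float):
            kwargs[key] = float(value)
        else:
            kwargs[key] = value
    return SimulationConfig(**kwargs)
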