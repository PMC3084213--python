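# cincat

Tools for turning heterogeneous chromosome-instability (CIN) screen hits into
a confidence-scored gene catalogue and carrying that catalogue through
ontology enrichment, cross-species candidate projection, somatic-mutation
cross-referencing and genetic-interaction profile clustering. A seeded
synthetic-data generator with planted ground truth makes every stage testable
without any external downloads.

## Components

| module | what it does |
| --- | --- |
| `cincat.catalogue` | parse screen-hit / gene-metadata TSVs, integrate hits into a deduplicated catalogue, assign HIGH/LOW confidence (≥2 independent sources or any STRONG hit), summarize essential vs non-essential proportions |
| `cincat.ontology` | OBO 1.2 parsing into a DAG, GAF / two-column annotation readers, true-path annotation propagation over `is_a` and `part_of` |
| `cincat.enrichment` | exact hypergeometric upper-tail test per term, Bonferroni correction over terms tested, fold enrichment, TSV writers and a DAG edge-list export |
| `cincat.projection` | orthology-based and enriched-term-based (fold ≥ 3, inclusive) human candidate sets plus overlap statistics |
| `cincat.mutation` | candidate × mutation-table cross-reference with per-source counts and a pooled two-proportion z-test (no continuity correction) |
| `cincat.cluster` | correlation distance (centered / uncentered, pairwise-complete), UPGMA average linkage with deterministic tie-breaking, tree cutting, co-cluster checks, shared-interaction counts, newick export |
| `cincat.simulate` | seeded generators for all of the above with planted CIN genes, enriched terms, mutation enrichment and a co-functional query group |
| `cincat.pipeline` / `cincat.cli` | file-driven orchestration with a byte-reproducible JSON run report |

## CLI

Generate a complete synthetic fixture and run the whole pipeline on it:

```sh
cincat simulate --seed 42 --out-dir fixtures/
cincat run --config fixtures/pipeline.cfg
```

Each stage is also available stand-alone, reading/writing plain TSV/JSON:

```sh
cincat integrate --screens ctf.tsv --screens gcr.tsv --meta meta.tsv --out catalogue.tsv
cincat enrich --obo go.obo --gaf annots.tsv --study study.txt \
              --background background.txt --alpha 0.05 --out enrichment.tsv
cincat project --catalogue catalogue.tsv --orthology orthology.tsv \
               --enrichment enrichment.tsv --human-gaf human_annots.tsv \
               --obo go.obo --fold-min 3 --out-dir out/
cincat xref --candidates out/candidates_go.tsv --mutations mutations.tsv \
            --universe human_universe.tsv --out xref.json
cincat cluster --matrix matrix.tsv --metric centered --cut 5 \
               --queries q1,q2,q3,q4 --out-dir clust/
```

Pipeline and simulation configs are flat `key = value` text files; `simulate`
writes a ready-to-run `pipeline.cfg` next to its fixture files.

## Notes on conventions

- Confidence: a gene is HIGH iff it has ≥ 2 distinct evidence sources or at
  least one STRONG hit; "source" means the study/screen label, not the assay.
- Enrichment background N counts all background genes (every gene is
  implicitly annotated to the namespace root); Bonferroni multiplies by the
  number of terms actually tested (k ≥ 1), which is configurable behaviour
  by construction (pass a pre-filtered result list downstream if you need
  whole-ontology correction).
- Percentages are printed integer-rounded at ≥ 10% and to one decimal below.
- Clustering defaults to centered (Pearson) correlation distance; the
  uncentered variant is available via `--metric uncentered`.
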