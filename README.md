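# famvarnet

Family-based exome variant prioritization and per-patient protein-interaction
network inference, packaged as a tested, reusable pipeline:

1. **variant_io** — multi-sample VCF 4.2, 6-column PED, gene-panel and
   side-car TSV annotation tables (population MAFs, ClinVar categories,
   15-tool predictor scores, regulatory/QTL features) read into typed records.
2. **family_filter** — candidate-panel low-frequency filtering (MAF < 0.04 in
   both databases, call quality > 30, heterozygous in ≥1 affected member),
   carrier matrices, per-member counts, shared-in-affected intersections and
   same-gene co-carriage (linkage / compound-heterozygosity) groups.
3. **prioritization** — per-tool neutral/moderate/damaging categorization,
   damaging-vote counts, REVEL ranking with quartiles, and the +/* rule
   engine (≥2 affected carriers + ≥4 damaging votes, or ≥4 votes +
   eQTL/sQTL/ClinVar evidence; tail-ranked low-evidence variants excluded).
4. **interaction** — per-patient protein node sets, prior-corrected noisy-OR
   combination of evidence-channel scores with confidence tiers at
   0.15/0.4/0.7/0.9, and hypergeometric term enrichment with
   Benjamini–Hochberg FDR per category.
5. **synthetic_data** — a seeded synthetic-family generator with a
   ground-truth manifest, plus a packaged six-member family example dataset
   (three affected members) whose filtering, segregation, prioritization and
   network properties are asserted throughout the test suite.
6. **cli / pipeline** — a single reproducible run with YAML config, stage
   subcommands, TSV/JSON outputs and a machine-readable `summary.json`.

## CLI

```sh
# materialize the packaged example dataset (VCF/PED/panel/TSVs + run.yaml)
famvarnet fixture --out example/

# full run; prints the JSON summary, writes TSVs under example/results/
famvarnet run --config example/run.yaml

# per-stage subcommands (stop after the named stage)
famvarnet filter --config example/run.yaml
famvarnet rank --config example/run.yaml
famvarnet prioritize --config example/run.yaml
famvarnet network --config example/run.yaml

# synthetic family with a planted ground-truth manifest
famvarnet simulate --seed 1 --out sim/
```

Outputs per run: `filtered_variants.tsv`, `decisions.tsv`,
`heatmap_scores.tsv` / `heatmap_categories.tsv`, `network_<patient>.tsv` +
`.sif`, `enrichment.tsv`, `summary.json`, `famvarnet.log`.

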