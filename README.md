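# grnpipe

Cancer type-specific gene regulatory network (GRN) analysis from expression
data:

- **Synthetic corpora** (`grnpipe.synthetic`) — multi-class expression
  matrices with planted class-specific TF hubs, gold-standard TF→target pair
  lists (with decoys), partially attenuated query samples, and survival
  cohorts with a planted binary-expression hazard effect.
- **Preprocessing** (`grnpipe.preprocess`) — probe→gene averaging, per-array
  total normalization to a fixed scale, robust MAD-based sample QC.
- **GRN reconstruction** (`grnpipe.grn`) — Spearman association of
  gold-standard pairs with CLR-style background correction, Infomap/Leiden
  community detection, hypergeometric community→class assignment, structure
  metrics, GraphML export.
- **Classification** (`grnpipe.classify`) — stratified half split,
  one-vs-rest random forests over GRN feature sets, classification scores in
  [0, 1], precision–sensitivity curves with step-wise AUC and bootstrap CIs.
- **GRN status** (`grnpipe.status`) — importance-weighted capped-z-distance
  score standardized so each class's training samples average exactly 100%.
- **Network influence** (`grnpipe.influence`) — signed, importance-weighted
  ranking of TFs by how under-established their subnetwork is in a query
  group (most negative = strongest reactivation candidate).
- **Survival** (`grnpipe.survival`) — hand-rolled Kaplan–Meier, log-rank,
  single-covariate Cox (Breslow ties, Newton), and the best-cutoff scan over
  all distinct expression values strictly between the quartiles with
  Benjamini–Hochberg FDR gating (q < 0.10, smallest p wins).

## CLI

```bash
grnpipe simulate --seed 1 --out out/sim          # corpus + gold standard
grnpipe run --config config.yaml --out out/run   # full pipeline
grnpipe build-grn|train|validate|classify|status|nis --config config.yaml --out out/stage
grnpipe preprocess --expression expr.tsv --probe-map map.tsv --out out/prep
grnpipe simulate-survival --n-patients 300 --beta 1.5 --out cohort.csv
grnpipe survival --data cohort.csv --out out/surv
```

`config.yaml` holds every parameter (see `grnpipe.pipeline.RunConfig`); a
single global `seed` fans out deterministically to per-stage seeds, and
every output file embeds the resolved config hash. A full run emits the
sample table, expression matrix, gold standard, validation/query score
matrices, per-class precision–sensitivity curves with an AUC summary,
per-class GraphML networks with structure metrics, GRN-status tables, and
NIS tables.

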