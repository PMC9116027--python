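# spotcount

Statistical characterization of spatial transcriptomics count matrices:
which count model does each gene need, and are the zeros "real"?

For every gene in a gene × location count matrix, `spotcount` fits four
count models — Poisson, negative binomial (NB), zero-inflated Poisson
(ZIP) and zero-inflated negative binomial (ZINB) — with the per-location
total count as an offset in the mean. On top of the fits it runs:

- **four likelihood ratio tests** (P vs ZIP, P vs NB, NB vs ZINB,
  ZIP vs ZINB) with Bonferroni correction over the genes tested, to flag
  zero inflation and overdispersion;
- **AIC model selection** per gene, plus dataset-level summaries (zero
  proportion, variance/mean ratios, model-preference fractions);
- **cross-gene trend fits** of the mean→zero-proportion and mean→variance
  relationships under transcriptome-wide Poisson and NB models
  (Gauss–Newton nonlinear least squares), scored by MSE;
- **cluster-specific re-analysis**: locations are clustered
  (log-normalization → variance-stabilized HVG selection → PCA → SNN
  graph → Louvain), the panel is re-run inside each cluster, and
  after/before proportion ratios are reported;
- **conditional analysis**: the panel re-run with per-location cell-type
  compositions as covariates in the count-component mean.

NB fits that fail to converge (typically sample variance below the mean,
which drives the dispersion to infinity) fall back to a moment-based GEE
plug-in estimate; the candidate with the smaller AIC is kept.

A fully seeded synthetic-data module generates matrices from all four
families, Poisson mixtures over location clusters, and Dirichlet cell-type
mixtures — with ground truth — so the entire pipeline is testable without
external downloads.

## CLI

```bash
# simulate a matrix with known truth (writes sim.mtx + ID files + truth JSON)
spotcount simulate --seed 1 --out sim

# full pipeline: filter -> summaries -> trends -> gene panel (+ extras)
spotcount run-all sim.mtx --out-dir results/ --cluster --seed 1

# individual stages
spotcount summarize counts.csv --out summaries.tsv
spotcount trend summaries.tsv --out trends.json
spotcount fit-genes counts.csv --out panel.tsv          # --no-offset to drop offsets
spotcount cluster counts.csv --out labels.tsv --seed 1  # --labels to inject external labels
spotcount cluster-panel counts.csv labels.tsv --out-dir results/
spotcount conditional counts.csv compositions.csv --out panel_cond.tsv
```

Accepted input formats: MatrixMarket `.mtx` with companion
`<stem>.genes.tsv` / `<stem>.locations.tsv` ID files, or dense CSV/TSV
with gene rows and a location-ID header; gzipped variants work. Offsets
are always recomputed from column sums, never read from disk.

## Layout

| path | contents |
| --- | --- |
| `src/spotcount/matrix.py` | `CountMatrix` container (gene-major, recomputed offsets) |
| `src/spotcount/models.py` | likelihoods, moments, MLE + GEE-fallback fitting |
| `src/spotcount/genes.py` | filtering, summaries, LRTs, AIC panel |
| `src/spotcount/trends.py` | cross-gene Gauss–Newton trend fits |
| `src/spotcount/grouping.py` | clustering + cluster-specific panels + ratios |
| `src/spotcount/conditional.py` | composition-covariate panel |
| `src/spotcount/simulate.py` | seeded generators with ground truth |
| `src/spotcount/io.py`, `cli.py`, `pipeline.py` | readers/writers, CLI, orchestration |
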