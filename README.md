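# plastex

Expression-plasticity analysis toolkit for two-taxon, two-environment
RNA-seq designs. Given gene × sample count matrices for two taxa (e.g. a
crop and its wild ancestor) grown in two environments, the pipeline

1. runs per-taxon negative-binomial differential expression between
   environments with group (population / inbred-line) covariates
   (median-of-ratios size factors, method-of-moments dispersions,
   Wald tests, BH/BY FDR control, a flagged-gene removal step),
2. classifies every gene into a cross-taxon response category
   (`non_DE`, `maize_specific`, `teosinte_specific`, `shared_same`,
   `shared_opposite`) and refines assimilation candidates against
   external evidence sets,
3. computes Monte-Carlo resampling overlap/enrichment statistics
   (with an exact hypergeometric oracle) and Fisher-exact term
   enrichment with Benjamini–Yekutieli correction,
4. builds per-taxon weighted co-expression networks in one environment
   (soft-power adjacency, topological overlap, average-linkage modules
   with eigengene merging), scores module preservation in the other
   environment via permutation Z statistics (none/moderate/high bands
   at 2 and 10), and ranks hub genes,
5. compares per-gene variability statistics (panel coefficient of
   variation, diversity tables) across categories with Mann-Whitney U
   tests,

and it ships a fully seeded synthetic-data generator that plants known
response categories, enriched annotation sets, a line-panel expression
matrix with category-dependent variance, and a per-gene diversity table —
so the whole pipeline can be exercised end to end with ground truth.

## Test

```sh
python -m pytest -q tests/
```

The eight tests in `tests/test_acceptance.py::TestSupplementaryTargets`
require the original study's supplementary CSV files, which are not
redistributable with this repository; they fail with a descriptive
message unless `PLASTEX_SUPPLEMENTARY_DIR` points at a directory
containing `Maize_DE.csv`, `Teosinte_DE.csv`, `Maize_readcounts.csv`,
`Teosinte_readcounts.csv` and `Flowering_genes.csv`. Everything else is
self-contained.

## CLI

```sh
# generate a synthetic experiment with ground truth
plastex simulate --n-genes 2000 --seed 1 --out sim/

# differential expression for one taxon
plastex de --counts sim/counts_maize.tsv --design sim/design_maize.tsv \
    --out de_maize.tsv

# cross-taxon categories
plastex classify --de-maize de_maize.tsv --de-teosinte de_teosinte.tsv \
    --out categories.tsv

# Monte-Carlo overlap enrichment of two gene sets
plastex enrich --candidate cand.txt --annotation ann.txt \
    --background bg.txt --seed 1

# panel CV vs categories
plastex variability --panel sim/panel.tsv --categories categories.tsv \
    --out cv_comparisons.tsv

# everything from one config
plastex run-all --config config.yaml
```

A minimal `config.yaml`:

```yaml
seed: 1
out_dir: out
alpha_fdr: 0.05
n_resamples: 10000
simulate:
  n_genes: 2000
network:
  beta: 6
  min_module_size: 30
  merge_cutoff: 0.25
  n_permutations: 200
coexpress_max_genes: 400
panel:
  n_lines: 200
```

Replace the `simulate` block with an `inputs` block
(`maize_counts`, `maize_design`, `teosinte_counts`, `teosinte_design`,
optionally `de_maize`/`de_teosinte` for precomputed DE tables,
`flag_genes`, `selection`, `fixed_regulatory`, `term_map`, `panel`,
`diversity`) to run on real tables. All outputs are TSV plus one
`report.json`; the report is a pure function of config + seed.

## Layout

- `src/plastex/synthetic.py` — seeded NB count simulator with planted
  categories, annotation sets, panel and diversity tables
- `src/plastex/io.py` — delimited-text readers/writers (counts, designs,
  DE tables with column-alias mapping, gene sets, term maps)
- `src/plastex/diffexpr.py` — size factors, dispersions, NB GLM Wald
  tests, BH/BY adjustment, flagged-gene removal
- `src/plastex/classify.py` — response categories and candidate refinement
- `src/plastex/setstats.py` — resampling enrichment, hypergeometric
  oracle, Fisher term enrichment
- `src/plastex/coexpression.py` — expression filter, transform, soft
  power, TOM, modules, preservation, hubs
- `src/plastex/variability.py` — CV, Mann-Whitney U, category comparisons
- `src/plastex/pipeline.py`, `src/plastex/cli.py` — orchestration and CLI
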