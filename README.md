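# ggmnet

Graphical-Gaussian-model (GGM) gene co-expression networks from bulk
RNA-seq expression matrices: shrinkage partial correlations aggregated over
random gene subsets, signed edge selection with a Pearson co-filter, Markov
clustering (MCL) into gene modules, module enrichment statistics,
cross-species conservation scoring, and module expression profiles — plus
synthetic-data generators with planted ground truth so every stage can be
validated end to end without any external download.

## Who this is for

Systems biologists who have an FPKM gene-by-sample matrix (typically a
compendium of many RNA-seq runs) and want a *sparse* co-expression network:
in a GGM, an edge means two genes remain correlated after conditioning on
all other genes, so indirect co-expression through shared neighbors is
discounted. Modules of such a network group genes by direct co-regulation
("guilt by association") and can be annotated by term enrichment, promoter
motifs, and conservation against a second species' network.

## The method in brief

1. **Filter & transform.** Drop genes with max FPKM < 20 across samples;
   transform to log2(FPKM + 1), which removes most of the RNA-seq
   mean-variance dependency.
2. **Partial correlations.** For each of many iterations, draw a random
   gene subset and estimate Schafer–Strimmer shrinkage partial correlations
   (identity target, analytic shrinkage intensity λ*). For every gene pair
   keep the estimate of smallest absolute value across iterations, sign
   retained — a conservative aggregation that suppresses subset artifacts.
3. **Edges.** Admit a pair iff pcor ≥ 0.035 and PCC ≥ 0.35 (or both ≤ the
   negated thresholds); the edge sign is the pcor sign.
4. **Modules.** Cluster the sign-blind topology with MCL (inflation 1.5);
   keep modules of ≥ 5 genes, numbered by descending size. Report
   transitivity against the Erdős–Rényi expectation 2E/(N(N−1)).
5. **Annotation.** Hypergeometric term enrichment (BH-adjusted per module),
   binomial promoter-motif enrichment over both-strand IUPAC scans,
   conserved-interaction scoring through a homolog map, module mean
   profiles over ordered sample groups, and neighbor-voting AUROC against
   known gene sets.

See `docs/methods.md` for the full model, estimator formulas, parameter
defaults, and the synthetic generator's scope.

## Worked example

Generate a synthetic scenario with 8 planted 20-gene modules among 200
genes (400 samples), then run the full pipeline with a desk-scale sampling
plan (200 iterations of 80-gene subsets) and thresholds suited to the
planted effect size:

```bash
ggmnet simulate --out-dir scen --n-genes 200 --n-modules 8 \
    --module-size 20 --n-samples 400 --seed 1
```

```python
from ggmnet import PipelineConfig
PipelineConfig(
    expression_path="scen/expression.tsv", out_dir="out",
    n_iterations=200, subset_size=80,
    pcor_threshold=0.04, pcc_threshold=0.15,
    annotations_path="scen/annotations.tsv",
    partner_network_path="scen/partner_edges.tsv",
    homolog_map_path="scen/homologs.tsv",
    motif="GNATATNC", promoters_path="scen/promoters.fasta",
    seed=1,
).to_yaml("config.yml")
```

```bash
ggmnet run --config config.yml
```

prints

```
INFO:ggmnet.preprocessing:low-expression filter kept 200 of 200 genes (max FPKM >= 20)
INFO:ggmnet.estimation:sampled pcor estimation: 200 iterations x 80 genes, pair coverage 100.0%
INFO:ggmnet.estimation:selected 390 positive and 20 negative edges
INFO:ggmnet.network:MCL: 11 modules >= 5 genes (173 genes), 3 genes in small modules
done: 200 genes kept, 410 edges (390+/20-), 11 modules
```

Reading the numbers: all 200 genes clear the FPKM filter (the generator's
base expression range is chosen to be realistic for network-analysis
input); every gene pair was co-sampled at least once; 410 edges survive the
dual threshold, overwhelmingly positive — the 20 negative edges are
threshold-grazing noise, planted associations being positive. MCL finds 11
modules: the 8 planted ones (sometimes split, plus small noise groups),
covering 173 of the 176 connected genes. The manifest
(`out/manifest.yml`) records the headline counts,

```
clustering_coefficient: 0.36083   # vs random expectation 0.0266
network_wide_percent_conserved: 67.6136
```

— the network is ~14× more clustered than a random graph of its size, and
two thirds of its genes keep a conserved interaction in the partner network
(which was generated with 80% homolog coverage and 20% edge rewiring).
Per-module tables (`modules.tsv`, `go_enrichment.tsv`,
`motif_enrichment.tsv`, `conservation_modules.tsv`) carry the per-gene and
per-module detail.

Every stage is also callable on its own (`ggmnet estimate`, `ggmnet edges`,
`ggmnet cluster`, `ggmnet enrich-go`, `ggmnet enrich-motif`,
`ggmnet conserve`, `ggmnet profile`), and the same functionality is a plain
Python API (`import ggmnet`).

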