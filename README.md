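# virome-ap

Analysis toolkit for case/control gut-virome studies: alignment-based
vOTU profiling, diversity and ordination statistics, differential-feature
selection, severity-gradient trajectory detection, random-forest
diagnostics, and cross-kingdom virus–bacterium–clinical correlation
networks. A synthetic-cohort generator with planted ground truth makes
every pipeline stage verifiable offline, without access to any real
cohort.

## Modules

| module           | what it does |
|------------------|--------------|
| `synthetic_data` | catalogs, abundance matrices, metadata, read alignments and ground truth with planted differential / monotone / correlation structure |
| `profiling`      | best-hit resolution, coverage-breadth presence calls (interval merge), RPK-normalized relative abundance, family/host aggregation |
| `ecology`        | alpha diversity, sample-accumulation rarefaction, Bray–Curtis/Jaccard, PCoA, PERMANOVA (9,999-permutation default) and pairwise PERMANOVA |
| `differential`   | Wilcoxon rank-sum (exact for small tie-free inputs), BH-FDR, fold-change + abundance filters, covariate-adjusted OLS validation, Fisher exact KO-occurrence tests, host/family summaries |
| `trajectory`     | cumulative set abundance across ordered severity strata, monotone-trajectory detection, per-severity classifiers |
| `classifier`     | random forest with repeated stratified CV, rank-statistic AUC, leak-free feature-count curves, combined virus+bacteria models |
| `network`        | all-pairs Spearman, BH-thresholded signed graphs, topology metrics (average degree, average path length), hub ranking, group comparison |

## CLI

Every stage is exposed through the `virome-ap` command:

```bash
# synthetic cohort with planted ground truth
virome-ap simulate --config cfg.yaml --outdir data/ --seed 7

# alignments -> abundance matrix (SAM dir or .aln.tsv dir)
virome-ap profile --aln data/alignments --catalog data/catalog.tsv \
    --min-breadth 0.10 --out votu_abund.tsv

# diversity, PCoA, PERMANOVA
virome-ap ecology --abund votu_abund.tsv --meta data/metadata.tsv \
    --metric bray_curtis --permutations 9999 --seed 7 --outdir eco/

# differential features (add --validate for covariate-adjusted check)
virome-ap diff --abund votu_abund.tsv --meta data/metadata.tsv \
    --fc 1.2 --q 0.05 --min-abund 1e-4 --out diff.tsv

# severity trajectories
virome-ap trajectory --abund votu_abund.tsv --meta data/metadata.tsv \
    --order MAP,MSAP,SAP --out traj.tsv

# random-forest diagnostics
virome-ap classify --features votu_abund.tsv \
    --features2 data/bacterial_abundance.tsv --meta data/metadata.tsv \
    --folds 5 --repeats 5 --seed 7 --out clf.json

# cross-kingdom network
virome-ap network --virus votu_abund.tsv \
    --bacteria data/bacterial_abundance.tsv --clinical clinical.tsv \
    --rho 0.4 --q 0.05 --outdir net/
```

`cfg.yaml` may override any `SyntheticConfig` field (cohort sizes,
planted effect sizes, sparsity, read depth, ...).

## Conventions

- Coordinates are 0-based half-open internally; SAM's 1-based
  convention is converted at the reader boundary.
- Best-hit ties are broken by lexicographically smallest vOTU id.
- Shannon entropy uses the natural log.
- Permutation p-values use the (hits + 1)/(permutations + 1) correction.
- Rows of abundance matrices are renormalized to sum to 1 after
  presence filtering; this is recorded in the output header.
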