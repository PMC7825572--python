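# ncoocnet

Co-occurrence network inference and community statistics for
functional-gene OTU tables, with a synthetic-data generator providing
known ground truth.

The pipeline, per treatment group:

1. **Preprocess** — keep OTUs present in every replicate of the group
   with a summed relative abundance above 0.01%, then close samples to
   relative abundances.
2. **Edge significance** — Spearman scores between all retained pairs;
   candidates at |r| ≥ 0.7; per-candidate permutation null (independent
   row shuffles with a compositional renormalization step — metadata
   variables are never renormalized) and bootstrap distribution (sample
   columns resampled with replacement); unstable edges (null mean inside
   the central 95% bootstrap interval) are discarded; p-values from the
   bootstrap Gaussian at the permutation mean, Brown-merged and
   Benjamini–Hochberg corrected; edges kept at q ≤ 0.05.
3. **Topology** — clustering coefficient (degree ≥ 2 nodes), diameter and
   shortest-path count over finite distances, average neighbors 2E/N,
   density 2E/(N(N−1)); degree / closeness / betweenness centralities
   (component-local normalization); keystone taxa under configurable
   joint-threshold presets (`AOA`, `nirS`, `nosZ`); networks with
   < 10 nodes are excluded from topology analysis.
4. **Community statistics** — observed OTUs, Chao1, Shannon,
   Gini–Simpson, evenness (and optional Faith PD with a newick tree),
   Bray–Curtis distances, PCoA, PERMANOVA, Spearman Mantel tests against
   soil variables, and Pearson diversity–environment correlations.

## CLI

```bash
# synthetic dataset with a planted association and linked soil variable
ncoocnet simulate --n-taxa 50 --n-replicates 5 --depth 10000 \
    --planted-edge 0,1,0.95 --seed 1 --out data/

# per-treatment networks + topology + keystones (+ metadata nodes)
ncoocnet network --table data/otu_table.tsv --metadata data/metadata.tsv \
    --group CK --group AR --seed 1 --out run/

# topology / keystones of a saved network
ncoocnet topology --net run/network_CK.graphml --keystone-preset nosZ

# diversity, ordination, PERMANOVA, Mantel
ncoocnet stats --table data/otu_table.tsv --metadata data/metadata.tsv \
    --seed 1 --out statsdir/

# everything at once
ncoocnet all --table data/otu_table.tsv --metadata data/metadata.tsv \
    --seed 1 --out run/
```

Network runs accept a YAML config (`--config`) with keys `threshold`,
`n_permutations`, `n_bootstraps`, `ci`, `alpha`, `renormalize`,
`exact_enumeration_max_n`, `p_method`, `seed`. Outputs are GraphML,
edge-list TSVs, tab-delimited reports and a JSON run manifest; runs are
byte-reproducible under a fixed seed.

## File formats

- OTU table: tab-delimited, OTUs as rows, sample columns, final
  `taxonomy` column (`;`-separated lineage, `g__` prefixes optional).
  Sample ids `<group>_<replicate>` carry the treatment label.
- Metadata: tab-delimited, samples as rows, numeric columns, `NA` for
  missing.
- Ground truth: tab-delimited `taxon_i  taxon_j  target_spearman`.

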