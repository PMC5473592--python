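# repliseq

How many DNA-extraction replicates, and how many reads, does a sediment
metabarcoding survey need? Benthic communities are patchy at the
centimetre scale, so a single 0.5 g scoop of sediment underestimates a
sample's diversity and inflates its apparent distance to other samples —
and no amount of extra sequencing of that one scoop fixes it. `repliseq`
is a resampling framework for replicate OTU tables (rows = OTUs, columns
= sequencing datasets, one per extraction replicate) that separates the
two effects: it simulates in-silico pooling of `n` replicates at constant
total depth, and depth gradients at fixed replication, and measures what
each does to alpha diversity and to sample separability. It is aimed at
researchers designing or evaluating marker-gene surveys of sediment
eukaryotes (protists and meio-/macrofauna), and at anyone who wants
exact rarefaction machinery with reproducible subsampling simulations.

## What it computes

- **Rarefaction**: exact expected OTU richness in a random subsample of
  `n` of `N` reads (Hurlbert), `E[S_n] = Σ_i [1 − C(N−N_i, n)/C(N, n)]`,
  with the exact Heck et al. variance from pairwise joint-absence terms —
  both evaluated in log-gamma space and verified against exhaustive
  enumeration and R vegan's `rarefy`. Shannon diversity (natural log)
  under repeated hypergeometric subsampling.
- **Pooling simulations**: richness/Shannon versus the number of pooled
  replicates `n`, each contributing `r = ⌊15,000/n⌋` reads so total depth
  stays constant; the *relative gain* is the pooled estimate over the
  single-replicate mean.
- **Beta diversity**: Bray–Curtis (`Σ|x−y|/Σ(x+y)` on relative
  abundances) and Jaccard (`1 − |∩|/|∪|` on presence/absence)
  within-sample divergence versus depth, and mean silhouette scores
  (`(b−a)/max(a,b)` on a Bray–Curtis matrix, sample-of-origin clusters)
  versus depth and versus replication.
- **Taxonomic subsets**: every simulation can filter to protist or
  metazoan OTUs — always *after* subsampling, mimicking a taxonomic
  target sequenced with universal eukaryote primers.
- **Synthetic studies**: a Dirichlet-multinomial generator with
  per-category patchiness (metazoa patchier than protists, via a
  concentration parameter and a dominance cap) that reproduces the study
  design — 3 samples × 10 replicates, uneven depths, long-tailed
  abundances, ~16% singleton OTUs — plus a homogeneous null counterpart.

See `docs/methods.md` for the model details and design choices.

## Worked example

```python
import repliseq as rs

study = rs.preset_study("paperlike", seed=1)      # 3 samples x 10 replicates
design = rs.PoolingDesign(n_values=(1, 2, 5, 10), total_depth=15000,
                          iterations=25, seed=1)
res = rs.pooled_alpha_vs_n(study.table, study.taxonomy, "all", design)
richness = res["richness"].mean
gain = richness.div(richness.loc[1], axis=1)
print(gain.round(2))
```

```
                S1    S2    S3
n_replicates                  
1             1.00  1.00  1.00
2             1.23  1.24  1.25
5             1.50  1.53  1.58
10            1.65  1.69  1.81
```

Reading: at a fixed budget of 15,000 reads per sample, splitting those
reads across 10 pooled extraction replicates recovers 65–81% more OTUs
than spending them all on one replicate — extra replication captures
diversity that extra depth cannot, because each scoop simply does not
contain every taxon. The same study shows mean silhouette separability
rising from 0.24 (single replicates) to 0.44 (5 pooled replicates), and
intra-sample Bray–Curtis divergence falling from 0.69 at 500 reads to
0.53 at 15,000.

The same analyses run from the shell:

```bash
repliseq synth --preset paperlike --seed 1 --out-dir synth
repliseq describe --otu-table synth/otu_table.tsv \
    --taxonomy synth/taxonomy.tsv --sample-map synth/sample_map.tsv
# -> 50000 OTUs, 30 datasets, 667308 reads; 1573 singletons
#    (16.4% of OTUs, 0.24% of reads)
repliseq alpha-pooling --otu-table synth/otu_table.tsv \
    --taxonomy synth/taxonomy.tsv --sample-map synth/sample_map.tsv \
    --iterations 100 --seed 1 --out-dir results
```

`repliseq run --config config.toml` executes the full battery (overview
table, rarefaction curves for replicates and pooled samples, pooling
simulations, divergence and silhouette versus depth and replication, and
a singleton-sensitivity rerun) into a results directory with a manifest
of config, seed and output checksums; rerunning with the same seed
reproduces every output byte-for-byte.

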