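# Methods

`repliseq` quantifies how two experimental-design knobs — sequencing depth
and the number of DNA-extraction replicates per sample — shape
alpha-diversity estimates and sample separability in eukaryote
metabarcoding of marine sediments. Its inputs are an OTU read-count table
(rows = OTUs, columns = sequencing datasets, one per extraction replicate)
and a taxonomy mapping each OTU to a coarse category: *protist*
(operationally, a classified eukaryote that is not metazoan, fungal or
Viridiplantae), *metazoa*, or *other*. Upstream processing (denoising,
chimera removal, OTU clustering, taxonomic classification) is out of
scope; the table is consumed as-is, and singleton OTUs are retained by
default so every dataset remains a representative sample of the
underlying abundance distribution.

## Rarefaction

Rarefied richness is the expected number of OTUs in a random subsample of
`n` reads drawn without replacement from a dataset of `N` total reads
(Hurlbert's formulation):

    E[S_n] = Σ_i [ 1 − C(N − N_i, n) / C(N, n) ]

with `N_i` the read count of OTU `i`. The exact sampling variance (Heck
et al.) follows from the pairwise joint-absence probabilities
`q_ij = C(N − N_i − N_j, n) / C(N, n)`:

    Var[S_n] = Σ_i q_i(1 − q_i) + 2 Σ_{i<j} (q_ij − q_i q_j)

Both are evaluated in log-gamma space, so tables with 10⁵–10⁶ reads do
not overflow, and the variance sum is grouped over distinct abundance
values so cost is quadratic in the number of *distinct* counts, not the
number of OTUs. The functions are exact at the boundaries (`n = 0`,
`n = N`), refuse `n > N` (no extrapolation), and are verified in the test
suite against exhaustive enumeration of every subsample for all abundance
configurations with ≤ 12 reads, and against R vegan's `rarefy`.

Shannon diversity (natural log, the vegan default) has no convenient
closed form under subsampling, so it is estimated by repeated (default
100×) multivariate-hypergeometric subsampling, reported as the mean with
the empirical standard error of that mean.

## Dissimilarity and separability

Bray–Curtis dissimilarity `Σ|x−y| / Σ(x+y)` is computed on the relative
abundances of the vectors being compared (for simulations: of the
*subsample*, not the parent dataset); Jaccard `1 − |∩|/|∪|` on
presence/absence. Within-sample divergence is the mean over unordered
replicate pairs of a sample. Separability is the mean silhouette score of
the replicates under their sample-of-origin labels, computed on a
precomputed Bray–Curtis matrix: `s = (b − a)/max(a, b)` per replicate,
where `a` is the mean dissimilarity to its own sample's replicates and
`b` the smallest mean dissimilarity to another sample's. Scores keep the
standard [−1, 1] range (well-separated data land in [0, 1]; negative
means are reported, never clipped), and singleton clusters score 0.

## Simulations

All four simulations share one subsampling primitive and one randomness
contract: the draw for (dataset, depth, iteration) comes from a random
stream derived deterministically from (seed, dataset id, depth,
iteration). Results are therefore bit-reproducible, independent of
evaluation order, and the `n = 1` pooling simulations reduce *exactly* to
the corresponding single-replicate depth simulations.

1. **Alpha vs depth** — per replicate and depth: subsample the full
   community to the depth, *then* filter to the category, then compute
   richness and Shannon. Filtering after subsampling mimics targeting a
   taxonomic subset with universal eukaryote primers at a given total
   depth; the reverse order (filter first) concentrates the depth budget
   on the category and answers a different question (a regression test
   pins the order).
2. **Pooled alpha vs replication** — for each number of pooled replicates
   `n`: draw `n` distinct replicates uniformly, subsample
   `r = ⌊15,000/n⌋` reads from each, merge, filter, compute diversity.
   Total merged depth stays ~constant (within `n − 1` reads of 15,000
   when `n ∤ 15,000`, a < 0.5% deviation), separating the replication
   effect from the depth effect. The *relative gain* at a given `n` is
   the mean diversity divided by the `n = 1` mean.
3. **Divergence / silhouette vs depth** — per depth (default 500 to
   15,000 in 500-read steps): subsample every replicate deep enough,
   compute mean within-sample Bray–Curtis and Jaccard, and the mean
   silhouette over all replicates.
4. **Silhouette vs replication** — per `n`: randomly partition each
   sample's replicates into `⌊R/n⌋` disjoint pseudo-replicates of `n`
   members (leftovers discarded), subsample each member to
   `r = ⌊15,000/n⌋` reads, merge, and score the pseudo-replicates'
   silhouette. At least 2 pseudo-replicates per sample are required, so
   `n ≤ 5` for 10 replicates.

Reported errors are the across-iteration standard deviation divided by
√iterations (the Monte-Carlo error of the reported mean); per-iteration
raw values are kept on the result object for any other summary.

**Shallow replicates.** Subsampling `r` reads from a replicate with fewer
than `r` reads is impossible without replacement, yet uneven replicate
depths (here 2,500–37,000 reads) make such collisions routine, e.g. at
`n = 5`, `r = 3,000`. Two policies are provided. `exclude` removes
too-shallow replicates from the selection pool (default for the pooled
alpha simulation, where the `n = 1` case must coincide with rarefaction to
15,000 reads over the deep replicates). `all_reads` keeps them,
contributing every read they have — the convention of vegan's `rrarefy`,
and the default for the pseudo-replicate silhouette simulation, whose
fixed `⌊R/n⌋`-pool structure presumes all replicates participate. The
exact `n = 1` reduction holds under `exclude`.

Datasets below 15,000 reads are excluded from depth-evaluation analyses
(`min_depth`, configurable); excluded datasets and skipped grid points
are logged, since these exclusions determine which replicates stand
behind every curve.

## Synthetic studies

The generator emulates the study design end-to-end so the whole pipeline
is testable without any sequence data: 3 samples × 10 extraction
replicates, per-replicate depths uniform on 2,500–37,000 reads, a
protist-majority pool (64% protist / 8% metazoan / 28% other OTUs,
allocated exactly), and a long-tailed log-normal base abundance
distribution over 50,000 OTUs with σ = 3.0. At these depths roughly
9,500 OTUs are observed of which ~16% are study-wide singletons,
i.e. deep in the regime where richness is far from a complete census —
the regime the replication question lives in. A `tiny` preset
(3 × 3 × 200 OTUs, 500–2,000 reads) exists for fast smoke tests.

Heterogeneity is compound Dirichlet-multinomial with one refinement. Per
sample, the base abundances are perturbed by a log-normal per-OTU
multiplier (σ_shift, default 1.0), creating between-sample structure.
Per replicate, composition is drawn from a Dirichlet centred on the
sample composition whose per-OTU concentration is

    α_i = min(θ_c · p_i, κ_c)

with `θ_c` the category's concentration (lower = patchier; default 3,000
for protists/other, 300 for metazoa) and `κ_c` a per-category *dominance
cap* (default 50 for protists/other, 0.2 for metazoa). Gamma draws are
rescaled to keep every OTU's expected abundance at `p_i`, so patchiness
differs by category without biasing mean composition. The cap is the
scientifically load-bearing part: with plain `α_i = θ_c·p_i`, a
category's dominant OTUs are always compositionally stable (large α),
while the real mechanism of metazoan heterogeneity is precisely that
*individual large organisms* dominate a 0.5 g sediment scoop or are
absent from it — dominant metazoan taxa must swap identity between
replicates. The cap bounds every metazoan OTU's concentration at 0.2
(CV > 200%), reproducing both the huge replicate-to-replicate swings in
metazoan read share (5%–94% in the default study) and the observable
ordering of within-category divergence (metazoa ≈ 0.67 Bray–Curtis
vs protists ≈ 0.54 at 5,000 reads), which plain Dirichlet concentration
ratios cannot produce at any θ once the protist rare-tail sampling floor
(≈ 0.49) is accounted for. Finally, reads are drawn multinomially at the
replicate's depth (sequencing noise).

The **null study** removes both heterogeneity layers (σ_shift = 0, all
concentrations and caps at 10⁹): replicates become plain multinomial
samples of one shared community. It calibrates the pipeline's null
behaviour — pooled richness gain stays within [0.97, 1.03] for
n = 1…5, mean silhouette within ±0.1 of zero, and intra-sample
Bray–Curtis sits on the closed-form multinomial noise floor
`Σ_i E|A_i−B_i|/(2d)` with `A_i, B_i ~ Poisson(d·p_i)` (checked in the
tests via modified Bessel functions).

### What the generator does not model

PCR and sequencing error, chimeras, index-hopping bias, rRNA gene
copy-number variation between taxa, and spatial autocorrelation between
replicates (replicates are exchangeable draws). Passing tests therefore
demonstrate that the *statistical machinery* recovers replication and
depth effects from controlled heterogeneity of this form — not that real
sediment data are free of the additional biases above.

## Problem sizes and numerical choices

Simulations in the tests and the acceptance script use 25 iterations per
condition and the depth/replication grids {500, 2,500, 5,000, 15,000}
and n ∈ {1, 2, 5, 10}; the pipeline defaults are the full analysis
scales (100 iterations, 500-read grid). Invariant checks use a 1e-9
absolute tolerance; `1 − exp(·)` terms are clamped to [0, 1]; non-integer
grid depths are rejected; depths beyond a dataset's total are skipped
with a log notice, never extrapolated. Jaccard is the classic set
dissimilarity (vegan's binary formulation is algebraically identical;
asserted against scipy on random sets). Pearson correlation of richness
with depth returns r = 0 for constant richness (degenerate but defined)
and refuses zero-variance depths.

## Known limitations

- The analytic richness SE applies Heck's formula to single datasets;
  across-replicate curves use the empirical SEM instead, and the two are
  not interchangeable.
- The dominance cap is a coarse, single-parameter account of organism
  size; it does not model body-size spectra or biomass-to-read scaling.
- Silhouette scores on few replicates (e.g. 2 pseudo-replicates per
  sample at n = 5) are noisy; the simulation reports the Monte-Carlo mean
  over iterations, which remains comparable across n but is not a
  substitute for more replication.
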