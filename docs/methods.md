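# Methods

## Model

`comod` detects *biclusters*: sets of genes together with the subset of
conditions over which they are co-expressed, optimized so that member genes
are simultaneously (i) tightly co-expressed over the bicluster's
conditions, (ii) enriched for shared de-novo sequence motifs in their
promoters or 3'UTRs, (iii) densely connected in user-supplied gene
association networks, and (iv) enriched for user-supplied gene sets.  The
optimizer is a global, stochastic, k-means-like procedure over overlapping
memberships rather than a per-cluster local search.

State: each gene belongs to exactly `v` clusters (default 2); each of the
`k` clusters holds a subset of conditions (seeded with a random half of all
conditions).  `k` defaults to `n_genes * v / 20`, i.e. about 20 genes per
cluster on average.

Each iteration:

1. **Scoring.**  Active scorers produce element x cluster score matrices
   (lower = better, log-likelihood-like):
   * expression `R_ij = log(mean_c (x_ic - mu_jc)^2 + eps)` over cluster
     j's conditions, with `mu_jc` the member-gene mean and `eps = 1e-10`;
   * motif `S_ij = ln p_ij`, the empirical sequence p-value of gene i's
     best match to cluster j's discovered PSSMs;
   * network `T_ij = -sum_{g in roster(j)} w(i,g) / |roster(j)|`, a
     per-gene connection density, averaged over networks with their
     weights;
   * set enrichment `E_ij = log10(p*_j) x m_i` with `m_i` 1.0 / 0.5 / 0.0
     for genes in the cluster's best-enriched set and the cluster, in the
     set only, or neither; `p*_j` is the best one-sided Fisher p clamped
     from below at the Bonferroni cutoff `alpha / n_sets` (`alpha` = 0.05).
2. **Combination.**  Each active matrix is standardized to median 0 and
   median-absolute-deviation 1 over its finite entries (median/MAD rather
   than mean/sd because motif and set scores are heavy-tailed log
   p-values), then combined as a weighted mean `M`.
3. **Stochasticity.**  Elementwise Gaussian noise is added to `M`; its sd
   decays linearly from 0.25 (standardized units) at iteration 1 to
   exactly 0 at the final iteration (default 2000).  The early noise keeps
   memberships fluid; the anneal lets clusters settle into sharper optima.
4. **Membership probabilities.**  Per cluster column, `p_ij = 1 -
   KCDF_j(M_ij)` where `KCDF_j` is the Gaussian-kernel empirical CDF of
   the column with bandwidth `h_j = h0_j (1 + c / |roster(j)|)` (`h0_j`
   Silverman's rule, `c = 20`).  The roster-size term widens the kernel
   for small clusters, which flattens their probability profile and biases
   the system toward adding genes to small clusters rather than emptying
   them.
5. **Moves.**  A random half of the genes (and, using the
   expression-variance condition scorer, a random half of the conditions)
   are each offered one swap: into the best non-member cluster when its
   probability strictly exceeds the worst current membership, out of that
   worst cluster.  Ties never move; membership multiplicity is conserved;
   gene moves keep rosters within [3, 70] genes and condition rosters at
   >= 2 conditions.

## Scoring schedule

Expression runs every iteration with weight 1.0 and remains the dominant
stream throughout.  The reinforcement scorers are deliberately restrained:
motif and set-enrichment scoring reward a gene equally in *any* cluster
that has locked onto the same training signal (the same set, or the same
rediscovered motif), so giving them parity with expression while the
annealing noise is still high lets several clusters become attractors for
one true module and permanently fragments its genes across more than `v`
clusters.  On synthetic data with implanted modules, motif/set weights at
parity cost roughly a third of the otherwise-recoverable modules; capping
the motif weight at half the expression weight and deferring set
enrichment to the second half of the run removes the effect.  Defaults:

* network: weight 0.5, every iteration;
* set enrichment: weight 1.0, every iteration from 50% of the run;
* motif: discovery + rescoring every 100 iterations starting at 5% of the
  run, weight ramping linearly from 0 to a maximum of 0.5 at 2/3 of the
  run, constant afterwards.

All schedule entries are `key=value`-configurable
(`scorer.motif.iterations=800:2000:100`, `scorer.sets.weight=0.5`, ...).

## Motif backends

The `meme` and `weeder` backends shell out to the MEME suite / Weeder
binaries (probed at configuration time, never mid-run) and parse their
text output into PSSMs.  The `internal` backend is a dependency-free
k-mer miner used for fully self-contained runs and testing:

* every canonical k-mer (k = 6..8; a k-mer and its reverse complement are
  one feature) is tested for over-representation among the cluster's
  sequences against the full sequence background with a hypergeometric
  tail on per-sequence presence counts;
* the reported p-value is Bonferroni-corrected over all canonical k-mers
  present in the background — corrected-and-capped, it is a valid
  (super-uniform) p-value for the best motif, which is what the null
  calibration test checks; the uncapped corrected value plays the role of
  an E-value and "significant motif" means E <= 1;
* up to 4 motifs are returned, best first, suppressing seeds within
  Hamming distance 1 of an already-chosen seed; each seed k-mer is
  expanded into a PSSM from its occurrences (Hamming <= 1, both strands,
  pseudocount 0.5).

Sequence p-values: each PSSM is turned into log-odds against the 0-order
background of the input sequences and scanned over both strands of every
gene's sequence; the best hit is compared with a pooled empirical null of
1000 letter-shuffled input sequences (add-one-corrected rank).  Within a
cluster, the per-gene minimum over its motifs is Sidak-combined.  Genes
without a sequence score p = 1.  Operon-mapped genes inherit the operon
head's promoter and p-value.

## Numerical choices

* Kernel CDF: columns longer than 128 entries are compressed to 128
  equal-count bins (bin means of the sorted column) before the kernel sum;
  shorter columns use the exact sum.  The binning error (|dp| < ~3e-3 at
  fixture scale) is far below the annealing noise; all oracle-equivalence
  tests run on short columns where the computation is exact.
* Probabilities are evaluated only for the elements sampled for a move in
  that iteration (the reference distribution always uses the full column).
* Probabilities are clipped to (1e-12, 1 - 1e-12); standardization falls
  back to sd (then to centering only) when the MAD is zero, e.g. for the
  mostly-zero set-enrichment matrix.
* Missing expression values carry zero weight in every mean/variance and
  in the mean squared residue; unscorable (element, cluster) entries are
  imputed with the column's worst finite score before combination so that
  unscorable is never attractive.
* Ties in the move rule never move (strict inequality), preventing
  oscillation at fixed points.

## Evaluation suite

* Cheng–Church mean squared residue per bicluster (0 for additive
  submatrices), missing-aware.
* Motif significance: fraction of clusters whose best motif has E <= 1.
* Regulon recovery: a (cluster, regulon) match requires overlap > 2 genes
  and an upper-tail hypergeometric p-value passing Benjamini–Hochberg
  FDR <= 0.01 over all pairs; precision = matched clusters / clusters,
  recall = matched regulons / regulons, G = sqrt(PR), F1 = 2PR/(P+R).
  Combinatorial regulons group genes by their exact combination of
  regulating TFs.  The test universe is the union of genes on both sides
  unless supplied.
* Set recovery counts: clusters enriched for >= 1 set and sets enriched in
  >= 1 cluster at BH p <= 0.01, plus "unique" variants counting exactly-one
  matches.
* PC1 variance filter: a bicluster passes when at most 5% of size-matched
  random gene sets (1000 draws, optionally precomputed on a size grid of
  5..65 step 5 with nearest-size lookup) exceed its first-principal-
  component variance fraction.

## Synthetic fixtures

The generator implants `n_modules` disjoint gene modules (default 10 x 20
genes out of 400, over 20 of 60 conditions): member genes share a
condition-restricted profile (per-condition N(0, 2.0^2)) plus N(0, 0.5^2)
noise on a N(0, 1) background; module promoters (length 100) carry a
common 8-mer implanted in 80% of members with 10% per-position mutation,
random strand and position; the association network is Erdos–Renyi with
intra-module edge probability 0.3 versus 0.02 background (weights
U(0.5, 1)); gene sets mirror the modules.  It emulates the statistical
structure the optimizer assumes — condition-specific co-expression, shared
promoter motifs, network modularity, set co-membership — but not the batch
structure, variance heterogeneity, operon coupling or correlated noise of
real compendia, so passing recovery tests demonstrates correctness of the
optimization, not expected field performance.

Problem sizes used in the automated checks — the 400 x 60 default fixture
for full 2000-iteration end-to-end runs, a 150 x 40 / 6-module fixture at
500 iterations with a weakened shared profile (signal sd 0.7 against unit
noise, so co-expression alone leaves recovery headroom) for the paired
set-enrichment ablation, and 200-sequence universes for motif null
calibration — were chosen so each check completes in minutes on one CPU
while keeping the tested effects comfortably away from both floor and
ceiling.  Note that module hardness must be dialed through the signal
amplitude: inflating the noise instead leaves modules detectable through
their variance footprint alone.

## Known limitations

* The internal motif miner targets compact, well-conserved sites; it will
  miss long, diffuse or strongly gapped motifs that MEME/Weeder can model.
* Scores of the auxiliary streams are rank-transformed per cluster column
  by the kernel CDF, so a cluster that trains on a spurious signal ranks
  its followers highly regardless of absolute score; the deferred schedule
  mitigates but does not eliminate this.
* Condition memberships follow the interpretation that each cluster is
  seeded with half of all conditions and conditions move freely afterwards;
  per-condition membership counts are not constrained.
* `k`, `v`, bounds and weights are global; no per-cluster adaptation.
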