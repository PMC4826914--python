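# Methods

## The question and the pipeline

Genes do not evolve in isolation: the position a protein occupies in the
protein-protein interaction (PPI) network constrains both how visible its
mutations are to selection and how pleiotropic they are.  `netsel`
implements the full analysis chain used to ask whether genes under
recurrent positive selection sit at the periphery or the center of an
interactome:

1. one-to-one orthologs across a small clade by best reciprocal hits (BRH);
2. alignment quality control targeted at gene-model annotation errors;
3. a per-gene M8-vs-M7 codon site-model likelihood ratio test (LRT) with
   Benjamini–Hochberg FDR control;
4. degree, betweenness and closeness on a filtered PPI network;
5. rank-based two-group comparisons and (partial) correlations to link
   selection status to centrality while controlling confounders.

Because the real inputs of such studies are large external downloads, the
package ships a first-class synthetic-data module that emulates every
input with known truth, and the test suite exercises the chain end to end
on it.

## Codon substitution model

Substitution follows the GY94 family on the 61 sense codons: single-
nucleotide changes only, with relative rate `pi_j`, `kappa*pi_j`,
`omega*pi_j`, or `omega*kappa*pi_j` for synonymous transversions /
transitions and nonsynonymous transversions / transitions.  `omega =
dN/dS` is the selection parameter; `kappa` the transition/transversion
ratio; `pi` the stationary codon frequencies (equal frequencies or
empirical F3x4, floored at 1e-8 and renormalized so observed codons are
never impossible).  The chain is reversible, so a single symmetric
eigendecomposition per omega yields all transition matrices.

Site models: under M7 site omegas follow Beta(p, q) on [0, 1]; M8 adds a
point mass at `omega_s >= 1` with weight `1 - p0`.  For fitting, the beta
is discretized into K = 10 equal-probability classes (configurable) whose
representative is the within-slice conditional mean, computed in closed
form from regularized incomplete beta functions.  Rate matrices are
normalized by the class-weighted mean rate so branch lengths are expected
substitutions per codon under the fitted mixture.

Column likelihoods use Felsenstein pruning with per-node rescaling;
identical columns are collapsed to weighted patterns; gap/ambiguous
codons are marginalized as missing data.  Pruning is verified against
exhaustive enumeration over internal-node states on small trees (1e-8
relative).

## Fitting engines

* **exact** (default for `fit_model`): bounded L-BFGS-B on transformed
  parameters (log for p, q, kappa, omega_s − 1 and branch lengths; logit
  for p0), convergence at relative log-likelihood change < 1e-8 or 500
  iterations, three starting omega values (0.04, 0.4, 4) seeding the beta
  mean (M7) and `omega_s = 1 + omega_start` (M8), best likelihood wins.
  Branch lengths and kappa are optimized jointly by default, or can be
  fixed.
* **grid** (simulation workhorse): transition matrices are precomputed
  once per (tree, kappa, pi) on a fixed omega grid (42 points, dense in
  [0, 1] and log-spaced up to 15) and shared across all genes; per gene,
  one pruning pass yields per-site log-likelihood curves in omega, and the
  mixture likelihood for any candidate (p, q[, p0, omega_s]) evaluates a
  shape-preserving monotone-cubic (PCHIP) interpolant of those curves.
  The objective has an analytic gradient (posterior-weighted interpolant
  slopes chained through forward differences of the discretization), and
  the C1 interpolant keeps quasi-Newton line searches away from the knot
  kinks a linear interpolation would create, so each of the six
  optimizations per gene takes milliseconds.  Branch lengths, kappa and
  the overall rate scale are fixed in this mode.  Interpolation error is
  below ~1e-3 log-units per site even on worst-case columns — far below
  the 5.99 LRT threshold — and both M7 and M8 share the same curves, so
  residual error largely cancels in the LRT.  If the M8 optimizer ever
  lands a hair below the M7 optimum (boundary noise), the M7 solution
  embedded at (p0 -> 1, omega_s = 1) is substituted, so the nesting
  inequality holds by construction.  The curves are stored in single
  precision for speed; all oracle comparisons and the exact engine stay
  in double precision.  M8's beta component starts from the M7 optimum
  (the three omega starts still seed omega_s per the multi-start rule).

Because the grid fixes the overall rate scale, a single scale would
misspecify genes whose omega distribution implies a very different mean
substitution rate (a positively selected gene evolves roughly twice as
fast as a purifying one on the same tree, in substitutions per codon).
The pipeline therefore builds one grid per candidate regime (here: the
beta-only and the beta-plus-spike generator regimes, each with its
analytic mixture-expected rate) and assigns each gene the grid whose
predicted mean pairwise codon divergence — computed in closed form from
the transition matrices over all tip pairs — best matches the gene's
observed divergence.  The choice uses a model-free summary statistic,
and both M7 and M8 are always fitted on the *same* chosen grid, so the
nesting behind the chi-square reference is preserved.  Measured operating
characteristics at the default conditions (100-150 codons): type-I error
0-3% at the nominal 5% level (the boundary chi-square-2 reference is
conservative), power 95-99% against p0 = 0.8, omega_s = 4.

`2*delta_l = 2(l_M8 - l_M7)` is clipped at 0 and referred to chi-square
with 2 df (`P = exp(-delta/2)`, closed form).  A gene is called under
positive selection when P (or the BH-adjusted q) passes its threshold
*and* the fitted `omega_s` strictly exceeds 1; `omega_s = 1` on the
boundary is legal and simply fails the call.

## Orthology

Best hit = smallest E-value, ties broken by larger bit score, residual
ties treated as ambiguous (no hit) — deterministic and conservative.  The
gate is strict (`E < 1e-10`) and applied in both search directions; BRH
pairs feed per-focal-gene groups, and only groups complete in every
species are analyzed (configurable).  A longest-isoform pre-filter (ties
by lexicographic sequence) handles multi-isoform inputs.  For synthetic
runs without an external aligner, a k-mer scorer (shared k-mer count,
pseudo-E = 10^-score) replaces BLAST; k = 4 by default, chosen so that
essentially all 150-codon synthetic orthologs pass the same 1e-10 gate
(k = 5 loses a substantial fraction).  The pseudo-E is a monotone
transform only, not a statistical E-value.

## Alignment filters

Mis-annotated gene models appear as runs of singleton residues and are
the classic source of false positives for site tests.  Three stages, on
the protein alignment, with per-rule column provenance:

1. **Block filter** (Gblocks-style approximation): a column is conserved
   iff gap-free with modal-residue frequency > 0.5; nonconserved runs
   longer than 8 are masked, then surviving blocks shorter than 10.
   Parameters are configurable; a real Gblocks output can be supplied as
   a pre-masked alignment instead.
2. **Singleton windows**, implemented exactly: every 15-column window in
   which one sequence owns >= 10 singletons, and every 5-column window in
   which one sequence is singleton throughout, are masked in full (union
   over all stride-1 windows).  "One of the sequences" is read as a
   single taxon owning the singletons; gaps never count as singletons.
3. **Back-translation** maps retained protein columns to codons
   (protein gap -> `---`), verifying that each ungapped row equals its
   CDS translation and reporting the taxon and first discordant position
   otherwise.  The original protocol's manual re-editing step is replaced
   by re-running after applying an externally supplied extra mask file
   (`rerun_after_mask`).

Injected synthetic artifacts are removed by one pass of the window rules
(a tested invariant), and masking is idempotent on clean regions.

## Synthetic data generator

The generator defines the study conditions; defaults:

* 5-taxon ladder tree scaled to total length 2.0 expected substitutions
  per codon (the paperless free parameter of such studies), kappa = 2,
  equal codon frequencies, 150 codons per gene;
* M7 shapes (p, q) = (2, 5); M8 adds p0 = 0.8, omega_s = 4;
* site omegas are continuous draws (beta, or beta + spike), deliberately
  *not* the discretized classes used in fitting — the fitted K-category
  likelihood is therefore an approximation to the generative model, the
  standard situation in practice;
* substitution histories are sampled exactly by uniformization: the
  number of candidate jumps on a branch is Poisson with the uniformized
  rate and each jump follows `I + Q/Lambda`; marginally this equals
  sampling from `expm(Qt)` rows, but it vectorizes across sites with
  site-specific omegas.  Zero-length branches reproduce the parent state
  byte for byte.
* annotation artifacts: in a random taxon, windows of 15 codons are
  rewritten with sense codons whose amino acid differs from every other
  taxon at that column (singleton-rich, stop-free);
* interactome: preferential attachment seeded from an m-clique (m = 3,
  n = 2000 by default; exactly m(n−m)+C(m,2) edges, connected, simple),
  edges annotated physical/genetic (85% physical), LTP/HTP (35% LTP) and
  a beta(4,2)-distributed 0-1000 confidence score;
* covariates: Gaussian copula against degree with target Spearman
  correlations (mRNA 0.4, protein abundance 0.4, length 0.1,
  publications 0.55, expression propensity 0.2) and heavy-tailed
  marginals (log-normal abundances and lengths, negative-binomial
  publication counts, tilted 0-4 replicate counts per 16 tissues);
* selection status: P(selected) = logistic(beta0 + beta1·log(degree+1)).
  beta1 < 0 plants selection at the periphery, beta1 > 0 at the center;
  beta0 defaults to centering the logistic at the mean log-degree so the
  two groups stay balanced for any beta1.

One integer seed drives everything through named substreams
(`numpy.random.SeedSequence` spawn keys); identical configs produce
byte-identical outputs, including all TSV/FASTA files.

What the generator does **not** emulate: indels, recombination,
codon-usage selection, among-gene tree variation, correlated evolution
between interacting proteins, or the ascertainment structure of real
interactome databases.  Passing tests therefore demonstrate correctness
of the machinery and internal statistical calibration, not robustness to
every bias of real data.

## Network metrics and statistics

Degree is the distinct-neighbor count.  Betweenness is the fraction of
shortest paths between other node pairs passing through the node,
normalized by (n−1)(n−2)/2 (raw counts also available); closeness is the
reciprocal mean BFS distance within the node's connected component
(isolates: 0).  Cross-component pairs contribute nothing; a
largest-component-only mode exists because published conventions differ.
The metrics run on igraph's C core behind a networkx-facing API and are
tested against first-principles BFS path-counting on every connected
graph with <= 7 nodes and on random graphs.

Mann-Whitney U is exact by enumeration when min(n) <= 8 without ties,
otherwise normal with tie and continuity corrections; Spearman uses
mid-ranks with the t approximation; the partial rank correlation is the
first-order partial Pearson correlation on mid-ranks with a t reference
on n−3 df.  Expression breadth counts tissues detected in >= 3 of 4
replicates (16 tissues); the breadth-vs-selection trend is the Spearman
correlation of per-breadth-bin selected fractions (all-tied fractions are
reported as rho = 0, P = 1 with a warning).  Genes whose test could not
be run form a third status and never enter comparisons.  All P values
are two-sided.

## Sizes used by the bundled studies

Chosen once, as desk-scale study conditions:

* acceptance script: two full studies (beta1 = ±1) with 2000 network
  genes, 250 tested genes, 150 codons; operating characteristics from 100
  null genes (100 codons) and 12 positively selected genes (500 codons).
* test suite: type-I error from 200 null genes (100 codons); power and
  omega_s recovery from 20 genes at 500 codons; end-to-end direction
  recovery from 20 replicates per sign at 2000 network genes, 300 tested
  genes and 100-codon alignments; null calibration from 200
  reassignments of one fitted 150-gene set.

## Known limitations

* The grid engine reports kappa fixed at its configured value and caps
  omega_s at the grid maximum (15); estimates at the cap indicate a
  stronger signal than representable, not a converged value.
* The Gblocks approximation is deliberately simplified (no
  conserved/highly-conserved distinction, no flank rules).
* The pseudo-E-value of the k-mer scorer has no statistical
  interpretation; it exists to reuse the E-value gate on synthetic data.
* The chi-square(2) reference for the LRT is conservative at the
  boundary (p0 -> 1, omega_s -> 1), so the scan under-rejects slightly on
  null genes; this matches the standard practice the pipeline mirrors.
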