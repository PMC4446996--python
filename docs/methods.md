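# Methods

## Model and estimators

Each peak is treated independently under a one-way random-effects model:
the normalized density of individual *j* in species *i* is
`Y_ij = μ + α_i + ε_ij`, with species effect `α_i ~ (0, σ²_α)` and
individual effect `ε_ij ~ (0, σ²_ε)`, both random and additive. The
decomposition

```
SS_between = Σ_i n_i (ȳ_i − ȳ)²,   SS_within = Σ_i Σ_j (y_ij − ȳ_i)²
```

gives the method-of-moments estimates `S² = SS_within/(N−k)` and
`S²_α = (MS_between − S²)/n₀`, with `MS_between = SS_between/(k−1)` and the
unbalanced-design effective sample size `n₀ = (N − Σ n_i²/N)/(k−1)`. The
per-peak statistic is `epi-FST = S²_α/(S²_α + S²)`, the AMOVA-style
fixation index applied to peak densities.

Properties the test suite verifies on every random instance: SS
conservation (total and per-species), agreement with an independent OLS
ANOVA fit, location/scale invariance of the statistic, and the bound
`−1/(n₀−1) ≤ epi-FST ≤ 1` with equality at 1 iff `SS_within = 0 <
SS_between`. The *minimum* is attained in the opposite corner — species
means equal (`MS_between = 0`) with positive within-species variance —
where the statistic equals `−S²/n₀ / (S²(1 − 1/n₀)) = −1/(n₀−1)` exactly,
independent of the data scale. At n₀ = 6 this is −0.2; the minimum
increases monotonically to 0 as n₀ → ∞.

`n₀` is computed from the data by default, but can be overridden (e.g.
pinned to an integer) through the `n0` argument everywhere the statistic is
computed; an 11 + 4 two-species design gives 88/15 ≈ 5.8667, so the
attainable minimum is −15/73 ≈ −0.2055 unless n₀ is pinned to 6.

### Degenerate input

A peak that is constant within every species *and* across species has
`S²_α = S² = 0`; its epi-FST is reported as NaN with a `fst_defined = False`
flag and excluded from gene-level averages. Coercing such peaks to 0 would
bias gene means toward "no divergence", so they are dropped, with a
`partial_coverage` flag on any gene that mixes defined and undefined peaks.
Negative epi-FST values are never clamped.

## Permutation test

Significance per peak comes from shuffling individuals between species
(group sizes preserved), recomputing the statistic, and reporting
`p = (r + 1)/(n_perm + 1)` where `r` counts permuted statistics ≥ the
observed one. The add-one estimator never reports p = 0 at finite
permutation count. Permuted statistics that are undefined count as
not-as-extreme; an undefined observed statistic yields p = 1 with the flag
set. Each peak uses an independent child stream spawned from the master
seed (`numpy.random.SeedSequence`), so a single integer reproduces a whole
table and peaks are mutually independent. For designs of ≤ 12 samples an
exhaustive mode enumerates all distinct label assignments
(`N!/Π n_i!` of them) and applies the same add-one correction; the sampled
p converges to the enumerated tail, which the suite checks directly.

The default is 10,000 permutations per peak; the calibration tests use 200–
500 permutations on 200–1,000 simulated peaks, sizes chosen to make the
discreteness of the p-value grid negligible next to the Kolmogorov–Smirnov
sampling error at those counts.

## Gene aggregation and TSS proximity

A peak belongs to a gene when its interval overlaps the gene body extended
by `flank_bp` (default 50,000 bp) on both sides, clamped at 0, on the same
chromosome — any-overlap, half-open intervals, strand ignored since both
sides are extended equally. Any-overlap is the common BED-intersection
default and avoids dropping boundary-spanning peaks; a midpoint-containment
mode is available for sensitivity checks. Gene scores are unweighted
arithmetic means over defined per-peak values (no width or density
weighting). Increasing the flank can only add peaks (verified as a
monotonicity property).

TSS proximity classifies a peak as "near" when it overlaps
`[tss − w, tss + w)` for any anchor TSS (default w = 2,000 bp), counting
each peak once. "Unique" mode keeps one TSS per gene — the longest
transcript's, ties broken by smallest coordinate. BED carries no transcript
length, so the TSS reader interprets the BED score column as transcript
length; with no usable score the tie-break alone decides. The "all"-mode
fraction is necessarily ≥ the unique-mode fraction (superset of anchors).

## PCA and windowed divergence

Samples are observations, peaks are variables; columns are mean-centered,
never scaled, so the decomposition is an eigenanalysis of the covariance
matrix and the eigenvalue sum equals the total variance of the centered
data. The covariance divisor is *n* (configurable to *n*−1) to keep the
eigenvalue-sum identity exact under that convention. Implementation is an
SVD of the centered matrix with a deterministic sign convention (largest-
magnitude loading of each axis made positive); centroid distances are
invariant to axis reflection regardless, because both centroids flip
together.

Sliding windows are `[s, s + window)` for `s = 0, step, 2·step, …` with the
last start ≤ length − window (defaults 1 Mb windows, 100 kb step); a
chromosome shorter than one window yields a single truncated window.
Within each window a fresh (re-centered) PCA is run on the peaks whose
intervals overlap the window, species centroids ("ellipse of dispersion"
centers, i.e. per-species mean scores) are taken in the first 2 components
by default — the dimensionality used for plotting, configurable — and all
pairwise Euclidean distances are reported. Windows with fewer than
`min_peaks = 2` peaks get NaN distances (one peak gives a rank-deficient,
meaningless axis system).

## Association analyses

Spearman correlations use average ranks for ties and the standard
large-sample p approximation, dropping incomplete pairs; a constant vector
yields a flagged undefined coefficient. SNP counts are attributed to
windows proportionally to the overlapped fraction of each SNP interval:
sliding windows overlap one another, so point-assignment would double-count
ambiguously, while proportional attribution is deterministic and additive.

Top-K over-representation ranks genes by score (descending; ties by more
contributing peaks, then gene id), restricts the universe to genes with a
defined score intersected with any user-supplied universe, and reports the
one-sided hypergeometric upper tail `P(X ≥ m)` for the overlap `m` between
the top `k` and the `K` set members. A label-permutation mode with the
add-one estimator is provided as a robustness alternative. The
hypergeometric p is exactly valid but discrete: the realized null rate of
`p < 0.05` equals the largest attainable level below 0.05, which the
calibration test computes and compares against 1,000 random-label
replicates at universe 5,000 / 500 set members / top 500 — sizes at which
the attainable level (≈ 0.038–0.05) sits close to nominal.

## Synthetic data

The generator draws from exactly the model the estimator assumes: normal
`α_i` and `ε_ij` (normality is the minimal choice making the moment
identities `E[S²] = σ²_ε`, `E[S²_α] = σ²_α` exact), mean μ = 10,
σ²_α = σ²_ε = 1 by default, truncated at 0 since real normalized densities
are non-negative. At the default scales truncation touches < 1% of draws
(asserted in tests); heavier truncation triggers a warning because it
distorts the variance structure. Default species sizes are
{human: 11, chimp: 4, macaque: 3} — a realistically unbalanced primate
design that exercises n₀ and the degrees-of-freedom bookkeeping. A
configurable fraction of peaks (default 0.2) carries the species effect;
the rest are null, giving simulated data a realistic mixture. Peaks are
2 kb intervals placed uniformly without overlap (or regularly spaced).

The annotation generator tiles genes over the synthetic genome, emits 1–3
TSSs per gene with distinct transcript lengths, a Poisson SNP track in
fixed windows, and a DE gene set drawn with a single bias knob: weight
`divergent_gene_bias` for genes whose ±50 kb neighbourhood contains a
divergent peak, weight 1 otherwise (bias 1 = no association).

What the simulation does *not* emulate: phylogenetic (tree-structured)
covariance between species effects, spatial autocorrelation of peak
densities along the genome, heavy-tailed or heteroskedastic density noise,
peak-width variation, missing samples, and any real normalization pipeline.
Passing tests therefore demonstrate the estimators' correctness and
calibration under the stated model, not robustness to those departures on
real ChIP-seq data.

## Problem sizes and numerics

The shipped suite runs the oracle comparison on 1,000 random instances,
null calibration on 1,000 peaks × 500 permutations, estimator recovery on
10,000 peaks, and enrichment calibration on 1,000 replicates — sizes at
which Monte-Carlo error is small relative to the asserted tolerances while
the whole suite stays fast on one CPU. Conservation and oracle agreements
are asserted at 1e−9 relative tolerance; recovery at 3 Monte-Carlo standard
errors; calibration by KS at α = 0.01. Sum-of-squares are computed in the
group-centered form (not the expanded difference of squares) to avoid
cancellation at large grand means.

## Known limitations

- Two-level designs only (species / individual); no hierarchical AMOVA
  with populations nested in species.
- epi-FST is a moment estimator; no likelihood or Bayesian variant, and no
  shrinkage across peaks.
- The permutation test assumes exchangeability of individuals across
  species under the null — batch structure violating this is not modelled.
- Peaks are analysed in a single shared coordinate system; cross-assembly
  lift-over is out of scope, as are peak calling and density normalization.
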