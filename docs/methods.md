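# Methods

This note documents the models and procedures implemented in `weaknet`, the
conventions chosen where several were defensible, and what the synthetic
benchmark does and does not establish.

## Normalization and the differential screen

**TMM factors.** Between-sample scaling uses the trimmed mean of M-values.
The reference sample is the one whose library-size-scaled upper quartile is
closest to the mean upper quartile (a deterministic rule). For sample *k*
against reference *r*, with relative abundances p = x/N, each shared
positive gene contributes M = log2(p_k/p_r) and A = ½·log2(p_k·p_r); genes
in the most extreme 30% of M or 5% of A on either side are trimmed, and the
factor is 2 to the weighted mean of the surviving M values, weights being
the inverse asymptotic (binomial) variances of M. Factors are rescaled to
geometric mean 1. These are the standard trim fractions for this estimator,
and the test suite checks the result against an independent step-by-step
evaluation of the formula.

**Log transform.** `log2(value/factor + pseudocount)` with pseudocount 1.0 —
zero-safe and conventional for TPM-scale data. The pseudocount compresses
fold changes of low-abundance genes toward 1; this is visible in the
generator's power analyses and is a property of the pipeline, not a bug.

**Two-group test.** Per gene, the difference of group means of normalized
log2 values is the effect (fc = 2^log2fc — a deliberate convention: the
ratio-of-raw-means alternative is not used, keeping the effect consistent
with the log-scale linear model). The default test moderates the pooled
per-gene variance with an empirical-Bayes prior: log sample variances are
fitted by method of moments to a scaled-F model (trigamma inversion by
Newton iteration), giving prior df d₀ and prior variance s₀²; the moderated
t uses d₀ + d_g degrees of freedom. An unmoderated pooled t and a Welch t
are exposed for oracle comparisons and heteroscedastic data. No
multiple-testing correction is applied in the default screen — the weak
regime is deliberately permissive, and reproducibility is enforced by the
cross-cohort intersection instead; Benjamini–Hochberg q-values are available
(`bh_adjust`, `bh=True` in enrichment).

**Screen thresholds.** Default grid (1.5, 0.05), (1.25, 0.05), (1.1, 0.1);
the (1.1, 0.1) pair is the weak screen used downstream. "Up" means
fc ≥ threshold, "down" fc ≤ 1/threshold, both with p ≤ p-threshold.

## Over-representation

Exact one-sided hypergeometric tail P(X ≥ k), computed via the survival
function of the hypergeometric distribution (log-space internally, exact to
well below 1e-12 against brute-force sums for all universes ≤ 25). The
universe is the intersection of graph genes and measured genes: restricting
to measured signaling genes keeps the null honest. The reported odds ratio
is the sample cross-product ratio a·d/(b·c); a Haldane +0.5 is applied to
all cells only when a zero in b or c would make the ratio undefined (k = 0
reports OR = 0). The conditional-MLE estimator was not used because the
downstream consumers of the table only rank by p. Reporting threshold
p ≤ 0.15 by default — permissive by design, matching the weak-signal
philosophy of the screen.

## Cascade inference

The iterative linker treats signaling as directed and unweighted: shortest
paths are minimal hop counts, found by BFS layering with a predecessor DAG
and full tie enumeration. Per iteration, paths are computed for *every*
current V0 × V1 pair (not only newly promoted sources); under
`tie_policy="all"` the final edge set is the same either way (checked as a
property on random graphs), only the iteration log differs.

Conventions, each a genuine free choice:

- **Ties.** All tied shortest paths are kept by default; the alternative
  `lexicographic-first` yields a minimal, deterministic network. Both are
  logged in the output metadata.
- **Promotion.** Only genes belonging to V1 are promoted; linker genes never
  join V0. Consequence: a linker that lies between two targets does not seed
  new searches.
- **Termination.** The loop stops when V1 is empty *or* no remaining V1 gene
  is reachable within `max_depth`; remaining genes are reported as
  `unreachable_targets`. (A pure "until all genes are promoted" rule would
  never terminate on disconnected graphs.) Each non-final iteration promotes
  at least one gene, so termination within |V1| + 1 iterations is asserted
  on every run.
- **Depth bound.** `max_depth=6` bounds path search on dense graphs;
  unreachable-within-depth is treated as unreachable and reported.
- **Direction.** Strictly direction-respecting; `undirected_copy()` gives a
  symmetrized fallback for very sparse graphs.

## Distance statistics

A gene's statistic is the mean directed shortest-path distance to the
*reachable* members of the target set. Unreachable (gene, target) pairs are
excluded from the mean rather than capped at a large constant — densities
stay finite and interpretable — and `n_reachable_targets` is reported per
gene so the censoring is visible. A gene in the target set contributes its
own distance 0. Group comparisons use a two-sided Mann–Whitney U (normal
approximation with tie correction by default; an exact small-sample mode is
provided) because hop-count averages are discrete and skewed; this test is a
package addition, recorded as such in the output metadata.

## Separability

Classical (metric, eigen-based) MDS is used instead of stress-majorization
because it is deterministic and equals PCA on Euclidean distances, making
"the first principal coordinate" well-defined. Axes have arbitrary sign, so
each component is oriented to put the case-group mean at or above the
control-group mean. The logistic model (intercept + first coordinate) is
fitted by IRLS to a relative deviance change < 1e-10 (max 100 iterations);
the covariate is standardized to unit variance by default so |β| and OR are
comparable across gene subsets. Complete separation is detected (vanishing
deviance or a diverging slope) and flagged rather than raised; the Wald p is
then not reported.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes:

- **Graph.** Gene universe G0001…; overlapping pathways sampled with
  replacement across pathways (real pathway collections overlap heavily, and
  the enrichment universe logic must be exercised under overlap); directed
  edges with probability `edge_density_within` between pathway-sharing genes
  and `edge_density_between` otherwise; no self-loops.
- **Planted cascades.** Disjoint chains of `planted_cascade_length` hops from
  fresh source genes to fresh target genes, inserted after random edges.
  Random edges that would shortcut a planted pair below the planted length
  are then pruned (deterministically), so each planted path is a minimal
  cascade *by construction* — without this the notion of "recovering" the
  planted cascade by shortest-path search would be ill-posed.
- **Expression.** TPM-scale log-normal noise: case samples are
  exp(N(μ_g + log fc_g, σ)), controls exp(N(μ_g, σ)), with μ_g uniform per
  cohort in `baseline_log_mean_range` and fc_g the planted fold change
  (uniform in `activation_fc_range` for genes of activated pathways, exactly
  1 elsewhere). Cohorts are independent.

Defaults (chosen once as a small, realistic weak-activation study):
50 genes, 5 pathways of 6–12 members, within/between edge densities
0.12/0.01, 2 activated pathways with fc ∈ [1.1, 1.5], two cohorts of
80 control + 80 case samples, dispersion 0.5 on the natural-log scale,
baseline log-means in [1, 5] (≈2.7–150 TPM), one planted 3-hop cascade.
Larger stated configurations are used where a property needs a
better-connected graph: the distance-ordering benchmark uses 300 genes,
12 pathways (10–18 members), densities 0.10/0.006 and ten 2-hop cascades —
at the 50-gene default the reachable background is tiny and dominated by the
cascade's own linkers, so "sources closer than background" is not a property
that geometry can plant. The enrichment-recovery benchmark uses 250 genes,
20 pathways (12–20 members), 5 activated with fc ∈ [1.15, 1.3].

**What the generator does not emulate:** library-size variation and
gene-length bias (TPMs are simulated directly, not counts), batch structure,
covariates (age/sex), correlated noise between genes, and cell-type mixing.
Passing the recovery benchmarks therefore shows the algorithms are correct
and calibrated under the stated noise model — not that real bulk-tissue
confounding is handled.

## Numerical and edge-case choices

- TMM: all-zero samples are rejected by name; a sample with |M| < 1e-6
  everywhere gets factor 1; zero weights fall back to the unweighted mean.
- Moderated test: genes with zero pooled variance get t = 0 (p = 1) under
  the unmoderated test and shrink to the prior under moderation; infinite
  prior df (no excess variance across genes) degenerates to a common
  variance with effectively normal tails.
- MDS: eigenvalues below 1e-9 of the leading one count as non-positive;
  fewer positive eigenvalues than requested components returns the available
  ones with a warning.
- Shortest paths: returned in lexicographic node order; all reported
  quantities are invariant to input edge/gene ordering.
- Determinism: a single integer seed fixes every artifact byte-for-byte;
  all set-valued outputs are sorted before serialization.

## Benchmark problem sizes

The test suite and `scripts/acceptance.py` use deliberately small problems:
200 random ≤12-node graphs for the cascade oracle, 50 simulations per
recovery rate, 2,000 genes for null calibration, 200 replicates for logistic
recovery. These sizes give stable rates (binomial SE ≈ 3% at 50 runs) while
keeping a full run in seconds to a few minutes on one CPU.

## Known limitations

- The moderated test assumes a common variance model per gene across groups;
  no mean–variance trend is modeled (the Welch option is the escape hatch).
- Fold-change estimates inherit the pseudocount's shrinkage at low abundance.
- The cascade algorithm's output grows quickly on dense graphs under
  `tie_policy="all"`; use `lexicographic-first` or a smaller `max_depth`
  there.
- Distance censoring (dropping unreachable pairs) biases group comparisons
  when reachability itself differs between groups; the per-gene
  `n_reachable_targets` column is provided precisely so users can check
  this.
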