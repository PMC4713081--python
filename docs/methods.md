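# Methods

This note documents the models implemented in `trnreduce`, their
assumptions, the defaults that matter, and what the synthetic-data
generator does and does not emulate.

## The scientific question

When a bacterial lineage becomes host-restricted, its genome shrinks by
irreversible gene loss. Regulatory genes are shed faster than the genes
they control, but not uniformly: the analyses here ask whether the *kind*
of regulation a transcription factor exerts — activation, repression, or
both ("dual") — predicts how long it survives genome reduction, and
whether any preference is explained by dual TFs' tendency to be network
hubs (global regulators) and nucleoid-associated proteins (NAPs).

## Network reconstruction (regulog + BBH)

Target-genome TRNs are projected from a reference network: an interaction
TF→TG is inferred in a genome iff both endpoints have orthologs there.
Orthology is operational: bidirectional best hits over similarity tables,
with a pair accepted only when both directional best hits satisfy,
strictly, e-value < 1e-6, percent identity > 30 and alignment length
> 60% of the query *and* of the subject protein. The 60% rule is applied
to both lengths deliberately (the conservative reading of "each
protein"); best-hit ties are broken by bitscore and then subject id so
runs are reproducible. The reconstruction inherits the usual regulog
assumptions — conserved sequence implies conserved interaction and
conserved regulatory mode — and inherits their failure modes at large
evolutionary distance; nothing in the package tries to repair them.

Node kinds matter throughout: sigma factors are first-class regulators
(the globality metric needs them) but are never counted as TFs in any
conservation statistic.

## Conservation statistics

For one genome and one TF type, with N TFs in the reference pool, K of
them of the type, n conserved TFs in the genome and k of those of the
type, the one-sided null "no preferential conservation" (f_i = k/n no
greater than f_r = K/N) is tested by the hypergeometric upper tail
P(X ≥ k), X ~ Hyp(N, K, n). The tail *includes* the observed k, the
standard convention for a one-sided "greater" discrete test. N counts
every reference TF including those with no classified regulatory type;
this keeps k ≤ n ≤ N internally consistent when n (the conserved-TF
count) includes unclassified TFs, and matches the use of total
orthologous-TF counts as the sampling frame. Genomes with n = 0 are
reported as untestable and dropped from downstream combination rather
than imputed.

Per-type p-values are combined across genomes with Fisher's method,
X = −2Σln p ~ χ²(2m). Zero p-values (possible only by underflow) are
clamped to the smallest positive float with a warning. No further
multiple-testing correction is applied.

## Globality score

G(x) = ¼·( TFR/(N_TF+N_SF−1) + GR/N_G + SF/N_SF + CR/(N_TF−1) ),

where TFR counts regulator-kind targets of x (TFs or sigma factors —
the denominator spans both), GR its non-regulatory targets, SF the sigma
factors sharing at least one target with x, and CR the other TFs doing
so. Auto-regulation is excluded from TFR and CR, matching the "−1"
denominators. A degenerate network (for example no sigma factors) zeroes
the affected term with a logged warning instead of dividing by zero.
Scores are kept at full precision internally; display rounding is
half-even to 4 decimals, which cannot reorder ranks. The "global
regulator" flag used downstream is the top decile of G by default
(configurable), or may be supplied directly as annotation.

## Independent contrasts

Felsenstein's recursion in post-order: contrast (x_a − x_b)/√(v_a+v_b)
at each bifurcation, weighted-average ancestral value, branch
augmentation v + v_a·v_b/(v_a+v_b). Under Brownian evolution the
standardized contrasts are iid N(0, σ²); the test suite verifies this
calibration directly and cross-checks the recursion against dendropy's
independent implementation. Polytomies are resolved into caterpillars of
zero-length branches (deterministic per seed) before computing
contrasts. If a node's combined daughter variance is exactly zero, the
two variances are perturbed by a configurable epsilon (default 1e-8,
logged); with the epsilon disabled this raises an error naming the node.

Bivariate analyses positivize the x-contrasts (flipping the paired
y-contrast signs) and then use correlation and regression through the
origin with n_contrasts − 1 degrees of freedom — the convention of the
standard contrast-analysis tooling; through-origin statistics are
invariant to the arbitrary daughter ordering. Diagnostics (Shapiro-Wilk
on standardized contrasts; |contrast| against √variance) are reported
but never gate the analysis, and no branch-length transformation is
applied automatically.

Nine variables are carried into the contrast tables, each paired with
genome size: genome size itself, per-type conserved-TF counts, per-type
fractions, global-regulator fraction and NAP fraction. Genomes where a
fraction is undefined (n = 0) are pruned from that trait's tree.

## Multivariate regression

Each TF-type fraction is regressed, with intercept, on genome size,
global-regulator fraction and NAP fraction. Coefficients are also
reported standardized, b_j = β_j·sd(X_j)/sd(Y) with sample (n−1) sds:
full standardization is the one convention that makes the b's unit-free
and mutually comparable. Predictor importance is judged by |b| among
coefficients with p < 0.05 (df = n − 4). The default regresses raw
per-genome values (the intercept belongs there); a contrasts-mode is
available for phylogenetically corrected regression. Near-collinear
designs warn with variance-inflation factors; the Pearson correlation
between the global and NAP fractions is always reported, since the two
are expected to be largely redundant.

## Synthetic genome-reduction scenarios

The generator produces the complete input stack and is itself tested
code. Its defaults are the study conditions of the package's validation:

* **Reference network**: 196 TFs, 7 sigma factors, 1,581 target genes
  (1,784 nodes) and exactly 4,058 interactions. Type proportions
  activator/repressor/dual/unclassified = 0.40/0.35/0.22/0.03 — an
  activator-majority pool with ~3% unclassified, at realistic scale for
  an enteric reference TRN. Out-degrees follow a rank^−1 hub profile;
  dual TFs occupy the hub ranks, NAPs are sampled among the top-weight
  duals (so NAP and global flags correlate strongly without being
  identical), and the top decile of TFs by out-degree is flagged global.
* **Phylogeny**: Yule pure-birth, ultrametric, rescaled to a root-to-tip
  height of 1.0 expected-loss units; 64 genomes by default.
* **Gene loss**: every gene present at the root is lost independently on
  each branch with survival exp(−λ·m·t). The class hazards λ are
  activator 0.8, repressor 0.5, dual 0.1, and 0.3 for target genes,
  sigma factors and unclassified TFs — the planted ground truth is the
  ordering λ_act > λ_rep > λ_dual. m is a per-branch lognormal rate
  multiplier (log-sd 1.0, median 1): a relaxed loss clock emulating
  lifestyle heterogeneity, in which host-restricted lineages shed genes
  much faster than free-living relatives. This ingredient is essential,
  not cosmetic: on a strict clock every daughter pair at a bifurcation
  has *identical* expected loss, so genome size and TF composition would
  co-vary only through second-order sampling noise and the contrast
  correlations would carry almost no recoverable sign. Because m
  multiplies every class hazard alike, it never distorts the planted
  ordering.
* **Genome sizes**: 150,000 + 2,516·(surviving genes) bp + N(0, 20,000)
  noise, anchoring a fully intact genome near 4.6 Mbp and a nearly empty
  one near 0.16 Mbp. Lifestyle categories (free-living, host-restricted,
  obligate, tiny) are assigned by quartile of surviving gene count, for
  reporting parity only.
* **Hit tables**: each present gene gets a reciprocal forward/reverse
  hit with identity ~ U(35, 95), e-value 10^−U(8,50) and 80% coverage.
  Decoy hits (optional fraction) are built to fail exactly one
  acceptance predicate — sub-threshold identity, or a missing reciprocal
  partner — and use fresh ids, so a correct BBH filter must return
  exactly the present-gene map.

What the generator does **not** emulate: sequences (hit statistics are
drawn, not aligned), gene gain, horizontal transfer, duplication,
regulatory rewiring, binding-site turnover, correlated loss of operons,
or any dependence of loss on network position. Passing the end-to-end
tests therefore shows that the pipeline recovers a planted
differential-loss signal through all of its stages — not that real
genomes behave like the simulator.

## Problem sizes and numerical choices

The validation study uses 10 independent scenarios of 64 genomes against
the full-scale 1,784-gene reference (a few seconds per scenario); the
hypergeometric kernel is verified exhaustively against exact rational
enumeration for all parameter combinations with N ≤ 12 and is computed
via scipy's log-space survival function, stable far beyond N = 10,000.
Brownian calibration of contrasts uses 20 trees of 64 leaves. Fisher
combination uses the exact χ² survival function; the even-df closed form
is used as an independent oracle in tests. All simulations are seeded;
identical seeds give byte-identical outputs, including written scenario
directories and pipeline reports.

## Known limitations

* The regulog projection is only as good as its conservation
  assumptions; the package reproduces the method, it does not validate
  it biologically.
* The one-to-one BBH map ignores paralogy; in-paralogs collapse to one
  best hit or to none.
* Fraction traits treat conserved-TF counts as exchangeable draws; very
  small n makes the hypergeometric test weak rather than wrong
  (discreteness keeps it conservative).
* The relaxed loss clock draws branch multipliers independently, so
  lifestyle is not heritable along the tree beyond what shared branches
  induce; a heritable-lifestyle model would concentrate reduction in
  clades, as real symbiont radiations do.
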