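# Methods

## Pipeline model

The package treats gene regulation as a directed network whose edges
run from regulators (transcription factors and miRNAs) to targets
(genes, TFs, miRNAs; miRNA→miRNA edges are disallowed).  A final edge
must be supported twice over: physically possible (present in the
candidate set assembled from predicted and experimentally supported
interactions) and active in the tissue (strong co-expression of the
paired tumor/normal log-ratio profiles).  The assumptions are the usual
ones of co-expression filtering: regulation manifests as monotone
association of expression ratios across patients, TFs may activate or
repress (either correlation sign), and miRNA regulation is repressive,
so only negative correlations are biologically admissible for miRNA
regulators.

## Expression processing

Ratios are `log2((I_TU + α)/(I_AN + α))` with
`α = (q0.25(I_TU) + q0.25(I_AN))/2`.  The 25% quantiles are pooled over
all entries of each matrix — the penalty is a single scalar per tissue
class, not per patient (a per-patient reading is conceivable but is not
the default and is not implemented).  Quantiles use linear
interpolation between order statistics throughout the package.  Probe
rows are averaged into entity rows *after* ratio computation.  The
differential statistic is a one-sample two-sided t-test of each
entity's ratios against zero; zero-variance rows yield missing values
rather than errors.  As α → ∞ all ratios shrink to zero, so α trades
sensitivity to low-intensity probes against ratio stability.

## Co-expression scoring

For each candidate pair the regulator profile is regressed on the
target profile (y = regulator, x = target, in that orientation — the
Cook's outlier set is orientation sensitive, so the convention is fixed
and documented).  Cook's distance uses the closed form for a
two-parameter fit, `D_i = e_i² h_ii / (2 s² (1−h_ii)²)`; it is verified
in the tests against both a leave-one-out brute-force oracle and
statsmodels.  Samples with D > 0.5 are removed in a single pass (no
iteration), and Pearson r is computed on the remainder.  Pairs are
unscorable — dropped and counted, never imputed — when a profile is
missing, variance is zero, or fewer than `min_samples` (default 10)
samples remain.  A sum of squared residuals at the rounding level of
the data (SSE ≤ (1e−12·scale)²) is treated as a perfect fit with all
distances zero, so exactly collinear profiles do not produce spurious
outliers.

Default cutoffs are 0.6 (TF regulators) and 0.45 (miRNA regulators);
the sign constraint applies to miRNA regulators only — a TF repressing
a miRNA legitimately shows negative correlation, so no sign rule is
imposed on TF→miRNA edges.

## Scale-free cutoff selection

Degree distributions are raw (unbinned) relative frequencies over
degrees ≥ 1; zero-degree nodes are excluded.  Both models are fit by
OLS on log-transformed frequencies: `log P = c − γ log k` and
`log P = c − λ log k − α k`.  The truncated model nests the power law,
so its R² is never lower where both are defined.  Conventions: fewer
than 3 (power) / 4 (truncated) support points, or a zero-variance
response (e.g. a uniform distribution), give R² = 0 — the same
convention a degenerate or empty network receives in a cutoff scan, so
"completely not scale-free" and "unfittable" are represented
identically.  Per direction the reported R² is the better of the two
models; ties go to the power law for parsimony.  Maximum-likelihood
power-law fitting is deliberately out of scope: it provides no R² on
the scale the selection criterion is defined on.

The steady-state rule: on a grid (default 0.00–0.90, step 0.05), the
selected cutoff is the smallest grid point whose next `window` points
(default 2) all stay within `tol` (default 0.05) of its R², for both
the in- and out-direction curves.  Points without a full window of
successors cannot qualify; if no point qualifies, the cutoff maximizing
min(R²_in, R²_out) is returned with a warning.  This makes the rule
monotone and invariant to extending the grid beyond the selected point.

## Network analysis

Connectivity is weak (direction-ignoring): regulatory networks have
many pure sources and sinks, and strong connectivity would shatter
them.  Module detection is walktrap (igraph) on the undirected view
with weights |r|, walk length 4, cut at maximal modularity; module ids
are relabeled 1..K by decreasing size for determinism.  Edge
betweenness is computed on the directed, unweighted graph; each ordered
node pair contributes 1 split equally over its tied geodesics.  An
undirected mode exists behind a flag.  The implementation (igraph,
Brandes) is pinned in the tests to an exhaustive path-enumeration
oracle, including the invariant that total betweenness equals the sum
of all finite shortest-path lengths.

The core network thresholds at the linearly interpolated empirical
quantile (default 0.99) of the betweenness values of *all* edges of the
largest component, keeping edges strictly above it.  The threshold is
computed before any node-type restriction; the expectation that core
nodes are regulators is checked afterwards and violations are warned
about, not removed.  Quantile 0 is accepted (keep everything above the
minimum); quantile ≥ 1 is rejected.  Feedforward loops are ordered
triples (A→B, B→C, A→C); feedback loops are directed 2- and 3-cycles,
each counted once per node set and configuration.

## Enrichment

Generic over-representation only: one-sided hypergeometric upper-tail
p-values against an explicit background, BH step-up FDR (statsmodels).
This is a stand-in for external web tools (DAVID-style modified Fisher
tests, miRNA-set tools), whose database snapshots are not bundled;
annotation input is GMT.

## Synthetic data generator

The generator emulates the study conditions end to end: a 96-patient
paired cohort; unit-variance latent log-ratio profiles; planted edges
with loading 0.8 for TFs (sign positive with probability 0.7) and −0.6
for miRNAs; regulator out-degrees wired by preferential attachment
(heavy-tailed); ~30% of miRNAs TF-regulated and a few TF→TF edges, so
regulator-to-regulator layers exist; candidate sets with 50% uniform
decoy edges; 5% of true edges carrying one sample whose target value is
replaced by an 8-SD point (a leverage outlier, reliably above the
Cook's 0.5 threshold); 10% of true edges flagged as experimentally
supported.  Intensities are exponentiated log2-normal values around
baselines N(8, 1) with per-probe offsets (SD 0.3), 20% of entities
measured by two probes, and small per-cell measurement noise (SD 0.05)
— positive, roughly log-normal, RMA-like.  Each target has exactly one
planted regulator: with loadings near 0.8, two parents could not both
hold their planted Pearson correlation under the shared-latent-factor
construction.

Panel sizes default to 400 genes / 30 TFs / 25 miRNAs — a desk-scale
panel whose ~350 true edges give stable precision/recall estimates.
The separate scale-free digraph generator (spanning arborescence by
preferential attachment, then extra edges with preferential sources
and in-degree-deficient targets until every node has in-degree ≥ 2)
reproduces the global network's two structural signatures: a
heavy-tailed out-degree distribution (log-log power-law fit R² > 0.8
at 1700 nodes / 4200 edges) and enough wiring redundancy that deleting
the top-1% betweenness edges leaves weak connectivity intact.  The
planted-partition generator produces weighted undirected benchmarks
for module recovery.

What the generator does **not** emulate: probe-level microarray
artifacts, batch effects, RMA normalization itself, correlated noise
between patients, combinatorial regulation of one target by several
regulators, and realistic in-degree distributions for the expression
panel.  Passing tests therefore demonstrate correctness of the
pipeline's logic and its statistical behavior under the planted model,
not performance on real microarray data.

## Problem sizes and determinism

Tests and the acceptance script run at desk scale: panels of a few
hundred entities × 96 patients, networks of ≤ 1700 nodes / 4200 edges,
module benchmarks of 90 nodes.  All randomness flows through
`numpy.random.default_rng` seeded from explicit config fields; the same
seed regenerates byte-identical TSV bundles, and a pipeline rerun with
the same config produces a byte-identical summary JSON.

## Known limitations

- Correlation cutoff selection inherits the granularity of the grid;
  the steady-state rule is one reasonable operationalization of
  "R² stops changing", parameterized by `tol`/`window`.
- Cook's filtering is single-pass; masked multiple outliers in one
  profile pair may survive.
- The hypergeometric test ignores annotation overlap structure and GO
  hierarchy.
- Edge direction enters betweenness and loop counting but not module
  detection (walktrap is defined for undirected graphs).
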