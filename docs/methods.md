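# Methods

This note documents the models implemented in `synscreen`, the choices made
where the underlying methodology left the design open, and what the
synthetic-data generators do and do not emulate.

## Dose-response metrics

Each (drug, cell line, condition) series is fitted with the four-parameter
logistic `v(d) = bottom + (top − bottom)/(1 + (d/EC50)^h)` by bounded
least squares (scipy `curve_fit`), started from a non-parametric guess
(observed extremes; midpoint crossing interpolated in log dose). Optimizer
failure never raises: the result is flagged `converged=False` and the
non-parametric fallback parameters are used, so a 200+ drug screen always
yields a complete metrics table.

* **GI50** is the dose where the *fitted* curve crosses viability 0.5
  relative to vehicle. If the curve never reaches 0.5 within the tested
  range, GI50 is censored at the maximum tested dose and flagged; censored
  values enter fold changes at face value so ranking remains defined. A
  crossing *below* the lowest tested dose is returned at its analytic value
  rather than censored — censoring a hyper-potent drug at the *maximum*
  dose would invert its rank. An optional T0 (time-zero) input switches to
  growth-inhibition scaling; by default vehicle-relative viability is used
  because T0 reads are not modelled.
* **AUC** is the trapezoid of [0, 1]-clipped viability over a unit-spaced
  dose index (an 8-dose series has maximum AUC 7). The dose ladders in this
  setting are log-spaced and shared within a screen, so the index axis is a
  monotone reparametrization common to all drugs; AUC thresholds
  (difference > 0.9, percent change > 25%) are configuration values on that
  scale.
* **z-scores** use the sample standard deviation across drugs within one
  cell line; GI50-derived quantities are standardized on log10 doses to
  match the log-spaced ladder. Zero-variance inputs yield all-zero scores
  with a warning.

## Hit nomination

The HSA filter requires the combination to beat the better single agent by
the margin (default 0.10 inhibition) at a minimum number of doses
(default 3). The five selection criteria are implemented as fractions of
cell lines rather than absolute counts so the same configuration covers
both a full panel and subsets: fold change ≥ 5 in ≥ 1/2 of lines;
AUC difference > 0.9 in ≥ 1/2; AUC percent change > 25% in ≥ 2/3;
combination GI50 (criterion 4) and AUC (criterion 5) z-scores in the top
half of drugs in ≥ 1/2 of lines, both additionally requiring the drug's
*mean* minimum viability across lines ≤ 0.15. "Top" for criteria 4–5 means
the most sensitive half — lowest combination GI50/AUC — which the source
methodology leaves implicit. Percentile ranks use average-rank tie
handling. Nomination takes drugs with ≥ 4 of 5 votes, ordered by vote
count, then mean combination-AUC z-score (most sensitive first), then drug
id. Non-quantitative considerations (safety, clinical utility) are out of
scope.

## Synergy

Bliss excess is observed minus `E_A + E_B − E_A·E_B` per matrix cell, using
the dose-0 row/column of the plate as single-agent margins; the mean excess
summarizes the matrix. The combination index uses the mutually exclusive
Chou–Talalay form (no cross-term), evaluated at each cell's *observed*
affected fraction — appropriate for a full anchor-by-drug matrix rather
than a fixed-ratio ray. Median-effect parameters come from the least-squares
line of log(fa/(1−fa)) on log D; affected fractions outside (1e-4, 1−1e-4)
are excluded from the fit and the corresponding CI cells marked undefined
(the logit diverges there), with exclusion counts reported. The synergy
call "CI < 1" is strict, with no tolerance band; combinations are ranked by
the count of synergistic cells, ties broken by mean CI then identifier.
Self-combination of one median-effect drug across both axes (dose
additivity) gives CI = 1 to machine precision and serves as the standing
Loewe-consistency oracle in the tests.

## Interaction models

Counts: per-gene negative-binomial GLM with variance `μ + α·μ²`, natural-log
link with coefficients rescaled to log2 to match the conventional
presentation, and `log(size factor)` offsets (median-of-ratios size factors
normalized to geometric mean 1; library-size fallback when no gene is
nonzero everywhere). The full model (intercept, x_d, x_c, x_dc) is compared
to the reduced model (no x_dc) by LRT against χ²(1), BH-corrected; default
call threshold q < 0.01. Dispersion is a per-gene method-of-moments
estimate floored at 1e-8, or may be supplied when known (as in
simulation-based calibration); empirical-Bayes dispersion shrinkage is
deliberately not reproduced. An all-zero interaction column is treated as
the degenerate "models coincide" case (LRT 0, p 1); all-zero genes are
reported NA and excluded from testing.

Log-intensity (phosphoproteomic) features use ordinary least squares on the
same design and a nested F-test with df (1, n−4); this replaces
empirical-Bayes moderation, which is a documented deviation. The
preprocessing helper applies log10, within-feature median imputation and
rank-mean quantile normalization. Closed-form check: at n = 2 per arm the
F-test's power for a 1.0 log10-unit interaction against noise sd 0.2 is
0.753 at raw α = 0.05 (noncentral F, ncp 12.5); the test suite pins the
implementation to that analytic value rather than to an aspirational
detection rate.

Genes are ranked by the signed interaction coefficient `β_idc`
(descending, ties by identifier) to feed enrichment.

## Enrichment engine

The classic unweighted KS running sum: +1/hits at member positions,
−1/(N−hits) elsewhere; the enrichment score is the signed maximum
deviation. Weighting is exposed as an option but off by default since the
underlying statistic is the plain KS form. Regulon members with mode −1
contribute at mirrored ranks (N−1−i), so a repressed target of an active
regulator scores in the same direction as an induced one; rank collisions
after mirroring accumulate increments and the miss penalty applies only to
unoccupied ranks. The permutation null draws B (default 1000) random
same-size member sets on the fixed ranking, with an independent seeded
stream per set size so results are invariant to set iteration order; a
closed-form O(hits) extremum evaluates each permutation. NKS = ES / mean
|null ES|; p-values are two-sided permutation tails bounded below by
1/(B+1), BH-corrected across sets. Conventional overlap minima: 3 for
phosphotyrosine data, 30 for serine/threonine; regulon and preranked GSEA
use the q < 0.1 significance convention by default.

## Network integration

Upstream inputs are KSEA kinases at q ≤ 0.05 (weight = enrichment score)
plus directly measured kinases passing residue-specific cuts (q ≤ 0.5 for
pY, q ≤ 0.01 for pST; weight = `β_idc`); downstream inputs are master
regulators at q < 0.05 with |score| ≥ 5. Diffusion is the restart-based
random walk `h = r·p + (1−r)·W·h` with r = 0.15, W the column-stochastic
degree-normalized adjacency (isolated nodes keep their heat), seeded with
|weights| — signs are carried as direction labels, not heat. The iteration
conserves total seed mass and admits a dense linear-solve oracle,
which is why this kernel was chosen over a matrix exponential; the kernel
choice is configurable in principle and qualitative behaviour matches.
Edges are treated as undirected by default (reference networks mix edge
semantics). A node's linker score is min(upstream heat, downstream heat) —
heat received from *both* evidence layers; the product alternative is a
flagged option. The subnetwork keeps all inputs plus the top
`round(size_factor·(|up|+|down|))` positive-score non-input nodes,
selected deterministically from the sorted scores (the fixed point a
threshold bisection would reach). If no node is heated by both sources the
inputs-only subnetwork is returned with a warning.

## Synthetic data: what is emulated, and what is not

The generators produce every input the pipeline consumes, with planted
truth and full determinism under their seed.

* **Screen** (defaults: 292 drugs × 8 lines × 8 log-spaced doses spanning
  1 nM–10 μM). Drug-level 4PL parameters (log-EC50 uniform over 30 nM–1 μM,
  floor uniform on [0, 0.25], slope uniform on [0.9, 1.8]) are jittered per
  cell line so a drug's behaviour is correlated across lines. The anchor
  contributes a fixed inhibition (`anchor_ic25_effect`, default 0.15)
  composed with the drug under Bliss independence for non-sensitizers —
  this *defines* "no interaction". The default 0.15 models a primarily
  cytostatic anchor whose solo AUC contribution stays below the screen's
  average combination shift; the nominal "IC25" is exposed as a parameter
  rather than hard-coded because assay endpoint and duration change what a
  quarter-maximal dose does to a 5-day viability read. A planted sensitizer
  is left-shifted `gi50_shift_fold`-fold (default 5) *and* has its
  combination floor multiplied by `sensitizer_kill_factor` (default 0.5): a
  true combination hit is both more potent and cytotoxic, which is what the
  minimum-viability gate in criteria 4–5 screens for; setting the factor to
  1 gives a pure potency shift (used when checking exact fold-change
  recovery). Noise is additive Gaussian (default sd 0.03, a plate-CV-scale
  choice) truncated to [0, 1]. Not emulated: plate-layout artefacts, edge
  effects, batch structure, replicate-level variance components.
* **Dose matrices** are built under exact Bliss independence, independence
  plus a constant excess (clipped to [0, 1] — recovery is exact only while
  unclipped), or exact dose additivity (one median-effect drug split across
  both axes).
* **Counts** follow NB with variance `μ + α μ²` (default α = 0.05), log2
  baselines N(log2(100), 1), main effects N(0, 0.5), log-normal size
  factors around 1 (geometric mean 1), and a planted `β_idc` of chosen
  magnitude and random sign on a chosen fraction of genes. Not emulated:
  gene-length effects, dispersion-mean trends, outlier genes.
* **Phosphopeptides** are fold changes: zero-centred Gaussian noise with a
  constant offset added to the planted kinase's substrates. No
  spectral-level or missingness simulation.
* **Networks** are a background Erdős–Rényi layer over non-path nodes plus
  a planted path whose interior nodes are the truth linkers; the upstream
  endpoint is wired into the background while the downstream endpoint is
  not, which keeps the planted path the *unique* route between the
  endpoints.

Because the generators realize the null models the statistics assume,
passing tests demonstrate correctness and calibration of the machinery —
not robustness to the real-data pathologies listed above.

## Problem sizes

The test suite and the acceptance script run at sizes chosen to make each
check statistically meaningful at interactive cost: 1,000 random screens
for the HSA oracle; 100 Monte-Carlo fits for noisy 4PL recovery; 2,000
genes for null calibration of the interaction LRT (known dispersion
supplied, isolating test calibration from dispersion estimation) and 500
planted genes for its power; exhaustive list lengths N ≤ 100 for the KS
oracle; 150 simulations for KSEA null uniformity; 50-node graphs for the
diffusion oracle and 20 seeded 200-node instances for linker recovery; and
20 seeded 200-drug screens (4 cell lines) for end-to-end nomination
recall/precision.

## Known limitations

* The NB LRT relies on χ²(1) asymptotics at 12 samples; calibration is
  verified by simulation at the default design but will degrade for very
  low counts or extreme dispersion, and method-of-moments dispersion is
  noisy at n = 3 per arm (supplying a known or externally estimated
  dispersion is supported and recommended for power studies).
* Censored GI50s enter fold changes at face value; fold changes involving
  censored values are flagged but not interval-estimated.
* The combination index is undefined where observed inhibition saturates;
  heavily saturated matrices lose cells from the summary.
* Mode-aware enrichment reflects ranks rather than re-signing scores; for
  lists dominated by one sign the mirrored null remains exchangeable but
  the ES magnitude is not comparable across differently signed regulons.
* Diffusion treats all edges as undirected and unweighted unless weights
  are provided; edge-type semantics of mixed networks are ignored.
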