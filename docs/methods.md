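# Methods

This note records the models, estimators and design choices behind
butolscreen, and what the synthetic data do and do not emulate.

## The screen being modeled

A plasmid library of random 2–3 kb genomic inserts (≈14,000 clones over a
4.64 Mb genome, ≈7.5-fold coverage) is serially transferred through batch
cultures at rising n-butanol concentrations (default 0.5, 0.9, 1.3,
1.7 % v/v), alongside solvent-free control transfers. After each transfer
the plasmid pool is hybridized against the unchallenged pool on two-channel
arrays. Genes whose inserts confer tolerance enrich; genes harmful when
present in multicopy deplete. Candidates are then validated individually by
growth kinetics at 0 % and 0.5 % butanol.

## Synthetic data generator

**Genome and library.** Genes are non-overlapping intervals (0-based,
half-open) placed uniformly; strand is stored but ignored by coverage math
(hybridization is strand-agnostic). Inserts are uniform over the genome
with lengths uniform in the configured range; fold coverage is
Σ insert lengths / genome length, exactly.

**Selection truth.** Target genes are sampled well separated (no insert
can span two targets) and every clone overlapping a target inherits that
gene's selection coefficient: tolerance targets s > 0 and toxic targets
s < 0 in the challenged arm; independently drawn control-arm targets model
general growth advantage, the class the control-arm subtraction exists to
remove. Selection itself acts per clone: abundances follow
a_i ← a_i·exp(w_k·s_i) with renormalization after every transfer, so
abundances sum to 1 throughout. Assigning s by gene content rather than
per clone reflects that an insert's fitness effect comes from the genes it
carries, and gives clean recovery truth; at ≈7.5× coverage independent
per-clone draws could never produce a visible depletion signal, because a
gene loses only 1/n_cover of its hybridization signal when one covering
clone crashes.

**Per-step weights** w_k (default 1.0, 0.22, 0.10, 0.05) compress
selection at later transfers: as the concentration climbs toward the
tolerance ceiling even tolerant clones barely grow, so fitness differences
shrink and most competitive sorting happens in the first challenge. The
resulting enrichment profiles rise strongly at step 1 and then saturate —
the shape such screens report for their averaged profiles. The weights
matter statistically: with constant per-step selection the null bulk keeps
declining after renormalization, so re-centered profiles grow linearly
with step index, and a four-point one-sample t on a linear ramp cannot
fall below p ≈ 0.03 regardless of effect size.

**Array model.** Each covered gene gets `probes_per_gene` probes (default
2) with per-probe baseline intensities 2^U(6,16) (probe affinity, shared
by both channels). The sample channel is baseline × (gene's summed clone
abundance / its unchallenged value); neutral selection therefore gives a
log-ratio of exactly 0. Dye bias adds a cubic polynomial in centered A
(amplitude within ±0.5 log2, removable by LOWESS), Gaussian noise of sd
`noise_sd` (default 0.2) acts on the log2 scale, a hybridization
background (default 100 intensity units) is added to both channels, and
both channels clip at a 16-bit scanner ceiling (65535). Background and
saturation bound the log-ratios the way real arrays do; without them,
crashed or saturated spots form degenerate clusters at the extremes of the
intensity range that drag the normalization fit.

**Growth curves.** Lagged logistic: OD stays at OD₀ until the lag ends,
then OD(t) = K·OD₀·e^{µ(t−lag)}/(K−OD₀+OD₀·e^{µ(t−lag)}), with additive
Gaussian OD noise truncated at zero. A lagged logistic is the simplest
model showing the three phases a plate reader resolves. Scenario defaults:
15-min sampling for 24 h, lag 2 h, OD₀ 0.05, K 1.3, noise sd 0.005 —
typical for a microplate kinetic run in minimal medium.

**What is not emulated:** spatial array artifacts, printing/batch effects,
sequence-specific hybridization efficiency beyond the per-probe baseline,
transformation efficiency and colony picking, replicate-level biological
variation in growth curves beyond reader noise, and any sequence-level
content (no bases are generated). Passing tests therefore demonstrate the
statistics behave as designed under these idealized conditions, not that
the pipeline is robust to every artifact of real arrays.

## Normalization

`lowess_normalize` regresses M on A (statsmodels LOWESS, span 0.3 of the
points, three robustifying iterations) and returns the residual. Rows with
non-positive intensities are dropped with a logged count; more than 50 %
dropped is an error. Spots whose intensity falls below the 2 % quantile of
the reference channel are excluded from the trend *fit* (their trend value
is interpolated, and they are still normalized and returned): this is the
usual low-intensity feature filter, and it prevents the near-background
cluster produced by strongly depleted genes from bending the local fit. If
fewer than max(10, 25 %) of spots survive the floor, the fit falls back to
all spots.

## Differential calling

One-sample two-sided Student's t of each gene's step values against 0;
challenge steps are treated as independent observations. That is a
documented simplification — serial transfers are dependent, and the step
values share the same reference pool — so the p-values are calibrated
under the generator's null (verified 3–5 % calls at α = 0.05) but should
be read as ranking scores on real data. Raw p < 0.05 with no
multiple-testing correction is the default convention of this screen
design; `correction="bh"` switches to Benjamini–Hochberg. With a ~95 %
null genome, raw-α calling necessarily yields a high false-discovery rate
(≈0.05·n_null false calls); the package's own end-to-end recovery tests
therefore run candidate calling under BH, where measured sensitivity is
≥ 0.95 with FDR ≤ 0.1 at 1200–2000 genes. Zero-variance profiles are
flagged: nonzero mean gives p = 0 with `degenerate_variance` set, zero
mean is never called. The control filter removes (gene, direction) pairs
significant in the control arm and is idempotent.

## CAST clustering

Affinity is (Pearson r + 1)/2; constant profiles get r defined as 0
(affinity 0.5) and are flagged. A Euclidean mode (1/(1+d)) is available.
The loop seeds each cluster with the unassigned element of maximal total
affinity to the remaining pool, adds the highest-affinity outside element
while its mean affinity to the cluster is ≥ t, removes the lowest member
while below t, and closes the cluster when stable; all ties break
lexicographically on gene id so runs are reproducible. The add/remove loop
is capped at 1000 sweeps per cluster (CAST can in principle oscillate; the
cap closes the cluster as-is with a warning). Default t = 0.8 — a common
working value; no fidelity to any particular published clustering is
claimed, since the original threshold is unreported. The cluster count is
not guaranteed monotone in t (greedy algorithm).

## GO enrichment

Hypergeometric tail P(X ≥ k) via scipy, cross-checked in the tests against
an exact integer-arithmetic tail sum to 1e-12. The log odds ratio is
log2((k/n)/(K/N)), reported as −inf when k = 0. Ancestor propagation
(transitive closure over a term→parent edge table) is on by default.
Correction is BH by default, BY optional. Terms absent from the population
are skipped; a study-only term is an annotation inconsistency and raises.

## Growth-rate estimation and tolerance statistics

`fit_mu_max` offers two estimators:

* **Sliding window (default):** maximum slope of ln OD over windows of
  `window_points` consecutive readings above `min_od` (defaults 5 and
  0.02), reporting the winning window and its R². Simple and
  assumption-light, but with additive OD noise the max-over-windows rule
  carries an upward selection bias that is *additive* per strain and does
  not cancel in ratio statistics.
* **OD band (`od_band`, used by the screen):** one log-linear fit over the
  readings with OD inside a fixed band (0.08–0.45 by default). Because the
  logistic trajectory is a fixed function of µ·t, fitting every strain
  over the same OD band under-reads µ by the same multiplicative factor
  for all strains, which cancels exactly in the tolerance ratio and hence
  in IIE/RSGR. Simulation at the screen's conditions shows the band mode
  recovers a true IIE of 49.1 % with bias ≈ +0.5 and sd ≈ 1.4 percentage
  points, where the sliding-window mode is 5–10 points low.

An optional centered moving average (`smooth_points`) can pre-smooth the
OD series; during exponential growth it multiplies OD by a constant and so
does not bias the slope. Curves that never rise give µ_max = 0 with a
`flat` flag; too few usable points is an error naming the count.

`screen_gene` pairs replicate r of the clone with replicate r of the wild
type, computes per-pairing IIE and RSGR, and reports their mean ± sd (sd
across replicate pairings, and the column is labeled sd). The p-value is a
two-sample two-sided Student's t on the per-replicate tolerance ratios —
IIE is a ratio statistic, so the test compares ratios rather than raw µ.
Unequal replicate counts fall back to comparing each clone replicate
against the wild-type mean, with a warning. Degenerate inputs (both ratio
sets constant) give p = 1 when equal and p = 0 when different.

## Pipeline

One `ScreenConfig` (YAML-loadable) fixes every stage parameter and the
global seed; per-stage seeds are derived from it, every output table
carries a config-hash + seed header, and identical configs reproduce
byte-identical tables. Stage failures abort with the stage name. The
growth-validation stage screens the called candidates individually; only
selection-target genes carry a true growth effect, so insert neighbours
that hitchhiked through the array stage fail validation — mirroring the
real screen, where most array candidates did not validate. Problem sizes
in the shipped tests are scaled down from the study's (380–2500 genes,
1200–6000 clones, 8 seeds for the recovery property) so the whole suite
runs in well under a minute of simulation time; the statistics do not
depend on the absolute scale.

## Known limitations

* The one-sample-t-across-steps design has bounded power against
  monotonically ramping profiles (four points, high serial correlation);
  the screen works in the saturating-selection regime its generator
  defaults to.
* LOWESS normalization attenuates genuine enrichment where shifted spots
  locally dominate an intensity region; background, saturation and the
  low-intensity fit filter bound, but do not remove, this effect.
* IIE/RSGR error bars are the sd over four replicate pairings; with n = 4
  they are themselves noisy.
* GO results depend entirely on the supplied annotation tables; no
  ontology files are parsed beyond a two-column parent-edge list.
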