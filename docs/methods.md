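# Methods

## Problem and pipeline

`grangernet` implements a directed brain-network analysis pipeline for
region-of-interest (ROI) time series, of the kind used to contrast a
patient group against controls from source-reconstructed MEG/EEG
recordings. The stages are:

1. **Connectivity.** Per subject, a weighted directed network from
   pairwise Granger causality (GC) and a weighted undirected network from
   Pearson correlation (PCC).
2. **Binarization.** Proportional thresholding with the retained fraction
   chosen by global cost-efficiency maximization.
3. **Topology.** Four global and four nodal graph properties per binary
   network (4 + 4n features).
4. **Weighted-network rankings.** Group-level strongest-connection,
   group-difference, out-strength and out-strength-difference lists, with
   consensus hub identification.
5. **Statistics and classification.** Normality-gated group tests per
   feature; Mann–Whitney screening followed by a linear SVM on a
   stratified 70/30 split.

Because no clinical recordings are distributed, a synthetic-data module
generates stationary multivariate autoregressive (MVAR) cohorts with a
known causal graph; every stage is validated against that ground truth.

## Granger causality (time domain, pairwise)

For an ordered region pair (Y, X) two least-squares autoregressions of
order p are fitted on a common effective window (targets start after p
samples):

- full: X_t on p lags of X and p lags of Y,
- reduced: X_t on p lags of X.

With maximum-likelihood residual variances Σ′_xx (reduced) and Σ_xx
(full), the directed influence is F_{Y→X} = ln(Σ′_xx / Σ_xx) ≥ 0. The ML
divisor (1/n_eff) and the shared window make the nested-model inequality
exact; a round-off guard clips values above −1e-8 to 0 and treats
anything more negative as a numerical failure.

Pairwise-bivariate GC is used rather than conditional multivariate GC: a
116-variate VAR at order 5 has 580 coefficients per equation and is not
identifiable from 1000 samples. Conditional, spectral and time-varying GC
are out of scope.

No intercept is fitted; the pipeline z-scores every region (population
standard deviation) before model fitting. Internally the per-pair
regressions are solved from the Gram matrix of the shared lagged design
via Schur complements — algebraically the normal equations — which makes
the 116-region case (13,340 bivariate fits) take well under a second; the
test suite verifies exact agreement (≤1e-12) with explicitly assembled
per-pair least squares.

## Lag-order selection

BIC(p) = n_eff · ln det(Σ̂_p) + k · ln(n_eff), with k = p·n² free
coefficients, minimized over candidate orders (default 1–10). All
candidates are scored on the same effective window — targets begin after
`max_order` samples — so the criteria are comparable; ties go to the
smaller order. In pipeline "bic" mode the order is selected per subject
and the modal order is applied to every subject, mirroring the use of a
single study-wide order.

## Thresholding

Weights are first normalized per subject: PCC weights are rectified by
absolute value (the proportional threshold needs a non-negative strength
ordering; whether negative correlations should instead be zeroed is an
open choice, noted here), then all weights are divided by the maximum
off-diagonal magnitude. Proportional binarization keeps the
k = floor(PSW·M) strongest connections (M = n(n−1) directed,
n(n−1)/2 undirected, mirrored), with deterministic tie-breaking by
(weight desc, row asc, col asc) — which also makes threshold sets nested
across PSW. The scan averages GCE = E − PSW across all subjects per grid
point (default grid 0.05–0.50, step 0.05) and applies the single argmax
PSW to every subject of that method; averaging across the pooled cohort
rather than per group is an assumption, made because one optimum per
method is reported downstream.

## Graph metrics and conventions

Distances are unweighted shortest paths (scipy's Dijkstra on the binary
adjacency). Conventions, each oracle-tested:

- unreachable pairs contribute 0 to efficiencies and are excluded from
  the characteristic path length (error if no pair is reachable);
- directed clustering is the Fagiolo generalization (all directed
  triangle motifs, reciprocal-degree correction);
- nodal degree is in+out for directed graphs (out-only available via
  `degree_mode="out"`);
- a node's neighborhood for local efficiency is the union of in- and
  out-neighbors; local efficiency is the (directed) global efficiency of
  the induced subgraph, 0 with fewer than two neighbors.

The feature vector is [GCC, GCLP, GE, GLE] then per-region
[NCC, NE, NLE, NDC] in label order — 468 entries for 116 regions.

## Hubs

Group-mean normalized GCA matrices feed four rankings: top-20 link
strengths (patient group), top-20 absolute group differences (sign
retained to distinguish increases from decreases), top-5 out-strength
regions, and top-5 out-strength differences. A region is a hub when it
appears in ≥2 of the four lists (configurable); edge lists contribute
both endpoints at most once per list so a region dominating one list
cannot inflate its count.

## Statistics and classification

Each feature's group comparison is gated by a one-sample
Kolmogorov–Smirnov test against a normal with the sample's estimated
mean/sd (the Lilliefors correction for estimated moments is documented
but not applied, matching common practice with the plain K-S name); both
samples normal → unpaired two-sided t-test, otherwise two-sided
Mann–Whitney U (exact for group sizes ≤20, tie-corrected normal
approximation above). No multiple-testing correction is applied in the
screening step, matching the p < 0.05 protocol it reproduces.

Classification: Mann–Whitney screen at α = 0.05, stratified 70/30 split
(round-half-up per class: 34/14 subjects → 24+10 train, 10+4 validation),
features standardized with training-set statistics only, linear SVM with
C = 1 (kernel and C were unspecified upstream; both are exposed), and
accuracy/precision/recall/F1/Cohen's κ/ROC-AUC on the validation set with
the decision-function score. By default the screen runs on training rows
only; `paper_mode=True` screens on all subjects, reproducing the
published protocol at the cost of selection leakage (caveat intended).

## Synthetic cohorts

A subject is x_t = Σ_k A_k x_{t−k} + e_t with e_t ~ N(0, Q), Q positive
definite, companion spectral radius < 1 (checked for every emitted
subject), 500 burn-in samples discarded. Per-subject seeds derive from
`SeedSequence([cohort_seed, subject_index])`. The default cohort
(`demo_cohort_spec`) is 20 regions — 116 is supported but reserved for
full-scale runs — with 14 control-like ("HC") and 34 patient-like
("TLE") subjects, 1000 samples at 500 Hz, a random sparse stable base
network, and the patient effect: +0.3 added to the lag-1 gains of 5 edges
leaving 3 designated source regions. The effect is additive on coupling
gains, not on noise power, because the phenomenon being emulated is
elevated directed connection strength. No effect-size estimate exists
upstream; 0.3 was chosen for comfortable test power and is a free
parameter.

What the generator does **not** emulate: source leakage and field spread,
nonstationarity, 1/f spectra, volume-conduction-correlated noise, and
inter-subject anatomical variability. Passing tests therefore demonstrate
correctness of the estimators and the pipeline's discriminative behavior
under ideal stationary linear dynamics, not performance on real MEG.

### Order-misspecification study

`order_study_cohort_spec` isolates the effect of lag-order choice: source
channels are white noise (so no autocorrelation aliases lag-5 information
into shorter lags), target channels have own dynamics at lags 1 and 5,
and the group effect (+0.4 on five source→target edges) sits at lag 5.
Candidate orders below 5 are provably blind to the discriminative
coupling. Classification AUC per order is averaged over 5 stratified
splits (the protocol being mirrored repeats its experiments). On this
cohort, orders ≥5 beat orders <5 by a wide margin (mean AUC ≈0.85 vs
≈0.55 across replicates), but the surface plateaus above order 5: at
n = 1000 the variance cost of a few extra bivariate-lag parameters is
negligible, so the argmax order is noise-tied across {5..10} rather than
concentrated at 4–6. A sharp optimum at the generating order would
require either much shorter series or the kinds of real-data
nonstationarity this generator deliberately omits; this limitation is a
property of the stationary synthetic world, not of the estimators.

## Numerical choices and problem sizes

- TSV output at %.17g (full double round-trip).
- Rank-deficient designs (duplicated/constant channels) are rejected with
  a condition diagnostic rather than silently pseudo-inverted.
- Test-scale geometry is 20 regions (84 features) for speed; the
  116-region feature count and matrix shapes are asserted directly.
  End-to-end recovery tests use 10 seeds; example-level simulations use
  10–20 replicates.
- The analysis drivers (`analysis/01…07`) run the default 20-region
  cohort in a few seconds per stage and the order study in about two
  minutes.

## Known limitations

- Pairwise GC cannot distinguish direct from mediated influence.
- The K-S normality gate with estimated moments is anti-conservative
  (Lilliefors caveat above).
- `select_representative` (max-power signal choice among per-region
  candidates) is exposed but unused by the default pipeline; its natural
  inputs are upstream of this package's scope.
- Hub "statistical prominence" is operationalized as the ≥2-of-4
  frequency rule; other consensus rules are plausible.
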