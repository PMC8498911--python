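# Methods

## Model and assumptions

The pipeline estimates differential TF *activity* from two kinds of
data that are informative in complementary ways.

**Regulon inference assumes transcript-level coupling.** In
cross-sectional cohorts the TF's transcript abundance varies between
individuals, and — to the extent that protein activity tracks
transcript — its targets co-vary with it. Partial correlations, rather
than marginal ones, are used so that an edge reflects conditional
dependence between the TF and a target given all other measured genes,
which suppresses indirect target–target associations. This is the
standard premise of TF-coexpression reverse engineering; where a TF's
activity is decoupled from its transcript in the cohort tissue, the
method is blind to it.

**Activity scoring does not assume transcript-level coupling.** The
enrichment stage asks only whether a TF's regulon is displaced toward
the extremes of the perturbation signature. A TF activated purely
post-transcriptionally (flat mRNA, shifted targets) is exactly the case
the method is designed to catch.

**Linear-Gaussian structure.** All inference is correlation-based and
therefore sensitive only to (approximately) linear co-variation on the
log2 expression scale; saturating or switch-like regulation is captured
only through its linear component.

## Stages and key formulas

1. *Signature*: per-gene log2FC and moderated t. The variance prior
   (d₀, s₀²) is fitted by matching the mean and variance of log s²_g to
   the scaled-F sampling model (digamma/trigamma moments, trigamma
   inverse by damped Newton). If fewer than two positive variances
   exist the fit falls back to the ordinary t with a logged warning; if
   the observed log-variance spread is below its sampling expectation,
   d₀ = ∞ and all genes share s₀². DEG calls use strict inequalities
   (log2FC > 1, p < 0.05) on raw p-values; no multiplicity correction
   at this stage.
2. *Ortholog projection*: genes without a partner in the two-column map
   are eliminated; ambiguous (one-to-many or many-to-one) pairs are
   dropped by default (`ambiguity="first"` keeps the first listed).
   Dropping is the conservative choice when the mapping source gives no
   preference order.
3. *Batch adjustment* (optional): per gene, each batch is standardized
   to its own mean/SD and rescaled to the pooled moments — ComBat-style
   location/scale without empirical-Bayes shrinkage of batch
   parameters, which small simulated studies do not need. Batches with
   a single sample are rejected.
4. *Per-cohort networks*: analytic target-to-identity shrinkage
   λ\* = ΣVar̂(r̂)/Σr̂² (unbiased w-moment variance estimator), clipped
   to [0, 1]; partial correlations from the Cholesky inverse of R\*.
   Two-sided p-values come from the empirical null
   f₀(r;κ) ∝ (1−r²)^((κ−3)/2) via the exact transform
   t = r√(κ−1)/√(1−r²) ~ t(κ−1); with κ = n−1 this is the classical
   correlation test, and κ is otherwise fitted (below). BH across the
   TF-incident pairs; only TF-incident pairs are tested, since
   downstream scoring consumes TF-anchored regulons only.
5. *Meta-network*: signed Z per cohort, √n-weighted Stouffer
   combination, sign-coherence across *significant* cohorts (a weak,
   non-significant opposite sign does not veto; `coherence="strict"`
   makes it veto). Retention requires coherence, |Z| ≥ Φ⁻¹(0.975), and
   significance in at least one cohort, so every consensus edge traces
   back to a per-cohort FDR-controlled discovery.
6. *Regulons*: mor = tanh(Z/z_scale) with z_scale = 3 (|Z| ≈ 3 ⇒
   |mor| ≈ 0.76, saturating around |Z| ≈ 6–9); likelihood = |Z|
   normalized to (0, 1] within the regulon (scoring is invariant to the
   normalization). TFs with fewer than `min_regulon_size` (default 10)
   retained targets are dropped: small regulons make the enrichment
   statistic unstable.
7. *aREA scoring*: rank quantiles with average ranks for ties;
   x = mor·q₂ + (1−|mor|)·q₁; NES = Σwx/√Σw². The analytic null
   N(0, 1) is the default; a seeded gene-permutation null is provided
   because small or heavily tied regulons deviate from normality — the
   deviation is measured in the test suite, not assumed away. Multiple
   replicate signatures are first summarized by a one-sample moderated
   t of the per-replicate log2FCs. Master call: raw p < 0.01 (BH FDR is
   reported alongside for transparency).
8. *Communities / ORA*: unweighted Clauset–Newman–Moore greedy
   modularity (weighted variant behind a flag) on the TF–target graph
   of master regulons; one-sided hypergeometric over-representation per
   community against user-supplied GMT collections, BH within each
   community's table. Communities are unranked gene lists, which is why
   over-representation rather than a ranked running-sum statistic is
   the appropriate test.

## Empirical-null fitting (κ)

κ is estimated by maximizing the truncated f₀ likelihood over the
observations inside the central 95% quantile band of the TF-incident
partial correlations. Two opposing failure modes set this band: true
edges contaminate the extreme tails (arguing for a narrow band), while
the null distribution of *shrunk* partial correlations is slightly
heavier-tailed than f₀, so fitting only the narrow center understates
the null spread and inflates far-tail significance. Calibration
simulations showed a 90% band yields ~3× inflated tail p-values and
empirical FDR ≈ 1.6× nominal, while the 95% band gives conservative,
FDR-controlling tails at no sensitivity cost. When fewer than 20 pairs
are available the fit is flagged unstable; on failure κ falls back to
n−1 (the classical null) with a logged warning.

## Synthetic-data generator

`synthdata` emulates the study design end-to-end: a gene universe with
disjoint planted regulons (signed targets, per-target strength in
(0, 1]), a treated-vs-control replicate study, and several
cross-sectional cohorts of heterogeneous size.

- *Signature studies*: target expression is baseline +
  Σ strength·mor·activity + N(0, noise_sd²), where activity is 0 plus δ
  in treated samples for shifted TFs. The TF's own transcript is
  baseline plus noise — treatment changes activity, not TF mRNA, so
  recovering the TF *must* go through its regulon.
- *Cohorts*: per sample, each TF has latent activity a ~ N(0,1); its
  transcript is baseline + r_tf·a + √(1−r_tf²)·z (transcript–activity
  correlation r_tf, default 0.9), and targets respond linearly to the
  transcript deviation. Driving targets from the transcript (rather
  than from a latent factor the transcript merely reflects) makes each
  planted TF–target pair a genuine conditional dependence between
  measured variables; in a pure latent-factor design the co-targets
  collectively absorb the factor and the TF-incident partial
  correlations are capped near √τ/(2√(1+kτ)) (~0.1 for 20-target
  regulons), which no sample size rescues.
- *Batch structure*: additive per-(batch, gene) N(0, batch_sd²) offsets
  on flagged cohorts, split into two batches. No scale effects,
  count-based noise, probe-level structure, or dropout are simulated.

Defaults describe a compact study: 300 genes, 10 TFs × 20 targets,
noise SD 0.5 (log2 scale), 10 vs 10 replicates, three cohorts of 200.
Strengths are uniform on (0.5, 1] with 25% repressed targets.
Everything is a pure function of (config, truth, seed); cohorts use
deterministically spawned RNG substreams.

What passing tests therefore show: the pipeline recovers planted
structure under linear-Gaussian data with homoskedastic noise and
transcript-coupled regulation. They do not show robustness to
count-distributed noise, nonlinear regulation, overlapping regulons, or
activity–transcript decoupling in cohorts — all of which degrade real
data.

A note on additive batch effects: genome-wide additive offsets barely
impair partial-correlation edge recovery even unadjusted, because the
batch indicator is itself linearly reconstructable from the other genes
and is conditioned away (and the empirical null absorbs the rest).
Batch adjustment remains worthwhile — it restores full sensitivity and
removes the batch factor from the estimated networks — but the failure
mode it prevents is milder here than for marginal-correlation methods.

## Numerical choices

- Strict inequalities at every published threshold (DEG cuts, master
  p); boundary values are excluded.
- p-values are clipped below at the smallest positive float; p = 0
  entering the Z-transform is clamped with a logged warning.
- Ties: average ranks throughout.
- r values are clipped to [−1, 1] and |r| = 1 maps to p = 0⁺.
- Partial-correlation matrices are symmetrized ((P+Pᵀ)/2) after
  inversion to remove round-off asymmetry.
- Deterministic outputs: TSV writers use a fixed float format; the run
  manifest contains no timestamps, so identical config + seed gives a
  byte-identical run directory.

## Known limitations

- No pleiotropy/shadow correction: overlapping or correlated regulons
  are reported as-is, and correlated targets inflate |NES| relative to
  the independence null.
- The analytic N(0,1) NES null degrades for regulons near the minimum
  size; use the permutation null there.
- f₀ is an approximation to the true null of shrunk partial
  correlations; the 95%-band fit errs conservative.
- Single-sample (per-specimen) activity matrices, heterogeneity
  statistics for the meta-analysis (Q, I²), and ranked GSEA are out of
  scope.
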