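# Methods

This note documents the statistical models the package implements, the
design choices made where the procedure was genuinely open, what the
synthetic generators do and do not emulate, and the numerical
conventions.

## Differential proteomics consensus

Label-free (LFQ) intensities are log2-transformed; a zero intensity on
disk means "not quantified" and is treated as missing from the moment a
table is read.  Features are testable when they carry at least
`min_valid` (default 3) present values in every compared group.

Each knockout clone is contrasted against the shared control with an
unpaired two-tailed Welch t-test (Satterthwaite degrees of freedom);
per-contrast q-values are step-up Benjamini–Hochberg.  Degenerate
inputs follow explicit conventions: zero variance in both groups with
equal means gives p = 1; zero variance with unequal means gives the
smallest positive double, with a warning.

Clones are combined with an equal-weight **signed Stouffer** statistic,
zᵢ = sign(log2FCᵢ)·Φ⁻¹(1 − pᵢ/2), combined z = Σzᵢ/√k.  The two-tailed
per-clone p-values carry no direction, so the fold-change sign is
re-attached before pooling; an unsigned combination would reward
features that move in opposite directions in different clones.  A
per-clone p of exactly 0 is capped at z = 37 (≈ the double-precision
limit) with a warning.  The BH family for the combined q is the set of
features testable in every clone.

A feature is a consensus differential protein iff it passes p < 0.05
and |log2FC| > 0.5 in **every** clone, with the same sign everywhere,
and its combined q < 0.005.  The per-clone criteria and the combined-q
gate are applied jointly (intersective reading); both thresholds are
exposed in the configuration.

Technical LC-MS/MS runs are averaged into one value per biological
replicate before testing (a configuration switch), because treating
runs as replicates would pseudo-replicate the biology.  Averaging uses
the geometric mean (arithmetic on the log2 scale): arithmetic averaging
of linear-scale log-normal intensities skews replicate values and makes
the downstream t-test measurably conservative.

**Small-sample caveat.** With 3 replicates per group the
Welch–Satterthwaite approximation is conservative: the true null
rejection rate at nominal 0.05 is ≈ 0.035 (this is a property of the
test, not of this implementation — scipy's `ttest_ind` reproduces it).
The calibration test therefore checks exact uniformity at 8 replicates
per group, and checks at 3 replicates only that the rate never exceeds
nominal.

## IP-MS interactor calling

The five-group pulldown design comprises two experimental groups
(intact bait), two plain controls (e.g. IgG and empty vector), and one
domain-negative control (bait with the domain of interest deleted).
Missing values — overwhelmingly proteins below detection in control
pulldowns — are imputed per sample from
Normal(mean_obs − 1.8·sd_obs, (0.3·sd_obs)²), the standard
missing-not-at-random model with the conventional width/down-shift
defaults.  Imputation is used only here; the label-free proteome module
relies on the valid-value filter instead, mirroring the two workflows'
respective conventions.

"Enriched versus the controls" is read conservatively as *each
experimental group versus each control group* (all pairwise tests must
pass, q < 0.05 and log2FC > 2); a pooled-control mode is available by
configuration.  Enrichment is one-directional: pulldown enrichment is
gain-of-signal by construction.  Criterion 2 (the domain-negative
control must not be enriched versus the plain controls) uses the same
compound (q, log2FC) threshold by default, switchable to q alone.  A
protein is called iff criterion 1 and criterion 2 both hold.  Group
roles are configuration, not hard-coded construct names.

## Phosphoproteomics and kinase activity (KSEA)

Sites with localization probability strictly greater than 0.75 are
confident.  Per-site log2(Ctrl/KO) ratios come from the same Welch
machinery; positive means higher phosphorylation in control, i.e. the
kinase is activated by the knocked-out protein.  Because a site's ratio
confounds kinase activity with the carrier protein's abundance change,
each ratio is normalized by subtracting the protein's log2 ratio from
the matched label-free proteome; sites whose protein is unquantified
are excluded by default (flagged, switchable).  The orientation of the
protein ratios cannot be verified internally — it is a caller contract.

Site significance (p < 0.05) is assessed on the raw, pre-normalization
contrasts (configuration-switchable): the filter mirrors a
site-selection step applied to the measured ratios before normalization
enters.

Kinase activity is the **plain arithmetic mean** of the normalized
ratios of its annotated substrate sites (exact protein/residue/position
match), reported only for kinases with ≥ 5 qualifying sites.  The
familiar KSEA z-statistic ((mean_set − mean_all)·√m / sd_all) is
provided separately as a clearly labeled secondary score.  Consensus
across knockout clones takes the kinases quantified in all contrasts;
"activated" means positive in every contrast.

## Upstream regulators

The knowledge base is a user-supplied signed regulator→target table —
the scoring statistic, not any proprietary network content, is what is
implemented.  With observed directions dₜ ∈ {±1} (down-in-KO = −1 for
a regulator the target protein activates), the activation z of a
regulator with n overlapping targets is Σₜ sign(edgeₜ)·dₜ/√n, bounded
by ±√n and attaining the bound exactly at full consistency.  Overlap
significance is the upper-tail hypergeometric probability of drawing at
least the observed number of targets in the differential set from the
tested universe.  Interactor→kinase linking emits only activating (+1)
edges, because the biological question is which bound protein can
directly *activate* a downstream kinase.

## Cohort activity scores

Expression is assumed log-scale and median-centerable; genes are
standardized to mean 0, sd 1 (ddof = 1) across cohort samples before
scoring (median/MAD standardization is a configuration alternative).
The weighted-Z score of set G in sample s is Σ_g w_g z_{gs}/√(Σ w_g²)
with unit weights by default — no weighting scheme is asserted beyond
what the score's definition requires.  Induced and repressed signatures
are always scored separately, never merged with flipped signs.

Spearman correlations use mid-ranks and the t-approximation on n − 2
degrees of freedom; |ρ| = 1 reports the smallest positive double.
Overexpression frequencies standardize every sample against the
*reference stage's* mean and sd (e.g. tumor-adjacent normal tissue) and
count z > 2 strictly.

## Triage and survival

Criterion 1 (recurrent amplification) defaults to amplification-only
calls (GISTIC +2) at frequency > 0.10 in ≥ 2 cohorts; amplification +
gain ({1, 2}) is an option since the portal-level convention is
ambiguous.  Criterion 2 correlates per-stage **mean** expression with
stage rank: demanding ρ > 0.9 is only meaningful on the stage-aggregated
trend (sample-level correlations over thousands of samples cannot
plausibly reach 0.9); sample-level mode is retained as an option.
Venn regions are counted over all 8 subsets of the three criterion
sets; the intersection is ordered by maximal amplification frequency.

χ² trend statistics use the Pearson statistic with an upper-tail p and
Cramér's V = √(χ²/(n·(min(r,c) − 1))), labeled weak (< 0.2), moderate
(< 0.6) or strong.

Survival strata are compared with the two-group log-rank test; the
hazard ratio is the observed/expected form (O₁/E₁)/(O₂/E₂) with CI
exp(ln HR ± 1.96·√(1/E₁ + 1/E₂)), i.e. attributed to the log-rank
procedure rather than a proportional-hazards fit.  The default
expression cutpoint is the median.  Note the O/E estimator is biased
toward 1 under very long follow-up (when the low-hazard arm dominates
late risk sets); the synthetic survival generator's default censoring
window keeps roughly half the subjects as events, where the estimator
is near-unbiased.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *statistical structure* the pipeline is
built for, with defaults chosen once as the emulated study conditions:

- **Proteome** — log-normal intensities (log2 mean 25, sd 2), a control
  plus 3 knockout clones, 3 biological replicates × 2 technical runs,
  10% differential features at |log2FC| = 1.5 with clone-consistent
  direction, per-run noise sd 0.4, and logistic-in-intensity (MNAR)
  missingness with midpoint 3 sd below the mean intensity — a
  detection-limit regime in which the ≥ 3-valid-values filter leaves
  the tested set nearly complete.
- **IP-MS** — the five-group design at 4 replicates per group (the
  emulated 20-run acquisition over five conditions); true interactors
  present only in experimental groups at +5 log2 units, below
  detection elsewhere; decoys bound to the domain retained by the
  domain-negative construct (present there and in the experimentals);
  uniform background.
- **Phosphoproteome** — site ratio = kinase shift + carrier-protein
  shift + noise, with a matched protein matrix carrying only the
  protein shifts, so protein normalization is *required* to recover the
  pure kinase signal; a stated fraction of sites receives localization
  probability below 0.75.
- **Cohort** — latent activity increasing with ordinal stage plus
  Gaussian noise; signature genes load on the activity; one designated
  gene's expression coupled to its discrete copy-number call at a
  target Pearson r; exponential survival with log-hazard proportional
  to standardized activity (constant hazard: the planted hazard ratio
  is analytically known) and independent uniform censoring.

Not emulated: peptide-level quantification, retention-time or batch
structure, protein-group ambiguity, inter-cohort normalization
differences, correlated gene-gene backgrounds, and non-proportional
hazards.  Passing recovery tests therefore demonstrates correctness of
the statistical chain under its own model assumptions, not robustness
to every artifact of real acquisitions.

## Numerical conventions

- BH is step-up with enforced monotonicity, clipped to [0, 1].
- All generators are bit-for-bit deterministic under their seed
  (`numpy.random.default_rng`); imputation takes its own seed.
- Welch contrasts require ≥ 2 valid values per group per feature;
  features below that are reported with NaN statistics and excluded
  from the BH family.
- Ties in ranking tables break lexicographically (documented in each
  function); Spearman ties use mid-ranks.
- Stage codes are contiguous ordered integers; sample reconciliation
  across cohort files is by intersection with a logged drop count.

## Problem sizes used in tests

The default test and acceptance runs use 2000-feature proteomes,
500-feature IP-MS matrices, 4–8 kinases × 10 substrates, 500-sample
cohorts and 500-subject-per-arm survival draws — sizes at which every
Monte-Carlo tolerance in the suite corresponds to ≥ 3 standard errors
of the measured quantity.  Stochastic recovery quantities with
single-run standard errors comparable to their tolerance (consensus
FDR, log-rank HR) are measured pooled over a few generator seeds.
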