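# Methods

## The problem

Reprogramming somatic cells to pluripotency resets most of the DNA
methylome to the embryonic stem cell (ESC) configuration, but a fraction of
CpGs ends up in the wrong state. Comparing iPSC cohorts against both their
parental cells and reference ESCs on a methylation array (beta values
β = M/(M+U) ∈ [0,1] per CpG probe) lets those failures be found and
*typed*: did the cell fail to change a parental state it should have
changed (epigenetic memory), or did it acquire a state found in neither
parent nor ESC (a de novo aberration)? The package implements that
workflow plus the downstream questions it raises — are the aberrations
concentrated at reprogramming-factor binding sites, at CpG islands, near
transcription start sites, and do they recur in tumors?

## Differential methylation

For two sample groups A and B, each probe gets

* Δβ = mean β(A) − mean β(B), computed over non-missing values
  (a probe missing in more than half of a group has no defined group mean);
* a two-sided Wilcoxon rank-sum (Mann–Whitney U) p-value — the exact null
  distribution when the combined sample size is ≤ 20 with no ties,
  otherwise the normal approximation with mid-ranks and tie-corrected
  variance (the switchover is a documented default; the groups here are
  independent clones, which is why the rank-*sum* rather than the paired
  signed-rank test is the right statistic);
* a Benjamini–Hochberg adjusted q-value computed across **all** tested
  probes on the array.

A probe is significant iff |Δβ| > 0.2 (strictly — a difference of exactly
0.2 fails) and q < 0.05. When a group offers fewer than two values
(e.g. a single parental-fibroblast batch) the rank test is undefined and
the caller falls back to the |Δβ| threshold alone, reporting p and q as
NaN and noting the fallback in the log.

The rank-sum and step-up computations are delegated to scipy/statsmodels;
the test suite verifies both against independent brute-force
implementations (full label enumeration for every split with n ≤ 10;
a literal step-up loop on random p-vectors).

## State calling and the Class I–IV taxonomy

A group's methylation state is the state of its mean beta:
HYPER if β > 0.7, HYPO if β < 0.3, INTERMEDIATE otherwise (strict
inequalities; boundary values and undefined means are INTERMEDIATE).
Using the group mean rather than a per-sample majority vote keeps the call
monotone in the data and matches how group-level methylation is usually
summarised.

Each significant CpG is classified from the (fibroblast, ESC, iPSC) state
triple:

| FIB   | ESC   | iPSC  | class | meaning               |
|-------|-------|-------|-------|-----------------------|
| HYPO  | HYPO  | HYPER | I     | de novo methylation   |
| HYPO  | HYPER | HYPO  | II    | failed methylation    |
| HYPER | HYPO  | HYPER | III   | failed demethylation  |
| HYPER | HYPER | HYPO  | IV    | de novo demethylation |

Every other triple — any INTERMEDIATE state, or an iPSC state equal to the
ESC state — is UNCLASSIFIED: a probe is only assigned a class when all
three reference points are clear and the iPSC is actually aberrant.
Classes II and III are the "memory" (failure-to-change) classes; I and IV
are de novo.

Two scopes are reported. *Shared* aberrations classify probes significant
between the pooled iPSC cohorts and ESCs, using the pooled-iPSC mean.
*Factor-specific* aberrations classify probes significant between the Y
and T cohorts twice, once per cohort against the same fibroblast/ESC
states (per-subtype means, not the pooled mean — the cohort that matches
the ESC state is simply not aberrant and comes out UNCLASSIFIED).

**Observed/expected class ratios.** "More Class II than expected by
chance" needs a null. The one implemented: the eligible universe is every
probe with clear (non-INTERMEDIATE) fibroblast and ESC states; each of
n_draws = 10,000 resamples draws as many probes as observed, uniformly
without replacement, and assigns each the class its (FIB, ESC) states
would imply if the iPSC state were flipped relative to ESC. The ratio is
observed/mean(null); the empirical p is the plus-one-corrected tail in the
direction of the deviation. This uniform-redraw null is this package's
definition of "expected by chance" and is stated here prominently because
other definitions (e.g. matched on array composition) are possible.

## Permutation enrichment at binding regions

Probe positions are 1-based array coordinates; peaks are 0-based half-open
BED intervals; a probe at position p overlaps [s, e) iff s ≤ p−1 < e.
Both conventions are kept native and reconciled only at this comparison.

The test: count query probes inside ≥ 1 interval; redraw B = 10,000
equally sized probe sets from the sampling universe (default: all probes
on the array) without replacement and recount;

p_enrichment = (#{null ≥ observed} + 1) / (B + 1),

and symmetrically for depletion. The plus-one estimator is unbiased
against zero p-values, so the floor is 1/(B+1). On small universes the
null overlap count is exactly hypergeometric, which the tests exploit as a
closed-form oracle. An "extreme" call (the red-diamond criterion) means
the observed count lies outside the entire B-draw null range.

Gene-level counting changes the unit: a gene is hit when ≥ 1 aberrant
probe within ±5 kb of its TSS lies in a peak; multiple probes in one
promoter count once, and the null recounts genes per redraw. Uniform
redraws from the whole array are the default because that is the
conventional null, even though it confounds island context with peak
density; callers can pass a restricted universe to stratify.

Island-context enrichment and the TSS-distance histogram reuse the same
redraw machinery and need no extra assumptions.

## Concordance and tumor profiling

* Sample similarity: pairwise-complete Pearson correlation of beta
  columns; average-linkage hierarchical clustering of 1 − r, cut at k.
  This deterministic clustering replaces consensus (resampled) clustering
  deliberately: at this scale it yields the same partitions without the
  stochastic machinery.
* PCA on probe-wise mean-centered data (full SVD, deterministic up to
  sign), probes with missing values dropped.
* RRBS vs array: sequencing methylation = methylated/total reads at sites
  with ≥ 5× coverage, joined to probes on exact (chromosome, position);
  Pearson r over the intersection. Both assays measure absolute
  methylation, so no normalisation is applied. The exact-coordinate join
  is a documented choice; fuzzier matching rules would only add pairs.
* Tumor vs normal: per-CpG Δβ of unmatched group means
  (tumor − normal); a CpG is cancer-hypermethylated when Δβ > 0.2. Each
  (scope, class) stratum of iPSC-aberrant CpGs is tested for overlap with
  the directionally matching cancer set (hyper for Classes I/III, hypo for
  II/IV) using the same permutation engine over all shared CpGs. The
  permutation overlap test is this package's definition of that
  enrichment; matched-pair designs are out of scope.

## The synthetic-data generator

The generator is first-class, tested code: it defines the conditions under
which everything above is validated.

* **Design**: 1 fibroblast culture profiled as 3 technical replicates
  (so rank tests against it are defined; configurable to 1, which triggers
  the threshold fallback), 5 ESC lines, 9 Y-iPSC and 6 T-iPSC clones.
* **Noise model**: each sample's beta is drawn from a Beta distribution
  with the planted state's mean and concentration κ
  (variance μ(1−μ)/(κ+1)) — the standard bounded-fraction model. Defaults:
  μ_hyper = 0.85, μ_hypo = 0.15, κ = 100 (sd ≈ 0.036 at μ = 0.15). With
  these defaults planted group means essentially never cross the 0.7/0.3
  state thresholds, which is what makes exact recovery assertions
  meaningful; κ is configurable and the state-recoverability invariant is
  asserted on generated data rather than assumed.
* **Labels**: per probe one of NULL (one state everywhere), REPROGRAMMED
  (fibroblast differs, every pluripotent group matches ESC — the dominant
  feature of real data, needed for realistic clustering structure;
  default fraction 0), four shared classes, and four factor-specific
  classes whose affected cohort is drawn 50/50 between Y and T. Default
  mixture: 10% per named class, 20% NULL.
* **Peaks**: fixed-width (200 bp) intervals centered on probe positions;
  coverage odds are `enrichment_odds`-fold higher for aberrant probes
  (base rate 0.1). Probe positions are spaced ≥ 2 kb apart so a peak never
  covers a neighbouring probe and the planted odds ratio is exact.
* **RRBS**: binomial reads at fixed depth from one sample's betas.
  **Tumor/normal**: unmatched cohorts, lowly methylated everywhere except
  a designated hypermethylated probe set.
* **Determinism**: all draws use NumPy's seeded PCG64 generator; identical
  configs and seeds give byte-identical outputs on any platform.

What the generator does *not* emulate — and hence what passing tests do
not show about real arrays: probe-level technical artifacts (type I/II
probe chemistry, batch and position effects), spatial correlation of
methylation along the genome, realistic island-context/peak confounding,
sex chromosomes, copy-number distortion of betas, and biological
within-cohort heterogeneity beyond beta noise. Results on real data
therefore need the usual array QC and batch handling upstream of this
package.

## Numerical and design choices

* Missing betas propagate as NaN and are excluded pairwise; >50% missing
  in a group voids that group's mean for the probe. How failed probes were
  treated in comparable published analyses is typically unstated; this is
  a conservative default.
* Exact rank-sum null for combined n ≤ 20 without ties; mid-ranks plus
  tie-corrected normal approximation otherwise.
* Strict inequalities everywhere a threshold is crossed (|Δβ| > 0.2,
  β > 0.7, β < 0.3), so boundary values never pass.
* Empirical p-values are plus-one corrected and never zero; enrichment and
  depletion tails both count ties at the observed value, so
  p_enr + p_dep ≥ 1.
* Probe and sample order never affect results; permutation-based outputs
  are deterministic given their seed.

## Problem sizes

The test suite and the acceptance script run the full pipeline at 2,000
probes with the default group sizes, B = 10,000 permutations for single
enrichment tests, B = 499 for the 200-replicate calibration experiment,
100 replicates for the planted-enrichment power experiment, and brute-force
oracles at n ≤ 10 (rank test) and ≤ 60 p-values (FDR). These sizes give
binomial standard errors comfortably inside the asserted tolerances while
keeping a full run in tens of seconds on one CPU.

## Known limitations

* The fibroblast "group" is one biological sample in the emulated design;
  treating technical replicates as a group understates biological
  variance.
* FDR is computed array-wide per comparison; region-level (bump) calling,
  empirical-Bayes moderation and batch correction are out of scope.
* The uniform permutation null ignores probe-composition structure
  (island density, probe spacing); the stratified-universe option exists
  but is off by default to match the conventional analysis.
* Gene assignment uses the single nearest gene per probe; promoters
  sharing CpGs between genes are not modelled.
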