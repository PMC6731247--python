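# Methods

This note documents the models, defaults and numerical choices behind
`sigreverse`, and what the synthetic-data generators do and do not emulate.

## Disease signatures

**Scaled-fold contrast.** For a gene with control-group mean ⟨c⟩ and
disease-group mean ⟨d⟩ on the linear intensity scale, the scaled fold
f = (⟨d⟩ − ⟨c⟩)/(⟨d⟩ + ⟨c⟩) is bounded in (−1, 1) for positive
intensities; |f| ≥ 0.20 corresponds roughly to a 1.5-fold change.
Significance is the two-sample Student *t*-test at p < α (default 0.05,
equal-variance; Welch available via `welch=True`). Expression matrices are
log2-scale by convention, so `scaled_fold_profile` exponentiates (2^x) to
form the fold while running the *t*-test on the log2 values, where the
Gaussian noise assumption holds and the null is exactly calibrated;
`log_scale=False` accepts linear-intensity matrices directly. The
significance filter is deliberately a *t*-test at p < 0.05 rather than a
fold-confidence-interval criterion: the two are equivalent choices for a
"95% confidence" filter, and the *t*-test form composes cleanly with the
null-calibration guarantees asserted by the test suite.

**Stage regression.** For ordinal disease-stage series the model is a
per-gene fixed-effects least-squares fit, expression ~ intercept + stage +
categorical covariate indicators (dummy-coded, first level dropped). Only
fixed terms are modelled — no random-effects structure is assumed. The
stage coefficient's two-sided *t* p-value is mapped to a signed Z via the
standard-normal quantile, Z = sign(β)·Φ⁻¹(1 − p/2). Collinear covariates
are dropped with a warning; a constant stage is an error. Disease scales
that decrease with progression (e.g. cognitive scores) are negated with
`reverse_profile`, an involution that leaves p-values untouched.

**Z cap.** All p→Z conversions cap |Z| at 8.2. Φ⁻¹ overflows to infinity
once p underflows double precision (≈ 5·10⁻³²⁴, i.e. |Z| ≈ 8.2 on the
two-sided scale used here); perfect fits would otherwise produce
infinities that poison means and distances downstream.

**Representative signatures.** Across P input profiles, each gene's
retained senses are summed; fraction = (n↑ − n↓)/P with absent genes
contributing 0, and genes are kept when |fraction| strictly exceeds the
threshold (default 0.20) *and* a one-sample *t* on the per-profile sense
values against 0 gives p < α. The denominator is the total number of
profiles, not the number measuring the gene, so thresholds are comparable
across genes. Unanimous nonzero senses give the *t* a zero denominator;
they are treated as maximal evidence (p = 0) rather than dropped — a
perfectly reproducible call is not missing data.

## Drug profiles

**Rank transform.** Per-sample expression-change ranks R (1 = most
upregulated) map to 1 − 2(R − R_min)/(R_max − R_min) ∈ [−1, 1]. Inputs
that are not a contiguous integer permutation (average ranks from ties)
are re-ranked by stable order first. Replicates are averaged per feature
and filtered by a one-sample *t* against 0 at p < α; identical nonzero
replicates (zero variance) are retained, identical zeros dropped. Probe →
gene collapse keeps, per gene, the largest-|value| probe among those that
survived filtering — significance gates magnitude, so an insignificant
probe can never outvote a significant one; ties break by probe order.

**Cell-identity profile.** With per-feature rank fractions r (sample) and
r₀ (background compendium), scaled so 0 is the highest-expressed feature,
the relative rank is (r₀ − r)/r₀ for r < r₀ and (r₀ − r)/(1 − r₀) for
r > r₀, 0 at r = r₀ — positive when the feature is expressed higher in
the sample than in the background. Features with r₀ exactly 0 or 1 are
computed by the non-degenerate branch and flagged with a warning.

**Treatment profiles.** Treated and vehicle groups must share a plate, so
any per-plate offset cancels exactly in the contrast (this holds for both
methods; the fold method works on ratios of intensities scaled by the same
per-gene plate factor). The `fold` method mirrors the disease contrast;
the `zscore` method uses Z = (m_t − m_c)/(SD_c·√(1/n_t + 1/n_c)), a
plate-control-referenced standardised difference, retained at |Z| > 3.
With triplicates SD_c has 2 degrees of freedom, so this Z is
t₂-distributed under the null and the |Z| > 3 filter retains ~9% of null
genes rather than the ~0.3% a Gaussian would suggest — profiles are
correspondingly noisy, which is the realistic operating regime for
triplicate screens and is what the enrichment statistics are calibrated
against. Multiple plate replicates of a drug are kept as separate
profiles.

## Connectivity scoring

**Concordance + enrichment.** Over the gene overlap of a categorical query
and a signed target, score = (n↑↑ + n↓↓ − n↑↓ − n↓↑)/total ∈ [−1, 1];
zero overlap yields a flagged undefined result, never an exception. The
enrichment probability is the exact Poisson-binomial upper tail of the
match count (computed by dynamic-programming convolution, O(n²), intended
for overlaps ≤ 10⁴; it reduces to the ordinary binomial tail for equal
probabilities). The tail is taken in the observed direction — over
matches when agreements dominate, over mismatches otherwise — and the
direction is recorded. Per-gene match probabilities default to the
uniform 1/2; `regulation_frequencies` derives a background table from any
profile database (each gene's up-call fraction among its calls), and the
end-to-end pipeline uses that table: a gene that the database calls
predominantly in one sense contributes correspondingly less surprise.
This frequency scaling materially improves the specificity of hit
selection — with the uniform background, small-overlap chance
anti-correlations reach p < 0.05 at roughly the nominal rate and, with
~45 non-reverser drugs, typically produce a spurious hit; frequency
scaling removes them because the planted signature genes are exactly the
ones the database regulates consistently.

**Regression Z.** Continuous profile pairs are compared by ordinary least
squares of one profile on the other over their overlap; the slope's
two-sided p maps to a signed, capped Z. Overlaps below 4 genes or a
zero-variance side are undefined (NaN with a warning), and are skipped by
`set_correlation_summary`.

**Rank queries.** Profiles are ordered by score (ascending for
anti-correlation), ties broken lexicographically by drug name for
reproducibility, undefined-overlap profiles placed last and flagged.

**KS rank enrichment.** For m hits among N ranks, D is the maximal
positive deviation of the cumulative hit fraction from the diagonal,
max_i (i/m − r_i/N) — one-sided, enrichment toward top ranks only. The
null redistributes the m hits uniformly (seeded generator);
p = (1 + #{D_perm ≥ D_obs})/(n_perm + 1), the add-one estimator, which is
never zero and has floor 1/(n_perm + 1). Under the null this p is uniform
up to the discreteness of the estimator, verified by a goodness-of-fit
test in the suite.

## Consensus analysis

Hit compounds are drugs with ≥ `min_signatures` (default 2) defined
results having score < 0 and enrichment p < α. Selection is monotone:
shrinking α or raising the threshold never adds drugs. The consistently
regulated cohort uses the sum-sense-change ratio (1/P)Σ sign(g_i), absent
genes counting 0, kept when |ratio| strictly exceeds 1/3. UPGMA
(average-linkage) clustering uses 1 − concordance score by default
(1 − Pearson optionally); pairs with no usable overlap get the maximum
distance 2 with a warning. Merge heights follow the ultrametric
convention — half the average inter-cluster distance — so two profiles at
distance d join at height d/2, and heights are non-decreasing by
construction (asserted on every dendrogram). Over-representation of gene
cohorts uses the hypergeometric upper tail per set with
Benjamini–Hochberg adjustment across sets; both choices are the field's
defaults for categorical ORA.

## Synthetic data: what it emulates, what it does not

Expression is Gaussian on the log2 scale (SD 1) around gene-specific
baselines (mean 7, SD 1) — i.e. log-normal intensities, the standard
microarray picture. Effects are shifts in units of the noise SD; plate
effects are additive per-plate, per-gene offsets (SD 0.5) shared by every
sample on a plate; non-reverser drugs perturb random gene sets of the same
size as a reverser's target set, with random signs, so database queries
are tested for specificity as well as sensitivity. All generators take an
explicit seed and are bit-reproducible; no global random state is used.

Default study conditions: disease studies of 1000 genes with a 50-up/
50-down signature at 3 noise-SD and 5 control vs 5 disease samples (the
regime where two-sample *t* power at α = 0.05 is ≈ 0.97, so ≥ 90% planted
recovery is expected with margin); stage series of 40 samples over stages
0–3; screens of 50 drugs, 5 reversers at reversal fraction 0.8 and effect
3, in triplicate over 5 plates. Null-calibration checks use 10⁴ genes,
where the 99% binomial band around 5% retention is ±0.56 percentage
points. These sizes keep a full screen under ~10 s while leaving every
statistic in its calibrated regime; the acceptance script re-runs them at
exactly these sizes.

Deliberately not modelled: probe-level intensity files and RMA
normalisation (inputs are normalised matrices), sequencing counts,
heteroscedastic or correlated gene noise, dose–response and
treatment-duration effects, batch structure beyond the additive plate
offset, and any annotation/ID translation (gene identifiers are opaque
strings). Passing tests therefore demonstrate the statistical machinery
is correct and calibrated under the stated noise model — not that the
pipeline is robust to the full messiness of real array data (probe
cross-hybridisation, batch-confounded designs, outlier samples).

## Known limitations

* The Poisson-binomial tail is exact but O(n²); overlaps far beyond 10⁴
  genes would need a different algorithm (FFT or normal approximation).
* The KS null assumes exchangeable ranks; if a database contains many
  near-duplicate profiles the effective universe is smaller than N and
  the p-value is anti-conservative.
* `regulation_frequencies` estimated from a small database is itself
  noisy; with very few profiles the uniform background is the safer
  choice.
* The stage regression is a fixed-effects model; series with strong
  within-subject correlation would need a mixed model, which is out of
  scope.
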