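# Methods

This note documents the statistical models, the numerical choices, and the
design decisions behind `lesionflora`, in the spirit of a package vignette.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Sampling model and vocabulary

The sampling unit is a *foliar lesion* ("sample"); a *fungal record* is the
isolation of one fungal taxon from one lesion. Taxa are observed at two
ranks: morphologically identified **genera**, and fingerprint-delineated
**MOTUs** (molecular operational taxonomic units, a species proxy) with
**genomic types** (GTs) nested inside them as strain proxies. All
statistics consume a samples × taxa count matrix at one of these ranks.
Lesions from the same tree are treated as independent samples; `tree_id`
is carried in the metadata so a sensitivity analysis at the tree level
remains possible.

## Fingerprint taxonomy

Profiles are fixed-grid band-intensity vectors (uniform bins spanning
200–3500 bp). Percent similarity is 100 × the Pearson correlation of two
vectors; negative values are kept (the dissimilarity scale 100 − S runs to
200). The two primers' similarity matrices are combined by **element-wise
averaging** before clustering. The averaging choice is a genuine design
decision: composite-experiment software does not document its mechanism,
and averaging is order-preserving, symmetric, and lets bands resolved by
either primer contribute discriminating signal; the per-primer matrices
remain available if a different consensus is wanted.

UPGMA is implemented directly (average-linkage Lance–Williams update) so
that tie-breaking is deterministic: among merges tied at the minimum
dissimilarity, the pair whose member labels sort first lexicographically
is merged. The implementation is cross-checked in the tests against a
brute-force average-linkage oracle (all sizes n ≤ 6) and against scipy's
`linkage(method="average")`. Cutting the single consensus dendrogram at
65 / 75 / 85 % yields genus clusters / MOTUs / GTs; because one ultrametric
tree is cut three times the partitions are nested by construction (and
tested).

Reproducibility: re-running 10 % of isolates per primer gives a per-primer
mean duplicate similarity; the overall cut-off is the mean of the two, and
a conservative floor of 95 % is used operationally. The **isolation
redundancy coefficient (IRC)** groups records by (genus, lesion), links
pairs at ≥ 95 % consensus similarity, and counts each connected component
of size k as k − 1 redundant records — components rather than raw pairs so
transitive redundancy is not double-counted. IRC = 100 × redundant / total
records. Whether the 95 % linkage should use consensus or per-primer
similarity is not externally fixed; the consensus is the default and the
threshold is a parameter.

## Diversity indices

Shannon diversity is computed as the standard positive entropy
H′ = −Σ pᵢ log₁₀ pᵢ (common logarithm, so H′max = log₁₀ S and
J′ = H′/log₁₀ S ∈ [0, 1]). Fisher's α solves
S/N = [(1 − x)/x][−ln(1 − x)] by bisection-safe Brent root-finding on
x ∈ (10⁻¹², 1 − 10⁻¹²) to 10⁻¹⁰, then α = N(1 − x)/x; the inverse identity
α ln(1 + N/α) = S is verified to 10⁻⁶ in the tests. Abundance classes use
half-open intervals with the upper bound in the lower class: rare (0, 1],
infrequent (1, 2], frequent (2, 5], very frequent (5, 100]. AO/FO are kept
at full precision internally and rounded to two decimals only in exports.

## Species abundance distributions

Five models are fitted to the vector of per-taxon counts:

* **logseries** — zero-truncated pmf P(n) = −xⁿ/(n ln(1−x)); the free-ML
  estimate of x coincides with the Fisher (S, N) solution.
* **lognormal** — continuous lognormal density on untransformed counts;
  the ML (μ̂, σ̂) are the mean and population SD of log n. A
  Poisson-lognormal would treat the discreteness properly; the continuous
  form is the simpler reading and the choice is isolated in one function.
* **geometric series** — Motomura's rank model: rank i receives a share
  ∝ k(1−k)^{i−1}; the likelihood is the multinomial of the ranked counts
  over those shares, maximised over k by bounded 1-D search.
* **broken stick** — no free parameters; rank shares
  (1/S) Σ_{j≥i} 1/j, same multinomial likelihood.
* **neutral mZSM** — metacommunity zero-sum multinomial,
  S(n) ∝ (θ/n)(1 − n/J)^{θ−1} with J pinned to N, normalised over
  n = 1..J−1 and maximised over θ on a log scale. The information
  criteria charge this fit k = 2 data-determined quantities (θ and J).
  This accounting matters: the mZSM converges to the logseries as J → ∞,
  so with equal parameter counts the two models tie on logseries-like
  data and model selection between them would be a coin flip; charging
  the zero-sum constraint as a parameter is consistent with how
  dispersal-limited neutral fits are scored in community SAD comparisons.

Note the two likelihood conventions: per-species abundance likelihoods
(logseries, lognormal, mZSM) versus per-individual rank-multinomial
likelihoods (geometric, broken stick). The rank models' likelihoods are on
a much larger scale, so cross-family ΔAIC values are indicative only; in
practice the even-abundance rank models are so far from lesion-community
data that the ordering is unambiguous.

AICc uses n = S (number of taxa) as the sample size —
AICc = −2ℓ + 2k + 2k(k+1)/(S−k−1) — and BIC uses k ln S. Akaike/Schwarz
weights are exp(−Δᵢ/2)/Σ exp(−Δⱼ/2); a model is flagged best only when the
gap to the runner-up exceeds 2.

Goodness of fit: Pearson χ² compares observed taxa per Preston doubling
octave (1, 2–3, 4–7, …, left-inclusive) with S × the model's class
probability (for the rank models, with the count of predicted rank
abundances falling in each octave), pooling octaves right-to-left until
every expected count is ≥ 1; degrees of freedom are classes − 1 − k
(floored at 1). The KS statistic compares the empirical abundance CDF with
the model CDF on the model's support, with the continuous-null p-value —
conservative for discrete data, which suits its accept/reject role. The
tests verify by simulation (200 replicates) that a model fitted to its own
data is accepted (p > 0.05) in ≥ 90 % of cases and that a grossly wrong
model is rejected.

## Richness extrapolation

Accumulation curves resample whole lesions (1000 permutations by default,
seeded) and report mean richness with 2.5/97.5 percentile bounds per
number of samples. Chao1 uses the small-sample multiplier,
Ŝ = S + ((N−1)/N) f₁²/(2f₂), with the f₁(f₁−1)/2 fallback at f₂ = 0; the
classic form sits behind a flag. ACE uses the standard rare/abundant split
at 10 records with coverage C = 1 − f₁/N_rare and the γ² ≥ 0 CV term,
falling back to Chao1 when every rare taxon is a singleton. Jackknife
(first and second order) and bootstrap are **incidence-based**
(sample-oriented, consistent with the accumulation curves); Chao1 and ACE
are **abundance-based**. Mixed families are deliberate: the estimator
families follow the data each formula naturally consumes, and published
genus-level values from the rare-tail counts are reproduced exactly only
by Chao1, which is therefore the only estimator held to an exact external
value in the tests. Standard errors and CIs come from a 200-replicate
bootstrap over samples (analytic SEs of the various software
implementations are not documented well enough to reproduce).

Asymptote fitting: five self-starting nonlinear models (asymptotic
regression, 3-parameter logistic, Lomolino, Michaelis–Menten, Weibull) via
least squares with heuristic starts (asymptote start = 1.1 × final
richness, midpoint = median sample count); non-converging models are
skipped and reported. Gaussian residual log-likelihood (with the residual
variance counted as a parameter) feeds the same AICc/BIC + Δ>2 machinery.

## Co-occurrence

For taxa occupying n₁ and n₂ of M samples the shared-sample count is
exactly hypergeometric. Tails are inclusive of the observed value:
p_gt = P(j ≥ j_obs), p_lt = P(j ≤ j_obs); no continuity correction. Pairs
expected to share < 1 sample (n₁n₂/M < 1) are filtered as untestable;
remaining pairs are positive (p_gt < α), negative (p_lt < α), else random.
No multiple-testing correction is applied by default, matching the
model's standard usage; a Benjamini–Hochberg option exists. The exact
tails are validated against 100 000-draw permutation nulls (within 3
Monte-Carlo SEs) and full enumeration for M ≤ 6, and the discrete test's
type-I behaviour is confirmed conservative (< 7 % positive calls at
α = 0.05 under independence).

## Community comparison

Bray–Curtis dissimilarity is computed on square-root-transformed counts
(damping dominant taxa); samples with fewer than 5 records are excluded
before testing (configurable). PERMANOVA uses Anderson's distance-based
decomposition; SS_total = SS_within + SS_among holds by construction and
is cross-checked against PCoA coordinates. The permutation scheme is free
permutation of sample labels, which is equivalent to residual permutation
under a reduced model for the one-factor designs used here; p = (1 +
#{F* ≥ F})/(1 + n_perm), with exhaustive enumeration available for tiny
designs. Pairwise group tests are Bonferroni-adjusted. The pseudo-F is
cross-checked against scikit-bio's `permanova` in the tests.

Dispersion homogeneity (PERMDISP) embeds the distance matrix by principal
coordinates and compares distances to group centroids by ANOVA F with
permutation of those distances; negative eigenvalues contribute through
the imaginary-axis correction (real-part minus imaginary-part squared
distances, floored at 0). Cross-checked against scikit-bio's `permdisp`.

Kruskal–Wallis is tie-corrected (scipy); Dunn's z uses the pooled
tie-corrected variance with two-sided normal p-values and a Bonferroni
multiplier equal to the number of pairs. For two groups the KW p-value
equals the two-sided Mann–Whitney normal approximation with ties, which
the tests assert as an equivalence oracle.

Host-level clustering applies the same UPGMA engine to Euclidean distances
between host AO profiles (via a 100 − d pseudo-similarity wrapper); the
cophenetic correlation c is the Pearson correlation between original and
tree-implied distances.

## Synthetic-data generator

The generator reproduces the survey's statistical structure so the
pipeline can be exercised with known ground truth. Defaults are the study
conditions and are not tuning knobs:

* **Pool**: Fisher's logseries with α = 106 and N = 2064 — the α implied
  by the survey totals (320 MOTUs in 2064 records). S = round(α ln(1+N/α))
  species draw iid logseries counts, then single records are moved
  (weighted, never emptying a species) until the total is exactly N, so
  realised (S, N) recover α exactly.
* **Genera**: an abundance-weighted restaurant process inserts MOTUs from
  most to least abundant; a MOTU joins an existing genus with odds
  ∝ genus record total and ∝ its own abundance (concentration 500, genus
  size capped at 17 MOTUs). This concentrates dominant MOTUs into a few
  speciose genera, giving ≈ 90–120 genera of which > 80 % are rare
  (≤ 1 % of records) — the survey's structure. Assemblage types are
  assigned per genus by deficit-weighted sampling toward record shares of
  0.56 / 0.39 / 0.04 / 0.008 / 0.002 (coelomycetes … zygomycetes).
* **Sampling design**: 9 palm hosts with 32/31/19/14/13/12/8/3/2 lesions
  (134 samples), lesion types drawn at the observed frequencies
  (TDB 0.49, LLS 0.16, SLS 0.18, PP 0.17), lesions nested in trees. Every
  pool record is placed, so realised totals are exact. Each taxon draws a
  Dirichlet host-preference (concentration 8 × host shares; smaller =
  stronger host fidelity) and a weaker lesion-type preference
  (concentration 40). Within a host, records spread over lesions with
  weights combining a truncated-Gamma per-lesion capacity (shape 0.25,
  cap 2.0) and a Gamma clumping factor whose shape grows with log
  abundance (0.10 × (1 + 0.6 ln n)). These four numbers were calibrated
  once against the survey's per-lesion richness histogram (median 5
  MOTUs per lesion, long upper tail) and then frozen. Empty lesions are
  topped up with one record from the richest same-host lesion, since the
  design contains only colonised lesions.
* **Redundancy**: 6.54 % of records (the survey's IRC) are converted into
  re-isolations of an organism already recorded in the same lesion; the
  affected record ids are the ground truth for IRC recovery.
* **Fingerprints**: per primer, profiles are sums of nested sparse
  components (genus + MOTU + GT + organism) plus per-measurement noise
  over 400 bins, with component variances chosen so expected similarities
  interleave the cut-offs: same genus ≈ 70 %, same MOTU ≈ 82 %, same GT
  ≈ 90 %, same organism (duplicates and redundant isolations) ≈ 96 %.
  A constant baseline keeps intensities non-negative (clipping at zero is
  negligible at these scales). 10 % of records receive duplicate re-runs.

What the generator does **not** emulate: gel-level artefacts (lane
distortion, molecular-weight calibration error), phylogenetic structure in
host specificity, seasonal or spatial autocorrelation, and taxon-specific
culturability bias. Passing recovery tests therefore demonstrates that the
pipeline is correct and well-calibrated under the stated stochastic model,
not that real fingerprint data are this clean; on real gels the
reproducibility ceiling, not the generator's margins, limits MOTU
resolution.

## Problem sizes used in the checks

Statistical properties are verified at sizes chosen to make the checks
sharp yet quick on a single CPU: exact-vs-Monte-Carlo co-occurrence tails
at M ≤ 20 with 100 000 draws; Fisher-α recovery over 50 Poisson-process
communities at N ≈ 2000; SAD model selection over 100 logseries
communities at the survey scale (α = 47-style, N = 2064); MOTU-recovery
ARI on a 400-record subsample of the default simulation (full-size
clustering of all 2064 records is quadratic-to-cubic and adds nothing to
the check); PERMANOVA and Kruskal–Wallis type-I error over 500 null
simulations of 24–30 samples with 199 permutations (at which the
permutation p-value grid makes the nominal 0.05 level exact); brute-force
UPGMA and hypergeometric oracles exhaust all sizes n ≤ 6.

## Known limitations

* The consensus mechanism (averaging similarities) and the IRC similarity
  basis (consensus vs per-primer) are documented choices, not externally
  fixed facts; both are configurable.
* The continuous lognormal ignores discreteness at abundance 1–2 and its
  AICc is therefore slightly optimistic for rare-tail-heavy data.
* Analytic standard errors for richness estimators are not implemented;
  uncertainty is bootstrap-only.
* PERMANOVA here is single-factor; nested or multi-factor designs (e.g.
  host × lesion type) are out of scope.
* The per-taxon Dirichlet host tilt induces exchangeable host preferences;
  it cannot represent trait-mediated host specialisation shared by related
  taxa.
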