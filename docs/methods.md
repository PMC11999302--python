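# Methods

## Index construction

`svikit` builds a composite vulnerability ranking of small areas (census
tracts, small areas, sezioni) for one hazard at a time. The construction is
deliberately simple — its intended users are local-authority staff, not
statisticians — and every stage is inspectable:

1. **Hierarchy.** A YAML document declares indicators, their domains, the
   domain→dimension mapping, each indicator's vulnerability direction, and
   whether it is required for its domain to be considered complete. The
   three dimensions are fixed: sensitivity, adaptive capacity and enhanced
   exposure. Adaptive-capacity sub-abilities (prepare / respond / recover)
   are carried as reporting metadata only; they are never an aggregation
   level, because the weighting operates on domains.
2. **Normalization.** Every indicator column is z-scored,
   Z = (x − μ)/σ, with σ the *sample* standard deviation (ddof = 1). The
   convention is recorded per column in `normalization_params`, so either
   convention can be reproduced downstream; because a z-score is invariant
   to positive affine rescaling of the raw column, the percent-vs-proportion
   ambiguity of land-cover shares has no effect on scores (a test asserts
   this). Direction alignment negates the z-columns of
   vulnerability-reducing indicators (tree cover, volunteering), which is
   equivalent to negating the raw values before standardizing.
3. **Tiering and weighting.** The availability profile counts, per domain,
   the m indicators present and usable, and flags *depleted* domains:
   missing required indicators relative to the declared design, or reduced
   to one indicator out of a multi-indicator design. A domain *designed*
   with a single indicator is not depleted — depletion is always relative to
   design, otherwise complete single-indicator domains (e.g. Mobility in the
   flood preset) would poison an otherwise ideal configuration. Tier
   precedence is 4 > 3 > 2 > 1: a dimension with zero available domains
   forces tier 4; exactly one available domain forces tier 3; any depleted
   domain forces tier 2. Weights are W = 1/m per indicator, halved to
   1/(2m) inside depleted domains under tiers 2–3. Tier 3 is numerically
   identical to tier 2 — its meaning is a mandatory robustness caveat, not a
   different formula.
4. **Aggregation.** The SVI is the **sum** of domain scores (not their
   mean), so dimension scores partition the index exactly. A consequence is
   that configurations with more domains span wider score ranges — one of
   the reasons scores are never comparable across configurations or cities.
5. **Classification.** Default: the SVI is internally standardized and cut
   at ±0.5, ±1.5, ±2.5 into seven bands labelled *extremely low* …
   *extremely high*; intervals are left-closed/right-open, so boundary
   values classify deterministically. Quantile (septile) breaks are the
   alternative; there, class boundaries are value-based, so tied scores
   always share a class (keeping classification monotone in the score), and
   an all-equal score vector is rejected as degenerate rather than
   arbitrarily split.

## The tier-4 fallback

When a whole dimension is unrepresented, no reweighting can fake the
missing information, and the hierarchical index is abandoned: the
correlation matrix of the aligned z-scores is eigendecomposed, component k
receives weight λₖ/p (its proportion of total variance), and the composite
is the weighted sum of component scores over the retained set. Choices
made where the procedure is underdetermined:

- **Retention:** smallest leading set of components reaching 80 %
  cumulative variance, configurable; retaining everything is supported (the
  composite is then a full variance-weighted combination).
- **Sign orientation:** eigenvector signs are arbitrary, so each component
  is flipped to make its loading sum non-negative (first nonzero loading
  positive on an exact tie). Since most indicators point toward
  vulnerability after alignment, this orients the composite the same way.
- **Weighted sum vs weighted mean:** implemented as the weighted sum of
  retained components, with a normalize-to-mean option; the ranking — the
  decision-relevant output — is identical.

The output is flagged "not a Social Vulnerability Index" end to end,
mirroring how the tier is meant to be communicated to decision makers.

## Missing data

Three policies: `error` (abort, naming the first offending cell),
`median_impute` (column medians, imputed cells listed), and the default
`renormalize_weights`, which leaves values untouched and rescales each
domain's weights per area over the indicators observed for that area so the
domain's weight sum is preserved. Renormalization is the default because
imputation invents data, while renormalization only reallocates trust within
a domain; an area observing nothing in a domain contributes 0 there and is
flagged. The tier-4 PCA path needs a complete matrix, so under the
renormalize policy the pipeline median-imputes for that path only and
records a caveat.

Columns that are entirely missing or constant are treated as unavailable at
profiling time (they carry no ranking information and have undefined
z-scores); at normalization time a constant column is an error by default,
since it usually signals a data-preparation mistake, with an explicit
drop-with-warning policy available.

## Synthetic data

The generator draws a latent vulnerability L ~ N(0,1) per area and emits
indicator j as s_j·λ_j·L + ε with ε ~ N(0, noise_sd²), s_j = −1 for
vulnerability-reducing indicators. Defaults — 500 areas, loading 0.8,
noise sd 0.6 — give indicators correlating 0.8 with the latent factor, a
strong-but-noisy census-proxy regime. The optional
`logistic_percent` transform (100/(1+e^(−x))) moves values onto a
census-like percent scale; it is monotone but *not* affine, so z-scores do
change — tests assert rank stability (Spearman ≥ 0.99 between SVIs with and
without the transform on the default conditions) rather than score
identity. Degradation scenarios delete columns to reproduce each tier's
data situation: named required indicators (tier 2), all but one domain of a
dimension (tier 3), or a whole dimension (tier 4).

What the generator does *not* emulate: spatial autocorrelation of the
latent field, correlated indicator noise, heterogeneous per-indicator
loadings within one run (unless passed explicitly), or population-size
heteroscedasticity of census rates. Passing recovery tests therefore show
that the pipeline's arithmetic preserves a latent ranking under independent
noise — not that any real census table has a one-factor structure.

## Problem sizes and numerics

Tests and the acceptance script run on simulated tables of 50–500 areas,
sizes at which every stage is effectively instantaneous and which already
exceed the statistical needs of the properties being checked (rank
correlations stabilize well below n = 500). Exactness claims (weight sums,
oracle equivalence against a naive double-loop evaluation, affine
invariance) are asserted at 1e-12–1e-15; statistical claims (latent
recovery ρ ≥ 0.9 tier 1, ≥ 0.85 tier 4 at the default generator
conditions with seed 42) were frozen from an oracle run before release.
Correlation matrices are symmetrized and clipped to [−1, 1] before
eigendecomposition (`numpy.linalg.eigh`), and eigenvalues clipped at 0, to
keep closed-form degenerate cases (duplicated columns) exact.

## Known limitations

- Scores are relative within one analysis; no cross-city comparability.
- Spatial I/O is GeoJSON only; no reprojection (geometries and CRS pass
  through untouched).
- No outlier handling or winsorization — cleaning is upstream work.
- The PCA-duplication robustness property (duplicating a column disturbs
  the tier-4 ranking less than it disturbs an equal-weight mean) is a
  strong tendency at the default generator conditions, not a theorem; with
  few indicators or near-threshold retention it can invert.
- The ordinal class boundaries are a convention; the field uses both
  sd-bands and quantiles, and the choice visibly changes maps. Both are
  provided, neither is privileged.
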