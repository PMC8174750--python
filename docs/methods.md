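# Methods

This note documents the statistical procedures implemented in
`mycoassembly`, the defaults they ship with, the design choices that
were genuinely open, and what the synthetic-data tests do and do not
demonstrate about real data.

## Data model

Count tables are samples × ASVs with nonnegative integer entries;
readers accept either orientation and normalize to samples-as-rows.
Rarefaction draws a multivariate hypergeometric sample per row
(subsampling without replacement), so every retained sample sums
exactly to the requested depth; samples below the depth are dropped and
reported, never padded. Taxon aggregation sums columns within a rank
label and conserves row totals exactly. Unclassified ranks use the
literal token `unclassified`; taxonomy label matching is
case-insensitive. All stochastic operations take an explicit seed (int
or `numpy.random.Generator`); there is no global random state.

## Diversity and transforms

* Shannon index on natural logs (base configurable); zero for a sample
  dominated by a single taxon.
* clr transform: counts + pseudocount (default 1), closed to
  proportions, log-centered per sample. The pseudocount is a
  convention, not an estimate; Aitchison distances depend on it for
  sparse tables.
* Hellinger transform: square root of proportions.
* Bray–Curtis is computed on raw counts by default (the convention of
  the ordination stacks this mirrors); a proportion-based variant is a
  flag. For rarefied tables the two coincide up to scale.
* PCoA is classical scaling of the Gower-centered matrix −½·J·D²·J by
  dense symmetric eigendecomposition. Axes are returned for positive
  eigenvalues; negative eigenvalues are reported unmodified (Cailliez
  correction available but off by default, so coordinates correspond to
  the distances actually supplied).

## Permutation tests

All permutation p-values follow the add-one convention
p = (1 + #{stat* ≥ stat}) / (1 + B), one-sided on the test's natural
direction, with a relative tolerance of 1e−9 when counting ties.
`exact=True` enumerates all n! label permutations (guarded to n ≤ 8);
the identity permutation is then part of the reference set and the
plain fraction is reported. Permutation is unrestricted label
exchange — the sampling designs targeted here are single-factor — with
group sizes held fixed.

* Kruskal–Wallis: H on midranks with the standard tie correction;
  degenerate all-equal input returns H = 0, p = 1.
* Dunn post hoc: pairwise z on mean ranks with tie-corrected pooled
  variance, Bonferroni over all pairs (the only built-in adjustment, by
  design).
* PERMANOVA: Anderson's pseudo-F from within/between sums of squared
  distances, computed directly on the distance matrix. Pairwise
  follow-ups subset the matrix per pair and Bonferroni-adjust.
* PERMDISP: distances to group centroids are computed from the Gower
  matrix itself, d²(i, c_g) = G_ii − 2(Gv)_i/n_g + v'Gv/n_g², which
  carries the negative-eigenvalue correction (imaginary-axis
  contributions subtract) without forming coordinates. The F statistic
  is one-way ANOVA on these distances. The permutation scheme
  *recomputes* the centroid distances for every relabeling (permuting
  the Gower matrix), because permuting fixed distances — which were
  measured from the observed grouping's own centroids — is mildly
  anticonservative (type-I ≈ 0.07 at n = 16 in our null simulations vs
  0.04–0.06 for the recomputing scheme). Centroids are group means, not
  spatial medians. Tukey HSD on the centroid distances serves as the
  post hoc comparison.

## Distance decay

Geographic distances use the Haversine formula on a sphere of radius
6,378.137 km (configurable); same-site samples are at distance 0.

* Mantel: Pearson (default) or Spearman correlation of the condensed
  upper triangles; permutation relabels one matrix's rows and columns
  jointly; one-sided greater.
* Mantel correlogram: distance classes from Sturges' rule on the pair
  distances (override with `n_classes`); per class, the statistic is
  the negated Pearson correlation between the community matrix and the
  class-membership indicator, so positive r means within-class
  similarity. Class tests are two-sided (the correlogram convention),
  corrected progressively: class k is Holm-adjusted among the first k
  tested classes. Classes whose midpoint exceeds half the maximum
  distance are reported but untested.
* MRM: OLS on the unfolded pair vectors; p-values permute the response
  matrix and refit — two-sided on coefficients, one-sided on R².
  Collinear predictors abort with the design-matrix condition number.
* Zero-distance masking: pairs at zero geographic distance are removed
  from the correlation; the permutation still relabels whole samples
  (never individual pairs), and the retained-pair correlation is
  recomputed per relabeling, so the null respects the matrix structure.
  This is our resolution of a detail the underlying procedure leaves
  unstated.

## Abundance-occupancy core

Computed on a table rarefied to a common depth (enforced). Per ASV:
mean relative abundance p̂, its standard error across samples,
occupancy (fraction of samples with a detection), and site consistency
(fraction of sites with ≥ 1 detection). Ranking score is
½·(occupancy/max) + ½·(site consistency/max), ties broken by
descending abundance then ASV id; the weights are configurable because
the composite index in the literature this follows is not fully
specified.

The contribution curve divides the mean pairwise Bray–Curtis of each
ranked prefix by the full-table mean. By default each pair's
denominator is the *full-table* read total, which makes the curve
additive in taxa and monotone from ~0 to exactly 1 — each rank's
percent increase is then that taxon's share of the community's
turnover, and the 10% final-percent-increase rule cuts the ranking
where marginal taxa stop mattering. The literal subtable Bray–Curtis
(`denominator="subset"`) is available but is not additive: a single
dominant variable taxon can already carry a ratio near 1, after which
percent increases are uninformative. Core = ranks 1…k*, where k* is
the last rank with percent increase ≥ the threshold; rank 1 is always
included.

## Sloan neutral fit

`N` defaults to the common depth of the rarefied table; the detection
limit is d = 1/N. The single parameter m is estimated by bounded
scalar least squares (m ∈ (10⁻⁶, 1], Brent-style bounded minimization,
xatol 10⁻⁹) of observed occupancy against
1 − BetaCDF(d; N·m·p̂, N·m·(1 − p̂)), unweighted across taxa on the
untransformed occupancy scale. R² is 1 − SS_res/SS_tot about the mean
observed occupancy and may be negative when the occupancy pattern
anti-correlates with the neutral expectation (as real sediment
communities can).

The 95% band around each prediction starts from the Wilson score
interval with n = number of samples. Because the curve is evaluated at
the *estimated* abundance p̂, whose sampling error is substantial for
rare taxa, the band additionally propagates that error: the prediction
is evaluated at p̂ ± 1.96·SE and the resulting half-widths are combined
with the Wilson half-widths in quadrature (the two error sources are
independent). On fully neutral simulations the plain Wilson band flags
~15% of taxa as deviating; the combined band flags 2–4%, matching the
nominal rate. `abundance_error=False` restores the plain band.

Deviation labels require strict exceedance of the band; boundary
equality is neutral. A caveat worth knowing: predicted occupancy is
monotone in m only for taxa at or above the detection limit. For
p < 1/N, strong immigration pins the taxon's abundance below d and the
predicted occupancy eventually *declines* with m; this is a real
property of the model, not a numerical artifact.

The Table-style summary join reports every ASV that is in ≥ 1 core and
significant in ≥ 1 differential-abundance comparison at adjusted
p < α (default 0.05), listing core memberships, per-core deviation
labels in core order, and comparison directions from the sign of the
log₂ fold change. Differential-abundance results are consumed as an
input table; the package does not reimplement the underlying
negative-binomial test.

## Synthetic data generator

`simulate_neutral_samples` is the exact sampling dual of the fitted
model: composition ~ Dirichlet(N·m·p), reads ~ Multinomial(N). The
marginal per-taxon relative abundance is Beta(N·m·p, N·m·(1−p)), so
the generator/fit pair forms a closed loop: `fit_sloan` applied to
generator output must recover m. The exact detection probability under
this dual is the Beta-binomial zero-class 1 − B(a, b+N)/B(a, b)
(`exact_occupancy`); the fit uses the conventional BetaCDF(1/N)
approximation, which differs by < 0.05 in occupancy over the relevant
range — the duality test compares against the exact form so that its
tolerance is purely binomial.

`simulate_study` reproduces a global survey's geometry: 16 real
coastal site coordinates spanning two ocean basins, 12 individuals per
site, three sample types (leaf/root/sediment), 576 samples. Site
metacommunities derive from one global log-normal pool by adding a
Gaussian log-abundance field whose between-site correlation is
exp(−distance/decay_scale) (Cholesky of the site–site kernel), which
induces the distance decay of community similarity the Mantel stack
tests — turnover is generated by metacommunity perturbation, not by
simulating dispersal. Planted structures provide classification ground
truth: "selected" taxa at a low fixed count in every sample
(occupancy 1, low abundance → above the band), "dispersal-limited"
taxa at 20% abundance in the samples of exactly one site (high
abundance, low occupancy → below), with row totals restored by
re-rarefaction. A handful of nonfungal host taxa on leaves exercise
the domain filter.

Defaults (chosen once, as the study conditions the generator emulates):
N = 5,000 reads/sample (the mean post-filter depth such surveys
report), migration rates per type leaf 0.001 / root 0.002 / sediment
0.001, log-normal σ = 3 (μ cancels on normalization), 600 taxa,
decay_scale 2,000 km, site log-field σ = 1, 5 planted selected + 5
dispersal-limited taxa. 600 taxa rather than the several thousand of a
real survey keeps the full design fast while preserving the rank-
abundance shape; the per-type read-depth raggedness of real data
(2–82,870 reads) is *not* emulated — rows are exactly N.

`simulate_core_community` provides ground truth for core recovery: 10
driver taxa over a sparse neutral background, with a strict occupancy
staircase (driver j absent from 2(j−1) samples) so the ranking orders
them deterministically, and rising per-sample variability plus
geometric weight growth so each driver contributes ≥ 10% to the
contribution curve while each rare background taxon contributes a
sliver.

What passing these tests shows: the estimators are consistent with
their own model, calibrated under the null, and able to recover planted
truth at realistic design sizes. What they do not show: robustness to
compositional artifacts of real sequencing (primer bias, chimeras,
variable depth), to taxa violating the single-metacommunity assumption,
or to confounding between dispersion and location in unbalanced
PERMANOVA designs — the dispersion test is reported alongside precisely
because the location test cannot distinguish these.

## Problem sizes in the test and acceptance suites

Parameter recovery runs at 180 samples × 5,000 reads × 2,000 taxa
(m = 0.001) and 150 × 5,000 × 1,000 (m = 0.014); observed relative
errors are ≤ 5% and ≤ 15% across seeds. Calibration uses 20 seeds of
150 × 1,000 × 500 taxa at m = 0.005. Type-I control uses 500 null
replicates of n = 16 with 199 permutations per test, rejecting at the
exact attainable level p ≤ 0.05 = 10/200. Exhaustive-enumeration
equivalence is checked at n = 5–6 against brute-force oracles written
independently in the tests.

## Known limitations

* Single-factor permutation designs only; no strata/nested PERMANOVA.
* No phylogeny-aware metrics (no tree in the target analyses).
* The Sloan fit assumes one shared metacommunity per fitted table; fit
  site-structured data per habitat, not pooled, or m will absorb the
  between-site variance (visible in the worked example, where the
  leaf-table fit returns m ≈ 0.005 against a within-site m of 0.001).
* Bray–Curtis core contributions use the additive full-denominator
  convention by default; results are not comparable across the two
  denominator conventions.
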