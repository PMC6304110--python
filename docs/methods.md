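# Methods

## Analysis units and size correction

All between-community metrics are inter-specific, so specimens are
aggregated to species means first (per site; missing measurement cells are
excluded pairwise). Size correction fits one ordinary least-squares
regression per trait, `trait = a + b·mass`, across the species of one
community and keeps the residuals; residuals therefore sum to zero and are
uncorrelated with mass by construction, which the test suite asserts to
1e-9 relative tolerance. Traits and mass are used untransformed — the
residuals model absolute (mm) deviations from the allometric expectation —
and the regression is per community, consistent with the per-community
PCA. An alternative specimen-level residual path
(`residual_level="specimen"`, residuals averaged to species afterwards) is
provided because the aggregation point is a genuinely open modelling
choice; the default is species-level because packing metrics count
species, not specimens. A trait needs at least three complete
(trait, mass) pairs; fewer is an error naming the trait rather than a
silently weaker fit.

## Morphospace and packing metrics

PCA operates on the covariance matrix of the residuals (all traits share
mm units, so correlation-matrix PCA would discard meaningful scale
differences; `scale_pca=True` switches). Scores are centred projections;
component signs follow a deterministic convention (the largest-magnitude
loading of each component is made positive) so repeated runs are
bit-identical. Rank-deficient input succeeds with zero-variance trailing
components and a warning, since dropping components silently would change
the reported explained-variance vector.

Each community is decomposed separately — hull areas from different
communities then live in different coordinate systems and are compared
only as areas, not overlaid. `joint_pca=True` places both communities in
one shared space when commensurable coordinates are wanted. Nearest
neighbour and centroid distances use the Euclidean metric in the full
retained component space (default k = 10, clipped to n − 1); the minimum
convex polygon is computed on the first two axes only, where the
explained variance concentrates and where an area is well defined without
a density assumption. Degenerate hulls (fewer than three points, or
collinear points) report area 0 with an explicit flag instead of raising.

Because the per-variant analysis (all species vs insectivores only)
refits the regression and the PCA, the insectivore hull can exceed the
all-species hull between coordinate systems; the subset-monotonicity
property (removing species cannot grow the hull) holds, and is tested,
within one coordinate system.

## Rank-sum test and rarefied bootstrap

The two-sided Wilcoxon rank-sum test uses the exact null distribution
when n₁ + n₂ ≤ 20 and the pooled sample is tie-free, otherwise the normal
approximation with mid-ranks, tie correction and continuity correction
(scipy's `mannwhitneyu` supplies both branches). The reported statistic
is the rank sum R₁ of the first sample together with the equivalent
Mann–Whitney U₁ = R₁ − n₁(n₁+1)/2, since different software traditions
print either. When U₁ sits exactly at its null mean the two-sided p is
reported as 1.

Richness control subsamples **without replacement** (rarefaction
semantics): with replacement, a 22-of-23 draw would duplicate species and
inject spurious zero nearest-neighbour distances. The classical bootstrap
is available behind `with_replacement=True`. Defaults are k = 22 species
and B = 500 replicates. Within each replicate the statistic is recomputed
from the subsample alone — the centroid is the subsample centroid — and
the two per-species vectors are compared by the rank-sum test. No single
adjusted p-value is produced; the replicate p-value distribution is
summarised by its median and the proportion ≤ 0.05. One master seed
spawns independent per-replicate streams (`numpy.random.SeedSequence`),
so results are bit-reproducible and replicate r can be regenerated alone.

## Isotope metrics

Species means are the default analysis unit (community metrics describe
inter-species structure); `level="specimen"` exists for intra-species
variability questions. Both δ axes are treated as commensurate
(1‰ δ¹³C = 1‰ δ¹⁵N), the standard convention for these metrics. CD is the
*mean* distance to centroid — the morphospace stage reports a median, and
the two deliberately differ because each follows the convention of its
own literature. TA reuses the same convex-hull primitive as the
morphospace MCP.

The Bayesian SEA uses the conjugate normal–inverse-Wishart model: prior
d.f. ν₀ = 3 (dimension + 1, the smallest proper choice), prior scale
10⁻³·I, prior mean at the sample mean with negligible weight. The
covariance posterior is then inverse-Wishart(ν₀ + n, 10⁻³·I + S) with S
the centred scatter matrix, sampled directly — no MCMC, hence
deterministic given the seed and free of convergence diagnostics. Each
draw maps to SEA = π·√det(Σ). The point summary is the histogram mode
(Freedman–Diaconis bins) and the 50/75/95% intervals are central
quantiles, nested by construction. For n large the posterior median
approaches SEAc (tested at n = 500 within 5%); for n near the minimum the
prior is vague enough that interval *relative* width, not absolute width,
is the meaningful concentration measure, and that is what the width
monotonicity test compares. Groups below `min_group_n = 3` species are
flagged `insufficient_n` instead of being forced through an ellipse fit
that would degenerate to a line segment.

The trophic enrichment factor defaults to 3.4‰ of δ¹⁵N per trophic level,
the conventional cross-taxon average; it is a parameter, not a constant.

## Synthetic data generator

The generator emulates exactly the structure the analysis assumes:
species trait means linear in body mass with guild offsets and normal
residuals, log-normal body masses per guild (bat masses span ~3 g to
>200 g, so a normal model would produce negative masses), independent
measurement noise per specimen, and per-guild bivariate-normal isotope
niches with specimen-level replicate scatter. Guild covariances must be
symmetric positive semi-definite (exactly singular covariances are
allowed so degenerate scenarios can be constructed deliberately).

The bundled fixture fixes the seed (180849) and mirrors the motivating
study system's shape: a forest community of 48 morphospace / 39 isotope
species across four guilds including seven fruitbats, and a savannah
community of 23 / 17 species with a single fruitbat, with forest guilds
given 4–8× larger δ¹³C variance. Its values are openly synthetic: the
fixture reproduces the qualitative contrasts (forest hull and CR larger,
forest NN smaller with fruitbats included) and the published species
counts, not any measured numbers.

What passing on synthetic data does *not* show: real communities violate
the generator's assumptions in known ways — allometries are closer to
power laws than lines, trait residuals carry phylogenetic signal so
species are not independent draws, guild isotope clouds are skewed and
heavy-tailed rather than Gaussian, and detection/capture bias structures
which species enter the sample at all. Results on real data therefore
depend on assumptions the tests cannot certify; the tests certify the
estimators and the plumbing.

## Numerical choices and problem sizes

Ties in the rank-sum test get mid-ranks; an all-constant pooled sample
returns p = 1. Hull degeneracy is detected by scipy's Qhull error rather
than a tolerance of our own. Trait values generated for specimens are
floored at 0.1 mm (physical lengths). Stochastic tests fix seeds and use
tolerances sized from the sampling distribution of the quantity under
test (e.g. √det of a 2×2 Wishart at n = 50 has ≈14% relative s.d., so
per-guild SEA recovery is asserted at 2.5σ with a tighter 15% band on the
guild-averaged ratio). The default test run uses B = 200–2000 bootstrap
replicates and 200–6000 posterior draws depending on what the test
measures; the acceptance script uses the full defaults (B = 500,
10 000 draws) plus a B = 2000 null-calibration run, and completes in well
under a minute.

## Known limitations

- Hull areas from per-community PCAs are not in a shared coordinate
  system (use `joint_pca` when that matters).
- No phylogenetic correction anywhere; species are treated as independent.
- No diet mixing models, tissue-discrimination corrections or
  ellipse-overlap statistics; niche breadth is descriptive.
- The d > 2 hull volume over all ten component axes is not implemented;
  area on the first two axes is the supported hull measure.
- The Bayesian ellipse assumes bivariate normality within a group; with
  n barely above 3 the posterior mostly reflects the likelihood's heavy
  tail, and the credible intervals should be read accordingly.
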