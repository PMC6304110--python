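# nichepack

Quantitative comparison of ecological communities along two complementary
axes: **species packing in a size-corrected trait morphospace** and
**stable-isotope niche breadth** in the (δ¹³C, δ¹⁵N) plane. The package was
built for two-community questions of the kind ecologists ask about richness
gradients — does a richer community pack more species into the same
morphological and trophic space, or does it occupy a larger space? — with
bat communities (rainforest vs savannah) as the motivating system.

## What it computes

**Morphospace.** Specimens are averaged to species; each of ten linear
measurements (four external, six craniodental, mm) is regressed on body
mass by OLS and the residuals — size-corrected trait values — enter a PCA.
Species packing on the component axes is summarised by

* nearest-neighbour distance *NN* (mean ± s.d. of
  min<sub>j≠i</sub>‖xᵢ − xⱼ‖),
* distance to the community centroid (mean and median of ‖xᵢ − x̄‖),
* minimum convex polygon (MCP) area of the first two axes.

Communities of unequal richness are compared by a two-sided Wilcoxon
rank-sum test on the per-species metric vectors and by a **rarefied
bootstrap**: both communities are repeatedly subsampled (without
replacement) to a common richness *k*, the metric is recomputed inside
each subsample, and the distribution of per-replicate medians and rank-sum
p-values is reported (median p, proportion of p ≤ 0.05).

**Isotopic niche.** For species-mean (δ¹³C, δ¹⁵N) points, the six
community-wide Layman metrics — NR, CR, CD, MNND, SDNND, TA — plus the
standard ellipse area SEA = π√(λ₁λ₂) (λ = covariance eigenvalues), the
small-sample corrected SEAc = SEA·(n−1)/(n−2), and a Bayesian posterior
for SEA from a conjugate normal–inverse-Wishart model (mode and nested
50/75/95% credible intervals), community-wide and per foraging group
(open-air, clutter-edge, clutter, fruitbat). NR/3.4‰ converts the δ¹⁵N
range into trophic levels.

A synthetic-community generator (log-normal masses, linear allometry with
guild offsets, per-guild bivariate-normal isotope niches) makes every
stage testable end to end; a deterministic two-community fixture
(48 vs 23 morphospace species, 39 vs 17 isotope species) ships with the
package.

## Worked example

```python
import nichepack as nk

fx = nk.study_fixture()          # bundled synthetic two-community data
report = nk.run_comparison(
    fx["forest_traits"], fx["savannah_traits"],
    fx["forest_isotopes"], fx["savannah_isotopes"],
    nk.ComparisonConfig(seed=1, n_reps=500),
)
print(report.summary())
```

prints (abridged):

```
community      variant            metric   value  dispersion
   forest          all       nn_distance   5.071       1.670
 savannah          all       nn_distance   5.641       2.392
   forest          all          mcp_area 605.230         NaN
 savannah          all          mcp_area 336.975         NaN
...
Isotopic niche summary — forest
NR (d15N range): 5.71 per mil   CR (d13C range): 10.64 per mil
TA (hull area): 47.27 per mil^2
SEA: 13.49   SEAc: 13.86 per mil^2
```

Read: in the synthetic forest community species sit closer together in
morphospace (mean NN 5.07 < 5.64) while covering a larger area
(MCP 605 > 337), and its isotopic niche is both wider in δ¹³C
(CR 10.6‰ vs 5.0‰) and larger in total area (TA 47.3‰² vs 14.9‰²) — the
qualitative pattern the generator is parameterised to emulate. The same
pipeline runs from the shell:

```bash
nichepack simulate --seed 7 --output data/
nichepack compare --traits-a data/forest_traits.csv --traits-b data/savannah_traits.csv \
    --isotopes-a data/forest_isotopes.csv --isotopes-b data/savannah_isotopes.csv \
    --seed 7 --k 22 --reps 500 --output report/
```

writing `report_morpho.csv`, `report_isotope.csv`, `report.json` and
`provenance.json`.

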