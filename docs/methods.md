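# Methods

This note records the statistical models implemented in `foresthab`, the
choices made where the methods literature leaves latitude, and what the
synthetic-data validation does and does not establish.

## Study design assumed

All analyses operate on stem-mapped censuses: every woody stem with
DBH ≥ 1 cm carries a plot id, species, life form (tree/shrub), x/y position
in meters, and DBH in cm. Plots are rectangles gridded into square quadrats
(default 10 m × 10 m); coordinates are half-open per axis
(`0 ≤ x < width`), and a stem at (x, y) belongs to quadrat
(⌊x/q⌋, ⌊y/q⌋). The canonical configuration is four 1-ha plots
representing four disturbance regimes, treated as four "habitats"
(communities). The quadrat matrix (species × quadrat counts) conserves the
stem total exactly and is the input to every matrix-based method.

## Torus-translation association test

Statistic: Harms-style relative density
RD = (stems in habitat / habitat area) ÷ (all stems / total area), on the
combined quadrat grid (plots concatenated along x, 40 × 10 cells for the
canonical design). Null model: the habitat map is transformed while the
stems stay fixed; the transform family is the 4 map variants (identity,
180° rotation, x-mirror, mirrored rotation) × all W·H torus translations —
4·W·H = 1,600 maps, i.e. 1 real and 1,599 translated. Tail probabilities
include the observed map in its own null set and count ties toward both
tails: p₊ = (#{null RD ≥ obs} + 1)/1600, p₋ analogously. Classification is
two-tailed at level α (default 0.05): positive when p₊ ≤ α/2, negative
when p₋ ≤ α/2. Only species with ≥ 5 stems are tested (the conventional
"more than four individuals" rule, configurable).

Two structural properties of this design are worth knowing:

- **Effective null size.** With whole plots as habitats, every habitat
  spans the full map height, so y-translations do not move stems across
  habitat boundaries, and the mirror/rotation variants reproduce the same
  40 column-blocks. The 1,600 maps therefore contain only 40 *distinct*
  habitat placements (each 40-fold duplicated). The smallest attainable
  tail probability is exactly 40/1600 = 0.025 = α/2: a positive call
  requires the observed placement to be the strict maximum of 40
  exchangeable blocks.
- **Conservatism under ties.** Counting ties in both tails makes the test
  conservative whenever integer stem counts tie at the rejection boundary.
  At realistic densities (~120 stems per species over 4 ha) the realized
  positive rate on preference-free censuses is ≈ 0.016 rather than the
  nominal 0.025; it approaches 0.025 as abundances grow and ties thin out.
  The validation suite asserts the one-sided guarantee (never
  anti-conservative); a strict two-sided calibration check is retained and
  is expected to fail by this margin.

Power at the design's canonical effect size is high: a species with a
10-fold intensity preference and ~300 stems is classified positive for its
plot in ≥ 90% of replicates (measured: 100/100).

## Network specialization (H2′, connectance)

The species × community matrix of stem totals is scored with
H2 = −Σ p_ij ln p_ij (natural logs), rescaled between its extremes under
fixed marginals: H2′ = (H2max − H2)/(H2max − H2min), clipped to [0, 1].
H2max is the entropy of the continuous independence distribution
r_i c_j/m² (the sum of the two marginal entropies); an exact
integer-constrained maximum is available behind `integer_max=True` for
sensitivity analysis. H2min uses full enumeration of integer tables when
the grand total is ≤ 12 (the greedy heuristic provably overshoots the true
minimum on some small marginals) and otherwise a greedy allocation that
repeatedly places min(row remainder, column remainder) in the cell with
the largest remaining marginal product. Degenerate marginals
(H2max = H2min) report H2′ = 0. Connectance is nonzero cells / (S·C).

## IndVal

Group-equalized IndVal ("IndVal.g"): specificity
A = mean abundance in the group / summed group means, fidelity B =
occupancy fraction within the group, IndVal = max over groups of √(A·B).
p-values permute site group labels: Monte-Carlo with the +1 correction
(default 999 permutations), or exhaustive enumeration of distinct label
arrangements (`n_perm=None`, used for exact small-sample work). p-values
are reported per species for its best group, uncorrected by default (a
Holm adjustment is available), matching the conventional one-row-per-
species indicator table.

## Dispersion, ordination, RDA

Dissimilarity defaults to Bray–Curtis on untransformed quadrat abundances;
a pair of entirely empty quadrats is defined to have dissimilarity 0 (with
a warning) or can be dropped. PCoA eigendecomposes the Gower-centered
matrix and keeps negative eigenvalues. The dispersion test embeds quadrats
by PCoA, measures each quadrat's distance to its own group *centroid*
combining real and imaginary axes as z = √max(0, d²ᵣₑₐₗ − d²ᵢₘₐg), then
compares groups by one-way ANOVA (parametric p) and optionally by label
permutation. Centroids (not spatial medians) are used — simpler and
exactly testable against plain geometry on Euclidean inputs; this is a
deliberate deviation from the median default of the common R
implementation. Singleton groups are excluded with a warning; distances
indistinguishable from numerical noise are treated as degenerate (F
undefined, p = 1).

RDA fractions are *marginal*: each topographic covariate alone, fraction =
SS(fitted)/SS(total)·100 over the column-centered (by default
Hellinger-transformed) species matrix, permutation p by shuffling the
covariate across quadrats. Aspect (circular, degrees) is expanded to a
sin/cos pair and reported jointly. Marginal fractions are not a variance
partition: they only sum to the joint fit on orthogonal designs (verified
in tests).

## Diversity summaries

Importance value IV = (relative abundance% + relative frequency% +
relative basal area%)/3 per community; relative frequency's denominator is
the sum of occupied-quadrat counts over species, so each component sums to
100% and IVs sum to 100. Basal area is π(DBH/2)² summed per species,
reported in cm² and m². The species-accumulation curve is the exact
sample-based (rarefaction) form: with T sites and species i occupying T_i,
E[S(n)] = S − Σ_i C(T−T_i, n)/C(T, n); the SD uses the joint-absence
probabilities q_ij = C(T−|A_i ∪ A_j|, n)/C(T, n) in
Var = Σ p_i(1−p_i) + 2Σ_{i<j}(q_ij − p_i p_j). Combinatorics run in log
space (gammaln). Kruskal–Wallis delegates to SciPy with the all-ties
degenerate case defined as H = 0, p = 1.

## Pair-correlation function

ĝ(r) = A²/(2πr n(n−1)) Σ_{i≠j} k_h(r − d_ij)/W(Δ), Epanechnikov kernel,
translation edge correction W(Δ) = (a−|Δx|)(b−|Δy|). The bandwidth default
is Stoyan's rule 0.15/√λ̂, applied as the kernel *half-width* (the rule is
conventionally quoted without a kernel-scale convention; the half-width
reading keeps the smoothing support explicit). The cross version
normalizes by n_a n_b/A² and equals 1 under independence. Envelopes are
pointwise rank envelopes: (1−coverage)(n_sim+1)/2 must be a positive
integer k; 199 simulations with k = 1 give the standard 99% band.
Incompatible (coverage, n_sim) pairs are rejected with the nearest valid
n_sim named. Bivariate nulls: random labeling (default; labels permuted
among fixed stem positions) or independent CSR re-draws. The Thomas
closed form g(r) = 1 + exp(−r²/(4σ²))/(4πσ²κ) (κ per m²) is the
validation oracle; at κ = 10/ha, σ = 2 m in a 150 m window (~22 expected
parents, ~900 stems per realization), averages of 10–20 realizations track
it to a mean relative error typically well under 0.2 — the residual spread
is dominated by Poisson fluctuation of the realized parent count, which
rescales the cluster amplitude by 1/P per realization.

## Synthetic censuses

The generator emulates the canonical four-plot census: per species × plot
counts ~ Poisson(λ); positions uniform or Thomas (Poisson(κ·area ha)
parents, N(0, σ²) offsets, out-of-plot offspring re-drawn — plots are
bounded, not tori); DBH ~ lognormal(μ_log = 1.5, σ_log = 0.6) on the cm
scale, truncated at 1 cm (mean ≈ 5–6 cm with a realistic right tail). The
default species pool has a geometric rank-abundance profile (ratio 0.85)
around 120 stems per species over 4 ha — the per-species density of a
typical temperate deciduous census of ~90 species and ~11,000 stems.
Community preference is an intensity contrast: the preferred plot carries
fold× each other plot's intensity with the species total preserved
(non-preferred plots get total/(fold + P − 1)). Randomness is hierarchical
(one SeedSequence per species × plot), so editing one species never
perturbs another's stems.

What the generator does *not* emulate: topographic dependence of stem
placement, interspecific interactions, size–distance correlations,
succession or mortality. Passing tests therefore demonstrate correctness
of the statistical machinery under known truth, not field realism of any
particular ecological conclusion.

## Validation problem sizes

The suites run at sizes chosen to keep the full run in minutes on one
core: exhaustive torus enumeration on 2 × 2 grids (16 maps);
accumulation-curve brute force at 6 sites; H2min enumeration at totals
≤ 12; IndVal exhaustive enumeration at 6 sites; type-I study with 200
null censuses × 20 species (16,000 species–habitat pairs); power study
with 100 replicates; dispersion calibration with 200–300 simulations of
99-permutation tests; point-pattern checks with 150–1,200 points.

## Known limitations

- The torus family's 40-fold degeneracy (above) bounds attainable
  significance at α/2 = 0.025 for whole-plot habitats; finer-grained
  habitat maps (e.g. topographic classes) would not share it, but are out
  of scope here.
- Greedy H2min beyond total ≤ 12 is a heuristic upper bound on
  specialization's denominator; H2′ can be slightly underestimated on
  adversarial marginals.
- Marginal RDA fractions are interpretable per covariate only; they do not
  partition variance.
- The dispersion test uses centroids; results can differ from
  median-based implementations on skewed clouds.
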