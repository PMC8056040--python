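# foresthab

Habitat-specialization analyses for stem-mapped forest censuses: do woody
plant species distribute themselves at random across forest stands under
different disturbance regimes, or do they specialize?

The package is aimed at community ecologists working with mapped plot
networks (e.g. four 1-ha plots, every stem with DBH ≥ 1 cm tagged, mapped
and measured, plots gridded into 10 m × 10 m quadrats). It implements the
full analysis chain for that design:

- **Torus-translation habitat association.** For species *s* and habitat
  *h*, the statistic is the relative density
  RD = (nₕ/Aₕ) / (n/A); the null translates the habitat map (not the
  stems) around the toroidal quadrat grid in all shifts of four map
  variants (identity, 180° rotation, mirror, mirrored rotation). Four 1-ha
  plots concatenated into a 40 × 10 grid give 4·40·10 = 1,600 maps — one
  real, 1,599 translated. Species are classified +/−/none at two-tailed
  level α with tie-conservative tail probabilities.
- **Bipartite network specialization.** The species × community stem-count
  matrix is scored with the entropy-based H2′ index,
  H2′ = (H2max − H2)/(H2max − H2min) ∈ [0, 1], plus connectance
  (realized / possible links).
- **IndVal indicator species analysis** (group-equalized A·B, permutation
  p-values).
- **Composition structure:** Bray–Curtis dissimilarities, PCoA, a
  betadisper-style multivariate dispersion test (ANOVA and permutation),
  and marginal RDA fractions for topographic covariates.
- **Diversity summaries:** importance values
  IV = (rel. abundance% + rel. frequency% + rel. basal area%)/3, exact
  sample-based species-accumulation curves (mean and SD), Kruskal–Wallis
  comparisons, occurrence-overlap (Venn) counts.
- **Point patterns:** pair-correlation g(r) with Epanechnikov kernel,
  translation edge correction, and pointwise Monte-Carlo rank envelopes
  (CSR or random-labeling nulls).
- **Synthetic censuses:** a seeded generator (Poisson abundances, uniform
  or Thomas-cluster positions, truncated-lognormal DBH, controllable
  plot-preference fold changes) so every stage is testable without field
  data.

## Worked example

```python
import foresthab as fh

cfg = fh.default_config(n_species=12, mean_abundance=150, seed=11)
cfg = fh.apply_preferences(cfg, [
    fh.PreferenceSpec("sp01", "P4", 10.0),   # 10x preference for plot P4
    fh.PreferenceSpec("sp02", "P2", 8.0),
    fh.PreferenceSpec("sp03", "P1", 6.0),
])
census = fh.generate_census(cfg)             # 1,699 stems over four 1-ha plots

qm = fh.filter_min_abundance(fh.grid_stems(census), 5)
hmap = fh.build_combined_map(census)         # 40 x 10 torus, 1,600 maps
assoc = fh.torus_test(qm, hmap, alpha=0.05)
print(assoc[assoc["class"] != "none"])
```

```text
species life_form habitat  observed_rd  p_pos  p_neg    class
   sp03     shrub      P1       2.6359 0.0250 1.0000 positive
   sp02     shrub      P2       2.9878 0.0250 1.0000 positive
   sp03     shrub      P2       0.3502 1.0000 0.0250 negative
   sp01     shrub      P4       3.0143 0.0250 1.0000 positive
```

The three seeded preferences are recovered (observed RD ≈ 2.6–3.0, i.e.
stem density in the preferred plot about three times the plot-wide
average), plus one induced avoidance; with whole plots as habitats the
smallest attainable p is 40/1600 = 0.025, so these are the strongest calls
the design can make. Network-level specialization of the same census:

```python
net = fh.build_network(fh.grid_stems(census))
fh.h2prime(net), fh.connectance(net)         # (0.1552, 1.0)
```

and the headline summary — `summarize_associations(assoc)` — reports 4
significant pairs over 12 species tested (3 positive, 1 negative, 33.33%).

A published 57-species association table for four disturbance regimes
(plantation / twice-cut / once-cut / old-growth) ships as a fixture for the
reporting layer: `fh.reference_long_table()`.

The same chain is scriptable: `foresthab simulate|grid|metrics|dispersion|
rda|network|torus|indval|pcf|summarize|run-all` (see `foresthab --help`),
with `run-all` driving every stage from one YAML config into a run
directory with provenance sidecars.

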