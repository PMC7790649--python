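# dendropatterns

Radial growth-pattern clustering and growth-release reconstruction for
dendroecology.

In boreal old-growth stands driven by recurrent insect outbreaks (notably
spruce budworm, *Choristoneura fumiferana*), understory conifers spend
decades suppressed, then accede to the canopy in a single step of radial
growth when an outbreak kills the trees above them. `dendropatterns`
implements the combined analysis of **radial growth patterns** and **growth
releases** used to reconstruct that disturbance history from tree-ring
series and plot inventories:

1. **20-segment profiles.** Each tree series (ring widths in mm/yr) is
   divided into 20 contiguous segments of near-equal ring count — the
   counts never differ by more than one ring — so trees of different ages
   become comparable 20-variable shape profiles.
2. **Pattern identification.** The standardized profile matrix is
   partitioned by k-means (1,000 random restarts of Lloyd's algorithm,
   best-of by within-cluster sum of squares). The number of patterns k is
   chosen by maximizing the **simple structure index** (SSI); clusters are
   then named by deterministic shape rules (linear / bell / ascending /
   sine) and ranked low / moderate / high within a shape by mean ring width.
3. **Release detection.** The percent growth change for year *t* is

   %GC = (M₂ − M₁) / M₁ × 100

   with M₁ the mean ring width of the 10-year window ending at *t* and M₂
   the mean of the following 10 years. Years classify as major release
   (%GC ≥ 50), minor release (25 ≤ %GC < 50), minor suppression
   (−50 < %GC ≤ −25) or major suppression (%GC ≤ −50). Site chronologies
   give the percentage of trees per class per year, loess-smoothed (50 %
   span), with peak detection for disturbance episodes.
4. **Stand structure.** Dominant height DH (mean of the 100 tallest trees
   per hectare — four per 400 m² plot), canopy layers (dominant ≥ DH;
   codominant ≥ 2/3 DH; intermediary > 1/2 DH; suppressed below), stand
   summaries, and the cohort basal area proportion
   CBAP = 1 − BA(first cohort)/BA(total), 0 for a single-cohort stand and 1
   when the first cohort is fully replaced.
5. **Association tests.** A fixed-margin Monte-Carlo chi-square test links
   patterns to canopy layers or species, and a stratified (site-blocked)
   permutation F-test with Holm-adjusted pairwise comparisons compares tree
   and growth attributes between patterns.
6. **Synthetic generator.** A seeded simulator produces ring series, plot
   inventories and truth tables for outbreak-driven stands from nine
   archetypal growth patterns, so every stage is testable without field
   data.

## Worked example

```python
import dendropatterns as dp

# simulate an eight-plot outbreak-driven study
cfg = dp.SimulationConfig(noise_sigma=0.05)
plots, series, truth = dp.simulate_dataset(cfg, seed=7)

# 20-segment profiles -> SSI-selected k-means patterns
matrix = dp.standardize_segment_matrix([dp.segment_series(s) for s in series])
sel = dp.select_pattern_count(matrix, range(2, 13), n_restarts=500, seed=7)
part = dp.name_patterns(sel.best, matrix)
print(f"SSI selects k={sel.k_best} (SSI={sel.best.ssi:.2f})")

# %GC release chronology and its peaks
gc = [dp.percent_growth_change(s) for s in series]
chron = dp.site_change_chronology(gc, site_id="all")
for p in dp.detect_release_peaks(chron):
    print(f"release peak {p.year} ({p.start_year}-{p.end_year}), height {p.height:.1f}%")
```

prints

```
SSI selects k=9 (SSI=2.46)
release peak 1893 (1878-1910), height 32.4%
release peak 1940 (1925-1956), height 43.9%
release peak 1959 (1956-1975), height 21.3%
release peak 1992 (1975-1995), height 10.2%
```

The SSI criterion recovers the nine generating archetypes (40 trees each,
8 for the rare high-bell pattern), and the release chronology shows one
peak per scheduled outbreak episode (1870–1890, 1910–1940, 1950–1960,
1975–1990), the 1910–1940 episode being the most severe. Pattern sizes,
stand summaries (e.g. plot S1: DH = 16.60 m; 20 codominant, 9 intermediary,
10 suppressed, 2 dominant trees) and association tests follow the same API;
see `docs/methods.md` for the model details.

The same pipeline runs from the shell:

```sh
dendropatterns simulate --out-dir sim --seed 7
dendropatterns all --rings sim/rings.csv --inventory sim/inventory.csv \
    --saplings sim/saplings.csv --out-dir results --seed 7
```

Inputs may be Tucson/rwl decadal files or long-form CSV
(`tree_id,year,width_mm`); inventories are CSV with columns
`tree_id,species,dbh_cm,height_m,vitality,crown_status,plot_id,plot_area_m2`.

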