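# phylotrends

Spatiotemporal trends in the phylogenetic diversity (PD) of local species
assemblages, estimated from DNA-barcode occurrence records.

Large barcode repositories (BOLD/GBIF exports) make it possible to ask how
the evolutionary breadth of local insect assemblages — not just their
species richness — varies across latitude and through time. `phylotrends`
implements that analysis as a reusable, tested pipeline:

1. **Record cleaning** — occurrence rows with missing species names,
   missing/invalid coordinates, missing collection years, or barcode
   lengths outside 600–700 bp are removed, each charged to the first rule
   it fails, with exact accounting.
2. **Assemblage binning** — records sharing a rounded coordinate
   (2 decimal places ≈ 1 km) and collection year form an assemblage;
   species are deduplicated and assemblages with fewer than 10 species
   are dropped.
3. **Diversity metrics** — per assemblage: mean pairwise patristic
   distance (MPD), its standardized effect size under a tip-label
   randomization null,

   `ses.MPD = (MPD_obs − mean(MPD_null)) / sd(MPD_null)` ,

   with 99 randomizations by default (positive = overdispersion,
   negative = phylogenetic clustering); Faith's PD; and the *exact*
   rarefied Faith's PD at m = 10, computed in closed form from per-branch
   subtending counts rather than by resampling.
4. **Trend models** — Gaussian models of ses.MPD with |latitude|,
   (scaled) year, hemisphere, optional site environment and their year
   interactions; a Matérn-correlated spatial random field over
   great-circle distances plus a decade/site random effect; VIF
   screening; ML fitting with AIC model selection; Moran's I residual
   correlograms; marginal-effect grids; and replicate fits across six
   continental regions.

Because the repository snapshots behind published analyses are not
reproducible, the package ships a first-class **synthetic-data generator**:
a Yule tree, Brownian-motion trait, and an assemblage sampler driven by a
signed dispersion parameter d (negative = environmental filtering →
clustering; positive = repulsion → overdispersion) that follows a planted
linear model in standardized |latitude| and year. Every downstream stage
can therefore be verified against known truth, including recovery of a
planted latitude × year interaction — the qualitative signature of
phylogenetic diversity rising through time fastest at high latitudes.

## Worked example

```python
from phylotrends import ScenarioConfig, generate_dataset, apply_filters, \
    build_assemblages, pd_table
from phylotrends.trends import TrendDesign, aic_select, fit_lm, model_menu, \
    prepare_trend_frame

cfg = ScenarioConfig(seed=11)          # 15 sites x 20 years, planted beta_int = +0.6
ds = generate_dataset(cfg)
print(f"occurrence rows: {len(ds.occurrence_table)}")

clean, report = apply_filters(ds.occurrence_table)
print(f"removed per rule: {report.removed}")

assemblages, extra = build_assemblages(clean)
print(f"assemblages: {extra['assemblages']} (duplicates removed: {extra['duplicate_records_removed']})")

metrics = pd_table(assemblages, ds.true_tree, n_rand=99, seed=1)
print(f"mean ses.mpd z: {metrics['z'].mean():.3f}")

frame, _ = prepare_trend_frame(metrics)
design = TrendDesign(frame)
table, best = aic_select([fit_lm(design, terms) for terms in model_menu()])
print(f"selected: {' + '.join(best.terms)}")
print(best.summary_frame().round(4))
```

Output:

```
occurrence rows: 7556
removed per rule: {'missing_species': 302, 'invalid_coordinates': 302, 'missing_year': 302, 'length_out_of_range': 302}
assemblages: 300 (duplicates removed: 302)
mean ses.mpd z: -0.338
selected: abs_latitude + year_s + abs_latitude:year_s
                     estimate      se       p
(Intercept)           -0.6526  0.1436  0.0000
abs_latitude           0.0098  0.0039  0.0118
year_s                -0.3570  0.1436  0.0135
abs_latitude:year_s    0.0182  0.0039  0.0000
```

Reading the output: the generator planted 302 violations of each cleaning
rule and the filter report recovers those counts exactly. The mean ses.MPD
of −0.34 reflects the overall phylogenetic clustering planted through a
negative baseline dispersion. AIC selection keeps the latitude × year
interaction, and its positive sign (+0.018 per degree of |latitude| per
scaled-year unit, p ≈ 1e-5) recovers the planted gradient: assemblage PD
rises through time at high latitudes while equatorial assemblages stay
clustered.

The same analysis runs from the shell:

```bash
phylotrends run-all --out-dir runs/demo --seed 11
phylotrends report --run-dir runs/demo
```

which writes the occurrence table, filter report, assemblage table,
per-assemblage diversity CSV, global and per-region fit summaries,
before/after Moran correlograms, a marginal-effects grid and a markdown
report. Reruns with the same config produce byte-identical CSVs.
`simulate`, `filter`, `pd` and `trends` run the individual stages; use
`--config <file>` for YAML configuration (see `docs/methods.md`).

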