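# amfspread

Dispersal inference for inoculated arbuscular mycorrhizal fungi (AMF) in
field restoration experiments.

Restoring native AMF communities to degraded grasslands usually means
inoculating "nurse" plants and hoping the fungi spread outward — but how
far and how fast individual taxa actually move through soil is hard to
measure, because most inoculated taxa are also present at background
levels before inoculation.  `amfspread` implements the inference machinery
for experiments that track inoculated OTUs along a distance gradient
(0 / 0.5 / 1 / 2 m from the nurse-plant row, three inoculation treatments,
randomized blocks, optional host-plant "bridge" and "island" plot sides):

* per-OTU **distance contrasts**: OLS of relative abundance on distance
  (categorical) + block, marginal means, pooled-error F tests, nurse-row
  enrichment vs controls, and the 2-m bridge-vs-island test;
* a five-category **spread classifier** (no spread, spread to 0.5 m,
  distance decay, spread to 2 m, unknown) with the bridge/island override,
  applied to one *trial* per OTU per inoculum per site-year;
* **virtual OTUs**: collapsing a bootstrap support tree (merge clades whose
  internal nodes have support < 70 or zero genetic distance, never across
  reference sequences) and a cross-site dominance consistency summary;
* community-level **MANOVA** (Pillai's trace), the family-level
  spread-vs-no-spread chi-square test, and plant richness / Shannon /
  evenness from point-intersect cover tables;
* a **synthetic-data generator**: Dirichlet-multinomial OTU counts over
  the full plot design with known per-OTU spread kernels, random support
  trees with a brute-force collapse oracle, and plant cover tables — so
  every stage is testable at desk scale.

See `docs/methods.md` for the model, the decision rules, and an honest
account of which generative signals the classifier can and cannot recover.

## Worked example

Simulate a one-site experiment (7 blocks, five inoculated OTUs — one per
spread kernel — plus 40 background taxa, sequencing depth 10⁴), classify
every trial, and tabulate:

```python
from amfspread import (SimConfig, simulate_experiment, to_proportions,
                       classify_trials, tabulate_categories)

cfg = SimConfig(n_blocks=7, n_years=1, n_otus_inocula=5,
                n_otus_background=40, seed=42)
sim = simulate_experiment(cfg)
prop = to_proportions(sim.table)
records = classify_trials(prop, sim.profiles["site1"], "site1", 1)
print(tabulate_categories([r.trial for r in records]).to_string(index=False))
```

```
 site  year  NO_SPREAD  SPREAD_0_5  DISTANCE_DECAY  SPREAD_2M  UNKNOWN  n_trials
site1     1          5           1               1          1        2        10
```

Each of the five OTUs is in both inocula, hence 10 trials; the counts
always partition the trials.  Comparing against `sim.truth` shows what
happened here: the no-spread, spread-to-0.5 and spread-to-2-m OTUs were
recovered under both inocula (5 = 4 + 1 stray decay trial), the NULL OTU
landed in UNKNOWN twice, and the distance-decay OTU split between
NO_SPREAD and neighboring categories — the expected behaviour for a
boundary category (see the methods note).

The bundled cross-site dominance table shows the consistency summary on
published-scale inputs:

```python
from amfspread import cross_site_votus, consistency_summary
table, headline = consistency_summary(cross_site_votus())
print(headline)
```

```
{'n_selected': 15, 'n_dominant': 13, 'fraction_dominant': 0.8666666666666667, 'dominant_breakdown': {'NO_SPREAD': 11, 'SPREAD_0_5': 1, 'DISTANCE_DECAY': 0, 'SPREAD_2M': 1}}
```

13 of the 15 virtual OTUs assessed across sites (~87 %) keep a strict
majority of their trials in one spread category — taxa tend to behave
consistently across sites — and most of those are dominated by no-spread.

The same stages are available from the shell:

```sh
amfspread simulate --seed 42 --out-dir run/
amfspread classify --otu-table run/otu_counts.tsv --metadata run/metadata.tsv \
                   --inocula run/inocula.tsv --out-dir run/
amfspread collapse --tree run/tree.nwk --out run/votu_map.tsv
amfspread summarize-votus --trials run/trials.tsv --votu-map run/votu_map.tsv \
                          --out-dir run/
amfspread run --seed 42 --out-dir run/   # everything, with a manifest
```

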