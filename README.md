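# yamcross

Cross-compatibility analytics for yam (*Dioscorea* spp.) breeding crossing
blocks.

Yam is a dioecious, mostly vegetatively propagated staple crop, and its
breeding depends on hand pollination with notoriously low success: most
pollinated flowers set no fruit, and most fruits carry fewer viable seeds
than their six ovules would allow. Interspecific crosses face additional
pre-zygotic barriers (no fruit set at all) and post-zygotic barriers (fruit
set without viable seed), often in one cross direction only. `yamcross` is
for breeders and quantitative geneticists who keep multi-year crossing-block
records and want to quantify those barriers and the factors behind them.

## What it computes

For each *directed* cross-combination (female parent listed first;
reciprocals are never merged), pollination batches are pooled and four
indices derived:

- **Crossability rate** = 100 · fruits set / flowers pollinated.
- **ACR** (average crossability rate) of a parent or group = the unweighted
  mean of crossability rates over its cross-combinations.
- **PHC** (percentage high crossability) of a parent = 100 · (# of its
  combinations whose rate strictly exceeds the species-wide mean rate) /
  (# of its combinations).
- **SPE** (seed production efficiency) = 100 · viable seeds /
  (6 · flowers pollinated), six being the expected ovule count per yam
  fruit.
- **Germination rate** = 100 · seedlings emerged / seeds sown.

Group summaries report combination-level means ± sample SD (n−1), and a
pooled multi-species row sums the counts while averaging the group means and
SDs — the convention under which published two-species program summaries
reproduce cell-for-cell.

Around the indices sits the supporting analysis battery: Jaccard
(allele-presence) and IBS distances plus observed heterozygosity from SNP
genotypes (VCF or dosage CSV), Pearson correlations, sequential
(Type-I) ANOVA, pooled-variance t tests with a Shapiro–Wilk check, weekly
weather aggregation over a flowering window (a day is rainy when rainfall
strictly exceeds 0.5 mm), OLS weather regression, Tukey-HSD pollinator
comparisons and Fisher-LSD germination comparisons. A synthetic-data module
generates crossing blocks, genotype panels, weather series and germination
records with known ground truth for end-to-end validation.

## Worked example

Simulate a two-species crossing block and summarize it by cross type:

```python
from yamcross import (SimulationConfig, simulate_crossing_block,
                      aggregate_to_combinations, combination_summaries,
                      group_summary)

cfg = SimulationConfig(seed=7)
block, truth = simulate_crossing_block(cfg)
comb = combination_summaries(aggregate_to_combinations(block))
print(group_summary(comb, ["cross_type"]).round(2).to_string(index=False))
```

```
   cross_type  n_combinations  flowers_pollinated  acr_mean  acr_sd  spe_mean  spe_sd
interspecific              10                1225      2.22    4.88      0.00    0.00
intraspecific             100               14409     26.94   16.30      8.88    5.57
```

The intraspecific ACR lands near the configured fruit-set baselines (~32%
for *D. alata*, ~23% for *D. rotundata*), while the interspecific rows show
the injected hybridization barriers: a low crossability rate overall
(pre-zygotic failure) and SPE pinned at zero where fruits set but no seed
develops (post-zygotic failure).

Pooling the published species-level intraspecific summaries of the IITA
program (2010–2020), which ship with the package:

```python
from yamcross import IITA_INTRASPECIFIC_SPECIES_ROWS, pooled_row
print(pooled_row(IITA_INTRASPECIFIC_SPECIES_ROWS).round(3).to_string())
```

```
n_females                 570.000
n_males                   576.000
n_combinations           2062.000
flowers_pollinated     509154.000
yearly_crosses_mean     23143.365
yearly_crosses_sd       10629.025
acr_mean                   27.565
acr_sd                     18.760
spe_mean                    9.235
spe_sd                      5.130
```

i.e. 509,154 flowers pollinated over eleven years, a pooled intraspecific
ACR of 27.57 ± 18.76% and SPE of 9.23%.

The same stages are available from a shell via the `yamcross` CLI
(`simulate`, `indices`, `relatedness`, `associate`, `germination`,
`report`); every run writes a JSON provenance manifest next to its outputs.

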