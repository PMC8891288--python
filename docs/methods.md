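# Methods

## Indices and aggregation conventions

The analysis unit is the *directed* cross-combination — an ordered (female,
male) accession pair. Direction is part of the identity because yam species
show unilateral incompatibility: a cross can succeed in one direction and
fail in the reverse, so reciprocals are never merged. A cross is
intraspecific iff the two (case/whitespace-normalized) species tokens match;
a "wild" marker in a species label is split into a separate boolean so
forest-sourced accessions group apart from cultivated ones without becoming
a different species.

Batches are pooled to combination-level counts before any rate is taken:
crossability rate = 100·fruits/flowers and SPE = 100·seeds/(6·flowers) are
ratios of summed counts, not means of batch ratios. Six ovules per fruit is
the standard expectation for yam; it is a parameter (`ovules_per_fruit`)
rather than a constant, and a batch whose seed count exceeds 6·fruits is
flagged with a warning, not rejected, since six is an expectation rather
than a biological bound.

Parent-level ACR is the unweighted mean of a parent's combination rates, and
PHC counts combinations *strictly* above the species-wide mean rate. That
threshold is itself the unweighted mean over all the species' combinations.
Unweighted (per-combination, not per-flower) semantics run through the whole
ladder: group summaries report combination-level means ± sample SD (n−1
denominator), and the pooled multi-species row sums counts while averaging
the group means and the group SDs. This convention was chosen because it
exactly reproduces the published two-species intraspecific pooled summary
(509,154 flowers; ACR 27.57 ± 18.76; SPE 9.23; yearly crosses 23,143.37 ±
10,629.02) from its species rows — three independent cells confirm the
mean-of-means and mean-of-SDs rules. A flowers-weighted variant sits behind
`weighted=True` for sensitivity analysis. The published interspecific pooled
ACR (6.09%) is *not* reproducible as the unweighted mean of the printed
per-direction means; its weighting is unstated, so the package emits both
variants and asserts neither.

Degenerate cases: a batch or aggregate with zero flowers has an undefined
rate and is excluded with a logged warning (never coerced to 0%);
single-combination groups report SD = 0 with a `sd_degenerate` flag; a
combination whose pooled seed count is unknown (any contributing batch
lacking a seed count) keeps SPE unknown rather than partially summed, but
still contributes its crossability rate.

## Genetic relatedness

Genotypes are unphased diploid alternate-allele dosages {0, 1, 2, missing}
at biallelic SNPs. Two distances are implemented because practice uses both:

- **Jaccard dissimilarity** (default): each genotype at a locus is encoded
  as the set of alleles present (0 → {ref}, 1 → {ref, alt}, 2 → {alt});
  over the pairwise-complete loci the distance is 1 − |∩|/|∪| of the pooled
  per-locus presence indicators. The allele-presence encoding is stated
  prominently because a raw-dosage-as-binary variant would give different
  numbers; with this encoding a het vs. hom-ref locus contributes 1/2.
- **IBS distance**: 1 − mean per-locus shared-allele fraction, with
  |Δdosage| ∈ {0, 1, 2} mapping to sharing {1, 0.5, 0}. This is an L1
  metric on dosages scaled to [0, 1].

Missing calls are pairwise-deleted per sample pair (the convention of the
common SNP-distance tooling); a pair with no shared called locus is an
error, not a silent NaN. Monomorphic loci are dropped before matrix
computation (logged) — they carry no relational information and inflate IBS
similarity. Observed heterozygosity is simply the fraction of a sample's
non-missing calls equal to dosage 1. Allele flips across input files are out
of scope; inputs are assumed consistently called.

## Statistical battery

- ANOVA uses sequential (Type-I) sums of squares in the order the factors
  are listed (year, location, cross-combination for the historical design);
  order-dependence of Type-I SS is documented behaviour, not a bug, and the
  order is configurable by reordering the list.
- The two-sample t test is pooled-variance Student's t by default with a
  Welch option; the Shapiro–Wilk check is reported alongside, never used to
  silently substitute a rank test.
- Weekly weather aggregation sums rainfall and counts rainy days (strictly
  > 0.5 mm) and averages every other parameter; weeks are consecutive 7-day
  blocks from a configurable species anchor date (flowering windows differ:
  roughly August–October for *D. rotundata*, October–November for
  *D. alata*), and a week with more than two consecutive missing days is
  flagged incomplete.
- The weather regression is plain OLS on weekly aggregates with no
  multiple-testing correction across parameters (matching common practice
  for this analysis; stated here so readers apply their own if desired).
  Collinear predictor sets are rejected by a design-matrix condition-number
  check rather than silently dropped.
- Pollinator comparisons require the controlled design (every technician on
  a shared combination set) and use one-way ANOVA + Tukey HSD at a 5%
  family-wise level. Germination comparisons use ANOVA + Fisher LSD at a 5%
  per-comparison level; LSD is hand-implemented
  (t₍α/2,df₎·√(MSE·(1/nᵢ+1/nⱼ))) since no installed package provides it, and
  is unit-tested against that closed form.

## Synthetic-data generator

The generator emulates the data-generating process the analysis assumes, at
sizes a test suite can regenerate in seconds; all generators are pure
functions of (config, seed) and keep running totals as an aggregation
oracle.

- **Fruit set** is binomial at the pollination-batch level (the granularity
  of real crossing-block records) with a logit-linear predictor:
  cross-type baseline + year + site + pollinator + weekly-weather term +
  combination effect. Defaults: intraspecific baselines 0.317 (*D. alata*)
  and 0.234 (*D. rotundata*) and interspecific 0.06, matching the published
  ACR levels; site effects ±0.34 logits (Ibadan favourable, Abuja not),
  year SD 0.3, pollinator SD 0.5 (technicians differ several-fold),
  combination SD 0.8, weather coefficient 0.2 per standardized weekly
  anomaly. Eight technicians, two sites, eleven years (2010–2020).
- **Seed set** is Binomial(6·fruits, q) with q = 0.33 per ovule, so SPE/ACR
  ≈ ⅓ as observed intraspecifically. Interspecific combinations are split
  between a *pre-zygotic* regime (fruit-set logit pushed down ~6 logits: no
  fruit) and a *post-zygotic* regime (normal fruit set, q = 0: fruit
  without seed). Seed viability is a single per-ovule probability; no
  embryo/endosperm stage distinction.
- **Genotypes**: per-locus ancestral frequencies U(0.05, 0.5); subgroup
  frequencies Balding–Nichols with Fst = 0.5; per-parent inbreeding
  F ~ U(0, 0.6) so expected observed heterozygosity is 2p(1−p)(1−F); 25% of
  parents are near-clones of an earlier same-pool parent (5% of loci
  redrawn), reproducing the near-identical accessions real panels contain.
  Realized Jaccard distances span ~0.01–0.6; the published panels reach
  0.84, an upper tail this model does not produce, so conclusions about
  extreme-distance pairs do not transfer.
- **Germination** is Binomial(seeds sown, g) per family with
  logit g = logit(0.5) + 0.4·(distance − mean distance). At the default 100
  families × 50 seeds and the generator's distance spread this yields a
  family-level Pearson correlation near 0.2 — the magnitude reported for
  real crossbred seed — with the sign recovered in ≈98% of replicates.
- **Weather** is a per-parameter seasonal sinusoid + Gaussian noise for ten
  daily parameters, with an August rainfall dip and dry Novembers as in the
  West-African humid savanna; monthly climatology is matched in expectation
  only. Genetic distance does **not** affect intraspecific fruit set by
  default (the observed null), but a slope knob exists for power studies.

What passing on synthetic data does *not* show: the generator has no
flowering phenology, no pollinator–combination interaction, no ploidy
variation, no spatial field structure, and batch sizes are Poisson rather
than operationally planned — effects estimated from real records can be
confounded in ways these tests cannot reveal.

## Problem sizes and numerical choices

The validation suite uses scaled-down blocks (tens of parents, ~10⁴ flowers
where binomial consistency is checked, 10⁴ loci where heterozygosity
recovery is checked, 500 replicates for sign-recovery and flagging rates,
2,000 replicates for test calibration) — large enough that 3-standard-error
bands are decisive, small enough to regenerate quickly. Percentages are
computed in full precision and rounded to 2 dp only in outputs. Ratios with
zero denominators raise typed errors rather than returning sentinels.
Distance matrices validate symmetry and zero diagonal on construction.
Derived RNG seeds stay below 2³¹.

## Known limitations

Record-level historical crossing data are not publicly deposited, so the
published multi-year tables enter only as species-level summary rows
(bundled as `IITA_INTRASPECIFIC_SPECIES_ROWS`) and conventions are verified
through pooled-row arithmetic rather than re-derivation from raw records.
Mean-squares tables from the original unbalanced design cannot be
reconstructed without the raw data (their df bookkeeping is unstated).
No GWAS, kinship, population-structure inference, imputation, or
mixed-effects modelling is included.
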