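"""Synthetic crossing blocks, genotypes, weather and germination data.

The generator emulates the statistical structure of a dioecious yam breeding
program's hand-pollination records so that the analysis pipeline can be
validated against known ground truth:

* fruit set is binomial at the pollination-batch level, with a logit-scale
  linear predictor: cross-type baseline + year + site + pollinator + weekly
  weather term + combination effect;
* viable seeds are binomial on 6 x fruits (six ovules per fruit) with a
  per-ovule success probability — zero under a post-zygotic barrier regime
  (fruit set without seed), while a pre-zygotic regime suppresses fruit set
  itself;
* parental SNP genotypes follow per-locus allele frequencies with per-parent
  inbreeding F, so expected observed heterozygosity is 2p(1-p)(1-F); a
  Balding-Nichols-style divergence parameter spreads pairwise distances;
* germination is binomial per family with a logit that increases with the
  parents' genetic distance;
* daily weather is a seasonal sinusoid plus noise for ten parameters.

Every generator is a pure function of (config, seed): reruns are
bit-identical, and running totals are kept as an aggregation oracle.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .records import PollinationRecord
from .relatedness import DistanceMatrix, GenotypeMatrix

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_parents",
    "simulate_crossing_block",
    "simulate_germination",
    "simulate_weather",
]


def _logistic(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


@dataclasses.dataclass
class SimulationConfig:
    """Knobs for the synthetic crossing-block generator.

    Defaults mirror the conditions of a large two-species yam program:
    intraspecific baseline fruit-set probabilities near the published ACR
    levels of D. alata (~0.32) and D. rotundata (~0.23), an interspecific
    baseline near 0.06, a per-ovule seed probability of ~0.33 (so SPE/ACR is
    about one third), two sites of unequal quality, eleven years, eight
    pollinating technicians per species, and six-ovule fruits.  Parent-panel
    and batch counts are scaled down from the program's (hundreds of parents,
    half a million flowers) to sizes a test suite can regenerate quickly.
    """

    seed: int = 0
    species: tuple[str, ...] = ("d. alata", "d. rotundata")
    n_females: int = 12
    n_males: int = 12
    years: tuple[int, ...] = tuple(range(2010, 2021))
    sites: tuple[str, ...] = ("ibadan", "abuja")
    n_pollinators: int = 8
    combinations_per_species: int = 60
    batches_per_combination: int = 3
    mean_flowers_per_batch: float = 40.0

    # logit-scale fruit-set model
    baseline_intra: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"d. alata": 0.317, "d. rotundata": 0.234})
    baseline_inter: float = 0.06
    year_sd: float = 0.3
    site_effects: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"ibadan": 0.34, "abuja": -0.34})
    pollinator_sd: float = 0.5
    combination_sd: float = 0.8
    weather_beta: float = 0.2  # per standardized weekly rainfall
    distance_slope_fruit: float = 0.0  # genetic distance -> fruit set (null)

    # seed set
    ovules_per_fruit: int = 6
    seed_set_prob: float = 0.33
    # fraction of interspecific combinations under each barrier regime
    prezygotic_fraction: float = 0.5
    include_interspecific: bool = True
    n_interspecific: int = 10

    # genotypes
    n_loci: int = 500
    maf_range: tuple[float, float] = (0.05, 0.5)
    inbreeding_range: tuple[float, float] = (0.0, 0.6)
    divergence: float = 0.5  # Balding-Nichols Fst between subgroups
    n_subgroups: int = 3
    clone_fraction: float = 0.25  # share of parents that are near-clones
    clone_mutation: float = 0.05  # loci redrawn when cloning

    # germination
    n_families: int = 100
    seeds_per_family: int = 50
    germination_base: float = 0.5
    germination_distance_slope: float = 0.4  # logit per unit distance

    def validate(self) -> None:
        for name, p in {"baseline_inter": self.baseline_inter,
                        "seed_set_prob": self.seed_set_prob,
                        "germination_base": self.germination_base,
                        **{f"baseline_intra[{k}]": v
                           for k, v in self.baseline_intra.items()}}.items():
            if not 0.0 < p < 1.0:
                raise ValueError(f"{name} = {p} outside (0, 1)")
        lo, hi = self.inbreeding_range
        if not (0.0 <= lo <= hi < 1.0):
            raise ValueError(f"inbreeding_range {self.inbreeding_range} "
                             "must satisfy 0 <= lo <= hi < 1")


@dataclasses.dataclass
class GroundTruth:
    """Injected truth carried alongside each synthetic dataset."""

    combination_p: dict[tuple[str, str], float] = dataclasses.field(default_factory=dict)
    combination_regime: dict[tuple[str, str], str] = dataclasses.field(default_factory=dict)
    totals: dict[str, int] = dataclasses.field(default_factory=dict)
    parent_inbreeding: dict[str, float] = dataclasses.field(default_factory=dict)
    expected_heterozygosity: dict[str, float] = dataclasses.field(default_factory=dict)
    pollinator_effects: dict[str, float] = dataclasses.field(default_factory=dict)
    year_effects: dict[int, float] = dataclasses.field(default_factory=dict)
    site_effects: dict[str, float] = dataclasses.field(default_factory=dict)
    weather_beta: float = 0.0
    seed_set_prob: float = 0.0
    germination_slope: float = 0.0


# ---------------------------------------------------------------------------
# parents
# ---------------------------------------------------------------------------

def _parent_labels(cfg: SimulationConfig) -> dict[str, tuple[list[str], list[str]]]:
    out = {}
    for sp in cfg.species:
        tag = "".join(w[0] for w in sp.replace(".", "").split()).upper()
        females = [f"{tag}F{i:03d}" for i in range(cfg.n_females)]
        males = [f"{tag}M{i:03d}" for i in range(cfg.n_males)]
        out[sp] = (females, males)
    return out


def simulate_parents(cfg: SimulationConfig,
                     seed: int | None = None) -> tuple[GenotypeMatrix, GroundTruth]:
    """Simulate the sequenced parent panel (all species pooled).

    Per-locus ancestral allele frequencies are uniform on ``maf_range``;
    subgroup frequencies are drawn from a Balding-Nichols beta around them
    (divergence = Fst), which spreads pairwise distances the way distinct
    breeding pools do.  Genotypes are drawn with per-parent inbreeding F, so
    a parent's expected observed heterozygosity is mean_loci 2p(1-p)(1-F).
    A ``clone_fraction`` of parents are near-clones of an earlier parent in
    the same subgroup (all but a ``clone_mutation`` share of loci copied),
    emulating the nearly identical accessions breeding panels carry; together
    with between-pool divergence this spreads pairwise distances from ~0.02
    up past 0.6.  A near-clone's calls are a draw from the same genotype
    model as its source, so its expected heterozygosity is unchanged.
    """
    cfg.validate()
    if cfg.n_loci < 100:
        raise ValueError("n_loci must be >= 100")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    labels = _parent_labels(cfg)
    samples = [s for sp in cfg.species for side in labels[sp] for s in side]

    p_anc = rng.uniform(*cfg.maf_range, size=cfg.n_loci)
    fst = cfg.divergence
    group_of = {s: hash_group for hash_group, s in
                ((i % cfg.n_subgroups, s) for i, s in enumerate(samples))}
    group_freqs = {}
    for g in range(cfg.n_subgroups):
        if fst > 0:
            a = p_anc * (1 - fst) / fst
            b = (1 - p_anc) * (1 - fst) / fst
            group_freqs[g] = np.clip(rng.beta(a, b), 1e-4, 1 - 1e-4)
        else:
            group_freqs[g] = p_anc

    def draw(p: np.ndarray, F: float, loci: np.ndarray | slice) -> np.ndarray:
        p = p[loci]
        p_het = 2 * p * (1 - p) * (1 - F)
        p_homalt = p * p + F * p * (1 - p)
        u = rng.uniform(size=len(p))
        return np.where(u < p_homalt, 2.0,
                        np.where(u < p_homalt + p_het, 1.0, 0.0))

    truth = GroundTruth()
    calls = np.empty((len(samples), cfg.n_loci))
    all_loci = np.arange(cfg.n_loci)
    for i, s in enumerate(samples):
        p = group_freqs[group_of[s]]
        earlier = [j for j in range(i) if group_of[samples[j]] == group_of[s]]
        if earlier and rng.uniform() < cfg.clone_fraction:
            # near-clone of an earlier same-pool parent: same F, calls copied
            # except a redrawn clone_mutation share of loci
            src = int(rng.choice(earlier))
            F = truth.parent_inbreeding[samples[src]]
            calls[i] = calls[src]
            n_mut = int(round(cfg.clone_mutation * cfg.n_loci))
            mut = rng.choice(all_loci, size=n_mut, replace=False)
            calls[i, mut] = draw(p, F, mut)
        else:
            F = float(rng.uniform(*cfg.inbreeding_range))
            calls[i] = draw(p, F, all_loci)
        truth.parent_inbreeding[s] = F
        truth.expected_heterozygosity[s] = float(
            np.mean(2 * p * (1 - p) * (1 - F)))
    g = GenotypeMatrix(samples=samples,
                       loci=[f"SNP{j:05d}" for j in range(cfg.n_loci)],
                       calls=calls)
    return g, truth


# ---------------------------------------------------------------------------
# crossing block
# ---------------------------------------------------------------------------

def _flowering_anchor(species: str, year: int) -> _dt.date:
    # D. rotundata flowers August-October; D. alata October-November.
    month = 10 if "alata" in species else 8
    return _dt.date(year, month, 1)


def simulate_crossing_block(
    cfg: SimulationConfig,
    parents: GenotypeMatrix | None = None,
    seed: int | None = None,
    distances: DistanceMatrix | None = None,
) -> tuple[list[PollinationRecord], GroundTruth]:
    """Simulate pollination batches with injected factor effects.

    Fruits per batch ~ Binomial(flowers, p) with
    logit p = baseline(cross type) + year + site + pollinator + weather +
    combination (+ optional genetic-distance term).  Viable seeds ~
    Binomial(6 x fruits, q); q = ``seed_set_prob`` for compatible crosses and
    q = 0 under the post-zygotic barrier regime, while pre-zygotic barriers
    push the fruit-set logit far down instead.  Running totals are stored in
    the returned truth as an aggregation oracle.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    labels = _parent_labels(cfg)
    truth = GroundTruth(weather_beta=cfg.weather_beta,
                        seed_set_prob=cfg.seed_set_prob)

    truth.year_effects = {y: float(rng.normal(0, cfg.year_sd))
                          for y in cfg.years}
    truth.site_effects = dict(cfg.site_effects)
    pollinators = [f"P{i:02d}" for i in range(cfg.n_pollinators)]
    truth.pollinator_effects = {p: float(rng.normal(0, cfg.pollinator_sd))
                                for p in pollinators}

    # directed combinations: intraspecific per species, plus interspecific
    combos: list[tuple[str, str, str, str, str]] = []  # fem, mal, fsp, msp, regime
    for sp in cfg.species:
        females, males = labels[sp]
        for _ in range(cfg.combinations_per_species):
            f = females[rng.integers(len(females))]
            m = males[rng.integers(len(males))]
            combos.append((f, m, sp, sp, "compatible"))
    if cfg.include_interspecific and len(cfg.species) >= 2:
        for k in range(cfg.n_interspecific):
            i, j = rng.choice(len(cfg.species), size=2, replace=False)
            fsp, msp = cfg.species[i], cfg.species[j]
            f = labels[fsp][0][rng.integers(cfg.n_females)]
            m = labels[msp][1][rng.integers(cfg.n_males)]
            regime = ("prezygotic"
                      if rng.uniform() < cfg.prezygotic_fraction
                      else "postzygotic")
            combos.append((f, m, fsp, msp, regime))

    records: list[PollinationRecord] = []
    tot = {"flowers": 0, "fruits": 0, "seeds": 0}
    for fem, mal, fsp, msp, regime in combos:
        if fsp == msp:
            base = _logit(cfg.baseline_intra[fsp])
        elif regime == "prezygotic":
            base = _logit(cfg.baseline_inter) - 6.0  # fruit set ~ absent
        else:
            base = _logit(cfg.baseline_inter)
        comb_eff = float(rng.normal(0, cfg.combination_sd))
        if cfg.distance_slope_fruit and distances is not None:
            try:
                d = distances.lookup(fem, mal)
            except ValueError:
                d = 0.0
            comb_eff += cfg.distance_slope_fruit * d
        q = 0.0 if regime == "postzygotic" else cfg.seed_set_prob

        for _ in range(cfg.batches_per_combination):
            year = int(rng.choice(cfg.years))
            site = str(rng.choice(cfg.sites))
            pol = str(rng.choice(pollinators))
            week = int(rng.integers(0, 8))
            weather_z = float(rng.normal())  # standardized weekly anomaly
            eta = (base + truth.year_effects[year]
                   + truth.site_effects.get(site, 0.0)
                   + truth.pollinator_effects[pol]
                   + cfg.weather_beta * weather_z + comb_eff)
            p = float(_logistic(eta))
            flowers = 1 + int(rng.poisson(cfg.mean_flowers_per_batch - 1))
            fruits = int(rng.binomial(flowers, p))
            seeds = int(rng.binomial(cfg.ovules_per_fruit * fruits, q))
            date = (_flowering_anchor(fsp, year)
                    + _dt.timedelta(days=7 * week + int(rng.integers(0, 7))))
            records.append(PollinationRecord(
                date=date, site=site,
                female_accession=fem, male_accession=mal,
                female_species=fsp, male_species=msp,
                flowers_pollinated=flowers, fruits_set=fruits,
                viable_seeds=seeds, pollinator_id=pol))
            tot["flowers"] += flowers
            tot["fruits"] += fruits
            tot["seeds"] += seeds
        key = (fem, mal)
        truth.combination_p[key] = float(_logistic(base + comb_eff))
        truth.combination_regime[key] = regime
    truth.totals = tot
    return records, truth


# ---------------------------------------------------------------------------
# germination
# ---------------------------------------------------------------------------

def simulate_germination(
    cfg: SimulationConfig,
    distances: Sequence[float],
    seed: int | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate family germination counts whose success rises with distance.

    ``distances`` supplies one parental genetic distance per family (families
    are drawn with replacement if fewer distances than ``n_families``).
    Germinated ~ Binomial(seeds_per_family, g) with
    logit g = logit(base) + slope * (distance - mean distance); the default
    slope makes the realized family-level Pearson correlation with distance
    ~0.2 at 100 families x 50 seeds.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    d = np.asarray(distances, dtype=float)
    if len(d) == 0:
        raise ValueError("need at least one family distance")
    if len(d) < cfg.n_families:
        d = rng.choice(d, size=cfg.n_families, replace=True)
    else:
        d = rng.choice(d, size=cfg.n_families, replace=False)
    eta = (_logit(cfg.germination_base)
           + cfg.germination_distance_slope * (d - d.mean()))
    g = _logistic(eta)
    germinated = rng.binomial(cfg.seeds_per_family, g)
    df = pd.DataFrame({
        "family": [f"FAM{i:04d}" for i in range(len(d))],
        "cross_category": "intraspecific supervised",
        "distance": d,
        "seeds_sown": cfg.seeds_per_family,
        "seeds_germinated": germinated,
    })
    truth = GroundTruth(germination_slope=cfg.germination_distance_slope,
                        totals={"sown": int(df["seeds_sown"].sum()),
                                "germinated": int(df["seeds_germinated"].sum())})
    return df, truth


# ---------------------------------------------------------------------------
# weather
# ---------------------------------------------------------------------------

_WEATHER_PARAMS = {
    # name: (annual mean, seasonal amplitude, phase day-of-year peak, noise sd)
    "rainfall": (4.2, 3.8, 170, 3.0),        # mm/day, wet mid-year
    "evaporation": (3.5, 1.0, 30, 0.4),
    "wind_speed": (1.9, 0.5, 40, 0.3),
    "solar_radiation": (15.0, 3.0, 60, 1.0),
    "tmin": (22.4, 1.5, 80, 0.8),
    "tmax": (31.6, 2.5, 50, 1.0),
    "rhmin": (50.3, 12.0, 200, 4.0),
    "rhmax": (92.8, 4.0, 200, 2.0),
    "sunshine": (5.8, 1.5, 20, 1.0),
}


def simulate_weather(cfg: SimulationConfig, start: str = "2010-01-01",
                     end: str = "2010-12-31",
                     seed: int | None = None, *,
                     noise: float = 1.0,
                     august_dip: float = 3.0) -> pd.DataFrame:
    """Daily weather series: per-parameter seasonal sinusoid + noise.

    Emulates a West-African humid-savanna climatology: a mid-year wet season
    with a dip in August (``august_dip`` subtracts from daily rainfall in
    August, floored at zero) and dry Novembers.  Rainy days fall out of the
    rainfall series via the strict > 0.5 mm rule at aggregation time.  Set
    ``noise=0`` for an analytic, fully deterministic series.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    dates = pd.date_range(start, end, freq="D")
    if len(dates) < 1:
        raise ValueError("empty date range")
    doy = dates.day_of_year.to_numpy(dtype=float)
    out = {"date": dates}
    for name, (mean, amp, peak, sd) in _WEATHER_PARAMS.items():
        base = mean + amp * np.cos(2 * np.pi * (doy - peak) / 365.25)
        vals = base + noise * rng.normal(0, sd, size=len(dates))
        if name == "rainfall":
            vals = vals - august_dip * (dates.month == 8).astype(float)
            vals = np.clip(vals, 0.0, None)
        if name in {"sunshine", "evaporation", "wind_speed", "solar_radiation"}:
            vals = np.clip(vals, 0.0, None)
        out[name] = vals
    return pd.DataFrame(out)
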