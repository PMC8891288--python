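"""Cross-compatibility indices and the aggregation ladder.

Four indices quantify crossing-block success in yam breeding:

* **crossability rate** — fruits set per 100 flowers hand-pollinated, for one
  directed cross-combination;
* **ACR** (average crossability rate) — the unweighted mean of crossability
  rates over the combinations involving a parent (or within a group);
* **PHC** (percentage high crossability) — the share of a parent's
  combinations whose crossability rate *strictly* exceeds the species-wide
  mean rate;
* **SPE** (seed production efficiency) — viable seeds per 100 potential
  ovules, taking six ovules per pollinated flower.

Crossbred-seed **germination rate** is seedlings emerged per 100 seeds sown.

The aggregation ladder runs combination -> parent -> species/group -> pooled:
group means and SDs are unweighted over combination-level values, and a
pooled row over groups sums the counts while averaging the group means and
the group SDs (the convention under which published multi-species summary
rows reproduce exactly).
"""

from __future__ import annotations

import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .records import OVULES_PER_FRUIT

__all__ = [
    "UndefinedRateError",
    "crossability_rate",
    "seed_production_efficiency",
    "germination_rate",
    "parent_acr",
    "parent_phc",
    "species_overall_mean",
    "combination_summaries",
    "parent_summaries",
    "group_summary",
    "pooled_row",
    "germination_summaries",
    "IITA_INTRASPECIFIC_SPECIES_ROWS",
]


class UndefinedRateError(ValueError):
    """A ratio with zero denominator (no flowers / no seeds sown)."""


# ---------------------------------------------------------------------------
# elementary indices
# ---------------------------------------------------------------------------

def crossability_rate(fruits: int, flowers: int) -> float:
    """Fruits set per 100 flowers pollinated."""
    if flowers <= 0:
        raise UndefinedRateError("crossability rate undefined for zero flowers")
    if fruits < 0 or fruits > flowers:
        raise ValueError(f"fruits_set {fruits} outside [0, flowers={flowers}]")
    return 100.0 * fruits / flowers


def seed_production_efficiency(viable_seeds: int, flowers: int,
                               ovules_per_fruit: int = OVULES_PER_FRUIT) -> float:
    """Viable seeds per 100 potential ovules (``ovules_per_fruit`` per flower)."""
    if flowers <= 0:
        raise UndefinedRateError("SPE undefined for zero flowers")
    if viable_seeds < 0:
        raise ValueError("viable_seeds must be non-negative")
    return 100.0 * viable_seeds / (ovules_per_fruit * flowers)


def germination_rate(germinated: int, sown: int) -> float:
    """Seedlings emerged per 100 seeds sown."""
    if sown <= 0:
        raise UndefinedRateError("germination rate undefined for zero seeds sown")
    if germinated < 0 or germinated > sown:
        raise ValueError(f"germinated {germinated} outside [0, sown={sown}]")
    return 100.0 * germinated / sown


def parent_acr(rates: Sequence[float]) -> float:
    """Average crossability rate: unweighted mean over combination rates."""
    if len(rates) == 0:
        raise ValueError("ACR undefined for an empty rate list")
    return float(np.mean(rates))


def parent_phc(rates: Sequence[float], overall_mean: float) -> float:
    """Percentage of combination rates strictly above the species-wide mean."""
    if len(rates) == 0:
        raise ValueError("PHC undefined for an empty rate list")
    above = sum(1 for r in rates if r > overall_mean)
    return 100.0 * above / len(rates)


def species_overall_mean(rates: Sequence[float]) -> float:
    """Species-wide mean crossability rate: unweighted over combinations.

    This is the PHC threshold.  It is identical to :func:`parent_acr` applied
    to every combination of the species pooled; a separate name keeps the
    threshold's role explicit at call sites.
    """
    return parent_acr(rates)


# ---------------------------------------------------------------------------
# combination -> parent -> group ladder
# ---------------------------------------------------------------------------

def combination_summaries(agg: pd.DataFrame,
                          ovules_per_fruit: int = OVULES_PER_FRUIT) -> pd.DataFrame:
    """Attach crossability rate and SPE to an aggregated combination table.

    ``agg`` is the output of :func:`yamcross.records.aggregate_to_combinations`.
    Combinations whose pooled seed count is unknown get SPE = NA; they still
    carry a crossability rate.
    """
    out = agg.copy()
    zero = out["flowers_pollinated"] <= 0
    if zero.any():
        warnings.warn(f"excluding {int(zero.sum())} zero-flower aggregate(s): "
                      "undefined crossability rate", stacklevel=2)
        out = out[~zero].copy()
    out["crossability_rate"] = (
        100.0 * out["fruits_set"] / out["flowers_pollinated"])
    seeds = out["viable_seeds"].astype("Float64")
    out["spe"] = (100.0 * seeds
                  / (ovules_per_fruit * out["flowers_pollinated"])).astype("Float64")
    return out


def parent_summaries(comb: pd.DataFrame, role: str = "female") -> pd.DataFrame:
    """Per-parent ACR and PHC over that parent's combinations.

    ``role`` selects which side of the cross defines "a parent's
    combinations": ``female``, ``male`` or ``any`` (either side).  The PHC
    threshold is the species-wide mean computed per female-side species
    (unweighted over all that species' combinations in ``comb``).
    """
    if role not in {"female", "male", "any"}:
        raise ValueError(f"unknown role {role!r}")
    thresholds = (comb.groupby("female_species")["crossability_rate"]
                  .mean().to_dict())

    frames = []
    roles = ["female", "male"] if role == "any" else [role]
    for side in roles:
        sub = comb[[f"{side}_accession", "female_species",
                    "crossability_rate"]].rename(
            columns={f"{side}_accession": "accession"})
        frames.append(sub)
    pooled = pd.concat(frames, ignore_index=True)

    rows = []
    for acc, grp in pooled.groupby("accession"):
        rates = grp["crossability_rate"].to_numpy()
        # threshold from the (female-side) species this parent's crosses sit in
        sp = grp["female_species"].mode().iat[0]
        rows.append({
            "accession": acc,
            "role": role,
            "species": sp,
            "n_combinations": len(rates),
            "acr": parent_acr(rates),
            "phc": parent_phc(rates, thresholds[sp]),
        })
    return pd.DataFrame(rows).sort_values("accession").reset_index(drop=True)


def group_summary(comb: pd.DataFrame, group_keys: Sequence[str],
                  *, weighted: bool = False) -> pd.DataFrame:
    """Mean +/- sample SD of combination-level ACR and SPE per group.

    Group statistics are unweighted over cross-combinations by default; pass
    ``weighted=True`` for a flowers-weighted sensitivity variant.  Sample SD
    uses the n-1 denominator; single-combination groups report sd = 0 and are
    flagged in ``sd_degenerate``.  Totals (flowers, combinations, distinct
    female/male parents) are summed per group.
    """
    if not group_keys:
        raise ValueError("group_keys must be non-empty")
    rows = []
    for key, grp in comb.groupby(list(group_keys), dropna=False):
        key = key if isinstance(key, tuple) else (key,)
        acr_vals = grp["crossability_rate"].to_numpy(dtype=float)
        spe_vals = grp["spe"].dropna().to_numpy(dtype=float)
        if weighted:
            w = grp["flowers_pollinated"].to_numpy(dtype=float)
            acr_mean = float(np.average(acr_vals, weights=w))
            spe_w = grp.loc[grp["spe"].notna(), "flowers_pollinated"].to_numpy(dtype=float)
            spe_mean = (float(np.average(spe_vals, weights=spe_w))
                        if len(spe_vals) else math.nan)
        else:
            acr_mean = float(np.mean(acr_vals))
            spe_mean = float(np.mean(spe_vals)) if len(spe_vals) else math.nan
        rows.append({
            **dict(zip(group_keys, key)),
            "n_combinations": len(grp),
            "n_females": grp["female_accession"].nunique(),
            "n_males": grp["male_accession"].nunique(),
            "flowers_pollinated": int(grp["flowers_pollinated"].sum()),
            "acr_mean": acr_mean,
            "acr_sd": float(np.std(acr_vals, ddof=1)) if len(acr_vals) > 1 else 0.0,
            "spe_mean": spe_mean,
            "spe_sd": (float(np.std(spe_vals, ddof=1))
                       if len(spe_vals) > 1 else (0.0 if len(spe_vals) else math.nan)),
            "sd_degenerate": len(acr_vals) < 2,
        })
    return pd.DataFrame(rows)


_POOLED_SUM_COLS = ("n_females", "n_males", "n_combinations",
                    "flowers_pollinated")
_POOLED_MEAN_COLS = ("yearly_crosses_mean", "yearly_crosses_sd",
                     "acr_mean", "acr_sd", "spe_mean", "spe_sd")


def pooled_row(group_rows: pd.DataFrame) -> pd.Series:
    """Pool group-level summary rows into one "sum/mean (+/- SD)" row.

    Counts are summed; means are the unweighted mean of group means; SDs are
    the unweighted mean of group SDs.  This is the convention under which a
    published two-species intraspecific summary reproduces cell-for-cell.
    """
    if len(group_rows) < 2:
        raise ValueError("pooling needs at least two group rows")
    out: dict[str, float] = {}
    for col in _POOLED_SUM_COLS:
        if col in group_rows:
            out[col] = float(group_rows[col].sum())
    for col in _POOLED_MEAN_COLS:
        if col in group_rows:
            out[col] = float(group_rows[col].mean())
    return pd.Series(out)


# ---------------------------------------------------------------------------
# germination
# ---------------------------------------------------------------------------

def germination_summaries(germ: pd.DataFrame,
                          group_keys: Sequence[str] = ("cross_category",)
                          ) -> pd.DataFrame:
    """Germination rates per group from seeds sown/germinated counts.

    ``germ`` needs ``seeds_sown`` and ``seeds_germinated`` columns plus the
    grouping columns (typically ``cross_category`` in {intraspecific
    supervised, interspecific supervised, open-pollinated}, ``species``,
    ``year``).  Per-group rate is pooled: 100 * sum(germinated) / sum(sown).
    A per-family ``germination_rate`` column is also attached to the input
    copy for family-level statistics.
    """
    bad = germ["seeds_germinated"] > germ["seeds_sown"]
    if bad.any():
        raise ValueError(f"{int(bad.sum())} row(s) with germinated > sown")
    grouped = (germ.groupby(list(group_keys), dropna=False)
               .agg(seeds_sown=("seeds_sown", "sum"),
                    seeds_germinated=("seeds_germinated", "sum"),
                    n_families=("seeds_sown", "size"))
               .reset_index())
    grouped["germination_rate"] = (
        100.0 * grouped["seeds_germinated"] / grouped["seeds_sown"])
    return grouped


# ---------------------------------------------------------------------------
# published intraspecific summary rows (IITA crossing blocks, 2010-2020)
# ---------------------------------------------------------------------------

#: Species-level intraspecific crossing-block summaries published for the
#: IITA yam breeding program, 2010-2020 (counts of parents, combinations and
#: flowers; yearly crosses, ACR and SPE as combination-level mean +/- SD).
#: Record-level data behind these rows are not publicly deposited; the rows
#: serve as inputs for pooled-row arithmetic and for scaling synthetic blocks.
IITA_INTRASPECIFIC_SPECIES_ROWS = pd.DataFrame(
    [
        {"species": "d. alata", "n_females": 205, "n_males": 229,
         "n_combinations": 796, "yearly_crosses_mean": 16058.64,
         "yearly_crosses_sd": 8144.28, "flowers_pollinated": 176645,
         "acr_mean": 31.73, "acr_sd": 18.89, "spe_mean": 9.31, "spe_sd": 6.50},
        {"species": "d. rotundata", "n_females": 365, "n_males": 347,
         "n_combinations": 1266, "yearly_crosses_mean": 30228.09,
         "yearly_crosses_sd": 13113.77, "flowers_pollinated": 332509,
         "acr_mean": 23.40, "acr_sd": 18.63, "spe_mean": 9.16, "spe_sd": 3.76},
    ]
)
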