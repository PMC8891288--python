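"""Parental genetic relatedness from SNP genotypes.

Genotypes are unphased diploid dosage calls (count of the alternate allele:
0, 1, 2, or missing) at biallelic loci.  Two pairwise distances are offered:

* **Jaccard dissimilarity** on allele-presence encodings: each genotype at a
  locus is the set of alleles it carries (dosage 0 -> {ref}, 1 -> {ref, alt},
  2 -> {alt}); over all loci where both samples are called, the distance is
  1 - |intersection| / |union| of the pooled presence-indicator sets.
* **IBS distance** (identity by state): 1 minus the mean per-locus fraction
  of alleles shared state-by-state, |dosage_a - dosage_b| mapping to sharing
  1, 0.5, 0.

Missing calls are handled by pairwise deletion.  Observed heterozygosity per
sample is the fraction of its non-missing calls equal to dosage 1.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .records import CrossCombination

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "DistanceMatrix",
    "read_genotypes",
    "jaccard_distance",
    "ibs_distance",
    "pairwise_distance_matrix",
    "observed_heterozygosity",
    "heterozygosity_table",
    "distance_for_cross",
]


@dataclasses.dataclass
class GenotypeMatrix:
    """Samples x biallelic loci, dosage calls in {0, 1, 2}, NaN = missing."""

    samples: list[str]
    loci: list[str]
    calls: np.ndarray  # float array, shape (n_samples, n_loci)
    n_skipped_multiallelic: int = 0

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape != (len(self.samples), len(self.loci)):
            raise ValueError("calls shape inconsistent with labels")
        ok = np.isnan(self.calls) | np.isin(self.calls, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = np.unique(self.calls[~ok])
            raise ValueError(f"dosage calls outside {{0,1,2,missing}}: {bad}")

    def row(self, sample: str) -> np.ndarray:
        return self.calls[self.samples.index(sample)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.calls, index=self.samples, columns=self.loci)


@dataclasses.dataclass
class DistanceMatrix:
    samples: list[str]
    values: np.ndarray
    metric: str  # "jaccard" or "ibs"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.samples)
        if v.shape != (n, n):
            raise ValueError("distance matrix shape inconsistent with labels")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix diagonal not zero")
        self.values = v

    def lookup(self, a: str, b: str) -> float:
        return float(self.values[self.samples.index(a), self.samples.index(b)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.samples, columns=self.samples)


# ---------------------------------------------------------------------------
# input
# ---------------------------------------------------------------------------

def read_genotypes(source: str | Path) -> GenotypeMatrix:
    """Read genotypes from a VCF (biallelic SNPs, GT field) or a dosage CSV.

    CSV layout: first column sample IDs, header row of locus IDs, cells in
    {0, 1, 2} or empty/NA for missing.  VCF records that are not biallelic
    are skipped and counted.  Unphased and phased GT separators are both
    accepted; any missing allele makes the call missing.
    """
    path = Path(source)
    if path.suffix in {".vcf", ".gz", ".bcf"} or str(path).endswith(".vcf.gz"):
        return _read_vcf(path)
    return _read_dosage_csv(path)


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    loci: list[str] = []
    rows: list[np.ndarray] = []
    skipped = 0
    for variant in vcf:
        if len(variant.ALT) != 1 or variant.ALT[0] in (".", ""):
            skipped += 1
            continue
        # gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
        g = variant.gt_types.astype(float)
        dosage = np.where(g == 3, 2.0, g)
        dosage[g == 2] = np.nan
        rows.append(dosage)
        loci.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
    if skipped:
        logger.info("skipped %d non-biallelic VCF record(s)", skipped)
    calls = (np.vstack(rows).T if rows
             else np.empty((len(samples), 0)))
    return GenotypeMatrix(samples=samples, loci=loci, calls=calls,
                          n_skipped_multiallelic=skipped)


def _read_dosage_csv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, index_col=0)
    calls = df.to_numpy(dtype=float)
    ok = np.isnan(calls) | np.isin(calls, (0.0, 1.0, 2.0))
    if not ok.all():
        i, j = np.argwhere(~ok)[0]
        raise ValueError(
            f"invalid dosage {calls[i, j]!r} for sample {df.index[i]!r} "
            f"at locus {df.columns[j]!r} (expected 0, 1, 2 or NA)")
    return GenotypeMatrix(samples=[str(s) for s in df.index],
                          loci=[str(c) for c in df.columns], calls=calls)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def _pairwise_complete(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("call vectors differ in length")
    mask = ~np.isnan(a) & ~np.isnan(b)
    if not mask.any():
        raise ValueError("no shared non-missing loci between the two samples")
    return mask


def jaccard_distance(a: Sequence[float], b: Sequence[float]) -> float:
    """Jaccard dissimilarity of pooled allele-presence sets (see module doc)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    mask = _pairwise_complete(a, b)
    a, b = a[mask], b[mask]
    # presence indicators per locus: ref carried (dosage < 2), alt carried (> 0)
    a_ref, a_alt = a < 2, a > 0
    b_ref, b_alt = b < 2, b > 0
    inter = np.sum(a_ref & b_ref) + np.sum(a_alt & b_alt)
    union = np.sum(a_ref | b_ref) + np.sum(a_alt | b_alt)
    return 1.0 - inter / union


def ibs_distance(a: Sequence[float], b: Sequence[float]) -> float:
    """One minus mean state-by-state allele sharing over shared loci."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    mask = _pairwise_complete(a, b)
    shared = 1.0 - np.abs(a[mask] - b[mask]) / 2.0
    return float(1.0 - shared.mean())


_METRICS = {"jaccard": jaccard_distance, "ibs": ibs_distance}


def pairwise_distance_matrix(g: GenotypeMatrix, metric: str = "jaccard",
                             *, drop_monomorphic: bool = True) -> DistanceMatrix:
    """Symmetric zero-diagonal distance matrix over all sample pairs.

    Monomorphic loci (no alternate or no reference allele observed among the
    non-missing calls) carry no relational information and inflate IBS
    similarity, so they are dropped first (logged).  Missing calls are
    pairwise-deleted per pair; a pair with no shared called locus is an error.
    """
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose jaccard or ibs")
    if len(g.samples) < 2:
        raise ValueError("need at least two samples")
    calls = g.calls
    if drop_monomorphic and calls.shape[1]:
        with np.errstate(invalid="ignore"):
            freq = np.nanmean(calls, axis=0) / 2.0
        poly = (freq > 0) & (freq < 1)
        n_drop = int((~poly).sum())
        if n_drop:
            logger.info("dropping %d monomorphic locus/loci", n_drop)
        calls = calls[:, poly]
        if calls.shape[1] == 0:
            raise ValueError("no polymorphic loci left")
    fn = _METRICS[metric]
    n = len(g.samples)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d[i, j] = d[j, i] = fn(calls[i], calls[j])
            except ValueError as exc:
                raise ValueError(
                    f"pair ({g.samples[i]}, {g.samples[j]}): {exc}") from exc
    return DistanceMatrix(samples=list(g.samples), values=d, metric=metric)


# ---------------------------------------------------------------------------
# heterozygosity
# ---------------------------------------------------------------------------

def observed_heterozygosity(calls: Sequence[float]) -> float:
    """Fraction of non-missing calls that are heterozygous (dosage 1)."""
    calls = np.asarray(calls, dtype=float)
    ok = ~np.isnan(calls)
    if not ok.any():
        raise ValueError("all calls missing for this sample")
    return float(np.mean(calls[ok] == 1.0))


def heterozygosity_table(g: GenotypeMatrix) -> pd.DataFrame:
    """Observed heterozygosity and locus count per sample."""
    rows = []
    for i, s in enumerate(g.samples):
        calls = g.calls[i]
        n_used = int((~np.isnan(calls)).sum())
        rows.append({"sample": s,
                     "het": observed_heterozygosity(calls),
                     "n_loci_used": n_used})
    return pd.DataFrame(rows)


def distance_for_cross(combination: CrossCombination,
                       d: DistanceMatrix) -> float:
    """Parental distance for a cross, NaN when either parent is unsequenced."""
    try:
        return d.lookup(combination.female_accession,
                        combination.male_accession)
    except ValueError:
        return float("nan")
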