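"""Hand-pollination records: reading, validation, cross classification, aggregation.

A crossing-block record is one pollination *batch*: on a given date, at a
given site, a technician pollinated some number of female flowers of one
accession with pollen from one male accession, and the batch later yielded a
count of fruits and (sometimes) viable seeds.  Cross direction matters in a
dioecious crop — the female parent is always listed first and reciprocal
crosses are kept distinct, because unilateral incompatibility (success in one
direction only) is a real phenomenon in interspecific yam crosses.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import io
import json
import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "PollinationRecord",
    "CrossCombination",
    "ValidationIssue",
    "ValidationReport",
    "normalize_species",
    "read_pollination_records",
    "write_pollination_records",
    "classify_cross",
    "aggregate_to_combinations",
    "load_column_map",
    "REQUIRED_COLUMNS",
    "OVULES_PER_FRUIT",
]

#: Expected number of ovules (hence potential seeds) per yam fruit.
OVULES_PER_FRUIT = 6

#: Canonical column names a record table must provide (after column mapping).
REQUIRED_COLUMNS = (
    "date",
    "site",
    "female_accession",
    "male_accession",
    "female_species",
    "male_species",
    "flowers_pollinated",
    "fruits_set",
)

#: Optional canonical columns.
OPTIONAL_COLUMNS = ("pollinator_id", "viable_seeds")

_WILD_RE = re.compile(r"\bwild\b", flags=re.IGNORECASE)


@dataclasses.dataclass(frozen=True)
class PollinationRecord:
    """One hand-pollination batch."""

    date: _dt.date
    site: str
    female_accession: str
    male_accession: str
    female_species: str
    male_species: str
    flowers_pollinated: int
    fruits_set: int
    viable_seeds: int | None = None
    pollinator_id: str | None = None
    female_wild: bool = False
    male_wild: bool = False

    @property
    def year(self) -> int:
        return self.date.year


@dataclasses.dataclass(frozen=True)
class CrossCombination:
    """A directed female x male pairing; reciprocals are distinct."""

    female_accession: str
    male_accession: str
    female_species: str
    male_species: str
    female_wild: bool = False
    male_wild: bool = False

    @property
    def cross_type(self) -> str:
        return (
            "intraspecific"
            if self.female_species == self.male_species
            else "interspecific"
        )


@dataclasses.dataclass(frozen=True)
class ValidationIssue:
    row: int
    rule: str
    severity: str  # "reject" or "warning"
    message: str


@dataclasses.dataclass
class ValidationReport:
    n_records: int = 0
    n_rejected: int = 0
    n_warnings: int = 0
    issues: list[ValidationIssue] = dataclasses.field(default_factory=list)

    @property
    def n_accepted(self) -> int:
        return self.n_records - self.n_rejected

    def add(self, issue: ValidationIssue) -> None:
        self.issues.append(issue)
        if issue.severity == "reject":
            self.n_rejected += 1
        else:
            self.n_warnings += 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [dataclasses.asdict(i) for i in self.issues],
            columns=["row", "rule", "severity", "message"],
        )


def normalize_species(label: str) -> tuple[str, bool]:
    """Normalize a species label to a lowercase token plus a wild flag.

    Labels are matched case- and whitespace-insensitively; a trailing/embedded
    "wild" marker (forest-sourced accessions of an otherwise cultivated
    species) is split off into a boolean so that e.g. cultivated and wild
    D. bulbifera group separately without being treated as different species.
    """
    wild = bool(_WILD_RE.search(label))
    token = _WILD_RE.sub(" ", label)
    token = re.sub(r"\s+", " ", token).strip().lower()
    return token, wild


def load_column_map(path: str | Path) -> dict[str, str]:
    """Load a {source header -> canonical name} mapping from YAML or JSON."""
    text = Path(path).read_text(encoding="utf-8")
    if str(path).endswith(".json"):
        mapping = json.loads(text)
    else:
        mapping = yaml.safe_load(text)
    if not isinstance(mapping, Mapping):
        raise ValueError(f"column map in {path} is not a mapping")
    return {str(k): str(v) for k, v in mapping.items()}


def _parse_count(value: object, field: str) -> int:
    """Parse a non-negative integer count; '7.5' and '-1' are rejected."""
    if value is None or (isinstance(value, float) and pd.isna(value)):
        raise ValueError(f"missing {field}")
    s = str(value).strip()
    if s == "":
        raise ValueError(f"missing {field}")
    try:
        as_float = float(s)
    except ValueError:
        raise ValueError(f"non-integer count in {field}: {value!r}") from None
    if not as_float.is_integer():
        raise ValueError(f"non-integer count in {field}: {value!r}")
    n = int(as_float)
    if n < 0:
        raise ValueError(f"negative count in {field}: {value!r}")
    return n


def _parse_optional_count(value: object, field: str) -> int | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    if s == "" or s.lower() in {"na", "nan", "-", "unknown"}:
        return None
    return _parse_count(s, field)


def read_pollination_records(
    source: str | Path | io.TextIOBase,
    column_map: Mapping[str, str] | None = None,
    *,
    enforce_six_ovule: bool = True,
    sep: str | None = None,
) -> tuple[list[PollinationRecord], ValidationReport]:
    """Read a delimited-text table of pollination batches.

    Each row either becomes a :class:`PollinationRecord` or an itemized
    rejection in the returned :class:`ValidationReport`.  Row-level rules:

    * counts must parse as non-negative integers (rejection otherwise);
    * ``fruits_set <= flowers_pollinated`` (rejection);
    * ``flowers_pollinated >= 1`` (rejection; a batch with no flowers has an
      undefined crossability rate);
    * ``viable_seeds <= 6 * fruits_set`` (warning only when
      ``enforce_six_ovule`` — six ovules per fruit is an expectation, not a
      hard bound).

    A missing required column is a fatal :class:`ValueError` naming it.
    The delimiter is auto-detected from the filename extension (``.tsv`` ->
    tab, else comma) unless ``sep`` is given.
    """
    if sep is None:
        name = getattr(source, "name", str(source))
        sep = "\t" if str(name).endswith((".tsv", ".tab", ".txt")) else ","
    df = pd.read_csv(source, sep=sep, dtype=str, keep_default_na=False)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")

    report = ValidationReport(n_records=len(df))
    records: list[PollinationRecord] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        rowd = dict(zip(df.columns, row))
        try:
            date = _dt.date.fromisoformat(str(rowd["date"]).strip())
        except ValueError:
            report.add(ValidationIssue(idx, "bad-date", "reject",
                                       f"unparseable date {rowd['date']!r}"))
            continue
        try:
            flowers = _parse_count(rowd["flowers_pollinated"], "flowers_pollinated")
            fruits = _parse_count(rowd["fruits_set"], "fruits_set")
            seeds = _parse_optional_count(rowd.get("viable_seeds"), "viable_seeds")
        except ValueError as exc:
            report.add(ValidationIssue(idx, "non-integer count", "reject", str(exc)))
            continue
        if flowers == 0:
            report.add(ValidationIssue(idx, "zero flowers", "reject",
                                       "batch with zero flowers pollinated"))
            continue
        if fruits > flowers:
            report.add(ValidationIssue(
                idx, "fruits exceed flowers", "reject",
                f"fruits_set {fruits} > flowers_pollinated {flowers}"))
            continue
        if (enforce_six_ovule and seeds is not None
                and seeds > OVULES_PER_FRUIT * fruits):
            report.add(ValidationIssue(
                idx, "seeds exceed six-ovule expectation", "warning",
                f"viable_seeds {seeds} > {OVULES_PER_FRUIT} x fruits_set {fruits}"))
        fem_sp, fem_wild = normalize_species(str(rowd["female_species"]))
        mal_sp, mal_wild = normalize_species(str(rowd["male_species"]))
        if not fem_sp or not mal_sp:
            report.add(ValidationIssue(idx, "empty species", "reject",
                                       "empty species label"))
            continue
        pollinator = str(rowd.get("pollinator_id", "")).strip() or None
        records.append(PollinationRecord(
            date=date,
            site=str(rowd["site"]).strip(),
            female_accession=str(rowd["female_accession"]).strip(),
            male_accession=str(rowd["male_accession"]).strip(),
            female_species=fem_sp,
            male_species=mal_sp,
            flowers_pollinated=flowers,
            fruits_set=fruits,
            viable_seeds=seeds,
            pollinator_id=pollinator,
            female_wild=fem_wild,
            male_wild=mal_wild,
        ))
    return records, report


def write_pollination_records(records: Iterable[PollinationRecord],
                              path: str | Path) -> None:
    """Write records to canonical CSV; a read back round-trips field-for-field."""
    rows = []
    for r in records:
        d = dataclasses.asdict(r)
        d["date"] = r.date.isoformat()
        d["female_species"] = r.female_species + (" wild" if r.female_wild else "")
        d["male_species"] = r.male_species + (" wild" if r.male_wild else "")
        del d["female_wild"], d["male_wild"]
        rows.append(d)
    cols = list(REQUIRED_COLUMNS) + list(OPTIONAL_COLUMNS)
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def classify_cross(record: PollinationRecord) -> CrossCombination:
    """Directed combination for a record; intraspecific iff species match."""
    if not record.female_species or not record.male_species:
        raise ValueError("species labels must be non-empty")
    return CrossCombination(
        female_accession=record.female_accession,
        male_accession=record.male_accession,
        female_species=record.female_species,
        male_species=record.male_species,
        female_wild=record.female_wild,
        male_wild=record.male_wild,
    )


_COMBINATION_COLS = [
    "female_accession", "male_accession",
    "female_species", "male_species",
    "female_wild", "male_wild", "cross_type",
]


def aggregate_to_combinations(
    records: Sequence[PollinationRecord],
    grouping: Sequence[str] = (),
) -> pd.DataFrame:
    """Sum counts per directed cross-combination (x optional grouping keys).

    ``grouping`` may contain any of ``year``, ``site``, ``pollinator``.
    Viable-seed totals stay "unknown" (NA) for a key if *any* contributing
    batch lacks a seed count — a partial sum would understate seed set and
    silently bias seed-production efficiency.  Flower and fruit totals are
    always complete, so crossability rate is never lost.
    """
    allowed = {"year", "site", "pollinator"}
    bad = set(grouping) - allowed
    if bad:
        raise ValueError(f"unknown grouping key(s): {sorted(bad)}")
    if not records:
        return pd.DataFrame(columns=_COMBINATION_COLS + list(grouping) +
                            ["flowers_pollinated", "fruits_set", "viable_seeds"])
    rows = []
    for r in records:
        c = classify_cross(r)
        row = {
            "female_accession": c.female_accession,
            "male_accession": c.male_accession,
            "female_species": c.female_species,
            "male_species": c.male_species,
            "female_wild": c.female_wild,
            "male_wild": c.male_wild,
            "cross_type": c.cross_type,
            "flowers_pollinated": r.flowers_pollinated,
            "fruits_set": r.fruits_set,
            "viable_seeds": r.viable_seeds,
        }
        if "year" in grouping:
            row["year"] = r.year
        if "site" in grouping:
            row["site"] = r.site
        if "pollinator" in grouping:
            row["pollinator"] = r.pollinator_id
        rows.append(row)
    df = pd.DataFrame(rows)
    keys = _COMBINATION_COLS + [k for k in ("year", "site", "pollinator")
                                if k in grouping]
    df["viable_seeds"] = df["viable_seeds"].astype("Float64")
    agg = (
        df.groupby(keys, dropna=False)
        .agg(
            flowers_pollinated=("flowers_pollinated", "sum"),
            fruits_set=("fruits_set", "sum"),
            viable_seeds=("viable_seeds", lambda s: s.sum() if s.notna().all()
                          else pd.NA),
            n_batches=("flowers_pollinated", "size"),
        )
        .reset_index()
    )
    agg["viable_seeds"] = agg["viable_seeds"].astype("Float64")
    return agg
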