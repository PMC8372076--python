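"""Core data types and CSV I/O for individual mosquito genotype records.

One mosquito = one :class:`GenotypeRecord` carrying a collection date
(year, month), a zone label and unphased genotype codes at the voltage-gated
sodium channel loci V1016I, F1534C and optionally V410L.  Records are
tabulated into per-stratum genotype count tables and, for the temporal
selection models, collapsed into monthly :class:`SampleSeries` of
(resistant homozygote, heterozygote, susceptible homozygote) counts.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ZONES = ("spray", "buffer", "citywide", "unassigned")

#: Valid unphased genotype codes per locus (susceptible-homozygote first).
GENOTYPE_CODES = {
    "g1016": ("VV", "VI", "II"),
    "g1534": ("FF", "FC", "CC"),
    "g410": ("VV", "VL", "LL"),
}

#: Resistance allele letter per locus (Ile1016, Cys1534, Leu410).
RESISTANT_ALLELE = {"g1016": "I", "g1534": "C", "g410": "L"}

LOCUS_COLUMN = {1016: "g1016", 1534: "g1534", 410: "g410"}

#: Ordered two-locus genotype classes (1016 genotype x 1534 genotype).
TWO_LOCUS_CLASSES = (
    "VV/FF", "VV/FC", "VV/CC",
    "VI/FF", "VI/FC", "VI/CC",
    "II/FF", "II/FC", "II/CC",
)

#: Ordered one-locus genotype classes (R = resistance allele).
ONE_LOCUS_CLASSES = ("RR", "RS", "SS")

CSV_COLUMNS = ("sample_id", "year", "month", "zone", "lat", "lon",
               "g1016", "g1534", "g410")
_MANDATORY_COLUMNS = ("sample_id", "year", "month", "zone", "g1016", "g1534")


@dataclass(frozen=True)
class GenotypeRecord:
    """A single genotyped mosquito."""

    sample_id: str
    year: int
    month: int
    zone: str = "unassigned"
    lat: float | None = None
    lon: float | None = None
    g1016: str | None = None
    g1534: str | None = None
    g410: str | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.month <= 12:
            raise ValueError(f"month must be in 1..12, got {self.month}")
        if self.zone not in ZONES:
            raise ValueError(f"zone must be one of {ZONES}, got {self.zone!r}")
        for col in ("g1016", "g1534", "g410"):
            val = getattr(self, col)
            if val is not None and val not in GENOTYPE_CODES[col]:
                raise ValueError(
                    f"{col} must be one of {GENOTYPE_CODES[col]} or None, got {val!r}"
                )

    @property
    def has_two_locus(self) -> bool:
        """True when genotyped at both V1016I and F1534C."""
        return self.g1016 is not None and self.g1534 is not None


def month_index(year: int, month: int) -> int:
    """Months since year 0, used for ordering and generation gaps."""
    return year * 12 + (month - 1)


def two_locus_class(record: GenotypeRecord) -> str | None:
    """Genotype class ``"VI/FC"`` etc., or None if either locus is missing."""
    if not record.has_two_locus:
        return None
    return f"{record.g1016}/{record.g1534}"


def one_locus_class(record: GenotypeRecord, locus: int) -> str | None:
    """Collapse a per-locus code to RR/RS/SS (R = resistance allele)."""
    col = LOCUS_COLUMN[locus]
    code = getattr(record, col)
    if code is None:
        return None
    n_res = code.count(RESISTANT_ALLELE[col])
    return ONE_LOCUS_CLASSES[2 - n_res]


def _parse_value(raw: str, col: str, row_num: int):
    raw = raw.strip()
    if col in ("year", "month"):
        try:
            return int(raw)
        except ValueError:
            raise ValueError(f"row {row_num}: unparseable {col} {raw!r}") from None
    if col in ("lat", "lon"):
        return float(raw) if raw else None
    if col == "zone":
        return raw if raw else "unassigned"
    if col in GENOTYPE_CODES:
        if not raw or raw.lower() in ("na", "nan", "missing", "."):
            return None
        if raw not in GENOTYPE_CODES[col]:
            logger.warning("row %d: unknown %s code %r mapped to missing",
                           row_num, col, raw)
            return None
        return raw
    return raw


def read_genotype_csv(path) -> list[GenotypeRecord]:
    """Read one-row-per-mosquito records from CSV.

    Unknown genotype strings are mapped to missing with a logged warning;
    missing mandatory columns or unparseable year/month are hard errors.
    """
    records: list[GenotypeRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in _MANDATORY_COLUMNS:
            if col not in header:
                raise ValueError(f"missing mandatory column {col!r} in {path}")
        for i, row in enumerate(reader, start=2):
            kwargs = {}
            for col in CSV_COLUMNS:
                if col in row and row[col] is not None:
                    kwargs[col] = _parse_value(row[col], col, i)
            zone = kwargs.get("zone", "unassigned")
            if zone not in ZONES:
                logger.warning("row %d: unknown zone %r mapped to 'unassigned'",
                               i, zone)
                kwargs["zone"] = "unassigned"
            records.append(GenotypeRecord(**kwargs))
    logger.info("read %d records from %s", len(records), path)
    return records


def write_genotype_csv(records: Iterable[GenotypeRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for r in records:
            writer.writerow([
                r.sample_id, r.year, r.month, r.zone,
                "" if r.lat is None else repr(r.lat),
                "" if r.lon is None else repr(r.lon),
                r.g1016 or "", r.g1534 or "", r.g410 or "",
            ])


def records_to_frame(records: Sequence[GenotypeRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


@dataclass
class GenotypeCountTable:
    """Genotype-class counts for one (period, zone) stratum.

    ``classes`` is either the 9 ordered two-locus classes or the 3 ordered
    one-locus classes; ``counts`` aligns with it.
    """

    period: tuple
    zone: str | None
    classes: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.classes),):
            raise ValueError("counts must align with classes")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def count(self, cls: str) -> int:
        return int(self.counts[self.classes.index(cls)])


def tabulate(
    records: Iterable[GenotypeRecord],
    period: str = "year",
    by_zone: bool = False,
    locus_mode: str = "two-locus",
    locus: int = 1534,
) -> list[GenotypeCountTable]:
    """Tabulate records into per-stratum genotype count tables.

    Parameters
    ----------
    period
        ``"year"`` or ``"month"`` (= calendar year-month) stratification.
    by_zone
        Additionally stratify by zone label.
    locus_mode
        ``"two-locus"`` counts the 9 joint 1016x1534 classes (records
        missing either locus are excluded); ``"one-locus"`` counts RR/RS/SS
        at ``locus`` (records missing that locus are excluded).

    Records are never double-counted; strata are returned sorted by
    (period, zone).  An empty eligible set yields an empty list.
    """
    if period not in ("year", "month"):
        raise ValueError("period must be 'year' or 'month'")
    if locus_mode not in ("two-locus", "one-locus"):
        raise ValueError("locus_mode must be 'two-locus' or 'one-locus'")
    classes = TWO_LOCUS_CLASSES if locus_mode == "two-locus" else ONE_LOCUS_CLASSES
    cls_index = {c: k for k, c in enumerate(classes)}

    strata: dict[tuple, np.ndarray] = {}
    n_in = n_dropped = 0
    for rec in records:
        n_in += 1
        cls = (two_locus_class(rec) if locus_mode == "two-locus"
               else one_locus_class(rec, locus))
        if cls is None:
            n_dropped += 1
            continue
        per = (rec.year,) if period == "year" else (rec.year, rec.month)
        key = (per, rec.zone if by_zone else None)
        if key not in strata:
            strata[key] = np.zeros(len(classes), dtype=np.int64)
        strata[key][cls_index[cls]] += 1
    logger.info("tabulated %d records (%d dropped for missing genotypes)",
                n_in, n_dropped)
    return [
        GenotypeCountTable(period=per, zone=zone, classes=classes,
                           counts=strata[(per, zone)])
        for per, zone in sorted(strata, key=lambda k: (k[0], str(k[1])))
    ]


def tables_to_frame(tables: Sequence[GenotypeCountTable]) -> pd.DataFrame:
    """Tidy frame: stratum columns, then genotype-class columns, then total."""
    rows = []
    for t in tables:
        row: dict = {"year": t.period[0]}
        if len(t.period) > 1:
            row["month"] = t.period[1]
        if t.zone is not None:
            row["zone"] = t.zone
        row.update(dict(zip(t.classes, t.counts.tolist())))
        row["total"] = t.total
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class SampleSeries:
    """Monthly one-locus genotype counts at strictly increasing time points.

    ``months`` holds (year, month) labels; ``counts`` is an integer array of
    shape (T, 3) over (n_RR, n_RS, n_SS).  Months with no sample simply do
    not appear; generation gaps are recovered from the calendar labels.
    """

    months: list[tuple[int, int]]
    counts: np.ndarray
    locus: int | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.months), 3):
            raise ValueError("counts must have shape (len(months), 3)")
        idx = [month_index(y, m) for y, m in self.months]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("months must be strictly increasing")

    def __len__(self) -> int:
        return len(self.months)

    @property
    def n(self) -> np.ndarray:
        """Individuals per time point."""
        return self.counts.sum(axis=1)

    @property
    def t(self) -> np.ndarray:
        """Months elapsed since the first time point."""
        base = month_index(*self.months[0])
        return np.array([month_index(y, m) - base for y, m in self.months])

    def resistance_allele_counts(self) -> np.ndarray:
        """Resistance allele count per time point (2*n_RR + n_RS)."""
        return 2 * self.counts[:, 0] + self.counts[:, 1]

    def resistance_freq(self) -> np.ndarray:
        return self.resistance_allele_counts() / (2 * self.n)


def to_sample_series(
    tables: Sequence[GenotypeCountTable],
    locus: int,
    window: tuple[tuple[int, int], tuple[int, int]] | None = None,
) -> SampleSeries:
    """Assemble monthly one-locus tables into a :class:`SampleSeries`.

    ``tables`` must be one-locus tables stratified by calendar month (the
    output of :func:`tabulate` with ``period="month"``); ``window`` is an
    inclusive ((year, month), (year, month)) range.
    """
    entries = []
    for t in tables:
        if t.classes != ONE_LOCUS_CLASSES:
            raise ValueError("to_sample_series requires one-locus tables")
        if len(t.period) != 2:
            raise ValueError("to_sample_series requires monthly strata")
        if t.total == 0:
            continue
        if window is not None:
            lo, hi = (month_index(*window[0]), month_index(*window[1]))
            if not lo <= month_index(*t.period) <= hi:
                continue
        entries.append((t.period, t.counts))
    if not entries:
        raise ValueError("no sampled months inside the requested window")
    entries.sort(key=lambda e: month_index(*e[0]))
    months = [e[0] for e in entries]
    counts = np.stack([e[1] for e in entries])
    return SampleSeries(months=months, counts=counts, locus=locus)
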