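"""Data model and I/O for flowering tables, climate tables, and the published
province-level fit table.

A species' flowering phenology is recorded at month resolution as a first and a
last flowering month. Windows may wrap the year boundary (e.g. Nov-Feb in
tropical provinces); wrapped windows are handled by linearizing the month axis
(months past December continue as 13, 14, ...). Each window is reduced to the
two parameters the null model consumes: its midpoint and its duration in
months.
"""

from __future__ import annotations

import csv
import hashlib
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

GROWTH_FORMS = ("woody", "herbaceous")

#: sha256 of the packaged province fit table; guards against accidental edits.
_TABLE1_SHA256 = "5b355878b891bbec95357b60928b4310a5b9ef445f97f3d45fa7a459f53df90f"
_TABLE1_RESOURCE = "table1_glm_fits.csv"
_TABLE1_N_ROWS = 27


class ValidationError(ValueError):
    """Raised when an input row violates the data contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FloweringRecord:
    """One species' flowering window in one region.

    ``first_month > last_month`` is legal and denotes a window wrapping the
    December/January seam.
    """

    species_id: str
    region_id: str
    growth_form: str
    first_month: int
    last_month: int

    def __post_init__(self) -> None:
        if self.growth_form not in GROWTH_FORMS:
            raise ValidationError(
                f"growth_form must be one of {GROWTH_FORMS}, got {self.growth_form!r}"
            )
        for name in ("first_month", "last_month"):
            m = getattr(self, name)
            if not isinstance(m, (int, np.integer)) or not 1 <= int(m) <= 12:
                raise ValidationError(f"{name} must be an integer in 1..12, got {m!r}")

    @property
    def wraps(self) -> bool:
        return self.first_month > self.last_month

    def months(self) -> tuple[int, ...]:
        """Calendar months (1..12) this window covers."""
        if not self.wraps:
            return tuple(range(self.first_month, self.last_month + 1))
        return tuple(range(self.first_month, 13)) + tuple(range(1, self.last_month + 1))


@dataclass(frozen=True)
class FloweringRange:
    """Midpoint/duration reduction of a flowering window.

    ``midpoint`` is real-valued in (0, 12]: even durations give half-month
    values, and wrapped windows reduce modulo 12 (a Nov-Feb window has midpoint
    0.5, i.e. the Dec/Jan seam).
    """

    midpoint: float
    duration: int
    wraps: bool

    def __post_init__(self) -> None:
        if not 0 < self.midpoint <= 12:
            raise ValidationError(f"midpoint must lie in (0, 12], got {self.midpoint}")
        if not 1 <= self.duration <= 12:
            raise ValidationError(f"duration must lie in 1..12, got {self.duration}")


@dataclass(frozen=True)
class TemporalDomain:
    """A contiguous inclusive run of months within which ranges are placed.

    The axis is linearized: ``end_month`` may exceed 12 for a domain spanning
    the year seam (e.g. Nov..Feb is start=11, end=14). ``n_bins`` is the domain
    length n.
    """

    start_month: int
    end_month: int

    def __post_init__(self) -> None:
        if not 1 <= self.start_month <= 12:
            raise ValidationError(f"start_month must be in 1..12, got {self.start_month}")
        if not 1 <= self.n_bins <= 12:
            raise ValidationError(
                f"domain must span 1..12 months, got n={self.n_bins} "
                f"({self.start_month}..{self.end_month})"
            )

    @property
    def n_bins(self) -> int:
        return self.end_month - self.start_month + 1

    def months(self) -> tuple[int, ...]:
        """Calendar months of each bin, in domain order."""
        return tuple((m - 1) % 12 + 1 for m in range(self.start_month, self.end_month + 1))

    def __str__(self) -> str:  # e.g. "4-10"
        return f"{self.start_month}-{(self.end_month - 1) % 12 + 1}"


@dataclass(frozen=True)
class RichnessCurve:
    """Observed number of species flowering per domain month."""

    domain: TemporalDomain
    counts: tuple[int, ...]
    n_dropped: int = 0  # species with zero overlap after domain truncation

    def __post_init__(self) -> None:
        if len(self.counts) != self.domain.n_bins:
            raise ValidationError(
                f"counts length {len(self.counts)} != domain n_bins {self.domain.n_bins}"
            )
        if any(c < 0 for c in self.counts):
            raise ValidationError("richness counts must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)


@dataclass(frozen=True)
class ClimateRecord:
    """Monthly climate normals for one region: mean minimum temperature (degC),
    mean monthly precipitation (mm), mean monthly sunshine duration (h)."""

    region_id: str
    month: int
    t_min: float
    mmp: float
    sunshine: float

    def __post_init__(self) -> None:
        if not 1 <= self.month <= 12:
            raise ValidationError(f"month must be in 1..12, got {self.month}")
        if self.mmp < 0:
            raise ValidationError(f"precipitation must be >= 0, got {self.mmp}")
        if not 0 <= self.sunshine <= 744:
            raise ValidationError(f"sunshine hours must be in [0, 744], got {self.sunshine}")


@dataclass(frozen=True)
class GroupFit:
    """F, R^2, P and domain period for one species group, as published."""

    f: float
    r2: float
    p: float
    p_censored: bool  # True when the source prints an upper bound ("<0.001")
    period: TemporalDomain


@dataclass(frozen=True)
class Table1Row:
    """One province row of the published observed-vs-predicted fit table."""

    province: str
    latitude: float
    groups: dict[str, GroupFit] = field(hash=False)

    def fit(self, group: str) -> GroupFit:
        return self.groups[group]


# ---------------------------------------------------------------------------
# Midpoint/duration reduction
# ---------------------------------------------------------------------------


def to_range(record: FloweringRecord) -> FloweringRange:
    """Reduce a flowering window to its midpoint and duration.

    Wrapped windows are linearized (first .. last+12); the midpoint is reduced
    modulo 12 into (0, 12], so Nov-Feb yields midpoint 0.5 with duration 4.
    """
    first = record.first_month
    last = record.last_month + 12 if record.wraps else record.last_month
    duration = last - first + 1
    midpoint = (first + last) / 2.0
    midpoint = math.fmod(midpoint, 12.0)
    if midpoint <= 0:
        midpoint += 12.0
    return FloweringRange(midpoint=midpoint, duration=duration, wraps=record.wraps)


def _overlap_months(record: FloweringRecord, domain: TemporalDomain) -> int:
    dom = set(domain.months())
    return sum(1 for m in record.months() if m in dom)


def observed_richness(
    records: Iterable[FloweringRecord], domain: TemporalDomain
) -> RichnessCurve:
    """Count, for each domain month, the species whose window covers it.

    Windows are clipped to the domain; a species with no overlap contributes
    nothing and is tallied in ``n_dropped``. An empty record set yields an
    all-zero curve.
    """
    months = domain.months()
    index = {m: i for i, m in enumerate(months)}
    counts = [0] * domain.n_bins
    dropped = 0
    for rec in records:
        hit = False
        for m in rec.months():
            i = index.get(m)
            if i is not None:
                counts[i] += 1
                hit = True
        if not hit:
            dropped += 1
    return RichnessCurve(domain=domain, counts=tuple(counts), n_dropped=dropped)


def truncated_durations(
    records: Iterable[FloweringRecord], domain: TemporalDomain
) -> list[int]:
    """Durations of each species' window after clipping to the domain.

    Species with zero overlap are dropped (the null model requires ranges
    inside the bounded domain).
    """
    out = []
    for rec in records:
        d = _overlap_months(rec, domain)
        if d > 0:
            out.append(d)
    return out


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TableDialect:
    """Column mapping and delimiter for delimited flowering/climate tables."""

    delimiter: str = ","
    species_col: str = "species_id"
    region_col: str = "region_id"
    growth_form_col: str = "growth_form"
    first_col: str = "first_month"
    last_col: str = "last_month"


@dataclass(frozen=True)
class FloraTable:
    """Result of reading a flowering table: the valid records plus the count of
    rows excluded for incomplete flowering information."""

    records: tuple[FloweringRecord, ...]
    n_excluded: int

    def __iter__(self) -> Iterator[FloweringRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def read_flora_table(path: str | Path, dialect: TableDialect | None = None) -> FloraTable:
    """Read a delimited flowering table.

    Rows with a missing first or last month are excluded and counted, mirroring
    the source compilation rule that species with incomplete flowering
    information are dropped. An out-of-range month raises ``ValidationError``
    naming the offending row.
    """
    dialect = dialect or TableDialect()
    records: list[FloweringRecord] = []
    n_excluded = 0
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=dialect.delimiter)
        required = {
            dialect.species_col,
            dialect.region_col,
            dialect.growth_form_col,
            dialect.first_col,
            dialect.last_col,
        }
        missing = required - set(reader.fieldnames or ())
        if missing:
            raise ValidationError(f"flora table missing columns: {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            first_raw = (row[dialect.first_col] or "").strip()
            last_raw = (row[dialect.last_col] or "").strip()
            if not first_raw or not last_raw:
                n_excluded += 1
                continue
            try:
                first, last = int(first_raw), int(last_raw)
            except ValueError as exc:
                raise ValidationError(f"row {i}: non-integer month {first_raw!r}/{last_raw!r}") from exc
            try:
                records.append(
                    FloweringRecord(
                        species_id=row[dialect.species_col].strip(),
                        region_id=row[dialect.region_col].strip(),
                        growth_form=row[dialect.growth_form_col].strip(),
                        first_month=first,
                        last_month=last,
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"row {i}: {exc}") from exc
    return FloraTable(records=tuple(records), n_excluded=n_excluded)


def write_flora_table(
    records: Iterable[FloweringRecord], path: str | Path, dialect: TableDialect | None = None
) -> None:
    dialect = dialect or TableDialect()
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=dialect.delimiter)
        writer.writerow(
            [dialect.species_col, dialect.region_col, dialect.growth_form_col,
             dialect.first_col, dialect.last_col]
        )
        for r in records:
            writer.writerow([r.species_id, r.region_id, r.growth_form, r.first_month, r.last_month])


def read_climate_table(path: str | Path, delimiter: str = ",") -> list[ClimateRecord]:
    """Read a delimited monthly climate table (region_id, month, t_min, mmp, sunshine)."""
    out: list[ClimateRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        required = {"region_id", "month", "t_min", "mmp", "sunshine"}
        missing = required - set(reader.fieldnames or ())
        if missing:
            raise ValidationError(f"climate table missing columns: {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            try:
                out.append(
                    ClimateRecord(
                        region_id=row["region_id"].strip(),
                        month=int(row["month"]),
                        t_min=float(row["t_min"]),
                        mmp=float(row["mmp"]),
                        sunshine=float(row["sunshine"]),
                    )
                )
            except (ValueError, ValidationError) as exc:
                raise ValidationError(f"row {i}: {exc}") from exc
    return out


def write_climate_table(
    records: Iterable[ClimateRecord], path: str | Path, delimiter: str = ","
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(["region_id", "month", "t_min", "mmp", "sunshine"])
        for r in records:
            writer.writerow([r.region_id, r.month, r.t_min, r.mmp, r.sunshine])


# ---------------------------------------------------------------------------
# Published fit table fixture
# ---------------------------------------------------------------------------


def _parse_p(raw: str) -> tuple[float, bool]:
    raw = raw.strip()
    if raw.startswith("<"):
        return float(raw[1:]), True
    return float(raw), False


def load_table1_fixture() -> list[Table1Row]:
    """Load the packaged 27-province observed-vs-predicted fit table.

    The file is checksum-pinned; a wrong checksum or row count raises
    ``RuntimeError`` (packaging error).
    """
    ref = resources.files("mdephen.data").joinpath(_TABLE1_RESOURCE)
    data = ref.read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _TABLE1_SHA256:
        raise RuntimeError(
            f"packaged fit table checksum mismatch: {digest} != {_TABLE1_SHA256}"
        )
    rows: list[Table1Row] = []
    reader = csv.DictReader(data.decode("utf-8").splitlines())
    for row in reader:
        groups = {}
        for g in ("all", "herb", "woody"):
            p, censored = _parse_p(row[f"{g}_p"])
            groups[g] = GroupFit(
                f=float(row[f"{g}_f"]),
                r2=float(row[f"{g}_r2"]),
                p=p,
                p_censored=censored,
                period=TemporalDomain(int(row[f"{g}_start"]), int(row[f"{g}_end"])),
            )
        rows.append(Table1Row(province=row["province"], latitude=float(row["latitude"]), groups=groups))
    if len(rows) != _TABLE1_N_ROWS:
        raise RuntimeError(f"packaged fit table has {len(rows)} rows, expected {_TABLE1_N_ROWS}")
    return rows
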