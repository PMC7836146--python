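"""Domain types for longitudinal pregnancy records and their CSV round-trip.

A :class:`PregnancyRecord` bundles the static maternal predictors (height,
pre-pregnancy weight, age, uterine height, abdominal circumference), the
single-shot fetal ultrasound biometry (femur length, fetal abdominal
circumference, biparietal diameter, head circumference, amniotic fluid
index), an irregular series of (gestational week, maternal weight) antenatal
visits, parity, the delivery week and — when known — the birthweight outcome
in grams.

Units are fixed by the schema: maternal weights in kg, birthweight in grams,
lengths/circumferences in cm, gestational age in decimal completed weeks.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace

__all__ = [
    "AntenatalVisit",
    "PregnancyRecord",
    "Cohort",
    "ReadLog",
    "STATIC_PREDICTORS",
    "VALIDATION_RANGES",
    "SchemaError",
    "RecordError",
    "validate_record",
    "read_cohort_csv",
    "write_cohort_csv",
]

#: Static predictor field names, in canonical model-input order.
STATIC_PREDICTORS = ("h", "w", "a", "uh", "acp", "fl", "acf", "bpd", "hc", "afi")

# Observed cohort min/max widened by 10% of the range on each side: the
# published summary describes one hospital population, not biological limits.
_COHORT_MINMAX = {
    "h": (144.0, 184.0),
    "w": (35.0, 163.0),
    "a": (18.0, 46.0),
    "uh": (26.0, 73.0),
    "acp": (73.0, 145.0),
    "fl": (5.9, 8.2),
    "acf": (28.9, 41.7),
    "bpd": (7.9, 10.5),
    "hc": (29.3, 39.2),
    "afi": (2.0, 29.6),
    "delivery_week": (37.0, 44.0),
}


def _widen(lo: float, hi: float, frac: float = 0.10) -> tuple[float, float]:
    pad = (hi - lo) * frac
    return lo - pad, hi + pad


#: Strict-validation ranges per field (widened cohort ranges; hard physical
#: bounds for visits, parity and birthweight).
VALIDATION_RANGES: dict[str, tuple[float, float]] = {
    **{k: _widen(lo, hi) for k, (lo, hi) in _COHORT_MINMAX.items()},
    "visit_week": (4.0, 45.0),
    "visit_weight": (30.0, 200.0),
    "birthweight": (500.0, 6000.0),
    "parity": (0.0, float("inf")),
}

CSV_COLUMNS = [
    "id", "h", "w", "a", "uh", "acp", "fl", "acf", "bpd", "hc", "afi",
    "parity", "delivery_week", "birthweight", "visits",
]


class SchemaError(ValueError):
    """The CSV header does not match the documented schema."""


class RecordError(ValueError):
    """A row violates the record invariants (strict mode only)."""


@dataclass(frozen=True)
class AntenatalVisit:
    """One antenatal check-up: gestational age (weeks) and maternal weight (kg)."""

    week: float
    weight: float


@dataclass(frozen=True)
class PregnancyRecord:
    id: str
    h: float
    w: float
    a: float
    uh: float
    acp: float
    fl: float
    acf: float
    bpd: float
    hc: float
    afi: float
    visits: tuple[AntenatalVisit, ...]
    parity: int
    delivery_week: float
    birthweight: float | None = None

    def static_values(self) -> tuple[float, ...]:
        """The 10 static predictors in canonical order."""
        return tuple(getattr(self, name) for name in STATIC_PREDICTORS)


@dataclass
class Cohort:
    records: list[PregnancyRecord]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subset(self, records: list[PregnancyRecord], note: str | None = None) -> "Cohort":
        prov = dict(self.provenance)
        if note:
            prov["note"] = note
        return Cohort(records=list(records), provenance=prov)


@dataclass
class ReadLog:
    """Outcome of a lenient read: rows kept, dropped, and why."""

    n_read: int = 0
    n_kept: int = 0
    dropped: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_dropped(self) -> int:
        return len(self.dropped)


def validate_record(r: PregnancyRecord) -> list[str]:
    """Return human-readable invariant violations; empty list iff valid."""
    out: list[str] = []
    for name in STATIC_PREDICTORS + ("delivery_week",):
        lo, hi = VALIDATION_RANGES[name]
        v = getattr(r, name)
        if not (lo <= v <= hi):
            out.append(f"{name}={v} outside [{lo:g}, {hi:g}]")
    if r.parity < 0:
        out.append(f"parity={r.parity} negative")
    if r.birthweight is not None:
        lo, hi = VALIDATION_RANGES["birthweight"]
        if not (lo <= r.birthweight <= hi):
            out.append(f"birthweight={r.birthweight} outside [{lo:g}, {hi:g}]")
    wlo, whi = VALIDATION_RANGES["visit_week"]
    glo, ghi = VALIDATION_RANGES["visit_weight"]
    for v in r.visits:
        if not (wlo <= v.week <= whi):
            out.append(f"visit week={v.week} outside [{wlo:g}, {whi:g}]")
        if not (glo <= v.weight <= ghi):
            out.append(f"visit weight={v.weight} outside [{glo:g}, {ghi:g}]")
    weeks = [v.week for v in r.visits]
    if any(b <= a for a, b in zip(weeks, weeks[1:])):
        out.append("visits not sorted strictly increasing by week")
    return out


def _format_visits(visits: tuple[AntenatalVisit, ...]) -> str:
    return ";".join(f"{repr(v.week)}:{repr(v.weight)}" for v in visits)


def _parse_visits(s: str) -> tuple[AntenatalVisit, ...]:
    if not s:
        return ()
    out = []
    for item in s.split(";"):
        wk, wt = item.split(":")
        out.append(AntenatalVisit(week=float(wk), weight=float(wt)))
    return tuple(out)


def _record_to_row(r: PregnancyRecord) -> list[str]:
    row = [r.id]
    row += [repr(float(getattr(r, name))) for name in STATIC_PREDICTORS]
    row.append(str(int(r.parity)))
    row.append(repr(float(r.delivery_week)))
    row.append("" if r.birthweight is None else repr(float(r.birthweight)))
    row.append(_format_visits(r.visits))
    return row


def _row_to_record(row: dict[str, str]) -> PregnancyRecord:
    bw = row.get("birthweight", "")
    return PregnancyRecord(
        id=row["id"],
        **{name: float(row[name]) for name in STATIC_PREDICTORS},
        parity=int(row["parity"]),
        delivery_week=float(row["delivery_week"]),
        birthweight=float(bw) if bw not in ("", None) else None,
        visits=_parse_visits(row.get("visits", "")),
    )


def write_cohort_csv(cohort: Cohort, path) -> None:
    """Write one-row-per-pregnancy CSV; floats use shortest round-trip repr."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(CSV_COLUMNS)
        for r in cohort.records:
            w.writerow(_record_to_row(r))


def read_cohort_csv(path, strict: bool = True) -> tuple[Cohort, ReadLog]:
    """Read a cohort CSV.

    In strict mode any invariant violation or unparseable row raises
    :class:`RecordError`; in lenient mode such rows are dropped and listed in
    the returned :class:`ReadLog`.  A malformed header always raises
    :class:`SchemaError`.
    """
    log = ReadLog()
    records: list[PregnancyRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in CSV_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
        seen_ids: set[str] = set()
        for row in reader:
            log.n_read += 1
            rid = row.get("id", f"<row {log.n_read}>")
            try:
                rec = _row_to_record(row)
            except (KeyError, ValueError) as exc:
                if strict:
                    raise RecordError(f"row {rid}: unparseable field ({exc})") from exc
                log.dropped.append((rid, f"unparseable: {exc}"))
                continue
            violations = validate_record(rec)
            if rec.id in seen_ids:
                violations.append("duplicate record id")
            if violations:
                if strict:
                    raise RecordError(f"row {rid}: " + "; ".join(violations))
                log.dropped.append((rid, "; ".join(violations)))
                continue
            seen_ids.add(rec.id)
            records.append(rec)
            log.n_kept += 1
    return Cohort(records=records, provenance={"source": str(path)}), log


def read_cohort_long_csv(path, strict: bool = True) -> tuple[Cohort, ReadLog]:
    """Alternate long-format reader: one row per visit.

    Expects columns ``id,week,weight`` plus the wide static columns repeated
    per row; static values are taken from each id's first row.
    """
    import pandas as pd

    df = pd.read_csv(path)
    needed = {"id", "week", "weight"} | set(STATIC_PREDICTORS) | {"parity", "delivery_week"}
    missing = needed - set(df.columns)
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(sorted(missing))}")
    log = ReadLog()
    records = []
    for rid, grp in df.groupby("id", sort=False):
        log.n_read += 1
        grp = grp.sort_values("week")
        first = grp.iloc[0]
        bw = first.get("birthweight")
        rec = PregnancyRecord(
            id=str(rid),
            **{name: float(first[name]) for name in STATIC_PREDICTORS},
            parity=int(first["parity"]),
            delivery_week=float(first["delivery_week"]),
            birthweight=None if bw is None or pd.isna(bw) else float(bw),
            visits=tuple(
                AntenatalVisit(float(t), float(x)) for t, x in zip(grp["week"], grp["weight"])
            ),
        )
        violations = validate_record(rec)
        if violations:
            if strict:
                raise RecordError(f"id {rid}: " + "; ".join(violations))
            log.dropped.append((str(rid), "; ".join(violations)))
            continue
        records.append(rec)
        log.n_kept += 1
    return Cohort(records=records, provenance={"source": str(path)}), log


def strip_outcome(r: PregnancyRecord) -> PregnancyRecord:
    """Copy of a record without its birthweight label (pure-prediction use)."""
    return replace(r, birthweight=None)
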