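"""Tabular input/output and purchase-history assembly.

Reads dispensing records and institutional-stay records from delimited
text, harmonises ATC/DDD codes against a correction map, arranges
purchases into chronological per-person-per-ATC histories, and writes
the eight-field drug use period file.

Missing values are an explicit tri-state (``None`` vs. a value), never
sentinel zeros: downstream decision rules branch on whether the
dispensed DDD amount was registered at all.
"""

from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Purchase",
    "InstitutionalStay",
    "History",
    "CodeMap",
    "ExceptionRecord",
    "InputFormatError",
    "is_valid_atc",
    "read_purchases",
    "write_purchases",
    "read_stays",
    "write_stays",
    "harmonize",
    "sort_histories",
    "write_periods",
    "read_periods",
    "write_exceptions",
    "merge_stays",
    "hospital_days_between",
]

# ATC grammar: letter, +2 digits, +letter, +letter, +2 digits — valid
# truncations are the classification levels 1, 3, 4, 5 and 7.
_ATC_RE = re.compile(r"^[A-Z]$|^[A-Z]\d{2}$|^[A-Z]\d{2}[A-Z]$|^[A-Z]\d{2}[A-Z]{2}$|^[A-Z]\d{2}[A-Z]{2}\d{2}$")


def is_valid_atc(code: str) -> bool:
    """True if *code* matches the ATC code grammar at level 1/3/4/5/7."""
    return bool(_ATC_RE.match(code))


class InputFormatError(ValueError):
    """A delimited input could not be interpreted.

    Carries ``row_errors``: a list of ``(row_number, message)`` pairs
    where row numbers refer to the data file including its header row
    (first data row is row 2).
    """

    def __init__(self, message: str, row_errors: Sequence[tuple[int, str]] = ()):
        self.row_errors = list(row_errors)
        if self.row_errors:
            detail = "; ".join(f"row {r}: {m}" for r, m in self.row_errors[:20])
            if len(self.row_errors) > 20:
                detail += f"; … {len(self.row_errors) - 20} more"
            message = f"{message} ({detail})"
        super().__init__(message)


@dataclass(frozen=True)
class Purchase:
    """One dispensing event.

    ``ddd_amount`` is the total amount dispensed expressed in Defined
    Daily Doses (DDD); ``vnr`` is the Nordic Article number identifying
    the exact package. ``vnr_mixed`` marks a same-day merge of rows
    with differing package identifiers; ``merged`` marks any same-day
    merge (see :func:`sort_histories`).
    """

    person_id: str
    date: dt.date
    atc: str | None = None
    vnr: str | None = None
    n_packages: int | None = None
    ddd_amount: float | None = None
    dose_dispensing: bool = False
    vnr_mixed: bool = False
    merged: bool = False

    def __post_init__(self) -> None:
        if self.n_packages is not None and self.n_packages < 1:
            raise ValueError(f"n_packages must be >= 1, got {self.n_packages}")
        if self.ddd_amount is not None and self.ddd_amount < 0:
            raise ValueError(f"ddd_amount must be >= 0, got {self.ddd_amount}")
        if self.atc is not None and not is_valid_atc(self.atc):
            raise ValueError(f"not a valid ATC code: {self.atc!r}")


@dataclass(frozen=True)
class InstitutionalStay:
    """A hospital or long-term-care interval; purchases pause during it.

    ``discharge`` is ``None`` for a stay that is still open at the end
    of the data. Day counting treats the interval as half-open
    ``[admission, discharge)``: the discharge day is not a hospital day.
    """

    person_id: str
    admission: dt.date
    discharge: dt.date | None = None

    def __post_init__(self) -> None:
        if self.discharge is not None and self.discharge < self.admission:
            raise ValueError("discharge precedes admission")

    @property
    def length_days(self) -> float:
        """Stay length in days; ``inf`` for an open stay."""
        if self.discharge is None:
            return float("inf")
        return (self.discharge - self.admission).days


@dataclass(frozen=True)
class History:
    """Chronologically ordered purchases of one ATC code by one person."""

    person_id: str
    atc: str
    purchases: tuple[Purchase, ...]

    def __post_init__(self) -> None:
        dates = [p.date for p in self.purchases]
        if any(b < a for a, b in zip(dates, dates[1:])):
            raise ValueError("history purchases are not in chronological order")

    def __len__(self) -> int:
        return len(self.purchases)


@dataclass(frozen=True)
class ExceptionRecord:
    """A purchase routed to the exceptions sink, with the reason."""

    purchase: Purchase
    reason: str


@dataclass(frozen=True)
class CodeMap:
    """Corrections applied before modelling.

    ``atc_renames`` maps superseded ATC codes to their current code;
    chains (A→B, B→C) are collapsed to terminal codes at construction
    so that applying the map twice equals applying it once. ``ddd_fills``
    maps a package identifier (vnr) to its DDD content per package,
    used to fill unregistered DDD amounts.
    """

    atc_renames: Mapping[str, str] = field(default_factory=dict)
    ddd_fills: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        collapsed: dict[str, str] = {}
        for old in self.atc_renames:
            seen = {old}
            cur = self.atc_renames[old]
            while cur in self.atc_renames:
                if cur in seen:
                    raise ValueError(f"cyclic ATC rename chain through {cur!r}")
                seen.add(cur)
                cur = self.atc_renames[cur]
            collapsed[old] = cur
        object.__setattr__(self, "atc_renames", collapsed)


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

#: Standard column names; a schema maps these onto the actual file header.
PURCHASE_COLUMNS = (
    "person_id",
    "date",
    "atc",
    "vnr",
    "n_packages",
    "ddd_amount",
    "dose_dispensing",
)

_TRUE_STRINGS = {"1", "true", "yes", "t", "y"}
_FALSE_STRINGS = {"0", "false", "no", "f", "n", ""}


def _read_table(source: str | Path | IO[str], sep: str) -> pd.DataFrame:
    try:
        return pd.read_csv(source, sep=sep, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return pd.DataFrame()


def _parse_date(text: str, date_format: str | None) -> dt.date:
    if date_format is not None:
        return dt.datetime.strptime(text, date_format).date()
    return dt.date.fromisoformat(text)


def read_purchases(
    source: str | Path | IO[str],
    schema: Mapping[str, str] | None = None,
    sep: str = ",",
    date_format: str | None = None,
) -> list[Purchase]:
    """Read dispensing records from delimited text.

    Parameters
    ----------
    source
        Path or open text stream with a header row.
    schema
        Mapping from the standard column names in
        :data:`PURCHASE_COLUMNS` to the columns actually present, so
        national register exports can be adapted without code changes.
        Unmapped optional columns are treated as absent.
    sep
        Field separator (comma or tab).
    date_format
        ``strptime`` format; ISO-8601 by default.

    Empty files yield an empty list. Rows whose dates or numeric fields
    cannot be parsed are rejected collectively via
    :class:`InputFormatError` listing the offending row numbers.
    Blank vnr / DDD cells are preserved as missing, never coerced to 0.
    """
    schema = dict(schema or {})
    colmap = {std: schema.get(std, std) for std in PURCHASE_COLUMNS}
    df = _read_table(source, sep)
    if df.empty and len(df.columns) == 0:
        return []
    for required in ("person_id", "date"):
        if colmap[required] not in df.columns:
            raise InputFormatError(f"missing required column {colmap[required]!r}")

    purchases: list[Purchase] = []
    errors: list[tuple[int, str]] = []
    have = {std: colmap[std] in df.columns for std in PURCHASE_COLUMNS}
    for idx, row in enumerate(df.itertuples(index=False)):
        rowno = idx + 2  # header is row 1
        rec = dict(zip(df.columns, row))

        def cell(std: str) -> str:
            return str(rec[colmap[std]]).strip() if have[std] else ""

        try:
            date = _parse_date(cell("date"), date_format)
        except ValueError:
            errors.append((rowno, f"unparseable date {cell('date')!r}"))
            continue
        atc = cell("atc") or None
        if atc is not None and not is_valid_atc(atc):
            # kept: harmonize() routes invalid codes to the exceptions sink
            pass
        try:
            n_packages = int(cell("n_packages")) if cell("n_packages") else None
            ddd_amount = float(cell("ddd_amount")) if cell("ddd_amount") else None
        except ValueError as exc:
            errors.append((rowno, str(exc)))
            continue
        dd_raw = cell("dose_dispensing").lower()
        if dd_raw in _TRUE_STRINGS:
            dose_dispensing = True
        elif dd_raw in _FALSE_STRINGS:
            dose_dispensing = False
        else:
            errors.append((rowno, f"unparseable boolean {dd_raw!r}"))
            continue
        try:
            purchases.append(
                Purchase(
                    person_id=cell("person_id"),
                    date=date,
                    atc=atc if atc and is_valid_atc(atc) else None,
                    vnr=cell("vnr") or None,
                    n_packages=n_packages,
                    ddd_amount=ddd_amount,
                    dose_dispensing=dose_dispensing,
                )
            )
        except ValueError as exc:
            errors.append((rowno, str(exc)))
    if errors:
        raise InputFormatError("malformed purchase file", errors)
    return purchases


def write_purchases(
    purchases: Iterable[Purchase], sink: str | Path | IO[str], sep: str = ","
) -> None:
    """Write purchases in the standard column layout (lossless round trip)."""
    rows = []
    for p in purchases:
        rows.append(
            {
                "person_id": p.person_id,
                "date": p.date.isoformat(),
                "atc": p.atc or "",
                "vnr": p.vnr or "",
                "n_packages": "" if p.n_packages is None else p.n_packages,
                "ddd_amount": "" if p.ddd_amount is None else repr(p.ddd_amount),
                "dose_dispensing": int(p.dose_dispensing),
            }
        )
    pd.DataFrame(rows, columns=list(PURCHASE_COLUMNS)).to_csv(sink, sep=sep, index=False)


def read_stays(
    source: str | Path | IO[str],
    schema: Mapping[str, str] | None = None,
    sep: str = ",",
    date_format: str | None = None,
) -> list[InstitutionalStay]:
    """Read institutional stays; blank discharge means still in care."""
    schema = dict(schema or {})
    cols = {k: schema.get(k, k) for k in ("person_id", "admission", "discharge")}
    df = _read_table(source, sep)
    if df.empty and len(df.columns) == 0:
        return []
    for required in ("person_id", "admission"):
        if cols[required] not in df.columns:
            raise InputFormatError(f"missing required column {cols[required]!r}")
    stays: list[InstitutionalStay] = []
    errors: list[tuple[int, str]] = []
    has_discharge = cols["discharge"] in df.columns
    for idx, rec in enumerate(df.to_dict("records")):
        rowno = idx + 2
        try:
            admission = _parse_date(str(rec[cols["admission"]]).strip(), date_format)
            d_raw = str(rec[cols["discharge"]]).strip() if has_discharge else ""
            discharge = _parse_date(d_raw, date_format) if d_raw else None
            stays.append(
                InstitutionalStay(
                    person_id=str(rec[cols["person_id"]]),
                    admission=admission,
                    discharge=discharge,
                )
            )
        except ValueError as exc:
            errors.append((rowno, str(exc)))
    if errors:
        raise InputFormatError("malformed stay file", errors)
    return stays


def write_stays(
    stays: Iterable[InstitutionalStay], sink: str | Path | IO[str], sep: str = ","
) -> None:
    rows = [
        {
            "person_id": s.person_id,
            "admission": s.admission.isoformat(),
            "discharge": s.discharge.isoformat() if s.discharge else "",
        }
        for s in stays
    ]
    pd.DataFrame(rows, columns=["person_id", "admission", "discharge"]).to_csv(
        sink, sep=sep, index=False
    )


# ---------------------------------------------------------------------------
# harmonisation and history assembly
# ---------------------------------------------------------------------------


def harmonize(
    purchases: Iterable[Purchase], code_map: CodeMap | None = None
) -> tuple[list[Purchase], list[ExceptionRecord]]:
    """Apply ATC renames and DDD fills; route unfixable rows to a sink.

    Returns ``(kept, exceptions)``. Superseded ATC codes are replaced by
    their current code; a missing DDD amount is filled from the package
    map (DDD per package × number of packages) where a mapping exists.
    Purchases still lacking an ATC code are retained in the exceptions
    sink rather than silently dropped, keeping the pipeline total and
    auditable. Idempotent: a second application is a no-op.
    """
    code_map = code_map or CodeMap()
    kept: list[Purchase] = []
    exceptions: list[ExceptionRecord] = []
    for p in purchases:
        if p.atc is not None and p.atc in code_map.atc_renames:
            p = replace(p, atc=code_map.atc_renames[p.atc])
        if p.ddd_amount is None and p.vnr is not None and p.vnr in code_map.ddd_fills:
            per_pack = code_map.ddd_fills[p.vnr]
            p = replace(p, ddd_amount=per_pack * (p.n_packages or 1))
        if p.atc is None:
            exceptions.append(ExceptionRecord(p, "missing ATC code"))
        else:
            kept.append(p)
    return kept, exceptions


def _merge_same_day(group: list[Purchase]) -> Purchase:
    first = group[0]
    if len(group) == 1:
        return first
    ddd_values = [p.ddd_amount for p in group if p.ddd_amount is not None]
    npk_values = [p.n_packages for p in group if p.n_packages is not None]
    vnrs = {p.vnr for p in group}
    same_vnr = len(vnrs) == 1 and None not in vnrs
    return Purchase(
        person_id=first.person_id,
        date=first.date,
        atc=first.atc,
        vnr=first.vnr if same_vnr else None,
        n_packages=sum(npk_values) if npk_values else None,
        ddd_amount=sum(ddd_values) if ddd_values else None,
        dose_dispensing=any(p.dose_dispensing for p in group),
        vnr_mixed=not same_vnr,
        merged=True,
    )


def sort_histories(purchases: Iterable[Purchase]) -> list[History]:
    """Group purchases into chronological per-(person, ATC) histories.

    Same-day purchases of the same ATC code are merged into one purchase
    whose DDD amount and package count are sums; the vnr survives only
    when identical across the merged rows, otherwise the merge is marked
    ``vnr_mixed``. Purchases without an ATC code are ignored here (they
    belong in the exceptions sink; see :func:`harmonize`).
    """
    buckets: dict[tuple[str, str], list[Purchase]] = {}
    for p in purchases:
        if p.atc is None:
            continue
        buckets.setdefault((p.person_id, p.atc), []).append(p)
    histories: list[History] = []
    for (person_id, atc), group in sorted(buckets.items()):
        group.sort(key=lambda p: p.date)
        merged: list[Purchase] = []
        day: list[Purchase] = []
        for p in group:
            if day and p.date != day[0].date:
                merged.append(_merge_same_day(day))
                day = []
            day.append(p)
        merged.append(_merge_same_day(day))
        histories.append(History(person_id, atc, tuple(merged)))
    return histories


# ---------------------------------------------------------------------------
# period file
# ---------------------------------------------------------------------------

#: The eight output fields of a drug use period, in file order.
PERIOD_COLUMNS = (
    "start_date",
    "end_date",
    "person_id",
    "atc",
    "total_ddd",
    "hospital_days",
    "n_purchases",
    "mean_ddd_per_day",
)


def write_periods(periods: Iterable, sink: str | Path | IO[str], sep: str = ",") -> None:
    """Write drug use periods as the eight-field delimited file.

    Dates are ISO-8601; dose fields carry four decimal digits so the
    read-back reproduces the periods.
    """
    rows = []
    for per in periods:
        rows.append(
            {
                "start_date": per.start.isoformat(),
                "end_date": per.end.isoformat(),
                "person_id": per.person_id,
                "atc": per.atc,
                "total_ddd": f"{per.total_ddd:.4f}",
                "hospital_days": per.hospital_days,
                "n_purchases": per.n_purchases,
                "mean_ddd_per_day": f"{per.mean_ddd_per_day:.4f}",
            }
        )
    pd.DataFrame(rows, columns=list(PERIOD_COLUMNS)).to_csv(sink, sep=sep, index=False)


def read_periods(source: str | Path | IO[str], sep: str = ","):
    """Read a period file back into :class:`~pre2dup.core.DrugUsePeriod` records."""
    from .core import DrugUsePeriod  # local import to avoid a cycle

    df = _read_table(source, sep)
    if df.empty and len(df.columns) == 0:
        return []
    missing = [c for c in PERIOD_COLUMNS if c not in df.columns]
    if missing:
        raise InputFormatError(f"missing period columns {missing}")
    periods = []
    for rec in df.to_dict("records"):
        periods.append(
            DrugUsePeriod(
                person_id=str(rec["person_id"]),
                atc=str(rec["atc"]),
                start=dt.date.fromisoformat(str(rec["start_date"])),
                end=dt.date.fromisoformat(str(rec["end_date"])),
                total_ddd=float(rec["total_ddd"]),
                n_purchases=int(rec["n_purchases"]),
                hospital_days=int(rec["hospital_days"]),
                mean_ddd_per_day=float(rec["mean_ddd_per_day"]),
            )
        )
    return periods


def write_exceptions(
    exceptions: Iterable[ExceptionRecord], sink: str | Path | IO[str], sep: str = ","
) -> None:
    """Write the exceptions sink: the original row fields plus a reason."""
    rows = []
    for rec in exceptions:
        p = rec.purchase
        rows.append(
            {
                "person_id": p.person_id,
                "date": p.date.isoformat(),
                "atc": p.atc or "",
                "vnr": p.vnr or "",
                "n_packages": "" if p.n_packages is None else p.n_packages,
                "ddd_amount": "" if p.ddd_amount is None else repr(p.ddd_amount),
                "dose_dispensing": int(p.dose_dispensing),
                "reason": rec.reason,
            }
        )
    cols = list(PURCHASE_COLUMNS) + ["reason"]
    pd.DataFrame(rows, columns=cols).to_csv(sink, sep=sep, index=False)


# ---------------------------------------------------------------------------
# stay arithmetic (shared by preprocess and core)
# ---------------------------------------------------------------------------


def merge_stays(
    stays: Iterable[InstitutionalStay],
) -> dict[str, list[tuple[dt.date, dt.date | None]]]:
    """Merge each person's stays so stored stays never overlap.

    Overlapping or abutting stays (re-admission on the discharge day,
    e.g. a transfer between institutions) merge into one continuous
    stay. Returns per-person sorted ``(admission, discharge)`` tuples
    with ``None`` discharge meaning open-ended.
    """
    by_person: dict[str, list[InstitutionalStay]] = {}
    for s in stays:
        by_person.setdefault(s.person_id, []).append(s)
    merged: dict[str, list[tuple[dt.date, dt.date | None]]] = {}
    for person, plist in by_person.items():
        plist.sort(key=lambda s: s.admission)
        out: list[tuple[dt.date, dt.date | None]] = []
        for s in plist:
            if out and (out[-1][1] is None or s.admission <= out[-1][1]):
                adm, dis = out[-1]
                if dis is None or s.discharge is None:
                    out[-1] = (adm, None)
                else:
                    out[-1] = (adm, max(dis, s.discharge))
            else:
                out.append((s.admission, s.discharge))
        merged[person] = out
    return merged


def hospital_days_between(
    stays: Sequence[tuple[dt.date, dt.date | None]], start: dt.date, end: dt.date
) -> int:
    """Count hospital days in the half-open interval ``[start, end)``.

    A day is a hospital day if it falls inside some merged stay
    ``[admission, discharge)``.
    """
    if end <= start:
        return 0
    total = 0
    for admission, discharge in stays:
        lo = max(start, admission)
        hi = end if discharge is None else min(end, discharge)
        if hi > lo:
            total += (hi - lo).days
    return total
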