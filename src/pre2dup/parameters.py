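"""The three-level expert parameter hierarchy.

Restriction parameters keep the joining of purchases realistic. They
live on three levels, from coarse to fine:

* **global** — caps that apply to every purchase and can never be
  overridden (maximum refill gap, maximum in-period hospital stay,
  maximum daily dose, maximum single-purchase length, …);
* **ATC class** — dose limits and refill lengths per classification
  prefix at any level of the ATC hierarchy; the finest defined prefix
  of a purchase's code wins;
* **package (vnr)** — per-package refill-length and dose limits derived
  from pack size, divisibility and dosing frequency; these override the
  ATC-class values.

Parameter files are human-editable YAML. Each ATC/vnr file is a list of
records (canonical, allows duplicate detection) or a plain mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import IO, Any, Iterable, Mapping

import yaml

__all__ = [
    "GlobalParams",
    "AtcParams",
    "PackageParams",
    "ParameterSpace",
    "ParameterError",
    "load_parameter_space",
    "resolve_atc",
    "resolve_package",
]


class ParameterError(ValueError):
    """Invalid parameter input; carries field-level messages."""

    def __init__(self, messages: Iterable[str]):
        self.messages = list(messages)
        super().__init__("; ".join(self.messages))


@dataclass(frozen=True)
class GlobalParams:
    """Global caps; apply to all purchases and cannot be overridden.

    Attributes
    ----------
    max_refill_gap_days
        Maximum refill time in the sliding-average calculus; a longer
        (hospital-adjusted) gap restarts the treatment segment. 300 d.
    max_hospital_days_in_period
        Longest continuous institutional stay a period may contain or
        extend over. 30 d.
    max_ddd_per_day
        Dose ceiling guarding against purchases a few days apart. 10.
    max_single_purchase_days
        Hard cap on the modelled duration of a lone purchase. 150 d.
    dvar
        Weight on the coefficient of variation in the purchase-
        regularity multiplier ``1 + dvar·cv``. 0.5.
    adherence_slack
        Relative allowance for non-perfect adherence when a duration is
        derived from a typical daily dose. 0.2.
    mode_min_purchases
        A learned refill-length mode is used only when its joined count
        exceeds this. 10.
    refill_source_min_purchases
        Periods contribute refill-length observations only with at
        least this many purchases. 6.
    ddd_avg_min_purchases
        Sliding dose averages require at least this many purchases. 3.
    """

    max_refill_gap_days: int = 300
    max_hospital_days_in_period: int = 30
    max_ddd_per_day: float = 10.0
    max_single_purchase_days: int = 150
    dvar: float = 0.5
    adherence_slack: float = 0.2
    mode_min_purchases: int = 10
    refill_source_min_purchases: int = 6
    ddd_avg_min_purchases: int = 3

    def __post_init__(self) -> None:
        errors = []
        for f in fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, (int, float)) or isinstance(v, bool) or not v > 0:
                errors.append(f"{f.name}: must be strictly positive, got {v!r}")
        for name in ("dvar", "adherence_slack"):
            v = getattr(self, name)
            if isinstance(v, (int, float)) and not 0 <= v <= 1:
                errors.append(f"{name}: must lie in [0, 1], got {v!r}")
        if errors:
            raise ParameterError(errors)


@dataclass(frozen=True)
class AtcParams:
    """Expert limits for one ATC classification prefix.

    ``min_ddd_per_day`` is the period-splitting lower dose limit: a
    sliding average below it means the next purchase is further away
    than regular use of the drug would allow. ``common_ddd_per_day`` is
    the fallback daily dose when no better duration estimate exists.
    """

    atc_prefix: str
    min_ddd_per_day: float
    common_ddd_per_day: float
    min_period_days: int
    max_refill_days: int

    def __post_init__(self) -> None:
        errors = []
        for name in ("min_ddd_per_day", "common_ddd_per_day", "min_period_days", "max_refill_days"):
            v = getattr(self, name)
            if not v > 0:
                errors.append(f"{self.atc_prefix}.{name}: must be positive, got {v!r}")
        if self.min_ddd_per_day > self.common_ddd_per_day:
            errors.append(
                f"{self.atc_prefix}: min_ddd_per_day ({self.min_ddd_per_day}) exceeds "
                f"common_ddd_per_day ({self.common_ddd_per_day})"
            )
        if errors:
            raise ParameterError(errors)


@dataclass(frozen=True)
class PackageParams:
    """Expert refill-length limits for one drug package (vnr).

    Lengths are anchored to the pack's content: e.g. 30 non-dividable
    once-daily capsules give a typical refill length of 30 days, a
    minimum of 15 days (two capsules daily as the maximum dose) and a
    maximum of 30 — or 1.2 × 30 to allow some non-adherence. The
    corresponding DDD-per-day values are the doses at those lengths, so
    ``ddd_per_day_at_min`` (shortest refill) is the package's *upper*
    dose limit and ``ddd_per_day_at_max`` its *lower* dose limit.
    """

    vnr: str
    min_refill_days: int
    max_refill_days: int
    typical_refill_days: int
    ddd_per_day_at_min: float
    ddd_per_day_at_max: float
    ddd_per_day_typical: float

    def __post_init__(self) -> None:
        errors = []
        for name in (
            "min_refill_days",
            "max_refill_days",
            "typical_refill_days",
            "ddd_per_day_at_min",
            "ddd_per_day_at_max",
            "ddd_per_day_typical",
        ):
            v = getattr(self, name)
            if not v > 0:
                errors.append(f"vnr {self.vnr}.{name}: must be positive, got {v!r}")
        if not errors and not (
            self.min_refill_days <= self.typical_refill_days <= self.max_refill_days
        ):
            errors.append(
                f"vnr {self.vnr}: refill lengths must satisfy min <= typical <= max, got "
                f"{self.min_refill_days}/{self.typical_refill_days}/{self.max_refill_days}"
            )
        if errors:
            raise ParameterError(errors)


@dataclass(frozen=True)
class ParameterSpace:
    """Global constants plus the ATC and package lookup tables."""

    global_params: GlobalParams = field(default_factory=GlobalParams)
    atc_table: Mapping[str, AtcParams] = field(default_factory=dict)
    vnr_table: Mapping[str, PackageParams] = field(default_factory=dict)

    def resolve_atc(self, atc: str) -> AtcParams | None:
        return resolve_atc(atc, self)

    def resolve_package(self, vnr: str | None) -> PackageParams | None:
        return resolve_package(vnr, self)


def resolve_atc(atc: str, space: ParameterSpace) -> AtcParams | None:
    """Return the entry for the finest (longest) defined prefix of *atc*.

    The ATC hierarchy is encoded in the code string itself, so prefix
    matching walks the classification from drug substance up to the
    anatomical main group. ``None`` when no prefix is defined.
    """
    if not atc:
        raise ValueError("empty ATC code")
    for length in range(len(atc), 0, -1):
        entry = space.atc_table.get(atc[:length])
        if entry is not None:
            return entry
    return None


def resolve_package(vnr: str | None, space: ParameterSpace) -> PackageParams | None:
    """Exact-key package lookup; ``None`` for a missing identifier."""
    if vnr is None:
        return None
    return space.vnr_table.get(vnr)


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------


def _load_yaml(source: str | Path | IO[str] | None) -> Any:
    if source is None:
        return None
    if hasattr(source, "read"):
        return yaml.safe_load(source)
    return yaml.safe_load(Path(source).read_text(encoding="utf-8"))


def _records(data: Any, key_field: str, filename: str) -> list[dict]:
    """Normalise a YAML table (list of records, or mapping key → fields)."""
    if data is None:
        return []
    if isinstance(data, Mapping):
        return [{key_field: str(k), **(v or {})} for k, v in data.items()]
    if isinstance(data, list):
        out = []
        for i, rec in enumerate(data):
            if not isinstance(rec, Mapping) or key_field not in rec:
                raise ParameterError([f"{filename}: record {i} lacks {key_field!r}"])
            out.append({**rec, key_field: str(rec[key_field])})
        return out
    raise ParameterError([f"{filename}: expected a list or mapping"])


def load_parameter_space(
    global_file: str | Path | IO[str] | None = None,
    atc_file: str | Path | IO[str] | None = None,
    vnr_file: str | Path | IO[str] | None = None,
    global_overrides: Mapping[str, Any] | None = None,
) -> ParameterSpace:
    """Load and validate the parameter space from up to three YAML files.

    An absent global file yields the documented defaults. Duplicate ATC
    prefixes or vnr keys, unknown fields and invariant violations are
    rejected with field-level messages collected into one
    :class:`ParameterError`.
    """
    errors: list[str] = []

    gdata = _load_yaml(global_file) or {}
    if not isinstance(gdata, Mapping):
        raise ParameterError(["global parameter file must be a mapping"])
    gdata = {**gdata, **(global_overrides or {})}
    known = {f.name for f in fields(GlobalParams)}
    unknown = set(gdata) - known
    if unknown:
        errors.append(f"unknown global parameters: {sorted(unknown)}")
    try:
        glob = GlobalParams(**{k: v for k, v in gdata.items() if k in known})
    except ParameterError as exc:
        errors.extend(exc.messages)
        glob = GlobalParams()

    atc_table: dict[str, AtcParams] = {}
    seen_dup: list[str] = []
    for rec in _records(_load_yaml(atc_file), "atc_prefix", "atc parameter file"):
        try:
            entry = AtcParams(**rec)
        except ParameterError as exc:
            errors.extend(exc.messages)
            continue
        except TypeError as exc:
            errors.append(f"atc {rec.get('atc_prefix')}: {exc}")
            continue
        if entry.atc_prefix in atc_table:
            seen_dup.append(entry.atc_prefix)
        atc_table[entry.atc_prefix] = entry
    if seen_dup:
        errors.append(f"duplicate ATC prefixes: {sorted(set(seen_dup))}")

    vnr_table: dict[str, PackageParams] = {}
    seen_dup = []
    for rec in _records(_load_yaml(vnr_file), "vnr", "vnr parameter file"):
        try:
            entry = PackageParams(**rec)
        except ParameterError as exc:
            errors.extend(exc.messages)
            continue
        except TypeError as exc:
            errors.append(f"vnr {rec.get('vnr')}: {exc}")
            continue
        if entry.vnr in vnr_table:
            seen_dup.append(entry.vnr)
        vnr_table[entry.vnr] = entry
    if seen_dup:
        errors.append(f"duplicate vnr keys: {sorted(set(seen_dup))}")

    if errors:
        raise ParameterError(errors)
    return ParameterSpace(global_params=glob, atc_table=atc_table, vnr_table=vnr_table)
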