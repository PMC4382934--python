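"""The decision procedure: from purchase histories to drug use periods.

Each person's purchases of one ATC code are walked chronologically.
For every purchase the expected refill length

``ERFL_i = DDD_i · (1 + DVAR · DDDAVGcv) / DDDAVG_i``

predicts how many days the dispensed amount will last, given the
person's local dose level and purchasing regularity. Consecutive
purchases join into one drug use period when the expected supply
reaches the next purchase; when it falls short, a stockpiling test
(a locally depressed dose average flanked by higher ones means the
person bought ahead and then consumed the stock) may still bridge the
gap by pooling the current purchase with the previous one. The end of
a period is extended beyond its last purchase by the remaining supply,
damped by ``1 + e^{-k}`` for periods with few purchases, and pushed
across hospital days during which register-visible consumption pauses.

The whole pipeline iterates: periods built with expert parameters
yield per-package refill-length modes, which replace the expert
typical lengths, and the periods are rebuilt until the result is
stable.
"""

from __future__ import annotations

import datetime as dt
import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, NamedTuple, Sequence

from .io import (
    History,
    InstitutionalStay,
    Purchase,
    hospital_days_between,
    merge_stays,
    sort_histories,
)
from .parameters import AtcParams, GlobalParams, PackageParams, ParameterSpace
from .preprocess import DoseProfile, GapSeries, preprocess_history
from .refill import build_refill_distributions, mode_table

__all__ = [
    "Limit",
    "ErflResult",
    "DrugUsePeriod",
    "PipelineResult",
    "expected_refill_length",
    "stockpiling_test",
    "combined_two_purchase_reach",
    "single_purchase_duration",
    "period_end",
    "supply_days",
    "build_periods",
    "run_pipeline",
]

#: Tolerance for comparisons of day quantities before date rounding.
EPS = 1e-9
#: Rounding slack when flooring day counts to dates: absorbs harmless
#: float residue (e.g. the vanishing 1 + e^{-k} damping term).
DAY_EPS = 1e-6


def _reaches(supply_days_value: float, gap_days: int) -> bool:
    """Does a supply of so many days reach a purchase *gap_days* later?

    Dates are day-granular while supply estimates are continuous: a
    supply that runs out during the day of the next purchase is taken
    to reach it, so the test is ``supply > gap − 1`` rather than
    ``supply ≥ gap``.
    """
    return supply_days_value - (gap_days - 1) > EPS


class Limit(Enum):
    """Which restriction shaped an expected refill length."""

    NONE = "none"
    PACKAGE_MAX = "package_max"
    ATC_MAX = "atc_max"
    GLOBAL_DOSE_CAP = "global_dose_cap"
    LOWER_DOSE_SPLIT = "lower_dose_split"


@dataclass(frozen=True)
class ErflResult:
    erfl_days: float
    dose_used: float
    limit_applied: Limit = Limit.NONE

    def __post_init__(self) -> None:
        if not self.erfl_days > 0:
            raise ValueError("expected refill length must be positive")


@dataclass(frozen=True)
class DrugUsePeriod:
    """One constructed episode of continuous use of one drug.

    ``mean_ddd_per_day`` spreads the dispensed total over the period's
    non-hospital days. ``purchases`` carries the member purchases for
    refill-length learning and auditing; it does not take part in
    equality.
    """

    person_id: str
    atc: str
    start: dt.date
    end: dt.date
    total_ddd: float
    n_purchases: int
    hospital_days: int
    mean_ddd_per_day: float
    purchases: tuple[Purchase, ...] = field(default=(), compare=False, repr=False)
    flags: tuple[str, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("period end precedes start")
        if self.n_purchases < 1:
            raise ValueError("a period contains at least one purchase")

    @property
    def length_days(self) -> int:
        return (self.end - self.start).days


# ---------------------------------------------------------------------------
# parameter resolution helpers
# ---------------------------------------------------------------------------


def _resolved(purchase: Purchase, space: ParameterSpace, modes: Mapping[str, int]):
    """(package params, ATC params, typical refill length) for a purchase.

    The learned population mode for the package, when available,
    overrides the expert typical refill length.
    """
    pkg = space.resolve_package(purchase.vnr)
    atc = space.resolve_atc(purchase.atc) if purchase.atc else None
    typical = None
    if purchase.vnr is not None and purchase.vnr in modes:
        typical = modes[purchase.vnr]
    elif pkg is not None:
        typical = pkg.typical_refill_days
    return pkg, atc, typical


def _lower_dose_limit(pkg: PackageParams | None, atc: AtcParams | None) -> float | None:
    # the dose at the package's maximum refill length is its lower
    # dose limit; the ATC entry supplies it only when no package does
    if pkg is not None:
        return pkg.ddd_per_day_at_max
    if atc is not None:
        return atc.min_ddd_per_day
    return None


def _dose_cap(pkg: PackageParams | None, glob: GlobalParams) -> float:
    cap = glob.max_ddd_per_day
    if pkg is not None:
        cap = min(cap, pkg.ddd_per_day_at_min)
    return cap


def _split_duration(
    purchase: Purchase,
    typical_refill: int | None,
    atc: AtcParams | None,
    glob: GlobalParams,
) -> float:
    """Duration of a purchase that closes its period on the low-dose rule."""
    n_pack = purchase.n_packages or 1
    if typical_refill is not None:
        return float(typical_refill * n_pack)
    if purchase.ddd_amount is not None and atc is not None:
        return purchase.ddd_amount / atc.common_ddd_per_day
    if atc is not None:
        return float(atc.min_period_days)
    return 1.0


# ---------------------------------------------------------------------------
# the elementary decisions
# ---------------------------------------------------------------------------


def expected_refill_length(
    purchase: Purchase,
    ddd_avg_i: float,
    cv: float | None,
    space: ParameterSpace,
    modes: Mapping[str, int] | None = None,
) -> ErflResult:
    """Expected refill length of one purchase, with every limit applied.

    The dose used is the sliding average clamped from above by the
    global dose cap and, where defined, the package's dose at minimum
    refill length. A sliding average *below* the resolved lower dose
    limit means the next purchase is further away than regular use
    would allow: the purchase gets a package-refill-length based
    duration and the period is flagged to end after it
    (``Limit.LOWER_DOSE_SPLIT``). Otherwise the raw expected length
    ``DDD·(1 + dvar·cv)/dose`` is truncated to the package maximum
    (times the package count) or, lacking package data, the ATC-class
    maximum refill length.
    """
    modes = modes or {}
    glob = space.global_params
    pkg, atc, typical = _resolved(purchase, space, modes)

    lower = _lower_dose_limit(pkg, atc)
    if lower is not None and ddd_avg_i < lower:
        return ErflResult(
            erfl_days=max(1.0, _split_duration(purchase, typical, atc, glob)),
            dose_used=ddd_avg_i,
            limit_applied=Limit.LOWER_DOSE_SPLIT,
        )

    limit = Limit.NONE
    dose_used = ddd_avg_i
    cap = _dose_cap(pkg, glob)
    if dose_used > cap:
        dose_used = cap
        limit = Limit.GLOBAL_DOSE_CAP

    if purchase.ddd_amount is None:
        # no registered amount: fall back on package/ATC lengths
        if typical is not None:
            return ErflResult(float(typical * (purchase.n_packages or 1)), dose_used, limit)
        fallback = float(atc.min_period_days) if atc is not None else 1.0
        return ErflResult(fallback, dose_used, limit)

    multiplier = 1.0 + glob.dvar * (cv or 0.0)
    erfl = purchase.ddd_amount * multiplier / dose_used
    n_pack = purchase.n_packages or 1
    if pkg is not None and erfl > pkg.max_refill_days * n_pack:
        erfl = float(pkg.max_refill_days * n_pack)
        limit = Limit.PACKAGE_MAX
    elif pkg is None and atc is not None and erfl > atc.max_refill_days:
        erfl = float(atc.max_refill_days)
        limit = Limit.ATC_MAX
    return ErflResult(max(erfl, EPS), dose_used, limit)


def stockpiling_test(
    ddd_avg_prev: float | None,
    ddd_avg_cur: float | None,
    ddd_avg_next: float | None,
) -> bool:
    """True when the current sliding average is a strict local minimum.

    A dose average lower than both neighbours is the signature of
    stock use: a short gap (buying ahead) followed by a long one
    (consuming the stock). With any of the three averages missing the
    test is negative.
    """
    if ddd_avg_prev is None or ddd_avg_cur is None or ddd_avg_next is None:
        return False
    return ddd_avg_cur < ddd_avg_prev and ddd_avg_cur < ddd_avg_next


def combined_two_purchase_reach(
    prev: Purchase,
    cur: Purchase,
    ddd_avg: float,
    cv: float | None,
    space: ParameterSpace,
    modes: Mapping[str, int] | None = None,
) -> float:
    """Expected reach (days) of the previous and current purchase pooled.

    Evaluated as if one purchase of the combined DDD amount had
    happened at the previous purchase's date; used when the stockpiling
    test fires. Package truncation uses the pooled package count.
    """
    glob = space.global_params
    pkg, atc, _ = _resolved(cur, space, modes or {})
    dose_used = min(ddd_avg, _dose_cap(pkg, glob))
    combined_ddd = (prev.ddd_amount or 0.0) + (cur.ddd_amount or 0.0)
    reach = combined_ddd * (1.0 + glob.dvar * (cv or 0.0)) / dose_used
    n_pack = (prev.n_packages or 1) + (cur.n_packages or 1)
    if pkg is not None:
        reach = min(reach, float(pkg.max_refill_days * n_pack))
    elif atc is not None:
        reach = min(reach, float(atc.max_refill_days))
    return reach


def single_purchase_duration(
    purchase: Purchase,
    modes: Mapping[str, int] | None,
    neighbor_dose: float | None,
    space: ParameterSpace,
) -> tuple[float, str]:
    """Modelled duration (days) of a purchase standing alone.

    Information sources, best first:

    1. the dose of the person's nearest drug use period of the same
       drug with at least two purchases;
    2. the population's most common refill length for the package,
       times the number of packages;
    3. the dispensed amount with an adherence allowance over the
       typical daily dose (package, else ATC class);
    4. the ATC-class minimum period length;
    5. one day, flagged, when nothing at all is known.

    The result never exceeds the global single-purchase cap.
    """
    glob = space.global_params
    modes = modes or {}
    pkg = space.resolve_package(purchase.vnr)
    atc = space.resolve_atc(purchase.atc) if purchase.atc else None
    n_pack = purchase.n_packages or 1

    duration: float | None = None
    source = "unmodelled"
    if neighbor_dose is not None and neighbor_dose > 0 and purchase.ddd_amount:
        duration = purchase.ddd_amount / neighbor_dose
        source = "neighbor_dose"
    elif purchase.vnr is not None and purchase.vnr in modes:
        duration = float(modes[purchase.vnr] * n_pack)
        source = "refill_mode"
    elif purchase.ddd_amount:
        typical_dose = None
        if pkg is not None:
            typical_dose = pkg.ddd_per_day_typical
        elif atc is not None:
            typical_dose = atc.common_ddd_per_day
        if typical_dose:
            duration = purchase.ddd_amount * (1.0 + glob.adherence_slack) / typical_dose
            source = "typical_dose"
    if duration is None and atc is not None:
        duration = float(atc.min_period_days)
        source = "atc_min_period"
    if duration is None:
        duration = 1.0
    return min(max(duration, 1.0), float(glob.max_single_purchase_days)), source


def _extend_over_hospital(
    start: dt.date,
    base_days: float,
    stays: Sequence[tuple[dt.date, dt.date | None]],
    glob: GlobalParams,
) -> dt.date:
    """Push a supply end date across hospital days; truncate at long stays.

    Hospital days falling inside the supply window are added to it,
    re-counted over the grown window until a fixed point (guarded at
    100 rounds). A single continuous stay longer than the global limit
    instead truncates the period at its admission date: such a stay
    cannot be bridged.
    """
    base_days = max(0.0, base_days)
    hd_prev = -1
    end = start + dt.timedelta(days=math.floor(base_days + DAY_EPS))
    for _ in range(100):
        # a long continuous stay beginning inside the window truncates
        for admission, discharge in stays:
            length = float("inf") if discharge is None else (discharge - admission).days
            if length > glob.max_hospital_days_in_period and start <= admission < end:
                return max(start, admission)
            if length > glob.max_hospital_days_in_period and admission < start and (
                discharge is None or discharge > start
            ):
                return start
        hd = hospital_days_between(stays, start, end)
        if hd == hd_prev:
            break
        hd_prev = hd
        end = start + dt.timedelta(days=math.floor(base_days + hd + DAY_EPS))
    return end


def supply_days(
    ddd: float, ddd_avg: float, cv: float | None, k: int, glob: GlobalParams
) -> float:
    """Remaining supply after a period's last purchase, in days.

    ``DDD·(1 + dvar·cv) / (DDDAVG·(1 + e^{-k}))``: the damping term
    shortens the extension for periods with very few purchases, where
    apparent stock is least trustworthy, and vanishes as the purchase
    count *k* grows.
    """
    return ddd * (1.0 + glob.dvar * (cv or 0.0)) / (ddd_avg * (1.0 + math.exp(-k)))


def _single_end(
    start: dt.date,
    duration: float,
    stays: Sequence[tuple[dt.date, dt.date | None]],
    glob: GlobalParams,
) -> dt.date:
    """End of a single-purchase period: hard cap, long-stay truncation."""
    end = start + dt.timedelta(days=math.floor(duration + DAY_EPS))
    for admission, discharge in stays:  # merged stays are sorted
        length = float("inf") if discharge is None else (discharge - admission).days
        if length <= glob.max_hospital_days_in_period:
            continue
        if admission < start and (discharge is None or discharge > start):
            return start
        if start <= admission < end:
            return admission
    return end


def period_end(
    last: Purchase,
    ddd_avg_i: float,
    cv: float | None,
    k: int,
    stays: Sequence[tuple[dt.date, dt.date | None]],
    glob: GlobalParams,
) -> dt.date:
    """End date of a period from its last purchase.

    The base supply comes from :func:`supply_days`. Hospital days
    inside the extension are added iteratively; a continuous stay
    longer than the global limit truncates the period at its
    admission. End dates round down to whole days.
    """
    base = supply_days(last.ddd_amount or 0.0, ddd_avg_i, cv, k, glob)
    return _extend_over_hospital(last.date, base, stays, glob)


# ---------------------------------------------------------------------------
# history scan
# ---------------------------------------------------------------------------


@dataclass
class _Cluster:
    indices: list[int]
    close_reason: str = "supply_exhausted"
    split_erfl: float | None = None  # duration when closed by the low-dose rule
    flags: list[str] = field(default_factory=list)


def _long_stay_in_gap(
    stays: Sequence[tuple[dt.date, dt.date | None]],
    a: dt.date,
    b: dt.date,
    glob: GlobalParams,
) -> bool:
    """A continuous stay longer than the limit overlapping ``[a, b)``."""
    for admission, discharge in stays:
        length = float("inf") if discharge is None else (discharge - admission).days
        if length <= glob.max_hospital_days_in_period:
            continue
        lo = max(a, admission)
        hi = b if discharge is None else min(b, discharge)
        if hi > lo:
            return True
    return False


def _scan_segment(
    history: History,
    seg: list[int],
    profile: DoseProfile,
    gaps: GapSeries,
    modes: Mapping[str, int],
    stays: Sequence[tuple[dt.date, dt.date | None]],
    space: ParameterSpace,
) -> list[_Cluster]:
    """Split one treatment segment into period clusters, left to right."""
    glob = space.global_params
    purchases = history.purchases
    clusters: list[_Cluster] = [_Cluster([seg[0]])]

    def close(reason: str, split_erfl: float | None = None) -> None:
        clusters[-1].close_reason = reason
        clusters[-1].split_erfl = split_erfl

    if len(seg) == 2 and all(profile.ddd_avg[i] is None for i in seg):
        # too few purchases for sliding averages: the pair joins only if
        # the gap is inside the package/ATC maximum refill reach
        i, j = seg
        p = purchases[i]
        pkg, atc, _ = _resolved(p, space, modes)
        n_pack = p.n_packages or 1
        if pkg is not None:
            max_reach = float(pkg.max_refill_days * n_pack)
        elif atc is not None:
            max_reach = float(atc.max_refill_days)
        else:
            max_reach = float(glob.max_single_purchase_days)
        raw_gap = gaps.raw_gap_days[i]
        if raw_gap <= max_reach + EPS and not _long_stay_in_gap(
            stays, p.date, purchases[j].date, glob
        ):
            clusters[-1].indices.append(j)
        else:
            close("max_refill_exceeded")
            clusters.append(_Cluster([j]))
        return clusters

    for pos, i in enumerate(seg[:-1]):
        j = seg[pos + 1]
        net = gaps.net_gap_days[i]
        av = profile.ddd_avg[i]
        connect: bool
        split_erfl: float | None = None
        reason = "supply_exhausted"

        if _long_stay_in_gap(stays, purchases[i].date, purchases[j].date, glob):
            # an unbridgeable institutional stay separates the purchases
            connect = False
            reason = "long_hospital_stay"
        elif av is None:
            pkg, atc, typical = _resolved(purchases[i], space, modes)
            if typical is not None:
                reach = float(typical * (purchases[i].n_packages or 1))
            elif atc is not None:
                reach = float(atc.min_period_days)
            else:
                reach = 1.0
            connect = _reaches(reach, net)
            clusters[-1].flags.append("bridged_without_dose")
        else:
            res = expected_refill_length(
                purchases[i], av, profile.ddd_avg_cv, space, modes
            )
            if res.limit_applied is Limit.LOWER_DOSE_SPLIT:
                connect = False
                reason = "lower_dose_split"
                split_erfl = res.erfl_days
            elif _reaches(res.erfl_days, net):
                connect = True
            else:
                prev_in_cluster = (
                    len(clusters[-1].indices) >= 2 and clusters[-1].indices[-2] == i - 1
                )
                prev_av = profile.ddd_avg[i - 1] if prev_in_cluster else None
                next_av = profile.ddd_avg[j]
                if stockpiling_test(prev_av, av, next_av):
                    reach = combined_two_purchase_reach(
                        purchases[i - 1],
                        purchases[i],
                        av,
                        profile.ddd_avg_cv,
                        space,
                        modes,
                    )
                    span = gaps.net_gap_days[i - 1] + net
                    connect = _reaches(reach, span)
                else:
                    connect = False

        if connect:
            clusters[-1].indices.append(j)
        else:
            close(reason, split_erfl)
            clusters.append(_Cluster([j]))
    return clusters


def _make_period(
    history: History,
    cluster: _Cluster,
    end: dt.date,
    stays: Sequence[tuple[dt.date, dt.date | None]],
) -> DrugUsePeriod:
    members = tuple(history.purchases[i] for i in cluster.indices)
    start = members[0].date
    total_ddd = sum(p.ddd_amount or 0.0 for p in members)
    hosp = hospital_days_between(stays, start, end)
    span = (end - start).days
    mean_dose = total_ddd / max(1, span - hosp)
    return DrugUsePeriod(
        person_id=history.person_id,
        atc=history.atc,
        start=start,
        end=end,
        total_ddd=total_ddd,
        n_purchases=len(members),
        hospital_days=hosp,
        mean_ddd_per_day=mean_dose,
        purchases=members,
        flags=tuple(cluster.flags),
    )


def build_periods(
    history: History,
    profile: DoseProfile,
    gaps: GapSeries,
    modes: Mapping[str, int] | None,
    stays,
    space: ParameterSpace,
) -> list[DrugUsePeriod]:
    """Construct the drug use periods of one (person, ATC) history.

    Two passes: the chronological scan first partitions the purchases
    into clusters (treatment-restart boundaries always close; the
    expected refill length, the stockpiling branch and the low-dose
    split decide the rest), then each cluster's end date and dose
    summary are computed. Single purchases standing next to
    multi-purchase periods of the same drug borrow their dose from the
    nearest such period. Emitted periods never overlap: an end
    extension is clamped a day short of the next purchase.
    """
    if len(history.purchases) == 0:
        return []
    modes = modes or {}
    glob = space.global_params
    merged = _as_merged_stays(stays, history.person_id)

    clusters: list[_Cluster] = []
    for seg in gaps.segments():
        seg_clusters = _scan_segment(history, seg, profile, gaps, modes, merged, space)
        if clusters:
            clusters[-1].close_reason = "segment_boundary"
        clusters.extend(seg_clusters)

    n = len(history.purchases)
    ends: list[dt.date | None] = [None] * len(clusters)

    # multi-purchase clusters first: their doses seed the singles
    for ci, cluster in enumerate(clusters):
        if len(cluster.indices) < 2:
            continue
        last_i = cluster.indices[-1]
        last = history.purchases[last_i]
        av = profile.ddd_avg[last_i]
        if cluster.close_reason == "lower_dose_split" and cluster.split_erfl is not None:
            end = _extend_over_hospital(last.date, cluster.split_erfl, merged, glob)
        elif av is not None:
            end = period_end(
                last, av, profile.ddd_avg_cv, len(cluster.indices), merged, glob
            )
        else:
            # no usable sliding average: fall back on the single-purchase
            # rules, applied to the last purchase
            duration, source = single_purchase_duration(last, modes, None, space)
            cluster.flags.append(f"end_from_single_rules:{source}")
            end = _extend_over_hospital(last.date, duration, merged, glob)
        ends[ci] = _clamp_end(end, last_i, last.date, history)

    # dose lookup for singles: nearest multi-purchase period of this drug
    multi = [
        (ci, cluster)
        for ci, cluster in enumerate(clusters)
        if len(cluster.indices) >= 2
    ]

    def nearest_dose(date: dt.date) -> float | None:
        best: tuple[int, float] | None = None
        for ci, cluster in multi:
            start = history.purchases[cluster.indices[0]].date
            end = ends[ci] or history.purchases[cluster.indices[-1]].date
            if start <= date <= end:
                dist = 0
            else:
                dist = min(abs((date - start).days), abs((date - end).days))
            members = [history.purchases[i] for i in cluster.indices]
            total = sum(p.ddd_amount or 0.0 for p in members)
            span = max(1, (end - start).days - hospital_days_between(merged, start, end))
            dose = total / span
            if dose > 0 and (best is None or dist < best[0]):
                best = (dist, dose)
        return best[1] if best else None

    for ci, cluster in enumerate(clusters):
        if len(cluster.indices) != 1:
            continue
        i = cluster.indices[0]
        p = history.purchases[i]
        duration, source = single_purchase_duration(p, modes, nearest_dose(p.date), space)
        if source == "unmodelled":
            cluster.flags.append("unmodelled_duration")
        cluster.flags.append(f"single:{source}")
        # lone purchases keep the hard length cap: no hospital-day
        # extension, only truncation at an unbridgeable stay
        end = _single_end(p.date, duration, merged, glob)
        ends[ci] = _clamp_end(end, i, p.date, history)

    return [
        _make_period(history, cluster, ends[ci], merged)
        for ci, cluster in enumerate(clusters)
    ]


def _clamp_end(
    end: dt.date, last_index: int, last_date: dt.date, history: History
) -> dt.date:
    """Periods never overlap: stop a day before the next purchase."""
    if last_index + 1 < len(history.purchases):
        nxt = history.purchases[last_index + 1].date - dt.timedelta(days=1)
        end = min(end, nxt)
    return max(end, last_date)


def _as_merged_stays(stays, person_id: str) -> list[tuple[dt.date, dt.date | None]]:
    if stays is None:
        return []
    if isinstance(stays, dict):
        return stays.get(person_id, [])
    return merge_stays(s for s in stays if s.person_id == person_id).get(person_id, [])


# ---------------------------------------------------------------------------
# the iterated pipeline
# ---------------------------------------------------------------------------


class PipelineResult(NamedTuple):
    periods: list[DrugUsePeriod]
    modes: dict[str, int]
    n_iterations: int
    converged: bool


def _signature(periods: Iterable[DrugUsePeriod]) -> frozenset:
    return frozenset(
        (p.person_id, p.atc, p.start, p.end, p.n_purchases, round(p.total_ddd, 6))
        for p in periods
    )


def run_pipeline(
    purchases: Iterable[Purchase],
    stays: Iterable[InstitutionalStay] | None,
    space: ParameterSpace,
    max_iter: int = 5,
    initial_modes: Mapping[str, int] | None = None,
) -> PipelineResult:
    """Run the full construction, iterating until the periods are stable.

    The first pass uses expert parameters only (or ``initial_modes``
    from an earlier population run). Each further pass learns the
    per-package refill-length modes from the previous period set and
    rebuilds; iteration stops when the period set repeats exactly.
    Non-convergence within ``max_iter`` passes returns the last state
    with a warning.
    """
    glob = space.global_params
    histories = sort_histories(purchases)
    merged = merge_stays(stays or [])
    pre = [
        (h, *preprocess_history(h, merged, glob))
        for h in histories
    ]

    def build(modes: Mapping[str, int]) -> list[DrugUsePeriod]:
        out: list[DrugUsePeriod] = []
        for h, gaps, profile in pre:
            out.extend(build_periods(h, profile, gaps, modes, merged, space))
        return out

    modes = dict(initial_modes or {})
    periods = build(modes)
    if not periods:
        return PipelineResult(periods, modes, 1, True)
    prev_sig = _signature(periods)
    iteration = 1
    converged = False
    while iteration < max_iter:
        modes = mode_table(build_refill_distributions(periods, glob))
        periods = build(modes)
        iteration += 1
        sig = _signature(periods)
        if sig == prev_sig:
            converged = True
            break
        prev_sig = sig
    if not converged and max_iter > 1:
        warnings.warn(
            f"period construction did not stabilise in {max_iter} iterations",
            stacklevel=2,
        )
    if max_iter == 1:
        converged = True
    return PipelineResult(periods, modes, iteration, converged)
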