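"""Pre-processing: refill gaps and sliding temporal dose averages.

For every purchase history this module computes

* hospital-adjusted refill gaps (days in institutional care are
  subtracted from the time between purchases, since drug use in
  hospital is not visible in the dispensing register);
* the sliding weighted temporal average of the daily dose,
  ``DDDAVG_i`` — a (1, 4, 1)-weighted ratio of dispensed DDD amounts to
  the net days they had to cover;
* the coefficient of variation of those averages, ``DDDAVGcv``, a
  per-person-per-drug measure of purchasing regularity.

These quantities do not change over pipeline iterations, so they are
computed once per history.
"""

from __future__ import annotations

import datetime as dt
import math
import statistics
from dataclasses import dataclass, replace
from typing import Sequence

from .io import History, InstitutionalStay, hospital_days_between, merge_stays
from .parameters import GlobalParams

__all__ = [
    "GapSeries",
    "DoseProfile",
    "compute_gaps",
    "compute_ddd_avg",
    "compute_cv",
    "calculated_refill_times",
    "preprocess_history",
]


@dataclass(frozen=True)
class GapSeries:
    """Inter-purchase gaps of one history, with hospital adjustment.

    For ``n`` purchases the three gap vectors have length ``n - 1``;
    entry ``i`` describes the interval from purchase ``i`` to ``i+1``.
    ``segment_id`` has length ``n`` and marks treatment restarts: a new
    segment begins whenever the net gap exceeds the maximum refill time,
    since the drug cannot have lasted from one purchase to the next.
    """

    raw_gap_days: tuple[int, ...]
    hospital_days_in_gap: tuple[int, ...]
    net_gap_days: tuple[int, ...]
    segment_id: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(g < 1 for g in self.net_gap_days):
            raise ValueError("net gaps must be >= 1 day")
        if any(h > r for h, r in zip(self.hospital_days_in_gap, self.raw_gap_days)):
            raise ValueError("hospital days cannot exceed the raw gap")
        if any(b < a for a, b in zip(self.segment_id, self.segment_id[1:])):
            raise ValueError("segment ids must be non-decreasing")

    def segments(self) -> list[list[int]]:
        """Purchase indices grouped by segment, in order."""
        out: list[list[int]] = []
        for i, seg in enumerate(self.segment_id):
            if not out or self.segment_id[i - 1] != seg:
                out.append([])
            out[-1].append(i)
        return out


@dataclass(frozen=True)
class DoseProfile:
    """Per-purchase sliding dose averages and their regularity measure.

    ``ddd_avg[i]`` is ``None`` when the average could not be computed
    (too few purchases in the segment, or unregistered/zero DDD amounts
    in the weighting window). ``ddd_avg_cv`` is ``None`` with fewer
    than two computed averages.
    """

    ddd_avg: tuple[float | None, ...]
    ddd_avg_cv: float | None = None

    def __post_init__(self) -> None:
        if any(v is not None and v <= 0 for v in self.ddd_avg):
            raise ValueError("ddd_avg must be positive where present")
        if self.ddd_avg_cv is not None and self.ddd_avg_cv < 0:
            raise ValueError("ddd_avg_cv must be non-negative")


def compute_gaps(
    history: History,
    stays: Sequence[InstitutionalStay] | dict | None,
    global_params: GlobalParams,
) -> GapSeries:
    """Compute raw, hospital and net gaps plus segment boundaries.

    ``stays`` may be raw stay records (merged here) or an already merged
    per-person mapping from :func:`pre2dup.io.merge_stays`. Hospital
    days are counted over the half-open interval ``[date_i, date_{i+1})``.
    The net gap is floored at one day so downstream dose ratios stay
    finite when a stay spans an entire gap; the global dose cap bounds
    the resulting dose.
    """
    merged = _person_stays(stays, history.person_id)
    raw: list[int] = []
    hosp: list[int] = []
    net: list[int] = []
    for a, b in zip(history.purchases, history.purchases[1:]):
        r = (b.date - a.date).days
        h = hospital_days_between(merged, a.date, b.date)
        raw.append(r)
        hosp.append(h)
        net.append(max(1, r - h))
    seg_id = [0] * len(history.purchases)
    seg = 0
    for i, g in enumerate(net):
        if g > global_params.max_refill_gap_days:
            seg += 1
        seg_id[i + 1] = seg
    return GapSeries(tuple(raw), tuple(hosp), tuple(net), tuple(seg_id))


def _person_stays(stays, person_id: str) -> list[tuple[dt.date, dt.date | None]]:
    if stays is None:
        return []
    if isinstance(stays, dict):
        return stays.get(person_id, [])
    return merge_stays(s for s in stays if s.person_id == person_id).get(person_id, [])


def compute_ddd_avg(
    history: History, gaps: GapSeries, global_params: GlobalParams
) -> DoseProfile:
    """Sliding weighted temporal dose average per purchase.

    Within each treatment segment of at least ``ddd_avg_min_purchases``
    purchases, purchase *i* gets

    ``(DDD_{i-1} + 4·DDD_i + DDD_{i+1}) / (T_{i-1} + 4·T_i + T_{i+1})``

    where ``T_i`` is the net (hospital-subtracted) gap from purchase
    *i* to *i+1*. The first purchase of a segment uses weights (5, 1)
    over *(i, i+1)* and the last (1, 5) over *(i−1, i)*, with the last
    gap imputed under the assumption that the dose did not change:
    ``T_last = DDD_last / (DDD_{last-1} / T_{last-1})``.

    Histories with fewer than the minimum number of purchases are
    passed to the decision procedure without pre-processing: every
    entry is ``None``. Zero or unregistered DDD amounts make the
    averages of the purchases whose windows touch them ``None``.
    """
    n = len(history.purchases)
    avg: list[float | None] = [None] * n
    if n < global_params.ddd_avg_min_purchases:
        return DoseProfile(tuple(avg))
    ddd = [p.ddd_amount for p in history.purchases]
    for seg in gaps.segments():
        m = len(seg)
        if m < global_params.ddd_avg_min_purchases:
            continue
        d = [ddd[i] for i in seg]
        t: list[float | None] = [float(gaps.net_gap_days[i]) for i in seg[:-1]]
        # impute the open-ended last gap from the previous dose level
        if d[-1] and d[-2] and d[-2] > 0:
            t.append(d[-1] / (d[-2] / t[-1]))
        else:
            t.append(None)

        def ok(*values) -> bool:
            return all(v is not None and v > 0 for v in values)

        for j, i in enumerate(seg):
            if j == 0:
                if ok(d[0], d[1], t[0], t[1]):
                    avg[i] = (5 * d[0] + d[1]) / (5 * t[0] + t[1])
            elif j == m - 1:
                if ok(d[m - 2], d[m - 1], t[m - 2], t[m - 1]):
                    avg[i] = (d[m - 2] + 5 * d[m - 1]) / (t[m - 2] + 5 * t[m - 1])
            else:
                if ok(d[j - 1], d[j], d[j + 1], t[j - 1], t[j], t[j + 1]):
                    avg[i] = (d[j - 1] + 4 * d[j] + d[j + 1]) / (
                        t[j - 1] + 4 * t[j] + t[j + 1]
                    )
    return DoseProfile(tuple(avg))


def compute_cv(profile: DoseProfile) -> DoseProfile:
    """Attach the coefficient of variation of the computed averages.

    One value per (person, ATC): the sample standard deviation of the
    present ``ddd_avg`` values divided by their mean; ``None`` with
    fewer than two values.
    """
    values = [v for v in profile.ddd_avg if v is not None]
    if len(values) < 2:
        return replace(profile, ddd_avg_cv=None)
    cv = statistics.stdev(values) / statistics.fmean(values)
    return replace(profile, ddd_avg_cv=cv)


def calculated_refill_times(
    history: History, profile: DoseProfile
) -> tuple[float | None, ...]:
    """Diagnostic refill time per purchase: ``DDD_i / DDDAVG_i`` (days).

    This is the expected refill length with the regularity multiplier
    left at one — the quantity printed in audit output; the
    ``1 + dvar·cv`` multiplier enters only the connection and
    period-end decisions.
    """
    out: list[float | None] = []
    for p, a in zip(history.purchases, profile.ddd_avg):
        if a is None or p.ddd_amount is None:
            out.append(None)
        else:
            out.append(p.ddd_amount / a)
    return tuple(out)


def preprocess_history(
    history: History,
    stays,
    global_params: GlobalParams,
) -> tuple[GapSeries, DoseProfile]:
    """Convenience wrapper: gaps, sliding averages and cv in one call."""
    gaps = compute_gaps(history, stays, global_params)
    profile = compute_cv(compute_ddd_avg(history, gaps, global_params))
    return gaps, profile
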