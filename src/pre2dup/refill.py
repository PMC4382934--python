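"""Package refill-length distributions and mode selection.

After the decision procedure has run once, the observed gaps between
purchases inside well-populated drug use periods form, per package
(vnr), an empirical refill-length histogram. Counts are consolidated
by moving every bin's mass to the nearest local maximum, and the mode
of the consolidated histogram — when backed by enough purchases —
becomes the package's expected refill length, replacing the
expert-guessed typical length on subsequent iterations.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Mapping

import pandas as pd

from .parameters import GlobalParams

__all__ = [
    "RefillDistribution",
    "collect_refill_observations",
    "join_to_local_maxima",
    "select_mode",
    "build_refill_distributions",
    "mode_table",
    "write_mode_table",
    "read_mode_table",
]

#: Neighbourhood half-width (days) for the local-maximum search. The
#: histogram procedure itself gives no algorithmic detail beyond
#: "nearest local maximum"; a ±3-day window consolidates near-peak mass
#: (weekday effects, a day or two of slack) without merging genuinely
#: distinct refill rhythms, and is isolated here for easy replacement.
JOIN_WINDOW_DAYS = 3


@dataclass(frozen=True)
class RefillDistribution:
    """Raw and consolidated refill-length histogram of one package."""

    vnr: str
    raw_hist: Mapping[int, int]
    joined_hist: Mapping[int, int]
    mode_days: int | None
    mode_count: int

    def __post_init__(self) -> None:
        if sum(self.raw_hist.values()) != sum(self.joined_hist.values()):
            raise ValueError("joining must conserve the total count")
        if any(d < 1 for d in self.raw_hist):
            raise ValueError("refill lengths must be >= 1 day")


def collect_refill_observations(
    periods: Iterable, global_params: GlobalParams
) -> dict[str, Counter[int]]:
    """Per-vnr raw refill-length histograms from a set of periods.

    Only periods with at least ``refill_source_min_purchases`` member
    purchases contribute, so that the gaps reflect settled continuous
    use. For each non-final member purchase the raw calendar gap to the
    next member is recorded under the purchase's vnr — hospital stays
    are *not* subtracted here, since the package content, not the
    consumption time, is what the refill length measures. A purchase of
    several identical packages contributes the gap divided by the
    package count. Excluded: dose-dispensing purchases (the package is
    split across persons), rows mixing different vnrs, and final
    purchases of periods.
    """
    obs: dict[str, Counter[int]] = {}
    for period in periods:
        members = getattr(period, "purchases", ())
        if len(members) < global_params.refill_source_min_purchases:
            continue
        for cur, nxt in zip(members, members[1:]):
            if cur.dose_dispensing or cur.vnr is None or cur.vnr_mixed:
                continue
            gap = (nxt.date - cur.date).days
            n_pack = cur.n_packages or 1
            if n_pack > 1:
                gap = gap / n_pack
            days = max(1, int(round(gap)))
            obs.setdefault(cur.vnr, Counter())[days] += 1
    return obs


def _climb(day: int, hist: Mapping[int, int], window: int) -> int:
    """Hill-climb *day* to its local maximum within ±window days.

    At each step the target is the bin with the highest count in the
    neighbourhood, ties broken toward the shorter refill length. The
    (count, −day) objective increases strictly, so the walk terminates.
    """
    cur = day
    while True:
        best = cur
        best_count = hist.get(cur, 0)
        for d in range(cur - window, cur + window + 1):
            c = hist.get(d, 0)
            if c > best_count or (c == best_count and c > 0 and d < best):
                best, best_count = d, c
        if best == cur:
            return cur
        cur = best


def join_to_local_maxima(
    raw_hist: Mapping[int, int], window: int = JOIN_WINDOW_DAYS
) -> dict[int, int]:
    """Move every bin's count to its nearest local maximum.

    Deterministic (ties toward the shorter length), conserves the total
    count, and is idempotent: surviving bins are pairwise more than
    *window* days apart, so a second pass moves nothing.
    """
    joined: Counter[int] = Counter()
    targets: dict[int, int] = {}
    for day, count in raw_hist.items():
        if day not in targets:
            targets[day] = _climb(day, raw_hist, window)
        joined[targets[day]] += count
    return dict(joined)


def select_mode(
    joined_hist: Mapping[int, int], global_params: GlobalParams
) -> int | None:
    """The refill length with the highest consolidated count.

    Returned only when that count strictly exceeds
    ``mode_min_purchases``; rarely purchased packages keep their
    expert-defined lengths. Ties break toward the shorter length.
    """
    if not joined_hist:
        return None
    day, count = min(joined_hist.items(), key=lambda kv: (-kv[1], kv[0]))
    if count > global_params.mode_min_purchases:
        return day
    return None


def build_refill_distributions(
    periods: Iterable, global_params: GlobalParams
) -> dict[str, RefillDistribution]:
    """Full histogram → joined histogram → mode, per package."""
    out: dict[str, RefillDistribution] = {}
    for vnr, raw in collect_refill_observations(periods, global_params).items():
        joined = join_to_local_maxima(raw)
        mode = select_mode(joined, global_params)
        out[vnr] = RefillDistribution(
            vnr=vnr,
            raw_hist=dict(raw),
            joined_hist=joined,
            mode_days=mode,
            mode_count=joined.get(mode, 0) if mode is not None else 0,
        )
    return out


def mode_table(distributions: Mapping[str, RefillDistribution]) -> dict[str, int]:
    """vnr → learned typical refill length, for packages with a mode."""
    return {
        vnr: d.mode_days for vnr, d in distributions.items() if d.mode_days is not None
    }


def write_mode_table(
    distributions: Mapping[str, RefillDistribution],
    sink: str | Path | IO[str],
    sep: str = "\t",
) -> None:
    """Export learned refill lengths (vnr, mode_days, mode_count)."""
    rows = [
        {"vnr": vnr, "mode_days": d.mode_days, "mode_count": d.mode_count}
        for vnr, d in sorted(distributions.items())
        if d.mode_days is not None
    ]
    pd.DataFrame(rows, columns=["vnr", "mode_days", "mode_count"]).to_csv(
        sink, sep=sep, index=False
    )


def read_mode_table(source: str | Path | IO[str], sep: str = "\t") -> dict[str, int]:
    """Load a previously exported mode table as vnr → mode_days."""
    try:
        df = pd.read_csv(source, sep=sep, dtype={"vnr": str})
    except pd.errors.EmptyDataError:
        return {}
    return {str(r.vnr): int(r.mode_days) for r in df.itertuples(index=False)}
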