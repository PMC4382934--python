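"""Shared constructors and invariant checks for the test suite."""

from __future__ import annotations

import datetime as dt
from collections import defaultdict

from pre2dup import Purchase
from pre2dup.core import expected_refill_length
from pre2dup.io import merge_stays, sort_histories
from pre2dup.preprocess import preprocess_history

START = dt.date(2005, 1, 1)


def make_history(
    gaps,
    ddd=10.0,
    person="P1",
    atc="N05AH02",
    vnr=None,
    n_packages=1,
    start=START,
):
    """Purchases at cumulative *gaps* (days); scalar or per-purchase DDD."""
    n = len(gaps) + 1
    ddds = [ddd] * n if isinstance(ddd, (int, float)) else list(ddd)
    purchases = []
    date = start
    for i in range(n):
        purchases.append(
            Purchase(
                person_id=person,
                date=date,
                atc=atc,
                vnr=vnr,
                n_packages=n_packages,
                ddd_amount=ddds[i],
            )
        )
        if i < len(gaps):
            date = date + dt.timedelta(days=int(gaps[i]))
    return sort_histories(purchases)[0]


def eq1_reference(ddds, net_gaps):
    """Independent transcription of the sliding weighted dose average.

    One segment: interior weights (1, 4, 1), boundary weights (5, 1)
    and (1, 5), last gap imputed assuming the previous dose level.
    """
    n = len(ddds)
    assert n >= 3 and len(net_gaps) == n - 1
    t = [float(g) for g in net_gaps]
    t.append(ddds[-1] / (ddds[-2] / t[-1]))
    out = []
    for i in range(n):
        if i == 0:
            out.append((5 * ddds[0] + ddds[1]) / (5 * t[0] + t[1]))
        elif i == n - 1:
            out.append((ddds[-2] + 5 * ddds[-1]) / (t[-2] + 5 * t[-1]))
        else:
            out.append(
                (ddds[i - 1] + 4 * ddds[i] + ddds[i + 1])
                / (t[i - 1] + 4 * t[i] + t[i + 1])
            )
    return out


def assert_period_invariants(periods, purchases, stays, space):
    """Structural and cap invariants of a constructed period set.

    * every (merged) purchase belongs to exactly one period of its key;
    * periods of one key are date-ordered and never overlap;
    * dispensed DDDs are conserved;
    * no single-purchase period exceeds the global length cap;
    * no within-period net gap exceeds the maximum refill time;
    * no applied dose exceeds the global dose cap;
    * no period contains a continuous institutional stay longer than
      the global hospital limit.
    """
    glob = space.global_params
    merged = merge_stays(stays or [])
    histories = {(h.person_id, h.atc): h for h in sort_histories(purchases)}

    by_key = defaultdict(list)
    for p in periods:
        by_key[(p.person_id, p.atc)].append(p)

    assert set(by_key) == set(histories), "every history yields periods"

    total_in = sum(
        p.ddd_amount or 0.0 for h in histories.values() for p in h.purchases
    )
    total_out = sum(p.total_ddd for p in periods)
    assert abs(total_in - total_out) <= 1e-6 * max(1.0, total_in), "DDD conserved"

    for key, plist in by_key.items():
        plist.sort(key=lambda p: p.start)
        history = histories[key]
        members = [m for p in plist for m in p.purchases]
        assert members == list(history.purchases), "purchases partitioned, in order"
        for a, b in zip(plist, plist[1:]):
            assert a.end < b.start, "periods never overlap"
        stays_p = merged.get(key[0], [])
        for p in plist:
            if p.n_purchases == 1:
                assert p.length_days <= glob.max_single_purchase_days
            for m1, m2 in zip(p.purchases, p.purchases[1:]):
                raw = (m2.date - m1.date).days
                hosp = sum(
                    max(
                        0,
                        (
                            (min(m2.date, dis) if dis else m2.date)
                            - max(m1.date, adm)
                        ).days,
                    )
                    for adm, dis in stays_p
                )
                assert max(1, raw - hosp) <= glob.max_refill_gap_days
            for adm, dis in stays_p:
                if dis is not None and (dis - adm).days <= glob.max_hospital_days_in_period:
                    continue
                inside = adm >= p.start and dis is not None and dis <= p.end
                assert not inside, "no period swallows an unbridgeable stay"

    # applied doses respect the global cap
    for key, history in histories.items():
        _, profile = preprocess_history(history, merged, glob)
        for purchase, av in zip(history.purchases, profile.ddd_avg):
            if av is None:
                continue
            res = expected_refill_length(purchase, av, profile.ddd_avg_cv, space)
            assert res.dose_used <= glob.max_ddd_per_day + 1e-9
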