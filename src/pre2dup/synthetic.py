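"""Synthetic dispensing cohorts with known ground truth.

Registry data cannot be shipped, so every behaviour the decision
procedure must handle is emulated here: steady refills, stockpiling
bursts, mid-stream dose changes, institutional stays that suspend
purchasing, single purchases, and restarts after a long break. The
generator records the *true* episode structure and dose trajectory as
explicit state — an episode break happens where the simulated person
is coded as discontinuing, never by any gap heuristic — so scoring
against the truth cannot trivially encode the method under test.

Refill timing: a refill lands exactly on the package-depletion day
with probability ``on_schedule_prob``; otherwise the interval is
perturbed by multiplicative log-normal jitter truncated at ±3σ. The
point mass reproduces the spikes at package-size refill lengths that
real dispensing histograms show; the log-normal tail supplies the
few-days-early/late scatter around them.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import InstitutionalStay, Purchase

__all__ = [
    "PROFILE_KINDS",
    "PersonProfile",
    "Episode",
    "GroundTruth",
    "generate_cohort",
    "score_against_truth",
    "default_cohort_profiles",
    "matching_parameter_space",
]

PROFILE_KINDS = (
    "regular",
    "stockpiler",
    "irregular",
    "dose_change",
    "hospitalized",
    "single_buyer",
    "restart_after_gap",
)


@dataclass(frozen=True)
class PersonProfile:
    """Recipe for one simulated person's purchasing of one drug.

    ``true_dose`` is the consumed dose in DDD/day; ``package_ddd`` the
    DDD content of one package (``package_units`` tablets/capsules);
    the refill interval is then ``package_ddd·n_packages/true_dose``
    days. Supplies per purchase should stay within a three-month
    dispensing limit, as register rules cap them there.
    """

    person_id: str
    profile_kind: str = "regular"
    atc: str = "N05AH02"
    vnr: str = "141473"
    true_dose: float = 1.0
    package_ddd: float = 30.0
    package_units: int = 30
    n_packages: int = 1
    refill_jitter: float = 0.05
    on_schedule_prob: float = 0.35
    n_purchases: int = 8
    stay_every_k_purchases: int = 3
    stay_length_range: tuple[int, int] = (5, 25)
    restart_gap_days: int = 330
    dose_change_factor: float = 2.0

    def __post_init__(self) -> None:
        if self.profile_kind not in PROFILE_KINDS:
            raise ValueError(f"unknown profile kind {self.profile_kind!r}")
        if not self.true_dose > 0:
            raise ValueError("true_dose must be positive")
        if not 0 <= self.refill_jitter < 0.5:
            raise ValueError("refill_jitter must lie in [0, 0.5)")
        if self.base_interval_days < 1:
            raise ValueError(
                f"infeasible profile: refill interval "
                f"{self.base_interval_days:.2f} d is shorter than one day"
            )

    @property
    def base_interval_days(self) -> float:
        return self.package_ddd * self.n_packages / self.true_dose


@dataclass(frozen=True)
class Episode:
    """One true interval of continuous use, with its dose trajectory."""

    start: dt.date
    end: dt.date
    dose_segments: tuple[tuple[dt.date, dt.date, float], ...]

    @property
    def mean_dose(self) -> float:
        total = sum((e - s).days * d for s, e, d in self.dose_segments)
        days = sum((e - s).days for s, e, d in self.dose_segments)
        return total / max(1, days)


@dataclass
class GroundTruth:
    """True episodes and exposure per (person, ATC)."""

    episodes: dict[tuple[str, str], list[Episode]] = field(default_factory=dict)

    def exposure_days(self, key: tuple[str, str]) -> int:
        return sum((e.end - e.start).days for e in self.episodes.get(key, []))


def _interval(rng: np.random.Generator, base: float, profile: PersonProfile) -> int:
    """One refill interval: on-schedule point mass + truncated log-normal."""
    sigma = profile.refill_jitter
    if sigma == 0 or rng.random() < profile.on_schedule_prob:
        factor = 1.0
    else:
        z = float(np.clip(rng.normal(0.0, 1.0), -3.0, 3.0))
        factor = float(np.exp(sigma * z))
    return max(1, int(round(base * factor)))


def _simulate_person(
    profile: PersonProfile,
    start: dt.date,
    end: dt.date,
    rng: np.random.Generator,
) -> tuple[list[Purchase], list[InstitutionalStay], list[Episode]]:
    purchases: list[Purchase] = []
    stays: list[InstitutionalStay] = []
    dose_log: list[tuple[dt.date, float]] = []  # dose in force from this date

    n = 1 if profile.profile_kind == "single_buyer" else profile.n_purchases
    date = start + dt.timedelta(days=int(rng.integers(0, 30)))
    true_dose = profile.true_dose
    base = profile.package_ddd * profile.n_packages / true_dose
    restart_at = n // 2 if profile.profile_kind == "restart_after_gap" else None
    dose_change_at = n // 2 if profile.profile_kind == "dose_change" else None
    episode_breaks: list[int] = []  # purchase index that STARTS a new episode
    debt = 0.0  # stock carried by a stockpiler (negative supply debt)

    for i in range(n):
        if date > end:
            n = i
            break
        purchases.append(
            Purchase(
                person_id=profile.person_id,
                date=date,
                atc=profile.atc,
                vnr=profile.vnr,
                n_packages=profile.n_packages,
                ddd_amount=profile.package_ddd * profile.n_packages,
            )
        )
        dose_log.append((date, true_dose))
        if i == n - 1:
            break

        if dose_change_at is not None and i + 1 == dose_change_at:
            true_dose = profile.true_dose * profile.dose_change_factor
            base = profile.package_ddd * profile.n_packages / true_dose

        if restart_at is not None and i + 1 == restart_at:
            gap = profile.restart_gap_days + int(rng.integers(0, 60))
            episode_breaks.append(i + 1)
            date = date + dt.timedelta(days=gap)
            continue

        if profile.profile_kind == "stockpiler" and i % 4 == 1:
            # buy ahead: half interval now, the stock stretches the next
            gap = max(1, int(round(base * 0.5)))
            debt += base - gap
        else:
            gap = _interval(rng, base + debt, profile)
            debt = 0.0

        if (
            profile.profile_kind == "hospitalized"
            and (i + 1) % profile.stay_every_k_purchases == 0
        ):
            lo, hi = profile.stay_length_range
            stay_len = int(rng.integers(lo, hi + 1))
            offset = 1 + int(rng.integers(0, max(1, gap // 2)))
            admission = date + dt.timedelta(days=offset)
            stays.append(
                InstitutionalStay(
                    person_id=profile.person_id,
                    admission=admission,
                    discharge=admission + dt.timedelta(days=stay_len),
                )
            )
            # drugs are supplied in care: depletion and the next
            # purchase shift by the stay length
            gap += stay_len

        date = date + dt.timedelta(days=gap)

    # assemble true episodes from the explicit discontinuation state
    episodes: list[Episode] = []
    bounds = [0] + episode_breaks + [len(purchases)]
    for a, b in zip(bounds, bounds[1:]):
        if a >= b:
            continue
        members = purchases[a:b]
        seg_doses = dose_log[a:b]
        last_date, last_dose = seg_doses[-1]
        stay_tail = sum(
            (s.discharge - s.admission).days
            for s in stays
            if s.discharge is not None and s.admission >= last_date
        )
        supply = profile.package_ddd * profile.n_packages / last_dose
        ep_end = last_date + dt.timedelta(days=int(round(supply)) + stay_tail)
        seg: list[tuple[dt.date, dt.date, float]] = []
        for (d0, dose), (d1, _) in zip(seg_doses, seg_doses[1:]):
            seg.append((d0, d1, dose))
        seg.append((last_date, ep_end, last_dose))
        episodes.append(Episode(members[0].date, ep_end, tuple(seg)))
    return purchases, stays, episodes


def generate_cohort(
    profiles: Sequence[PersonProfile],
    start: dt.date,
    end: dt.date,
    seed: int,
) -> tuple[list[Purchase], list[InstitutionalStay], GroundTruth]:
    """Simulate purchases, stays and the true episode structure.

    Deterministic for a given seed: each profile gets an independent
    stream derived from ``(seed, profile index)``.
    """
    if end <= start:
        raise ValueError("cohort date range is empty")
    purchases: list[Purchase] = []
    stays: list[InstitutionalStay] = []
    truth = GroundTruth()
    for idx, profile in enumerate(profiles):
        rng = np.random.default_rng((int(seed) * 1_000_003 + idx) % (2**31 - 1))
        p, s, eps = _simulate_person(profile, start, end, rng)
        purchases.extend(p)
        stays.extend(s)
        truth.episodes[(profile.person_id, profile.atc)] = eps
    return purchases, stays, truth


def default_cohort_profiles(
    n_per_kind: int = 10,
    kinds: Sequence[str] = PROFILE_KINDS,
    doses: Sequence[float] = (0.33, 0.5, 1.0, 2.0),
    jitter: float = 0.05,
) -> list[PersonProfile]:
    """A mixed cohort cycling profile kinds over realistic dose levels.

    Package sizes are chosen so each purchase covers at most about a
    three-month supply at the profile's dose; each distinct package
    gets its own vnr, as in a real register.
    """
    profiles: list[PersonProfile] = []
    packages = {0.33: 32.34, 0.5: 30.0, 1.0: 30.0, 2.0: 56.0}
    vnrs = {0.33: "100033", 0.5: "100050", 1.0: "100100", 2.0: "100200"}
    counter = 0
    for kind in kinds:
        for j in range(n_per_kind):
            dose = doses[counter % len(doses)]
            profiles.append(
                PersonProfile(
                    person_id=f"S{counter:05d}",
                    profile_kind=kind,
                    true_dose=dose,
                    package_ddd=packages.get(dose, 30.0),
                    refill_jitter=0.2 if kind == "irregular" else jitter,
                    on_schedule_prob=0.1 if kind == "irregular" else 0.35,
                    n_purchases=10,
                    vnr=vnrs.get(dose, "100100"),
                )
            )
            counter += 1
    return profiles


def matching_parameter_space(profiles: Sequence[PersonProfile]):
    """An expert parameter set covering a simulated cohort's drugs.

    Mirrors what a parameter author would define from package
    knowledge: the typical refill length is the pack's duration at the
    intended dose, the maximum allows 50% slack, and the dose limits
    bracket the intended dose (3× above, 1/1.5 below).
    """
    from .parameters import AtcParams, PackageParams, ParameterSpace

    atc_table: dict[str, AtcParams] = {}
    vnr_table: dict[str, PackageParams] = {}
    for pr in profiles:
        if pr.atc not in atc_table:
            atc_table[pr.atc] = AtcParams(
                atc_prefix=pr.atc,
                min_ddd_per_day=0.05,
                common_ddd_per_day=1.0,
                min_period_days=15,
                max_refill_days=150,
            )
        if pr.vnr not in vnr_table:
            base = pr.base_interval_days / pr.n_packages
            vnr_table[pr.vnr] = PackageParams(
                vnr=pr.vnr,
                min_refill_days=max(1, int(base / 3)),
                max_refill_days=int(base * 1.5) + 1,
                typical_refill_days=int(round(base)),
                ddd_per_day_at_min=pr.true_dose * 3,
                ddd_per_day_at_max=pr.true_dose / 1.5,
                ddd_per_day_typical=pr.true_dose,
            )
    return ParameterSpace(atc_table=atc_table, vnr_table=vnr_table)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def score_against_truth(periods: Iterable, truth: GroundTruth) -> dict:
    """Compare constructed periods with the generator's ground truth.

    Episodes are matched in chronological order per (person, ATC).
    Reported per key: episode-count error, absolute start/end errors in
    days and the relative dose error; cohort summaries give medians and
    90th percentiles.
    """
    by_key: dict[tuple[str, str], list] = {}
    for p in periods:
        by_key.setdefault((p.person_id, p.atc), []).append(p)
    for v in by_key.values():
        v.sort(key=lambda p: p.start)

    rows = []
    for key, true_eps in truth.episodes.items():
        est = by_key.get(key, [])
        for te, pe in zip(true_eps, est):
            start_err = abs((pe.start - te.start).days)
            end_err = abs((pe.end - te.end).days)
            dose_err = abs(pe.mean_ddd_per_day - te.mean_dose) / te.mean_dose
            rows.append(
                {
                    "person_id": key[0],
                    "atc": key[1],
                    "episode_count_error": len(est) - len(true_eps),
                    "start_abs_error_days": start_err,
                    "end_abs_error_days": end_err,
                    "dose_rel_error": dose_err,
                }
            )
        if not true_eps and est:
            rows.append(
                {
                    "person_id": key[0],
                    "atc": key[1],
                    "episode_count_error": len(est),
                    "start_abs_error_days": None,
                    "end_abs_error_days": None,
                    "dose_rel_error": None,
                }
            )

    def _summary(field: str) -> dict[str, float]:
        values = [r[field] for r in rows if r[field] is not None]
        if not values:
            return {"median": float("nan"), "p90": float("nan")}
        arr = np.asarray(values, dtype=float)
        return {
            "median": float(np.median(arr)),
            "p90": float(np.percentile(arr, 90)),
        }

    return {
        "per_key": rows,
        "n_keys": len(truth.episodes),
        "n_matched": len(rows),
        "episode_count_accuracy": (
            float(np.mean([r["episode_count_error"] == 0 for r in rows]))
            if rows
            else float("nan")
        ),
        "start_abs_error_days": _summary("start_abs_error_days"),
        "end_abs_error_days": _summary("end_abs_error_days"),
        "dose_rel_error": _summary("dose_rel_error"),
    }
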