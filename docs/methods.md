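# Methods

`pre2dup` converts per-person prescription-purchase histories into
continuous **drug use periods** — episodes of assumed continuous use of
one ATC-coded drug, with an estimated average daily dose in DDD/day.
This note describes the model, its parameters, the numerical choices,
what the synthetic cohorts do and do not emulate, and the known
limitations.

## The model

### Inputs and output

The inputs are dispensing records (person, purchase date, ATC code,
package identifier *vnr*, package count, dispensed amount in Defined
Daily Doses) and institutional-stay intervals (hospital and long-term
care), during which drug use is invisible to the dispensing register.
The output is, per person and ATC code, a set of non-overlapping
periods, each carrying start and end dates, the dispensed DDD total,
the number of member purchases, the hospital days inside the period
and the mean dose `total_ddd / (period days − hospital days)`.

### Sliding temporal dose average

For each history (one person, one ATC code, chronological, same-day
rows merged) the local dose level at purchase *i* is the weighted
ratio

```
DDDAVG_i = (DDD_{i−1} + 4·DDD_i + DDD_{i+1}) / (T_{i−1} + 4·T_i + T_{i+1})
```

where `T_i` is the **net** gap (calendar days minus hospital days,
floored at one day) from purchase *i* to *i+1*. The first purchase of
a treatment segment uses weights (5, 1) over *(i, i+1)*, the last
(1, 5) over *(i−1, i)*; the last purchase's open-ended gap is imputed
assuming the previous dose level, `T_n = DDD_n/(DDD_{n−1}/T_{n−1})`.
A net gap longer than the maximum refill time (300 days) restarts the
segment: the drug cannot have lasted across it. Averages require at
least three purchases per segment; shorter histories reach the
decision procedure unprocessed. The coefficient of variation of the
averages, `DDDAVGcv` (sample SD / mean, one value per person × ATC),
measures purchasing regularity.

### The decision procedure

Walking each history left to right, purchase *i* joins its successor
into the same period when its **expected refill length**

```
ERFL_i = DDD_i · (1 + DVAR·DDDAVGcv) / DDDAVG_i        (DVAR = 0.5)
```

reaches the next purchase. Irregular buyers get a proportionally
longer reach through the cv multiplier. Three corrections guard the
plain ratio:

* **dose caps** — the dose in the denominator is clamped at the global
  maximum (10 DDD/day) and at the package's dose at minimum refill
  length, so purchases a few days apart cannot produce absurd doses;
* **length caps** — the resulting reach is truncated at the package
  maximum refill length × package count (or, without package data, the
  ATC-class maximum), so stockpiling or as-needed use cannot join
  purchases across unrealistic spans;
* **low-dose split** — a sliding average below the package's (else the
  ATC class's) lower dose limit means the next purchase is further
  away than regular use of this drug allows; the purchase gets a
  package-based duration and closes its period.

When the reach falls short, the **stockpiling test** asks whether
`DDDAVG_i` is a strict local minimum between its neighbours — the
signature of buying ahead (short gap) and then consuming the stock
(long gap). If so, the previous and current purchases are pooled, as
if one purchase of the combined amount had happened at the previous
date; the connection holds when the pooled reach covers both gaps.
A connection is also refused outright when a continuous institutional
stay longer than the global limit (30 days) lies in the gap (see
*Design choices*).

Histories of two purchases (no sliding averages) join only when the
raw gap is inside the package/ATC maximum refill reach. A purchase
standing alone gets its duration from, in order of preference: the
dose of the person's nearest multi-purchase period of the same drug;
the population's most common refill length for the package × package
count; the dispensed amount with a 20% non-adherence allowance over
the typical daily dose; the ATC-class minimum period length; one day
(flagged). Single-purchase durations never exceed 150 days.

### Period end

A closed period ends at its last purchase plus the remaining supply

```
END = date_k + DDD_k·(1 + 0.5·DDDAVGcv) / (DDDAVG_k·(1 + e^−k)) + HD_k
```

where *k* is the number of member purchases — the `1 + e^−k` damping
halves the extension of a one-purchase period, where apparent stock is
least trustworthy, and vanishes for long periods — and `HD_k` counts
hospital days falling inside the extension, found by fixed-point
iteration (extend, re-count stay days inside the window, repeat; the
count is a non-decreasing bounded integer, so the loop terminates — a
100-round guard is kept for safety). A single continuous stay longer
than 30 days truncates the period at its admission date instead.

### Learning refill lengths (the outer iteration)

After a first pass built on expert parameters alone, each package's
observed refill lengths (raw calendar gaps between member purchases of
periods with ≥ 6 purchases; gaps divided by the package count for
multi-pack rows; dose-dispensing and mixed-package rows excluded) form
a histogram. Every bin's count is moved to its nearest local maximum
by hill-climbing within a ±3-day window (ties toward the shorter
length), consolidating the few-days-early/late scatter around true
refill rhythms; the mode of the consolidated histogram, when its count
exceeds 10 purchases, becomes the package's typical refill length and
overrides the expert guess. Periods are rebuilt with the learned
modes until the period set repeats exactly (typically 2–3 passes; a
`max_iter` guard returns the last state with a warning).

## Parameters

Global caps (never overridden):

| parameter | default | unit | role |
|---|---|---|---|
| `max_refill_gap_days` | 300 | d | segment restart threshold in the averaging |
| `max_hospital_days_in_period` | 30 | d | longest continuous stay a period may contain |
| `max_ddd_per_day` | 10 | DDD/d | dose ceiling |
| `max_single_purchase_days` | 150 | d | hard cap on a lone purchase |
| `dvar` | 0.5 | – | weight on cv in the regularity multiplier |
| `adherence_slack` | 0.2 | – | non-adherence allowance for typical-dose durations |
| `mode_min_purchases` | 10 | count | evidence threshold for a learned mode |
| `refill_source_min_purchases` | 6 | count | period size required to teach refill lengths |
| `ddd_avg_min_purchases` | 3 | count | minimum purchases for sliding averages |

ATC-class entries (per classification prefix, finest defined level
wins) carry the lower dose limit, the common daily dose, the minimum
period length and the maximum refill length. Package (vnr) entries
carry minimum/typical/maximum refill lengths with their corresponding
DDD-per-day values; they derive from pack size, divisibility and
dosing frequency (a 30-capsule once-daily pack: typical 30 d, maximum
30 d or 1.2×30 d with adherence slack, minimum 15 d at two capsules a
day) and override the ATC entries. The repository ships a small
illustrative set, not any national parameter inventory; users supply
their own tables as YAML.

## Design choices

* **Same-day duplicate rows** (same person, ATC, date) are merged by
  summing amounts and package counts before modelling, since the gap
  arithmetic divides by inter-purchase times that would otherwise be
  zero. The merge is flagged; a merge across different vnrs is marked
  mixed and excluded from refill learning.
* **Day granularity.** All gap arithmetic uses whole-day differences;
  supply estimates are continuous. A supply that runs out during the
  calendar day of the next purchase is taken to reach it, so the
  connection test is `ERFL > gap − 1` rather than `ERFL ≥ gap`.
  Under the stricter rule a refill arriving under a day "late"
  relative to the smoothed expectation would split an otherwise steady
  history, which contradicts the long continuous periods the method is
  designed to recover. Period end dates round down to whole days
  (with 10⁻⁶ d slack absorbing float residue); ties in comparisons use
  a 10⁻⁹ d tolerance.
* **Unbridgeable stays also split interior gaps.** The 30-day
  hospital cap is stated for the end-of-period extension; we apply the
  same reasoning to connections, refusing to join two purchases when a
  single continuous stay longer than the cap lies between them. A
  period should never silently span an interval the register cannot
  see and the cap declares unbridgeable.
* **Low-dose splits end the period with a package-based duration**,
  not the usual end formula — the sliding average that triggered the
  split is by definition an unreliable dose estimate.
* **cv uses the sample standard deviation** (n−1 divisor) and is
  computed per person × ATC across segments jointly.
* **Segment restarts use net gaps**, consistent with every other use
  of consumption time; boundary weights (5,1)/(1,5) apply per segment.
* **The stockpiling rescue requires the previous purchase to be in
  the same open period** — pooling across a closed boundary would
  resurrect a period already ended.
* **Two-purchase histories** join iff the raw gap is within the
  package maximum × package count (else the ATC maximum, else the
  global single-purchase cap).
* **Periods never overlap**: an end extension is clamped one day
  short of the next purchase of the same drug.

## The synthetic cohorts

The generator emulates the behaviours the method must distinguish:
steady refills, stockpiling bursts (an early half-interval purchase
followed by a stretched gap), mid-stream dose changes, institutional
stays that delay the next purchase by the stay length, single buyers,
high-jitter irregular use, and restarts after a >300-day break. The
true episode structure is explicit generator state — a break happens
where the person is coded as discontinuing, never by a gap heuristic
— so scoring against the truth does not presuppose the method's own
rules. Purchase amounts are exact package contents; intervals land
exactly on the package-depletion day with probability
`on_schedule_prob` (default 0.35) and otherwise carry multiplicative
log-normal jitter truncated at ±3σ. The point mass reflects the
spikes at package-size refill lengths that real dispensing histograms
show; a purely continuous jitter model would spread the histogram so
thinly that no single day could be the true mode at realistic sample
sizes.

What the cohorts do **not** emulate: registered amounts that disagree
with actual consumption, prescription switches within an ATC code
(different vnrs in one history), seasonal or as-needed use, dose
titration schedules, co-payment-driven purchase timing, and
data-quality artefacts beyond missing DDD/ATC fields. Passing tests
therefore show that the construction recovers episodes and doses under
controlled purchasing behaviours — not that it is calibrated for any
particular national register.

Problem sizes used by the test suite and the acceptance script —
chosen to exercise every code path at desk scale: ~1,000 mixed-profile
histories for the structural/cap audit, 4 × 50 regular users for dose
recovery, 30 persons × 9 purchases for refill-mode learning.

## Limitations

* Span monotonicity ("adding a purchase inside a period never
  shortens it") holds in the constant-dose constructions we test, but
  is not a theorem: an extra purchase perturbs `DDDAVGcv` and the last
  purchase's sliding average, and the `1 + 0.5·cv` end factor can
  shrink slightly.
* Drug remaining in the body after a period's end is out of scope; a
  period ends when the modelled supply does.
* The refill-length joining neighbourhood (±3 days) and its tie rule
  are a documented implementation choice, isolated behind
  `join_to_local_maxima` for easy replacement.
* Expert parameter quality dominates accuracy for drugs with varying
  patterns of use; the shipped tables are illustrative only.
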