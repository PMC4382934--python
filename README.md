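# pre2dup

**Continuous drug use periods from prescription purchase histories.**

Register-based pharmacoepidemiology needs to know *when* a person was
using a drug, but dispensing registers only record *when they bought
it*. First-generation exposure methods bridge the gap with fixed
assumptions — one DDD per day, one tablet per day, a flat grace
period — that ignore personal dosing, dose changes and purchasing
behaviour. `pre2dup` implements a second-generation construction: each
person's purchases of each ATC-coded drug are walked chronologically,
and a stockpiling-aware decision procedure joins them into
non-overlapping **drug use periods** with an estimated average daily
dose, using the person's own purchase history rather than a dosing
assumption.

The core quantities, per purchase *i* of one person × ATC history
(`DDD_i` = amount dispensed in Defined Daily Doses, `T_i` = hospital-
adjusted days to the next purchase):

* sliding temporal dose average
  `DDDAVG_i = (DDD_{i−1} + 4·DDD_i + DDD_{i+1}) / (T_{i−1} + 4·T_i + T_{i+1})`
  with boundary weights (5, 1)/(1, 5) and its coefficient of variation
  `DDDAVGcv` (purchasing regularity);
* expected refill length
  `ERFL_i = DDD_i·(1 + 0.5·DDDAVGcv)/DDDAVG_i` — purchases join one
  period while the expected supply reaches the next purchase, with a
  local-minimum stockpiling test rescuing buy-ahead patterns;
* period end
  `END = date_k + DDD_k·(1 + 0.5·DDDAVGcv)/(DDDAVG_k·(1 + e^{−k})) + HD_k`,
  damped for periods with few purchases and pushed across in-period
  hospital days.

A three-level expert parameter hierarchy (global caps → ATC-class
limits → package/vnr refill lengths) keeps the joins realistic, and an
outer iteration learns each package's typical refill length from the
population's own refill-length histograms (counts consolidated to the
nearest local maximum), replacing expert guesses where the data
suffice. Details: [`docs/methods.md`](docs/methods.md).

Intended users: pharmacoepidemiologists and register researchers
turning national dispensing data (ATC/DDD-coded, package-identified)
into exposure timelines, and methodologists who need a transparent,
parameterised, testable reference implementation.

## Worked example

The packaged example is the classic stockpiling pattern: five
purchases of 10 DDD at gaps of 10, 5, 15 and 10 days (average dose one
DDD/day). The second purchase arrives early (buying ahead), the third
gap is long (using the stock) — a naive supply rule would split the
history there.

```python
from pre2dup import Pre2Dup
from pre2dup.datasets import load_example_history, load_example_parameters

results = Pre2Dup(load_example_history(), params=load_example_parameters()).fit()
print(results.summary())
print(results.periods_frame.to_string(index=False))
```

```
Drug use period construction
================================================================
purchases used     : 5
exception rows     : 0
periods            : 1
iterations         : 2
learned modes      : 0 packages

ATC  periods  median d   mean d  med DDD/d
------------------------------------------
N          1        50     50.0       1.00

start_date   end_date person_id     atc  total_ddd  hospital_days  n_purchases  mean_ddd_per_day
2005-01-01 2005-02-20        P1 N05AH02       50.0              0            5               1.0
```

All five purchases land in **one** period: at the third purchase the
sliding average dips to 0.80 DDD/day and the plain supply estimate
(12.5 days) misses the 15-day gap, but the dip is a strict local
minimum between 1.33 and 0.92 — the stockpiling signature — so the
pooled previous-plus-current supply (≥ 20 days) bridges it. The period
runs from the first purchase to 10 days past the last one (the
remaining supply under the `1 + e^{−5}` damping), and the estimated
dose is 1.00 DDD/day: 50 DDD over 50 days.

The same run from the shell:

```bash
pre2dup run \
    --purchases src/pre2dup/data/stockpiling_example_purchases.csv \
    --config    src/pre2dup/data/run_config.yaml \
    --out       periods.csv
```

Other commands: `pre2dup simulate` (synthetic cohorts with ground
truth), `pre2dup score` (periods vs. truth), `pre2dup validate-config`.

## Repository layout

```
src/pre2dup/
  io.py          reading/writing purchases, stays, periods; histories
  parameters.py  global / ATC-class / package parameter hierarchy
  preprocess.py  net gaps, sliding dose averages, regularity cv
  refill.py      refill-length histograms, joining, mode selection
  core.py        the decision procedure and the iterated pipeline
  model.py       Pre2Dup / Pre2DupResults model objects
  synthetic.py   cohort generator with explicit ground truth
  cli.py         run / simulate / validate-config / score
  data/          packaged worked example + parameter templates
```

Limitations and modelling assumptions — including what the synthetic
cohorts do and do not emulate — are documented in
[`docs/methods.md`](docs/methods.md).
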