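# Package (vnr) parameters: refill-length limits with the daily doses
# they correspond to. Example: a 10-DDD pack used at one DDD per day
# lasts 10 days; twice that dose gives the minimum length, and the
# maximum allows use down to 0.28 DDD/day.
- vnr: "141473"
  min_refill_days: 5
  max_refill_days: 36
  typical_refill_days: 10
  ddd_per_day_at_min: 2.0
  ddd_per_day_at_max: 0.28
  ddd_per_day_typical: 1.0
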