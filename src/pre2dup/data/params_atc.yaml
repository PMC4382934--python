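# ATC-class parameters: a list of records, one per classification
# prefix (any level). The finest defined prefix of a purchase's code
# applies.
- atc_prefix: N05A            # antipsychotics
  min_ddd_per_day: 0.1        # below this the period is split
  common_ddd_per_day: 1.0     # fallback daily dose
  min_period_days: 15
  max_refill_days: 120
- atc_prefix: N
  min_ddd_per_day: 0.05
  common_ddd_per_day: 1.0
  min_period_days: 15
  max_refill_days: 150
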