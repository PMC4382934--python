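# Global caps. These are the documented defaults, written out so the
# file doubles as a commented template; none may be overridden by
# ATC- or package-level entries.
max_refill_gap_days: 300        # longer net gaps restart the treatment segment
max_hospital_days_in_period: 30 # longest continuous stay a period may bridge
max_ddd_per_day: 10             # dose ceiling for purchases a few days apart
max_single_purchase_days: 150   # hard cap on a lone purchase's duration
dvar: 0.5                       # weight on cv in the regularity multiplier
adherence_slack: 0.2            # non-perfect-adherence allowance
mode_min_purchases: 10          # joined-count threshold for a learned mode
refill_source_min_purchases: 6  # min purchases for a period to teach refills
ddd_avg_min_purchases: 3        # min purchases for sliding dose averages
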