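# Frequency-response dialects of the picture-sort instrument.
#
# servings_per_day maps each ordinal response label to a daily-servings
# value.  The child instrument uses 4 scored categories (the two-step
# "every day" probe is collapsed upstream into "once a day" vs "more than
# once per day"); the adult instrument uses 5.  Anchors: never -> 0,
# more than once per day -> 2.  "sometimes" (child) is the midpoint of
# everything between never and daily; "sometimes but not weekly" (adult)
# is roughly monthly (1/30); "weekly" is 1/7.
child:
  categories: [never, sometimes, once a day, more than once per day]
  servings_per_day:
    never: 0.0
    sometimes: 0.5
    once a day: 1.0
    more than once per day: 2.0
adult:
  categories: [never, sometimes but not weekly, weekly, every day, more than once per day]
  servings_per_day:
    never: 0.0
    sometimes but not weekly: 0.033
    weekly: 0.143
    every day: 1.0
    more than once per day: 2.0
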