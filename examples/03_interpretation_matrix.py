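"""Reading joint trends with the leadership interpretation matrix.

Classifies a few trend combinations and prints the prescribed diagnostics
and actions. The same ambiguity — "are near misses rising because safety is
worse, or because reporting is better?" — resolves differently depending on
what harm and total reporting volume are doing.
"""

from nm3 import Trend, classify_pattern, trend_direction

# Trend labels come from least-squares slopes on the rate series:
print("nm series [0.8, 1.0, 1.3, 1.5, 1.8, 2.0] ->",
      trend_direction([0.8, 1.0, 1.3, 1.5, 1.8, 2.0]).value)
print("harm series [1.1, 1.0, 0.9, 0.9, 0.8, 0.7] ->",
      trend_direction([1.1, 1.0, 0.9, 0.9, 0.8, 0.7]).value)
print()

scenarios = [
    ("NM up, harm down, reporting stable",
     (Trend.INCREASING, Trend.DECREASING, Trend.FLAT, False)),
    ("NM up, harm flat, reporting up",
     (Trend.INCREASING, Trend.FLAT, Trend.INCREASING, False)),
    ("NM down, harm down, reporting down",
     (Trend.DECREASING, Trend.DECREASING, Trend.DECREASING, False)),
    ("everything flat, no SPC signals",
     (Trend.FLAT, Trend.FLAT, Trend.FLAT, False)),
    ("NM and harm both rising",
     (Trend.INCREASING, Trend.INCREASING, Trend.INCREASING, False)),
]

for title, inputs in scenarios:
    a = classify_pattern(*inputs)
    print(f"{title}\n  pattern: {a.pattern_id.value}")
    print(f"  reading: {a.interpretation_text}")
    print(f"  action : {a.action_text}\n")

# Note the last case: near misses and harm rising together has no named row
# in the matrix — it is deliberately left unclassified with an "investigate
# harm rise" diagnostic rather than given a reassuring label.
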