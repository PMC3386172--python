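"""Transition patterns: the sixteen control-to-stress banding classes.

Rebuilds per-locus pattern records from the bundled IR29 shoot class counts
and summarises the three biological groups.
"""

from msapkit import classify_pattern, datasets, pattern_summary, round_display
from msapkit.pattern_dynamics import PATTERN_CLASSES

counts = datasets.pattern_class_counts("IR29", "shoot")
records = [classify_pattern(quad)
           for quad, klass in PATTERN_CLASSES.items()
           for _ in range(counts[klass])]
summary = pattern_summary(records)

for group in ("no_change", "demethylation", "methylation"):
    print(f"{group:14s} {summary.group_counts[group]:5d} loci "
          f"({round_display(summary.group_pcts[group]):.1f}%)")

print(f"\nOf {summary.grand_total} scored loci, half keep their methylation")
print("state under 24 h of salt stress; demethylation events outnumber new")
print("methylation events in IR29 shoots.")
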