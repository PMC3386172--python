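"""Independence of methylation level and treatment.

Builds the 3x2 methylation-level by treatment table for IR29 shoots and
tests independence with Pearson chi-square and the likelihood-ratio (G)
statistic, then prints adjusted residuals to locate the signal.
"""

import numpy as np

from msapkit import (adjusted_residuals, datasets, level_by_treatment_table,
                     likelihood_ratio_test, pearson_chi_square)

control = datasets.band_type_counts("IR29", "shoot", "control")
stress = datasets.band_type_counts("IR29", "shoot", "salinity")
table = level_by_treatment_table(control, stress)

print("counts (rows: unmethylated / hemimethylated / fully methylated):")
print(table.counts)
for res in (pearson_chi_square(table), likelihood_ratio_test(table)):
    print(f"{res.method:17s} statistic = {res.statistic:7.3f}  "
          f"df = {res.df}  p = {res.p_value:.2e}")
print("adjusted residuals:")
print(np.round(adjusted_residuals(table).residuals, 2))

print("\nBoth tests reject independence: the distribution over methylation")
print("levels shifts under salinity. Residuals beyond +/-2 show the shift is")
print("driven by more unmethylated and fewer hemimethylated loci under stress.")
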