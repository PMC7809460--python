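"""Hedges' g from per-sex summary statistics.

Builds a four-row toy study table (two species, both sexes), converts it
into male-minus-female standardised mean differences, and shows the SD
recovery helpers for studies that only report an SE or a 95% CI.
"""

import pandas as pd

from avimeta import build_effect_table, effects_to_frame, sd_from_ci, sd_from_se

table = pd.DataFrame(
    [
        # species, study, variable, season, sex, n, mean, sd
        ("Parus_major", "study01", "PHA", "breeding", "male", 12, 1.10, 0.30, "sd"),
        ("Parus_major", "study01", "PHA", "breeding", "female", 14, 0.95, 0.28, "sd"),
        ("Molothrus_ater", "study02", "PHA", "non-breeding", "male", 9, 0.80, 0.35, "sd"),
        ("Molothrus_ater", "study02", "PHA", "non-breeding", "female", 10, 0.88, 0.33, "sd"),
    ],
    columns=["species", "study", "variable", "season", "sex", "n", "mean", "sd", "dispersion"],
)

result = build_effect_table(table)
print(effects_to_frame(result.effects).round(4).to_string(index=False))
# g > 0 means the trait is higher in males, g < 0 higher in females;
# v is the sampling variance used as the known error in the meta-model.

print()
print("SD recovered from SE 0.08 with n=12:", round(sd_from_se(0.08, 12), 4))
print("SD recovered from 95% CI (0.9, 1.3) with n=12:", round(sd_from_ci(0.9, 1.3, 12), 4))
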