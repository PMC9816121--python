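"""Participant-level stratified train/validation/test split.

Participants are stratified by study, binned into quartiles of their
minimum total BMD across images, and split 70/15/15 within each bin, so
subset BMD distributions stay balanced and no participant's images are
divided across subsets.
"""

import numpy as np
import pandas as pd

from pqctseg import stratified_split

rng = np.random.default_rng(5)
rows = []
for i in range(200):
    study = "normative" if i < 160 else "fracture"
    base_bmd = rng.uniform(150, 420)
    for site in ("radius", "tibia"):
        rows.append(
            {
                "participant": f"P{i:04d}",
                "study": study,
                "tt_bmd": base_bmd + rng.normal(0, 8),
            }
        )
table = pd.DataFrame(rows)

assignment = stratified_split(table, seed=0)
print(assignment.value_counts().to_string())

merged = table.merge(assignment.rename("subset"), left_on="participant", right_index=True)
print("\nmean Tt.BMD by subset (stratification keeps these close):")
print(merged.groupby("subset")["tt_bmd"].mean().round(1).to_string())

split_participants = merged.groupby("participant")["subset"].nunique()
print(f"\nparticipants with images in more than one subset: "
      f"{(split_participants > 1).sum()}")
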