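"""Simulate a rearing dataset from a species preset and inspect it.

Draws individuals from the published two-component Weibull mixture for
Necrodes littoralis across its ten-temperature rearing design, then
summarizes what a rearing experiment of this kind looks like.
"""

import numpy as np

import thermomix as tm

design = tm.species_preset("necrodes_littoralis", n=500, seed=7)
data = tm.sample_dataset(design)

print(f"simulated {len(data)} individuals of {data.species_label}")
print(f"temperatures: {sorted(set(data.temp))}")
df = data.to_frame()
print(df.groupby("temp_C")["dev_time_days"].agg(["count", "mean", "std"]).round(2))
print(
    "\nEach row of the table is one rearing temperature: cohort size, mean and\n"
    "SD of development time in days. Development is faster (smaller D) at\n"
    "warmer temperatures because the thermal budget k = D(T - t0) accrues faster."
)
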