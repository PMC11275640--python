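"""Absorbance from raw detector counts, with four-point replicate averaging.

Builds one synthetic measurement (sample, white-reference and dark counts on
the 500-978 nm grid), converts it to absorbance A = -log10((S-D)/(W-D)), and
averages four replicate points the way a fruit is measured around its
equator.
"""

import numpy as np

from strawspec import (RawIntensityRecord, average_replicates,
                       compute_absorbance, vis_nir_grid)

grid = vis_nir_grid()
rng = np.random.default_rng(0)

white = np.full(len(grid), 40000.0)      # white-plate counts
dark = np.full(len(grid), 1200.0)        # dark current

# a fruit that absorbs ~1 AU with a band near 680 nm, four replicate points
records = []
for point in range(4):
    true_absorbance = 1.0 + 0.3 * np.exp(-0.5 * ((grid.values - 680) / 15) ** 2)
    counts = (white - dark) * 10.0 ** (-true_absorbance)
    sample = dark + counts * (1.0 + rng.normal(0, 0.01, len(grid)))
    records.append(RawIntensityRecord(grid, sample, white, dark))

single = compute_absorbance(records[0])
averaged = average_replicates(records)

i680 = int(np.argmin(np.abs(grid.values - 680)))
print(f"absorbance at 680 nm, single point : {single[i680]:.4f} AU")
print(f"absorbance at 680 nm, 4-point mean : {averaged[i680]:.4f} AU")
print(f"replicate scatter at 680 nm        : "
      f"{np.std([compute_absorbance(r)[i680] for r in records], ddof=1):.4f} AU")
# The 4-point mean sits near the true 1.3 AU; averaging shrinks the
# per-point measurement scatter by a factor of two.
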