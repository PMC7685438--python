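"""How much power does a weak fold change leave on the table?

Computes exact-test power at a handful of design points and traverses a
small grid, showing how replication, depth and dispersion trade off when
the effect is a 1.05-1.5x fold change under a genome-wide Bonferroni
cutoff.
"""

import numpy as np

from powerdeg import bonferroni_cutoff, est_power, traverse_grid

alpha = bonferroni_cutoff(0.05, 15000)
print(f"genome-wide per-test level: {alpha:.2g}")

print("\npower at a 30% fold change, 1,024 mean fragments:")
for n in (3, 5, 8, 12):
    for phi0 in (0.0005, 0.004, 0.016):
        p = est_power(n, rho=1.3, lambda0=1024.0, phi0=phi0, alpha=alpha)
        print(f"  n={n:>2} per group, dispersion {phi0:<7}: power {p:.3f}")

print("\neven extreme designs struggle with a 5% fold change:")
p = est_power(13, rho=1.05, lambda0=65536.0, phi0=0.0005, alpha=alpha)
print(f"  n=13, 65,536 mean fragments, dispersion 0.0005: power {p:.3f}")

print("\nsmall grid traversal (rows = product of axis lengths):")
grid = traverse_grid(
    {
        "n": [3, 6, 12],
        "rho": [1.1, 1.3, 1.5],
        "lambda0": [1024.0],
        "phi0": [0.004],
    },
    alpha=alpha,
)
print(grid.table[["n", "rho", "power"]].pivot(index="n", columns="rho", values="power").round(3))
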