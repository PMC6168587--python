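"""Anisotropy and funneling efficiency versus inter-fluorophore distance.

Runs a small Förster-lattice sweep (GFP, R0 = 4.7 nm) and prints the r(d) and
eps(d) table.  Scale n_realizations/repeats up for publication-quality curves.
"""

from polim2d import distance_sweep

table = distance_sweep(
    [3.5, 5.0, 6.5, 9.0, 13.0],
    r0=4.7,
    n_side=5,
    n_realizations=200,
    repeats=3,
    seed=1,
)
print(table.to_string(index=False, float_format=lambda x: f"{x:.3f}"))
print(
    "r falls and eps rises as the lattice gets denser: eps > 0.5 flags\n"
    "spacings below ~7 nm, i.e. densely aggregated fluorophores."
)
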