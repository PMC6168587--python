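"""Build a polarization portrait and read off its contrasts.

Constructs the portrait of a single in-plane dipole at 30 degrees plus an
isotropic background, then prints the modulation depths/phases and the
fluorescence anisotropy at two excitation orientations.
"""

import numpy as np

from polim2d import (
    AngleGrid,
    PolarizationPortrait,
    anisotropy,
    modulation_emission,
    modulation_excitation,
)

grid = AngleGrid.default()

# 60% single dipole at 30 deg, 40% isotropic ensemble
dipole = (
    np.cos(np.deg2rad(30.0 - grid.ex)) ** 2 * np.cos(np.deg2rad(30.0 - grid.em)) ** 2
)
iso = 0.25 * (1 + 0.5 * np.cos(np.deg2rad(2 * (grid.ex - grid.em))))
portrait = PolarizationPortrait.from_samples(0.6 * dipole + 0.4 * iso, grid)

m_ex, th_ex = modulation_excitation(portrait)
m_em, th_em = modulation_emission(portrait)
print(f"M_ex = {m_ex:.3f} at theta_ex = {th_ex:.1f} deg")
print(f"M_em = {m_em:.3f} at theta_em = {th_em:.1f} deg")
print(f"r(0 deg)  = {anisotropy(portrait, 0.0):.3f}")
print(f"r(45 deg) = {anisotropy(portrait, 45.0):.3f}")
print(
    "Partial alignment shows up as M > 0 and makes the anisotropy depend on\n"
    "the excitation orientation -- the artifact the funneling contrast avoids."
)
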