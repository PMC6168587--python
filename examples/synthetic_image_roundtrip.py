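"""Render a synthetic two-region stack and recover its eps map.

The phantom has equal brightness everywhere but eps = 0.2 on the left and
0.65 on the right (monomer-like vs fibril-like packing); the analysis must
separate the regions even though the intensity image cannot.
"""

import numpy as np

from polim2d import AngleGrid, build_portraits, epsilon_map
from polim2d.synth import NoiseModel, render_stack, two_region_phantom

grid = AngleGrid.default()
truth = two_region_phantom(shape=(8, 16), intensity=1e4,
                           noise=NoiseModel(kind="poisson"))
frames, _ = render_stack(truth, grid, seed=1)

stack = build_portraits(frames, grid)
maps = epsilon_map(stack)
left, right = maps.eps[:, :8], maps.eps[:, 8:]
print(f"intensity left/right: {stack.intensity[:, :8].mean():.0f} / "
      f"{stack.intensity[:, 8:].mean():.0f} counts (indistinguishable)")
print(f"eps left  = {np.nanmean(left):.3f} +/- {np.nanstd(left):.3f}  (truth 0.20)")
print(f"eps right = {np.nanmean(right):.3f} +/- {np.nanstd(right):.3f}  (truth 0.65)")
print("The funneling contrast separates packing states at equal brightness.")
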