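import numpy as np
import pytest
from hypothesis import settings

from polim2d import AngleGrid, PolarizationPortrait

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid() -> AngleGrid:
    return AngleGrid.default()


def portrait_from_model(coeff_map, grid=None) -> PolarizationPortrait:
    """Portrait sampled (noise-free) from a named coefficient set."""
    from polim2d.portraits import coeffs_from_dict

    grid = grid or AngleGrid.default()
    model = PolarizationPortrait(coeffs_from_dict(coeff_map))
    return PolarizationPortrait.from_samples(model.evaluate(grid.ex, grid.em), grid)


def rotate_portrait(portrait: PolarizationPortrait, delta: float) -> PolarizationPortrait:
    """The same physical portrait with the sample rotated by ``delta`` degrees."""
    grid = portrait.grid or AngleGrid.default()
    vals = portrait.evaluate(grid.ex - delta, grid.em - delta)
    return PolarizationPortrait.from_samples(vals, grid)


def single_dipole_values(theta: float, grid: AngleGrid) -> np.ndarray:
    """I ~ cos^2(theta - phi_ex) cos^2(theta - phi_em): one in-plane dipole."""
    return (
        np.cos(np.deg2rad(theta - grid.ex)) ** 2
        * np.cos(np.deg2rad(theta - grid.em)) ** 2
    )
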