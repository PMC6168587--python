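"""Synthetic polarization image stacks with known ground truth.

Every pixel is rendered from the same portrait model the analysis fits:

    I(phi_ex, phi_em) = intensity * [(1 - eps) * I_noET + eps * I_funnel]

with per-pixel truth maps for eps, the excitation modulation (M_ex, theta_ex),
the funnel emission polarization (M_f, theta_f) and the mean intensity in
camera counts.  Shot noise is Poisson; an optional EMCCD excess-noise factor
(sqrt(2) for electron multiplication) widens it, and additive Gaussian read
noise can be layered on top.  The generator emulates an ideal polarization
microscope — no PSF blur, drift, flat-field error or polarizer leakage — so
round trips test the estimators, not optics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .portraits import AngleGrid, design_matrix
from .sfa import funnel_coeffs, no_transfer_coeffs

NOISE_KINDS = ("none", "poisson", "poisson_gaussian")


@dataclass
class NoiseModel:
    """Per-frame camera noise.

    kind: "none", "poisson" (shot noise) or "poisson_gaussian" (shot + read).
    excess: multiplicative excess-noise factor; sqrt(2) models the EM register
    of an EMCCD (variance doubled at constant mean).  read_noise: Gaussian
    sigma in counts.
    """

    kind: str = "poisson"
    excess: float = 1.0
    read_noise: float = 0.0

    def __post_init__(self):
        if self.kind not in NOISE_KINDS:
            raise ValueError(f"noise kind must be one of {NOISE_KINDS}")
        if self.excess < 1.0 or self.read_noise < 0.0:
            raise ValueError("excess >= 1 and read_noise >= 0 required")

    def apply(self, expected: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "none":
            return expected.copy()
        f2 = self.excess**2
        noisy = f2 * rng.poisson(expected / f2).astype(float)
        if self.kind == "poisson_gaussian" and self.read_noise > 0:
            noisy += rng.normal(0.0, self.read_noise, size=noisy.shape)
        return noisy


@dataclass
class TruthMaps:
    """Per-pixel ground truth for a rendered stack (all shapes equal)."""

    eps: np.ndarray
    m_ex: np.ndarray
    theta_ex: np.ndarray
    m_f: np.ndarray
    theta_f: np.ndarray
    intensity: np.ndarray
    noise: NoiseModel = field(default_factory=NoiseModel)

    def __post_init__(self):
        maps = [self.eps, self.m_ex, self.theta_ex, self.m_f, self.theta_f, self.intensity]
        maps = [np.asarray(m, dtype=float) for m in maps]
        shape = maps[0].shape
        if any(m.shape != shape for m in maps):
            raise ValueError("all truth maps must share one shape")
        self.eps, self.m_ex, self.theta_ex, self.m_f, self.theta_f, self.intensity = maps
        for name, m in (("eps", self.eps), ("m_ex", self.m_ex), ("m_f", self.m_f)):
            if np.any((m < 0) | (m > 1)):
                raise ValueError(f"{name} must lie in [0, 1]")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be >= 0")

    @classmethod
    def uniform(
        cls, shape, eps=0.0, m_ex=0.0, theta_ex=0.0, m_f=0.0, theta_f=0.0,
        intensity=1e4, noise: NoiseModel | None = None,
    ) -> "TruthMaps":
        full = lambda v: np.full(shape, float(v))
        return cls(
            full(eps), full(m_ex), full(theta_ex), full(m_f), full(theta_f),
            full(intensity), noise or NoiseModel(),
        )


def truth_coeff_planes(truth: TruthMaps, family: str = "aligned_iso") -> np.ndarray:
    """Noise-free per-pixel portrait coefficients implied by the truth maps."""
    noet = no_transfer_coeffs(truth.m_ex, truth.theta_ex, family)
    fun = funnel_coeffs(truth.m_ex, truth.theta_ex, truth.m_f, truth.theta_f)
    return truth.intensity * ((1.0 - truth.eps) * noet + truth.eps * fun)


def render_stack(
    truth: TruthMaps,
    grid: AngleGrid | None = None,
    seed: int = 0,
    family: str = "aligned_iso",
):
    """Render a (n_frames, h, w) stack plus a sidecar describing it.

    The sidecar lists the (phi_ex, phi_em) pair per frame and records the noise
    model; it is what an acquisition would store next to the TIFF.
    """
    grid = grid or AngleGrid.default()
    planes = truth_coeff_planes(truth, family)  # (9, h, w)
    dm = design_matrix(grid.ex, grid.em)  # (F, 9)
    expected = np.tensordot(dm, planes, axes=1)  # (F, h, w)
    rng = np.random.default_rng(seed)
    frames = truth.noise.apply(expected, rng)
    sidecar = {
        "angles": [
            {"frame": i, "ex_deg": float(ex), "em_deg": float(em)}
            for i, (ex, em) in enumerate(grid.pairs)
        ],
        "noise": {"kind": truth.noise.kind, "excess": truth.noise.excess,
                  "read_noise": truth.noise.read_noise},
        "family": family,
        "seed": int(seed),
    }
    return frames, sidecar


# ---------------------------------------------------------------------------
# Phantoms


def two_region_phantom(
    shape=(16, 32), eps_left=0.2, eps_right=0.65, intensity=1e4,
    m_ex=0.1, theta_ex=30.0, m_f=0.2, theta_f=30.0, noise: NoiseModel | None = None,
) -> TruthMaps:
    """Two homogeneous regions differing only in eps, equal brightness.

    Mirrors the contrast between loosely packed (monomer-like, low eps) and
    densely aggregated (fibril-like, high eps) protein at identical expression
    level — the case where an intensity image is blind.
    """
    truth = TruthMaps.uniform(
        shape, m_ex=m_ex, theta_ex=theta_ex, m_f=m_f, theta_f=theta_f,
        intensity=intensity, noise=noise,
    )
    truth.eps[:, : shape[1] // 2] = eps_left
    truth.eps[:, shape[1] // 2 :] = eps_right
    return truth


def anticorrelation_phantom(
    shape=(24, 24), eps_bright=0.15, eps_dim=0.6,
    intensity_bright=2e4, intensity_dim=4e3, noise: NoiseModel | None = None,
) -> TruthMaps:
    """Bright/low-eps background with a dim/high-eps disk.

    Emulates a field where the densest aggregates are partially quenched, so
    fluorescence intensity anti-correlates with transfer efficiency; recovery
    of the truth pattern shows eps is an intensity-independent contrast.
    """
    truth = TruthMaps.uniform(
        shape, eps=eps_bright, m_ex=0.05, theta_ex=0.0, m_f=0.1, theta_f=0.0,
        intensity=intensity_bright, noise=noise,
    )
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    cy, cx = (shape[0] - 1) / 2, (shape[1] - 1) / 2
    disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= (min(shape) / 3.5) ** 2
    truth.eps[disk] = eps_dim
    truth.intensity[disk] = intensity_dim
    return truth


def calibration_phantoms(
    shape=(8, 8), intensity=1e4, theta=0.0, noise: NoiseModel | None = None,
):
    """The two microscope validation samples, as truth maps.

    Phantom A ("artificial molecule"): dipolar absorption and dipolar emission
    along ``theta`` everywhere — M_ex = M_em = 1.  Phantom B (unpolarized dye):
    flat portrait, M_ex = M_em = 0.  A checks for polarization artifacts, B for
    frame-to-frame transmission artifacts.
    """
    noise = noise or NoiseModel()
    phantom_a = TruthMaps.uniform(
        shape, eps=0.0, m_ex=1.0, theta_ex=theta, m_f=1.0, theta_f=theta,
        intensity=intensity, noise=noise,
    )
    phantom_b = TruthMaps.uniform(
        shape, eps=1.0, m_ex=0.0, m_f=0.0, intensity=intensity, noise=noise
    )
    return phantom_a, phantom_b


def preset_truth(name: str, counts: float = 1e4, noise: NoiseModel | None = None) -> TruthMaps:
    """Build a named phantom; calibA/calibB select the validation samples."""
    if name == "calibA":
        return calibration_phantoms(intensity=counts, noise=noise)[0]
    if name == "calibB":
        return calibration_phantoms(intensity=counts, noise=noise)[1]
    if name == "two-region":
        return two_region_phantom(intensity=counts, noise=noise)
    if name == "anticorr":
        return anticorrelation_phantom(
            intensity_bright=2 * counts, intensity_dim=0.4 * counts, noise=noise
        )
    raise ValueError(
        f"unknown preset {name!r}; choose from two-region, anticorr, calibA, calibB"
    )
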