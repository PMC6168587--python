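"""Polarization contrasts: modulation depths/phases and fluorescence anisotropy.

The angle-marginals of a portrait are cosine curves:

    A(phi_ex) = c00 + c20*cos 2*phi_ex + s20*sin 2*phi_ex
    B(phi_em) = c00 + c02*cos 2*phi_em + s02*sin 2*phi_em

Their relative amplitude is the modulation depth M (0 for isotropic dipole
ensembles, 1 for uniaxial alignment) and their phase theta is the mean in-plane
alignment axis.  Fluorescence anisotropy r = (I_par - I_perp)/(I_par + 2*I_perp)
is evaluated from the fitted portrait model at a chosen excitation orientation,
which allows the (0 deg, 45 deg) comparison even though phi_ex = 45 deg is not
on the default acquisition grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .portraits import PolarizationPortrait, PortraitStack


def _mod_from(c00, c, s):
    """Modulation depth and phase (deg, [0,180)) from marginal coefficients."""
    c00 = np.asarray(c00, dtype=float)
    c = np.asarray(c, dtype=float)
    s = np.asarray(s, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.hypot(c, s) / c00
    theta = np.rad2deg(0.5 * np.arctan2(s, c)) % 180.0
    # phase of a flat curve is undefined
    theta = np.where(m > 0, theta, np.nan)
    return m, theta


def modulation_excitation(portrait: PolarizationPortrait):
    """(M_ex, theta_ex) of the phi_em-averaged excitation curve."""
    if portrait.mean_intensity <= 0:
        raise ValueError("modulation undefined for non-positive mean intensity")
    m, theta = _mod_from(portrait["c00"], portrait["c20"], portrait["s20"])
    return float(m), float(theta)


def modulation_emission(portrait: PolarizationPortrait):
    """(M_em, theta_em) of the phi_ex-averaged emission curve."""
    if portrait.mean_intensity <= 0:
        raise ValueError("modulation undefined for non-positive mean intensity")
    m, theta = _mod_from(portrait["c00"], portrait["c02"], portrait["s02"])
    return float(m), float(theta)


def anisotropy(portrait: PolarizationPortrait, phi0: float = 0.0) -> float:
    """Fluorescence anisotropy with excitation polarized along ``phi0``.

    I_par is the model intensity at (phi0, phi0) and I_perp at (phi0, phi0+90);
    r = (I_par - I_perp) / (I_par + 2 I_perp).  NaN where the total intensity
    denominator is non-positive.
    """
    i_par = float(portrait.evaluate(phi0, phi0))
    i_perp = float(portrait.evaluate(phi0, phi0 + 90.0))
    denom = i_par + 2.0 * i_perp
    if denom <= 0:
        return float("nan")
    return (i_par - i_perp) / denom


def anisotropy_pair_difference(
    portrait: PolarizationPortrait, phi_a: float = 0.0, phi_b: float = 45.0
) -> float:
    """|r(phi_a) - r(phi_b)|: orientation dependence of the anisotropy readout.

    Zero for rotationally symmetric portraits; grows with net dipole alignment,
    which is exactly the regime where plain anisotropy stops being a reliable
    energy-transfer contrast.
    """
    return abs(anisotropy(portrait, phi_a) - anisotropy(portrait, phi_b))


@dataclass
class ContrastMaps:
    """Per-pixel contrast planes sharing one validity mask.

    ``r`` maps excitation orientation (deg) -> anisotropy plane; the declared
    orientations live in ``fa_orientations``.
    """

    m_ex: np.ndarray
    theta_ex: np.ndarray
    m_em: np.ndarray
    theta_em: np.ndarray
    r: dict = field(default_factory=dict)
    intensity: np.ndarray | None = None
    mask: np.ndarray | None = None
    fa_orientations: tuple = (0.0, 45.0)

    def summary(self) -> pd.DataFrame:
        """Mean and SD of each contrast over the mask."""
        planes = {
            "M_ex": self.m_ex,
            "theta_ex": self.theta_ex,
            "M_em": self.m_em,
            "theta_em": self.theta_em,
            "intensity": self.intensity,
        }
        for phi, plane in self.r.items():
            planes[f"r@{phi:g}"] = plane
        rows = []
        for name, plane in planes.items():
            if plane is None:
                continue
            vals = plane[self.mask] if self.mask is not None else plane.ravel()
            vals = vals[np.isfinite(vals)]
            rows.append(
                {
                    "contrast": name,
                    "mean": float(np.mean(vals)) if vals.size else np.nan,
                    "sd": float(np.std(vals)) if vals.size else np.nan,
                    "n_pixels": int(vals.size),
                }
            )
        return pd.DataFrame(rows)


def _evaluate_planes(stack: PortraitStack, phi_ex: float, phi_em: float) -> np.ndarray:
    from .portraits import design_matrix

    dm = design_matrix(phi_ex, phi_em)  # (9,)
    return np.tensordot(dm, stack.coeffs, axes=1)


def _anisotropy_plane(stack: PortraitStack, phi0: float) -> np.ndarray:
    i_par = _evaluate_planes(stack, phi0, phi0)
    i_perp = _evaluate_planes(stack, phi0, phi0 + 90.0)
    denom = i_par + 2.0 * i_perp
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, (i_par - i_perp) / denom, np.nan)
    return r


def compute_contrasts(
    stack: PortraitStack, fa_orientations=(0.0, 45.0)
) -> ContrastMaps:
    """All contrast planes of a portrait stack (masked pixels -> NaN)."""
    c = stack.coeffs
    m_ex, theta_ex = _mod_from(c[0], c[1], c[2])
    m_em, theta_em = _mod_from(c[0], c[3], c[4])
    r = {float(phi): _anisotropy_plane(stack, float(phi)) for phi in fa_orientations}
    nanmask = np.where(stack.mask, 1.0, np.nan)
    return ContrastMaps(
        m_ex=m_ex * nanmask,
        theta_ex=theta_ex * nanmask,
        m_em=m_em * nanmask,
        theta_em=theta_em * nanmask,
        r={phi: plane * nanmask for phi, plane in r.items()},
        intensity=c[0].copy(),
        mask=stack.mask,
        fa_orientations=tuple(float(p) for p in fa_orientations),
    )
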