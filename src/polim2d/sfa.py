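"""Single funnel approximation (SFA): the energy funneling efficiency epsilon.

The SFA decomposes a normalized polarization portrait into a linear combination

    I(phi_ex, phi_em) = (1 - eps) * I_noET + eps * I_funnel

where ``I_noET`` describes emission by the dipoles that absorbed the light (no
energy transfer; excitation and emission angle dependence are correlated) and
``I_funnel`` describes emission after transfer to an effective common emitter
with fixed polarization (M_f, theta_f) — excitation and emission dependence
fully decouple, i.e. all polarization memory is lost.  The weight eps of the
funnel term is the energy funneling efficiency: 0 means no homo-FRET, 1 means
every detected photon was emitted after transfer.  Because both components are
constrained to reproduce the measured excitation modulation (M_ex, theta_ex),
eps is insensitive to the local degree of dipole alignment, which is what makes
it a robust aggregation contrast where plain anisotropy is not.

Two no-transfer model families are provided:

``aligned_iso`` (default)
    A fraction M_ex of perfectly aligned dipoles at theta_ex plus a fraction
    (1 - M_ex) of a 3D-isotropic ensemble.  The isotropic part is the portrait
    1 + 1/2 cos 2(phi_ex - phi_em), whose anisotropy is the fundamental
    r0 = 0.4 of parallel absorption/emission dipoles.
``two_delta``
    Two equal in-plane dipole populations at theta_ex +/- beta with
    cos 2*beta = M_ex, the classic SFA ansatz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .contrasts import modulation_excitation
from .portraits import (
    AngleGrid,
    PolarizationPortrait,
    PortraitStack,
    coeffs_from_dict,
    design_matrix,
)

NOET_FAMILIES = ("aligned_iso", "two_delta")


def _aligned_coeffs(theta_deg):
    """Coefficients of (1 + cos2(ex-t))(1 + cos2(em-t)), c00 = 1."""
    t = np.deg2rad(2.0 * np.asarray(theta_deg, dtype=float))
    c, s = np.cos(t), np.sin(t)
    return np.stack(
        [np.ones_like(c), c, s, c, s, c * c, c * s, s * c, s * s], axis=0
    )


def _iso_coeffs(shape=()):
    """Coefficients of 1 + 1/2 cos2(ex-em): the r0 = 0.4 isotropic portrait."""
    c = np.zeros((9,) + shape)
    c[0] = 1.0
    c[5] = 0.5
    c[8] = 0.5
    return c


def no_transfer_coeffs(m_ex, theta_ex, family: str = "aligned_iso") -> np.ndarray:
    """Coefficient planes of the no-transfer component (broadcasts over maps)."""
    m_ex = np.asarray(m_ex, dtype=float)
    if np.any((m_ex < 0) | (m_ex > 1)):
        raise ValueError("M_ex must lie in [0, 1]")
    theta_ex = np.asarray(theta_ex, dtype=float)
    if family == "aligned_iso":
        return m_ex * _aligned_coeffs(theta_ex) + (1.0 - m_ex) * _iso_coeffs(m_ex.shape)
    if family == "two_delta":
        beta = 0.5 * np.rad2deg(np.arccos(np.clip(m_ex, 0.0, 1.0)) )
        return 0.5 * (_aligned_coeffs(theta_ex + beta) + _aligned_coeffs(theta_ex - beta))
    raise ValueError(f"unknown no-transfer family {family!r}")


def no_transfer_component(
    m_ex: float, theta_ex: float, family: str = "aligned_iso"
) -> PolarizationPortrait:
    """Normalized no-transfer portrait with excitation modulation ``m_ex``."""
    return PolarizationPortrait(no_transfer_coeffs(m_ex, theta_ex, family))


def funnel_coeffs(m_ex, theta_ex, m_f, theta_f) -> np.ndarray:
    """Coefficient planes of the separable funnel component (c00 = 1)."""
    m_ex = np.asarray(m_ex, dtype=float)
    m_f = np.asarray(m_f, dtype=float)
    if np.any((m_f < 0) | (m_f > 1)):
        raise ValueError("M_f must lie in [0, 1]")
    tx = np.deg2rad(2.0 * np.asarray(theta_ex, dtype=float))
    tf = np.deg2rad(2.0 * np.asarray(theta_f, dtype=float))
    a_c, a_s = m_ex * np.cos(tx), m_ex * np.sin(tx)
    b_c, b_s = m_f * np.cos(tf), m_f * np.sin(tf)
    one = np.ones_like(a_c * b_c)
    return np.stack(
        [one, a_c + 0 * one, a_s + 0 * one, b_c + 0 * one, b_s + 0 * one,
         a_c * b_c, a_c * b_s, a_s * b_c, a_s * b_s],
        axis=0,
    )


def funnel_component(
    m_ex: float, theta_ex: float, m_f: float, theta_f: float
) -> PolarizationPortrait:
    """Portrait (1 + M_ex cos2(ex-theta_ex)) * (1 + M_f cos2(em-theta_f))."""
    return PolarizationPortrait(funnel_coeffs(m_ex, theta_ex, m_f, theta_f))


@dataclass
class SFAResult:
    """Single-funnel fit of one portrait."""

    eps: float
    m_f: float
    theta_f: float
    residual: float  # RMS misfit relative to the mean intensity
    converged: bool
    m_ex: float = np.nan
    theta_ex: float = np.nan


def fit_sfa(
    portrait: PolarizationPortrait,
    family: str = "aligned_iso",
    residual_threshold: float = 0.05,
    n_theta_starts: int = 4,
) -> SFAResult:
    """Fit (eps, M_f, theta_f) by bounded least squares on the acquisition grid.

    The excitation polarization of both components is pinned to the measured
    (M_ex, theta_ex); only the funnel weight and its emission polarization are
    free.  theta_f is multi-started (default 4 starts spanning 180 deg) to
    avoid the 90-degree-shifted local minimum; near-identical residuals are
    resolved toward the smaller eps.  A residual above ``residual_threshold``
    (fraction of the mean intensity) flags a single-funnel model violation via
    ``converged = False``.
    """
    grid = portrait.grid if portrait.grid is not None else AngleGrid.default()
    norm = portrait.normalize()
    if norm.values is not None:
        target = norm.values
    else:
        target = norm.evaluate(grid.ex, grid.em)

    m_ex, theta_ex = modulation_excitation(norm)
    if not np.isfinite(theta_ex):
        theta_ex = 0.0
    m_ex = min(m_ex, 1.0)

    noet = no_transfer_coeffs(m_ex, theta_ex, family)
    dm = design_matrix(grid.ex, grid.em)
    noet_vals = dm @ noet
    # excitation factor shared by both funnel terms
    exc = 1.0 + m_ex * np.cos(np.deg2rad(2.0 * (grid.ex - theta_ex)))
    cos_em = np.cos(np.deg2rad(2.0 * grid.em))
    sin_em = np.sin(np.deg2rad(2.0 * grid.em))

    def resid(x):
        eps, m_f, theta_f = x
        em = 1.0 + m_f * (
            np.cos(np.deg2rad(2.0 * theta_f)) * cos_em
            + np.sin(np.deg2rad(2.0 * theta_f)) * sin_em
        )
        model = (1.0 - eps) * noet_vals + eps * exc * em
        return model - target

    best = None
    starts = theta_ex + np.arange(n_theta_starts) * (180.0 / max(n_theta_starts, 1))
    for theta0 in starts:
        sol = least_squares(
            resid,
            x0=[0.5, 0.3, theta0],
            bounds=([0.0, 0.0, -np.inf], [1.0, 1.0, np.inf]),
            method="trf",
        )
        if (
            best is None
            or sol.cost < best.cost - 1e-12
            or (abs(sol.cost - best.cost) <= 1e-12 and sol.x[0] < best.x[0])
        ):
            best = sol

    eps, m_f, theta_f = best.x
    rms = float(np.sqrt(np.mean(best.fun**2)))
    theta_f = theta_f % 180.0 if eps * m_f > 1e-6 else float("nan")
    return SFAResult(
        eps=float(eps),
        m_f=float(m_f),
        theta_f=float(theta_f),
        residual=rms,
        converged=bool(rms <= residual_threshold),
        m_ex=m_ex,
        theta_ex=theta_ex,
    )


@dataclass
class SFAMaps:
    """Per-pixel single-funnel fit planes."""

    eps: np.ndarray
    m_f: np.ndarray
    theta_f: np.ndarray
    residual: np.ndarray
    converged: np.ndarray
    mask: np.ndarray

    def summary(self) -> dict:
        """Mean and SD of eps over converged, unmasked pixels."""
        ok = self.mask & self.converged
        vals = self.eps[ok]
        return {
            "eps_mean": float(np.mean(vals)) if vals.size else float("nan"),
            "eps_sd": float(np.std(vals)) if vals.size else float("nan"),
            "n_pixels": int(vals.size),
            "n_model_violation": int(np.sum(self.mask & ~self.converged)),
        }


def epsilon_map(
    stack: PortraitStack,
    family: str = "aligned_iso",
    residual_threshold: float = 0.05,
) -> SFAMaps:
    """Run the single-funnel fit on every unmasked pixel of a portrait stack.

    Pixels whose portrait is flat to machine precision carry no polarization
    information at all (an unpolarized source and complete transfer to an
    isotropic emitter are indistinguishable), so they are masked rather than
    assigned an eps.
    """
    h, w = stack.height, stack.width
    with np.errstate(divide="ignore", invalid="ignore"):
        content = np.linalg.norm(stack.coeffs[1:], axis=0) / stack.coeffs[0]
    mask = stack.mask & (content > 1e-10)
    eps = np.full((h, w), np.nan)
    m_f = np.full((h, w), np.nan)
    theta_f = np.full((h, w), np.nan)
    residual = np.full((h, w), np.nan)
    converged = np.zeros((h, w), dtype=bool)
    for row in range(h):
        for col in range(w):
            if not mask[row, col]:
                continue
            res = fit_sfa(
                stack.portrait(row, col),
                family=family,
                residual_threshold=residual_threshold,
            )
            eps[row, col] = res.eps
            m_f[row, col] = res.m_f
            theta_f[row, col] = res.theta_f
            residual[row, col] = res.residual
            converged[row, col] = res.converged
    return SFAMaps(eps, m_f, theta_f, residual, converged, mask)


def epsilon_contours(eps_plane: np.ndarray, level: float):
    """Iso-contours of an epsilon map at a chosen threshold.

    Returns a list of (n, 2) arrays of (row, col) vertices; everything inside a
    closed contour is on one side of ``level``.
    """
    from skimage import measure

    filled = np.nan_to_num(eps_plane, nan=-1.0)
    return measure.find_contours(filled, level)
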