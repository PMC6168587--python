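"""Polarization portraits: the per-pixel intensity surface I(phi_ex, phi_em).

A polarization portrait is the fluorescence intensity of one pixel recorded as a
function of two angles: the orientation of the linearly polarized excitation
light (phi_ex) and the orientation of the emission analyzer (phi_em).  For an
ensemble of fixed dipoles observed through ideal polarizers, the portrait is a
trigonometric polynomial of second angular order, so it is fully described by
nine Fourier coefficients over the basis

    {1, cos 2*phi_ex, sin 2*phi_ex} x {1, cos 2*phi_em, sin 2*phi_em}.

This module holds the angle-grid bookkeeping, the least-squares projection of a
raw frame stack onto this basis, and evaluation/normalization utilities.  All
angles are in degrees, measured in the sample plane, and taken modulo 180
(dipoles have no head/tail distinction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

#: Coefficient order used throughout the package.
COEFF_NAMES = ("c00", "c20", "s20", "c02", "s02", "cc", "cs", "sc", "ss")

N_COEFFS = len(COEFF_NAMES)

#: Default excitation polarizer orientations (degrees).
DEFAULT_EX_ANGLES = (0.0, 30.0, 60.0, 90.0, 120.0, 150.0)
#: Default emission analyzer orientations (degrees).
DEFAULT_EM_ANGLES = (0.0, 45.0, 90.0, 135.0)


class ConfigurationError(ValueError):
    """Raised when inputs and acquisition metadata are inconsistent."""


def _wrap180(angles):
    return np.asarray(angles, dtype=float) % 180.0


@dataclass(frozen=True)
class AngleGrid:
    """The ordered set of (phi_ex, phi_em) polarizer pairs of an acquisition.

    ``ex`` and ``em`` are per-frame angle arrays of equal length; frame ``i`` of
    any stack described by this grid was taken at ``(ex[i], em[i])``.
    """

    ex: np.ndarray
    em: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "ex", _wrap180(np.atleast_1d(self.ex)))
        object.__setattr__(self, "em", _wrap180(np.atleast_1d(self.em)))
        if self.ex.shape != self.em.shape or self.ex.ndim != 1:
            raise ConfigurationError("ex and em angle lists must be 1D and equal length")

    @classmethod
    def default(cls) -> "AngleGrid":
        """The 24-frame grid: all pairs of {0,30,...,150} x {0,45,90,135},
        excitation-major order."""
        ex, em = np.meshgrid(DEFAULT_EX_ANGLES, DEFAULT_EM_ANGLES, indexing="ij")
        return cls(ex.ravel(), em.ravel())

    @classmethod
    def from_pairs(cls, pairs) -> "AngleGrid":
        pairs = np.asarray(pairs, dtype=float)
        return cls(pairs[:, 0], pairs[:, 1])

    @property
    def pairs(self) -> np.ndarray:
        """(n_frames, 2) array of (phi_ex, phi_em) pairs."""
        return np.stack([self.ex, self.em], axis=1)

    @property
    def ex_angles(self) -> np.ndarray:
        """Distinct excitation angles, sorted."""
        return np.unique(self.ex)

    @property
    def em_angles(self) -> np.ndarray:
        """Distinct emission angles, sorted."""
        return np.unique(self.em)

    def __len__(self) -> int:
        return self.ex.size


def design_matrix(ex_deg, em_deg) -> np.ndarray:
    """Second-order Fourier design matrix, rows ordered as COEFF_NAMES."""
    ex = np.deg2rad(np.asarray(ex_deg, dtype=float))
    em = np.deg2rad(np.asarray(em_deg, dtype=float))
    ce, se = np.cos(2 * ex), np.sin(2 * ex)
    cm, sm = np.cos(2 * em), np.sin(2 * em)
    one = np.ones_like(ce)
    return np.stack([one, ce, se, cm, sm, ce * cm, ce * sm, se * cm, se * sm], axis=-1)


def coeffs_from_dict(d) -> np.ndarray:
    """Build a coefficient vector from a (possibly partial) name->value mapping."""
    c = np.zeros(N_COEFFS)
    for k, v in d.items():
        c[COEFF_NAMES.index(k)] = v
    return c


@dataclass
class PolarizationPortrait:
    """A single portrait in its 9-coefficient Fourier representation.

    ``values``/``grid`` hold the raw samples the coefficients were fitted from,
    when available; ``residual`` is the RMS misfit of that projection.
    """

    coeffs: np.ndarray
    grid: AngleGrid | None = None
    values: np.ndarray | None = None
    residual: float = 0.0

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.shape != (N_COEFFS,):
            raise ValueError(f"coeffs must have shape ({N_COEFFS},)")

    @classmethod
    def from_coeffs(cls, mapping) -> "PolarizationPortrait":
        return cls(coeffs_from_dict(mapping))

    @classmethod
    def from_samples(cls, values, grid: AngleGrid) -> "PolarizationPortrait":
        """Least-squares projection of intensity samples onto the Fourier basis."""
        values = np.asarray(values, dtype=float)
        if values.shape != (len(grid),):
            raise ConfigurationError(
                f"got {values.shape[0]} samples for {len(grid)} angle pairs"
            )
        dm = design_matrix(grid.ex, grid.em)
        coeffs, *_ = np.linalg.lstsq(dm, values, rcond=None)
        resid = float(np.sqrt(np.mean((dm @ coeffs - values) ** 2)))
        return cls(coeffs, grid=grid, values=values, residual=resid)

    def __getitem__(self, name: str) -> float:
        return float(self.coeffs[COEFF_NAMES.index(name)])

    @property
    def mean_intensity(self) -> float:
        """The angle-averaged intensity c00."""
        return float(self.coeffs[0])

    def evaluate(self, phi_ex, phi_em):
        """Model intensity at arbitrary angle pairs (degrees, 180-periodic)."""
        dm = design_matrix(phi_ex, phi_em)
        return dm @ self.coeffs

    def normalize(self) -> "PolarizationPortrait":
        """Scale so that c00 = 1.  Raises on non-positive mean intensity."""
        c00 = self.mean_intensity
        if c00 <= 0:
            raise ValueError("cannot normalize a portrait with c00 <= 0")
        return replace(
            self,
            coeffs=self.coeffs / c00,
            values=None if self.values is None else self.values / c00,
            residual=self.residual / c00,
        )


@dataclass
class PortraitStack:
    """Per-pixel portraits of an image, stored as coefficient planes.

    ``coeffs`` has shape (9, height, width); ``mask`` flags pixels with enough
    signal for downstream contrasts; ``residual`` is the per-pixel RMS misfit.
    """

    coeffs: np.ndarray
    grid: AngleGrid
    mask: np.ndarray
    residual: np.ndarray

    @property
    def height(self) -> int:
        return self.coeffs.shape[1]

    @property
    def width(self) -> int:
        return self.coeffs.shape[2]

    @property
    def intensity(self) -> np.ndarray:
        """Mean-intensity (c00) plane."""
        return self.coeffs[0]

    def plane(self, name: str) -> np.ndarray:
        return self.coeffs[COEFF_NAMES.index(name)]

    def portrait(self, row: int, col: int) -> PolarizationPortrait:
        return PolarizationPortrait(self.coeffs[:, row, col].copy(), grid=self.grid)


def estimate_noise(frames: np.ndarray) -> float:
    """Robust per-pixel noise scale from frame-to-frame fluctuations.

    Uses the median absolute deviation of the high-pass (frame-minus-pixel-mean)
    signal; adequate to set a signal mask, not a calibrated camera model.
    """
    resid = frames - frames.mean(axis=0, keepdims=True)
    mad = np.median(np.abs(resid))
    return float(1.4826 * mad)


def build_portraits(
    frames,
    grid: AngleGrid,
    background=None,
    mask_threshold: float | str | None = None,
) -> PortraitStack:
    """Fit per-pixel polarization portraits to an image stack.

    Parameters
    ----------
    frames : array (n_frames, height, width)
        One image per (phi_ex, phi_em) pair, in the order given by ``grid``.
    grid : AngleGrid
        Angle pair per frame; its length must match the number of frames.
    background : None, scalar, or (n_frames,) array
        Constant or per-frame background subtracted before fitting.  Pixels
        that go negative are clipped to zero (count logged).
    mask_threshold : None, float, or "auto"
        Pixels with mean intensity below this are masked.  ``"auto"`` uses
        3x a robust noise estimate from the frame stack; ``None`` masks only
        non-positive pixels.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise ConfigurationError("frames must be a (n_frames, height, width) array")
    if frames.shape[0] != len(grid):
        raise ConfigurationError(
            f"stack has {frames.shape[0]} frames but the angle grid lists "
            f"{len(grid)} pairs"
        )
    if background is not None:
        bg = np.asarray(background, dtype=float)
        if bg.ndim == 1:
            if bg.size != frames.shape[0]:
                raise ConfigurationError("per-frame background length mismatch")
            bg = bg[:, None, None]
        frames = frames - bg
        n_neg = int(np.sum(frames < 0))
        if n_neg:
            logger.info("background subtraction clipped %d negative pixels", n_neg)
            frames = np.clip(frames, 0.0, None)

    n_frames, h, w = frames.shape
    dm = design_matrix(grid.ex, grid.em)
    flat = frames.reshape(n_frames, h * w)
    coeffs, *_ = np.linalg.lstsq(dm, flat, rcond=None)
    resid = np.sqrt(np.mean((dm @ coeffs - flat) ** 2, axis=0))

    c00 = coeffs[0]
    if mask_threshold == "auto":
        thr = 3.0 * estimate_noise(frames)
    elif mask_threshold is None:
        thr = 0.0
    else:
        thr = float(mask_threshold)
    mask = c00 > thr
    logger.info("portrait fit: %d/%d pixels pass the intensity mask", mask.sum(), mask.size)

    return PortraitStack(
        coeffs=coeffs.reshape(N_COEFFS, h, w),
        grid=grid,
        mask=mask.reshape(h, w),
        residual=resid.reshape(h, w),
    )
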