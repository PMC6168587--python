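"""Readers, writers, configuration and the end-to-end analysis pipelines.

File conventions: image stacks are multi-page grayscale TIFF (one frame per
(phi_ex, phi_em) pair); the angle list travels in a YAML sidecar of records
``{frame, ex_deg, em_deg}``; result maps are written as float32 multi-page
TIFF, tables as CSV and run metadata as JSON carrying a hash of the analysis
configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .contrasts import ContrastMaps, compute_contrasts
from .portraits import AngleGrid, ConfigurationError, PortraitStack, build_portraits
from .sfa import SFAMaps, epsilon_map

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Tunable knobs of the analyze pipeline.

    background: None, a constant, or "per-frame-median" (subtract each frame's
    median — suited to stacks with dark margins).  mask_threshold: counts, or
    "auto" for 3x a robust noise estimate.  g_factor: scalar detection ratio
    t(90)/t(0) of the emission path, applied as a smooth transmission
    correction over the analyzer angle (1 = ideal).  noet_family selects the
    no-transfer portrait model; residual_threshold (fraction of the mean
    intensity) flags single-funnel model violations.
    """

    background: float | str | None = None
    mask_threshold: float | str | None = "auto"
    g_factor: float = 1.0
    noet_family: str = "aligned_iso"
    residual_threshold: float = 0.05
    fa_orientations: tuple = (0.0, 45.0)

    def __post_init__(self):
        if isinstance(self.mask_threshold, (int, float)) and self.mask_threshold < 0:
            raise ConfigurationError("mask_threshold must be >= 0")
        if self.residual_threshold < 0:
            raise ConfigurationError("residual_threshold must be >= 0")
        if self.noet_family not in ("aligned_iso", "two_delta"):
            raise ConfigurationError("noet_family must be aligned_iso or two_delta")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "fa_orientations" in data:
            data["fa_orientations"] = tuple(float(x) for x in data["fa_orientations"])
        return cls(**data)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Readers / writers


def read_stack(path) -> np.ndarray:
    """Multi-page TIFF -> float (n_frames, h, w) array."""
    frames = tifffile.imread(path)
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    return frames


def write_stack(path, frames) -> None:
    tifffile.imwrite(
        path, np.asarray(frames, dtype=np.float32), photometric="minisblack"
    )


def read_angles(path) -> AngleGrid:
    """YAML sidecar (list of {frame, ex_deg, em_deg}) -> AngleGrid."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if isinstance(data, dict):  # allow a top-level {"angles": [...]} document
        data = data.get("angles", data)
    try:
        records = sorted(data, key=lambda rec: rec["frame"])
        ex = [float(rec["ex_deg"]) for rec in records]
        em = [float(rec["em_deg"]) for rec in records]
    except (TypeError, KeyError) as exc:
        raise ConfigurationError(f"malformed angle sidecar {path}: {exc}") from exc
    return AngleGrid(ex, em)


def write_angles(path, grid: AngleGrid) -> None:
    records = [
        {"frame": i, "ex_deg": float(ex), "em_deg": float(em)}
        for i, (ex, em) in enumerate(grid.pairs)
    ]
    with open(path, "w") as fh:
        yaml.safe_dump({"angles": records}, fh)


def write_planes(path, planes: dict) -> None:
    """Named float planes -> multi-page float32 TIFF (page order recorded in
    the page description tags)."""
    arrays = [np.asarray(p, dtype=np.float32) for p in planes.values()]
    tifffile.imwrite(
        path,
        np.stack(arrays),
        photometric="minisblack",
        description=json.dumps(list(planes)),
    )


# ---------------------------------------------------------------------------
# Pipelines


def _apply_g_factor(frames: np.ndarray, grid: AngleGrid, g: float) -> np.ndarray:
    """Divide out the analyzer-angle transmission t(phi) = 1 + (g-1) sin^2."""
    if g == 1.0:
        return frames
    t = 1.0 + (g - 1.0) * np.sin(np.deg2rad(grid.em)) ** 2
    return frames / t[:, None, None]


@dataclass
class AnalysisResult:
    portraits: PortraitStack
    contrasts: ContrastMaps
    sfa: SFAMaps
    metadata: dict = field(default_factory=dict)


def analyze(
    stack_path,
    angles_path,
    config: AnalysisConfig | None = None,
    out_dir=None,
) -> AnalysisResult:
    """Full pipeline: stack -> portraits -> contrasts -> epsilon map.

    When ``out_dir`` is given, writes contrast and SFA planes (float32 TIFF),
    a per-image summary CSV and a JSON metadata record with the config hash.
    """
    config = config or AnalysisConfig()
    t0 = time.time()
    frames = read_stack(stack_path)
    grid = read_angles(angles_path)
    frames = _apply_g_factor(frames, grid, config.g_factor)

    background = config.background
    if background == "per-frame-median":
        background = np.median(frames, axis=(1, 2))
    stack = build_portraits(
        frames, grid, background=background, mask_threshold=config.mask_threshold
    )
    contrasts = compute_contrasts(stack, fa_orientations=config.fa_orientations)
    sfa_maps = epsilon_map(
        stack,
        family=config.noet_family,
        residual_threshold=config.residual_threshold,
    )
    metadata = {
        "polim2d_version": __version__,
        "config": asdict(config),
        "config_hash": config.hash(),
        "stack": str(stack_path),
        "n_frames": int(frames.shape[0]),
        "shape": list(frames.shape[1:]),
        "n_masked": int((~stack.mask).sum()),
        "sfa_summary": sfa_maps.summary(),
        "runtime_s": None,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        planes = {
            "intensity": contrasts.intensity,
            "M_ex": contrasts.m_ex,
            "theta_ex": contrasts.theta_ex,
            "M_em": contrasts.m_em,
            "theta_em": contrasts.theta_em,
            "eps": sfa_maps.eps,
            "M_f": sfa_maps.m_f,
            "theta_f": sfa_maps.theta_f,
            "sfa_residual": sfa_maps.residual,
            "mask": stack.mask.astype(np.float32),
        }
        for phi, plane in contrasts.r.items():
            planes[f"r@{phi:g}"] = plane
        write_planes(out / "maps.tif", planes)
        from .portraits import COEFF_NAMES

        coeff_planes = {name: stack.coeffs[i] for i, name in enumerate(COEFF_NAMES)}
        coeff_planes["fit_residual"] = stack.residual
        coeff_planes["mask"] = stack.mask.astype(np.float32)
        write_planes(out / "portraits.tif", coeff_planes)

        summary = contrasts.summary()
        sfa_sum = sfa_maps.summary()
        summary = pd.concat(
            [
                summary,
                pd.DataFrame(
                    [{"contrast": "eps", "mean": sfa_sum["eps_mean"],
                      "sd": sfa_sum["eps_sd"], "n_pixels": sfa_sum["n_pixels"]}]
                ),
            ],
            ignore_index=True,
        )
        summary.to_csv(out / "summary.csv", index=False)
        metadata["runtime_s"] = round(time.time() - t0, 3)
        with open(out / "metadata.json", "w") as fh:
            json.dump(metadata, fh, indent=2, default=str)
    logger.info("analyze done in %.2fs", time.time() - t0)
    return AnalysisResult(stack, contrasts, sfa_maps, metadata)


def check_config_hash(metadata_paths) -> str:
    """Refuse to mix products computed under different configurations."""
    hashes = set()
    for path in metadata_paths:
        with open(path) as fh:
            hashes.add(json.load(fh)["config_hash"])
    if len(hashes) > 1:
        raise ConfigurationError(f"mixed configuration hashes: {sorted(hashes)}")
    return hashes.pop()


def validate(
    stack_a_path,
    stack_b_path,
    angles_path,
    high_tol: float = 0.1,
    low_tol: float = 0.1,
) -> dict:
    """Daily microscope calibration check on the two test samples.

    Sample A (artificial molecule) must look fully polarized: M_ex and M_em
    within ``high_tol`` of 1.  Sample B (unpolarized dye) must look flat:
    modulations below ``low_tol``; its residual modulation estimates any
    frame-to-frame transmission artifact.  Returns a PASS/FAIL report per
    channel with the measured modulations.
    """
    grid = read_angles(angles_path)
    report = {"pass": True, "channels": {}}
    for label, path, expect_high in (("A", stack_a_path, True), ("B", stack_b_path, False)):
        frames = read_stack(path)
        stack = build_portraits(frames, grid)
        contrasts = compute_contrasts(stack)
        m_ex = float(np.nanmean(contrasts.m_ex))
        m_em = float(np.nanmean(contrasts.m_em))
        if expect_high:
            ok_ex, ok_em = m_ex >= 1 - high_tol, m_em >= 1 - high_tol
            diagnosis = "fully polarized" if ok_ex and ok_em else (
                "expected a fully polarized response; got M_ex=%.3f M_em=%.3f "
                "(inputs swapped, or polarization artifacts in the light path?)"
                % (m_ex, m_em)
            )
        else:
            ok_ex, ok_em = m_ex <= low_tol, m_em <= low_tol
            diagnosis = "unpolarized" if ok_ex and ok_em else (
                "expected a flat response; residual artifact modulation "
                "M_ex=%.3f M_em=%.3f (transmission drift or swapped inputs?)"
                % (m_ex, m_em)
            )
        report["channels"][label] = {
            "M_ex": m_ex,
            "M_em": m_em,
            "excitation_pass": bool(ok_ex),
            "emission_pass": bool(ok_em),
            "diagnosis": diagnosis,
        }
        report["pass"] &= bool(ok_ex and ok_em)
    return report
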