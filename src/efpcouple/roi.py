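"""Per-subject functional ROI selection by seed coactivation.

Within a target mask (the amygdala in the study design), voxels are
split into a "salience-related" cluster — high coactivation with a
small spherical salience-network seed (anterior insula, 4-mm radius) —
and a "non-salience" cluster with low coactivation.  Coactivation is
the Pearson correlation of each target voxel with the seed's mean
time-course; the salience cluster keeps voxels strictly above both the
85th percentile of valid correlations and the absolute floor 0.2, the
non-salience cluster keeps voxels strictly below both the 15th
percentile and the ceiling 0.2.  Selection is meant to run on a
different task than the downstream coupling test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import BOLDDataset

__all__ = [
    "SeedSpec",
    "ROISelectionConfig",
    "ROISelectionResult",
    "seed_timecourse",
    "voxelwise_seed_correlation",
    "select_salience_clusters",
    "select_for_subject",
]


@dataclass
class SeedSpec:
    """Spherical seed: mm center, mm radius (boundary inclusive)."""

    center_mm: tuple = (36.0, 18.0, 4.0)  # right anterior insula
    radius_mm: float = 4.0
    label: str = "salience-seed"

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")
        if len(self.center_mm) != 3:
            raise ValueError("center_mm must be (x, y, z)")


@dataclass
class ROISelectionConfig:
    high_pctile: float = 85.0
    low_pctile: float = 15.0
    high_floor: float = 0.2
    # reading "at least below 0.2" as r < 0.2 (the wording is ambiguous
    # between 0.2 and -0.2; configurable here)
    low_ceiling: float = 0.2
    target_mask_label: str = "target"

    def __post_init__(self) -> None:
        if not 0 < self.low_pctile < self.high_pctile < 100:
            raise ValueError("need 0 < low_pctile < high_pctile < 100")
        if self.high_floor < 0:
            raise ValueError("high_floor must be non-negative")


@dataclass
class ROISelectionResult:
    """Seed correlations and the two disjoint cluster memberships.

    Indices refer to positions within the target-mask voxel vector that
    produced ``voxel_r``.
    """

    voxel_r: np.ndarray
    salience_voxels: np.ndarray
    nonsalience_voxels: np.ndarray
    high_threshold: float = np.nan
    low_threshold: float = np.nan

    @property
    def n_salience(self) -> int:
        return len(self.salience_voxels)

    @property
    def n_nonsalience(self) -> int:
        return len(self.nonsalience_voxels)


def seed_timecourse(bold: BOLDDataset, seed: SeedSpec) -> np.ndarray:
    """Mean time-course over voxels whose centers lie inside the sphere."""
    d = np.linalg.norm(bold.coords_mm - np.asarray(seed.center_mm)[None, :], axis=1)
    members = np.where(d <= seed.radius_mm + 1e-9)[0]
    if len(members) == 0:
        raise ValueError(
            f"seed {seed.label!r} at {seed.center_mm} (r={seed.radius_mm} mm) "
            "contains no voxel center"
        )
    return bold.data[members].mean(axis=0)


def voxelwise_seed_correlation(
    bold: BOLDDataset, seed_ts: np.ndarray, target_mask_label: str = "target"
) -> np.ndarray:
    """Pearson r of every target-mask voxel with the seed time-course.

    Zero-variance voxels (or a zero-variance seed) yield NaN, recorded
    as missing rather than raising.
    """
    seed_ts = np.asarray(seed_ts, dtype=float)
    if len(seed_ts) != bold.n_volumes:
        raise ValueError("seed time-course length must equal the number of volumes")
    y = bold.mask_data(target_mask_label)
    if y.shape[0] == 0:
        raise ValueError(f"target mask {target_mask_label!r} is empty")
    yc = y - y.mean(axis=1, keepdims=True)
    sc = seed_ts - seed_ts.mean()
    denom = np.sqrt(np.sum(yc**2, axis=1) * np.sum(sc**2))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (yc @ sc) / denom
    r[~np.isfinite(r)] = np.nan
    return r


def select_salience_clusters(
    voxel_r: np.ndarray, cfg: ROISelectionConfig | None = None
) -> ROISelectionResult:
    """Split target voxels into salience / non-salience clusters.

    Percentiles use linear interpolation over the valid (non-missing)
    correlations; both the percentile rule and the floor/ceiling rule
    are strict inequalities, so tied values at the threshold are
    excluded and the two clusters are disjoint on every input.
    """
    cfg = cfg or ROISelectionConfig()
    voxel_r = np.asarray(voxel_r, dtype=float)
    valid = np.isfinite(voxel_r)
    if valid.sum() == 0:
        raise ValueError("all seed correlations are missing")
    if valid.sum() < 7:
        raise ValueError("need at least 7 valid voxels for percentile rules")
    r_valid = voxel_r[valid]
    hi = float(np.percentile(r_valid, cfg.high_pctile))
    lo = float(np.percentile(r_valid, cfg.low_pctile))
    with np.errstate(invalid="ignore"):
        sal = valid & (voxel_r > hi) & (voxel_r > cfg.high_floor)
        non = valid & (voxel_r < lo) & (voxel_r < cfg.low_ceiling)
    return ROISelectionResult(
        voxel_r=voxel_r,
        salience_voxels=np.where(sal)[0],
        nonsalience_voxels=np.where(non)[0],
        high_threshold=hi,
        low_threshold=lo,
    )


def select_for_subject(
    selection_bold: BOLDDataset,
    seed: SeedSpec | None = None,
    cfg: ROISelectionConfig | None = None,
) -> ROISelectionResult:
    """Seed extraction, correlation and cluster selection in one call.

    ``selection_bold`` should be the selection task's data (a separate
    run from the one used for downstream coupling tests).
    """
    seed = seed or SeedSpec()
    cfg = cfg or ROISelectionConfig()
    ts = seed_timecourse(selection_bold, seed)
    r = voxelwise_seed_correlation(selection_bold, ts, cfg.target_mask_label)
    return select_salience_clusters(r, cfg)
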