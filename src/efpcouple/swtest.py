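"""Nonparametric sliding-window correlation test against a shuffled null.

For one subject and ROI, Pearson correlations between the EFP
time-course and each ROI voxel's BOLD signal are computed along a
sliding window of w TRs in 1-TR steps (window 1: samples 1..w, window
2: 2..w+1, ...), and averaged across windows per voxel — the "real"
distribution of size n (the number of ROI voxels).  The null keeps the
BOLD windows in place but reassigns the *intact* EFP windows to random
window positions (shuffling windows, never the samples within a
window), recomputes the same per-voxel window-averaged correlations,
and repeats 100 times, pooling a null distribution of size 100 x n.
The subject's ROI is called above chance when the median of the real
distribution exceeds the 95th percentile of its null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .efp import EFPTimecourse

__all__ = [
    "SWConfig",
    "SWTestResult",
    "DEFAULT_WINDOW_SWEEP",
    "window_span_s",
    "sliding_window_corr",
    "shuffle_windows_null",
    "above_chance_decision",
    "run_sw_test",
    "window_sweep",
    "above_chance_fraction",
]

DEFAULT_WINDOW_SWEEP = (10, 20, 30, 40, 50)


@dataclass
class SWConfig:
    window_trs: int = 30
    step_trs: int = 1
    n_perm: int = 100
    chance_pctile: float = 95.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.window_trs <= 2:
            raise ValueError("window_trs must exceed 2")
        if self.step_trs < 1:
            raise ValueError("step_trs must be at least 1")
        if self.n_perm < 1:
            raise ValueError("n_perm must be at least 1")
        if not 0 < self.chance_pctile < 100:
            raise ValueError("chance_pctile must lie in (0, 100)")


@dataclass
class SWTestResult:
    """Real and null window-averaged correlation distributions.

    ``display_real_scale`` is the factor (100) by which real-distribution
    frequencies are multiplied for side-by-side plotting against the
    null; it never enters the decision.
    """

    real_dist: np.ndarray
    null_dist: np.ndarray
    window_trs: int
    real_median: float = np.nan
    chance_level: float = np.nan
    above_chance: bool = False
    display_real_scale: int = 100

    def __post_init__(self) -> None:
        self.real_dist = np.asarray(self.real_dist, dtype=float)
        self.null_dist = np.asarray(self.null_dist, dtype=float)


def window_span_s(window_trs: int, tr: float = 1.5) -> float:
    """Temporal span of a window in seconds (e.g. 30 TR -> 45 s)."""
    return window_trs * tr


def _efp_values(efp) -> np.ndarray:
    return efp.values if isinstance(efp, EFPTimecourse) else np.asarray(efp, dtype=float)


def _window_stats(ts: np.ndarray, w: int, step: int):
    """Strided windows with per-window sums and sums of squares."""
    win = sliding_window_view(ts, w, axis=-1)[..., ::step, :]
    s = win.sum(axis=-1)
    ss = (win**2).sum(axis=-1)
    return win, s, ss


def _mean_windowed_r(bw, bs, bss, ew, es, ess, w: int) -> np.ndarray:
    """Per-voxel mean of windowed Pearson r; degenerate windows -> r = 0.

    ``bw`` is (voxels, windows, w); ``ew`` is (windows, w).  Degenerate
    (zero-variance) windows are counted as r = 0 identically in the
    real and null branches so the comparison stays fair.
    """
    cross = np.einsum("vit,it->vi", bw, ew)
    cov = w * cross - bs * es[None, :]
    var_b = w * bss - bs**2
    var_e = w * ess - es**2
    denom2 = var_b * var_e[None, :]
    degenerate = denom2 <= 0
    if np.any(degenerate):
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance window(s) contribute r = 0",
            stacklevel=3,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(degenerate, 0.0, cov / np.sqrt(np.where(degenerate, 1.0, denom2)))
    return r.mean(axis=1)


def _check_lengths(efp_vals: np.ndarray, voxel_ts: np.ndarray, cfg: SWConfig):
    voxel_ts = np.atleast_2d(np.asarray(voxel_ts, dtype=float))
    n_t = voxel_ts.shape[1]
    if len(efp_vals) != n_t:
        raise ValueError(
            f"EFP length {len(efp_vals)} != BOLD volumes {n_t}; align first"
        )
    if n_t < cfg.window_trs:
        raise ValueError("series shorter than one window")
    return voxel_ts


def sliding_window_corr(efp, voxel_ts, cfg: SWConfig) -> np.ndarray:
    """Per-voxel mean of sliding-window Pearson correlations."""
    e = _efp_values(efp)
    voxel_ts = _check_lengths(e, voxel_ts, cfg)
    w = cfg.window_trs
    bw, bs, bss = _window_stats(voxel_ts, w, cfg.step_trs)
    ew, es, ess = _window_stats(e, w, cfg.step_trs)
    return _mean_windowed_r(bw, bs, bss, ew, es, ess, w)


def shuffle_windows_null(efp, voxel_ts, cfg: SWConfig, permutations=None) -> np.ndarray:
    """Pooled null: intact EFP windows reassigned to window positions.

    For each of ``n_perm`` permutations, the BOLD window at position i
    is paired with the unaltered EFP window starting at position
    pi(i), where pi is a seeded random permutation (without
    replacement) of all valid window start indices; per-voxel
    window-averaged correlations are computed exactly as in the real
    case.  Returns all ``n_perm * n_voxels`` values.  ``permutations``
    (a list of index arrays) overrides the RNG — passing identity
    permutations reproduces the real distribution, which is used as a
    self-check.
    """
    e = _efp_values(efp)
    voxel_ts = _check_lengths(e, voxel_ts, cfg)
    w = cfg.window_trs
    bw, bs, bss = _window_stats(voxel_ts, w, cfg.step_trs)
    ew, es, ess = _window_stats(e, w, cfg.step_trs)
    n_win = ew.shape[0]
    rng = np.random.default_rng(cfg.rng_seed)
    if permutations is None:
        permutations = [rng.permutation(n_win) for _ in range(cfg.n_perm)]
    out = []
    for pi in permutations:
        pi = np.asarray(pi, dtype=int)
        out.append(_mean_windowed_r(bw, bs, bss, ew[pi], es[pi], ess[pi], w))
    return np.concatenate(out)


def above_chance_decision(result: SWTestResult) -> bool:
    """Median of real distribution above the null's 95th percentile?"""
    if result.real_dist.size == 0 or result.null_dist.size == 0:
        raise ValueError("real and null distributions must be populated")
    return bool(result.real_median > result.chance_level)


def run_sw_test(efp, voxel_ts, cfg: SWConfig | None = None) -> SWTestResult:
    """Full single-subject, single-ROI test for one window size."""
    cfg = cfg or SWConfig()
    real = sliding_window_corr(efp, voxel_ts, cfg)
    null = shuffle_windows_null(efp, voxel_ts, cfg)
    res = SWTestResult(
        real_dist=real,
        null_dist=null,
        window_trs=cfg.window_trs,
        real_median=float(np.median(real)),
        chance_level=float(np.percentile(null, cfg.chance_pctile)),
    )
    res.above_chance = above_chance_decision(res)
    return res


def window_sweep(efp, voxel_ts, windows=DEFAULT_WINDOW_SWEEP, cfg: SWConfig | None = None) -> dict:
    """One test per window size; returns ``{window_trs: SWTestResult}``."""
    cfg = cfg or SWConfig()
    return {int(w): run_sw_test(efp, voxel_ts, replace(cfg, window_trs=int(w))) for w in windows}


def above_chance_fraction(results: list[SWTestResult]) -> float:
    """Cohort helper: fraction of subjects flagged above chance."""
    if not results:
        raise ValueError("no results given")
    return float(np.mean([r.above_chance for r in results]))
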