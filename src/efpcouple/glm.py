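"""Voxel-wise GLM of BOLD on the EFP regressor, group tests, and FDR.

Per subject, each voxel's prepared time-course (detrended, high-passed
at 0.001 Hz, demeaned) is regressed on the EFP time-course aligned to
the volume grid, yielding a map of effect sizes (beta) and t values.
At the group level the per-subject betas are tested voxel-wise with a
two-tailed one-sample t-test against zero (or a paired t-test when
contrasting two EFP models), and corrected for multiple comparisons
with the Benjamini-Hochberg false-discovery-rate procedure, optionally
restricted to a voxel subset such as an anatomical target mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datasets import BOLDDataset
from .efp import EFPTimecourse
from .synthetic import HRFKernel

__all__ = [
    "GLMConfig",
    "EffectMap",
    "GroupStats",
    "prepare_voxel_signals",
    "align_efp_to_volumes",
    "first_level_glm",
    "group_one_sample",
    "group_paired_contrast",
    "fdr_bh",
]


@dataclass
class GLMConfig:
    """First-level options.

    The high-pass is realized as discrete-cosine drift regression
    (removing fluctuations slower than ``highpass_hz``); the EFP
    regressor is z-scored by default so betas are comparable across
    models, and is not HRF-convolved unless requested.
    """

    highpass_hz: float = 0.001
    detrend: bool = True
    demean: bool = True
    standardize_regressor: bool = True
    efp_convolve_hrf: bool = False

    def __post_init__(self) -> None:
        if self.highpass_hz < 0:
            raise ValueError("highpass_hz must be non-negative")


@dataclass
class EffectMap:
    """Per-voxel regression effect of one subject and regressor."""

    beta: np.ndarray
    tstat: np.ndarray
    dof: int
    subject_id: str = ""
    regressor_name: str = "efp"

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.tstat = np.asarray(self.tstat, dtype=float)
        if self.beta.shape != self.tstat.shape:
            raise ValueError("beta and tstat must align")


@dataclass
class GroupStats:
    """Voxel-wise group test with FDR-adjusted significance."""

    t: np.ndarray
    p: np.ndarray
    q: np.ndarray
    sig_mask: np.ndarray
    test: str
    alpha: float
    n_subjects: int
    degenerate: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))
    pos_mask: np.ndarray | None = None  # directional helpers (paired contrast)
    neg_mask: np.ndarray | None = None


# ---------------------------------------------------------------------------
# signal preparation
# ---------------------------------------------------------------------------

def _dct_drift_basis(n: int, tr: float, cutoff_hz: float) -> np.ndarray:
    """Unit-norm DCT-II drift columns with frequency <= cutoff_hz.

    Column ``k`` oscillates at ``k / (2 n tr)`` Hz; the constant term is
    excluded (the demean step handles it).
    """
    if cutoff_hz <= 0:
        return np.empty((n, 0))
    k_max = int(np.floor(2 * n * tr * cutoff_hz))
    t = np.arange(n)
    cols = [np.cos(np.pi * k * (2 * t + 1) / (2 * n)) for k in range(1, k_max + 1)]
    if not cols:
        return np.empty((n, 0))
    basis = np.column_stack(cols)
    return basis / np.linalg.norm(basis, axis=0, keepdims=True)


def prepare_voxel_signals(bold: BOLDDataset, cfg: GLMConfig | None = None) -> BOLDDataset:
    """Detrend, high-pass and demean every voxel time-course, in that order."""
    cfg = cfg or GLMConfig()
    y = bold.data
    n = bold.n_volumes
    if n < 4:
        raise ValueError("need at least 4 volumes to prepare signals")
    if cfg.detrend:
        t = np.arange(n) - (n - 1) / 2
        slope = (y @ t) / (t @ t)
        y = y - np.mean(y, axis=1, keepdims=True) - slope[:, None] * t[None, :]
    if cfg.highpass_hz > 0:
        basis = _dct_drift_basis(n, bold.tr, cfg.highpass_hz)
        if basis.shape[1]:
            y = y - (y @ basis) @ basis.T
    if cfg.demean:
        y = y - np.mean(y, axis=1, keepdims=True)
    return bold.with_data(y)


# ---------------------------------------------------------------------------
# first level
# ---------------------------------------------------------------------------

def align_efp_to_volumes(efp: EFPTimecourse, bold: BOLDDataset) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-sample mapping of EFP timestamps to volume times.

    Returns ``(volume_indices, efp_values)``: volume ``i`` (acquired at
    ``i * TR``) is paired with the EFP value whose timestamp is nearest,
    provided it lies within half a step; warm-up volumes (before the
    first valid EFP value) are dropped from both sides.
    """
    vt = bold.volume_times
    j = np.rint((vt - efp.t0) / efp.dt).astype(int)
    ok = (j >= 0) & (j < len(efp.values))
    ok &= np.abs(vt - (efp.t0 + j * efp.dt)) <= efp.dt / 2 + 1e-9
    if not np.any(ok):
        raise ValueError("no volumes overlap the valid EFP time-course")
    return np.where(ok)[0], efp.values[j[ok]]


def first_level_glm(
    bold: BOLDDataset,
    efp: EFPTimecourse,
    cfg: GLMConfig | None = None,
    hrf: HRFKernel | None = None,
) -> EffectMap:
    """Per-voxel OLS of prepared BOLD on ``[EFP, intercept]``.

    The EFP is aligned to the volume grid (warm-up trimmed), optionally
    HRF-convolved, and z-scored unless ``standardize_regressor`` is
    off.  Returns beta and t per voxel with ``dof = volumes - 2``.
    """
    cfg = cfg or GLMConfig()
    vol_idx, reg = align_efp_to_volumes(efp, bold)
    if cfg.efp_convolve_hrf:
        kern = (hrf or HRFKernel()).sample(efp.dt)
        reg = np.convolve(reg, kern)[: len(reg)] * efp.dt
    trimmed = bold.with_data(bold.data[:, vol_idx])
    prepared = prepare_voxel_signals(trimmed, cfg)
    y = prepared.data
    n = y.shape[1]
    if np.std(reg) == 0:
        raise ValueError("degenerate input: EFP regressor has zero variance")
    if cfg.standardize_regressor:
        reg = (reg - reg.mean()) / reg.std()

    x = reg - reg.mean()  # intercept absorbed; y is demeaned per voxel
    sxx = x @ x
    beta = (y @ x) / sxx
    resid = y - beta[:, None] * x[None, :] - np.mean(y, axis=1, keepdims=True)
    dof = n - 2
    sigma2 = np.sum(resid**2, axis=1) / dof
    se = np.sqrt(sigma2 / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    return EffectMap(beta=beta, tstat=t, dof=dof, subject_id=bold.subject_id)


# ---------------------------------------------------------------------------
# group level
# ---------------------------------------------------------------------------

def _one_sample(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two-tailed one-sample t against 0 along axis 0.

    Voxels with zero across-subject variance are flagged degenerate and
    set to t = 0, p = 1 (conservative: never significant).
    """
    s, _ = values.shape
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    degenerate = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(~degenerate, mean / (sd / np.sqrt(s)), 0.0)
    p = 2 * stats.t.sf(np.abs(t), df=s - 1)
    p[degenerate] = 1.0
    return t, p, degenerate


def _stack_betas(maps: list[EffectMap]) -> np.ndarray:
    shapes = {m.beta.shape for m in maps}
    if len(shapes) != 1:
        raise ValueError("all effect maps must share one voxel set")
    return np.stack([m.beta for m in maps])


def group_one_sample(maps: list[EffectMap], alpha: float = 0.05, subset=None) -> GroupStats:
    """Voxel-wise two-tailed one-sample t-test of betas against zero.

    FDR (Benjamini-Hochberg) at ``alpha`` across all voxels, or across
    the ``subset`` indices only (e.g. an anatomical mask).
    """
    if len(maps) < 3:
        raise ValueError("group test needs at least 3 subjects")
    betas = _stack_betas(maps)
    t, p, degenerate = _one_sample(betas)
    sig, q = fdr_bh(p, q_level=alpha, subset=subset)
    sig &= ~degenerate
    return GroupStats(
        t=t, p=p, q=q, sig_mask=sig, test="one-sample", alpha=alpha,
        n_subjects=len(maps), degenerate=degenerate,
    )


def group_paired_contrast(
    maps_a: list[EffectMap], maps_b: list[EffectMap], alpha: float = 0.05, subset=None
) -> GroupStats:
    """Voxel-wise paired t-test of two regressors' effect maps.

    Tests ``a - b`` per voxel, two-tailed, FDR-corrected at ``alpha``.
    Directional helper masks threshold each direction at ``alpha / 2``
    (FDR-corrected), matching the display convention for one-sided
    contrast maps at p < 0.025 when alpha = 0.05.
    """
    if len(maps_a) != len(maps_b):
        raise ValueError("paired contrast needs the same subjects in both lists")
    for ma, mb in zip(maps_a, maps_b):
        if ma.subject_id != mb.subject_id:
            raise ValueError(
                f"subject order mismatch: {ma.subject_id!r} vs {mb.subject_id!r}"
            )
    if len(maps_a) < 3:
        raise ValueError("group test needs at least 3 subjects")
    diffs = _stack_betas(maps_a) - _stack_betas(maps_b)
    t, p, degenerate = _one_sample(diffs)
    sig, q = fdr_bh(p, q_level=alpha, subset=subset)
    sig &= ~degenerate
    sig_half, _ = fdr_bh(p, q_level=alpha / 2, subset=subset)
    sig_half &= ~degenerate
    return GroupStats(
        t=t, p=p, q=q, sig_mask=sig, test="paired", alpha=alpha,
        n_subjects=len(maps_a), degenerate=degenerate,
        pos_mask=sig_half & (t > 0), neg_mask=sig_half & (t < 0),
    )


def fdr_bh(p, q_level: float = 0.05, subset=None) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR.

    Returns ``(reject_mask, adjusted_q)`` over the full vector.  With
    ``subset`` (index array), the correction runs among those entries
    only; entries outside the subset are never rejected and get q = NaN.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject = np.zeros(p.shape, dtype=bool)
    q = np.full(p.shape, np.nan)
    idx = np.arange(p.size) if subset is None else np.asarray(subset, dtype=int)
    rej, padj, _, _ = multipletests(p.ravel()[idx], alpha=q_level, method="fdr_bh")
    reject.ravel()[idx] = rej
    q.ravel()[idx] = padj
    return reject, q
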