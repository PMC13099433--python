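"""Synthetic EEG-fMRI cohort generator with known ground truth.

The downstream analyses (EFP computation, voxel-wise GLM, seed-based
ROI selection, sliding-window permutation testing, reactivity coupling)
assume a specific statistical structure in the data: a slowly
fluctuating latent emotional drive, EEG whose band power tracks that
latent, BOLD voxels coupled to the HRF-convolved latent on top of AR(1)
noise, a seed region co-fluctuating with a subset of target-mask
voxels, and continuous ratings whose distance from the neutral anchor
scales with the latent.  This module generates multi-subject data with
exactly that structure and returns the ground-truth parameters and
voxel labels used to create it, so every stage of the pipeline can be
exercised as a parameter-recovery problem.

All generators are pure functions of their arguments including the RNG
seed.  Durations, sampling rates and the run layout default to the
study protocol (250-Hz EEG, TR = 1.5 s, the 867-s movie run with its
501-s and 321-s scenes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .datasets import BOLDDataset
from .efp import EEGRecording
from .reactivity import RatingTrace
from .timeline import TaskTimeline, build_run_timeline, required_volumes

__all__ = [
    "LatentTrace",
    "CouplingSpec",
    "HRFKernel",
    "SyntheticSubject",
    "CohortConfig",
    "make_latent",
    "simulate_eeg",
    "simulate_bold",
    "simulate_ratings",
    "simulate_subject",
    "simulate_cohort",
    "bold_regressor",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class LatentTrace:
    """A latent drive sampled at ``dt``-second intervals."""

    values: np.ndarray
    dt: float
    label: str = "latent"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.values.ndim != 1 or len(self.values) < 2:
            raise ValueError("latent trace needs at least 2 samples")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("latent values must be finite")

    @property
    def duration_s(self) -> float:
        return len(self.values) * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) * self.dt

    def at(self, t: np.ndarray) -> np.ndarray:
        """Linear interpolation at arbitrary times (end values held)."""
        return np.interp(t, self.times, self.values)


@dataclass
class CouplingSpec:
    """Ground-truth effect sizes the analyses are meant to estimate.

    beta_bold
        BOLD units per unit (1 SD) of the HRF-convolved latent drive.
    ar1_phi, noise_sd
        Lag-1 coefficient and stationary SD of the additive voxel noise.
    frac_coupled_voxels
        Fraction of brain voxels coupled to the latent.
    seed_coupling_r
        Target Pearson correlation between salience-truth target voxels
        and the seed signal.
    rating_slope, rating_noise_sd
        Rating points per latent unit, and the SD of rating noise.
    """

    beta_bold: float = 0.5
    ar1_phi: float = 0.3
    noise_sd: float = 1.0
    frac_coupled_voxels: float = 0.25
    seed_coupling_r: float = 0.6
    rating_slope: float = 1.0
    rating_noise_sd: float = 0.5

    def __post_init__(self) -> None:
        vals = [
            self.beta_bold, self.ar1_phi, self.noise_sd,
            self.frac_coupled_voxels, self.seed_coupling_r,
            self.rating_slope, self.rating_noise_sd,
        ]
        if not all(np.isfinite(vals)):
            raise ValueError("all coupling parameters must be finite")
        if abs(self.ar1_phi) >= 1:
            raise ValueError("ar1_phi must lie in (-1, 1)")
        if self.noise_sd < 0 or self.rating_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if not 0 <= self.frac_coupled_voxels <= 1:
            raise ValueError("frac_coupled_voxels must lie in [0, 1]")
        if not -1 <= self.seed_coupling_r <= 1:
            raise ValueError("seed_coupling_r must lie in [-1, 1]")


@dataclass
class HRFKernel:
    """Canonical double-gamma hemodynamic response function.

    Response gamma peaking at 6 s minus an undershoot gamma peaking at
    16 s scaled by ``ratio`` (1/6), truncated at 32 s and normalized to
    unit peak.
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    ratio: float = 1.0 / 6.0
    duration_s: float = 32.0

    def sample(self, dt: float) -> np.ndarray:
        from scipy.stats import gamma

        t = np.arange(0, self.duration_s + dt / 2, dt)
        h = gamma.pdf(t, self.peak_delay, scale=1.0) - self.ratio * gamma.pdf(
            t, self.undershoot_delay, scale=1.0
        )
        return h / np.max(np.abs(h))


@dataclass
class SyntheticSubject:
    """One subject's generated data plus the truth that produced it."""

    subject_id: str
    truth: CouplingSpec
    rng_seed: int
    eeg: EEGRecording | None = None
    bold: BOLDDataset | None = None
    ratings: dict = field(default_factory=dict)  # scene -> RatingTrace
    timeline: TaskTimeline | None = None
    scene_levels: dict = field(default_factory=dict)
    latent: LatentTrace | None = None


@dataclass
class CohortConfig:
    """Study-condition defaults for synthetic subjects.

    The run layout is the movie run of the protocol (867 s: 501-s
    farewell scene and 321-s snakes scene with fixation gaps), EEG at
    250 Hz with a 4-8 Hz carrier band, BOLD at TR = 1.5 s.  The snakes
    scene is generated as the higher-arousal scene (mean latent level
    1.0 vs 0.5), with between-subject variation in scene levels so that
    reactivity and EFP-amplitude differences co-vary across subjects.
    """

    run: TaskTimeline | None = None  # None -> protocol movie run
    scene_levels: dict = field(default_factory=lambda: {"snakes": 1.0, "farewell": 0.5})
    scene_level_sd: float = 0.3  # between-subject SD of each scene level
    fluct_scale: float = 0.5  # SD of within-run latent fluctuation
    latent_dt: float = 0.25
    latent_cutoff_hz: float = 0.1
    eeg_fs: float = 250.0
    carrier_band: tuple = (4.0, 8.0)
    eeg_noise_sd: float = 1.0
    mod_depth: float = 0.5
    tr: float = 1.5
    n_brain_voxels: int = 120
    n_target_voxels: int = 40
    target_salience_frac: float = 0.15
    hrf: HRFKernel = field(default_factory=HRFKernel)

    def timeline(self) -> TaskTimeline:
        return self.run if self.run is not None else build_run_timeline("movie")


def _rng(rng_seed) -> np.random.Generator:
    return np.random.default_rng(rng_seed)


def _child_seed(master: int, *key: int) -> int:
    """Deterministic 31-bit child seed for an independent substream."""
    return int(np.random.SeedSequence([int(master), *key]).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# latent drive
# ---------------------------------------------------------------------------

def make_latent(duration_s: float, dt: float, cutoff_hz: float = 0.1, rng_seed: int = 0) -> LatentTrace:
    """Low-pass-filtered Gaussian noise, demeaned and scaled to unit SD.

    The latent stands in for a slowly fluctuating emotional drive; the
    cutoff (default 0.1 Hz) sets its timescale.
    """
    if duration_s <= 0 or dt <= 0:
        raise ValueError("duration_s and dt must be positive")
    if duration_s < 10 * dt:
        raise ValueError("duration_s must cover at least 10 samples")
    fs = 1.0 / dt
    if not 0 < cutoff_hz < fs / 2:
        raise ValueError("cutoff must lie in (0, Nyquist)")
    n = int(round(duration_s / dt))
    white = _rng(rng_seed).standard_normal(n)
    sos = sps.butter(4, cutoff_hz, btype="lowpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, white)
    x = x - np.mean(x)
    sd = np.std(x)
    if sd > 0:
        x = x / sd
    return LatentTrace(values=x, dt=dt)


# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------

def simulate_eeg(
    latent: LatentTrace,
    fs: float = 250.0,
    carrier_band=(4.0, 8.0),
    rng_seed: int = 0,
    noise_sd: float = 1.0,
    mod_depth: float = 0.5,
) -> EEGRecording:
    """EEG whose carrier-band power envelope tracks the latent.

    The carrier is a constant-modulus frequency-modulated sinusoid
    whose instantaneous frequency wanders inside ``carrier_band`` —
    this keeps the quarter-second power envelope free of the
    chi-squared estimation noise a stochastic carrier would add, so the
    envelope is ``(1 + mod_depth * latent)`` (clipped positive) up to
    band-capture effects.  Broadband white noise of SD ``noise_sd`` is
    added on both electrodes of the Pz-FCz derivation.
    """
    f_lo, f_hi = carrier_band
    if not (0 < f_lo < f_hi < fs / 2):
        raise ValueError(f"carrier band {carrier_band} outside (0, fs/2)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = _rng(rng_seed)
    n = int(round(latent.duration_s * fs))
    t = np.arange(n) / fs
    lat_up = latent.at(t)
    envelope = np.clip(1.0 + mod_depth * lat_up, 0.05, None)

    # instantaneous frequency: smoothed random walk mapped into the band
    f_c, half_bw = (f_lo + f_hi) / 2, (f_hi - f_lo) / 2
    drift = np.cumsum(rng.standard_normal(n))
    sos = sps.butter(2, min(0.5, fs / 8), btype="lowpass", fs=fs, output="sos")
    drift = sps.sosfiltfilt(sos, drift)
    sd = np.std(drift)
    if sd > 0:
        drift = drift / sd
    # keep the wander inside the flat center of the band so band-pass
    # power measurements are not modulated by filter roll-off
    inst_f = f_c + 0.5 * half_bw * np.tanh(drift)
    phase = 2 * np.pi * np.cumsum(inst_f) / fs + rng.uniform(0, 2 * np.pi)
    carrier = np.sqrt(2.0) * np.cos(phase)

    pz = envelope * carrier + noise_sd * rng.standard_normal(n)
    fcz = noise_sd * rng.standard_normal(n)
    samples = np.vstack([pz, fcz])
    return EEGRecording(samples=samples, fs=fs, channel_labels=["Pz", "FCz"], reference="AFz")


# ---------------------------------------------------------------------------
# BOLD
# ---------------------------------------------------------------------------

def bold_regressor(latent: LatentTrace, tr: float, n_volumes: int, hrf: HRFKernel | None = None) -> np.ndarray:
    """HRF-convolved latent, resampled to volume times and z-scored.

    Volume ``i`` is sampled at ``i * tr``; the convolution is causal
    (the response lags the drive).  A zero-variance result is returned
    as zeros rather than rescaled.
    """
    hrf = hrf or HRFKernel()
    kern = hrf.sample(latent.dt)
    conv = np.convolve(latent.values, kern)[: len(latent.values)] * latent.dt
    conv_trace = LatentTrace(conv, latent.dt) if len(conv) >= 2 else latent
    x = conv_trace.at(np.arange(n_volumes) * tr)
    x = x - np.mean(x)
    sd = np.std(x)
    return x / sd if sd > 0 else x


def _ar1_noise(rng: np.random.Generator, shape, phi: float, sd: float) -> np.ndarray:
    """AR(1) noise with stationary SD ``sd`` and lag-1 coefficient ``phi``."""
    n_series, n_t = shape
    if sd == 0:
        return np.zeros(shape)
    innov_sd = sd * math.sqrt(1 - phi**2)
    x = np.empty(shape)
    x[:, 0] = sd * rng.standard_normal(n_series)
    eps = innov_sd * rng.standard_normal((n_series, n_t - 1))
    for i in range(1, n_t):
        x[:, i] = phi * x[:, i - 1] + eps[:, i - 1]
    return x


def _lattice_coords(n: int) -> np.ndarray:
    side = int(math.ceil(n ** (1 / 3)))
    grid = np.stack(np.meshgrid(*([np.arange(side)] * 3), indexing="ij"), axis=-1)
    return grid.reshape(-1, 3)[:n]


def simulate_bold(
    latent: LatentTrace,
    n_voxels: int,
    spec: CouplingSpec,
    tr: float = 1.5,
    hrf: HRFKernel | None = None,
    rng_seed: int = 0,
) -> BOLDDataset:
    """Voxels coupled to the HRF-convolved latent plus AR(1) noise.

    The first ``floor(frac_coupled_voxels * n_voxels)`` voxels equal
    ``beta_bold * x + AR(1)`` where ``x`` is the unit-SD HRF-convolved
    resampled latent; the rest are pure AR(1) noise.  Ground-truth
    labels are returned in the masks ``coupled_truth`` and
    ``uncoupled_truth``.
    """
    if n_voxels < 2:
        raise ValueError("n_voxels must be at least 2")
    if tr <= 0:
        raise ValueError("tr must be positive")
    rng = _rng(rng_seed)
    n_vol = required_volumes(latent.duration_s, tr)
    x = bold_regressor(latent, tr, n_vol, hrf)
    n_coupled = int(math.floor(spec.frac_coupled_voxels * n_voxels))
    noise = _ar1_noise(rng, (n_voxels, n_vol), spec.ar1_phi, spec.noise_sd)
    data = noise
    data[:n_coupled] += spec.beta_bold * x[None, :]
    masks = {
        "brain": np.arange(n_voxels),
        "coupled_truth": np.arange(n_coupled),
        "uncoupled_truth": np.arange(n_coupled, n_voxels),
    }
    return BOLDDataset(
        data=data,
        tr=tr,
        voxel_coords=_lattice_coords(n_voxels),
        masks=masks,
    )


# ---------------------------------------------------------------------------
# ratings
# ---------------------------------------------------------------------------

def simulate_ratings(
    latent_per_scene: dict,
    spec: CouplingSpec,
    rng_seed: int = 0,
    rating_dt: float = 0.5,
) -> dict:
    """Continuous 1-7 ratings tracking each scene's latent drive.

    ``rating = 4 + rating_slope * latent + noise``, saturated into
    [1, 7], sampled every ``rating_dt`` seconds.
    """
    if not latent_per_scene:
        raise ValueError("at least one scene latent is required")
    rng = _rng(rng_seed)
    out = {}
    for scene in sorted(latent_per_scene):
        lat = latent_per_scene[scene]
        t = np.arange(0, lat.duration_s - rating_dt / 2, rating_dt)
        vals = 4.0 + spec.rating_slope * lat.at(t)
        vals = vals + spec.rating_noise_sd * rng.standard_normal(len(t))
        out[scene] = RatingTrace(t=t, values=np.clip(vals, 1.0, 7.0), scene=scene)
    return out


# ---------------------------------------------------------------------------
# whole subjects and cohorts
# ---------------------------------------------------------------------------

def _run_latent(
    cfg: CohortConfig, levels: dict, rng_seed: int
) -> tuple[LatentTrace, dict]:
    """Run-long latent: per-condition step levels plus smooth fluctuation."""
    tl = cfg.timeline()
    n = int(round(tl.total_s / cfg.latent_dt))
    t = np.arange(n) * cfg.latent_dt
    level = np.zeros(n)
    for onset, dur, cond in tl.events:
        if cond in levels:
            level[(t >= onset) & (t < onset + dur)] = levels[cond]
    fluct = make_latent(tl.total_s, cfg.latent_dt, cfg.latent_cutoff_hz, rng_seed)
    values = level + cfg.fluct_scale * fluct.values[:n]
    lat = LatentTrace(values, cfg.latent_dt, label="run")
    scene_latents = {}
    for cond in levels:
        windows = tl.windows(cond)
        if not windows:
            continue
        onset, end = windows[0]
        sel = (t >= onset) & (t < end)
        scene_latents[cond] = LatentTrace(values[sel], cfg.latent_dt, label=cond)
    return lat, scene_latents


def _seed_target_bold(
    bold: BOLDDataset,
    x: np.ndarray,
    spec: CouplingSpec,
    cfg: CohortConfig,
    rng: np.random.Generator,
) -> BOLDDataset:
    """Append seed-sphere and target-mask voxels to a brain dataset.

    The seed signal mixes the BOLD drive ``x`` with an independent
    smooth component; salience-truth target voxels are constructed to
    correlate ``seed_coupling_r`` with it (and hence partially with the
    EFP-tracked drive), while the remaining target voxels are pure
    AR(1) noise.
    """
    n_vol = bold.n_volumes

    def _z(v):
        v = v - v.mean()
        s = v.std()
        return v / s if s > 0 else v

    eta = _z(_ar1_noise(rng, (1, n_vol), 0.8, 1.0)[0])
    s = _z(x + eta) if np.std(x) > 0 else eta  # seed signal, corr ~0.7 with x

    # seed sphere: center voxel plus its 6 lattice neighbours (all within
    # a 4-mm radius at 2.2-mm spacing)
    side = bold.voxel_coords.max() + 3
    center = np.array([side, side, side])
    offsets = np.array(
        [[0, 0, 0], [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
    )
    seed_coords = center[None, :] + offsets
    seed_data = s[None, :] + 0.2 * rng.standard_normal((7, n_vol))

    n_target = cfg.n_target_voxels
    n_sal = int(math.floor(cfg.target_salience_frac * n_target))
    r = spec.seed_coupling_r
    tgt_noise = _ar1_noise(rng, (n_target, n_vol), spec.ar1_phi, 1.0)
    tgt = np.array([_z(v) for v in tgt_noise])
    tgt[:n_sal] = r * s[None, :] + math.sqrt(max(0.0, 1 - r**2)) * tgt[:n_sal]
    tgt *= max(spec.noise_sd, 0.5)  # arbitrary BOLD scale
    tgt_coords = _lattice_coords(n_target) + np.array([0, 0, side + 3])

    v0 = bold.n_voxels
    masks = dict(bold.masks)
    masks["seed"] = np.arange(v0, v0 + 7)
    masks["target"] = np.arange(v0 + 7, v0 + 7 + n_target)
    masks["salience_truth"] = np.arange(v0 + 7, v0 + 7 + n_sal)
    masks["nonsalience_truth"] = np.arange(v0 + 7 + n_sal, v0 + 7 + n_target)
    return BOLDDataset(
        data=np.vstack([bold.data, seed_data, tgt]),
        tr=bold.tr,
        voxel_coords=np.vstack([bold.voxel_coords, seed_coords, tgt_coords]),
        spacing=bold.spacing,
        # place the seed-sphere center at mm coordinate (36, 18, 4)
        origin=np.array([36.0, 18.0, 4.0]) - center * bold.spacing,
        masks=masks,
        subject_id=bold.subject_id,
    )


def simulate_subject(
    subject_id: str,
    truth: CouplingSpec,
    rng_seed: int,
    cfg: CohortConfig | None = None,
    with_eeg: bool = True,
    with_bold: bool = True,
    with_ratings: bool = True,
) -> SyntheticSubject:
    """Generate one fully self-consistent subject.

    EEG, BOLD and ratings all derive from the same run-long latent
    drive.  Each component uses an independent seeded substream, so
    disabling one (for speed) leaves the others bit-identical.
    """
    cfg = cfg or CohortConfig()
    tl = cfg.timeline()
    rng_lvl = _rng(_child_seed(rng_seed, 0))
    levels = {
        scene: mu + cfg.scene_level_sd * rng_lvl.standard_normal()
        for scene, mu in sorted(cfg.scene_levels.items())
    }
    latent, scene_latents = _run_latent(cfg, levels, _child_seed(rng_seed, 1))

    subj = SyntheticSubject(
        subject_id=subject_id,
        truth=truth,
        rng_seed=rng_seed,
        timeline=tl,
        scene_levels=levels,
        latent=latent,
    )
    if with_eeg:
        subj.eeg = simulate_eeg(
            latent,
            fs=cfg.eeg_fs,
            carrier_band=cfg.carrier_band,
            rng_seed=_child_seed(rng_seed, 2),
            noise_sd=cfg.eeg_noise_sd,
            mod_depth=cfg.mod_depth,
        )
    if with_bold:
        bold = simulate_bold(
            latent,
            cfg.n_brain_voxels,
            truth,
            tr=cfg.tr,
            hrf=cfg.hrf,
            rng_seed=_child_seed(rng_seed, 3),
        )
        bold.subject_id = subject_id
        x = bold_regressor(latent, cfg.tr, bold.n_volumes, cfg.hrf)
        subj.bold = _seed_target_bold(bold, x, truth, cfg, _rng(_child_seed(rng_seed, 4)))
    if with_ratings:
        subj.ratings = simulate_ratings(
            scene_latents, truth, rng_seed=_child_seed(rng_seed, 5)
        )
    return subj


def simulate_cohort(
    n_subjects: int,
    template: CouplingSpec | None = None,
    between_subject_sd: float = 0.1,
    rng_seed: int = 0,
    cfg: CohortConfig | None = None,
    with_eeg: bool = True,
    with_bold: bool = True,
    with_ratings: bool = True,
) -> list:
    """Generate a cohort with subject effects drawn around a template.

    Each subject's ``beta_bold`` is drawn from a normal centered on the
    template value with SD ``between_subject_sd`` (clipped at 0); the
    remaining coupling parameters are shared.  The master seed
    reproduces the cohort exactly.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be at least 2")
    if between_subject_sd < 0:
        raise ValueError("between_subject_sd must be non-negative")
    template = template or CouplingSpec()
    subjects = []
    for i in range(n_subjects):
        subj_seed = _child_seed(rng_seed, 1000 + i)
        beta = template.beta_bold
        if between_subject_sd > 0:
            beta = max(
                0.0,
                beta + between_subject_sd * _rng(_child_seed(subj_seed, 99)).standard_normal(),
            )
        truth = replace(template, beta_bold=beta)
        subjects.append(
            simulate_subject(
                f"sub-{i + 1:03d}",
                truth,
                subj_seed,
                cfg=cfg,
                with_eeg=with_eeg,
                with_bold=with_bold,
                with_ratings=with_ratings,
            )
        )
    return subjects
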