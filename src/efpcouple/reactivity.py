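"""Emotional-reactivity indices and their coupling with EFP amplitude.

Participants continuously rate their emotional reaction to two movie
scenes on a 1-7 scale where 4 is the neutral anchor.  The reactivity
index of a scene is the mean absolute distance of the rating from the
neutral anchor over the scene timeline — capturing the range of the
emotional response rather than its valence.  Across subjects, the
difference in reactivity between the two scenes (by convention the
high-intensity scene minus the low-intensity scene) is compared with
the difference in mean EFP amplitude over the same scene windows, with
paired t-tests per measure and a Pearson correlation between them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .efp import EFPTimecourse

__all__ = [
    "RatingTrace",
    "ReactivityResult",
    "NEUTRAL_ANCHOR",
    "reactivity_index",
    "efp_amplitude",
    "scene_difference_tests",
    "correlate_reactivity_efp",
]

NEUTRAL_ANCHOR = 4.0  # "no emotional reaction" midpoint of the 1-7 scale
RATING_MIN, RATING_MAX = 1.0, 7.0


@dataclass
class RatingTrace:
    """Continuous rating samples for one subject and scene."""

    t: np.ndarray
    values: np.ndarray
    scene: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.t.shape != self.values.shape or self.t.ndim != 1:
            raise ValueError("t and values must be 1-D and equal length")
        if len(self.t) == 0:
            raise ValueError("rating trace must be non-empty")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly ascending")


@dataclass
class ReactivityResult:
    """Cohort-level reactivity / EFP-amplitude coupling summary."""

    per_subject: pd.DataFrame = field(default_factory=pd.DataFrame)
    scene_pair: tuple = ("", "")
    paired_t_ratings: float = np.nan
    paired_p_ratings: float = np.nan
    paired_t_efp: float = np.nan
    paired_p_efp: float = np.nan
    cohort_r: float = np.nan
    cohort_r_p: float = np.nan
    n_subjects: int = 0


def _resample_step(trace: RatingTrace, dt: float = 0.5) -> np.ndarray:
    """Previous-value (step) resampling to a uniform grid over the trace.

    Continuous ratings are recorded whenever the subject moves the
    scale, so between samples the last value is held.
    """
    if len(trace.t) == 1:
        return trace.values.copy()
    grid = np.arange(trace.t[0], trace.t[-1] + dt / 2, dt)
    idx = np.searchsorted(trace.t, grid + 1e-12, side="right") - 1
    return trace.values[np.maximum(idx, 0)]


def reactivity_index(trace: RatingTrace, resample_dt: float = 0.5) -> float:
    """Mean absolute deviation of ratings from the neutral anchor.

    Ratings are centered at the neutral anchor (4), converted to
    absolute reactivity and averaged over a uniform step-resampled
    timeline.  Values outside the 1-7 scale are rejected.
    """
    if np.any(trace.values < RATING_MIN - 1e-9) or np.any(trace.values > RATING_MAX + 1e-9):
        raise ValueError("ratings must lie within the 1-7 scale")
    vals = _resample_step(trace, resample_dt)
    return float(np.mean(np.abs(vals - NEUTRAL_ANCHOR)))


def efp_amplitude(efp: EFPTimecourse, window, absolute: bool = False) -> float:
    """Mean EFP amplitude over a scene window ``[t_start, t_end]``.

    ``absolute=True`` averages absolute values instead of the raw mean.
    """
    t_start, t_end = window
    vals = efp.window_values(t_start, t_end)
    if len(vals) == 0:
        raise ValueError(f"no EFP samples inside window [{t_start}, {t_end}]")
    return float(np.mean(np.abs(vals) if absolute else vals))


def _complete_subjects(cohort: pd.DataFrame, scene_pair) -> pd.DataFrame:
    """Wide per-subject table, dropping subjects missing either scene."""
    required = {"subject", "scene", "rating_index", "efp_amp"}
    if not required.issubset(cohort.columns):
        raise ValueError(f"cohort table needs columns {sorted(required)}")
    a, b = scene_pair
    wide = cohort.pivot_table(
        index="subject", columns="scene", values=["rating_index", "efp_amp"]
    )
    have = [s for s in (a, b) if ("rating_index", s) in wide.columns]
    if len(have) < 2:
        raise ValueError(f"cohort table lacks scenes {scene_pair}")
    complete = wide[[("rating_index", a), ("rating_index", b), ("efp_amp", a), ("efp_amp", b)]].dropna()
    n_dropped = len(wide) - len(complete)
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} subject(s) missing a scene", stacklevel=3)
    return complete


def scene_difference_tests(cohort: pd.DataFrame, scene_pair=("snakes", "farewell")) -> ReactivityResult:
    """Paired two-tailed t-tests of scene differences across subjects.

    ``cohort`` is a long table with columns ``subject, scene,
    rating_index, efp_amp``.  Differences are taken as the first scene
    of ``scene_pair`` minus the second.  Subjects missing a scene are
    dropped with a warning.
    """
    a, b = scene_pair
    wide = _complete_subjects(cohort, scene_pair)
    if len(wide) < 3:
        raise ValueError("paired tests need at least 3 complete subjects")
    rat_a, rat_b = wide[("rating_index", a)].to_numpy(), wide[("rating_index", b)].to_numpy()
    efp_a, efp_b = wide[("efp_amp", a)].to_numpy(), wide[("efp_amp", b)].to_numpy()

    def _paired(u, v):
        d = u - v
        if np.std(d, ddof=1) == 0:
            # degenerate differences: identical -> no effect (t=0, p=1);
            # constant nonzero shift -> unbounded evidence
            if np.all(d == 0):
                return 0.0, 1.0
            return float(np.sign(d[0]) * np.inf), 0.0
        t, p = stats.ttest_rel(u, v)
        return float(t), float(p)

    t_rat, p_rat = _paired(rat_a, rat_b)
    t_efp, p_efp = _paired(efp_a, efp_b)
    per_subject = pd.DataFrame(
        {
            "subject": wide.index,
            "rating_diff": rat_a - rat_b,
            "efp_amp_diff": efp_a - efp_b,
        }
    ).reset_index(drop=True)
    return ReactivityResult(
        per_subject=per_subject,
        scene_pair=(a, b),
        paired_t_ratings=float(t_rat),
        paired_p_ratings=float(p_rat),
        paired_t_efp=float(t_efp),
        paired_p_efp=float(p_efp),
        n_subjects=len(wide),
    )


def correlate_reactivity_efp(cohort: pd.DataFrame, scene_pair=("snakes", "farewell")) -> tuple:
    """Cross-subject Pearson correlation of scene differences.

    Correlates the per-subject difference in reactivity index with the
    per-subject difference in mean EFP amplitude between the two
    scenes; returns ``(r, two-tailed p)``.
    """
    wide = _complete_subjects(cohort, scene_pair)
    if len(wide) < 4:
        raise ValueError("correlation needs at least 4 complete subjects")
    a, b = scene_pair
    d_rat = (wide[("rating_index", a)] - wide[("rating_index", b)]).to_numpy()
    d_efp = (wide[("efp_amp", a)] - wide[("efp_amp", b)]).to_numpy()
    if np.ptp(d_rat) == 0 or np.ptp(d_efp) == 0:
        raise ValueError("degenerate input: zero variance in a difference vector")
    r, p = stats.pearsonr(d_rat, d_efp)
    return float(r), float(p)
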