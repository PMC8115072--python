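"""Event-locked directionality consistency (DC).

Trial direction series are epoched around task events (stimulus or speech
onset). At each event-locked timepoint the mean resultant length of the
per-trial wave directions — the directionality consistency, DC in [0, 1] —
measures how reproducibly the wave travels in the same direction across
trials. Per-timepoint Rayleigh p-values are corrected across the analysis
window with the Benjamini-Hochberg step-up procedure, and a shuffled-
timepoint surrogate band (independent circular shifts of each trial's
series) provides the chance range of DC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

from .dirstats import circular_mean, rayleigh_test, resultant_length
from .wavefit import WaveFitSeries

__all__ = [
    "TrialSet",
    "DCResult",
    "epoch_trials",
    "directionality_consistency",
    "fdr_correct",
    "rt_split",
]

MIN_TRIALS = 10


@dataclass
class TrialSet:
    """Time-aligned direction/R^2 series for a set of trials."""

    directions: np.ndarray  # (n_trials, n_timepoints), deg; NaN = invalid fit
    r2: np.ndarray  # (n_trials, n_timepoints)
    timepoints: np.ndarray  # s relative to event
    event_label: str
    reaction_times: np.ndarray | None = None  # s per trial
    fs: float = 100.0

    @property
    def n_trials(self) -> int:
        return self.directions.shape[0]


@dataclass
class DCResult:
    timepoints: np.ndarray  # s
    dc: np.ndarray  # [0, 1]
    mean_direction: np.ndarray  # deg
    mean_r2: np.ndarray
    p_raw: np.ndarray
    p_fdr: np.ndarray
    null_band: tuple[float, float]  # (lo, hi) DC
    n_per_timepoint: np.ndarray = field(default=None)


def epoch_trials(
    fits: WaveFitSeries,
    events: list[float],
    window: tuple[float, float] = (2.0, 2.0),
    rt: list[float] | None = None,
    artifact_intervals: list[tuple[float, float]] | None = None,
    event_label: str = "stimulus",
    min_trials: int = MIN_TRIALS,
) -> TrialSet:
    """Epoch a wave-fit series around task events.

    ``window`` is (pre_s, post_s). Trials whose window extends past the
    recording edge are dropped with a warning; trials overlapping any
    artifact interval are excluded. Fewer than ``min_trials`` surviving
    trials is an error (too few for across-trial circular statistics).
    """
    import warnings

    pre, post = window
    fs = fits.fs_analysis
    n_pre = int(round(pre * fs))
    n_post = int(round(post * fs))
    rel_t = np.arange(-n_pre, n_post + 1) / fs
    t0, t1 = fits.t[0], fits.t[-1]
    artifact_intervals = artifact_intervals or []
    rows_dir, rows_r2, kept_rt = [], [], []
    rt = list(rt) if rt is not None else None
    for i, ev in enumerate(events):
        if ev - pre < t0 - 1e-9 or ev + post > t1 + 1e-9:
            warnings.warn(
                f"trial at {ev:.3f}s extends past the recording edge; dropped",
                stacklevel=2,
            )
            continue
        if any(ev - pre < e and s < ev + post for s, e in artifact_intervals):
            continue
        center = int(round((ev - t0) * fs))
        sl = slice(center - n_pre, center + n_post + 1)
        rows_dir.append(fits.direction[sl])
        rows_r2.append(fits.r2[sl])
        if rt is not None:
            kept_rt.append(rt[i])
    if len(rows_dir) < min_trials:
        raise ValueError(
            f"only {len(rows_dir)} valid trials after exclusion "
            f"(minimum {min_trials}); across-trial DC is not assessable"
        )
    return TrialSet(
        directions=np.array(rows_dir),
        r2=np.array(rows_r2),
        timepoints=rel_t,
        event_label=event_label,
        reaction_times=np.array(kept_rt) if rt is not None else None,
        fs=fs,
    )


def fdr_correct(p_raw: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p_raw = np.asarray(p_raw, dtype=float)
    if p_raw.size == 0:
        return p_raw.copy()
    if np.any((p_raw < 0) | (p_raw > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p_raw, method="fdr_bh")[1]


def _dc_per_timepoint(directions: np.ndarray) -> tuple[np.ndarray, ...]:
    """(dc, mean_dir, p_raw, n) per column, pairwise-complete over NaN."""
    T = directions.shape[1]
    dc = np.full(T, np.nan)
    mean_dir = np.full(T, np.nan)
    p_raw = np.ones(T)
    n_t = np.zeros(T, dtype=int)
    for t in range(T):
        col = directions[:, t]
        col = col[np.isfinite(col)]
        n_t[t] = col.size
        if col.size >= 2:
            dc[t] = resultant_length(col)
            mean_dir[t] = circular_mean(col)
            _, _, p_raw[t] = rayleigh_test(col)
    return dc, mean_dir, p_raw, n_t


def directionality_consistency(
    ts: TrialSet,
    n_surrogates: int = 200,
    seed: int = 0,
) -> DCResult:
    """Across-trial directionality consistency with FDR and null band.

    DC(t) is the mean resultant length of trial directions at t;
    ``p_raw`` is the per-timepoint Rayleigh p, ``p_fdr`` its BH
    correction across the window. The null band holds the pooled
    2.5th/97.5th percentiles of DC recomputed after circularly shifting
    each trial's direction series by an independent random offset
    (preserving within-trial autocorrelation).
    """
    if ts.n_trials < MIN_TRIALS:
        raise ValueError(f"DC requires >= {MIN_TRIALS} trials")
    dc, mean_dir, p_raw, n_t = _dc_per_timepoint(ts.directions)
    p_fdr = fdr_correct(p_raw)
    rng = np.random.default_rng(seed)
    T = ts.directions.shape[1]
    null_dcs = []
    for _ in range(n_surrogates):
        shifts = rng.integers(0, T, size=ts.n_trials)
        shifted = np.array(
            [np.roll(ts.directions[i], shifts[i]) for i in range(ts.n_trials)]
        )
        sdc, _, _, _ = _dc_per_timepoint(shifted)
        null_dcs.append(sdc)
    pooled = np.concatenate(null_dcs)
    pooled = pooled[np.isfinite(pooled)]
    band = (float(np.percentile(pooled, 2.5)), float(np.percentile(pooled, 97.5)))
    return DCResult(
        timepoints=ts.timepoints,
        dc=dc,
        mean_direction=mean_dir,
        mean_r2=np.nanmean(ts.r2, axis=0),
        p_raw=p_raw,
        p_fdr=p_fdr,
        null_band=band,
        n_per_timepoint=n_t,
    )


def rt_split(ts: TrialSet) -> tuple[TrialSet, TrialSet]:
    """Median split of trials by reaction time; ties go to the fast half."""
    if ts.reaction_times is None:
        raise ValueError("reaction times are required for an RT split")
    rt = np.asarray(ts.reaction_times, dtype=float)
    med = np.median(rt)
    fast = rt <= med
    slow = ~fast

    def subset(mask):
        return TrialSet(
            directions=ts.directions[mask],
            r2=ts.r2[mask],
            timepoints=ts.timepoints,
            event_label=ts.event_label,
            reaction_times=rt[mask],
            fs=ts.fs,
        )

    return subset(fast), subset(slow)
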