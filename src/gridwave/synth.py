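"""Synthetic surface-LFP generator with planted traveling waves.

Produces multichannel recordings on a regular 2D electrode lattice in which
every quantity the analysis pipeline estimates — oscillation peak frequency,
travel direction, spatial frequency, amplitude topography, task-locked
direction alignment — is planted with known ground truth, so each stage can
be validated by recovery rather than by eye.

Model: each active wave component contributes, at electrode i with position
(x_i, y_i) in mm,

    A * g_i * cos(2*pi*f*t - k_rad*(x_i*cos(theta) + y_i*sin(theta)) + phi0)

where theta is the direction of travel (deg, 0 = +x, counterclockwise
positive), k_rad = k * pi/180 the spatial frequency converted from deg/mm to
rad/mm, and g_i a per-electrode gain ("amplitude topography", unit mean).
On top of the planar oscillation each channel carries an independent
1/f^exponent aperiodic background scaled to a given standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GridGeometry",
    "WaveComponent",
    "RegimeSchedule",
    "Recording",
    "make_grid",
    "synthesize",
    "inject_artifact",
]

MAX_SPATIAL_FREQ = 90.0  # deg/mm; spatial Nyquist ceiling for a 2 mm pitch


@dataclass(frozen=True)
class GridGeometry:
    """Electrode layout: 2D coordinates (mm), pitch, bad-channel mask.

    x runs along the long (septotemporal) axis, increasing with column
    index (posterior -> anterior by convention); y runs along the
    transverse axis, increasing with row index.
    """

    coords: np.ndarray  # (n_electrodes, 2) in mm
    pitch: float
    n_rows: int
    n_cols: int
    bad_channels: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2 or not np.all(np.isfinite(coords)):
            raise ValueError("coords must be a finite (n, 2) array")
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")
        object.__setattr__(self, "coords", coords)
        bad = frozenset(int(b) for b in self.bad_channels)
        if any(b < 0 or b >= len(coords) for b in bad):
            raise ValueError("bad_channels outside electrode index range")
        object.__setattr__(self, "bad_channels", bad)

    @property
    def n_electrodes(self) -> int:
        return len(self.coords)

    @property
    def usable(self) -> np.ndarray:
        """Indices of electrodes not flagged bad, in ascending order."""
        return np.array(
            [i for i in range(self.n_electrodes) if i not in self.bad_channels],
            dtype=int,
        )

    def with_bad_channels(self, bad: set[int]) -> "GridGeometry":
        return replace(self, bad_channels=frozenset(bad))


@dataclass(frozen=True)
class WaveComponent:
    """One planted plane-wave oscillation."""

    center_freq: float  # Hz
    direction: float  # deg in [0, 360), direction of travel
    spatial_freq: float  # deg/mm
    amplitude: float = 1.0  # a.u. (uV)
    amp_topography: np.ndarray | None = None  # per-electrode gain, unit mean
    phase0: float = 0.0  # deg

    def __post_init__(self) -> None:
        if not 0 < self.spatial_freq <= MAX_SPATIAL_FREQ:
            raise ValueError(
                f"spatial_freq must be in (0, {MAX_SPATIAL_FREQ}] deg/mm"
            )
        if not 0 < self.center_freq <= 32:
            raise ValueError("center_freq must be in (0, 32] Hz")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        object.__setattr__(self, "direction", float(self.direction) % 360.0)

    def gains(self, n_electrodes: int) -> np.ndarray:
        if self.amp_topography is None:
            return np.ones(n_electrodes)
        g = np.asarray(self.amp_topography, dtype=float)
        if g.shape != (n_electrodes,):
            raise ValueError("amp_topography length must match electrode count")
        if np.any(g < 0):
            raise ValueError("amp_topography gains must be non-negative")
        return g / g.mean()  # normalise to unit mean


@dataclass(frozen=True)
class RegimeSchedule:
    """Which components are active when, plus task-trial structure.

    ``segments`` is an ordered list of (start_s, end_s, component_ids):
    within a segment only the listed components (indices into the component
    list handed to :func:`synthesize`) oscillate. ``trial_events`` carry
    (time_s, label); if ``task_component`` is set, then within
    ``align_window_s`` relative to each event the wave adopts that
    component's direction with probability ``align_prob`` per trial,
    overriding the segment schedule — emulating post-event direction
    alignment across trials.
    """

    segments: tuple = ()  # ((start_s, end_s, (ids,)), ...)
    trial_events: tuple = ()  # ((time_s, label), ...)
    align_window_s: tuple[float, float] = (0.0, 0.0)
    align_prob: float = 0.0
    task_component: int | None = None

    def __post_init__(self) -> None:
        segs = tuple(
            (float(s), float(e), tuple(int(c) for c in cs))
            for s, e, cs in self.segments
        )
        for s, e, _ in segs:
            if e <= s:
                raise ValueError("segment end must exceed start")
        for (s0, e0, _), (s1, e1, _) in zip(segs, segs[1:]):
            if s1 < e0:
                raise ValueError("segments must be non-overlapping and time-ordered")
        object.__setattr__(self, "segments", segs)
        object.__setattr__(
            self,
            "trial_events",
            tuple((float(t), str(lbl)) for t, lbl in self.trial_events),
        )
        if not 0.0 <= self.align_prob <= 1.0:
            raise ValueError("align_prob must be in [0, 1]")


@dataclass
class Recording:
    """Channels x samples LFP matrix with geometry and annotations.

    ``annotations`` is a list of (start_s, end_s, label) intervals;
    labels in use are ``"artifact"`` and ``"trial"``.
    """

    data: np.ndarray  # (n_channels, n_samples), uV
    fs: float
    geometry: GridGeometry
    annotations: list[tuple[float, float, str]] = field(default_factory=list)
    events: list[tuple[float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2D (channels x samples)")
        if self.data.shape[0] != self.geometry.n_electrodes:
            raise ValueError("data row count must equal electrode count")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.data.shape[1]) / self.fs

    def artifact_intervals(self) -> list[tuple[float, float]]:
        return [(s, e) for s, e, lbl in self.annotations if lbl == "artifact"]


def make_grid(
    n_rows: int, n_cols: int, pitch: float = 2.0, bad: set[int] | None = None
) -> GridGeometry:
    """Regular lattice of ``n_rows`` x ``n_cols`` electrodes at ``pitch`` mm.

    Electrode 0 sits at the origin; index increases along columns first
    (row-major), x along columns and y along rows.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("grid dimensions must be >= 1")
    if pitch <= 0:
        raise ValueError("pitch must be positive")
    rows, cols = np.mgrid[0:n_rows, 0:n_cols]
    coords = np.column_stack([cols.ravel() * pitch, rows.ravel() * pitch])
    return GridGeometry(
        coords=coords,
        pitch=float(pitch),
        n_rows=int(n_rows),
        n_cols=int(n_cols),
        bad_channels=frozenset(bad or ()),
    )


def _one_over_f_noise(
    rng: np.random.Generator, n_samples: int, fs: float, exponent: float
) -> np.ndarray:
    """Unit-SD noise with power spectrum proportional to 1/f^exponent."""
    white = rng.standard_normal(n_samples)
    if exponent == 0:
        return white
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    # amplitude shaping: power ~ f^-exponent  =>  amplitude ~ f^(-exponent/2);
    # the DC bin is zeroed rather than amplified
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    shaped = np.fft.irfft(spec * shape, n=n_samples)
    sd = shaped.std()
    return shaped / sd if sd > 0 else shaped


def _activity_matrix(
    schedule: RegimeSchedule,
    n_components: int,
    times: np.ndarray,
    rng: np.random.Generator,
    ramp_s: float,
) -> np.ndarray:
    """Per-component activation envelope in [0, 1] over time.

    Segment edges get raised-cosine ramps of ``ramp_s`` seconds to limit
    broadband switching transients. Trial alignment windows override the
    segment schedule for aligned trials.
    """
    act = np.zeros((n_components, times.size))
    if not schedule.segments:
        act[:] = 1.0
    else:
        for start, end, ids in schedule.segments:
            env = _window_envelope(times, start, end, ramp_s)
            for cid in ids:
                act[cid] = np.maximum(act[cid], env)
    if schedule.task_component is not None and schedule.trial_events:
        w0, w1 = schedule.align_window_s
        for t_ev, _lbl in schedule.trial_events:
            if rng.random() >= schedule.align_prob:
                continue
            env = _window_envelope(times, t_ev + w0, t_ev + w1, ramp_s)
            inside = env > 0
            act[:, inside] *= 1.0 - env[inside]
            act[schedule.task_component, inside] = np.maximum(
                act[schedule.task_component, inside], env[inside]
            )
    return act


def _window_envelope(
    times: np.ndarray, start: float, end: float, ramp_s: float
) -> np.ndarray:
    env = np.zeros_like(times)
    inside = (times >= start) & (times < end)
    env[inside] = 1.0
    if ramp_s > 0:
        rise = (times >= start) & (times < start + ramp_s)
        env[rise] = 0.5 * (1 - np.cos(np.pi * (times[rise] - start) / ramp_s))
        fall = (times >= end - ramp_s) & (times < end)
        env[fall] = np.minimum(
            env[fall], 0.5 * (1 - np.cos(np.pi * (end - times[fall]) / ramp_s))
        )
    return env


def synthesize(
    geometry: GridGeometry,
    components: list[WaveComponent],
    schedule: RegimeSchedule | None = None,
    aperiodic_exponent: float = 2.0,
    noise_sd: float = 1.0,
    duration_s: float = 60.0,
    fs: float = 512.0,
    seed: int = 0,
    ramp_s: float = 0.1,
) -> Recording:
    """Render a Recording with planted plane waves plus 1/f background.

    The background is generated independently per channel (no spatial
    correlation) by spectrally shaping white noise to 1/f^exponent and
    scaling it to ``noise_sd``. The same seed and parameters always yield
    a bit-identical Recording.
    """
    schedule = schedule or RegimeSchedule()
    for comp in components:
        if comp.center_freq * 2 >= fs:
            raise ValueError("fs must exceed twice the highest synthesized frequency")
    if schedule.segments and schedule.segments[-1][1] > duration_s + 1e-9:
        raise ValueError("duration must cover the schedule")
    rng = np.random.default_rng(seed)
    n_samples = int(round(duration_s * fs))
    times = np.arange(n_samples) / fs
    n_elec = geometry.n_electrodes
    data = np.zeros((n_elec, n_samples))

    activity = _activity_matrix(schedule, len(components), times, rng, ramp_s)
    for ci, comp in enumerate(components):
        k_rad = comp.spatial_freq * np.pi / 180.0  # rad/mm
        theta = np.deg2rad(comp.direction)
        proj = geometry.coords @ np.array([np.cos(theta), np.sin(theta)])  # mm
        gains = comp.gains(n_elec)
        phase = (
            2 * np.pi * comp.center_freq * times[None, :]
            - k_rad * proj[:, None]
            + np.deg2rad(comp.phase0)
        )
        data += (
            comp.amplitude
            * gains[:, None]
            * activity[ci][None, :]
            * np.cos(phase)
        )
    if noise_sd > 0:
        for ch in range(n_elec):
            data[ch] += noise_sd * _one_over_f_noise(
                rng, n_samples, fs, aperiodic_exponent
            )
    events = [(t, lbl) for t, lbl in schedule.trial_events]
    return Recording(data=data, fs=fs, geometry=geometry, events=events)


def _merge_intervals(
    intervals: list[tuple[float, float]]
) -> list[tuple[float, float]]:
    merged: list[list[float]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def inject_artifact(
    rec: Recording,
    windows: list[tuple[float, float]],
    kind: str = "step",
    magnitude_uv: float = 500.0,
) -> Recording:
    """Superimpose large transients (electrode pops / cable movement).

    ``step`` adds a DC jump of ``magnitude_uv`` across all channels inside
    each window; ``highfreq`` adds a large-amplitude fast oscillation.
    Windows are annotated (overlaps merged) so downstream screening can be
    validated against ground truth.
    """
    if kind not in ("step", "highfreq"):
        raise ValueError("kind must be 'step' or 'highfreq'")
    if not windows:
        return rec
    for s, e in windows:
        if s < 0 or e > rec.duration_s or e <= s:
            raise ValueError("artifact windows must lie within the recording")
    data = rec.data.copy()
    t = rec.times
    for s, e in windows:
        mask = (t >= s) & (t < e)
        if kind == "step":
            # alternate sign each sample: maximal line length for a given
            # magnitude, mimicking an electrode pop
            burst = magnitude_uv * np.where(np.arange(mask.sum()) % 2 == 0, 1.0, -1.0)
            data[:, mask] += burst[None, :]
        else:
            data[:, mask] += magnitude_uv * np.sin(
                2 * np.pi * 80.0 * t[mask]
            )[None, :]
    annotations = list(rec.annotations) + [
        (s, e, "artifact") for s, e in _merge_intervals(windows)
    ]
    # re-merge artifact annotations across old and new
    art = _merge_intervals([(s, e) for s, e, lbl in annotations if lbl == "artifact"])
    other = [a for a in annotations if a[2] != "artifact"]
    return Recording(
        data=data,
        fs=rec.fs,
        geometry=rec.geometry,
        annotations=other + [(s, e, "artifact") for s, e in art],
        events=list(rec.events),
    )
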