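"""Plane-wave fitting of band-limited phase fields.

For one center frequency the recording is band-passed (center +/- 1.5 Hz),
Hilbert-transformed, and resampled to the analysis rate. At each timepoint
the per-electrode phases phi_i are fit to a traveling plane wave

    phi_i  ~  phi0 - k_rad * (x_i * cos(theta) + y_i * sin(theta))

by exhaustive search over a lattice of directions theta (1 deg steps over
360 deg) and spatial frequencies k (1 deg/mm steps up to 90 deg/mm, the
spatial Nyquist limit of a 2 mm pitch). theta is the direction of travel
(phase decreases along it). The fit score maximized on the lattice is the
mean resultant length of the phase residuals; the reported goodness of fit
R^2 is the squared circular-circular correlation between observed and
fitted phases. Per-timepoint validity requires the observed R^2 to exceed
a percentile of an electrode-location-shuffle null distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal

from .synth import GridGeometry, Recording

__all__ = [
    "AnalyticBand",
    "WaveFit",
    "WaveFitSeries",
    "extract_band",
    "fit_plane_wave",
    "permutation_null",
    "fit_series",
    "circ_corr",
    "wavelength_mm",
    "wave_speed_mm_s",
    "spatial_nyquist_deg_per_mm",
]

MIN_ELECTRODES = 8  # minimum usable electrodes for a plane-wave fit
DIRECTION_STEP_DEG = 1.0
K_STEP_DEG_MM = 1.0
K_MAX_DEG_MM = 90.0


def wavelength_mm(spatial_freq_deg_mm: float) -> float:
    """Wavelength (mm) of a plane wave with spatial frequency in deg/mm.

    One full cycle is 360 deg of phase, so lambda = 360 / k. In radian
    units this is the usual lambda = 2*pi / k_rad.
    """
    return 360.0 / spatial_freq_deg_mm


def wave_speed_mm_s(spatial_freq_deg_mm: float, freq_hz: float) -> float:
    """Propagation speed (mm/s): wavelength times temporal frequency."""
    return wavelength_mm(spatial_freq_deg_mm) * freq_hz


def spatial_nyquist_deg_per_mm(pitch_mm: float) -> float:
    """Highest resolvable spatial frequency for a given electrode pitch.

    Phase can advance at most half a cycle (180 deg) between adjacent
    electrodes, giving 180 / pitch deg/mm — 90 deg/mm at 2 mm pitch,
    the ceiling of the search lattice.
    """
    return 180.0 / pitch_mm


@dataclass
class AnalyticBand:
    """Per-channel analytic amplitude and phase for one center frequency."""

    center_freq: float
    bandwidth: float  # Hz, full width (default 3 => center +/- 1.5)
    amplitude: np.ndarray  # (channels, timepoints), z-scored per channel
    phase: np.ndarray  # (channels, timepoints), radians in (-pi, pi]
    fs_analysis: float
    valid_mask: np.ndarray  # (timepoints,), bool
    raw_amplitude_mean: np.ndarray | None = None  # channel-mean envelope, pre-z

    @property
    def n_timepoints(self) -> int:
        return self.phase.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_timepoints) / self.fs_analysis


@dataclass
class WaveFit:
    """Plane-wave parameters at a single timepoint."""

    direction: float  # deg, direction of travel; NaN if undefined
    spatial_freq: float  # deg/mm
    phase_offset: float  # deg
    r2: float
    wavelength: float  # mm, = 360 / spatial_freq
    speed: float  # mm/s, = wavelength * center_freq
    null_threshold: float = np.nan
    is_valid: bool = False
    score: float = np.nan  # mean resultant length of residuals at optimum


@dataclass
class WaveFitSeries:
    """Per-timepoint plane-wave fits at the analysis rate."""

    center_freq: float
    fs_analysis: float
    t: np.ndarray
    direction: np.ndarray  # deg
    spatial_freq: np.ndarray  # deg/mm
    phase_offset: np.ndarray  # deg
    r2: np.ndarray
    wavelength: np.ndarray  # mm
    speed: np.ndarray  # mm/s
    null_threshold: np.ndarray
    valid: np.ndarray  # bool
    extras: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.t.size

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t": self.t,
                "direction_deg": self.direction,
                "k_deg_per_mm": self.spatial_freq,
                "r2": self.r2,
                "wavelength_mm": self.wavelength,
                "speed_mm_s": self.speed,
                "valid": self.valid,
            }
        )


# ---------------------------------------------------------------------------
# band extraction
# ---------------------------------------------------------------------------

def _resample_complex(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Polyphase (anti-aliased) resampling of a complex analytic signal."""
    frac = Fraction(fs_out / fs_in).limit_denominator(10000)
    up, down = frac.numerator, frac.denominator
    if up == down:
        return x
    return signal.resample_poly(x.real, up, down, axis=-1) + 1j * signal.resample_poly(
        x.imag, up, down, axis=-1
    )


def extract_band(
    rec: Recording,
    center_freq: float,
    fs_analysis: float = 30.0,
    bandwidth: float = 3.0,
    amp_percentile: float = 10.0,
    min_cycles: float = 3.0,
) -> AnalyticBand:
    """Band-pass + Hilbert transform around a center frequency.

    Zero-phase Butterworth band-pass at center +/- bandwidth/2, analytic
    signal per channel, resampled (anti-aliased polyphase) to the analysis
    rate. Amplitude is z-scored within channel across the whole block.

    Low-power gating: the channel-mean raw envelope is thresholded at its
    ``amp_percentile`` percentile; timepoints below it, or inside a
    contiguous above-threshold run shorter than ``min_cycles / center_freq``
    seconds, are marked invalid.
    """
    half = bandwidth / 2.0
    lo, hi = center_freq - half, center_freq + half
    if lo <= 0:
        raise ValueError("band lower edge must be positive")
    if hi >= rec.fs / 2:
        raise ValueError("band upper edge must be below Nyquist")
    if fs_analysis <= 2 * center_freq:
        raise ValueError("fs_analysis must exceed twice the center frequency")
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=rec.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.data, axis=1)
    analytic = signal.hilbert(filtered, axis=1)
    analytic = _resample_complex(analytic, rec.fs, fs_analysis)
    amp_raw = np.abs(analytic)
    phase = np.angle(analytic)
    mu = amp_raw.mean(axis=1, keepdims=True)
    sd = amp_raw.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    amp_z = (amp_raw - mu) / sd

    mean_env = amp_raw[rec.geometry.usable].mean(axis=0)
    thresh = np.percentile(mean_env, amp_percentile)
    above = mean_env > thresh
    min_run = int(np.ceil(min_cycles / center_freq * fs_analysis))
    valid = _runs_at_least(above, min_run)

    # artifact intervals invalidate their timepoints outright
    t = np.arange(valid.size) / fs_analysis
    for s, e in rec.artifact_intervals():
        valid &= ~((t >= s) & (t < e))

    return AnalyticBand(
        center_freq=center_freq,
        bandwidth=bandwidth,
        amplitude=amp_z,
        phase=phase,
        fs_analysis=fs_analysis,
        valid_mask=valid,
        raw_amplitude_mean=mean_env,
    )


def _runs_at_least(above: np.ndarray, min_run: int) -> np.ndarray:
    """True where the surrounding contiguous True-run has length >= min_run."""
    valid = np.zeros_like(above)
    n = above.size
    i = 0
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            if j - i >= min_run:
                valid[i:j] = True
            i = j
        else:
            i += 1
    return valid


# ---------------------------------------------------------------------------
# lattice machinery
# ---------------------------------------------------------------------------

class _Lattice:
    """Precomputed search lattice for a fixed set of electrode coordinates.

    Rows of the design matrix hold exp(+1j * k_rad * proj(theta)) for every
    (theta, k) pair, so that for unit phasors E_i = exp(1j * phi_i) the
    residual mean resultant length at (theta, k) is |row . E| / n — the
    quantity maximized by the search. complex64 keeps the (32400, n) matrix
    small and routes the scoring through a single BLAS matmul.
    """

    def __init__(self, coords: np.ndarray):
        self.coords = np.asarray(coords, dtype=float)
        self.dirs = np.arange(0.0, 360.0, DIRECTION_STEP_DEG)
        self.ks = np.arange(K_STEP_DEG_MM, K_MAX_DEG_MM + 1e-9, K_STEP_DEG_MM)
        th = np.deg2rad(self.dirs)
        proj = self.coords @ np.vstack([np.cos(th), np.sin(th)])  # (n, D)
        k_rad = self.ks * np.pi / 180.0  # (K,)
        # phase model: phi_i = phi0 - k_rad * proj_i(theta)
        # residual phasor uses +k_rad * proj so that |sum E_i * W_i| peaks
        # at the true (theta, k)
        expo = k_rad[:, None, None] * proj.T[None, :, :]  # (K, D, n)
        self.W = np.exp(1j * expo).reshape(-1, self.coords.shape[0]).astype(
            np.complex64
        )  # (K*D, n)
        # index ordering: row = ki * D + di; ties toward smaller k then
        # smaller theta are honoured by taking the first argmax in this order
        self.n = self.coords.shape[0]

    def scores(self, phasors: np.ndarray) -> np.ndarray:
        """|W @ E| / n for unit phasors E of shape (n,) or (n, m)."""
        return np.abs(self.W @ phasors.astype(np.complex64)) / self.n

    def best(self, phasors: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(theta_deg, k, score) of the lattice maximum per column."""
        prod = self.W @ phasors.astype(np.complex64)
        sc2 = prod.real**2 + prod.imag**2  # defer sqrt to the maximum only
        flat = np.argmax(sc2, axis=0)
        ki, di = np.divmod(flat, self.dirs.size)
        best = np.sqrt(np.take_along_axis(sc2, flat[None, ...], axis=0)[0]) / self.n
        return self.dirs[di], self.ks[ki], best


_lattice_cache: dict[bytes, _Lattice] = {}


def _get_lattice(coords: np.ndarray) -> _Lattice:
    key = np.ascontiguousarray(coords).tobytes()
    lat = _lattice_cache.get(key)
    if lat is None:
        lat = _Lattice(coords)
        if len(_lattice_cache) > 8:
            _lattice_cache.clear()
        _lattice_cache[key] = lat
    return lat


def circ_corr(alpha: np.ndarray, beta: np.ndarray) -> float:
    """Circular-circular correlation (Jammalamadaka-SenGupta).

    Returns 0 when either sample has no angular dispersion (the
    correlation is undefined there; 0 is the no-information convention).
    """
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    a = np.angle(np.exp(1j * alpha).mean())
    b = np.angle(np.exp(1j * beta).mean())
    sa = np.sin(alpha - a)
    sb = np.sin(beta - b)
    denom = np.sqrt((sa**2).sum() * (sb**2).sum())
    if denom == 0:
        return 0.0
    return float((sa * sb).sum() / denom)


def _fit_one(
    phases: np.ndarray, coords: np.ndarray, center_freq: float
) -> WaveFit:
    lat = _get_lattice(coords)
    E = np.exp(1j * phases)
    # spatially uniform phase: no gradient, direction undefined
    if np.allclose(np.angle(E / E[0]), 0.0, atol=1e-9):
        return WaveFit(
            direction=np.nan,
            spatial_freq=0.0,
            phase_offset=float(np.rad2deg(np.angle(E[0]))),
            r2=0.0,
            wavelength=np.inf,
            speed=np.inf,
            score=1.0,
        )
    theta, k, score = lat.best(E[:, None])
    theta, k, score = float(theta[0]), float(k[0]), float(score[0])
    k_rad = k * np.pi / 180.0
    th = np.deg2rad(theta)
    proj = coords @ np.array([np.cos(th), np.sin(th)])
    offset = float(np.angle((E * np.exp(1j * k_rad * proj)).mean()))
    predicted = offset - k_rad * proj
    r2 = circ_corr(phases, predicted) ** 2
    wavelength = 360.0 / k
    return WaveFit(
        direction=theta,
        spatial_freq=k,
        phase_offset=float(np.rad2deg(offset)),
        r2=float(r2),
        wavelength=wavelength,
        speed=wavelength * center_freq,
        score=score,
    )


def fit_plane_wave(
    phases: np.ndarray,
    geometry: GridGeometry,
    center_freq: float = 1.0,
) -> WaveFit:
    """Fit a traveling plane wave to one timepoint's electrode phases.

    ``phases`` are radians per electrode (full grid indexing); bad channels
    and non-finite phases are dropped. Requires >= 8 usable electrodes.
    Lattice ties resolve toward smaller spatial frequency, then smaller
    direction angle. ``center_freq`` only scales the reported speed.
    """
    phases = np.asarray(phases, dtype=float)
    usable = [i for i in geometry.usable if np.isfinite(phases[i])]
    if len(usable) < MIN_ELECTRODES:
        raise ValueError(
            f"plane-wave fit needs >= {MIN_ELECTRODES} usable electrodes, "
            f"got {len(usable)}"
        )
    return _fit_one(phases[usable], geometry.coords[usable], center_freq)


def permutation_null(
    phases: np.ndarray,
    geometry: GridGeometry,
    n_iter: int = 200,
    percentile: float = 99.0,
    seed: int | np.random.Generator = 0,
    center_freq: float = 1.0,
) -> float:
    """Electrode-location-shuffle null threshold for the fit R^2.

    The electrode-to-coordinate assignment is permuted ``n_iter`` times,
    the full lattice fit is repeated on each permutation, and the stated
    percentile of the shuffled R^2 values is returned.
    """
    if n_iter < 20:
        warnings.warn("n_iter < 20 gives an unstable null percentile", stacklevel=2)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    phases = np.asarray(phases, dtype=float)
    usable = [i for i in geometry.usable if np.isfinite(phases[i])]
    coords = geometry.coords[usable]
    ph = phases[usable]
    null_r2 = _null_r2(ph, coords, n_iter, rng)
    return float(np.percentile(null_r2, percentile))


def _circ_corr_cols(alpha: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Columnwise circular-circular correlation of (n, m) angle arrays."""
    a = np.angle(np.exp(1j * alpha).mean(axis=0))
    b = np.angle(np.exp(1j * beta).mean(axis=0))
    sa = np.sin(alpha - a[None, :])
    sb = np.sin(beta - b[None, :])
    denom = np.sqrt((sa**2).sum(axis=0) * (sb**2).sum(axis=0))
    num = (sa * sb).sum(axis=0)
    out = np.zeros(alpha.shape[1])
    ok = denom > 0
    out[ok] = num[ok] / denom[ok]
    return out


def _null_r2(
    ph: np.ndarray, coords: np.ndarray, n_iter: int, rng: np.random.Generator
) -> np.ndarray:
    """Shuffled-electrode R^2 samples for one timepoint's phases."""
    lat = _get_lattice(coords)
    n = ph.size
    perms = rng.permuted(
        np.broadcast_to(np.arange(n), (n_iter, n)), axis=1
    )  # (m, n)
    obs = ph[perms.T]  # (n, m): column j = permuted phases
    E = np.exp(1j * obs)
    theta, k, _score = lat.best(E)
    th = np.deg2rad(theta)
    k_rad = k * np.pi / 180.0
    proj = coords @ np.vstack([np.cos(th), np.sin(th)])  # (n, m)
    arg = E * np.exp(1j * k_rad[None, :] * proj)
    offset = np.angle(arg.mean(axis=0))  # (m,)
    predicted = offset[None, :] - k_rad[None, :] * proj  # (n, m)
    return _circ_corr_cols(obs, predicted) ** 2


def fit_series(
    band: AnalyticBand,
    geometry: GridGeometry,
    null_iters: int = 200,
    ci_percent: float = 99.0,
    seed: int = 0,
    fit_invalid: bool = True,
) -> WaveFitSeries:
    """Plane-wave fit at every timepoint of an analytic band.

    The permutation null (and hence validity) is evaluated only at
    timepoints passing the band's amplitude gate; gated timepoints carry
    ``valid = False`` (their fits are still reported when
    ``fit_invalid``, matching the per-timepoint direction traces used in
    event-locked analyses).
    """
    usable = geometry.usable
    coords = geometry.coords[usable]
    if usable.size < MIN_ELECTRODES:
        raise ValueError("need >= 8 usable electrodes")
    lat = _get_lattice(coords)
    T = band.n_timepoints
    phases = band.phase[usable]  # (n, T)
    E = np.exp(1j * phases)
    theta, k, score = lat.best(E)  # (T,) each

    th = np.deg2rad(theta)
    k_rad = k * np.pi / 180.0
    proj = coords @ np.vstack([np.cos(th), np.sin(th)])  # (n, T)
    offset = np.angle((E * np.exp(1j * k_rad[None, :] * proj)).mean(axis=0))
    r2 = _circ_corr_cols(phases, offset[None, :] - k_rad[None, :] * proj) ** 2

    rng = np.random.default_rng(seed)
    null_thr = np.full(T, np.nan)
    valid = np.zeros(T, dtype=bool)
    for t in range(T):
        if not band.valid_mask[t]:
            continue
        nr2 = _null_r2(phases[:, t], coords, null_iters, rng)
        null_thr[t] = np.percentile(nr2, ci_percent)
        valid[t] = r2[t] > null_thr[t]

    if not fit_invalid:
        theta = np.where(band.valid_mask, theta, np.nan)
    wavelength = 360.0 / k
    return WaveFitSeries(
        center_freq=band.center_freq,
        fs_analysis=band.fs_analysis,
        t=band.times,
        direction=theta.astype(float),
        spatial_freq=k.astype(float),
        phase_offset=np.rad2deg(offset),
        r2=r2,
        wavelength=wavelength,
        speed=wavelength * band.center_freq,
        null_threshold=null_thr,
        valid=valid,
        extras={"score": score, "amp_gate": band.valid_mask.copy()},
    )
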