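"""Oscillation-peak discovery from wavelet spectra.

The preferred oscillation frequencies of a recording are found channel by
channel: a Morlet wavelet spectrum (log-spaced frequencies, 1-32 Hz) is
time-averaged, the aperiodic 1/f trend is removed by a robust straight-line
fit in log-log coordinates, the residuals are z-scored, and local maxima
above +1 SD count as channel peaks. Channel peaks that cluster within a
2 Hz band on at least five electrodes form a consensus peak whose center is
the mean of the member peak frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
import statsmodels.api as sm

from .synth import Recording

__all__ = [
    "ChannelSpectrum",
    "ConsensusPeak",
    "wavelet_spectrum",
    "detrend_and_score",
    "find_consensus_peaks",
]

#: complex Morlet mother wavelet: bandwidth 1.5, center frequency 1.0.
#: Fixed for reproducibility; the log frequency grid supplies 42 voices
#: per octave over the 5 octaves between 1 and 32 Hz (211 frequencies).
MORLET_WAVELET = "cmor1.5-1.0"


@dataclass
class ChannelSpectrum:
    """Time-averaged wavelet power for one channel, with detrended z-scores."""

    channel: int
    freqs: np.ndarray  # Hz, log-spaced, strictly increasing
    power: np.ndarray  # mean wavelet power per frequency
    adjusted_z: np.ndarray | None = None  # residual z-scores after detrending

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")


@dataclass
class ConsensusPeak:
    """A preferred center frequency shared by >= min_channels electrodes."""

    center_freq: float
    member_channels: tuple[int, ...]
    member_peak_freqs: tuple[float, ...]


def _time_average_mask(
    n_samples: int, fs: float, artifact_intervals: list[tuple[float, float]]
) -> np.ndarray:
    keep = np.ones(n_samples, dtype=bool)
    t = np.arange(n_samples) / fs
    for s, e in artifact_intervals:
        keep &= ~((t >= s) & (t < e))
    return keep


def wavelet_spectrum(
    rec: Recording,
    n_freqs: int = 211,
    fmin: float = 1.0,
    fmax: float = 32.0,
) -> list[ChannelSpectrum]:
    """Morlet wavelet power spectrum, time-averaged per usable channel.

    Frequencies are logarithmically spaced between ``fmin`` and ``fmax``
    (defaults give 42 voices per octave over 1-32 Hz). Artifact-annotated
    intervals are excluded from the time average.
    """
    if fmax >= rec.fs / 2:
        raise ValueError("fmax must be below the Nyquist frequency")
    if fmin <= 0 or fmax <= fmin or n_freqs < 2:
        raise ValueError("need 0 < fmin < fmax and n_freqs >= 2")
    freqs = np.logspace(np.log10(fmin), np.log10(fmax), n_freqs)
    dt = 1.0 / rec.fs
    scales = pywt.frequency2scale(MORLET_WAVELET, freqs * dt)
    n_samples = rec.data.shape[1]
    keep = _time_average_mask(n_samples, rec.fs, rec.artifact_intervals())
    # cone of influence: the cmorB-C envelope is exp(-t^2/B), so the wavelet
    # at scale s has temporal sigma = s*sqrt(B/2) samples; samples closer
    # than 2 sigma to either edge are excluded from that frequency's average
    bw = float(MORLET_WAVELET.split("cmor")[1].split("-")[0])
    coi = np.minimum(
        (2.0 * scales * np.sqrt(bw / 2.0)).astype(int), n_samples // 2 - 1
    )
    spectra = []
    for ch in rec.geometry.usable:
        x = rec.data[ch] - rec.data[ch].mean()  # remove DC leakage
        coefs, _ = pywt.cwt(x, scales, MORLET_WAVELET,
                            sampling_period=dt, method="fft")
        power = np.empty(n_freqs)
        for fi in range(n_freqs):
            m = keep.copy()
            c = coi[fi]
            if c > 0:
                m[:c] = False
                m[-c:] = False
            power[fi] = (np.abs(coefs[fi, m]) ** 2).mean()
        spectra.append(ChannelSpectrum(channel=int(ch), freqs=freqs, power=power))
    return spectra


def detrend_and_score(spec: ChannelSpectrum) -> ChannelSpectrum:
    """Remove the 1/f trend and z-score the residual spectrum.

    A robust line (iteratively reweighted least squares, Tukey bisquare)
    is fit to log power vs log frequency, subtracted, and the residuals
    are standardized to zero mean / unit SD (``adjusted_z``).
    """
    if np.any(spec.power <= 0):
        raise ValueError("power must be strictly positive for log detrending")
    logf = np.log10(spec.freqs)
    logp = np.log10(spec.power)
    X = sm.add_constant(logf)
    import warnings as _warnings

    with _warnings.catch_warnings():
        # an exact power law drives the robust scale to zero; harmless here
        _warnings.simplefilter("ignore")
        fit = sm.RLM(logp, X, M=sm.robust.norms.TukeyBiweight()).fit()
    resid = logp - fit.predict(X)
    sd = resid.std()
    if sd < 1e-9 * max(1.0, np.abs(logp).max()):
        # trend captured the spectrum exactly: no oscillatory structure
        z = np.zeros_like(resid)
    else:
        z = (resid - resid.mean()) / sd
    return ChannelSpectrum(
        channel=spec.channel, freqs=spec.freqs, power=spec.power, adjusted_z=z
    )


def _local_maxima(z: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima; plateau ties break toward lower frequency."""
    idx = []
    n = z.size
    i = 1
    while i < n - 1:
        if z[i] > z[i - 1]:
            j = i
            while j + 1 < n and z[j + 1] == z[j]:
                j += 1
            if j + 1 < n and z[j + 1] < z[j]:
                idx.append(i)  # lower-frequency edge of the plateau
            i = j + 1
        else:
            i += 1
    return np.array(idx, dtype=int)


def find_consensus_peaks(
    specs: list[ChannelSpectrum],
    z_thresh: float = 1.0,
    bandwidth: float = 2.0,
    min_channels: int = 5,
) -> list[ConsensusPeak]:
    """Cluster per-channel spectral peaks into grid-consensus frequencies.

    Channel peaks are local maxima of ``adjusted_z`` above ``z_thresh``.
    Clustering is greedy: the strongest unassigned peak seeds a cluster
    which absorbs, per channel, the nearest unassigned peak within
    +/- bandwidth/2 of the seed (total span <= bandwidth). Clusters with
    at least ``min_channels`` distinct channels are returned, strongest
    first, with center_freq = mean of member peak frequencies.
    """
    if not specs:
        raise ValueError("no spectra supplied")
    peaks = []  # (z, freq, channel)
    for spec in specs:
        z = spec.adjusted_z
        if z is None:
            spec = detrend_and_score(spec)
            z = spec.adjusted_z
        for i in _local_maxima(z):
            if z[i] > z_thresh:
                peaks.append((float(z[i]), float(spec.freqs[i]), spec.channel))
    peaks.sort(reverse=True)
    assigned = [False] * len(peaks)
    consensus = []
    half = bandwidth / 2.0
    for seed_i, (seed_z, seed_f, _seed_ch) in enumerate(peaks):
        if assigned[seed_i]:
            continue
        members: dict[int, tuple[float, float, int]] = {}  # channel -> (z, f, idx)
        for j, (z, f, ch) in enumerate(peaks):
            if assigned[j] or abs(f - seed_f) > half:
                continue
            if ch not in members or abs(f - seed_f) < abs(members[ch][1] - seed_f):
                members[ch] = (z, f, j)
        if len(members) >= min_channels:
            for _, (_, _, j) in members.items():
                assigned[j] = True
            chans = tuple(sorted(members))
            mfreqs = tuple(members[ch][1] for ch in chans)
            consensus.append(
                ConsensusPeak(
                    center_freq=float(np.mean(mfreqs)),
                    member_channels=chans,
                    member_peak_freqs=mfreqs,
                )
            )
        else:
            assigned[seed_i] = True  # seed cannot anchor a consensus
    consensus.sort(key=lambda p: p.center_freq)
    return consensus
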