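"""Configuration, I/O, artifact screening, electrode subsetting and
end-to-end orchestration.

The native on-disk container is an HDF5 matrix (channels x samples) with a
JSON sidecar carrying sampling rate, electrode coordinates, bad channels
and annotations. The pipeline runs: consensus-peak discovery -> band
extraction -> per-timepoint plane-wave fits with permutation validity ->
direction distributions -> (optional) event-locked DC -> (optional)
direction classifier for bimodal frequencies.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import h5py
import numpy as np

from . import classify as _classify
from . import dirstats as _dirstats
from . import spectral as _spectral
from . import trials as _trials
from . import wavefit as _wavefit
from .synth import GridGeometry, Recording

__all__ = [
    "PipelineConfig",
    "write_recording",
    "read_recording",
    "line_length_screen",
    "subsample_electrodes",
    "rotate_geometry",
    "run_pipeline",
]

logger = logging.getLogger("gridwave")


@dataclass
class PipelineConfig:
    """Analysis defaults.

    Each default is the value used throughout the analysis: the 1-32 Hz
    spectral band sampled at 211 log-spaced wavelet frequencies; 30 Hz
    analysis rate for baseline wave fits (above twice the highest wave
    frequency studied) and 100 Hz for event-locked trial data; 3 Hz
    (center +/- 1.5) extraction bandwidth; lowest-decile amplitude gate
    with a 3-cycle minimum run; 200-iteration electrode-shuffle null at
    the 99th percentile; 10 deg direction bins smoothed over 60 deg with
    the 25% secondary-peak bimodality rule; 45 deg angle-split wedges;
    10,000-iteration label-shuffle SVM null.
    """

    band_hz: tuple[float, float] = (1.0, 32.0)
    n_wavelet_freqs: int = 211
    analysis_fs: float = 30.0
    trial_fs: float = 100.0
    bandwidth_hz: float = 3.0
    amp_percentile: float = 10.0
    min_cycles: float = 3.0
    null_iters: int = 200
    ci_percent: float = 99.0
    bins_deg: float = 10.0
    smooth_deg: float = 60.0
    bimodal_frac: float = 0.25
    split_halfwidth_deg: float = 45.0
    svm_null_iters: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 50 < self.ci_percent < 100:
            raise ValueError("ci_percent must be in (50, 100)")
        for name in (
            "n_wavelet_freqs",
            "analysis_fs",
            "trial_fs",
            "bandwidth_hz",
            "amp_percentile",
            "min_cycles",
            "null_iters",
            "bins_deg",
            "smooth_deg",
            "bimodal_frac",
            "split_halfwidth_deg",
            "svm_null_iters",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# container I/O
# ---------------------------------------------------------------------------

def write_recording(rec: Recording, path: str | Path) -> None:
    """Write an HDF5 data matrix plus a ``<path>.json`` sidecar."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data)
    sidecar = {
        "fs": rec.fs,
        "coords_mm": rec.geometry.coords.tolist(),
        "pitch_mm": rec.geometry.pitch,
        "n_rows": rec.geometry.n_rows,
        "n_cols": rec.geometry.n_cols,
        "bad_channels": sorted(rec.geometry.bad_channels),
        "annotations": [list(a) for a in rec.annotations],
        "events": [list(e) for e in rec.events],
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_recording(path: str | Path, sidecar: str | Path | None = None) -> Recording:
    """Read a recording written by :func:`write_recording`."""
    path = Path(path)
    sidecar = Path(sidecar) if sidecar else path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"sidecar not found: {sidecar}")
    meta = json.loads(sidecar.read_text())
    if "fs" not in meta:
        raise ValueError("sidecar missing sampling rate 'fs'")
    with h5py.File(path, "r") as f:
        data = f["data"][...]
    coords = np.asarray(meta["coords_mm"], dtype=float)
    if data.shape[0] != len(coords):
        raise ValueError(
            f"data has {data.shape[0]} rows but sidecar lists {len(coords)} electrodes"
        )
    geom = GridGeometry(
        coords=coords,
        pitch=float(meta.get("pitch_mm", 2.0)),
        n_rows=int(meta.get("n_rows", 1)),
        n_cols=int(meta.get("n_cols", len(coords))),
        bad_channels=frozenset(meta.get("bad_channels", [])),
    )
    return Recording(
        data=data,
        fs=float(meta["fs"]),
        geometry=geom,
        annotations=[(float(s), float(e), str(l)) for s, e, l in meta.get("annotations", [])],
        events=[(float(t), str(l)) for t, l in meta.get("events", [])],
    )


# ---------------------------------------------------------------------------
# artifact screening
# ---------------------------------------------------------------------------

def line_length_screen(
    rec: Recording,
    window_s: float = 1.0,
    threshold_mads: float = 8.0,
) -> list[tuple[float, float]]:
    """Line-length artifact detector.

    Per channel, the sliding-window line length (sum of absolute
    sample-to-sample differences over ``window_s``) is compared with that
    channel's own median + ``threshold_mads`` * MAD; windows where any
    channel exceeds its threshold are flagged and merged into intervals.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    n_win = max(2, int(round(window_s * rec.fs)))
    absdiff = np.abs(np.diff(rec.data, axis=1))
    kernel = np.ones(n_win - 1)
    flagged = np.zeros(absdiff.shape[1] + 1, dtype=bool)
    for ch in rec.geometry.usable:
        ll = np.convolve(absdiff[ch], kernel, mode="same")
        med = np.median(ll)
        mad = np.median(np.abs(ll - med))
        if mad == 0 and med == 0:
            continue  # constant channel: zero line length everywhere
        thr = med + threshold_mads * max(mad, 1e-12)
        flagged[:-1] |= ll > thr
    if not flagged.any():
        return []
    idx = np.flatnonzero(flagged)
    gaps = np.flatnonzero(np.diff(idx) > 1)
    starts = np.r_[idx[0], idx[gaps + 1]]
    ends = np.r_[idx[gaps], idx[-1]]
    return [(float(s / rec.fs), float((e + 1) / rec.fs)) for s, e in zip(starts, ends)]


# ---------------------------------------------------------------------------
# electrode subsetting / rotation
# ---------------------------------------------------------------------------

def rotate_geometry(geom: GridGeometry, rotation_deg: float) -> GridGeometry:
    """Express electrode positions in a frame rotated by ``rotation_deg``.

    This is the passive transform modeling a physical rotation of the
    grid: the electrodes' coordinates in the new frame are the old ones
    rotated by -rotation_deg, so a plane wave fixed in space acquires a
    fitted direction shifted by -rotation_deg.
    """
    a = np.deg2rad(rotation_deg)
    R = np.array([[np.cos(a), np.sin(a)], [-np.sin(a), np.cos(a)]])
    return GridGeometry(
        coords=geom.coords @ R.T,
        pitch=geom.pitch,
        n_rows=geom.n_rows,
        n_cols=geom.n_cols,
        bad_channels=geom.bad_channels,
    )


def subsample_electrodes(
    geom: GridGeometry,
    rows: int | None = None,
    cols: int | None = None,
    x_offset_mm: float = 0.0,
    y_offset_mm: float = 0.0,
    rotation_deg: float = 0.0,
    min_electrodes: int = 6,
) -> tuple[GridGeometry, np.ndarray]:
    """Select a rows x cols subgrid (optionally offset), optionally rotated.

    Returns the new geometry and the indices of the selected electrodes in
    the parent grid, so valid timepoints identified on the full grid can
    be reused for subgrid refits. Rotation is applied to the returned
    coordinate frame (see :func:`rotate_geometry`).
    """
    rows = rows if rows is not None else geom.n_rows
    cols = cols if cols is not None else geom.n_cols
    x0, y0 = x_offset_mm, y_offset_mm
    x1 = x0 + (cols - 1) * geom.pitch
    y1 = y0 + (rows - 1) * geom.pitch
    eps = 1e-9
    sel = np.flatnonzero(
        (geom.coords[:, 0] >= x0 - eps)
        & (geom.coords[:, 0] <= x1 + eps)
        & (geom.coords[:, 1] >= y0 - eps)
        & (geom.coords[:, 1] <= y1 + eps)
    )
    if sel.size != rows * cols:
        raise ValueError(
            f"requested {rows}x{cols} subgrid at offset ({x0}, {y0}) selects "
            f"{sel.size} electrodes; subset must lie within the grid"
        )
    if sel.size < min_electrodes:
        raise ValueError(f"subset must keep >= {min_electrodes} electrodes")
    bad = frozenset(
        int(np.flatnonzero(sel == b)[0]) for b in geom.bad_channels if b in sel
    )
    sub = GridGeometry(
        coords=geom.coords[sel],
        pitch=geom.pitch,
        n_rows=rows,
        n_cols=cols,
        bad_channels=bad,
    )
    if rotation_deg:
        sub = rotate_geometry(sub, rotation_deg)
    return sub, sel


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_pipeline(
    config: PipelineConfig,
    recording: Recording,
    events: list[tuple[float, str, float]] | None = None,
    out_dir: str | Path | None = None,
    classifier_null_iters: int | None = None,
) -> dict:
    """Run the full analysis on one recording.

    ``events`` rows are (time_s, label, reaction_time_s); when absent the
    DC stage is skipped. Returns a report dict keyed by stage; when
    ``out_dir`` is given, per-frequency fit tables (TSV) and a JSON
    summary are written alongside a config snapshot.
    """
    report: dict = {"config": asdict(config)}
    fmin, fmax = config.band_hz

    logger.info("screening artifacts (line length)")
    artifacts = line_length_screen(recording)
    rec = recording
    if artifacts:
        rec = Recording(
            data=recording.data,
            fs=recording.fs,
            geometry=recording.geometry,
            annotations=list(recording.annotations)
            + [(s, e, "artifact") for s, e in artifacts],
            events=list(recording.events),
        )
    report["artifacts"] = artifacts

    logger.info("stage: spectral peaks")
    try:
        specs = _spectral.wavelet_spectrum(
            rec, n_freqs=config.n_wavelet_freqs, fmin=fmin, fmax=fmax
        )
        specs = [_spectral.detrend_and_score(s) for s in specs]
        peaks = _spectral.find_consensus_peaks(specs)
    except Exception as exc:  # pragma: no cover - stage tagging
        raise RuntimeError(f"[spectral_peaks] {exc}") from exc
    report["consensus_peaks"] = [
        {"center_freq": p.center_freq, "n_channels": len(p.member_channels)}
        for p in peaks
    ]

    report["frequencies"] = {}
    splits_by_freq: dict[float, tuple[np.ndarray, np.ndarray]] = {}
    bands_by_freq = {}
    for peak in peaks:
        f0 = peak.center_freq
        if f0 - config.bandwidth_hz / 2 <= 0.05:
            logger.info("peak at %.2f Hz too close to DC for the extraction "
                        "band; skipped", f0)
            report["frequencies"][f"{f0:.4f}"] = {"skipped": "band below DC"}
            continue
        logger.info("stage: wave fit at %.2f Hz", f0)
        try:
            band = _wavefit.extract_band(
                rec,
                f0,
                fs_analysis=config.analysis_fs,
                bandwidth=config.bandwidth_hz,
                amp_percentile=config.amp_percentile,
                min_cycles=config.min_cycles,
            )
            fits = _wavefit.fit_series(
                band,
                rec.geometry,
                null_iters=config.null_iters,
                ci_percent=config.ci_percent,
                seed=config.seed,
            )
        except Exception as exc:
            raise RuntimeError(f"[wave_fit @ {f0:.2f} Hz] {exc}") from exc
        try:
            dist = _dirstats.build_distribution(
                fits.direction[fits.valid],
                bin_deg=config.bins_deg,
                bimodal_fraction=config.bimodal_frac,
            )
        except Exception as exc:
            raise RuntimeError(f"[direction_stats @ {f0:.2f} Hz] {exc}") from exc
        freq_report = {
            "n_valid": int(fits.valid.sum()),
            "modes_deg": list(dist.modes),
            "modality": dist.modality,
            "test": {"name": dist.test_name, "statistic": dist.statistic, "p": dist.p},
        }
        if dist.modality == "bidirectional":
            idx0, idx1 = _dirstats.angle_split(
                fits.direction,
                (dist.modes[0], dist.modes[1]),
                half_width=config.split_halfwidth_deg,
            )
            idx0 = idx0[fits.valid[idx0]]
            idx1 = idx1[fits.valid[idx1]]
            splits_by_freq[f0] = (idx0, idx1)
            bands_by_freq[f0] = band
            try:
                ds = _classify.build_dataset(
                    band, (idx0, idx1), geometry=rec.geometry, seed=config.seed
                )
                result = _classify.shuffle_null(
                    ds,
                    n_iter=classifier_null_iters or config.svm_null_iters,
                    seed=config.seed,
                )
                freq_report["classifier"] = {
                    "accuracy": result.accuracy,
                    "null_p50": result.null_p50,
                    "null_p99": result.null_p99,
                    "significant": result.significant,
                    "n_per_class": ds.counts[0],
                }
            except ValueError as exc:
                freq_report["classifier"] = {"skipped": str(exc)}
                logger.info("classifier skipped at %.2f Hz: %s", f0, exc)
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            fits.to_frame().to_csv(out / f"fits_{f0:.2f}Hz.tsv", sep="\t", index=False)
        report["frequencies"][f"{f0:.4f}"] = freq_report

    if events:
        for peak in peaks:
            f0 = peak.center_freq
            logger.info("stage: trial DC at %.2f Hz", f0)
            try:
                band_t = _wavefit.extract_band(
                    rec,
                    f0,
                    fs_analysis=config.trial_fs,
                    bandwidth=config.bandwidth_hz,
                    amp_percentile=config.amp_percentile,
                    min_cycles=config.min_cycles,
                )
                fits_t = _wavefit.fit_series(
                    band_t,
                    rec.geometry,
                    null_iters=config.null_iters,
                    ci_percent=config.ci_percent,
                    seed=config.seed,
                )
                ts = _trials.epoch_trials(
                    fits_t,
                    [t for t, _lbl, _rt in events],
                    rt=[rt for _t, _lbl, rt in events],
                    artifact_intervals=rec.artifact_intervals(),
                )
                dc = _trials.directionality_consistency(ts, seed=config.seed)
            except ValueError as exc:
                report["frequencies"][f"{f0:.4f}"]["dc"] = {"skipped": str(exc)}
                continue
            except Exception as exc:
                raise RuntimeError(f"[trial_dc @ {f0:.2f} Hz] {exc}") from exc
            report["frequencies"][f"{f0:.4f}"]["dc"] = {
                "max_dc": float(np.nanmax(dc.dc)),
                "n_sig_fdr": int(np.sum(dc.p_fdr < 0.05)),
                "null_band": list(dc.null_band),
            }
    else:
        logger.info("no events supplied; DC stage skipped")
        report["dc_skipped"] = True

    if len(splits_by_freq) >= 3:
        report["ratio_gradient"] = _classify.direction_ratio_and_gradient(
            splits_by_freq, bands_by_freq, rec.geometry
        )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=1, default=str))
    return report
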