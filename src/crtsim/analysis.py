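"""Quantification of trial behavior and population rhythms.

Metrics follow the published analysis protocol: linear-detrended summed MLN
voltage feeds a 400 Hz spectrogram (400 ms Hann window, 360 ms overlap) and
per-epoch FFT power spectra; behavioral performance is the rms eye-target
error and the count of high-velocity ("saccade-like") gaze displacements
exceeding 0.5 index units per 2.5 ms sample.  Sweep results are summarized
as mean +/- SD across model instances (seeds) per perturbation cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "EpochMetrics",
    "epoch_spectra",
    "fft_power",
    "band_power",
    "dominant_frequency",
    "spectrogram_peak_frequency",
    "rms_error",
    "count_high_velocity",
    "trial_metrics",
    "summarize_sweep",
]

ALPHA_BAND = (8.0, 12.0)  # Hz
NORMAL_EPOCH = (4.0, 6.0)  # s
PERTURBED_EPOCH = (6.0, 8.0)  # s
VELOCITY_THRESHOLD = 0.5  # index units per sample


@dataclass(frozen=True)
class EpochMetrics:
    epoch: tuple[float, float]
    rms_error: float
    n_high_velocity: int
    alpha_power: float


def _epoch_slice(n: int, fs: float, epoch: tuple[float, float]) -> slice:
    start, end = epoch
    i0, i1 = round(start * fs), round(end * fs)
    if not 0 <= i0 < i1 <= n:
        raise ValueError(f"epoch {epoch} outside the recorded series")
    return slice(i0, i1)


def epoch_spectra(
    mln_sum: np.ndarray,
    epochs: tuple[tuple[float, float], ...] = (NORMAL_EPOCH, PERTURBED_EPOCH),
    fs: float = 400.0,
    window_s: float = 0.4,
    overlap_s: float = 0.36,
):
    """Spectrogram of the detrended series plus per-epoch FFT power.

    Returns ``(freqs, frame_times, sxx, epoch_spectra)`` where
    ``epoch_spectra`` maps each epoch to ``(fft_freqs, power)``.
    """
    x = signal.detrend(np.asarray(mln_sum, dtype=float))
    nperseg = round(window_s * fs)
    noverlap = round(overlap_s * fs)
    freqs, times, sxx = signal.spectrogram(
        x, fs=fs, window="hann", nperseg=nperseg, noverlap=noverlap, detrend=False
    )
    per_epoch = {}
    for epoch in epochs:
        seg = x[_epoch_slice(x.size, fs, epoch)]
        per_epoch[epoch] = fft_power(seg, fs)
    return freqs, times, sxx, per_epoch


def fft_power(x: np.ndarray, fs: float = 400.0) -> tuple[np.ndarray, np.ndarray]:
    """One-sided FFT power spectrum of the linearly detrended segment."""
    x = signal.detrend(np.asarray(x, dtype=float))
    power = np.abs(np.fft.rfft(x)) ** 2
    return np.fft.rfftfreq(x.size, 1.0 / fs), power


def band_power(
    x: np.ndarray, fs: float = 400.0, band: tuple[float, float] = ALPHA_BAND
) -> float:
    """Integrated FFT power in a frequency band (trapezoid over bins)."""
    freqs, power = fft_power(x, fs)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if sel.sum() < 2:
        raise ValueError("band too narrow for the available resolution")
    return float(np.trapezoid(power[sel], freqs[sel]))


def dominant_frequency(
    x: np.ndarray,
    fs: float = 400.0,
    fmin: float = 2.0,
    fmax: float | None = None,
) -> float:
    """Frequency of maximal FFT power above fmin (and below fmax if given)."""
    freqs, power = fft_power(x, fs)
    sel = freqs >= fmin
    if fmax is not None:
        sel &= freqs <= fmax
    return float(freqs[sel][np.argmax(power[sel])])


def spectrogram_peak_frequency(
    mln_sum: np.ndarray,
    epoch: tuple[float, float],
    fs: float = 400.0,
    fmin: float = 2.0,
) -> float:
    """Peak spectrogram frequency averaged over frames inside an epoch."""
    freqs, times, sxx, _ = epoch_spectra(mln_sum, epochs=(), fs=fs)
    fsel = freqs >= fmin
    tsel = (times >= epoch[0]) & (times < epoch[1])
    if not np.any(tsel):
        raise ValueError("no spectrogram frames inside the epoch")
    peaks = freqs[fsel][np.argmax(sxx[fsel][:, tsel], axis=0)]
    return float(peaks.mean())


def rms_error(
    eye: np.ndarray,
    target: np.ndarray,
    epoch: tuple[float, float] | None = None,
    fs: float = 400.0,
) -> float:
    """Root-mean-square eye-target error over an epoch (index units)."""
    eye = np.asarray(eye, dtype=float)
    target = np.asarray(target, dtype=float)
    if eye.shape != target.shape:
        raise ValueError("eye and target series must be aligned")
    if epoch is not None:
        sl = _epoch_slice(eye.size, fs, epoch)
        eye, target = eye[sl], target[sl]
    return float(np.sqrt(np.mean((eye - target) ** 2)))


def count_high_velocity(
    eye: np.ndarray,
    epoch: tuple[float, float] | None = None,
    threshold: float = VELOCITY_THRESHOLD,
    fs: float = 400.0,
) -> int:
    """Samples where |instantaneous eye speed| strictly exceeds threshold.

    Speed is the per-sample displacement (index units per 2.5 ms at the
    default rate); this counts both large saccade-like jumps and rapid
    jerky movements.
    """
    eye = np.asarray(eye, dtype=float)
    if epoch is not None:
        eye = eye[_epoch_slice(eye.size, fs, epoch)]
    return int(np.sum(np.abs(np.diff(eye)) > threshold))


def trial_metrics(record, epoch: tuple[float, float]) -> EpochMetrics:
    """All per-epoch metrics for one trial record."""
    fs = record.record_rate
    return EpochMetrics(
        epoch=epoch,
        rms_error=rms_error(record.eye, record.target, epoch, fs),
        n_high_velocity=count_high_velocity(record.eye, epoch, fs=fs),
        alpha_power=band_power(
            record.mln_sum[_epoch_slice(record.mln_sum.size, fs, epoch)], fs
        ),
    )


def summarize_sweep(
    records,
    normal_epoch: tuple[float, float] = NORMAL_EPOCH,
    perturbed_epoch: tuple[float, float] = PERTURBED_EPOCH,
) -> pd.DataFrame:
    """Per-cell summary of a perturbation sweep.

    ``records`` is an iterable of TrialRecords.  Rows are keyed by (task,
    perturbation kind, strength, seed) with normal- and perturbed-epoch
    metrics and the perturbed/normal rms ratio; ``.attrs["cells"]`` holds
    the seed-averaged mean +/- SD table.
    """
    rows = []
    for rec in records:
        normal = trial_metrics(rec, normal_epoch)
        pert = trial_metrics(rec, perturbed_epoch)
        rows.append(
            {
                "task": rec.task.kind,
                "kind": rec.perturbation.kind,
                "strength": rec.perturbation.strength,
                "seed": rec.seed,
                "rms_normal": normal.rms_error,
                "rms_perturbed": pert.rms_error,
                "rms_ratio": (
                    pert.rms_error / normal.rms_error
                    if normal.rms_error > 0
                    else np.nan
                ),
                "n_saccade_normal": normal.n_high_velocity,
                "n_saccade_perturbed": pert.n_high_velocity,
                "alpha_normal": normal.alpha_power,
                "alpha_perturbed": pert.alpha_power,
            }
        )
    if not rows:
        raise ValueError("no trial records supplied")
    table = pd.DataFrame(rows)
    cells = (
        table.groupby(["task", "kind", "strength"])
        .agg(["mean", "std"])
        .drop(columns="seed")
    )
    table.attrs["cells"] = cells
    return table
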