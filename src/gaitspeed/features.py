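"""The 32-feature parameterization of 5-second windows.

Each window of the four analysis channels (z_lp, xy_lp, z_bp, xy_bp) is
summarized by time-domain statistics (mean, range, excess kurtosis, signal
entropy, range of the autocovariance), the XY-with-Z correlation for each
filter, and frequency-domain statistics of a Hamming-windowed periodogram
restricted to the 0.25-12 Hz gait band (spectral entropy, dominant
frequency and its power, and the fraction of band power in the dominant
bin). The fixed registry below assigns the 32 slots:

==========  =======================================================
slots       statistic x channel
==========  =======================================================
f01-f20     {mean, range, kurtosis, signal entropy, autocov range}
            x {z_lp, xy_lp, z_bp, xy_bp}
f21-f22     Pearson r(xy, z) for the low-pass and band-pass pairs
f23-f30     {spectral entropy, dominant frequency, dominant power,
            energy ratio} x {z_bp, xy_bp}
f31-f32     spectral entropy of z_lp and xy_lp
==========  =======================================================

Dominant-frequency statistics are not computed on the low-pass channels
because their spectra are DC-dominated; spectral entropy, which is
scale-invariant, is retained for them. The registry is configurable so an
alternative 32-slot assignment can be swapped in.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy import stats as sp_stats

from gaitspeed.io import (
    FEATURE_COLUMNS,
    FEATURE_TABLE_COLUMNS,
    N_FEATURES,
    AccelRecording,
    TestAnnotation,
    validate_feature_table,
)
from gaitspeed.preprocess import ChannelSet, Window, make_channels, segment_windows

HISTOGRAM_BINS = 20
AUTOCOV_MAX_LAG_S = 2.5
NFFT = 512
BAND_HZ = (0.25, 12.0)

_CHANNELS = ("z_lp", "xy_lp", "z_bp", "xy_bp")
_TIME_STATS = ("mean", "range", "kurtosis", "signal_entropy", "autocov_range")
_FREQ_STATS = ("spectral_entropy", "dom_freq", "dom_mag", "energy_ratio")


def _build_registry() -> list[dict]:
    reg = []
    for stat in _TIME_STATS:
        for ch in _CHANNELS:
            reg.append({"channel": ch, "statistic": stat})
    reg.append({"channel": "xy_lp/z_lp", "statistic": "pearson_r"})
    reg.append({"channel": "xy_bp/z_bp", "statistic": "pearson_r"})
    for stat in _FREQ_STATS:
        for ch in ("z_bp", "xy_bp"):
            reg.append({"channel": ch, "statistic": stat})
    reg.append({"channel": "z_lp", "statistic": "spectral_entropy"})
    reg.append({"channel": "xy_lp", "statistic": "spectral_entropy"})
    assert len(reg) == N_FEATURES
    return reg


FEATURE_REGISTRY: list[dict] = _build_registry()
FEATURE_NAMES: list[str] = [
    f"{r['statistic']}({r['channel']})" for r in FEATURE_REGISTRY
]


def export_registry(path: str | Path) -> Path:
    """Write the slot -> (channel, statistic) registry as JSON."""
    path = Path(path)
    units = {"mean": "G", "range": "G", "kurtosis": "", "signal_entropy": "bits",
             "autocov_range": "G^2", "pearson_r": "", "spectral_entropy": "bits",
             "dom_freq": "Hz", "dom_mag": "G^2/Hz", "energy_ratio": ""}
    payload = {
        FEATURE_COLUMNS[i]: {**r, "units": units[r["statistic"]]}
        for i, r in enumerate(FEATURE_REGISTRY)
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


# ---------------------------------------------------------------------------
# time domain


def time_features(w: np.ndarray,
                  histogram_bins: int = HISTOGRAM_BINS,
                  autocov_max_lag_s: float = AUTOCOV_MAX_LAG_S,
                  fs: float = 50.0) -> tuple[float, float, float, float, float]:
    """(mean, range, excess kurtosis, signal entropy, autocovariance range).

    Kurtosis is the population excess kurtosis (0 for a normal
    population). Signal entropy is the Shannon entropy, in bits, of the
    window's amplitude histogram (``histogram_bins`` equal bins spanning
    the window's own min-max range). The autocovariance is the biased
    (1/N) estimate over lags 0 .. floor(autocov_max_lag_s * fs); its range
    is max - min. A constant window maps to (value, 0, 0, 0, 0).
    """
    w = np.asarray(w, dtype=float)
    if len(w) < 2:
        raise ValueError("window must hold at least 2 samples")
    mean = float(w.mean())
    rng = float(np.ptp(w))
    if rng == 0.0:
        return (mean, 0.0, 0.0, 0.0, 0.0)
    kurt = float(sp_stats.kurtosis(w, fisher=True, bias=True))
    counts, _ = np.histogram(w, bins=histogram_bins, range=(w.min(), w.max()))
    p = counts / counts.sum()
    p = p[p > 0]
    entropy = float(-(p * np.log2(p)).sum())
    d = w - mean
    n = len(w)
    max_lag = min(int(math.floor(autocov_max_lag_s * fs)), n - 1)
    acov = np.correlate(d, d, mode="full")[n - 1: n + max_lag] / n
    acov_range = float(acov.max() - acov.min())
    return (mean, rng, kurt, entropy, acov_range)


def corr_feature(xy: np.ndarray, z: np.ndarray) -> float:
    """Pearson correlation of the XY and Z windows; 0 if either is constant."""
    xy = np.asarray(xy, dtype=float)
    z = np.asarray(z, dtype=float)
    if len(xy) != len(z):
        raise ValueError(f"length mismatch: {len(xy)} vs {len(z)}")
    if len(xy) < 2:
        raise ValueError("windows must hold at least 2 samples")
    if np.ptp(xy) == 0.0 or np.ptp(z) == 0.0:
        return 0.0
    r = np.corrcoef(xy, z)[0, 1]
    return float(np.clip(r, -1.0, 1.0))


# ---------------------------------------------------------------------------
# frequency domain


@dataclass
class SpectrumEstimate:
    """One-sided periodogram with its gait-band mask."""

    frequencies: np.ndarray
    power: np.ndarray
    band_mask: np.ndarray

    @property
    def band_frequencies(self) -> np.ndarray:
        return self.frequencies[self.band_mask]

    @property
    def band_power(self) -> np.ndarray:
        return self.power[self.band_mask]


def spectrum(w: np.ndarray, fs: float, nfft: int = NFFT,
             band: tuple[float, float] = BAND_HZ) -> SpectrumEstimate:
    """Hamming-windowed periodogram of one channel window.

    Zero-padded to ``nfft`` points (grid spacing fs/nfft, about 0.098 Hz
    at 50 Hz); the band mask selects the 0.25-12 Hz gait band inclusive.
    """
    w = np.asarray(w, dtype=float)
    if len(w) < 2:
        raise ValueError("window must hold at least 2 samples")
    if len(w) > nfft:
        raise ValueError(f"window of {len(w)} samples exceeds nfft={nfft}")
    f, p = sp_signal.periodogram(w, fs=fs, window="hamming", nfft=nfft,
                                 detrend=False, scaling="density")
    mask = (f >= band[0]) & (f <= band[1])
    if not mask.any():
        raise ValueError(f"band {band} Hz empty on the fs={fs} grid")
    return SpectrumEstimate(frequencies=f, power=p, band_mask=mask)


def freq_features(spec: SpectrumEstimate) -> tuple[float, float, float, float]:
    """(spectral entropy, dominant frequency, its power, energy ratio).

    Spectral entropy is the Shannon entropy (bits) of the band power
    normalized to a probability mass. The dominant frequency is the
    maximal band bin (ties broken toward the lowest frequency); the energy
    ratio is that bin's share of total band power. An all-zero band maps
    to (0, 0, 0, 0).
    """
    p = spec.band_power
    f = spec.band_frequencies
    total = float(p.sum())
    if total <= 0.0:
        return (0.0, 0.0, 0.0, 0.0)
    pn = p / total
    nz = pn[pn > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    i = int(np.argmax(p))  # argmax returns the first (lowest-frequency) max
    return (entropy, float(f[i]), float(p[i]), float(p[i] / total))


# ---------------------------------------------------------------------------
# assembly


def window_features(win: Window, fs: float = 50.0,
                    histogram_bins: int = HISTOGRAM_BINS,
                    autocov_max_lag_s: float = AUTOCOV_MAX_LAG_S,
                    nfft: int = NFFT) -> np.ndarray:
    """Compute the 32-element feature vector for one window."""
    ch = win.channels()
    vec = np.empty(N_FEATURES)
    tf = {name: time_features(ch[name], histogram_bins, autocov_max_lag_s, fs)
          for name in _CHANNELS}
    k = 0
    for si in range(len(_TIME_STATS)):
        for name in _CHANNELS:
            vec[k] = tf[name][si]
            k += 1
    vec[k] = corr_feature(ch["xy_lp"], ch["z_lp"]); k += 1
    vec[k] = corr_feature(ch["xy_bp"], ch["z_bp"]); k += 1
    specs = {name: freq_features(spectrum(ch[name], fs, nfft))
             for name in ("z_bp", "xy_bp")}
    for si in range(len(_FREQ_STATS)):
        for name in ("z_bp", "xy_bp"):
            vec[k] = specs[name][si]
            k += 1
    for name in ("z_lp", "xy_lp"):
        vec[k] = freq_features(spectrum(ch[name], fs, nfft))[0]
        k += 1
    assert k == N_FEATURES
    if not np.isfinite(vec).all():
        bad = [FEATURE_NAMES[i] for i in np.flatnonzero(~np.isfinite(vec))]
        raise ValueError(f"non-finite features: {bad}")
    return vec


def extract_features(windows: Iterable[Window], fs: float = 50.0,
                     **kwargs) -> np.ndarray:
    """Feature matrix (n_windows x 32) for a sequence of windows."""
    rows = [window_features(w, fs=fs, **kwargs) for w in windows]
    return np.asarray(rows).reshape(-1, N_FEATURES)


def build_feature_table(recordings: Sequence[AccelRecording],
                        annotations: Sequence[TestAnnotation],
                        **kwargs) -> pd.DataFrame:
    """Run preprocessing + feature extraction over a cohort.

    For every annotation, each recording of the same subject whose span
    covers the annotated interval contributes one row per window per
    location. Returns the validated feature-table DataFrame.
    """
    by_subject: dict[str, list[AccelRecording]] = {}
    for rec in recordings:
        by_subject.setdefault(rec.subject_id, []).append(rec)
    rows = []
    for ann in annotations:
        for rec in by_subject.get(ann.subject_id, []):
            if not (rec.t[0] <= ann.t_start and ann.t_end <= rec.t[-1]):
                continue
            cs = make_channels(rec)
            wins = segment_windows(cs, ann)
            if not wins:
                continue
            X = extract_features(wins, fs=rec.fs, **kwargs)
            for w, x in zip(wins, X):
                rows.append({
                    "subject_id": ann.subject_id,
                    "test_id": ann.test_id,
                    "window_index": w.index,
                    "location": rec.location,
                    **dict(zip(FEATURE_COLUMNS, x)),
                    "truth_speed_mps": ann.truth_speed,
                })
    df = pd.DataFrame(rows, columns=FEATURE_TABLE_COLUMNS)
    return validate_feature_table(df)
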