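"""Signal conditioning: dual filtering, yaw-invariant channels, windowing.

Each axis is low-pass (12 Hz) and band-pass (0.25-12 Hz) filtered with a
4th-order Butterworth applied forward-backward (zero phase). The in-plane
axes are collapsed to the rotation-invariant magnitude XY = sqrt(X^2 + Y^2)
after filtering, yielding four analysis channels per device: Z and XY for
each filter. Channels are cut into 5-second non-overlapping windows aligned
to the annotated test start; a trailing partial window is dropped, so a
360 s test yields exactly 72 windows.

Filtering runs on the whole recording before windowing to avoid per-window
edge transients; the first and last 2 s of the filtered recording are
excluded from any window because forward-backward filtering distorts the
edges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal

from gaitspeed.io import AccelRecording, TestAnnotation

DEFAULT_LOWPASS_HZ = 12.0
DEFAULT_BAND_HZ = (0.25, 12.0)
DEFAULT_ORDER = 4
DEFAULT_WINDOW_S = 5.0
EDGE_TRIM_S = 2.0


class SignalTooShortError(ValueError):
    """Input shorter than the zero-phase filter transient."""


class WindowingError(ValueError):
    """Annotation interval not covered by usable recording samples."""


@dataclass
class ChannelSet:
    """The four derived analysis series for one recording."""

    z_lp: np.ndarray
    xy_lp: np.ndarray
    z_bp: np.ndarray
    xy_bp: np.ndarray
    fs: float
    t: np.ndarray
    subject_id: str = ""
    location: str = ""

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("z_lp", "xy_lp", "z_bp", "xy_bp"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"channel {name} length differs from timestamps")
        if (self.xy_lp < 0).any() or (self.xy_bp < 0).any():
            raise ValueError("xy magnitude channels must be non-negative")

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class Window:
    """One 5-second block of the four channels with its speed label."""

    index: int
    start_time: float
    truth_speed: float
    z_lp: np.ndarray
    xy_lp: np.ndarray
    z_bp: np.ndarray
    xy_bp: np.ndarray

    @property
    def n_samples(self) -> int:
        return len(self.z_lp)

    def channels(self) -> dict[str, np.ndarray]:
        return {"z_lp": self.z_lp, "xy_lp": self.xy_lp,
                "z_bp": self.z_bp, "xy_bp": self.xy_bp}


def _check_length(x: np.ndarray, fs: float, order: int) -> None:
    # sosfiltfilt needs > 3 * (2 * n_sections + 1) samples per pass
    padlen = 3 * (2 * order + 1)
    if len(x) <= padlen:
        raise SignalTooShortError(
            f"signal of {len(x)} samples too short for zero-phase order-{order} "
            f"filter (needs > {padlen})"
        )


def lowpass(x: np.ndarray, fs: float, cutoff: float = DEFAULT_LOWPASS_HZ,
            order: int = DEFAULT_ORDER) -> np.ndarray:
    """Zero-phase Butterworth low-pass; same length as the input."""
    x = np.asarray(x, dtype=float)
    if not fs > 2 * cutoff:
        raise ValueError(f"fs={fs} Hz cannot support a {cutoff} Hz cutoff")
    _check_length(x, fs, order)
    sos = signal.butter(order, cutoff, btype="low", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def bandpass(x: np.ndarray, fs: float,
             band: tuple[float, float] = DEFAULT_BAND_HZ,
             order: int = DEFAULT_ORDER) -> np.ndarray:
    """Zero-phase Butterworth band-pass; same length as the input."""
    x = np.asarray(x, dtype=float)
    lo, hi = band
    if not (0 < lo < hi):
        raise ValueError(f"invalid band {band}")
    if not fs > 2 * hi:
        raise ValueError(f"fs={fs} Hz cannot support a {hi} Hz upper edge")
    _check_length(x, fs, order)
    sos = signal.butter(order, (lo, hi), btype="band", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def xy_magnitude(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Planar magnitude sqrt(x^2 + y^2), invariant to yaw about Z."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    return np.hypot(x, y)


def make_channels(rec: AccelRecording,
                  lowpass_cutoff_hz: float = DEFAULT_LOWPASS_HZ,
                  band_hz: tuple[float, float] = DEFAULT_BAND_HZ,
                  order: int = DEFAULT_ORDER) -> ChannelSet:
    """Filter each axis, then reduce to the four yaw-invariant channels.

    Filtering precedes the XY magnitude so that the nonlinearity does not
    fold high-frequency content into the pass band.
    """
    ax_lp = lowpass(rec.ax, rec.fs, lowpass_cutoff_hz, order)
    ay_lp = lowpass(rec.ay, rec.fs, lowpass_cutoff_hz, order)
    az_lp = lowpass(rec.az, rec.fs, lowpass_cutoff_hz, order)
    ax_bp = bandpass(rec.ax, rec.fs, band_hz, order)
    ay_bp = bandpass(rec.ay, rec.fs, band_hz, order)
    az_bp = bandpass(rec.az, rec.fs, band_hz, order)
    return ChannelSet(
        z_lp=az_lp,
        xy_lp=xy_magnitude(ax_lp, ay_lp),
        z_bp=az_bp,
        xy_bp=xy_magnitude(ax_bp, ay_bp),
        fs=rec.fs,
        t=rec.t,
        subject_id=rec.subject_id,
        location=rec.location,
    )


def segment_windows(cs: ChannelSet, ann: TestAnnotation,
                    win_s: float = DEFAULT_WINDOW_S,
                    edge_trim_s: float = EDGE_TRIM_S,
                    max_gap_factor: float = 2.0) -> list[Window]:
    """Cut the annotated interval into non-overlapping labelled windows.

    Windows start at ``ann.t_start`` and hold ``floor(fs * win_s)``
    samples each; ``floor(duration / win_s)`` windows are produced and
    the trailing remainder is discarded. Windows overlapping the filter
    edge-transient region (first/last ``edge_trim_s`` of the recording)
    or a sampling gap larger than ``max_gap_factor / fs`` are invalid:
    transient overlap raises, gap overlap drops the window.
    """
    n_win = math.floor((ann.t_end - ann.t_start) / win_s)
    if n_win == 0:
        return []
    spw = math.floor(cs.fs * win_s)
    t = cs.t
    usable_lo = t[0] + edge_trim_s
    usable_hi = t[-1] - edge_trim_s
    if ann.t_start < usable_lo or ann.t_end > usable_hi:
        raise WindowingError(
            f"annotation [{ann.t_start}, {ann.t_end}] s not inside the usable "
            f"recording span [{usable_lo:.3f}, {usable_hi:.3f}] s "
            f"(recording [{t[0]:.3f}, {t[-1]:.3f}] s minus {edge_trim_s} s "
            "edge transients)"
        )
    max_gap = max_gap_factor / cs.fs
    out: list[Window] = []
    for k in range(n_win):
        w_start = ann.t_start + k * win_s
        i0 = int(np.searchsorted(t, w_start - 0.5 / cs.fs))
        i1 = i0 + spw
        if i1 > len(t):
            raise WindowingError(
                f"window {k} starting at {w_start} s runs past the recording end"
            )
        tw = t[i0:i1]
        if np.diff(tw).max(initial=0.0) > max_gap:
            continue  # sampling gap: features assume contiguous blocks
        out.append(Window(
            index=k,
            start_time=w_start,
            truth_speed=ann.truth_speed,
            z_lp=cs.z_lp[i0:i1],
            xy_lp=cs.xy_lp[i0:i1],
            z_bp=cs.z_bp[i0:i1],
            xy_bp=cs.xy_bp[i0:i1],
        ))
    return out
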