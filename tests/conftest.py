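"""Shared fixtures: a small synthetic cohort and simple signal builders."""

from __future__ import annotations

import numpy as np
import pytest

from gaitspeed.features import build_feature_table
from gaitspeed.io import AccelRecording
from gaitspeed.synth import SynthConfig, SubjectParams, simulate_cohort


def make_recording(fs: float = 50.0, duration: float = 30.0,
                   ax=None, ay=None, az=None, location: str = "sacrum",
                   side: str = "midline", subject_id: str = "S01",
                   ) -> AccelRecording:
    n = int(round(duration * fs)) + 1
    t = np.arange(n) / fs
    zeros = np.zeros(n)
    return AccelRecording(
        subject_id=subject_id, location=location, side=side, fs=fs, t=t,
        ax=zeros if ax is None else np.broadcast_to(ax, n).astype(float),
        ay=zeros if ay is None else np.broadcast_to(ay, n).astype(float),
        az=zeros if az is None else np.broadcast_to(az, n).astype(float),
    )


def yaw_rotate(rec: AccelRecording, theta: float) -> AccelRecording:
    """The same motion observed by a device mounted with extra yaw."""
    c, s = np.cos(theta), np.sin(theta)
    return AccelRecording(
        subject_id=rec.subject_id, location=rec.location, side=rec.side,
        fs=rec.fs, t=rec.t,
        ax=c * rec.ax - s * rec.ay,
        ay=s * rec.ax + c * rec.ay,
        az=rec.az.copy(),
    )


def default_subject(subject_id: str = "S01", severity: float = 0.0,
                    seed: int = 0) -> SubjectParams:
    """Subject parameters with no idiosyncrasies (unit gain, zero offset)."""
    rng = np.random.default_rng(seed)
    return SubjectParams(
        subject_id=subject_id, gain_mult=1.0, cadence_offset_hz=0.0,
        severity=severity,
        yaw={loc: float(rng.uniform(0, 2 * np.pi))
             for loc in ("sacrum", "thigh", "shank")},
        phase_offsets={loc: rng.uniform(0, 2 * np.pi, size=(3, 4))
                       for loc in ("sacrum", "thigh", "shank")},
    )


SMALL_COHORT_CONFIG = SynthConfig(n_subjects=4, test_duration_s=60.0,
                                  standing_duration_s=30.0, n_standing=2,
                                  seed=7)


@pytest.fixture(scope="session")
def small_cohort():
    """4 subjects x (5 walking + 2 standing) tests, 60 s walks."""
    return simulate_cohort(SMALL_COHORT_CONFIG)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    return build_feature_table(small_cohort.recordings,
                               small_cohort.annotations)
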