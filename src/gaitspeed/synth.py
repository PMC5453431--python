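"""Synthetic multi-site gait accelerometry.

The generator emulates 50 Hz tri-axial recordings from sacrum, thigh and
shank devices during treadmill walking (0-1.9 m/s) and quiet standing,
with the statistical structure the estimation method relies on:

* cadence rises with belt speed (step frequency = c0 + c1 * speed, default
  0.8 Hz + 0.9 Hz per m/s, so 1.7 Hz at 1.0 m/s);
* harmonic amplitude grows with speed (proportional to gain * speed^0.8,
  zero when standing) and is larger at distal locations;
* the device yaw about its Z axis is arbitrary per placement, exercising
  the orientation-invariance of the XY magnitude;
* impairment severity in [0, 1] adds cycle-time jitter, alternate-step
  amplitude asymmetry, and harmonic attenuation, and drives the generated
  clinical scores (EDSS_SR, MSWS, T25FW comfortable speed, fall history).

The signal model is harmonic-plus-noise, not biomechanical: a shared
stride phase drives K = 4 harmonics per channel on top of a static
gravity projection, plus white Gaussian noise. Each trial recording
carries a lead-in/lead-out margin around the annotated interval
(the treadmill ramp), so annotated windows sit clear of filter edge
transients. All randomness flows from one master seed through
numpy SeedSequence spawning (subject -> trial -> location).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from gaitspeed.io import (
    AccelRecording,
    SubjectRecord,
    TestAnnotation,
    write_annotations,
    write_recording,
    write_subjects,
)

K_HARMONICS = 4
HARMONIC_WEIGHTS = (1.0, 0.5, 0.25, 0.12)
LOCATION_GAIN_G = {"sacrum": 0.18, "thigh": 0.35, "shank": 0.55}
LOCATION_GRAVITY_Z = {"sacrum": 0.15, "thigh": 0.20, "shank": 0.10}
LOCATION_SIDE = {"sacrum": "midline", "thigh": "right", "shank": "right"}


@dataclass
class SynthConfig:
    """Study conditions for a synthetic cohort.

    Defaults mirror the treadmill protocol the method was designed for:
    six-minute tests at five fixed speeds plus 30 s quiet-standing bouts,
    sampled at 50 Hz.
    """

    n_subjects: int = 17
    speeds: tuple[float, ...] = (0.5, 0.75, 1.0, 1.25, 1.5)
    n_standing: int = 6
    test_duration_s: float = 360.0
    standing_duration_s: float = 30.0
    fs: float = 50.0
    locations: tuple[str, ...] = ("sacrum", "thigh", "shank")
    cadence_intercept_hz: float = 0.8
    cadence_slope: float = 0.9          # Hz per m/s
    speed_exponent: float = 0.8
    noise_sd_g: float = 0.02
    severity: float = 0.0
    lead_s: float = 10.0                # ramp margin around the annotation
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.fs > 24:
            raise ValueError("fs must exceed 24 Hz to carry the 12 Hz band")
        if any(s < 0 for s in self.speeds):
            raise ValueError("speeds must be non-negative")
        if not 0 <= self.severity <= 1:
            raise ValueError("severity must lie in [0, 1]")


@dataclass
class SubjectParams:
    """Per-subject gait idiosyncrasies, drawn once per subject."""

    subject_id: str
    gain_mult: float           # lognormal amplitude multiplier
    cadence_offset_hz: float
    severity: float
    yaw: dict[str, float]      # per-location device yaw, radians
    phase_offsets: dict[str, np.ndarray]  # per-location harmonic phases


@dataclass
class SynthCohort:
    """Recordings + annotations + subject metadata + generative truth."""

    recordings: list[AccelRecording]
    annotations: list[TestAnnotation]
    subjects: list[SubjectRecord]
    truth: pd.DataFrame  # per (subject, test): speed, cadence, severity, jitter

    def write(self, outdir: str | Path) -> Path:
        """Emit the CSV/JSON file set the io layer reads, plus truth.csv."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rec_dir = outdir / "recordings"
        rec_dir.mkdir(exist_ok=True)
        counters: dict[tuple[str, str], int] = {}
        for rec in self.recordings:
            key = (rec.subject_id, rec.location)
            counters[key] = counters.get(key, 0) + 1
            name = f"{rec.subject_id}_{rec.location}_{counters[key]:03d}.csv"
            write_recording(rec, rec_dir / name)
        write_annotations(self.annotations, outdir / "annotations.csv")
        write_subjects(self.subjects, outdir / "subjects.csv")
        self.truth.to_csv(outdir / "truth.csv", index=False, float_format="%.9g")
        return outdir


def _draw_subject(subject_id: str, severity: float,
                  rng: np.random.Generator,
                  locations: Sequence[str]) -> SubjectParams:
    return SubjectParams(
        subject_id=subject_id,
        gain_mult=float(np.exp(rng.normal(0.0, 0.15))),
        cadence_offset_hz=float(rng.normal(0.0, 0.05)),
        severity=severity,
        yaw={loc: float(rng.uniform(0, 2 * math.pi)) for loc in locations},
        phase_offsets={loc: rng.uniform(0, 2 * math.pi, size=(3, K_HARMONICS))
                       for loc in locations},
    )


def _smooth_noise(n: int, fs: float, rng: np.random.Generator,
                  smooth_s: float = 1.0) -> np.ndarray:
    """Unit-SD noise low-passed by a moving average (~1/smooth_s Hz)."""
    w = max(int(round(smooth_s * fs)), 1)
    x = rng.standard_normal(n + w)
    kern = np.ones(w) / w
    y = np.convolve(x, kern, mode="valid")[:n]
    sd = y.std()
    return y / sd if sd > 0 else y


def _stride_phase(n: int, fs: float, step_hz: float, jitter_sd: float,
                  rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """Cumulative step phase with smooth frequency jitter.

    Returns (phase in steps, realized fractional cycle-time jitter SD).
    """
    if step_hz <= 0:
        return np.zeros(n), 0.0
    j = jitter_sd * _smooth_noise(n, fs, rng)
    f_inst = step_hz * np.clip(1.0 + j, 0.2, None)
    phase = np.cumsum(f_inst) / fs
    return phase, float(j.std())


def simulate_trial(speed: float, params: SubjectParams, location: str,
                   seed: np.random.SeedSequence | int,
                   cfg: SynthConfig | None = None,
                   duration_s: float | None = None,
                   phase: np.ndarray | None = None) -> AccelRecording:
    """Generate one device recording for one treadmill test.

    ``phase`` lets the caller share a single stride-phase trajectory
    across the devices of one trial (they are on the same body). The
    recording spans ``lead + duration + lead`` seconds; the test proper
    occupies [lead, lead + duration].
    """
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(seed)
    duration = duration_s if duration_s is not None else (
        cfg.test_duration_s if speed > 0 else cfg.standing_duration_s)
    total = duration + 2 * cfg.lead_s
    n = int(round(total * cfg.fs)) + 1
    t = np.arange(n) / cfg.fs
    sev = params.severity

    g_z = LOCATION_GRAVITY_Z[location]
    g_plane = math.sqrt(max(1.0 - g_z ** 2, 0.0))
    # device-frame signals before yaw: w = planar "forward", v = planar
    # "lateral", z = out-of-plane (anterior/posterior)
    z = np.full(n, g_z)
    u = np.full(n, g_plane)
    v = np.zeros(n)

    if speed > 0:
        step_hz = cfg.cadence_intercept_hz + cfg.cadence_slope * speed \
            + params.cadence_offset_hz
        jitter_sd = 0.02 + 0.12 * sev
        if phase is None:
            phase, _ = _stride_phase(n, cfg.fs, step_hz, jitter_sd, rng)
        amp = (LOCATION_GAIN_G[location] * params.gain_mult
               * speed ** cfg.speed_exponent * (1.0 - 0.3 * sev))
        # alternate-step asymmetry: modulation at the stride (half-step) rate
        asym = 1.0 + 0.25 * sev * np.cos(math.pi * phase)
        po = params.phase_offsets[location]
        for k in range(K_HARMONICS):
            a_k = amp * HARMONIC_WEIGHTS[k]
            arg = 2 * math.pi * (k + 1) * phase
            z += a_k * asym * np.cos(arg + po[0, k])
            u += 0.8 * a_k * asym * np.cos(arg + po[1, k])
            v += 0.5 * a_k * asym * np.cos(arg + po[2, k])

    cy, sy = math.cos(params.yaw[location]), math.sin(params.yaw[location])
    ax = cy * u - sy * v + rng.normal(0.0, cfg.noise_sd_g, n)
    ay = sy * u + cy * v + rng.normal(0.0, cfg.noise_sd_g, n)
    az = z + rng.normal(0.0, cfg.noise_sd_g, n)

    return AccelRecording(
        subject_id=params.subject_id, location=location,
        side=LOCATION_SIDE[location], fs=cfg.fs,
        t=t, ax=ax, ay=ay, az=az,
    )


def _simulate_subject_tests(params: SubjectParams, tests: list[dict],
                            cfg: SynthConfig,
                            ss: np.random.SeedSequence
                            ) -> tuple[list[AccelRecording], list[TestAnnotation], list[dict]]:
    recs: list[AccelRecording] = []
    anns: list[TestAnnotation] = []
    truth_rows: list[dict] = []
    trial_seeds = ss.spawn(len(tests))
    t_offset = 0.0  # session clock: tests are consecutive, not overlapping
    for test, tss in zip(tests, trial_seeds):
        speed = test["speed"]
        duration = test["duration"]
        phase_rng = np.random.default_rng(tss)
        step_hz = 0.0
        jitter = 0.0
        phase = None
        n = int(round((duration + 2 * cfg.lead_s) * cfg.fs)) + 1
        if speed > 0:
            step_hz = (cfg.cadence_intercept_hz + cfg.cadence_slope * speed
                       + params.cadence_offset_hz)
            phase, jitter = _stride_phase(
                n, cfg.fs, step_hz, 0.02 + 0.12 * params.severity, phase_rng)
        loc_seeds = tss.spawn(len(cfg.locations))
        for loc, lss in zip(cfg.locations, loc_seeds):
            rec = simulate_trial(speed, params, loc, lss, cfg,
                                 duration_s=duration, phase=phase)
            rec.t = rec.t + t_offset
            recs.append(rec)
        anns.append(TestAnnotation(
            subject_id=params.subject_id, test_id=test["test_id"],
            test_type=test["test_type"], t_start=t_offset + cfg.lead_s,
            t_end=t_offset + cfg.lead_s + duration, truth_speed=speed,
        ))
        t_offset += duration + 2 * cfg.lead_s + 1.0
        truth_rows.append({
            "subject_id": params.subject_id, "test_id": test["test_id"],
            "speed_mps": speed, "step_hz": step_hz,
            "severity": params.severity, "cycle_time_jitter": jitter,
        })
    return recs, anns, truth_rows


def simulate_cohort(cfg: SynthConfig | None = None) -> SynthCohort:
    """Generate a normal (healthy) treadmill cohort.

    Each subject completes one six-minute walking test per configured
    speed plus ``n_standing`` quiet-standing bouts labelled 0 m/s, at
    every configured device location.
    """
    cfg = cfg or SynthConfig()
    master = np.random.SeedSequence(cfg.seed)
    subj_seeds = master.spawn(cfg.n_subjects)
    recordings, annotations, truth_rows, subjects = [], [], [], []
    for i, ss in enumerate(subj_seeds):
        sid = f"H{i + 1:02d}"
        prng = np.random.default_rng(ss)
        params = _draw_subject(sid, cfg.severity, prng, cfg.locations)
        tests = [
            {"test_id": f"W{j + 1}", "test_type": "treadmill_walk",
             "speed": sp, "duration": cfg.test_duration_s}
            for j, sp in enumerate(cfg.speeds)
        ] + [
            {"test_id": f"P{j + 1}", "test_type": "PCT",
             "speed": 0.0, "duration": cfg.standing_duration_s}
            for j in range(cfg.n_standing)
        ]
        recs, anns, rows = _simulate_subject_tests(params, tests, cfg, ss)
        recordings.extend(recs)
        annotations.extend(anns)
        truth_rows.extend(rows)
        subjects.append(SubjectRecord(subject_id=sid, cohort="healthy"))
    return SynthCohort(recordings, annotations, subjects,
                       pd.DataFrame(truth_rows))


def simulate_ms_cohort(cfg: SynthConfig | None = None,
                       n_subjects: int = 30) -> SynthCohort:
    """Generate an impaired cohort with severity-driven clinical scores.

    Each subject's impairment severity is drawn uniformly in [0, 1] and
    sets the comfortable walking speed (1.4 - 0.9 * severity m/s plus
    noise), the three 6MWT belt speeds (comfortable and +/-20%), the
    clinical scores (MSWS = 0.2 + 0.7 * severity, EDSS_SR = 7.5 *
    severity, both plus noise and clipped to range), and the fall
    probability. Scores are synthetic monotone functions of severity,
    not literature-calibrated.
    """
    cfg = cfg or SynthConfig()
    master = np.random.SeedSequence(cfg.seed)
    subj_seeds = master.spawn(n_subjects)
    recordings, annotations, truth_rows, subjects = [], [], [], []
    for i, ss in enumerate(subj_seeds):
        sid = f"MS{i + 1:02d}"
        prng = np.random.default_rng(ss)
        severity = float(prng.uniform(0.0, 1.0))
        params = _draw_subject(sid, severity, prng, cfg.locations)
        comfortable = float(np.clip(
            1.4 - 0.9 * severity + prng.normal(0.0, 0.05), 0.2, 1.9))
        speeds = [max(0.13, 0.8 * comfortable), comfortable,
                  min(1.9, 1.2 * comfortable)]
        tests = [
            {"test_id": f"W{j + 1}", "test_type": "sixMWT",
             "speed": sp, "duration": cfg.test_duration_s}
            for j, sp in enumerate(speeds)
        ]
        recs, anns, rows = _simulate_subject_tests(params, tests, cfg, ss)
        recordings.extend(recs)
        annotations.extend(anns)
        truth_rows.extend(rows)
        subjects.append(SubjectRecord(
            subject_id=sid, cohort="MS",
            edss_sr=float(np.clip(7.5 * severity + prng.normal(0, 0.5), 0, 10)),
            msws=float(np.clip(0.2 + 0.7 * severity + prng.normal(0, 0.05), 0, 1)),
            fell_last_6mo=bool(prng.random() < 0.15 + 0.55 * severity),
            t25fw_speed=float(np.clip(comfortable + prng.normal(0, 0.03), 0.1, 2.5)),
        ))
    return SynthCohort(recordings, annotations, subjects,
                       pd.DataFrame(truth_rows))


def comfortable_test_ids(cohort: SynthCohort) -> dict[str, str]:
    """Map each impaired subject to their comfortable-speed 6MWT (W2)."""
    return {s.subject_id: "W2" for s in cohort.subjects if s.cohort == "MS"}


def study_annotation_plan(
        test_duration_s: float = 360.0,
        standing_duration_s: float = 30.0,
        lead_s: float = 10.0,
) -> tuple[list[TestAnnotation], list[TestAnnotation]]:
    """Replay the study's protocol structure at the annotation layer.

    Healthy arm: 10 treadmill subjects with 5 fixed-speed walking tests
    each, and 7 controls with three self-paced 6MWTs plus six 30 s
    quiet-standing bouts each, one control completing an extra 6MWT.
    Impaired arm: 30 subjects with three 6MWTs each (comfortable and
    +/-20%), one subject completing an extra 6MWT. Returns
    (healthy, impaired) annotation lists — 114 and 91 test-level
    observations respectively.
    """
    t0 = lead_s
    healthy: list[TestAnnotation] = []
    for i in range(10):
        sid = f"A{i + 1:02d}"
        for j, sp in enumerate((0.5, 0.75, 1.0, 1.25, 1.5)):
            healthy.append(TestAnnotation(sid, f"W{j + 1}", "treadmill_walk",
                                          t0, t0 + test_duration_s, sp))
    for i in range(7):
        sid = f"C{i + 1:02d}"
        comfortable = 1.1 + 0.05 * i
        for j, mult in enumerate((0.8, 1.0, 1.2)):
            healthy.append(TestAnnotation(sid, f"W{j + 1}", "sixMWT",
                                          t0, t0 + test_duration_s,
                                          round(mult * comfortable, 3)))
        for j in range(6):
            healthy.append(TestAnnotation(sid, f"P{j + 1}", "PCT",
                                          t0, t0 + standing_duration_s, 0.0))
    healthy.append(TestAnnotation("C01", "W4", "sixMWT",
                                  t0, t0 + test_duration_s, 1.1))
    impaired: list[TestAnnotation] = []
    for i in range(30):
        sid = f"MS{i + 1:02d}"
        comfortable = 0.5 + 1.3 * i / 29
        for j, mult in enumerate((0.8, 1.0, 1.2)):
            impaired.append(TestAnnotation(sid, f"W{j + 1}", "sixMWT",
                                           t0, t0 + test_duration_s,
                                           round(mult * comfortable, 3)))
    impaired.append(TestAnnotation("MS01", "W4", "sixMWT",
                                   t0, t0 + test_duration_s, 0.52))
    return healthy, impaired
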