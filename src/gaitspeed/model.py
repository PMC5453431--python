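"""Support-vector regression of walking speed on window features.

A model maps the concatenated 32-feature vectors from an ordered
combination of device locations (sacrum, thigh, shank; 7 nonempty
combinations) to the walking speed of the 5-second window. Features are
standardized to zero mean / unit variance using training rows only, then
fed to an RBF-kernel epsilon-SVR (C = 1, epsilon = 0.1 m/s, bandwidth
1/(M * pooled variance), i.e. the common default regime for standardized
features). Per-window estimates are floored at 0 m/s and aggregated to a
single test-level estimate by the median across the test's windows.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from gaitspeed.io import FEATURE_COLUMNS, LOCATIONS, N_FEATURES

ALL_COMBOS: tuple[tuple[str, ...], ...] = (
    ("sacrum",), ("thigh",), ("shank",),
    ("sacrum", "thigh"), ("sacrum", "shank"), ("thigh", "shank"),
    ("sacrum", "thigh", "shank"),
)


class LocationCombo(tuple):
    """Ordered, duplicate-free subset of the device locations."""

    def __new__(cls, locations: Sequence[str] | str):
        if isinstance(locations, str):
            locations = [s.strip() for s in locations.split(",") if s.strip()]
        locations = tuple(locations)
        if not locations:
            raise ValueError("a location combination cannot be empty")
        for loc in locations:
            if loc not in LOCATIONS:
                raise ValueError(f"unknown location {loc!r}")
        if len(set(locations)) != len(locations):
            raise ValueError(f"duplicate locations in {locations}")
        return super().__new__(cls, locations)

    @property
    def n_features(self) -> int:
        return N_FEATURES * len(self)

    def __str__(self) -> str:
        return ",".join(self)


@dataclass(frozen=True)
class SpeedModelConfig:
    """SVR hyperparameters; the defaults are the package's fixed regime."""

    kernel: str = "rbf"
    C: float = 1.0
    epsilon: float = 0.1
    gamma: str | float = "scale"

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class SpeedModel:
    """Fitted regressor for one location combination."""

    combo: LocationCombo
    config: SpeedModelConfig
    scaler: StandardScaler
    svr: SVR
    training_subjects: tuple[str, ...]
    seed: int | None = None

    @property
    def n_features(self) -> int:
        return self.combo.n_features

    def predict_windows(self, X: np.ndarray) -> np.ndarray:
        """Per-window speed estimates, floored at 0 m/s."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} feature columns for combo "
                f"{self.combo}, got {X.shape[1] if X.ndim == 2 else X.shape}"
            )
        raw = self.svr.predict(self.scaler.transform(X))
        return np.maximum(raw, 0.0)

    # -- serialization: JSON manifest + npz coefficient block ---------------

    def save(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest = {
            "combo": list(self.combo),
            "config": asdict(self.config),
            "config_hash": self.config.hash(),
            "training_subjects": list(self.training_subjects),
            "seed": self.seed,
            "scaler": {
                "mean": self.scaler.mean_.tolist(),
                "scale": self.scaler.scale_.tolist(),
            },
            "svr": {
                "gamma_value": float(self.svr._gamma),
                "intercept": self.svr.intercept_.tolist(),
            },
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        np.savez(outdir / "coefficients.npz",
                 support_vectors=self.svr.support_vectors_,
                 dual_coef=self.svr.dual_coef_)
        return outdir

    @classmethod
    def load(cls, outdir: str | Path) -> "SpeedModel":
        outdir = Path(outdir)
        manifest = json.loads((outdir / "manifest.json").read_text())
        blob = np.load(outdir / "coefficients.npz")
        combo = LocationCombo(manifest["combo"])
        config = SpeedModelConfig(**manifest["config"])
        scaler = StandardScaler()
        scaler.mean_ = np.asarray(manifest["scaler"]["mean"])
        scaler.scale_ = np.asarray(manifest["scaler"]["scale"])
        scaler.var_ = scaler.scale_ ** 2
        scaler.n_features_in_ = len(scaler.mean_)
        svr = SVR(kernel=config.kernel, C=config.C, epsilon=config.epsilon,
                  gamma=config.gamma)
        svr.support_vectors_ = blob["support_vectors"]
        svr.dual_coef_ = blob["dual_coef"]
        svr.intercept_ = np.asarray(manifest["svr"]["intercept"])
        svr._gamma = manifest["svr"]["gamma_value"]
        # libsvm internals needed by predict()
        svr._sparse = False
        svr.fit_status_ = 0
        svr.shape_fit_ = (len(blob["support_vectors"]), combo.n_features)
        svr.support_ = np.arange(len(blob["support_vectors"]), dtype=np.int32)
        svr._n_support = np.asarray([len(blob["support_vectors"]), 0], dtype=np.int32)
        svr._dual_coef_ = svr.dual_coef_
        svr._intercept_ = svr.intercept_
        svr._probA = np.empty(0)
        svr._probB = np.empty(0)
        svr.n_features_in_ = combo.n_features
        return cls(combo=combo, config=config, scaler=scaler, svr=svr,
                   training_subjects=tuple(manifest["training_subjects"]),
                   seed=manifest.get("seed"))


@dataclass
class TestPrediction:
    """Window-level and median test-level speed estimates for one test."""

    subject_id: str
    test_id: str
    window_estimates: np.ndarray
    truth: float

    def __post_init__(self) -> None:
        self.window_estimates = np.asarray(self.window_estimates, dtype=float)
        if len(self.window_estimates) == 0:
            raise ValueError("a test prediction needs at least one window")
        if (self.window_estimates < 0).any():
            raise ValueError("window estimates must be non-negative")

    @property
    def median_estimate(self) -> float:
        return float(np.median(self.window_estimates))

    @property
    def error(self) -> float:
        """Estimate minus truth (positive = overestimate)."""
        return self.median_estimate - self.truth


def assemble_design(ft: pd.DataFrame, combo: LocationCombo
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, pd.DataFrame]:
    """Build the design matrix for one location combination.

    Rows are windows present at *every* location of the combo (windows
    missing any location are dropped); columns are ordered by combo order,
    then registry order. Returns (X, y, subject groups, index frame with
    subject_id/test_id/window_index).
    """
    combo = LocationCombo(combo)
    sub = ft[ft["location"].isin(combo)]
    wide = sub.pivot_table(
        index=["subject_id", "test_id", "window_index", "truth_speed_mps"],
        columns="location", values=FEATURE_COLUMNS, sort=False,
    )
    # canonical row order: the fit must not depend on input row order
    wide = wide.sort_index(level=["subject_id", "test_id", "window_index"])
    # keep only windows complete across the combo
    complete = wide.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        import logging
        logging.getLogger(__name__).info(
            "assemble_design: dropped %d windows missing a location", n_dropped)
    wide = wide[complete]
    if wide.empty:
        raise ValueError(f"no windows cover all locations in combo {combo}")
    cols = [(f, loc) for loc in combo for f in FEATURE_COLUMNS]
    X = wide[cols].to_numpy(dtype=float)
    idx = wide.index.to_frame(index=False)
    y = idx["truth_speed_mps"].to_numpy(dtype=float)
    groups = idx["subject_id"].to_numpy()
    return X, y, groups, idx[["subject_id", "test_id", "window_index"]]


def train(X: np.ndarray, y: np.ndarray,
          config: SpeedModelConfig | None = None,
          combo: LocationCombo | Sequence[str] = ("sacrum",),
          subjects: Sequence[str] = (),
          seed: int | None = None) -> SpeedModel:
    """Fit standardization + SVR on training windows.

    Standardization statistics come from the training rows only;
    the fit is deterministic given (X, y, config).
    """
    combo = LocationCombo(combo)
    config = config or SpeedModelConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[1] != combo.n_features:
        raise ValueError(
            f"X must be (n, {combo.n_features}) for combo {combo}; got {X.shape}"
        )
    if not np.isfinite(X).all():
        bad = sorted(set(np.argwhere(~np.isfinite(X))[:, 1].tolist()))
        raise ValueError(f"non-finite entries in feature columns {bad}")
    if not np.isfinite(y).all():
        raise ValueError("non-finite labels")
    scaler = StandardScaler().fit(X)
    svr = SVR(kernel=config.kernel, C=config.C, epsilon=config.epsilon,
              gamma=config.gamma, cache_size=500)
    svr.fit(scaler.transform(X), y)
    return SpeedModel(combo=combo, config=config, scaler=scaler, svr=svr,
                      training_subjects=tuple(sorted(set(subjects))), seed=seed)


def predict_test(model: SpeedModel, ft: pd.DataFrame,
                 subject_id: str, test_id: str) -> TestPrediction:
    """Predict all windows of one test and aggregate by the median."""
    sub = ft[(ft["subject_id"] == subject_id) & (ft["test_id"] == test_id)]
    if sub.empty:
        raise ValueError(f"no windows for test ({subject_id}, {test_id})")
    X, y, _, _ = assemble_design(sub, model.combo)
    est = model.predict_windows(X)
    truth = float(np.unique(y)[0])
    return TestPrediction(subject_id=subject_id, test_id=test_id,
                          window_estimates=est, truth=truth)


def predict_tests(model: SpeedModel, ft: pd.DataFrame) -> list[TestPrediction]:
    """One :class:`TestPrediction` per (subject, test) in the table."""
    out = []
    for (sid, tid), _ in ft.groupby(["subject_id", "test_id"], sort=True):
        out.append(predict_test(model, ft, sid, tid))
    return out
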