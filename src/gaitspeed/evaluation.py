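"""Agreement and clinical-validity statistics for speed estimates.

Performance of the regressor is judged at the test level (median window
estimate per test) against the treadmill speed, via

* leave-one-subject-out (LOSO) cross-validation on the normal cohort, or
  a single transfer model trained on all normal subjects and applied to
  the impaired cohort;
* RMSE of the test-level errors;
* Bland-Altman limits of agreement (mean difference +/- 1.96 SD of the
  differences, the 95% interval for the disagreement between the two
  measurements);
* ordinary least squares of truth on estimate, y = m * y_hat + b, with a
  percentile-bootstrap 95% confidence band (test pairs resampled);
* impairment-stratified error (Mild / Moderate / Severe by Timed-25-Foot-
  Walk comfortable speed), Pearson correlations of error and of speed
  with clinical scores, and a Mann-Whitney U comparison of comfortable
  speed between fallers and non-fallers.

The error sign convention throughout is estimate - truth, so a positive
bias means the model overestimates speed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from gaitspeed.io import SubjectRecord
from gaitspeed.model import (
    LocationCombo,
    SpeedModel,
    SpeedModelConfig,
    TestPrediction,
    assemble_design,
    predict_tests,
    train,
)

ALPHA = 0.05


# ---------------------------------------------------------------------------
# cross-validation


def loso_evaluate(ft: pd.DataFrame, combo: LocationCombo | Sequence[str],
                  config: SpeedModelConfig | None = None,
                  seed: int | None = None) -> list[TestPrediction]:
    """Leave-one-subject-out predictions for every test in the table.

    Each subject is held out once; a model fitted on the remaining
    subjects (standardization statistics included) scores the held-out
    subject's tests, so no subject's rows ever influence the model that
    scores them.
    """
    combo = LocationCombo(combo)
    subjects = sorted(ft["subject_id"].unique())
    if len(subjects) < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    preds: list[TestPrediction] = []
    for held_out in subjects:
        train_ft = ft[ft["subject_id"] != held_out]
        test_ft = ft[ft["subject_id"] == held_out]
        if test_ft.empty:
            import logging
            logging.getLogger(__name__).warning(
                "subject %s has no test windows; skipped", held_out)
            continue
        X, y, groups, _ = assemble_design(train_ft, combo)
        model = train(X, y, config=config, combo=combo,
                      subjects=np.unique(groups), seed=seed)
        preds.extend(predict_tests(model, test_ft))
    return sorted(preds, key=lambda p: (p.subject_id, p.test_id))


def transfer_evaluate(train_ft: pd.DataFrame, test_ft: pd.DataFrame,
                      combo: LocationCombo | Sequence[str],
                      config: SpeedModelConfig | None = None,
                      seed: int | None = None
                      ) -> tuple[SpeedModel, list[TestPrediction]]:
    """Train once on the full normal cohort; predict the impaired cohort."""
    combo = LocationCombo(combo)
    X, y, groups, _ = assemble_design(train_ft, combo)
    model = train(X, y, config=config, combo=combo,
                  subjects=np.unique(groups), seed=seed)
    return model, predict_tests(model, test_ft)


# ---------------------------------------------------------------------------
# agreement statistics


def _arrays(preds: Sequence[TestPrediction]) -> tuple[np.ndarray, np.ndarray]:
    est = np.array([p.median_estimate for p in preds], dtype=float)
    truth = np.array([p.truth for p in preds], dtype=float)
    return est, truth


def rmse(preds: Sequence[TestPrediction]) -> float:
    """Root-mean-square of the test-level errors, in m/s."""
    if len(preds) == 0:
        raise ValueError("rmse needs at least one prediction")
    est, truth = _arrays(preds)
    return float(np.sqrt(np.mean((est - truth) ** 2)))


def bland_altman(preds: Sequence[TestPrediction]
                 ) -> tuple[float, float, float]:
    """(bias, LOA low, LOA high) of the estimate-truth differences.

    LOA = bias +/- 1.96 * sample SD of the differences — the 95% interval
    within which the disagreement between the two measurements is
    expected to fall.
    """
    if len(preds) < 2:
        raise ValueError("Bland-Altman needs at least 2 predictions")
    est, truth = _arrays(preds)
    d = est - truth
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return (bias, bias - 1.96 * sd, bias + 1.96 * sd)


@dataclass
class AgreementRegression:
    """OLS fit of truth on estimate with a bootstrap confidence band."""

    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    boot_slopes: np.ndarray
    boot_intercepts: np.ndarray

    def band(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Pointwise 95% percentile band of the bootstrap fitted lines."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        lines = self.boot_slopes[:, None] * x[None, :] + self.boot_intercepts[:, None]
        return (np.percentile(lines, 2.5, axis=0),
                np.percentile(lines, 97.5, axis=0))


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    xm, ym = x.mean(), y.mean()
    sxx = ((x - xm) ** 2).sum()
    m = float(((x - xm) * (y - ym)).sum() / sxx)
    return m, float(ym - m * xm)


def agreement_regression(preds: Sequence[TestPrediction],
                         n_boot: int = 1000,
                         seed: int | None = None) -> AgreementRegression:
    """Fit truth = m * estimate + b; bootstrap the 95% confidence band.

    The slope says how faithfully the estimate tracks changes in true
    speed (1 = perfect tracking); the intercept is the systematic offset.
    Test pairs are resampled with replacement, percentile method.
    """
    if len(preds) < 3:
        raise ValueError("agreement regression needs at least 3 predictions")
    est, truth = _arrays(preds)
    if np.ptp(est) == 0.0:
        raise ValueError("estimates have zero variance; regression undefined")
    m, b = _ols(est, truth)
    rng = np.random.default_rng(seed)
    n = len(est)
    slopes = np.empty(n_boot)
    intercepts = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        xb, yb = est[idx], truth[idx]
        if np.ptp(xb) == 0.0:  # degenerate resample: keep the point fit
            slopes[i], intercepts[i] = m, b
            continue
        slopes[i], intercepts[i] = _ols(xb, yb)
    return AgreementRegression(
        slope=m, intercept=b,
        slope_ci=(float(np.percentile(slopes, 2.5)),
                  float(np.percentile(slopes, 97.5))),
        intercept_ci=(float(np.percentile(intercepts, 2.5)),
                      float(np.percentile(intercepts, 97.5))),
        boot_slopes=slopes, boot_intercepts=intercepts,
    )


@dataclass
class AgreementReport:
    """Test-level agreement summary for one location combination."""

    n_tests: int
    rmse: float
    bias: float
    loa: tuple[float, float]
    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    residuals: np.ndarray

    def to_dict(self) -> dict:
        return {
            "n_tests": self.n_tests, "rmse_mps": self.rmse,
            "bias_mps": self.bias,
            "loa_mps": [self.loa[0], self.loa[1]],
            "slope": self.slope, "intercept": self.intercept,
            "slope_ci95": list(self.slope_ci),
            "intercept_ci95": list(self.intercept_ci),
        }


def agreement_report(preds: Sequence[TestPrediction], n_boot: int = 1000,
                     seed: int | None = None) -> AgreementReport:
    """RMSE + Bland-Altman + agreement regression in one report."""
    est, truth = _arrays(preds)
    bias, lo, hi = bland_altman(preds)
    reg = agreement_regression(preds, n_boot=n_boot, seed=seed)
    return AgreementReport(
        n_tests=len(preds), rmse=rmse(preds), bias=bias, loa=(lo, hi),
        slope=reg.slope, intercept=reg.intercept,
        slope_ci=reg.slope_ci, intercept_ci=reg.intercept_ci,
        residuals=est - truth,
    )


# ---------------------------------------------------------------------------
# clinical validity


def impairment_group(t25fw_speed: float) -> str:
    """Impairment group from the Timed-25-Foot-Walk comfortable speed.

    Mild: speed >= 1.1 m/s; Severe: speed <= 0.7 m/s; Moderate between.
    """
    if t25fw_speed < 0:
        raise ValueError("speed must be non-negative")
    if t25fw_speed >= 1.1:
        return "Mild"
    if t25fw_speed <= 0.7:
        return "Severe"
    return "Moderate"


def grouped_agreement(preds: Sequence[TestPrediction],
                      subjects: Sequence[SubjectRecord]
                      ) -> dict[str, dict]:
    """Per-impairment-group RMSE and LOA.

    Subjects without a T25FW speed are excluded from the grouping with a
    warning.
    """
    by_id = {s.subject_id: s for s in subjects}
    groups: dict[str, list[TestPrediction]] = {"Mild": [], "Moderate": [], "Severe": []}
    for p in preds:
        s = by_id.get(p.subject_id)
        if s is None or s.t25fw_speed is None:
            import logging
            logging.getLogger(__name__).warning(
                "subject %s lacks t25fw_speed; excluded from grouped analysis",
                p.subject_id)
            continue
        groups[impairment_group(s.t25fw_speed)].append(p)
    out = {}
    for name, gp in groups.items():
        if len(gp) < 2:
            out[name] = {"n_tests": len(gp), "rmse_mps": None, "loa_mps": None}
            continue
        bias, lo, hi = bland_altman(gp)
        out[name] = {"n_tests": len(gp), "rmse_mps": rmse(gp),
                     "bias_mps": bias, "loa_mps": [lo, hi]}
    return out


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if len(x) < 3:
        raise ValueError("Pearson correlation needs at least 3 pairs")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("zero variance; correlation undefined")
    r, p = sp_stats.pearsonr(x, y)  # two-sided p from t with n-2 df
    return float(r), float(p)


def error_score_correlation(preds: Sequence[TestPrediction],
                            subjects: Sequence[SubjectRecord],
                            score: str, per_subject: bool = False
                            ) -> tuple[float, float]:
    """Pearson r (and two-sided p) of test-level error against a score.

    ``score`` is ``"edss_sr"`` or ``"msws"``. By default each test is one
    observation; ``per_subject=True`` averages a subject's errors first.
    """
    if score not in ("edss_sr", "msws"):
        raise ValueError(f"unknown score {score!r}")
    by_id = {s.subject_id: s for s in subjects}
    err, sc = [], []
    for p in preds:
        s = by_id.get(p.subject_id)
        val = getattr(s, score, None) if s else None
        if val is None:
            continue
        err.append(p.error)
        sc.append(val)
    err, sc = np.asarray(err), np.asarray(sc)
    if per_subject:
        sid = [p.subject_id for p in preds
               if by_id.get(p.subject_id) and getattr(by_id[p.subject_id], score) is not None]
        df = pd.DataFrame({"sid": sid, "err": err, "sc": sc})
        agg = df.groupby("sid").mean()
        err, sc = agg["err"].to_numpy(), agg["sc"].to_numpy()
    return _pearson(err, sc)


def speed_score_correlation(speeds: Sequence[float], scores: Sequence[float]
                            ) -> tuple[float, float]:
    """Pearson r (and p) of comfortable walking speed against a score."""
    return _pearson(np.asarray(speeds, dtype=float),
                    np.asarray(scores, dtype=float))


def fall_group_test(speeds: Sequence[float], fell: Sequence[bool]
                    ) -> tuple[float, float, float]:
    """Compare comfortable speed between fallers and non-fallers.

    Returns (mean(Fall) - mean(NoFall) in m/s, Mann-Whitney U of the Fall
    group, two-sided p). The U test is exact when the smaller group has
    <= 8 subjects and there are no ties, else the tie-corrected normal
    approximation.
    """
    speeds = np.asarray(speeds, dtype=float)
    fell = np.asarray(fell, dtype=bool)
    if len(speeds) != len(fell):
        raise ValueError("speeds and fall flags must align")
    fall = speeds[fell]
    nofall = speeds[~fell]
    if len(fall) == 0 or len(nofall) == 0:
        raise ValueError("both fall groups must be nonempty")
    ties = len(np.unique(speeds)) < len(speeds)
    if min(len(fall), len(nofall)) <= 8 and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sp_stats.mannwhitneyu(fall, nofall, alternative="two-sided",
                                method=method)
    return (float(fall.mean() - nofall.mean()), float(res.statistic),
            float(res.pvalue))


def clinical_validity_report(preds: Sequence[TestPrediction],
                             subjects: Sequence[SubjectRecord],
                             comfortable_test_ids: Mapping[str, str] | None = None
                             ) -> dict:
    """Error/score correlations, grouped error, and fall-group comparison.

    ``comfortable_test_ids`` maps subject_id to the test id of that
    subject's comfortable-speed walk; when given, speed-score correlations
    and the fall comparison use those tests' estimated and true speeds.
    """
    report: dict = {"alpha": ALPHA}
    for score in ("edss_sr", "msws"):
        try:
            r, p = error_score_correlation(preds, subjects, score)
            report[f"error_vs_{score}"] = {"r": r, "p": p,
                                           "significant": p < ALPHA}
        except ValueError as e:
            report[f"error_vs_{score}"] = {"error": str(e)}
    report["by_impairment_group"] = grouped_agreement(preds, subjects)
    if comfortable_test_ids:
        by_id = {s.subject_id: s for s in subjects}
        rows = []
        for p in preds:
            if comfortable_test_ids.get(p.subject_id) != p.test_id:
                continue
            s = by_id.get(p.subject_id)
            if s is None:
                continue
            rows.append((s, p))
        for score in ("edss_sr", "msws"):
            pairs = [(p, getattr(s, score)) for s, p in rows
                     if getattr(s, score) is not None]
            if len(pairs) >= 3:
                entry: dict = {}
                try:
                    est_r, est_p = speed_score_correlation(
                        [p.median_estimate for p, _ in pairs],
                        [v for _, v in pairs])
                    entry["estimated"] = {"r": est_r, "p": est_p}
                except ValueError as e:
                    entry["estimated"] = {"error": str(e)}
                try:
                    tr_r, tr_p = speed_score_correlation(
                        [p.truth for p, _ in pairs], [v for _, v in pairs])
                    entry["ground_truth"] = {"r": tr_r, "p": tr_p}
                except ValueError as e:
                    entry["ground_truth"] = {"error": str(e)}
                report[f"speed_vs_{score}"] = entry
        flagged = [(s, p) for s, p in rows if s.fell_last_6mo is not None]
        if flagged and any(s.fell_last_6mo for s, _ in flagged) \
                and any(not s.fell_last_6mo for s, _ in flagged):
            entry = {}
            for label, values in (
                    ("estimated", [p.median_estimate for s, p in flagged]),
                    ("ground_truth", [p.truth for s, p in flagged])):
                try:
                    d, _, p_val = fall_group_test(
                        values, [s.fell_last_6mo for s, _ in flagged])
                    entry[label] = {"diff_mps": d, "p": p_val}
                except (ValueError, ZeroDivisionError) as e:
                    entry[label] = {"error": str(e)}
            report["fall_speed_difference"] = entry
    return report
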