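"""Calibration of accumulated counts into seconds, and report metrics.

The accumulators yield abstract units of subjective time.  To compare with
durations in seconds, an epsilon-SVR (RBF kernel) maps the per-layer count
vector of each trial to the trial's *physical* duration under k-fold
cross-validation — the regression is trained on physical durations only,
never on human reports, which enter (if at all) solely as a reference
series for RMSE.  All scene types are pooled in a single regression, so any
scene-wise biases in the estimates reflect the change statistics of the
scenes, not per-scene fitting.

The deliberately small error penalty (1e-3) keeps the regressor heavily
regularised: estimates compress toward the middle of the trained range,
which is exactly the regression-to-the-mean (Vierordt) character of human
duration reports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .thresholds import AccumulatorVector

__all__ = [
    "CalibrationSpec",
    "EstimateSet",
    "fit_and_predict_cv",
    "fit_cv_models",
    "predict_with_models",
    "compute_nme",
    "compute_rmse",
    "scene_bias_deviations",
    "variance_by_duration",
]


@dataclass(frozen=True)
class CalibrationSpec:
    """epsilon-SVR hyperparameters and the cross-validation layout.

    Defaults: RBF kernel with coefficient (gamma) 1e-4, error penalty 1e-3,
    10 folds.  ``epsilon`` (the insensitivity width) defaults to the common
    library default 0.1.  ``standardize`` optionally z-scores the count
    features (off by default: raw counts are the features).
    """

    kernel: str = "rbf"
    kernel_coefficient: float = 1e-4
    penalty: float = 1e-3
    epsilon: float = 0.1
    n_folds: int = 10
    fold_seed: int = 0
    standardize: bool = False
    penalty_reference_n: int | None = None

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if min(self.kernel_coefficient, self.penalty, self.epsilon) <= 0:
            raise ValueError("SVR hyperparameters must be positive")
        if self.penalty_reference_n is not None and self.penalty_reference_n < 1:
            raise ValueError("penalty_reference_n must be positive")

    def effective_penalty(self, n_train: int) -> float:
        """Per-sample penalty actually used for a fit on ``n_train`` trials.

        The SVR penalty bounds each trial's dual coefficient, so the total
        capacity of the fitted function scales with n_train * C.  When
        ``penalty_reference_n`` is set, the per-sample penalty is rescaled
        by reference_n / n_train so a scaled-down design keeps the same
        total capacity as the reference experiment (at the reference size
        the factor is exactly 1).
        """
        if self.penalty_reference_n is None:
            return self.penalty
        return self.penalty * self.penalty_reference_n / max(n_train, 1)

    def make_svr(self, n_train: int | None = None) -> SVR:
        return SVR(
            kernel=self.kernel,
            gamma=self.kernel_coefficient,
            C=self.effective_penalty(n_train) if n_train else self.penalty,
            epsilon=self.epsilon,
        )


@dataclass
class EstimateSet:
    """Out-of-fold duration estimates for a set of trials.

    ``frame`` columns: trial_id, regime, scene_type, true_s, predicted_s,
    predicted_clamped_s, fold.  Negative raw predictions are kept as-is;
    the clamped column floors them at zero.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {
            "trial_id", "regime", "scene_type", "true_s",
            "predicted_s", "predicted_clamped_s", "fold",
        }
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"EstimateSet missing columns {sorted(missing)}")
        if not np.isfinite(self.frame["predicted_s"]).all():
            raise ValueError("non-finite prediction")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def durations(self) -> np.ndarray:
        """Distinct true durations, ascending."""
        return np.sort(self.frame["true_s"].unique())

    def mean_estimates_by_duration(self) -> pd.Series:
        return self.frame.groupby("true_s")["predicted_s"].mean()

    def loglog_slope(self) -> float:
        """Slope of log mean estimate vs log true duration (clamped means)."""
        m = self.frame.groupby("true_s")["predicted_s"].mean()
        m = m[m > 0]
        return float(
            stats.linregress(np.log(m.index.to_numpy()), np.log(m.to_numpy())).slope
        )

    def rank_correlation(self, by_fold: bool = True) -> float:
        """Spearman rank correlation between predictions and true durations.

        Each fold's regressor carries its own intercept (roughly the median
        duration of its training trials), so predictions from different
        folds differ by an additive nuisance offset that says nothing about
        duration discrimination.  The default therefore rank-correlates
        within each fold and averages across folds; ``by_fold=False`` pools
        all out-of-fold predictions instead.
        """
        df = self.frame
        if not by_fold:
            return float(stats.spearmanr(df["predicted_s"], df["true_s"]).statistic)
        rhos = [
            stats.spearmanr(g["predicted_s"], g["true_s"]).statistic
            for _, g in df.groupby("fold")
            if g["true_s"].nunique() > 1
        ]
        if not rhos:
            raise ValueError("no fold with more than one distinct duration")
        return float(np.mean(rhos))


def _design_matrix(
    accumulators: Sequence[AccumulatorVector], layer_order: Sequence[str] | None
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if not accumulators:
        raise ValueError("no trials")
    if layer_order is None:
        layer_order = list(accumulators[0].counts)
    X = np.stack([a.as_array(layer_order) for a in accumulators])
    y = np.array([a.duration_s for a in accumulators], dtype=np.float64)
    if np.isnan(y).any():
        raise ValueError("every trial needs a true duration_s")
    return X, y, list(layer_order)


def fit_cv_models(
    X: np.ndarray,
    y: np.ndarray,
    spec: CalibrationSpec,
    train_duration_range: tuple[float, float] | None = None,
) -> list[tuple[np.ndarray, np.ndarray, object, object]]:
    """Fit one SVR per fold; return (train_idx, test_idx, model, scaler).

    ``train_duration_range`` optionally restricts each fold's *training*
    trials to durations inside [lo, hi] (test trials are untouched),
    mimicking block-wise range regression.
    """
    if len(y) < spec.n_folds:
        raise ValueError(f"need at least n_folds={spec.n_folds} trials, got {len(y)}")
    if np.ptp(y) == 0:
        warnings.warn("constant targets: predictions will sit at that constant")
    kf = KFold(n_splits=spec.n_folds, shuffle=True, random_state=spec.fold_seed)
    models = []
    for train_idx, test_idx in kf.split(X):
        if train_duration_range is not None:
            lo, hi = train_duration_range
            keep = (y[train_idx] >= lo) & (y[train_idx] <= hi)
            if not keep.any():
                raise ValueError("train_duration_range excludes all training trials")
            train_idx = train_idx[keep]
        scaler = None
        Xtr = X[train_idx]
        if spec.standardize:
            scaler = StandardScaler().fit(Xtr)
            Xtr = scaler.transform(Xtr)
        model = spec.make_svr(n_train=len(train_idx)).fit(Xtr, y[train_idx])
        models.append((train_idx, test_idx, model, scaler))
    return models


def predict_with_models(
    models, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Out-of-fold predictions for ``X`` under a fitted fold layout.

    Reuses the fold partition the models were fitted with, so counts
    obtained under a different condition (e.g. another attention level) can
    be pushed through a calibration learned under the baseline condition.
    """
    pred = np.full(len(X), np.nan)
    fold = np.full(len(X), -1)
    for k, (_, test_idx, model, scaler) in enumerate(models):
        Xt = X[test_idx]
        if scaler is not None:
            Xt = scaler.transform(Xt)
        pred[test_idx] = model.predict(Xt)
        fold[test_idx] = k
    if np.isnan(pred).any():
        raise RuntimeError("fold layout does not cover every trial")
    return pred, fold


def fit_and_predict_cv(
    accumulators: Sequence[AccumulatorVector],
    spec: CalibrationSpec | None = None,
    layer_order: Sequence[str] | None = None,
    regime: str = "full_frame",
    train_duration_range: tuple[float, float] | None = None,
) -> EstimateSet:
    """Cross-validated count-to-seconds calibration.

    Every trial is predicted exactly once, by the model of the fold in
    which it was held out; fold sizes differ by at most one.  Trials are
    sorted by trial_id before the fold split, so the result is a function
    of (trials, fold_seed) alone, not of input order; output rows follow
    the sorted order.
    """
    spec = spec or CalibrationSpec()
    accumulators = sorted(accumulators, key=lambda a: a.trial_id)
    X, y, _ = _design_matrix(accumulators, layer_order)
    models = fit_cv_models(X, y, spec, train_duration_range)
    pred, fold = predict_with_models(models, X)
    frame = pd.DataFrame(
        {
            "trial_id": [a.trial_id for a in accumulators],
            "regime": regime,
            "scene_type": [a.scene_type for a in accumulators],
            "true_s": y,
            "predicted_s": pred,
            "predicted_clamped_s": np.maximum(pred, 0.0),
            "fold": fold,
        }
    )
    return EstimateSet(frame=frame)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def compute_nme(estimates: EstimateSet) -> dict:
    """Normalised mean error: (predicted - true)/true per trial.

    Returns per-duration means and an overall mean that weights the
    duration levels equally (not by trial count).
    """
    df = estimates.frame
    if df.empty:
        raise ValueError("empty estimate set")
    if (df["true_s"] <= 0).any():
        raise ValueError("true duration must be positive for NME")
    err = (df["predicted_s"] - df["true_s"]) / df["true_s"]
    per_duration = err.groupby(df["true_s"]).mean()
    return {
        "nme_per_duration": per_duration.to_dict(),
        "nme_overall": float(per_duration.mean()),
    }


def compute_rmse(
    estimates: EstimateSet, reference: np.ndarray | pd.Series | None = None
) -> float:
    """Root-mean-squared error of the estimates, in seconds.

    Against the physical durations by default; pass ``reference`` (e.g.
    human reports, aligned to the same trials) to score against an external
    series instead.
    """
    df = estimates.frame
    if df.empty:
        raise ValueError("empty estimate set")
    ref = df["true_s"].to_numpy() if reference is None else np.asarray(reference)
    if len(ref) != len(df):
        raise ValueError(f"reference length {len(ref)} != {len(df)} trials")
    return float(np.sqrt(np.mean((df["predicted_s"].to_numpy() - ref) ** 2)))


def scene_bias_deviations(
    estimates: EstimateSet, per_duration: bool = True
) -> dict:
    """Mean deviation of each scene's estimates from the grand mean, in %.

    Default: within each duration level, each scene's mean estimate is
    expressed as a percentage deviation from that level's grand mean, then
    averaged over levels (equal weight per level).  ``per_duration=False``
    pools all trials instead.  Scenes missing at some duration simply omit
    that cell (with a warning).
    """
    df = estimates.frame
    scenes = df["scene_type"].unique()
    if len(scenes) < 2:
        raise ValueError("scene bias needs at least 2 scene types")
    if not per_duration:
        grand = df["predicted_s"].mean()
        by_scene = df.groupby("scene_type")["predicted_s"].mean()
        scores = (100.0 * (by_scene - grand) / grand).to_dict()
        return {"scene_deviation_pct": scores, "per_duration": {}}
    cells = []
    for dur, g in df.groupby("true_s"):
        grand = g["predicted_s"].mean()
        present = g["scene_type"].unique()
        absent = set(scenes) - set(present)
        if absent:
            warnings.warn(f"duration {dur}: no trials for scenes {sorted(absent)}")
        for scene, gs in g.groupby("scene_type"):
            cells.append(
                {
                    "true_s": dur,
                    "scene_type": scene,
                    "deviation_pct": 100.0 * (gs["predicted_s"].mean() - grand) / grand,
                    "n_trials": len(gs),
                }
            )
    table = pd.DataFrame(cells)
    scores = table.groupby("scene_type")["deviation_pct"].mean().to_dict()
    ranking = sorted(scores, key=scores.get, reverse=True)
    return {
        "scene_deviation_pct": scores,
        "scene_order": ranking,
        "per_duration": table,
    }


def variance_by_duration(estimates: EstimateSet) -> dict:
    """Per-duration mean and SD of estimates, and the SD-versus-mean slope.

    A slope close to the coefficient of variation of the estimates is the
    scalar-variability (Weber-for-time) signature: spread growing in
    proportion to the estimated duration.  Durations with a single trial
    are omitted (SD undefined).
    """
    df = estimates.frame
    g = df.groupby("true_s")["predicted_s"]
    table = g.agg(mean="mean", sd="std", n="count").reset_index()
    kept = table[table["n"] >= 2]
    if len(kept) < 2:
        raise ValueError("need >= 2 durations with >= 2 trials each")
    fit = stats.linregress(kept["mean"].to_numpy(), kept["sd"].to_numpy())
    return {
        "per_duration": kept,
        "sd_vs_mean_slope": float(fit.slope),
        "sd_vs_mean_stderr": float(fit.stderr),
    }
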