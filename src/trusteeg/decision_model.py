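"""Decoding trust vs distrust decisions from MEC features.

The decoder is an L2-regularized logistic regression on the 148 per-parcel
charge features, fit on observations restricted to SCL 70/90 % (the 50 %
level is the random-response baseline and is excluded).  Each observation
is one (participant, SCL, decision) cell; train/test partitions and
cross-validation folds are grouped by participant so that no participant
straddles a split.

Coefficient uncertainty comes from a nonparametric bootstrap: observations
are resampled with replacement, the model refit, and per-area coefficients
summarized by their mean and percentile confidence interval.  A reduced
model keeps only the top-k areas by mean absolute coefficient (k = 28 by
default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)

from .containers import TRUST
from .errors import ConfigError, DataError
from .labels import PARCEL_LABELS
from .mec import META_COLUMNS

DEFAULT_N_BOOT = 10_000
DEFAULT_TOP_K = 28
DEFAULT_TEST_FRACTION = 0.2
EXCLUDED_SCL = 50


@dataclass
class ObservationSet:
    """Feature matrix + binary labels (1 = trust) + participant groups."""

    features: pd.DataFrame      # rows x parcels, fixed column order
    y: np.ndarray               # 0/1
    groups: np.ndarray          # participant ids
    scl: np.ndarray

    def __post_init__(self) -> None:
        if len(self.features) != len(self.y):
            raise DataError("features and labels disagree in length")

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    def subset(self, mask: np.ndarray) -> "ObservationSet":
        mask = np.asarray(mask, dtype=bool)
        return ObservationSet(
            features=self.features.loc[mask].reset_index(drop=True),
            y=self.y[mask],
            groups=self.groups[mask],
            scl=self.scl[mask],
        )


@dataclass
class FittedModel:
    """Standardization statistics plus the refit logistic model."""

    estimator: LogisticRegression
    mean: np.ndarray
    scale: np.ndarray
    feature_names: list[str]

    def _transform(self, features: pd.DataFrame) -> np.ndarray:
        x = features[self.feature_names].to_numpy(float)
        return (x - self.mean) / self.scale

    def predict(self, obs: ObservationSet) -> np.ndarray:
        return self.estimator.predict(self._transform(obs.features))

    def predict_proba(self, obs: ObservationSet) -> np.ndarray:
        return self.estimator.predict_proba(self._transform(obs.features))[:, 1]


@dataclass
class Metrics:
    """Classification quality measures plus the confusion matrix.

    ``confusion_raw[i, j]``: true class i (0 = distrust, 1 = trust)
    predicted as j.  ``confusion_pct`` row-normalizes to percentages.
    """

    accuracy: float
    f1: float
    precision: float
    recall: float
    auc: float | None
    confusion_raw: np.ndarray
    confusion_pct: np.ndarray
    n_obs: int
    per_fold: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "f1": self.f1,
            "precision": self.precision,
            "recall": self.recall,
            "auc": self.auc,
            "confusion_raw": self.confusion_raw.tolist(),
            "confusion_pct": self.confusion_pct.tolist(),
            "n_obs": self.n_obs,
            "per_fold": self.per_fold,
        }


def assemble_observations(mec_table: pd.DataFrame) -> ObservationSet:
    """Build the decoder's observation set from a MEC feature table.

    Drops SCL = 50 rows; remaining rows become observations labeled by the
    decision, grouped by participant.
    """
    if len(mec_table) == 0:
        raise DataError("MEC table is empty")
    keep = mec_table["scl"] != EXCLUDED_SCL
    table = mec_table.loc[keep].reset_index(drop=True)
    if len(table) == 0:
        raise DataError("no observations left after excluding SCL=50")
    parcel_cols = [c for c in table.columns if c not in META_COLUMNS]
    # keep the canonical parcel order where applicable; custom parcel sets
    # (reduced head models in tests) pass through in their own order
    ordered = [c for c in PARCEL_LABELS if c in parcel_cols] or parcel_cols
    return ObservationSet(
        features=table[ordered],
        y=(table["decision"] == TRUST).to_numpy(int),
        groups=table["participant"].to_numpy(int),
        scl=table["scl"].to_numpy(int),
    )


def split_by_participant(
    obs: ObservationSet,
    test_fraction: float = DEFAULT_TEST_FRACTION,
    seed: int = 0,
) -> tuple[ObservationSet, ObservationSet]:
    """Random participant-level holdout split (participants, not rows)."""
    if not 0.0 < test_fraction < 1.0:
        raise ConfigError("test fraction must be in (0, 1)")
    participants = np.unique(obs.groups)
    if len(participants) < 2:
        raise DataError("need at least two participants to split")
    rng = np.random.default_rng(seed)
    n_test = max(1, int(round(test_fraction * len(participants))))
    test_ids = rng.choice(participants, size=n_test, replace=False)
    test_mask = np.isin(obs.groups, test_ids)
    return obs.subset(~test_mask), obs.subset(test_mask)


def _new_estimator(c: float = 1.0) -> LogisticRegression:
    # default penalty is the L2 ridge; C is its inverse strength
    return LogisticRegression(C=c, solver="lbfgs", max_iter=5000, tol=1e-10)


def fit_logistic_bootstrap(
    train: ObservationSet,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    c: float = 1.0,
) -> tuple[FittedModel, pd.DataFrame]:
    """Fit the decoder and bootstrap its coefficients.

    Features are standardized on training statistics.  The returned report
    has one row per area: bootstrap-mean coefficient, 2.5/97.5 percentile
    interval, and rank by mean |coefficient| (ties broken by the fixed
    parcel order).  ``n_boot = 0`` skips resampling (the report then holds
    the point estimate with degenerate intervals).
    """
    if len(np.unique(train.y)) < 2:
        raise DataError("training set contains a single class")
    x = train.features.to_numpy(float)
    mean = x.mean(axis=0)
    scale = x.std(axis=0, ddof=0)
    scale[scale == 0] = 1.0
    xs = (x - mean) / scale

    final = _new_estimator(c)
    final.fit(xs, train.y)
    model = FittedModel(
        estimator=final, mean=mean, scale=scale, feature_names=train.feature_names
    )

    rng = np.random.default_rng(seed)
    n = len(train.y)
    if n_boot > 0:
        betas = np.empty((n_boot, x.shape[1]))
        for b in range(n_boot):
            while True:
                idx = rng.integers(0, n, size=n)
                if len(np.unique(train.y[idx])) == 2:
                    break
            est = _new_estimator(c)
            est.fit(xs[idx], train.y[idx])
            betas[b] = est.coef_[0]
        beta_mean = betas.mean(axis=0)
        ci_low = np.percentile(betas, 2.5, axis=0)
        ci_high = np.percentile(betas, 97.5, axis=0)
        n_boot_done = n_boot
    else:
        beta_mean = final.coef_[0]
        ci_low = beta_mean.copy()
        ci_high = beta_mean.copy()
        n_boot_done = 0

    report = pd.DataFrame(
        {
            "parcel": train.feature_names,
            "beta_mean": beta_mean,
            "ci_low": ci_low,
            "ci_high": ci_high,
        }
    )
    # rank 1 = largest |beta|; ties broken by the fixed parcel order
    order = np.lexsort((np.arange(len(report)), -np.abs(beta_mean)))
    ranks = np.empty(len(report), dtype=int)
    ranks[order] = np.arange(1, len(report) + 1)
    report["rank"] = ranks
    report.attrs["n_boot"] = n_boot_done
    return model, report


def select_top_areas(report: pd.DataFrame, k: int = DEFAULT_TOP_K) -> list[str]:
    """The k areas with largest mean |coefficient| (fixed-order tie-break)."""
    if not 1 <= k <= len(report):
        raise ConfigError(f"k must be in [1, {len(report)}]")
    return report.sort_values("rank").head(k)["parcel"].tolist()


def _metrics_from_predictions(
    y_true: np.ndarray, y_pred: np.ndarray, proba: np.ndarray | None
) -> Metrics:
    conf = np.zeros((2, 2), dtype=int)
    for t, p in zip(y_true, y_pred):
        conf[int(t), int(p)] += 1
    row_sums = conf.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(row_sums > 0, 100.0 * conf / row_sums, np.nan)
    auc = None
    if proba is not None and len(np.unique(y_true)) == 2:
        auc = float(roc_auc_score(y_true, proba))
    return Metrics(
        accuracy=float(accuracy_score(y_true, y_pred)),
        f1=float(f1_score(y_true, y_pred, zero_division=0)),
        precision=float(precision_score(y_true, y_pred, zero_division=0)),
        recall=float(recall_score(y_true, y_pred, zero_division=0)),
        auc=auc,
        confusion_raw=conf,
        confusion_pct=pct,
        n_obs=len(y_true),
    )


def evaluate(model: FittedModel, test: ObservationSet) -> Metrics:
    """All quality measures of a fitted model on a held-out set.

    AUC is omitted (None, with the fact recorded in the metrics) when the
    test set contains a single class.
    """
    if test.n_obs == 0:
        raise DataError("empty test set")
    pred = model.predict(test)
    proba = model.predict_proba(test)
    return _metrics_from_predictions(test.y, pred, proba)


def crossvalidate(
    obs: ObservationSet,
    k_folds: int = 10,
    seed: int = 0,
    n_features: list[str] | None = None,
    c: float = 1.0,
) -> Metrics:
    """Participant-grouped k-fold cross-validation.

    Participants are shuffled once (seeded) and partitioned into k folds;
    each fold's observations are predicted by a model trained on the rest.
    Pooled out-of-fold predictions give the headline metrics; per-fold
    metrics are kept in ``Metrics.per_fold``.
    """
    if k_folds < 2:
        raise ConfigError("need at least two folds")
    participants = np.unique(obs.groups)
    if len(participants) < k_folds:
        raise DataError(
            f"{len(participants)} participants cannot fill {k_folds} folds"
        )
    if n_features is not None:
        obs = ObservationSet(
            features=obs.features[n_features],
            y=obs.y,
            groups=obs.groups,
            scl=obs.scl,
        )
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(participants)
    folds = np.array_split(shuffled, k_folds)

    y_pool: list[np.ndarray] = []
    pred_pool: list[np.ndarray] = []
    proba_pool: list[np.ndarray] = []
    per_fold = []
    for i, fold_ids in enumerate(folds):
        test_mask = np.isin(obs.groups, fold_ids)
        train, test = obs.subset(~test_mask), obs.subset(test_mask)
        model, _ = fit_logistic_bootstrap(train, n_boot=0, seed=seed, c=c)
        pred = model.predict(test)
        proba = model.predict_proba(test)
        y_pool.append(test.y)
        pred_pool.append(pred)
        proba_pool.append(proba)
        fold_m = _metrics_from_predictions(test.y, pred, proba)
        per_fold.append(
            {
                "fold": i,
                "n_obs": fold_m.n_obs,
                "accuracy": fold_m.accuracy,
                "f1": fold_m.f1,
            }
        )
    metrics = _metrics_from_predictions(
        np.concatenate(y_pool), np.concatenate(pred_pool), np.concatenate(proba_pool)
    )
    metrics.per_fold = per_fold
    return metrics
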