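"""Decoder tests: bookkeeping oracles, IRLS agreement, metric arithmetic."""

import numpy as np
import pandas as pd
import pytest

from trusteeg.containers import DISTRUST, TRUST
from trusteeg.decision_model import (
    ObservationSet,
    assemble_observations,
    crossvalidate,
    evaluate,
    fit_logistic_bootstrap,
    select_top_areas,
    split_by_participant,
)
from trusteeg.errors import DataError
from trusteeg.labels import PARCEL_LABELS


def synthetic_mec_table(n_participants=110, rng=None, scls=(50, 70, 90),
                        effect=0.0, effect_cols=()):
    """Full-cell MEC table with Gaussian features (one row per cell)."""
    rng = rng or np.random.default_rng(0)
    rows = []
    for pid in range(n_participants):
        for scl in scls:
            for dec in (TRUST, DISTRUST):
                feats = rng.normal(size=len(PARCEL_LABELS))
                row = dict(zip(PARCEL_LABELS, feats))
                if dec == TRUST and effect:
                    for c in effect_cols:
                        row[c] += effect
                rows.append(
                    {"participant": pid, "scl": scl, "decision": dec,
                     "n_trials": 10, **row}
                )
    return pd.DataFrame(rows)


def irls_oracle(x, y, c=1.0, max_iter=200):
    """Independent Newton/IRLS solver of the L2-penalized logistic objective
    0.5 ||w||^2 + c * sum log(1 + exp(-y~ (x w + b))) with free intercept."""
    n, p = x.shape
    xb = np.hstack([x, np.ones((n, 1))])
    theta = np.zeros(p + 1)
    pen = np.eye(p + 1)
    pen[-1, -1] = 0.0  # intercept unpenalized
    for _ in range(max_iter):
        f = xb @ theta
        prob = 1.0 / (1.0 + np.exp(-f))
        grad = pen @ theta + c * xb.T @ (prob - y)
        w = prob * (1 - prob)
        hess = pen + c * (xb.T * w) @ xb
        step = np.linalg.solve(hess, grad)
        theta -= step
        if np.abs(grad).max() < 1e-12:
            break
    return theta[:p], theta[p]


class TestBookkeeping:
    def test_observation_counts_and_split(self):
        """110 full-cell participants: 440 observations after excluding
        SCL=50; a 22-participant holdout leaves 352 train / 88 test rows."""
        table = synthetic_mec_table(110)
        obs = assemble_observations(table)
        assert obs.n_obs == 440
        assert set(np.unique(obs.scl)) == {70, 90}
        train, test = split_by_participant(obs, test_fraction=0.2, seed=0)
        assert len(np.unique(test.groups)) == 22
        assert train.n_obs == 352
        assert test.n_obs == 88

    def test_only_scl50_rows_rejected(self):
        table = synthetic_mec_table(5, scls=(50,))
        with pytest.raises(DataError):
            assemble_observations(table)

    def test_feature_column_order_is_canonical(self):
        table = synthetic_mec_table(3)
        obs = assemble_observations(table)
        assert obs.feature_names == PARCEL_LABELS

    def test_split_deterministic_and_disjoint(self):
        obs = assemble_observations(synthetic_mec_table(30))
        for seed in (0, 1, 7):
            tr1, te1 = split_by_participant(obs, seed=seed)
            tr2, te2 = split_by_participant(obs, seed=seed)
            assert np.array_equal(te1.groups, te2.groups)
            assert not set(tr1.groups) & set(te1.groups)


class TestLogisticFit:
    def test_sign_recovery_on_separable_toy(self, rng):
        n = 60
        x = rng.normal(size=(n, 2))
        y = (x[:, 0] - x[:, 1] > 0).astype(int)
        obs = ObservationSet(
            features=pd.DataFrame(x, columns=["a", "b"]),
            y=y, groups=np.arange(n), scl=np.full(n, 70),
        )
        model, report = fit_logistic_bootstrap(obs, n_boot=0, seed=0)
        betas = dict(zip(report.parcel, report.beta_mean))
        assert betas["a"] > 0 > betas["b"]

    def test_matches_irls_oracle(self, rng):
        """The fitted coefficients equal an independent IRLS solve, 1e-6."""
        n = 80
        x = rng.normal(size=(n, 2))
        logit = 0.8 * x[:, 0] - 0.5 * x[:, 1]
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
        obs = ObservationSet(
            features=pd.DataFrame(x, columns=["a", "b"]),
            y=y, groups=np.arange(n), scl=np.full(n, 70),
        )
        model, report = fit_logistic_bootstrap(obs, n_boot=0, seed=0, c=1.0)
        xs = (x - x.mean(0)) / x.std(0)
        want_w, want_b = irls_oracle(xs, y, c=1.0)
        assert np.allclose(report.beta_mean.to_numpy(), want_w, atol=1e-6)
        assert model.estimator.intercept_[0] == pytest.approx(want_b, abs=1e-6)

    def test_single_class_rejected(self, rng):
        obs = ObservationSet(
            features=pd.DataFrame(rng.normal(size=(10, 3))),
            y=np.ones(10, dtype=int), groups=np.arange(10), scl=np.full(10, 70),
        )
        with pytest.raises(DataError):
            fit_logistic_bootstrap(obs, n_boot=0, seed=0)

    def test_permuted_labels_cis_cover_zero(self):
        """On label-permuted data, nearly all bootstrap CIs contain zero."""
        rng = np.random.default_rng(3)
        table = synthetic_mec_table(40, rng=rng, scls=(70, 90))
        obs = assemble_observations(table)
        perm = ObservationSet(
            features=obs.features,
            y=rng.permutation(obs.y),
            groups=obs.groups, scl=obs.scl,
        )
        _, report = fit_logistic_bootstrap(perm, n_boot=300, seed=0)
        covers = (report.ci_low <= 0) & (0 <= report.ci_high)
        assert covers.mean() >= 0.90


class TestSelection:
    def test_default_k(self):
        report = pd.DataFrame(
            {"parcel": PARCEL_LABELS,
             "beta_mean": np.linspace(1, 0, 148),
             "rank": np.arange(1, 149)}
        )
        assert len(select_top_areas(report)) == 28

    def test_all_equal_betas_fixed_order_tiebreak(self, rng):
        n = 60
        obs = ObservationSet(
            features=pd.DataFrame(
                rng.normal(size=(n, 5)), columns=list("abcde")
            ),
            y=rng.integers(0, 2, size=n), groups=np.arange(n),
            scl=np.full(n, 70),
        )
        _, report = fit_logistic_bootstrap(obs, n_boot=0, seed=0)
        report["beta_mean"] = 1.0
        order = np.lexsort((np.arange(5), -np.abs(report.beta_mean)))
        ranks = np.empty(5, int)
        ranks[order] = np.arange(1, 6)
        report["rank"] = ranks
        assert select_top_areas(report, 3) == ["a", "b", "c"]

    def test_k_equal_total_is_identity(self):
        report = pd.DataFrame(
            {"parcel": list("abc"), "beta_mean": [0.3, -0.9, 0.1],
             "rank": [2, 1, 3]}
        )
        assert set(select_top_areas(report, 3)) == {"a", "b", "c"}


class TestMetrics:
    @staticmethod
    def _obs(x, y):
        return ObservationSet(
            features=pd.DataFrame(x), y=np.asarray(y),
            groups=np.arange(len(y)), scl=np.full(len(y), 70),
        )

    def test_hand_arithmetic(self):
        """pred [1,1,0,0] vs truth [1,0,0,1]: all measures are 0.5."""
        from trusteeg.decision_model import _metrics_from_predictions

        m = _metrics_from_predictions(
            np.array([1, 0, 0, 1]), np.array([1, 1, 0, 0]), None
        )
        assert m.accuracy == m.precision == m.recall == m.f1 == 0.5
        assert m.confusion_raw.tolist() == [[1, 1], [1, 1]]
        assert np.allclose(m.confusion_pct, 50.0)

    def test_perfect_predictions(self, rng):
        x = rng.normal(size=(40, 2))
        y = (x[:, 0] > 0).astype(int)
        x[:, 0] += 10 * (2 * y - 1)  # widen the margin
        obs = self._obs(x, y)
        model, _ = fit_logistic_bootstrap(obs, n_boot=0, seed=0)
        m = evaluate(model, obs)
        assert m.accuracy == m.f1 == m.auc == 1.0

    def test_constant_trust_predictor_on_balanced_set(self):
        from trusteeg.decision_model import _metrics_from_predictions

        y = np.array([1, 1, 0, 0])
        m = _metrics_from_predictions(y, np.ones(4, dtype=int), None)
        assert m.accuracy == 0.5
        assert m.recall == 1.0

    def test_f1_is_harmonic_mean(self, rng):
        from trusteeg.decision_model import _metrics_from_predictions

        y = rng.integers(0, 2, size=50)
        pred = rng.integers(0, 2, size=50)
        m = _metrics_from_predictions(y, pred, None)
        if m.precision + m.recall > 0:
            want = 2 * m.precision * m.recall / (m.precision + m.recall)
            assert m.f1 == pytest.approx(want)


class TestCrossValidation:
    def test_fold_grouping_and_determinism(self):
        obs = assemble_observations(synthetic_mec_table(25, scls=(70, 90)))
        m1 = crossvalidate(obs, k_folds=5, seed=3)
        m2 = crossvalidate(obs, k_folds=5, seed=3)
        assert m1.accuracy == m2.accuracy
        assert len(m1.per_fold) == 5
        assert sum(f["n_obs"] for f in m1.per_fold) == obs.n_obs

    def test_too_few_participants_rejected(self):
        obs = assemble_observations(synthetic_mec_table(4, scls=(70, 90)))
        with pytest.raises(DataError):
            crossvalidate(obs, k_folds=10, seed=0)

    def test_informative_features_decoded(self):
        """Planted class separation is recovered by grouped CV."""
        rng = np.random.default_rng(9)
        table = synthetic_mec_table(
            30, rng=rng, scls=(70, 90), effect=1.5,
            effect_cols=PARCEL_LABELS[:10],
        )
        obs = assemble_observations(table)
        m = crossvalidate(obs, k_folds=5, seed=0)
        assert m.accuracy > 0.8
        assert m.auc > 0.85
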