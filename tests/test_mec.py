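"""Mean-electric-charge tests: integration oracles and feature assembly."""

import numpy as np
import pandas as pd
import pytest

from trusteeg.containers import DISTRUST, TRUST, EpochSet
from trusteeg.errors import ConfigError
from trusteeg.inverse import AreaCurrent
from trusteeg.labels import PARCEL_LABELS
from trusteeg.mec import (
    TimeInterval,
    baseline_correct_area,
    compute_mec,
    mec_features,
)
from trusteeg.synthdata import ChoiceModel, ExperimentSpec, simulate_decisions, simulate_epochs


def _area(current, sfreq=500.0, tmin_ms=0.0):
    current = np.atleast_2d(current)
    return AreaCurrent(
        current=current,
        parcel_labels=[f"P{i}" for i in range(current.shape[0])],
        sfreq=sfreq,
        tmin_ms=tmin_ms,
    )


class TestInterval:
    def test_off_grid_endpoint_rejected(self):
        with pytest.raises(ConfigError):
            TimeInterval(500.0, 755.0)

    def test_too_short_rejected(self):
        with pytest.raises(ConfigError):
            TimeInterval(500.0, 505.0)

    def test_width(self):
        assert TimeInterval(500.0, 750.0).width_ms == 250.0


class TestComputeMEC:
    def test_constant_current_rectangle(self):
        """Constant current I over [t1, t2) integrates to I*(t2-t1)."""
        area = _area(np.full((3, 101), 2.5))
        out = compute_mec(area, TimeInterval(0.0, 100.0))
        assert np.allclose(out, 2.5 * 100.0)

    def test_adjacent_intervals_add(self, rng):
        area = _area(rng.normal(size=(5, 50)))
        a = compute_mec(area, TimeInterval(0.0, 10.0))
        b = compute_mec(area, TimeInterval(10.0, 20.0))
        ab = compute_mec(area, TimeInterval(0.0, 20.0))
        assert np.abs(a + b - ab).max() < 1e-10 * max(np.abs(ab).max(), 1.0)

    def test_every_grid_split_adds(self, rng):
        area = _area(rng.normal(size=(2, 41)))
        full = compute_mec(area, TimeInterval(0.0, 80.0))
        for mid in range(10, 80, 10):
            left = compute_mec(area, TimeInterval(0.0, float(mid)))
            right = compute_mec(area, TimeInterval(float(mid), 80.0))
            assert np.allclose(left + right, full, atol=1e-10)

    def test_half_sine_closed_form(self):
        """Sampled half-sine vs its analytic integral, better than 1e-3."""
        t_ms = np.arange(0, 101) * 2.0  # 500 Hz, 0..200 ms
        period = 200.0
        current = np.sin(np.pi * t_ms / period)
        area = _area(current)
        got = compute_mec(area, TimeInterval(0.0, 200.0))[0]
        want = 2.0 * period / np.pi  # integral of sin(pi t/T) over [0, T]
        assert abs(got - want) / want < 1e-3

    def test_zero_signal_zero_charge(self):
        area = _area(np.zeros((4, 60)))
        out = compute_mec(area, TimeInterval(0.0, 100.0))
        assert np.all(out == 0.0)

    def test_interval_outside_span_rejected(self):
        area = _area(np.zeros((1, 50)))
        with pytest.raises(ConfigError):
            compute_mec(area, TimeInterval(0.0, 200.0))

    def test_off_sampling_grid_rejected(self):
        area = _area(np.zeros((1, 50)), sfreq=256.0)  # 3.906 ms steps
        with pytest.raises(ConfigError):
            compute_mec(area, TimeInterval(10.0, 30.0))


class TestBaselineCorrection:
    def test_stationary_floor_removed(self, rng):
        """A flat noise floor integrates to ~zero after correction."""
        area = _area(np.full((3, 600), 4.0), tmin_ms=-200.0)
        out = baseline_correct_area(area, inflation=1.0)
        assert np.abs(out.current).max() < 1e-12

    def test_normalization_scale_invariant(self, rng):
        cur = np.abs(rng.normal(size=(4, 600))) + 1.0
        a = baseline_correct_area(_area(cur, tmin_ms=-200.0))
        b = baseline_correct_area(_area(10.0 * cur, tmin_ms=-200.0))
        assert np.allclose(a.current, b.current, atol=1e-12)

    def test_requires_prestimulus_samples(self, rng):
        area = _area(np.abs(rng.normal(size=(2, 100))), tmin_ms=0.0)
        with pytest.raises(ConfigError):
            baseline_correct_area(area)


@pytest.fixture(scope="module")
def cohort(lead32):
    spec = ExperimentSpec(n_participants=3, n_channels=32, seed=21)
    decisions = simulate_decisions(spec, ChoiceModel())
    epochs = simulate_epochs(spec, decisions, lead32)
    return spec, decisions, epochs


class TestFeatures:
    def test_feature_count_per_row(self, cohort, lead32, op32):
        _, _, epochs = cohort
        table = mec_features(epochs, op32, lead32)
        parcel_cols = [c for c in table.columns if c in PARCEL_LABELS]
        assert len(parcel_cols) == 148
        assert np.isfinite(table[parcel_cols].to_numpy()).all()

    def test_missing_cell_absent(self, lead32, op32):
        """A participant with no distrusting SCL-90 trials has no such row."""
        spec = ExperimentSpec(n_participants=1, n_channels=32, seed=2)
        choice = ChoiceModel(p_trust_by_scl={50: 0.5, 70: 0.7, 90: 1.0})
        decisions = simulate_decisions(spec, choice)
        epochs = simulate_epochs(spec, decisions, lead32)
        table = mec_features(epochs, op32, lead32)
        cells = set(zip(table.scl, table.decision))
        assert (90, DISTRUST) not in cells
        assert (90, TRUST) in cells

    def test_linear_without_baseline_normalization(self, cohort, lead32, op32):
        """The raw chain (no baseline debiasing) is linear in amplitude."""
        _, _, epochs = cohort
        a = mec_features(epochs, op32, lead32, baseline_ms=None)
        doubled = EpochSet(
            data=2.0 * epochs.data, labels=epochs.labels,
            sfreq=epochs.sfreq, tmin_ms=epochs.tmin_ms,
        )
        b = mec_features(doubled, op32, lead32, baseline_ms=None)
        cols = [c for c in a.columns if c in PARCEL_LABELS]
        assert np.allclose(
            b[cols].to_numpy(), 2.0 * a[cols].to_numpy(), rtol=1e-6
        )

    def test_scale_invariant_with_normalization(self, cohort, lead32, op32):
        """The debiased chain measures currents relative to the cell's own
        noise floor, so a global amplitude rescaling changes nothing."""
        _, _, epochs = cohort
        a = mec_features(epochs, op32, lead32)
        doubled = EpochSet(
            data=2.0 * epochs.data, labels=epochs.labels,
            sfreq=epochs.sfreq, tmin_ms=epochs.tmin_ms,
        )
        b = mec_features(doubled, op32, lead32)
        cols = [c for c in a.columns if c in PARCEL_LABELS]
        assert np.allclose(b[cols].to_numpy(), a[cols].to_numpy(), rtol=1e-5)

    def test_trial_order_invariant(self, cohort, lead32, op32):
        _, _, epochs = cohort
        perm = np.random.default_rng(0).permutation(epochs.n_trials)
        shuffled = EpochSet(
            data=epochs.data[perm],
            labels=epochs.labels.iloc[perm].reset_index(drop=True),
            sfreq=epochs.sfreq, tmin_ms=epochs.tmin_ms,
        )
        a = mec_features(epochs, op32, lead32)
        b = mec_features(shuffled, op32, lead32)
        cols = [c for c in a.columns if c in PARCEL_LABELS]
        pd.testing.assert_frame_equal(
            a.sort_values(["participant", "scl", "decision"]).reset_index(drop=True),
            b.sort_values(["participant", "scl", "decision"]).reset_index(drop=True),
            check_exact=False, rtol=1e-9,
        )
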