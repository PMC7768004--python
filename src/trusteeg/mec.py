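"""Mean electric charge (MEC): time-integrated per-parcel source current.

The MEC statistic mu_b(t1, t2) for brain area ``b`` is the time integral of
the area's mean electric current over the interval [t1, t2), taken on a
10 ms grid anchored at the stimulus (intervals are half-open labels; the
trapezoidal integral runs over the closed sample span, so adjacent
intervals add exactly).  Units: current [a.u.] x ms.

Features for the decision decoder are built per observation cell: all
trials of one (participant, SCL, decision) combination are averaged to an
ERP, source-localized, aggregated to the 148 parcels and integrated over
the feature window (500-750 ms by default).

Before integration the per-parcel current is baseline-corrected against the
cell's own pre-stimulus mean.  The magnitude aggregation |standardized
current| has a positive noise floor proportional to the residual noise of
the cell average (hence to 1/sqrt(trials in the cell)); because trial
counts differ systematically between cells, uncorrected charges would
encode how many trials a cell has rather than how active a parcel is.
Subtracting each parcel's pre-stimulus level -- the source-space analogue
of ERP baseline correction -- removes that floor, so a cell with no
stimulus-locked activity integrates to zero mean charge regardless of its
size.  Corrected charges can therefore be negative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import EpochSet
from .errors import ConfigError, DataError
from .erp import average_erp
from .headmodel import LeadField
from .inverse import InverseOperator, apply_sloreta, area_mean_current, AreaCurrent

logger = logging.getLogger(__name__)

GRID_MS = 10.0

#: Default feature window [ms]: the interval that gave the best decoder.
DEFAULT_FEATURE_WINDOW = (500.0, 750.0)

META_COLUMNS = ["participant", "scl", "decision", "n_trials"]

#: Default pre-stimulus window [ms] for the area-current baseline correction.
DEFAULT_MEC_BASELINE = (-200.0, 0.0)


def baseline_correct_area(
    area: AreaCurrent,
    baseline_ms: tuple[float, float] = DEFAULT_MEC_BASELINE,
    inflation: float | None = None,
    normalize: bool = True,
) -> AreaCurrent:
    """Subtract each parcel's mean pre-stimulus current level and express
    the result in units of that level (a noise-floor-relative current).

    Removes the cell-size-dependent noise floor of the magnitude
    aggregation (see module docstring).

    When the sensor epochs were themselves baseline-corrected over the same
    ``m``-sample window, pre-stimulus noise variance is deflated by
    ``1 - 1/m`` and post-stimulus variance inflated by ``1 + 1/m`` (each
    post-stimulus sample carries the baseline-mean estimation error).  The
    subtracted level is therefore scaled by
    ``sqrt((1 + 1/m) / (1 - 1/m))`` so that the cancellation of the noise
    floor is exact in expectation.  ``inflation=None`` (default) computes
    that factor from the window; pass ``1.0`` for data that were never
    sensor-baseline-corrected.
    """
    t1, t2 = baseline_ms
    if t1 >= t2 or t2 > 1e-9:
        raise ConfigError("area-current baseline must lie in the pre-stimulus span")
    times = area.times_ms
    inside = (times >= t1 - 1e-9) & (times < t2 - 1e-9)
    m = int(inside.sum())
    if m == 0:
        raise ConfigError("area-current baseline window contains no samples")
    if inflation is None:
        inflation = np.sqrt((1.0 + 1.0 / m) / (1.0 - 1.0 / m)) if m > 1 else 1.0
    level = area.current[:, inside].mean(axis=1, keepdims=True)
    corrected = area.current - inflation * level
    if normalize:
        # express current in units of the cell's own noise floor: the
        # residual noise of a cell average scales with 1/sqrt(trials), and
        # without this normalization the feature *scale* (not just the
        # mean) would encode the cell size
        grand = float(level.mean())
        if grand > 0:
            corrected = corrected / grand
    return AreaCurrent(
        current=corrected,
        parcel_labels=list(area.parcel_labels),
        sfreq=area.sfreq,
        tmin_ms=area.tmin_ms,
    )


@dataclass(frozen=True)
class TimeInterval:
    """Half-open interval [t1, t2) on the 10 ms grid, at least one bin long."""

    t1: float
    t2: float

    def __post_init__(self) -> None:
        for t in (self.t1, self.t2):
            if abs(t / GRID_MS - round(t / GRID_MS)) > 1e-9:
                raise ConfigError(f"interval endpoint {t} ms is off the 10 ms grid")
        if self.t2 - self.t1 < GRID_MS - 1e-9:
            raise ConfigError("interval must span at least one 10 ms bin")

    @property
    def width_ms(self) -> float:
        return self.t2 - self.t1


def compute_mec(area: AreaCurrent, interval: TimeInterval) -> np.ndarray:
    """Trapezoidal integral of each parcel's current over the interval.

    Returns one charge value per parcel (current x ms).  The interval must
    lie within the area-current span and its endpoints on the sampling grid.
    """
    times = area.times_ms
    step = 1000.0 / area.sfreq
    for t in (interval.t1, interval.t2):
        pos = (t - area.tmin_ms) / step
        if abs(pos - round(pos)) > 1e-6:
            raise ConfigError(f"endpoint {t} ms is not on the sampling grid")
    i1 = int(round((interval.t1 - area.tmin_ms) / step))
    i2 = int(round((interval.t2 - area.tmin_ms) / step))
    if i1 < 0 or i2 >= len(times) or i1 >= i2:
        raise ConfigError(
            f"interval [{interval.t1}, {interval.t2}) outside the current span"
        )
    return np.trapezoid(area.current[:, i1 : i2 + 1], dx=step, axis=1)


def mec_features(
    epochs: EpochSet,
    op: InverseOperator,
    lead: LeadField,
    window: TimeInterval | None = None,
    baseline_ms: tuple[float, float] | None = DEFAULT_MEC_BASELINE,
) -> pd.DataFrame:
    """Per-observation MEC feature table.

    One row per (participant, SCL, decision) cell with at least one trial:
    columns ``participant, scl, decision, n_trials`` plus one charge column
    per parcel in the fixed label order.  Cells with no trials are simply
    absent (the missing combinations are logged).
    """
    window = window or TimeInterval(*DEFAULT_FEATURE_WINDOW)
    if epochs.n_trials == 0:
        raise DataError("no epochs to build features from")
    rows = []
    for (pid, scl, dec), group_idx in epochs.labels.groupby(
        ["participant", "scl", "decision"], sort=True
    ).indices.items():
        cell = epochs.subset(np.isin(np.arange(epochs.n_trials), group_idx))
        charges = cell_mec(cell, op, lead, window, baseline_ms=baseline_ms)
        rows.append(
            {
                "participant": int(pid),
                "scl": int(scl),
                "decision": dec,
                "n_trials": cell.n_trials,
                **dict(zip(lead.parcel_labels, charges)),
            }
        )
    participants = epochs.labels["participant"].unique()
    levels = epochs.labels["scl"].unique()
    expected = len(participants) * len(levels) * 2
    if len(rows) < expected:
        logger.info(
            "MEC features: %d of %d possible cells present", len(rows), expected
        )
    return pd.DataFrame(rows)


def cell_mec(
    cell: EpochSet,
    op: InverseOperator,
    lead: LeadField,
    window: TimeInterval,
    baseline_ms: tuple[float, float] | None = DEFAULT_MEC_BASELINE,
) -> np.ndarray:
    """MEC vector (148 charges) for one already-selected cell of trials."""
    erp = average_erp(cell)
    return erp_mec(
        erp.values, erp.sfreq, erp.tmin_ms, op, lead, window, baseline_ms=baseline_ms
    )


def erp_mec(
    values: np.ndarray,
    sfreq: float,
    tmin_ms: float,
    op: InverseOperator,
    lead: LeadField,
    window: TimeInterval,
    baseline_ms: tuple[float, float] | None = DEFAULT_MEC_BASELINE,
) -> np.ndarray:
    """MEC vector for one pre-averaged ERP (channels x samples)."""
    src = apply_sloreta(op, values, sfreq=sfreq, tmin_ms=tmin_ms)
    area = area_mean_current(src, lead)
    if baseline_ms is not None:
        area = baseline_correct_area(area, baseline_ms)
    return compute_mec(area, window)


def mec_table_to_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format="%.12g")


def mec_table_from_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
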