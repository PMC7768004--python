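"""Event-related potential estimation and the experimental case algebra.

Trials are grouped into the six basic cases T50, D50, T70, D70, T90, D90
(decision x source-credibility level) and their unions: A_s = T_s u D_s per
level, and T / D pooled over levels.  All are expressed through one
:class:`CaseLabel` with ``ANY`` wildcards, so every hypothesis contrast is a
pair of case selections rather than special-cased code.

The "cognitive ERP" is the ERP further averaged over a designated
26-electrode subset around the vertex, the signal on which the interval
scans operate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import DISTRUST, TRUST, EpochSet
from .errors import ConfigError, DataError

logger = logging.getLogger(__name__)

ANY = "ANY"


@dataclass(frozen=True)
class CaseLabel:
    """A trial-selection predicate: SCL level (or ANY) x decision (or ANY)."""

    scl: int | str = ANY
    decision: str = ANY

    def __post_init__(self) -> None:
        if self.decision not in (TRUST, DISTRUST, ANY):
            raise ConfigError(f"unknown decision {self.decision!r}")

    def mask(self, labels: pd.DataFrame) -> np.ndarray:
        m = np.ones(len(labels), dtype=bool)
        if self.scl != ANY:
            m &= labels["scl"].to_numpy() == int(self.scl)
        if self.decision != ANY:
            m &= labels["decision"].to_numpy() == self.decision
        return m

    def __str__(self) -> str:
        dec = {TRUST: "T", DISTRUST: "D", ANY: "A"}[self.decision]
        lvl = "" if self.scl == ANY else str(self.scl)
        return f"{dec}{lvl}" if (dec != "A" or lvl) else "ALL"


# the named cases of the design
T50, D50 = CaseLabel(50, TRUST), CaseLabel(50, DISTRUST)
T70, D70 = CaseLabel(70, TRUST), CaseLabel(70, DISTRUST)
T90, D90 = CaseLabel(90, TRUST), CaseLabel(90, DISTRUST)
A50, A70, A90 = CaseLabel(50, ANY), CaseLabel(70, ANY), CaseLabel(90, ANY)
T_ALL, D_ALL = CaseLabel(ANY, TRUST), CaseLabel(ANY, DISTRUST)
BASIC_CASES = [T50, D50, T70, D70, T90, D90]


@dataclass
class ERP:
    """Trial-averaged potential: channels x samples [uV]."""

    values: np.ndarray
    n_trials: int
    sfreq: float
    tmin_ms: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.n_trials < 1:
            raise DataError("an ERP must average at least one trial")
        if not np.all(np.isfinite(self.values)):
            raise DataError("non-finite values in ERP")

    @property
    def times_ms(self) -> np.ndarray:
        return self.tmin_ms + 1000.0 * np.arange(self.values.shape[1]) / self.sfreq


@dataclass
class CognitiveSet:
    """The designated cognitive-electrode subset (26 channels by default)."""

    channel_indices: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.channel_indices)) != len(self.channel_indices):
            raise ConfigError("cognitive channel indices must be distinct")
        if any(i < 0 for i in self.channel_indices):
            raise ConfigError("cognitive channel indices must be nonnegative")


def select_case(epochs: EpochSet, case: CaseLabel) -> EpochSet:
    """Exactly the trials whose labels match ``case`` (may be empty)."""
    return epochs.subset(case.mask(epochs.labels))


def reject_artifacts(epochs: EpochSet, threshold_uv: float = 100.0) -> EpochSet:
    """Drop trials whose absolute amplitude exceeds ``threshold_uv``.

    A deterministic peak threshold stands in for interactive artifact
    screening; the count of dropped trials is logged.
    """
    if not threshold_uv > 0:
        raise ConfigError("artifact threshold must be positive")
    peak = np.max(np.abs(epochs.data), axis=(1, 2))
    keep = peak <= threshold_uv
    dropped = int((~keep).sum())
    if dropped:
        logger.info("artifact rejection: dropped %d of %d trials", dropped, len(keep))
    if not keep.any():
        logger.warning("artifact rejection removed every trial")
    return epochs.subset(keep)


def baseline_correct(
    epochs: EpochSet, window_ms: tuple[float, float] = (-200.0, 0.0)
) -> EpochSet:
    """Subtract the per-trial, per-channel mean over the pre-stimulus window."""
    t1, t2 = window_ms
    if t1 >= t2:
        raise ConfigError("baseline window must have positive length")
    if t1 < epochs.tmin_ms - 1e-9 or t2 > 1e-9:
        raise ConfigError(
            f"baseline window [{t1}, {t2}) must lie in the pre-stimulus span"
        )
    times = epochs.times_ms
    inside = (times >= t1) & (times < t2)
    if not inside.any():
        raise ConfigError("baseline window contains no samples")
    mean = epochs.data[:, :, inside].mean(axis=2, keepdims=True)
    return EpochSet(
        data=(epochs.data - mean).astype(epochs.data.dtype),
        labels=epochs.labels.copy(),
        sfreq=epochs.sfreq,
        tmin_ms=epochs.tmin_ms,
    )


def average_erp(epochs: EpochSet) -> ERP:
    """Pointwise mean over trials."""
    if epochs.n_trials == 0:
        raise DataError("cannot average an empty epoch set")
    return ERP(
        values=epochs.data.mean(axis=0, dtype=np.float64),
        n_trials=epochs.n_trials,
        sfreq=epochs.sfreq,
        tmin_ms=epochs.tmin_ms,
    )


def cognitive_erp(erp: ERP, cog: CognitiveSet) -> np.ndarray:
    """Mean over the cognitive channels: one value per sample."""
    idx = np.asarray(cog.channel_indices, dtype=int)
    if idx.size == 0:
        raise ConfigError("cognitive set is empty")
    if idx.max() >= erp.values.shape[0]:
        raise ConfigError("cognitive channel index out of range")
    return erp.values[idx].mean(axis=0)


def erp_to_csv(erp: ERP, path) -> None:
    """Long-format export: time_ms, channel, value_uV."""
    n_ch, n_s = erp.values.shape
    df = pd.DataFrame(
        {
            "time_ms": np.repeat(erp.times_ms, n_ch),
            "channel": np.tile(np.arange(n_ch), n_s),
            "value_uV": erp.values.T.ravel(),
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")
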