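"""In-memory containers for epoched EEG and their HDF5/CSV round-trips.

An :class:`EpochSet` is the pipeline's raw material: a ``trials x channels x
samples`` array in microvolts, stimulus-locked, with one label row per trial
(participant id, source-credibility level, trust/distrust decision).  Time is
expressed in milliseconds relative to stimulus onset at 0 ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd

from .errors import DataError

LABEL_COLUMNS = ("participant", "trial", "scl", "decision")

TRUST = "trust"
DISTRUST = "distrust"


@dataclass
class EpochSet:
    """Labeled trial tensor with sampling metadata.

    Parameters
    ----------
    data
        Array of shape ``(n_trials, n_channels, n_samples)``, microvolts.
    labels
        One row per trial with columns ``participant, trial, scl, decision``.
    sfreq
        Sampling frequency in Hz.
    tmin_ms
        Time of the first sample, milliseconds relative to stimulus onset.
    """

    data: np.ndarray
    labels: pd.DataFrame
    sfreq: float
    tmin_ms: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DataError("epoch data must be trials x channels x samples")
        if len(self.labels) != self.data.shape[0]:
            raise DataError(
                f"{len(self.labels)} label rows for {self.data.shape[0]} trials"
            )
        missing = [c for c in LABEL_COLUMNS if c not in self.labels.columns]
        if missing:
            raise DataError(f"label table missing columns {missing}")
        self.labels = self.labels.reset_index(drop=True)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        """Sample times in ms relative to stimulus onset."""
        return self.tmin_ms + 1000.0 * np.arange(self.n_samples) / self.sfreq

    def subset(self, mask: np.ndarray) -> "EpochSet":
        """New EpochSet containing the trials where ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        return EpochSet(
            data=self.data[mask],
            labels=self.labels.loc[mask].reset_index(drop=True),
            sfreq=self.sfreq,
            tmin_ms=self.tmin_ms,
        )

    def sample_index(self, t_ms: float) -> int:
        """Index of the sample at time ``t_ms`` (must lie on the grid)."""
        pos = (t_ms - self.tmin_ms) * self.sfreq / 1000.0
        idx = int(round(pos))
        if abs(pos - idx) > 1e-6:
            raise DataError(f"time {t_ms} ms is not on the sampling grid")
        if not 0 <= idx <= self.n_samples:
            raise DataError(f"time {t_ms} ms outside the epoch")
        return idx

    # ------------------------------------------------------------------ I/O
    def to_hdf5(self, path, group: str = "/") -> None:
        """Write the container to an HDF5 file.

        Layout: ``/data`` float32, ``/labels`` compound table, attributes
        ``sfreq`` and ``tmin_ms``.
        """
        with h5py.File(path, "a") as f:
            g = f.require_group(group)
            for name in ("data", "labels"):
                if name in g:
                    del g[name]
            g.create_dataset("data", data=self.data.astype(np.float32))
            lab = self.labels
            rec = np.rec.fromarrays(
                [
                    lab["participant"].to_numpy(np.int64),
                    lab["trial"].to_numpy(np.int64),
                    lab["scl"].to_numpy(np.int64),
                    np.array(
                        [s.encode() for s in lab["decision"].astype(str)],
                        dtype="S12",
                    ),
                ],
                names=list(LABEL_COLUMNS),
            )
            g.create_dataset("labels", data=rec)
            g.attrs["sfreq"] = float(self.sfreq)
            g.attrs["tmin_ms"] = float(self.tmin_ms)

    @classmethod
    def from_hdf5(cls, path, group: str = "/") -> "EpochSet":
        with h5py.File(path, "r") as f:
            g = f[group]
            data = g["data"][...]
            rec = g["labels"][...]
            labels = pd.DataFrame(
                {
                    "participant": rec["participant"].astype(int),
                    "trial": rec["trial"].astype(int),
                    "scl": rec["scl"].astype(int),
                    "decision": [s.decode() for s in rec["decision"]],
                }
            )
            return cls(
                data=data,
                labels=labels,
                sfreq=float(g.attrs["sfreq"]),
                tmin_ms=float(g.attrs["tmin_ms"]),
            )


def concat_epochs(sets: list[EpochSet]) -> EpochSet:
    """Concatenate epoch sets sharing sampling metadata along trials."""
    if not sets:
        raise DataError("no epoch sets to concatenate")
    first = sets[0]
    for s in sets[1:]:
        if s.sfreq != first.sfreq or s.tmin_ms != first.tmin_ms:
            raise DataError("epoch sets differ in sampling metadata")
        if s.data.shape[1:] != first.data.shape[1:]:
            raise DataError("epoch sets differ in channel/sample counts")
    return EpochSet(
        data=np.concatenate([s.data for s in sets], axis=0),
        labels=pd.concat([s.labels for s in sets], ignore_index=True),
        sfreq=first.sfreq,
        tmin_ms=first.tmin_ms,
    )
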