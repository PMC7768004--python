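"""Synthetic cohort generator for the source-credibility experiment.

The generator emulates the study design the analysis assumes: each
participant sees 180 stimuli, 60 at each source-credibility level (SCL 50,
70, 90 %), and responds "trust" or "distrust" with a trust probability that
increases with SCL.  Epoched EEG is produced by a forward model: ongoing
background activity (white dipole noise projected through the lead field,
sampled equivalently in sensor space through a Cholesky factor of its exact
covariance) plus condition-locked effect waveforms confined to named
cortical parcels and a post-stimulus latency window, plus white sensor
noise.

Default condition structure: trusting trials carry a late positive effect in
the 28 "credibility loop" parcels over 372-796 ms; distrusting trials carry
the same topography at a fraction of the amplitude; the effect grows mildly
with SCL.  This gives every downstream contrast (trust vs distrust, and
between SCL levels within a decision) a nonzero ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import DISTRUST, TRUST, EpochSet
from .errors import ConfigError
from .headmodel import LeadField
from .labels import CREDIBILITY_LOOP_AREAS

#: Default trust probability per SCL level.  SCL 50 % is the random-response
#: baseline; 70/90 rise roughly with the displayed credibility score.
DEFAULT_P_TRUST = {50: 0.50, 70: 0.72, 90: 0.90}

#: Default effect-source amplitude [nA*m per dipole] for trusting trials.
#: Chosen so the summed projection of the default 28 target parcels peaks
#: near 4 uV at the most affected electrode -- the size of a healthy late
#: positive ERP component against ~10 uV single-trial background.
DEFAULT_EFFECT_AMPLITUDE = 0.15
#: Distrusting trials carry the same topography at this fraction.
DEFAULT_DISTRUST_FRACTION = 0.35
#: Mild SCL modulation of the effect amplitude.
DEFAULT_SCL_GAIN = {50: 0.8, 70: 1.0, 90: 1.2}


@dataclass
class ExperimentSpec:
    """Design of the simulated experiment."""

    n_participants: int = 110
    n_trials_per_scl: int = 60
    scl_levels: tuple[int, ...] = (50, 70, 90)
    sfreq: float = 500.0
    epoch_window_ms: tuple[float, float] = (-200.0, 1000.0)
    n_channels: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        t0, t1 = self.epoch_window_ms
        if not t0 <= 0.0 < t1:
            raise ConfigError("epoch window must contain the stimulus at 0 ms")
        if self.n_participants < 1 or self.n_trials_per_scl < 1:
            raise ConfigError("participant and trial counts must be positive")
        # 10 ms bins downstream must hold an integer number of samples
        if abs(self.sfreq * 0.01 - round(self.sfreq * 0.01)) > 1e-9:
            raise ConfigError(f"sfreq {self.sfreq} Hz does not tile 10 ms bins")
        if len(set(self.scl_levels)) != len(self.scl_levels):
            raise ConfigError("duplicate SCL levels")

    @property
    def trials_per_participant(self) -> int:
        return self.n_trials_per_scl * len(self.scl_levels)

    @property
    def n_samples(self) -> int:
        t0, t1 = self.epoch_window_ms
        return int(round((t1 - t0) * self.sfreq / 1000.0))

    def times_ms(self) -> np.ndarray:
        return self.epoch_window_ms[0] + 1000.0 * np.arange(self.n_samples) / self.sfreq


@dataclass
class ChoiceModel:
    """Bernoulli trust-decision model, one probability per SCL level."""

    p_trust_by_scl: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_P_TRUST)
    )

    def __post_init__(self) -> None:
        probs = list(self.p_trust_by_scl.values())
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ConfigError("trust probabilities must lie in [0, 1]")
        levels = sorted(self.p_trust_by_scl)
        for lo, hi in zip(levels, levels[1:]):
            if self.p_trust_by_scl[lo] > self.p_trust_by_scl[hi]:
                raise ConfigError("trust probability must be nondecreasing in SCL")


@dataclass
class EffectSpec:
    """A condition-locked source-level effect.

    ``decision`` restricts the effect to trusting or distrusting trials
    (``None`` = both); ``scl_gain`` scales the amplitude per SCL level
    (missing level -> gain 1).  The waveform occupies ``window_ms`` and is
    applied identically to every dipole of every target parcel.
    """

    target_areas: list[str] = field(
        default_factory=lambda: list(CREDIBILITY_LOOP_AREAS)
    )
    window_ms: tuple[float, float] = (372.0, 796.0)
    amplitude: float = DEFAULT_EFFECT_AMPLITUDE
    waveform: str = "raised_cosine"
    decision: str | None = None
    scl_gain: dict[int, float] = field(default_factory=dict)

    def gain_for(self, scl: int) -> float:
        return self.scl_gain.get(scl, 1.0)

    def waveform_values(self, times_ms: np.ndarray) -> np.ndarray:
        t1, t2 = self.window_ms
        if t2 <= t1:
            raise ConfigError("effect window must have positive length")
        w = np.zeros_like(times_ms, dtype=float)
        inside = (times_ms >= t1) & (times_ms < t2)
        if self.waveform == "raised_cosine":
            phase = (times_ms[inside] - t1) / (t2 - t1)
            w[inside] = 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))
        elif self.waveform == "boxcar":
            w[inside] = 1.0
        else:
            raise ConfigError(f"unknown waveform {self.waveform!r}")
        return w


@dataclass
class NoiseSpec:
    """Background-activity and sensor-noise levels.

    ``source_noise_sd`` is the per-dipole white current noise [nA*m] whose
    lead-field projection forms spatially correlated background EEG;
    ``sensor_noise_sd`` is independent white noise per electrode [uV].
    """

    source_noise_sd: float = 1.2
    sensor_noise_sd: float = 3.0
    noise_color: str = "white"

    def __post_init__(self) -> None:
        if self.source_noise_sd < 0 or self.sensor_noise_sd < 0:
            raise ConfigError("noise standard deviations must be nonnegative")
        if self.noise_color not in ("white", "one_over_f"):
            raise ConfigError(f"unknown noise color {self.noise_color!r}")


def default_effects(
    amplitude: float = DEFAULT_EFFECT_AMPLITUDE,
    target_areas: list[str] | None = None,
    window_ms: tuple[float, float] = (372.0, 796.0),
    distrust_fraction: float = DEFAULT_DISTRUST_FRACTION,
    scl_gain: dict[int, float] | None = None,
) -> list[EffectSpec]:
    """The shipped default condition structure (see module docstring)."""
    areas = list(target_areas) if target_areas is not None else list(
        CREDIBILITY_LOOP_AREAS
    )
    gains = dict(scl_gain) if scl_gain is not None else dict(DEFAULT_SCL_GAIN)
    return [
        EffectSpec(
            target_areas=areas,
            window_ms=window_ms,
            amplitude=amplitude,
            decision=TRUST,
            scl_gain=gains,
        ),
        EffectSpec(
            target_areas=areas,
            window_ms=window_ms,
            amplitude=amplitude * distrust_fraction,
            decision=DISTRUST,
            scl_gain=gains,
        ),
    ]


def _participant_rng(seed: int, participant: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), int(participant), int(stream)])
    )


def simulate_decisions(spec: ExperimentSpec, choice: ChoiceModel) -> pd.DataFrame:
    """Draw one decision table for the whole cohort.

    Returns one row per (participant, trial) with columns
    ``participant, trial, scl, decision``; exactly ``n_trials_per_scl`` rows
    per SCL level per participant, trial order randomized per participant.
    """
    for lvl in spec.scl_levels:
        if lvl not in choice.p_trust_by_scl:
            raise ConfigError(f"choice model lacks a probability for SCL {lvl}")
    frames = []
    scl_block = np.repeat(np.asarray(spec.scl_levels, dtype=int), spec.n_trials_per_scl)
    for pid in range(spec.n_participants):
        rng = _participant_rng(spec.seed, pid, 0)
        scl = rng.permutation(scl_block)
        p = np.array([choice.p_trust_by_scl[int(s)] for s in scl])
        trusting = rng.random(len(scl)) < p
        frames.append(
            pd.DataFrame(
                {
                    "participant": pid,
                    "trial": np.arange(len(scl)),
                    "scl": scl,
                    "decision": np.where(trusting, TRUST, DISTRUST),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def decisions_to_csv(decisions: pd.DataFrame, path) -> None:
    decisions.to_csv(path, index=False)


def decisions_from_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def _condition_effect_matrix(
    spec: ExperimentSpec,
    lead: LeadField,
    effects: list[EffectSpec],
    scl: int,
    decision: str,
) -> np.ndarray:
    """Sensor-space effect (channels x samples) for one condition cell."""
    times = spec.times_ms()
    out = np.zeros((lead.n_channels, spec.n_samples))
    t0, t1 = spec.epoch_window_ms
    for eff in effects:
        if eff.decision is not None and eff.decision != decision:
            continue
        w1, w2 = eff.window_ms
        if w1 < t0 or w2 > t1:
            raise ConfigError(
                f"effect window [{w1}, {w2}) outside epoch [{t0}, {t1})"
            )
        unknown = [a for a in eff.target_areas if a not in lead.parcel_labels]
        if unknown:
            raise ConfigError(f"effect references unknown parcels {unknown}")
        pattern = lead.parcel_pattern(eff.target_areas)
        amp = eff.amplitude * eff.gain_for(scl)
        out += np.outer(pattern * amp, eff.waveform_values(times))
    return out


def _one_over_f_filter(n_samples: int) -> np.ndarray:
    """rFFT amplitude profile with ~1/sqrt(f) shape, unit average power."""
    freqs = np.fft.rfftfreq(n_samples)
    amp = np.ones_like(freqs)
    nonzero = freqs > 0
    amp[nonzero] = 1.0 / np.sqrt(freqs[nonzero] / freqs[nonzero][0])
    # normalize so filtered white noise keeps unit variance
    weight = np.ones_like(freqs)
    weight[1:-1] = 2.0  # two-sided spectrum weights for rfft
    amp /= np.sqrt((weight * amp**2).sum() / n_samples)
    return amp


def simulate_epochs(
    spec: ExperimentSpec,
    decisions: pd.DataFrame,
    lead: LeadField,
    effects: list[EffectSpec] | None = None,
    noise: NoiseSpec | None = None,
) -> EpochSet:
    """Forward-model epoched EEG for every trial in ``decisions``.

    The per-trial signal is the condition cell's effect topography plus
    correlated background (projected dipole noise) plus sensor noise.  The
    draw is seeded per participant from ``spec.seed``, so simulating the
    cohort in one call or participant-by-participant yields bit-identical
    epochs.
    """
    if len(decisions) == 0:
        raise ConfigError("decision table is empty")
    effects = effects if effects is not None else []
    noise = noise if noise is not None else NoiseSpec()
    if lead.n_channels != spec.n_channels:
        raise ConfigError(
            f"lead field has {lead.n_channels} channels, spec {spec.n_channels}"
        )
    n_samp = spec.n_samples
    n_ch = lead.n_channels

    # condition cells present in the table
    cells = {}
    for scl, dec in decisions[["scl", "decision"]].drop_duplicates().itertuples(
        index=False
    ):
        cells[(int(scl), dec)] = _condition_effect_matrix(
            spec, lead, effects, int(scl), dec
        )

    # exact covariance of projected white dipole noise + sensor noise
    cov = noise.sensor_noise_sd**2 * np.eye(n_ch)
    if noise.source_noise_sd > 0:
        cov = cov + noise.source_noise_sd**2 * (lead.gain @ lead.gain.T)
    if noise.sensor_noise_sd > 0 or noise.source_noise_sd > 0:
        chol = np.linalg.cholesky(cov + 1e-12 * np.trace(cov) / n_ch * np.eye(n_ch))
    else:
        chol = None
    color = _one_over_f_filter(n_samp) if noise.noise_color == "one_over_f" else None

    data = np.empty((len(decisions), n_ch, n_samp), dtype=np.float32)
    labels = decisions.reset_index(drop=True)
    label_blocks = []
    row = 0
    for pid, group in labels.groupby("participant", sort=True):
        # trial draws are keyed by (seed, participant, trial order); keep the
        # per-participant trial order canonical so any subset is reproducible
        group = group.sort_values("trial", kind="stable")
        rng = _participant_rng(spec.seed, int(pid), 1)
        k = len(group)
        if chol is not None:
            z = rng.standard_normal((k, n_ch, n_samp))
            if color is not None:
                z = np.fft.irfft(np.fft.rfft(z, axis=-1) * color, n=n_samp, axis=-1)
            block = np.einsum("ij,kjt->kit", chol, z)
        else:
            block = np.zeros((k, n_ch, n_samp))
        for i, (_, trial) in enumerate(group.iterrows()):
            block[i] += cells[(int(trial["scl"]), trial["decision"])]
        data[row : row + k] = block.astype(np.float32)
        label_blocks.append(group)
        row += k

    ordered = pd.concat(label_blocks, ignore_index=True)
    return EpochSet(
        data=data,
        labels=ordered,
        sfreq=spec.sfreq,
        tmin_ms=spec.epoch_window_ms[0],
    )
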