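"""End-to-end orchestration: one reproducible run from config + seed.

``run_all`` executes the full analysis on a synthetic cohort: simulate
decisions and epochs, artifact-reject and baseline-correct, estimate case
ERPs, test the trust-rate/SCL relationship, scan every hypothesis contrast
for significant 10 ms intervals, source-localize per-cell ERPs, integrate
MEC features, and decode trust vs distrust (holdout + grouped
cross-validation, full and reduced models).

The cohort is processed one participant at a time: each participant's
epochs are simulated, cleaned and reduced to (a) per-trial cognitive bin
means for the scans and (b) per-cell ERPs for the source/MEC path, then
discarded.  Because epoch draws are keyed per participant, this streaming
path is bit-identical to materializing the whole cohort at once.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .decision_model import (
    FittedModel,
    Metrics,
    ObservationSet,
    assemble_observations,
    crossvalidate,
    evaluate,
    fit_logistic_bootstrap,
    select_top_areas,
    split_by_participant,
)
from .erp import (
    A50,
    A70,
    A90,
    BASIC_CASES,
    D50,
    D70,
    D90,
    D_ALL,
    T50,
    T70,
    T90,
    T_ALL,
    CaseLabel,
    CognitiveSet,
    ERP,
    baseline_correct,
    reject_artifacts,
)
from .errors import ConfigError, DataError, TrustEEGError
from .headmodel import LeadField, build_head_model, cognitive_channel_indices
from .inverse import InverseOperator, compute_inverse_operator
from .mec import TimeInterval, erp_mec
from .scanstats import (
    ScanResult,
    cognitive_bin_means,
    scan_bin_means,
    trust_rate_test,
    trust_trend_test,
)
from .synthdata import (
    ChoiceModel,
    EffectSpec,
    ExperimentSpec,
    NoiseSpec,
    default_effects,
    simulate_decisions,
    simulate_epochs,
)

logger = logging.getLogger(__name__)

#: The hypothesis contrasts scanned by a full run, in reporting order.
SCAN_PAIRS: list[tuple[CaseLabel, CaseLabel]] = [
    (A50, A70), (A50, A90), (A70, A90),            # SCL effect, pooled decisions
    (T50, T70), (T50, T90), (T70, T90),            # SCL effect within trusting
    (D50, D70), (D50, D90), (D70, D90),            # SCL effect within distrusting
    (T_ALL, D_ALL), (T90, D90), (T70, D70), (T50, D50),  # decision effect
]


@dataclass
class RunConfig:
    """Everything a run needs besides the seed."""

    experiment: ExperimentSpec = field(default_factory=ExperimentSpec)
    choice: ChoiceModel = field(default_factory=ChoiceModel)
    effects: list[EffectSpec] = field(default_factory=default_effects)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    n_dipoles: int = 2048
    inverse_alpha: float | None = None  # None -> 1 % relative default
    n_cognitive: int = 26
    artifact_threshold_uv: float = 100.0
    baseline_window_ms: tuple[float, float] = (-200.0, 0.0)
    scan_alpha: float = 0.01
    scan_span_ms: tuple[float, float] = (250.0, 800.0)
    scan_correction: str | None = None
    mec_window_ms: tuple[float, float] = (500.0, 750.0)
    mec_baseline_ms: tuple[float, float] | None = (-200.0, 0.0)
    n_boot: int = 10_000
    top_k: int = 28
    test_fraction: float = 0.2
    k_folds: int = 10
    l2_c: float = 1.0
    out_dir: str | None = None

    # ------------------------------------------------------------ serialization
    def to_dict(self) -> dict:
        e = self.experiment
        return {
            "experiment": {
                "n_participants": e.n_participants,
                "n_trials_per_scl": e.n_trials_per_scl,
                "scl_levels": list(e.scl_levels),
                "sfreq": e.sfreq,
                "epoch_window_ms": list(e.epoch_window_ms),
                "n_channels": e.n_channels,
                "seed": e.seed,
            },
            "choice": {"p_trust_by_scl": dict(self.choice.p_trust_by_scl)},
            "effects": [
                {
                    "target_areas": list(eff.target_areas),
                    "window_ms": list(eff.window_ms),
                    "amplitude": eff.amplitude,
                    "waveform": eff.waveform,
                    "decision": eff.decision,
                    "scl_gain": dict(eff.scl_gain),
                }
                for eff in self.effects
            ],
            "noise": {
                "source_noise_sd": self.noise.source_noise_sd,
                "sensor_noise_sd": self.noise.sensor_noise_sd,
                "noise_color": self.noise.noise_color,
            },
            "n_dipoles": self.n_dipoles,
            "inverse_alpha": self.inverse_alpha,
            "n_cognitive": self.n_cognitive,
            "artifact_threshold_uv": self.artifact_threshold_uv,
            "baseline_window_ms": list(self.baseline_window_ms),
            "scan_alpha": self.scan_alpha,
            "scan_span_ms": list(self.scan_span_ms),
            "scan_correction": self.scan_correction,
            "mec_window_ms": list(self.mec_window_ms),
            "mec_baseline_ms": (
                list(self.mec_baseline_ms) if self.mec_baseline_ms else None
            ),
            "n_boot": self.n_boot,
            "top_k": self.top_k,
            "test_fraction": self.test_fraction,
            "k_folds": self.k_folds,
            "l2_c": self.l2_c,
            "out_dir": self.out_dir,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        exp = d.pop("experiment", {})
        if "scl_levels" in exp:
            exp["scl_levels"] = tuple(int(s) for s in exp["scl_levels"])
        if "epoch_window_ms" in exp:
            exp["epoch_window_ms"] = tuple(exp["epoch_window_ms"])
        choice_d = d.pop("choice", {})
        choice = ChoiceModel(
            p_trust_by_scl={
                int(k): float(v)
                for k, v in choice_d.get(
                    "p_trust_by_scl", ChoiceModel().p_trust_by_scl
                ).items()
            }
        )
        effects_d = d.pop("effects", None)
        if effects_d is None:
            effects = default_effects()
        else:
            effects = [
                EffectSpec(
                    target_areas=list(ed["target_areas"]),
                    window_ms=tuple(ed["window_ms"]),
                    amplitude=float(ed["amplitude"]),
                    waveform=ed.get("waveform", "raised_cosine"),
                    decision=ed.get("decision"),
                    scl_gain={int(k): float(v) for k, v in ed.get("scl_gain", {}).items()},
                )
                for ed in effects_d
            ]
        noise_d = d.pop("noise", {})
        for key in (
            "baseline_window_ms", "scan_span_ms", "mec_window_ms", "mec_baseline_ms"
        ):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        try:
            return cls(
                experiment=ExperimentSpec(**exp),
                choice=choice,
                effects=effects,
                noise=NoiseSpec(**noise_d),
                **d,
            )
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        try:
            return cls.from_dict(yaml.safe_load(Path(path).read_text()))
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse config: {exc}") from exc

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def default_config(n_channels: int = 64) -> RunConfig:
    """The shipped default configuration (64-channel desk-scale cohort)."""
    return RunConfig(experiment=ExperimentSpec(n_channels=n_channels))


@dataclass
class RunReport:
    """Everything a run computed, in memory."""

    config: RunConfig
    seed: int
    decisions: pd.DataFrame
    trust_test: object
    trust_trend: object
    case_erps: dict[str, ERP]
    scans: list[ScanResult]
    mec_table: pd.DataFrame
    observations: ObservationSet
    full_model: FittedModel
    coefficients: pd.DataFrame
    holdout_metrics: Metrics
    reduced_areas: list[str]
    reduced_metrics: Metrics
    cv_metrics: Metrics
    n_rejected: int
    lead: LeadField
    inverse_op: InverseOperator
    cognitive: CognitiveSet


def _stage(name: str):
    logger.info("stage: %s", name)
    return time.time()


def simulate_cohort_summaries(
    config: RunConfig,
    lead: LeadField,
    op: InverseOperator,
    cog: CognitiveSet,
    decisions: pd.DataFrame,
):
    """Stream participants: per-trial bin means, per-cell MEC, case ERPs."""
    spec = config.experiment
    window = TimeInterval(*config.mec_window_ms)
    case_sums: dict[str, np.ndarray] = {}
    case_counts: dict[str, int] = {}
    bin_frames = []
    mec_rows = []
    n_rejected = 0
    for pid, dec_p in decisions.groupby("participant", sort=True):
        epochs = simulate_epochs(spec, dec_p, lead, config.effects, config.noise)
        kept = reject_artifacts(epochs, config.artifact_threshold_uv)
        n_rejected += epochs.n_trials - kept.n_trials
        if kept.n_trials == 0:
            logger.warning("participant %s: all trials rejected", pid)
            continue
        clean = baseline_correct(kept, config.baseline_window_ms)
        bin_frames.append(cognitive_bin_means(clean, cog, config.scan_span_ms))
        for case in BASIC_CASES:
            m = case.mask(clean.labels)
            if m.any():
                key = str(case)
                block = clean.data[m].sum(axis=0, dtype=np.float64)
                case_sums[key] = case_sums.get(key, 0.0) + block
                case_counts[key] = case_counts.get(key, 0) + int(m.sum())
        for (scl, dec), idx in clean.labels.groupby(
            ["scl", "decision"], sort=True
        ).indices.items():
            cell_mean = clean.data[idx].mean(axis=0, dtype=np.float64)
            charges = erp_mec(
                cell_mean, spec.sfreq, spec.epoch_window_ms[0], op, lead, window,
                baseline_ms=config.mec_baseline_ms,
            )
            mec_rows.append(
                {
                    "participant": int(pid),
                    "scl": int(scl),
                    "decision": dec,
                    "n_trials": len(idx),
                    **dict(zip(lead.parcel_labels, charges)),
                }
            )
    if not bin_frames:
        raise DataError("every trial of every participant was rejected")
    bin_table = pd.concat(bin_frames, ignore_index=True)
    case_erps = {
        key: ERP(
            values=case_sums[key] / case_counts[key],
            n_trials=case_counts[key],
            sfreq=spec.sfreq,
            tmin_ms=spec.epoch_window_ms[0],
        )
        for key in case_sums
    }
    return bin_table, pd.DataFrame(mec_rows), case_erps, n_rejected


def run_all(config: RunConfig, seed: int | None = None, out_dir=None) -> RunReport:
    """Execute the full pipeline; write artifacts if an output dir is set.

    ``seed`` overrides ``config.experiment.seed`` when given.  Any stage
    failure is re-raised with the stage name prepended; artifacts written
    by earlier stages are retained.
    """
    if seed is not None:
        config.experiment.seed = int(seed)
    seed = config.experiment.seed
    out = Path(out_dir or config.out_dir) if (out_dir or config.out_dir) else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    stage = "setup"
    try:
        _stage(stage)
        lead = build_head_model(
            n_channels=config.experiment.n_channels, n_dipoles=config.n_dipoles
        )
        op = compute_inverse_operator(lead, config.inverse_alpha)
        cog = CognitiveSet(cognitive_channel_indices(lead, config.n_cognitive))

        stage = "simulate-decisions"
        _stage(stage)
        decisions = simulate_decisions(config.experiment, config.choice)
        if out is not None:
            decisions.to_csv(out / "decisions.csv", index=False)

        stage = "trust-rate-test"
        _stage(stage)
        if len(config.experiment.scl_levels) < 2:
            logger.warning(
                "single SCL level: trust-rate and trend tests skipped"
            )
            trust = trend = None
        else:
            trust = trust_rate_test(decisions)
            trend = trust_trend_test(decisions)
        if out is not None and trust is not None:
            (out / "trust_test.json").write_text(
                json.dumps(
                    {
                        "chi2": trust.statistic,
                        "p_value": trust.p_value,
                        "trust_rate": trust.extra["trust_rate"],
                        "trend_z": trend.statistic,
                        "trend_p_value": trend.p_value,
                    },
                    indent=2,
                )
            )

        stage = "simulate-epochs+erp+mec"
        _stage(stage)
        bin_table, mec_table, case_erps, n_rejected = simulate_cohort_summaries(
            config, lead, op, cog, decisions
        )
        logger.info(
            "cohort: %d trials kept, %d rejected, %d MEC cells",
            len(bin_table), n_rejected, len(mec_table),
        )
        if out is not None:
            mec_table.to_csv(out / "mec_table.csv", index=False, float_format="%.12g")

        stage = "interval-scans"
        _stage(stage)
        scans = []
        for c1, c2 in SCAN_PAIRS:
            try:
                scans.append(
                    scan_bin_means(
                        bin_table, c1, c2,
                        alpha=config.scan_alpha,
                        correction=config.scan_correction,
                    )
                )
            except DataError as exc:
                # a design without some level simply lacks those contrasts
                logger.warning("scan %s vs %s skipped: %s", c1, c2, exc)
        if out is not None:
            pd.concat([s.runs_frame() for s in scans], ignore_index=True).to_csv(
                out / "scan_runs.tsv", sep="\t", index=False
            )
            pd.concat([s.pvalues_frame() for s in scans], ignore_index=True).to_csv(
                out / "scan_pvalues.csv", index=False
            )

        stage = "decoding"
        _stage(stage)
        if set(config.experiment.scl_levels) <= {50}:
            raise ConfigError(
                "decoding requires SCL levels beyond 50 %: SCL=50 observations "
                "are excluded from the model by design"
            )
        obs = assemble_observations(mec_table)
        train, test = split_by_participant(obs, config.test_fraction, seed=seed)
        full_model, coef = fit_logistic_bootstrap(
            train, n_boot=config.n_boot, seed=seed, c=config.l2_c
        )
        holdout = evaluate(full_model, test)
        reduced_areas = select_top_areas(coef, config.top_k)
        reduced_train = ObservationSet(
            features=train.features[reduced_areas],
            y=train.y, groups=train.groups, scl=train.scl,
        )
        reduced_model, _ = fit_logistic_bootstrap(
            reduced_train, n_boot=0, seed=seed, c=config.l2_c
        )
        reduced_test = ObservationSet(
            features=test.features[reduced_areas],
            y=test.y, groups=test.groups, scl=test.scl,
        )
        reduced = evaluate(reduced_model, reduced_test)
        cv = crossvalidate(obs, k_folds=config.k_folds, seed=seed, c=config.l2_c)
        if out is not None:
            coef.to_csv(out / "coefficients.csv", index=False, float_format="%.12g")
            (out / "metrics.json").write_text(
                json.dumps(
                    {
                        "holdout_full": holdout.to_dict(),
                        "holdout_reduced": reduced.to_dict(),
                        "cv_full": cv.to_dict(),
                        "reduced_areas": reduced_areas,
                    },
                    indent=2,
                )
            )

        stage = "manifest"
        if out is not None:
            import scipy
            import sklearn

            (out / "manifest.json").write_text(
                json.dumps(
                    {
                        "config_hash": config.config_hash(),
                        "seed": seed,
                        "versions": {
                            "trusteeg": __version__,
                            "numpy": np.__version__,
                            "pandas": pd.__version__,
                            "scipy": scipy.__version__,
                            "scikit-learn": sklearn.__version__,
                        },
                        "n_trials_kept": int(len(bin_table)),
                        "n_trials_rejected": int(n_rejected),
                        "n_mec_cells": int(len(mec_table)),
                        "n_significant_bins": int(
                            sum((s.p_values <= s.alpha).sum() for s in scans)
                        ),
                    },
                    indent=2,
                )
            )
    except TrustEEGError as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc

    return RunReport(
        config=config,
        seed=seed,
        decisions=decisions,
        trust_test=trust,
        trust_trend=trend,
        case_erps=case_erps,
        scans=scans,
        mec_table=mec_table,
        observations=obs,
        full_model=full_model,
        coefficients=coef,
        holdout_metrics=holdout,
        reduced_areas=reduced_areas,
        reduced_metrics=reduced,
        cv_metrics=cv,
        n_rejected=n_rejected,
        lead=lead,
        inverse_op=op,
        cognitive=cog,
    )
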