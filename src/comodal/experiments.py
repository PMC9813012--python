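"""End-to-end experiment harness: learning runs, manipulation sweeps,
architecture comparison and parameter sweeps.

Every experiment is a pure function of an :class:`ExperimentConfig` and a
seed list: a training track is generated, a model is built and trained, and
a freshly generated held-out track from the same schedule distribution is
scored.  Sweeps return tidy DataFrames with one row per (cell, repeat) so
aggregates are always recomputable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import evaluation as ev
from .model import TrainedModel, RunResult, build_model, run_inference, train
from .params import ModelParams, ScheduleParams, StimulusParams, TeachingParams
from .stimulus import (ChunkSpec, StimulusTrack, apply_delay, apply_missing,
                       build_sequence, default_chunks)


@dataclass
class ExperimentConfig:
    """Everything one learning experiment needs, minus the seed.

    ``model`` holds the shared per-module hyperparameters (the input
    dimensionality is set per modality from the stimulus configuration).
    ``C_test`` defaults to ``C // 4`` held-out epochs.  ``m`` / ``d`` select
    the pair-replacement probability and inter-modal delay, and
    ``manipulate`` says whether the manipulation is applied to the training
    signals, the test signals, or both.
    """

    model: ModelParams = field(default_factory=lambda: ModelParams(
        N=600, S=200, force_interval=2))
    teaching: TeachingParams = field(default_factory=TeachingParams)
    stimulus: StimulusParams = field(default_factory=StimulusParams)
    schedule: ScheduleParams = field(default_factory=lambda: ScheduleParams(C=300))
    variant: str = "original"
    C_test: Optional[int] = None
    m: float = 0.0
    d: float = 0.0
    manipulate: str = "train"           # "train" | "test" | "both"
    window_sd: float = 20.0
    no_response_threshold: float = 0.3
    epoch_statistic: str = "mean"

    def __post_init__(self) -> None:
        if self.manipulate not in ("train", "test", "both"):
            raise ValueError("manipulate must be 'train', 'test' or 'both'")

    @property
    def chunks(self) -> List[ChunkSpec]:
        return default_chunks()

    def n_test_epochs(self) -> int:
        return self.C_test if self.C_test is not None else max(8, self.schedule.C // 4)


@dataclass
class EvalReport:
    """Scores of one trained model on one held-out track."""

    accuracy: float
    confusion: pd.DataFrame
    accuracy_rc1: float
    accuracy_rc2: float
    seed: int
    variant: str
    extras: Dict[str, float] = field(default_factory=dict)


def _spawn_seeds(seed: int, n: int) -> List[int]:
    """Independent child seeds below 2**31 derived from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2 ** 31) for s in ss.generate_state(n)]


def make_tracks(
    config: ExperimentConfig, seed: int
) -> Tuple[StimulusTrack, StimulusTrack]:
    """Generate (train, test) tracks and apply the configured manipulations."""
    s_train, s_test, s_man_tr, s_man_te = _spawn_seeds(seed, 4)
    sched_tr = replace(config.schedule, seed=s_train)
    sched_te = replace(config.schedule, C=config.n_test_epochs(), seed=s_test)
    chunks = config.chunks
    track_tr = build_sequence(sched_tr, chunks, config.stimulus)
    track_te = build_sequence(sched_te, chunks, config.stimulus)
    if config.m > 0:
        if config.manipulate in ("train", "both"):
            track_tr = apply_missing(track_tr, config.m,
                                     np.random.default_rng(s_man_tr))
        if config.manipulate in ("test", "both"):
            track_te = apply_missing(track_te, config.m,
                                     np.random.default_rng(s_man_te))
    if config.d > 0:
        if config.manipulate in ("train", "both"):
            track_tr = apply_delay(track_tr, config.d,
                                   config.schedule.delayed_modality)
        if config.manipulate in ("test", "both"):
            track_te = apply_delay(track_te, config.d,
                                   config.schedule.delayed_modality)
    return track_tr, track_te


def evaluate_model(
    model: TrainedModel,
    track: StimulusTrack,
    config: ExperimentConfig,
    seed: int,
    record_stride: int = 0,
) -> Tuple[EvalReport, RunResult]:
    """Score a trained model on a track (association and module level)."""
    res = run_inference(model, track, seed=seed, record_stride=record_stride)
    chunk_names = [c.name for c in track.chunks]
    kw = dict(window_sd=config.window_sd,
              no_response_threshold=config.no_response_threshold,
              dt=track.dt, statistic=config.epoch_statistic)
    acc, cm = ev.evaluate_outputs(res.o, track.annotations, chunk_names, **kw)
    acc1, _ = ev.evaluate_outputs(res.z1, track.annotations, chunk_names, **kw)
    acc2, _ = ev.evaluate_outputs(res.z2, track.annotations, chunk_names, **kw)
    report = EvalReport(accuracy=acc, confusion=cm, accuracy_rc1=acc1,
                        accuracy_rc2=acc2, seed=seed, variant=model.variant)
    return report, res


def run_learning_experiment(
    config: ExperimentConfig,
    seed: int = 0,
    record_stride: int = 0,
    return_artifacts: bool = False,
):
    """Generate tracks, build and train a model, score it on held-out data.

    Returns the :class:`EvalReport`, or with ``return_artifacts=True`` a
    tuple ``(report, model, train_log, test_track, inference_result)`` for
    downstream trajectory analysis.
    """
    s_model, s_train, s_eval = _spawn_seeds(seed + 2 ** 20, 3)
    track_tr, track_te = make_tracks(config, seed)
    I1 = config.stimulus.n_text_dims
    I2 = config.stimulus.n_image_dims
    model = build_model(
        config.variant,
        config.model.with_input(I1), config.model.with_input(I2),
        config.teaching, np.random.default_rng(s_model))
    model, log = train(model, track_tr, seed=s_train)
    report, res = evaluate_model(model, track_te, config, seed=s_eval,
                                 record_stride=record_stride)
    if return_artifacts:
        return report, model, log, track_te, res
    return report


def run_cooccurrence_sweep(
    config: ExperimentConfig,
    m_grid: Sequence[float] = (0.0, 0.5, 1.0),
    seeds: Sequence[int] = (0, 1, 2),
    protocols: Sequence[str] = ("train", "test"),
) -> pd.DataFrame:
    """Accuracy as a function of the pair-replacement probability ``m``.

    ``protocol="train"`` trains on manipulated signals and tests clean;
    ``"test"`` trains clean and tests on manipulated signals.  One row per
    (m, protocol, seed).
    """
    rows = []
    for m in m_grid:
        for protocol in protocols:
            for seed in seeds:
                cfg = replace(config, m=float(m), d=0.0, manipulate=protocol)
                rep = run_learning_experiment(cfg, seed=seed)
                rows.append({"m": float(m), "protocol": protocol, "seed": seed,
                             "accuracy": rep.accuracy,
                             "accuracy_rc1": rep.accuracy_rc1,
                             "accuracy_rc2": rep.accuracy_rc2})
    return pd.DataFrame(rows)


def run_delay_sweep(
    config: ExperimentConfig,
    d_grid: Sequence[float] = (0.0, 125.0, 250.0),
    seeds: Sequence[int] = (0, 1, 2),
    protocols: Sequence[str] = ("train", "test"),
) -> pd.DataFrame:
    """Accuracy as a function of the inter-modal delay ``d`` (ms)."""
    rows = []
    for d in d_grid:
        for protocol in protocols:
            for seed in seeds:
                cfg = replace(config, d=float(d), m=0.0, manipulate=protocol)
                rep = run_learning_experiment(cfg, seed=seed)
                rows.append({"d": float(d), "protocol": protocol, "seed": seed,
                             "accuracy": rep.accuracy,
                             "accuracy_rc1": rep.accuracy_rc1,
                             "accuracy_rc2": rep.accuracy_rc2})
    return pd.DataFrame(rows)


def run_variant_comparison(
    config: ExperimentConfig,
    variants: Sequence[str] = ("original", "a1", "a2", "a3"),
    seeds: Sequence[int] = tuple(range(10)),
) -> pd.DataFrame:
    """Association- and module-level accuracy for each interaction variant."""
    rows = []
    for variant in variants:
        for seed in seeds:
            cfg = replace(config, variant=variant)
            rep = run_learning_experiment(cfg, seed=seed)
            rows.append({"variant": variant, "seed": seed,
                         "accuracy": rep.accuracy,
                         "accuracy_rc1": rep.accuracy_rc1,
                         "accuracy_rc2": rep.accuracy_rc2})
    return pd.DataFrame(rows)


def run_parameter_sweep(
    config: ExperimentConfig,
    grid: Dict[str, Sequence],
    seeds: Sequence[int] = (0,),
) -> pd.DataFrame:
    """Accuracy over a cartesian grid of :class:`ModelParams` fields.

    ``grid`` maps field names (e.g. ``tau``, ``g``, ``N``, ``S``, ``p``) to
    value lists; every combination is trained and scored per seed.
    """
    import itertools

    names = list(grid)
    rows = []
    for values in itertools.product(*(grid[n] for n in names)):
        overrides = dict(zip(names, values))
        mp = replace(config.model, **overrides)
        cfg = replace(config, model=mp)
        for seed in seeds:
            rep = run_learning_experiment(cfg, seed=seed)
            row = {**{k: v for k, v in overrides.items()}, "seed": seed,
                   "accuracy": rep.accuracy,
                   "accuracy_rc1": rep.accuracy_rc1,
                   "accuracy_rc2": rep.accuracy_rc2}
            rows.append(row)
    return pd.DataFrame(rows)
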