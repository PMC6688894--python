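"""Baby-step curriculum training over severity-graded synthetic stages.

The training pool starts as the original labelled dataset and grows stage by
stage with synthetically corrupted copies of good-quality samples: heavily
corrupted ("easy") stages first, subtle ("hard") stages last.  After each
stage the best validation checkpoint seen so far is retained.  Two baselines
share the machinery: the *anti*-curriculum reverses the stage order, and the
*control*-curriculum randomly partitions the pooled synthetic samples into
equal stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import kspace_artefacts as ka
from .classifiers import ModelState, TrainConfig, Trainer, encode_dataset
from .phantom import CineSequence

__all__ = ["Sample", "Curriculum", "CurriculumRunLog", "StageRecord",
           "build_curriculum", "curriculum_train"]

ORDER_MODES = ("curriculum", "anti", "control")


@dataclass
class Sample:
    """A labelled sequence with identity and origin bookkeeping."""

    id: str
    seq: CineSequence
    origin: str                      # "original" or "synthetic"
    stage: int | None = None         # severity level that produced it, if synthetic


@dataclass
class StageRecord:
    stage: int
    pool_size: int
    epochs: int
    best_val_metric: float
    checkpoint_epoch: int
    seen_ids: set[str] = field(default_factory=set)
    original_artefact_seen: bool = False


@dataclass
class CurriculumRunLog:
    stages: list[StageRecord] = field(default_factory=list)

    def pool_sizes(self) -> list[int]:
        return [s.pool_size for s in self.stages]

    def total_epochs(self) -> int:
        return sum(s.epochs for s in self.stages)


@dataclass
class Curriculum:
    """Ordered synthetic stages D^1..D^b plus the always-present original set."""

    stages: list[list[Sample]]
    original_set: list[Sample]
    order_mode: str = "curriculum"

    def __post_init__(self) -> None:
        if self.order_mode not in ORDER_MODES:
            raise ValueError(f"order_mode must be one of {ORDER_MODES}; got {self.order_mode!r}")
        if not self.stages:
            raise ValueError("curriculum must have at least one stage")

    @property
    def b(self) -> int:
        return len(self.stages)


def build_curriculum(base_set: list[Sample] | list[CineSequence],
                     artefact_types: list[str],
                     schedule: ka.SeveritySchedule | dict,
                     samples_per_stage: int,
                     order_mode: str = "curriculum",
                     seed: int = 0) -> Curriculum:
    """Create severity-graded synthetic stages from good-quality base samples.

    Each stage holds ``samples_per_stage`` freshly corrupted copies of
    randomly chosen good base samples at that stage's severity, labelled as
    artefacts, cycling over ``artefact_types``.  ``schedule`` is one
    :class:`~cineqc.kspace_artefacts.SeveritySchedule` or a dict mapping each
    artefact type to its schedule.  Stage order follows ``order_mode``:
    most-to-least severe (curriculum), reversed (anti), or a seeded random
    partition of the pooled synthetic samples (control).
    """
    if samples_per_stage < 1:
        raise ValueError("samples_per_stage must be >= 1")
    if not base_set:
        raise ValueError("base set is empty")
    samples = [
        s if isinstance(s, Sample) else Sample(id=f"orig{i}", seq=s, origin="original")
        for i, s in enumerate(base_set)
    ]
    good = [s for s in samples if s.seq.label == "good"]
    if not good:
        raise ValueError("base set has no good-quality samples to corrupt")

    schedules = schedule if isinstance(schedule, dict) else {schedule.artefact_type: schedule}
    for t in artefact_types:
        if t not in schedules:
            raise ValueError(f"no severity schedule for artefact type {t!r}")
    b = next(iter(schedules.values())).b
    if any(s.b != b for s in schedules.values()):
        raise ValueError("all schedules must have the same number of levels")

    rng = np.random.default_rng(seed)
    stages: list[list[Sample]] = []
    counter = 0
    for level in range(1, b + 1):
        stage: list[Sample] = []
        for m in range(samples_per_stage):
            base = good[int(rng.integers(len(good)))]
            a_type = artefact_types[(counter + m) % len(artefact_types)]
            corrupted = ka.corrupt_at_level(base.seq, schedules[a_type], level,
                                            seed=int(rng.integers(0, 2**31)))
            stage.append(Sample(id=f"synth-L{level}-{m}", seq=corrupted,
                                origin="synthetic", stage=level))
        counter += samples_per_stage
        stages.append(stage)

    if order_mode == "anti":
        stages = stages[::-1]
    elif order_mode == "control":
        pooled = [s for stage in stages for s in stage]
        perm = rng.permutation(len(pooled))
        splits = np.array_split(perm, b)
        stages = [[pooled[int(i)] for i in split] for split in splits]
    return Curriculum(stages=stages, original_set=samples, order_mode=order_mode)


def curriculum_train(state: ModelState, curriculum: Curriculum,
                     val_set: list[CineSequence], config: TrainConfig
                     ) -> tuple[ModelState, CurriculumRunLog]:
    """Staged training: pool = originals + stages 1..i, k epochs per stage.

    The original samples (including every original artefact case, whose
    severity is unknown) stay in the pool at every stage.  After each stage
    the best-so-far validation checkpoint is selected; the returned state
    carries those weights.
    """
    pool_ids = {id(s.seq) for stage in curriculum.stages for s in stage}
    pool_ids |= {id(s.seq) for s in curriculum.original_set}
    if any(id(v) in pool_ids for v in val_set):
        raise ValueError("validation set overlaps the curriculum training pool")

    trainer = Trainer(state, config, val_set)
    log = CurriculumRunLog()
    orig_artefact_ids = {s.id for s in curriculum.original_set if s.seq.label != "good"}

    pool: list[Sample] = list(curriculum.original_set)
    for i, stage in enumerate(curriculum.stages, start=1):
        pool = pool + stage
        x, y = encode_dataset([s.seq for s in pool], state.spec)
        ids = [s.id for s in pool]
        seen: set[str] = set()
        for _ in range(config.epochs_per_stage):
            record = trainer.run_epoch(x, y, ids=ids)
            seen.update(record["seen_ids"])
        log.stages.append(StageRecord(
            stage=i,
            pool_size=len(pool),
            epochs=config.epochs_per_stage,
            best_val_metric=trainer.best_metric,
            checkpoint_epoch=trainer.best_epoch,
            seen_ids=seen,
            original_artefact_seen=orig_artefact_ids.issubset(seen) if orig_artefact_ids else False,
        ))
    trainer.restore_best()
    return state, log
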