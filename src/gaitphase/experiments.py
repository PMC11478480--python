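"""End-to-end study driver: simulate a cohort, train both stages, and
evaluate own- versus cross-subject performance.

This reproduces the study design on synthetic data: one condition
classifier trained on all subjects' training trials, one phase estimator
per subject, the third trial of every scenario held out for testing, and a
full (training subject × testing subject) evaluation grid whose diagonal is
the own-subject result.  Normalization statistics are fit per subject on
that subject's training recordings; at test time each subject's data uses
their own normalization.

Problem sizes default to a compact configuration (see docs/methods.md) so
that a full study runs on a single CPU in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluation import (
    ConfusionMatrix,
    CrossSubjectGrid,
    cross_subject_evaluation,
    wc_confusion,
)
from .models import (
    PhaseEstimatorConfig,
    TrainedModel,
    WcClassifierConfig,
    _classifier_windows,
    fit_norm_stats_per_subject,
    predict_wc,
    train_phase_estimator,
    train_wc_classifier,
)
from .signal_io import FsrRecording, make_split
from .synthetic_gait import default_scripts, make_cohort, simulate_protocol


@dataclass
class StudyConfig:
    """Sizes and hyperparameters of one synthetic study run."""

    seed: int = 0
    n_subjects: int = 4
    trials_per_script: int = 3
    strides_level: int = 30
    strides_seg: int = 8
    test_trial_index: int = 3
    val_fraction: float = 0.2
    wc_epochs: int = 10
    wc_hop: int = 75
    wc_folds: int = 1
    phase_epochs: int = 12
    phase_hop: int = 10
    variant: int = 1
    eval_hop: int = 15


@dataclass
class StudyResult:
    """Everything a study run computes."""

    wc_accuracy: float
    confusion: ConfusionMatrix
    grid: CrossSubjectGrid
    own_rmse: float
    own_r2: float
    cross_rmse: float
    cross_r2: float
    per_condition_own: dict = field(default_factory=dict)
    wc_model: TrainedModel | None = None
    phase_models: dict = field(default_factory=dict)
    n_samples: int = 0


def run_study(cfg: StudyConfig | None = None, **overrides) -> StudyResult:
    """Simulate, train and evaluate one full synthetic study."""
    if cfg is None:
        cfg = StudyConfig(**overrides)
    seed = int(cfg.seed) % (2**31)

    cohort = make_cohort(cfg.n_subjects, seed)
    scripts = default_scripts(cfg.strides_level, cfg.strides_seg)
    dataset = simulate_protocol(cohort, scripts, cfg.trials_per_script)
    split = make_split(dataset, cfg.test_trial_index, cfg.val_fraction)
    stats = fit_norm_stats_per_subject(split.train_recordings)

    # Stage 1: one classifier for the whole cohort.
    wc_cfg = WcClassifierConfig(
        max_epochs=cfg.wc_epochs, hop=cfg.wc_hop, folds=cfg.wc_folds, seed=seed + 11
    )
    wc_model = train_wc_classifier(split, wc_cfg, norm_stats=stats)

    # Held-out window accuracy and cohort confusion.
    subj_blocks, Xs, ys = [], [], []
    for rec, sl in split.test:
        Xw, yw = _classifier_windows([(rec, sl)], stats, wc_cfg.seq_len, cfg.eval_hop)
        if len(Xw):
            Xs.append(Xw)
            ys.append(yw)
            subj_blocks.append(np.repeat(rec.subject_id, len(yw)))
    X_test, y_test = np.concatenate(Xs), np.concatenate(ys)
    _, y_hat = predict_wc(wc_model, X_test)
    confusion = wc_confusion(y_test, y_hat, subjects=np.concatenate(subj_blocks))
    wc_accuracy = float(np.mean(y_hat == y_test))

    # Stage 2: one phase estimator per subject (teacher-forced condition code).
    phase_models: dict[str, TrainedModel] = {}
    test_by_subject: dict[str, list[FsrRecording]] = {}
    for rec in split.test_recordings:
        test_by_subject.setdefault(rec.subject_id, []).append(rec)
    for k, profile in enumerate(cohort):
        s = profile.subject_id
        subj_data = [r for r in dataset if r.subject_id == s]
        subj_split = make_split(subj_data, cfg.test_trial_index, cfg.val_fraction)
        ph_cfg = PhaseEstimatorConfig(
            variant=cfg.variant, max_epochs=cfg.phase_epochs, hop=cfg.phase_hop,
            seed=seed + 101 + k,
        )
        phase_models[s] = train_phase_estimator(
            subj_split, ph_cfg, norm_stats=stats[s]
        )

    grid = cross_subject_evaluation(
        phase_models, test_by_subject, wc_model, hop=cfg.eval_hop, norm_stats=stats
    )
    # per-condition own-subject means over the grid diagonal
    S = len(grid.subjects)
    eye = np.eye(S, dtype=bool)
    from .signal_io import WALKING_CONDITIONS

    diag = {
        wc: {
            "rmse": float(np.nanmean(grid.rmse[:, :, w][eye])),
            "r2": float(np.nanmean(grid.r2[:, :, w][eye])),
        }
        for w, wc in enumerate(WALKING_CONDITIONS)
    }
    return StudyResult(
        wc_accuracy=wc_accuracy,
        confusion=confusion,
        grid=grid,
        own_rmse=grid.own_mean("rmse"),
        own_r2=grid.own_mean("r2"),
        cross_rmse=grid.cross_mean("rmse"),
        cross_r2=grid.cross_mean("r2"),
        per_condition_own=diag,
        wc_model=wc_model,
        phase_models=phase_models,
        n_samples=int(sum(r.n_samples for r in dataset)),
    )
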