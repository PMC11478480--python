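"""The two cascaded sequence models and the serial inference pipeline.

Stage 1 classifies the walking condition from a 100-sample window of the 10
normalized FSR channels; stage 2 regresses the CSF phase pair
(cos θ, sin θ) from a 25-sample window of the chosen feature variant, which
may include the stage-1 condition code as a one-hot block.  Both stages are
two-layer bidirectional LSTMs with dropout and a dense head:

    classifier:  Bi-LSTM(128) → drop 0.25 → Bi-LSTM(64) → drop 0.25
                 → dense 64 (relu) → 5-way softmax
    estimator:   Bi-LSTM(128) → drop 0.25 → Bi-LSTM(32) → drop 0.25
                 → dense 2 (tanh) → linear 2

Training uses Adam (lr 0.001), batch 100, early stopping with patience 5 on
validation loss; the classifier additionally supports k-fold
cross-validation (default 5 folds), returning the best fold's model.
During stage-2 training the condition block defaults to ground-truth labels
(teacher forcing); at inference the classifier's per-sample argmax is
always injected.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.model_selection import KFold

from ._recurrent import Adam, BiLSTM, Dense, Dropout, Network, mse, softmax, softmax_xent
from .phase_features import (
    NormStats,
    apply_minmax,
    build_features,
    build_windows,
    decode_phase,
    encode_phase,
    fit_norm_stats,
    variant_width,
    VARIANT_BLOCKS,
)
from .signal_io import DataError, DataSplit, FsrRecording, WALKING_CONDITIONS


@dataclass
class WcClassifierConfig:
    """Hyperparameters of the walking-condition classifier."""

    hidden1: int = 128
    hidden2: int = 64
    dropout: tuple = (0.25, 0.25)
    dense: int = 64
    n_classes: int = 5
    seq_len: int = 100
    input_width: int = 10
    batch_size: int = 100
    learning_rate: float = 1e-3
    patience: int = 5
    folds: int = 5
    max_epochs: int = 100
    hop: int = 1
    seed: int = 0

    def __post_init__(self):
        if min(self.hidden1, self.hidden2, self.dense) <= 0:
            raise ValueError("layer widths must be positive")
        if not all(0.0 <= d < 1.0 for d in self.dropout):
            raise ValueError("dropout rates must be in [0, 1)")
        if self.n_classes != len(WALKING_CONDITIONS):
            raise ValueError("classifier must have one class per walking condition")


@dataclass
class PhaseEstimatorConfig:
    """Hyperparameters of the continuous gait-phase estimator."""

    hidden1: int = 128
    hidden2: int = 32
    dropout: tuple = (0.25, 0.25)
    dense: int = 2
    output: int = 2
    seq_len: int = 25
    variant: int = 1
    batch_size: int = 100
    learning_rate: float = 1e-3
    patience: int = 5
    max_epochs: int = 100
    hop: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.output != 2:
            raise ValueError("the CSF regression head must have width 2")

    @property
    def input_width(self) -> int:
        return variant_width(self.variant)


@dataclass
class TrainedModel:
    """A trained network plus everything needed to reuse it."""

    network: Network
    config: object
    history: list = field(default_factory=list)
    fold_histories: list = field(default_factory=list)
    norm_stats: NormStats | None = None
    kind: str = "wc"  # "wc" or "phase"

    @property
    def feature_variant(self) -> int | None:
        return getattr(self.config, "variant", None)

    # -- persistence ---------------------------------------------------
    def save(self, path) -> None:
        meta = {
            "kind": self.kind,
            "config": asdict(self.config),
            "history": self.history,
            "fold_histories": self.fold_histories,
        }
        arrays = {f"param_{i}": p for i, p in enumerate(self.network.params())}
        if isinstance(self.norm_stats, NormStats):
            arrays["norm_min"] = self.norm_stats.channel_min
            arrays["norm_max"] = self.norm_stats.channel_max
            meta["fore_max"] = self.norm_stats.fore_max
            meta["back_max"] = self.norm_stats.back_max
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["meta"]))
        cfg_cls = WcClassifierConfig if meta["kind"] == "wc" else PhaseEstimatorConfig
        cfg_dict = dict(meta["config"])
        if "dropout" in cfg_dict:
            cfg_dict["dropout"] = tuple(cfg_dict["dropout"])
        cfg = cfg_cls(**cfg_dict)
        net = (
            build_wc_classifier(cfg) if meta["kind"] == "wc" else build_phase_estimator(cfg)
        )
        params = [data[f"param_{i}"] for i in range(len(net.params()))]
        net.set_state(params)
        stats = None
        if "norm_min" in data:
            stats = NormStats(
                data["norm_min"], data["norm_max"], meta["fore_max"], meta["back_max"]
            )
        return cls(
            network=net,
            config=cfg,
            history=meta["history"],
            fold_histories=meta.get("fold_histories", []),
            norm_stats=stats,
            kind=meta["kind"],
        )


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

def build_wc_classifier(cfg: WcClassifierConfig) -> Network:
    """Table-stack classifier network; identical weights for identical seeds."""
    rng = np.random.default_rng(cfg.seed)
    return Network(
        [
            BiLSTM(cfg.input_width, cfg.hidden1, rng, return_sequences=True),
            Dropout(cfg.dropout[0]),
            BiLSTM(2 * cfg.hidden1, cfg.hidden2, rng, return_sequences=False),
            Dropout(cfg.dropout[1]),
            Dense(2 * cfg.hidden2, cfg.dense, rng, activation="relu"),
            Dense(cfg.dense, cfg.n_classes, rng),
        ]
    )


def build_phase_estimator(cfg: PhaseEstimatorConfig) -> Network:
    """Table-stack CSF regressor; linear two-unit output."""
    rng = np.random.default_rng(cfg.seed)
    return Network(
        [
            BiLSTM(cfg.input_width, cfg.hidden1, rng, return_sequences=True),
            Dropout(cfg.dropout[0]),
            BiLSTM(2 * cfg.hidden1, cfg.hidden2, rng, return_sequences=False),
            Dropout(cfg.dropout[1]),
            Dense(2 * cfg.hidden2, cfg.dense, rng, activation="tanh"),
            Dense(cfg.dense, cfg.output, rng),
        ]
    )


# ---------------------------------------------------------------------------
# Fitting machinery
# ---------------------------------------------------------------------------

def _batched_forward(net: Network, X: np.ndarray, batch: int) -> np.ndarray:
    outs = [net.forward(X[i : i + batch]) for i in range(0, len(X), batch)]
    return np.concatenate(outs, axis=0)


def _eval_loss(net, X, y, loss_fn, batch) -> float:
    total, n = 0.0, 0
    for i in range(0, len(X), batch):
        out = net.forward(X[i : i + batch])
        l, _ = loss_fn(out, y[i : i + batch])
        total += l * len(out)
        n += len(out)
    return total / max(n, 1)


def fit_network(
    net: Network,
    loss_fn,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    batch_size: int = 100,
    learning_rate: float = 1e-3,
    max_epochs: int = 100,
    patience: int = 5,
    rng: np.random.Generator | None = None,
) -> list[dict]:
    """Mini-batch Adam training with early stopping on validation loss.

    Stops after ``patience`` consecutive epochs without validation
    improvement and restores the best parameters.  Returns the per-epoch
    history of train/validation losses.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    opt = Adam(net.params(), lr=learning_rate)
    history: list[dict] = []
    best_val = np.inf
    best_state = net.get_state()
    bad_epochs = 0
    have_val = len(X_val) > 0
    for epoch in range(1, max_epochs + 1):
        perm = rng.permutation(len(X_train))
        train_loss, seen = 0.0, 0
        for start in range(0, len(perm), batch_size):
            idx = perm[start : start + batch_size]
            xb = np.ascontiguousarray(X_train[idx])
            out = net.forward(xb, train=True, rng=rng)
            l, dout = loss_fn(out, y_train[idx])
            net.backward(dout)
            opt.step(net.grads())
            train_loss += l * len(idx)
            seen += len(idx)
        train_loss /= max(seen, 1)
        val_loss = (
            _eval_loss(net, X_val, y_val, loss_fn, batch_size) if have_val else train_loss
        )
        history.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})
        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_state = net.get_state()
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= patience:
                break
    net.set_state(best_state)
    return history


# ---------------------------------------------------------------------------
# Window assembly from splits
# ---------------------------------------------------------------------------

def _stats_for(stats, rec: FsrRecording) -> NormStats:
    """Resolve per-subject statistics: a dict maps subject id -> NormStats."""
    if isinstance(stats, dict):
        try:
            return stats[rec.subject_id]
        except KeyError:
            raise DataError(f"no normalization statistics for subject {rec.subject_id}")
    return stats


def fit_norm_stats_per_subject(recordings: list[FsrRecording]) -> dict[str, NormStats]:
    """Min–max/regional statistics fit separately per subject (each subject's
    own training recordings define their normalization)."""
    by_subject: dict[str, list] = {}
    for rec in recordings:
        by_subject.setdefault(rec.subject_id, []).append(rec)
    return {s: fit_norm_stats(recs) for s, recs in by_subject.items()}


def _classifier_windows(part, stats, seq_len, hop):
    """Windows of the 10 normalized channels with the condition label at the
    window's final sample."""
    Xs, ys = [], []
    for rec, sl in part:
        forces = apply_minmax(rec, _stats_for(stats, rec)).forces[sl]
        labels = np.asarray(rec.wc)[sl]
        w, lab, _ = build_windows(forces, labels, seq_len, hop)
        if len(w):
            Xs.append(w)
            ys.append(lab.astype(int))
    if not Xs:
        return np.empty((0, seq_len, 10)), np.empty(0, int)
    return np.concatenate(Xs), np.concatenate(ys)


def _estimator_windows(part, stats, cfg, hop, wc_codes_by_rec=None):
    """Feature windows paired with the CSF pair of the end-sample phase."""
    Xs, ys = [], []
    for rec, sl in part:
        if rec.phase is None:
            raise DataError(
                f"recording {rec.key()} has no ground-truth phase to train on"
            )
        rec_stats = _stats_for(stats, rec)
        rec_n = apply_minmax(rec, rec_stats)
        codes = None if wc_codes_by_rec is None else wc_codes_by_rec[rec.key()]
        fm = build_features(rec_n, rec_stats, variant=cfg.variant, wc_code=codes)
        w, phase_end, _ = build_windows(
            fm.values[sl], np.asarray(rec.phase)[sl], cfg.seq_len, hop
        )
        if len(w):
            Xs.append(w)
            ys.append(encode_phase(phase_end))
    if not Xs:
        raise DataError("no training windows (recordings shorter than seq_len?)")
    return np.concatenate(Xs), np.concatenate(ys)


# ---------------------------------------------------------------------------
# Training protocols
# ---------------------------------------------------------------------------

def train_wc_classifier(
    split: DataSplit,
    cfg: WcClassifierConfig,
    norm_stats: NormStats | None = None,
) -> TrainedModel:
    """Train the condition classifier per the study protocol.

    Normalization statistics are fit on the training recordings (unless
    supplied) and frozen.  With ``cfg.folds > 1`` the pooled train+val
    windows are k-folded; each fold trains with early stopping and the model
    from the fold with the best validation loss is returned together with
    all fold histories.  With ``folds == 1`` the split's own train/val
    blocks are used directly.
    """
    if norm_stats is None:
        norm_stats = fit_norm_stats(split.train_recordings)
    Xtr, ytr = _classifier_windows(split.train, norm_stats, cfg.seq_len, cfg.hop)
    Xval, yval = _classifier_windows(split.validation, norm_stats, cfg.seq_len, cfg.hop)
    present = set(np.unique(ytr))
    missing = [WALKING_CONDITIONS[c] for c in range(cfg.n_classes) if c not in present]
    if missing:
        raise DataError(f"walking condition(s) absent from training data: {missing}")

    fold_histories: list[list[dict]] = []
    if cfg.folds > 1:
        X = np.concatenate([Xtr, Xval]) if len(Xval) else Xtr
        y = np.concatenate([ytr, yval]) if len(yval) else ytr
        kf = KFold(n_splits=cfg.folds, shuffle=True, random_state=cfg.seed)
        best = (np.inf, None, None)
        for k, (tr_idx, va_idx) in enumerate(kf.split(X)):
            net = build_wc_classifier(cfg)
            hist = fit_network(
                net, softmax_xent, X[tr_idx], y[tr_idx], X[va_idx], y[va_idx],
                batch_size=cfg.batch_size, learning_rate=cfg.learning_rate,
                max_epochs=cfg.max_epochs, patience=cfg.patience,
                rng=np.random.default_rng(cfg.seed + 1 + k),
            )
            fold_histories.append(hist)
            fold_best = min(h["val_loss"] for h in hist)
            if fold_best < best[0]:
                best = (fold_best, net, hist)
        net, history = best[1], best[2]
    else:
        net = build_wc_classifier(cfg)
        history = fit_network(
            net, softmax_xent, Xtr, ytr, Xval, yval,
            batch_size=cfg.batch_size, learning_rate=cfg.learning_rate,
            max_epochs=cfg.max_epochs, patience=cfg.patience,
            rng=np.random.default_rng(cfg.seed + 1),
        )
    return TrainedModel(
        network=net, config=cfg, history=history, fold_histories=fold_histories,
        norm_stats=norm_stats, kind="wc",
    )


def train_phase_estimator(
    split: DataSplit,
    cfg: PhaseEstimatorConfig,
    norm_stats: NormStats | None = None,
    wc_model: TrainedModel | None = None,
    teacher_forcing: bool = True,
) -> TrainedModel:
    """Train the CSF phase regressor on the split's 80/20 blocks.

    The condition block of the feature variant uses ground-truth labels by
    default (teacher forcing); pass ``teacher_forcing=False`` with a trained
    classifier to train on stage-1 predictions instead.
    """
    if norm_stats is None:
        norm_stats = fit_norm_stats(split.train_recordings)
    wc_codes = None
    if not teacher_forcing:
        if wc_model is None:
            raise ValueError("teacher_forcing=False requires a trained wc_model")
        wc_codes = {}
        for rec, _ in split.train + split.validation:
            if rec.key() not in wc_codes:
                wc_codes[rec.key()] = predict_wc_per_sample(
                    wc_model, rec, _stats_for(norm_stats, rec)
                )
    Xtr, ytr = _estimator_windows(split.train, norm_stats, cfg, cfg.hop, wc_codes)
    Xval, yval = (
        _estimator_windows(split.validation, norm_stats, cfg, cfg.hop, wc_codes)
        if split.validation
        else (np.empty((0,) + Xtr.shape[1:]), np.empty((0, 2)))
    )
    net = build_phase_estimator(cfg)
    history = fit_network(
        net, mse, Xtr, ytr, Xval, yval,
        batch_size=cfg.batch_size, learning_rate=cfg.learning_rate,
        max_epochs=cfg.max_epochs, patience=cfg.patience,
        rng=np.random.default_rng(cfg.seed + 1),
    )
    return TrainedModel(
        network=net, config=cfg, history=history, norm_stats=norm_stats, kind="phase"
    )


# ---------------------------------------------------------------------------
# Prediction and the serial pipeline
# ---------------------------------------------------------------------------

def predict_wc(model: TrainedModel, windows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-window class probabilities (rows sum to 1) and argmax labels."""
    cfg = model.config
    if windows.ndim != 3 or windows.shape[1:] != (cfg.seq_len, cfg.input_width):
        raise ValueError(
            f"windows shape {windows.shape} does not match "
            f"(n, {cfg.seq_len}, {cfg.input_width})"
        )
    logits = _batched_forward(model.network, windows, cfg.batch_size)
    probs = softmax(logits)
    return probs, probs.argmax(axis=1)


def predict_wc_per_sample(
    model: TrainedModel,
    recording: FsrRecording,
    norm_stats: NormStats,
    hop: int = 1,
) -> np.ndarray:
    """Per-sample predicted condition codes for one recording.

    Windows end every ``hop`` samples; between window ends the last exported
    classification is held, and samples before the first complete window get
    code -1 (no prediction yet).
    """
    cfg = model.config
    forces = apply_minmax(recording, norm_stats).forces
    windows, _, ends = build_windows(forces, None, cfg.seq_len, hop)
    codes = np.full(recording.n_samples, -1, dtype=int)
    if len(windows) == 0:
        return codes
    _, labels = predict_wc(model, windows)
    for e, nxt, lab in zip(ends, list(ends[1:]) + [recording.n_samples], labels):
        codes[e:nxt] = lab
    return codes


@dataclass
class PipelineResult:
    """Per-sample output of the serial two-stage pipeline.

    ``valid`` marks samples at which a phase estimate was produced (window
    ends); earlier samples are never extrapolated.
    """

    wc_pred: np.ndarray          # per-sample condition code, -1 before warm-up
    phase_pred: np.ndarray       # per-sample phase in [0, 100), NaN where invalid
    csf_pred: np.ndarray         # (n_eval, 2) raw CSF outputs
    eval_indices: np.ndarray     # sample indices with phase estimates
    valid: np.ndarray            # boolean mask over samples


def run_pipeline(
    recording: FsrRecording,
    phase_model: TrainedModel,
    wc_model: TrainedModel | None = None,
    hop: int = 1,
    wc_source: str = "model",
    norm_stats: NormStats | None = None,
) -> PipelineResult:
    """Run classification → phase estimation serially on one recording.

    The stage-1 argmax condition code is held between exports and injected
    into the stage-2 feature windows exactly as the variant dictates; the
    phase comes from decoding the two-unit CSF output.  ``hop`` subsamples
    the evaluation points (hop = 1 estimates at every sample once both
    windows are warm).  ``wc_source="truth"`` bypasses stage 1 and uses the
    recording's own labels (ablation aid).
    """
    cfg = phase_model.config
    stats = norm_stats if norm_stats is not None else phase_model.norm_stats
    if stats is None:
        raise ValueError("phase model carries no normalization statistics")
    stats = _stats_for(stats, recording)
    needs_wc = "wc" in VARIANT_BLOCKS[cfg.variant]
    if not needs_wc and wc_model is not None:
        warnings.warn(
            f"variant {cfg.variant} ignores the walking-condition code; "
            "the supplied classifier is unused",
            stacklevel=2,
        )
    if needs_wc and wc_source == "model":
        if wc_model is None:
            raise ValueError(f"variant {cfg.variant} needs a trained classifier")
        codes = predict_wc_per_sample(wc_model, recording, stats, hop=hop)
        warmup = wc_model.config.seq_len - 1
    else:
        codes = np.asarray(recording.wc, dtype=int)
        warmup = 0
    rec_n = apply_minmax(recording, stats)
    fm = build_features(rec_n, stats, variant=cfg.variant, wc_code=codes)
    windows, _, ends = build_windows(fm.values, None, cfg.seq_len, hop)
    # drop windows whose condition code is still unset (stage-1 warm-up)
    warm_start = max(warmup, cfg.seq_len - 1)
    keep = ends >= warm_start
    windows, ends = windows[keep], ends[keep]
    n = recording.n_samples
    phase_per_sample = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    if len(windows):
        csf = _batched_forward(phase_model.network, windows, cfg.batch_size)
        # a (numerically possible) zero output decodes to phase 0
        zero = (csf[:, 0] == 0.0) & (csf[:, 1] == 0.0)
        csf[zero, 0] = 1.0
        phase = decode_phase(csf)
        phase_per_sample[ends] = phase
        valid[ends] = True
    else:
        csf = np.empty((0, 2))
    return PipelineResult(
        wc_pred=codes,
        phase_pred=phase_per_sample,
        csf_pred=csf,
        eval_indices=ends,
        valid=valid,
    )
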