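"""Phase-error metrics, confusion matrices, own-/cross-subject grids, and
the input-feature ablation report.

Phase errors are circular by default: the per-sample error is
``e = ((est − true + 50) mod 100) − 50``, so an estimate of 0.5 against a
truth of 99.5 counts as 1 unit, not 99.  Derived metrics:

* RMSE — root mean square of ``e`` (phase units on the 0–100 cycle);
* R² — coefficient of determination on the CSF regression targets,
  pooled over both (cos, sin) components;
* rRMSE — RMSE divided by the mean estimated phase, as a percentage;
* APEE — mean absolute circular phase error, as a percentage of the cycle;
* NRMSE — RMSE divided by the 100-unit phase range, as a percentage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from .models import PhaseEstimatorConfig, TrainedModel, run_pipeline, train_phase_estimator
from .phase_features import encode_phase
from .signal_io import DataError, WALKING_CONDITIONS, WC_TO_CODE


def circular_phase_error(est: np.ndarray, true: np.ndarray, circular: bool = True) -> np.ndarray:
    """Signed phase error on the 0–100 cycle (wrapped into [-50, 50))."""
    diff = np.asarray(est, float) - np.asarray(true, float)
    if not circular:
        return diff
    return np.mod(diff + 50.0, 100.0) - 50.0


def _metric_block(true, est, est_csf=None, circular=True) -> dict:
    e = circular_phase_error(est, true, circular=circular)
    rmse = float(np.sqrt(np.mean(e * e)))
    csf_true = encode_phase(true)
    csf_est = encode_phase(est) if est_csf is None else np.asarray(est_csf, float)
    ss_res = float(np.sum((csf_true - csf_est) ** 2))
    ss_tot = float(np.sum((csf_true - csf_true.mean(axis=0)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    mean_est = float(np.mean(est))
    rrmse = rmse / mean_est * 100.0 if mean_est != 0 else np.nan
    return {
        "rmse": rmse,
        "r2": r2,
        "rrmse": rrmse,
        "apee": float(np.mean(np.abs(e))),
        "nrmse": rmse / 100.0 * 100.0,
        "n": int(len(e)),
    }


@dataclass
class PhaseErrorSummary:
    """Overall and per-condition phase-error metrics."""

    overall: dict
    per_condition: dict = field(default_factory=dict)

    def condition_mean(self, metric: str) -> float:
        """Unweighted mean of a per-condition metric over the conditions
        present — the aggregation used for headline numbers."""
        return aggregate_per_condition(
            [blk[metric] for blk in self.per_condition.values()]
        )


def aggregate_per_condition(values) -> float:
    """Headline aggregate: the unweighted mean of per-condition values."""
    return float(np.mean(np.asarray(values, dtype=float)))


def nrmse_from_rmse(rmse: float) -> float:
    """NRMSE in percent: RMSE over the 100-unit phase range, times 100."""
    return rmse / 100.0 * 100.0


def phase_error_metrics(
    true_phase: np.ndarray,
    est_phase: np.ndarray,
    wc: np.ndarray | None = None,
    mask: np.ndarray | None = None,
    est_csf: np.ndarray | None = None,
    circular: bool = True,
) -> PhaseErrorSummary:
    """Compute the full metric block, overall and per walking condition.

    ``mask`` restricts evaluation to valid samples (it is intersected with
    finiteness of both series).  ``est_csf`` supplies the raw model outputs
    for the R² computation; otherwise the decoded phase is re-encoded.
    """
    true_phase = np.asarray(true_phase, float)
    est_phase = np.asarray(est_phase, float)
    if true_phase.shape != est_phase.shape:
        raise DataError("true and estimated phase series differ in length")
    ok = np.isfinite(true_phase) & np.isfinite(est_phase)
    if mask is not None:
        ok &= np.asarray(mask, bool)
    if not np.any(ok):
        raise DataError("no overlapping valid samples to evaluate")
    idx = np.flatnonzero(ok)
    csf = None
    if est_csf is not None:
        est_csf = np.asarray(est_csf, float)
        if len(est_csf) == len(true_phase):
            csf = est_csf[idx]
        elif len(est_csf) == len(idx):
            csf = est_csf
        else:
            raise DataError("est_csf length matches neither series nor mask")
    overall = _metric_block(true_phase[idx], est_phase[idx], csf, circular)
    per_condition = {}
    if wc is not None:
        wc = np.asarray(wc)
        for name, code in WC_TO_CODE.items():
            sel = idx[wc[idx] == code]
            if len(sel):
                pos = np.flatnonzero(wc[idx] == code)
                per_condition[name] = _metric_block(
                    true_phase[sel], est_phase[sel],
                    None if csf is None else csf[pos], circular,
                )
    return PhaseErrorSummary(overall=overall, per_condition=per_condition)


# ---------------------------------------------------------------------------
# Walking-condition confusion
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    """5×5 condition confusion: counts plus per-subject row percentages."""

    counts: np.ndarray
    pct_mean: np.ndarray
    pct_sd: np.ndarray
    labels: tuple = WALKING_CONDITIONS

    @property
    def accuracy(self) -> float:
        total = self.counts.sum()
        return float(np.trace(self.counts) / total) if total else np.nan


def wc_confusion(
    true_labels: np.ndarray,
    pred_labels: np.ndarray,
    subjects: np.ndarray | None = None,
) -> ConfusionMatrix:
    """Confusion counts and row-normalized percentages.

    With per-window ``subjects``, the percentage matrix is computed per
    subject and reported as mean ± SD across subjects, mirroring how a
    cohort-level confusion table is assembled.
    """
    k = len(WALKING_CONDITIONS)
    true_labels = np.asarray(true_labels, int)
    pred_labels = np.asarray(pred_labels, int)
    for arr, what in ((true_labels, "true"), (pred_labels, "predicted")):
        bad = (arr < 0) | (arr >= k)
        if np.any(bad):
            raise DataError(f"unknown {what} label code(s): {np.unique(arr[bad])}")
    counts = _sk_confusion(true_labels, pred_labels, labels=range(k))
    if subjects is None:
        subjects = np.zeros(len(true_labels), dtype=int)
    subjects = np.asarray(subjects)
    pcts = []
    for s in np.unique(subjects):
        sel = subjects == s
        c = _sk_confusion(true_labels[sel], pred_labels[sel], labels=range(k)).astype(float)
        rows = c.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            pcts.append(np.where(rows > 0, c / rows * 100.0, np.nan))
    stack = np.stack(pcts)
    return ConfusionMatrix(
        counts=counts,
        pct_mean=np.nanmean(stack, axis=0),
        pct_sd=np.nanstd(stack, axis=0),
    )


# ---------------------------------------------------------------------------
# Own-/cross-subject evaluation
# ---------------------------------------------------------------------------

@dataclass
class CrossSubjectGrid:
    """RMSE/R² for every (training subject, testing subject, condition).

    The diagonal holds the own-subject results; aggregate means are
    unweighted over conditions and subject pairs.
    """

    subjects: list
    rmse: np.ndarray  # (S, S, 5), NaN where a condition is absent
    r2: np.ndarray

    def _agg(self, arr: np.ndarray, diagonal: bool) -> float:
        S = len(self.subjects)
        mask = np.eye(S, dtype=bool) if diagonal else ~np.eye(S, dtype=bool)
        per_wc = [np.nanmean(arr[:, :, w][mask]) for w in range(arr.shape[2])]
        return aggregate_per_condition([v for v in per_wc if np.isfinite(v)])

    def own_mean(self, metric: str = "rmse") -> float:
        return self._agg(getattr(self, metric), diagonal=True)

    def cross_mean(self, metric: str = "rmse") -> float:
        return self._agg(getattr(self, metric), diagonal=False)


def evaluate_pipeline(
    recordings: list,
    phase_model: TrainedModel,
    wc_model: TrainedModel | None,
    hop: int = 1,
    norm_stats=None,
) -> PhaseErrorSummary:
    """Run the serial pipeline over recordings and score against the
    generator's ground-truth phase (per-condition grouping uses the true
    condition labels).  ``norm_stats`` overrides the model's stored
    statistics, e.g. with the test subject's own normalization."""
    trues, ests, csfs, wcs = [], [], [], []
    for rec in recordings:
        if rec.phase is None:
            raise DataError(f"recording {rec.key()} lacks ground-truth phase")
        res = run_pipeline(rec, phase_model, wc_model, hop=hop, norm_stats=norm_stats)
        idx = res.eval_indices
        trues.append(np.asarray(rec.phase)[idx])
        ests.append(res.phase_pred[idx])
        csfs.append(res.csf_pred)
        wcs.append(np.asarray(rec.wc)[idx])
    return phase_error_metrics(
        np.concatenate(trues),
        np.concatenate(ests),
        wc=np.concatenate(wcs),
        est_csf=np.concatenate(csfs),
    )


def cross_subject_evaluation(
    phase_models: dict,
    test_recordings: dict,
    wc_model: TrainedModel | None,
    hop: int = 1,
    norm_stats=None,
) -> CrossSubjectGrid:
    """Evaluate every trained model on every subject's held-out test data.

    ``phase_models`` maps subject id → per-subject phase model;
    ``test_recordings`` maps subject id → list of test recordings.  Missing
    entries raise :class:`DataError` naming the subject.
    """
    subjects = sorted(phase_models)
    if len(subjects) < 2:
        raise DataError("cross-subject evaluation needs at least 2 subjects")
    for s in subjects:
        if s not in test_recordings or not test_recordings[s]:
            raise DataError(f"no test recordings for subject {s}")
    S, K = len(subjects), len(WALKING_CONDITIONS)
    rmse = np.full((S, S, K), np.nan)
    r2 = np.full((S, S, K), np.nan)
    for i, train_subj in enumerate(subjects):
        model = phase_models[train_subj]
        for j, test_subj in enumerate(subjects):
            summary = evaluate_pipeline(
                test_recordings[test_subj], model, wc_model, hop=hop,
                norm_stats=norm_stats,
            )
            for wc, blk in summary.per_condition.items():
                w = WC_TO_CODE[wc]
                rmse[i, j, w] = blk["rmse"]
                r2[i, j, w] = blk["r2"]
    return CrossSubjectGrid(subjects=subjects, rmse=rmse, r2=r2)


# ---------------------------------------------------------------------------
# Input-feature ablation
# ---------------------------------------------------------------------------

def ablation_report(
    split,
    base_cfg: PhaseEstimatorConfig,
    wc_model: TrainedModel | None,
    variants=(1, 2, 3, 4, 5),
    hop: int = 1,
    norm_stats=None,
) -> dict[int, PhaseErrorSummary]:
    """Train and evaluate one phase model per feature variant.

    All variants share the split, the seed and every other hyperparameter,
    so differences isolate the input features.  Variants without a
    condition block are evaluated without the classifier.
    """
    from dataclasses import replace

    from .phase_features import VARIANT_BLOCKS

    report = {}
    for v in variants:
        cfg = replace(base_cfg, variant=v)
        model = train_phase_estimator(split, cfg, norm_stats=norm_stats)
        needs_wc = "wc" in VARIANT_BLOCKS[v]
        report[v] = evaluate_pipeline(
            split.test_recordings, model, wc_model if needs_wc else None,
            hop=hop, norm_stats=norm_stats,
        )
    return report
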