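"""Evaluation: ROC AUC, percentile-bootstrap confidence intervals, the
overfitting-gap model-selection criterion, cross-validation orchestration,
greedy forward feature selection, and the Kruskal-Wallis comparison used in
the windowing experiment.

The selection criterion: among epochs whose overfitting gap
(train AUC - validation AUC) is at most a threshold, pick the epoch with
the highest validation AUC. The threshold starts at 0.05 and is escalated
in steps of 0.01 until at least one epoch qualifies; the final threshold is
reported alongside the chosen epoch.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

from .errors import ConfigurationError, HncnetError

_GAP_TOL = 1e-9  # guards <= comparisons against float escalation error


class UndefinedMetricError(HncnetError):
    """AUC requested for single-class labels."""


# ---------------------------------------------------------------------------
# ROC AUC
# ---------------------------------------------------------------------------

def roc_auc(labels, scores) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) + 0.5 * P(tie)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ConfigurationError("scores must be finite")
    if len(np.unique(labels)) < 2:
        raise UndefinedMetricError("AUC is undefined for single-class labels")
    return float(roc_auc_score(labels, scores))


def _rank_auc_rows(labels: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Row-wise tied-rank AUC for matrices of resampled (label, score) pairs.

    Rows with a single class yield NaN.
    """
    ranks = stats.rankdata(scores, axis=1, method="average")
    npos = labels.sum(axis=1)
    nneg = labels.shape[1] - npos
    with np.errstate(invalid="ignore", divide="ignore"):
        auc = (np.where(labels == 1, ranks, 0.0).sum(axis=1) - npos * (npos + 1) / 2.0) / (npos * nneg)
    auc[(npos == 0) | (nneg == 0)] = np.nan
    return auc


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_ci(labels, scores, n_resamples: int = 1000, level: float = 0.95,
                 seed: int = 0, max_retries: int = 20) -> tuple[float, float]:
    """Percentile bootstrap CI for the ROC AUC.

    (label, score) pairs are resampled with replacement; single-class
    resamples are redrawn up to ``max_retries`` times and then skipped with
    a warning.
    """
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    roc_auc(labels, scores)  # validates the sample itself
    n = len(labels)
    rng = np.random.default_rng(seed)

    idx = rng.integers(0, n, size=(n_resamples, n))
    aucs = _rank_auc_rows(labels[idx], scores[idx])
    for _ in range(max_retries):
        bad = np.isnan(aucs)
        if not bad.any():
            break
        redraw = rng.integers(0, n, size=(int(bad.sum()), n))
        aucs[bad] = _rank_auc_rows(labels[redraw], scores[redraw])
    skipped = int(np.isnan(aucs).sum())
    if skipped:
        warnings.warn(f"{skipped} degenerate bootstrap resamples skipped")
        aucs = aucs[~np.isnan(aucs)]
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(aucs, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SelectionCriterion:
    initial_gap_threshold: float = 0.05
    escalation_step: float = 0.01
    mode: str = "gap_constrained"  # | "best_val_auc" | "lowest_val_loss"

    def __post_init__(self):
        if self.initial_gap_threshold < 0 or self.escalation_step <= 0:
            raise ConfigurationError("thresholds must be >= 0 and the step > 0")
        if self.mode not in ("gap_constrained", "best_val_auc", "lowest_val_loss"):
            raise ConfigurationError(f"unknown selection mode {self.mode!r}")


def _unpack_logs(logs):
    """Accept EpochLog objects or (train_auc, val_auc[, val_loss]) tuples."""
    epochs, tr, va, vl = [], [], [], []
    for i, log in enumerate(logs):
        if hasattr(log, "train_auc"):
            epochs.append(log.epoch)
            tr.append(log.train_auc)
            va.append(log.val_auc)
            vl.append(getattr(log, "val_loss", np.nan))
        else:
            epochs.append(i + 1)
            tr.append(log[0])
            va.append(log[1])
            vl.append(log[2] if len(log) > 2 else np.nan)
    return np.array(epochs), np.array(tr), np.array(va), np.array(vl)


def select_model(logs, crit: SelectionCriterion = SelectionCriterion()) -> tuple[int, float]:
    """Return (chosen epoch, final threshold used).

    Gap-constrained mode: eligible epochs have train AUC - val AUC <=
    threshold; among them the highest validation AUC wins (ties -> earliest
    epoch). If no epoch qualifies the threshold escalates by
    ``escalation_step`` until one does. The other modes ignore the
    threshold and report it unchanged.
    """
    if len(logs) == 0:
        raise ConfigurationError("select_model needs at least one epoch log")
    epochs, tr, va, vl = _unpack_logs(logs)

    if crit.mode == "best_val_auc":
        return int(epochs[int(np.argmax(va))]), crit.initial_gap_threshold
    if crit.mode == "lowest_val_loss":
        if np.isnan(vl).any():
            raise ConfigurationError("lowest_val_loss mode requires val_loss in the logs")
        return int(epochs[int(np.argmin(vl))]), crit.initial_gap_threshold

    gaps = tr - va
    threshold = crit.initial_gap_threshold
    while True:
        eligible = np.nonzero(gaps <= threshold + _GAP_TOL)[0]
        if eligible.size:
            best = eligible[int(np.argmax(va[eligible]))]
            return int(epochs[best]), float(threshold)
        threshold += crit.escalation_step


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    mode: str                                  # "cohort_split" | "kfold"
    outcome: str = ""
    auc: dict = field(default_factory=dict)    # split -> AUC (cohort split)
    ci: dict = field(default_factory=dict)     # split -> [lo, hi]
    fold_auc: dict = field(default_factory=dict)   # split -> per-fold list
    fold_mean: dict = field(default_factory=dict)  # split -> mean
    fold_range: dict = field(default_factory=dict) # split -> [min, max]
    selection: dict = field(default_factory=dict)  # chosen epoch(s), threshold(s)

    def to_json(self) -> str:
        def _round(x):
            if isinstance(x, dict):
                return {k: _round(v) for k, v in sorted(x.items())}
            if isinstance(x, (list, tuple)):
                return [_round(v) for v in x]
            if isinstance(x, float):
                return round(x, 10)
            return x

        return json.dumps(_round(asdict(self)), sort_keys=True, indent=1)


def run_cv(images, labels, test_images, test_labels, *, k: int = 5,
           build_fn: Callable, train_cfg, criterion: SelectionCriterion = SelectionCriterion(),
           seed: int = 0, clinical=None, test_clinical=None) -> EvalReport:
    """Stratified k-fold CV with a fixed external test set.

    Per fold: train on k-1 folds with the held-out fold as validation,
    select the epoch with the gap-constrained criterion, then score the
    external test set with the selected weights.
    """
    from dataclasses import replace as _replace

    from sklearn.model_selection import StratifiedKFold

    from .training import restore_epoch, train_model

    labels = np.asarray(labels)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    report = EvalReport(mode="kfold")
    per_split: dict[str, list[float]] = {"train": [], "validation": [], "test": []}
    for fold, (tr_idx, va_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        model = build_fn(seed=seed + fold)
        train_set = {"x": images[tr_idx], "y": labels[tr_idx]}
        val_set = {"x": images[va_idx], "y": labels[va_idx]}
        if clinical is not None:
            train_set["clinical"] = clinical[tr_idx]
            val_set["clinical"] = clinical[va_idx]
        cfg = _replace(train_cfg, seed=train_cfg.seed + fold)
        model, logs, ckpts = train_model(model, train_set, val_set, cfg)
        epoch, threshold = select_model(logs, criterion)
        restore_epoch(model, ckpts, epoch)
        per_split["train"].append(roc_auc(labels[tr_idx], model.predict_proba(
            images[tr_idx], clinical=None if clinical is None else clinical[tr_idx])))
        per_split["validation"].append(roc_auc(labels[va_idx], model.predict_proba(
            images[va_idx], clinical=None if clinical is None else clinical[va_idx])))
        per_split["test"].append(roc_auc(test_labels, model.predict_proba(
            test_images, clinical=test_clinical)))
        report.selection[f"fold{fold}"] = {"epoch": epoch, "threshold": threshold}
    for split, values in per_split.items():
        report.fold_auc[split] = [float(v) for v in values]
        report.fold_mean[split] = float(np.mean(values))
        report.fold_range[split] = [float(np.min(values)), float(np.max(values))]
    return report


# ---------------------------------------------------------------------------
# forward feature selection
# ---------------------------------------------------------------------------

def forward_feature_selection(candidate_features: Sequence[str],
                              eval_fn: Callable[[list], float],
                              patience: int = 0) -> list:
    """Greedy forward selection over named candidate features.

    ``eval_fn`` maps a feature subset (possibly empty, which scores the
    baseline model) to a validation AUC. At each step the candidate giving
    the highest ``eval_fn`` is added; ties break toward the earlier
    candidate in declared order. Selection stops after ``patience + 1``
    consecutive steps without strict improvement over the incumbent, and
    any non-improving tail is discarded.
    """
    if not candidate_features:
        raise ConfigurationError("need at least one candidate feature")
    selected: list = []
    remaining = list(candidate_features)
    best_auc = float(eval_fn([]))  # incumbent: the model without clinical features
    best_len = 0
    stale = 0
    while remaining:
        step_scores = [eval_fn(selected + [c]) for c in remaining]
        j = int(np.argmax(step_scores))  # first index on ties
        if step_scores[j] > best_auc:
            best_auc = step_scores[j]
            stale = 0
            selected.append(remaining.pop(j))
            best_len = len(selected)
        else:
            stale += 1
            if stale > patience:
                break
            selected.append(remaining.pop(j))
    return selected[:best_len]


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------

def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Rank-based H with tie correction; p from the chi-squared
    approximation with (#groups - 1) degrees of freedom."""
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ConfigurationError("need >= 2 nonempty groups")
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(flat == flat[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*[np.asarray(g, dtype=float) for g in groups])
    return float(h), float(p)
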