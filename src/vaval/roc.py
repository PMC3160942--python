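"""ROC curves and AUC for categorical cause-of-death methods.

Two constructions are provided.  For a hard categorical method (a physician
coder, or the engine's final verdict) each cause contributes one operating
point from its one-vs-rest 2×2 — FPR = 1 − specificity on x, TPR =
sensitivity on y — and the empirical curve through those points (anchored at
(0,0) and (1,1)) is integrated by trapezoid.  For a method with per-cause
scores (the engine's posteriors) all (death, cause) one-vs-rest pairs are
pooled and a threshold sweep gives the usual score-based curve, whose
trapezoidal AUC equals the Mann–Whitney concordance statistic.

Overall performance is called adequate when AUC strictly exceeds 0.75.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .agreement import two_by_two

ADEQUACY_CUTOFF = 0.75


@dataclass
class ROCResult:
    """An empirical ROC curve: (FPR, TPR) points, AUC, and the adequacy call."""

    points: list[tuple[float, float]]
    auc: float
    adequate: bool

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=["fpr", "tpr"])


def adequacy(auc: float) -> bool:
    """Strictly-greater-than-0.75 rule for adequate overall performance."""
    if not (0.0 <= auc <= 1.0):
        raise ValueError(f"AUC must lie in [0, 1], got {auc}")
    return auc > ADEQUACY_CUTOFF


def _finalize(points: np.ndarray) -> ROCResult:
    """Anchor, sort by (FPR, TPR), deduplicate, integrate."""
    pts = np.vstack([points, [[0.0, 0.0], [1.0, 1.0]]])
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    pts = np.unique(pts[order], axis=0)
    auc = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    return ROCResult(points=[tuple(p) for p in pts], auc=auc, adequate=adequacy(auc))


def roc_from_categorical(pred, gold, categories) -> ROCResult:
    """One operating point per cause from its one-vs-rest 2×2.

    A cause never observed in the gold standard has undefined sensitivity;
    its point is skipped with a warning.
    """
    pred, gold = list(pred), list(gold)
    if len(pred) != len(gold):
        raise ValueError("prediction and gold vectors must be paired")
    pts = []
    for cause in categories:
        t = two_by_two(pred, gold, cause)
        sens, *_ = t.sensitivity
        spec, *_ = t.specificity
        if sens is None or spec is None:
            warnings.warn(
                f"cause {cause!r} absent from gold standard; ROC point skipped",
                stacklevel=2,
            )
            continue
        pts.append((1.0 - spec / 100.0, sens / 100.0))
    return _finalize(np.array(pts or np.empty((0, 2))))


def roc_from_scores(scores, gold, categories) -> ROCResult:
    """Pooled one-vs-rest score-threshold ROC for a probabilistic method.

    ``scores`` is an (n_deaths × n_categories) array (or DataFrame with the
    categories as columns) of per-death per-cause scores; ``gold`` gives the
    true cause of each death.  Every (death, cause) pair is pooled as one
    binary classification instance and the threshold is swept over the
    observed scores.  The trapezoidal AUC of the resulting curve equals the
    Mann–Whitney probability that a randomly chosen positive pair outscores
    a randomly chosen negative one (ties counting half).
    """
    categories = list(categories)
    if isinstance(scores, pd.DataFrame):
        scores = scores.reindex(columns=categories).to_numpy(dtype=float)
    scores = np.asarray(scores, dtype=float)
    gold = list(gold)
    if scores.shape != (len(gold), len(categories)):
        raise ValueError(
            f"scores shape {scores.shape} does not match "
            f"({len(gold)}, {len(categories)})"
        )
    idx = {c: j for j, c in enumerate(categories)}
    y = np.zeros_like(scores, dtype=bool)
    for i, g in enumerate(gold):
        if g in idx:  # indeterminate gold rows contribute only negatives
            y[i, idx[g]] = True
    y, s = y.ravel(), scores.ravel()

    if np.ptp(s) == 0.0:
        warnings.warn("constant scores: ROC is the chance diagonal", stacklevel=2)
        return _finalize(np.empty((0, 2)))

    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative pair")
    order = np.argsort(-s, kind="stable")
    y_sorted, s_sorted = y[order], s[order]
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(~y_sorted)
    # one operating point per distinct threshold (last index of each run)
    last = np.r_[np.nonzero(np.diff(s_sorted))[0], len(s_sorted) - 1]
    pts = np.column_stack([fps[last] / n_neg, tps[last] / n_pos])
    return _finalize(pts)
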