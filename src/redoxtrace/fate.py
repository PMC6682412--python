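"""Logistic cell-fate model: the OxD 'death threshold'.

A cell's OxD at an early decision time (default 40 min after an
oxidative insult) predicts whether it dies many hours later.  A
maximum-likelihood logistic regression of terminal fate on decision
OxD,

    P(death | OxD) = 1 / (1 + exp(-(beta0 + beta1 * OxD))),

yields the decision boundary OxD* = -beta0/beta1 where the predicted
death probability crosses 0.5.  Classification is scored with false
positives (alive cells predicted dead) and false negatives (dead cells
predicted alive) expressed as fractions of ALL cells, so that

    accuracy = 1 - FP - FN

holds exactly; per-class rates are reported alongside.  Perfectly
separated data (no class overlap) have no finite MLE: the model then
falls back to the midpoint between the highest alive OxD and the
lowest dead OxD, with a separation flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm

__all__ = ["FateModel", "ClassificationScore", "fit_logistic", "decision_threshold", "classify_and_score"]


@dataclass(frozen=True)
class FateModel:
    """Fitted log-odds coefficients and the derived OxD decision boundary."""

    beta0: float
    beta1: float
    threshold_oxd: float
    n_cells: int
    converged: bool = True
    separated: bool = False

    def predict_proba(self, oxd) -> np.ndarray:
        z = self.beta0 + self.beta1 * np.asarray(oxd, dtype=float)
        return 1.0 / (1.0 + np.exp(-z))


@dataclass(frozen=True)
class ClassificationScore:
    """Confusion counts plus the additive accuracy decomposition."""

    n: int
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    false_positive_rate: float   # FP / n (fraction of all cells)
    false_negative_rate: float   # FN / n
    fp_rate_per_class: float     # FP / (alive cells)
    fn_rate_per_class: float     # FN / (dead cells)


def _separation_gap(oxd: np.ndarray, died: np.ndarray):
    """If classes are perfectly separated on OxD, return the gap (lo, hi)."""
    alive_max = oxd[~died].max()
    dead_min = oxd[died].min()
    if alive_max < dead_min:
        return float(alive_max), float(dead_min)
    return None


def fit_logistic(
    oxd: Sequence[float],
    died: Sequence[bool],
    min_n: int = 20,
    ridge: float = 0.0,
) -> FateModel:
    """Maximum-likelihood logistic fit of fate on decision OxD.

    Requires both classes and at least ``min_n`` cells.  On complete
    separation the MLE diverges; the returned model then carries the
    class-boundary midpoint as its threshold with ``separated=True``.
    An optional ridge penalty stabilizes near-degenerate data.
    """
    x = np.asarray(oxd, dtype=float)
    y = np.asarray(died, dtype=bool)
    ok = np.isfinite(x)
    x, y = x[ok], y[ok]
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} cells, got {x.size}")
    if y.all() or (~y).all():
        raise ValueError("both fates must be present to fit the model")

    gap = _separation_gap(x, y)
    if gap is not None:
        mid = 0.5 * (gap[0] + gap[1])
        # steep but finite surrogate slope through the midpoint
        slope = 4.0 / max(gap[1] - gap[0], 1e-6)
        return FateModel(
            beta0=-slope * mid, beta1=slope, threshold_oxd=mid,
            n_cells=int(x.size), converged=False, separated=True,
        )

    exog = sm.add_constant(x)
    model = sm.Logit(y.astype(float), exog)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if ridge > 0:
            res = model.fit_regularized(alpha=ridge, L1_wt=0.0, disp=0)
            converged = True
        else:
            res = model.fit(disp=0, maxiter=200)
            converged = bool(res.mle_retvals.get("converged", True))
    beta0, beta1 = float(res.params[0]), float(res.params[1])
    if beta1 == 0:
        raise ValueError("degenerate fit: zero slope")
    return FateModel(
        beta0=beta0, beta1=beta1, threshold_oxd=-beta0 / beta1,
        n_cells=int(x.size), converged=converged, separated=False,
    )


def decision_threshold(model: FateModel) -> float:
    """OxD at which predicted death probability crosses 0.5 (-beta0/beta1)."""
    if model.beta1 == 0:
        raise ValueError("threshold undefined for zero slope")
    return -model.beta0 / model.beta1


def classify_and_score(
    model: FateModel, oxd: Sequence[float], died: Sequence[bool]
) -> ClassificationScore:
    """Score threshold predictions (OxD > threshold => dead) against fates.

    FP/FN rates use the total cell count as denominator so accuracy,
    FP and FN decompose additively; per-class rates are included too.
    """
    x = np.asarray(oxd, dtype=float)
    y = np.asarray(died, dtype=bool)
    if x.size == 0:
        raise ValueError("empty input")
    pred = x > model.threshold_oxd
    tp = int(np.sum(pred & y))
    tn = int(np.sum(~pred & ~y))
    fp = int(np.sum(pred & ~y))
    fn = int(np.sum(~pred & y))
    n = x.size
    n_alive = int(np.sum(~y))
    n_dead = int(np.sum(y))
    return ClassificationScore(
        n=n, tp=tp, tn=tn, fp=fp, fn=fn,
        # defined via the additive decomposition so accuracy = 1 - FP - FN
        # holds by construction (FP, FN as fractions of all cells)
        accuracy=1.0 - (fp + fn) / n,
        false_positive_rate=fp / n,
        false_negative_rate=fn / n,
        fp_rate_per_class=fp / n_alive if n_alive else float("nan"),
        fn_rate_per_class=fn / n_dead if n_dead else float("nan"),
    )
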