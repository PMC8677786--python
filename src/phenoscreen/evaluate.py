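"""Cross-validated performance estimation and reliability diagnostics.

Predictive performance is measured by mean absolute error (MAE), with
performance on unseen compounds estimated by k-fold cross-validation
(default k=10).  The per-prediction reliability score — the standard
deviation of the individual trees' predictions — is validated by its
rank correlation with the realised absolute error on held-out compounds:
a positive Spearman coefficient means low tree disagreement does flag
low prediction error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pct import (
    Ensemble,
    TrainingSet,
    TreeParams,
    fit_ensemble,
    predict_ensemble_many,
)

TARGETS = ("rfp", "egfp")


def mae(predictions: Sequence[float], truths: Sequence[float]) -> float:
    """Mean absolute error between two equal-length sequences."""
    p = np.asarray(predictions, dtype=float)
    t = np.asarray(truths, dtype=float)
    if p.shape != t.shape or p.ndim != 1:
        raise ValueError("predictions and truths must be equal-length 1-d")
    if p.size == 0:
        raise ValueError("empty input")
    return float(np.abs(p - t).mean())


@dataclass
class CVReport:
    """Held-out predictions of a k-fold cross-validation run.

    ``rows`` holds one record per held-out compound (truth, prediction,
    per-target tree-sd, absolute error, fold index).  ``aggregate_mae``
    pools absolute errors over all held-out predictions; ``fold_mae``
    reports per-fold means alongside.
    """

    k: int
    rows: pd.DataFrame
    fold_mae: pd.DataFrame  # k rows, columns rfp/egfp
    aggregate_mae: dict[str, float]
    seed: int

    def __post_init__(self) -> None:
        counts = self.rows.groupby("fold").size()
        if len(counts) != self.k:
            raise ValueError("folds do not cover the dataset")


def assign_folds(n: int, k: int, seed: int) -> np.ndarray:
    """Fold index per record: seeded shuffle, then contiguous blocks;
    the n % k remainder records go one-per-fold starting at fold 0."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds dataset size n={n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    base, rem = divmod(n, k)
    folds = np.empty(n, dtype=int)
    start = 0
    for f in range(k):
        size = base + (1 if f < rem else 0)
        folds[order[start : start + size]] = f
        start += size
    return folds


def kfold_mae(
    ts: TrainingSet, params: TreeParams, k: int = 10, seed: int = 0
) -> CVReport:
    """k-fold cross-validation of the bagging ensemble.

    For each fold an ensemble is fitted on the remaining records (with a
    per-fold seed spawned from the root seed) and the held-out records
    are predicted.  The aggregate MAE pools the absolute errors of all
    held-out predictions.
    """
    n = len(ts)
    folds = assign_folds(n, k, seed)
    fold_seeds = np.random.SeedSequence(seed).spawn(k)
    rows = []
    for f in range(k):
        held = np.flatnonzero(folds == f)
        train = np.flatnonzero(folds != f)
        sub = TrainingSet([ts.records[i] for i in train])
        ens = fit_ensemble(sub, params, seed=int(fold_seeds[f].generate_state(1)[0] % 2**31))
        preds = predict_ensemble_many(
            ens, [ts.records[i].fingerprint for i in held]
        )
        for i, pred in zip(held, preds):
            rec = ts.records[i]
            rows.append(
                {
                    "id": rec.id,
                    "fold": f,
                    "rfp_true": rec.rfp,
                    "egfp_true": rec.egfp,
                    "rfp_pred": pred.rfp_mean,
                    "egfp_pred": pred.egfp_mean,
                    "rfp_sd": pred.rfp_sd,
                    "egfp_sd": pred.egfp_sd,
                    "rfp_abs_err": abs(pred.rfp_mean - rec.rfp),
                    "egfp_abs_err": abs(pred.egfp_mean - rec.egfp),
                }
            )
    frame = pd.DataFrame(rows)
    fold_mae = frame.groupby("fold")[["rfp_abs_err", "egfp_abs_err"]].mean()
    fold_mae.columns = list(TARGETS)
    aggregate = {
        "rfp": float(frame["rfp_abs_err"].mean()),
        "egfp": float(frame["egfp_abs_err"].mean()),
    }
    return CVReport(
        k=k, rows=frame, fold_mae=fold_mae, aggregate_mae=aggregate, seed=seed
    )


@dataclass(frozen=True)
class ReliabilityDiagnostic:
    """Spearman rank correlation between tree-sd and absolute error."""

    target: str
    coefficient: float
    n_pairs: int

    def __post_init__(self) -> None:
        if not -1.0 <= self.coefficient <= 1.0:
            raise ValueError("correlation outside [-1, 1]")


def reliability_error_correlation(
    report: CVReport, target: str
) -> ReliabilityDiagnostic:
    """Rank (Spearman) correlation between per-prediction reliability sd
    and realised absolute error on held-out compounds.

    Spearman is used because the claim being checked is a monotone
    association, not a linear one; ties take mid-ranks.  A constant sd
    vector leaves the correlation undefined and raises.
    """
    if target not in TARGETS:
        raise ValueError(f"unknown target {target!r}")
    sd = report.rows[f"{target}_sd"].to_numpy()
    err = report.rows[f"{target}_abs_err"].to_numpy()
    if sd.size < 3:
        raise ValueError("need at least 3 held-out predictions")
    if np.ptp(sd) == 0:
        raise ValueError("constant sd vector: correlation undefined")
    rho = stats.spearmanr(sd, err).statistic
    return ReliabilityDiagnostic(
        target=target, coefficient=float(rho), n_pairs=int(sd.size)
    )


def plot_reliability(report: CVReport, path: str) -> None:
    """Write a simple sd-vs-absolute-error scatter (one panel per target)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(8, 3.5), sharey=False)
    for ax, target in zip(axes, TARGETS):
        ax.scatter(
            report.rows[f"{target}_sd"],
            report.rows[f"{target}_abs_err"],
            s=6,
            alpha=0.5,
        )
        ax.set_xlabel(f"{target} tree sd")
        ax.set_ylabel(f"{target} |error|")
        ax.set_title(target.upper())
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
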