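"""Evaluation statistics for the simulation study.

Misclassification rate (MC) is the class-proportion-weighted per-class
error  MC = sum_y pi_y * m_y / n_y  with pi_y the class's share of the
evaluated sample, m_y its misclassification count and n_y its size; under
this weighting MC reduces to the plain error fraction, but the formula is
kept explicit so fixed external priors can be substituted.

Feature-selection quality is measured by the false-positive count (#FP,
selected features outside the true signal set) and the true contribution
(TC, the share of dissimilarity weight mass landing on the true signal
features).  Scenario-level winners are compared by PAMA (probability of
achieving the maximum accuracy) and P95 (probability of achieving at least
95% of the best accuracy).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EvalRecord",
    "ScenarioSummary",
    "misclassification_rate",
    "false_positive_count",
    "true_contribution",
    "pama",
    "p95",
    "records_to_frame",
    "summarize_records",
]


@dataclass
class EvalRecord:
    """One classifier's result on one simulated replicate."""

    scenario_id: str
    classifier_id: str
    rep: int
    mc: float
    n_false_positive: int | None = None
    true_contribution: float | None = None
    null_model: bool = False


@dataclass
class ScenarioSummary:
    """Per-classifier averages across the replicates of one scenario.

    ``mean_tc`` averages over all replicates (a null model contributes 0);
    ``mean_tc_nonnull`` averages only replicates where the penalized fit
    selected at least one feature.  Both conventions are reported because
    published averages rarely state which was used.
    """

    scenario_id: str
    classifier_id: str
    n_reps: int
    mean_mc: float
    mean_fp: float | None = None
    mean_tc: float | None = None
    mean_tc_nonnull: float | None = None
    n_null: int = 0


def misclassification_rate(y_true, y_pred) -> float:
    """Class-proportion-weighted misclassification rate in [0, 1]."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    for v in (y_true, y_pred):
        if not np.all(np.isin(v, [0, 1])):
            raise ValueError("labels must be binary in {0, 1}")
    n = y_true.size
    mc = 0.0
    for cls in (0, 1):
        mask = y_true == cls
        ny = int(mask.sum())
        if ny == 0:
            continue
        pi_y = ny / n
        my = int(np.sum(y_pred[mask] != cls))
        mc += pi_y * my / ny
    return float(mc)


def false_positive_count(support, true_signal) -> int:
    """Number of selected features outside the true signal set."""
    return len(set(map(int, support)) - set(map(int, true_signal)))


def true_contribution(w, true_signal) -> float:
    """Total dissimilarity weight mass placed on the true signal features."""
    arr = np.asarray(getattr(w, "w", w), dtype=float)
    idx = np.asarray(sorted(set(map(int, true_signal))), dtype=int)
    if idx.size == 0:
        return 0.0
    return float(arr[idx].sum())


def _as_table(accuracy_table) -> np.ndarray:
    t = np.asarray(accuracy_table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 1:
        raise ValueError("accuracy table must be 2-d with at least one scenario row")
    return t


def pama(accuracy_table) -> np.ndarray:
    """Fraction of scenario rows where each classifier attains the row
    maximum accuracy; exact ties credit every tied classifier."""
    t = _as_table(accuracy_table)
    wins = t == t.max(axis=1, keepdims=True)
    return wins.mean(axis=0)


def p95(accuracy_table) -> np.ndarray:
    """Fraction of scenario rows where each classifier reaches at least
    95% of the row-maximum accuracy (boundary inclusive)."""
    t = _as_table(accuracy_table)
    ok = t >= 0.95 * t.max(axis=1, keepdims=True)
    return ok.mean(axis=0)


def records_to_frame(records) -> pd.DataFrame:
    """Tidy per-replicate results: one row per (scenario, classifier, rep)."""
    return pd.DataFrame(
        [
            {
                "scenario_id": r.scenario_id,
                "classifier": r.classifier_id,
                "rep": r.rep,
                "mc": r.mc,
                "n_fp": r.n_false_positive,
                "tc": r.true_contribution,
                "null_model": r.null_model,
            }
            for r in records
        ]
    )


def summarize_records(records) -> list[ScenarioSummary]:
    """Aggregate per-replicate records into per-scenario, per-classifier means."""
    df = records_to_frame(records)
    out: list[ScenarioSummary] = []
    for (sid, clf), grp in df.groupby(["scenario_id", "classifier"], sort=True):
        has_fs = grp["n_fp"].notna().any()
        nonnull = grp[~grp["null_model"].astype(bool)]
        out.append(
            ScenarioSummary(
                scenario_id=sid,
                classifier_id=clf,
                n_reps=len(grp),
                mean_mc=float(grp["mc"].mean()),
                mean_fp=float(grp["n_fp"].mean()) if has_fs else None,
                mean_tc=float(grp["tc"].mean()) if has_fs else None,
                mean_tc_nonnull=(
                    float(nonnull["tc"].mean()) if has_fs and len(nonnull) else None
                ),
                n_null=int(grp["null_model"].sum()),
            )
        )
    return out
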