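"""Scoring of predicted turning angles against clinician-style labels.

Three headline metrics:

* accuracy — percent of predictions whose quantised bin matches the label;
* MAE — mean absolute error in degrees between the *continuous* predicted
  angle and the discrete label (label quantisation error, up to 22.5 deg,
  is part of the metric by construction);
* weighted precision (WPrec) — per-bin precision combined with weights
  proportional to each bin's true-label count. A bin that has true labels
  but is never predicted contributes precision 0 with its full weight
  (the zero-support rule), which penalises missed bins.

Plus a speed MAE when ground-truth angular speed exists, grouped
breakdowns, and Cohen's kappa for inter-rater agreement checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .skeleton import TurnAnnotation

__all__ = [
    "EvalReport",
    "bin_accuracy",
    "mae_angle",
    "mae_speed",
    "weighted_precision",
    "confusion_matrix",
    "evaluate",
    "grouped_report",
    "cohen_kappa",
]


@dataclass
class EvalReport:
    """Metric bundle for one (sub)set of turns."""

    accuracy_pct: float
    mae_deg: float
    wprec_pct: float
    n: int
    mae_omega_deg_s: float | None = None
    confusion: pd.DataFrame | None = field(default=None, repr=False)
    group_key: str | None = None

    def to_dict(self) -> dict:
        d = {
            "group": self.group_key,
            "n": self.n,
            "accuracy_pct": self.accuracy_pct,
            "mae_deg": self.mae_deg,
            "wprec_pct": self.wprec_pct,
        }
        if self.mae_omega_deg_s is not None:
            d["mae_omega_deg_s"] = self.mae_omega_deg_s
        return d


def _paired(pred, label, name="inputs"):
    p = np.asarray(pred)
    l = np.asarray(label)
    if p.size == 0:
        raise ValueError(f"{name}: empty input")
    if p.shape != l.shape:
        raise ValueError(f"{name}: length mismatch ({p.shape} vs {l.shape})")
    return p, l


def bin_accuracy(pred_bins: Sequence, label_bins: Sequence) -> float:
    """Percent of predicted bins that match their labels."""
    p, l = _paired(pred_bins, label_bins, "bin_accuracy")
    return 100.0 * float(np.mean(p == l))


def mae_angle(pred_deg: Sequence[float], label_deg: Sequence[float]) -> float:
    """Mean absolute error (deg) of continuous predictions vs discrete labels."""
    p, l = _paired(pred_deg, label_deg, "mae_angle")
    return float(np.mean(np.abs(p.astype(float) - l.astype(float))))


def mae_speed(pred_omega: Sequence[float], true_omega: Sequence[float]) -> float:
    """Mean absolute error of angular speed (deg/s)."""
    p, l = _paired(pred_omega, true_omega, "mae_speed")
    return float(np.mean(np.abs(p.astype(float) - l.astype(float))))


def confusion_matrix(pred_bins: Sequence, label_bins: Sequence) -> pd.DataFrame:
    """Label x prediction count table over the union of observed bins.

    Rows are true labels, columns predictions; row sums are per-label
    counts and the grand total is n.
    """
    p, l = _paired(pred_bins, label_bins, "confusion_matrix")
    bins = sorted(set(p.tolist()) | set(l.tolist()))
    table = pd.DataFrame(0, index=bins, columns=bins, dtype=int)
    for li, pi in zip(l.tolist(), p.tolist()):
        table.loc[li, pi] += 1
    table.index.name = "label"
    table.columns.name = "pred"
    return table


def weighted_precision(
    pred_bins: Sequence,
    label_bins: Sequence,
    zero_support: str = "zero",
) -> float:
    """Precision per bin, weighted by each bin's true-label count, in percent.

    precision(b) = TP(b) / (all predictions of b). Weights are the
    true-label counts normalised over bins that carry weight.

    ``zero_support`` controls bins with true labels but no predictions:
    ``"zero"`` (default) counts them as precision 0 with full weight;
    ``"drop"`` removes them (and renormalises the weights), the other
    convention seen in the wild.
    """
    if zero_support not in ("zero", "drop"):
        raise ValueError("zero_support must be 'zero' or 'drop'")
    cm = confusion_matrix(pred_bins, label_bins)
    support = cm.sum(axis=1)  # true-label counts
    predicted = cm.sum(axis=0)  # prediction counts
    tp = pd.Series(np.diag(cm), index=cm.index)
    total = 0.0
    weight_sum = 0.0
    for b in cm.index:
        if support[b] == 0:
            continue  # bin never occurs as a true label: no weight
        if predicted[b] == 0:
            if zero_support == "drop":
                continue
            prec = 0.0
        else:
            prec = tp[b] / predicted[b]
        total += support[b] * prec
        weight_sum += support[b]
    if weight_sum == 0:
        raise ValueError("no bin has true-label support")
    return 100.0 * total / weight_sum


def evaluate(
    pred_deg: Sequence[float],
    label_deg: Sequence[float],
    label_set=(45, 90, 135, 180, 225, 270, 315, 360),
    pred_omega: Sequence[float] | None = None,
    true_omega: Sequence[float] | None = None,
    group_key: str | None = None,
) -> EvalReport:
    """Full report: quantise predictions, then accuracy / MAE / WPrec.

    ``pred_deg`` are continuous estimated angles; ``label_deg`` discrete
    bin labels. Speed MAE is included when both omega series are given.
    """
    from .geometry import quantize_to_bin

    p, l = _paired(pred_deg, label_deg, "evaluate")
    pred_bins = [quantize_to_bin(abs(float(v)), label_set) for v in p]
    labels = [int(v) for v in l]
    report = EvalReport(
        accuracy_pct=bin_accuracy(pred_bins, labels),
        mae_deg=mae_angle(p, l),
        wprec_pct=weighted_precision(pred_bins, labels),
        n=len(labels),
        confusion=confusion_matrix(pred_bins, labels),
        group_key=group_key,
    )
    if pred_omega is not None and true_omega is not None:
        report.mae_omega_deg_s = mae_speed(pred_omega, true_omega)
    return report


def grouped_report(
    estimates: pd.DataFrame,
    annotations: Sequence[TurnAnnotation] | pd.DataFrame,
    group_by: str,
    label_set=(45, 90, 135, 180, 225, 270, 315, 360),
) -> list[EvalReport]:
    """Per-group evaluation joined on ``clip_id``, with Avg. and pooled rows.

    Parameters
    ----------
    estimates : DataFrame
        Columns ``clip_id``, ``theta_deg`` and optionally ``omega_deg_s``.
    annotations : list of TurnAnnotation or DataFrame
        Must cover every estimate's ``clip_id``.
    group_by : str
        One of ``scenario``, ``location``, ``group``, ``subject_id``,
        ``label_bin``.

    Returns
    -------
    One EvalReport per group value (sorted), then an ``Avg.`` report whose
    metrics are the unweighted means of the group metrics (the convention
    used when tables average across rows), then an ``overall`` report
    pooling all samples. Note the two differ whenever group sizes differ.
    """
    if isinstance(annotations, pd.DataFrame):
        ann = annotations.copy()
    else:
        ann = pd.DataFrame(
            [
                {
                    "clip_id": a.clip_id,
                    "label_deg": a.label_deg,
                    "subject_id": a.subject_id,
                    "group": a.group,
                    "scenario": a.scenario,
                    "location": a.location,
                }
                for a in annotations
            ]
        )
    allowed = ("scenario", "location", "group", "subject_id", "label_bin")
    if group_by not in allowed:
        raise ValueError(f"group_by must be one of {allowed}")
    merged = estimates.merge(ann, on="clip_id", how="left", validate="one_to_one")
    unmatched = merged.loc[merged["label_deg"].isna(), "clip_id"].tolist()
    if unmatched:
        raise ValueError(f"clip_id(s) with no annotation: {unmatched}")
    if group_by == "label_bin":
        merged["label_bin"] = merged["label_deg"].astype(int)

    reports: list[EvalReport] = []
    for key, sub in merged.groupby(group_by, sort=True):
        reports.append(
            evaluate(
                sub["theta_deg"].to_numpy(),
                sub["label_deg"].to_numpy(),
                label_set=label_set,
                pred_omega=sub["omega_deg_s"].to_numpy()
                if "omega_deg_s" in sub and "true_omega_deg_s" in sub
                else None,
                true_omega=sub["true_omega_deg_s"].to_numpy()
                if "true_omega_deg_s" in sub
                else None,
                group_key=str(key),
            )
        )
    avg = EvalReport(
        accuracy_pct=float(np.mean([r.accuracy_pct for r in reports])),
        mae_deg=float(np.mean([r.mae_deg for r in reports])),
        wprec_pct=float(np.mean([r.wprec_pct for r in reports])),
        n=int(sum(r.n for r in reports)),
        group_key="Avg.",
    )
    pooled = evaluate(
        merged["theta_deg"].to_numpy(),
        merged["label_deg"].to_numpy(),
        label_set=label_set,
        group_key="overall",
    )
    return reports + [avg, pooled]


def cohen_kappa(rater_a: Sequence, rater_b: Sequence) -> float:
    """Cohen's kappa: (p_o - p_e) / (1 - p_e) with marginal-product p_e.

    When both raters use a single identical category p_e = 1 and the
    statistic is undefined; perfect observed agreement is then reported as
    1.0 by convention (and 0.0 if they use single, different categories).
    """
    a, b = _paired(rater_a, rater_b, "cohen_kappa")
    cats = sorted(set(a.tolist()) | set(b.tolist()))
    n = a.size
    p_o = float(np.mean(a == b))
    p_e = sum(
        (np.sum(a == c) / n) * (np.sum(b == c) / n) for c in cats
    )
    if np.isclose(p_e, 1.0):
        return 1.0 if np.isclose(p_o, 1.0) else 0.0
    return float((p_o - p_e) / (1.0 - p_e))
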