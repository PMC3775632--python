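"""Cohort modes: per-sample scoring, group ANOVA, box-plot summaries, ROC.

In 2-D mode every sample column is scored independently against each
signature (the 1-D comparison run once per column), yielding a
signatures-by-samples matrix of signed test statistics.  Those
per-sample statistics are then compared across sample groups with a
one-way ANOVA, summarized as box plots (median-colored at the +/-2
convention), and - when the groups are exactly "positive"/"negative" -
used as a classification score evaluated by ROC/AUC and by accuracy at
a fixed statistic cutoff (default 2, roughly p < 0.05 for a t score).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as skmetrics

from bdfunc.engine import (
    InsufficientOverlapError,
    score_bidirectional,
)
from bdfunc.signatures import BidirectionalSignature

logger = logging.getLogger(__name__)

__all__ = [
    "ScoreMatrix",
    "GroupComparison",
    "ClassifierResult",
    "score_samples",
    "group_anova",
    "anova_table",
    "summarize_boxplot",
    "classify",
    "classify_matrix",
]

#: box color rule: median statistic > +2 -> activation (red),
#: < -2 -> inhibition (green), otherwise neutral.
MEDIAN_COLOR_CUTOFF = 2.0

CLASSIFIER_LABELS = frozenset({"positive", "negative"})


@dataclass(frozen=True)
class ScoreMatrix:
    """Signatures x samples matrix of signed per-sample test statistics."""

    scores: pd.DataFrame                    # rows: signatures, cols: samples
    groups: pd.Series                       # sample -> group label (NaN = unlabelled)
    method: str
    flags: pd.DataFrame                     # same shape, ';'-joined per-cell flags
    skipped: tuple[tuple[str, str], ...] = ()

    def labelled(self) -> tuple[pd.DataFrame, pd.Series]:
        """Scores and groups restricted to samples with a group label."""
        keep = self.groups.notna()
        return self.scores.loc[:, keep[keep].index], self.groups[keep]


@dataclass(frozen=True)
class GroupComparison:
    """One-way ANOVA of one signature's per-sample statistics across groups."""

    signature: str
    group_means: dict[str, float]
    group_ns: dict[str, int]
    f_statistic: float
    anova_p: float


@dataclass(frozen=True)
class ClassifierResult:
    """ROC evaluation of per-sample scores against positive/negative labels."""

    signature: str
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    cutoff: float
    accuracy: float
    sensitivity: float
    specificity: float

    @property
    def roc_points(self) -> list[tuple[float, float]]:
        return list(zip(self.fpr.tolist(), self.tpr.tolist()))


def score_samples(
    table: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    sigs: Sequence[BidirectionalSignature],
    method: str = "t",
    min_per_side: int = 3,
    t_flavor: str = "welch",
) -> ScoreMatrix:
    """Run the 1-D comparison separately on every sample column.

    *table* is a gene-by-sample numeric frame indexed by gene symbol.
    Gene matching is resolved once per signature against the shared row
    index; each cell is then the chosen two-sample statistic on that
    column's matched activated vs inhibited values.  Signatures with
    insufficient overlap are omitted (and reported in ``skipped``).
    """
    if table.shape[1] < 1:
        raise ValueError("need at least one sample column")
    index = pd.Index([str(g).strip().upper() for g in table.index])
    mat = table.to_numpy(dtype=float)
    groups = pd.Series(groups, dtype=object).reindex(table.columns)

    rows: dict[str, np.ndarray] = {}
    flag_rows: dict[str, list[str]] = {}
    skipped: list[tuple[str, str]] = []
    pos_of = pd.Series(np.arange(len(index)), index=index)
    pos_of = pos_of[~pos_of.index.duplicated(keep="first")]
    for sig in sigs:
        act_idx = pos_of.reindex(sig.activated).dropna().to_numpy(dtype=int)
        inh_idx = pos_of.reindex(sig.inhibited).dropna().to_numpy(dtype=int)
        if len(act_idx) < min_per_side or len(inh_idx) < min_per_side:
            exc = InsufficientOverlapError(sig.name, len(act_idx), len(inh_idx), min_per_side)
            skipped.append((sig.name, str(exc)))
            logger.warning("%s", exc)
            continue
        stats_row = np.empty(mat.shape[1])
        flags_row = []
        for j in range(mat.shape[1]):
            act = mat[act_idx, j]
            inh = mat[inh_idx, j]
            keep_a, keep_i = np.isfinite(act), np.isfinite(inh)
            score = score_bidirectional(
                act[keep_a], inh[keep_i], method=method, t_flavor=t_flavor,
                signature=sig.name,
            )
            stats_row[j] = score.statistic
            flags_row.append(";".join(score.flags))
        rows[sig.name] = stats_row
        flag_rows[sig.name] = flags_row
    if not rows:
        raise InsufficientOverlapError("<all>", 0, 0, min_per_side)
    scores = pd.DataFrame(rows, index=table.columns).T
    flags = pd.DataFrame(flag_rows, index=table.columns).T
    return ScoreMatrix(
        scores=scores, groups=groups, method=method, flags=flags,
        skipped=tuple(skipped),
    )


def group_anova(
    scores: pd.Series | Sequence[float],
    groups: Sequence[str] | pd.Series,
    signature: str = "",
) -> GroupComparison:
    """One-way fixed-effects ANOVA of per-sample statistics across groups.

    Requires >= 2 distinct groups, each with >= 2 samples.  With exactly
    two groups this is equivalent to a pooled two-sample t-test
    (F = t^2), but it is reported as an ANOVA either way.
    """
    s = np.asarray(scores, dtype=float)
    g = np.asarray(pd.Series(groups, dtype=object))
    keep = pd.notna(g) & np.isfinite(s)
    s, g = s[keep], g[keep]
    labels, inverse = np.unique(g, return_inverse=True)
    if len(labels) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    per_group = [s[inverse == k] for k in range(len(labels))]
    small = [str(labels[k]) for k, vals in enumerate(per_group) if len(vals) < 2]
    if small:
        raise ValueError(f"ANOVA needs >= 2 samples per group; too few in: {small}")
    f, p = stats.f_oneway(*per_group)
    # identical group means with zero within-group variance -> F = 0/0
    if not np.isfinite(f):
        f, p = (0.0, 1.0) if np.allclose([v.mean() for v in per_group],
                                         per_group[0].mean()) else (f, p)
    return GroupComparison(
        signature=signature,
        group_means={str(lab): float(vals.mean()) for lab, vals in zip(labels, per_group)},
        group_ns={str(lab): int(len(vals)) for lab, vals in zip(labels, per_group)},
        f_statistic=float(f),
        anova_p=float(p),
    )


def anova_table(m: ScoreMatrix) -> pd.DataFrame:
    """Group comparison for every signature row of a score matrix."""
    scores, groups = m.labelled()
    recs = []
    for sig_name, row in scores.iterrows():
        cmp = group_anova(row, groups, signature=str(sig_name))
        rec = {"signature": sig_name, "f_statistic": cmp.f_statistic,
               "anova_p": cmp.anova_p}
        for lab in sorted(cmp.group_means):
            rec[f"mean[{lab}]"] = cmp.group_means[lab]
            rec[f"n[{lab}]"] = cmp.group_ns[lab]
        recs.append(rec)
    return pd.DataFrame(recs)


def summarize_boxplot(m: ScoreMatrix) -> pd.DataFrame:
    """Five-number summary + color per (signature, group).

    Quartiles use linear interpolation (type 7).  Color encodes the
    median-statistic rule: red above +2 (activation), green below -2
    (inhibition), grey otherwise.
    """
    scores, groups = m.labelled()
    if scores.size == 0:
        raise ValueError("empty score matrix")
    recs = []
    for sig_name, row in scores.iterrows():
        for lab in pd.unique(groups.dropna()):
            vals = row[groups[groups == lab].index].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            if len(vals) == 0:
                continue
            q0, q1, q2, q3, q4 = np.percentile(vals, [0, 25, 50, 75, 100])
            color = ("red" if q2 > MEDIAN_COLOR_CUTOFF
                     else "green" if q2 < -MEDIAN_COLOR_CUTOFF else "grey")
            recs.append({
                "signature": sig_name, "group": lab, "n": len(vals),
                "min": q0, "q1": q1, "median": q2, "q3": q3, "max": q4,
                "color": color,
            })
    return pd.DataFrame(recs)


def classify(
    scores: pd.Series | Sequence[float],
    labels: Sequence[str] | pd.Series,
    cutoff: float = 2.0,
    invert: bool = False,
    signature: str = "",
) -> ClassifierResult:
    """Evaluate per-sample statistics as a binary classifier.

    Labels must be "positive"/"negative" (case-insensitive).  The ROC
    sweeps all score thresholds with higher score predicting positive
    (set ``invert=True`` for inhibition-oriented signatures); AUC is the
    trapezoid area, equal to the tie-adjusted Mann-Whitney probability
    that a random positive outscores a random negative.  Accuracy,
    sensitivity and specificity are reported at the fixed rule
    ``score > cutoff  =>  predicted positive`` (strict).
    """
    s = np.asarray(scores, dtype=float)
    lab = pd.Series(labels, dtype=object).astype(str).str.strip().str.lower()
    keep = lab.isin(CLASSIFIER_LABELS).to_numpy() & np.isfinite(s)
    s, lab = s[keep], lab[keep]
    y = (lab == "positive").to_numpy()
    if y.all() or not y.any():
        raise ValueError("classifier needs at least one positive and one negative sample")
    if invert:
        s = -s
    fpr, tpr, thresholds = skmetrics.roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    pred = s > cutoff
    tp = int((pred & y).sum())
    tn = int((~pred & ~y).sum())
    return ClassifierResult(
        signature=signature,
        fpr=fpr, tpr=tpr, thresholds=thresholds,
        auc=auc,
        cutoff=float(cutoff),
        accuracy=(tp + tn) / len(y),
        sensitivity=tp / int(y.sum()),
        specificity=tn / int((~y).sum()),
    )


def classify_matrix(m: ScoreMatrix, cutoff: float = 2.0, invert: bool = False) -> list[ClassifierResult]:
    """Run :func:`classify` for every signature row of a score matrix."""
    scores, groups = m.labelled()
    return [
        classify(row, groups, cutoff=cutoff, invert=invert, signature=str(sig))
        for sig, row in scores.iterrows()
    ]
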