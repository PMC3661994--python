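"""Agreement metrics between automatic and reference component labels.

The positive class is ARTIFACT — the filter's detection target — so
sensitivity is the fraction of reference artifacts the filter also flags
and specificity the fraction of reference RSN candidates it spares.
Subject-wise:

    sens_n = TP_n / (TP_n + FN_n)
    spec_n = TN_n / (FP_n + TN_n)
    acc_n  = (TP_n + TN_n) / N_n^src

and across subjects the *global* accuracy pools the counts,

    acc_glob = (sum TP_n + sum TN_n) / sum N_n^src,

which up-weights subjects with many components; the mean of the per-subject
accuracies <acc_n> does not, which is why threshold training maximizes the
mean rather than the pooled version.

Metrics with a zero denominator are undefined and reported as NaN; they are
excluded pairwise from means and rank tests (the exclusion count is logged,
never silently zeroed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from .io import ARTIFACT, LabelSet

logger = logging.getLogger(__name__)


@dataclass
class ConfusionCounts:
    """TP/FN/FP/TN with ARTIFACT as the positive class."""

    TP: int
    FN: int
    FP: int
    TN: int

    @property
    def n(self) -> int:
        return self.TP + self.FN + self.FP + self.TN


@dataclass
class SubjectMetrics:
    subject_id: str
    sens: float
    spec: float
    acc: float


def confusion_counts(auto: LabelSet, ref: LabelSet) -> ConfusionCounts:
    """Tally agreement between automatic and reference labels."""
    if len(auto) != len(ref):
        raise InputError(
            f"label length mismatch: auto={len(auto)} ref={len(ref)}"
        )
    a = auto.is_artifact
    r = ref.is_artifact
    return ConfusionCounts(
        TP=int(np.sum(a & r)),
        FN=int(np.sum(~a & r)),
        FP=int(np.sum(a & ~r)),
        TN=int(np.sum(~a & ~r)),
    )


def subject_metrics(c: ConfusionCounts, subject_id: str = "") -> SubjectMetrics:
    """Sensitivity, specificity and accuracy for one subject.

    Undefined ratios (zero denominator) come back as NaN, never as 0.
    """
    sens = c.TP / (c.TP + c.FN) if (c.TP + c.FN) > 0 else float("nan")
    spec = c.TN / (c.FP + c.TN) if (c.FP + c.TN) > 0 else float("nan")
    if c.n == 0:
        raise InputError("empty confusion counts")
    acc = (c.TP + c.TN) / c.n
    return SubjectMetrics(subject_id=subject_id, sens=sens, spec=spec, acc=acc)


def global_accuracy(counts: list[ConfusionCounts]) -> float:
    """Pooled accuracy over subjects: (sum TP + sum TN) / sum N_src.

    This is *not* the mean of per-subject accuracies; the two agree only
    when all subjects contribute the same number of components.
    """
    if not counts:
        raise InputError("need at least one subject")
    num = sum(c.TP + c.TN for c in counts)
    den = sum(c.n for c in counts)
    if den == 0:
        raise InputError("no components in any subject")
    return num / den


def rank_sum_compare(a, b) -> float:
    """Two-sided Mann-Whitney-Wilcoxon rank-sum p-value between two samples.

    NaNs are dropped.  The exact null distribution is used when the smaller
    sample has at most 8 values and there are no ties; otherwise the normal
    approximation with midranks and tie correction is used.  Two samples
    whose pooled values are all identical give p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) == 0 or len(b) == 0:
        raise InputError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(a), len(b)) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def evaluate_subjects(pairs: list[tuple[LabelSet, LabelSet]]) -> pd.DataFrame:
    """Per-subject confusion counts and metrics for (auto, ref) label pairs."""
    rows = []
    n_na = 0
    for auto, ref in pairs:
        c = confusion_counts(auto, ref)
        m = subject_metrics(c, subject_id=ref.subject_id)
        n_na += int(np.isnan(m.sens)) + int(np.isnan(m.spec))
        rows.append(
            dict(subject=ref.subject_id, N_src=c.n, TP=c.TP, FN=c.FN, FP=c.FP,
                 TN=c.TN, sens=m.sens, spec=m.spec, acc=m.acc)
        )
    if n_na:
        logger.info("%d undefined (NaN) metric values excluded from summaries", n_na)
    return pd.DataFrame(rows)
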