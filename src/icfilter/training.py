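"""Threshold training by exhaustive scan of the (p_moco, p_pow) grid.

Both thresholds are scanned on a logarithmic grid over
10^-50 <= p_moco_crit, p_pow_crit <= 10^-1.  Component p-values are computed
once per cohort; each grid point only re-applies the cheap threshold
comparisons.  The objective is the mean over subjects of the subject-wise
accuracy <acc_n> against the reference labels — deliberately not the pooled
global accuracy, which would over-weight subjects with many components.

Tie-breaking among equal maxima is deterministic: the grid is scanned with
the most stringent thresholds first (descending |log10 p|, p_moco outer,
p_pow inner) and the first maximum encountered is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .criteria import BandConfig, FilterThresholds, compute_component_scores
from .errors import InputError
from .io import ICTimecourseSet, LabelSet, MotionParams

@dataclass
class GridSpec:
    """Log10 grid for both threshold axes (defaults: -50 .. -1, step 0.5)."""

    log10_min: float = -50.0
    log10_max: float = -1.0
    step: float = 0.5

    def __post_init__(self) -> None:
        if not self.log10_min < self.log10_max:
            raise InputError("log10_min must be below log10_max")
        if not self.step > 0:
            raise InputError("step must be positive")
        if len(self.log10_values()) < 4:
            raise InputError("grid needs at least 4 points per axis")

    def log10_values(self) -> np.ndarray:
        """Ascending log10 threshold values (e.g. -50.0, -49.5, ..., -1.0)."""
        n = int(np.floor((self.log10_max - self.log10_min) / self.step + 1e-9)) + 1
        return self.log10_min + self.step * np.arange(n)

    def values(self) -> np.ndarray:
        return 10.0 ** self.log10_values()


@dataclass
class AccuracySurface:
    """Mean subject-wise accuracy over the threshold grid, with its argmax."""

    p_moco_values: np.ndarray  # ascending
    p_pow_values: np.ndarray  # ascending
    mean_acc: np.ndarray  # shape (len(p_moco_values), len(p_pow_values))
    best: FilterThresholds = None  # type: ignore[assignment]
    best_mean_acc: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (log10_p_moco, log10_p_pow, mean_acc)."""
        lm = np.log10(self.p_moco_values)
        lp = np.log10(self.p_pow_values)
        mm, pp = np.meshgrid(lm, lp, indexing="ij")
        return pd.DataFrame(
            dict(log10_p_moco=mm.ravel(), log10_p_pow=pp.ravel(),
                 mean_acc=self.mean_acc.ravel())
        )


@dataclass
class _ScoredSubject:
    """Cached per-component p-values and truth for fast re-thresholding."""

    subject_id: str
    p_moco: np.ndarray
    p_pow: np.ndarray
    forced_artifact: np.ndarray  # degenerate components: artifact at any threshold
    truth_artifact: np.ndarray


def _score_cohort(cohort, band: BandConfig, estimator: str) -> list[_ScoredSubject]:
    scored = []
    for tcs, motion, labels in cohort:
        if len(labels) != tcs.n_components:
            raise InputError(
                f"subject {tcs.subject_id}: {len(labels)} labels for "
                f"{tcs.n_components} components"
            )
        try:
            df = compute_component_scores(tcs, motion, band, estimator=estimator)
        except Exception as exc:
            raise InputError(f"subject {tcs.subject_id} could not be scored: {exc}") from exc
        zero_var = df["zero_variance"].to_numpy(dtype=bool)
        scored.append(
            _ScoredSubject(
                subject_id=tcs.subject_id,
                p_moco=np.where(zero_var, np.inf, df["p_moco"].to_numpy()),
                p_pow=df["p_pow"].to_numpy(),
                forced_artifact=zero_var | df["band_power_zero"].to_numpy(dtype=bool),
                truth_artifact=labels.is_artifact,
            )
        )
    return scored


def optimize_from_scores(
    scored: list[_ScoredSubject], grid: GridSpec
) -> AccuracySurface:
    """Scan the threshold grid over pre-computed component p-values."""
    if not scored:
        raise InputError("cohort is empty")
    moco_vals = grid.values()
    pow_vals = grid.values()
    nA, nB = len(moco_vals), len(pow_vals)
    surface = np.zeros((nA, nB))
    for s in scored:
        hits_m = s.p_moco[:, None] < moco_vals[None, :]  # (L, nA)
        hits_p = s.p_pow[:, None] < pow_vals[None, :]  # (L, nB)
        pred = hits_m[:, :, None] | hits_p[:, None, :] | s.forced_artifact[:, None, None]
        correct = pred == s.truth_artifact[:, None, None]
        surface += correct.mean(axis=0)
    surface /= len(scored)

    # deterministic argmax: most stringent thresholds scanned first
    best_i = best_j = 0
    best_val = -np.inf
    for i in range(nA):  # moco_vals ascending = descending |log10|
        for j in range(nB):
            if surface[i, j] > best_val + 1e-15:
                best_val = surface[i, j]
                best_i, best_j = i, j
    return AccuracySurface(
        p_moco_values=moco_vals,
        p_pow_values=pow_vals,
        mean_acc=surface,
        best=FilterThresholds(
            p_moco_crit=float(moco_vals[best_i]), p_pow_crit=float(pow_vals[best_j])
        ),
        best_mean_acc=float(best_val),
    )


def grid_search_thresholds(
    cohort: list[tuple[ICTimecourseSet, MotionParams, LabelSet]],
    band: BandConfig | None = None,
    grid: GridSpec | None = None,
    estimator: str = "periodogram",
) -> AccuracySurface:
    """Train the filter thresholds on a labelled cohort.

    Scores every component once (criteria I and II), then exhaustively
    evaluates the mean subject-wise accuracy at every grid point and returns
    the full surface together with the maximizing threshold pair.
    """
    band = band or BandConfig()
    grid = grid or GridSpec()
    return optimize_from_scores(_score_cohort(cohort, band, estimator), grid)
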