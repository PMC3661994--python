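"""Readers and writers for the plain-text formats used throughout.

The on-disk dialects are deliberately minimal:

* **mixing matrix** ("melodic_mix" style): whitespace-delimited numeric text,
  one time point per row, one independent component (IC) per column.  The
  columns are the IC time courses, i.e. the columns of the mixing matrix A
  in the linear model x = A s.
* **motion parameters** (".par" style): six whitespace-delimited numeric
  columns per row — three rotations (radians) followed by three translations
  (millimetres), the standard output of rigid-body realignment.
* **label table**: TSV of (component_index, label) with 1-based component
  indices and labels in {ARTIFACT, RSN_CANDIDATE} (case-insensitive).
* **score table**: TSV with a fixed header, one row per scored component.

Component indices are 1-based in every user-facing file and report;
internal arrays use file order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, InputError

ARTIFACT = "ARTIFACT"
RSN_CANDIDATE = "RSN_CANDIDATE"
LABELS = (ARTIFACT, RSN_CANDIDATE)

#: minimum number of time points for any scorable time course
MIN_TIMEPOINTS = 8

SCORE_COLUMNS = [
    "subject",
    "component",
    "r_moco",
    "p_moco",
    "ks_D",
    "p_pow",
    "label",
    "reason",
]


@dataclass
class ICTimecourseSet:
    """Per-subject IC time courses: T time points x L components, plus TR."""

    subject_id: str
    timecourses: np.ndarray  # shape (T, L)
    tr_seconds: float

    def __post_init__(self) -> None:
        self.timecourses = np.atleast_2d(np.asarray(self.timecourses, dtype=float))
        if self.timecourses.shape[0] < MIN_TIMEPOINTS:
            raise InputError(
                f"need at least {MIN_TIMEPOINTS} time points, "
                f"got {self.timecourses.shape[0]}"
            )
        if not np.all(np.isfinite(self.timecourses)):
            raise InputError("time courses contain non-finite values")
        if not self.tr_seconds > 0:
            raise InputError(f"tr_seconds must be positive, got {self.tr_seconds}")

    @property
    def n_timepoints(self) -> int:
        return self.timecourses.shape[0]

    @property
    def n_components(self) -> int:
        return self.timecourses.shape[1]


@dataclass
class MotionParams:
    """Six rigid-body realignment traces: T rows x 6 columns."""

    subject_id: str
    values: np.ndarray  # shape (T, 6)
    column_roles: tuple = ("rot_x", "rot_y", "rot_z", "trans_x", "trans_y", "trans_z")
    units: tuple = ("rad", "rad", "rad", "mm", "mm", "mm")

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != 6:
            raise FormatError(
                f"motion parameters must have 6 columns, got {self.values.shape[1]}"
            )
        if not np.all(np.isfinite(self.values)):
            raise InputError("motion parameters contain non-finite values")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]


@dataclass
class LabelSet:
    """Per-component reference or automatic labels for one subject."""

    subject_id: str
    labels: np.ndarray  # shape (L,), entries in LABELS

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        bad = [x for x in self.labels if x not in LABELS]
        if bad:
            raise InputError(f"unknown labels: {sorted(set(map(str, bad)))}")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def is_artifact(self) -> np.ndarray:
        return np.asarray([x == ARTIFACT for x in self.labels], dtype=bool)


def _parse_matrix(path) -> np.ndarray:
    """Parse whitespace-delimited numeric text; blank lines are ignored."""
    rows = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if width is None:
                width = len(tokens)
            elif len(tokens) != width:
                raise FormatError(
                    f"{path}: row {lineno} has {len(tokens)} columns, expected {width}"
                )
            try:
                values = [float(t) for t in tokens]
            except ValueError as exc:
                raise FormatError(f"{path}: row {lineno}: non-numeric token") from exc
            if any(math.isnan(v) or math.isinf(v) for v in values):
                raise FormatError(f"{path}: row {lineno}: non-finite value")
            rows.append(values)
    if not rows:
        raise FormatError(f"{path}: file contains no data rows")
    return np.asarray(rows, dtype=float)


def read_timecourses(path, tr_seconds: float, subject_id: str | None = None) -> ICTimecourseSet:
    """Read a mixing-matrix text file into an :class:`ICTimecourseSet`.

    Rows are time points, columns are component time courses, exactly as
    stored on disk; no reordering or truncation is performed.
    """
    matrix = _parse_matrix(path)
    if matrix.shape[0] < MIN_TIMEPOINTS:
        raise InputError(
            f"{path}: need at least {MIN_TIMEPOINTS} time points, got {matrix.shape[0]}"
        )
    return ICTimecourseSet(
        subject_id=subject_id or str(path), timecourses=matrix, tr_seconds=tr_seconds
    )


def read_motion_params(path, subject_id: str | None = None, order: str = "rot-trans") -> MotionParams:
    """Read a 6-column motion-parameter file.

    ``order`` states which triplet comes first on disk: ``"rot-trans"``
    (rotations then translations, the realignment tool's native convention)
    or ``"trans-rot"``.  Columns are returned in rotations-first order either
    way, with unit metadata (rad, rad, rad, mm, mm, mm).
    """
    matrix = _parse_matrix(path)
    if matrix.shape[1] != 6:
        raise FormatError(
            f"{path}: motion file must have exactly 6 columns, got {matrix.shape[1]}"
        )
    if order == "trans-rot":
        matrix = matrix[:, [3, 4, 5, 0, 1, 2]]
    elif order != "rot-trans":
        raise ValueError(f"unknown motion column order: {order!r}")
    return MotionParams(subject_id=subject_id or str(path), values=matrix)


def write_matrix(matrix: np.ndarray, path) -> None:
    """Write a numeric matrix as whitespace-delimited text, full precision."""
    np.savetxt(path, np.atleast_2d(matrix), fmt="%.17g")


def write_motion_params(motion: MotionParams, path) -> None:
    write_matrix(motion.values, path)


def read_label_file(path, subject_id: str | None = None) -> LabelSet:
    """Read a (component_index, label) TSV into a dense, complete LabelSet.

    Indices are 1-based; every component 1..L (L = largest index present)
    must appear exactly once.
    """
    entries: dict[int, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if tokens[0].lower() in ("component", "component_index", "index"):
                continue  # optional header
            if len(tokens) != 2:
                raise FormatError(f"{path}: row {lineno}: expected 2 columns")
            try:
                idx = int(tokens[0])
            except ValueError as exc:
                raise FormatError(f"{path}: row {lineno}: bad component index") from exc
            if idx < 1:
                raise InputError(
                    f"{path}: row {lineno}: component indices are 1-based, got {idx}"
                )
            label = tokens[1].upper()
            if label not in LABELS:
                raise FormatError(f"{path}: row {lineno}: unknown label {tokens[1]!r}")
            if idx in entries:
                raise FormatError(f"{path}: duplicate entry for component {idx}")
            entries[idx] = label
    if not entries:
        raise FormatError(f"{path}: empty label file")
    n = max(entries)
    missing = sorted(set(range(1, n + 1)) - set(entries))
    if missing:
        raise InputError(f"{path}: labels missing for components {missing}")
    labels = np.asarray([entries[i] for i in range(1, n + 1)], dtype=object)
    return LabelSet(subject_id=subject_id or str(path), labels=labels)


def write_label_file(labels: LabelSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("component\tlabel\n")
        for i, lab in enumerate(labels.labels, start=1):
            fh.write(f"{i}\t{lab}\n")


def write_score_table(scores: pd.DataFrame, path) -> None:
    """Write a score table as TSV with the fixed header.

    p-values are written in scientific notation with 6 significant digits
    (so an exact zero appears as ``0.000000e+00``).
    """
    missing = [c for c in SCORE_COLUMNS if c not in scores.columns]
    if missing:
        raise InputError(f"score table is missing columns {missing}")
    out = scores[SCORE_COLUMNS].copy()
    for col in ("r_moco", "p_moco", "ks_D", "p_pow"):
        out[col] = out[col].map(lambda v: f"{v:.6e}")
    out["reason"] = out["reason"].fillna("").replace("", "-")
    out.to_csv(path, sep="\t", index=False)


def read_score_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=["nan"])
    missing = [c for c in SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: score table is missing columns {missing}")
    df["reason"] = df["reason"].replace("-", "")
    for col in ("r_moco", "p_moco", "ks_D", "p_pow"):
        df[col] = pd.to_numeric(df[col])
    df["component"] = df["component"].astype(int)
    return df
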