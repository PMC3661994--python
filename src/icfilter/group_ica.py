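"""Group-level analysis by temporal concatenation of component maps.

Single-subject component spatial maps are stacked along the component axis
("time" for the second-level decomposition), optionally keeping only the
components the filter labelled RSN candidates, and a secondary ICA is run
on the joint matrix.  The point of the stage is the *effect of filtering*:
with artifact maps left in, group sources are contaminated; after filtering,
the planted network templates are recovered cleanly.

The second-level engine is a standard FastICA (tanh contrast, symmetric
decorrelation) on PCA-whitened data.  The model order can be fixed, taken
from a broken-stick eigenvalue rule, or from the Laplace approximation to
the Bayesian evidence of a probabilistic-PCA model (Minka's formula); the
Laplace estimate is known to misbehave on large noisy concatenations, so
the order is pluggable rather than trusted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.special import gammaln
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .errors import InputError
from .io import LabelSet
from .synthetic import SpatialMapSet

logger = logging.getLogger(__name__)


@dataclass
class GroupICAResult:
    group_maps: np.ndarray  # (q, V), unit-variance rows
    mixing: np.ndarray  # (N2, q)
    model_order: int
    n_iter: int
    converged: bool


def concatenate_maps(
    sets: list[SpatialMapSet],
    filter_labels: list[LabelSet] | None = None,
    zscore_rows: bool = True,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Row-stack subject component maps, optionally keeping RSN candidates only.

    Returns the stacked matrix (N2 x V with N2 the total retained component
    count) and a provenance table mapping each row to (subject, component).
    Rows can be z-scored (mean 0, sd 1 over voxels) before stacking.
    """
    if not sets:
        raise InputError("no map sets given")
    V = sets[0].n_voxels
    if any(s.n_voxels != V for s in sets):
        raise InputError("voxel counts differ between subjects")
    if filter_labels is not None and len(filter_labels) != len(sets):
        raise InputError("one label set per subject required")
    blocks, prov = [], []
    for i, s in enumerate(sets):
        keep = np.ones(s.n_components, dtype=bool)
        if filter_labels is not None:
            lab = filter_labels[i]
            if len(lab) != s.n_components:
                raise InputError(
                    f"subject {s.subject_id}: {len(lab)} labels for "
                    f"{s.n_components} maps"
                )
            keep = ~lab.is_artifact
            if not keep.any():
                warnings.warn(
                    f"subject {s.subject_id}: all components filtered out",
                    stacklevel=2,
                )
        for j in np.flatnonzero(keep):
            row = s.maps[j]
            if zscore_rows:
                sd = row.std()
                if sd > 0:
                    row = (row - row.mean()) / sd
            blocks.append(row)
            prov.append(dict(subject=s.subject_id, component=int(j) + 1))
    if not blocks:
        raise InputError("no components remain after filtering")
    return np.vstack(blocks), pd.DataFrame(prov)


def _eigenvalues(data: np.ndarray) -> tuple[np.ndarray, int, int]:
    """Descending covariance eigenvalues; d = rows (variables), N = cols."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    d, N = data.shape
    centered = data - data.mean(axis=1, keepdims=True)
    cov = centered @ centered.T / N
    evals = np.linalg.eigvalsh(cov)[::-1]
    return np.clip(evals, 0.0, None), d, N


def _laplace_log_evidence(evals: np.ndarray, d: int, N: int, k: int) -> float:
    """Minka's Laplace approximation to the log evidence of a k-source model."""
    lam = evals.copy()
    floor = max(lam[0], 1.0) * 1e-12
    lam = np.clip(lam, floor, None)
    v = float(np.mean(lam[k:]))
    m = d * k - k * (k + 1) / 2.0
    i = np.arange(1, k + 1)
    log_pU = float(np.sum(gammaln((d - i + 1) / 2.0)
                          - ((d - i + 1) / 2.0) * np.log(np.pi))) - k * np.log(2.0)
    log_det_Az = 0.0
    lam_hat = np.concatenate([lam[:k], np.full(d - k, v)])
    for a in range(k):
        diff_inv = 1.0 / lam_hat[a + 1 :] - 1.0 / lam_hat[a]
        diff = lam[a] - lam[a + 1 :]
        log_det_Az += float(np.sum(np.log(np.clip(diff_inv, floor, None))
                                   + np.log(np.clip(diff, floor, None))
                                   + np.log(N)))
    return (log_pU
            - (N / 2.0) * float(np.sum(np.log(lam[:k])))
            - (N * (d - k) / 2.0) * np.log(v)
            + ((m + k) / 2.0) * np.log(2.0 * np.pi)
            - 0.5 * log_det_Az
            - (k / 2.0) * np.log(N))


def estimate_model_order(
    data: np.ndarray, method: str = "laplace", q: int | None = None
) -> int:
    """Estimate the number of group sources in a rows-by-voxels matrix.

    ``fixed`` returns ``q`` unchanged; ``broken_stick`` counts eigenvalues
    whose variance share exceeds the broken-stick expectation; ``laplace``
    maximizes Minka's Laplace evidence over candidate orders up to the
    numerical rank.
    """
    if method == "fixed":
        if q is None or q < 1:
            raise InputError("method='fixed' requires a positive q")
        return int(q)
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape[0] < 4:
        raise InputError("need at least 4 rows")
    evals, d, N = _eigenvalues(data)
    rank = int(np.sum(evals > evals[0] * 1e-10))
    if rank < 2:
        raise InputError("degenerate covariance (rank < 2)")
    if method == "broken_stick":
        share = evals / evals.sum()
        expectation = np.array(
            [np.sum(1.0 / np.arange(j + 1, d + 1)) / d for j in range(d)]
        )
        order = 0
        for j in range(d):
            if share[j] > expectation[j]:
                order += 1
            else:
                break
        return max(order, 1)
    if method == "laplace":
        kmax = min(rank, d - 1, N - 1)
        ks = np.arange(1, kmax + 1)
        evidence = [_laplace_log_evidence(evals, d, N, int(k)) for k in ks]
        return int(ks[int(np.argmax(evidence))])
    raise ValueError(f"unknown model-order method {method!r}")


def _whiten(data: np.ndarray, q: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA-whiten the concatenated map matrix down to q dimensions.

    Treats voxels as samples of an N2-dimensional variable.  Returns
    (Z, K, mean) with Z of shape (V, q), unit sample covariance, and K the
    (q, N2) whitening matrix such that Z = (X - mean).T @ K.T.
    """
    X = np.atleast_2d(np.asarray(data, dtype=float))
    N2, V = X.shape
    if q > min(N2, V):
        raise InputError(f"q={q} exceeds data rank bound {min(N2, V)}")
    mean = X.mean(axis=1, keepdims=True)
    Xc = X - mean
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    if s[q - 1] <= s[0] * 1e-12:
        raise InputError(f"data rank below requested order q={q}")
    K = (U[:, :q] / s[:q]).T * np.sqrt(V - 1)
    Z = Xc.T @ K.T
    return Z, K, mean


def _negentropy(sources: np.ndarray) -> float:
    """Sum of log-cosh negentropy approximations over unit-variance sources."""
    g_gauss = 0.3745672075  # E[log cosh(nu)] for standard normal nu
    z = sources / sources.std(axis=0, keepdims=True)
    return float(np.sum((np.mean(np.log(np.cosh(z)), axis=0) - g_gauss) ** 2))


def secondary_ica(
    data: np.ndarray,
    q: int,
    seed: int,
    tol: float = 1e-6,
    max_iter: int = 500,
    n_restarts: int = 5,
) -> GroupICAResult:
    """Secondary ICA on the concatenated map matrix (N2 x V).

    Mean-centers, PCA-whitens to ``q`` dimensions, then runs FastICA with
    tanh (log-cosh) contrast and symmetric decorrelation.  The fixed-point
    iteration can converge to local optima, so ``n_restarts`` runs with
    different derived seeds are performed and the solution with the largest
    negentropy objective is kept.  Group maps are returned with unit
    variance over voxels; ``mixing`` maps each original concatenated row
    onto the q group sources.  Deterministic under seed.
    """
    Z, K, _ = _whiten(data, q)
    best = None
    for restart in range(max(1, n_restarts)):
        ica = FastICA(
            whiten=False,  # data already whitened to q dimensions above
            fun="logcosh",
            algorithm="parallel",
            tol=tol,
            max_iter=max_iter,
            random_state=(int(seed) + 7919 * restart) % (2**31),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            s = ica.fit_transform(Z)  # (V, q)
        score = _negentropy(s)
        if best is None or score > best[0]:
            best = (score, s, ica.n_iter_)
    _, sources, n_iter = best
    converged = n_iter < max_iter
    if not converged:
        logger.warning("FastICA did not converge within %d iterations", max_iter)
    maps = np.asarray(sources).T  # (q, V)
    sds = maps.std(axis=1, keepdims=True)
    sds[sds == 0] = 1.0
    maps = maps / sds
    # mixing: least-squares projection of the original rows onto the maps
    X = np.atleast_2d(np.asarray(data, dtype=float))
    Xc = X - X.mean(axis=1, keepdims=True)
    mixing = Xc @ np.linalg.pinv(maps)
    return GroupICAResult(
        group_maps=maps,
        mixing=mixing,
        model_order=q,
        n_iter=int(n_iter),
        converged=bool(converged),
    )


def match_maps(maps: np.ndarray, templates: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Best one-to-one assignment of recovered maps to templates.

    Maximizes the summed |Pearson correlation| (Hungarian algorithm); the
    absolute value absorbs the sign ambiguity of ICA.  Returns (map index
    per template, |r| per template).
    """
    maps = np.atleast_2d(maps)
    templates = np.atleast_2d(templates)
    K = templates.shape[0]
    if maps.shape[0] < K:
        raise InputError("fewer maps than templates")
    corr = np.zeros((K, maps.shape[0]))
    for a in range(K):
        for b in range(maps.shape[0]):
            corr[a, b] = abs(float(np.corrcoef(templates[a], maps[b])[0, 1]))
    rows, cols = linear_sum_assignment(-corr)
    return cols, corr[rows, cols]
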