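"""Conditioning assessment: PCA, guided-PCA delta statistic, permutation
tests and univariate feature counts.

The delta statistic of guided PCA quantifies how much of a data set's
leading variance is explained by a known two-group split.  With X the
column-centered samples x features matrix and Y the samples x 2 group
indicator matrix (columns scaled to unit length), the guided direction
v_g is the first right singular vector of Y'X, and

    delta = var(X v_g) / var(X v_1),

with v_1 the first right singular vector of X itself.  Since v_1 maximises
the variance of X v over unit vectors, 0 < delta <= 1; values near 1 mean
the group split aligns with the dominant variance direction (a batch /
conditioning effect).  Significance comes from a permutation test: group
labels are permuted m times and the one-sided p-value is the fraction of
permuted delta values that exceed the observed one.

Here the two groups are a *conditioning set* (samples injected at position
n after a blank, pooled over cycles of one deconditioning type) and the
*reference set* (samples at position 8, the conditioned state).  Per
position the module also counts features whose peak area, RT or peak width
differ from the reference (Welch t-test, Benjamini-Hochberg FDR < alpha).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io import PeakTable

__all__ = [
    "DeltaResult",
    "pca_overview",
    "gpca_delta",
    "permutation_p",
    "welch_ttest",
    "bh_fdr",
    "conditioning_curve",
    "blank_pca",
]


# -- PCA -------------------------------------------------------------------

def pca_overview(X, n_components: int = 2, scale: bool = False):
    """PCA by SVD of the column-centered (optionally autoscaled) matrix.

    Returns (scores, loadings, variance_fractions).  Sign convention: the
    largest-magnitude loading of each component is positive.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be a 2-D matrix with >= 2 rows")
    Xc = X - X.mean(axis=0)
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        Xc = Xc / np.where(sd > 0, sd, 1.0)
    if not np.any(Xc):
        raise ValueError("constant matrix: PCA undefined")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    n_components = min(n_components, len(s))
    var = s**2 / (X.shape[0] - 1)
    frac = var / var.sum()
    scores = U[:, :n_components] * s[:n_components]
    loadings = Vt[:n_components].T
    for c in range(n_components):
        i = np.argmax(np.abs(loadings[:, c]))
        if loadings[i, c] < 0:
            loadings[:, c] *= -1
            scores[:, c] *= -1
    return scores, loadings, frac[:n_components]


# -- guided PCA ------------------------------------------------------------

def _indicator(groups) -> np.ndarray:
    g = np.asarray(groups)
    levels = np.unique(g)
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {len(levels)}")
    Y = np.column_stack([(g == lv).astype(float) for lv in levels])
    n = Y.sum(axis=0)
    if (n == 0).any():
        raise ValueError("empty group")
    return Y / np.sqrt(n)


def _first_right_singular(M: np.ndarray) -> np.ndarray:
    _, _, Vt = np.linalg.svd(M, full_matrices=False)
    return Vt[0]


def gpca_delta(X, groups) -> float:
    """Guided-PCA delta for a two-group split of the rows of X."""
    X = np.asarray(X, dtype=float)
    Y = _indicator(groups)
    Xc = X - X.mean(axis=0)
    if not np.any(Xc):
        raise ValueError("zero total variance")
    v1 = _first_right_singular(Xc)
    vg = _first_right_singular(Y.T @ Xc)
    var1 = np.var(Xc @ v1, ddof=1)
    varg = np.var(Xc @ vg, ddof=1)
    return float(varg / var1)


def permutation_p(X, groups, m: int = 1000, seed: int = 0):
    """One-sided permutation p-value for the observed delta.

    Labels are permuted uniformly m times; p = #{delta_hat < delta_p} / m
    (strict inequality, no add-one correction).  Set ``conservative`` via
    :func:`permutation_p_conservative` if a positively biased estimate is
    preferred.
    """
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    if m < 1:
        raise ValueError("m must be >= 1")
    delta = gpca_delta(X, groups)
    rng = np.random.default_rng(seed)
    perm = np.empty(m)
    for i in range(m):
        perm[i] = gpca_delta(X, rng.permutation(groups))
    p = float(np.sum(delta < perm) / m)
    return p, delta, perm


def permutation_p_conservative(X, groups, m: int = 1000, seed: int = 0):
    """(count + 1) / (m + 1) variant of :func:`permutation_p`."""
    p, delta, perm = permutation_p(X, groups, m=m, seed=seed)
    return (np.sum(delta < perm) + 1.0) / (m + 1.0), delta, perm


@dataclass
class DeltaResult:
    """Guided-PCA comparison of one conditioning set against the reference."""

    position_n: int
    delta: float
    p_value: float
    m: int
    seed: int
    delta_perm: np.ndarray = field(repr=False, default=None)


# -- univariate ------------------------------------------------------------

def welch_ttest(x, y):
    """Unequal-variance t-test with Welch-Satterthwaite df; two-sided p.

    Degenerate inputs with zero variance in both groups give t = 0, p = 1
    when the means are equal (identical constant groups are not evidence of
    a difference) and p = 0 otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 observations per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return 0.0, float(len(x) + len(y) - 2), 1.0
        return np.inf if x.mean() > y.mean() else -np.inf, float(
            len(x) + len(y) - 2
        ), 0.0
    res = sps.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def _welch_matrix(A, B):
    """Row-wise Welch t-test p-values for matrices A, B (features x reps)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        res = sps.ttest_ind(A, B, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float).copy()
    # rows with zero variance in both groups: scipy yields NaN
    degenerate = np.isnan(p)
    if degenerate.any():
        eq = np.isclose(A.mean(axis=1), B.mean(axis=1))
        p[degenerate & eq] = 1.0
        p[degenerate & ~eq] = 0.0
    return p


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# -- conditioning curves ---------------------------------------------------

def conditioning_curve(
    table: PeakTable,
    cycle_type: str,
    reference_position: int = 8,
    m: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, list[DeltaResult]]:
    """Delta, permutation p and significant-feature counts per position.

    For every conditioning position n (1 .. reference_position-1) the set
    of samples at position n over all cycles of ``cycle_type`` is compared
    with the position-``reference_position`` set: guided-PCA delta with a
    permutation test on the area matrix, plus per-feature Welch t-tests on
    area, RT and width, BH-adjusted within each metric, counting adjusted
    p < alpha.  Positions with fewer than two samples per set are skipped
    with a warning.  Reproducible given (m, seed): each position draws its
    permutations from a seed spawned from ``seed`` and n.
    """
    seq = table.sequence
    sel = (seq["cycle_type"] == cycle_type) & (seq["sample_class"] == "sample")
    pos = seq.loc[sel, "position_after_blank"]
    ref_cols = pos.index[pos == reference_position]
    if len(ref_cols) < 2:
        raise ValueError(
            f"fewer than 2 reference samples at position {reference_position} "
            f"in {cycle_type} cycles"
        )
    ref_X = table.area[ref_cols].to_numpy(dtype=float).T

    rows, results = [], []
    for n in range(1, reference_position):
        cols = pos.index[pos == n]
        if len(cols) < 2:
            warnings.warn(f"position {n}: fewer than 2 samples, skipped", stacklevel=2)
            continue
        X = np.vstack([table.area[cols].to_numpy(dtype=float).T, ref_X])
        groups = np.array([0] * len(cols) + [1] * len(ref_cols))
        sub_seed = int(
            np.random.SeedSequence([seed, n]).generate_state(1)[0] % (2**31)
        )
        p, delta, perm = permutation_p(X, groups, m=m, seed=sub_seed)
        results.append(DeltaResult(n, delta, p, m, sub_seed, perm))

        counts = {}
        for metric in ("area", "rt", "width"):
            A = getattr(table, metric)[cols].to_numpy(dtype=float)
            B = getattr(table, metric)[ref_cols].to_numpy(dtype=float)
            counts[f"n_sig_{metric}"] = int(
                (bh_fdr(_welch_matrix(A, B)) < alpha).sum()
            )
        rows.append(
            {"cycle_type": cycle_type, "position_n": n, "delta": delta,
             "p_value": p, **counts}
        )
    return pd.DataFrame(rows), results


# -- blank PCA -------------------------------------------------------------

def blank_pca(table: PeakTable, non_informative_ids, n_components: int = 2):
    """PCA of the blanks restricted to non-informative features.

    Returns (scores DataFrame annotated with within-group blank position,
    loadings DataFrame, variance fractions).  Carry-over features load on
    the blanks injected immediately after a sample run, so first-position
    blanks separate from later ones.
    """
    seq = table.sequence
    blank_cols = seq.index[seq["sample_class"] == "blank"]
    ids = pd.Index(non_informative_ids)
    if len(blank_cols) < 3:
        raise ValueError("need >= 3 blanks for a blank PCA")
    if len(ids) < 2:
        raise ValueError("need >= 2 non-informative features")
    X = table.area.loc[ids, blank_cols].to_numpy(dtype=float).T
    scores, loadings, frac = pca_overview(X, n_components=n_components)
    sc = pd.DataFrame(
        scores, index=blank_cols,
        columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
    )
    sc["blank_position"] = seq.loc[blank_cols, "position_after_blank"].astype(int)
    sc["cycle_type"] = seq.loc[blank_cols, "cycle_type"]
    ld = pd.DataFrame(
        loadings, index=ids, columns=[f"PC{i + 1}" for i in range(loadings.shape[1])]
    )
    return sc, ld, frac
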