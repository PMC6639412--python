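"""Test-retest reliability (ICC(3,1)) and matrix-level association (Mantel).

ICC(3,1) is the two-way mixed-effects, single-rater, consistency intraclass
correlation of a connection's strength across the two session days.  The
Mantel test measures how much variance in one symmetric matrix (e.g. the
heritability matrix) is explained by another (e.g. the ICC matrix), with
significance from joint row+column label permutations — entries of such
matrices are not independent, so an ordinary correlation test would be
anticonservative.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def icc_3_1(day1, day2) -> float:
    """ICC(3,1): (BMS - EMS) / (BMS + (k-1) EMS) with k = 2 raters.

    Consistency form: invariant to a constant offset between days.
    """
    x1 = np.asarray(day1, dtype=float)
    x2 = np.asarray(day2, dtype=float)
    if x1.shape != x2.shape or x1.ndim != 1 or x1.size < 3:
        raise ValueError("need two paired vectors of equal length >= 3")
    data = np.column_stack([x1, x2])
    n, k = data.shape
    grand = data.mean()
    subj_means = data.mean(axis=1)
    rater_means = data.mean(axis=0)
    ss_rows = k * np.sum((subj_means - grand) ** 2)
    ss_cols = n * np.sum((rater_means - grand) ** 2)
    ss_tot = np.sum((data - grand) ** 2)
    ss_err = ss_tot - ss_rows - ss_cols
    bms = ss_rows / (n - 1)
    ems = ss_err / ((n - 1) * (k - 1))
    if bms <= 0:
        raise ValueError("zero between-subject variance: ICC undefined")
    return float((bms - ems) / (bms + (k - 1) * ems))


def icc_matrix(day1: np.ndarray, day2: np.ndarray) -> np.ndarray:
    """Column-wise ICC(3,1) for (n_subjects, n_connections) day tables."""
    a = np.asarray(day1, dtype=float)
    b = np.asarray(day2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("day tables must have the same shape")
    return np.array([icc_3_1(a[:, j], b[:, j]) for j in range(a.shape[1])])


def _masked_offdiag(m: np.ndarray, mask: np.ndarray):
    iu = np.triu_indices(m.shape[0], k=1)
    keep = mask[iu]
    return iu[0][keep], iu[1][keep]


def mantel_test(
    m1: np.ndarray,
    m2: np.ndarray,
    n_perm: int = 5000,
    seed: int = 0,
    mask: np.ndarray | None = None,
    exact: bool = False,
):
    """Mantel test of association between two symmetric matrices.

    R^2 is the squared Pearson correlation of the off-diagonal entries
    (restricted to ``mask`` where given; the mask is a property of the
    analysis frame and is not permuted).  The null permutes the row and
    column labels of ``m2`` jointly; p = (1 + #{R2_null >= R2_obs}) /
    (n_perm + 1), or the exhaustive fraction over all n! permutations with
    ``exact`` (identity included).

    Returns (R2, p).
    """
    a = np.asarray(m1, dtype=float)
    b = np.asarray(m2, dtype=float)
    n = a.shape[0]
    if a.shape != (n, n) or b.shape != (n, n):
        raise ValueError("matrices must be square and of equal size")
    if n < 3:
        raise ValueError("need at least 3 areas")
    if mask is None:
        mask = np.isfinite(a) & np.isfinite(b)
    mask = np.asarray(mask, dtype=bool)
    rows, cols = _masked_offdiag(a, mask)
    if rows.size < 3:
        raise ValueError("fewer than 3 unmasked connections")
    v1 = a[rows, cols]

    def r2_against(perm):
        v2 = b[np.ix_(perm, perm)][rows, cols]
        r = np.corrcoef(v1, v2)[0, 1]
        return r * r

    identity = np.arange(n)
    obs = r2_against(identity)
    if exact:
        if n > 8:
            raise ValueError("exact enumeration is limited to 8 areas")
        total = math.factorial(n)
        exceed = sum(
            r2_against(np.asarray(p)) >= obs - 1e-12
            for p in itertools.permutations(range(n))
        )
        return float(obs), exceed / total
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if r2_against(perm) >= obs - 1e-12:
            exceed += 1
    return float(obs), (1.0 + exceed) / (n_perm + 1.0)
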