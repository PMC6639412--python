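"""Family-aware group-level significance and FDR screening of connections.

The group statistic per connection is the mean Fisher-z across subjects; its
null distribution is built by sign-flipping whole families jointly, which
preserves the within-family dependence of twin data while testing the
exchangeable "no connectivity" null.  Benjamini-Hochberg controls the FDR
across connections.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .simulate import _family_pairs


def block_permutation_test(
    z_by_subject: np.ndarray,
    cohort: pd.DataFrame,
    n_perm: int = 10000,
    seed: int = 0,
    exact: bool = False,
) -> np.ndarray:
    """Two-sided family-block sign-flip p-values per connection.

    ``z_by_subject`` is (n_subjects, n_connections).  Each permutation flips
    the sign of all members of a family jointly; the statistic is the mean
    across subjects.  p = (1 + #{|null| >= |obs|}) / (n_perm + 1).  With
    ``exact`` all 2^n_families flip patterns are enumerated and
    p = #{|null| >= |obs|} / 2^F (the identity pattern included).
    """
    z = np.atleast_2d(np.asarray(z_by_subject, dtype=float))
    if z.shape[0] != len(cohort):
        raise ValueError("one row per subject required")
    pairs, _ = _family_pairs(cohort)
    n, n_conn = z.shape
    fam_sums = z[pairs[:, 0]] + z[pairs[:, 1]]  # (n_fam, n_conn)
    obs = np.abs(z.mean(axis=0))
    n_fam = len(pairs)
    if exact:
        if n_fam > 20:
            raise ValueError("exact enumeration is limited to 20 families")
        signs = np.array(list(itertools.product((1.0, -1.0), repeat=n_fam)))
        null = np.abs(signs @ fam_sums) / n
        return (null >= obs[None, :] - 1e-12).sum(axis=0) / signs.shape[0]
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives very coarse p-values", stacklevel=2)
    rng = np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(n_perm, n_fam)) * 2.0 - 1.0
    null = np.abs(signs @ fam_sums) / n
    exceed = (null >= obs[None, :] - 1e-12).sum(axis=0)
    return (1.0 + exceed) / (n_perm + 1.0)


def bh_fdr(p_raw, q: float = 0.05) -> pd.DataFrame:
    """Benjamini-Hochberg step-up adjustment and keep mask at level ``q``."""
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    keep, p_fdr, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return pd.DataFrame({"p_raw": p, "p_fdr": p_fdr, "keep": keep})


def screen_connections(
    z_long: pd.DataFrame,
    cohort: pd.DataFrame,
    q: float = 0.05,
    n_perm: int = 10000,
    seed: int = 0,
    session: str = "all",
) -> pd.DataFrame:
    """Connection screen from a long-format connectivity table.

    Returns one row per connection: area_a, area_b, p_raw, p_fdr, keep.
    """
    wide = z_long[z_long["session"] == session].pivot_table(
        index="subject_id", columns=["area_a", "area_b"], values="z"
    )
    wide = wide.loc[cohort["subject_id"]]
    p_raw = block_permutation_test(wide.to_numpy(), cohort, n_perm=n_perm, seed=seed)
    out = bh_fdr(p_raw, q=q)
    out.insert(0, "area_b", [c[1] for c in wide.columns])
    out.insert(0, "area_a", [c[0] for c in wide.columns])
    return out
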