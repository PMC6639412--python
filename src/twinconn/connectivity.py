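"""ROI time series -> per-subject Fisher-z connectivity tables.

Nuisance (motion) regression is applied per run by default, runs are
concatenated, and connectivity is the Fisher r-to-z transformed Pearson
correlation of the residuals.  Session-day tables use runs 1-2 (day 1) and
runs 3-4 (day 2).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

SESSIONS = ("all", "day1", "day2")


def _with_intercept(nuisance: np.ndarray) -> np.ndarray:
    x = np.asarray(nuisance, dtype=float)
    if x.ndim != 2:
        raise ValueError("nuisance must be 2-D")
    col_sd = x.std(axis=0)
    has_const = np.any((col_sd == 0) & (x.mean(axis=0) != 0))
    if not has_const:
        x = np.column_stack([np.ones(len(x)), x])
    return x


def regress_nuisance(series: np.ndarray, nuisance: np.ndarray) -> np.ndarray:
    """Residualise ``series`` (T x R) against the nuisance design (T x C).

    An intercept column is added if absent.  Rank-deficient designs are
    handled by a minimum-norm least-squares solve; linearly dependent
    columns are reported with a warning.
    """
    y = np.asarray(series, dtype=float)
    x = _with_intercept(nuisance)
    if y.shape[0] != x.shape[0]:
        raise ValueError("series and nuisance must have the same number of rows")
    if y.shape[0] <= x.shape[1] + 2:
        raise ValueError("too few time points for the nuisance design")
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        log.warning(
            "nuisance design is rank deficient (%d of %d columns independent); "
            "dependent columns contribute nothing", rank, x.shape[1]
        )
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ beta


def fisher_z_matrix(residuals, areas: list[str] | None = None) -> pd.DataFrame:
    """Fisher r-to-z connectivity matrix of (concatenated) residual series.

    ``residuals`` is a T x R array or a list of per-run residual arrays that
    are concatenated in time.  The diagonal is undefined and set to NaN.
    Perfectly correlated or zero-variance columns raise, naming the columns.
    """
    if isinstance(residuals, (list, tuple)):
        resid = np.vstack([np.asarray(r, dtype=float) for r in residuals])
    else:
        resid = np.asarray(residuals, dtype=float)
    t, r = resid.shape
    if t <= r:
        raise ValueError("need more time points than areas")
    if areas is None:
        areas = [f"roi{i}" for i in range(r)]
    sd = resid.std(axis=0)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(f"zero-variance columns: {[areas[i] for i in zero]}")
    corr = np.corrcoef(resid, rowvar=False)
    off = np.abs(corr - np.eye(r))
    if np.any(off >= 1.0 - 1e-12):
        i, j = np.unravel_index(np.argmax(off), off.shape)
        raise ValueError(
            f"|r| = 1 between {areas[i]} and {areas[j]}: Fisher transform undefined"
        )
    with np.errstate(divide="ignore"):
        z = np.arctanh(corr)
    np.fill_diagonal(z, np.nan)
    return pd.DataFrame(z, index=areas, columns=areas)


def session_runs(n_runs: int, session: str) -> list[int]:
    """Run indices (0-based) belonging to a session label."""
    if session == "all":
        return list(range(n_runs))
    if session == "day1":
        return [i for i in (0, 1) if i < n_runs]
    if session == "day2":
        return [i for i in (2, 3) if i < n_runs]
    raise ValueError(f"unknown session {session!r}")


def subject_connectivity(
    runs: list[pd.DataFrame],
    motion: list[pd.DataFrame],
    regress_per_run: bool = True,
    sessions: tuple[str, ...] = SESSIONS,
) -> dict[str, pd.DataFrame]:
    """Session -> Fisher-z matrix for one subject.

    With ``regress_per_run`` (default) motion is regressed out within each
    run before temporal concatenation; otherwise regression is done on the
    concatenated data.
    """
    if len(runs) != len(motion):
        raise ValueError("runs and motion lists must align")
    areas = list(runs[0].columns)
    out: dict[str, pd.DataFrame] = {}
    if regress_per_run:
        resid = [
            regress_nuisance(r.to_numpy(), m.to_numpy()) for r, m in zip(runs, motion)
        ]
    else:
        y = np.vstack([r.to_numpy() for r in runs])
        x = np.vstack([m.to_numpy() for m in motion])
        full = regress_nuisance(y, x)
        bounds = np.cumsum([0] + [len(r) for r in runs])
        resid = [full[bounds[i]:bounds[i + 1]] for i in range(len(runs))]
    for ses in sessions:
        idx = session_runs(len(runs), ses)
        if not idx:
            continue
        out[ses] = fisher_z_matrix([resid[i] for i in idx], areas)
    return out


def connectivity_long(
    matrices: dict[str, dict[str, pd.DataFrame]]
) -> pd.DataFrame:
    """Long table (subject_id, session, area_a, area_b, z) from nested dicts."""
    records = []
    for sid, per_session in matrices.items():
        for ses, zmat in per_session.items():
            areas = list(zmat.columns)
            arr = zmat.to_numpy()
            for i in range(len(areas)):
                for j in range(i + 1, len(areas)):
                    records.append((sid, ses, areas[i], areas[j], arr[i, j]))
    return pd.DataFrame(
        records, columns=["subject_id", "session", "area_a", "area_b", "z"]
    )
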