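"""Synthetic twin cohorts, heritable phenotypes, ROI time series and area graphs.

Everything downstream of raw imaging is testable against these generators:
they produce a pedigree of MZ/DZ twin pairs with covariates, per-subject
scalar phenotypes with a prescribed heritability under the additive-genetic
covariance model (within-pair phenotypic correlation ``2*phi*h2``), Gaussian
ROI time series with prescribed per-subject connectivity, and a 48-area
visual-cortex-like adjacency graph with a known hierarchical-level profile.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

MZ = "MZ"
DZ = "DZ"

#: Covariate columns carried by a cohort table, in canonical order.
COVARIATE_COLUMNS = ("age", "sex", "mean_fd", "recon_version")

#: Adult age range (years), shared within a twin pair.
AGE_RANGE = (22.0, 36.0)

#: Log-normal parameters for mean framewise displacement (mm).
MEAN_FD_LOG_MEAN = np.log(0.12)
MEAN_FD_LOG_SD = 0.35


def generate_pedigree(n_mz: int, n_dz: int, seed: int = 0) -> pd.DataFrame:
    """Generate a twin cohort of ``n_mz`` MZ and ``n_dz`` DZ pairs.

    Ages are uniform on 22-36 y and identical within a pair; MZ co-twins
    share sex, DZ co-twins' sexes are independent; mean framewise
    displacement is log-normal and independent across co-twins;
    reconstruction-software version is shared within a family (twins are
    scanned in the same study period).

    Returns a DataFrame with columns subject_id, family_id, zygosity,
    age, sex, mean_fd, recon_version.
    """
    if n_mz < 0 or n_dz < 0:
        raise ValueError("pair counts must be non-negative")
    if n_mz + n_dz == 0:
        raise ValueError("at least one twin pair is required")
    rng = np.random.default_rng(seed)
    n_fam = n_mz + n_dz
    zygosity = np.array([MZ] * n_mz + [DZ] * n_dz)
    ages = rng.uniform(*AGE_RANGE, size=n_fam)
    first_sex = rng.integers(0, 2, size=n_fam)
    second_sex = np.where(zygosity == MZ, first_sex, rng.integers(0, 2, size=n_fam))
    recon = rng.integers(0, 2, size=n_fam)
    mean_fd = rng.lognormal(MEAN_FD_LOG_MEAN, MEAN_FD_LOG_SD, size=(n_fam, 2))

    rows = []
    for f in range(n_fam):
        fam_id = f"F{f:04d}"
        for k, sex in enumerate((first_sex[f], second_sex[f])):
            rows.append(
                {
                    "subject_id": f"{fam_id}S{k + 1}",
                    "family_id": fam_id,
                    "zygosity": zygosity[f],
                    "age": float(ages[f]),
                    "sex": int(sex),
                    "mean_fd": float(mean_fd[f, k]),
                    "recon_version": int(recon[f]),
                }
            )
    return pd.DataFrame(rows)


def validate_pedigree(cohort: pd.DataFrame) -> list[str]:
    """Return a list of invariant violations (empty if the cohort is valid)."""
    problems: list[str] = []
    required = {"subject_id", "family_id", "zygosity"} | set(COVARIATE_COLUMNS)
    missing = required - set(cohort.columns)
    if missing:
        return [f"missing columns: {sorted(missing)}"]
    if cohort["subject_id"].duplicated().any():
        problems.append("duplicate subject_id")
    sizes = cohort.groupby("family_id").size()
    bad = sizes[sizes != 2]
    if len(bad):
        problems.append(f"families without exactly 2 members: {list(bad.index)}")
    zyg_n = cohort.groupby("family_id")["zygosity"].nunique()
    if (zyg_n > 1).any():
        problems.append("zygosity not constant within family")
    if not set(cohort["zygosity"]).issubset({MZ, DZ}):
        problems.append("zygosity values outside {MZ, DZ}")
    if (cohort["mean_fd"] <= 0).any():
        problems.append("non-positive mean_fd")
    return problems


def _family_pairs(cohort: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Index pairs (n_fam, 2) into the cohort rows plus 2*phi per family."""
    problems = validate_pedigree(cohort)
    if problems:
        raise ValueError("; ".join(problems))
    codes, _ = pd.factorize(cohort["family_id"], sort=True)
    order = np.argsort(codes, kind="stable")
    pairs = order.reshape(-1, 2)
    zyg = cohort["zygosity"].to_numpy()
    phi2 = np.where(zyg[pairs[:, 0]] == MZ, 1.0, 0.5)
    return pairs, phi2


def design_matrix(
    cohort: pd.DataFrame, covariates: tuple[str, ...] | list[str] = COVARIATE_COLUMNS
) -> np.ndarray:
    """Intercept + the requested covariate columns, as a dense array."""
    cols = [np.ones(len(cohort))]
    cols += [cohort[c].to_numpy(dtype=float) for c in covariates]
    return np.column_stack(cols)


def generate_phenotypes(
    cohort: pd.DataFrame,
    h2_true,
    mean=0.0,
    total_var: float = 1.0,
    covariate_effects: dict[str, float] | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Simulate phenotypes with additive-genetic within-pair covariance.

    ``h2_true`` and ``mean`` may be scalars or length-P vectors; the result is
    (n_subjects, P).  For each family the random part ``u`` is bivariate
    normal with variance ``total_var`` and within-pair covariance
    ``2*phi*h2_true*total_var`` (2*phi = 1 for MZ, 0.5 for DZ); covariate
    effects enter as ``X @ beta`` on top.
    """
    h2 = np.atleast_1d(np.asarray(h2_true, dtype=float))
    if np.any((h2 < 0) | (h2 > 1)):
        raise ValueError("h2_true must lie in [0, 1]")
    if total_var <= 0:
        raise ValueError("total_var must be positive")
    mu = np.broadcast_to(np.atleast_1d(np.asarray(mean, dtype=float)), h2.shape)
    n = len(cohort)
    n_p = h2.shape[0]
    pairs, phi2 = _family_pairs(cohort)
    rng = np.random.default_rng(seed)

    rho = phi2[:, None] * h2[None, :]  # (n_fam, P)
    g1 = rng.standard_normal((len(pairs), n_p))
    g2 = rng.standard_normal((len(pairs), n_p))
    u1 = g1
    u2 = rho * g1 + np.sqrt(1.0 - rho**2) * g2
    u = np.empty((n, n_p))
    u[pairs[:, 0]] = u1
    u[pairs[:, 1]] = u2
    y = mu[None, :] + np.sqrt(total_var) * u
    if covariate_effects:
        for name, beta in covariate_effects.items():
            b = np.broadcast_to(np.atleast_1d(np.asarray(beta, dtype=float)), (n_p,))
            y = y + cohort[name].to_numpy(dtype=float)[:, None] * b[None, :]
    return y


def generate_phenotype(
    cohort: pd.DataFrame,
    h2_true: float,
    mean: float = 0.0,
    total_var: float = 1.0,
    covariate_effects: dict[str, float] | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Single-phenotype convenience wrapper around :func:`generate_phenotypes`."""
    return generate_phenotypes(
        cohort, [h2_true], mean, total_var, covariate_effects, seed
    )[:, 0]


def nearest_positive_definite(corr: np.ndarray, eps: float = 1e-6):
    """Clip eigenvalues at ``eps`` and restore the unit diagonal.

    Returns (repaired matrix, Frobenius distance to the input).
    """
    c = np.asarray(corr, dtype=float)
    w, v = np.linalg.eigh((c + c.T) / 2.0)
    w_clipped = np.clip(w, eps, None)
    fixed = (v * w_clipped) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    return fixed, float(np.linalg.norm(fixed - c, "fro"))


@dataclass
class TimeseriesBundle:
    """Per-subject simulated runs, motion regressors and PD-repair flags."""

    areas: list[str]
    runs: dict[str, list[pd.DataFrame]]
    motion: dict[str, list[pd.DataFrame]]
    flagged: list[tuple[str, float]]


MOTION_COLUMNS = [
    f"{p}_{ax}" for p in ("trans", "rot") for ax in ("x", "y", "z")
]
MOTION_COLUMNS += [f"{c}_dt" for c in MOTION_COLUMNS]


def _motion_regressors(rng, n_t: int, mean_fd: float) -> pd.DataFrame:
    """12 smoothed-noise motion columns (6 parameters + backward differences)."""
    base = rng.standard_normal((n_t + 10, 6))
    kernel = np.ones(11) / 11.0
    smooth = np.column_stack(
        [np.convolve(base[:, j], kernel, mode="valid") for j in range(6)]
    )[:n_t]
    smooth *= mean_fd
    deriv = np.zeros_like(smooth)
    deriv[1:] = np.diff(smooth, axis=0)
    return pd.DataFrame(np.hstack([smooth, deriv]), columns=MOTION_COLUMNS)


def generate_timeseries(
    cohort: pd.DataFrame,
    subject_z: np.ndarray,
    areas: list[str],
    n_timepoints: int = 1200,
    n_runs: int = 4,
    seed: int = 0,
    motion_leak: float = 0.1,
    pd_tolerance: float = 0.5,
) -> TimeseriesBundle:
    """Simulate per-run ROI series with per-subject target connectivity.

    ``subject_z`` is (n_subjects, R, R) of target Fisher-z values (diagonal
    ignored).  The population correlation of each subject's series is the
    nearest positive-definite repair of ``tanh(z)``; subjects whose target
    needed a repair with Frobenius distance above ``pd_tolerance`` are
    reported in ``flagged``.  Motion regressors are smoothed noise scaled by
    the subject's mean FD and leak into the series with weight
    ``motion_leak`` (removed later by nuisance regression).
    """
    r = len(areas)
    if n_timepoints < 10 * r:
        raise ValueError("n_timepoints must be at least 10x the number of areas")
    z = np.asarray(subject_z, dtype=float)
    if z.shape != (len(cohort), r, r):
        raise ValueError("subject_z must be (n_subjects, n_areas, n_areas)")
    if np.any(np.abs(np.tanh(z)) >= 1.0):
        raise ValueError("target correlations must have magnitude < 1")
    rng = np.random.default_rng(seed)
    runs: dict[str, list[pd.DataFrame]] = {}
    motion: dict[str, list[pd.DataFrame]] = {}
    flagged: list[tuple[str, float]] = []
    for s, sid in enumerate(cohort["subject_id"]):
        corr = np.tanh(z[s])
        np.fill_diagonal(corr, 1.0)
        corr_pd, dist = nearest_positive_definite(corr)
        if dist > pd_tolerance:
            flagged.append((sid, dist))
        chol = np.linalg.cholesky(corr_pd)
        mean_fd = float(cohort["mean_fd"].iloc[s])
        leak_w = rng.standard_normal((12, r)) * motion_leak
        runs[sid] = []
        motion[sid] = []
        for _ in range(n_runs):
            series = rng.standard_normal((n_timepoints, r)) @ chol.T
            mot = _motion_regressors(rng, n_timepoints, mean_fd)
            series = series + mot.to_numpy() @ leak_w
            runs[sid].append(pd.DataFrame(series, columns=areas))
            motion[sid].append(mot)
    return TimeseriesBundle(areas=list(areas), runs=runs, motion=motion, flagged=flagged)


# --------------------------------------------------------------------------
# Area graph fixture and the two-component ground-truth curve
# --------------------------------------------------------------------------

_HEMI_AREAS = [
    "V1", "V2v", "V2d", "V3v", "V3d", "hV4", "VO1", "VO2", "PHC1", "PHC2",
    "LO1", "LO2", "TO1", "TO2", "V3A", "V3B", "IPS0", "IPS1", "IPS2", "IPS3",
    "IPS4", "IPS5", "SPL1", "FEF",
]

_HEMI_EDGES = [
    ("V1", "V2v"), ("V1", "V2d"), ("V2v", "V3v"), ("V2d", "V3d"),
    ("V3v", "hV4"), ("hV4", "VO1"), ("VO1", "VO2"), ("VO2", "PHC1"),
    ("PHC1", "PHC2"), ("V3d", "LO1"), ("LO1", "LO2"), ("LO2", "TO1"),
    ("TO1", "TO2"), ("V3d", "V3A"), ("V3A", "V3B"), ("V3A", "IPS0"),
    ("IPS0", "IPS1"), ("IPS1", "IPS2"), ("IPS2", "IPS3"), ("IPS3", "IPS4"),
    ("IPS4", "IPS5"), ("IPS5", "SPL1"), ("IPS5", "FEF"),
]

#: Root area label per hemisphere of the packaged graph.
HEMISPHERE_ROOTS = ("L_V1", "R_V1")

#: Early-visual area labels (both hemispheres) used for the restricted slope test.
EARLY_VISUAL_AREAS = tuple(
    f"{h}_{a}" for h in ("L", "R") for a in ("V1", "V2v", "V2d", "V3v", "V3d")
)


def generate_area_graph(levels_spec) -> pd.DataFrame:
    """Edge list DataFrame (area_a, area_b) from (area, neighbors) pairs."""
    edges = []
    seen = set()
    for area, neighbors in levels_spec:
        for nb in neighbors:
            if nb == area:
                raise ValueError(f"self-loop on area {area!r}")
            key = tuple(sorted((area, nb)))
            if key not in seen:
                seen.add(key)
                edges.append(key)
    if not edges:
        raise ValueError("empty edge list: no graph")
    return pd.DataFrame(sorted(edges), columns=["area_a", "area_b"])


def visual_area_graph(hemispheres: tuple[str, ...] = ("L", "R")) -> pd.DataFrame:
    """Packaged 48-area fixture: 24 areas per hemisphere, connected within
    each hemisphere, with V1 as the designated root."""
    spec = []
    for h in hemispheres:
        adj: dict[str, list[str]] = {f"{h}_{a}": [] for a in _HEMI_AREAS}
        for a, b in _HEMI_EDGES:
            adj[f"{h}_{a}"].append(f"{h}_{b}")
        spec += list(adj.items())
    return generate_area_graph(spec)


@dataclass(frozen=True)
class PlasticityCurve:
    """Generative two-component heritability curve over hierarchical level.

    h2(eta) = h_max - a1*exp(-b1*eta) - a2*exp(+b2*eta): the decaying term is
    the short-term component, the growing term the long-term component.
    Defaults give a non-monotonic curve on eta in [0, 10] peaking near
    eta ~ 2.5 and declining to ~0.10 at the top of the hierarchy.
    """

    a1: float = 0.25
    b1: float = 1.5
    a2: float = 0.0085
    b2: float = 0.35
    h_max: float = 0.5

    def short_term(self, eta):
        return self.a1 * np.exp(-self.b1 * np.asarray(eta, dtype=float))

    def long_term(self, eta):
        return self.a2 * np.exp(self.b2 * np.asarray(eta, dtype=float))

    def h2(self, eta):
        return np.clip(self.h_max - self.short_term(eta) - self.long_term(eta), 0.0, 1.0)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class LinearProfile:
    """Monotone-linear alternative truth, for curvature null calibration."""

    intercept: float = 0.42
    slope: float = -0.02

    def h2(self, eta):
        return np.clip(self.intercept + self.slope * np.asarray(eta, dtype=float), 0.0, 1.0)


def connection_h2_from_levels(levels: pd.Series, curve, clip=(0.0, 1.0)) -> pd.Series:
    """Per-connection true h2 whose per-area mean equals ``curve.h2`` exactly.

    With R areas and all pairwise connections, setting the connection truth to
    g(eta_i) + g(eta_j) - mean(h) with g = (h - mean(h)/(R-1)) * (R-1)/(R-2)
    makes each area's mean over its R-1 connections equal h(eta_area).
    Values are clipped to ``clip`` afterwards (a no-op for the default
    generative curves, whose range keeps all connection values inside [0, 1]).
    """
    areas = list(levels.index)
    r = len(areas)
    if r < 3:
        raise ValueError("need at least 3 areas")
    h = np.asarray(curve.h2(levels.to_numpy()), dtype=float)
    h_bar = h.mean()
    g = (h - h_bar / (r - 1)) * (r - 1) / (r - 2)
    g_by_area = dict(zip(areas, g))
    out = {}
    for a, b in itertools.combinations(areas, 2):
        out[(a, b)] = float(np.clip(g_by_area[a] + g_by_area[b] - h_bar, *clip))
    idx = pd.MultiIndex.from_tuples(out.keys(), names=["area_a", "area_b"])
    return pd.Series(list(out.values()), index=idx, name="h2_true")
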