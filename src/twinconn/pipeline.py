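"""Config-driven orchestration of the analysis stages.

Stages: simulate -> connectivity -> screen -> heritability -> reliability ->
hierarchy -> fit.  All tabular outputs are long-format TSV; model fits go to
JSON.  Every source of randomness is seeded from the config, so a rerun with
the same config is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import connectivity as conn_mod
from . import gradient, hierarchy, reliability, screening, simulate
from .heritability import heritability_table

log = logging.getLogger(__name__)

CONNECTIVITY_COVARIATES = ("age", "sex", "mean_fd", "recon_version")
ANATOMY_COVARIATES = ("age", "sex")


@dataclass
class PipelineConfig:
    out_dir: str = "out"
    seed: int = 0
    # cohort / simulation
    n_mz: int = 123
    n_dz: int = 67
    hemispheres: tuple = ("L", "R")
    n_timepoints: int = 1200
    n_runs: int = 4
    areas_subset: list | None = None     # optional list of area labels
    simulate_timeseries: bool = True     # False: write connection tables directly
    # screening
    q_fdr: float = 0.05
    n_perm: int = 10000
    # reliability
    n_perm_mantel: int = 5000
    # hierarchy
    roots: tuple = simulate.HEMISPHERE_ROOTS
    level_offset: int = 0
    # models
    h_max: float = 0.5
    loss: str = "soft_l1"
    regress_per_run: bool = True
    early_areas: tuple = simulate.EARLY_VISUAL_AREAS
    covariates_connectivity: tuple = CONNECTIVITY_COVARIATES
    covariates_anatomy: tuple = ANATOMY_COVARIATES
    truth: dict = field(default_factory=lambda: simulate.PlasticityCurve().to_dict())

    def validate(self) -> None:
        if not 0.0 < self.q_fdr < 1.0:
            raise ValueError("q_fdr must lie in (0, 1)")
        if self.n_perm < 1 or self.n_perm_mantel < 1:
            raise ValueError("permutation counts must be positive")
        if not 0.0 < self.h_max <= 1.0:
            raise ValueError("h_max must lie in (0, 1]")
        if self.seed is None:
            raise ValueError("an explicit seed is required")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _seeds(cfg: PipelineConfig) -> dict[str, int]:
    rng = np.random.default_rng(cfg.seed)
    names = ("pedigree", "phenotypes", "timeseries", "screen", "mantel", "anatomy")
    return {k: int(v) for k, v in zip(names, rng.integers(0, 2**31 - 1, len(names)))}


# --------------------------------------------------------------------------
# Stages
# --------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig) -> dict:
    """Write pedigree, edges, truth, connection (or time-series) tables and
    anatomical phenotype tables for a synthetic cohort."""
    cfg.validate()
    out = Path(cfg.out_dir)
    seeds = _seeds(cfg)
    cohort = simulate.generate_pedigree(cfg.n_mz, cfg.n_dz, seed=seeds["pedigree"])
    edges = simulate.visual_area_graph(cfg.hemispheres)
    if cfg.areas_subset:
        keep = set(cfg.areas_subset)
        edges = edges[edges["area_a"].isin(keep) & edges["area_b"].isin(keep)].reset_index(drop=True)
    roots = tuple(r for r in cfg.roots if r in set(edges["area_a"]) | set(edges["area_b"]))
    levels = hierarchy.levels_table(edges, roots, cfg.level_offset).set_index("area")["eta"]
    curve = simulate.PlasticityCurve(**cfg.truth)
    conn_truth = simulate.connection_h2_from_levels(levels, curve)

    rng = np.random.default_rng(seeds["phenotypes"])
    mean_z = rng.normal(0.30, 0.05, size=len(conn_truth))
    subj_z = simulate.generate_phenotypes(
        cohort, conn_truth.to_numpy(), mean=mean_z, total_var=0.02,
        covariate_effects={"mean_fd": -0.05}, seed=seeds["phenotypes"],
    )

    _write_tsv(cohort, out / "pedigree.tsv")
    _write_tsv(edges, out / "edges.tsv")

    areas = sorted(levels.index)
    if cfg.simulate_timeseries:
        a_idx = {a: i for i, a in enumerate(areas)}
        zmats = np.zeros((len(cohort), len(areas), len(areas)))
        for k, (a, b) in enumerate(conn_truth.index):
            zmats[:, a_idx[a], a_idx[b]] = subj_z[:, k]
            zmats[:, a_idx[b], a_idx[a]] = subj_z[:, k]
        bundle = simulate.generate_timeseries(
            cohort, zmats, areas, cfg.n_timepoints, cfg.n_runs,
            seed=seeds["timeseries"],
        )
        for sid in cohort["subject_id"]:
            for r, (ts, mot) in enumerate(zip(bundle.runs[sid], bundle.motion[sid]), 1):
                _write_tsv(ts, out / "timeseries" / f"{sid}_run{r}.tsv")
                _write_tsv(mot, out / "motion" / f"{sid}_run{r}.tsv")
        if bundle.flagged:
            log.warning("non-embeddable connectivity targets repaired beyond "
                        "tolerance for: %s", bundle.flagged)
    else:
        rows = []
        for s, sid in enumerate(cohort["subject_id"]):
            for k, (a, b) in enumerate(conn_truth.index):
                rows.append((sid, "all", a, b, subj_z[s, k]))
        _write_tsv(
            pd.DataFrame(rows, columns=["subject_id", "session", "area_a", "area_b", "z"]),
            out / "connectivity.tsv",
        )

    # anatomical phenotypes with a monotonically decreasing h2 profile
    anat_h2 = np.clip(0.8 - 0.012 * np.exp(0.35 * levels.loc[areas].to_numpy(dtype=float)), 0.05, 0.95)
    for name, shift in (("thickness", 2.5), ("volume", 5.0)):
        vals = simulate.generate_phenotypes(
            cohort, anat_h2, mean=shift, total_var=0.1,
            covariate_effects={"age": 0.01, "sex": 0.05},
            seed=seeds["anatomy"] + (0 if name == "thickness" else 1),
        )
        _write_tsv(
            pd.DataFrame(vals, columns=areas).assign(subject_id=cohort["subject_id"].to_numpy())
            [["subject_id"] + areas],
            out / f"{name}.tsv",
        )

    truth = {
        "curve": curve.to_dict(),
        "anatomical_h2": dict(zip(areas, anat_h2.tolist())),
        "connection_h2": {f"{a}|{b}": v for (a, b), v in conn_truth.items()},
        "seeds": seeds,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    return {"cohort": cohort, "edges": edges, "levels": levels, "truth": truth}


def stage_connectivity(cfg: PipelineConfig) -> pd.DataFrame:
    out = Path(cfg.out_dir)
    cohort = pd.read_csv(out / "pedigree.tsv", sep="\t")
    matrices = {}
    for sid in cohort["subject_id"]:
        runs, motion = [], []
        for r in range(1, cfg.n_runs + 1):
            runs.append(pd.read_csv(out / "timeseries" / f"{sid}_run{r}.tsv", sep="\t"))
            motion.append(pd.read_csv(out / "motion" / f"{sid}_run{r}.tsv", sep="\t"))
        matrices[sid] = conn_mod.subject_connectivity(
            runs, motion, regress_per_run=cfg.regress_per_run
        )
    table = conn_mod.connectivity_long(matrices)
    _write_tsv(table, out / "connectivity.tsv")
    return table


def stage_screen(cfg: PipelineConfig) -> pd.DataFrame:
    out = Path(cfg.out_dir)
    cohort = pd.read_csv(out / "pedigree.tsv", sep="\t")
    z_long = pd.read_csv(out / "connectivity.tsv", sep="\t")
    screen = screening.screen_connections(
        z_long, cohort, q=cfg.q_fdr, n_perm=cfg.n_perm, seed=_seeds(cfg)["screen"]
    )
    dropped = screen[~screen["keep"]]
    for _, row in dropped.iterrows():
        log.info("connection %s-%s excluded: FDR p=%.4g > %.2g",
                 row["area_a"], row["area_b"], row["p_fdr"], cfg.q_fdr)
    _write_tsv(screen, out / "screen.tsv")
    return screen


def _kept_wide(out: Path, cohort: pd.DataFrame, session: str) -> pd.DataFrame:
    z_long = pd.read_csv(out / "connectivity.tsv", sep="\t")
    screen = pd.read_csv(out / "screen.tsv", sep="\t")
    kept = set(map(tuple, screen[screen["keep"]][["area_a", "area_b"]].to_numpy()))
    wide = z_long[z_long["session"] == session].pivot_table(
        index="subject_id", columns=["area_a", "area_b"], values="z"
    )
    wide = wide[[c for c in wide.columns if tuple(c) in kept]]
    return wide.loc[cohort["subject_id"]]


def stage_heritability(cfg: PipelineConfig) -> pd.DataFrame:
    out = Path(cfg.out_dir)
    cohort = pd.read_csv(out / "pedigree.tsv", sep="\t")
    wide = _kept_wide(out, cohort, "all")
    res = heritability_table(wide, cohort, covariates=cfg.covariates_connectivity)
    res[["area_a", "area_b"]] = [list(c) for c in wide.columns]
    res = res[["area_a", "area_b", "h2", "sigma_g2", "sigma_e2", "lrt_stat", "p",
               "ci_low", "ci_high", "converged"]]
    _write_tsv(res, out / "heritability.tsv")

    for name in ("thickness", "volume"):
        path = out / f"{name}.tsv"
        if path.exists():
            table = pd.read_csv(path, sep="\t").set_index("subject_id").loc[cohort["subject_id"]]
            anat = heritability_table(table, cohort, covariates=cfg.covariates_anatomy)
            anat = anat.rename(columns={"phenotype_id": "area"})
            _write_tsv(anat, out / f"heritability_{name}.tsv")
    return res


def stage_reliability(cfg: PipelineConfig) -> dict:
    out = Path(cfg.out_dir)
    cohort = pd.read_csv(out / "pedigree.tsv", sep="\t")
    day1 = _kept_wide(out, cohort, "day1")
    day2 = _kept_wide(out, cohort, "day2")
    icc = reliability.icc_matrix(day1.to_numpy(), day2.to_numpy())
    icc_df = pd.DataFrame(
        {"area_a": [c[0] for c in day1.columns],
         "area_b": [c[1] for c in day1.columns],
         "icc": icc}
    )
    _write_tsv(icc_df, out / "icc.tsv")
    icc_series = pd.Series(icc, index=pd.MultiIndex.from_tuples(day1.columns))
    area_icc = gradient.area_profile(icc_series)
    area_icc = area_icc.rename(columns={"mean": "mean_icc"})
    _write_tsv(area_icc, out / "area_icc.tsv")

    herit = pd.read_csv(out / "heritability.tsv", sep="\t")
    areas = sorted(set(herit["area_a"]) | set(herit["area_b"]))
    idx = {a: i for i, a in enumerate(areas)}
    n = len(areas)
    h2_mat = np.full((n, n), np.nan)
    icc_mat = np.full((n, n), np.nan)
    for _, row in herit.iterrows():
        h2_mat[idx[row["area_a"]], idx[row["area_b"]]] = row["h2"]
        h2_mat[idx[row["area_b"]], idx[row["area_a"]]] = row["h2"]
    for _, row in icc_df.iterrows():
        if row["area_a"] in idx and row["area_b"] in idx:
            icc_mat[idx[row["area_a"]], idx[row["area_b"]]] = row["icc"]
            icc_mat[idx[row["area_b"]], idx[row["area_a"]]] = row["icc"]
    r2, p = reliability.mantel_test(
        h2_mat, icc_mat, n_perm=cfg.n_perm_mantel, seed=_seeds(cfg)["mantel"]
    )
    result = {"mantel_r2": r2, "mantel_p": p, "n_perm": cfg.n_perm_mantel}
    (out / "mantel.json").write_text(json.dumps(result, indent=1))
    return result


def stage_hierarchy(cfg: PipelineConfig) -> pd.DataFrame:
    out = Path(cfg.out_dir)
    edges = pd.read_csv(out / "edges.tsv", sep="\t")
    roots = tuple(r for r in cfg.roots if r in set(edges["area_a"]) | set(edges["area_b"]))
    levels = hierarchy.levels_table(edges, roots, cfg.level_offset)
    _write_tsv(levels, out / "levels.tsv")
    return levels


def stage_fit(cfg: PipelineConfig) -> dict:
    out = Path(cfg.out_dir)
    levels = pd.read_csv(out / "levels.tsv", sep="\t").set_index("area")["eta"]
    herit = pd.read_csv(out / "heritability.tsv", sep="\t")
    h2_series = pd.Series(
        herit["h2"].to_numpy(),
        index=pd.MultiIndex.from_frame(herit[["area_a", "area_b"]]),
    )
    profile = gradient.area_profile(h2_series)
    eta = levels.loc[profile["area"]].to_numpy(dtype=float)
    y = profile["mean"].to_numpy()

    fit_lin = gradient.fit_polynomial(eta, y, 1)
    fit_quad = gradient.fit_polynomial(eta, y, 2)
    f, df1, df2, p_nested = gradient.nested_f_test(fit_lin, fit_quad)
    t_early, df_early, p_early = gradient.early_visual_slope(profile, levels, cfg.early_areas)
    two = gradient.fit_two_component(eta, y, h_max=cfg.h_max, loss=cfg.loss)

    fits = {
        "linear": {"params": fit_lin.params.tolist(), "r2": fit_lin.r2,
                   "f": fit_lin.f_stat, "df1": fit_lin.df1, "df2": fit_lin.df2,
                   "p": fit_lin.p_value},
        "quadratic": {"params": fit_quad.params.tolist(), "r2": fit_quad.r2,
                      "f": fit_quad.f_stat, "df1": fit_quad.df1,
                      "df2": fit_quad.df2, "p": fit_quad.p_value},
        "nested_f": {"f": f, "df1": df1, "df2": df2, "p": p_nested},
        "early_visual": {"t": t_early, "df": df_early, "p": p_early},
        "two_component": {"a1": two.a1_, "b1": two.b1_, "a2": two.a2_,
                          "b2": two.b2_, "h_max": cfg.h_max, "r2": two.r2_,
                          "converged": two.converged_},
    }

    preds = pd.DataFrame({
        "area": profile["area"], "eta": eta, "observed": y,
        "sem": profile["sem"],
        "linear": fit_lin.predict(eta), "quadratic": fit_quad.predict(eta),
        "two_component": two.predict(eta) if two.converged_ else np.nan,
    })
    _write_tsv(preds, out / "predictions.tsv")

    # component comparison against ICC and anatomical heritability profiles
    comparisons = {}
    targets = {}
    area_icc_path = out / "area_icc.tsv"
    if area_icc_path.exists():
        t = pd.read_csv(area_icc_path, sep="\t")
        targets["icc"] = t.set_index("area")["mean_icc"]
    for name in ("thickness", "volume"):
        path = out / f"heritability_{name}.tsv"
        if path.exists():
            t = pd.read_csv(path, sep="\t")
            targets[name] = t.set_index("area")["h2"]
    if two.converged_:
        for name, series in targets.items():
            common = [a for a in profile["area"] if a in series.index]
            e = levels.loc[common].to_numpy(dtype=float)
            v = series.loc[common].to_numpy(dtype=float)
            b_s, aic_s, _ = gradient.component_intercept_fit(e, v, two, "short")
            b_l, aic_l, _ = gradient.component_intercept_fit(e, v, two, "long")
            w = gradient.akaike_weights([aic_s, aic_l])
            comparisons[name] = {
                "beta_short": b_s, "aic_short": aic_s,
                "beta_long": b_l, "aic_long": aic_l,
                "weight_short": float(w[0]), "weight_long": float(w[1]),
                "rel_likelihood_short_vs_long": gradient.relative_likelihood(aic_s, aic_l),
            }
    fits["component_comparison"] = comparisons
    (out / "fits.json").write_text(json.dumps(fits, indent=1, sort_keys=True))
    return fits


def validate_inputs(cfg: PipelineConfig) -> list[str]:
    """Schema and cross-file consistency checks; returns collected problems."""
    out = Path(cfg.out_dir)
    problems: list[str] = []
    ped_path = out / "pedigree.tsv"
    if not ped_path.exists():
        return [f"missing {ped_path}"]
    cohort = pd.read_csv(ped_path, sep="\t")
    problems += simulate.validate_pedigree(cohort)
    edges_path = out / "edges.tsv"
    areas: set[str] = set()
    if edges_path.exists():
        edges = pd.read_csv(edges_path, sep="\t")
        if not {"area_a", "area_b"}.issubset(edges.columns):
            problems.append("edges.tsv must have columns area_a, area_b")
        else:
            areas = set(edges["area_a"]) | set(edges["area_b"])
    else:
        problems.append(f"missing {edges_path}")
    ts_dir = out / "timeseries"
    if ts_dir.exists() and areas:
        sample = sorted(ts_dir.glob("*.tsv"))[:1]
        for path in sample:
            cols = set(pd.read_csv(path, sep="\t", nrows=0).columns)
            extra = cols - areas
            if extra:
                problems.append(f"{path.name}: columns not in area list: {sorted(extra)}")
    conn_path = out / "connectivity.tsv"
    if conn_path.exists():
        z = pd.read_csv(conn_path, sep="\t")
        unknown = set(z["subject_id"]) - set(cohort["subject_id"])
        if unknown:
            problems.append(f"connectivity subjects not in pedigree: {sorted(unknown)[:5]}")
    return problems


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns the model-fit bundle."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_simulate(cfg)
    if cfg.simulate_timeseries:
        stage_connectivity(cfg)
    stage_screen(cfg)
    stage_hierarchy(cfg)
    stage_heritability(cfg)
    if cfg.simulate_timeseries:
        stage_reliability(cfg)
    fits = stage_fit(cfg)
    manifest = {
        "config": asdict(cfg),
        "config_hash": cfg.digest(),
        "seeds": _seeds(cfg),
        "versions": {
            "twinconn": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True, default=str))
    return fits


def demo_config(out_dir: str, seed: int = 0) -> PipelineConfig:
    """Small one-command synthetic demo: 40+20 pairs, 12 areas, short runs."""
    areas = ["L_" + a for a in ("V1", "V2v", "V2d", "V3v", "V3d", "hV4", "VO1",
                                "LO1", "LO2", "TO1", "V3A", "IPS0")]
    return PipelineConfig(
        out_dir=out_dir, seed=seed, n_mz=40, n_dz=20,
        hemispheres=("L",), areas_subset=areas,
        n_timepoints=160, n_runs=4,
        n_perm=500, n_perm_mantel=500,
        early_areas=tuple(a for a in simulate.EARLY_VISUAL_AREAS if a.startswith("L_")),
    )
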