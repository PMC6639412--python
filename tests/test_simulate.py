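import numpy as np
import pandas as pd
import pytest

import twinconn as tc
from twinconn.simulate import (
    MZ,
    DZ,
    PlasticityCurve,
    nearest_positive_definite,
    validate_pedigree,
)


@pytest.mark.parametrize(
    "n_mz,n_dz,n_subj,n_fam",
    [(123, 67, 380, 190), (1, 0, 2, 1), (0, 5, 10, 5)],
)
def test_pedigree_composition(n_mz, n_dz, n_subj, n_fam):
    coh = tc.generate_pedigree(n_mz, n_dz, seed=1)
    assert len(coh) == n_subj
    assert coh["family_id"].nunique() == n_fam
    assert validate_pedigree(coh) == []
    counts = coh["zygosity"].value_counts()
    assert counts.get(MZ, 0) == 2 * n_mz and counts.get(DZ, 0) == 2 * n_dz


def test_pedigree_invariants_and_reproducibility():
    a = tc.generate_pedigree(20, 10, seed=7)
    b = tc.generate_pedigree(20, 10, seed=7)
    pd.testing.assert_frame_equal(a, b)
    # ages shared within pair, MZ co-twins share sex, fd positive, adult range
    for _, fam in a.groupby("family_id"):
        assert fam["age"].nunique() == 1
        if fam["zygosity"].iloc[0] == MZ:
            assert fam["sex"].nunique() == 1
    assert a["age"].between(22, 36).all()
    assert (a["mean_fd"] > 0).all()


@pytest.mark.parametrize("n_mz,n_dz", [(-1, 3), (0, 0)])
def test_pedigree_bad_arguments(n_mz, n_dz):
    with pytest.raises(ValueError):
        tc.generate_pedigree(n_mz, n_dz)


def test_phenotype_full_heritability_makes_mz_identical():
    coh = tc.generate_pedigree(30, 30, seed=2)
    y = tc.generate_phenotype(coh, 1.0, seed=3)
    s = pd.Series(y, index=coh["family_id"].to_numpy())
    for fam, grp in s.groupby(level=0):
        zyg = coh.loc[coh["family_id"] == fam, "zygosity"].iloc[0]
        if zyg == MZ:
            assert grp.iloc[0] == pytest.approx(grp.iloc[1], abs=1e-12)


def _twin_correlations(coh, y):
    out = {}
    for zyg in (MZ, DZ):
        sub = coh[coh["zygosity"] == zyg]
        v = pd.Series(y, index=coh.index).loc[sub.index].to_numpy().reshape(-1, 2)
        out[zyg] = np.corrcoef(v[:, 0], v[:, 1])[0, 1]
    return out


def test_phenotype_twin_correlations_match_expectation():
    """rMZ = h2 and rDZ = h2/2 under the additive model (closed form)."""
    coh = tc.generate_pedigree(5000, 5000, seed=4)
    r = _twin_correlations(coh, tc.generate_phenotype(coh, 0.6, seed=5))
    assert r[MZ] == pytest.approx(0.6, abs=0.03)
    assert r[DZ] == pytest.approx(0.3, abs=0.03)
    r0 = _twin_correlations(coh, tc.generate_phenotype(coh, 0.0, seed=6))
    assert abs(r0[MZ]) < 0.03 and abs(r0[DZ]) < 0.03


def test_phenotype_within_pair_covariance_matches_model():
    coh = tc.generate_pedigree(1000, 1000, seed=8)
    tv = 2.5
    y = tc.generate_phenotype(coh, 0.5, total_var=tv, seed=9)
    v = pd.Series(y, index=coh["zygosity"].to_numpy())
    for zyg, phi2 in ((MZ, 1.0), (DZ, 0.5)):
        pairs = v.loc[zyg].to_numpy().reshape(-1, 2)
        cov = np.cov(pairs[:, 0], pairs[:, 1])[0, 1]
        expected = phi2 * 0.5 * tv
        se = tv / np.sqrt(len(pairs))  # rough MC standard error
        assert cov == pytest.approx(expected, abs=4 * se)


def test_phenotype_covariate_effects_enter_linearly():
    coh = tc.generate_pedigree(50, 50, seed=10)
    base = tc.generate_phenotype(coh, 0.4, seed=11)
    shifted = tc.generate_phenotype(
        coh, 0.4, covariate_effects={"age": 0.2}, seed=11
    )
    np.testing.assert_allclose(shifted - base, 0.2 * coh["age"].to_numpy())


def test_phenotype_rejects_invalid_h2():
    coh = tc.generate_pedigree(2, 2, seed=1)
    with pytest.raises(ValueError):
        tc.generate_phenotype(coh, 1.2)


@pytest.mark.parametrize("target_r", [0.0, 0.5])
def test_timeseries_recovers_target_correlation(target_r):
    coh = tc.generate_pedigree(1, 0, seed=1)
    z = np.arctanh(target_r) * (1 - np.eye(2))
    bundle = tc.generate_timeseries(
        coh, np.broadcast_to(z, (2, 2, 2)).copy(), ["a", "b"],
        n_timepoints=50000, n_runs=1, seed=2, motion_leak=0.0,
    )
    series = bundle.runs[coh["subject_id"].iloc[0]][0].to_numpy()
    r = np.corrcoef(series.T)[0, 1]
    # Fisher sampling error ~ 1/sqrt(T-3)
    assert r == pytest.approx(target_r, abs=0.02)


def test_timeseries_flags_non_embeddable_targets():
    coh = tc.generate_pedigree(1, 0, seed=1)
    r = np.array([[1, 0.9, 0.9], [0.9, 1, -0.9], [0.9, -0.9, 1]])
    z = np.arctanh(np.clip(r, -0.999, 0.999))
    np.fill_diagonal(z, 0.0)
    bundle = tc.generate_timeseries(
        coh, np.broadcast_to(z, (2, 3, 3)).copy(), list("abc"),
        n_timepoints=100, n_runs=1, seed=3, pd_tolerance=0.05,
    )
    assert len(bundle.flagged) == 2


def test_nearest_positive_definite_is_identity_on_pd_input(rng):
    a = rng.standard_normal((5, 8))
    c = np.corrcoef(a)
    fixed, dist = nearest_positive_definite(c)
    assert dist < 1e-10
    np.testing.assert_allclose(fixed, c, atol=1e-10)


def test_area_graph_chain_and_errors():
    edges = tc.generate_area_graph([("A", ["B"]), ("B", ["C"])])
    assert len(edges) == 2
    with pytest.raises(ValueError):
        tc.generate_area_graph([("A", ["A"])])
    with pytest.raises(ValueError):
        tc.generate_area_graph([])


def test_packaged_graph_has_48_areas_connected_per_hemisphere():
    import networkx as nx

    edges = tc.visual_area_graph()
    g = nx.Graph(list(edges.itertuples(index=False, name=None)))
    assert g.number_of_nodes() == 48
    comps = list(nx.connected_components(g))
    assert len(comps) == 2
    assert all(len(c) == 24 for c in comps)


def test_connection_truth_round_trips_to_area_means(area_levels):
    """Per-area means of the connection-level truth equal the curve exactly."""
    curve = PlasticityCurve()
    conn = tc.connection_h2_from_levels(area_levels, curve)
    profile = tc.area_profile(conn).set_index("area")["mean"]
    expected = pd.Series(curve.h2(area_levels.to_numpy()), index=area_levels.index)
    pd.testing.assert_series_equal(
        profile.sort_index(), expected.sort_index(), check_names=False, atol=1e-12
    )


def test_default_curve_is_non_monotonic_with_interior_peak():
    curve = PlasticityCurve()
    eta = np.arange(11)
    h = curve.h2(eta)
    peak = int(np.argmax(h))
    assert 1 <= peak <= 4
    assert h[0] < h[peak] and h[-1] < h[peak]
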