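"""Dyad table construction, the lme4 bridge, LRTs and diagnostics."""

import numpy as np
import pandas as pd
import pytest

from cookin import lmm
from cookin.lmm import (
    FULL_TERMS,
    MAIN_TERMS,
    THREEWAY_TERMS,
    DyadicMixedModel,
    LmmFit,
    build_dyad_table,
    dyad_design,
    fit_lmm_models,
    gvif,
    lrt,
)

from conftest import simulate_dyadic_data


# ---------------------------------------------------------------------------
# design construction (no R needed)
# ---------------------------------------------------------------------------


def tiny_dyads(rs=(0.0, 0.0, 0.25, 0.5), F=(0.97, 1.2, 2.0, 0.5)):
    return (
        pd.DataFrame({
            "id_a": ["a", "a", "a", "b"],
            "id_b": ["b", "c", "d", "c"],
            "r": rs,
            "age_diff": [1.0, 4.0, 9.0, 16.0],
            "gm_level": ["same_group_same_matriline", "same_group_diff_matriline",
                         "diff_group_diff_matriline", "diff_group_diff_matriline"],
            "kin_class": ["nonkin", "nonkin", "kin", "kin"],
        }),
        pd.DataFrame(np.array([[0, F[0], F[1], F[2]],
                               [F[0], 0, F[3], 1.0],
                               [F[1], F[3], 0, 1.0],
                               [F[2], 1.0, 1.0, 0]]),
                     index=list("abcd"), columns=list("abcd")),
    )


def test_build_dyad_table_transforms():
    dyads, dist = tiny_dyads()
    data = build_dyad_table(dist, dyads)
    assert len(data) == 4
    assert data["y"].iloc[0] == pytest.approx(np.sqrt(0.97))   # sqrt of the F-value
    assert data["rel"].mean() == pytest.approx(0.0, abs=1e-12)
    assert data["rel"].std(ddof=0) == pytest.approx(1.0)
    assert data["aged"].mean() == pytest.approx(0.0, abs=1e-12)
    # dummies: reference level carries (0, 0)
    ref = data[data["gm_level"] == "diff_group_diff_matriline"]
    assert (ref[["d_ss", "d_sd"]] == 0).all().all()
    assert (data["rel_d_ss_aged"] == data["rel"] * data["d_ss"] * data["aged"]).all()


def test_constant_relatedness_is_an_error():
    dyads, dist = tiny_dyads(rs=(0.25, 0.25, 0.25, 0.25))
    with pytest.raises(ValueError, match="z-transform"):
        build_dyad_table(dist, dyads)


def test_missing_distance_is_an_error():
    dyads, dist = tiny_dyads()
    with pytest.raises(KeyError):
        build_dyad_table(dist.drop(index="d", columns="d"), dyads)


def test_dyad_design_releveling():
    df = pd.DataFrame({
        "gm_level": ["same_group_same_matriline", "same_group_diff_matriline",
                     "diff_group_diff_matriline"],
        "rel_z": [0.0, 1.0, -1.0],
        "aged_z": [1.0, 0.0, -1.0],
    })
    default = dyad_design(df)
    assert default["d_ss"].tolist() == [1.0, 0.0, 0.0]
    assert default["d_sd"].tolist() == [0.0, 1.0, 0.0]
    relev = dyad_design(df, ref_level="same_group_same_matriline")
    # with the ss reference, its row carries (0, 0)
    assert relev[["d_ss", "d_sd"]].iloc[0].tolist() == [0.0, 0.0]
    assert relev.attrs["dummy_levels"]["reference"] == "same_group_same_matriline"


def test_full_terms_bookkeeping():
    assert len(FULL_TERMS) == 11
    assert len(THREEWAY_TERMS) == 2
    assert len(MAIN_TERMS) == 4


def test_gvif_orthogonal_design():
    data = simulate_dyadic_data(13, n_members=40, n_dyads=400)
    out = gvif(data)
    assert set(out.index) == {"rel", "gm", "aged"}
    assert (out > 0.9).all() and (out < 1.2).all()


def test_lrt_contract():
    def fit(terms, ll, reml=False):
        return LmmFit(name="m", fixed_terms=terms, loglik=ll,
                      coef=pd.DataFrame(), varcomp=pd.Series(dtype=float),
                      sigma2=1.0, reml=reml, n_obs=100)

    full = fit(FULL_TERMS, -50.0)
    null = fit([], -60.0)
    res = lrt(full, null)
    assert res.df == 11
    assert res.chi_sq == pytest.approx(20.0)
    same = lrt(full, fit(FULL_TERMS[:-2], -50.0))
    assert same.df == 2 and same.chi_sq == 0.0 and same.p == 1.0
    with pytest.raises(ValueError):
        lrt(full, fit(["not_nested"], -55.0))
    with pytest.raises(ValueError):
        lrt(full, fit([], -60.0, reml=True))
    with pytest.raises(ValueError):
        lrt(null, full)


def test_ols_collapse_matches_least_squares():
    data = simulate_dyadic_data(3, n_members=25, n_dyads=150,
                                beta={"aged": 0.2}, sd_member=0.0)
    m = DyadicMixedModel(fixed=["rel", "aged"], random="none").fit(data)
    X = np.column_stack([np.ones(len(data)), data["rel"], data["aged"]])
    beta_ls, *_ = np.linalg.lstsq(X, data["y"].to_numpy(), rcond=None)
    assert np.allclose(m.coef_["estimate"].to_numpy(), beta_ls, atol=1e-10)


# ---------------------------------------------------------------------------
# fits through the lme4 backend
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def sim_fits():
    data = simulate_dyadic_data(42, n_members=30, n_dyads=250,
                                beta={"aged": 0.15, "d_ss": -0.2})
    no3 = [t for t in FULL_TERMS if t not in THREEWAY_TERMS]
    fits = fit_lmm_models(
        data,
        [{"name": "full", "fixed": FULL_TERMS},
         {"name": "null", "fixed": []},
         {"name": "no3way", "fixed": no3},
         {"name": "full_reml", "fixed": FULL_TERMS, "reml": True}],
        random="slopes",
    )
    return data, fits


def test_df_bookkeeping_full_null_and_threeway(sim_fits):
    _, fits = sim_fits
    full_null = lrt(fits["full"], fits["null"])
    assert full_null.df == 11
    three = lrt(fits["full"], fits["no3way"])
    assert three.df == 2
    assert 0.0 <= three.p <= 1.0


def test_nested_loglik_ordering(sim_fits):
    _, fits = sim_fits
    assert fits["full"].loglik >= fits["no3way"].loglik - 1e-6
    assert fits["no3way"].loglik >= fits["null"].loglik - 1e-6


def test_fit_surfaces(sim_fits):
    _, fits = sim_fits
    full = fits["full"]
    assert full.n_params_fixed == 12
    assert len(full.coef) == 12
    assert {"estimate", "se", "t"} <= set(full.coef.columns)
    # one variance component per random intercept+slope per member slot
    assert len(full.varcomp) == 2 * (len(FULL_TERMS) + 1)
    assert (full.varcomp >= 0).all()
    assert full.sigma2 > 0
    reml = fits["full_reml"]
    assert reml.reml and not full.reml


def test_parameter_recovery():
    beta = {"aged": 0.3, "rel": -0.15}
    data = simulate_dyadic_data(7, n_members=40, n_dyads=500, beta=beta)
    fits = fit_lmm_models(data, [{"name": "m", "fixed": MAIN_TERMS}],
                          random="intercepts")
    coef = fits["m"].coef
    for term, true in beta.items():
        est, se = coef.loc[term, "estimate"], coef.loc[term, "se"]
        assert est == pytest.approx(true, abs=4 * se)


def test_member_slot_symmetry():
    data = simulate_dyadic_data(17, n_members=25, n_dyads=200)
    swapped = data.copy()
    swapped["id_a"], swapped["id_b"] = data["id_b"], data["id_a"]
    f1 = fit_lmm_models(data, [{"name": "m", "fixed": MAIN_TERMS}], random="intercepts")["m"]
    f2 = fit_lmm_models(swapped, [{"name": "m", "fixed": MAIN_TERMS}], random="intercepts")["m"]
    assert np.allclose(f1.coef["estimate"], f2.coef["estimate"], atol=1e-6)


def test_reduce_and_report_shape():
    data = simulate_dyadic_data(5, n_members=30, n_dyads=250, beta={"aged": 0.2})
    rep = lmm.reduce_and_report(data, random="intercepts")
    assert rep["full_vs_null"].df == 11
    assert rep["threeway"].df == 2
    assert {b.df for b in rep["twoway"].values()} == {1, 2}
    assert set(rep["main"]) == {"rel", "aged", "gm"}
    assert rep["main"]["gm"].df == 2
    assert rep["reduced_fit"].reml
    assert set(rep["gm_contrasts"]) == {
        "same_group_same_matriline vs diff_group_diff_matriline",
        "same_group_diff_matriline vs diff_group_diff_matriline",
        "same_group_diff_matriline vs same_group_same_matriline",
    }
    for c in rep["gm_contrasts"].values():
        assert c["lrt"].df == 1
        assert np.isfinite(c["estimate"]) and c["se"] > 0


def test_unrelated_only_bookkeeping():
    data = simulate_dyadic_data(9, n_members=30, n_dyads=300, beta={"aged": 0.2})
    rep = lmm.unrelated_only(data, random="intercepts")
    assert rep["n_dyads"] == (data["kin_class"] == "nonkin").sum()
    assert rep["interaction"].df == 2
    assert rep["gm"].df == 2
    assert rep["aged"].df == 1


def test_leave_one_subject_out_stability():
    data = simulate_dyadic_data(23, n_members=20, n_dyads=190)
    subjects = sorted(set(data["id_a"]))[:3]
    table = lmm.leave_one_subject_out(data, fixed=["rel", "aged"],
                                      random="intercepts", subjects=subjects)
    assert table.shape[0] == 3
    base = fit_lmm_models(data, [{"name": "m", "fixed": ["rel", "aged"]}],
                          random="intercepts")["m"].coef["estimate"]
    # homogeneous simulated data: no subject shifts any estimate drastically
    assert (table.max() - table.min()).abs().max() < 5 * base.abs().max() + 0.5


def test_slot_randomization_invariance():
    data = simulate_dyadic_data(29, n_members=20, n_dyads=150)
    table = lmm.slot_randomization(data, fixed=["rel", "aged"],
                                   random="intercepts", k=3, seed=1)
    spread = table.max() - table.min()
    assert (spread.abs() < 0.05).all()


def test_fit_lrt_replicates_frame():
    frames = []
    for rep in range(4):
        d = simulate_dyadic_data(100 + rep, n_members=20, n_dyads=120)
        d["rep"] = rep
        frames.append(d)
    stacked = pd.concat(frames, ignore_index=True)
    out = lmm.fit_lrt_replicates(stacked, MAIN_TERMS,
                                 [t for t in MAIN_TERMS if t != "rel"],
                                 random="intercepts")
    assert len(out) == 4
    assert (out["df"] == 1).all()
    assert out["chi_sq"].ge(0).all()
    assert out["p"].between(0, 1).all()
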