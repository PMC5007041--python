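"""Dyadic linear mixed model of acoustic distance.

The response for an unordered dyad (a, b) is the square root of its
pairwise DFA F-value.  Fixed effects are the z-transformed relatedness
coefficient, the two dummy variables of the three-level group-matrilineal
membership factor (reference: different group & different matriline), the
z-transformed square root of age difference, and every two- and three-way
product of these — eleven terms besides the intercept.  Both dyad members
enter as crossed random factors; the "slopes" structure adds one
independent variance component per fixed covariate to each factor (random
intercepts and slopes without intercept–slope correlations).

Model fitting is delegated to lme4 (lmer, nloptwrap/BOBYQA on the profiled
deviance) through an Rscript batch bridge; everything else — design
construction, transforms, the reduction procedure, likelihood-ratio tests,
stability diagnostics and generalized VIFs — lives here.  Likelihood-ratio
tests always compare ML fits; REML is used for reported coefficient tables.
"""

from __future__ import annotations

import json
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FULL_TERMS",
    "MAIN_TERMS",
    "TWOWAY_BLOCKS",
    "THREEWAY_TERMS",
    "LmmFit",
    "LrtResult",
    "DyadicMixedModel",
    "build_dyad_table",
    "dyad_design",
    "fit_lmm_models",
    "lrt",
    "reduce_and_report",
    "unrelated_only",
    "leave_one_subject_out",
    "slot_randomization",
    "gvif",
    "RBackendError",
]

GM_REFERENCE = "diff_group_diff_matriline"

MAIN_TERMS = ["rel", "d_ss", "d_sd", "aged"]
TWOWAY_BLOCKS = {
    "rel:gm": ["rel_d_ss", "rel_d_sd"],
    "rel:aged": ["rel_aged"],
    "gm:aged": ["d_ss_aged", "d_sd_aged"],
}
THREEWAY_TERMS = ["rel_d_ss_aged", "rel_d_sd_aged"]
FULL_TERMS = MAIN_TERMS + sum(TWOWAY_BLOCKS.values(), []) + THREEWAY_TERMS


class RBackendError(RuntimeError):
    pass


@dataclass
class LmmFit:
    """One fitted dyadic LMM."""

    name: str
    fixed_terms: list[str]
    loglik: float
    coef: pd.DataFrame            # index term, columns estimate/se/t
    varcomp: pd.Series
    sigma2: float
    reml: bool
    n_obs: int
    converged: bool = True
    singular: bool = False
    messages: list[str] = field(default_factory=list)

    @property
    def n_params_fixed(self) -> int:
        return len(self.fixed_terms) + 1  # + intercept


@dataclass
class LrtResult:
    chi_sq: float
    df: int
    p: float


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------


def _zscore(x: np.ndarray, what: str) -> np.ndarray:
    sd = np.std(x)
    if sd <= 0 or not np.isfinite(sd):
        raise ValueError(f"cannot z-transform constant column {what!r}; "
                         "the analysed dyads carry no variation in it")
    return (x - np.mean(x)) / sd


def dyad_design(df: pd.DataFrame, ref_level: str = GM_REFERENCE) -> pd.DataFrame:
    """Dummy and product columns for a dyad table, given the reference level.

    Expects ``rel_z``, ``aged_z`` and ``gm_level`` to be present; the two
    dummies always carry the canonical names d_ss / d_sd but indicate the
    two non-reference levels (in the fixed order same_group_same_matriline,
    same_group_diff_matriline, diff_group_diff_matriline minus the
    reference).
    """
    levels = ["same_group_same_matriline", "same_group_diff_matriline",
              "diff_group_diff_matriline"]
    if ref_level not in levels:
        raise ValueError(f"unknown gm reference level {ref_level!r}")
    non_ref = [lv for lv in levels if lv != ref_level]
    out = df.copy()
    out["d_ss"] = (df["gm_level"] == non_ref[0]).astype(float)
    out["d_sd"] = (df["gm_level"] == non_ref[1]).astype(float)
    out.attrs["dummy_levels"] = {"d_ss": non_ref[0], "d_sd": non_ref[1],
                                 "reference": ref_level}
    out["rel_d_ss"] = out["rel_z"] * out["d_ss"]
    out["rel_d_sd"] = out["rel_z"] * out["d_sd"]
    out["rel_aged"] = out["rel_z"] * out["aged_z"]
    out["d_ss_aged"] = out["d_ss"] * out["aged_z"]
    out["d_sd_aged"] = out["d_sd"] * out["aged_z"]
    out["rel_d_ss_aged"] = out["rel_z"] * out["d_ss"] * out["aged_z"]
    out["rel_d_sd_aged"] = out["rel_z"] * out["d_sd"] * out["aged_z"]
    out = out.rename(columns={"rel_z": "rel", "aged_z": "aged"})
    return out


def build_dyad_table(distance_matrix: pd.DataFrame, dyads: pd.DataFrame) -> pd.DataFrame:
    """Join acoustic distances onto analysed dyads and apply the transforms.

    Transforms, in order: y = sqrt(F); age difference is square-root
    transformed; relatedness and sqrt(age difference) are z-scored over the
    analysed dyads only.  Returns one row per kin/nonkin dyad with the full
    design (canonical member order id_a < id_b).
    """
    analysed = dyads[dyads["kin_class"].isin(["kin", "nonkin"])].copy()
    if analysed.empty:
        raise ValueError("no analysed (kin or nonkin) dyads")
    ids = set(distance_matrix.index.astype(str))
    missing = [
        (a, b) for a, b in zip(analysed["id_a"], analysed["id_b"])
        if a not in ids or b not in ids
    ]
    if missing:
        raise KeyError(f"dyads missing from the distance matrix: {missing[:5]}"
                       + ("..." if len(missing) > 5 else ""))
    dm = distance_matrix.copy()
    dm.index = dm.index.astype(str)
    dm.columns = dm.columns.astype(str)
    F = np.array([dm.loc[a, b] for a, b in zip(analysed["id_a"], analysed["id_b"])],
                 dtype=float)
    if (F < 0).any():
        raise ValueError("negative acoustic distances")
    analysed["F"] = F
    analysed["y"] = np.sqrt(F)
    analysed["rel_z"] = _zscore(analysed["r"].to_numpy(dtype=float), "relatedness")
    analysed["aged_z"] = _zscore(np.sqrt(analysed["age_diff"].to_numpy(dtype=float)),
                                 "sqrt(age difference)")
    return dyad_design(analysed)


# ---------------------------------------------------------------------------
# the R bridge
# ---------------------------------------------------------------------------


def _rscript_path() -> str:
    exe = shutil.which("Rscript")
    if exe is None:
        raise RBackendError("Rscript not found on PATH; the dyadic LMM backend needs R + lme4")
    return exe


def _backend_script() -> Path:
    return Path(resources.files("cookin") / "r" / "fit_lmm.R")


def _run_backend(data: pd.DataFrame, payload: dict, timeout: int = 3600) -> list[dict]:
    with tempfile.TemporaryDirectory(prefix="cookin_lmm_") as tmp:
        tmp = Path(tmp)
        data_csv = tmp / "data.csv"
        jobs_json = tmp / "jobs.json"
        out_json = tmp / "out.json"
        data.to_csv(data_csv, index=False)
        jobs_json.write_text(json.dumps(payload))
        cmd = [_rscript_path(), "--vanilla", str(_backend_script()),
               str(data_csv), str(jobs_json), str(out_json)]
        proc = subprocess.run(cmd, capture_output=True, text=True, timeout=timeout)
        if proc.returncode != 0 or not out_json.exists():
            raise RBackendError(f"lme4 backend failed:\n{proc.stderr[-4000:]}")
        return json.loads(out_json.read_text())


def _as_list(x) -> list:
    if x is None:
        return []
    return x if isinstance(x, list) else [x]


def fit_lmm_models(
    data: pd.DataFrame,
    models: list[dict],
    random: str = "slopes",
    random_cols: list[str] | None = None,
    response: str = "y",
) -> dict[str, LmmFit]:
    """Fit a batch of dyadic LMMs in one R session.

    Each model dict needs ``name`` and ``fixed`` (list of design columns)
    and may override ``reml`` (default False), ``random`` and
    ``random_cols``.  The random part defaults to intercept + independent
    slopes for every full-model covariate when ``random='slopes'``, or
    crossed intercepts only when ``random='intercepts'``.
    """
    default_rnd = FULL_TERMS if random_cols is None else random_cols
    payload = {
        "response": response,
        "id_a": "id_a",
        "id_b": "id_b",
        "models": [
            {
                "name": m["name"],
                "fixed": m["fixed"],
                "reml": bool(m.get("reml", False)),
                "random": m.get("random", random),
                "random_cols": m.get("random_cols", default_rnd),
            }
            for m in models
        ],
    }
    cols = {"id_a", "id_b", response}
    for m in payload["models"]:
        cols |= set(m["fixed"]) | set(m["random_cols"] or [])
    use = [c for c in data.columns if c in cols]
    raw = _run_backend(data[use], payload)

    fits: dict[str, LmmFit] = {}
    for res, m in zip(raw, payload["models"]):
        if not res.get("ok", False):
            raise RBackendError(f"model {res.get('name')}: {res.get('error')}")
        coef = pd.DataFrame(
            {
                "estimate": _as_list(res["estimate"]),
                "se": _as_list(res["se"]),
                "t": _as_list(res["t"]),
            },
            index=_as_list(res["coef_names"]),
        )
        varcomp = pd.Series(_as_list(res["vc_var"]), index=_as_list(res["vc_group"]),
                            dtype=float)
        varcomp = varcomp[~varcomp.index.str.startswith("Residual")]
        fits[res["name"]] = LmmFit(
            name=res["name"],
            fixed_terms=list(m["fixed"]),
            loglik=float(res["loglik"]),
            coef=coef,
            varcomp=varcomp,
            sigma2=float(res["sigma2"]),
            reml=bool(res["reml"]),
            n_obs=int(res["n_obs"]),
            converged=bool(res["converged"]),
            singular=bool(res["singular"]),
            messages=_as_list(res.get("messages")),
        )
    return fits


def fit_lrt_replicates(
    data: pd.DataFrame,
    full_fixed: list[str],
    reduced_fixed: list[str],
    rep_col: str = "rep",
    random: str = "intercepts",
    response: str = "y",
) -> pd.DataFrame:
    """Full-vs-reduced ML LRT per replicate subset (one R session).

    Returns a DataFrame with columns rep, chi_sq, df, p.
    """
    payload = {
        "response": response,
        "id_a": "id_a",
        "id_b": "id_b",
        "by_rep": rep_col,
        "models": [
            {"name": "full", "fixed": full_fixed, "reml": False,
             "random": random, "random_cols": full_fixed},
            {"name": "reduced", "fixed": reduced_fixed, "reml": False,
             "random": random, "random_cols": full_fixed},
        ],
    }
    cols = set(full_fixed) | {"id_a", "id_b", response, rep_col}
    raw = _run_backend(data[[c for c in data.columns if c in cols]], payload)
    by_name = {r["name"]: r for r in raw}
    ll_full = np.asarray(_as_list(by_name["full"]["loglik"]), dtype=float)
    ll_red = np.asarray(_as_list(by_name["reduced"]["loglik"]), dtype=float)
    df = len(full_fixed) - len(reduced_fixed)
    chi = np.clip(2.0 * (ll_full - ll_red), 0.0, None)
    return pd.DataFrame({
        "rep": _as_list(by_name["full"]["rep"]),
        "chi_sq": chi,
        "df": df,
        "p": stats.chi2.sf(chi, df),
    })


# ---------------------------------------------------------------------------
# estimator-style surface
# ---------------------------------------------------------------------------


class DyadicMixedModel:
    """Estimator-style wrapper around one dyadic LMM specification.

    Parameters
    ----------
    fixed : list of design-column names (default: the 11 full-model terms)
    random : "slopes" (intercept + independent slope per covariate, per
        member slot), "intercepts", or "none" (ordinary least squares)
    reml : report REML estimates (True) or ML (False)

    After ``fit(data)``: ``coef_``, ``varcomp_``, ``loglik_``, ``sigma2_``,
    ``converged_``, ``singular_``, ``n_obs_``.
    """

    def __init__(self, fixed: list[str] | None = None, random: str = "slopes",
                 reml: bool = False):
        self.fixed = fixed
        self.random = random
        self.reml = reml

    def get_params(self, deep: bool = True) -> dict:
        return {"fixed": self.fixed, "random": self.random, "reml": self.reml}

    def set_params(self, **kw) -> "DyadicMixedModel":
        for k, v in kw.items():
            setattr(self, k, v)
        return self

    def fit(self, data: pd.DataFrame, y=None) -> "DyadicMixedModel":
        fixed = list(self.fixed) if self.fixed is not None else list(FULL_TERMS)
        if self.random == "none":
            import statsmodels.api as sm

            X = sm.add_constant(data[fixed]) if fixed else pd.DataFrame(
                {"const": np.ones(len(data))}, index=data.index)
            ols = sm.OLS(data["y"], X).fit()
            self.coef_ = pd.DataFrame({
                "estimate": ols.params, "se": ols.bse, "t": ols.tvalues})
            self.varcomp_ = pd.Series(dtype=float)
            self.loglik_ = float(ols.llf)
            self.sigma2_ = float(ols.scale)
            self.converged_ = True
            self.singular_ = False
        else:
            fitres = fit_lmm_models(
                data, [{"name": "m", "fixed": fixed, "reml": self.reml}],
                random=self.random,
            )["m"]
            self.coef_ = fitres.coef
            self.varcomp_ = fitres.varcomp
            self.loglik_ = fitres.loglik
            self.sigma2_ = fitres.sigma2
            self.converged_ = fitres.converged
            self.singular_ = fitres.singular
        self.fixed_terms_ = fixed
        self.n_obs_ = len(data)
        return self

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        """Population-level prediction from the fixed effects."""
        beta = self.coef_["estimate"]
        out = np.full(len(data), beta.iloc[0])
        for term in self.fixed_terms_:
            key = [k for k in beta.index if k == term]
            if key:
                out = out + beta[key[0]] * data[term].to_numpy(dtype=float)
        return out


def lrt(fit_full: LmmFit, fit_reduced: LmmFit) -> LrtResult:
    """Likelihood-ratio test of two nested ML fits on the same rows."""
    if fit_full.reml or fit_reduced.reml:
        raise ValueError("LRTs require ML fits (reml=False)")
    if fit_full.n_obs != fit_reduced.n_obs:
        raise ValueError("fits use different numbers of rows")
    if not set(fit_reduced.fixed_terms) <= set(fit_full.fixed_terms):
        raise ValueError("models are not nested")
    df = fit_full.n_params_fixed - fit_reduced.n_params_fixed
    if df <= 0:
        raise ValueError("reduced model must have fewer fixed parameters")
    chi = max(0.0, 2.0 * (fit_full.loglik - fit_reduced.loglik))
    return LrtResult(chi_sq=chi, df=df, p=float(stats.chi2.sf(chi, df)))


# ---------------------------------------------------------------------------
# the reduction procedure
# ---------------------------------------------------------------------------


def reduce_and_report(
    data: pd.DataFrame,
    alpha: float = 0.05,
    random: str = "slopes",
    contrasts: bool = True,
    reml_tables: bool = True,
) -> dict:
    """Full-model test, interaction pruning, and main-effect inference.

    Procedure: (1) full vs intercept-only null LRT (df 11); (2) LRT of the
    three-way interaction (df 2); if non-significant, (3) LRT of each
    two-way block against the model with all two-ways; if all are
    non-significant, (4) main-effects model with per-term LRTs and,
    optionally, the three pairwise group-matrilineal contrasts by
    releveling and refitting.  All LRTs compare ML fits; coefficient tables
    come from REML refits when ``reml_tables``.
    """
    no3 = [t for t in FULL_TERMS if t not in THREEWAY_TERMS]
    jobs = [
        {"name": "full", "fixed": FULL_TERMS},
        {"name": "null", "fixed": []},
        {"name": "no3way", "fixed": no3},
    ]
    for block, terms in TWOWAY_BLOCKS.items():
        jobs.append({"name": f"no3way_drop_{block}",
                     "fixed": [t for t in no3 if t not in terms]})
    jobs.append({"name": "main", "fixed": MAIN_TERMS})
    for term in ("rel", "aged"):
        jobs.append({"name": f"main_drop_{term}",
                     "fixed": [t for t in MAIN_TERMS if t != term]})
    jobs.append({"name": "main_drop_gm",
                 "fixed": [t for t in MAIN_TERMS if t not in ("d_ss", "d_sd")]})
    if contrasts:
        jobs.append({"name": "main_drop_d_ss", "fixed": [t for t in MAIN_TERMS if t != "d_ss"]})
        jobs.append({"name": "main_drop_d_sd", "fixed": [t for t in MAIN_TERMS if t != "d_sd"]})
    if reml_tables:
        jobs.append({"name": "full_reml", "fixed": FULL_TERMS, "reml": True})
        jobs.append({"name": "main_reml", "fixed": MAIN_TERMS, "reml": True})

    if random == "matched":
        # random slopes follow each model family's own covariates (the
        # interaction-bearing models keep the full slope set; the reduced
        # family carries slopes for the main terms only)
        for job in jobs:
            job["random"] = "slopes"
            job["random_cols"] = (
                MAIN_TERMS if job["name"].startswith("main") else FULL_TERMS
            )
    fits = fit_lmm_models(data, jobs, random=random if random != "matched" else "slopes")

    report: dict = {"alpha": alpha, "random": random, "n_dyads": len(data)}
    report["full_vs_null"] = lrt(fits["full"], fits["null"])
    report["threeway"] = lrt(fits["full"], fits["no3way"])
    report["full_fit"] = fits["full_reml"] if reml_tables else fits["full"]

    report["twoway"] = {}
    for block in TWOWAY_BLOCKS:
        report["twoway"][block] = lrt(fits["no3way"], fits[f"no3way_drop_{block}"])
    report["threeway_ns"] = report["threeway"].p >= alpha
    report["twoway_ns"] = all(r.p >= alpha for r in report["twoway"].values())
    report["reduction_clean"] = report["threeway_ns"] and report["twoway_ns"]

    # main effects are always read off the main-effects model; whether the
    # textbook pruning path reached it cleanly is recorded above
    report["main"] = {}
    report["main"]["rel"] = lrt(fits["main"], fits["main_drop_rel"])
    report["main"]["aged"] = lrt(fits["main"], fits["main_drop_aged"])
    report["main"]["gm"] = lrt(fits["main"], fits["main_drop_gm"])
    report["reduced_fit"] = fits["main_reml"] if reml_tables else fits["main"]

    if contrasts:
        # third pairwise contrast needs a releveled design
        relev = dyad_design(
            data.rename(columns={"rel": "rel_z", "aged": "aged_z"}),
            ref_level="same_group_same_matriline",
        )
        jobs2 = [
            {"name": "relev_main", "fixed": MAIN_TERMS},
            {"name": "relev_drop_d_sd",
             "fixed": [t for t in MAIN_TERMS if t != "d_sd"]},
        ]
        if reml_tables:
            jobs2.append({"name": "relev_main_reml", "fixed": MAIN_TERMS, "reml": True})
        if random == "matched":
            fits2 = fit_lmm_models(relev, jobs2, random="slopes", random_cols=MAIN_TERMS)
        else:
            fits2 = fit_lmm_models(relev, jobs2, random=random)
        table_fit = fits["main_reml"] if reml_tables else fits["main"]
        relev_fit = fits2.get("relev_main_reml", fits2["relev_main"])
        ss_lv = "same_group_same_matriline"
        sd_lv = "same_group_diff_matriline"
        report["gm_contrasts"] = {
            f"{ss_lv} vs {GM_REFERENCE}": {
                "lrt": lrt(fits["main"], fits["main_drop_d_ss"]),
                "estimate": float(table_fit.coef.loc["d_ss", "estimate"]),
                "se": float(table_fit.coef.loc["d_ss", "se"]),
            },
            f"{sd_lv} vs {GM_REFERENCE}": {
                "lrt": lrt(fits["main"], fits["main_drop_d_sd"]),
                "estimate": float(table_fit.coef.loc["d_sd", "estimate"]),
                "se": float(table_fit.coef.loc["d_sd", "se"]),
            },
            f"{sd_lv} vs {ss_lv}": {
                "lrt": lrt(fits2["relev_main"], fits2["relev_drop_d_sd"]),
                "estimate": float(relev_fit.coef.loc["d_sd", "estimate"]),
                "se": float(relev_fit.coef.loc["d_sd", "se"]),
            },
        }
    return report


def main_effects_lrts(
    data: pd.DataFrame,
    random: str = "slopes",
    random_cols: list[str] | None = None,
) -> dict[str, LrtResult]:
    """Per-term LRTs from the main-effects (reduced) model.

    The random part carries an intercept and independent slopes for the
    reduced model's own covariates (kept identical between the full and
    dropped fits of every comparison, so the LRTs test fixed effects only).
    """
    rnd = list(random_cols) if random_cols is not None else list(MAIN_TERMS)
    jobs = [{"name": "main", "fixed": MAIN_TERMS}]
    for t in ("rel", "aged"):
        jobs.append({"name": f"drop_{t}", "fixed": [x for x in MAIN_TERMS if x != t]})
    jobs.append({"name": "drop_gm",
                 "fixed": [x for x in MAIN_TERMS if x not in ("d_ss", "d_sd")]})
    fits = fit_lmm_models(data, jobs, random=random, random_cols=rnd)
    return {
        "rel": lrt(fits["main"], fits["drop_rel"]),
        "aged": lrt(fits["main"], fits["drop_aged"]),
        "gm": lrt(fits["main"], fits["drop_gm"]),
    }


def unrelated_only(
    data: pd.DataFrame,
    alpha: float = 0.05,
    random: str = "slopes",
    min_rows: int = 30,
) -> dict:
    """Re-run the familiarity analysis on the r = 0 (nonkin) dyads only.

    Relatedness terms drop out; the model is gm dummies + age difference
    with their interaction, and the key LRT is the gm x age-difference
    interaction (df 2).
    """
    sub = data[data["kin_class"] == "nonkin"].copy()
    if len(sub) < min_rows:
        raise ValueError(f"only {len(sub)} nonkin dyads; need >= {min_rows}")
    fixed_full = ["d_ss", "d_sd", "aged", "d_ss_aged", "d_sd_aged"]
    fixed_noint = ["d_ss", "d_sd", "aged"]
    jobs = [
        {"name": "full", "fixed": fixed_full},
        {"name": "noint", "fixed": fixed_noint},
        {"name": "drop_gm", "fixed": ["aged"]},
        {"name": "drop_aged", "fixed": ["d_ss", "d_sd"]},
        {"name": "null", "fixed": []},
    ]
    fits = fit_lmm_models(data=sub, models=jobs, random=random, random_cols=fixed_full)
    report = {
        "n_dyads": len(sub),
        "interaction": lrt(fits["full"], fits["noint"]),
        "gm": lrt(fits["noint"], fits["drop_gm"]),
        "aged": lrt(fits["noint"], fits["drop_aged"]),
        "fit": fits["noint"],
    }
    return report


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


def leave_one_subject_out(
    data: pd.DataFrame,
    fixed: list[str] | None = None,
    random: str = "slopes",
    subjects: list[str] | None = None,
) -> pd.DataFrame:
    """Refit the model dropping all dyads of each subject in turn.

    Returns one row per dropped subject with the fixed-effect estimates;
    summary ranges against the all-data fit indicate influential subjects.
    """
    fixed = list(fixed) if fixed is not None else list(FULL_TERMS)
    if subjects is None:
        subjects = sorted(set(data["id_a"]) | set(data["id_b"]))
    rows = []
    for s in subjects:
        sub = data[(data["id_a"] != s) & (data["id_b"] != s)]
        fit = fit_lmm_models(sub, [{"name": "m", "fixed": fixed}],
                             random=random, random_cols=fixed)["m"]
        rows.append(pd.Series(fit.coef["estimate"].values,
                              index=fit.coef.index, name=s))
    return pd.DataFrame(rows)


def slot_randomization(
    data: pd.DataFrame,
    fixed: list[str] | None = None,
    random: str = "slopes",
    k: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Randomize which member occupies random-factor slot A vs B, refit.

    Fixed-effect estimates should be essentially invariant; the returned
    frame has one row of estimates per randomization.
    """
    fixed = list(fixed) if fixed is not None else list(FULL_TERMS)
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(k):
        swap = rng.random(len(data)) < 0.5
        d = data.copy()
        a = d["id_a"].to_numpy().copy()
        b = d["id_b"].to_numpy().copy()
        d["id_a"] = np.where(swap, b, a)
        d["id_b"] = np.where(swap, a, b)
        fit = fit_lmm_models(d, [{"name": "m", "fixed": fixed}],
                             random=random, random_cols=fixed)["m"]
        rows.append(pd.Series(fit.coef["estimate"].values, index=fit.coef.index,
                              name=f"rand{i}"))
    return pd.DataFrame(rows)


def gvif(data: pd.DataFrame, terms: list[str] | None = None) -> pd.Series:
    """Generalized variance inflation factors from a main-effects OLS design.

    The gm factor's two dummies form one term; values are reported as
    GVIF^(1/(2 df)) so they are comparable across terms of different df.
    """
    groups = {"rel": ["rel"], "gm": ["d_ss", "d_sd"], "aged": ["aged"]}
    if terms is not None:
        groups = {t: groups[t] for t in terms}
    cols = sum(groups.values(), [])
    X = data[cols].to_numpy(dtype=float)
    R = np.corrcoef(X, rowvar=False)
    det_R = np.linalg.det(R)
    out = {}
    for term, members in groups.items():
        i1 = [cols.index(c) for c in members]
        i2 = [i for i in range(len(cols)) if i not in i1]
        d1 = np.linalg.det(R[np.ix_(i1, i1)])
        d2 = np.linalg.det(R[np.ix_(i2, i2)]) if i2 else 1.0
        g = d1 * d2 / det_R
        out[term] = g ** (1.0 / (2.0 * len(members)))
    return pd.Series(out)
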