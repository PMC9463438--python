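"""Multilevel models of two-wave verbal ability and related estimators.

Implements the model roster of the analysis:

* a three-level random-intercept model (wave rows nested in persons nested
  in families) for the two-wave phenotype, with SES blocks, polygenic scores
  and ancestry PCs as fixed effects;
* a two-level conditional model of the Wave-3 score given the Wave-1 score;
* a G×E specification with mean-centered PGS × SES-summary products;
* a sibling fixed-effects (within-family) check for the PGS terms;
* likelihood-ratio tests between nested maximum-likelihood fits;
* a companion single-level OLS R² reported alongside every multilevel fit;
* the Falconer twin-correlation heritability descriptive.

Mixed models are estimated with :class:`statsmodels` ``MixedLM``: the family
intercept is the random-effect group level, the person intercept enters as a
variance component, and the residual variance is the wave-level term.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "ModelFit",
    "GxEFit",
    "LRTResult",
    "TwinSummary",
    "fit_lmm",
    "fit_gxe",
    "lrt",
    "ols_r2",
    "sibling_fe",
    "falconer_h2",
    "falconer_from_correlations",
    "conditional_wave3_frame",
]


class ConvergenceError(RuntimeError):
    """Mixed-model optimization failed after the configured restarts."""


@dataclass
class ModelFit:
    """Estimates from one model fit.

    ``varcomp`` holds the variance components on the variance scale, keyed by
    level name (``family`` / ``person`` / ``wave``); ``m2ll`` is −2 times the
    maximized log-likelihood; ``df_model`` counts all estimated parameters
    (fixed effects + variance parameters); ``ols_r2`` is the companion
    single-level least-squares R² on the same fixed-effect design.
    """

    params: pd.Series
    bse: pd.Series
    varcomp: dict
    m2ll: float
    df_model: int
    n_obs: int
    n_persons: int
    n_families: int
    ols_r2: float
    method: str
    converged: bool
    response: str = "pvt_score"
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "estimates": {k: float(v) for k, v in self.params.items()},
            "se": {k: float(v) for k, v in self.bse.items()},
            "varcomp": {k: float(v) for k, v in self.varcomp.items()},
            "m2ll": float(self.m2ll),
            "df_model": int(self.df_model),
            "n": {
                "obs": int(self.n_obs),
                "persons": int(self.n_persons),
                "families": int(self.n_families),
            },
            "ols_r2": float(self.ols_r2),
            "method": self.method,
            "converged": bool(self.converged),
            "response": self.response,
            "extra": self.extra,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelFit":
        return cls(
            params=pd.Series(d["estimates"]),
            bse=pd.Series(d["se"]),
            varcomp=d["varcomp"],
            m2ll=d["m2ll"],
            df_model=d["df_model"],
            n_obs=d["n"]["obs"],
            n_persons=d["n"]["persons"],
            n_families=d["n"]["families"],
            ols_r2=d["ols_r2"],
            method=d["method"],
            converged=d["converged"],
            response=d.get("response", "pvt_score"),
            extra=d.get("extra", {}),
        )


def _check_design(data: pd.DataFrame, cols) -> None:
    x = np.column_stack(
        [np.ones(len(data))] + [data[c].to_numpy(dtype=float) for c in cols]
    )
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        _, r = np.linalg.qr(x)
        diag = np.abs(np.diag(r))
        tol = diag.max() * 1e-10
        names = ["Intercept", *cols]
        bad = [names[i] for i in np.where(diag < tol)[0]]
        raise ValueError(f"singular design; collinear column(s): {bad}")


def ols_r2(data: pd.DataFrame, response: str, fixed) -> float:
    """Coefficient of determination of a single-level least-squares fit.

    Runs over the supplied rows (person-wave observations for the three-level
    models) with the same fixed-effect design as the companion multilevel
    model.
    """
    y = data[response].to_numpy(dtype=float)
    if len(y) < 2 or y.std(ddof=1) == 0:
        raise ValueError("zero response variance")
    x = sm.add_constant(data[list(fixed)].to_numpy(dtype=float), has_constant="add")
    return float(sm.OLS(y, x).fit().rsquared)


def _fit_mixed(model, reml=True, maxiter=200, restarts=3):
    methods = ["lbfgs", "bfgs", "powell"]
    last = None
    last_exc = None
    for attempt in range(restarts + 1):
        method = methods[min(attempt, len(methods) - 1)]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit(reml=reml, method=method, maxiter=maxiter)
            if res.converged:
                return res
            last = res
        except (np.linalg.LinAlgError, ValueError) as exc:  # pragma: no cover
            last_exc = exc
    if last is not None:
        return last  # boundary fits can report converged=False yet be usable
    raise ConvergenceError(f"mixed model failed to converge: {last_exc}")


def fit_lmm(
    data: pd.DataFrame,
    response: str,
    fixed,
    family_col: str = "family_id",
    person_col: str | None = "person_id",
    method: str = "reml",
) -> ModelFit:
    """Fit a random-intercept model with family (and optionally person) levels.

    With ``person_col`` given this is the three-level configuration: family
    random intercept, person variance component, wave-level residual. With
    ``person_col=None`` it is the two-level configuration (family intercept,
    person-level residual) used by the conditional Wave-3 model. ``method``
    is ``"reml"`` or ``"ml"``; fits that feed a likelihood-ratio test must
    use ML.

    Raises on singular designs (naming the collinear columns) and on
    persistent non-convergence.
    """
    fixed = list(fixed)
    if data[response].isna().any():
        raise ValueError("response contains missing values")
    if data[family_col].nunique() < 2:
        raise ValueError("need at least two families")
    if method not in ("reml", "ml"):
        raise ValueError("method must be 'reml' or 'ml'")
    _check_design(data, fixed)

    work = data[[response, family_col, *fixed]].copy()
    work[family_col] = data[family_col].astype(str)
    if person_col is not None:
        if data.groupby(family_col)[person_col].nunique().max() == 1:
            raise ValueError(
                "every family holds a single person: the person variance "
                "component is not identified; fit with person_col=None"
            )
        work["_person"] = data[person_col].astype(str)
    formula = f"{response} ~ " + (" + ".join(fixed) if fixed else "1")
    vc = {"person": "0 + C(_person)"} if person_col is not None else None
    model = smf.mixedlm(
        formula, work, groups=work[family_col], re_formula="1", vc_formula=vc
    )
    res = _fit_mixed(model, reml=(method == "reml"))

    varcomp = {"family": float(res.cov_re.iloc[0, 0])}
    if person_col is not None:
        varcomp["person"] = float(res.vcomp[0])
        varcomp["wave"] = float(res.scale)
    else:
        varcomp["person"] = float(res.scale)
    n_vpar = 1 + (1 if person_col is not None else 0) + 1  # family + vc + scale
    return ModelFit(
        params=res.fe_params.copy(),
        bse=res.bse_fe.copy(),
        varcomp=varcomp,
        m2ll=-2.0 * float(res.llf),
        df_model=len(res.fe_params) + n_vpar,
        n_obs=len(work),
        n_persons=int(data[person_col].nunique()) if person_col else len(work),
        n_families=int(data[family_col].nunique()),
        ols_r2=ols_r2(data, response, fixed) if fixed else float("nan"),
        method=method,
        converged=bool(res.converged),
        response=response,
    )


@dataclass
class LRTResult:
    statistic: float
    df: int
    pvalue: float

    def to_dict(self):
        return {
            "statistic": float(self.statistic),
            "df": int(self.df),
            "pvalue": float(self.pvalue),
        }


def lrt(fit_reduced: ModelFit, fit_full: ModelFit) -> LRTResult:
    """Likelihood-ratio test between nested maximum-likelihood fits.

    statistic = (−2LL reduced) − (−2LL full); df = difference in parameter
    counts; p from the chi-square upper tail.
    """
    if fit_reduced.method == "reml" or fit_full.method == "reml":
        if list(fit_reduced.params.index) != list(fit_full.params.index):
            raise ValueError(
                "REML likelihoods are not comparable across differing fixed effects; "
                "fit both models by ML"
            )
    stat = fit_reduced.m2ll - fit_full.m2ll
    df = fit_full.df_model - fit_reduced.df_model
    if stat < 0 or df < 0:
        raise ValueError(
            "nesting violation: the full model must not fit worse than the reduced model"
        )
    p = float(stats.chi2.sf(stat, df)) if df > 0 else (1.0 if stat == 0 else 0.0)
    return LRTResult(statistic=float(stat), df=int(df), pvalue=p)


@dataclass
class GxEFit:
    """Main-effects and interaction fits plus their likelihood-ratio test."""

    main: ModelFit
    interaction: ModelFit
    test: LRTResult


def fit_gxe(
    data: pd.DataFrame,
    response: str,
    pgs_cols,
    ses_col: str,
    controls=(),
    family_col: str = "family_id",
    person_col: str | None = "person_id",
) -> GxEFit:
    """G×E specification: PGS × SES-summary products added to main effects.

    The polygenic scores and the SES summary score are mean-centered before
    the products are formed, so main effects keep their at-the-mean
    interpretation. Both models are fit by ML and compared with a
    likelihood-ratio test with one df per product term.
    """
    pgs_cols = list(pgs_cols)
    work = data.copy()
    cen = {}
    for c in [*pgs_cols, ses_col]:
        cen[c] = work[c] - work[c].mean()
    prod_cols = []
    for c in pgs_cols:
        name = f"{c}_x_{ses_col}"
        work[name] = cen[c] * cen[ses_col]
        prod_cols.append(name)
    main_fixed = [*pgs_cols, ses_col, *controls]
    full_fixed = [*main_fixed, *prod_cols]
    main = fit_lmm(work, response, main_fixed, family_col, person_col, method="ml")
    inter = fit_lmm(work, response, full_fixed, family_col, person_col, method="ml")
    return GxEFit(main=main, interaction=inter, test=lrt(main, inter))


def sibling_fe(
    data: pd.DataFrame,
    response: str,
    predictors,
    family_col: str = "family_id",
    person_col: str = "person_id",
    sibtype_col: str = "sibship_type",
) -> ModelFit:
    """Within-family (sibling fixed-effects) estimator for person-level terms.

    Restricts to families with at least two distinct (non-MZ) siblings,
    demeans response and predictors within family, and fits least squares on
    the demeaned data with family-clustered standard errors. Family-constant
    predictors drop out by construction; a family whose siblings share
    identical predictor values contributes no information to that predictor.
    """
    predictors = list(predictors)
    work = data.copy()
    if sibtype_col in work.columns:
        work = work[work[sibtype_col] != "mz"]
    n_per_fam = work.groupby(family_col)[person_col].transform("nunique")
    work = work[n_per_fam >= 2]
    if work.empty:
        raise ValueError("no families with two or more non-MZ siblings")

    within_var = 0.0
    for c in predictors:
        within_var += work.groupby(family_col)[c].transform(
            lambda s: s - s.mean()
        ).pow(2).sum()
    if within_var <= 0:
        raise ValueError("no within-family variance in any predictor")

    grp = work.groupby(family_col)
    y = (work[response] - grp[response].transform("mean")).to_numpy(dtype=float)
    x = np.column_stack(
        [
            (work[c] - grp[c].transform("mean")).to_numpy(dtype=float)
            for c in predictors
        ]
    )
    keep = x.std(axis=0) > 0
    names = [c for c, k in zip(predictors, keep) if k]
    res = sm.OLS(y, x[:, keep]).fit(
        cov_type="cluster", cov_kwds={"groups": work[family_col].to_numpy()}
    )
    return ModelFit(
        params=pd.Series(res.params, index=names),
        bse=pd.Series(res.bse, index=names),
        varcomp={},
        m2ll=-2.0 * float(res.llf),
        df_model=int(res.df_model),
        n_obs=len(work),
        n_persons=int(work[person_col].nunique()),
        n_families=int(work[family_col].nunique()),
        ols_r2=float(res.rsquared),
        method="within-family OLS, cluster-robust",
        converged=True,
        response=response,
    )


# ---------------------------------------------------------------------------
# twins


@dataclass
class TwinSummary:
    n_mz_pairs: int
    n_dz_pairs: int
    r_mz: float
    r_dz: float
    h2: float

    def to_dict(self):
        return {
            "n_mz_pairs": self.n_mz_pairs,
            "n_dz_pairs": self.n_dz_pairs,
            "r_mz": float(self.r_mz),
            "r_dz": float(self.r_dz),
            "h2": float(self.h2),
        }


def falconer_from_correlations(r_mz: float, r_dz: float) -> float:
    """Falconer's formula h² = 2 (r_MZ − r_DZ), truncated to [0, 1]."""
    for r in (r_mz, r_dz):
        if not -1.0 <= r <= 1.0:
            raise ValueError("twin correlations must lie in [-1, 1]")
    return float(np.clip(2.0 * (r_mz - r_dz), 0.0, 1.0))


def _pair_correlation(scores_by_pair) -> float:
    a = np.array([s for s, _ in scores_by_pair] + [t for _, t in scores_by_pair])
    b = np.array([t for _, t in scores_by_pair] + [s for s, _ in scores_by_pair])
    return float(np.corrcoef(a, b)[0, 1])


def falconer_h2(
    cohort: pd.DataFrame,
    score_col: str = "pvt_score",
    wave_col: str = "wave",
    sibtype_col: str = "sibship_type",
    family_col: str = "family_id",
    person_col: str = "person_id",
) -> TwinSummary:
    """Twin-based heritability descriptive from MZ and DZ pairs.

    Scores are standardized within wave, averaged over waves per person, and
    within-pair Pearson correlations are computed with double-entry pairing.
    """
    work = cohort[[person_col, family_col, sibtype_col, wave_col, score_col]].dropna()
    z = work.groupby(wave_col)[score_col].transform(
        lambda s: (s - s.mean()) / s.std(ddof=1)
    )
    person_scores = (
        work.assign(_z=z)
        .groupby([person_col, family_col, sibtype_col])["_z"]
        .mean()
        .reset_index()
    )
    pairs = {}
    for zyg in ("mz", "dz"):
        sub = person_scores[person_scores[sibtype_col] == zyg]
        plist = []
        for _, fam in sub.groupby(family_col):
            if len(fam) == 2:
                plist.append(tuple(fam["_z"].to_numpy()))
        pairs[zyg] = plist
        if len(plist) < 2:
            raise ValueError(f"need at least 2 {zyg.upper()} pairs, got {len(plist)}")
    r_mz = _pair_correlation(pairs["mz"])
    r_dz = _pair_correlation(pairs["dz"])
    return TwinSummary(
        n_mz_pairs=len(pairs["mz"]),
        n_dz_pairs=len(pairs["dz"]),
        r_mz=r_mz,
        r_dz=r_dz,
        h2=falconer_from_correlations(r_mz, r_dz),
    )


# ---------------------------------------------------------------------------
# conditional Wave-3 frame


def conditional_wave3_frame(
    data: pd.DataFrame,
    response: str = "pvt_score",
    wave_col: str = "wave",
    person_col: str = "person_id",
) -> pd.DataFrame:
    """One row per person with both wave scores, for the conditional model.

    Persons lacking either wave's score are excluded (the conditional model
    requires two phenotype measures). Covariates are taken from the Wave-3
    row; the Wave-1 score is added as ``pvt_w1``.
    """
    w1 = data[data[wave_col] == 1].set_index(person_col)[response]
    w3 = data[data[wave_col] == 3].set_index(person_col)
    both = w3.index.intersection(w1.index)
    out = w3.loc[both].reset_index()
    out["pvt_w1"] = w1.loc[both].to_numpy()
    return out
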