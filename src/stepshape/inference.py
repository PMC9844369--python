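"""Block-level mixed-effects inference.

Each outcome measure (clearing height, RQA measures, dispersion measures,
...) is summarised per participant x step-height condition x block and fit
with a linear mixed-effects model: fixed effects for the step-height
condition, the block index within condition, and their interaction (all
numeric covariates), plus a random intercept per participant.  Fixed-effect
t statistics use the residual-degrees-of-freedom convention
df = n_rows − n_fixed_effects, which reproduces the study design's t(30)
for 34 analysable blocks and 4 coefficients.  The per-block binary jump
indicator is fit with a random-intercept logistic model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "FitResult",
    "FIXED_EFFECTS",
    "residual_df",
    "build_block_table",
    "fit_lmm",
    "fit_binomial_glmm",
    "assemble_results",
]

FIXED_EFFECTS = ["Intercept", "step_height", "block", "step_height:block"]


@dataclass
class FitResult:
    response: str
    terms: pd.DataFrame  # index = fixed effect; columns beta, se, t, df, p
    r2: float | None
    converged: bool
    method: str = "lmm"
    notes: list = field(default_factory=list)


def residual_df(n_rows: int, n_fixed: int = 4) -> int:
    """Residual-degrees-of-freedom convention for fixed-effect t-tests."""
    return n_rows - n_fixed


def build_block_table(measure_rows: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long measures table into one row per participant x condition x block.

    Expects columns (participant, step_height, block, analysis, measure,
    value); measure columns become ``analysis_measure``.  The step-height
    condition is coded numerically 1, 2, ... in ascending height order, and
    block runs 1..B within condition.  Missing blocks are simply absent
    rows (never imputed).
    """
    df = measure_rows.copy()
    heights = sorted(df["step_height"].unique())
    df["condition"] = df["step_height"].map({h: i + 1 for i, h in enumerate(heights)})
    df["colname"] = df["analysis"].astype(str) + "_" + df["measure"].astype(str)
    wide = df.pivot_table(
        index=["participant", "condition", "block"],
        columns="colname",
        values="value",
        aggfunc="first",
    ).reset_index()
    wide.columns.name = None
    return wide


def _design(table: pd.DataFrame) -> pd.DataFrame:
    d = table.copy()
    d["step_height"] = d["condition"].astype(float)
    d["interaction"] = d["step_height"] * d["block"].astype(float)
    return d


def fit_lmm(table: pd.DataFrame, response: str, alpha: float = 0.05) -> FitResult:
    """Random-intercept linear mixed model of one block-level measure.

    Fixed effects: intercept, step-height condition (numeric), block within
    condition (numeric), and their interaction.  p-values come from a t
    distribution with residual df = n − 4.
    """
    if response not in table.columns:
        raise KeyError(f"missing measure column: {response}")
    d = _design(table).dropna(subset=[response])
    if d["participant"].nunique() < 2 or d["block"].nunique() < 2:
        raise ValueError("need at least 2 participants and 2 blocks")
    y = d[response].to_numpy(float)
    df_resid = residual_df(len(d))
    notes: list = []

    if np.ptp(y) == 0:
        terms = pd.DataFrame(
            {"beta": [y[0], 0.0, 0.0, 0.0], "se": np.nan, "t": np.nan,
             "df": df_resid, "p": np.nan},
            index=FIXED_EFFECTS,
        )
        return FitResult(response, terms, r2=None, converged=True,
                         notes=["constant response; slopes degenerate, R2 undefined"])

    model = smf.mixedlm(
        f"Q('{response}') ~ step_height + block + interaction",
        data=d,
        groups=d["participant"],
    )
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = model.fit(reml=True, method=["lbfgs", "powell"])
            converged = bool(fit.converged)
        except Exception as exc:  # singular fits on degenerate inputs
            notes.append(f"mixed model failed ({exc}); OLS fallback")
            fit = None
            converged = False

    if fit is not None:
        names = ["Intercept", "step_height", "block", "interaction"]
        beta = np.array([fit.params[n] for n in names])
        se = np.array([fit.bse[n] for n in names])
        # statsmodels' fittedvalues are conditional on the random effects,
        # so R^2 below reflects the full (fixed + random) model
        fitted = np.asarray(fit.fittedvalues)
    else:
        X = sm.add_constant(d[["step_height", "block", "interaction"]].to_numpy(float))
        ols = sm.OLS(y, X).fit()
        beta, se = ols.params, ols.bse
        fitted = ols.fittedvalues

    tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals), df_resid)
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else None
    terms = pd.DataFrame(
        {"beta": beta, "se": se, "t": tvals, "df": df_resid, "p": pvals,
         "significant": pvals < alpha},
        index=FIXED_EFFECTS,
    )
    return FitResult(response, terms, r2=r2, converged=converged, notes=notes)


def fit_binomial_glmm(table: pd.DataFrame, response: str = "jump",
                      alpha: float = 0.05) -> FitResult:
    """Random-intercept logistic model of the per-block jump indicator.

    Fit by variational Bayes (statsmodels BinomialBayesMixedGLM); the
    posterior mean/SD of each fixed effect is reported as beta/se with a
    normal z-test.  An all-zero or all-one indicator carries no slope
    information; the result is flagged accordingly.
    """
    d = _design(table).dropna(subset=[response])
    y = d[response].to_numpy(float)
    notes: list = []
    if np.ptp(y) == 0:
        terms = pd.DataFrame(
            {"beta": np.nan, "se": np.nan, "t": np.nan, "df": np.nan, "p": np.nan},
            index=FIXED_EFFECTS,
        )
        return FitResult(response, terms, r2=None, converged=False, method="binomial_glmm",
                         notes=["degenerate indicator: no variation in outcome"])
    exog = sm.add_constant(d[["step_height", "block", "interaction"]].to_numpy(float))
    ident = np.zeros(1, dtype=int)
    exog_vc = d["participant"].astype("category").cat.codes.to_numpy()
    vc_mat = (exog_vc[:, None] == np.arange(exog_vc.max() + 1)[None, :]).astype(float)
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = sm.BinomialBayesMixedGLM(y, exog, vc_mat, ident)
            fit = model.fit_vb()
            beta = fit.fe_mean
            se = fit.fe_sd
        except Exception as exc:
            notes.append(f"variational GLMM failed ({exc}); plain GLM fallback")
            converged = False
            glm = sm.GLM(y, exog, family=sm.families.Binomial()).fit()
            beta, se = glm.params, glm.bse
    z = beta / se
    p = 2 * stats.norm.sf(np.abs(z))
    if np.any(np.abs(beta) > 15):
        notes.append("possible complete separation: extreme coefficients")
        converged = False
    terms = pd.DataFrame(
        {"beta": beta, "se": se, "t": z, "df": np.nan, "p": p, "significant": p < alpha},
        index=FIXED_EFFECTS,
    )
    return FitResult(response, terms, r2=None, converged=converged,
                     method="binomial_glmm", notes=notes)


def assemble_results(block_table: pd.DataFrame,
                     measures: list[str] | None = None,
                     jump_column: str | None = None,
                     alpha: float = 0.05) -> dict:
    """One FitResult per measure plus a tidy coefficient table.

    Returns ``{"fits": {measure: FitResult}, "coefficients": DataFrame,
    "descriptives": DataFrame, "notices": [...]}`` with deterministic
    ordering.
    """
    id_cols = {"participant", "condition", "block", "step_height", "interaction"}
    if measures is None:
        measures = [c for c in block_table.columns
                    if c not in id_cols and c != jump_column]
    notices: list[str] = []
    fits: dict[str, FitResult] = {}
    rows = []
    for m in sorted(measures):
        if m not in block_table.columns:
            raise KeyError(f"missing measure column: {m}")
        if block_table[m].dropna().empty:
            notices.append(f"measure {m} has no data; fit skipped")
            continue
        res = fit_lmm(block_table, m, alpha)
        fits[m] = res
        t = res.terms.reset_index(names="term")
        t.insert(0, "measure", m)
        t.insert(1, "r2", res.r2)
        rows.append(t)
    if jump_column is not None and jump_column in block_table.columns:
        res = fit_binomial_glmm(block_table, jump_column, alpha)
        fits[jump_column] = res
        t = res.terms.reset_index(names="term")
        t.insert(0, "measure", jump_column)
        t.insert(1, "r2", np.nan)
        rows.append(t)
    coef = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
    desc = (
        block_table.groupby(["condition", "block"], as_index=False)
        .mean(numeric_only=True)
        .drop(columns=[c for c in ("interaction",) if c in block_table.columns],
              errors="ignore")
    )
    return {"fits": fits, "coefficients": coef, "descriptives": desc, "notices": notices}
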