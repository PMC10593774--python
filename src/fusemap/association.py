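"""Sex-stratified linear association models with effect sizes and Bonferroni
multiplicity control.

Each model regresses an embedding score (or its longitudinal change) on one
predictor of interest plus covariates of no interest (age / delta-age, site),
within one sex stratum, via OLS; the predictor's unstandardized coefficient,
two-sided p value and partial eta-squared are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

__all__ = [
    "ModelSpec",
    "AssociationResult",
    "fit_linear_model",
    "partial_eta_squared",
    "bonferroni_threshold",
    "run_model_set",
]


@dataclass
class ModelSpec:
    """One stratified linear model: dv ~ iv + covariates within `stratum`."""

    dv: str
    iv: str
    covariates: list = field(default_factory=list)
    stratum: str | None = None  # value of the 'sex' column, or None for all
    family_size: int = 1
    interaction: str | None = None  # optional second IV for iv:other interaction
    categorical: tuple = ("site",)


@dataclass
class AssociationResult:
    b: float
    p: float
    eta_sq_partial: float
    n: int
    passed_bonferroni: bool
    alpha_adjusted: float


def partial_eta_squared(t_stat: float, df_residual: float) -> float:
    """t^2 / (t^2 + df_residual); equals SS_effect / (SS_effect + SS_resid)
    for a single added-last predictor."""
    if df_residual < 1:
        raise ValueError("df_residual must be >= 1")
    t2 = float(t_stat) ** 2
    return t2 / (t2 + float(df_residual))


def bonferroni_threshold(alpha_family: float, m: int) -> float:
    """Family-wise adjusted per-test alpha = alpha / m."""
    if m < 1:
        raise ValueError("family size m must be >= 1")
    return alpha_family / m


def _term(name: str, categorical) -> str:
    return f"C({name})" if name in categorical else name


def fit_linear_model(spec: ModelSpec, data: pd.DataFrame, alpha_family: float = 0.05) -> AssociationResult:
    """OLS fit of one ModelSpec with listwise deletion.

    Raises on < 10 usable observations or a rank-deficient design.
    """
    df = data
    if spec.stratum is not None:
        df = df[df["sex"].astype(str).str.lower() == str(spec.stratum).lower()]
    used = [spec.dv, spec.iv, *spec.covariates]
    if spec.interaction:
        used.append(spec.interaction)
    missing_cols = [c for c in used if c not in df.columns]
    if missing_cols:
        raise ValueError(f"columns not in data: {missing_cols}")
    df = df.dropna(subset=used)
    n = len(df)
    if n < 10:
        raise ValueError(f"only {n} observations after listwise deletion (< 10)")

    rhs = [spec.iv] + [_term(c, spec.categorical) for c in spec.covariates]
    if spec.interaction:
        rhs += [spec.interaction, f"{spec.iv}:{spec.interaction}"]
    formula = f"{spec.dv} ~ " + " + ".join(rhs)
    res = smf.ols(formula, data=df).fit()

    rank = np.linalg.matrix_rank(res.model.exog)
    if rank < res.model.exog.shape[1]:
        names = res.model.exog_names
        aliased = [names[i] for i in range(len(names)) if np.all(res.model.exog[:, i] == 0)]
        raise ValueError(f"rank-deficient design matrix (aliased: {aliased or 'collinear terms'})")

    b = float(res.params[spec.iv])
    p = float(res.pvalues[spec.iv])
    t = float(res.tvalues[spec.iv])
    eta = partial_eta_squared(t, res.df_resid)
    alpha_adj = bonferroni_threshold(alpha_family, spec.family_size)
    return AssociationResult(
        b=b, p=p, eta_sq_partial=eta, n=n,
        passed_bonferroni=bool(p < alpha_adj), alpha_adjusted=alpha_adj,
    )


def run_model_set(specs: list[ModelSpec], data: pd.DataFrame, alpha_family: float = 0.05) -> pd.DataFrame:
    """Fit a family of models and return a tidy one-row-per-model table."""
    rows = []
    for spec in specs:
        res = fit_linear_model(spec, data, alpha_family)
        rows.append(
            {
                "dv": spec.dv,
                "iv": spec.iv,
                "covariates": "+".join(spec.covariates),
                "stratum": spec.stratum,
                "b": res.b,
                "p": res.p,
                "eta_sq_partial": res.eta_sq_partial,
                "n": res.n,
                "alpha_adjusted": res.alpha_adjusted,
                "passed_bonferroni": res.passed_bonferroni,
            }
        )
    return pd.DataFrame(rows)
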