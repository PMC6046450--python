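"""Gaussian random-intercept mixed models with backward elimination.

Repeated measures on the same birds inside shared nests call for random
intercepts on bird and nest identity.  Fitting is restricted maximum
likelihood via statsmodels MixedLM; crossed random factors are encoded
as variance components on a single all-encompassing group.  Backward
elimination drops the fixed term with the largest Wald p >= 0.05, one
per step; random effects are never eliminated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm


class ModelConvergenceError(RuntimeError):
    """Raised when REML fitting fails to converge, with diagnostics attached."""


@dataclass
class ModelFit:
    formula: str
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    group_variances: dict[str, float]
    residual_variance: float
    n: int
    reml_criterion: float
    term_pvalues: dict[str, float] = field(default_factory=dict)
    dropped_terms: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "formula": self.formula,
            "estimates": self.params.to_dict(),
            "std_errors": self.bse.to_dict(),
            "t_values": self.tvalues.to_dict(),
            "p_values": self.pvalues.to_dict(),
            "term_p_values": self.term_pvalues,
            "group_variances": self.group_variances,
            "residual_variance": self.residual_variance,
            "n": self.n,
            "reml_criterion": self.reml_criterion,
            "dropped_terms": self.dropped_terms,
        }


def _fit_once(data: pd.DataFrame, response: str, fixed: list[str], groups: list[str]) -> tuple:
    formula = f"{response} ~ " + (" + ".join(fixed) if fixed else "1")
    if len(groups) == 1:
        model = sm.MixedLM.from_formula(formula, data=data, groups=data[groups[0]])
    else:
        model = sm.MixedLM.from_formula(
            formula,
            data=data,
            groups=np.ones(len(data)),
            re_formula="0",
            vc_formula={g: f"0 + C({g})" for g in groups},
        )
    # optimizers disagree near the variance boundary (lbfgs can report
    # convergence on a degenerate fit): keep the best-likelihood converged fit
    candidates = []
    errors = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("lbfgs", "powell", "cg"):
            try:
                fit = model.fit(reml=True, method=method, maxiter=2000)
            except (np.linalg.LinAlgError, ValueError) as exc:
                errors.append(f"{method}: {exc}")
                continue
            llf = float(fit.llf) if np.isfinite(fit.llf) else -np.inf
            ok = bool(getattr(fit, "converged", True)) and np.isfinite(fit.fe_params).all()
            candidates.append((ok, llf, fit))
            if not ok:
                errors.append(f"{method}: not converged")
    converged = [(llf, fit) for ok, llf, fit in candidates if ok]
    if not converged:
        raise ModelConvergenceError(
            f"REML did not converge for {formula!r} (n={len(data)}, groups={groups}): {errors}"
        )
    result = max(converged, key=lambda t: t[0])[1]
    return model, result, formula


def _term_columns(model, term: str) -> list[int]:
    design_info = model.data.design_info
    for name, sl in design_info.term_name_slices.items():
        if name == term or name == f"C({term})":
            return list(range(sl.start, sl.stop))
    raise KeyError(f"term {term!r} not in design: {list(design_info.term_name_slices)}")


def _term_pvalue(model, result, term: str) -> float:
    cols = _term_columns(model, term)
    k_fe = len(result.fe_params)
    if len(cols) == 1:
        return float(result.pvalues.iloc[cols[0]])
    contrast = np.zeros((len(cols), len(result.params)))
    for row, col in enumerate(cols):
        contrast[row, col] = 1.0
    return float(np.squeeze(result.wald_test(contrast[:, :k_fe], scalar=True).pvalue)) if k_fe else 1.0


def fit_random_intercept_model(
    data: pd.DataFrame,
    response: str,
    fixed: list[str],
    groups: list[str],
    backward: bool = False,
    alpha: float = 0.05,
) -> ModelFit:
    """Fit response ~ fixed effects + random intercept per grouping factor.

    With ``backward=True``, non-significant fixed terms (Wald p >= alpha)
    are removed one at a time, largest p first, to reach the minimal
    model.  Returns fixed-effect estimates with Wald t/p, per-factor
    random-intercept variances, and the residual variance.
    """
    data = data.dropna(subset=[response] + [c for c in fixed if c in data.columns]).copy()
    if len(data) <= len(fixed) + 2:
        raise ValueError("too few observations for the requested fixed effects")
    remaining = list(fixed)
    dropped: list[str] = []
    while True:
        model, result, formula = _fit_once(data, response, remaining, groups)
        term_p = {t: _term_pvalue(model, result, t) for t in remaining}
        if not backward or not remaining:
            break
        worst = max(term_p, key=term_p.get)
        if term_p[worst] < alpha:
            break
        remaining.remove(worst)
        dropped.append(worst)

    k_fe = len(result.fe_params)
    if len(groups) == 1:
        group_vars = {groups[0]: float(result.cov_re.iloc[0, 0])}
    else:
        names = result.model.exog_vc.names
        group_vars = {name: float(v) for name, v in zip(names, result.vcomp)}
    return ModelFit(
        formula=formula,
        params=result.fe_params,
        bse=result.bse.iloc[:k_fe],
        tvalues=result.tvalues.iloc[:k_fe],
        pvalues=result.pvalues.iloc[:k_fe],
        group_variances=group_vars,
        residual_variance=float(result.scale),
        n=len(data),
        reml_criterion=float(result.llf),
        term_pvalues=term_p,
        dropped_terms=dropped,
    )
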