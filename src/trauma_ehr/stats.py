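"""Exposure–outcome statistics: contingency tables, Pearson chi-square,
2×2 odds ratios with Woolf confidence intervals, and covariate-adjusted
logistic regression.

Conventions follow the classical epidemiological presentation of a cohort
cross-tabulated against a binary exposure: chi-square tests are uncorrected
Pearson (no Yates continuity correction), "Unknown" categories are retained
as rows by default, and no multiple-testing adjustment is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

Z95 = sps.norm.ppf(0.975)  # 1.959964...


@dataclass
class ContingencyTable:
    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-dimensional")
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("labels do not match counts shape")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if min(self.counts.shape) < 2:
            raise ValueError("degenerate table: need at least 2 rows and 2 columns")


@dataclass
class EffectEstimate:
    measure: str  # "OR" or "chi_square"
    point: float
    ci_low: float | None = None
    ci_high: float | None = None
    df: int | None = None
    p_value: float | None = None
    adjusted: bool = False
    covariates: list[str] = field(default_factory=list)
    converged: bool | None = None


def build_table(
    cohort: pd.DataFrame,
    variable: str,
    exposure: str = "csa",
    categories: list[str] | None = None,
    drop_unknown: bool = False,
) -> ContingencyTable:
    """Cross-tabulate a categorical variable against the binary exposure.

    ``Unknown`` categories are kept as ordinary rows unless ``drop_unknown``
    is set (matching reports that re-test distributions with unknowns
    removed).
    """
    if variable not in cohort.columns:
        raise KeyError(f"variable {variable!r} not in cohort")
    df = cohort
    if drop_unknown:
        df = df[df[variable] != "Unknown"]
    exp = df[exposure].astype(bool).map({False: "no_csa", True: "csa"})
    tab = pd.crosstab(df[variable], exp).reindex(columns=["no_csa", "csa"], fill_value=0)
    if categories is not None:
        keep = [c for c in categories if c in tab.index]
        tab = tab.reindex(keep)
    return ContingencyTable(
        row_labels=[str(r) for r in tab.index],
        col_labels=["no_csa", "csa"],
        counts=tab.to_numpy(),
    )


def pearson_chi_square(table: ContingencyTable) -> EffectEstimate:
    """Uncorrected Pearson chi-square test of independence.

    X² = Σ (O−E)²/E with expected counts from the product of margins;
    df = (r−1)(c−1).  Zero margins make the test undefined and raise.
    """
    counts = table.counts
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("zero margin: chi-square undefined")
    chi2, p, dof, _ = sps.chi2_contingency(counts, correction=False)
    return EffectEstimate(
        measure="chi_square", point=float(chi2), df=int(dof), p_value=float(p)
    )


def odds_ratio_2x2(a: float, b: float, c: float, d: float) -> EffectEstimate:
    """Odds ratio for outcome-in-exposed vs outcome-in-unexposed.

    Cell layout: a = unexposed without outcome, b = unexposed with outcome,
    c = exposed without outcome, d = exposed with outcome, so
    OR = (d/c)/(b/a) = ad/bc.  The 95% CI is Woolf's log-normal interval,
    exp(ln OR ± 1.96·sqrt(1/a+1/b+1/c+1/d)).  Zero cells get the standard
    0.5 continuity add, with a warning.
    """
    cells = np.array([a, b, c, d], dtype=float)
    if (cells < 0).any():
        raise ValueError("counts must be non-negative")
    if (cells == 0).any():
        warnings.warn("zero cell: adding 0.5 to every cell (Haldane-Anscombe)", stacklevel=2)
        cells = cells + 0.5
    a, b, c, d = cells
    log_or = np.log(a * d / (b * c))
    se = np.sqrt((1 / cells).sum())
    return EffectEstimate(
        measure="OR",
        point=float(np.exp(log_or)),
        ci_low=float(np.exp(log_or - Z95 * se)),
        ci_high=float(np.exp(log_or + Z95 * se)),
        p_value=float(2 * sps.norm.sf(abs(log_or / se))),
    )


def odds_ratio_from_proportions(
    p_unexposed: float,
    p_exposed: float,
    n_unexposed: int | None = None,
    n_exposed: int | None = None,
) -> EffectEstimate:
    """Odds ratio from outcome proportions in each exposure group.

    The point estimate is the exact odds ratio of the two proportions.  When
    group sizes are supplied, counts are reconstructed as ``round(p·n)`` to
    attach a Woolf confidence interval; reconstruction from rounded published
    percentages can shift the point estimate by ~0.01–0.02, so the
    proportion-exact point estimate is always reported.
    """
    for p in (p_unexposed, p_exposed):
        if not 0 < p < 1:
            raise ValueError("proportions must be in (0, 1)")
    point = (p_exposed / (1 - p_exposed)) / (p_unexposed / (1 - p_unexposed))
    est = EffectEstimate(measure="OR", point=float(point))
    if n_unexposed is not None and n_exposed is not None:
        b = round(p_unexposed * n_unexposed)
        d = round(p_exposed * n_exposed)
        ci = odds_ratio_2x2(n_unexposed - b, b, n_exposed - d, d)
        est.ci_low, est.ci_high, est.p_value = ci.ci_low, ci.ci_high, ci.p_value
    return est


class SeparationError(RuntimeError):
    """Raised when a logistic fit fails to converge (e.g. perfect separation)."""


def fit_logistic(
    data: pd.DataFrame,
    outcome: str,
    exposure: str = "csa",
    covariates: list[str] | None = None,
    reference_levels: dict[str, str] | None = None,
) -> EffectEstimate:
    """Maximum-likelihood logistic regression; returns the exposure OR.

    Categorical covariates are dummy-expanded against a stated reference
    level (defaults: sex=M, ethnicity=White).  The returned estimate carries
    exp(beta) for the exposure with its Wald 95% CI.  Non-convergence or
    (quasi-)separation raises ``SeparationError`` rather than returning a
    silent result.
    """
    covariates = list(covariates or [])
    refs = {"sex": "M", "ethnicity": "White"}
    refs.update(reference_levels or {})

    y = data[outcome].astype(float)
    X = pd.DataFrame({exposure: data[exposure].astype(float)}, index=data.index)
    for cov in covariates:
        col = data[cov]
        if col.dtype.kind in "biufc":
            X[cov] = col.astype(float)
        else:
            ref = refs.get(cov, sorted(col.astype(str).unique())[0])
            dummies = pd.get_dummies(col.astype(str), prefix=cov, dtype=float)
            X = pd.concat([X, dummies.drop(columns=[f"{cov}_{ref}"], errors="ignore")], axis=1)
    X = sm.add_constant(X, has_constant="add")

    # IRLS (GLM/Binomial) is robust to quasi-separation in sparse nuisance
    # dummies, where straight Newton on the logit likelihood stalls
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
    except Exception as err:  # separation or numerical failure
        raise SeparationError(f"logistic fit failed: {err}") from err
    if not getattr(res, "converged", True):
        raise SeparationError("logistic fit did not converge")

    beta = float(res.params[exposure])
    se = float(res.bse[exposure])
    if not np.isfinite(beta) or not np.isfinite(se) or abs(beta) > 15:
        raise SeparationError(
            f"exposure coefficient degenerate (beta={beta:.3g}, se={se:.3g}); "
            "likely separation on the exposure"
        )
    return EffectEstimate(
        measure="OR",
        point=float(np.exp(beta)),
        ci_low=float(np.exp(beta - Z95 * se)),
        ci_high=float(np.exp(beta + Z95 * se)),
        p_value=float(res.pvalues[exposure]),
        adjusted=bool(covariates),
        covariates=covariates,
        converged=True,
    )
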