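"""Repeatability, reproducibility and accuracy statistics on counts.

Per-section neuron counts from repeated analyses (same analyst, two
blinded passes), from different analysts, or from automated methods are
compared with:

* Bland-Altman limits of agreement — bias ± 1.96 × SD of the paired
  differences — the standard agreement metric for two measurement
  procedures on the same units;
* Pearson correlation of a method's counts against a consensus
  reference count (accuracy);
* ordinary-least-squares models relating the (absolute) difference
  between repeated counts to candidate explanatory variables (mean
  count, analysis time, analyst experience, section condition), with
  nested models compared by F-test and ranked by adjusted R².
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.anova import anova_lm

__all__ = [
    "BlandAltmanResult",
    "bland_altman",
    "accuracy_correlation",
    "RepeatabilityModels",
    "repeatability_model",
]


@dataclass(frozen=True)
class BlandAltmanResult:
    """Limits of agreement between two paired count series.

    Note: plots of this kind sometimes label the interval lines "95%
    confidence intervals"; what is computed here (and usually plotted)
    are Bland-Altman *limits of agreement*, bias ± 1.96 × SD of the
    differences with the sample (n−1) standard deviation.
    """

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int

    def as_dict(self) -> dict:
        return {
            "bias": self.bias, "sd_diff": self.sd_diff,
            "loa_low": self.loa_low, "loa_high": self.loa_high, "n": self.n,
        }


def _paired(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1-D arrays of equal length")
    return a, b


def bland_altman(a: Sequence[float], b: Sequence[float]) -> BlandAltmanResult:
    """Bland-Altman agreement of paired counts a and b.

    bias = mean(a − b); limits of agreement = bias ± 1.96 × sd(a − b)
    with the sample standard deviation (ddof = 1).  Swapping a and b
    flips the sign of the bias and mirrors the limits.
    """
    a, b = _paired(a, b)
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        bias=bias, sd_diff=sd,
        loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd, n=int(a.size),
    )


def accuracy_correlation(estimates: Sequence[float], reference: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation of method estimates against a reference count.

    Returns (r, two-sided p from the t transform).  Raises if either
    variable has zero variance (correlation undefined).
    """
    a, b = _paired(estimates, reference)
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined: a variable has zero variance")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


@dataclass(frozen=True)
class RepeatabilityModels:
    """Fitted candidate models for the repeatability analysis."""

    table: pd.DataFrame  # one row per candidate model
    best: str  # formula of the model with highest adjusted R²
    fits: dict  # formula -> statsmodels results object
    anova: pd.DataFrame | None  # nested F-test comparisons, when any

    @property
    def best_fit(self):
        return self.fits[self.best]


def _check_full_rank(data: pd.DataFrame, fit) -> None:
    exog = fit.model.exog
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        names = fit.model.exog_names
        # identify columns whose removal restores full rank
        bad = [
            names[j]
            for j in range(exog.shape[1])
            if np.linalg.matrix_rank(np.delete(exog, j, axis=1)) == rank
        ]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")


def repeatability_model(
    data: pd.DataFrame,
    response: str,
    candidate_predictors: Sequence[Sequence[str]],
) -> RepeatabilityModels:
    """Compare OLS models of count-difference magnitude on predictors.

    ``data`` holds one row per repeated analysis with the response
    column (typically the absolute difference between the two counts)
    and predictor columns; categorical predictors (e.g. section
    condition) may be strings.  Each candidate predictor subset is fit
    by OLS; models are ranked by adjusted R², and every nested pair of
    candidates is compared with an F-test.
    """
    if len(candidate_predictors) < 2:
        raise ValueError("need at least 2 candidate predictor subsets")
    fits, rows = {}, []
    formulas = []
    for preds in candidate_predictors:
        rhs = " + ".join(preds) if preds else "1"
        formula = f"{response} ~ {rhs}"
        fit = smf.ols(formula, data=data).fit()
        if fit.df_resid <= 0:
            raise ValueError(f"model {formula!r}: more parameters than observations")
        _check_full_rank(data, fit)
        fits[formula] = fit
        formulas.append((formula, set(preds)))
        rows.append(
            {
                "formula": formula,
                "n_predictors": len(preds),
                "adj_r2": float(fit.rsquared_adj),
                "r2": float(fit.rsquared),
                "f_pvalue": float(fit.f_pvalue) if len(preds) else np.nan,
                "aic": float(fit.aic),
            }
        )
    table = pd.DataFrame(rows).sort_values("adj_r2", ascending=False).reset_index(drop=True)

    anova_rows = []
    for (f1, p1) in formulas:
        for (f2, p2) in formulas:
            if p1 < p2:  # f1 strictly nested in f2
                cmp = anova_lm(fits[f1], fits[f2])
                anova_rows.append(
                    {
                        "reduced": f1, "full": f2,
                        "F": float(cmp["F"].iloc[-1]),
                        "p_value": float(cmp["Pr(>F)"].iloc[-1]),
                    }
                )
    anova = pd.DataFrame(anova_rows) if anova_rows else None
    best = str(table.loc[0, "formula"])
    return RepeatabilityModels(table=table, best=best, fits=fits, anova=anova)
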