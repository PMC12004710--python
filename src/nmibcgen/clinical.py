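"""Cross-cohort Fisher/BH comparison and survival plumbing.

The two-cohort mutation-frequency comparison uses the two-sided Fisher
exact test (summation of hypergeometric table probabilities <= the
observed table's) with Benjamini-Hochberg adjustment across genes and a
significance cutoff of adjusted p < 0.1.  Cox regression, Kaplan-Meier
curves, log-rank tests and logistic regression delegate to lifelines
and statsmodels; multivariable Cox models are gated on all covariates
having variance inflation factor < 5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Stable under input reordering; enforced monotone; idempotent on
    already-adjusted monotone vectors."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.empty(n)
    adjusted[order] = np.minimum(ranked, 1.0)
    return adjusted


@dataclass(frozen=True)
class CohortComparison:
    gene: str
    mutant_a: int
    total_a: int
    mutant_b: int
    total_b: int
    p: float
    p_adjusted: float
    significant: bool


def fisher_cohort_table(counts: pd.DataFrame, alpha: float = 0.1) -> list:
    """Per-gene two-sided Fisher comparison of two cohorts.

    ``counts`` is indexed by gene with columns mutant_european /
    total_european / mutant_chinese / total_chinese (or any two cohorts
    in that column order)."""
    cols = list(counts.columns)
    ma, ta, mb, tb = cols[:4]
    ps = {}
    for gene, row in counts.iterrows():
        if row[ma] > row[ta] or row[mb] > row[tb]:
            raise ValueError(f"{gene}: mutant count exceeds total")
        table = [[int(row[ma]), int(row[ta] - row[ma])],
                 [int(row[mb]), int(row[tb] - row[mb])]]
        ps[gene] = stats.fisher_exact(table, alternative="two-sided")[1]
    adjusted = bh_adjust(np.array(list(ps.values())))
    out = []
    for (gene, p), padj in zip(ps.items(), adjusted):
        row = counts.loc[gene]
        out.append(CohortComparison(
            gene=str(gene), mutant_a=int(row[ma]), total_a=int(row[ta]),
            mutant_b=int(row[mb]), total_b=int(row[tb]), p=float(p),
            p_adjusted=float(padj), significant=bool(padj < alpha)))
    return out


def comparison_table(comparisons: list) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene": c.gene, "mutant_a": c.mutant_a, "total_a": c.total_a,
        "mutant_b": c.mutant_b, "total_b": c.total_b, "p": c.p,
        "p_adjusted": c.p_adjusted, "significant": c.significant,
    } for c in comparisons]).set_index("gene")


# ---------------------------------------------------------------------------
# survival plumbing

def variance_inflation_factors(X: pd.DataFrame) -> pd.Series:
    """VIF per covariate from OLS of each column on the rest."""
    from statsmodels.stats.outliers_influence import variance_inflation_factor
    from statsmodels.tools import add_constant
    Xc = add_constant(X.astype(float), has_constant="add")
    vifs = {}
    for i, col in enumerate(Xc.columns):
        if col == "const":
            continue
        with np.errstate(divide="ignore"):
            vifs[col] = variance_inflation_factor(Xc.to_numpy(), i)
    return pd.Series(vifs)


class CollinearityError(ValueError):
    """A multivariable model violates the VIF < 5 gate."""


def cox_regression(df: pd.DataFrame, duration_col: str = "rfs_months",
                   event_col: str = "event", covariates=None,
                   vif_threshold: float = 5.0):
    """Cox proportional-hazards fit (lifelines) with a VIF gate.

    Multivariable models whose covariates include any VIF >=
    ``vif_threshold`` are rejected with the offending variables named.
    Returns the fitted CoxPHFitter."""
    from lifelines import CoxPHFitter
    covariates = list(covariates or
                      [c for c in df.columns if c not in (duration_col, event_col)])
    if df[event_col].sum() == 0:
        raise ValueError("no events observed")
    if len(covariates) > 1:
        vifs = variance_inflation_factors(df[covariates])
        bad = vifs[(vifs >= vif_threshold) | ~np.isfinite(vifs)]
        if len(bad):
            raise CollinearityError(
                f"VIF >= {vif_threshold} for: {list(bad.index)}")
    model = CoxPHFitter()
    model.fit(df[[duration_col, event_col] + covariates],
              duration_col=duration_col, event_col=event_col)
    return model


def hazard_ratio_table(model) -> pd.DataFrame:
    summary = model.summary
    return pd.DataFrame({
        "hr": np.exp(summary["coef"]),
        "hr_low": np.exp(summary["coef lower 95%"]),
        "hr_high": np.exp(summary["coef upper 95%"]),
        "p": summary["p"],
    })


def km_logrank(df: pd.DataFrame, group_col: str,
               duration_col: str = "rfs_months", event_col: str = "event"):
    """Kaplan-Meier fits per group plus the (multivariate) log-rank p."""
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test
    groups = df[group_col].unique()
    if len(groups) < 2:
        raise ValueError("log-rank needs >= 2 groups")
    fits = {}
    for g in groups:
        sub = df[df[group_col] == g]
        km = KaplanMeierFitter()
        km.fit(sub[duration_col], sub[event_col], label=str(g))
        fits[g] = km
    res = multivariate_logrank_test(df[duration_col], df[group_col],
                                    df[event_col])
    return fits, float(res.p_value)


def logistic_recurrence(df: pd.DataFrame, covariates, horizon_months: float = 24.0,
                        duration_col: str = "rfs_months", event_col: str = "event"):
    """Logistic regression of 2-year recurrence on covariates.

    Samples censored before the horizon without an event are excluded;
    perfect separation is flagged via statsmodels' convergence warning
    machinery (the fit is returned regardless)."""
    import statsmodels.api as sm
    recurred = (df[event_col] == 1) & (df[duration_col] <= horizon_months)
    at_risk = recurred | (df[duration_col] >= horizon_months)
    sub = df[at_risk]
    y = recurred[at_risk].astype(int)
    X = sm.add_constant(sub[list(covariates)].astype(float), has_constant="add")
    model = sm.Logit(y, X)
    try:
        return model.fit(disp=0)
    except Exception as exc:  # separation / non-convergence
        raise ValueError(f"logistic fit failed (possible separation): {exc}")


__all__ = [
    "bh_adjust", "CohortComparison", "fisher_cohort_table", "comparison_table",
    "variance_inflation_factors", "CollinearityError", "cox_regression",
    "hazard_ratio_table", "km_logrank", "logistic_recurrence",
]
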