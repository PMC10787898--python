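"""Hypothesis testing for fluctuation/tension comparisons.

Pairwise Mann-Whitney U tests with Bonferroni-adjusted alpha (0.05 divided
by the number of comparisons, printed floored to 3 decimals: 0.016 for 3),
an ANOVA route gated on normality, and a linear mixed-effects model on
log-tension with random intercepts for replicate set and for cell nested in
set.  The mixed model is the guard against pseudo-replication: hundreds of
FBR measurements per cell do not make independent evidence, and pooling
them in a naive rank test wildly overstates significance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["TestResult", "significance_stars", "mann_whitney_bonferroni",
           "anova_bonferroni", "compare_groups", "lmm_compare"]


@dataclass
class TestResult:
    test: str
    group_a: str
    group_b: str
    statistic: float
    p_value: float
    adjusted_alpha: float
    stars: str


def significance_stars(p: float, adjusted_alpha: float = 0.05) -> str:
    """Star convention: 'ns' above the adjusted threshold, '*' below it,
    '**' below 0.001 (never more stars than the threshold admits)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if p >= adjusted_alpha:
        return "ns"
    if p < min(0.001, adjusted_alpha):
        return "**"
    return "*"


def _adjusted_alpha(n_comparisons: int, alpha: float = 0.05) -> float:
    """Bonferroni-adjusted alpha, floored at 3 decimals for reporting
    (0.05/3 -> 0.016)."""
    return np.floor(alpha / n_comparisons * 1000.0) / 1000.0


def mann_whitney_bonferroni(samples: dict, n_comparisons: int | None = None,
                            alpha: float = 0.05) -> list[TestResult]:
    """All pairwise two-sided Mann-Whitney U tests between the named groups,
    judged at the Bonferroni-adjusted alpha."""
    names = list(samples)
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    if n_comparisons is None:
        n_comparisons = max(len(pairs), 1)
    adj = _adjusted_alpha(n_comparisons, alpha)
    out = []
    for a, b in pairs:
        xa, xb = np.asarray(samples[a]), np.asarray(samples[b])
        if min(xa.size, xb.size) < 3:
            raise ValueError("need at least 3 observations per group")
        if np.array_equal(xa, xb):
            stat, p = np.nan, 1.0
        else:
            stat, p = sps.mannwhitneyu(xa, xb, alternative="two-sided")
        out.append(TestResult("mann-whitney", a, b, float(stat), float(p),
                              adj, significance_stars(p, adj)))
    return out


def anova_bonferroni(samples: dict, alpha: float = 0.05) -> list[TestResult]:
    """One-way ANOVA followed by pairwise t tests at Bonferroni-adjusted
    alpha (used when the data pass a normality gate)."""
    names = list(samples)
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    adj = _adjusted_alpha(max(len(pairs), 1), alpha)
    out = []
    for a, b in pairs:
        xa, xb = np.asarray(samples[a]), np.asarray(samples[b])
        stat, p = sps.ttest_ind(xa, xb)
        out.append(TestResult("anova-pairwise-t", a, b, float(stat),
                              float(p), adj, significance_stars(p, adj)))
    return out


def compare_groups(samples: dict, alpha: float = 0.05,
                   normality_alpha: float = 0.05) -> list[TestResult]:
    """Normality-gated dispatch: pairwise t tests when every group passes a
    Shapiro-Wilk test at ``normality_alpha``, Mann-Whitney otherwise."""
    normal = all(sps.shapiro(np.asarray(v))[1] > normality_alpha
                 for v in samples.values())
    if normal:
        return anova_bonferroni(samples, alpha)
    return mann_whitney_bonferroni(samples, alpha=alpha)


def lmm_compare(df: pd.DataFrame, response: str = "log_tension",
                fixed: str = "phase", cell_col: str = "cell_id",
                set_col: str = "set_id", categorical: bool = True):
    """Linear mixed model: ``response ~ fixed`` with random intercepts for
    replicate set and for cell nested within set, fit by REML.

    Returns a dict with the fixed-effect estimate(s), standard error(s) and
    p value(s), plus the fitted statsmodels results object.  With a single
    cell per set the cell-level intercept is degenerate with the set level;
    the model then drops to set-level intercepts with a warning.
    """
    import statsmodels.formula.api as smf

    df = df.copy()
    if df[set_col].nunique() < 2:
        raise ValueError("need at least 2 replicate sets")
    cells_per_set = df.groupby(set_col)[cell_col].nunique()
    nested_ok = (cells_per_set > 1).any()
    fixed_term = f"C({fixed})" if categorical else fixed
    formula = f"{response} ~ {fixed_term}"
    if nested_ok:
        vc = {"cell": f"0 + C({cell_col})"}
    else:
        warnings.warn("single cell per replicate set: cell-level intercepts "
                      "are degenerate; using set-level intercepts only")
        vc = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, df, groups=df[set_col],
                            re_formula="1", vc_formula=vc)
        fit = model.fit(reml=True)
    fe = fit.fe_params
    terms = [t for t in fe.index if t != "Intercept"]
    # small-sample inference: Wald z p-values are anti-conservative with a
    # handful of cells, so fixed effects are tested against a t
    # distribution with cell-level degrees of freedom
    n_cells = df.groupby([set_col, cell_col]).ngroups
    dof = max(n_cells - len(fe), 1)
    p_t = {t: float(2.0 * sps.t.sf(abs(fe[t] / fit.bse_fe[t]), dof))
           for t in terms}
    return {
        "estimates": {t: float(fe[t]) for t in terms},
        "std_errors": {t: float(fit.bse_fe[t]) for t in terms},
        "p_values": p_t,
        "dof": dof,
        "fold_changes": {t: float(np.exp(fe[t])) for t in terms},
        "converged": bool(fit.converged),
        "result": fit,
    }
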