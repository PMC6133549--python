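"""Association and comparison statistics.

The headline analysis regresses each infant's evoked percent BOLD change on
the network-mean pre-stimulus connectivity with gestational age (decimal
weeks) as a covariate, reporting the psFC slope, its p-value, and the
age-adjusted Pearson correlation (response residualised on GA, then
correlated with psFC). Supporting analyses: one model per ROI pair,
one-way repeated-measures ANOVA across networks with Tukey HSD on the
within-subject error term, an RM-ANOVA over stimulus number for stability,
and sensitivity re-runs excluding brainstem nodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "AssociationResult",
    "AnovaResult",
    "psfc_association",
    "edgewise_association",
    "rm_anova",
    "compare_network_connectivity",
    "stimulus_stability",
    "sensitivity_excluding_brainstem",
    "BRAINSTEM_EXCLUSIONS",
]

# sensitivity analysis: drop brainstem nodes from each network
BRAINSTEM_EXCLUSIONS: dict[str, tuple[str, ...]] = {
    "DPMS": ("PAG", "RVM"),
    "Control": ("PON",),
}


@dataclass(frozen=True)
class AssociationResult:
    label: str
    beta: float
    p_value: float
    ga_coefficient: float
    adjusted_r: float
    adjusted_r_p: float
    n: int

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "beta": self.beta,
            "p_value": self.p_value,
            "ga_coefficient": self.ga_coefficient,
            "adjusted_r": self.adjusted_r,
            "adjusted_r_p": self.adjusted_r_p,
            "n": self.n,
        }


@dataclass(frozen=True)
class AnovaResult:
    levels: tuple[str, ...]
    f_statistic: float
    p_value: float
    df_effect: int
    df_error: int
    tukey: pd.DataFrame  # columns: level_a, level_b, mean_diff, q, p_adj

    def to_dict(self) -> dict:
        return {
            "levels": list(self.levels),
            "F": self.f_statistic,
            "p": self.p_value,
            "df": [self.df_effect, self.df_error],
            "tukey": self.tukey.to_dict(orient="records"),
        }


def _residualise_on_ga(y: np.ndarray, ga: np.ndarray) -> np.ndarray:
    X = sm.add_constant(ga)
    return np.asarray(sm.OLS(y, X).fit().resid)


def psfc_association(
    percent_change,
    psfc,
    ga_weeks,
    label: str = "network",
    partial: bool = False,
) -> AssociationResult:
    """Linear model percent_change ~ intercept + psFC + GA.

    ``adjusted_r`` is the Pearson correlation between the GA-residualised
    response and the psFC values; with ``partial=True`` the psFC vector is
    residualised on GA as well (classical partial correlation).
    """
    y = np.asarray(percent_change, dtype=float)
    x = np.asarray(psfc, dtype=float)
    ga = np.asarray(ga_weeks, dtype=float)
    n = y.size
    if n < 4:
        raise ValueError("need at least 4 infants for the adjusted model")
    if x.shape != y.shape or ga.shape != y.shape:
        raise ValueError("percent_change, psfc and ga_weeks must align")
    if np.any(np.isnan(y)) or np.any(np.isnan(x)) or np.any(np.isnan(ga)):
        raise ValueError("missing values are not allowed")
    if np.ptp(x) == 0:
        raise ValueError("psFC vector is constant; slope not identifiable")

    X = np.column_stack([np.ones(n), x, ga])
    fit = sm.OLS(y, X).fit()

    resid_y = _residualise_on_ga(y, ga)
    x_for_r = _residualise_on_ga(x, ga) if partial else x
    r, r_p = sps.pearsonr(resid_y, x_for_r)
    return AssociationResult(
        label=label,
        beta=float(fit.params[1]),
        p_value=float(fit.pvalues[1]),
        ga_coefficient=float(fit.params[2]),
        adjusted_r=float(r),
        adjusted_r_p=float(r_p),
        n=n,
    )


def edgewise_association(
    edge_psfc: pd.DataFrame,
    percent_change,
    ga_weeks,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One GA-adjusted model per ROI-pair column of ``edge_psfc``.

    Returns a table with per-edge beta, unadjusted p (as reported in the
    source analysis style), a Bonferroni column for transparency, and a
    significance flag at ``alpha`` on the unadjusted p.
    """
    rows = []
    for edge in edge_psfc.columns:
        res = psfc_association(
            percent_change, edge_psfc[edge].to_numpy(float), ga_weeks, label=edge
        )
        rows.append(
            {
                "edge": edge,
                "beta": res.beta,
                "p_value": res.p_value,
                "adjusted_r": res.adjusted_r,
            }
        )
    table = pd.DataFrame(rows)
    m = len(table)
    table["p_bonferroni"] = np.minimum(table["p_value"] * m, 1.0)
    table["significant"] = table["p_value"] < alpha
    return table


def rm_anova(table: pd.DataFrame) -> AnovaResult:
    """One-way repeated-measures ANOVA on a subjects x conditions table.

    Classical univariate F with subject as the blocking factor. Tukey HSD
    p-values use the studentized-range distribution on the within-subject
    (subject x condition interaction) error term. Degenerate input with no
    condition effect and no error returns F = 0, p = 1.
    """
    data = table.to_numpy(dtype=float)
    if np.any(np.isnan(data)):
        missing = [
            (table.index[i], table.columns[j])
            for i, j in zip(*np.nonzero(np.isnan(data)))
        ]
        raise ValueError(f"incomplete table; missing cells: {missing}")
    n, k = data.shape
    if k < 2:
        raise ValueError("need at least 2 within-subject conditions")
    if n < 2:
        raise ValueError(
            "repeated-measures ANOVA needs at least 2 subjects to "
            "estimate the error term"
        )
    grand = data.mean()
    cond_means = data.mean(axis=0)
    subj_means = data.mean(axis=1)
    ss_cond = n * np.sum((cond_means - grand) ** 2)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_cond - ss_subj
    df_cond, df_err = k - 1, (n - 1) * (k - 1)
    ms_cond = ss_cond / df_cond
    ms_err = max(ss_err / df_err, 0.0)

    scale = max(ss_total, 1.0)
    if ss_cond <= 1e-12 * scale:
        f_stat, p = 0.0, 1.0
    elif ms_err == 0.0:
        f_stat, p = np.inf, 0.0
    else:
        f_stat = ms_cond / ms_err
        p = float(sps.f.sf(f_stat, df_cond, df_err))

    rows = []
    se = np.sqrt(ms_err / n) if ms_err > 0 else 0.0
    for i in range(k):
        for j in range(i + 1, k):
            diff = cond_means[j] - cond_means[i]
            if se > 0:
                q = abs(diff) / se
                p_adj = float(sps.studentized_range.sf(q, k, df_err))
            else:
                q = 0.0 if diff == 0 else np.inf
                p_adj = 1.0 if diff == 0 else 0.0
            rows.append(
                {
                    "level_a": str(table.columns[i]),
                    "level_b": str(table.columns[j]),
                    "mean_diff": diff,
                    "q": q,
                    "p_adj": min(max(p_adj, 0.0), 1.0),
                }
            )
    return AnovaResult(
        levels=tuple(str(c) for c in table.columns),
        f_statistic=float(f_stat),
        p_value=float(p),
        df_effect=df_cond,
        df_error=df_err,
        tukey=pd.DataFrame(rows),
    )


def compare_network_connectivity(network_means: pd.DataFrame) -> AnovaResult:
    """RM-ANOVA of per-infant mean psFC across networks, with Tukey HSD."""
    return rm_anova(network_means)


def stimulus_stability(per_stimulus_psfc: pd.DataFrame) -> AnovaResult:
    """RM-ANOVA with stimulus number as the within-subject factor."""
    return rm_anova(per_stimulus_psfc)


def sensitivity_excluding_brainstem(
    network_means_excluded: pd.DataFrame,
    percent_change,
    ga_weeks,
) -> dict[str, AssociationResult]:
    """Re-run the network association on brainstem-excluded network means.

    ``network_means_excluded`` holds one column per reduced network
    (e.g. 'DPMS_noBrainstem', 'Control_noPON').
    """
    return {
        col: psfc_association(
            percent_change,
            network_means_excluded[col].to_numpy(float),
            ga_weeks,
            label=col,
        )
        for col in network_means_excluded.columns
    }
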