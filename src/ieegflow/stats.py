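"""Group-level inference for connectivity and power outcomes.

Values (e.g. trial-averaged PTE per channel pair) are first brought to
approximate normality with a rank-based ordered-quantile transform, then
contrasted between two conditions with a linear mixed model

    value ~ condition + (1 | subject)

whose 1-df condition effect is reported as F = t^2 with a Cohen's d
computed by the d = 2 t / sqrt(df) convention.  Multiple comparisons are
Benjamini-Hochberg corrected.  Evidence for replication across experiments
is quantified as the ratio BF10(original + replication) / BF10(original),
with Bayes factors obtained from a BIC approximation to the marginal
likelihoods; ratios of at least 3 count as evidence of replication and at
least 100 as decisive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as spstats

__all__ = [
    "StatReport",
    "ReplicationBF",
    "normalize_orq",
    "condition_contrast",
    "cohens_d",
    "fdr_bh",
    "bayes_factor_condition",
    "replication_bf",
]


@dataclass
class StatReport:
    """A 1-df condition contrast: F(df1, df2), p, effect size and direction."""

    F: float
    df1: int
    df2: int
    p: float
    cohens_d: float
    direction: str  # condition level with the larger fitted mean
    method: str = "mixed"  # mixed | ols-fallback


@dataclass
class ReplicationBF:
    """Replication evidence: BF10 ratio of joint vs original data."""

    bf_original: float
    bf_joint: float
    ratio: float
    verdict: str  # not replicated | replicated | decisive


def normalize_orq(values: np.ndarray) -> np.ndarray:
    """Ordered-quantile (rank-based inverse-normal) transform.

    Maps value -> Phi^-1((rank - 0.5) / n) with average ranks for ties, so
    any continuous input becomes approximately standard normal while the
    ordering is preserved exactly.
    """
    values = np.asarray(values, float)
    if values.size < 3:
        raise ValueError("need at least 3 values")
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite values")
    if np.ptp(values) == 0:
        raise ValueError("all values identical; transform undefined")
    ranks = spstats.rankdata(values, method="average")
    return spstats.norm.ppf((ranks - 0.5) / values.size)


def cohens_d(stat: float, df: float, kind: str = "t") -> float:
    """Effect size d = 2 t / sqrt(df) (t = sqrt(F) for a 1-df effect).

    This is the convention of mixed-model d-scores: the fixed-effect t and
    its denominator df determine d directly.  ``kind="F"`` takes the square
    root first (losing the sign).
    """
    if df <= 0:
        raise ValueError("df must be positive")
    t = np.sqrt(stat) if kind == "F" else stat
    return float(2 * t / np.sqrt(df))


def fdr_bh(pvals: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (reject mask, adjusted p-values)."""
    pvals = np.asarray(pvals, float)
    if pvals.size == 0:
        return np.zeros(0, bool), np.zeros(0)
    from statsmodels.stats.multitest import multipletests

    reject, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return reject, p_adj


def _check_table(table: pd.DataFrame) -> tuple[list, pd.DataFrame]:
    required = {"value", "condition", "subject"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table missing columns: {sorted(missing)}")
    levels = sorted(table["condition"].unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 condition levels, got {levels}")
    return levels, table


def _fit_mixed(table: pd.DataFrame, reml: bool = True):
    """MixedLM value ~ condition with a subject random intercept."""
    import statsmodels.formula.api as smf

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm("value ~ C(condition)", table, groups=table["subject"])
        return model.fit(reml=reml)


def condition_contrast(table: pd.DataFrame) -> StatReport:
    """Two-level condition contrast with subject random intercepts.

    ``table`` needs columns value / condition / subject (one row per
    analysis unit, e.g. a trial-averaged channel pair in one condition).
    With a single subject the model is unidentifiable and the contrast
    falls back to a fixed-effects one-way ANOVA with a warning.  Returns
    the condition F (t^2 of the fixed effect), a two-sided p on df2 =
    n - 2, and Cohen's d = 2 t / sqrt(df2) signed toward the level with
    the larger mean.
    """
    levels, table = _check_table(table)
    n = len(table)
    df2 = n - 2
    n_subjects = table["subject"].nunique()
    if n_subjects < 2:
        warnings.warn(
            "single subject: falling back to fixed-effects ANOVA", stacklevel=2
        )
        a = table.loc[table["condition"] == levels[0], "value"]
        b = table.loc[table["condition"] == levels[1], "value"]
        t, p = spstats.ttest_ind(b, a)
        t = float(t)
        report_method = "ols-fallback"
    else:
        res = _fit_mixed(table)
        # treatment coding: the single non-intercept fixed effect
        name = [k for k in res.params.index if "C(condition)" in k][0]
        se = float(res.bse[name])
        coef = float(res.params[name])
        if not np.isfinite(se) or se == 0:
            t = 0.0
        else:
            t = coef / se
        p = float(2 * spstats.t.sf(abs(t), df2))
        report_method = "mixed"
    d = cohens_d(abs(t), df2) * np.sign(t) if t != 0 else 0.0
    direction = levels[1] if t >= 0 else levels[0]
    return StatReport(
        F=float(t**2),
        df1=1,
        df2=df2,
        p=float(min(1.0, p)),
        cohens_d=float(d),
        direction=direction,
        method=report_method,
    )


def bayes_factor_condition(table: pd.DataFrame) -> float:
    """BF10 for the condition effect via the BIC approximation.

    Both the alternative (value ~ condition + (1|subject)) and the null
    (value ~ 1 + (1|subject)) retain the subject intercepts; models are fit
    by maximum likelihood and BF10 = exp((BIC0 - BIC1) / 2).  The implied
    prior is the unit-information prior, so magnitudes are comparable
    within this implementation rather than to default-prior packages.
    """
    import statsmodels.api as sm

    levels, table = _check_table(table)
    n = len(table)
    if table["subject"].nunique() < 2:
        raise ValueError("Bayes factor computation needs >= 2 subjects")
    res1 = _fit_mixed(table, reml=False)
    endog = table["value"].to_numpy(float)
    exog0 = np.ones((n, 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res0 = sm.MixedLM(endog, exog0, groups=table["subject"]).fit(reml=False)
    if not (np.isfinite(res1.llf) and np.isfinite(res0.llf)):
        raise ValueError("degenerate mixed-model fit; BF undefined")
    k1, k0 = 4, 3  # (fixed effects) + random-intercept var + residual var
    bic1 = k1 * np.log(n) - 2 * res1.llf
    bic0 = k0 * np.log(n) - 2 * res0.llf
    return float(np.exp((bic0 - bic1) / 2))


def replication_bf(original: pd.DataFrame, replication: pd.DataFrame) -> ReplicationBF:
    """Replication Bayes factor ratio BF10(joint) / BF10(original).

    Both tables must code the condition identically; the joint model pools
    the rows.  The verdict is "replicated" at ratio >= 3 and "decisive" at
    ratio >= 100.
    """
    if len(replication) == 0:
        raise ValueError("empty replication table")
    lv_o, _ = _check_table(original)
    lv_r, _ = _check_table(replication)
    if lv_o != lv_r:
        raise ValueError(f"condition codings differ: {lv_o} vs {lv_r}")
    bf_orig = bayes_factor_condition(original)
    joint = pd.concat([original, replication], ignore_index=True)
    bf_joint = bayes_factor_condition(joint)
    ratio = bf_joint / bf_orig
    verdict = (
        "decisive" if ratio >= 100 else "replicated" if ratio >= 3 else "not replicated"
    )
    return ReplicationBF(
        bf_original=bf_orig, bf_joint=bf_joint, ratio=float(ratio), verdict=verdict
    )
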