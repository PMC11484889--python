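"""Group-comparison wrappers and the nested mixed-model contract.

Neural statistics respect the nesting neurons-within-birds (and behavioral
ones birds-within-fathers): a random intercept per outer group and one per
inner group nested in it, fitted by maximum likelihood, with a two-sided
Wald p value for the condition effect.  Rank-sum tests are exact for small
combined samples and midrank/normal-approximate otherwise; no multiple-
testing correction is applied anywhere (p values are reported unadjusted).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf


@dataclass
class TestResult:
    name: str
    statistic: float
    p_value: float
    n: tuple[int, ...]
    effect: float | None = None
    note: str = ""


@dataclass
class LmmSpec:
    """Nested mixed-model contract: response ~ 1 + condition
    + (1 | outer) + (1 | outer:inner)."""

    response: str
    condition: str
    outer: str
    inner: str


@dataclass
class LmmResult:
    estimate: float
    se: float
    p_value: float
    var_outer: float
    var_inner: float
    var_resid: float
    n: int
    fallback: bool = False


def compare_groups(
    values_a, values_b, method: str = "rank_sum"
) -> TestResult:
    """Two-sided two-group comparison.

    ``rank_sum``: Wilcoxon rank-sum / Mann-Whitney, exact by enumeration when
    the combined n is <= 20 and tie-free, midranks + normal approximation
    otherwise.  ``t_two_sample``: Student's two-sample t.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    effect = float(np.median(a) - np.median(b))
    if method == "rank_sum":
        pooled = np.concatenate([a, b])
        if np.ptp(pooled) == 0:
            warnings.warn("constant pooled data: rank-sum p set to 1", stacklevel=2)
            return TestResult("rank_sum", 0.0, 1.0, (len(a), len(b)), 0.0, "constant data")
        ties = len(np.unique(pooled)) < len(pooled)
        mode = "exact" if (len(pooled) <= 20 and not ties) else "asymptotic"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=mode)
        return TestResult("rank_sum", float(res.statistic), float(res.pvalue), (len(a), len(b)), effect)
    if method == "t_two_sample":
        res = sps.ttest_ind(a, b)
        return TestResult(
            "t_two_sample", float(res.statistic), float(res.pvalue), (len(a), len(b)),
            float(a.mean() - b.mean()),
        )
    raise ValueError(f"unknown method {method!r}")


def one_sample_test(values, reference: float) -> TestResult:
    """Two-sided one-sample t test against a reference constant."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need n >= 2")
    if np.ptp(v) == 0:
        return TestResult(
            "one_sample_t", np.inf if v[0] != reference else 0.0,
            0.0 if v[0] != reference else 1.0, (len(v),),
            float(v.mean() - reference), "zero variance",
        )
    res = sps.ttest_1samp(v, reference)
    return TestResult(
        "one_sample_t", float(res.statistic), float(res.pvalue), (len(v),),
        float(v.mean() - reference),
    )


def fisher_2x2(table) -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 count table."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of nonnegative integers")
    if t.sum(axis=0).min() == 0 and t.sum(axis=1).min() == 0:
        return TestResult("fisher_exact", np.nan, 1.0, tuple(t.ravel()), note="empty margin")
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    return TestResult("fisher_exact", float(odds), float(p), tuple(t.ravel()))


def fit_nested_lmm(table: pd.DataFrame, spec: LmmSpec) -> LmmResult:
    """Fit ``response ~ 1 + condition + (1|outer) + (1|outer:inner)`` by ML.

    A singular nesting (every observation its own inner group) is flagged
    and fitted with the outer random intercept only.
    """
    df = table.copy()
    if df[spec.outer].nunique() < 2:
        raise ValueError("need >= 2 outer groups")
    df["_inner"] = df[spec.outer].astype(str) + ":" + df[spec.inner].astype(str)
    singular = df["_inner"].nunique() >= len(df)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if singular:
            model = smf.mixedlm(
                f"{spec.response} ~ {spec.condition}", df, groups=spec.outer, re_formula="1"
            )
        else:
            model = smf.mixedlm(
                f"{spec.response} ~ {spec.condition}", df,
                groups=spec.outer, re_formula="1",
                vc_formula={"inner": "0 + C(_inner)"},
            )
        fit = None
        last_err: Exception | None = None
        for opt in ("lbfgs", "cg", "powell"):
            try:
                fit = model.fit(reml=False, method=opt, disp=False)
                break
            except (np.linalg.LinAlgError, ValueError) as exc:  # ill-conditioned Hessian
                last_err = exc
        if fit is None:
            raise RuntimeError(f"mixed-model fit failed for all optimizers: {last_err}")
    if singular:
        warnings.warn(
            "one observation per inner group: fell back to the outer-only model",
            stacklevel=2,
        )
    term = spec.condition
    if term not in fit.params:
        # categorical condition: take the single non-intercept fixed term
        candidates = [k for k in fit.fe_params.index if k != "Intercept"]
        term = candidates[0]
    var_inner = 0.0 if singular else float(fit.vcomp[0])
    return LmmResult(
        estimate=float(fit.params[term]),
        se=float(fit.bse[term]),
        p_value=float(fit.pvalues[term]),
        var_outer=float(fit.cov_re.iloc[0, 0]),
        var_inner=var_inner,
        var_resid=float(fit.scale),
        n=len(df),
        fallback=singular,
    )
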