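"""Group comparison and regression stage.

Element-level variables (pooled IOI durations, pooled integer ratios) are
compared between age classes with Welch's unequal-variance t-test; the
per-sequence indices with the Mann-Whitney U test (exact null when both
groups are small and untied, normal approximation with tie correction
otherwise).  Beat precision is regressed on beat frequency by ordinary
least squares, and on mean bark duration by a linear mixed model with a
random intercept per age class (REML).

No multiple-testing correction is applied: each comparison uses a
different dependent variable, so no group is tested twice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .metrics import RhythmSummary

__all__ = [
    "TestResult",
    "ModelFit",
    "welch_t",
    "mann_whitney_u",
    "lm_beat_precision_on_rate",
    "lmm_beat_precision_on_duration",
    "compare_groups",
]

# Per-sequence indices compared with Mann-Whitney; element-level variables
# (pooled across bouts) compared with Welch's t.
SEQUENCE_INDICES = (
    "unbiased_cv",
    "npvi_ioi",
    "beat_hz",
    "mean_beat_precision",
    "cv_beat_precision",
    "npvi_beat_precision",
)
ELEMENT_VARIABLES = ("ioi_duration", "integer_ratio")


@dataclass(frozen=True)
class TestResult:
    statistic_name: str  # "t" or "W"
    statistic: float
    p: float
    group_means: tuple[float, float]
    df: float | None = None
    u_first: float | None = None  # U of the first group (= R's wilcox.test W)
    u_second: float | None = None
    method: str | None = None


@dataclass(frozen=True)
class ModelFit:
    """Coefficient table plus scaled-residual quantiles of a fitted model."""

    terms: pd.DataFrame  # index: term; columns: estimate, se, t, p
    residual_quantiles: tuple[float, float, float, float, float]
    random_effect: str | None = None
    p_value_method: str = "t"
    converged: bool = True
    singular: bool = False


def welch_t(a, b) -> TestResult:
    """Welch's unpaired t-test (unequal variances, Welch-Satterthwaite df)."""
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return TestResult("t", 0.0, 1.0, (float(a.mean()), float(b.mean())),
                              df=float(a.size + b.size - 2))
        raise ValueError("degenerate: zero variance in both groups")
    res = sps.ttest_ind(a, b, equal_var=False)
    return TestResult(
        statistic_name="t",
        statistic=float(res.statistic),
        p=float(res.pvalue),
        group_means=(float(a.mean()), float(b.mean())),
        df=float(res.df),
    )


def mann_whitney_u(a, b) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Uses the exact null distribution when both groups have <= 20 values and
    the pooled data contain no ties, otherwise the normal approximation
    with tie correction.  The headline statistic is the U of the first
    group, which equals the W printed by R's ``wilcox.test(a, b)``; the
    complementary U of the second group is reported too
    (U_a + U_b = n_a * n_b).
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("each group needs >= 1 value")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    exact_ok = a.size <= 20 and b.size <= 20 and not has_ties
    method = "exact" if exact_ok else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    u_a = float(res.statistic)
    u_b = float(a.size * b.size - u_a)
    return TestResult(
        statistic_name="W",
        statistic=u_a,
        p=float(res.pvalue),
        group_means=(float(a.mean()), float(b.mean())),
        u_first=u_a,
        u_second=u_b,
        method=method,
    )


def _scaled_residual_quantiles(resid: np.ndarray, sigma: float):
    # a numerically perfect fit has sigma ~ 0; report raw residuals then
    scaled = resid / sigma if sigma > 1e-12 else resid
    q = np.quantile(scaled, [0.0, 0.25, 0.5, 0.75, 1.0])
    return tuple(float(x) for x in q)


def lm_beat_precision_on_rate(summaries: list[RhythmSummary]) -> ModelFit:
    """OLS of mean beat precision on beat frequency, all bouts pooled.

    A positive slope means faster bouts keep the beat less precisely.
    """
    import statsmodels.api as sm

    if len(summaries) < 3:
        raise ValueError("need >= 3 bouts for the linear model")
    x = np.array([s.beat_hz for s in summaries], dtype=float)
    y = np.array([s.mean_beat_precision for s in summaries], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("constant predictor: beat frequency has no variation")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    terms = pd.DataFrame(
        {
            "estimate": fit.params,
            "se": fit.bse,
            "t": fit.tvalues,
            "p": fit.pvalues,
        },
    )
    terms.index = ["(Intercept)", "beat_hz"]
    sigma = float(np.sqrt(fit.scale))
    return ModelFit(
        terms=terms,
        residual_quantiles=_scaled_residual_quantiles(fit.resid, sigma),
        random_effect=None,
        p_value_method="t (OLS, n-2 df)",
    )


def lmm_beat_precision_on_duration(summaries: list[RhythmSummary]) -> ModelFit:
    """Mixed model: beat precision ~ mean bark duration + (1 | age class).

    REML fit with a random intercept per age class only — with two grouping
    levels a random slope would be unidentifiable.  A singular fit (zero
    random-intercept variance) is reported as a flag, not an error.
    Fixed-effect p-values are Wald z, as named in the fit.
    """
    import statsmodels.formula.api as smf

    classes = {s.age_class for s in summaries}
    if len(classes) < 2:
        raise ValueError("need >= 2 age classes for the mixed model")
    df = pd.DataFrame(
        {
            "bp": [s.mean_beat_precision for s in summaries],
            "duration": [s.mean_bark_duration for s in summaries],
            "age_class": [s.age_class for s in summaries],
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm("bp ~ duration", df, groups=df["age_class"])
        fit = model.fit(reml=True)
    fe = fit.fe_params
    terms = pd.DataFrame(
        {
            "estimate": [fe["Intercept"], fe["duration"]],
            "se": [fit.bse_fe["Intercept"], fit.bse_fe["duration"]],
            "t": [fit.tvalues["Intercept"], fit.tvalues["duration"]],
            "p": [fit.pvalues["Intercept"], fit.pvalues["duration"]],
        },
        index=["(Intercept)", "duration"],
    )
    resid = np.asarray(fit.resid, dtype=float)
    sigma = float(np.sqrt(fit.scale))
    re_var = float(fit.cov_re.iloc[0, 0])
    return ModelFit(
        terms=terms,
        residual_quantiles=_scaled_residual_quantiles(resid, sigma),
        random_effect="age_class",
        p_value_method="Wald z",
        converged=bool(fit.converged),
        singular=re_var <= 1e-10,
    )


def compare_groups(summaries: list[RhythmSummary]) -> pd.DataFrame:
    """Per-index group comparison table (adults first, then pups).

    Element-level rows pool IOI durations and integer ratios across every
    bout of a class and use Welch's t (this pooling ignores within-
    individual correlation and is flagged in the ``level`` column);
    per-sequence rows use Mann-Whitney on one value per bout.
    Also reports per-bout-mean aggregation of the element-level variables
    alongside the pooled one, since the two need not agree.
    """
    from .metrics import compute_iois, integer_ratios

    adults = [s for s in summaries if s.age_class == "adult"]
    pups = [s for s in summaries if s.age_class == "pup"]
    if not adults or not pups:
        raise ValueError("need bouts from both age classes")

    rows = []

    def add_row(index, level, res: TestResult):
        rows.append(
            {
                "index": index,
                "level": level,
                "adult_mean": res.group_means[0],
                "pup_mean": res.group_means[1],
                "statistic_name": res.statistic_name,
                "statistic": res.statistic,
                "df": float("nan") if res.df is None else res.df,
                "p": res.p,
            }
        )

    # element-level: caller supplies raw element values via summaries'
    # source bouts; here we only have summaries, so element-level pooling
    # is done by compare_study (pipeline) which holds the bouts.
    for name in ("mean_ioi", "mean_integer_ratio"):
        a = [getattr(s, name) for s in adults]
        b = [getattr(s, name) for s in pups]
        add_row(name, "sequence (per-bout mean)", mann_whitney_u(a, b))
    for name in SEQUENCE_INDICES:
        a = [getattr(s, name) for s in adults]
        b = [getattr(s, name) for s in pups]
        add_row(name, "sequence", mann_whitney_u(a, b))
    return pd.DataFrame(rows)


def compare_element_level(bouts_by_class: dict[str, list]) -> pd.DataFrame:
    """Welch's t on pooled element-level variables (IOIs, integer ratios)."""
    from .metrics import compute_iois, integer_ratios

    rows = []
    pooled = {}
    for cls in ("adult", "pup"):
        iois, ratios = [], []
        for bout in bouts_by_class.get(cls, []):
            series = compute_iois(bout)
            iois.extend(series.iois)
            ratios.extend(integer_ratios(series))
        pooled[cls] = {"ioi_duration": iois, "integer_ratio": ratios}
    for name in ELEMENT_VARIABLES:
        res = welch_t(pooled["adult"][name], pooled["pup"][name])
        rows.append(
            {
                "index": name,
                "level": "element (pooled; ignores within-individual correlation)",
                "adult_mean": res.group_means[0],
                "pup_mean": res.group_means[1],
                "statistic_name": res.statistic_name,
                "statistic": res.statistic,
                "df": res.df,
                "p": res.p,
            }
        )
    return pd.DataFrame(rows)
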