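"""Normality-gated test selection for pooled results.

Paired comparisons use a paired t-test when the differences pass the
D'Agostino-Pearson omnibus normality test, otherwise the Wilcoxon
signed-rank test (exact p for n <= 25 without ties, normal approximation
with continuity correction above).  Three-condition designs use
repeated-measures ANOVA with Tukey pairwise tests (normal residuals) or the
Friedman test with Dunn's post-test (Bonferroni over the three pairs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "NormalityResult",
    "TestReport",
    "normality_check",
    "paired_compare",
    "repeated_compare",
    "unpaired_compare",
]

NORMALITY_ALPHA = 0.05
MIN_OMNIBUS_N = 8


@dataclass
class NormalityResult:
    statistic: float | None
    p_value: float | None
    normal: bool
    note: str = ""


@dataclass
class TestReport:
    test_name: str
    statistic: float
    dof_or_n: float
    p_value: float
    normality_p: float | None = None
    post_hoc: pd.DataFrame | None = field(default=None, repr=False)
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "test_name": self.test_name,
            "statistic": self.statistic,
            "dof_or_n": self.dof_or_n,
            "p_value": self.p_value,
            "normality_p": self.normality_p,
        }
        d.update(self.extra)
        if self.post_hoc is not None:
            d["post_hoc"] = self.post_hoc.to_dict(orient="records")
        return d


def normality_check(x, alpha: float = NORMALITY_ALPHA) -> NormalityResult:
    """D'Agostino-Pearson K² omnibus test.

    Samples with n < 8 (the omnibus minimum) or zero variance are flagged
    "assume non-normal" without a statistic.
    """
    x = np.asarray(x, dtype=float)
    if x.size < MIN_OMNIBUS_N:
        return NormalityResult(None, None, normal=False, note="n < 8: assume non-normal")
    if np.ptp(x) == 0:
        return NormalityResult(None, None, normal=False, note="constant sample")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        k2, p = sps.normaltest(x)
    return NormalityResult(float(k2), float(p), normal=p >= alpha)


def _align_pairs(a: pd.DataFrame, b: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Match two long-format (unit_id, value) tables on unit_id."""
    merged = a.merge(b, on="unit_id", suffixes=("_a", "_b"))
    if len(merged) < len(a) or len(merged) < len(b):
        raise ValueError("samples are not fully matched on unit_id")
    return merged["value_a"].to_numpy(float), merged["value_b"].to_numpy(float)


def paired_compare(a, b, unit_ids=None) -> TestReport:
    """Compare two matched samples with normality-gated test selection.

    ``a``/``b`` may be plain value arrays (assumed aligned) or DataFrames
    with ``unit_id``/``value`` columns.
    """
    if isinstance(a, pd.DataFrame):
        x, y = _align_pairs(a, b)
    else:
        x, y = np.asarray(a, float), np.asarray(b, float)
        if x.size != y.size:
            raise ValueError("paired samples must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    d = x - y
    if np.all(d == 0):
        return TestReport("paired_t", 0.0, x.size - 1, 1.0, normality_p=None)
    norm = normality_check(d)
    if norm.normal:
        t, p = sps.ttest_rel(x, y)
        return TestReport("paired_t", float(t), x.size - 1, float(p), normality_p=norm.p_value)
    stat, p = _wilcoxon_signed_rank(d)
    return TestReport("wilcoxon", float(stat), x.size, float(p), normality_p=norm.p_value)


def _wilcoxon_signed_rank(d: np.ndarray, exact_max_n: int = 25) -> tuple[float, float]:
    """Wilcoxon signed-rank on differences: zeros dropped (Wilcoxon
    convention), mid-ranks for ties; exact p for small tie-free samples,
    otherwise normal approximation with continuity correction."""
    d = d[d != 0]
    if d.size == 0:
        return 0.0, 1.0
    ranks = sps.rankdata(np.abs(d))
    has_ties = np.unique(np.abs(d)).size < d.size
    method = "exact" if (d.size <= exact_max_n and not has_ties) else "approx"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sps.wilcoxon(d, correction=(method == "approx"), method=method)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# three-condition repeated designs


def _wide_from_long(df: pd.DataFrame, conditions: list[str] | None) -> pd.DataFrame:
    wide = df.pivot(index="unit_id", columns="condition", values="value")
    if conditions is not None:
        wide = wide[conditions]
    if wide.isna().any().any():
        missing = [
            f"{u}/{c}"
            for u in wide.index
            for c in wide.columns
            if pd.isna(wide.loc[u, c])
        ]
        raise ValueError(f"incomplete blocks; missing cells: {missing}")
    return wide


def _rm_anova(data: np.ndarray) -> dict:
    """Two-way repeated-measures ANOVA (units x conditions, no replication)
    with Greenhouse-Geisser epsilon."""
    n, k = data.shape
    grand = data.mean()
    cond_means = data.mean(axis=0)
    unit_means = data.mean(axis=1)
    ss_cond = n * np.sum((cond_means - grand) ** 2)
    ss_unit = k * np.sum((unit_means - grand) ** 2)
    ss_tot = np.sum((data - grand) ** 2)
    ss_err = ss_tot - ss_cond - ss_unit
    df_cond = k - 1
    df_err = (n - 1) * (k - 1)
    ms_cond = ss_cond / df_cond
    ms_err = ss_err / df_err if df_err > 0 else 0.0
    if ms_err <= 0:
        f_stat = 0.0 if ss_cond == 0 else np.inf
        p = 1.0 if ss_cond == 0 else 0.0
        eps = 1.0
        p_gg = p
    else:
        f_stat = ms_cond / ms_err
        p = float(sps.f.sf(f_stat, df_cond, df_err))
        # Greenhouse-Geisser epsilon from the double-centered covariance
        s = np.cov(data, rowvar=False, ddof=1)
        s_dc = s - s.mean(axis=0, keepdims=True) - s.mean(axis=1, keepdims=True) + s.mean()
        num = np.trace(s_dc) ** 2
        den = (k - 1) * np.sum(s_dc**2)
        eps = float(num / den) if den > 0 else 1.0
        eps = min(1.0, max(eps, 1.0 / (k - 1)))
        p_gg = float(sps.f.sf(f_stat, df_cond * eps, df_err * eps))
    return {
        "F": float(f_stat),
        "p": p,
        "p_gg": p_gg,
        "gg_epsilon": eps,
        "df_cond": df_cond,
        "df_err": df_err,
        "ms_err": ms_err,
    }


def _tukey_posthoc(data: np.ndarray, conditions: list[str], ms_err: float, df_err: int) -> pd.DataFrame:
    n, k = data.shape
    rows = []
    means = data.mean(axis=0)
    se = np.sqrt(ms_err / n) if ms_err > 0 else 0.0
    for i in range(k):
        for j in range(i + 1, k):
            diff = means[i] - means[j]
            if se > 0:
                q = abs(diff) / se
                p = float(sps.studentized_range.sf(q, k, df_err))
            else:
                q, p = (0.0, 1.0) if diff == 0 else (np.inf, 0.0)
            rows.append(
                {
                    "a": conditions[i],
                    "b": conditions[j],
                    "mean_diff": float(diff),
                    "statistic": float(q),
                    "p_value": p,
                }
            )
    return pd.DataFrame(rows)


def _dunn_posthoc(data: np.ndarray, conditions: list[str]) -> pd.DataFrame:
    """Dunn's post-test for the Friedman design: within-block ranks,
    pairwise z on rank sums, Bonferroni over the pairs."""
    n, k = data.shape
    ranks = sps.rankdata(data, axis=1)
    rank_sums = ranks.sum(axis=0)
    se = np.sqrt(n * k * (k + 1) / 6.0)
    n_pairs = k * (k - 1) // 2
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            z = (rank_sums[i] - rank_sums[j]) / se
            p = min(1.0, 2.0 * float(sps.norm.sf(abs(z))) * n_pairs)
            rows.append(
                {
                    "a": conditions[i],
                    "b": conditions[j],
                    "statistic": float(z),
                    "p_value": p,
                }
            )
    return pd.DataFrame(rows)


def repeated_compare(
    samples: pd.DataFrame,
    conditions: list[str] | None = None,
    post_hoc: bool = True,
) -> TestReport:
    """Compare >= 3 matched conditions (long table: unit_id, condition, value).

    Residual normality gates between repeated-measures ANOVA (+ Tukey) and
    the Friedman test (+ Dunn, Bonferroni-adjusted).  Both raw and
    Greenhouse-Geisser-corrected ANOVA p-values are reported.
    """
    if conditions is None:
        conditions = list(pd.unique(samples["condition"]))
    wide = _wide_from_long(samples, conditions)
    data = wide.to_numpy(float)
    n, k = data.shape
    if n < 3 or k < 3:
        raise ValueError("need >= 3 units and >= 3 conditions")

    residuals = (
        data
        - data.mean(axis=1, keepdims=True)
        - data.mean(axis=0, keepdims=True)
        + data.mean()
    )
    norm = normality_check(residuals.ravel())

    if norm.normal:
        res = _rm_anova(data)
        post = (
            _tukey_posthoc(data, conditions, res["ms_err"], res["df_err"]) if post_hoc else None
        )
        return TestReport(
            "rm_anova",
            res["F"],
            res["df_err"],
            res["p"],
            normality_p=norm.p_value,
            post_hoc=post,
            extra={"p_gg": res["p_gg"], "gg_epsilon": res["gg_epsilon"], "df_cond": res["df_cond"]},
        )
    if np.all(np.ptp(data, axis=1) == 0):
        # every block fully tied: no evidence of any condition effect
        q_stat, p = 0.0, 1.0
    else:
        q_stat, p = sps.friedmanchisquare(*[data[:, j] for j in range(k)])
    post = _dunn_posthoc(data, conditions) if post_hoc else None
    return TestReport(
        "friedman", float(q_stat), n, float(p), normality_p=norm.p_value, post_hoc=post
    )


def unpaired_compare(a, b) -> TestReport:
    """Two independent groups: unpaired t when both pass normality, else
    Mann-Whitney U."""
    x, y = np.asarray(a, float), np.asarray(b, float)
    if x.size < 3 or y.size < 3:
        raise ValueError("need at least 3 observations per group")
    na, nb = normality_check(x), normality_check(y)
    if na.normal and nb.normal:
        t, p = sps.ttest_ind(x, y)
        return TestReport("unpaired_t", float(t), x.size + y.size - 2, float(p),
                          normality_p=min(na.p_value, nb.p_value))
    u, p = sps.mannwhitneyu(x, y, alternative="two-sided")
    norm_p = None
    for r in (na, nb):
        if r.p_value is not None:
            norm_p = r.p_value if norm_p is None else min(norm_p, r.p_value)
    return TestReport("mann_whitney", float(u), x.size + y.size, float(p), normality_p=norm_p)
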