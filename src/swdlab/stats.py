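"""Normality-gated paired comparisons and sphericity-corrected rm-ANOVA.

The experimental unit is the animal: each measure is summarized per animal
per condition, differences are tested for normality (Shapiro–Wilk at
α = 0.05), and a paired t-test or Wilcoxon signed-rank test follows the
gate's verdict.  Multi-condition designs use a one-way repeated-measures
ANOVA with Greenhouse–Geisser (optionally Huynh–Feldt) corrected degrees of
freedom; pairwise post-hocs are Holm-corrected paired comparisons.
SE is always SD/√n across animals (mean ± SEM convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sst

__all__ = [
    "PairedSample",
    "StatResult",
    "normality_gate",
    "paired_compare",
    "rm_anova_gg",
    "holm_correction",
    "results_table",
]

ALPHA = 0.05


@dataclass
class PairedSample:
    """Per-animal values under two conditions, in matching order."""

    animal_ids: list[str]
    values_a: np.ndarray
    values_b: np.ndarray
    condition_a: str = "A"
    condition_b: str = "B"
    measure: str = "value"
    units: str = ""

    def __post_init__(self) -> None:
        self.values_a = np.asarray(self.values_a, dtype=float)
        self.values_b = np.asarray(self.values_b, dtype=float)
        if not (len(self.animal_ids) == self.values_a.size == self.values_b.size):
            raise ValueError("animal ids and both value vectors must align")
        if self.values_a.size < 2:
            raise ValueError("paired comparison needs n ≥ 2 animals")

    @property
    def differences(self) -> np.ndarray:
        """Condition B minus condition A, per animal."""
        return self.values_b - self.values_a


@dataclass
class StatResult:
    test_name: str
    statistic: float
    df: tuple[float, ...]          # () for Wilcoxon, (df,) for t, (df1, df2) for F
    p_value: float
    n: int
    conditions: tuple[str, ...]
    means: tuple[float, ...]
    sems: tuple[float, ...]
    normality_p: float | None = None
    alpha: float = ALPHA
    epsilon: float | None = None   # sphericity epsilon (rm-ANOVA only)
    measure: str = "value"
    posthoc: list["StatResult"] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / np.sqrt(x.size))


def normality_gate(differences: np.ndarray, alpha: float = ALPHA) -> tuple[float, bool]:
    """Shapiro–Wilk on the paired differences; parametric ⇔ p ≥ α.

    Degenerate (constant) difference vectors cannot reject normality and pass
    the gate with p = 1.
    """
    d = np.asarray(differences, dtype=float)
    if d.size < 3:
        raise ValueError(f"normality test requires n ≥ 3, got n = {d.size}")
    if np.ptp(d) == 0:
        return 1.0, True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat, p = sst.shapiro(d)
    return float(p), p >= alpha


def paired_compare(
    sample: PairedSample, alpha: float = ALPHA, method: str = "auto"
) -> StatResult:
    """Paired t-test if the differences pass the normality gate, else
    Wilcoxon signed-rank (exact p for n ≤ 25 without zero differences,
    normal approximation with continuity correction otherwise).

    ``method`` overrides the gate: "t" or "wilcoxon" force that branch,
    "auto" (default) follows the Shapiro–Wilk verdict.  All-zero differences
    are a degenerate no-effect result (statistic 0, p = 1) rather than an
    error.
    """
    if method not in ("auto", "t", "wilcoxon"):
        raise ValueError(f"unknown method {method!r}")
    d = sample.differences
    n = d.size
    common = dict(
        n=n,
        conditions=(sample.condition_a, sample.condition_b),
        means=(float(sample.values_a.mean()), float(sample.values_b.mean())),
        sems=(_sem(sample.values_a), _sem(sample.values_b)),
        measure=sample.measure,
        alpha=alpha,
    )
    if np.all(d == 0):
        return StatResult(
            test_name="degenerate (all differences zero)",
            statistic=0.0, df=(float(n - 1),), p_value=1.0,
            normality_p=1.0, **common,
        )
    norm_p, parametric = normality_gate(d, alpha)
    if method != "auto":
        parametric = method == "t"
    if parametric:
        res = sst.ttest_rel(sample.values_b, sample.values_a)
        return StatResult(
            test_name="paired t-test",
            statistic=float(res.statistic),
            df=(float(n - 1),),
            p_value=float(res.pvalue),
            normality_p=norm_p,
            **common,
        )
    use_exact = n <= 25 and not np.any(d == 0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if use_exact:
            try:
                res = sst.wilcoxon(d, method="exact")
            except ValueError:
                res = sst.wilcoxon(d, method="approx", correction=True)
        else:
            res = sst.wilcoxon(d, method="approx", correction=True)
    return StatResult(
        test_name="Wilcoxon signed-rank",
        statistic=float(res.statistic),
        df=(),
        p_value=float(res.pvalue),
        normality_p=norm_p,
        **common,
    )


def _gg_epsilon(data: np.ndarray) -> float:
    """Greenhouse–Geisser epsilon from the condition covariance matrix."""
    k = data.shape[1]
    S = np.cov(data, rowvar=False, ddof=1)
    C = np.eye(k) - np.ones((k, k)) / k
    M = C @ S @ C
    tr = np.trace(M)
    denom = (k - 1) * np.trace(M @ M)
    if denom <= 0:
        return 1.0
    eps = tr**2 / denom
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def rm_anova_gg(
    data: np.ndarray,
    conditions: Sequence[str] | None = None,
    correction: str = "gg",
    posthoc: bool = False,
    measure: str = "value",
) -> StatResult:
    """One-way repeated-measures ANOVA with sphericity-corrected df.

    ``data`` is a complete animals × conditions matrix (no imputation:
    missing cells are an error).  F = MS_condition / MS_error from the
    within-subject sums of squares; degrees of freedom are scaled by the
    Greenhouse–Geisser epsilon (``correction='hf'`` for Huynh–Feldt, 'none'
    to disable).  With k = 2 conditions ε = 1 and F equals the paired t².
    Optional Holm-corrected pairwise post-hocs via :func:`paired_compare`.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be a 2-D animals × conditions matrix")
    n, k = data.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 animals and 2 conditions")
    if np.any(~np.isfinite(data)):
        raise ValueError("missing or non-finite cells; no imputation is performed")
    if conditions is None:
        conditions = [f"cond_{j}" for j in range(k)]

    grand = data.mean()
    col_means = data.mean(axis=0)
    row_means = data.mean(axis=1)
    ss_cond = n * np.sum((col_means - grand) ** 2)
    resid = data - row_means[:, None] - col_means[None, :] + grand
    ss_err = np.sum(resid**2)
    df1, df2 = k - 1, (k - 1) * (n - 1)

    if ss_cond == 0:
        F, p, eps = 0.0, 1.0, _gg_epsilon(data)
        dfc = (eps * df1, eps * df2)
    else:
        ms_cond = ss_cond / df1
        ms_err = ss_err / df2
        if correction == "gg":
            eps = _gg_epsilon(data)
        elif correction == "hf":
            e_gg = _gg_epsilon(data)
            eps = (n * df1 * e_gg - 2) / (df1 * (n - 1 - df1 * e_gg))
            eps = float(np.clip(eps, 1.0 / df1, 1.0))
        elif correction == "none":
            eps = 1.0
        else:
            raise ValueError(f"unknown correction {correction!r}")
        dfc = (eps * df1, eps * df2)
        if ms_err == 0:
            F, p = np.inf, 0.0
        else:
            F = float(ms_cond / ms_err)
            p = float(sst.f.sf(F, *dfc))

    post = None
    if posthoc:
        raw = []
        for i in range(k):
            for j in range(i + 1, k):
                raw.append(
                    paired_compare(
                        PairedSample(
                            animal_ids=[str(a) for a in range(n)],
                            values_a=data[:, i],
                            values_b=data[:, j],
                            condition_a=str(conditions[i]),
                            condition_b=str(conditions[j]),
                            measure=measure,
                        )
                    )
                )
        adjusted = holm_correction([r.p_value for r in raw])
        post = []
        for r, p_adj in zip(raw, adjusted):
            r.p_value = p_adj
            r.test_name += " (Holm-adjusted)"
            post.append(r)

    return StatResult(
        test_name=f"rm-ANOVA ({correction.upper()} corrected)"
        if correction != "none"
        else "rm-ANOVA",
        statistic=float(F),
        df=tuple(float(x) for x in dfc),
        p_value=float(p),
        n=n,
        conditions=tuple(str(c) for c in conditions),
        means=tuple(float(m) for m in col_means),
        sems=tuple(_sem(data[:, j]) for j in range(k)),
        epsilon=float(eps),
        measure=measure,
        posthoc=post,
    )


def holm_correction(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj.tolist()


def results_table(results: Sequence[StatResult]) -> pd.DataFrame:
    """Flatten results into the summary-table layout: comparison,
    mean ± SE per condition, n, test, statistic, df, p."""
    rows = []
    for r in results:
        mean_se = "; ".join(
            f"{c}: {m:.4g} ± {s:.4g}"
            for c, m, s in zip(r.conditions, r.means, r.sems)
        )
        rows.append(
            {
                "comparison": " vs ".join(r.conditions),
                "measure": r.measure,
                "mean_se": mean_se,
                "n": r.n,
                "test": r.test_name,
                "statistic": r.statistic,
                "df": ", ".join(f"{d:.4g}" for d in r.df),
                "p_value": r.p_value,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "comparison", "measure", "mean_se", "n", "test", "statistic",
            "df", "p_value",
        ],
    )
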