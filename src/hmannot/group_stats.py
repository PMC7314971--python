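"""Two-group comparison with a normality/variance-driven test choice.

For each per-sample metric: if both groups look normal (Shapiro-Wilk,
p >= 0.05), test variance homogeneity; homogeneous variances get Student's
t, heterogeneous get Welch's t (the classical t'); if either group departs
from normality, the Mann-Whitney U test is used. All tests are two-tailed
with significance at p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from hmannot.group_sets import GroupSpec

__all__ = ["StatTestResult", "choose_test", "compare_groups", "variance_f_test"]

ALPHA = 0.05


@dataclass(frozen=True)
class StatTestResult:
    variable: str
    test_used: str  # student_t | welch_t | mann_whitney_u
    p_value: float
    normality_p: tuple[float, float]
    variance_p: float | None
    significant: bool


def variance_f_test(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided F-test of equal variances (classical companion to t/t')."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        return 1.0
    if vy == 0 or vx == 0:
        return 0.0
    f = vx / vy
    dfx, dfy = len(x) - 1, len(y) - 1
    p_one = stats.f.sf(f, dfx, dfy) if f > 1 else stats.f.cdf(f, dfx, dfy)
    return float(min(1.0, 2.0 * p_one))


def choose_test(
    x: Sequence[float],
    y: Sequence[float],
    alpha_norm: float = ALPHA,
    alpha_var: float = ALPHA,
    variance_test: str = "f",
) -> tuple[str, tuple[float, float], float | None]:
    """Pick the comparison test from normality and variance checks.

    Returns ``(test_used, (normality_p_x, normality_p_y), variance_p)``;
    ``variance_p`` is None when the non-parametric branch is taken.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("each group needs at least 3 values")

    def _shapiro_p(v: np.ndarray) -> float:
        if np.ptp(v) == 0:
            return 1.0  # a constant sample cannot reject normality
        return float(stats.shapiro(v).pvalue)

    norm_p = (_shapiro_p(x), _shapiro_p(y))
    if norm_p[0] >= alpha_norm and norm_p[1] >= alpha_norm:
        if variance_test == "f":
            var_p = variance_f_test(x, y)
        elif variance_test == "levene":
            var_p = float(stats.levene(x, y).pvalue)
        else:
            raise ValueError(f"unknown variance test {variance_test!r}")
        return ("student_t" if var_p >= alpha_var else "welch_t"), norm_p, var_p
    return "mann_whitney_u", norm_p, None


def _mann_whitney_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann-Whitney p: exact for small untied samples, else
    normal approximation with continuity correction."""
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if len(x) + len(y) <= 20 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def run_test(x: Sequence[float], y: Sequence[float], test_used: str) -> float:
    """Two-tailed p-value of the selected test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if test_used == "student_t":
        if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
            return 1.0 if np.mean(x) == np.mean(y) else 0.0
        return float(stats.ttest_ind(x, y, equal_var=True).pvalue)
    if test_used == "welch_t":
        return float(stats.ttest_ind(x, y, equal_var=False).pvalue)
    if test_used == "mann_whitney_u":
        return _mann_whitney_p(x, y)
    raise ValueError(f"unknown test {test_used!r}")


def compare_groups(
    metrics: Mapping[str, Mapping[str, float]],
    spec: GroupSpec,
    alpha: float = ALPHA,
    force_test: str | None = None,
) -> list[StatTestResult]:
    """Apply the decision tree to each metric across a two-group design.

    ``metrics`` maps variable name -> {sample_id -> value}. Every sample in
    the grouping must have a value for every metric. ``force_test``
    bypasses the decision tree (used for sensitivity checks).
    """
    labels = spec.labels
    if len(labels) != 2:
        raise ValueError("compare_groups requires exactly two groups")
    results: list[StatTestResult] = []
    for variable in sorted(metrics):
        values = metrics[variable]
        for sample in spec.grouping:
            if sample not in values:
                raise ValueError(f"metric {variable!r} missing value for sample {sample!r}")
        x = [values[s] for s in spec.samples_in(labels[0])]
        y = [values[s] for s in spec.samples_in(labels[1])]
        if force_test is None:
            test_used, norm_p, var_p = choose_test(x, y)
        else:
            test_used, norm_p, var_p = force_test, (float("nan"), float("nan")), None
        p = run_test(x, y, test_used)
        results.append(
            StatTestResult(
                variable=variable,
                test_used=test_used,
                p_value=p,
                normality_p=norm_p,
                variance_p=var_p,
                significant=bool(p < alpha),
            )
        )
    return results


def write_stats_tsv(results: Sequence[StatTestResult], path) -> None:
    with open(path, "wt") as handle:
        handle.write("variable\ttest_used\tp_value\tsignificant\tnormality_p_x\tnormality_p_y\tvariance_p\n")
        for r in results:
            vp = "" if r.variance_p is None else f"{r.variance_p:.6g}"
            handle.write(
                f"{r.variable}\t{r.test_used}\t{r.p_value:.6g}\t{int(r.significant)}\t"
                f"{r.normality_p[0]:.6g}\t{r.normality_p[1]:.6g}\t{vp}\n"
            )
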