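"""Group-level statistics and reporting for psAFRET results.

Summaries are mean +/- sem per group.  Two groups are compared with a
two-tailed Welch t-test (unequal variances); three or more with one-way
ANOVA followed by Tukey-Kramer pairwise comparisons (studentized-range
based, valid for unequal group sizes).  Effect sizes use Cohen's d with the
pooled standard deviation in the denominator; a compatibility mode divides
by the pooled variance instead for cross-checking against reports that used
that convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError, NumericalError
from .fitting import PsafretResult

__all__ = [
    "GroupSummary",
    "TestResult",
    "summarize",
    "cohens_d",
    "welch_t",
    "anova_tukey",
    "plot_trace",
    "plot_groups",
    "report",
]


@dataclass
class GroupSummary:
    label: str
    n: int
    mean: float
    sem: float


@dataclass
class TestResult:
    name: str
    statistic: float
    p_value: float
    effect_size_d: float | None
    groups: tuple[str, ...]


def summarize(values, label: str = "") -> GroupSummary:
    """Mean +/- sem summary of one group (n >= 2)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise NumericalError(f"group '{label}' needs n >= 2, got {v.size}")
    return GroupSummary(
        label=label, n=v.size, mean=float(v.mean()), sem=float(v.std(ddof=1) / np.sqrt(v.size))
    )


def _pooled_sd(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    return float(np.sqrt(sp2))


def cohens_d(group_a, group_b, *, variance_denominator: bool = False) -> float:
    """Cohen's d = |mean_a - mean_b| / s_p with s_p the pooled SD.

    ``variance_denominator=True`` divides by the pooled variance s_p^2
    instead — a non-standard convention offered for compatibility with
    reports computed that way.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise NumericalError("cohens_d needs n >= 2 in each group")
    sp = _pooled_sd(a, b)
    if sp == 0:
        if a.mean() == b.mean():
            return 0.0
        raise NumericalError("zero pooled variance with unequal means: d undefined")
    denom = sp**2 if variance_denominator else sp
    return float(abs(a.mean() - b.mean()) / denom)


def welch_t(group_a, group_b, labels: tuple[str, str] = ("a", "b")) -> TestResult:
    """Two-tailed Welch t-test (unequal variances) with Cohen's d."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise NumericalError("welch_t needs n >= 2 in each group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return TestResult("welch_t", 0.0, 1.0, 0.0, labels)
        raise NumericalError("both groups have zero variance: t undefined")
    res = sps.ttest_ind(a, b, equal_var=False)
    return TestResult(
        name="welch_t",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        effect_size_d=cohens_d(a, b),
        groups=labels,
    )


def anova_tukey(groups: dict[str, np.ndarray], alpha: float = 0.05) -> list[TestResult]:
    """One-way ANOVA followed by Tukey-Kramer pairwise comparisons.

    Returns the ANOVA result first, then one :class:`TestResult` per pair
    (studentized-range statistic, Tukey-adjusted p, Cohen's d).  With fewer
    than three groups use :func:`welch_t` instead.
    """
    if len(groups) < 3:
        raise NumericalError("anova_tukey needs >= 3 groups; use welch_t for two")
    labels = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    for k, arr in zip(labels, arrays):
        if arr.size < 2:
            raise NumericalError(f"group '{k}' needs n >= 2")

    if all(np.ptp(arr) == 0 for arr in arrays) and len({arr.mean() for arr in arrays}) == 1:
        # identical constant groups: F = 0 by convention, nothing significant
        out = [TestResult("anova", 0.0, 1.0, None, tuple(labels))]
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                out.append(TestResult("tukey_kramer", 0.0, 1.0, 0.0, (labels[i], labels[j])))
        return out

    f_stat, f_p = sps.f_oneway(*arrays)
    results = [TestResult("anova", float(f_stat), float(f_p), None, tuple(labels))]
    tk = sps.tukey_hsd(*arrays)
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            results.append(
                TestResult(
                    name="tukey_kramer",
                    statistic=float(tk.statistic[i, j]),
                    p_value=float(tk.pvalue[i, j]),
                    effect_size_d=cohens_d(arrays[i], arrays[j]),
                    groups=(labels[i], labels[j]),
                )
            )
    return results


def plot_trace(result: PsafretResult, path: str | Path) -> None:
    """Anisotropy vs fraction photoswitched with the fitted line and endpoints."""
    if result.trace is None:
        raise DataError("result carries no trace to plot")
    tr = result.trace
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(tr.fraction, tr.r, "o", ms=4, color="0.4", label="data")
    xs = np.linspace(0.0, 1.0, 2)
    ax.plot(1.0 - xs, result.fit.a + result.fit.b * xs, "-", color="tab:red", label="fit")
    ax.plot([0.0], [result.r_et1], "s", color="tab:blue")
    ax.plot([1.0], [result.r_et0], "s", color="tab:green")
    ax.annotate(f"r_et1={result.r_et1:.3f}", (0.02, result.r_et1))
    ax.annotate(f"r_et0={result.r_et0:.3f}", (0.75, result.r_et0))
    ax.set_xlabel("fraction photoswitched F(t)")
    ax.set_ylabel("anisotropy r")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_groups(groups: dict[str, np.ndarray], path: str | Path, ylabel: str = "value") -> None:
    """Bar chart of group means with sem whiskers and individual points."""
    if not groups:
        raise DataError("no groups to plot")
    fig, ax = plt.subplots(figsize=(1.2 + 1.0 * len(groups), 4))
    rng = np.random.default_rng(0)  # jitter for point overlay only
    for i, (label, vals) in enumerate(groups.items()):
        vals = np.asarray(vals, dtype=float)
        if vals.size == 0:
            plt.close(fig)
            raise DataError(f"group '{label}' is empty")
        sem = vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else 0.0
        ax.bar(i, vals.mean(), yerr=sem, capsize=4, color="0.8", edgecolor="k")
        ax.plot(i + rng.uniform(-0.15, 0.15, vals.size), vals, "o", ms=4, color="0.2", alpha=0.7)
    ax.set_xticks(range(len(groups)), list(groups))
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def report(
    results: dict[str, list[PsafretResult]],
    out_dir: str | Path,
) -> pd.DataFrame:
    """Write summary table and figures for grouped psAFRET results.

    Produces a mean +/- sem table (delta_r and drFRET per group), bar charts
    for both quantities, and one trace plot per group's first result when a
    trace is attached.  Returns the summary table.
    """
    if not results or all(len(v) == 0 for v in results.values()):
        raise DataError("empty report input: no results in any group")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    delta_groups: dict[str, np.ndarray] = {}
    drfret_groups: dict[str, np.ndarray] = {}
    for label, res_list in results.items():
        if not res_list:
            raise DataError(f"group '{label}' is empty")
        dr = np.array([r.delta_r for r in res_list])
        df_ = np.array([r.drfret for r in res_list])
        delta_groups[label] = dr
        drfret_groups[label] = df_
        rows.append(
            {
                "group": label,
                "n": dr.size,
                "delta_r_mean": dr.mean(),
                "delta_r_sem": dr.std(ddof=1) / np.sqrt(dr.size) if dr.size > 1 else 0.0,
                "drfret_mean": df_.mean(),
                "drfret_sem": df_.std(ddof=1) / np.sqrt(df_.size) if df_.size > 1 else 0.0,
            }
        )
        first = res_list[0]
        if first.trace is not None:
            plot_trace(first, out_dir / f"trace_{label}.png")

    plot_groups(delta_groups, out_dir / "delta_r.png", ylabel="delta r")
    plot_groups(drfret_groups, out_dir / "drfret.png", ylabel="drFRET")
    table = pd.DataFrame(rows)
    table.to_csv(out_dir / "summary.csv", index=False)
    return table
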