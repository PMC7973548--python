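"""Condition-comparison statistics with a normality-gated test choice.

Every group of per-subject values is first screened with Shapiro-Wilk.
If all groups look Gaussian (p >= 0.05) a parametric test is used:
paired t for two paired groups, one-way repeated-measures ANOVA for three
or more epochs, one-way ANOVA for independent groups.  If any group fails
the gate, the nonparametric ladder applies: Wilcoxon signed-rank for two
paired groups, Friedman with Nemenyi post-hoc for repeated measures with
three or more epochs, Kruskal-Wallis for independent groups.  No
multiple-testing correction is applied across metrics.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as st

__all__ = ["StatReport", "select_test", "compare_epochs", "nemenyi_friedman"]

GATE_ALPHA = 0.05

_TEST_NAMES = {
    "paired t",
    "wilcoxon",
    "one-way anova",
    "kruskal",
    "rm-anova",
    "friedman+nemenyi",
    "all-tie",
}


@dataclass
class StatReport:
    """Outcome of a gated condition comparison."""

    test: str
    gate_p: dict
    statistic: float
    p_value: float
    n: int
    posthoc: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.test not in _TEST_NAMES:
            raise ValueError(f"unknown test name {self.test!r}")
        if self.n < 2:
            raise ValueError(f"need n >= 2 subjects, got {self.n}")

    def to_dict(self) -> dict:
        return asdict(self)


def _shapiro_p(values: np.ndarray) -> float:
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError(
            f"normality gate needs >= 3 values per group, got {v.size}"
        )
    if np.ptp(v) == 0:
        return 0.0  # degenerate: treat a constant group as non-Gaussian
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(st.shapiro(v).pvalue)


def select_test(groups: list, design: str) -> tuple[str, dict]:
    """Choose the test for a set of value groups under a given design.

    ``design`` is ``'paired'`` (two matched groups), ``'repeated'``
    (three or more matched epochs) or ``'independent'``.  Returns the
    test name and the per-group Shapiro-Wilk gate p-values.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if design == "paired" and k != 2:
        raise ValueError(f"paired design requires exactly 2 groups, got {k}")
    if design == "repeated" and k < 3:
        raise ValueError(
            f"repeated design requires >= 3 epochs, got {k} "
            "(use design='paired' for two)"
        )
    if design == "independent" and k < 2:
        raise ValueError(f"independent design requires >= 2 groups, got {k}")
    if design not in ("paired", "repeated", "independent"):
        raise ValueError(f"unknown design {design!r}")
    gate = {f"group{i}": _shapiro_p(g) for i, g in enumerate(groups)}
    normal = all(p >= GATE_ALPHA for p in gate.values())
    if design == "paired":
        name = "paired t" if normal else "wilcoxon"
    elif design == "repeated":
        name = "rm-anova" if normal else "friedman+nemenyi"
    else:
        name = "one-way anova" if normal else "kruskal"
    return name, gate


def nemenyi_friedman(block: np.ndarray) -> np.ndarray:
    """Nemenyi post-hoc p-values after a Friedman test.

    ``block`` is (n subjects x k epochs).  Within-subject ranks are
    averaged per epoch; the pairwise statistic
    ``q = |R_i - R_j| / sqrt(k (k+1) / (6 n))`` is referred to the
    studentized range distribution (``q * sqrt(2)``, k groups, infinite
    degrees of freedom).  Returns the (k x k) symmetric p-value matrix.
    """
    block = np.asarray(block, dtype=float)
    n, k = block.shape
    ranks = st.rankdata(block, axis=1)
    mean_ranks = ranks.mean(axis=0)
    denom = np.sqrt(k * (k + 1) / (6.0 * n))
    p = np.ones((k, k))
    for i, j in itertools.combinations(range(k), 2):
        q = abs(mean_ranks[i] - mean_ranks[j]) / denom
        pij = float(st.studentized_range.sf(q * np.sqrt(2), k, np.inf))
        p[i, j] = p[j, i] = min(max(pij, 0.0), 1.0)
    return p


def compare_epochs(
    samples: pd.DataFrame,
    metric: str | None = None,
    design: str = "repeated",
    baseline: str | None = None,
    subject_col: str = "subject",
    epoch_col: str = "epoch",
    value_col: str = "value",
) -> StatReport:
    """Run the gated comparison across epochs of a long-format table.

    ``samples`` holds one value per (subject, epoch[, metric]); repeated
    and paired designs require complete blocks.  For Friedman, the
    Nemenyi post-hoc p-values against the baseline epoch (first epoch in
    order of appearance unless given) are reported.
    """
    df = samples
    if metric is not None and "metric" in df.columns:
        df = df[df["metric"] == metric]
    if df.empty:
        raise ValueError(f"no samples for metric {metric!r}")
    epochs = list(dict.fromkeys(df[epoch_col]))
    if baseline is None:
        baseline = epochs[0]
    if baseline not in epochs:
        raise ValueError(f"baseline epoch {baseline!r} not present in data")

    if design in ("paired", "repeated"):
        wide = df.pivot_table(
            index=subject_col, columns=epoch_col, values=value_col, aggfunc="first"
        )[epochs]
        incomplete = wide.index[wide.isna().any(axis=1)].tolist()
        if incomplete:
            raise ValueError(
                f"incomplete blocks for subjects {incomplete}; repeated/"
                "paired designs need every epoch for every subject"
            )
        block = wide.to_numpy(dtype=float)
        groups = [block[:, i] for i in range(block.shape[1])]
        n = block.shape[0]
    else:
        groups = [
            df.loc[df[epoch_col] == e, value_col].to_numpy(dtype=float)
            for e in epochs
        ]
        n = min(len(g) for g in groups)
        block = None

    # all-tie degenerate case: every subject identical across epochs
    if block is not None and np.all(np.ptp(block, axis=1) == 0):
        return StatReport(
            test="all-tie",
            gate_p={},
            statistic=0.0,
            p_value=1.0,
            n=n,
        )

    test, gate = select_test(groups, design)
    posthoc: dict = {}
    if test == "paired t":
        res = st.ttest_rel(groups[0], groups[1])
        stat, p = float(res.statistic), float(res.pvalue)
    elif test == "wilcoxon":
        diffs = groups[1] - groups[0]
        if np.all(diffs == 0):
            stat, p = 0.0, 1.0
        else:
            res = st.wilcoxon(groups[0], groups[1])
            stat, p = float(res.statistic), float(res.pvalue)
    elif test == "one-way anova":
        res = st.f_oneway(*groups)
        stat, p = float(res.statistic), float(res.pvalue)
    elif test == "kruskal":
        res = st.kruskal(*groups)
        stat, p = float(res.statistic), float(res.pvalue)
    elif test == "rm-anova":
        from statsmodels.stats.anova import AnovaRM

        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n), len(groups)),
                "epoch": np.tile(np.arange(len(groups)), n),
                "value": block.reshape(-1),
            }
        )
        table = AnovaRM(long, "value", "subject", within=["epoch"]).fit().anova_table
        stat = float(table["F Value"].iloc[0])
        p = float(table["Pr > F"].iloc[0])
    else:  # friedman + nemenyi
        res = st.friedmanchisquare(*groups)
        stat, p = float(res.statistic), float(res.pvalue)
        pmat = nemenyi_friedman(block)
        b = epochs.index(baseline)
        posthoc = {
            f"{baseline} vs {e}": float(pmat[b, i])
            for i, e in enumerate(epochs)
            if e != baseline
        }
    return StatReport(
        test=test, gate_p=gate, statistic=stat, p_value=p, n=n, posthoc=posthoc
    )
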