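"""Windowed-replicate construction and the gated test-selection protocol.

Long trajectories are divided into non-overlapping 10-ns sub-trajectories;
each (chain, window) pair contributes one replicate value, so a 200-ns
tetramer run yields 80 repetitions per condition (20 per chain). Before
any comparison, normality (Shapiro–Wilk per group) and homoscedasticity
(Levene across groups) are gated at alpha = 0.05: if every gate passes, a
parametric plan is used (Student's t for two groups; one-way ANOVA with
Tukey's post hoc for more); otherwise a non-parametric plan (Mann–Whitney
for two groups; pairwise rank-sum with Bonferroni correction for more).

Successive windows of one trajectory are treated as independent
replicates, exactly as in the protocol this package reproduces; that
independence assumption is documented, not defended.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

DEFAULT_WINDOW_PS = 10_000.0
DEFAULT_ALPHA_GATE = 0.05
EXACT_MW_MAX_N = 20  # combined sample size for exact Mann-Whitney p-values


# ---------------------------------------------------------------------------
# replicate construction

def window_replicates(
    values_by_chain: dict,
    times: np.ndarray,
    window: float = DEFAULT_WINDOW_PS,
    aggregate: str = "mean",
    condition: str = "",
) -> pd.DataFrame:
    """Aggregate per-frame series into per-(chain, window) replicates.

    ``values_by_chain`` maps chain id to a per-frame value array on the
    shared time grid ``times`` (ps). Windows are consecutive and
    non-overlapping; a trailing partial window is discarded. ``aggregate``
    is "sum" (permeation counts) or "mean" (distances, H-bond counts).
    Returns a table with columns (condition, chain, window, value).
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    if aggregate not in ("sum", "mean"):
        raise ValueError(f"aggregate must be 'sum' or 'mean', got {aggregate!r}")
    times = np.asarray(times, dtype=np.float64)
    if len(times) < 2:
        raise ValueError("series needs at least 2 frames")
    dt = times[1] - times[0]
    frames_per_window = int(round(window / dt))
    n_frames = len(times)
    n_windows = n_frames // frames_per_window
    if frames_per_window < 1 or n_windows < 1:
        raise ValueError(
            f"window of {window} ps exceeds the series duration "
            f"({n_frames * dt} ps)"
        )
    rows = []
    agg = np.sum if aggregate == "sum" else np.mean
    for chain, values in values_by_chain.items():
        values = np.asarray(values, dtype=np.float64)
        if values.shape != times.shape:
            raise ValueError(f"chain {chain!r} series length mismatch")
        for w in range(n_windows):
            chunk = values[w * frames_per_window : (w + 1) * frames_per_window]
            rows.append(
                {"condition": condition, "chain": str(chain), "window": w,
                 "value": float(agg(chunk))}
            )
    return pd.DataFrame(rows, columns=["condition", "chain", "window", "value"])


def frames_per_window(window: float, frame_interval: float) -> int:
    """Number of saved frames in one window (e.g. 1000 for 10 ns at 10 ps)."""
    n = int(round(window / frame_interval))
    if n < 1:
        raise ValueError("window shorter than the frame interval")
    return n


def groups_from_table(table: pd.DataFrame, by: str = "condition"):
    """Split a replicate table into (labels, list of value arrays)."""
    labels = list(dict.fromkeys(table[by]))
    return labels, [table.loc[table[by] == lab, "value"].to_numpy() for lab in labels]


# ---------------------------------------------------------------------------
# test selection

@dataclass
class TestPlan:
    parametric: bool
    n_groups: int
    group_sizes: list
    test_name: str
    shapiro_p: list
    levene_p: float
    alpha_gate: float


@dataclass
class TestReport:
    comparison: list
    test_used: str
    gate_results: dict
    comparisons: list = field(default_factory=list)
    family_p: float | None = None  # ANOVA p for parametric multi-group plans

    def to_dict(self) -> dict:
        return {
            "comparison": self.comparison,
            "test_used": self.test_used,
            "gate_results": self.gate_results,
            "family_p": self.family_p,
            "comparisons": self.comparisons,
        }


def select_test(groups, alpha_gate: float = DEFAULT_ALPHA_GATE) -> TestPlan:
    """Choose the test per the gating protocol.

    Shapiro–Wilk per group and Levene across groups at ``alpha_gate``;
    all gates passing selects the parametric branch.
    """
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if len(g) < 3:
            raise ValueError("every group needs at least 3 values")
    shapiro_p = []
    for g in groups:
        if np.ptp(g) == 0:
            shapiro_p.append(0.0)  # a constant sample is non-normal
        else:
            shapiro_p.append(float(sps.shapiro(g).pvalue))
    if all(np.ptp(g) == 0 for g in groups):
        levene_p = 1.0
    else:
        levene_p = float(sps.levene(*groups).pvalue)
    parametric = all(p > alpha_gate for p in shapiro_p) and levene_p > alpha_gate
    if len(groups) == 2:
        name = "Student-t" if parametric else "Mann-Whitney"
    else:
        name = "ANOVA+Tukey" if parametric else "pairwise-Wilcoxon+Bonferroni"
    return TestPlan(
        parametric=parametric,
        n_groups=len(groups),
        group_sizes=[len(g) for g in groups],
        test_name=name,
        shapiro_p=shapiro_p,
        levene_p=levene_p,
        alpha_gate=alpha_gate,
    )


def mann_whitney(x, y):
    """Two-sided Mann–Whitney U.

    Exact p-value (distribution enumeration) for combined n <= 20 without
    ties; otherwise the normal approximation with tie and continuity
    corrections. Returns (U of the first sample, p).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    combined = np.concatenate([x, y])
    if np.ptp(combined) == 0:
        return float(len(x) * len(y) / 2), 1.0
    has_ties = len(np.unique(combined)) < len(combined)
    if len(combined) <= EXACT_MW_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def bonferroni(p: float, m: int) -> float:
    return min(1.0, p * m)


def compare_groups(groups_or_table, plan: TestPlan, labels=None) -> TestReport:
    """Execute a plan produced by :func:`select_test` on the same groups.

    Accepts either a replicate table (grouped by condition) or the list
    of value arrays. Two-sided p-values throughout; Bonferroni multiplies
    by the number of pairwise comparisons (capped at 1); Tukey's HSD
    p-values are family-corrected by construction.
    """
    if isinstance(groups_or_table, pd.DataFrame):
        labels, groups = groups_from_table(groups_or_table)
    else:
        groups = [np.asarray(g, dtype=np.float64) for g in groups_or_table]
        if labels is None:
            labels = [f"group{i}" for i in range(len(groups))]
    if len(groups) != plan.n_groups or [len(g) for g in groups] != plan.group_sizes:
        raise ValueError("groups do not match the ones the plan was built on")
    gates = {
        "shapiro_p": plan.shapiro_p,
        "levene_p": plan.levene_p,
        "alpha_gate": plan.alpha_gate,
    }
    report = TestReport(comparison=list(labels), test_used=plan.test_name,
                        gate_results=gates)

    if plan.n_groups == 2:
        a, b = groups
        if plan.parametric:
            res = sps.ttest_ind(a, b)
            stat, p = float(res.statistic), float(res.pvalue)
        else:
            stat, p = mann_whitney(a, b)
        report.comparisons.append(
            {"pair": (labels[0], labels[1]), "statistic": stat,
             "p_raw": p, "p_corrected": p}
        )
        return report

    pairs = list(combinations(range(plan.n_groups), 2))
    if plan.parametric:
        report.family_p = float(sps.f_oneway(*groups).pvalue)
        tukey = sps.tukey_hsd(*groups)
        for i, j in pairs:
            p = float(tukey.pvalue[i, j])
            report.comparisons.append(
                {"pair": (labels[i], labels[j]),
                 "statistic": float(np.mean(groups[i]) - np.mean(groups[j])),
                 "p_raw": p, "p_corrected": p}
            )
    else:
        m = len(pairs)
        for i, j in pairs:
            stat, p = mann_whitney(groups[i], groups[j])
            report.comparisons.append(
                {"pair": (labels[i], labels[j]), "statistic": stat,
                 "p_raw": p, "p_corrected": bonferroni(p, m)}
            )
    return report


def two_group_test(x, y, alpha_gate: float = DEFAULT_ALPHA_GATE,
                   labels=("a", "b")) -> TestReport:
    """Convenience: gate, select and run the two-group comparison."""
    plan = select_test([x, y], alpha_gate)
    return compare_groups([x, y], plan, labels=list(labels))
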