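"""Gated two-group differential-expression screen.

Each protein is tested with a gate: when both groups look Gaussian
(Shapiro-Wilk p > 0.1 in each) and the variances look homogeneous
(Brown-Forsythe/Levene p > 0.1), a two-sided pooled-variance Student t-test
is used; otherwise a two-sided Mann-Whitney U test with tie correction. A
protein is called up-regulated when its linear fold change (group A over
group B, computed as 2^(mean difference of log2 values)) exceeds 1.5 and the
final p-value is below 0.05; down-regulated below 0.67; otherwise not
significant. No multiple-testing correction is applied to the call, matching
the raw-p convention of the screen; a Benjamini-Hochberg column is reported
for reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import AbundanceMatrix, PipelineConfig

__all__ = ["GateResult", "gate_and_test", "fold_change", "screen_deps"]

STUDENT_T, MANN_WHITNEY = "student_t", "mann_whitney"
UP, DOWN, NS = "up", "down", "ns"


@dataclass
class GateResult:
    test_used: str
    p_value: float
    p_levene: float
    p_shapiro_a: float
    p_shapiro_b: float


def _shapiro_p(x: np.ndarray) -> float:
    # a (near-)constant group cannot be declared Gaussian; fail the gate
    if np.ptp(x) == 0:
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(stats.shapiro(x).pvalue)


def gate_and_test(
    x: np.ndarray,
    y: np.ndarray,
    alpha_gate: float = 0.1,
    *,
    welch: bool = False,
) -> GateResult:
    """Run the normality/variance gate, then the selected two-sided test.

    ``x`` is group A, ``y`` group B; each needs at least 3 finite values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError("each group needs at least 3 values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")

    const_x, const_y = np.ptp(x) == 0, np.ptp(y) == 0
    if const_x and const_y and x[0] == y[0]:
        warnings.warn("both groups constant and identical; p set to 1")
        return GateResult(MANN_WHITNEY, 1.0, np.nan, 0.0, 0.0)

    if const_x and const_y:
        p_lev = np.nan  # Levene undefined on two zero-spread groups
    else:
        p_lev = float(stats.levene(x, y, center="median").pvalue)
    p_sw_a = _shapiro_p(x)
    p_sw_b = _shapiro_p(y)

    gates_pass = (
        np.isfinite(p_lev)
        and p_lev > alpha_gate
        and p_sw_a > alpha_gate
        and p_sw_b > alpha_gate
    )
    if gates_pass:
        p = float(stats.ttest_ind(x, y, equal_var=not welch).pvalue)
        return GateResult(STUDENT_T, p, p_lev, p_sw_a, p_sw_b)
    p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
    return GateResult(MANN_WHITNEY, p, p_lev, p_sw_a, p_sw_b)


def fold_change(x: np.ndarray, y: np.ndarray) -> float:
    """Linear fold change 2^(mean(x) - mean(y)) for log2-scale inputs."""
    return float(2.0 ** (np.mean(x) - np.mean(y)))


def _call(ratio: float, p: float, config: PipelineConfig) -> str:
    if p < config.alpha_dep:
        if ratio > config.fc_up:
            return UP
        if ratio < config.fc_down:
            return DOWN
    return NS


def screen_deps(matrix: AbundanceMatrix, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Screen every protein of a completed two-group matrix.

    Returns a table ordered by protein id with group means, linear fold
    change, the gate p-values, the chosen test, its p-value, a BH-adjusted
    p-value column, and the regulation call.
    """
    config = config or PipelineConfig()
    if matrix.missing_mask.any():
        raise ValueError("screen_deps requires a completed (no-missing) matrix")
    ga, gb = matrix.group_labels
    cols_a, cols_b = matrix.columns_of(ga), matrix.columns_of(gb)
    records = []
    for i, pid in enumerate(matrix.protein_ids):
        x, y = matrix.values[i, cols_a], matrix.values[i, cols_b]
        gate = gate_and_test(x, y, config.alpha_gate, welch=config.welch)
        ratio = fold_change(x, y)
        records.append(
            {
                "protein_id": pid,
                "mean_A": float(np.mean(x)),
                "mean_B": float(np.mean(y)),
                "ratio": ratio,
                "test_used": gate.test_used,
                "p_value": gate.p_value,
                "gate_p_levene": gate.p_levene,
                "gate_p_shapiro_A": gate.p_shapiro_a,
                "gate_p_shapiro_B": gate.p_shapiro_b,
                "call": _call(ratio, gate.p_value, config),
            }
        )
    table = pd.DataFrame.from_records(records).set_index("protein_id")
    table = table.sort_index(kind="mergesort")
    table["p_adj_bh"] = stats.false_discovery_control(table["p_value"], method="bh")
    return table


def summarize_calls(dep_table: pd.DataFrame) -> dict[str, int]:
    """Counts of up/down/ns calls."""
    counts = dep_table["call"].value_counts()
    return {k: int(counts.get(k, 0)) for k in (UP, DOWN, NS)}


def volcano_plot(dep_table: pd.DataFrame, path, config: PipelineConfig | None = None):
    """Minimal volcano figure (log2 ratio vs -log10 p) written to ``path``.

    A convenience for eyeballing a screen; requires matplotlib.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    config = config or PipelineConfig()
    x = np.log2(dep_table["ratio"])
    y = -np.log10(np.maximum(dep_table["p_value"], 1e-300))
    colors = dep_table["call"].map({UP: "tab:red", DOWN: "tab:blue", NS: "0.6"})
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(x, y, s=6, c=colors, linewidths=0)
    for v in (np.log2(config.fc_up), np.log2(config.fc_down)):
        ax.axvline(v, color="0.3", lw=0.6, ls="--")
    ax.axhline(-np.log10(config.alpha_dep), color="0.3", lw=0.6, ls="--")
    ax.set_xlabel("log2 fold change (A / B)")
    ax.set_ylabel("-log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
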