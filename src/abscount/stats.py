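"""Case/control cluster-proportion comparison.

Cluster assignments are consumed as an input column (from any external
clustering, or from simulator truth in tests); this module computes
per-group cluster proportions, case/control fold changes reported to one
decimal, and a two-sided two-proportion z-test per cluster (Fisher's
exact test available as an alternative), optionally with
Benjamini-Hochberg correction.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest


def cluster_proportions(assignments: pd.DataFrame) -> pd.DataFrame:
    """Per-(group, cluster) counts and percentages.

    ``assignments`` needs columns ``cell_id``, ``group``, ``cluster``
    (one row per cell).  Percentages are reported to two decimals, as
    proportions are conventionally printed.
    """
    required = {"cell_id", "group", "cluster"}
    missing = required - set(assignments.columns)
    if missing:
        raise ValueError(f"assignments missing columns: {sorted(missing)}")
    if assignments.empty:
        raise ValueError("empty assignment table")
    if assignments["cell_id"].duplicated().any():
        raise ValueError("duplicate cell_id in assignments")
    tab = (
        assignments.groupby(["group", "cluster"], sort=True)
        .size()
        .rename("n")
        .reset_index()
    )
    totals = tab.groupby("group")["n"].transform("sum")
    tab["pct"] = (100.0 * tab["n"] / totals).round(2)
    return tab


def fold_change(p_case: float, p_control: float) -> float:
    """Case/control ratio of percentages, reported to one decimal.

    A zero control proportion leaves the ratio undefined (NaN).
    """
    if p_control == 0:
        return math.nan
    return round(p_case / p_control, 1)


def proportion_test(
    n_case_k: int,
    n_case: int,
    n_control_k: int,
    n_control: int,
    method: str = "ztest",
) -> float:
    """Two-sided p-value for a difference in cluster proportions."""
    if n_case <= 0 or n_control <= 0:
        raise ValueError("group totals must be positive")
    if n_case_k > n_case or n_control_k > n_control:
        raise ValueError("cluster count exceeds group total")
    if method == "ztest":
        if n_case_k / n_case == n_control_k / n_control:
            return 1.0  # includes the 0/0 and 1/1 edge cases
        _, p = proportions_ztest(
            [n_case_k, n_control_k], [n_case, n_control], alternative="two-sided"
        )
        return float(p)
    if method == "fisher":
        table = [
            [n_case_k, n_case - n_case_k],
            [n_control_k, n_control - n_control_k],
        ]
        return float(sps.fisher_exact(table, alternative="two-sided")[1])
    raise ValueError(f"unknown method {method!r}")


def compare_groups(
    assignments: pd.DataFrame,
    case: str = "case",
    control: str = "control",
    method: str = "ztest",
    fdr: bool = False,
) -> pd.DataFrame:
    """Per-cluster case-vs-control comparison table.

    Columns: cluster, n_case, n_control, pct_case, pct_control,
    fold_change, p_value, test (and q_value under ``fdr=True``).
    """
    groups = set(assignments["group"].unique())
    for g in (case, control):
        if g not in groups:
            raise ValueError(f"group {g!r} absent from assignments")
    tab = cluster_proportions(assignments)
    wide_n = tab.pivot(index="cluster", columns="group", values="n").fillna(0)
    wide_p = tab.pivot(index="cluster", columns="group", values="pct").fillna(0.0)
    n_case_total = int(wide_n[case].sum())
    n_control_total = int(wide_n[control].sum())
    rows = []
    for cluster in wide_n.index:
        nk_case = int(wide_n.loc[cluster, case])
        nk_ctrl = int(wide_n.loc[cluster, control])
        pct_case = float(wide_p.loc[cluster, case])
        pct_ctrl = float(wide_p.loc[cluster, control])
        rows.append(
            {
                "cluster": cluster,
                "n_case": nk_case,
                "n_control": nk_ctrl,
                "pct_case": pct_case,
                "pct_control": pct_ctrl,
                "fold_change": fold_change(pct_case, pct_ctrl),
                "p_value": proportion_test(
                    nk_case, n_case_total, nk_ctrl, n_control_total, method=method
                ),
                "test": method,
            }
        )
    out = pd.DataFrame(rows)
    if fdr:
        out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out
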