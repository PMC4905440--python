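"""Differential-expression screening on log2 microarray intensities.

The screen is deliberately plain: per-probe group means, absolute linear
fold change FC = 2^|Δmean|, a two-sample t-test (pooled-variance unpaired by
default), and the joint filter FC >= 2 and p < 0.05. Benjamini-Hochberg FDR
is computed across all tested probes and reported alongside, but the filter
itself uses the raw p-value. With n = 3 per group this design has limited
power and no variance moderation; it reproduces the published screening
behaviour exactly, which is the point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import CASE, CONTROL, ExpressionMatrix, ProbeAnnotation, ValidationError
from .enrichment import bh_fdr

UP = "up"
DOWN = "down"

DEFAULT_FC_THRESHOLD = 2.0
DEFAULT_P_THRESHOLD = 0.05

#: columns of a DEResult table, in output order
DE_COLUMNS = [
    "probe_id", "mean_control", "mean_case", "delta", "fc_abs",
    "direction", "t", "p_value", "fdr", "significant",
]


def fold_change(control_values, case_values) -> tuple[float, float, str]:
    """Return (delta, fc_abs, direction) for one probe.

    delta = mean(case) - mean(control) in log2 units; fc_abs = 2^|delta| is
    the linear absolute fold change; direction is ``up`` iff delta > 0.
    """
    control = np.asarray(control_values, dtype=float)
    case = np.asarray(case_values, dtype=float)
    for name, arr in (("control", control), ("case", case)):
        if arr.size < 2 or not np.isfinite(arr).all():
            raise ValidationError(f"{name} group needs >= 2 finite values")
    delta = float(case.mean() - control.mean())
    return delta, float(2.0 ** abs(delta)), (UP if delta > 0 else DOWN)


def t_test(control_values, case_values, mode: str = "pooled") -> tuple[float, float, float]:
    """Two-sided two-sample t-test; returns (t, df, p).

    Modes: ``pooled`` (equal-variance unpaired, the default used by the
    screen), ``welch``, and ``paired`` (requires equal group sizes).
    Degenerate zero-variance inputs: zero delta gives p = 1 by convention,
    nonzero delta gives the p -> 0 limit.
    """
    control = np.asarray(control_values, dtype=float)
    case = np.asarray(case_values, dtype=float)
    if control.size < 2 or case.size < 2:
        raise ValidationError("both groups need >= 2 values")
    if mode == "paired":
        if control.size != case.size:
            raise ValidationError("paired test requires equal group sizes")
        res = stats.ttest_rel(case, control)
        df = control.size - 1
    elif mode in ("pooled", "welch"):
        res = stats.ttest_ind(case, control, equal_var=(mode == "pooled"))
        df = float(res.df) if hasattr(res, "df") else control.size + case.size - 2
    else:
        raise ValidationError(f"unknown t-test mode {mode!r}")
    t, p = float(res.statistic), float(res.pvalue)
    if not np.isfinite(t):  # zero variance in both groups
        delta = float(case.mean() - control.mean())
        return (0.0, float(df), 1.0) if delta == 0 else (np.inf * np.sign(delta), float(df), 0.0)
    return t, float(df), p


def screen(
    matrix: ExpressionMatrix,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    test_mode: str = "pooled",
) -> pd.DataFrame:
    """Screen every probe; return a DEResult table.

    One row per probe with group means, delta, fc_abs, direction, t, p,
    BH-adjusted FDR (computed across all tested probes, reported but not
    used by the filter) and the joint significance flag
    ``fc_abs >= fc_threshold and p_value < p_threshold``.
    Rows are sorted by fc_abs descending, ties broken by ascending p then
    probe id, so outputs are byte-reproducible.
    """
    matrix.require_two_per_group()
    ctrl_cols = matrix.samples_in(CONTROL)
    case_cols = matrix.samples_in(CASE)
    ctrl = matrix.values[ctrl_cols].to_numpy()
    case = matrix.values[case_cols].to_numpy()

    rows = []
    for i, probe in enumerate(matrix.probe_ids):
        delta, fc_abs, direction = fold_change(ctrl[i], case[i])
        t, _df, p = t_test(ctrl[i], case[i], mode=test_mode)
        rows.append((probe, ctrl[i].mean(), case[i].mean(), delta, fc_abs, direction, t, p))
    df = pd.DataFrame(rows, columns=DE_COLUMNS[:8])
    df["fdr"] = bh_fdr(df["p_value"].to_numpy())
    df["significant"] = (df["fc_abs"] >= fc_threshold) & (df["p_value"] < p_threshold)
    df = df.sort_values(
        ["fc_abs", "p_value", "probe_id"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return df[DE_COLUMNS]


def significant_ids(results: pd.DataFrame, direction: str | None = None) -> list[str]:
    """Probe ids passing the screen, optionally restricted to up or down."""
    sig = results[results["significant"]]
    if direction is not None:
        sig = sig[sig["direction"] == direction]
    return sig["probe_id"].tolist()


def collapse_to_genes(
    results: pd.DataFrame, annotation: ProbeAnnotation, rule: str = "max_fc"
) -> pd.DataFrame:
    """Collapse probe-level results to one row per gene symbol.

    Keeps the probe with the largest fc_abs per symbol (ties by ascending p
    then probe id); probes without a symbol are dropped. Output gains a
    ``gene_symbol`` column and keeps the screen's sort order.
    """
    if rule != "max_fc":
        raise ValidationError(f"unknown collapse rule {rule!r}")
    symbols = annotation.symbol_map()
    annotated = results[results["probe_id"].isin(symbols)].copy()
    annotated["gene_symbol"] = annotated["probe_id"].map(symbols)
    annotated = annotated.sort_values(
        ["fc_abs", "p_value", "probe_id"], ascending=[False, True, True]
    )
    collapsed = annotated.drop_duplicates(subset="gene_symbol", keep="first")
    return collapsed.reset_index(drop=True)[["gene_symbol", *DE_COLUMNS]]
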