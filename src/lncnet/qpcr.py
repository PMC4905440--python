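"""Relative quantification of qPCR data by the 2^-ΔΔCt method.

Per sample, ΔCt = mean(target Ct) - mean(reference Ct); ΔΔCt references the
control-group mean ΔCt (the group-mean variant of the Livak calibrator,
appropriate for mean ± SEM group comparisons); RQ = 2^-ΔΔCt assumes perfect
doubling per cycle. The group comparison is an unpaired pooled t-test on
ΔΔCt, which is normally distributed under additive Ct noise — testing on RQ
itself would put the test on a skewed scale. Because centering by the
control mean is a constant shift, the test on ΔΔCt equals the test on ΔCt.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CASE, CONTROL, QPCRRecord, ValidationError
from .diffexpr import t_test

RQ_COLUMNS = ["sample_id", "group", "delta_ct", "ddct", "rq", "log2_rq"]


def delta_ct(record: QPCRRecord) -> float:
    """ΔCt = mean(target Ct) - mean(reference Ct) for one sample."""
    return float(np.mean(record.target_ct) - np.mean(record.reference_ct))


@dataclass
class QPCRSummary:
    per_sample: pd.DataFrame          # RQ_COLUMNS
    group_stats: pd.DataFrame         # group, n, mean_rq, sem_rq, mean_log2_rq, sem_log2_rq
    t: float
    p_value: float
    direction: str                    # up / down, case relative to control


def relative_quantity(records: list[QPCRRecord]) -> QPCRSummary:
    """Per-sample RQ plus group summary and case-vs-control test."""
    controls = [r for r in records if r.group == CONTROL]
    cases = [r for r in records if r.group == CASE]
    if len(controls) < 2:
        raise ValidationError("need >= 2 control samples to calibrate ΔΔCt")
    dct = {r.sample_id: delta_ct(r) for r in records}
    calibrator = float(np.mean([dct[r.sample_id] for r in controls]))

    rows = []
    for r in records:
        ddct = dct[r.sample_id] - calibrator
        rows.append((r.sample_id, r.group, dct[r.sample_id], ddct, 2.0 ** -ddct, -ddct))
    per_sample = pd.DataFrame(rows, columns=RQ_COLUMNS)

    stats_rows = []
    for group in (CONTROL, CASE):
        sub = per_sample[per_sample["group"] == group]
        n = len(sub)
        sem = lambda x: float(np.std(x, ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        stats_rows.append((
            group, n,
            float(sub["rq"].mean()), sem(sub["rq"]),
            float(sub["log2_rq"].mean()), sem(sub["log2_rq"]),
        ))
    group_stats = pd.DataFrame(
        stats_rows,
        columns=["group", "n", "mean_rq", "sem_rq", "mean_log2_rq", "sem_log2_rq"],
    )

    ctrl_ddct = per_sample.loc[per_sample["group"] == CONTROL, "ddct"].to_numpy()
    case_ddct = per_sample.loc[per_sample["group"] == CASE, "ddct"].to_numpy()
    if len(case_ddct) >= 2:
        t, _df, p = t_test(ctrl_ddct, case_ddct, mode="pooled")
    else:
        t, p = np.nan, np.nan
    mean_case_log2 = float(per_sample.loc[per_sample["group"] == CASE, "log2_rq"].mean())
    direction = "up" if mean_case_log2 > 0 else "down"
    return QPCRSummary(per_sample, group_stats, t, p, direction)


def read_ct_table(path) -> list[QPCRRecord]:
    """Read a Ct TSV: sample, group, target_ct_1..k, ref_ct_1..k columns."""
    df = pd.read_csv(path, sep="\t")
    tcols = sorted(c for c in df.columns if c.startswith("target_ct"))
    rcols = sorted(c for c in df.columns if c.startswith("ref_ct"))
    if not tcols or not rcols:
        raise ValidationError("Ct table needs target_ct_* and ref_ct_* columns")
    return [
        QPCRRecord(
            sample_id=str(row["sample"]),
            group=str(row["group"]),
            target_ct=tuple(row[c] for c in tcols if pd.notna(row[c])),
            reference_ct=tuple(row[c] for c in rcols if pd.notna(row[c])),
        )
        for _, row in df.iterrows()
    ]


def write_ct_table(records: list[QPCRRecord], path) -> None:
    k_t = max(len(r.target_ct) for r in records)
    k_r = max(len(r.reference_ct) for r in records)
    rows = []
    for r in records:
        row = {"sample": r.sample_id, "group": r.group}
        row.update({f"target_ct_{i+1}": v for i, v in enumerate(r.target_ct)})
        row.update({f"ref_ct_{i+1}": v for i, v in enumerate(r.reference_ct)})
        rows.append(row)
    cols = ["sample", "group"] + [f"target_ct_{i+1}" for i in range(k_t)] + [
        f"ref_ct_{i+1}" for i in range(k_r)
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
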