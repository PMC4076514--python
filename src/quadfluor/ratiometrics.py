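"""Per-cell expression ratios and control-median normalization.

Each cell's background-corrected means yield three ratios — CI-20:porin,
CIV-1:porin and CI-20:CIV-1 — computed per cell; cohort summaries are medians
over cells (never ratios of medians).  Within each experimental run the
control cohort's median of every ratio is set to 100 % and all cells of that
run (patients and control alike) are expressed relative to it, making the
control an internal standard per run; pooling concatenates normalized records
across runs and never recomputes a global control median.

The median convention throughout is the midpoint of the two central order
statistics for even n (numpy's default), so the within-run control median of
the normalized values is 100 exactly (up to two floating-point roundings).
Cells with a degenerate denominator are flagged as excluded with a reason —
never silently dropped.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np
import pandas as pd

from .errors import ValidationError
from .imgio import validate_measurements

#: ratio name -> (numerator column, denominator column)
RATIO_DEFS: Dict[str, Tuple[str, str]] = {
    "ci_porin": ("corr_ci20", "corr_porin"),
    "civ_porin": ("corr_civ1", "corr_porin"),
    "ci_civ": ("corr_ci20", "corr_civ1"),
}

RATIOS = tuple(RATIO_DEFS)

#: default degenerate-signal floor: 1e-6 of the 16-bit ceiling
DEFAULT_EPS = 65535 * 1e-6


def compute_ratios(measurements: pd.DataFrame, eps: float = DEFAULT_EPS) -> pd.DataFrame:
    """Fill the per-cell ratio columns of a measurement table.

    A cell whose denominator (or numerator) corrected mean is ``<= eps`` for
    any ratio is marked ``excluded`` with a reason naming the channel; its
    well-defined ratios are still recorded, degenerate ones are NaN.
    """
    df = validate_measurements(measurements.copy())
    excluded = np.zeros(len(df), dtype=bool)
    reasons = [[] for _ in range(len(df))]
    for name, (num_col, den_col) in RATIO_DEFS.items():
        num = df[num_col].to_numpy(dtype=float)
        den = df[den_col].to_numpy(dtype=float)
        bad_den = den <= eps
        bad_num = num <= eps
        ratio = np.full(len(df), np.nan)
        ok = ~bad_den
        ratio[ok] = num[ok] / den[ok]
        df[f"ratio_{name}"] = ratio
        for i in np.nonzero(bad_den)[0]:
            reasons[i].append(f"zero denominator ({den_col})")
        for i in np.nonzero(bad_num & ~bad_den)[0]:
            reasons[i].append(f"zero numerator ({num_col})")
        excluded |= bad_den | bad_num
    df["excluded"] = excluded
    df["exclude_reason"] = ["; ".join(sorted(set(r))) for r in reasons]
    return df


def normalize_to_control(run_records: pd.DataFrame, control_subject_id: str) -> pd.DataFrame:
    """Express every cell of one run relative to that run's control medians.

    For each ratio the median over non-excluded control cells defines 100 %;
    every cell's normalized value is ``100 * raw / median``.  Raises if the
    run has no usable control cells.
    """
    df = run_records.copy()
    if df["run"].nunique() > 1:
        raise ValidationError("normalize_to_control operates on records of a single run")
    ctrl = df[(df["subject"] == control_subject_id) & (~df["excluded"])]
    if ctrl.empty:
        raise ValidationError(
            f"run has no non-excluded control cells for subject {control_subject_id!r}"
        )
    for name in RATIOS:
        values = ctrl[f"ratio_{name}"].dropna()
        if values.empty:
            raise ValidationError(f"no control values for ratio {name}")
        m = float(np.median(values))
        if m <= 0:
            raise ValidationError(f"control median for {name} is not positive")
        df[f"norm_{name}"] = 100.0 * df[f"ratio_{name}"] / m
    return df


def pool_runs(all_normalized: pd.DataFrame) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Pool normalized records across runs and summarize medians.

    Returns ``(pooled_records, medians)``: the pooled records are the
    concatenation of the runs' normalized records; ``medians`` has one row per
    (subject, ratio) with the pooled median over all non-excluded cells, the
    cell count, and one ``run_<id>`` column per run (the consecutive-run view
    of a cohort figure).  A subject whose cells are all excluded is reported
    with count 0 and a missing median.
    """
    pooled = all_normalized.reset_index(drop=True)
    runs = sorted(pooled["run"].unique())
    rows = []
    for (subject, group), sub in pooled.groupby(["subject", "group"], sort=True):
        usable = sub[~sub["excluded"]]
        for name in RATIOS:
            values = usable[f"norm_{name}"].dropna()
            row = {
                "subject": subject,
                "group": group,
                "ratio": name,
                "n_cells": int(len(values)),
                "pooled_median": float(np.median(values)) if len(values) else np.nan,
            }
            for run in runs:
                rv = usable.loc[usable["run"] == run, f"norm_{name}"].dropna()
                row[f"run_{run}"] = float(np.median(rv)) if len(rv) else np.nan
            rows.append(row)
    return pooled, pd.DataFrame(rows)
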