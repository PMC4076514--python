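"""Non-parametric cohort comparison and figure-style exports.

Densitometric single-cell data are right-skewed and far from normal, so
patient-versus-control comparisons use the Mann–Whitney U test.  The test is
implemented here (midranks, tie-corrected normal approximation with
continuity correction, and an exact small-sample path by full enumeration of
rank assignments) so its behaviour is pinned by this package's tests;
established implementations serve only as cross-checks in the test suite.
"""

from __future__ import annotations

import math
from itertools import combinations
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ValidationError
from .ratiometrics import RATIOS

#: exact enumeration is used when both samples are at most this large
EXACT_MAX_N = 8


def _exact_two_sided_p(ranks_x_sum: float, n_x: int, n_y: int) -> float:
    """Exact p by enumerating all C(n_x + n_y, n_x) rank assignments.

    Valid only without ties (integer ranks).  Under the null the U statistic
    is symmetric about n_x*n_y/2, so the two-sided p doubles the lower tail of
    min(U_x, U_y), capped at 1.
    """
    n = n_x + n_y
    u_x = ranks_x_sum - n_x * (n_x + 1) / 2
    u_min = min(u_x, n_x * n_y - u_x)
    count = 0
    total = 0
    for combo in combinations(range(1, n + 1), n_x):
        total += 1
        u = sum(combo) - n_x * (n_x + 1) / 2
        if min(u, n_x * n_y - u) <= u_min + 1e-9:
            count += 1
    return min(1.0, count / total)


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Two-sided Mann–Whitney U test.

    Ranks are midranks (ties averaged).  When both samples have at most
    ``EXACT_MAX_N`` observations and there are no ties, the p-value is exact
    by full enumeration; otherwise the normal approximation with
    tie-corrected variance and a 0.5 continuity correction is used.  Returns
    ``(U, p)`` with ``U = min(U_x, U_y)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    n_x, n_y = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    r_x = float(ranks[:n_x].sum())
    u_x = r_x - n_x * (n_x + 1) / 2
    u_y = n_x * n_y - u_x
    u = min(u_x, u_y)

    has_ties = np.unique(pooled).size < pooled.size
    if max(n_x, n_y) <= EXACT_MAX_N and not has_ties:
        return u, _exact_two_sided_p(r_x, n_x, n_y)

    # tie-corrected normal approximation with continuity correction
    n = n_x + n_y
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))) if n > 1 else 0.0
    var = n_x * n_y / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return u, 1.0  # all observations identical
    mu = n_x * n_y / 2.0
    z = max(0.0, abs(u - mu) - 0.5) / math.sqrt(var)
    p = math.erfc(z / math.sqrt(2.0))
    return u, min(1.0, p)


def significance_stars(p: float) -> str:
    """Figure annotation convention: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def summarize_cohorts(
    pooled_records: pd.DataFrame,
    control_subject_id: str,
) -> pd.DataFrame:
    """Cohort summary: one row per (subject, ratio).

    Columns: n_cells (non-excluded), pooled median of the normalized ratio,
    per-run medians, and — for non-control subjects — the Mann–Whitney U and
    two-sided p versus the control's pooled cells with significance stars.
    Control rows carry no test (their pooled median is 100 by construction of
    per-run normalization only up to between-run differences).
    """
    if not (pooled_records["subject"] == control_subject_id).any():
        raise ValidationError(f"control subject {control_subject_id!r} absent from records")
    usable = pooled_records[~pooled_records["excluded"]]
    runs = sorted(pooled_records["run"].unique())
    rows = []
    for (subject, group), sub in usable.groupby(["subject", "group"], sort=True):
        for name in RATIOS:
            values = sub[f"norm_{name}"].dropna().to_numpy()
            row = {
                "subject": subject,
                "group": group,
                "ratio": name,
                "n_cells": int(values.size),
                "pooled_median": float(np.median(values)) if values.size else np.nan,
            }
            for run in runs:
                rv = sub.loc[sub["run"] == run, f"norm_{name}"].dropna()
                row[f"run_{run}"] = float(np.median(rv)) if len(rv) else np.nan
            if subject == control_subject_id:
                row.update({"U": np.nan, "p_value": np.nan, "stars": ""})
            else:
                ctrl = usable.loc[
                    usable["subject"] == control_subject_id, f"norm_{name}"
                ].dropna().to_numpy()
                if values.size and ctrl.size:
                    u, p = mann_whitney_u(values, ctrl)
                    row.update({"U": u, "p_value": p, "stars": significance_stars(p)})
                else:
                    row.update({"U": np.nan, "p_value": np.nan, "stars": ""})
            rows.append(row)
    return pd.DataFrame(rows)


def export_figure_data(
    pooled_records: pd.DataFrame,
    path,
    *,
    figure_path: Optional[str] = None,
) -> pd.DataFrame:
    """Write the per-cell long-format table behind a dots-and-median figure.

    One row per (cell, ratio) with columns (subject, group, run, cell_id,
    ratio_name, value); optionally renders a strip plot with per-cell dots
    and a median line per subject for each ratio.
    """
    usable = pooled_records[~pooled_records["excluded"]]
    frames = []
    for name in RATIOS:
        sub = usable[["subject", "group", "run", "cell_id", f"norm_{name}"]].dropna(
            subset=[f"norm_{name}"]
        )
        frames.append(
            sub.rename(columns={f"norm_{name}": "value"}).assign(ratio_name=name)
        )
    long_df = pd.concat(frames, ignore_index=True)[
        ["subject", "group", "run", "cell_id", "ratio_name", "value"]
    ]
    if path is not None:
        long_df.to_csv(path, index=False)
    if figure_path is not None:
        _render_figure(long_df, figure_path)
    return long_df


def _render_figure(long_df: pd.DataFrame, figure_path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ratios = list(dict.fromkeys(long_df["ratio_name"]))
    subjects = sorted(long_df["subject"].unique())
    fig, axes = plt.subplots(1, len(ratios), figsize=(4 * len(ratios), 4), squeeze=False)
    rng = np.random.default_rng(0)  # jitter is cosmetic only
    for ax, name in zip(axes[0], ratios):
        sub = long_df[long_df["ratio_name"] == name]
        for i, subject in enumerate(subjects):
            vals = sub.loc[sub["subject"] == subject, "value"].to_numpy()
            if not vals.size:
                continue
            xs = i + rng.uniform(-0.18, 0.18, vals.size)
            ax.plot(xs, vals, ".", ms=3, alpha=0.4)
            med = np.median(vals)
            ax.hlines(med, i - 0.3, i + 0.3, color="k", lw=2)
        ax.set_xticks(range(len(subjects)), subjects, rotation=30)
        ax.set_ylabel("% of control median")
        ax.set_title(name)
    fig.tight_layout()
    fig.savefig(figure_path, dpi=150)
    plt.close(fig)
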