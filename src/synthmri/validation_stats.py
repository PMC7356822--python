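"""Comparison statistics for phantom validation.

Percent difference between synthetic-scan and reference relaxation
values, Friedman rank tests for interday / intersession repeatability,
Bonferroni correction, and the per-concentration validation report.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, rankdata

from synthmri.synthetic_data import SYNTHETIC_COLUMNS

__all__ = [
    "percent_difference",
    "friedman_test",
    "bonferroni",
    "build_validation_report",
    "ValidationReport",
]


def percent_difference(t_synthetic, t_reference):
    """Signed percent difference 100 * (syn - ref) / ref; broadcasts."""
    syn = np.asarray(t_synthetic, dtype=float)
    ref = np.asarray(t_reference, dtype=float)
    if np.any(ref <= 0) or not np.all(np.isfinite(ref)):
        raise ValueError(f"reference values must be positive and finite, got {t_reference!r}")
    out = (syn - ref) / ref * 100.0
    return out if out.ndim else float(out)


def _tie_corrected_statistic(data: np.ndarray) -> tuple:
    n, k = data.shape
    ranks = np.apply_along_axis(rankdata, 1, data)  # mid-ranks within blocks
    rank_sums = ranks.sum(axis=0)
    q = 12.0 / (n * k * (k + 1)) * np.sum(rank_sums**2) - 3.0 * n * (k + 1)
    ties = 0.0
    for row in data:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts**3 - counts))
    c = 1.0 - ties / (n * k * (k**2 - 1))
    if c <= 0:
        # every block fully tied: no information, no treatment effect
        return 0.0, True
    return q / c, False


def friedman_test(data, method: str = "chi2"):
    """Friedman rank test for k matched treatments over n blocks.

    ``data`` is an (n blocks) x (k treatments) matrix.  Ties get
    mid-ranks with the standard tie correction.  ``method`` "chi2" uses
    the chi-square approximation with k - 1 degrees of freedom;
    "exact" enumerates all within-block rank permutations (only for
    small problems, n <= 8).

    Returns (statistic, df, p).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError(f"data must be a 2-D blocks x treatments matrix, got shape {data.shape}")
    n, k = data.shape
    if k < 2 or n < 2:
        raise ValueError(f"need >= 2 treatments and >= 2 blocks, got {n} x {k}")
    if not np.all(np.isfinite(data)):
        raise ValueError("data contains non-finite entries")

    stat, fully_tied = _tie_corrected_statistic(data)
    df = k - 1
    if fully_tied:
        return 0.0, df, 1.0
    if method == "chi2":
        return float(stat), df, float(chi2.sf(stat, df))
    if method == "exact":
        import math as _math

        n_perms = _math.factorial(k) ** n
        if n > 8 or n_perms > 2_000_000:
            raise ValueError(f"exact enumeration infeasible for {n} x {k} ({n_perms} permutations)")
        count = 0
        total = 0
        for perms in itertools.product(itertools.permutations(range(k)), repeat=n):
            permuted = np.stack([data[i, list(p)] for i, p in enumerate(perms)])
            s, tied = _tie_corrected_statistic(permuted)
            if tied:
                s = 0.0
            if s >= stat - 1e-12:
                count += 1
            total += 1
        return float(stat), df, count / total
    raise ValueError(f"unknown method {method!r}")


def bonferroni(p_values, alpha: float = 0.05):
    """Bonferroni adjustment: p_adj = min(1, m p); reject iff p_adj < alpha.

    Returns (adjusted p-values, reject flags) as arrays.
    """
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError(f"p-values must lie in [0, 1], got {p_values!r}")
    adjusted = np.minimum(1.0, len(p) * p)
    return adjusted, adjusted < alpha


@dataclass
class ValidationReport:
    """Output of :func:`build_validation_report`.

    ``table``: one row per (quantity, concentration) with the aggregated
    synthetic value, percent difference, and interday Friedman results.
    ``intersession``: one row per (quantity, day) Friedman test across
    the seven sessions (blocks = concentrations).
    ``per_session``: percent difference of every individual session.
    ``summary``: the headline bound checks and flags.
    """

    table: pd.DataFrame
    intersession: pd.DataFrame
    per_session: pd.DataFrame
    summary: dict

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, lineterminator="\n", float_format="%.6g")


def _validate_table(table: pd.DataFrame) -> None:
    required = ["quantity", "concentration_mM", "reference", *SYNTHETIC_COLUMNS]
    missing_cols = [c for c in required if c not in table.columns]
    if missing_cols:
        raise ValueError(f"validation table missing columns {missing_cols}")
    for _, row in table.iterrows():
        key = f"{row['quantity']} {row['concentration_mM']:g} mM"
        values = row[list(SYNTHETIC_COLUMNS)].to_numpy(float)
        if not np.all(np.isfinite(values)):
            raise ValueError(f"missing synthetic entries in row {key}")
        if not np.isfinite(row["reference"]) or row["reference"] <= 0:
            raise ValueError(f"invalid reference value in row {key}")


def build_validation_report(
    table: pd.DataFrame, aggregation: str = "mean", alpha: float = 0.05
) -> ValidationReport:
    """Build the per-concentration validation report.

    For every row the 14 synthetic sessions (2 days x 7 repetitions)
    are aggregated (``mean`` by default, ``median`` optional) and
    compared to the conventional reference by percent difference.
    Repeatability is assessed with Friedman tests: interday per row
    (k = 2 days, blocks = 7 session indices) and intersession per
    (quantity, day) (k = 7 sessions, blocks = concentrations), each
    family Bonferroni-corrected.

    The summary flags the known inconsistency of the claimed 5-8%
    difference band for T1 at 0.7-1.0 mM, which recomputation from the
    table does not support; that range is reported but not asserted.
    """
    _validate_table(table)
    if aggregation not in ("mean", "median"):
        raise ValueError(f"aggregation must be 'mean' or 'median', got {aggregation!r}")
    agg = np.mean if aggregation == "mean" else np.median

    day1_cols = [f"syn_1_{s}" for s in range(1, 8)]
    day2_cols = [f"syn_2_{s}" for s in range(1, 8)]

    rows = []
    per_session_rows = []
    for _, row in table.iterrows():
        syn = row[list(SYNTHETIC_COLUMNS)].to_numpy(float)
        ref = float(row["reference"])
        aggregated = float(agg(syn))
        interday = np.column_stack(
            [row[day1_cols].to_numpy(float), row[day2_cols].to_numpy(float)]
        )
        stat, df, p = friedman_test(interday)
        rows.append(
            {
                "quantity": row["quantity"],
                "concentration_mM": float(row["concentration_mM"]),
                "reference_ms": ref,
                "synthetic_ms": aggregated,
                "percent_difference": percent_difference(aggregated, ref),
                "interday_friedman_stat": stat,
                "interday_friedman_df": df,
                "interday_p": p,
            }
        )
        for col in SYNTHETIC_COLUMNS:
            per_session_rows.append(
                {
                    "quantity": row["quantity"],
                    "concentration_mM": float(row["concentration_mM"]),
                    "session": col,
                    "percent_difference": percent_difference(float(row[col]), ref),
                }
            )

    report = pd.DataFrame(rows)
    adjusted, reject = bonferroni(report["interday_p"], alpha=alpha)
    report["interday_p_bonferroni"] = adjusted
    report["interday_significant"] = reject

    intersession_rows = []
    for quantity in ("T1", "T2"):
        sub = table[table["quantity"] == quantity]
        for day, cols in ((1, day1_cols), (2, day2_cols)):
            block = sub[cols].to_numpy(float)  # concentrations x sessions
            stat, df, p = friedman_test(block)
            intersession_rows.append(
                {
                    "quantity": quantity,
                    "day": day,
                    "friedman_stat": stat,
                    "friedman_df": df,
                    "p": p,
                }
            )
    intersession = pd.DataFrame(intersession_rows)
    adj, rej = bonferroni(intersession["p"], alpha=alpha)
    intersession["p_bonferroni"] = adj
    intersession["significant"] = rej

    t1 = report[report["quantity"] == "T1"].set_index("concentration_mM")
    t2 = report[report["quantity"] == "T2"].set_index("concentration_mM")
    t2_short = t2.loc[[c for c in t2.index if 11.0 <= c <= 20.0], "percent_difference"]
    t2_long = t2.loc[[c for c in t2.index if 7.0 <= c <= 9.0], "percent_difference"]
    t1_mid = t1.loc[[c for c in t1.index if 0.7 <= c <= 1.0], "percent_difference"]
    summary = {
        "t1_percent_difference_0p2mM": float(t1.loc[0.2, "percent_difference"]),
        "t1_diff_gt_20pct_at_0p2mM": bool(abs(t1.loc[0.2, "percent_difference"]) > 20.0),
        "t2_max_abs_percent_difference_11_to_20mM": float(t2_short.abs().max()),
        "t2_all_lt_10pct_11_to_20mM": bool((t2_short.abs() < 10.0).all()),
        "t2_min_abs_percent_difference_7_to_9mM": float(t2_long.abs().min()),
        "t2_all_gt_20pct_7_to_9mM": bool((t2_long.abs() > 20.0).all()),
        "t1_0p7_to_1p0mM_abs_percent_difference_range": [
            float(t1_mid.abs().min()),
            float(t1_mid.abs().max()),
        ],
        "t1_0p7_to_1p0mM_claimed_5_to_8pct_consistent": bool(
            (t1_mid.abs() >= 5.0).all() and (t1_mid.abs() <= 8.0).all()
        ),
        "any_interday_significant": bool(report["interday_significant"].any()),
        "any_intersession_significant": bool(intersession["significant"].any()),
        "aggregation": aggregation,
        "alpha": alpha,
    }
    return ValidationReport(
        table=report,
        intersession=intersession,
        per_session=pd.DataFrame(per_session_rows),
        summary=summary,
    )
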