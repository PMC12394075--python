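"""Differential hydrogen–deuterium exchange analysis.

Works on tidy per-peptide uptake tables (columns ``start``, ``end``,
``sequence``, ``timepoint_s``, ``condition``, ``replicate``, ``percent_d``).
Provides the maximal-deuteration normalization, replicate-averaged uptake
curves, and Woods-plot classification of per-peptide condition differences
with the inclusive ±10 %D "unchanged" band.

Sign convention throughout: Δ%D = mean(condition B) − mean(condition A), so
negative values mean increased protection (slower exchange) in condition B.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["normalize_max_deuteration", "woods_table", "uptake_curve",
           "UPTAKE_COLUMNS"]

UPTAKE_COLUMNS = ["start", "end", "sequence", "timepoint_s", "condition",
                  "replicate", "percent_d"]

log = logging.getLogger(__name__)

#: peptides are keyed by interval and sequence so duplicate intervals from
#: different charge states collapse cleanly
PEPTIDE_KEY = ["start", "end", "sequence"]


def normalize_max_deuteration(table: pd.DataFrame,
                              max_label_fraction: float = 0.90) -> pd.DataFrame:
    """Rescale %D for incomplete labelling; values are capped at 100.

    Exchanged samples typically reach only ~90% of theoretical maximal
    deuteration; dividing by ``max_label_fraction`` reports uptake relative
    to the achievable maximum.  Rescaled values above 100 are capped with a
    warning (they indicate noise or an optimistic label fraction).
    """
    if not 0.0 < max_label_fraction <= 1.0:
        raise ValueError("max_label_fraction must lie in (0, 1]")
    out = table.copy()
    scaled = out["percent_d"] / max_label_fraction
    n_over = int((scaled > 100.0).sum())
    if n_over:
        warnings.warn(f"{n_over} uptake values exceeded 100 %D after "
                      "normalization and were capped", stacklevel=2)
    out["percent_d"] = np.minimum(scaled, 100.0)
    return out


def woods_table(table: pd.DataFrame, condition_a: str, condition_b: str,
                timepoints=None, threshold: float = 10.0,
                welch_test: bool = False) -> pd.DataFrame:
    """Per-peptide Δ%D between two conditions with Woods classification.

    Replicate means are compared per peptide × timepoint; ``|Δ%D| ≤
    threshold`` (boundary inclusive) is classified ``unchanged``, negative
    differences ``protected`` (slower exchange in B), positive
    ``deprotected``.  Peptides missing either condition are skipped with a
    log entry.  ``welch_test=True`` adds a Welch t-test p-value column
    (off by default; the classification itself uses no test).
    """
    present = set(table["condition"].unique())
    for cond in (condition_a, condition_b):
        if cond not in present:
            raise ValueError(f"condition {cond!r} absent from table")
    sub = table[table["condition"].isin([condition_a, condition_b])]
    if timepoints is not None:
        sub = sub[sub["timepoint_s"].isin(list(timepoints))]

    rows = []
    for (start, end, seq, t), grp in sub.groupby(PEPTIDE_KEY + ["timepoint_s"]):
        a = grp.loc[grp["condition"] == condition_a, "percent_d"].to_numpy()
        b = grp.loc[grp["condition"] == condition_b, "percent_d"].to_numpy()
        if a.size == 0 or b.size == 0:
            log.info("peptide %s-%s at t=%s s missing a condition; skipped",
                     start, end, t)
            continue
        delta = float(b.mean() - a.mean())
        if abs(delta) <= threshold:
            label = "unchanged"
        elif delta < 0:
            label = "protected"
        else:
            label = "deprotected"
        row = {"start": start, "end": end, "sequence": seq,
               "timepoint_s": t, "delta_pct_d": delta,
               "classification": label}
        if welch_test and a.size > 1 and b.size > 1:
            row["p_value"] = float(stats.ttest_ind(b, a, equal_var=False).pvalue)
        rows.append(row)
    return pd.DataFrame(rows)


def uptake_curve(table: pd.DataFrame, start: int, end: int,
                 condition: str, sequence: str | None = None) -> pd.DataFrame:
    """Replicate mean ± SD uptake vs time for one peptide and condition.

    A non-monotonic *mean* uptake curve is flagged (possible EX1 signature or
    back-exchange artifact) without altering any values; single-replicate
    timepoints report a missing SD.
    """
    mask = ((table["start"] == start) & (table["end"] == end)
            & (table["condition"] == condition))
    if sequence is not None:
        mask &= table["sequence"] == sequence
    sub = table[mask]
    if sub.empty:
        raise KeyError(f"no records for peptide {start}-{end} in condition "
                       f"{condition!r}")
    grouped = sub.groupby("timepoint_s")["percent_d"]
    out = pd.DataFrame({
        "timepoint_s": sorted(sub["timepoint_s"].unique()),
    })
    means = grouped.mean()
    sds = grouped.std(ddof=1)   # NaN for single replicates
    out["mean_pct_d"] = means.loc[out["timepoint_s"]].to_numpy()
    out["sd_pct_d"] = sds.loc[out["timepoint_s"]].to_numpy()
    out["non_monotonic"] = bool(np.any(np.diff(out["mean_pct_d"]) < 0))
    return out
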