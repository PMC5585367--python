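"""Downstream numeric summaries: size normalization, invasion, correlation.

* Spheroid sizes across seeding densities are expressed as a percentage of
  the same cell type's 5,000-cells-per-spheroid group mean (the reference
  density), so growth curves of differently sized cell types are
  comparable.
* Transwell invasion counts are averaged field -> well -> condition; the
  well is the experimental unit (fields within a well are
  pseudo-replicates), so fold changes and the unpaired two-tailed Student
  t-test operate on per-well means.
* The smoothness-vs-invasiveness association is summarized by Spearman
  rank correlation — the claim is ordinal and the group count tiny, so a
  p-value is only attached from n = 5 pairs upward.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientPointsError, ValidationError
from .io import CountTable

REFERENCE_CELLS_PER_SPHEROID = 5000


def normalize_sizes(
    areas: pd.DataFrame, reference_cells: int = REFERENCE_CELLS_PER_SPHEROID
) -> pd.DataFrame:
    """Normalize group-mean spheroid areas to the reference seeding density.

    Parameters
    ----------
    areas : DataFrame
        Columns ``cell_type``, ``cells_per_spheroid``, ``area`` (one row
        per measured spheroid; any consistent area unit).
    reference_cells : int
        Seeding density whose group mean defines 100 % for each cell type.

    Returns
    -------
    DataFrame with columns ``cell_type``, ``cells_per_spheroid``, ``n``,
    ``mean_area``, ``normalized_size_percent`` where the reference group of
    every cell type is exactly 100.
    """
    required = {"cell_type", "cells_per_spheroid", "area"}
    missing = required - set(areas.columns)
    if missing:
        raise ValidationError(f"areas table is missing column(s): {sorted(missing)}")
    if len(areas) == 0:
        raise ValidationError("areas table is empty")
    if (areas["area"] <= 0).any():
        raise ValidationError("areas must be strictly positive")

    grouped = (
        areas.groupby(["cell_type", "cells_per_spheroid"], sort=False)["area"]
        .agg(n="size", mean_area="mean")
        .reset_index()
    )
    out_rows = []
    for cell_type, sub in grouped.groupby("cell_type", sort=False):
        ref = sub[sub["cells_per_spheroid"] == reference_cells]
        if len(ref) == 0:
            raise ValidationError(
                f"no {reference_cells:,}-cell reference for {cell_type}"
            )
        ref_mean = float(ref["mean_area"].iloc[0])
        sub = sub.copy()
        sub["normalized_size_percent"] = 100.0 * sub["mean_area"] / ref_mean
        out_rows.append(sub)
    return pd.concat(out_rows, ignore_index=True)


@dataclass
class InvasionSummary:
    """Condition-level invasion statistics and pairwise comparisons.

    ``conditions``: one row per condition — mean of per-well means, SD
    (ddof=1, NaN for a single well), n_wells.
    ``pairwise``: one row per unordered condition pair — fold change
    (mean_a / mean_b) and the two-tailed unpaired t-test p-value on
    per-well means (NaN with ``p_available=False`` when a side has < 2
    wells or the statistic is degenerate).
    """

    conditions: pd.DataFrame
    pairwise: pd.DataFrame
    well_means: pd.DataFrame


def summarize_invasion(counts: CountTable, equal_var: bool = True) -> InvasionSummary:
    """Summarize a transwell invasion count table.

    Field counts are averaged within each well; wells are averaged within
    each condition. The default test is the classic pooled-variance
    (Student) unpaired two-tailed t-test; ``equal_var=False`` switches to
    Welch.
    """
    df = counts.frame
    well = (
        df.groupby(["condition_label", "well_id"], sort=False)["migrated_cell_count"]
        .mean()
        .reset_index()
        .rename(columns={"migrated_cell_count": "well_mean"})
    )
    cond = (
        well.groupby("condition_label", sort=False)["well_mean"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1), n_wells="size")
        .reset_index()
    )
    labels = list(cond["condition_label"])
    by_label = {
        lbl: well.loc[well["condition_label"] == lbl, "well_mean"].to_numpy()
        for lbl in labels
    }
    rows = []
    for a, b in itertools.combinations(labels, 2):
        wa, wb = by_label[a], by_label[b]
        mean_a, mean_b = wa.mean(), wb.mean()
        fold = mean_a / mean_b if mean_b != 0 else math.inf
        p = math.nan
        available = False
        if len(wa) >= 2 and len(wb) >= 2:
            t, p_val = stats.ttest_ind(wa, wb, equal_var=equal_var)
            if math.isfinite(p_val):
                p, available = float(p_val), True
            else:
                p = math.nan
        rows.append(
            {
                "condition_a": a,
                "condition_b": b,
                "mean_a": mean_a,
                "mean_b": mean_b,
                "fold_change": fold,
                "t_p_value": p,
                "p_available": available,
            }
        )
    pairwise = pd.DataFrame(
        rows,
        columns=[
            "condition_a",
            "condition_b",
            "mean_a",
            "mean_b",
            "fold_change",
            "t_p_value",
            "p_available",
        ],
    )
    return InvasionSummary(conditions=cond, pairwise=pairwise, well_means=well)


def correlate_chi_invasion(metrics, invasion) -> dict:
    """Spearman rank correlation between smoothness chi and invasion level.

    Parameters
    ----------
    metrics : iterable of (label, chi)
    invasion : iterable of (label, condition_mean)

    Returns
    -------
    dict with ``rho``, ``n``, and ``p_value`` (None below n = 5 — a rank
    p-value on fewer groups is not meaningful).
    """
    chi_map = dict(metrics)
    inv_map = dict(invasion)
    shared = [lbl for lbl in chi_map if lbl in inv_map]
    if len(shared) < 3:
        raise InsufficientPointsError(
            f"insufficient pairs for correlation: {len(shared)} shared labels (need >= 3)"
        )
    chi = np.array([chi_map[lbl] for lbl in shared], float)
    inv = np.array([inv_map[lbl] for lbl in shared], float)
    rho, p = stats.spearmanr(chi, inv)
    return {
        "rho": float(rho),
        "n": len(shared),
        "p_value": float(p) if len(shared) >= 5 else None,
        "labels": shared,
    }
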