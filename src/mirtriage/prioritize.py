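"""Priority miRNA views: top-k by magnitude and the same-direction list.

The three views mirror how the study triages its DE lists: the
changes of greatest magnitude up and down in each contrast, and the
miRNAs moving in the same direction in both contrasts (of special
interest because the xenograft passage enriches tumor cells).
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def top_k(de_table: pd.DataFrame, k: int = 10, direction: str = "up") -> pd.DataFrame:
    """Top-k rows of one sign, ranked by |fold change| descending.

    Ties break by ascending p-value, then lexicographic feature id.
    Fewer than k available rows are all returned. Expects a DE table
    that already passed the filter cascade, with columns feature_id,
    fold_change, p_value.
    """
    if k < 1:
        raise ValueError(f"top_k: k must be >= 1, got {k}")
    if direction not in ("up", "down"):
        raise ValueError(f"top_k: direction must be 'up' or 'down', got {direction!r}")
    sign = 1 if direction == "up" else -1
    sub = de_table[np.sign(de_table["fold_change"]) == sign].copy()
    sub["_mag"] = sub["fold_change"].abs()
    sub.sort_values(
        ["_mag", "p_value", "feature_id"],
        ascending=[False, True, True],
        inplace=True,
    )
    return sub.drop(columns="_mag").head(k).reset_index(drop=True)


def same_direction(de_a: pd.DataFrame, de_b: pd.DataFrame) -> pd.DataFrame:
    """Features DE in both tables with the same fold-change sign.

    Returns columns feature_id, fold_change_a, p_value_a,
    fold_change_b, p_value_b, sorted by fold_change_a descending. Both
    inputs are expected to have passed the filter cascade
    independently.
    """
    cols = ["feature_id", "fold_change", "p_value"]
    merged = de_a[cols].merge(de_b[cols], on="feature_id", suffixes=("_a", "_b"))
    same = merged[
        np.sign(merged["fold_change_a"]) == np.sign(merged["fold_change_b"])
    ].copy()
    same.sort_values(
        ["fold_change_a", "feature_id"], ascending=[False, True], inplace=True
    )
    return same.reset_index(drop=True)


def priority_table(
    de_tvn: pd.DataFrame,
    de_f1vt: pd.DataFrame,
    k: int | None = 10,
) -> pd.DataFrame:
    """The priority universe for target integration.

    Union of the top-k up/down lists of each contrast and the
    same-direction list, deduplicated by feature id: same-direction
    features get comparison ``both`` and carry both fold changes;
    the rest get their own contrast's row. ``k=None`` keeps every
    filtered feature instead of the top-k views (used when evaluating
    recovery on synthetic data).

    Returns columns mirna_id, comparison (TvN / F1vT / both), fc_tvn,
    p_tvn, fc_f1vt, p_f1vt (NaN where the contrast does not apply).
    """
    both = same_direction(de_tvn, de_f1vt)
    both_ids = set(both["feature_id"])
    if k is None:
        tvn_view, f1vt_view = de_tvn, de_f1vt
    else:
        tvn_view = pd.concat([top_k(de_tvn, k, "up"), top_k(de_tvn, k, "down")])
        f1vt_view = pd.concat([top_k(de_f1vt, k, "up"), top_k(de_f1vt, k, "down")])

    rows = []
    for _, r in both.iterrows():
        rows.append(
            (r["feature_id"], "both", r["fold_change_a"], r["p_value_a"],
             r["fold_change_b"], r["p_value_b"])
        )
    for _, r in tvn_view.iterrows():
        if r["feature_id"] not in both_ids:
            rows.append(
                (r["feature_id"], "TvN", r["fold_change"], r["p_value"],
                 np.nan, np.nan)
            )
    for _, r in f1vt_view.iterrows():
        if r["feature_id"] not in both_ids:
            rows.append(
                (r["feature_id"], "F1vT", np.nan, np.nan,
                 r["fold_change"], r["p_value"])
            )
    out = pd.DataFrame(
        rows,
        columns=["mirna_id", "comparison", "fc_tvn", "p_tvn", "fc_f1vt", "p_f1vt"],
    ).drop_duplicates(subset=["mirna_id", "comparison"])
    out.sort_values(["comparison", "mirna_id"], inplace=True)
    return out.reset_index(drop=True)
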