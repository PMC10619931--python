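"""Count normalization and detected-element calling.

TE counts are scaled by median-of-ratios size factors computed from the
gene count matrix (repeat counts are too sparse and too condition-driven
to estimate depth from).  A locus is called "detected" in a group of
units when its group-mean normalized count strictly exceeds a threshold
of 10.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import TEAnnotationRecord


def size_factors_median_of_ratios(gene_counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (genes in rows, units in columns).

    The per-gene reference is the geometric mean across units, computed
    over genes with strictly positive counts everywhere; a unit's factor
    is the median over those genes of count/reference.
    """
    if gene_counts.shape[1] == 0:
        raise ValueError("count matrix has no units")
    values = gene_counts.to_numpy(dtype=float)
    all_positive = (values > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "no gene has nonzero counts in all units; size factors undefined"
        )
    logs = np.log(values[all_positive])
    log_ref = logs.mean(axis=1)
    ratios = logs - log_ref[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    out = pd.Series(factors, index=gene_counts.columns, name="size_factor")
    return out


def normalize_counts(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """Divide each unit's column by its size factor."""
    missing = [u for u in counts.columns if u not in factors.index]
    if missing:
        raise ValueError(f"no size factor for units: {missing}")
    if (factors.loc[counts.columns] <= 0).any():
        raise ValueError("size factors must be positive")
    return counts / factors.loc[counts.columns]


def log_transform(normalized: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """log2(value + pseudocount); input values must be non-negative."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    values = normalized.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("negative values cannot be log-transformed")
    return pd.DataFrame(
        np.log2(values + pseudocount),
        index=normalized.index,
        columns=normalized.columns,
    )


def call_detected_elements(
    normalized: pd.DataFrame,
    groups: Mapping[str, str],
    annotation: Optional[Sequence[TEAnnotationRecord]] = None,
    threshold: float = 10.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Call detected elements per group and summarise detected ratios.

    ``groups`` maps each unit (column) to a group label; an element is
    detected in a group when its mean normalized count over the group's
    units is strictly greater than ``threshold``.  When ``annotation``
    is given, a per-subfamily summary is added whose denominator is the
    total number of elements of that subfamily in the annotation (the
    detected-ratio convention), restricted to elements present in it.

    Returns (calls, ratios): calls has one row per element x group with
    the group mean and the detected flag; ratios has one row per
    subfamily x group with detected counts, totals and the ratio.
    """
    missing = [u for u in normalized.columns if u not in groups]
    if missing:
        raise ValueError(f"units without group assignment: {missing}")
    group_units: dict[str, list] = {}
    for unit, group in groups.items():
        if unit in normalized.columns:
            group_units.setdefault(group, []).append(unit)
    for group, units in group_units.items():
        if not units:
            raise ValueError(f"group {group!r} has no units")

    calls_rows = []
    for group, units in group_units.items():
        means = normalized[units].mean(axis=1)
        for element_id, mean in means.items():
            calls_rows.append(
                {
                    "element_id": element_id,
                    "group": group,
                    "mean_normalized": float(mean),
                    "detected": bool(mean > threshold),
                }
            )
    calls = pd.DataFrame(
        calls_rows, columns=["element_id", "group", "mean_normalized", "detected"]
    )

    if annotation is None:
        return calls, pd.DataFrame(
            columns=["subfamily", "group", "n_detected", "n_total", "ratio"]
        )

    subfam_of = {rec.element_id: rec.subfamily for rec in annotation}
    totals = pd.Series(list(subfam_of.values())).value_counts()
    ratio_rows = []
    for group in group_units:
        sub = calls[(calls["group"] == group) & calls["element_id"].isin(subfam_of)]
        detected_by_subfam = (
            sub.assign(subfamily=sub["element_id"].map(subfam_of))
            .groupby("subfamily")["detected"]
            .sum()
        )
        for subfamily, total in totals.items():
            n_det = int(detected_by_subfam.get(subfamily, 0))
            ratio_rows.append(
                {
                    "subfamily": subfamily,
                    "group": group,
                    "n_detected": n_det,
                    "n_total": int(total),
                    "ratio": n_det / total,
                }
            )
    ratios = pd.DataFrame(
        ratio_rows, columns=["subfamily", "group", "n_detected", "n_total", "ratio"]
    )
    return calls, ratios
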