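"""Project node-level clusters and outliers back onto sites and calendar time."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .preprocess import PanelDataset
from .som import BmuAssignment

__all__ = [
    "daily_cluster_fractions",
    "daily_table_to_long",
    "outlier_timeline",
    "filter_period",
]


def _check_alignment(panel: PanelDataset, assignment: BmuAssignment, labels: np.ndarray):
    labels = np.asarray(labels)
    if len(assignment.bmu_index) != panel.n_rows:
        raise ValueError("assignment is not aligned to the panel rows")
    if assignment.bmu_index.max() >= labels.shape[0]:
        raise ValueError("labels are not aligned to the codebook nodes")
    return labels


def daily_cluster_fractions(
    panel: PanelDataset, assignment: BmuAssignment, labels: np.ndarray
) -> pd.DataFrame:
    """Per (site, calendar date): percentage of retained hours per cluster.

    Returns a wide table indexed by (site, date) with one column per cluster
    id; each row sums to 100.  Days with zero retained hours simply do not
    appear.  The calendar date is taken from the naive local timestamp.
    """
    labels = _check_alignment(panel, assignment, labels)
    cluster = labels[assignment.bmu_index]
    date = panel.timestamps.astype("datetime64[D]")
    counts = pd.crosstab([panel.sites, date], cluster)
    counts.index.names = ["site", "date"]
    counts.columns.name = "cluster"
    all_ids = sorted(np.unique(labels).tolist())
    counts = counts.reindex(columns=all_ids, fill_value=0)
    return counts.div(counts.sum(axis=1), axis=0) * 100.0


def daily_table_to_long(table: pd.DataFrame) -> pd.DataFrame:
    """Melt a wide daily-cluster table into (site, date, cluster, percent)."""
    long = table.stack().rename("percent").reset_index()
    long.columns = ["site", "date", "cluster", "percent"]
    return long


def outlier_timeline(
    panel: PanelDataset,
    assignment: BmuAssignment,
    labels: np.ndarray,
    flags: np.ndarray,
) -> pd.DataFrame:
    """Table of flagged samples: site, timestamp, qe, cluster of the BMU."""
    labels = _check_alignment(panel, assignment, labels)
    flags = np.asarray(flags, dtype=bool)
    if flags.shape[0] != panel.n_rows:
        raise ValueError("flags are not aligned to the panel rows")
    idx = np.flatnonzero(flags)
    df = pd.DataFrame(
        {
            "site": panel.sites[idx],
            "timestamp": panel.timestamps[idx],
            "qe": assignment.qe_sample[idx],
            "cluster": labels[assignment.bmu_index[idx]],
        }
    )
    return df.sort_values(["site", "timestamp"]).reset_index(drop=True)


def filter_period(panel: PanelDataset, period: str) -> PanelDataset:
    """Keep rows whose month-day falls in an inclusive ``MM-DD:MM-DD`` window.

    Windows wrapping the year end (e.g. ``12-15:01-15``) are supported.
    """
    try:
        start, end = period.split(":")
        m0, d0 = (int(p) for p in start.split("-"))
        m1, d1 = (int(p) for p in end.split("-"))
    except ValueError as exc:
        raise ValueError(f"period must look like 'MM-DD:MM-DD', got {period!r}") from exc
    ts = pd.DatetimeIndex(panel.timestamps)
    md = ts.month * 100 + ts.day
    lo, hi = m0 * 100 + d0, m1 * 100 + d1
    mask = (md >= lo) & (md <= hi) if lo <= hi else (md >= lo) | (md <= hi)
    return panel.take(np.asarray(mask))
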