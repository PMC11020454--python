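"""Transwell migration count analysis.

Consumes gated flow-cytometry counts of cells that crossed a transwell
membrane (one row per donor/condition/media/inhibitor/cell-class; duplicate
wells are averaged per donor first). Provides the paired Wnt-vs-control
media comparison and the inhibitor fold-change metric: per donor the ratio
of the with-inhibitor count to the without-inhibitor count in Wnt media,
summarized as the arithmetic mean over donors.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import statcore
from .errors import InvalidParameterError, PairingError, UndefinedRatioError

__all__ = ["load_records", "average_replicates", "migration_compare", "inhibitor_fold_change"]

REQUIRED = ("donor", "condition", "media", "inhibitor", "cell_class", "count")
KEY = ["donor", "condition", "media", "inhibitor", "cell_class"]


def load_records(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a transwell count table and coerce dtypes."""
    missing = [c for c in REQUIRED if c not in df.columns]
    if missing:
        raise InvalidParameterError(f"transwell table missing columns {missing}")
    out = df.copy()
    out["inhibitor"] = out["inhibitor"].astype(bool)
    counts = out["count"].to_numpy(dtype=float)
    if np.any(counts < 0) or np.any(counts != np.round(counts)):
        raise InvalidParameterError("counts must be non-negative integers")
    return out


def average_replicates(records: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean of duplicate wells per (donor, condition, media,
    inhibitor, cell_class)."""
    records = load_records(records)
    return records.groupby(KEY, as_index=False)["count"].mean()


def migration_compare(records: pd.DataFrame, condition, cell_class: str = "monocyte") -> statcore.TestResult:
    """Paired two-sided t-test of Wnt-media vs control-media counts per donor."""
    avg = average_replicates(records)
    sel = avg[
        (avg["condition"] == condition)
        & (avg["cell_class"] == cell_class)
        & (~avg["inhibitor"])
    ]
    wide = sel.pivot_table(index="donor", columns="media", values="count")
    for arm in ("control", "wnt"):
        if arm not in wide.columns:
            raise PairingError(f"no {arm!r}-media counts for condition {condition!r}")
    wide = wide[["control", "wnt"]]
    incomplete = wide.index[wide.isna().any(axis=1)].tolist()
    if incomplete:
        raise PairingError(f"donors missing one media arm: {incomplete}")
    if len(wide) < 2:
        raise PairingError("need both media arms for at least two donors")
    return statcore.paired_t(wide["wnt"].to_numpy(), wide["control"].to_numpy())


def inhibitor_fold_change(
    records: pd.DataFrame, condition, cell_class: str = "monocyte", media: str = "wnt"
):
    """Per-donor FC = count(with inhibitor) / count(without), plus the mean.

    The direct ratio within the chosen media arm (default Wnt) — no
    control-media normalization.
    """
    avg = average_replicates(records)
    sel = avg[
        (avg["condition"] == condition)
        & (avg["cell_class"] == cell_class)
        & (avg["media"] == media)
    ]
    wide = sel.pivot_table(index="donor", columns="inhibitor", values="count")
    if True not in wide.columns or False not in wide.columns:
        raise PairingError(f"condition {condition!r}: need counts with and without inhibitor")
    per_donor = {}
    for donor, row in wide.iterrows():
        if np.isnan(row[True]) or np.isnan(row[False]):
            raise PairingError(f"donor {donor!r} missing an inhibitor arm")
        if row[False] == 0:
            raise UndefinedRatioError(f"donor {donor!r}: zero count without inhibitor")
        per_donor[donor] = float(row[True] / row[False])
    return per_donor, float(np.mean(list(per_donor.values())))
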