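"""Relative expression quantification by the ddCt method.

For each sample i, dCt_i = Ct_target,i - Ct_reference,i; ddCt_i = dCt_i -
mean(dCt over the calibrator set); RQ_i = 2^(-ddCt_i). Amplification
efficiency is fixed at 2 (perfect doubling), appropriate when target and
reference efficiencies are equivalent. With the calibrator mean taken over
dCt, the geometric mean of RQ across the calibrator set is exactly 1. The
calibrator defaults to all samples; a named group (e.g. one strain) can be
selected instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .effects import mann_whitney

logger = logging.getLogger(__name__)

__all__ = ["CtTable", "relative_quantity", "group_compare_rq", "read_ct_table"]


@dataclass(frozen=True)
class CtTable:
    """Per-sample group label and target/reference cycle-threshold values."""

    table: pd.DataFrame  # columns: sample, group, ct_target, ct_reference

    def __post_init__(self) -> None:
        t = self.table
        for c in ("sample", "group", "ct_target", "ct_reference"):
            if c not in t.columns:
                raise ValueError(f"Ct table missing column {c!r}")
        if len(t) == 0:
            raise ValueError("Ct table is empty")
        for c in ("ct_target", "ct_reference"):
            v = pd.to_numeric(t[c], errors="coerce")
            if v.isna().any():
                bad = t["sample"][v.isna()].iloc[0]
                raise ValueError(f"missing/non-numeric {c} for sample {bad!r}")
            if not np.isfinite(v).all():
                raise ValueError(f"{c} must be finite")
            if ((v < 10) | (v > 40)).any():
                logger.warning(
                    "%s values outside the typical 10-40 cycle range", c
                )


def read_ct_table(path) -> CtTable:
    return CtTable(pd.read_csv(path))


def relative_quantity(
    table: CtTable, calibrator_group: str | None = None
) -> pd.Series:
    """Per-sample RQ = 2^(-ddCt), indexed by sample name.

    ``calibrator_group`` names the group whose mean dCt anchors the scale;
    by default the calibrator set is all samples.
    """
    t = table.table
    dct = t["ct_target"].astype(float) - t["ct_reference"].astype(float)
    if calibrator_group is None:
        cal = np.ones(len(t), bool)
    else:
        cal = (t["group"] == calibrator_group).to_numpy()
        if not cal.any():
            raise ValueError(
                f"calibrator group {calibrator_group!r} has no samples"
            )
    ddct = dct - dct[cal].mean()
    rq = np.power(2.0, -ddct)
    return pd.Series(rq.to_numpy(), index=t["sample"], name="RQ")


def group_compare_rq(rq: pd.Series, groups: pd.Series) -> float:
    """Two-sided Mann-Whitney p comparing RQ between exactly two groups."""
    g = np.asarray(groups)
    labels = pd.unique(g)
    if labels.size != 2:
        raise ValueError("RQ comparison needs exactly two groups")
    x = np.asarray(rq)[g == labels[0]]
    y = np.asarray(rq)[g == labels[1]]
    return mann_whitney(x, y)
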