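"""Stage-wise treatment comparison: log2FC(D/C) and per-stage one-way ANOVA.

For every (feature, stage) cell the deficit/control contrast is summarized
by the base-2 log ratio of arithmetic group means of raw concentrations and
by a two-group one-way ANOVA at that sampling point (no multiple-testing
correction across the table; the per-point P < alpha rule is applied as-is).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import OmicsMatrix
from .stats import one_way_anova

__all__ = ["StagewiseComparison", "log2_fold_change", "response_table",
           "response_frame", "write_response_table"]


@dataclass(frozen=True)
class StagewiseComparison:
    """One feature x stage treatment contrast."""

    feature_id: str
    stage_daa: int
    mean_C: float
    mean_D: float
    log2fc: float
    f_statistic: float
    p_value: float  # nan when a treatment arm is missing at this stage
    significant: bool
    degenerate: bool = False  # zero within-group variance with unequal means


def log2_fold_change(values_C, values_D) -> float:
    """log2 of the ratio of arithmetic group means, D over C."""
    c = np.asarray(values_C, dtype=float)
    d = np.asarray(values_D, dtype=float)
    if c.size == 0 or d.size == 0:
        raise ValueError("both groups must be non-empty")
    mc, md = float(c.mean()), float(d.mean())
    if mc <= 0 or md <= 0:
        raise ValueError("group means must be positive for a log2 ratio")
    return math.log2(md / mc)


def response_table(matrix: OmicsMatrix, alpha: float = 0.05) -> list[StagewiseComparison]:
    """One record per (feature, stage), input feature order then stage ascending.

    A stage present in only one treatment arm is emitted with p = nan and
    ``significant=False`` rather than aborting the table.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    records: list[StagewiseComparison] = []
    stages = matrix.stages()
    cols = {
        (t, s): matrix.samples_for(treatment=t, stage_daa=s)
        for t in ("C", "D") for s in stages
    }
    vals = matrix.values
    for feature in matrix.feature_ids:
        row = vals.loc[feature]
        for stage in stages:
            sc, sd = cols[("C", stage)], cols[("D", stage)]
            if not sc or not sd:
                present = row[sc or sd].to_numpy(dtype=float)
                mean_p = float(present.mean()) if present.size else float("nan")
                records.append(StagewiseComparison(
                    feature_id=feature, stage_daa=stage,
                    mean_C=mean_p if sc else float("nan"),
                    mean_D=mean_p if sd else float("nan"),
                    log2fc=float("nan"), f_statistic=float("nan"),
                    p_value=float("nan"), significant=False))
                continue
            c = row[sc].to_numpy(dtype=float)
            d = row[sd].to_numpy(dtype=float)
            f, p = one_way_anova(c, d)
            records.append(StagewiseComparison(
                feature_id=feature, stage_daa=stage,
                mean_C=float(c.mean()), mean_D=float(d.mean()),
                log2fc=log2_fold_change(c, d),
                f_statistic=f, p_value=p,
                significant=bool(p < alpha),
                degenerate=math.isinf(f)))
    return records


def response_frame(records: list[StagewiseComparison]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def write_response_table(records: list[StagewiseComparison], path: str | Path) -> None:
    response_frame(records).to_csv(path, sep="\t", index=False, lineterminator="\n")
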