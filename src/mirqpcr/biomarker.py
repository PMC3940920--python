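"""Dual-reference fold-change biomarker discovery.

A marker is called overexpressed in the index case when its relative level
is at least `fc_threshold`-fold (default 2.0, boundary inclusive) above the
mean of BOTH reference groups (healthy controls and other childhood
tumors).  Fold changes follow the delta-delta-Ct convention:

    fc = 2 ** (-(delta_ct_case - mean delta_ct_group))

i.e. group aggregation is the mean of delta_ct, the geometric mean on the
linear scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import NormalizedMatrix

log = logging.getLogger(__name__)

DEFAULT_FC_THRESHOLD = 2.0


@dataclass
class GroupDesign:
    """Index case vs named reference groups (control, other_tumor)."""

    case_sample: str
    reference_groups: dict[str, list[str]]

    def __post_init__(self) -> None:
        for name, members in self.reference_groups.items():
            if not members:
                raise ValueError(f"reference group {name!r} is empty")
            if self.case_sample in members:
                raise ValueError(
                    f"case sample {self.case_sample!r} is a member of reference "
                    f"group {name!r}"
                )


def group_mean_profile(norm: NormalizedMatrix, samples: list[str]) -> pd.DataFrame:
    """Per-assay group summary: mean delta_ct over expressing members.

    Assays expressed in no member are undefined (NaN); `n_expressed` records
    how many members contributed to each mean.
    """
    if not samples:
        raise ValueError("empty sample list")
    missing = [s for s in samples if s not in norm.delta_ct.columns]
    if missing:
        raise ValueError(f"sample(s) not in normalized matrix: {missing}")
    sub = norm.delta_ct[samples]
    return pd.DataFrame(
        {
            "mean_delta_ct": sub.mean(axis=1),
            "mean_linear": 2.0 ** (-sub.mean(axis=1)),
            "n_expressed": sub.notna().sum(axis=1),
        }
    )


def fold_change(case_delta_ct, group_mean_delta_ct):
    """Linear fold of the case over a group mean: 2**(-(case - group)).

    Accepts scalars or aligned pandas/numpy objects; undefined inputs
    propagate as NaN.  Swapping the arguments inverts the fold exactly.
    """
    return 2.0 ** (-(case_delta_ct - group_mean_delta_ct))


def fold_vs_other_from_referenced(fc_case_vs_control, fc_other_vs_control):
    """Case-vs-other-group fold from two folds both referenced to controls.

    Published marker tables often print the case and the comparison group
    each referenced to controls; their ratio is the direct case-vs-group fold.
    """
    return fc_case_vs_control / fc_other_vs_control


def call_overexpressed(fc_vs_control, fc_vs_other, threshold: float = DEFAULT_FC_THRESHOLD):
    """True iff both folds are >= threshold (inclusive); NaN folds never call."""
    if threshold < 1:
        raise ValueError("fold-change threshold must be >= 1")
    fc_c = np.asanyarray(fc_vs_control, dtype=float)
    fc_o = np.asanyarray(fc_vs_other, dtype=float)
    with np.errstate(invalid="ignore"):
        out = (fc_c >= threshold) & (fc_o >= threshold)
    if out.ndim == 0:
        return bool(out)
    return out


def fold_change_table(
    norm: NormalizedMatrix,
    design: GroupDesign,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    control_group: str = "control",
    other_group: str = "other_tumor",
) -> pd.DataFrame:
    """Per-assay fold changes of the index case against both references.

    Columns: case_delta_ct, fc_vs_control, fc_vs_other,
    fc_other_vs_control (the comparison group itself referenced to controls,
    the convention of published marker tables), overexpressed, evaluable.
    Assays not expressed in the case are never called.
    """
    case = norm.delta_ct[design.case_sample]
    ctrl = group_mean_profile(norm, design.reference_groups[control_group])
    other = group_mean_profile(norm, design.reference_groups[other_group])
    fc_c = fold_change(case, ctrl["mean_delta_ct"])
    fc_o = fold_change(case, other["mean_delta_ct"])
    evaluable = case.notna() & ctrl["mean_delta_ct"].notna() & other["mean_delta_ct"].notna()
    table = pd.DataFrame(
        {
            "case_delta_ct": case,
            "fc_vs_control": fc_c,
            "fc_vs_other": fc_o,
            "fc_other_vs_control": fold_change(
                other["mean_delta_ct"], ctrl["mean_delta_ct"]
            ),
            "evaluable": evaluable,
            "overexpressed": call_overexpressed(fc_c, fc_o, fc_threshold) & case.notna(),
        }
    )
    n_not_eval = int((~evaluable).sum())
    log.info(
        "fold-change table: %d assays, %d called overexpressed at >=%.3g-fold, "
        "%d not evaluable",
        len(table), int(table["overexpressed"].sum()), fc_threshold, n_not_eval,
    )
    return table


def rank_markers(table: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Top-k called markers by fc_vs_control (descending; ties by name).

    Returns the called subset with a 1-based `rank` column; when fewer than
    k markers are called, all of them are returned with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    called = table[table["overexpressed"]].copy()
    called["_name"] = called.index.astype(str)
    called = called.sort_values(
        ["fc_vs_control", "_name"], ascending=[False, True]
    ).drop(columns="_name")
    if len(called) < k:
        warnings.warn(
            f"only {len(called)} called markers available (k={k}); returning all",
            stacklevel=2,
        )
    top = called.head(k).copy()
    top["rank"] = np.arange(1, len(top) + 1)
    return top
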