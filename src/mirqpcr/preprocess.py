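"""Expression calling, sample QC and global-mean delta-Ct normalization.

Serum qPCR panels are normalized per sample against the mean Ct of all
miRNAs expressed anywhere in the cohort (global-mean method): for sample s,

    delta_ct(a, s) = Ct(a, s) - mean_{m in global set, expressed in s} Ct(m, s)

and the linear relative quantity is 2**(-delta_ct).  Lower Ct means higher
abundance; one cycle is a two-fold difference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import normalize_name
from .io import CtMatrix

log = logging.getLogger(__name__)

DEFAULT_CT_THRESHOLD = 37.0
DEFAULT_HEMOLYSIS_DELTA_THRESHOLD = 7.0  # Ct(miR-23a) - Ct(miR-451), cycles
DEFAULT_HEMOLYSIS_SINGLE_THRESHOLD = 5.0  # cycles below cohort-median miR-451 Ct
DEFAULT_SPIKEIN_MAX_DELTA = 2.0  # cycles from cohort median
DEFAULT_LOW_CALL_FRACTION = 0.5  # of the cohort-median expressed count

HEMOLYSIS_MARKER = "miR-451"
HEMOLYSIS_REFERENCE = "miR-23a"


@dataclass
class ExpressionMask:
    """Per-cell expression calls plus the cohort-wide expressed assay set."""

    expressed: pd.DataFrame  # bool, assays x samples
    global_set: list[str] = field(default_factory=list)  # matrix row order
    ct_threshold: float = DEFAULT_CT_THRESHOLD

    def __post_init__(self) -> None:
        if not self.global_set:
            self.global_set = list(self.expressed.index[self.expressed.any(axis=1)])


@dataclass
class NormalizedMatrix:
    """Globally normalized expression: delta_ct defined only where expressed."""

    delta_ct: pd.DataFrame
    sample_mean_ct: pd.Series

    @property
    def linear(self) -> pd.DataFrame:
        """Relative quantity 2**(-delta_ct); > 0 wherever defined."""
        return 2.0 ** (-self.delta_ct)

    @property
    def samples(self) -> pd.Index:
        return self.delta_ct.columns


def call_expressed(matrix: CtMatrix, ct_threshold: float = DEFAULT_CT_THRESHOLD) -> ExpressionMask:
    """Call a cell expressed when its Ct is finite and <= ct_threshold (inclusive)."""
    if ct_threshold <= 0:
        raise ValueError("ct_threshold must be positive")
    expressed = matrix.values.notna() & (matrix.values <= ct_threshold)
    mask = ExpressionMask(expressed=expressed, ct_threshold=ct_threshold)
    log.info(
        "expression calls at Ct<=%.4g: %d assays expressed in >=1 sample; "
        "per-sample counts %s..",
        ct_threshold, len(mask.global_set), expressed.sum(axis=0).head(5).to_dict(),
    )
    return mask


def _find_assay(matrix: CtMatrix, name: str) -> str | None:
    target = normalize_name(name)
    for a in matrix.assays:
        if normalize_name(a) == target:
            return a
    return None


def hemolysis_check(
    matrix: CtMatrix,
    sheet: pd.DataFrame | None = None,
    delta_threshold: float = DEFAULT_HEMOLYSIS_DELTA_THRESHOLD,
    single_threshold: float = DEFAULT_HEMOLYSIS_SINGLE_THRESHOLD,
    mir451_name: str = HEMOLYSIS_MARKER,
    mir23a_name: str = HEMOLYSIS_REFERENCE,
) -> pd.DataFrame:
    """Red-blood-cell contamination check based on miR-451.

    miR-451 is highly abundant in erythrocytes, so hemolysis pushes its Ct
    down.  With both markers measured, the sample is flagged when
    Ct(miR-23a) - Ct(miR-451) exceeds `delta_threshold`; with miR-451 alone,
    when its Ct falls more than `single_threshold` cycles below the cohort
    median.  Returns a per-sample frame (hemolysis_delta, hemolysis_risk).
    """
    row451 = _find_assay(matrix, mir451_name)
    if row451 is None:
        raise ValueError(
            f"hemolysis marker {mir451_name!r} not on the panel; "
            "disable the hemolysis check for this matrix"
        )
    ct451 = matrix.values.loc[row451]
    row23a = _find_assay(matrix, mir23a_name)
    if row23a is not None:
        delta = matrix.values.loc[row23a] - ct451
        risk = delta > delta_threshold
        rule = "two_marker"
    else:
        median = ct451.median()
        delta = median - ct451
        risk = delta > single_threshold
        rule = "single_marker"
    out = pd.DataFrame(
        {
            "sample_id": matrix.samples,
            "hemolysis_delta": delta.to_numpy(),
            "hemolysis_risk": risk.to_numpy(),
            "hemolysis_rule": rule,
        }
    ).set_index("sample_id", drop=False)
    if sheet is not None and "hemolysis_visual_flag" in sheet.columns:
        out["hemolysis_visual_flag"] = (
            sheet["hemolysis_visual_flag"].reindex(out.index).fillna(False).astype(bool)
        )
    for sid in out.index[out["hemolysis_risk"]]:
        log.info("sample %s flagged for hemolysis risk (%s rule)", sid, rule)
    return out


def spikein_check(
    matrix: CtMatrix,
    spikein_names: Sequence[str],
    max_delta: float = DEFAULT_SPIKEIN_MAX_DELTA,
) -> pd.DataFrame:
    """Technical QC on spike-in assays (e.g. cel-miR-39-3p).

    Each spike-in is added at a fixed amount before extraction, so its Ct
    should be flat across samples; `spikein_delta` is the largest absolute
    deviation from the cohort median across all listed spike-ins, and the
    sample fails when it exceeds `max_delta` cycles.
    """
    if not spikein_names:
        raise ValueError("at least one spike-in assay name is required")
    deltas = []
    for name in spikein_names:
        row = _find_assay(matrix, name)
        if row is None:
            raise ValueError(f"spike-in assay {name!r} not found in the Ct matrix")
        ct = matrix.values.loc[row]
        deltas.append((ct - ct.median()).abs())
    delta = pd.concat(deltas, axis=1).max(axis=1)
    fail = (delta > max_delta) | delta.isna()  # censored spike-in is a failure
    out = pd.DataFrame(
        {
            "sample_id": matrix.samples,
            "spikein_delta": delta.to_numpy(),
            "spikein_fail": fail.to_numpy(),
        }
    ).set_index("sample_id", drop=False)
    for sid in out.index[out["spikein_fail"]]:
        log.info("sample %s failed spike-in QC (delta > %.4g cycles)", sid, max_delta)
    return out


def qc_report(
    matrix: CtMatrix,
    mask: ExpressionMask,
    sheet: pd.DataFrame | None = None,
    spikein_names: Sequence[str] = (),
    hemolysis_delta_threshold: float = DEFAULT_HEMOLYSIS_DELTA_THRESHOLD,
    hemolysis_single_threshold: float = DEFAULT_HEMOLYSIS_SINGLE_THRESHOLD,
    spikein_max_delta: float = DEFAULT_SPIKEIN_MAX_DELTA,
    low_call_fraction: float = DEFAULT_LOW_CALL_FRACTION,
) -> pd.DataFrame:
    """One QC row per sample: spike-in delta, hemolysis delta and flags.

    Samples are flagged, never dropped; exclusion is the caller's decision.
    """
    report = pd.DataFrame({"sample_id": matrix.samples}).set_index("sample_id", drop=False)
    hemo = hemolysis_check(
        matrix, sheet,
        delta_threshold=hemolysis_delta_threshold,
        single_threshold=hemolysis_single_threshold,
    )
    report["hemolysis_delta"] = hemo["hemolysis_delta"]
    report["hemolysis_risk"] = hemo["hemolysis_risk"]
    if spikein_names:
        spike = spikein_check(matrix, spikein_names, max_delta=spikein_max_delta)
        report["spikein_delta"] = spike["spikein_delta"]
        report["spikein_fail"] = spike["spikein_fail"]
    else:
        report["spikein_delta"] = np.nan
        report["spikein_fail"] = False
    n_expr = mask.expressed.sum(axis=0)
    report["n_expressed"] = n_expr
    report["low_call_rate"] = n_expr < low_call_fraction * n_expr.median()
    report["flags"] = report.apply(
        lambda r: ";".join(
            f for f, on in (
                ("hemolysis_risk", r["hemolysis_risk"]),
                ("spikein_fail", r["spikein_fail"]),
                ("low_call_rate", r["low_call_rate"]),
            ) if on
        ),
        axis=1,
    )
    return report


def global_mean_normalize(
    matrix: CtMatrix,
    mask: ExpressionMask,
    spikein_names: Sequence[str] = (),
) -> NormalizedMatrix:
    """Global-mean delta-Ct normalization.

    The global set is every assay expressed in at least one cohort sample
    (spike-ins excluded: they are technical controls, not biology).  Each
    sample is centered on the mean Ct of the global-set members expressed in
    that sample, so censored cells never enter the mean.  delta_ct is defined
    only where the cell itself is expressed.
    """
    spike = {normalize_name(s) for s in spikein_names}
    gm_set = [a for a in mask.global_set if normalize_name(a) not in spike]
    if not gm_set:
        raise ValueError("global-mean set is empty: no expressed assays")
    inc = mask.expressed.loc[gm_set]
    counts = inc.sum(axis=0)
    if (counts == 0).any():
        empty = list(counts.index[counts == 0])
        raise ValueError(
            f"sample(s) with no expressed global-set assays: {', '.join(map(str, empty))}"
        )
    mean = matrix.values.loc[gm_set].where(inc).mean(axis=0)
    delta = matrix.values.sub(mean, axis=1).where(mask.expressed)
    log.info(
        "global-mean normalization: %d assays in the global set (%d spike-ins excluded)",
        len(gm_set), len(mask.global_set) - len(gm_set),
    )
    return NormalizedMatrix(delta_ct=delta, sample_mean_ct=mean)
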