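"""Targeted-assay quantification for longitudinal biomarker monitoring.

The discovery cohort identifies candidate markers; monitoring then runs a
small targeted panel (markers + housekeeping miRNAs + a spike-in) on serial
samples.  Levels are normalized to the mean Ct of housekeeping miRNAs
chosen for stability across the discovery cohort, referenced to a designated
comparator sample (an unaffected mutation-carrier relative in the original
design), and followed over time relative to the start of treatment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import normalize_name
from .io import CtMatrix
from .preprocess import ExpressionMask, NormalizedMatrix

log = logging.getLogger(__name__)


@dataclass
class HousekeeperSet:
    """Endogenous reference assays with their cross-sample dispersion."""

    assays: list[str]
    stability_score: pd.Series  # SD of normalized delta_ct, ascending


@dataclass
class MonitoringSeries:
    """Relative level of one marker over time, referenced to one sample."""

    marker: str
    points: list[tuple[int, float]]  # (day_offset, fold vs reference), sorted
    reference_sample: str


@dataclass
class RegressionResult:
    """OLS fit of one marker's series on another's."""

    slope: float
    intercept: float
    r: float
    p_value: float
    n: int


def select_housekeepers(
    norm: NormalizedMatrix,
    mask: ExpressionMask,
    k: int = 3,
    exclude: Sequence[str] = (),
) -> HousekeeperSet:
    """Pick the k most stable universally expressed assays.

    Candidates must be expressed in every cohort sample (a housekeeper that
    drops out is useless); stability is the standard deviation of the
    globally normalized delta_ct across samples, so sample-loading offsets
    do not masquerade as instability.  Ties break alphabetically.
    """
    if norm.delta_ct.shape[1] < 3:
        raise ValueError("housekeeper selection needs a cohort of >= 3 samples")
    skip = {normalize_name(e) for e in exclude}
    universal = [
        a for a in mask.expressed.index
        if mask.expressed.loc[a].all() and normalize_name(a) not in skip
    ]
    if len(universal) < k:
        raise ValueError(
            f"only {len(universal)} assays expressed in all samples; cannot select k={k}"
        )
    sd = norm.delta_ct.loc[universal].std(axis=1, ddof=1)
    order = sd.to_frame("sd").assign(name=lambda d: d.index.astype(str))
    order = order.sort_values(["sd", "name"])
    chosen = list(order.index[:k])
    log.info("selected housekeepers %s (SDs %s)", chosen, order["sd"].head(k).round(4).tolist())
    return HousekeeperSet(assays=chosen, stability_score=order["sd"].head(k))


def normalize_targeted(
    raw: CtMatrix | pd.DataFrame,
    housekeepers: Sequence[str],
) -> NormalizedMatrix:
    """Housekeeper-normalized delta_ct for a targeted panel.

    delta_ct(a, s) = Ct(a, s) - mean over housekeepers of Ct(h, s); the
    housekeeper mean plays the role the global mean plays in the discovery
    cohort.  Every housekeeper must be measured in every sample.
    """
    values = raw.values if isinstance(raw, CtMatrix) else raw
    by_norm = {normalize_name(a): a for a in values.index}
    rows = []
    for h in housekeepers:
        row = by_norm.get(normalize_name(h))
        if row is None:
            raise ValueError(f"housekeeper {h!r} not in the targeted matrix")
        rows.append(row)
    hk = values.loc[rows]
    if hk.isna().any().any():
        a, s = next(zip(*np.where(hk.isna().to_numpy())))
        raise ValueError(
            f"missing housekeeper measurement: assay {rows[a]!r}, "
            f"sample {values.columns[s]!r}"
        )
    hk_mean = hk.mean(axis=0)
    delta = values.sub(hk_mean, axis=1)
    return NormalizedMatrix(delta_ct=delta, sample_mean_ct=hk_mean)


def relative_to_reference(
    linear: pd.DataFrame,
    reference_sample: str,
    day_offsets: Mapping[str, int] | None = None,
) -> dict[str, MonitoringSeries]:
    """Divide each sample's linear level by the reference sample's.

    The reference maps to exactly 1.0 for every marker.  `day_offsets`
    (sample_id -> days relative to treatment start) orders the points;
    samples without a day offset (e.g. relatives) are omitted from the
    series points but remain in the returned ratio frame via
    `relative_levels`.
    """
    if reference_sample not in linear.columns:
        raise ValueError(f"reference sample {reference_sample!r} not measured")
    ref = linear[reference_sample]
    if ref.isna().any():
        missing = list(linear.index[ref.isna()])
        raise ValueError(
            f"reference sample {reference_sample!r} missing marker(s): {missing}"
        )
    ratios = linear.div(ref, axis=0)
    day_offsets = day_offsets or {}
    series: dict[str, MonitoringSeries] = {}
    for marker in ratios.index:
        pts = [
            (int(day_offsets[s]), float(ratios.loc[marker, s]))
            for s in ratios.columns
            if s in day_offsets and pd.notna(day_offsets[s])
        ]
        pts.sort(key=lambda t: t[0])
        series[marker] = MonitoringSeries(
            marker=marker, points=pts, reference_sample=reference_sample
        )
    return series


def relative_levels(linear: pd.DataFrame, reference_sample: str) -> pd.DataFrame:
    """Marker x sample frame of levels as folds of the reference sample."""
    if reference_sample not in linear.columns:
        raise ValueError(f"reference sample {reference_sample!r} not measured")
    return linear.div(linear[reference_sample], axis=0)


def pairwise_regression(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Ordinary least squares of y on x with a two-sided p for slope = 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must be paired and equal-length")
    if x.size < 3:
        raise ValueError("regression needs n >= 3 points")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    if np.ptp(y) == 0:  # flat response: slope 0, no association
        return RegressionResult(0.0, float(y[0]), 0.0, 1.0, int(x.size))
    fit = stats.linregress(x, y)
    p = fit.pvalue if np.isfinite(fit.pvalue) else 1.0
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        p_value=float(p),
        n=int(x.size),
    )
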