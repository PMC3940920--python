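"""-3p/-5p arm strand-bias construction and exact binomial testing.

Loss-of-function mutations in the DICER1 RNase IIIb domain impair cleavage
of the -5p strand of the precursor hairpin, so miRNAs produced by a mutant
tumor are expected to skew toward the -3p arm.  Given a list of
overexpressed assays, arm counting is only meaningful for *informative*
assays: the name specifies an arm AND the sister-arm probe exists on the
platform (otherwise an apparent excess could reflect probe content rather
than biology).  The excess of -3p among informative assays is tested with
an exact binomial test against a fair-arm null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from math import comb
from typing import Sequence

import pandas as pd

from .annotation import ARM_3P, ARM_5P, ARM_UNSPECIFIED, ProbePanel, parse_arm, sister_probe_present
from .preprocess import ExpressionMask

log = logging.getLogger(__name__)

ONE_SIDED_3P = "one_sided_3p"
TWO_SIDED = "two_sided"


@dataclass
class StrandBiasResult:
    """Counts and exact binomial p-value for -3p excess in a marker list."""

    n_input: int
    n_no_arm_info: int
    n_missing_sister: int
    n_informative: int
    n_3p: int
    n_5p: int
    p_value: float
    sidedness: str
    null_prob: float = 0.5
    excluded: dict[str, list[str]] | None = None

    def __post_init__(self) -> None:
        assert self.n_input == self.n_no_arm_info + self.n_missing_sister + self.n_informative
        assert self.n_informative == self.n_3p + self.n_5p


def informative_set(assays: Sequence[str], panel: ProbePanel) -> dict[str, list[str]]:
    """Partition a marker list into the three arm-informativeness classes.

    Each assay lands in exactly one of: informative_3p / informative_5p
    (arm named and sister probe on the platform), no_arm_info (no -3p/-5p
    suffix) or missing_sister (arm named but no opposite-arm probe).
    """
    if len(panel) == 0:
        raise ValueError("probe panel is empty")
    out: dict[str, list[str]] = {
        "informative_3p": [],
        "informative_5p": [],
        "no_arm_info": [],
        "missing_sister": [],
    }
    for a in assays:
        arm = parse_arm(a)
        if arm == ARM_UNSPECIFIED:
            out["no_arm_info"].append(a)
        elif not sister_probe_present(a, panel):
            out["missing_sister"].append(a)
        else:
            out["informative_3p" if arm == ARM_3P else "informative_5p"].append(a)
    for cls in ("no_arm_info", "missing_sister"):
        for a in out[cls]:
            log.info("strand-bias exclusion: %s (%s)", a, cls)
    return out


def count_arms(partition: dict[str, list[str]]) -> tuple[int, int]:
    """(n_3p, n_5p) among the informative assays of a partition."""
    return len(partition["informative_3p"]), len(partition["informative_5p"])


def exact_binomial_test(
    k: int,
    n: int,
    null_prob: float = 0.5,
    sidedness: str = ONE_SIDED_3P,
) -> float:
    """Exact binomial p-value for k '-3p' outcomes in n informative assays.

    One-sided (alternative: -3p excess): P(X >= k).  Two-sided: the
    minimum-likelihood method, summing the probability of every outcome no
    more likely than the observed one.  Computed in exact rational
    arithmetic and converted to float at the end.
    """
    if n == 0:
        raise ValueError("no informative microRNAs (n = 0)")
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, {n}]")
    if not 0 < null_prob < 1:
        raise ValueError("null_prob must be in (0, 1)")
    p = Fraction(null_prob)
    q = 1 - p
    pmf = [comb(n, j) * p**j * q ** (n - j) for j in range(n + 1)]
    if sidedness == ONE_SIDED_3P:
        total = sum(pmf[k:])
    elif sidedness == TWO_SIDED:
        total = sum(m for m in pmf if m <= pmf[k])
    else:
        raise ValueError(f"unknown sidedness {sidedness!r}")
    return float(total)


def strand_bias_test(
    assays: Sequence[str],
    panel: ProbePanel,
    null_prob: float = 0.5,
    sidedness: str = ONE_SIDED_3P,
) -> StrandBiasResult:
    """Full strand-bias analysis of a marker list against a probe panel."""
    part = informative_set(assays, panel)
    n_3p, n_5p = count_arms(part)
    n_inf = n_3p + n_5p
    p_value = exact_binomial_test(n_3p, n_inf, null_prob, sidedness) if n_inf else float("nan")
    result = StrandBiasResult(
        n_input=len(assays),
        n_no_arm_info=len(part["no_arm_info"]),
        n_missing_sister=len(part["missing_sister"]),
        n_informative=n_inf,
        n_3p=n_3p,
        n_5p=n_5p,
        p_value=p_value,
        sidedness=sidedness,
        null_prob=null_prob,
        excluded={
            "no_arm_info": part["no_arm_info"],
            "missing_sister": part["missing_sister"],
        },
    )
    log.info(
        "strand bias: %d input, %d informative (%d -3p / %d -5p), p=%.4g (%s, p0=%.3g)",
        result.n_input, n_inf, n_3p, n_5p, p_value, sidedness, null_prob,
    )
    return result


def dual_probe_universe(assays: Sequence[str], panel: ProbePanel) -> list[str]:
    """Assays whose name specifies an arm and whose sister probe is on the panel."""
    return [
        a for a in assays
        if parse_arm(a) != ARM_UNSPECIFIED and sister_probe_present(a, panel)
    ]


def strand_expression_fraction(mask: ExpressionMask, panel: ProbePanel) -> pd.DataFrame:
    """Per-sample %-3p and %-5p among expressed dual-probe assays.

    The universe is the platform-wide set of assays with both arm probes
    present; percentages are of each sample's expressed members of that
    universe, so pct_3p + pct_5p = 100 wherever defined.  Samples expressing
    no universe member get NaN fractions and an `undefined` flag.
    """
    universe = dual_probe_universe(list(mask.expressed.index), panel)
    arms = pd.Series({a: parse_arm(a) for a in universe})
    expr = mask.expressed.loc[universe]
    n_total = expr.sum(axis=0)
    n_3p = expr.loc[arms[arms == ARM_3P].index].sum(axis=0)
    pct_3p = 100.0 * n_3p / n_total.where(n_total > 0)
    out = pd.DataFrame(
        {
            "sample_id": mask.expressed.columns,
            "n_dual_expressed": n_total.to_numpy(),
            "pct_3p": pct_3p.to_numpy(),
            "pct_5p": (100.0 - pct_3p).to_numpy(),
            "undefined": (n_total == 0).to_numpy(),
        }
    ).set_index("sample_id", drop=False)
    return out
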