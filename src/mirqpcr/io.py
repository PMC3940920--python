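"""Readers and writers for Ct matrices and sample sheets.

A Ct matrix is assays x samples: header row of sample ids, one row per
assay.  Cells are either a finite cycle-threshold value or censored
(no amplification), written with tokens such as "Undetermined".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Tokens (case-insensitive, after stripping) recognized as censored cells.
DEFAULT_CENSOR_TOKENS = ("undetermined", "na", "", ">40")

#: Ct values above this many cycles are treated as censored on read.
DEFAULT_MAX_CYCLES = 40.0

VALID_GROUPS = ("case", "other_tumor", "control", "relative")

_SEP = {"tsv": "\t", "csv": ","}


@dataclass
class CtMatrix:
    """Raw cycle-threshold values with a censoring mask.

    ``values`` holds NaN exactly where ``censored`` is True: every
    (assay, sample) cell is either a finite Ct or censored, never both.
    """

    values: pd.DataFrame
    censored: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.censored.index) or not (
            self.values.columns.equals(self.censored.columns)
        ):
            raise ValueError("values and censored mask must share index/columns")
        nan = self.values.isna()
        if not nan.equals(self.censored.astype(bool)):
            raise ValueError(
                "every cell must be either a finite Ct or censored, never both"
            )
        if (self.values < 0).any().any():
            raise ValueError("negative Ct values are not meaningful")

    @property
    def assays(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def subset_samples(self, sample_ids: list[str]) -> "CtMatrix":
        return CtMatrix(self.values[sample_ids], self.censored[sample_ids])


def read_ct_matrix(
    path: str | Path,
    dialect: str = "tsv",
    censor_tokens: tuple[str, ...] = DEFAULT_CENSOR_TOKENS,
    max_cycles: float = DEFAULT_MAX_CYCLES,
) -> CtMatrix:
    """Parse a Ct matrix file (assays in rows, samples in columns).

    Censored entries are recognized from `censor_tokens` (case-insensitive);
    a finite Ct above `max_cycles` is also censored.  Any other non-numeric
    token is an error reported with its (assay, sample) coordinates.
    """
    raw = pd.read_csv(
        Path(path), sep=_SEP[dialect], index_col=0, dtype=str, keep_default_na=False
    )
    raw.index = raw.index.astype(str).str.strip()
    if raw.index.duplicated().any():
        dups = sorted(set(raw.index[raw.index.duplicated()]))
        raise ValueError(f"duplicate assay name(s) in {path}: {', '.join(dups)}")
    if raw.columns.duplicated().any():
        raise ValueError(f"duplicate sample id(s) in header of {path}")

    tokens = {t.lower() for t in censor_tokens}
    stripped = raw.apply(lambda col: col.str.strip())
    censored = stripped.apply(lambda col: col.str.lower().isin(tokens))
    values = stripped.mask(censored).apply(pd.to_numeric, errors="coerce")

    bad = values.isna() & ~censored
    if bad.any().any():
        a, s = next(zip(*np.where(bad.to_numpy())))
        raise ValueError(
            f"non-numeric, non-censored token {stripped.iat[a, s]!r} at "
            f"assay {raw.index[a]!r}, sample {raw.columns[s]!r} in {path}"
        )

    over = values > max_cycles
    censored = (censored | over).astype(bool)
    values = values.mask(censored)
    log.info(
        "read Ct matrix %s: %d assays x %d samples, %d censored cells",
        path, values.shape[0], values.shape[1], int(censored.to_numpy().sum()),
    )
    return CtMatrix(values, censored)


def write_ct_matrix(
    matrix: CtMatrix,
    path: str | Path,
    dialect: str = "tsv",
    censor_token: str = "Undetermined",
    float_format: str = "%.4f",
) -> None:
    out = matrix.values.map(lambda v: float_format % v if pd.notna(v) else censor_token)
    out.to_csv(Path(path), sep=_SEP[dialect])


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a TSV sample sheet; index = sample_id.

    Required columns: sample_id, group (case | other_tumor | control |
    relative).  Optional: day_offset (days relative to chemotherapy start,
    nullable), hemolysis_visual_flag (bool, default False).
    """
    sheet = pd.read_csv(Path(path), sep="\t", dtype={"sample_id": str})
    missing = {"sample_id", "group"} - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet {path} lacks column(s): {sorted(missing)}")
    if sheet["sample_id"].duplicated().any():
        raise ValueError(f"duplicate sample_id in {path}")
    bad_groups = set(sheet["group"]) - set(VALID_GROUPS)
    if bad_groups:
        raise ValueError(f"unknown group(s) {sorted(bad_groups)}; expected {VALID_GROUPS}")
    if "day_offset" not in sheet.columns:
        sheet["day_offset"] = pd.NA
    sheet["day_offset"] = pd.array(
        pd.to_numeric(sheet["day_offset"], errors="coerce"), dtype="Int64"
    )
    if "hemolysis_visual_flag" not in sheet.columns:
        sheet["hemolysis_visual_flag"] = False
    sheet["hemolysis_visual_flag"] = (
        sheet["hemolysis_visual_flag"]
        .map(lambda v: str(v).strip().lower() in {"true", "1", "yes"})
        .astype(bool)
    )
    return sheet.set_index("sample_id", drop=False)


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(Path(path), sep="\t", index=False)
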