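"""End-to-end orchestration: discovery and monitoring runs.

`run_discovery` chains expression calling -> sample QC -> global-mean
normalization -> dual-reference fold changes -> overexpression calls ->
ranking -> strand-bias test, writing machine-readable outputs plus a JSON
summary.  `run_monitor` handles the targeted longitudinal arm.  Both are
fully deterministic for fixed inputs and configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import biomarker, monitoring, preprocess, strand_bias
from .annotation import ProbePanel, load_mirbase_annotation, normalize_name, read_panel
from .io import CtMatrix, read_ct_matrix, read_sample_sheet
from .simulate import SPIKE_IN

log = logging.getLogger(__name__)

SUMMARY_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Paths and thresholds for a pipeline run; unknown YAML keys rejected."""

    ct_matrix: str | None = None
    sample_sheet: str | None = None
    panel: str | None = None
    gff3: str | None = None
    targeted_matrix: str | None = None
    out_dir: str = "."
    dialect: str = "tsv"
    ct_threshold: float = preprocess.DEFAULT_CT_THRESHOLD
    fc_threshold: float = biomarker.DEFAULT_FC_THRESHOLD
    hemolysis_delta_threshold: float = preprocess.DEFAULT_HEMOLYSIS_DELTA_THRESHOLD
    hemolysis_single_threshold: float = preprocess.DEFAULT_HEMOLYSIS_SINGLE_THRESHOLD
    spikein_max_delta: float = preprocess.DEFAULT_SPIKEIN_MAX_DELTA
    spikein_names: tuple[str, ...] = (SPIKE_IN,)
    sidedness: str = strand_bias.ONE_SIDED_3P
    null_prob: float = 0.5
    top_k: int = 10
    case_sample: str | None = None
    exclude_failed_qc: bool = False
    housekeepers: tuple[str, ...] | None = None
    n_housekeepers: int = 3
    reference_sample: str | None = None
    markers: tuple[str, ...] | None = None
    seed: int | None = None  # only the simulator consumes randomness


def load_run_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    for key in ("spikein_names", "housekeepers", "markers"):
        if raw.get(key) is not None:
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


def _resolve_case(sheet: pd.DataFrame, config: RunConfig) -> str:
    """The designated index case: configured, or the earliest-day case sample."""
    if config.case_sample is not None:
        if config.case_sample not in sheet.index:
            raise ValueError(f"case sample {config.case_sample!r} not in sample sheet")
        return config.case_sample
    cases = sheet[sheet["group"] == "case"]
    if len(cases) == 0:
        raise ValueError("sample sheet contains no case sample")
    if len(cases) == 1:
        return cases.index[0]
    with_day = cases.dropna(subset=["day_offset"])
    if len(with_day) != len(cases):
        raise ValueError(
            "multiple case samples but day_offset missing; cannot pick the index case"
        )
    return with_day.sort_values("day_offset").index[0]


def _echo_thresholds(config: RunConfig) -> dict:
    return {
        "ct_threshold": config.ct_threshold,
        "fc_threshold": config.fc_threshold,
        "hemolysis_delta_threshold": config.hemolysis_delta_threshold,
        "hemolysis_single_threshold": config.hemolysis_single_threshold,
        "spikein_max_delta": config.spikein_max_delta,
        "null_prob": config.null_prob,
        "sidedness": config.sidedness,
    }


def run_discovery(config: RunConfig) -> dict:
    """Run the full discovery pipeline and write its outputs.

    Outputs in `out_dir`: qc_report.tsv, normalized_delta_ct.tsv,
    normalized_linear.tsv, fold_changes.tsv, top_markers.tsv,
    arm_fractions.tsv, strand_bias.json, summary.json.  Returns the summary
    dict (all counts plus the echoed thresholds).
    """
    for name in ("ct_matrix", "sample_sheet", "panel"):
        path = getattr(config, name)
        if path is None or not Path(path).exists():
            raise FileNotFoundError(f"required input {name!r} missing: {path}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "read inputs"
    try:
        matrix = read_ct_matrix(config.ct_matrix, dialect=config.dialect)
        sheet = read_sample_sheet(config.sample_sheet)
        panel = read_panel(config.panel)
        unknown = [s for s in matrix.samples if s not in sheet.index]
        if unknown:
            raise ValueError(f"matrix sample(s) missing from sample sheet: {unknown}")
        case = _resolve_case(sheet, config)

        stage = "expression calling"
        mask = preprocess.call_expressed(matrix, config.ct_threshold)

        stage = "sample QC"
        qc = preprocess.qc_report(
            matrix, mask, sheet,
            spikein_names=config.spikein_names,
            hemolysis_delta_threshold=config.hemolysis_delta_threshold,
            hemolysis_single_threshold=config.hemolysis_single_threshold,
            spikein_max_delta=config.spikein_max_delta,
        )
        qc.to_csv(out / "qc_report.tsv", sep="\t", index=False)
        failed = list(qc.index[qc["flags"] != ""])
        if failed and config.exclude_failed_qc:
            keep = [s for s in matrix.samples if s not in failed or s == case]
            log.info("excluding %d QC-flagged samples: %s", len(failed), failed)
            matrix = matrix.subset_samples(keep)
            mask = preprocess.call_expressed(matrix, config.ct_threshold)

        stage = "global-mean normalization"
        norm = preprocess.global_mean_normalize(matrix, mask, config.spikein_names)
        norm.delta_ct.to_csv(out / "normalized_delta_ct.tsv", sep="\t")
        norm.linear.to_csv(out / "normalized_linear.tsv", sep="\t")

        stage = "fold changes"
        groups = {
            g: [s for s in sheet.index[sheet["group"] == g] if s in norm.samples]
            for g in ("control", "other_tumor")
        }
        design = biomarker.GroupDesign(case_sample=case, reference_groups=groups)
        table = biomarker.fold_change_table(norm, design, config.fc_threshold)
        if config.gff3:
            ann = load_mirbase_annotation(config.gff3, panel).set_index("assay_name")
            table = table.join(ann["chromosomal_location"], how="left")
        table.to_csv(out / "fold_changes.tsv", sep="\t", index_label="assay")

        stage = "ranking"
        top = biomarker.rank_markers(table, config.top_k)
        top.to_csv(out / "top_markers.tsv", sep="\t", index_label="assay")

        stage = "strand bias"
        called = list(table.index[table["overexpressed"]])
        sb = strand_bias.strand_bias_test(
            called, panel, null_prob=config.null_prob, sidedness=config.sidedness
        )
        (out / "strand_bias.json").write_text(
            json.dumps(dataclasses.asdict(sb), indent=1)
        )
        fractions = strand_bias.strand_expression_fraction(mask, panel)
        fractions.to_csv(out / "arm_fractions.tsv", sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"discovery stage {stage!r} failed: {exc}") from exc

    spike_norm = {normalize_name(s) for s in config.spikein_names}
    summary = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "case_sample": case,
        "n_assays": len(matrix.assays),
        "n_samples": int(len(norm.samples)),
        "n_discovery_samples": 1 + len(groups["control"]) + len(groups["other_tumor"]),
        "n_expressed": len(
            [a for a in mask.global_set if normalize_name(a) not in spike_norm]
        ),
        "n_qc_flagged": len(failed),
        "n_called": int(table["overexpressed"].sum()),
        "n_input": sb.n_input,
        "n_no_arm_info": sb.n_no_arm_info,
        "n_missing_sister": sb.n_missing_sister,
        "n_informative": sb.n_informative,
        "n_3p": sb.n_3p,
        "n_5p": sb.n_5p,
        "p_value": None if pd.isna(sb.p_value) else sb.p_value,
        "thresholds": _echo_thresholds(config),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    log.info("discovery summary: %s", summary)
    return summary


def run_monitor(config: RunConfig) -> dict:
    """Run the targeted longitudinal arm and write its outputs.

    Housekeepers come from the config or, when omitted, are auto-selected
    from the global discovery matrix (which must then be provided).  Writes
    monitoring_series.tsv and regression.json.
    """
    if config.targeted_matrix is None or not Path(config.targeted_matrix).exists():
        raise FileNotFoundError(f"targeted matrix missing: {config.targeted_matrix}")
    if config.reference_sample is None:
        raise ValueError("a reference (comparator) sample is required for monitoring")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    targeted = read_ct_matrix(config.targeted_matrix, dialect=config.dialect)
    sheet = read_sample_sheet(config.sample_sheet) if config.sample_sheet else None

    housekeepers = config.housekeepers
    if housekeepers is None:
        if config.ct_matrix is None:
            raise ValueError(
                "housekeepers not configured and no global matrix given for auto-selection"
            )
        cohort = read_ct_matrix(config.ct_matrix, dialect=config.dialect)
        mask = preprocess.call_expressed(cohort, config.ct_threshold)
        norm = preprocess.global_mean_normalize(cohort, mask, config.spikein_names)
        hk = monitoring.select_housekeepers(
            norm, mask, k=config.n_housekeepers, exclude=config.spikein_names
        )
        housekeepers = tuple(hk.assays)

    spike_on_panel = [
        s for s in config.spikein_names
        if any(normalize_name(a) == normalize_name(s) for a in targeted.assays)
    ]
    qc_warned = []
    if spike_on_panel:
        spike = preprocess.spikein_check(
            targeted, spike_on_panel, max_delta=config.spikein_max_delta
        )
        qc_warned = list(spike.index[spike["spikein_fail"]])
        for s in qc_warned:
            log.warning("sample %s fails targeted spike-in QC; proceeding", s)

    tnorm = monitoring.normalize_targeted(targeted, housekeepers)
    skip = {normalize_name(x) for x in (*housekeepers, *config.spikein_names)}
    markers = list(config.markers) if config.markers else [
        a for a in targeted.assays if normalize_name(a) not in skip
    ]
    linear = tnorm.linear.loc[markers]
    ratios = monitoring.relative_levels(linear, config.reference_sample)
    day_map = (
        {s: int(d) for s, d in sheet["day_offset"].dropna().items()}
        if sheet is not None else {}
    )
    series = monitoring.relative_to_reference(linear, config.reference_sample, day_map)

    rows = []
    for marker in markers:
        for s in ratios.columns:
            rows.append(
                {
                    "marker": marker,
                    "sample_id": s,
                    "day_offset": day_map.get(s, ""),
                    "relative_level": ratios.loc[marker, s],
                }
            )
    pd.DataFrame(rows).to_csv(out / "monitoring_series.tsv", sep="\t", index=False)

    regression = None
    if len(markers) >= 2:
        x, y = ratios.loc[markers[0]], ratios.loc[markers[1]]
        ok = x.notna() & y.notna()
        if ok.sum() >= 3:
            fit = monitoring.pairwise_regression(x[ok], y[ok])
            regression = {"x": markers[0], "y": markers[1], **dataclasses.asdict(fit)}
        else:
            log.info("regression refused: only %d paired points (need >= 3)", int(ok.sum()))
    (out / "regression.json").write_text(json.dumps(regression, indent=1))

    result = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "housekeepers": list(housekeepers),
        "reference_sample": config.reference_sample,
        "markers": markers,
        "spikein_warned_samples": qc_warned,
        "series": {
            m: [[d, lvl] for d, lvl in series[m].points] for m in markers
        },
        "regression": regression,
    }
    (out / "monitor_summary.json").write_text(json.dumps(result, indent=1))
    return result
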