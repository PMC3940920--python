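"""Synthetic serum qPCR cohorts with full ground truth.

The generator emulates the study design the analysis assumes: one index
tumor case profiled on a ~741-assay miRNA panel alongside other childhood
tumors and healthy controls, plus mutation-carrier relatives and serial
case samples for targeted monitoring.  The signal model on the Ct (cycle)
scale is

    Ct(a, s) = baseline(a) + shift(s) - log2(spike fold(a, s)) + noise

with Gaussian cycle-scale noise (the conventional qPCR error model),
per-sample loading shifts, detection censoring above a cycle limit, and a
programmed set of case-only spiked markers whose arms are skewed toward
-3p.  Everything needed to recompute expected pipeline outputs analytically
is returned as a SimTruth object and serialized to truth.json.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import ARM_3P, ARM_5P, ARM_UNSPECIFIED, ProbePanel, parse_arm, sister_probe_present, write_panel
from .io import CtMatrix, write_ct_matrix, write_sample_sheet

log = logging.getLogger(__name__)

SPIKE_IN = "cel-miR-39-3p"
HOUSEKEEPERS = ("miR-191-5p", "miR-30b-5p", "miR-30c-5p")
HEMOLYSIS_MARKER = "miR-451"
HEMOLYSIS_REFERENCE = "miR-23a"
SPECIAL_BASELINES = {
    HEMOLYSIS_MARKER: 19.0,
    HEMOLYSIS_REFERENCE: 24.0,
    HOUSEKEEPERS[0]: 24.5,
    HOUSEKEEPERS[1]: 25.0,
    HOUSEKEEPERS[2]: 25.5,
    SPIKE_IN: 20.0,
}


@dataclass
class SimConfig:
    """Study-design parameters of the simulated cohort.

    Defaults reproduce the structure of the emulated study: 741 human
    assays; 1 index case + 32 other tumors + 20 controls (53 discovery
    samples) + 2 carrier relatives + 3 extra longitudinal case samples;
    45 spiked markers spanning 3.4-40.3-fold of which 30 are
    arm-informative with a 70% -3p share (21/30).
    """

    seed: int
    n_assays: int = 741
    n_control: int = 20
    n_other_tumor: int = 32
    n_relatives: int = 2
    longitudinal_days: tuple[int, ...] = (-11, -2, 3, 12)
    baseline_ct_low: float = 22.0
    baseline_ct_high: float = 35.0
    sample_shift_sd: float = 0.5
    noise_sd: float = 0.5
    detection_limit: float = 37.0  # expression-call threshold downstream
    censor_limit: float = 40.0  # Ct above this is written as Undetermined
    spike_set_size: int = 45
    spike_fold_low: float = 3.4
    spike_fold_high: float = 40.3
    frac_informative_spiked: float = 30 / 45
    frac_3p_spiked: float = 0.7
    pair_prob: float = 1 / 3
    arm_suffix_probs: dict = field(
        default_factory=lambda: {"3p": 0.35, "5p": 0.20, "none": 0.45}
    )
    other_tumor_spike_count: int = 3
    other_tumor_fold_low: float = 2.0
    other_tumor_fold_high: float = 8.0
    hemolysis_samples: tuple[str, ...] = ()
    hemolysis_shift: float = -6.0
    spikein_fail_samples: tuple[str, ...] = ()
    spikein_fail_shift: float = 3.5
    flare_profile: dict = field(
        default_factory=lambda: {-11: 1.0, -2: 1.6, 3: 2.2, 12: 0.25}
    )
    hk_noise_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.spike_set_size > self.n_assays:
            raise ValueError("spike_set_size exceeds n_assays")
        for name, val in (
            ("n_assays", self.n_assays), ("n_control", self.n_control),
            ("n_other_tumor", self.n_other_tumor), ("n_relatives", self.n_relatives),
            ("spike_set_size", self.spike_set_size),
        ):
            if val < 0:
                raise ValueError(f"{name} must be >= 0")
        for name, p in (
            ("frac_informative_spiked", self.frac_informative_spiked),
            ("frac_3p_spiked", self.frac_3p_spiked),
            ("pair_prob", self.pair_prob),
        ):
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        missing_days = set(self.flare_profile) - set(self.longitudinal_days)
        # extra flare keys are fine; every longitudinal day needs a multiplier
        missing = set(self.longitudinal_days) - set(self.flare_profile)
        if missing:
            raise ValueError(f"flare_profile lacks day offset(s): {sorted(missing)}")
        del missing_days


@dataclass
class SimTruth:
    """Ground truth sufficient to recompute expected pipeline outputs."""

    seed: int
    index_case: str
    spiked: dict[str, dict]  # assay -> {fold, arm, cls}
    other_tumor_spikes: dict[str, dict[str, float]]  # sample -> {assay: fold}
    housekeepers: list[str]
    monitored_markers: list[str]
    baselines: dict[str, float]
    sample_shifts: dict[str, float]
    flare_profile: dict[int, float]
    hemolysis_samples: list[str]
    spikein_fail_samples: list[str]

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["flare_profile"] = {str(k): v for k, v in d["flare_profile"].items()}
        Path(path).write_text(json.dumps(d, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        d = json.loads(Path(path).read_text())
        d["flare_profile"] = {int(k): v for k, v in d["flare_profile"].items()}
        return cls(**d)


def _sample_ids(config: SimConfig) -> dict:
    days = sorted(config.longitudinal_days)
    case_samples = {d: f"PPB_d{d:+d}" for d in days}
    index_case = case_samples[days[0]]
    others = [f"OT{i:02d}" for i in range(1, config.n_other_tumor + 1)]
    controls = [f"CTRL{i:02d}" for i in range(1, config.n_control + 1)]
    relatives = ["MOTHER", "GRANDMOTHER", *(
        f"REL{i:02d}" for i in range(3, config.n_relatives + 1)
    )][: config.n_relatives]
    return {
        "case_samples": case_samples,
        "index_case": index_case,
        "other_tumor": others,
        "control": controls,
        "relatives": relatives,
    }


def _make_panel(config: SimConfig, rng: np.random.Generator) -> ProbePanel:
    """Synthetic probe names with realistic arm-suffix structure.

    Hairpins are drawn one at a time: with `pair_prob` the platform carries
    both arm probes of the hairpin; otherwise a single probe whose suffix
    (-3p / -5p / none) follows `arm_suffix_probs`.
    """
    probs = config.arm_suffix_probs
    keys = ("3p", "5p", "none")
    w = np.array([probs.get(k, 0.0) for k in keys], dtype=float)
    if w.sum() <= 0:
        raise ValueError("arm_suffix_probs must have positive total mass")
    w = w / w.sum()
    specials = [HEMOLYSIS_MARKER, HEMOLYSIS_REFERENCE, *HOUSEKEEPERS]
    target = config.n_assays - len(specials)
    if target < 0:
        raise ValueError(f"n_assays must be at least {len(specials)}")
    names: list[str] = []
    i = 0
    while len(names) < target:
        i += 1
        stem = f"miR-s{i:04d}"
        if len(names) + 2 <= target and rng.random() < config.pair_prob:
            names += [f"{stem}-3p", f"{stem}-5p"]
        else:
            suffix = keys[rng.choice(3, p=w)]
            names.append(stem if suffix == "none" else f"{stem}-{suffix}")
    return ProbePanel(names + specials, panel_id="synthetic-panel")


def _choose_spikes(
    config: SimConfig, panel: ProbePanel, rng: np.random.Generator
) -> dict[str, dict]:
    """Assign spiked case markers across arm-informativeness classes."""
    specials = {HEMOLYSIS_MARKER, HEMOLYSIS_REFERENCE, *HOUSEKEEPERS}
    pools: dict[str, list[str]] = {"informative_3p": [], "informative_5p": [],
                                   "no_arm_info": [], "missing_sister": []}
    for a in panel:
        if a in specials:
            continue
        arm = parse_arm(a)
        if arm == ARM_UNSPECIFIED:
            pools["no_arm_info"].append(a)
        elif not sister_probe_present(a, panel):
            pools["missing_sister"].append(a)
        else:
            pools["informative_3p" if arm == ARM_3P else "informative_5p"].append(a)

    n_inf = round(config.frac_informative_spiked * config.spike_set_size)
    n_3p = round(config.frac_3p_spiked * n_inf)
    n_5p = n_inf - n_3p
    n_non = config.spike_set_size - n_inf
    n_ms = min(1, n_non, len(pools["missing_sister"]))
    n_na = n_non - n_ms
    plan = {
        "informative_3p": n_3p,
        "informative_5p": n_5p,
        "no_arm_info": n_na,
        "missing_sister": n_ms,
    }
    spiked: dict[str, dict] = {}
    for cls, n in plan.items():
        if n > len(pools[cls]):
            raise ValueError(
                f"cannot spike {n} assays from class {cls!r}: only {len(pools[cls])} available"
            )
        chosen = rng.choice(len(pools[cls]), size=n, replace=False)
        for idx in sorted(chosen):
            a = pools[cls][idx]
            fold = float(
                2.0 ** rng.uniform(np.log2(config.spike_fold_low), np.log2(config.spike_fold_high))
            )
            spiked[a] = {"fold": fold, "arm": parse_arm(a), "cls": cls}
    return spiked


def simulate_cohort(
    config: SimConfig,
) -> tuple[CtMatrix, pd.DataFrame, ProbePanel, SimTruth]:
    """Generate the global discovery matrix, sample sheet, panel and truth.

    The matrix columns are the index case, other tumors, controls,
    relatives, then the remaining longitudinal case samples; the discovery
    cohort is the first 1 + n_other_tumor + n_control of these.
    Deterministic for a given config + seed.
    """
    rng = np.random.default_rng([int(config.seed), 0])
    panel = _make_panel(config, rng)
    ids = _sample_ids(config)
    days = sorted(config.longitudinal_days)
    samples = (
        [ids["index_case"]]
        + ids["other_tumor"]
        + ids["control"]
        + ids["relatives"]
        + [ids["case_samples"][d] for d in days[1:]]
    )

    assays = list(panel) + [SPIKE_IN]
    baselines = {
        a: SPECIAL_BASELINES.get(
            a, float(rng.uniform(config.baseline_ct_low, config.baseline_ct_high))
        )
        for a in assays
    }
    shifts = {s: float(rng.normal(0.0, config.sample_shift_sd)) for s in samples}

    spiked = _choose_spikes(config, panel, rng)
    # disjoint per-sample spike sets for the other-tumor group
    available = [a for a in panel if a not in spiked and a not in SPECIAL_BASELINES]
    rng.shuffle(available)
    ot_spikes: dict[str, dict[str, float]] = {}
    pos = 0
    for s in ids["other_tumor"]:
        take = available[pos: pos + config.other_tumor_spike_count]
        pos += config.other_tumor_spike_count
        ot_spikes[s] = {
            a: float(
                2.0
                ** rng.uniform(
                    np.log2(config.other_tumor_fold_low),
                    np.log2(config.other_tumor_fold_high),
                )
            )
            for a in take
        }

    quiet = {*HOUSEKEEPERS, SPIKE_IN}  # low technical noise rows
    base_vec = np.array([baselines[a] for a in assays])[:, None]
    shift_vec = np.array([shifts[s] for s in samples])[None, :]
    noise_sd = np.array(
        [config.hk_noise_sd if a in quiet else config.noise_sd for a in assays]
    )[:, None]
    ct = base_vec + shift_vec + rng.normal(0.0, 1.0, (len(assays), len(samples))) * noise_sd

    a_idx = {a: i for i, a in enumerate(assays)}
    s_idx = {s: j for j, s in enumerate(samples)}
    day_of_case = {v: k for k, v in ids["case_samples"].items()}
    for a, info in spiked.items():
        for sample, day in day_of_case.items():
            level = info["fold"] * config.flare_profile[day]
            ct[a_idx[a], s_idx[sample]] -= np.log2(level)
    for s, spikes in ot_spikes.items():
        for a, fold in spikes.items():
            ct[a_idx[a], s_idx[s]] -= np.log2(fold)
    for s in config.hemolysis_samples:
        ct[a_idx[HEMOLYSIS_MARKER], s_idx[s]] += config.hemolysis_shift
    for s in config.spikein_fail_samples:
        ct[a_idx[SPIKE_IN], s_idx[s]] += config.spikein_fail_shift
    ct = np.maximum(ct, 0.0)

    values = pd.DataFrame(ct, index=assays, columns=samples)
    censored = values > config.censor_limit
    values = values.mask(censored)
    matrix = CtMatrix(values, censored)

    rows = []
    for s in samples:
        if s in day_of_case:
            group, day = "case", day_of_case[s]
        elif s in ids["other_tumor"]:
            group, day = "other_tumor", pd.NA
        elif s in ids["control"]:
            group, day = "control", pd.NA
        else:
            group, day = "relative", pd.NA
        rows.append(
            {
                "sample_id": s,
                "group": group,
                "day_offset": day,
                "hemolysis_visual_flag": s in config.hemolysis_samples,
            }
        )
    sheet = pd.DataFrame(rows)
    sheet["day_offset"] = pd.array(sheet["day_offset"], dtype="Int64")
    sheet = sheet.set_index("sample_id", drop=False)

    monitored = [
        a for a, _ in sorted(spiked.items(), key=lambda kv: -kv[1]["fold"])[:2]
    ]
    truth = SimTruth(
        seed=int(config.seed),
        index_case=ids["index_case"],
        spiked=spiked,
        other_tumor_spikes=ot_spikes,
        housekeepers=list(HOUSEKEEPERS),
        monitored_markers=monitored,
        baselines=baselines,
        sample_shifts=shifts,
        flare_profile=dict(config.flare_profile),
        hemolysis_samples=list(config.hemolysis_samples),
        spikein_fail_samples=list(config.spikein_fail_samples),
    )
    log.info(
        "simulated cohort: %d assays (+1 spike-in) x %d samples, %d spiked markers",
        len(panel), len(samples), len(spiked),
    )
    return matrix, sheet, panel, truth


def simulate_longitudinal(config: SimConfig, truth: SimTruth) -> CtMatrix:
    """Targeted-panel Ct matrix: monitored markers + housekeepers + spike-in
    over the case time course and the relatives.

    Marker levels in the case follow the programmed flare multipliers on top
    of the diagnostic spike fold; relatives carry no spike effect;
    housekeepers are flat.  Shares baselines and sample shifts with the
    cohort truth; noise uses an independent substream of the seed.
    """
    rng = np.random.default_rng([int(config.seed), 1])
    ids = _sample_ids(config)
    days = sorted(config.longitudinal_days)
    missing = set(days) - set(config.flare_profile)
    if missing:
        raise ValueError(f"flare_profile lacks day offset(s): {sorted(missing)}")
    samples = [ids["case_samples"][d] for d in days] + ids["relatives"]
    assays = truth.monitored_markers + truth.housekeepers + [SPIKE_IN]

    quiet = {*truth.housekeepers, SPIKE_IN}
    ct = np.empty((len(assays), len(samples)))
    for i, a in enumerate(assays):
        sd = config.hk_noise_sd if a in quiet else config.noise_sd
        for j, s in enumerate(samples):
            shift = truth.sample_shifts.get(s, 0.0)
            val = truth.baselines[a] + shift + rng.normal(0.0, sd)
            if a in truth.spiked and s in ids["case_samples"].values():
                day = next(d for d, sid in ids["case_samples"].items() if sid == s)
                val -= np.log2(truth.spiked[a]["fold"] * config.flare_profile[day])
            ct[i, j] = val
    values = pd.DataFrame(np.maximum(ct, 0.0), index=assays, columns=samples)
    censored = values > config.censor_limit
    values = values.mask(censored)
    return CtMatrix(values, censored)


def write_synthetic_gff3(
    assays: list[str], path: str | Path, seed: int = 0
) -> dict[str, str]:
    """Write a synthetic miRBase-style GFF3 covering `assays`.

    Locations are invented deterministically from the seed; returns the
    name -> "chrom:start-end(strand)" truth map for round-trip tests.
    """
    rng = np.random.default_rng([int(seed), 2])
    lines = ["##gff-version 3"]
    truth: dict[str, str] = {}
    for i, a in enumerate(assays):
        chrom = f"chr{1 + i % 22}"
        start = int(rng.integers(1_000, 100_000_000))
        end = start + int(rng.integers(60, 120))
        strand = "+" if rng.random() < 0.5 else "-"
        lines.append(
            f"{chrom}\t.\tmiRNA\t{start}\t{end}\t.\t{strand}\t.\t"
            f"ID=SYN{i:07d};Name={a}"
        )
        truth[a] = f"{chrom}:{start}-{end}({strand})"
    Path(path).write_text("\n".join(lines) + "\n")
    return truth


def write_fixture(
    directory: str | Path,
    matrix: CtMatrix,
    sheet: pd.DataFrame,
    panel: ProbePanel,
    truth: SimTruth,
    targeted: CtMatrix | None = None,
) -> dict[str, Path]:
    """Write the cohort to disk (byte-stable for a given config + seed)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "ct_matrix": directory / "ct_matrix.tsv",
        "samples": directory / "samples.tsv",
        "panel": directory / "panel.txt",
        "truth": directory / "truth.json",
    }
    write_ct_matrix(matrix, paths["ct_matrix"])
    write_sample_sheet(sheet, paths["samples"])
    write_panel(panel, paths["panel"])
    truth.to_json(paths["truth"])
    if targeted is not None:
        paths["targeted"] = directory / "targeted.tsv"
        write_ct_matrix(targeted, paths["targeted"])
    return paths
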