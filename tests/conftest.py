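import pandas as pd
import pytest

from mirqpcr import (
    GroupDesign,
    call_expressed,
    fold_change_table,
    global_mean_normalize,
    simulate_cohort,
    simulate_longitudinal,
)
from mirqpcr.simulate import SPIKE_IN, SimConfig

# The 10 most-abundant case markers as printed in the published table,
# with their fold changes vs controls and the comparison ("other tumor")
# group's own fold vs controls.  Used as worked-example inputs.
TABLE1 = [
    ("miR-125a-3p", 40.28, 1.19),
    ("miR-125b-2-3p", 14.84, 0.71),
    ("miR-380-5p", 9.26, 0.30),
    ("miR-125b-1-3p", 6.41, 0.66),
    ("let-7f-2-3p", 5.92, 0.96),
    ("let-7a-3p", 5.87, 1.11),
    ("let-7b-3p", 4.57, 1.23),
    ("miR-708-3p", 4.15, 0.78),
    ("miR-138-1-3p", 3.95, 0.56),
    ("miR-532-3p", 3.43, 1.58),
]


@pytest.fixture(scope="session")
def table1_names():
    return [name for name, _, _ in TABLE1]


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition synthetic cohort shared across tests."""
    cfg = SimConfig(seed=11)
    matrix, sheet, panel, truth = simulate_cohort(cfg)
    return {"config": cfg, "matrix": matrix, "sheet": sheet, "panel": panel, "truth": truth}


@pytest.fixture(scope="session")
def default_normalized(default_cohort):
    mask = call_expressed(default_cohort["matrix"])
    norm = global_mean_normalize(default_cohort["matrix"], mask, [SPIKE_IN])
    return {"mask": mask, "norm": norm, **default_cohort}


@pytest.fixture(scope="session")
def default_discovery(default_normalized):
    sheet = default_normalized["sheet"]
    groups = {
        g: list(sheet.index[sheet["group"] == g]) for g in ("control", "other_tumor")
    }
    design = GroupDesign(default_normalized["truth"].index_case, groups)
    table = fold_change_table(default_normalized["norm"], design)
    return {"design": design, "table": table, **default_normalized}


@pytest.fixture(scope="session")
def default_targeted(default_cohort):
    return simulate_longitudinal(default_cohort["config"], default_cohort["truth"])


def toy_ct_frame(data: dict, samples: list[str]) -> pd.DataFrame:
    """Small assays x samples Ct frame from {assay: [ct...]}."""
    return pd.DataFrame.from_dict(data, orient="index", columns=samples, dtype=float)
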