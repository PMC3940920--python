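"""miRNA arm annotation and probe-panel bookkeeping.

Mature miRNAs derive from either the 5' or the 3' side of the precursor
hairpin and are named with a ``-5p`` / ``-3p`` suffix; legacy names
(e.g. ``miR-451``) carry no arm information.  Arm calls here are purely
name-based: the suffix is the field's naming convention, so the arm is a
total function of the assay name.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

log = logging.getLogger(__name__)

ARM_3P = "3p"
ARM_5P = "5p"
ARM_UNSPECIFIED = "unspecified"


def normalize_name(name: str) -> str:
    """Canonical form used for matching: strip, lowercase, drop 'hsa-'."""
    return name.strip().lower().removeprefix("hsa-")


def parse_arm(assay_name: str) -> str:
    """Return '3p', '5p' or 'unspecified' from the assay name suffix.

    Total and deterministic; tolerant of the species prefix and case.
    """
    n = normalize_name(assay_name)
    if n.endswith("-3p"):
        return ARM_3P
    if n.endswith("-5p"):
        return ARM_5P
    return ARM_UNSPECIFIED


def sister_name(assay_name: str) -> str:
    """Name of the opposite-arm mature miRNA (swap -3p <-> -5p suffix)."""
    arm = parse_arm(assay_name)
    if arm == ARM_UNSPECIFIED:
        raise ValueError(
            f"{assay_name!r} carries no -3p/-5p arm suffix; it has no sister arm"
        )
    stripped = assay_name.strip()
    return stripped[:-2] + ("5p" if arm == ARM_3P else "3p")


@dataclass
class ProbePanel:
    """The set of assay names present on a qRT-PCR platform."""

    assays: list[str]
    panel_id: str = ""
    _lookup: set[str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        norm = [normalize_name(a) for a in self.assays]
        if len(set(norm)) != len(norm):
            seen: set[str] = set()
            dup = next(n for n in norm if n in seen or seen.add(n))
            raise ValueError(f"duplicate assay name in panel: {dup!r}")
        self._lookup = set(norm)

    def __len__(self) -> int:
        return len(self.assays)

    def __iter__(self) -> Iterator[str]:
        return iter(self.assays)

    def __contains__(self, assay_name: str) -> bool:
        return normalize_name(assay_name) in self._lookup


def read_panel(path: str | Path, panel_id: str = "") -> ProbePanel:
    """Read a probe panel: one assay name per line, '#' starts a comment."""
    names = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            names.append(line)
    return ProbePanel(names, panel_id=panel_id or Path(path).stem)


def write_panel(panel: ProbePanel, path: str | Path) -> None:
    Path(path).write_text("\n".join(panel.assays) + "\n")


def sister_probe_present(assay_name: str, panel: ProbePanel) -> bool:
    """True iff the opposite-arm probe of `assay_name` exists on `panel`.

    Raises if the name carries no arm suffix (there is no sister to look for).
    """
    return sister_name(assay_name) in panel


def annotate_panel(
    panel: ProbePanel, locations: dict[str, str] | None = None
) -> pd.DataFrame:
    """Per-assay arm annotation table for a panel.

    Columns: assay_name, arm, sister_probe_present, chromosomal_location
    (display-only; empty when no location source matched the name).
    """
    locations = locations or {}
    rows = []
    for a in panel:
        arm = parse_arm(a)
        rows.append(
            {
                "assay_name": a,
                "arm": arm,
                "sister_probe_present": (
                    arm != ARM_UNSPECIFIED and sister_probe_present(a, panel)
                ),
                "chromosomal_location": locations.get(normalize_name(a), ""),
            }
        )
    return pd.DataFrame(
        rows, columns=["assay_name", "arm", "sister_probe_present", "chromosomal_location"]
    )


def load_mirbase_annotation(path: str | Path, panel: ProbePanel) -> pd.DataFrame:
    """Annotate a panel with genomic locations from a miRBase-style GFF3.

    Arm calls always come from name parsing; the GFF3 only contributes the
    (display-only) chromosomal location, joined on the normalized ``Name``
    attribute.  Degrades to name-only annotation with a warning when nothing
    in the file matches the panel.
    """
    import gffutils

    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # noqa: BLE001 - surface a uniform error
        raise ValueError(f"unreadable GFF3 file {path}: {exc}") from exc

    locations: dict[str, str] = {}
    for feat in db.all_features():
        names: Iterable[str] = feat.attributes.get("Name", [])
        for nm in names:
            locations.setdefault(
                normalize_name(nm), f"{feat.seqid}:{feat.start}-{feat.end}({feat.strand})"
            )

    table = annotate_panel(panel, locations)
    n_matched = int((table["chromosomal_location"] != "").sum())
    if len(panel) and n_matched == 0:
        warnings.warn(
            f"no GFF3 Name matched any of the {len(panel)} panel assays; "
            "annotation degrades to name-only",
            stacklevel=2,
        )
    log.info("GFF3 annotation: %d/%d panel assays located", n_matched, len(panel))
    return table
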