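"""Loaders for the bundled reference fixtures.

Bundled data:

* ``table7_tfl006.csv`` - per-bead TFL-006 (anti-beta2M-free heavy chain)
  normalized MFIs on the LS and LC class-I panels; an empty cell means the
  allele is absent from that vendor's panel.  NC/PC rows are the control
  beads.
* ``ls_classI.csv`` / ``lc_classI.csv`` - panel definition files derived
  from the presence/absence columns of that table.
* ``table1_unique.csv`` - the vendor-unique antigen rosters (class I and
  class II) as printed, kept verbatim even where they disagree with the
  per-bead table (see FIXTURE_CONFLICTS).
* ``antigen_map.csv`` - allele -> serologic base-antigen group.
* ``demo_frequencies.json`` - synthetic haplotype-frequency table for the
  cPRA engine demo (not registry data).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Dict, List

import pandas as pd

from .panels import AntigenMap, BeadPanel, HlaAllele, parse_allele, parse_bead
from .variants import MabReading

__all__ = [
    "data_path",
    "load_table7",
    "load_ls_class1_panel",
    "load_lc_class1_panel",
    "load_table1_unique",
    "load_antigen_map",
    "load_tfl006_readings",
    "load_demo_frequency_table",
    "FIXTURE_CONFLICTS",
]

#: alleles whose vendor assignment is internally inconsistent between the
#: bundled tables, kept verbatim as printed: B*82:01 / B*82:02 are listed as
#: unique to one vendor but present only on the other in the per-bead table;
#: B*15:11 is LS-only per-bead yet missing from the unique roster; the
#: DPB1*04:01\DPA1*01:03 pair appears in BOTH vendors' unique class-II lists.
FIXTURE_CONFLICTS = (
    "B*82:01",
    "B*82:02",
    "B*15:11",
    "DPB1*04:01\\DPA1*01:03",
)


def data_path(name: str) -> Path:
    return Path(resources.files("sabpipe").joinpath("data", name))


def load_table7(include_controls: bool = False) -> pd.DataFrame:
    """The per-bead beta2M-free heavy-chain MFI table (allele, ls_mfi, lc_mfi)."""
    df = pd.read_csv(data_path("table7_tfl006.csv"), dtype={"allele": str})
    if not include_controls:
        df = df[~df["allele"].isin(["NC", "PC"])].reset_index(drop=True)
    return df


def _panel_from_table7(vendor: str) -> BeadPanel:
    from .io import read_panel_csv

    name = {"LS": "ls_classI.csv", "LC": "lc_classI.csv"}[vendor]
    return read_panel_csv(data_path(name))


def load_ls_class1_panel() -> BeadPanel:
    """LS (LABScreen) class-I panel, lot 10."""
    return _panel_from_table7("LS")


def load_lc_class1_panel() -> BeadPanel:
    """LC (LIFECODES) class-I panel, lot 3005613."""
    return _panel_from_table7("LC")


def load_table1_unique() -> pd.DataFrame:
    """Vendor-unique antigen roster with parsed antigen objects attached."""
    df = pd.read_csv(data_path("table1_unique.csv"), dtype=str)
    df["antigen"] = [parse_bead(a).antigen for a in df["allele"]]
    return df


def load_antigen_map() -> AntigenMap:
    df = pd.read_csv(data_path("antigen_map.csv"), dtype=str)
    entries: Dict[str, str] = {}
    for allele, base in zip(df["allele"], df["base"]):
        entries[parse_allele(allele).name] = base
    return AntigenMap(entries=entries)


def load_tfl006_readings(vendor: str) -> List[MabReading]:
    """TFL-006 readings for one vendor's panel, keyed to its bead ids.

    Only the TFL-006 column is available per bead; W6/32 and HC-10 per-bead
    values are left unknown.
    """
    panel = {"LS": load_ls_class1_panel, "LC": load_lc_class1_panel}[vendor]()
    col = {"LS": "ls_mfi", "LC": "lc_mfi"}[vendor]
    df = load_table7()
    mfi_by_allele = {
        a: float(v) for a, v in zip(df["allele"], df[col]) if pd.notna(v)
    }
    readings = []
    for bead in panel.antigen_beads():
        name = bead.alleles[0].name
        if name in mfi_by_allele:
            readings.append(MabReading(bead_id=bead.bead_id,
                                       tfl006_mfi=mfi_by_allele[name]))
    return readings


def load_demo_frequency_table():
    from .cpra import load_frequency_table

    return load_frequency_table(data_path("demo_frequencies.json"))
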