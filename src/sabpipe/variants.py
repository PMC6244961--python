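"""Conformational-variant classification of class-I beads from three mAbs.

Recombinant class-I HLA on a bead may be present as the intact trimer
(heavy chain + beta2-microglobulin + peptide), as a peptide-free
beta2M-associated heavy chain, or as a beta2M-free ("denatured") heavy
chain.  Three monoclonal antibodies distinguish them:

* W6/32  - intact trimer
* HC-10  - peptide-free, beta2M-associated heavy chain
* TFL-006 - beta2M-free heavy chain (shared/public epitopes)

A bead is scored positive for a variant when the corresponding mAb's
normalized MFI is at or above the cutoff (default 1000).  A missing value
(allele absent from a vendor's panel, or a mAb not run) yields an *unknown*
flag, never ``False``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Optional

import pandas as pd

from .panels import BeadPanel, Control

__all__ = [
    "MabReading",
    "VariantFlags",
    "classify_bead",
    "summarize_panel_variants",
    "DEFAULT_VARIANT_CUTOFF",
]

DEFAULT_VARIANT_CUTOFF = 1000.0


class MabReading(NamedTuple):
    bead_id: str
    w632_mfi: Optional[float] = None
    hc10_mfi: Optional[float] = None
    tfl006_mfi: Optional[float] = None


def _flag(value: Optional[float], cutoff: float) -> Optional[bool]:
    if value is None:
        return None
    if value < 0:
        raise ValueError(f"mAb MFI must be >= 0 after floor-at-zero, got {value}")
    return value >= cutoff


@dataclass(frozen=True)
class VariantFlags:
    """Tri-state variant flags for one bead (True/False/None=unknown)."""

    bead_id: str
    has_intact: Optional[bool]
    has_peptide_free_hc: Optional[bool]
    has_b2m_free_hc: Optional[bool]
    cutoff: float = DEFAULT_VARIANT_CUTOFF


def classify_bead(reading: MabReading,
                  cutoff: float = DEFAULT_VARIANT_CUTOFF) -> VariantFlags:
    """Score one bead's variant content from its three mAb MFIs."""
    if reading.w632_mfi is None and reading.hc10_mfi is None \
            and reading.tfl006_mfi is None:
        raise ValueError(f"bead {reading.bead_id!r}: all three mAb values absent")
    return VariantFlags(
        bead_id=reading.bead_id,
        has_intact=_flag(reading.w632_mfi, cutoff),
        has_peptide_free_hc=_flag(reading.hc10_mfi, cutoff),
        has_b2m_free_hc=_flag(reading.tfl006_mfi, cutoff),
        cutoff=cutoff,
    )


def summarize_panel_variants(readings: Iterable[MabReading], panel: BeadPanel,
                             cutoff: float = DEFAULT_VARIANT_CUTOFF) -> pd.DataFrame:
    """Per-locus counts (and panel fractions) of each variant flag.

    Rows are loci plus a ``total`` row; ``n_beads`` counts antigen beads with
    at least one mAb value.  Fractions are over beads with a known value for
    that mAb, so an absent column never deflates a rate.
    """
    flags = []
    by_id = {r.bead_id: r for r in readings}
    for bead in panel.antigen_beads():
        if bead.bead_id not in by_id:
            continue
        flags.append((bead.locus.value, classify_bead(by_id[bead.bead_id], cutoff)))

    loci = sorted({locus for locus, _ in flags})
    rows = []
    for locus in loci + ["total"]:
        sel = [f for l, f in flags if locus == "total" or l == locus]
        row = {"locus": locus, "n_beads": len(sel)}
        for col, attr in (("intact", "has_intact"),
                          ("peptide_free_hc", "has_peptide_free_hc"),
                          ("b2m_free_hc", "has_b2m_free_hc")):
            known = [getattr(f, attr) for f in sel if getattr(f, attr) is not None]
            row[f"n_{col}_pos"] = sum(known)
            row[f"n_{col}_known"] = len(known)
            row[f"frac_{col}_pos"] = (sum(known) / len(known)) if known else float("nan")
        rows.append(row)
    return pd.DataFrame(rows).set_index("locus")
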