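"""HLA nomenclature, bead-panel representation, and panel set arithmetic.

A single-antigen-bead (SAB) panel is a set of polystyrene beads, each coated
with one recombinant HLA protein.  Class I and DRB beads carry a single
allele; DQ and DP beads carry a beta/alpha chain pair written with the
vendors' backslash convention (``DQB1*02:02\\DQA1*03:02``).  Cross-vendor
comparisons are restricted to the antigens present on both panels, so the
set arithmetic here (common vs vendor-unique antigens) underpins every
downstream statistic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Union

__all__ = [
    "Locus",
    "Control",
    "HlaAllele",
    "BeadSpec",
    "BeadPanel",
    "AntigenMap",
    "Antigen",
    "AlleleParseError",
    "UnmappedAlleleError",
    "parse_allele",
    "parse_bead",
    "common_alleles",
    "unique_alleles",
    "base_antigen",
    "allele_label",
]


class Locus(str, Enum):
    A = "A"
    B = "B"
    C = "C"
    DRB1 = "DRB1"
    DRB3 = "DRB3"
    DRB4 = "DRB4"
    DRB5 = "DRB5"
    DQB1 = "DQB1"
    DQA1 = "DQA1"
    DPB1 = "DPB1"
    DPA1 = "DPA1"


CLASS_I_LOCI = frozenset({Locus.A, Locus.B, Locus.C})

#: beta-chain locus -> compatible alpha-chain locus for paired beads
_PAIR_PARTNERS = {Locus.DQB1: Locus.DQA1, Locus.DPB1: Locus.DPA1}
_ALPHA_LOCI = frozenset(_PAIR_PARTNERS.values())

#: DRB3/4/5 encode the serologic antigens DR52/DR53/DR51
DRB345_BASE = {Locus.DRB3: "DR52", Locus.DRB4: "DR53", Locus.DRB5: "DR51"}

#: loci the cPRA listing rules cannot consider
EXCLUDED_CPRA_LOCI = frozenset({Locus.DQA1, Locus.DPA1, Locus.DPB1})


class Control(str, Enum):
    NONE = "none"
    POSITIVE = "positive_control"
    NEGATIVE = "negative_control"


class AlleleParseError(ValueError):
    """Raised for malformed allele or bead labels."""


class UnmappedAlleleError(KeyError):
    """Raised when an allele has no base-antigen group in the mapping table."""


_ALLELE_RE = re.compile(r"^(?P<locus>[A-Za-z0-9]+)\*(?P<fields>\d{2,3}(?::\d{2,3})+)$")


@dataclass(frozen=True, order=True)
class HlaAllele:
    """One HLA allele in WHO nomenclature.

    ``Cw`` is the conventional serology-era display prefix for locus C and is
    accepted on input; the canonical formatted form keeps it, matching how
    vendor panel sheets print C-locus beads.
    """

    locus: Locus
    fields: str  # colon-separated numeric fields, e.g. "02:03"

    @property
    def hla_class(self) -> str:
        return "I" if self.locus in CLASS_I_LOCI else "II"

    @property
    def name(self) -> str:
        prefix = "Cw" if self.locus is Locus.C else self.locus.value
        return f"{prefix}*{self.fields}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.name


def parse_allele(text: str) -> HlaAllele:
    """Parse one allele string such as ``"B*57:01"`` or ``"Cw*07:02"``.

    Backslash-joined pair labels are rejected here; use :func:`parse_bead`.
    """
    if not isinstance(text, str) or not text.strip():
        raise AlleleParseError("empty allele string")
    token = text.strip()
    if "\\" in token:
        raise AlleleParseError(
            f"{token!r} is a paired bead label; parse it with parse_bead()"
        )
    m = _ALLELE_RE.match(token)
    if m is None:
        raise AlleleParseError(f"malformed allele label {token!r}")
    locus_txt = m.group("locus")
    if locus_txt in ("Cw", "CW", "C"):
        locus = Locus.C
    else:
        try:
            locus = Locus(locus_txt)
        except ValueError:
            raise AlleleParseError(
                f"unknown locus {locus_txt!r} in allele label {token!r}"
            ) from None
    return HlaAllele(locus=locus, fields=m.group("fields"))


#: a bead's antigen identity: one allele, or a (beta, alpha) pair for DQ/DP
Antigen = Union[HlaAllele, tuple]


@dataclass(frozen=True)
class BeadSpec:
    bead_id: str
    alleles: tuple = ()
    control: Control = Control.NONE

    def __post_init__(self) -> None:
        if self.control is not Control.NONE:
            if self.alleles:
                raise AlleleParseError("control beads carry no HLA allele")
            return
        if len(self.alleles) == 1:
            if self.alleles[0].locus in _ALPHA_LOCI:
                raise AlleleParseError(
                    f"lone alpha-chain allele {self.alleles[0]} on bead {self.bead_id}"
                )
        elif len(self.alleles) == 2:
            beta, alpha = self.alleles
            if _PAIR_PARTNERS.get(beta.locus) is not alpha.locus:
                raise AlleleParseError(
                    f"invalid chain pairing {beta}\\{alpha} on bead {self.bead_id}"
                )
        else:
            raise AlleleParseError(f"bead {self.bead_id} must carry 1 or 2 alleles")

    @property
    def antigen(self) -> Antigen:
        """Antigen identity used for panel set arithmetic."""
        return self.alleles[0] if len(self.alleles) == 1 else self.alleles

    @property
    def locus(self) -> Optional[Locus]:
        return self.alleles[0].locus if self.alleles else None


def parse_bead(text: str, bead_id: Optional[str] = None) -> BeadSpec:
    """Parse a bead label: a single allele or a backslash-joined beta\\alpha pair.

    Pair order is normalized to (beta, alpha) regardless of input order.
    """
    token = text.strip()
    parts = token.split("\\")
    if len(parts) == 1:
        alleles = (parse_allele(parts[0]),)
    elif len(parts) == 2:
        a, b = parse_allele(parts[0]), parse_allele(parts[1])
        if a.locus in _PAIR_PARTNERS and _PAIR_PARTNERS[a.locus] is b.locus:
            alleles = (a, b)
        elif b.locus in _PAIR_PARTNERS and _PAIR_PARTNERS[b.locus] is a.locus:
            alleles = (b, a)
        else:
            raise AlleleParseError(
                f"cannot pair {a} with {b}: need one beta chain (DQB1/DPB1) "
                "and its alpha partner (DQA1/DPA1)"
            )
    else:
        raise AlleleParseError(f"too many backslashes in bead label {token!r}")
    return BeadSpec(bead_id=bead_id or token, alleles=alleles)


def format_antigen(antigen: Antigen) -> str:
    if isinstance(antigen, HlaAllele):
        return antigen.name
    return "\\".join(a.name for a in antigen)


@dataclass
class BeadPanel:
    """One vendor's bead panel (``LS`` = LABScreen, ``LC`` = LIFECODES)."""

    vendor: str
    lot: str = ""
    beads: list = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        n_neg = n_pos = 0
        for bead in self.beads:
            if bead.control is Control.NEGATIVE:
                n_neg += 1
            elif bead.control is Control.POSITIVE:
                n_pos += 1
            else:
                if bead.antigen in seen:
                    raise ValueError(
                        f"duplicate antigen {format_antigen(bead.antigen)} "
                        f"in {self.vendor} panel"
                    )
                seen.add(bead.antigen)
        if n_neg != 1:
            raise ValueError(
                f"{self.vendor} panel must contain exactly one negative-control "
                f"bead (found {n_neg})"
            )
        if n_pos > 1:
            raise ValueError(f"{self.vendor} panel has {n_pos} positive-control beads")

    def antigen_beads(self) -> list:
        return [b for b in self.beads if b.control is Control.NONE]

    def antigens(self, locus: Optional[Locus] = None) -> frozenset:
        return frozenset(
            b.antigen
            for b in self.antigen_beads()
            if locus is None or b.locus is locus
        )

    def bead_by_id(self, bead_id: str) -> BeadSpec:
        for b in self.beads:
            if b.bead_id == bead_id:
                return b
        raise KeyError(bead_id)

    @property
    def bead_ids(self) -> frozenset:
        return frozenset(b.bead_id for b in self.beads)

    def loci(self) -> frozenset:
        return frozenset(b.locus for b in self.antigen_beads())


def common_alleles(a: BeadPanel, b: BeadPanel, locus: Optional[Locus] = None) -> frozenset:
    """Antigens carried by both panels (optionally at one locus).

    Control beads are excluded.  Symmetric: equals the intersection of the
    two panels' antigen sets.
    """
    return a.antigens(locus) & b.antigens(locus)


def unique_alleles(a: BeadPanel, b: BeadPanel, locus: Optional[Locus] = None) -> frozenset:
    """Antigens carried by panel ``a`` but absent from panel ``b``."""
    return a.antigens(locus) - b.antigens(locus)


def allele_label(allele: HlaAllele) -> str:
    """Compact allele-level listing label, e.g. A*02:03 -> ``A0203``.

    This mirrors how allele-level specificities are written on unacceptable
    antigen lists alongside the serologic base group.
    """
    prefix = "Cw" if allele.locus is Locus.C else allele.locus.value
    return prefix + allele.fields.replace(":", "")


@dataclass
class AntigenMap:
    """Allele -> serologic base-antigen group (e.g. A*02:03 -> ``A2``).

    DRB3/4/5 alleles map to DR52/DR53/DR51 by locus rule.  DQA1, DPA1 and
    DPB1 reactivities have no base group here: unacceptable-antigen listing
    cannot consider them, so lookups return ``None`` and callers decide how
    to record the exclusion.
    """

    entries: Mapping[str, str] = field(default_factory=dict)

    def get(self, allele: HlaAllele) -> Optional[str]:
        """Base group, or None when the allele is unmapped/excluded."""
        if allele.locus in DRB345_BASE:
            return DRB345_BASE[allele.locus]
        if allele.locus in EXCLUDED_CPRA_LOCI:
            return None
        return self.entries.get(allele.name)

    def covers(self, alleles: Iterable[HlaAllele]) -> list:
        """Alleles at mappable loci that are missing from the table."""
        missing = []
        for al in alleles:
            if al.locus in EXCLUDED_CPRA_LOCI or al.locus in DRB345_BASE:
                continue
            if al.name not in self.entries:
                missing.append(al)
        return missing


def base_antigen(allele: HlaAllele, amap: AntigenMap) -> str:
    """Serologic base group of ``allele``; raises for unmapped alleles.

    Use :meth:`AntigenMap.get` when an unmapped allele should be handled by
    the caller (e.g. recorded as excluded) rather than raised.
    """
    base = amap.get(allele)
    if base is None:
        raise UnmappedAlleleError(
            f"{allele.name} has no base-antigen group (locus {allele.locus.value} "
            "is excluded from listing or the mapping table is incomplete)"
        )
    return base
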