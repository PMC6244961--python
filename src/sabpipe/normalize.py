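"""Raw trimmed-mean fluorescence -> normalized MFI and positivity calls.

The assay readout for each bead is a trimmed-mean fluorescence (MFI).  It is
corrected for three backgrounds measured alongside each run: a buffer-only
(PBS) reading, the antigen-free negative-control (NC) bead, and the mean of
negative-control sera run on each vendor's kit (NGS):

    normalized = (trimmed_mean - PBS) - NC - (NGS_LS + NGS_LC) / 2

The correction is applied literally and is not clamped: negative normalized
values are retained and handled by the positivity call (normalized >= cutoff,
default 500 MFI at 1/10 serum dilution).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, NamedTuple, Optional, Union

from .panels import Antigen, BeadPanel, Control

__all__ = [
    "RawBeadReading",
    "ControlSet",
    "ProfileRecord",
    "SerumProfile",
    "normalize_mfi",
    "normalize_profile",
    "call_positive",
    "DEFAULT_CUTOFF",
    "DEFAULT_DILUTION",
]

DEFAULT_CUTOFF = 500.0
DEFAULT_DILUTION = 0.1

SECONDARIES = ("FcMonoIgG", "IgHPolyFab")


class RawBeadReading(NamedTuple):
    bead_id: str
    trimmed_mean: float
    bead_count: int = 100


_ControlValue = Union[float, Mapping[str, float]]


def _check_nonneg(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value) or value < 0:
        raise ValueError(f"{name} must be finite and >= 0, got {value}")
    return value


@dataclass
class ControlSet:
    """Background readings for one run condition.

    Each control may be a scalar (applied to every bead) or a per-bead
    mapping keyed by bead id.
    """

    pbs: _ControlValue = 0.0
    nc: _ControlValue = 0.0
    ngs_ls: _ControlValue = 0.0
    ngs_lc: _ControlValue = 0.0

    def __post_init__(self) -> None:
        for name in ("pbs", "nc", "ngs_ls", "ngs_lc"):
            val = getattr(self, name)
            if isinstance(val, Mapping):
                for bead, v in val.items():
                    _check_nonneg(f"{name}[{bead}]", v)
            else:
                setattr(self, name, _check_nonneg(name, val))

    def _value(self, name: str, bead_id: str) -> float:
        val = getattr(self, name)
        if isinstance(val, Mapping):
            if bead_id not in val:
                raise KeyError(f"missing {name} control value for bead {bead_id!r}")
            return float(val[bead_id])
        return float(val)

    def for_bead(self, bead_id: str) -> tuple:
        return tuple(self._value(n, bead_id) for n in ("pbs", "nc", "ngs_ls", "ngs_lc"))


def normalize_mfi(trimmed_mean: float, pbs: float, nc: float,
                  ngs_ls: float, ngs_lc: float) -> float:
    """Background-corrected MFI; may be negative."""
    trimmed_mean = _check_nonneg("trimmed_mean", trimmed_mean)
    pbs = _check_nonneg("pbs", pbs)
    nc = _check_nonneg("nc", nc)
    ngs_ls = _check_nonneg("ngs_ls", ngs_ls)
    ngs_lc = _check_nonneg("ngs_lc", ngs_lc)
    return (trimmed_mean - pbs) - nc - (ngs_ls + ngs_lc) / 2.0


def call_positive(normalized: float, cutoff: float = DEFAULT_CUTOFF) -> bool:
    """Positivity at or above the cutoff (>= convention)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    return normalized >= cutoff


class ProfileRecord(NamedTuple):
    antigen: Antigen
    normalized_mfi: float
    positive: bool


@dataclass
class SerumProfile:
    """Normalized per-bead MFIs for one serum under one (vendor, secondary)."""

    serum_id: str
    vendor: str
    secondary: str
    records: Dict[str, ProfileRecord] = field(default_factory=dict)
    cutoff: float = DEFAULT_CUTOFF
    dilution: float = DEFAULT_DILUTION

    def positives(self) -> Dict[str, ProfileRecord]:
        return {k: r for k, r in self.records.items() if r.positive}

    def positive_antigens(self) -> frozenset:
        return frozenset(r.antigen for r in self.records.values() if r.positive)

    def mfi_by_antigen(self) -> Dict[Antigen, float]:
        return {r.antigen: r.normalized_mfi for r in self.records.values()}

    def restrict(self, antigens: Iterable[Antigen]) -> "SerumProfile":
        """Profile restricted to the given antigen universe (common set)."""
        keep = frozenset(antigens)
        return SerumProfile(
            serum_id=self.serum_id,
            vendor=self.vendor,
            secondary=self.secondary,
            records={k: r for k, r in self.records.items() if r.antigen in keep},
            cutoff=self.cutoff,
            dilution=self.dilution,
        )


def normalize_profile(raw: Iterable[RawBeadReading], controls: ControlSet,
                      panel: BeadPanel, serum_id: str = "", secondary: str = "",
                      cutoff: float = DEFAULT_CUTOFF,
                      dilution: float = DEFAULT_DILUTION) -> SerumProfile:
    """Normalize a full raw table against a panel; one record per antigen bead.

    Control beads (NC/PC) present in the raw table are used implicitly only
    through the supplied :class:`ControlSet`; they get no profile record.
    Raw bead ids that do not exist in the panel are an error (all offending
    ids are listed).
    """
    raw = list(raw)
    known = panel.bead_ids
    unknown = sorted({r.bead_id for r in raw} - known)
    if unknown:
        raise KeyError(
            f"raw readings reference beads absent from the {panel.vendor} panel: "
            + ", ".join(unknown)
        )
    records: Dict[str, ProfileRecord] = {}
    for reading in raw:
        bead = panel.bead_by_id(reading.bead_id)
        if bead.control is not Control.NONE:
            continue
        pbs, nc, ngs_ls, ngs_lc = controls.for_bead(reading.bead_id)
        norm = normalize_mfi(reading.trimmed_mean, pbs, nc, ngs_ls, ngs_lc)
        records[reading.bead_id] = ProfileRecord(
            antigen=bead.antigen,
            normalized_mfi=norm,
            positive=call_positive(norm, cutoff),
        )
    return SerumProfile(
        serum_id=serum_id,
        vendor=panel.vendor,
        secondary=secondary,
        records=records,
        cutoff=cutoff,
        dilution=dilution,
    )
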