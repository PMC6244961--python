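"""Unacceptable-antigen expansion and calculated panel-reactive antibody.

cPRA is the fraction of donors expected to carry at least one antigen
against which a candidate has antibody at or above the listing cutoff
(default 500 normalized MFI).  Positive beads are expanded into an
unacceptable-antigen set using listing rules: each positive allele adds
both its allele-level label and its serologic base group (A*02:03 adds
``A0203`` and ``A2``); positive DRB3/4/5 beads add DR52/DR53/DR51; DQA1-,
DPA1- and DPB1-borne reactivities cannot be listed and are recorded as
excluded.

Two probability engines are provided.  The haplotype engine assumes
Hardy-Weinberg pairing of population haplotypes:

    P(acceptable) = (sum of frequencies of haplotypes free of unacceptable
                     antigens) ** 2

The per-locus engine assumes linkage equilibrium across loci:

    P(acceptable) = prod over loci (1 - F_l) ** 2

with F_l the summed frequency of unacceptable antigens at locus l.  Both
combine populations by weighted averaging of P(acceptable), and both are
validated against a Monte-Carlo donor-sampling oracle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np

from .normalize import SerumProfile
from .panels import (
    AntigenMap,
    DRB345_BASE,
    EXCLUDED_CPRA_LOCI,
    HlaAllele,
    Locus,
    UnmappedAlleleError,
    allele_label,
)

__all__ = [
    "UnacceptableSet",
    "FrequencyTable",
    "Population",
    "CpraResult",
    "expand_unacceptable",
    "cpra_haplotype",
    "cpra_per_locus",
    "simulate_donors_oracle",
    "load_frequency_table",
]

_FREQ_TOL = 1e-9
DEFAULT_LISTING_CUTOFF = 500.0


@dataclass(frozen=True)
class UnacceptableSet:
    """Expanded unacceptable-antigen list plus the reactivities excluded by rule."""

    antigens: FrozenSet[str] = frozenset()
    excluded: Tuple[str, ...] = ()


def expand_unacceptable(profile: SerumProfile, amap: AntigenMap,
                        cutoff: float = DEFAULT_LISTING_CUTOFF) -> UnacceptableSet:
    """Expand positive beads of a normalized profile into an unacceptable set.

    An unmapped allele at a listable locus (A/B/C/DRB1/DQB1) is an error:
    the mapping table must cover the panel.  Excluded-locus reactivities
    (DQA1/DPA1/DPB1) are recorded under ``excluded``, never silently dropped.
    """
    antigens: set = set()
    excluded: List[str] = []
    for record in profile.records.values():
        if record.normalized_mfi < cutoff:
            continue
        alleles = (
            record.antigen if isinstance(record.antigen, tuple) else (record.antigen,)
        )
        for allele in alleles:
            if allele.locus in EXCLUDED_CPRA_LOCI:
                excluded.append(allele.name)
                continue
            if allele.locus in DRB345_BASE:
                antigens.add(DRB345_BASE[allele.locus])
                continue
            base = amap.get(allele)
            if base is None:
                raise UnmappedAlleleError(
                    f"allele {allele.name} is positive but has no base-antigen "
                    "entry in the mapping table"
                )
            antigens.add(base)
            antigens.add(allele_label(allele))
    return UnacceptableSet(antigens=frozenset(antigens), excluded=tuple(excluded))


@dataclass
class Population:
    name: str
    weight: float
    #: haplotype mode: list of (antigen frozenset, frequency)
    haplotypes: List[Tuple[FrozenSet[str], float]] = field(default_factory=list)
    #: per-locus mode: locus label -> antigen -> frequency
    locus_freqs: Dict[str, Dict[str, float]] = field(default_factory=dict)


@dataclass
class FrequencyTable:
    """Antigen/haplotype frequencies for one or more donor populations.

    ``haplotype`` mode lists whole multi-locus haplotypes (specified as base
    antigens); ``per_locus_antigen`` mode lists independent per-locus antigen
    frequencies.  Population weights must sum to 1, and each population's
    frequencies must sum to 1 (per haplotype set, or per locus).
    """

    mode: str
    populations: List[Population] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mode not in ("haplotype", "per_locus_antigen"):
            raise ValueError(f"unknown frequency-table mode {self.mode!r}")
        if not self.populations:
            raise ValueError("frequency table needs at least one population")
        wsum = sum(p.weight for p in self.populations)
        if abs(wsum - 1.0) > _FREQ_TOL:
            raise ValueError(f"population weights sum to {wsum}, expected 1")
        for pop in self.populations:
            if self.mode == "haplotype":
                fsum = sum(f for _, f in pop.haplotypes)
                if abs(fsum - 1.0) > _FREQ_TOL:
                    raise ValueError(
                        f"population {pop.name!r}: haplotype frequencies sum "
                        f"to {fsum}, expected 1"
                    )
            else:
                for locus, freqs in pop.locus_freqs.items():
                    fsum = sum(freqs.values())
                    if abs(fsum - 1.0) > _FREQ_TOL:
                        raise ValueError(
                            f"population {pop.name!r}, locus {locus}: antigen "
                            f"frequencies sum to {fsum}, expected 1"
                        )


@dataclass(frozen=True)
class CpraResult:
    cpra: float  # fraction in [0, 1]
    per_population: Dict[str, float]
    method: str
    n_draws: Optional[int] = None
    seed: Optional[int] = None
    standard_error: Optional[float] = None

    @property
    def percent(self) -> float:
        return 100.0 * self.cpra


def cpra_haplotype(ua: UnacceptableSet, table: FrequencyTable) -> CpraResult:
    """cPRA under Hardy-Weinberg pairing of population haplotypes."""
    if table.mode != "haplotype":
        raise ValueError("cpra_haplotype requires a haplotype-mode table")
    per_pop: Dict[str, float] = {}
    cpra = 0.0
    for pop in table.populations:
        total = sum(f for _, f in pop.haplotypes)
        clean = sum(f for antigens, f in pop.haplotypes if not (antigens & ua.antigens))
        # normalize away float drift in the (validated) frequency sum
        p_acceptable = min(1.0, (clean / total) ** 2)
        per_pop[pop.name] = max(0.0, 1.0 - p_acceptable)
        cpra += pop.weight * per_pop[pop.name]
    return CpraResult(cpra=cpra, per_population=per_pop, method="haplotype_hwe")


def cpra_per_locus(ua: UnacceptableSet, table: FrequencyTable) -> CpraResult:
    """cPRA under linkage equilibrium across independent loci."""
    if table.mode != "per_locus_antigen":
        raise ValueError("cpra_per_locus requires a per_locus_antigen-mode table")
    per_pop: Dict[str, float] = {}
    cpra = 0.0
    for pop in table.populations:
        p_acceptable = 1.0
        for freqs in pop.locus_freqs.values():
            f_l = min(1.0, sum(f for ag, f in freqs.items() if ag in ua.antigens))
            p_acceptable *= (1.0 - f_l) ** 2
        per_pop[pop.name] = max(0.0, 1.0 - p_acceptable)
        cpra += pop.weight * per_pop[pop.name]
    return CpraResult(cpra=cpra, per_population=per_pop, method="per_locus_le")


def simulate_donors_oracle(ua: UnacceptableSet, table: FrequencyTable,
                           n_draws: int, seed: int) -> CpraResult:
    """Monte-Carlo cPRA estimate by sampling donor genotypes.

    Donors are drawn as two haplotypes (or independent per-locus genotypes)
    i.i.d. from the table; the estimate is the fraction of donors carrying at
    least one unacceptable antigen, with its binomial standard error.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    weights = np.array([p.weight for p in table.populations])
    pop_idx = rng.choice(len(table.populations), size=n_draws, p=weights)
    unacceptable = np.zeros(n_draws, dtype=bool)
    per_pop: Dict[str, float] = {}
    for i, pop in enumerate(table.populations):
        sel = pop_idx == i
        n_pop = int(sel.sum())
        if n_pop == 0:
            per_pop[pop.name] = float("nan")
            continue
        if table.mode == "haplotype":
            freqs = np.array([f for _, f in pop.haplotypes])
            hit = np.array(
                [bool(antigens & ua.antigens) for antigens, _ in pop.haplotypes]
            )
            h1 = rng.choice(len(freqs), size=n_pop, p=freqs)
            h2 = rng.choice(len(freqs), size=n_pop, p=freqs)
            bad = hit[h1] | hit[h2]
        else:
            bad = np.zeros(n_pop, dtype=bool)
            for freqs_by_ag in pop.locus_freqs.values():
                ags = list(freqs_by_ag)
                freqs = np.array([freqs_by_ag[a] for a in ags])
                hit = np.array([a in ua.antigens for a in ags])
                g1 = rng.choice(len(ags), size=n_pop, p=freqs)
                g2 = rng.choice(len(ags), size=n_pop, p=freqs)
                bad |= hit[g1] | hit[g2]
        unacceptable[sel] = bad
        per_pop[pop.name] = float(bad.mean())
    estimate = float(unacceptable.mean())
    se = float(np.sqrt(estimate * (1.0 - estimate) / n_draws))
    return CpraResult(cpra=estimate, per_population=per_pop,
                      method="monte_carlo", n_draws=n_draws, seed=seed,
                      standard_error=se)


def load_frequency_table(path) -> FrequencyTable:
    """Read a frequency table from the JSON interchange format."""
    with open(path) as fh:
        doc = json.load(fh)
    mode = doc["mode"]
    pops = []
    for p in doc["populations"]:
        if mode == "haplotype":
            haps = [
                (frozenset(h["antigens"]), float(h["frequency"]))
                for h in p["haplotypes"]
            ]
            pops.append(Population(name=p.get("name", f"pop{len(pops)}"),
                                   weight=float(p["weight"]), haplotypes=haps))
        else:
            loci = {
                locus: {a: float(f) for a, f in freqs.items()}
                for locus, freqs in p["loci"].items()
            }
            pops.append(Population(name=p.get("name", f"pop{len(pops)}"),
                                   weight=float(p["weight"]), locus_freqs=loci))
    return FrequencyTable(mode=mode, populations=pops)
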