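"""Mechanistic generator of the full 2x2 (panel x secondary antibody) experiment.

The generator reproduces, from mechanism rather than by resampling, the
features of the assay the analysis pipeline is built to detect:

* **Bead composition.** Each bead carries fractions of intact-trimer
  (native), peptide-free heterodimer, and beta2M-free heavy-chain antigen.
  LC beads carry no beta2M-free heavy chain and little peptide-free
  heterodimer; LS beads carry all three, with beta2M-free material on most
  class-I beads.
* **Serum repertoire.** A serum is a set of antibody clones: native-specific
  clones bind the intact fraction of their target alleles; shared-epitope
  clones (peptide-free or beta2M-free class) bind the corresponding variant
  fraction across a breadth set of alleles (the "public" epitopes of the
  denatured heavy chain).
* **Detection.** Bound-IgG density D produces signal alpha*g(D)*D over
  background.  The Fc-specific monoclonal binds 1:1, g = 1.  The polyclonal
  F(ab')2 can bind several heavy-chain epitopes per IgG when bound IgG is
  sparse, but crowding/aggregation blocks multiple binding at high density:
  g(D) = 1 + (A - 1) * exp(-D / D0), strictly decreasing from g(0) = A to 1.
* **Noise and controls.** Multiplicative lognormal noise (default CV 0.15)
  and control emissions (PBS, NC bead, negative-serum means) constructed so
  the normalization formula is unbiased: a zero-signal bead normalizes to 0
  in expectation.

All randomness flows through one seeded generator; identical config + seed
reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np

from . import datasets
from .normalize import ControlSet, RawBeadReading
from .panels import BeadPanel, BeadSpec, CLASS_I_LOCI, Control, parse_bead

__all__ = [
    "CompositionFractions",
    "BeadComposition",
    "VendorProfile",
    "SerumClone",
    "SerumSpec",
    "DetectionModel",
    "ControlModel",
    "SimConfig",
    "SimTruth",
    "SimResult",
    "LS_PROFILE",
    "LC_PROFILE",
    "make_vendor_composition",
    "bound_density",
    "detect",
    "simulate_experiment",
    "serum_anti_denatured",
    "serum_pan_native",
    "serum_native",
    "serum_empty",
    "default_config",
    "load_sim_config",
    "make_synthetic_class2_panels",
]


# --------------------------------------------------------------------------
# bead composition

class CompositionFractions(dict):
    """Per-bead antigen-variant fractions; values sum to <= 1."""


@dataclass(frozen=True)
class VendorProfile:
    """Sampling ranges for a vendor's per-bead variant fractions.

    ``b2m_free_prevalence`` is the probability that a class-I bead carries
    any beta2M-free heavy chain at all; LC's is 0 by construction.
    Class-II beads never carry a beta2M-free fraction (no beta2M); their
    denatured-variant content is modelled through the peptide-free-like
    fraction, drawn from ``class2_variant_range``.
    """

    native_range: Tuple[float, float]
    peptide_free_range: Tuple[float, float]
    b2m_free_range: Tuple[float, float]
    b2m_free_prevalence: float
    class2_variant_range: Tuple[float, float] = (0.0, 0.0)


LS_PROFILE = VendorProfile(
    native_range=(0.35, 0.60),
    peptide_free_range=(0.05, 0.25),
    b2m_free_range=(0.10, 0.30),
    b2m_free_prevalence=0.85,
    class2_variant_range=(0.10, 0.30),
)

LC_PROFILE = VendorProfile(
    native_range=(0.60, 0.90),
    peptide_free_range=(0.00, 0.08),
    b2m_free_range=(0.0, 0.0),
    b2m_free_prevalence=0.0,
    class2_variant_range=(0.0, 0.0),
)

_VARIANT_KEYS = ("native", "peptide_free", "b2m_free")


def make_vendor_composition(panel: BeadPanel, profile: VendorProfile,
                            rng: np.random.Generator) -> Dict[str, Dict[str, float]]:
    """Draw per-bead variant fractions for one vendor's panel."""
    comp: Dict[str, Dict[str, float]] = {}
    for bead in panel.antigen_beads():
        is_class1 = bead.locus in CLASS_I_LOCI
        native = rng.uniform(*profile.native_range)
        if is_class1:
            pf = rng.uniform(*profile.peptide_free_range)
            if rng.uniform() < profile.b2m_free_prevalence:
                b2m = rng.uniform(*profile.b2m_free_range)
            else:
                b2m = 0.0
        else:
            pf = rng.uniform(*profile.class2_variant_range)
            b2m = 0.0
        total = native + pf + b2m
        if total > 1.0:
            native, pf, b2m = (x / total for x in (native, pf, b2m))
        comp[bead.bead_id] = {"native": native, "peptide_free": pf, "b2m_free": b2m}
    return comp


# --------------------------------------------------------------------------
# serum repertoire

@dataclass(frozen=True)
class SerumClone:
    """One antibody clone: epitope class, allele breadth, concentration.

    ``epitope_class``: ``native`` clones see the intact fraction of their
    target alleles; ``peptide_free`` / ``b2m_free`` clones see the shared
    epitopes of the corresponding variant fraction across their breadth set.
    Concentration is in arbitrary binding units (the MFI-equivalent density
    a fully-variant bead would accumulate).
    """

    epitope_class: str
    alleles: FrozenSet[str]
    concentration: float

    def __post_init__(self) -> None:
        if self.epitope_class not in _VARIANT_KEYS:
            raise ValueError(f"unknown epitope class {self.epitope_class!r}")
        if self.concentration < 0:
            raise ValueError("clone concentration must be >= 0")
        if not self.alleles:
            raise ValueError("clone breadth set must be non-empty")


@dataclass
class SerumSpec:
    serum_id: str
    clones: List[SerumClone] = field(default_factory=list)
    scenario: str = ""


def bound_density(clones: Sequence[SerumClone],
                  composition: Dict[str, float],
                  bead_alleles: Sequence) -> float:
    """Bound-IgG density on one bead: additive mass-action shorthand.

    Each clone contributes concentration x (matching variant fraction) when
    any of the bead's alleles falls in the clone's breadth set.
    """
    names = {a.name for a in bead_alleles}
    d = 0.0
    for clone in clones:
        if names & clone.alleles:
            d += clone.concentration * composition[clone.epitope_class]
    return d


# --------------------------------------------------------------------------
# detection

@dataclass(frozen=True)
class DetectionModel:
    """Secondary-antibody detection physics.

    The monoclonal Fc-specific secondary binds 1:1 (gain 1 at any density);
    the polyclonal F(ab')2 amplifies sparse IgG up to ``amp_max``-fold but
    loses multi-epitope access as bound IgG crowds (scale ``density_scale``).
    """

    secondary: str
    alpha: float = 1.0  # MFI per unit bound IgG at gain 1
    amp_max: float = 4.0
    density_scale: float = 1000.0
    noise_cv: float = 0.15
    background_mfi: float = 85.0

    def gain(self, density: float) -> float:
        if self.secondary == "FcMonoIgG":
            return 1.0
        return 1.0 + (self.amp_max - 1.0) * math.exp(-density / self.density_scale)


def _noise_factor(rng: np.random.Generator, cv: float) -> float:
    if cv <= 0:
        return 1.0
    sigma = math.sqrt(math.log1p(cv * cv))
    return float(rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma))


def detect(density: float, model: DetectionModel,
           rng: np.random.Generator) -> float:
    """Raw trimmed-mean MFI for one bead: background + amplified signal,
    with multiplicative lognormal noise, clipped at 0."""
    if density < 0:
        raise ValueError("bound density must be >= 0")
    mean = model.background_mfi + model.alpha * model.gain(density) * density
    return max(0.0, mean * _noise_factor(rng, model.noise_cv))


# --------------------------------------------------------------------------
# experiment

@dataclass(frozen=True)
class ControlModel:
    """Generative model for control emissions.

    Chosen so the printed normalization is unbiased: the serum-run
    nonspecific background equals nc_level + ngs_level in expectation, and
    the detection background equals pbs_level + nc_level + ngs_level, so a
    zero-signal bead normalizes to ~0.  The NC and NGS values emitted are
    therefore already-PBS-corrected residuals.
    """

    pbs_level: float = 55.0
    nc_level: float = 10.0
    ngs_level: float = 20.0
    noise_cv: float = 0.10
    positive_control_mfi: float = 15000.0

    @property
    def background_mfi(self) -> float:
        return self.pbs_level + self.nc_level + self.ngs_level


@dataclass
class SimConfig:
    panels: Dict[str, BeadPanel]
    sera: List[SerumSpec]
    vendor_profiles: Dict[str, VendorProfile] = field(
        default_factory=lambda: {"LS": LS_PROFILE, "LC": LC_PROFILE})
    detection: Dict[str, DetectionModel] = field(default_factory=dict)
    controls: ControlModel = field(default_factory=ControlModel)
    cutoff: float = 500.0
    dilution: float = 0.1

    def __post_init__(self) -> None:
        if not self.detection:
            bg = self.controls.background_mfi
            self.detection = {
                "FcMonoIgG": DetectionModel("FcMonoIgG", background_mfi=bg),
                "IgHPolyFab": DetectionModel("IgHPolyFab", background_mfi=bg),
            }


@dataclass
class SimTruth:
    """Ground truth for recovery tests: what the generator actually drew."""

    seed: int
    compositions: Dict[str, Dict[str, Dict[str, float]]]
    sera: List[SerumSpec]
    detection: Dict[str, DetectionModel]
    densities: Dict[str, Dict[str, Dict[str, float]]]  # serum -> vendor -> bead -> D

    def to_json(self) -> str:
        doc = {
            "seed": self.seed,
            "compositions": self.compositions,
            "sera": [
                {
                    "serum_id": s.serum_id,
                    "scenario": s.scenario,
                    "clones": [
                        {
                            "epitope_class": c.epitope_class,
                            "alleles": sorted(c.alleles),
                            "concentration": c.concentration,
                        }
                        for c in s.clones
                    ],
                }
                for s in self.sera
            ],
            "detection": {k: dataclasses.asdict(v) for k, v in self.detection.items()},
            "densities": self.densities,
        }
        return json.dumps(doc, indent=1, sort_keys=True)


@dataclass
class SimResult:
    truth: SimTruth
    raw_tables: Dict[Tuple[str, str, str], List[RawBeadReading]]
    control_sets: Dict[str, ControlSet]
    config: SimConfig
    files: List[Path] = field(default_factory=list)


def _make_controls(panel: BeadPanel, model: ControlModel,
                   rng: np.random.Generator) -> ControlSet:
    pbs = {}
    ngs_ls = {}
    ngs_lc = {}
    for bead in panel.beads:
        pbs[bead.bead_id] = model.pbs_level * _noise_factor(rng, model.noise_cv)
        ngs_ls[bead.bead_id] = model.ngs_level * _noise_factor(rng, model.noise_cv)
        ngs_lc[bead.bead_id] = model.ngs_level * _noise_factor(rng, model.noise_cv)
    nc = model.nc_level * _noise_factor(rng, model.noise_cv)
    return ControlSet(pbs=pbs, nc=nc, ngs_ls=ngs_ls, ngs_lc=ngs_lc)


def simulate_experiment(config: SimConfig, seed: int,
                        outdir: Optional[Path] = None) -> SimResult:
    """Run the full generative experiment.

    Returns in-memory raw tables, per-vendor control sets and the ground
    truth; when ``outdir`` is given, also writes the raw/control/panel CSV
    files (the dialect the normalize stage reads) plus ``truth.json``.
    """
    rng = np.random.default_rng(seed)
    compositions = {
        vendor: make_vendor_composition(panel, config.vendor_profiles[vendor], rng)
        for vendor, panel in config.panels.items()
    }
    control_sets = {
        vendor: _make_controls(panel, config.controls, rng)
        for vendor, panel in config.panels.items()
    }

    raw_tables: Dict[Tuple[str, str, str], List[RawBeadReading]] = {}
    densities: Dict[str, Dict[str, Dict[str, float]]] = {}
    for serum in config.sera:
        densities[serum.serum_id] = {}
        for vendor, panel in config.panels.items():
            dens = {}
            for bead in panel.antigen_beads():
                dens[bead.bead_id] = bound_density(
                    serum.clones, compositions[vendor][bead.bead_id], bead.alleles
                )
            densities[serum.serum_id][vendor] = dens
            for secondary, model in config.detection.items():
                readings = []
                for bead in panel.beads:
                    if bead.control is Control.POSITIVE:
                        mfi = config.controls.positive_control_mfi * _noise_factor(
                            rng, model.noise_cv)
                    elif bead.control is Control.NEGATIVE:
                        mfi = detect(0.0, model, rng)
                    else:
                        mfi = detect(dens[bead.bead_id], model, rng)
                    count = int(rng.integers(80, 120))
                    readings.append(RawBeadReading(bead.bead_id, round(mfi, 2), count))
                raw_tables[(serum.serum_id, vendor, secondary)] = readings

    truth = SimTruth(seed=seed, compositions=compositions, sera=config.sera,
                     detection=config.detection, densities=densities)
    result = SimResult(truth=truth, raw_tables=raw_tables,
                       control_sets=control_sets, config=config)
    if outdir is not None:
        result.files = _write_outputs(result, Path(outdir))
    return result


def _write_outputs(result: SimResult, outdir: Path) -> List[Path]:
    from . import io as sio  # local import to avoid a cycle

    outdir.mkdir(parents=True, exist_ok=True)
    rawdir = outdir / "raw"
    rawdir.mkdir(exist_ok=True)
    files = []
    for vendor, panel in result.config.panels.items():
        p = outdir / f"panel_{vendor}.csv"
        sio.write_panel_csv(panel, p)
        files.append(p)
        c = outdir / f"controls_{vendor}.csv"
        sio.write_controls_csv(result.control_sets[vendor], panel, c)
        files.append(c)
    for (serum, vendor, secondary), readings in result.raw_tables.items():
        p = rawdir / f"{serum}_{vendor}_{secondary}.csv"
        sio.write_raw_csv(readings, p)
        files.append(p)
    t = outdir / "truth.json"
    t.write_text(result.truth.to_json())
    files.append(t)
    return files


# --------------------------------------------------------------------------
# scenario builders (the study conditions)

def _class1_allele_names(panel: BeadPanel) -> List[str]:
    return sorted(
        b.alleles[0].name for b in panel.antigen_beads() if b.locus in CLASS_I_LOCI
    )


def serum_anti_denatured(serum_id: str, alleles: Sequence[str],
                         concentration: float = 650.0) -> SerumSpec:
    """Serum with a single anti-denatured (beta2M-free heavy chain) clone.

    The shared-epitope breadth spans the given alleles; the default
    concentration puts polyclonal-detected LS signals in the low-positive
    band (mostly 500-1000 MFI) with no LC reactivity, the Group-A pattern.
    """
    clone = SerumClone("b2m_free", frozenset(alleles), concentration)
    return SerumSpec(serum_id, [clone], scenario="anti_denatured")


def serum_pan_native(serum_id: str, alleles: Sequence[str],
                     concentration: float = 9000.0) -> SerumSpec:
    """High-titer serum reactive with intact HLA across a broad allele set
    (Group 1C pattern: high MFI on both vendors, both secondaries)."""
    clone = SerumClone("native", frozenset(alleles), concentration)
    return SerumSpec(serum_id, [clone], scenario="pan_native")


def serum_native(serum_id: str, alleles: Sequence[str],
                 concentration: float) -> SerumSpec:
    clone = SerumClone("native", frozenset(alleles), concentration)
    return SerumSpec(serum_id, [clone], scenario="native")


def serum_empty(serum_id: str) -> SerumSpec:
    return SerumSpec(serum_id, [], scenario="empty")


def default_config() -> SimConfig:
    """Default simulated cohort on the bundled class-I panels.

    Six sera spanning the reactivity patterns the assay comparison turns on:
    two anti-denatured-only (LS-only, low MFI), one pan-native high titer,
    one broad low-titer native, one narrow strong native, one nonreactive.
    """
    ls = datasets.load_ls_class1_panel()
    lc = datasets.load_lc_class1_panel()
    common = sorted(set(_class1_allele_names(ls)) & set(_class1_allele_names(lc)))
    ls_all = _class1_allele_names(ls)
    sera = [
        serum_anti_denatured("SIM-001", ls_all),
        serum_anti_denatured("SIM-002", ls_all, concentration=550.0),
        serum_pan_native("SIM-003", common),
        serum_native("SIM-004", common[::3], concentration=600.0),
        serum_native("SIM-005", common[:3], concentration=2500.0),
        serum_empty("SIM-006"),
    ]
    return SimConfig(panels={"LS": ls, "LC": lc}, sera=sera)


_SCENARIOS = {
    "anti_denatured": serum_anti_denatured,
    "pan_native": serum_pan_native,
    "native": serum_native,
}


def load_sim_config(path) -> SimConfig:
    """Build a SimConfig from a small YAML scenario file.

    Schema: optional ``panels: {LS: <csv>, LC: <csv>}`` (default: bundled
    class-I panels) and ``sera: [{id, scenario, concentration, alleles|n_alleles}]``
    with scenario one of anti_denatured / pan_native / native / empty.
    """
    import yaml

    from . import io as sio

    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if "panels" in doc:
        panels = {v: sio.read_panel_csv(p) for v, p in doc["panels"].items()}
    else:
        panels = {"LS": datasets.load_ls_class1_panel(),
                  "LC": datasets.load_lc_class1_panel()}
    common = sorted(
        set(_class1_allele_names(panels["LS"]))
        & set(_class1_allele_names(panels["LC"]))
    )
    ls_all = _class1_allele_names(panels["LS"])
    sera = []
    for entry in doc.get("sera", []):
        scenario = entry.get("scenario", "empty")
        serum_id = str(entry["id"])
        if scenario == "empty":
            sera.append(serum_empty(serum_id))
            continue
        if scenario not in _SCENARIOS:
            raise ValueError(f"unknown serum scenario {scenario!r}")
        alleles = entry.get("alleles")
        if alleles is None:
            pool = ls_all if scenario == "anti_denatured" else common
            alleles = pool[: int(entry.get("n_alleles", len(pool)))]
        kwargs = {}
        if "concentration" in entry:
            kwargs["concentration"] = float(entry["concentration"])
        sera.append(_SCENARIOS[scenario](serum_id, alleles, **kwargs))
    cfg = SimConfig(panels=panels, sera=sera)
    if "cutoff" in doc:
        cfg.cutoff = float(doc["cutoff"])
    return cfg


# --------------------------------------------------------------------------
# synthetic class-II demo panels

def make_synthetic_class2_panels() -> Tuple[BeadPanel, BeadPanel]:
    """Small synthetic class-II panels (shared DR/DQ core plus vendor-unique
    beads) for exercising the class-II pathway; not transcribed from any
    vendor sheet."""
    shared = [
        "DRB1*01:01", "DRB1*03:01", "DRB1*04:01", "DRB1*07:01", "DRB1*11:01",
        "DRB1*13:01", "DRB1*15:01", "DRB3*01:01", "DRB4*01:01", "DRB5*01:01",
        "DQB1*02:01\\DQA1*05:01", "DQB1*03:01\\DQA1*05:05",
        "DQB1*05:01\\DQA1*01:01", "DQB1*06:02\\DQA1*01:02",
    ]
    ls_unique = ["DRB1*09:02", "DQB1*06:09\\DQA1*01:02"]
    lc_unique = ["DRB1*08:02", "DQB1*02:02\\DQA1*05:01"]

    def build(vendor: str, uniques: List[str]) -> BeadPanel:
        beads = [
            parse_bead(label, bead_id=f"{vendor}2-{i:03d}")
            for i, label in enumerate(shared + uniques, start=1)
        ]
        beads.append(BeadSpec(bead_id=f"{vendor}2-NC", control=Control.NEGATIVE))
        beads.append(BeadSpec(bead_id=f"{vendor}2-PC", control=Control.POSITIVE))
        return BeadPanel(vendor=vendor, lot="synthetic", beads=beads)

    return build("LS", ls_unique), build("LC", lc_unique)
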