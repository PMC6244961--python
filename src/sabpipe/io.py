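"""File formats, run configuration and the end-to-end pipeline.

All tabular interchange is comma-separated UTF-8 with a mandatory header
row; allele strings are quoted where needed because DQ/DP pair labels
contain a backslash.  Reports round-trip losslessly between TSV and JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from . import __version__
from .concordance import ConditionQuartet, cohort_summary, per_serum_summary
from .cpra import expand_unacceptable, cpra_haplotype, cpra_per_locus, load_frequency_table
from .normalize import ControlSet, RawBeadReading, SerumProfile, normalize_profile
from .panels import BeadPanel, BeadSpec, Control, parse_bead
from .variants import MabReading, summarize_panel_variants

log = logging.getLogger("sabpipe")

__all__ = [
    "read_raw_csv",
    "write_raw_csv",
    "read_controls_csv",
    "write_controls_csv",
    "read_panel_csv",
    "write_panel_csv",
    "read_mab_csvs",
    "write_report",
    "read_report",
    "RunConfig",
    "run_pipeline",
]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {', '.join(missing)}")


def read_raw_csv(path) -> List[RawBeadReading]:
    """Read one raw bead-reading table (bead_id, trimmed_mean[, bead_count])."""
    df = pd.read_csv(path, dtype={"bead_id": str})
    _require_columns(df, ["bead_id", "trimmed_mean"], path)
    dup = df["bead_id"][df["bead_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate bead id(s): {', '.join(dup.unique())}")
    counts = df["bead_count"] if "bead_count" in df.columns else [100] * len(df)
    return [
        RawBeadReading(str(b), float(t), int(c))
        for b, t, c in zip(df["bead_id"], df["trimmed_mean"], counts)
    ]


def write_raw_csv(readings: Iterable[RawBeadReading], path) -> None:
    pd.DataFrame(readings).to_csv(path, index=False)


def read_controls_csv(path) -> ControlSet:
    """Per-bead control table (bead_id, pbs, nc, ngs_ls, ngs_lc).

    The nc column holds the (single) negative-control bead reading,
    replicated per row; its first value is used.
    """
    df = pd.read_csv(path, dtype={"bead_id": str})
    _require_columns(df, ["bead_id", "pbs", "nc", "ngs_ls", "ngs_lc"], path)
    return ControlSet(
        pbs=dict(zip(df["bead_id"], df["pbs"].astype(float))),
        nc=float(df["nc"].iloc[0]),
        ngs_ls=dict(zip(df["bead_id"], df["ngs_ls"].astype(float))),
        ngs_lc=dict(zip(df["bead_id"], df["ngs_lc"].astype(float))),
    )


def write_controls_csv(controls: ControlSet, panel: BeadPanel, path) -> None:
    rows = []
    for bead in panel.beads:
        pbs, nc, ngs_ls, ngs_lc = controls.for_bead(bead.bead_id)
        rows.append({"bead_id": bead.bead_id, "pbs": pbs, "nc": nc,
                     "ngs_ls": ngs_ls, "ngs_lc": ngs_lc})
    pd.DataFrame(rows).to_csv(path, index=False)


_CONTROL_FLAGS = {
    "": Control.NONE,
    "none": Control.NONE,
    "positive_control": Control.POSITIVE,
    "negative_control": Control.NEGATIVE,
}


def read_panel_csv(path) -> BeadPanel:
    """Panel definition file (vendor, lot, bead_id, allele_1, allele_2, control_flag)."""
    df = pd.read_csv(path, dtype=str).fillna("")
    _require_columns(
        df, ["vendor", "lot", "bead_id", "allele_1", "allele_2", "control_flag"], path
    )
    beads = []
    for row in df.itertuples(index=False):
        flag = _CONTROL_FLAGS.get(row.control_flag.strip().lower())
        if flag is None:
            raise ValueError(f"{path}: unknown control_flag {row.control_flag!r}")
        if flag is not Control.NONE:
            beads.append(BeadSpec(bead_id=row.bead_id, control=flag))
            continue
        label = row.allele_1 + ("\\" + row.allele_2 if row.allele_2 else "")
        beads.append(parse_bead(label, bead_id=row.bead_id))
    vendor = df["vendor"].iloc[0] if len(df) else ""
    lot = df["lot"].iloc[0] if len(df) else ""
    return BeadPanel(vendor=vendor, lot=lot, beads=beads)


def write_panel_csv(panel: BeadPanel, path) -> None:
    rows = []
    for bead in panel.beads:
        rows.append({
            "vendor": panel.vendor,
            "lot": panel.lot,
            "bead_id": bead.bead_id,
            "allele_1": bead.alleles[0].name if bead.alleles else "",
            "allele_2": bead.alleles[1].name if len(bead.alleles) > 1 else "",
            "control_flag": bead.control.value,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_mab_csvs(w632_path=None, hc10_path=None, tfl006_path=None) -> List[MabReading]:
    """Combine up to three raw mAb tables (same dialect as serum raw files)
    into per-bead three-mAb readings; a missing file leaves that mAb unknown."""
    tables = {}
    for name, p in (("w632", w632_path), ("hc10", hc10_path), ("tfl006", tfl006_path)):
        if p is not None:
            tables[name] = {r.bead_id: r.trimmed_mean for r in read_raw_csv(p)}
    if not tables:
        raise ValueError("at least one mAb file is required")
    bead_ids = sorted(set().union(*tables.values()))
    return [
        MabReading(
            bead_id=b,
            w632_mfi=tables.get("w632", {}).get(b),
            hc10_mfi=tables.get("hc10", {}).get(b),
            tfl006_mfi=tables.get("tfl006", {}).get(b),
        )
        for b in bead_ids
    ]


def write_report(df: pd.DataFrame, path, fmt: Optional[str] = None) -> None:
    """Serialize a report table as TSV or JSON (full float precision)."""
    path = Path(path)
    fmt = fmt or ("json" if path.suffix == ".json" else "tsv")
    if fmt == "tsv":
        df.to_csv(path, sep="\t", index=False)
    elif fmt == "json":
        path.write_text(json.dumps(
            {"columns": list(df.columns),
             "data": df.where(df.notna(), None).values.tolist()},
            indent=1, default=float))
    else:
        raise ValueError(f"unknown report format {fmt!r}")


def read_report(path, fmt: Optional[str] = None) -> pd.DataFrame:
    path = Path(path)
    fmt = fmt or ("json" if path.suffix == ".json" else "tsv")
    if fmt == "tsv":
        return pd.read_csv(path, sep="\t")
    doc = json.loads(path.read_text())
    return pd.DataFrame(doc["data"], columns=doc["columns"])


# --------------------------------------------------------------------------
# pipeline

_RAW_NAME_RE = re.compile(r"^(?P<serum>.+)_(?P<vendor>LS|LC)_(?P<sec>FcMonoIgG|IgHPolyFab)\.csv$")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run over a simulated or exported
    experiment directory (panel_*.csv, controls_*.csv, raw/*.csv)."""

    data_dir: Path
    out_dir: Path
    cutoff: float = 500.0
    high_cutoff: float = 1000.0
    variant_cutoff: float = 1000.0
    dilution: float = 0.1
    freq_table: Optional[Path] = None
    mab_files: Dict[str, Path] = field(default_factory=dict)  # w632/hc10/tfl006
    seed: Optional[int] = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.data_dir = Path(self.data_dir)
        self.out_dir = Path(self.out_dir)
        for cut in (self.cutoff, self.high_cutoff, self.variant_cutoff):
            if cut <= 0:
                raise ValueError("cutoffs must be > 0")
        if not self.data_dir.is_dir():
            raise FileNotFoundError(f"data directory {self.data_dir} does not exist")
        if self.freq_table is not None and not Path(self.freq_table).exists():
            raise FileNotFoundError(f"frequency table {self.freq_table} does not exist")


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"[{name}] {exc}") from exc
        return inner
    return wrap


def run_pipeline(config: RunConfig) -> Dict[str, object]:
    """normalize -> variants (optional) -> concordance -> cPRA (optional).

    Returns the manifest (also written to out_dir/manifest.json); every
    report lands in config.out_dir.
    """
    logging.basicConfig(level=config.log_level)
    config.out_dir.mkdir(parents=True, exist_ok=True)
    outputs: List[str] = []

    panels = {
        v: read_panel_csv(config.data_dir / f"panel_{v}.csv") for v in ("LS", "LC")
    }
    controls = {
        v: read_controls_csv(config.data_dir / f"controls_{v}.csv")
        for v in ("LS", "LC")
    }

    # -- normalize
    profiles: Dict[Tuple[str, str, str], SerumProfile] = {}
    normalize_stage = _stage("normalize")(normalize_profile)
    for raw_file in sorted((config.data_dir / "raw").glob("*.csv")):
        m = _RAW_NAME_RE.match(raw_file.name)
        if m is None:
            log.warning("skipping unrecognized raw file %s", raw_file.name)
            continue
        serum, vendor, sec = m.group("serum"), m.group("vendor"), m.group("sec")
        profiles[(serum, vendor, sec)] = normalize_stage(
            read_raw_csv(raw_file), controls[vendor], panels[vendor],
            serum_id=serum, secondary=sec,
            cutoff=config.cutoff, dilution=config.dilution,
        )
    norm_rows = [
        {"serum_id": s, "vendor": v, "secondary": sec, "bead_id": bead_id,
         "normalized_mfi": rec.normalized_mfi, "positive": rec.positive}
        for (s, v, sec), prof in profiles.items()
        for bead_id, rec in prof.records.items()
    ]
    write_report(pd.DataFrame(norm_rows), config.out_dir / "normalized.tsv")
    outputs.append("normalized.tsv")

    # -- variants (only when mAb files are supplied)
    if config.mab_files:
        readings = _stage("variants")(read_mab_csvs)(
            config.mab_files.get("w632"), config.mab_files.get("hc10"),
            config.mab_files.get("tfl006"))
        summary = summarize_panel_variants(readings, panels["LS"],
                                           cutoff=config.variant_cutoff)
        write_report(summary.reset_index(), config.out_dir / "variants.tsv")
        outputs.append("variants.tsv")

    # -- concordance on the common-antigen universe
    from .panels import common_alleles

    common = common_alleles(panels["LS"], panels["LC"])
    sera = sorted({s for s, _, _ in profiles})
    quartets = []
    for serum in sera:
        quartet = _stage("concordance")(ConditionQuartet)(
            serum_id=serum,
            profiles={
                (v, sec): profiles[(serum, v, sec)].restrict(common)
                for v in ("LS", "LC")
                for sec in ("FcMonoIgG", "IgHPolyFab")
            },
        )
        quartets.append(quartet)
    loci = sorted(
        {l for p in panels.values() for l in p.loci()}, key=lambda l: l.value
    )
    if quartets:
        write_report(per_serum_summary(quartets, loci),
                     config.out_dir / "per_serum.tsv")
        write_report(cohort_summary(quartets, loci),
                     config.out_dir / "cohort.tsv")
        outputs += ["per_serum.tsv", "cohort.tsv"]

    # -- cPRA
    if config.freq_table is None:
        log.warning("no frequency table supplied; cPRA stage skipped")
    elif quartets:
        from . import datasets

        amap = datasets.load_antigen_map()
        table = load_frequency_table(config.freq_table)
        engine = cpra_haplotype if table.mode == "haplotype" else cpra_per_locus
        rows = []
        for quartet in quartets:
            for (vendor, sec), prof in quartet.profiles.items():
                ua = _stage("cpra")(expand_unacceptable)(prof, amap, config.cutoff)
                res = engine(ua, table)
                rows.append({
                    "serum_id": quartet.serum_id, "vendor": vendor,
                    "secondary": sec, "n_unacceptable": len(ua.antigens),
                    "n_excluded": len(ua.excluded),
                    "cpra_percent": res.percent,
                })
        write_report(pd.DataFrame(rows), config.out_dir / "cpra.tsv")
        outputs.append("cpra.tsv")

    manifest = {
        "sabpipe_version": __version__,
        "seed": config.seed,
        "cutoff": config.cutoff,
        "high_cutoff": config.high_cutoff,
        "variant_cutoff": config.variant_cutoff,
        "dilution": config.dilution,
        "data_dir": str(config.data_dir),
        "n_sera": len(sera),
        "outputs": outputs,
    }
    (config.out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
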