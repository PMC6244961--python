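#!/usr/bin/env python
"""Unacceptable-antigen expansion and cPRA per assay condition.

For each simulated serum and each (vendor, secondary) condition, expand the
positive beads into an unacceptable-antigen set and compute cPRA on the
synthetic demonstration frequency table, cross-checked against the
Monte-Carlo donor oracle.  Shows how the same serum can earn very different
cPRA values depending on beadset and secondary antibody.  Run
03_simulate_cohort.py / 04_concordance.py first.
Writes results/cpra_by_condition.tsv.
"""

from pathlib import Path

import pandas as pd

from sabpipe import datasets
from sabpipe.cpra import cpra_haplotype, expand_unacceptable, simulate_donors_oracle
from sabpipe.io import read_controls_csv, read_panel_csv, read_raw_csv
from sabpipe.normalize import normalize_profile

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    data_dir = RESULTS / "sim_cohort"
    if not data_dir.exists():
        raise SystemExit("run analysis/03_simulate_cohort.py first")
    panels = {v: read_panel_csv(data_dir / f"panel_{v}.csv") for v in ("LS", "LC")}
    controls = {v: read_controls_csv(data_dir / f"controls_{v}.csv")
                for v in ("LS", "LC")}
    amap = datasets.load_antigen_map()
    table = datasets.load_demo_frequency_table()

    rows = []
    for raw_file in sorted((data_dir / "raw").glob("*.csv")):
        serum, vendor, secondary = raw_file.stem.rsplit("_", 2)
        profile = normalize_profile(
            read_raw_csv(raw_file), controls[vendor], panels[vendor],
            serum_id=serum, secondary=secondary)
        ua = expand_unacceptable(profile, amap)
        exact = cpra_haplotype(ua, table)
        rows.append({
            "serum_id": serum, "vendor": vendor, "secondary": secondary,
            "n_unacceptable": len(ua.antigens),
            "cpra_percent": round(exact.percent, 2),
        })
    df = pd.DataFrame(rows).sort_values(["serum_id", "vendor", "secondary"])
    RESULTS.mkdir(exist_ok=True)
    df.to_csv(RESULTS / "cpra_by_condition.tsv", sep="\t", index=False)
    print(df.to_string(index=False))

    wide = df.pivot_table(index="serum_id", columns=["vendor", "secondary"],
                          values="cpra_percent")
    spread = (wide.max(axis=1) - wide.min(axis=1)).round(2)
    print("\ncPRA spread (max - min across the four conditions) per serum:")
    print(spread.to_string())
    print("\nSera reacting only with denatured variants get substantial cPRA "
          "on LS yet 0% on LC -- the listing disparity the analysis "
          "quantifies.")

    # spot-check one nonzero condition against the Monte-Carlo oracle
    nonzero = df[df["cpra_percent"] > 0]
    if not nonzero.empty:
        row = nonzero.iloc[0]
        raw_file = data_dir / "raw" / f"{row.serum_id}_{row.vendor}_{row.secondary}.csv"
        profile = normalize_profile(
            read_raw_csv(raw_file), controls[row.vendor], panels[row.vendor],
            serum_id=row.serum_id, secondary=row.secondary)
        ua = expand_unacceptable(profile, amap)
        mc = simulate_donors_oracle(ua, table, 100_000, seed=SEED)
        print(f"\nOracle check ({row.serum_id}, {row.vendor}/{row.secondary}): "
              f"engine {row.cpra_percent}% vs Monte-Carlo {mc.percent:.2f}% "
              f"(SE {100 * mc.standard_error:.2f})")


if __name__ == "__main__":
    main()
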