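#!/usr/bin/env python
"""Run the full pipeline on the simulated cohort and summarize concordance.

Normalizes every (serum x vendor x secondary) raw table, restricts to the
common antigens, classifies each serum's reactivity group, and tallies
LS-vs-LC reactive counts with exact paired tests.  Run 03_simulate_cohort.py
first.  Writes results/pipeline/{normalized,per_serum,cohort}.tsv.
"""

from pathlib import Path

from sabpipe.io import RunConfig, read_report, run_pipeline

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    data_dir = RESULTS / "sim_cohort"
    if not data_dir.exists():
        raise SystemExit("run analysis/03_simulate_cohort.py first")
    out = RESULTS / "pipeline"
    manifest = run_pipeline(RunConfig(data_dir=data_dir, out_dir=out, seed=1))
    print("reports:", ", ".join(manifest["outputs"]))

    per_serum = read_report(out / "per_serum.tsv")
    print("\nPer-serum group labels:")
    print(per_serum[["serum_id", "group"]].to_string(index=False))
    cohort = read_report(out / "cohort.tsv")
    cohort = cohort[cohort["n_sera"] > 0]
    print("\nLS-vs-LC tallies (reactive sera only):")
    cols = ["locus", "secondary", "ls_gt_lc", "ls_eq_lc", "ls_lt_lc",
            "wilcoxon_p_one_sided"]
    print(cohort[cols].to_string(index=False))
    print("\nAnti-denatured sera react on LS only; pan-native sera on both "
          "vendors -- the tally is LS-heavy wherever denatured-variant "
          "reactivity dominates.")


if __name__ == "__main__":
    main()
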