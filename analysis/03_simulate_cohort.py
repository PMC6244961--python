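#!/usr/bin/env python
"""Generate the default synthetic serum cohort (seed 1).

Six sera spanning the reactivity patterns of interest -- two
anti-denatured-only, one pan-native high-titer, one broad low-titer native,
one narrow strong native, one nonreactive -- each measured on both vendor
panels with both secondary antibodies.  Raw CSVs, control files and the
ground truth land in results/sim_cohort/.
"""

from pathlib import Path

from sabpipe.simulate import default_config, simulate_experiment

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    cfg = default_config()
    outdir = RESULTS / "sim_cohort"
    result = simulate_experiment(cfg, seed=SEED, outdir=outdir)
    print(f"{len(result.files)} files written to {outdir}")
    for serum in cfg.sera:
        kinds = {c.epitope_class for c in serum.clones} or {"none"}
        print(f"  {serum.serum_id}: scenario={serum.scenario or 'empty':<15} "
              f"clones={len(serum.clones)} epitopes={'/'.join(sorted(kinds))}")


if __name__ == "__main__":
    main()
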