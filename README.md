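# sabpipe

Cross-vendor analysis of HLA antibody measurements from Luminex
single-antigen-bead (SAB) assays.

## The problem

Kidney-transplant candidates are screened for anti-HLA IgG with SAB assays:
each polystyrene bead carries one recombinant HLA protein, bound serum IgG
is detected with a phycoerythrin-conjugated secondary antibody, and the
per-bead mean fluorescence intensity (MFI) decides which antigens are
listed as *unacceptable* for organ allocation.  Two complications make this
readout vendor-dependent:

1. **Bead chemistry.** Class-I HLA is natively a trimer (heavy chain +
   β2-microglobulin + peptide).  One vendor's beads (LS) also carry
   "denatured" variants — peptide-free heterodimers and β2M-free heavy
   chains — whose cryptic epitopes bind antibodies that are generally not
   pathogenic; the other vendor's beads (LC) carry essentially none.
2. **Detection stoichiometry.** A polyclonal F(ab')₂ secondary
   (*IgHPolyFab*) can bind several heavy-chain epitopes per captured IgG and
   amplifies sparse signals; an Fc-specific monoclonal (*FcMonoIgG*) binds
   1:1 and does not.

The same serum can therefore earn a high calculated panel-reactive antibody
(cPRA) on one beadset/secondary combination and 0% on another, with direct
consequences for organ offers.  `sabpipe` implements the full analysis as a
tested library: MFI normalization and positivity calling, three-mAb
(W6/32 / HC-10 / TFL-006) variant classification of the panels,
intraindividual 2×2 (vendor × secondary) concordance with exact paired
tests, unacceptable-antigen expansion with a cPRA probability engine, and a
mechanistic simulator of the whole experiment that supplies ground truth
for recovery tests.

## Core quantities

* **Normalized MFI** for a bead with trimmed-mean fluorescence *T*:
  `normalized = (T − PBS) − NC − (NGS_LS + NGS_LC)/2`, where PBS is the
  buffer-only reading, NC the antigen-free control bead and NGS the
  negative-sera means of the two kits.  Positivity: normalized ≥ 500 (serum
  dilution 1/10); variant and "high-MFI" calls use ≥ 1000.
* **cPRA** from an unacceptable-antigen set *U* and population haplotype
  frequencies *f(h)*, assuming Hardy–Weinberg pairing:
  `cPRA = 1 − Σ_pop w_pop · ( Σ_{h ∩ U = ∅} f_pop(h) )²`,
  with a linkage-equilibrium per-locus form
  `P(acceptable) = Π_l (1 − F_l)²` as an alternative engine and a
  Monte-Carlo donor-sampling oracle for validation.
* **Exact paired tests** (sign test and Wilcoxon signed-rank, exact null up
  to n = 25 including mid-ranks for ties) for LS-vs-LC reactive counts and
  MFIs.
* **Detection model** of the simulator: bound-IgG density *D* yields signal
  `α·g(D)·D` with `g(D) = 1 + (A−1)·exp(−D/D₀)` for the amplifying
  polyclonal secondary and `g ≡ 1` for the 1:1 monoclonal.

## Worked example

Simulate a six-serum cohort and push it through the pipeline:

```bash
sabpipe simulate --seed 1 --outdir results/sim_cohort
sabpipe run --data-dir results/sim_cohort --out results/pipeline \
    --freqs src/sabpipe/data/demo_frequencies.json
```

or equivalently run the numbered drivers `analysis/01…05`.  The panel
arithmetic step prints the comparison universe:

```
locus  common  ls_only  lc_only  union
    A      28        3        2     33
    B      43        7        5     55
    C      13        3        5     21
```

i.e. the two class-I panels share 28 HLA-A, 43 HLA-B and 13 HLA-C antigens
— the only beads on which cross-vendor comparison is meaningful.  The
variant census (`analysis/02`) finds β2M-free heavy chain on 76/97 LS beads
and 0/96 LC beads at the 1000-MFI cutoff, and the pipeline's per-serum
report classifies the simulated sera by reactivity pattern:

```
serum_id  group
 SIM-001     1A    # anti-denatured only: LS-only, sub-1000 MFI
 SIM-003     1C    # pan-native high titer: high on both vendors
 SIM-006     nonreactive
```

Finally `analysis/05` shows the listing consequence — the same serum's cPRA
across the four conditions (demonstration frequency table):

```
serum_id  cPRA spread (max − min across conditions)
 SIM-001  86.8      # 86.8% on LS/IgHPolyFab, 0% on LC
 SIM-003   0.0      # true broad reactivity: high everywhere
```

A serum whose antibodies see only denatured heavy chains is maximally
sensitized on one vendor's assay and unsensitized on the other.

## Layout

```
src/sabpipe/       library: panels, normalize, variants, concordance,
                   cpra, simulate, io, cli (+ bundled data fixtures)
analysis/          numbered narrative drivers writing results/
tests/             pytest suite (unit, property and end-to-end checks)
docs/methods.md    models, parameters, design choices, limitations
```
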