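# Methods

This note records the models implemented in `sabpipe`, the defaults and why
they were chosen, and what the synthetic data can and cannot establish.

## Normalization and positivity

The background correction is applied exactly as written:

    normalized = (trimmed_mean − PBS) − NC − (NGS_LS + NGS_LC)/2

with PBS the buffer-only per-bead reading, NC the antigen-free control-bead
reading and NGS the per-bead means of negative-control sera run on each
vendor's kit.  Whether the NC and NGS terms were themselves PBS-corrected
upstream is not specified by the formula; we apply it literally and treat
the control semantics as the supplier's problem.  Negative normalized
values are retained (no clamping) — positivity handles them.  PBS and NGS
corrections are per-bead when per-bead control tables are supplied, scalar
otherwise.

Positivity is `normalized ≥ cutoff` with cutoff 500 MFI at serum dilution
1/10.  The ≥ convention (rather than >) is used uniformly because the
listing rule for unacceptable antigens is stated as "at or above"; the
difference matters only for values exactly at the cutoff.  The variant and
high-MFI calls use the same convention at 1000 MFI.

## Variant classification

Each class-I bead is scored with three mAbs: W6/32 (intact trimer), HC-10
(peptide-free β2M-associated heavy chain), TFL-006 (β2M-free heavy chain).
A flag is `value ≥ 1000`; an absent value yields an *unknown* flag, never
`false` — on the bundled panels only the TFL-006 column is available per
bead, so intact/peptide-free flags are exercised on synthetic data.  An
empty cell in the bundled table means "allele absent from that vendor's
panel", not zero binding.  Class II has no analogous mAb protocol; variant
classification is class-I only.

### Bundled panel fixtures

The per-bead TFL-006 table and the vendor-unique rosters are transcribed
verbatim, including their internal inconsistencies (`datasets.FIXTURE_CONFLICTS`):
B*82:01/B*82:02 appear with swapped vendor assignments between the two
tables, B*15:11 is LS-only per-bead but missing from the unique roster, and
one DP pair is listed as unique to both vendors.  We deliberately do not
"fix" the source tables; panel membership for set arithmetic is taken from
the per-bead table's presence/absence, which reproduces the shared-antigen
counts (A 28 / B 43 / C 13) regardless of how those conflicts are resolved.

## Concordance

Cross-vendor comparisons are restricted to the shared antigens.  For each
serum the four (vendor × secondary) profiles form a quartet over one
antigen universe; cohort tallies compare per-serum reactive counts LS vs
LC, dropping sera nonreactive in both.

Two paired nonparametric tests are provided.  The sign test uses the exact
binomial null (ties dropped).  The Wilcoxon signed-rank test drops zero
differences, mid-ranks ties, and computes the exact null for n ≤ 25 by a
generating-function convolution over doubled ranks (doubling makes
mid-ranks integral); beyond that, a normal approximation with continuity
and tie correction.  The exact path is implemented in-package because
library exact modes decline ties; tests verify it against full 2ⁿ
enumeration and against scipy where tie-free.  The one-sided Wilcoxon is
the default report because its n = 5 one-sided minimum (0.03125) matches
the granularity of small-cohort per-locus comparisons; both one- and
two-sided values are always emitted since the choice is not dictated by the
data.

### Reactivity groups

The A/B/C pattern descriptions are operationalized as follows.  Let H(v) be
the number of common antigens with normalized MFI ≥ 1000 on vendor v
(maximum over the two secondaries):

* **C** — H(LS) ≥ 2 and H(LC) ≥ 2 (consistently high on both beadsets);
* **B** — exactly one vendor with H ≥ 2;
* **A** — positives exist but neither vendor reaches 2 high-MFI antigens.

Group size 1 vs 2 is decided by the maximal per-condition positive count,
with ≥ 5 antigens meaning Group 1 (the boundary is included because
reported ranges start at 5).  Both thresholds are keyword-configurable;
the rules are an interpretation of described patterns, not a transcription
of an algorithm, and are documented as such.

## Unacceptable antigens and cPRA

Each positive bead adds its allele-level label and its serologic base group
(A*02:03 → `A0203` and `A2`); positive DRB3/4/5 beads add DR52/DR53/DR51;
DQB1 reactivity is listable, while DQA1-, DPA1- and DPB1-borne reactivity
cannot be listed and is recorded under `excluded` rather than dropped.  An
unmapped allele at a listable locus raises — the mapping table must cover
the panel.  The allele → base-group table ships as editable data covering
the bundled panels (standard serologic equivalences); it is data, not code.

Two engines bracket standard practice, since the registry calculator's
internal form is not public:

* **Haplotype / Hardy-Weinberg:** per population,
  `P(acceptable) = (Σ_{h∩U=∅} f(h))²`; populations combine by weighted
  averaging of `1 − P(acceptable)`.
* **Per-locus / linkage equilibrium:** `P(acceptable) = Π_l (1 − F_l)²`.

Haplotypes are specified as base antigens, so allele-level unacceptable
entries match only through their base group (which the expansion always
adds alongside).  Both engines are validated against a Monte-Carlo oracle
that samples donors as i.i.d. haplotype (or per-locus genotype) pairs; the
acceptance check uses 50 random tables at 10⁵ draws with a 3-standard-error
band per table.  Registry frequency tables are not bundled (they are
external, versioned data); a clearly-labelled synthetic demonstration table
ships instead.  Reproducing any specific registry percentage is out of
scope — the engine, not the registry, is the deliverable.

## The simulator

The generator is mechanistic: it draws bead compositions, computes
bound-IgG density per bead from the serum's clone repertoire, and converts
density to fluorescence through a detection model, then emits the raw and
control CSVs the pipeline reads plus a ground-truth JSON.

**Composition.**  Per class-I bead, fractions (native, peptide-free,
β2M-free) are drawn uniformly: LS native U(0.35, 0.60), peptide-free
U(0.05, 0.25), β2M-free U(0.10, 0.30) present on 85% of beads; LC native
U(0.60, 0.90), peptide-free U(0, 0.08), β2M-free ≡ 0.  The LC zero is
structural (the panel census finds none), so "no LC reactivity for
anti-denatured sera" is a designed property of the conditions, and tests of
it probe the pipeline's plumbing, not a statistical accident.  Sums > 1 are
renormalized.  Class-II beads get a peptide-free-like variant fraction on
LS only; no class-II variant assay exists, so this part of the truth is
generator-only.

**Binding.**  A clone contributes `concentration × matching fraction` to
every bead whose allele set intersects its breadth set; contributions add.
Concentration is in MFI-equivalent density units (α = 1).

**Detection.**  `signal = α · g(D) · D` with `g(D) = 1 + (A−1)·e^(−D/D₀)`
for the polyclonal secondary (g ≡ 1 monoclonal), A = 4, D₀ = 1000.  The
functional form is an invented concretization of the qualitative
hypothesis — multi-epitope binding when bound IgG is sparse, aggregation-
limited access when dense — and is config-replaceable.  A and D₀ place the
poly/mono crossover near MFI 3000–5000, the regime where measured signals
from the two secondaries are reported to converge; no quantitative
amplification factor exists to transcribe, so these are calibration
choices fixed once.  Noise is multiplicative lognormal, CV 0.15
(fluorescence-data convention), mean-one parameterization.

**Controls.**  Emissions are constructed so the correction formula is
unbiased: PBS per-bead level 55, NC 10, NGS 20 + 20, and the serum-run
nonspecific background equals NC + mean(NGS) in expectation, so a
zero-signal bead normalizes to ~0 (the NC/NGS values emitted are
already-PBS-corrected residuals).  The positive-control bead reports
~15000 MFI.

**Scenarios (study conditions).**  `serum_anti_denatured` is one β2M-free
clone with panel-wide breadth at concentration 650 (550 for the second
cohort serum): with LS β2M-free fractions of 0.1–0.3 and ~3.5× polyclonal
gain at these densities, polyclonal-detected LS signals land mostly in the
500–1000 band — the low-MFI, LS-only pattern — while monoclonal signals
stay sub-cutoff.  `serum_pan_native` is one native clone across the common
antigens at concentration 9000, putting densities at 3000–8000 where
amplification has collapsed and both secondaries read high on both vendors.
These concentrations were chosen analytically from the detection model to
realize the described regimes, before any recovery test was run, and are
part of the generator's definition of the conditions.

**Determinism.**  All draws flow through one `numpy` generator seeded per
run; identical config + seed reproduce byte-identical outputs.

## What the synthetic data does and does not show

Passing recovery tests show the pipeline correctly separates the designed
mechanisms (variant-restricted reactivity, amplification-dependent
secondary differences) under realistic noise.  They do not validate the
biology: real sera carry mixed repertoires, IgM/complement interference,
prozone effects at low dilutions and lot-to-lot bead variation, none of
which are modelled.  Complement assays, titration/prozone experiments and
clinical outcome interpretation are explicitly out of scope.

## Numerical choices and problem sizes

Exact-test enumeration is capped at n = 25 (DP over doubled ranks, ~O(n³)
worst case, instantaneous); brute-force 2ⁿ oracles in the tests stop at
n = 12.  The Monte-Carlo cPRA oracle uses 10⁵ draws (SE ≤ 0.16 percentage
points at cPRA 50%).  Pattern-recovery checks use 20 replicates of a
two-serum cohort on the full bundled class-I panels (~190 beads × 4
conditions per serum), which keeps the whole acceptance computation around
ten seconds.  Ties in the Wilcoxon ranks use mid-ranks; zero differences
are dropped; degenerate inputs (all ties, empty cohorts, profiles with no
positives) raise or return explicit markers rather than silent zeros.

## Known limitations

* The group-label rules and the high-MFI threshold (≥ 2 antigens at
  ≥ 1000) are one reasonable operationalization; sera near the boundaries
  can flip labels under resampling.
* The amplification law is phenomenological; only its monotone limits
  (g(0) = A, g(∞) = 1) are mechanism-anchored.
* The bundled allele → base-group table covers the bundled panels only and
  simplifies a few serologic splits; it is intended to be edited, not
  trusted as a nomenclature authority.
* cPRA output is only as good as the supplied frequency table; the bundled
  table is a synthetic demonstration, not registry data.
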