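# Methods

`mutspec` re-creates, at desk scale, the analysis used to profile genome-wide
mutation spectra in a haploid yeast mutagenesis comparison: an error-prone,
proofreading-deficient DNA polymerase δ mutator strain versus pulse
mutagenesis with ethyl methanesulfonate (EMS). This note records the models,
parameter choices, numerical details, and the limits of what the synthetic
data can show.

## Pipeline model

Input is a set of per-sample variant calls (VCF) against a reference genome
with gene annotation, plus the parental strain's own call set. A call is
accepted as an induced mutation only if it passes all five criteria:

1. read depth at the site ≥ 10;
2. not present in the parental strain (exact contig/pos/ref/alt match;
   position-only matching is deliberately not the default, as allele-exact is
   the conservative reading of "not present");
3. Phred variant quality ≥ 20 for substitutions, ≥ 50 for indels;
4. mapping quality ≥ 30;
5. variant allele fraction strictly > 0.90 (haploid expectation; "exceeds
   90%" is a strict inequality, all other thresholds are inclusive minima).

Every rejected record carries the full set of violated criteria, so the
filtering waterfall is auditable. Multi-allelic VCF rows are split into
per-allele records before filtering. An optional BED mask stands in for the
upstream removal of repetitive regions, which is a read-level operation
outside this package's scope. A missing annotation (depth, quality, VAF) is
an error, never a silent pass.

Accepted SNVs are then classified three ways:

- **Substitution class.** The 12 directed single-base changes are pooled
  with their reverse complements into six classes (2 transitions:
  A:T>G:C, G:C>A:T; 4 transversions), since double-stranded DNA makes a
  change and its complement indistinguishable without strand information.
  Spectra are pooled across the samples of a mutagen group and reported
  genome-wide and restricted to nonsynonymous (amino-acid-changing or
  stop-gaining) exonic calls.
- **Gene feature.** Exactly one of exon / intron / promoter / terminator /
  intergenic per SNV. Promoters are the 1 kb upstream of the gene start and
  terminators the 200 bp downstream of the gene end, both measured
  strand-aware on the coding strand. Overlaps resolve by precedence
  exon > intron > promoter > terminator > intergenic; where the margins of
  two genes overlap within the same precedence level, the nearer gene wins,
  with ties broken by lower gene start. (Precedence is applied before the
  nearest-gene rule, so a position in one gene's promoter and another's
  terminator is a promoter hit; the two rules cannot otherwise be ordered
  consistently, and single-assignment requires picking one.)
- **Protein impact.** The substitution is mapped onto the coding strand
  (minus-strand genes are reverse-complemented), the affected codon and
  within-codon position (1/2/3) located, and the standard nuclear genetic
  code applied: *preserved* (synonymous, including a stop that remains a
  stop), *changed*, or *stop gained*. Changes split into *conservative*
  (BLOSUM62 score strictly > 0, the common convention; the threshold is
  configurable) and *nonconservative*. Stop-loss and start-loss are ordinary
  changes (and counted nonconservative), not stop gains. The structure
  indicator counts stop gains plus changes in which either residue is Gly or
  Pro — the direction is not restricted by default because a gain or a loss
  of either residue perturbs backbone geometry; `to`/`from` variants are
  available. Its denominator is the number of amino-acid-level events
  (changes + stops), which is what makes the published-style percentages
  internally consistent; the stop-vs-Gly/Pro split is expressed over the
  indicator subset itself. Indels are counted in the per-sample summaries
  but excluded from spectrum and protein tables.

## Rate estimation

- **Mutation frequency** is resistant colonies / (colonies on the
  non-selective plate × dilution factor). **Fold elevation** is the ratio to
  the untreated or empty-vector control, reported half-up-rounded to an
  integer (so 17.5 reports as 18).
- **Per-site base-substitution rate** is the mean over strains of
  nᵢ / (sᵢ · g) — mutations over callable sites over generations — with
  SE = sd/√n. The mean-of-ratios (not ratio-of-means) form is used; with one
  strain the SE is reported as not available. g = 1 treats a chemical pulse
  as a single exposure; g ≈ 30 converts a mutator grown ~30 generations to a
  per-division rate.
- **Fluctuation analysis** estimates m, the expected mutations per culture,
  from parallel-culture mutant counts. The p0 method uses m = −ln(zero-mutant
  fraction) and needs at least one zero culture. The default MSS maximum
  likelihood uses the Ma–Sandri–Sarkar recursion
  p₀ = e^(−m), p_k = (m/k) Σᵢ pᵢ/(k−i+1), maximized by bounded scalar search
  on m ∈ [10⁻⁶, max count + 5] (tolerance 10⁻⁶), with a profile-likelihood
  95% CI (log-likelihood drop of χ²₀.₉₅,₁/2). The per-division rate is
  μ = m/N_final. MSS-MLE is the default because it is standard practice for
  the 5–20 cultures typical of these assays.

Numerical detail: the mutant-count distribution is heavy-tailed
(P(X ≥ k) ≈ m/k), so jackpot cultures can be arbitrarily large. Counts at or
above a ceiling of 1000 enter the likelihood as right-censored tail mass
P(X ≥ 1000) rather than point probabilities; below the ceiling the recursion
runs exactly to the largest observed count. This keeps the estimator
well-defined and fast without discarding jackpots.

## Synthetic data generator

The generator emulates the statistical structure the pipeline consumes, not
sequencing reads:

- **Genome**: i.i.d. background sequence at a target GC content (default
  0.38, yeast-like), with non-overlapping protein-coding genes (valid ORFs:
  ATG start, single stop at the end, codons drawn from the background base
  distribution with stops rejected) laid out with full promoter (1 kb) +
  terminator (200 bp) margins between gene bodies. Genes are single-CDS by
  default; an intron fraction inserts one intron per selected gene to
  exercise the intron feature class. Default study genome: 1 contig × 50 kb,
  10 genes.
- **Mutagen profiles** are probability weights over the six pooled classes.
  The presets encode only the two aggregate fractions reported for the
  mutagens — EMS 97% transitions, mutator 72% transversions — split
  uniformly within each aggregate, because per-class fractions are not
  published as numbers; both are fully overridable.
- **Mutations** are placed uniformly at eligible sites (A/T sites for A:T
  classes, G/C for G:C classes), without replacement.
- **Variant calls**: depth is negative binomial (mean 50, dispersion 5 —
  overdispersed coverage), true calls get VAF = 1.0 (haploid) and qualities
  above every threshold; inherited parental variants are rendered into each
  sample as they would be by real resequencing. Decoy calls each violate
  exactly one named criterion (depth < 10, quality < 20, MQ < 30,
  VAF ≤ 0.90, or present-in-parental), and the violated criterion is written
  to a truth table. Everything is seeded explicitly; fixed seeds give
  byte-identical FASTA/GFF3/VCF output.
- **Study defaults**: 2 groups × 5 clones; EMS mean 56 and mutator mean 7
  SNVs per strain (Poisson across strains), deletions 2.8/1.6 and insertions
  0.6/0.2 per strain, 30 parental variants, 5 decoys per sample. These echo
  the per-strain means of the motivating experiment at a genome ~1/240 the
  size of yeast's.

What the generator does *not* emulate: read-level error processes, alignment
artifacts, repetitive-region structure, real codon usage and gene length
distributions, linked mutations, and the true per-class spectra within the
transition/transversion aggregates. Passing tests therefore demonstrate the
correctness of the *analysis* (filtering logic, classification arithmetic,
estimator behavior), not concordance with any particular organism's biology.

## Problem sizes in the reproduction script

`scripts/acceptance.py` runs the study simulation at its defaults (2 × 5
clones, 50 kb genome), recomputes fold elevations from the published
colony-count tables taken as inputs, estimates per-site rates from the
pipeline's per-strain counts over 1.14 × 10⁷ callable sites (g = 1 for EMS,
g = 30 for the mutator), recovers a CAN1-style forward rate from 5 simulated
cultures at a true μ = 7.9 × 10⁻⁶ per division (N = 2 × 10⁶), and computes
codon-level percentages from 2000 mutations per mutagen on a denser 120 kb /
40-gene genome so the exonic subset is large enough for stable percentages.
Group-level quantities derived from the simulation are stochastic and sized
for quick turnaround; their run-to-run spread is visible by varying `--seed`.

## Known limitations

- The codon-level percentages under the presets differ somewhat from the
  published tables (e.g. the mutator's changed-amino-acid fraction) because
  the within-aggregate class split is uniform and the toy genes do not share
  yeast's codon usage; the published per-class spectra are shown only
  graphically and are deliberately not transcribed.
- Fluctuation estimates from 5 cultures are intrinsically noisy (the
  motivating assay also used 5); the estimator's calibration is established
  by CI-coverage simulations at 50 cultures in the test suite.
- No plating-efficiency or phenotypic-lag corrections are implemented.
- Welch's t-test in the count summary is a convenience for the two-group
  comparison, not a bespoke statistical contribution.
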