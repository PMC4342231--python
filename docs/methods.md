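# Methods

## The problem

Bread wheat (*Triticum aestivum*) is allohexaploid: most genes are present as
three homoeologous copies on the A, B and D subgenomes, each locus carrying
two alleles. Knocking a gene out therefore means stacking deletions at up to
three homoeoloci. Physical mutagenesis (heavy-ion irradiation) produces lines
with homozygous deletions of single homoeoloci; crossing these "primary"
mutants and screening F2 progeny can combine them. Two features of this
campaign need quantitative treatment:

1. **The genotyping assay is hemizygote-blind.** The fluorescent probe screen
   cannot distinguish one intact allele from two, so only *homozygous*
   deletions are detected. Expected detected-class ratios in an F2 are
   therefore not simple Mendelian ratios, and the absence of a class has to
   be tested against the correct expectation before it can be read as
   incompatibility (lethality) of a deletion combination.
2. **Deletions are large and invisible to the assay's own probes.** The
   physical extent of a deletion is bracketed by assaying the intactness of a
   panel of flanking genes placed at known distances in a syntenic model
   genome, using amplicon sequencing with aneuploid control stocks to
   resolve which subgenome each variant belongs to.

`delstack` implements both computations plus the synthetic-data generators
that stand in for the wet inputs.

## Segregation model (`cross_model`)

A genotype is the intact-allele dosage per homoeolocus, `(d_A, d_B, d_D)`
with `d ∈ {0, 1, 2}`. Parents are fully homozygous (`d ∈ {0, 2}`); the F1
dosage is the mean of the parental dosages. The three homoeoloci lie on
different homoeologous chromosomes, so independent assortment is assumed
(no recombination parameter). Selfing a hemizygous locus yields offspring
dosages 0/1/2 with probabilities 1/4, 1/2, 1/4; the F2 law over detected
classes is obtained by enumerating the `4^h` equally likely zygotes
(`h` = hemizygous F1 loci) and collapsing each through the hemizygote-blind
detector (`deleted_set = {locus : dosage 0}`). For the standard crosses this
gives, e.g., 3/16 : 3/16 : 1/16 : 9/16 (A : B : AB : none) for a primary ×
primary cross and 1/64 for the triple-deletion class in a tetra × primary
cross.

**Incompatibility test.** The sources state only that a chi-square
contingency analysis was performed. We use a per-class 1-df goodness of fit
on the two-cell split {class, not-class}, without Yates continuity
correction:

    X² = (O − np)²/(np) + ((n−O) − n(1−p))²/(n(1−p)),  p-value = P(χ²₁ ≥ X²).

For `O = 0` this collapses to `np/(1−p)` exactly. Flags: `*` for p < 0.05,
`**` for p < 0.01 (both configurable); a cell is bold when an expected class
was never observed and that absence is significant. This variant reproduces
the published flag pattern on the hexa-cross table (0/252 at 1/64 → p ≈
0.0455 `*`; 0/252 at 3/64 → p ≈ 4.3 × 10⁻⁴ `**`). One tetra-cross cell
(18/164 at 3/16, p ≈ 0.011) is flagged in the source at a level our default
test does not quite reach at 0.01; the exact software variant used there is
not recoverable, so the legend thresholds are treated as normative and the
test variant is documented rather than fitted.

Classes a table does not record (the screens did not report primary-deletion
counts in the tetra × tetra crosses) are not assumed to be zero; only
reported classes are tested. The undetected ("none") class is implicit as
`n` minus the listed counts.

**Power.** `incompatibility_power` simulates F2 families from the class law
with the lethal classes removed (renormalised) and reports the fraction of
families in which every lethal class is flagged at α₁. Because an absent
class gives a fixed statistic `np/(1−p)`, hexa-class (1/64) absence is a
step function of n: undetectable below n ≈ 242, always flagged above — which
is why several of the screened family sizes were uninformative for the
triple class. With an empty lethal set the function returns the mean
per-class false-flag rate (the empirical type-I error) instead, since "all
lethal classes flagged" is vacuous.

## Amplicon caller (`amplicon_caller`)

Homoeologues are ~96–98% identical, so reads from all three copies of a gene
map to one reference; subgenome-private divergence sites appear as variants
at ~1/3 frequency. Controls resolve ownership: a variant present in **every**
wild-type replicate but absent from exactly one nullisomic-tetrasomic line
(a stock lacking one homoeologous chromosome pair) is homoeologue-specific.
Variants absent from zero or multiple controls are left unassigned and
logged. Monosomic stocks are rejected as controls: one copy still yields
reads (and fluorescence), so they cannot certify absence.

* **Alignment** is exact ungapped placement: each read goes to the
  (reference, offset) pair maximising match count over *all* pairs, ties to
  the lowest reference id then lowest offset; a read is mapped iff its best
  identity ≥ 85% (default). The implementation seeds candidate placements
  with stride-sampled exact 12-mers and uses a pigeonhole bound — any
  placement with at most `(L − 15)/16` mismatches must share a sampled seed —
  to skip the exhaustive scan only when the candidate set provably contains
  the optimum; otherwise a branch-and-bound scan (primed with the candidate
  score) runs. Both paths return the exact argmax. Gapped alignment is out
  of scope: the synthetic reads are substitution-only.
* **SNP detection** keeps one record per (position, non-reference allele)
  with coverage ≥ 50× and allele frequency ≥ 5% (defaults), frequency
  reported as a percentage. Positions are 0-based in memory, 1-based in
  exported tables.
* **Intactness**: a gene copy is *deleted* in a mutant when all of its
  subgenome-specific variants are absent, *intact* when all are present,
  *unknown* when it has no specific variants or shows a partial
  (conflicting) pattern — conservative three-state semantics. When the
  mutant's per-position depth is available, a missing variant counts as
  deletion evidence only where the mutant has at least the calling floor of
  coverage: read depth tapers toward amplicon ends (fewer start positions
  cover them), and absence without calling power is not evidence. Tables
  read from disk carry no depth profile, so this gate is off for external
  data.
* PCR-duplicate handling is a logged duplicate-start-position fraction, no
  filtering; quality trimming is a pass-through hook (the generator has no
  quality model beyond substitution errors).

## Interval inference and synteny (`synteny_map`)

The marker panel places 20 flanking genes (plus the anchor) at signed kb
offsets on the syntenic model-genome grid; "Up" (negative) points toward the
distal end of the short arm. The anchor-adjacent genes have no stated
distance and get configurable ±10 kb placeholder offsets.

Given a mutant's per-marker intact/deleted/unknown profile with the anchor
deleted, the **minimum span** runs between the outermost deleted markers of
the contiguous run containing the anchor; the **maximum span** extends on
each side to the nearest marker beyond the run with a definite intact call.
Unknown calls are transparent for both bounds. If no intact marker exists on
a side the maximum is open there. A deleted marker separated from the run by
an intact one is excluded with a non-contiguity warning (possible
rearrangement, as seen on the 5D profiles). The maximum bound uses the
intact markers' own offsets (the worked example: deleted −400…+100, intact
at −700/+200 → bracket [500, 900] kb), following the published arithmetic
literally. By construction the bracket contains the true span whenever the
deletion endpoints fall between assayed markers, which is what the
parameter-recovery tests verify.

**Synteny classification** works per query gene on generic homology-hit
tables, using the single best hit per chromosome arm (lowest e-value, ties
by identity then length): no hit on any target arm → *translocated*; some
target-arm best hit not matched-or-beaten (identity **and** length) by any
off-target arm → *conserved*; otherwise *uncertain*. Region size is the sum
of distinct scaffold lengths over scaffolds carrying ≥ 1 conserved gene.
The published genome-scale totals (≈12.3 / 11.1 Mb) require the full diploid
progenitor assemblies and are exercised here only as rules on synthetic
tables.

## Synthetic data (`synthetic_data`)

The generator emulates the statistical structure the analysis assumes, not
wheat sequence:

* **References**: per gene, a random ancestral sequence (the mapping
  reference, standing in for the diploid-progenitor scaffolds) plus three
  subgenome copies, each receiving `round(L·d/2)` private substitutions at
  positions disjoint across subgenomes, so realised pairwise identity is
  `1 − d` up to rounding. Defaults: 800 bp amplicons (within the 500–1500 bp
  design window), divergence d = 0.03 (96–98% identity band). No
  transition/transversion bias; divergence sites are uniform.
* **Samples**: wild type (all copies), nulli-tetra (one subgenome absent
  genome-wide; chromosome dosage beyond presence/absence is not modelled),
  and deletion mutants whose span (up_kb ≤ 0 ≤ down_kb) removes every marker
  inside it on one subgenome, with the true span recorded. Random mutants
  draw each side uniformly from (0, 1250] kb, covering the observed regime
  from tens of kb to > 2 Mb.
* **Reads**: per present copy, Poisson(L·coverage/read_length) reads with
  uniform starts and i.i.d. substitution errors; defaults 200 bp reads, 60×
  per-copy coverage (above the 50× calling floor), 1% error. Byte-identical
  FASTQ given the same seed. Not modelled: homopolymer indels (the dominant
  real error mode of the platform), coverage variation between amplicons,
  PCR chimeras — so passing tests demonstrate threshold/subtraction logic,
  not robustness to platform-specific artefacts.
* **F2 populations**: locus-independent draws from the F1 selfing law, with
  lethal detected classes rejection-sampled away.

## Problem sizes and numerics

Test and analysis runs use the full 21-marker panel where the claim is about
the panel (zero-error exactness, interval recovery) and 5–9 gene subpanels
where the claim is about caller mechanics (robustness at 1% error over 20
mutants), chosen so the whole suite runs in well under a minute per module.
Parameter recovery uses ≥ 100 profile-level mutants plus read-level mutants
in the end-to-end tests. Stochastic assertions are seeded; the chi-square
null-calibration check uses 2 500 simulated families with np ≥ 10 and a
±0.02 band around the nominal 0.05.

Degenerate inputs: empty cross tables warn and return nothing; classes with
zero expectation and zero observation are skipped, with a positive
observation they raise; an all-lethal class set raises; an empty reference
set raises; reads longer than every reference raise.

## Known limitations

* The chi-square variant is a modelling choice (see above); multi-class
  contingency alternatives would give slightly different borderline flags.
* Ungapped alignment and substitution-only simulation understate real
  error structure; the 85%/5%/50× thresholds are taken as given, not tuned.
* Interval brackets assume deletions are contiguous on the marker grid;
  rearranged regions yield warnings, not spans.
* Scaffold-sum region sizes depend entirely on the supplied scaffold table;
  no assembly-completeness correction is applied.
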