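# Methods

## The genetic model

Sex in the modelled species is controlled by a single locus with three
alleles carried by three chromosome classes: X (female, recessive *m*),
Y<sup>m</sup> (male, dominant *M₁*) and Y<sup>h</sup> (hermaphrodite,
dominant *M₂*).  Viable genotypes are XX → female (F), XY<sup>m</sup> → male
(M) and XY<sup>h</sup> → hermaphrodite (H); all Y/Y-class combinations are
zygotic-lethal.  A hermaphrodite × male cross therefore segregates
F : H : M = 1 : 1 : 1 after lethality filtering.  The progeny generator
implements lethality by rejection sampling (lethal zygotes are redrawn),
which reproduces the conditional distribution exactly while keeping every
draw auditable.

## Synthetic data generator (`synthio`)

The generator emulates the structure of a three-sex floral transcriptome
screen against reference regions:

* Three reference regions by default, one per chromosome class, each
  carrying `genes_per_reference` plus-strand genes (exons 90–160 bp,
  introns 60–120 bp, 3–5 exons unless fixed per locus, `GT…AG` intron
  ends).  Every CDS starts with ATG, ends at a stop codon, is a multiple of
  three and contains no internal in-frame stop, so planted premature stops
  are the only truncations.
* Per gene, a presence pattern over {F, M, H} (defaults 0.6 / 0.3 / 0.1 for
  3 / 2 / 1 expressed sex types); the abnormal hermaphrodite classes HM and
  HF share H's haplotype.  Per expressed sex type, alternative-splicing
  events are planted independently at rate 0.2 each for intron retention,
  exon skipping and premature stop, plus non-synonymous substitutions at
  rate 0.3.  Planted point edits are kept ≥ 8 bp away from splice junctions
  and skipped-exon edges, and a skip is never adjacent to a retention in
  the same transcript, so each event leaves an unambiguous alignment
  signature; a premature stop and a substitution never target the same
  codon.  Every event is written to a truth ledger
  (gene, type, position, affected sex types).
* Three marker loci named after the canonical sex-linked genes
  (CpSVPL = three-sex marker, CpSERK = female-type, CpCAF1AL = male-type)
  carry engineered SNPs in their 3'UTR.  The three-sex SNP sits inside a
  `CATATG` context (allele-dependent NdeI site), the female-type SNP inside
  `ACTAGT` (SpeI), so PCR–RFLP assays are exercised without perturbing
  amino-acid comparisons.  Allele melting temperatures are spaced
  `delta_tm` (default 1.0 °C) apart around a marker-specific base Tm in
  76–81 °C.
* Expression values are log-normal (log-mean 1.0, log-sd 0.5, arbitrary
  linear units); "elevated" expression in the flower cohort is planted as a
  ×8 multiplier and "reduced" as ×1/8 so HIGH/LOW calls are unambiguous at
  the ×2 / ×0.5 thresholds.
* One root seed feeds named sub-streams (genome, presence, events,
  expression, progeny, melt), so a fixed config is byte-identical across
  runs and adding a component does not perturb the others.

What the generator does **not** emulate: read-level sequencing noise,
assembly artefacts, multiple isoforms per sex type, minus-strand genes,
paralogy and repeat structure.  Tests passing on this generator show the
pipeline's logic is exact under clean assembly, not that real transcriptome
assemblies would classify as cleanly.

## Transcript mapping (`bacmap`)

Transcripts are aligned to the genomic references with exact 15-mer seeds
chained colinearly (reference gaps up to 20 kb are treated as introns when
they exceed the transcript gap by ≥ 20 bp); inter-seed gaps are filled with
a small edit-distance DP and unseeded ends extended by direct comparison.
Identity is 1 − edits/aligned-columns, coverage is aligned transcript
bases / transcript length; acceptance thresholds default to 0.95 / 0.90.
Spliced alignment matters here: a transcript retaining an intron still maps
to its gene at ~1.0 identity, whereas alignment against the spliced gene
sequence would push it below threshold.  Each transcript is assigned to the
gene with the largest exon-span overlap of its best-scoring chain
(identity × coverage); ties break toward the lowest reference id, then the
lowest gene coordinate, and intergenic chains are discarded and logged.

The candidate screens are `NOT_F_BUT_MH` (absent in females AND present in
both males and hermaphrodites — "the other sex types" is read as both) and
`TWO_OR_THREE_SEXES`.

## Splicing classification (`asclass`)

Each sex type's transcript is globally aligned to the exon-chain sequence
with affine gap scores (match 2, mismatch −3, open −6, extend −1).  An
insertion is called an intron retention when it is string-equivalent to
inserting annotated intron *i* at its junction (the aligner may slide a
tied gap off the splice site when boundary bases repeat; equivalence
resolves the tie toward the annotated site) or within ±2 bp of it; deletions
are matched to exon spans the same way.  The CDS is located on the variant
transcript by mapping the annotated CDS anchors through the alignment and
translated with the standard code to the first stop; a stop before the
annotated end is a truncation, and a mapped CDS length not divisible by
three flags a frameshift.  Categories partition by precedence
exon jump > intron jump > AA short > no change; substitution-only genes are
"no change" but still count for sex grouping.  Sex grouping follows the
presence pattern plus pairwise amino-acid identity: two sexes expressed and
different → type_1; three expressed, all different → type_2; three
expressed, exactly one pair identical → type_3; otherwise none.  N- versus
C-terminal truncation is not distinguished: the category uses first-stop
logic only.

## Marker assays (`markerlab`)

PCR is exact-match (the assays are presence/absence calls; mismatch
tolerance would add unneeded knobs): forward primer on the plus strand,
reverse-complemented reverse primer downstream, all pairings ≤ 5 kb
returned shortest first.  Junction primers span the last 10 bases of exon
*i* and first 10 of exon *i+1* with the reverse primer 5 bases further in,
giving a 45 bp product that a retained intron abolishes.  Digestion cuts at
every non-overlapping recognition site (NdeI `CA^TATG`, SpeI `A^CTAGT`;
the table is extensible).

The melt model is a deliberate two-state logistic proxy, not
nearest-neighbour thermodynamics: a homoduplex melts as
F(T) = 1/(1+exp((T−Tm)/s)) with s = 0.5 °C, and a heterozygote is the equal
mixture of both homoduplex curves and two heteroduplex curves at Tm − 1 °C.
Gaussian noise (default sd 0.01) is added per grid point on the 65–90 °C,
0.2 °C grid.  Normalisation fits a linear baseline in each end window
(65–68 °C and 87–90 °C) and rescales by the baseline levels at the window
centres; because the proxy's plateaus are flat, extrapolating the fitted
lines across the grid would only amplify white noise far from the windows.
Clustering assigns each curve to the nearest reference-seeded centroid
under the maximum absolute pointwise difference, with singletons beyond
d = 0.05 normalised units (exposed as a flag).  Markers whose Y<sup>m</sup>
and Y<sup>h</sup> (or X and Y<sup>h</sup>) alleles coincide produce pooled
clusters (e.g. "H+M" at a female-type marker), which is exactly what the
segregation test expects.

## Segregation testing (`segtest`)

Pearson chi-square without continuity correction; expected counts
Eᵢ = N·rᵢ/Σr; critical values 3.841 (df 1) and 5.991 (df 2) hard-coded,
general df via the chi-squared survival function; display values rounded
half-up to two decimals.  One calibration caveat: at n = 96 the df = 1 test
against 1:2 is discrete — its exact size at the nominal 0.05 cut is ≈ 0.039
— so Monte-Carlo calibration is asserted against the nominal level for the
1:1:1 (df = 2) case and against the exact binomial tail for the pooled
ratios.

## Functional mapping (`wholemap`)

Expression classes are fold-changes against the per-locus panel median
(HIGH ≥ 2×, LOW ≤ 0.5×, else NOVAR, thresholds configurable).  The cohort
generator gives every sample a whole-bud baseline measurement alongside its
dissected-whorl measurement, mirroring a design with 28-days-before-
flowering whole buds next to whorl-dissected samples; the baseline anchors
the panel median at the unshifted level, which keeps the fold-change rule
well-posed even at loci where every flower class is shifted in the whorl of
interest (CpSVPL has no NOVAR class in the third whorl).  AS flags come
from junction RT-PCR: any junction with no product, or a product off the
model-predicted length by > 5 bp, flags AS.

The rule table is data (YAML-loadable), not code.  Third-whorl profiles in
locus order CpSERK / CpSVPL / CpCAF1AL:

| CpSERK | CpSVPL | CpCAF1AL | genotype | call |
|---|---|---|---|---|
| NOVAR, no AS | HIGH, no AS | HIGH, no AS | XY<sup>m</sup> | M |
| NOVAR, no AS | LOW, no AS | HIGH, no AS | XY<sup>h</sup> | H |
| NOVAR, AS | HIGH, no AS | LOW, AS | XY<sup>h</sup> | HM |
| NOVAR, AS | LOW, no AS | LOW, AS | XY<sup>h</sup> | HF |
| (any), AS | LOW, no AS | LOW, AS | XX, fourth whorl | F |

Anything else is UNKNOWN.  A predicted H is a *stable* hermaphrodite when
the marker genotypes show no XX pattern at CpSERK, XY<sup>h</sup> at CpSVPL
and no XY<sup>m</sup> pattern at CpCAF1AL.  The fourth-whorl "partial cDNA"
feature of XX at CpSVPL and the X/Y-specific expression marks are recorded
as annotations only; their operational definitions are insufficient to be
rules.  CpSERK's expression is always NOVAR in this scheme — only its AS
flag discriminates.

## Problem sizes and numerical choices

The test suite and the acceptance script use: 18-gene datasets for unit
checks and a 51-gene dataset (17 genes × 3 references, event rates
0.2/0.2/0.2) for splicing recovery; 10,000 Monte-Carlo replicates at n = 96
for calibration; 10,000 fuzz cases each for the PCR and digestion oracles;
200-sample progenies for HRM recovery (ΔTm 1.0 °C, noise sd 0.01, four
reference samples per expected cluster); and 50–200-sample flower cohorts
(log-normal expression noise sd 0.25 in the noisy setting).  Event-boundary
slack is ±2 bp; transcript/model identity below 0.95 over aligned columns
is treated as a mismatch error.  All simulations derive their randomness
from one root seed through named sub-streams.

## Known limitations

Exact primer matching cannot model mismatch-tolerant amplification; the
melt proxy ignores amplicon-sequence thermodynamics, so allele Tm values
must be supplied; minus-strand genes are supported only through reverse
complementation at mapping time; one representative transcript per
(gene, sex type) is assumed, as in assembled-contig screens; and the
dataset-scale gene counts of any particular real screen are not
reproduction targets — the pipeline reproduces structure and decision
rules, not dataset-dependent tallies.
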