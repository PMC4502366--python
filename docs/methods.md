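# Methods

## The problem this package models

Terrestrial isopods (Oniscidea) carry an atypical mitochondrial genome: a
~14-kb **linear monomer** with self-complementary (hairpin-forming)
palindromes at its termini, coexisting with a ~28-kb **circular dimer**
built from two monomer units joined head-to-head. Within an individual the
monomer copies are nearly identical — except for a small number of
**constitutive heteroplasmic sites**, several of which sit in tRNA
anticodons so that a single locus supplies tRNAs for two amino acids (a
"dual" tRNA gene, e.g. Ala/Val). `isomito` implements the complete
computational path used to characterise such genomes from short reads:
targeted assembly, pileup-based heteroplasmy calling, read-backed phasing,
functional interpretation of each site, and cross-species orthology of
sites.

## Synthetic data: the stated world

The simulator (`isomito.synthetic`) generates the object of study rather
than a generic genome:

* **Monomer**: random sequence, default 14,000 bp, with terminal
  palindromes `arm + loop + revcomp(arm)`. Arm/loop sizes are not published
  for these species; the defaults are 25 + 4 bp (long enough to detect,
  short enough not to dominate assembly), configurable.
* **Features**: an isopod-like complement of 13 CDS (stop-free under NCBI
  translation table 5), 2 rRNA and 22 tRNA genes, each tRNA carrying its
  isoacceptor's anticodon at a recorded span.
* **Heteroplasmies**: sites sharing a `haplotype_class` co-occur on the
  same haplotypes; k classes segregate independently, giving 2^k weighted
  haplotypes. This realises the published observation that co-spanning
  reads carry either all reference or all alternate alleles of a class.
  `UNLINKED` sites (individual-specific polymorphisms) are instead drawn
  per molecule as independent Bernoulli trials. The mechanism holding
  alleles near 0.5 is unknown; frequency is treated as a free parameter,
  with no replication/transmission model.
* **Reads**: paired-end, default 2x100 bp. A fragment comes from a linear
  monomer (never crossing the termini) or, with probability
  `dimer_fraction` (default 0.5; both forms are present in vivo but their
  proportions are unknown), from a circular head-to-head dimer whose
  fragments may cross both junctions. Errors are uniform substitutions
  only; qualities are constant Q30 and ignored downstream (the calling
  rule is count-based). No indel or homopolymer error model is simulated —
  platform artifacts are represented only by the downstream HOMOPOLYMER
  flag.
* **Insert size**: default 750 ± 75 bp. This matters for two stages: mate
  recruitment extends the assembly by roughly one insert length per
  iteration (a 2-kb seed must traverse ~6 kb per side in 10 iterations),
  and phasing of site pairs requires the pair distance to fall inside the
  mate span.

A truth table (read id, source haplotype, 0-based coordinate, strand,
molecule type) accompanies every simulation and is the oracle for the
mapping, pileup and phasing tests. What a green test establishes is that
the pipeline recovers what was planted under this idealised error model; it
says nothing about platform-specific artifacts, nuclear insertions
(numts), or contaminant reads, none of which are simulated.

## Mapping and pileups

A k-mer seed index (default k=21) collects candidate diagonals on both
strands; diagonals within the indel band cluster together. Verification is
ungapped comparison first, then a banded alignment (band 3, edit costs:
mismatch 1, gap 1) when the cluster spans several diagonals, when ungapped
identity fails the threshold, or when mismatches form a terminal block of
three or more inside the outermost 25 bp — the signature of an indel close
to a read end that a single voted diagonal would otherwise absorb as
substitutions. Reads that still fail are soft-clipped to their best
segment (Kadane scan, mismatch penalty 3), which is how dimer-junction
reads are placed; clipped bases contribute nothing to pileups. A read is
MAPPED at identity >= 0.9 over >= 30 aligned columns, AMBIGUOUS when two
distinct placements tie on score (ambiguous reads are excluded from
pileups so palindrome arms cannot cross-contaminate allele counts), else
UNMAPPED. Deletions are left-aligned by the traceback and counted at the
first deleted reference position.

## Calling rule

A site is called iff depth >= 100 ("at least") and the most frequent
non-reference allele — deletion included — exceeds frequency 0.2
(strictly). The inequalities are deliberate: ">=" for coverage, ">" for
frequency. Merged multi-sample tables report the observed frequency and
coverage of the calling allele in every sample, called or not, so a
0.04-frequency deletion in a second individual stays visible. Flags:
MULTIALLELIC (second non-reference allele above threshold), HOMOPOLYMER
(a run of >= 4 identical bases begins or ends within 1 bp of the site;
454-style artifact risk), LOW_TERMINAL_COVERAGE (< 300x inside a terminal
palindrome span).

## Phasing

A phasing unit is one read covering both sites, or a proper pair whose
mates cover one site each. Units showing a third allele, or pairs whose
mates disagree about a site, count as `n_other` (the published analyses
are silent on such conflicts; discarding them is conservative).
COMPLETE_LINKAGE requires the two minority cells to total <= 5% of
informative units with both majority cells populated; fewer than 20
informative units is INSUFFICIENT. Sites farther apart than the insert
span simply produce no units and fall out as INSUFFICIENT — no imputation
is attempted.

## Effect annotation

Translation uses NCBI table 5 (AGA/AGG = Ser, ATA = Met, TGA = Trp);
nonstandard start codons are ignored and translation begins at the
annotated `codon_start`. Anticodon identity is the table-5 decode of the
anticodon's reverse complement, with Leu1 = CUN, Leu2 = UUR, Ser1 = AGN,
Ser2 = UCN family labels. All codon/anticodon arithmetic happens on the
feature's annotated strand while reported alleles stay in reference-strand
space; dual identities are reported reference allele first (which can
invert the conventional gene-name order, e.g. "Val/Ala" for the locus
usually written Ala/Val — the reference allele at that site decodes to
Val). Frameshifts report the codon containing the deleted base, the first
stop of the shifted translation, and an affected range running to the
annotated protein's last residue. A site overlapped by several features
(a tRNA anticodon inside a CDS tail) accumulates one effect per feature;
no overlap falls back to NONCODING.

## Assembly

Canonical-k-mer de Bruijn unitigs (default k=31, abundance floor 3).
Unitig walks stop at branches and at already-emitted canonical k-mers;
that second rule is what terminates walks near the centres of terminal
palindromes and a few bases past dimer junctions instead of folding back
through the genome's reverse complement, so the assembled monomer ends
within ~half an arm of the true termini (terminal completeness is
reported separately by the tests; the inter-palindrome core must be exact).
During recruitment the graph additionally drops k-mers below 5% of the
median surviving abundance: at several hundred fold coverage, recurrent
sequencing errors exceed a small absolute floor and would otherwise
fragment unitigs — this is the moral equivalent of tip clipping, applied
before path walking. Seed selection scores contigs by
(coverage / median coverage) x (k-mer sharing with a related reference
mitogenome); recruitment maps all reads each cycle, recruits both mates of
any pair with a MAPPED read (mates of AMBIGUOUS reads only if themselves
MAPPED, which keeps palindrome arms from looping in ever more reads), and
stops early when the recruited set is stable; the cap stays at 10 cycles.
The final reference is the single longest contig across a small parameter
sweep (k in {21, 31, 41}, floor in {3, 5}), ties to higher coverage.

## Cross-species comparison

Unique shared k-mers are chained (longest collinear subsequence), chain
gaps up to 2,000 bp are closed by optimal global alignment (+1/-1/-2),
larger gaps stay unaligned as one-sided gap blocks, and both orientations
of the second genome are tried. At ~72% identity, conserved 15-mers
cluster into widely-spaced conserved runs, so genome-scale comparisons use
anchor k=11 (the k=15 default is kept for the contract; the error message
suggests lowering k). Percent identity is reported both gap-included
(identical columns over all columns — the figure used for the two-species
comparison) and gap-excluded. Orthologous-site projection follows
alignment columns; pairing tolerance defaults to 0 bp, but the Arg/Gly
anticodon site legitimately projects with a one-codon (3 bp) offset
between the two species because the anticodon sits one codon further into
the cox3 tail in one of them.

## Stand-ins for the deposited records

The two deposited monomer assemblies (KR013001/KR013002) cannot be fetched
in an offline environment. `isomito.standins` builds deterministic
synthetic stand-ins of the published lengths (14,129 / 14,154 bp) that
embed the published site geometry — the E273Q/D274H substitutions, the
F118I homopolymer-boundary site, the codon-92 frameshift with premature
stop at 106, the three anticodon heteroplasmies per species, terminal
hairpins, and a 28%-substitution divergence (with conserved tRNA bodies
and block indels reproducing the published coordinate offsets) between the
two. Tests against them verify that the machinery computes those printed
values from sequence; they are not a reproduction from the real records.

## Numerical and degenerate-input choices

* Odd k everywhere in de Bruijn space (no self-reverse-complement k-mers).
* Canonical k-mer = lexicographic min of the string and its reverse
  complement (equivalently, minimum of the 2-bit packings).
* Assembler and mapper tie-breaks are deterministic (sorted packed k-mer
  order; candidate ordering by score, strand, offset), so identical seeds
  give byte-identical outputs.
* Empty read sets assemble to an empty contig list, not an error; an
  assembly that collapses during recruitment raises with the failing
  iteration.
* Deletions in anticodon spans are classified TRNA_BODY (no anticodon to
  decode); deletions outside a CDS frame raise.

## Known limitations

* The mapper is a purpose-built verifier for this pipeline, not a general
  aligner: one indel tract per read, no split mapping beyond one-sided
  soft clips.
* Terminal palindrome bases beyond the hairpin centre are not assembled
  (inherent to the bidirected graph fold-back); lengths are still within
  1% of truth.
* The simulator's error model is substitution-only; homopolymer artifacts
  are only representable through the downstream flag.
* Phasing treats each pair of sites independently; no multi-site haplotype
  graph is built.
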