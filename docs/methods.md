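# Methods

`venomkit` re-implements, as a tested library, the desk side of a
venom-gland peptide-toxin discovery study: single-pass cDNA-library reads
(ESTs) and assembled transcriptome sequences are quality-filtered,
annotated by protein homology, clustered into contigs, segmented into
precursor regions, assigned cysteine frameworks and families, and
cross-validated against MALDI-TOF peak lists by theoretical mass.

## Quality control and annotation

An EST passes QC when its length is **strictly greater** than
`qc_min_len` (default 300 nt), the conventional high-quality threshold
for Sanger-sequenced library inserts.  Input is assumed insert-only;
`trim_flanks` optionally removes one configurable 5'/3' motif pair for
reads that still carry vector context.

Each passing EST is scanned in all six reading frames.  ORF candidates
are Met-to-stop, or open-ended at a sequence terminus so that 5'/3'
fragments remain searchable; the open-ended candidate of a frame's first
segment is emitted only when no Met occurs within its first ten residues,
which prevents translated 5'-UTR junk from shadowing the true CDS.  ORFs
crossing an ambiguous base (N) are discarded rather than inventing
residues.

ORFs are aligned by Smith-Waterman (BLOSUM62; a gap of length k costs
11 + k, the BLASTX default) against a reference protein set containing
toxin and cellular exemplars.  The best hit over all ORF x reference
pairs annotates the EST as toxin-like or cellular when its e-value passes
the cutoff (default 1e-5); otherwise the EST is a no-match.  E-values use
the Karlin-Altschul form `E = K·m·n·exp(-λS)` with the standard gapped
BLOSUM62 constants λ = 0.267, K = 0.041, shipped fixed so that e-values
are identical across installs; `calibrate_karlin_altschul()` refits both
from a shuffled-sequence null and the test suite confirms the shipped
values match this aligner's null within the fit's precision.  Ties break
by identity, then ORF length (a fragment's open-ended ORF covers the
whole remnant), then reference id.

The bundled reference FASTA
(`data/reference_exemplars.synthetic.fasta`) holds the two printed
purified-toxin matures plus synthetic toxin/cellular exemplars
(provenance-tagged per record); pipeline runs may supply any reference
FASTA whose descriptions carry `category=` tags.

## Clustering

Within each annotation category, ESTs are single-linkage clustered under
the overlap relation "best local nucleotide alignment spans >= 100
columns at >= 95% identity" (both configurable).  Exact duplicates are
collapsed first and a shared-16-mer prefilter proposes candidate pairs;
at the default thresholds any qualifying overlap necessarily shares many
exact 16-mers, and a test verifies the prefiltered partition equals the
all-pairs one.  Contigs report unique genes (distinct member nucleotide
strings after trimming a terminal poly-A run of >= 8 A) and unique
proteins (distinct predicted precursor strings) — under this reading the
gene-vs-protein count gap is exactly synonymous variation.  Size bins
(singleton, 2-5, 6-10, 11-15, 16-30, >30) use inclusive edges.

## Precursor segmentation

Toxin precursors follow signal peptide / optional propeptide / mature
peptide.  The signal cleavage site is scored over candidate positions
15-35: mean Kyte-Doolittle hydropathy of the putative h-region window
(six residues ending three before the cut; windows below mean hydropathy
1.0 are disqualified) plus the classic (-3,-1) small-residue bonuses
(+1.0/+1.5 for A/G/S/C/T).  A TSV of externally computed cleavage sites
(e.g. from a neural signal-peptide predictor) overrides the heuristic
when provided.

The propeptide/mature cut follows the Processing Quadruplet Motif: the
last arginine before the first cysteine (and within `max_pro_len` = 40)
with at least one acidic residue at P2-P4.  Both E and D are accepted as
acidic by default; `acidic="E"` restricts to glutamate.  No qualifying
arginine means no propeptide — mirroring natural R-loss variants — and
is not an error.

A C-terminal G, GK, GR or GKR is read as an amidation signal: the
glycine is consumed converting the preceding residue to an amide and
trailing K/R are excised processing residues.  Amidation is only called
when the ORF ends at a stop codon — a truncated C-terminus that happens
to end in glycine is not evidence of amidation.

Completeness is classified from start/stop evidence (full_length,
n_truncated, c_truncated, mature_only).  Two anomaly notes need a
reference mature length (in the pipeline, the cluster/family context):
`stop_readthrough` for a stop-terminated mature running well past it and
`premature_stop` for an internal stop.

**Cluster-informed refinement.** A 5'-truncated EST usually co-clusters
with intact copies of the same transcript, and a fragment whose internal
Met mimics a start codon looks full-length while being conspicuously
shorter than its cluster-mates.  The pipeline therefore re-segments any
toxin precursor that is flagged partial — or is >= 3 residues shorter
than the longest full-length member of its contig — by locating its
translation inside that member via an infix edit-distance alignment
(tolerating up to 25% edits) and transferring the mature start.  This is
the in-silico analogue of reading the boundary off the contig alignment,
and it is what lifts fragment mature-recovery close to the full-length
rate.

## Cysteine frameworks and families

Frameworks use adjacency notation (C3C4 juxtaposed iff the cysteines are
sequence-adjacent).  Disulfide templates are assigned only on an exact,
unique notation match from the bundled registry (ICK-6; MIT1-like-10;
the two-adjacent-pair 10-cysteine mode; the 8-cysteine ICK extension;
Kunitz-6 and DDH-6).  Kunitz and DDH share the plain six-cysteine
notation, so that notation is reported as ambiguous rather than guessed;
odd cysteine counts get an `unpaired_cys` note and no template.
Framework distance = Levenshtein distance between adjacency signatures
plus the cysteine-count difference; it is a metric, zero iff notations
coincide.

Families are single-linkage clusters over mature peptides: link when
global-alignment identity >= 40%, or >= 25% with framework distance
<= 1 (all configurable).  Labels (A, B, ...) are positional — descending
family size, then smallest member name — not biological claims.

## Masses and peak matching

Masses are residue sums plus water (via pyteomics), on the average scale
by default: linear-mode MALDI values and the printed theoretical MWs are
average-scale quantities.  Corrections: each disulfide -2 H
(2 x 1.00794 Da average), amidation -0.98476 Da (OH -> NH2); three
disulfides plus amidation total ~7.03 Da, i.e. the familiar "7 Da
lighter than the linear peptide".  Disulfide count defaults to
floor(n_cys/2), capped by the assigned template's pair count.  Peaks are
interpreted both as M+H (M = m/z - 1.00728) and as (M+2H)/2
(M = 2·m/z - 2·1.00728) and matched within a 2.0 Da default tolerance
(linear-mode accuracy).  Edman-prefix identification searches mature
peptides starting with the prefix (exact, then <= 1 mismatch), ranks by
the MW cross-check, and reports pass/fail per candidate.

## Synthetic library generator

The generator emulates the study conditions: category proportions
(53.58 / 25.73 / 20.69% toxin-like / cellular / no-match), 13 seed
families whose consensus scaffolds default to the A-M framework
notations (duplicates kept — several real families share the ICK
pattern), and Zipf-distributed (exponent 1.2) copy numbers over a
per-family gene inventory so most toxin ESTs fall in contigs.  Every
planted family is expressed at least once.  Each gene is one fixed cDNA
(ATG + signal + optional PQM-terminated propeptide + scaffolded mature +
amidation tail + stop + ATG-free UTRs + poly-A; toxin cDNAs land in the
~0.35-0.8 kb range the study reports); per-copy noise comprises point
mutations (0.002/nt), cysteine loss (0.01), stop gain via UAC->UAG
(0.005), stop readthrough via UGA->CGA (0.005) and 5'/3' fragmentation
(0.10), rates chosen to plant each anomaly the study describes at low
frequency.  Seed matures are rejection-sampled to < 20% pairwise
identity, mirroring families that descend from separate ancestors; this
is also what makes exact family recovery a meaningful test.  Cellular
transcripts reuse fixed cDNAs of synthetic housekeeping-like proteins;
no-match sequences are composition-preserving codon shuffles of those
cDNAs — a harder negative control than uniform-random DNA.  Ground-truth
manifest fields are re-derived from the mutated sequence, so the
manifest always describes what the transcript actually encodes.

What the generator does **not** emulate: sequencing error profiles,
chimeric clones, alternative splicing, genuinely mature-only transcripts
(all 5' fragments retain part of the signal/propeptide region),
fragmentation of cellular transcripts, and real spider codon-usage bias.
Passing recovery tests therefore demonstrate the pipeline's logic under
the stated noise model, not performance on raw trace data.

## Problem sizes and numerical choices

Test and acceptance libraries use 220-300 transcripts with ~25
references; annotation (ORFs x references) is the hot path, and these
sizes exercise every code path — contigs in all size bins, all anomaly
types — while keeping the default suite around two minutes.  All
randomness flows from one numpy `default_rng` seed; two runs with the
same config are byte-identical, and the pipeline summary embeds the
effective configuration.  Percentages print to 2 decimals.  Degenerate
inputs are defined, not errors: empty category summaries, empty
histograms, precursor sets with no toxins.

## Known limitations

* The signal-peptide heuristic is a two-feature stand-in for a neural
  predictor; on real sequences the import path for external predictions
  is preferred.
* E-values assume the Karlin-Altschul regime; for very short ORFs
  (< ~15 aa) the statistic is approximate and such ORFs are below the
  default `min_orf_aa` anyway.
* Cluster-informed refinement needs a full-length cluster-mate; singleton
  fragments keep their heuristic segmentation.
* Template assignment is notation-exact by design; near-adjacent (C-X-C)
  spacing does not influence it.
* `identify_by_nterm` assumes the Edman prefix starts exactly at the
  mature N-terminus.
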