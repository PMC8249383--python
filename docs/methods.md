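# Methods

## The model

Brassicaceae sporophytic self-incompatibility is controlled by the S-locus,
carrying the stigma receptor gene *SRK* and the pollen-coat ligand gene
*SCR*. S-haplotypes form a dominance hierarchy at the pollen level: dominant
haplotypes express small RNAs from S-linked hairpin precursors that direct
transcriptional silencing of *SCR* on more recessive haplotypes. In an
allotetraploid carrying one S-haplotype from each parental lineage (here
called A-like, from an outcrossing progenitor, and B-like, from a
self-compatible progenitor with a pseudogenized *SCR*), a B-encoded
dominance modifier with a target in the A haplotype predicts instant
self-compatibility of the new polyploid. The package operationalizes the
discovery chain for that prediction; each stage is an explicit, testable
operation.

### Inverted-repeat search

Hairpin precursors are near-palindromes, so candidates are found as
inverted repeats: local alignment of the locus against its own reverse
complement with match +4, mismatch −4, linear gap −8 per gapped column,
minimum score 50 and a maximum span (left-arm start to right-arm end) of
350 nt, the einverted parameter set used for this class of precursor.
Complementarity in this search is Watson–Crick only; G:T is a mismatch,
since the DNA palindrome itself is being scored.

The span constraint is enforced exactly by restricting the dynamic program
to the anti-diagonal band `n − max_span ≤ i + j ≤ n − 2` (with `j` indexing
the reverse complement): the anti-diagonal index never decreases along an
alignment path, so every path inside the band starts within span and never
lets the arms cross. The band is filled row-wise in numpy; the in-row gap
dependency is resolved with a running-maximum scan, which is exact for
linear gap costs. Reported hits are path-terminal local maxima (cells whose
diagonal successor does not score at least as high) at or above the score
threshold; overlapping hits are reduced greedily — highest score first,
ties by smaller span then leftmost arms — so each genomic arm footprint is
reported once. The tests hold this implementation to *exact* score and
coordinate agreement with a full-matrix pure-Python reference on hundreds
of random sequences, and the reference itself is validated against literal
enumeration of every (left arm, right arm) interval pair scored by global
alignment at small n.

### Hairpin screen

An inverted repeat is retained as a precursor candidate when it is
*expressed* and *hairpin-like*, in that order (expression first mirrors the
screening logic of the protocol this follows). Structure is evaluated on
countable features of the arm alignment rather than a thermodynamic fold:

* paired stem columns: A:T, G:C, or G:T — the wobble is admitted here
  because the folded molecule is RNA (> 20 required, strict);
* terminal loop: nucleotides between the arms (< 40 required, strict);
* mismatches: opposed bases that form no pair (≤ 4);
* asymmetric bulges: maximal runs of gap columns, each run counting once
  regardless of length (≤ 2).

Paired columns are summed across bulge-separated segments, not taken from
the longest helix, because the criteria bound mismatches and bulges
separately. Note one deliberate asymmetry: wobble pairing is strand-specific
(a G:U pair read from the opposite strand is A:C, which does not pair), so
hairpin metrics refer to the precursor's annotated strand.

Expression requires at least 5 read copies in the 21–24 nt size classes
overlapping the precursor; the protocol states no numeric cutoff, so this
default is a declared package choice, configurable everywhere it appears.

### Small-RNA handling

Reads are adapter-clipped (exact ≥ 8 nt 3' prefix match), restricted to
18–27 nt and collapsed to (sequence, copy count). Mapping is an exhaustive
scan of the supplied locus sequences on both strands at 0 (default) or 1
mismatch; all equally good placements are reported and multimapping reads
are weighted 1/n_placements in quantification (a unique-only mode exists).
Exact scanning at locus scale keeps the naive-scan oracle trivially cheap
and sidesteps aligner heuristics; competitive mapping against a whole
genome is out of scope, so cross-mapping to loci not supplied is not
modeled. N never matches anything, in either direction.

### Target affinity

sRNA–target affinity is a local alignment over the hybridized duplex — the
sRNA 5'→3' against the transcript read 3'→5' — scored match +1, mismatch
−1, gap −2 per gapped column (either strand of the duplex), G:U wobble
−0.5, with a hit cutoff of 18. Since a perfect duplex of length L scores
exactly L, an 18-nt perfect complement is the shortest possible hit. Scores
are half-integers and are accumulated as doubled integers, so cutoff
comparisons never touch floating point. Both target strands are scanned;
strand + means the sRNA hybridizes the forward transcript. Whether a score
of exactly 18.0 qualifies is ambiguous in the source protocol ("cutoff of
18" vs "affinity >18"); `>=` is the default and a strict comparator is one
flag away. Overlapping local optima are resolved per strand to the
maximal-scoring hit (ties: fewer gaps, then leftmost); hits from different
sRNAs that overlap on the target are merged into *target regions*, the unit
the pipeline counts.

### SRK diversity

π is the mean pairwise per-site difference and Watterson's estimator is
θ_W = S/(a_n·L_used) with a_n = Σ_{i<n} 1/i. Columns containing a gap or N
in any sequence are excluded entirely (complete deletion) — the missing-data
convention of the original tabulation tool is undocumented, so the stricter
convention was chosen and fixed. Multi-allelic columns count once in S;
estimates are rounded (4 decimals) only at report time.

### SCR pseudogenization and presence calls

Candidate *SCR* sequences are globally aligned to an intact reference CDS
(match +1, mismatch −1, gap open −5, extend −1 — affine, so a 31-bp deletion
is one indel, not 31; implemented via Biopython's `PairwiseAligner` with
`open_gap_score=-6` under its first-residue convention). Interior gap runs
are indels; any indel whose length is not a multiple of 3 makes the call
`frameshift_pseudogene`. Terminal overhangs are not indel evidence. Indel
*positions* inherit the usual left-shift ambiguity of alignment within
homopolymer runs; lengths and frame status do not.

The SCR motif scan translates all six reading frames and reports windows of
8 cysteines whose 7 inter-cysteine spacings each fall in a configurable
window (default 2–40 residues — the conserved-cysteine criterion names no
spacings, so these defaults are placeholders, not protocol values) with no
stop codon inside the motif.

Presence of an S-haplotype in a resequenced accession is called from a
per-base depth profile: breadth = fraction of positions at depth ≥ 1,
evenness = fraction within [0.25×, 4×] of the median depth, present when
breadth ≥ 0.9. "Broad and even" is qualitative in the source, so the 0.9
threshold is a declared default; depth tables are accepted as already
filtered (properly-paired selection happens upstream of this package).

## The synthetic generator

`sdmod.synth` emulates the study conditions so every stage runs with no
download: ~30 kb haplotypes (the sequenced haplotypes span ~23–31 kb) with
the gene order U-box — mirS3 — SCR — SRK — ARK3, U-box and ARK3 shared
between subgenomes (they are the conserved flanks that attract cross-mapped
reads in the absent-haplotype control). The B-like haplotype carries a
designed hairpin inside mirS3 (default 60-nt arms, 10-nt loop, 2 mismatches,
1 single-base bulge → einverted score 4·60 − 8·2 − 8·1 = 216) and an *SCR*
with a 0/1/31-bp deletion (the 1-bp and 31-bp variants overlap, as in the
western and eastern B haplotypes); the A-like haplotype carries degenerate
SCR fragments and, within 2 kb of them, a gapless target site whose designed
affinity (default 19 = 21 matches + 2 wobbles + 1 mismatch) is achieved by
converting complement columns to wobbles (target U opposite sRNA G) and
identities (which neither pair nor wobble).

Three constructions make planted-truth recovery deterministic rather than
merely probable: the hairpin loop and the 6-nt flanks of the arms are all-A
(A:A neither pairs nor wobbles, so the local aligner cannot profitably
extend the designed stem); designed mismatches edit only the right arm, so
the mature sRNA window is an exact genomic subsequence of the left arm; and
the designated mature 24-nt sRNA is emitted at 25× the per-position arm
depth (mature-sRNA accumulation), so it is always the dominant expressed
query. Reads otherwise start uniformly over the arms with lengths drawn
from a 21–24 nt distribution peaked at 24 and Poisson(srna_depth) copies
per position, plus 50 uniform background singletons of 18–27 nt.

Population samples follow the infinite-sites model: S ~ Poisson(θ·a_n·L)
segregating sites, each derived allele carried by a proper subset of
samples chosen uniformly among nonempty proper subsets. This makes θ_W
unbiased by construction (E[S] = θ·a_n·L regardless of the frequency
distribution), which is exactly what the recovery test asserts; it does
*not* reproduce the singleton-heavy frequency spectrum of a coalescent
sample, so π-based statistics beyond the mean are not to be interpreted.
Depth profiles are Poisson(20) per position for present haplotypes and
Poisson(14) restricted to the U-box/ARK3 intervals (~10% of the locus, well
below the 0.9 breadth threshold) for absent ones.

Background sequence is i.i.d. uniform over ACGT with no repeat structure —
sufficient for filter testing, declaredly unrealistic. Consequences for
interpretation: passing tests demonstrate correctness of the operations and
recoverability of planted signal above random background, not performance
on real repeat-rich S-locus sequence, where the inverted-repeat stage would
report transposon-derived palindromes and the expression screen carries the
real discriminative burden. Every generator operation draws from its own
(seed, tag)-derived stream, so outputs are byte-identical per seed and
adding an operation never perturbs another's draws.

## Problem sizes and determinism

The shipped analyses use one 30-kb haplotype pair, ~120 expressed read
positions, and 200 replicates at n = 4, L = 25 kb for the θ_W recovery
experiment — sizes chosen so the full suite and the acceptance script each
run in well under a minute of compute while keeping the Poisson/recovery
assertions statistically comfortable (3 standard errors). The pipeline
itself is deterministic given inputs; all synthetic randomness flows from a
single integer seed.

## Known limitations

* Hairpin structure is judged on the inverted-repeat alignment, not a
  partition-function fold; a candidate with high einverted score but poor
  thermodynamic stability would be over-called. The filter thresholds are
  defined on countable alignment features, which is what makes them
  testable here.
* Mapping is restricted to supplied loci (no genome-wide competitive
  mapping), qualities are ignored, and no normalization across libraries is
  attempted.
* Diversity is nucleotide-level only; synonymous/non-synonymous
  partitioning and windowed statistics are out of scope.
* Accession-level reproduction of the published counts requires the
  deposited BAC and sRNA data; the CLI accepts such inputs, but nothing in
  this repository downloads them.
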