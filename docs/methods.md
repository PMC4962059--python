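# Methods

## Scope and data model

`lncraft` implements the post-assembly half of a total-RNA-Seq
reannotation: it consumes a merged reference-guided annotation (GTF with
Cufflinks-style class codes), a genome FASTA, sequence libraries (smallRNA
precursors, curated full-length TEs with family/superfamily metadata,
proteins, coding CDSs) and Cuffdiff-style differential-expression tables.
It does not perform read processing, assembly, or expression estimation.

Internally all coordinates are 0-based half-open; GTF I/O converts at the
boundary (GTF is 1-based closed). Strand `.` is "unknown"; unknown-strand
transcripts are excluded from antisense logic with a warning. Class codes
are `reference`, `J`, `O`, `X`, `U` and `EST`.

## Curation

Fixed order: duplicate-reference merging → minimum-length filter → class
renaming → monoexonic clustering → EST integration. The order matters only
in that renaming must precede clustering (cluster ids build on the novel
naming) and integration comes last (external records are never renamed).
Re-running curation on its own output is a no-op.

* Duplicate merging keys on exact (chrom, strand, exon chain) equality;
  near-duplicates are left alone. The survivor is the lexicographically
  smallest id, the others become aliases.
* The length filter drops novel (J/O/X/U) transcripts strictly shorter
  than 57 nt; a 57-nt transcript is kept, and reference/EST records are
  never dropped.
* Renaming: J/O/X novel records become `<hostTranscript>_{j|O|X}_<k>`
  where the host is the reference transcript at the same locus (J) or the
  best-overlapping reference transcript on the same (O) / opposite (X)
  strand, and `k` counts in genomic order per host; U records (and
  unhostable J/O/X) become `TCONS_<8 digits>` in genomic order. Ids already
  matching their scheme are kept, which is what makes the step idempotent.
* Clustering fuses maximal chains of monoexonic U transcripts on one
  (chrom, strand) whose consecutive gaps (next start − previous end) are
  strictly below 500 nt; a 500-nt gap does not fuse. The fused record is a
  single monoexonic U transcript spanning the chain (`Cluster_t_<n>`,
  numbered in genomic order). An optional verification hook (off by
  default) re-extracts the fused genomic sequence and requires each member
  to be an exact substring of it.
* EST integration appends class-EST records, dropping exact exon-chain
  duplicates.

## Homology engine

A self-contained seed-and-extend search stands behind every homology step.
Library words of length `word_size` are hash-indexed once per library.

* **Exact mode** (100 % identity): hits are the maximal identical runs of
  length ≥ `word_size` shared by query and subject — seeds are extended
  outward while bases match. This mirrors a blastn restricted to 100 %
  identity and is checked in the tests against independent substring
  enumeration.
* **Any-identity mode**: for each (subject, diagonal) containing at least
  one exact seed, the optimal ungapped segment on that diagonal is found
  (maximum-sum segment under +1 match / −2 mismatch). The engine is
  deliberately ungapped: the classification thresholds it feeds (bit
  score, coverage, identity) concern contiguous sequence similarity, the
  brute-force references it is validated against enumerate ungapped
  segments, and the synthetic TE homology is substitution-only. Gap
  penalties remain in `SearchParams` for interface completeness but are
  unused.
* **Translated mode**: the query is translated in the requested sense
  frames (or a peptide is searched directly); exact 4-mer seeds are
  extended ungapped under BLOSUM62.

Scores are normalised with pinned ungapped Karlin–Altschul constants —
λ = 1.28, K = 0.46 for nucleotide +1/−2, λ = 0.3176, K = 0.134 for
BLOSUM62 — giving `S' = (λS − ln K)/ln 2` and `E = m·n·2^(−S')` with `m`
the query length and `n` the summed library length (so E-values scale
linearly with library size). Under these constants a raw nucleotide score
of 271 crosses the 500-bit TE threshold. The engine searches the query
strand as given; reverse-strand homology, if wanted, is the caller's
responsibility (the classification steps compare sense transcript
sequences to sense libraries).

Default parameter sets: exact matching at word 16 / E < 0.01 (smallRNA and
TE screening of pot-lncRNAs), word 12 / ≥ 95 % identity / ≥ 100 nt
(lincRNA target search), word 4 / E < 1e−3 (ORF-peptide protein matching —
the protein-match threshold is a pinned package choice, as the upstream
criterion names no tool), word 16 / E < 10 (TE best-hit search).

## Coding filter

An ORF runs from an ATG to the first in-frame stop (stop inside the
nucleotide span, excluded from `aa_length`); an ATG with no downstream
in-frame stop yields a 3′-partial ORF whose `aa_length` is the floor of
the remaining codons. Partial ORFs count toward the long-ORF criterion: a
3′-truncated coding region is still coding evidence. The decision order
is: ORF ≥ 120 aa → coding; length < 200 nt → coding bucket (reason
`short_transcript`, so the output remains a two-way partition of the
transcriptome); longest ORF's peptide matches the protein library →
coding; otherwise pot-lncRNA. The 120-aa and 200-nt bounds are strict/
inclusive exactly as stated ("< 120 aa", "≥ 200 bp"). By default only the
three sense frames are scanned (the assemblies this models are
strand-specific); six-frame scanning is available for unknown-strand
inputs. Only the longest ORF's peptide is searched ("the predicted
protein", singular).

## lncRNA subclassification

smallRNA matching takes precedence over TE matching (the published
categories are disjoint; the order is configurable). Antisense overlap is
exonic and contiguous: a lncNAT needs one (lnc exon × partner exon)
genomic intersection ≥ 10 nt with a transcript of *another* gene on the
opposite strand; 9 nt is a lincRNA. Overlap symmetry (A over B equals B
over A) is a tested invariant. NAT pairs are typed by the partner's own
verdict; lncNAT–lncNAT pairs are deduplicated as unordered pairs, and
partners outside the coding/lncNAT/siRNA-precursor typology are dropped.
A lincRNA with any perfect CDS hit (100 % identity, ≥ 100 nt) is counted
perfect only; near-exact means identity strictly between 95 and 100 %.
One target record per (lincRNA, CDS, class).

## TE classification

Best hit by bit score (ties: longer alignment, then lexicographically
smaller subject id). Thresholds are strict: HC requires bit > 500 *and*
query coverage > 50 %; PR requires bit > 250 *or* coverage > 30 %; HC is
checked first, and every HC-qualifying hit also satisfies the PR clause,
so the classes are disjoint by construction. "Coverage" is query coverage
— the fraction of the transcript covered by the alignment — because the
question asked of the classifier is how much of a transcript is
TE-derived; this is a package choice, as the criterion itself does not
name the side. Family and superfamily are copied from the best hit's
library metadata; report percentages use the canonical superfamily order
(RLG, RLC, RLX, RIL, DTA, DTC, DHH, DTM, DTH, DTT, RST).

## DE filtering and tabulation

Significance: status OK, |log2FC| ≥ 1, q ≤ 0.05 (both inclusive), outside
an optional exclusion region given as explicit coordinates (the use case
is a window around an introgressed mutant locus whose apparent
misregulation reflects sequence polymorphism; at full scale that window is
30 Mb, the synthetic genome uses a scaled 100-kb window). NOTEST/LOWDATA
features are treated as not expressed. `compute_log2fc` is plain
`log2(b/a)` over positive RPKM pairs and deliberately does not reproduce
Cuffdiff normalisation; printed fold changes from zero baselines (and a
few rows where the printed value differs from the ratio at two decimals)
are therefore flagged non-reproducible by ratio arithmetic, and only
ratio-consistent rows are used as worked examples. Pearson correlation of
paired fold changes uses `scipy.stats.pearsonr`, validated by simulation
(planted ρ = 0.7, n = 1,000, |r − ρ| < 0.05).

The bundled full-scale summary tables (classification counts per class,
TE-superfamily tabulation, RPKM worked rows) are arithmetic fixtures. Two
printed cells are internally inconsistent with their own numerators and
denominators — 117/622 prints as 18.2 % where the ratio gives 18.8 %, and
12/117 prints as 10.2 % where the ratio gives 10.3 % — the package
reports the arithmetically consistent values.

## Synthetic data

The generator plants one "unit" per transcript group (a coding locus with
optional novel isoform or same-strand overlap, an antisense pair, a
TE/siRNA/lincRNA transcript, a fragment chain…), assembles each unit in a
local buffer and places units on the genome with inter-unit gaps of
600–1,400 nt — above the 500-nt clustering threshold, so no accidental
fusions or overlaps occur. Sequences are written strand-aware, so
extraction (reverse-complementing minus-strand transcripts) recovers the
designed sequence exactly.

Key constructions and the defaults they pin:

* Coding transcripts: ORFs of 130–400 aa with random internal codons
  drawn from the 60 sense codons excluding ATG (start codon only at
  position 0). Met-free internals mean a CDS fragment planted elsewhere
  can never carry an in-frame start codon — which keeps the
  lincRNA-target construction from leaking into the protein-match filter.
  Translations populate the protein library; CDSs populate the target
  library.
* lncRNA lengths are 201 + Exp(mean − 201) capped at 4,179 nt with means
  535 (antisense) and 465 (intergenic) — matching both the published
  range and the category means, which a uniform draw over the range could
  not do simultaneously.
* Antisense overlaps are drawn from 10–29 nt (qualifying) and 5–8 nt
  (decoys, straddling the 10-nt rule); NAT partners are coding mRNAs,
  siRNA precursors, or a second lncRNA.
* TE transcripts copy library fragments sized against the pinned
  statistics: HC designs use ≥ 350-nt fragments at > 65 % coverage (bit
  well above 500), PR designs 150–239-nt fragments (bit between the 250
  and 500 cutoffs) with long flanks.
* lincRNA targets embed exact (perfect) or 2–5-interior-mismatch
  (near-exact, identity 95.8–98.7 %) CDS fragments of 110–160 nt, with
  six guard mismatches on each side so the alignment cannot extend past
  the planted fragment and blur the perfect/near-exact boundary.
* Monoexonic U fragments come as chains with intra-chain gaps of 50–480 nt
  (always fused) and isolated fragments (never fused, some under 200 nt).
* Every planted non-coding label is enforced by rejection sampling: the
  sequence is resampled until it has no ORF ≥ 120 aa (including 3′-partial
  ORFs — screening whole library entries this way also covers all their
  substrings), no qualifying exact match to the smallRNA/TE libraries,
  and (for target lincRNAs) no longest-ORF peptide hit against the
  protein library. Truth is therefore consistent with construction, and
  at mutation rate 0 a correct pipeline must recover it exactly.
* The DE table plants significant (|log2FC| in 1–4, q ≤ 0.05), null,
  discordant (large fold change, q > 0.05), NOTEST/LOWDATA and
  exclusion-region rows over reference-class features.

One seed drives named child streams (libraries, transcripts, layout,
genome, DE) via `SeedSequence.spawn`, making outputs byte-identical per
seed. The default scale — 2 chromosomes × 1 Mb, ~210 transcripts — was
chosen so a full simulate-plus-pipeline run takes a couple of seconds and
the randomized 100-seed invariant sweep uses a further-scaled config
(1 × 400 kb, ~60 transcripts); partition invariants are scale-free.

What the generator does *not* emulate: read-level noise, expression
estimation (RPKM values are drawn, not computed from reads), splice-site
sequence signals, genome repeat structure, GC composition, and gapped TE
divergence (mutations are i.i.d. substitutions). Passing the planted-label
recovery therefore demonstrates the correctness of the decision logic and
thresholds, not robustness to assembly artefacts or diverged homology on
real data.

## Numerical conventions

Percent values round half-away-from-zero: one decimal for superfamily-
style shares, two decimals for classification shares. Fold changes are
reported at two decimals. Ties in best-hit selection and all orderings
(report rows, renaming counters, cluster numbering) are deterministic.
Degenerate inputs raise rather than guess: empty transcript groups in
`length_stats`, zero RPKM baselines in `compute_log2fc`, fewer than three
pairs (or zero variance) in `correlate_lfc`, exons beyond contig ends in
sequence extraction.

## Known limitations

* The engine is ungapped; strongly diverged (indel-rich) TE relics that
  real gapped BLAST would recover may score lower here. Thresholding
  behaviour, not NCBI score parity, is the contract.
* Antisense overlap is measured on exons as one contiguous run; cumulative
  split overlaps just under 10 nt each do not qualify.
* `cluster_monoexonic` chains consecutive sorted fragments; for nested or
  overlapping monoexonic inputs (not produced by assemblers in practice)
  this can differ from all-pairs single linkage.
* Gene-level and transcript-level DE tables are handled independently;
  reconciling multi-isoform loci is out of scope.
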