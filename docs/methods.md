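# Methods

## The inference problem

A saturating in vivo transposon screen produces a pool of cells, each with
one transposon insertion. After growth selection, sequencing the
transposon–genome junctions yields a map of unique insertion coordinates
with read counts. Genes required for growth are depleted of insertions;
the task is to turn local depletion into a per-ORF essential /
non-essential call while controlling for everything else that shapes
insertion density: target-motif availability (PiggyBac requires TTAA,
Hermes prefers TnnnnA, AcDs is motif-free), reinsertion bias near the donor
locus, chromatin effects, mappability, and sheer library depth.

## Pipeline

**Insertion calling.** Reads are searched for the transposon tag (full
match anywhere; one mismatch tolerated for tags ≥ 20 bp, exact otherwise;
or a tag suffix of ≥ `min_overlap` bases at the read start), trimmed, and
optionally offset by a fixed number of post-tag bases for chemistries that
leave a stub. Mapped reads are dropped if MAPQ < 20 or the junction
(first-sequenced) base mismatches the reference. The junction coordinate is
the leftmost aligned base of a plus-strand read and the rightmost of a
minus-strand read; both orientations collapse to one forward-strand
coordinate, so a site is one genomic position regardless of which
transposon end was sequenced. All internal coordinates are 0-based
half-open; GFF3 (1-based inclusive) is converted at I/O only. A naive
exact-match mapper (unique hit → MAPQ 42, multi-hit → MAPQ 0, mirroring how
real aligners zero out ambiguous placements) supports fixture-scale
end-to-end runs; real screens use an external aligner and enter as SAM/BAM.

**Features.** Eight predictors per ORF (README). Conventions that matter:

- FI counts insertion-free *bases*; the flank before the first site and
  after the last site both count, so FI = 1 iff the ORF has no insertion
  and FI = 0 when every base is hit.
- NI's window is ±10 kb per side, clipped at chromosome ends, and includes
  the ORF's own sites; an empty window yields NI = 0 plus a
  `no_local_data` flag. Zero-target ORFs get `insertions_per_target` = 0
  plus a `no_target` flag — the classifier needs finite rows, and the flag
  preserves the fact that the zero is conventional.
- An insertion exactly on the start-codon base belongs to the ORF, not to
  the 100 bp upstream window (half-open convention).
- A site is "at a target" when its coordinate falls inside the motif span
  `[p, p + len)`; a target is assigned to an ORF when its match *start*
  lies in the ORF. Overlapping motif matches count at every start.

**Classification.** Random Forest, 200 trees, fixed seed, stratified
five-fold CV. The ROC sweep, trapezoidal AUC, Youden maximum and Euclidean
optimum are computed from their definitions (ties break toward lower FPR);
the threshold is chosen on pooled out-of-fold scores and then applied to
full-model probabilities — pooling avoids the optimism of thresholding on
refit scores, a bridge the procedure otherwise leaves open. Impurity-based
importances are renormalized to sum to 1.

**Curation.** Before verdicts are reported, ORFs are excluded (in order)
as: duplicated_region — the fraction of read-length k-mers (default k = 75)
occurring more than once in the genome (either strand) exceeds 0.5, or
membership in a user exclusion list (dubious annotations); length < 300 bp;
deleted in the assayed strains. Each removal carries exactly one reason.

**Training labels.** Native deletion-collection labels, or ortholog
transfer: a target gene is labeled essential only if its orthologs in both
source species are essential, non-essential only if both are
non-essential; conflicts, missing orthologs and ambiguous (many-to-many)
mappings are excluded with counts. A rule-based contradiction filter
replaces the manual visual screen of transferred labels: an
essential-labeled gene is dropped when its NI is at least the median NI of
non-essential genes, its FI < 0.25, and its neighborhood has ≥ 20 sites —
i.e. the gene is freely hit where data are dense. Non-essential labels are
never dropped by this filter.

**Cross-study analyses.** Transfer learning fits on a stratified 80%
sample of one study's training set and scores a stratified 20% sample of
another's, on the feature columns shared by name (the target-sequence
feature drops out against motif-free studies). Importance correlations are
Pearson r between renormalized importance vectors on the shared schema.
Verdict agreement and haploid/diploid comparisons operate on the common
non-excluded ORF universe; curation precedes haploinsufficiency
candidacy.

## Synthetic data

The generator draws an i.i.d. genome at a set GC content (default 0.40,
yeast-like), places non-overlapping ORFs (triangular lengths, default
300–2000 bp with mean 1 kb, placed longest-first for deterministic
packing), labels a fraction essential (default 0.20), and samples unique
insertion sites by Gumbel top-k from a per-base intensity that multiplies:

- a motif factor — zero off-motif for PiggyBac-like (an `off_motif_rate`
  option can emulate observed off-target insertions), weight w (default
  10) on TnnnnA for Hermes-like, flat for AcDs-like;
- a donor factor `1 + b·exp(−d/λ)` for chromosomal donors (defaults
  b = 10, λ = 50 kb), flat for plasmid donors;
- an essential-gene suppression ε (default 0.02) applied beyond a
  tolerated 5′ fringe (default 35 bp, matching the observed tolerance of
  insertions just downstream of essential start codons).

Read counts are gamma-Poisson (mean 100, dispersion 0.5 → CV ≈ 1.4,
truncated at 1 since unread sites are unobservable); jackpot clones
(Poisson, default rate 1/library) overwrite a random site's count with
10³–10⁵ × the mean, reproducing the extreme max/mean ratios real
libraries show. `emit_reads` turns a library back into tagged FASTQ
(random orientation per read) for end-to-end round trips.

What the generator does *not* model: chromatin/replication-timing biases,
sequence-composition effects on the aligner, diploid allelic structure
(ploidy is emulated only through suppression relaxation), PCR duplicates,
and the biological origin of jackpots. Passing recovery tests therefore
demonstrate the pipeline's correctness and its behavior under the modeled
biases — not performance on any real library, which is limited by the
unmodeled effects above and by annotation quality.

## Default study conditions and problem sizes

The reference simulated study is a 1 Mb genome (two 500 kb chromosomes),
500 ORFs, 20% essential, 100k unique insertions, ε = 0.02 — depth per bp
comparable to the deepest real screens. Under these conditions five-fold
CV AUC ≥ 0.95 and essential-set precision/recall ≥ 0.9 at the Youden
threshold hold across seeds, and thinning to 5k insertions measurably
lowers AUC. Unit and property tests use smaller genomes (50–200 kb) at
roughly the same insertion density with ~40–50% of the genome in ORFs.

## Numerical choices and degenerate inputs

- ROC requires both classes and non-constant scores; otherwise it raises
  rather than returning a degenerate curve.
- Youden/Euclidean ties break toward lower FPR (the more conservative
  operating point).
- The published-summary recomputation reports the max/mean read ratio
  against the integer-rounded mean, the convention the published table
  uses (e.g. 3,254,830 / 143 = 22,761); the full-precision ratio is kept
  alongside, and the package's own `LibraryStats` always reports full
  precision.
- Metagene offsets are strand-oriented with upstream negative; on the
  minus strand the offset of a site at position p relative to a gene
  ending at `end` is `end − p` (so the base just upstream of the start
  codon is −1 on both strands, and the minus-strand start-codon base maps
  to offset 1 rather than 0 — a deliberate, documented half-open
  asymmetry). Profiles are reported per gene per 10⁶ library insertions;
  any axis rescaling is display-only.
- Empty libraries raise in every summary; zero denominators in features
  return flagged zeros, never NaN.

## Known limitations

Duplicated-region detection is k-mer-exact and misses diverged repeats
that still confuse alignment. The contradiction filter is a reproducible
surrogate for expert visual screening, not a replacement. Essentiality is
treated as binary although it is quantitative; genes with conditional or
dosage-dependent essentiality will disagree with deletion-collection
references for reasons the classifier cannot see. The naive exact mapper
is for fixtures only — it does not handle mismatches, indels or quality.
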