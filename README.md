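# tnsight

Gene-essentiality inference from in vivo transposon mutagenesis (Tn-seq)
screens in yeasts.

In a saturating transposon screen, each cell in a large pool carries a
single transposon insertion; cells hit in a gene required for growth drop
out, so essential genes end up depleted of insertions. `tnsight` takes a
screen from raw transposon-tagged reads (or pre-mapped insertion sites) to a
per-ORF essentiality verdict, and provides the library-quality diagnostics
that determine whether such a screen can be trusted in the first place. It
is written for people running or re-analysing screens with the AcDs
(motif-free), Hermes (TnnnnA target) or PiggyBac (TTAA target) systems in
*S. cerevisiae*, *S. pombe*, *C. albicans* or a related yeast.

## Method

For every ORF, eight predictors are computed from the insertion map:

- **insertions**, **reads** — unique insertion sites in the ORF and their
  summed read counts;
- **NI** (Neighborhood Index) — ORF insertion density over the density of
  the surrounding ±10 kb window, `(n_ORF/L_ORF) / (n_win/L_win)`, which
  cancels positional biases such as donor-locus proximity and chromatin
  accessibility;
- **FI** (Freedom Index) — length of the largest insertion-free stretch of
  the ORF divided by ORF length (1 when untouched; near 1 flags an
  intolerant gene or domain);
- **insertions 100 bp upstream** of the start codon (strand-oriented);
- **insertions per target sequence** (motif-bearing transposons only);
- **reads/length** and **insertions/length**.

A Random Forest (200 trees, fixed seed) is trained on labeled essential /
non-essential genes — native deletion-collection labels, or labels
transferred from genes whose orthologs are essential in both model yeasts —
and validated by stratified five-fold cross-validation (AUC). The verdict
threshold maximizes the Youden index J = TPR − FPR over the pooled
out-of-fold ROC curve (the Euclidean distance-to-(0,1) optimum is computed
as a cross-check). ORFs that short-read mapping cannot score — duplicated
regions, ORFs < 300 bp, genes deleted in the assayed strains — are excluded
by a curation step rather than called.

A synthetic-data generator simulates the whole process (motif-constrained
insertion intensity, donor-proximity bias, essential-gene suppression with
a tolerated 5′ fringe, overdispersed read counts, jackpot clones) so every
stage is testable end-to-end without any sequencing download.

## Worked example

Simulate a screen, call insertions from its reads, and classify:

```bash
tnsight simulate --out study --seed 5 --n-orfs 50 --n-insertions 2000 --fastq
tnsight call --genome study/genome.fasta --fastq study/reads.fastq \
             --tag TTGGTTACGCAG --out study/called.tsv
tnsight features --genome study/genome.fasta --gff study/orfs.gff3 \
                 --insertions study/called.tsv --out study/features.tsv
tnsight classify --features study/features.tsv --labels study/labels.csv \
                 --out study/verdicts.csv
```

The classify step prints, for this fixture:

```json
{
  "auc_mean": 0.9527777777777778,
  "threshold": 0.6825943117554956,
  "n_essential": 12
}
```

i.e. five-fold CV ranks essential above non-essential genes ~95% of the
time on this tiny fixture, and 12 of the 50 ORFs clear the Youden-optimal
probability threshold of ~0.68. At the package's default study scale (1 Mb genome, 500 ORFs, 100k
unique insertions) the same pipeline reaches CV AUC ≈ 1.0 with precision
and recall ≈ 1.0 against the simulated truth (`analysis/03`).

The `analysis/` scripts are the narrative version of the same computations:
`01` recomputes the published six-study library summaries and shows that
classifier AUC tracks unique insertions (Pearson r ≈ 0.89) rather than read
depth (r ≈ 0.64); `02` runs the library-QC battery on a simulated screen;
`03` runs inference and the depth-degradation comparison; `04` runs
cross-study transfer and the min-target-count sweep for a TTAA-bound
transposon. Each writes small tables to `results/`.

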