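# premirna

Identification of microRNA precursor candidate regions in genomic
sequence, by direct scanning or guided by small-RNA sequencing reads.

Animal pre-miRNAs are ~60–120 nt stem-loops, but hairpin-shaped folds are
everywhere in a genome — most of them fragments of mRNAs, tRNAs, rRNAs,
sno/snRNAs or repeats ("pseudohairpins"). `premirna` separates genuine
precursor hairpins from pseudohairpins with a bootstrap-aggregated
committee of three complementary classifiers, trained on position-aware
sequence/structure features of a fixed 200-nt window centered on the
hairpin's terminal loop.

## Method

Every candidate is a 200-nt window with the central base of the dominant
terminal loop at index 99, folded to a dot-bracket structure (ViennaRNA
MFE at 37 °C; a built-in Nussinov-style folder is available where the
bindings are not). The window is described by **6,622 features**:

* **161 sliding windows × 40 densities** — 21-nt windows at 1-nt steps
  (80 tiling the left flank, 80 the right, one fixed window over the
  reference base), each contributing 4 mononucleotide, 16 dinucleotide
  and 20 structural-triplet densities. The 20 triplets are the length-3
  dot-bracket strings realizable inside a single hairpin (no `)` before
  `(`).
* **180 hydrogen-bond values** — per full-sequence window, the mean
  per-position bond weight (G·C = 3, A·U = G·U = 2, unpaired = 0).
* **CPB** — the maximum run of consecutive paired bases.
* **Profile score** — the candidate's best match, in [0, 1], against a
  library of *mature-anchored structural profiles*: encoded precursor
  structures (M/O/N inside the annotated mature arm, L/D/R in the
  flanks) are anchored-aligned, single-linkage clustered at ≥ 80%
  identity, progressively multiple-aligned, and condensed into
  per-column state-probability matrices that slide along a candidate's
  structure.

Classification is by **bagging**: K bootstrap resamples × three base
learners (Gaussian-kernel SVM, Gaussian Naive Bayes, best-first Gini
decision tree); the label is the majority of the 3K votes and the
positive-vote fraction is the confidence score (ties go negative).
Performance is reported as Sn = TP/(TP+FN), Sp = TN/(TN+FP),
Acc = (TP+TN)/total and the Matthews correlation coefficient, plus a
10-fold cross-validated ROC/AUC.

The NGS pipeline collapses reads to unique sequences with counts,
subtracts reads explained by annotation (mRNA → other ncRNA → known
precursors), clusters the surviving mapped reads, and keeps loci showing
the **two-peak signature** — two coverage peaks (the two precursor arms)
with summits ≤ 75 bp apart. Each qualifying summit pair yields a 250-nt
region centered on the pair midpoint, which is re-centered on its
terminal loop, classified, and reported with a reads-per-million (RPM)
abundance.

## Worked example

A fully synthetic, seeded run (no downloads):

```
premirna simulate --seed 7 --outdir demo/data
premirna build-profiles --datadir demo/data --out demo/library.json
premirna train --datadir demo/data --library demo/library.json \
               --out demo/model.pkl --seed 7
premirna evaluate --datadir demo/data --library demo/library.json \
                  --outdir demo/eval --seed 7
```

which prints (30 positives / 30 pseudohairpin negatives, half held out):

```
30 profiles -> demo/library.json
model (30 members) -> demo/model.pkl
Sn=80.00  Sp=100.00  Acc=90.00  MCC=0.82  AUC=0.999
```

Sn/Sp/Acc are percentages on the held-out half (15 sequences per class,
so each mistake moves Sn by ~6.7 points); AUC pools vote fractions from
10-fold cross-validation. Scanning the toy genome and running the
read-guided pipeline:

```
premirna scan --genome demo/data/genome.fa --model demo/model.pkl \
              --library demo/library.json --outdir demo/scan
premirna ngs --reads demo/data/reads.fastq \
             --alignments demo/data/alignments.bed \
             --genome demo/data/genome.fa --model demo/model.pkl \
             --library demo/library.json --outdir demo/ngs --min-reads 3
```

```
56 candidate regions -> demo/scan
31 regions classified, 30 positive -> demo/ngs
```

`demo/scan/hits.bed` holds the merged positive calls (BED score =
1000 × vote fraction; a hairpin's reverse complement also folds into a
hairpin, so most planted loci are called on both strands), and
`demo/ngs/candidates.tsv` one row per two-peak region:

```
seq_id  start  end   label  vote_fraction  rpm       summits
chrS    519    769   1      1.0000         30593.88  616,672
chrS    1226   1476  1      0.9333         31793.64  1323,1380
```

A vote fraction of 1.0000 means every committee member agreed; RPM is
the region's read count per million mapped reads. All 30 planted loci
are recovered.

Each subcommand writes a `manifest.json` (config, seed, input hashes,
version) beside its outputs, so runs are reproducible.

## File formats

FASTA (sequences; T→U normalized on read), BED6 (0-based half-open
intervals), a 1-based inclusive TSV coordinate dialect
(`seq_id  start  end  strand`, converted on read), FASTQ (reads), SAM or
BED (read alignments), JSON (profile library, manifests).
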