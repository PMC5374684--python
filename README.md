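# kmerForest

Sequence-only prediction of chromatin accessibility and scoring of
regulatory single-nucleotide variants, for computational biologists who
want to ask: *does this non-coding SNV disrupt a functional regulatory
element?* — using nothing but DNA sequence.

## The method

Most disease-associated variants from GWAS fall in non-coding DNA, where
their effect is presumed to run through the regulatory elements they sit
in. kmerForest turns that presumption into a quantitative score in two
stages:

**Stage 1 — learn which k-mers mark open chromatin.** Each sequence *s*
of length *L* is represented by its k-mer count vector
f^s = (x_1^s, …, x_n^s)ᵀ with n = 4^k features (a length-L sequence has
L−k+1 overlapping windows). A bagged random forest of full-depth,
unpruned Gini trees is trained to separate accessible ("open") regions —
in real use, DNase-seq peaks — from random genomic background. Because
every tree sees only a bootstrap resample, its out-of-bag (OOB) samples
form a built-in held-out set, and the importance of k-mer *j* is its
**mean decrease accuracy**:

    MDA_j = (1/B) Σ_b [ acc_b − acc_{b,j} ]

the average drop in tree *b*'s OOB accuracy when feature *j* is permuted
among its OOB samples. Sorting MDA scores prioritizes the k-mers — the
candidate binding words — that carry the accessibility signal.

**Stage 2 — score a variant by the k-mers it breaks.** An SNV at
position *p* alters exactly the k windows overlapping *p*. Its impact is
the accumulated change in k-mer importance across those windows,
Σ |MDA(alt k-mer) − MDA(ref k-mer)| (signed and per-window-mean variants
are also reported). A variant that destroys a high-MDA word scores high;
a background variant scores near zero.

**Conservation-weighted mode.** Functional sequence is under purifying
selection, so each k-mer occurrence can be down-weighted by cross-species
conservation: with fre_q ∈ [0,1] the per-base frequency that the human
nucleotide is retained across a multi-species alignment,

    x_i^{s*} = (1/k) Σ_j Σ_q fre_{q,j}

summing over the occurrences *j* of k-mer *i* and the k bases *q* of each
occurrence. Always x_i^{s*} ≤ x_i^s, with equality iff every touched
fre is 1 — so a missing track degrades gracefully to plain counts.

All experiments here run on a built-in synthetic generator that plants an
exact motif word (default `GATAAG`) into positive intervals, so every
claim is testable against ground truth without any download.

## Worked example

```python
import kmerforest as kf

config = kf.SimConfig(seed=0, genome_length=60_000, n_pos=100, n_neg=100,
                      n_pathogenic=80, n_normal=80)
genome, intervals, track, truth = kf.simulate_genome(config)
vocab = kf.KmerVocabulary(k=6)
matrix, _ = kf.build_feature_matrix(genome, intervals, vocab)

forest = kf.ForestConfig(n_trees=100, seed=1)
cv = kf.cross_validated_auc(matrix, forest, n_folds=5)
print(f"5-fold AUC  = {cv.mean_auc:.3f}   auPR = {cv.mean_aupr:.3f}")

model = kf.train_forest(matrix, forest)
print(f"OOB accuracy = {kf.oob_accuracy(model, matrix):.3f}")
table = kf.compute_mda(model, matrix, permutation_seed=2)
for kmer, mda, rank in kf.rank_kmers(table, vocab, top=3):
    print(f"rank {rank}: {kmer}  MDA = {mda:.4f}")

pathogenic, normal = kf.simulate_snp_panels(genome, truth, config, k=6)
sp, _ = kf.score_variant_set(genome, pathogenic, table, vocab)
sn, _ = kf.score_variant_set(genome, normal, table, vocab)
summary = kf.compare_score_distributions(sp, sn)
print(f"SNV separation AUC = {summary['separation_auc']:.3f}  "
      f"(mean score {summary['mean_a']:.4f} vs {summary['mean_b']:.4f})")
```

prints

```
5-fold AUC  = 0.938   auPR = 0.950
OOB accuracy = 0.850
rank 1: GATAAG  MDA = 0.0695
rank 2: ATAAGG  MDA = 0.0129
rank 3: CGATAA  MDA = 0.0111
SNV separation AUC = 1.000  (mean score 0.0808 vs 0.0006)
```

The classifier separates motif-enriched from background intervals (AUC
0.94), the planted word `GATAAG` tops the 4096-k-mer importance ranking
(runners-up are its shifted single-offset neighbours), and SNVs that hit
planted motifs score two orders of magnitude above background SNVs,
separating the two panels perfectly.

The same pipeline is available from the shell:

```bash
kmerforest simulate --seed 7 --out sim/
kmerforest train sim/genome.fa sim/intervals.bed --k 6 --trees 100 \
    --seed 1 --perm-seed 2 --out model/
kmerforest score sim/genome.fa sim/pathogenic.vcf model/mda.tsv \
    model/vocabulary.json --out scored_path/
kmerforest evaluate --scores-a scored_path/variant_scores.tsv \
    --scores-b scored_norm/variant_scores.tsv --out metrics/
```

## Layout

- `kmerforest.sequence_io` — FASTA/BED/VCF/bedGraph readers and writers,
  coordinate conventions, background-interval sampling
- `kmerforest.kmer_features` — k-mer vocabulary, sparse count and
  conservation-weighted vectors, SVMlight serialization
- `kmerforest.forest_mda` — bagged forest with per-tree OOB bookkeeping,
  OOB permutation importance, k-mer ranking
- `kmerforest.variant_scoring` — affected-window enumeration, SNV impact
  aggregates, panel comparison
- `kmerforest.synthetic_data` — seed-deterministic planted-motif
  benchmark generator
- `kmerforest.evaluation` — ROC/AUC, PR/auPR, stratified cross-validation
- `kmerforest.cli` — `kmerforest` command with simulate / train / score /
  evaluate subcommands

See `docs/methods.md` for modelling assumptions, parameter defaults, and
known limitations.
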