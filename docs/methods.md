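# Methods

This note documents the models and procedures implemented in `epmkit`, their
assumptions, the tunable parameters with their defaults, and the numerical
choices that matter for reproducing results.

## Flanking-region extraction and encoding

Genes are taken from GFF3 `gene` records (1-based inclusive coordinates;
internal arithmetic is 0-based half-open).  Anchors are the annotated gene
start and end, not annotated UTR edges.  Per gene we extract an upstream
block of `promoter_len` (default 1000 nt) + `utr5_len` (500 nt) ending at
the gene start, and a downstream block of `utr3_len` (500 nt) +
`terminator_len` (1000 nt) starting at the gene end; minus-strand genes use
the mirrored windows reverse-complemented, so the fused sequence always
reads 5'→3' in gene orientation.  The two blocks are joined by a
`spacer_len` (20 nt) run of `N`, which one-hot encodes as all-zero rows —
the spacer is `N` in sequence space and zero-padding in matrix space.
Windows running off a chromosome end are N-padded to full length rather
than dropped, so gene sets are stable across folds; genes shorter than
`utr5_len + utr3_len` are extracted anyway with a `windows_overlap` flag.
IUPAC ambiguity codes other than N in input FASTA are masked to N with a
warning (configurable to an error).

## Expression labels

Per gene, `logMaxTPM = log10(max over samples of TPM + 1)`.  The maximum
(rather than the mean) over the samples of the tissue under analysis is
used; the log base 10 and pseudocount +1 are configurable.  Transcript
isoform TPMs are summed per gene before labelling.  Class thresholds are the
empirical 25th/75th percentiles of the genome-wide logMaxTPM distribution
(linear-interpolation quantiles); genes strictly below Q1 are *low* (binary
label 0), strictly above Q3 *high* (1), everything else — including exact
ties — *medium* and excluded from binary training.

## Fold assembly

One fold per chromosome (leave-one-chromosome-out), or per species for the
multi-species scheme.  Two genes are homologous when their protein-level
hit has e-value < 0.001 **and** bit score > 50 (both strict); pairs are
symmetrised on load and self-hits dropped.  Under SSR/MSR, validation genes
with a qualifying homolog on a training chromosome are removed; SSRU keeps
them.  Only the training set is class-balanced (majority class down-sampled
without replacement, seeded); validation stays unbalanced, and accuracy is
therefore reported together with F1 and auROC.  The shuffled-sequence
control (SSC) applies a per-sequence mononucleotide shuffle that preserves
composition and leaves N rows (spacer, padding) in place; a
dinucleotide-preserving shuffle is available as an option.

## Classifier

Three convolutional blocks — each two valid-padding 1D convolutions
(kernel 8) with ReLU, then max pooling (8) and dropout (0.25) — followed by
two fully connected layers (128, 64) interspaced with dropout and a single
sigmoid output unit giving P(high expression).  Training minimises binary
cross-entropy with Adam; early stopping (patience 10), learning-rate
halving on plateau (patience 5), and restoration of the
best-validation-loss weights (batch-norm running statistics included).  At
prediction time a probability ≤ 0.5 means *low*, > 0.5 *high* (the
boundary counts as low).

Every convolutional and hidden dense layer is followed by batch
normalisation before its ReLU, and the default Adam learning rate is 0.03.
These two defaults go together and were a deliberate trainability
decision: at desk scale (a few hundred training genes, 3020-nt inputs, a
sparse planted signal) the un-normalised stack at lr 0.001 either
memorises the training set without generalising or sits at the ln 2
plateau indefinitely, regardless of dropout, weight decay, capacity or
epoch budget; with batch normalisation the loss geometry becomes
scale-invariant and an order-of-magnitude larger step size is the
appropriate regime (measured on the default synthetic task: lr 0.001 flat
at chance after 150 epochs; lr 0.01 → 0.96 validation accuracy; lr 0.03 →
0.98).  `ModelConfig(batch_norm=False, learning_rate=0.001)` recovers the
plain recipe for large-data settings.  The layer structure (6 conv, 3
pool, 2 hidden FC, 1 sigmoid unit) is unchanged by the normalisation
layers.

Optimisation of this network has a characteristic *ignition* behaviour on
sparse-signal data: the loss sits at the ln 2 chance plateau for some
10–20 epochs before the motif signal takes hold, and whether and when
ignition happens depends on the initialisation and the step size.  Three
schedule controls deal with this: `min_epochs` (early stopping and plateau
LR reduction only engage after it, so patience is not consumed by the
plateau); `plateau_restart_epoch` with `max_restarts` (when the best
validation loss is still above `plateau_loss` = 0.67 at the checkpoint
epoch, training abandons the attempt and retries — attempts cycle three
step-size regimes per initialisation seed (the base learning rate,
`restart_lr_factor` × base, and a two-level cycle straddling the base),
because the regimes ignite on complementary initialisations; seeds then
advance deterministically, so runs remain reproducible); and the plateau
LR halving once learning is underway (applied as a multiplicative scale on
the attempt's schedule).  The shuffled-sequence control is
trained with restarts disabled and a short schedule, since there is no
signal to ignite.

A practical consequence of ignition is that a run can terminate in a
*single-motif* solution (accuracy ≈ 0.93 on the default synthetic task,
where detecting either planted motif alone suffices for most genes) rather
than the complete two-motif solution (≥ 0.96).  Downstream analyses that
probe a single model — the genotype panel and the motif-ablation check —
therefore use the fold model with the lowest validation loss.

The network stack (convolutions, batch norm, pooling, dropout, dense
layers, Adam with optional decoupled weight decay) is implemented directly
on NumPy in float32, with reverse-mode gradients verified against finite
differences.  Filter counts, kernel and pool sizes, the FC widths and the
batch size are desk-scale choices (defaults `filters_per_block=(16, 32,
16)`, `batch=32`), all exposed in `ModelConfig`; identical seeds and a
fixed single-threaded BLAS give bitwise-reproducible training.

## Attribution

Contribution scores use DeepLIFT's rescale rule relative to a reference:
linear layers propagate multipliers through their weights, elementwise
nonlinearities use the exact secant ratio Δout/Δin, and max pooling routes
each pooled delta over its window proportionally to the squared input
deltas.  Any routing whose delta-weighted sum telescopes preserves
summation-to-delta; the squared-proportional rule was chosen because it
needs no division by per-element deltas and therefore holds to float
precision even when the pooled argmax differs between input and reference.
The default reference is the average over k per-sequence mononucleotide
shuffles (k = 10 in the library default, seeded; zero rows stay in place),
so the total actual score of a gene equals f(x) − mean f(ref) exactly;
an all-zeros reference is available.  Attribution runs in float64.
Hypothetical scores project the multipliers onto every base
(`hyp[i,b] = Σ_c m[i,c]·(onehot(b) − ref[i])_c`), and the actual score
matrix is the hypothetical matrix masked by the observed one-hot input.
Saliency profiles are plain positionwise means over sequences.

## Motif discovery

Seqlets are fixed-width windows (21 nt) of the per-position score track
whose |sum| exceeds the (1 − fdr) quantile (fdr = 0.01) of a null built
from positionwise permutations of every track (20 permutations, seeded);
at fdr = 0.05 the threshold admits several spurious windows per track,
which flood clustering with low-information motifs, so the stricter
default is used;
windows never cross the spacer, and overlaps are resolved greedily by
|sum|.  Seqlets split by sign into metacluster p0 (positive, high-
expression-associated) and p1 (negative); zero-sum windows are dropped.
Within a metacluster, seqlets are greedily agglomerated: each seqlet joins
the existing cluster whose *seed* patch it matches best (maximum Pearson
correlation over alignment offsets with ≥ 8 columns of overlap and both
orientations) if that correlation reaches 0.7, else it founds a new
cluster; clusters with fewer than 10 seqlets are discarded.  The CWM is the
mean aligned hypothetical patch, the PWM the aligned base-frequency matrix;
every EPM links to an explicit reverse-complement partner (name suffix
`R`).  Positional preferred ranges are the [Q1, Q3] of the member seqlets'
start offsets relative to the TSS (upstream half) or TTS (downstream half),
kept only when more than 10% of the motif's seqlets fall in that half.
Information content is Σ(2 + Σ p log2 p) bits, and the IUPAC consensus
takes, per column, the code covering all bases with frequency ≥ 0.25.
`trim_epm` keeps the contiguous run of columns with per-column IC ≥ 0.3
around the information peak (expanding outward from the maximum-IC column,
which is robust to single noisy flanking columns) and shifts the preferred
ranges accordingly; trimmed EPMs are what the scanners use.

EPM names follow `epm<Spec>-<S|M><condition><run?>-p<0|1>m<idx>[R]`,
e.g. `epmArth-S019-p0m06`; the run field is optional (both the long and the
short dialect parse).

## Scanning and statistics

PWM scanning uses log-odds scores against a 0-order background (default:
composition of the scanned sequences; pseudocount 0.01).  Exact p-values
come from a dynamic program over a discretised score lattice (bin 1e-4):
the null distribution of the integer window score is the convolution of
the per-column score distributions under the background, so
P(score ≥ s) is exact up to the lattice rounding.  The e-value of a match
is p × (scanned positions × strands); `scan` uses the corpus-wide search
space with a default e-value threshold of 1e-4, which suits wide,
information-rich motifs.  For per-gene presence questions (enrichment and
conservation) `presence_scan` restricts the search to each EPM's preferred
ranges and uses the *per-gene* in-range search space with a default
e-value of 0.01 — an 8-nt motif carries only 16 bits, so no corpus-wide
threshold can both detect it and stay specific; the per-gene in-range
e-value is the scale at which that trade-off is meaningful.

Enrichment of an EPM compares the odds of ≥1 in-range match in genes of its
own class (high for p0, low for p1) against the opposite class:
`log2[(f_own/(1−f_own)) / (f_opp/(1−f_opp))]` with a continuity correction
ε = 0.5 on the fractions (ε = 0 reproduces plain odds-ratio arithmetic and
is used by the oracle tests).  Occurrence counts are additionally tested
against an equal split by a 1-df chi-square goodness-of-fit test.
Similarity to reference PFMs (JASPAR format) is the best Pearson
correlation over offsets (≥ 4 aligned columns) and both orientations, with
a column-shuffling null (1000 shuffles; the observed value is included in
the null, so the minimum p is 1/(n+1)); e-value = p × number of references,
significant below 0.05.  Cross-model EPM clustering converts each consensus
to a distance `1 − SW/min(len)` where SW is a local alignment with an
IUPAC-aware substitution score (Jaccard overlap of the base sets, gap open
−1, extend −0.5, reverse complement also searched), followed by
average-linkage hierarchical clustering cut at height 0.5; singletons are
allowed.

## Genotype comparison

Applying a trained model to the per-genotype flanks of the same genes gives
a genes × genotypes probability matrix.  A gene is *differential* when the
population variance (divide by n) of its probabilities exceeds 0.005, else
*homogeneous*; per genotype, p ≤ 0.5 is the low class.  An EPM is
*conserved* for a gene when it has an in-range match in every genotype,
*mutated* when present in the reference genotype but absent somewhere, and
*absent* when the reference lacks it — absent is a third state excluded
from the two-way statistics.  Group percentages are bootstrapped by pooling
genes to sets of 100, 1000 times, seeded.  Set intersections use a
two-sided Fisher exact test; genotypes are clustered from the probability
matrix (Euclidean, average linkage) and exported as newick.  The
category-level comparison scales per-gene values (observed binary labels or
predicted probabilities, both in [0, 1]) and reports per category the
difference of means — −1 means expression only in species A, +1 only in
B — with a two-sided Wilcoxon rank-sum test, Benjamini–Hochberg correction
across categories, and the cross-category Spearman correlation between
observed and predicted shifts.

## Synthetic data generator

The generator emulates exactly the structures the analyses assume: i.i.d.
background sequence at GC 0.4; `n_chroms = 4` chromosomes ×
`genes_per_chrom = 500` genes of 2000 nt separated by 4000 nt intergenic
runs; an exact 25/50/25 low/medium/high class design; one high-class motif
(`CACCTGTC`) and one low-class motif (`AGATCCGA`), each planted in 90% of
its class's genes at a uniform offset 20–200 nt downstream of the TSS (in
gene orientation, respecting strand) and recorded in a truth table; 5% of
genes duplicated to another chromosome (gene body plus enough flank to make
the fused inputs identical, same designed class, targets drawn from the
same class so quartile counts are preserved) with a matching 12-column hit
table (e = 1e-30, bit = 200); TPM tables drawn from well-separated
lognormal components (low genes are a 50/50 mixture of exact zeros and a
weak component) with three replicate columns under multiplicative noise, so
quartile labelling recovers the designed classes (100% at zero noise);
and a 15-genotype panel (reference + 14) in which a seeded 40% of the
non-reference genotypes carry a 12-nt deletion that starts 2 nt before the
planted high-class motif instance in a seeded 50% of the motif-carrying
genes, with a complete edit ledger (the deleted flank is refilled from the
genomic sequence beyond the window so lengths are preserved).  The
`edited_gene_fraction` field exists so that motif-carrying genes split into
conserved and mutated groups, which the conservation statistics compare.
All randomness derives from the single config seed; outputs are
byte-identical across runs.

What the generator does **not** emulate: repeat structure, isochores,
transposable elements, nucleosome or chromatin context, correlated
expression between neighbouring genes, alignment/quantification noise in
TPM estimates, and real motif degeneracy (planted motifs are exact).
Passing tests on these data demonstrate that the pipeline machinery is
correct and that the model can recover clean causal signal; they do not
demonstrate performance on real genomes, where signal is weaker, denser
and confounded.

## Problem sizes and runtime choices

The default end-to-end experiment (4 × 500 genes, ~1000 binary-labelled)
trains one model per chromosome plus one shuffled control on a single CPU
core; attribution uses up to 300 validation genes per fold with k = 5
shuffled references.  These sizes keep a complete run in the ten-minute
range while leaving every statistic well-powered; they are package
defaults, not fixed constants.

## Known limitations

* The classifier is a binary quartile model; medium genes are never
  predicted, and no regression on continuous TPM is attempted.
* Seqlet aggregation is a single greedy pass with a seed-patch similarity
  rule — robust for well-separated planted motifs, but it does not
  re-refine cluster assignments the way full iterative aggregation tools
  do.
* Exact scan p-values assume a 0-order background; higher-order
  composition structure in real genomes will inflate match counts.
* The conservation caller equates "EPM present" with "≥1 in-range match at
  the per-gene e-value"; chance occurrences of short motifs are handled
  consistently (they appear in all genotypes and therefore read as
  conserved) but cannot be distinguished from functional instances.
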