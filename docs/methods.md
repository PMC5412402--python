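# Methods

This note documents the models and procedures implemented in `genefam`,
the free parameters that matter, the design choices made where the
methodology was genuinely open, and what the synthetic-data generator
does and does not emulate.

## Family identification by profile scanning

A motif profile is a log-odds PSSM over the 20 standard amino acids:

    score[p][a] = log2( (count[p][a] + c·bg[a]) / (n[p] + c) / bg[a] )

with counts from a seed alignment (gaps excluded), pseudocount `c`
(default 1.0) and background frequencies `bg` (average proteome
composition, renormalized Swiss-Prot release statistics). Every window of
profile width along a protein is scored as the position-wise sum; the
best window per protein is reported, and additional non-overlapping
windows above threshold are listed so proteins carrying two motif copies
are visible.

Survey pipelines built on profile HMMs use permissive E-value cutoffs; a
PSSM has no E-value, so the detection threshold is instead calibrated
empirically: the default is the 99th percentile of best-window scores on
background (family-free) sequences, giving a ~1% per-protein
false-positive rate by construction. On the simulator's default genome
this yields sensitivity 1.0 and false-positive rate ≈ 0.01. A full
profile HMM (match/insert/delete states, forward scores) is out of scope;
the PSSM is a deliberate simplification that keeps the operating
characteristics measurable.

## Conservation (logo) statistics

Per alignment column, frequencies are computed over non-gap residues;
top-residue identity is the max frequency; information content is
log2(20) − H(column) in bits, with no small-sample correction — exactly
the bit axis of a sequence logo. All-gap columns are flagged and carry 0
bits. These choices make the statistics exactly testable (identical
column = log2 20 ≈ 4.32 bits; uniform column = 0 bits).

## Subfamily classification

Genes are classified by C-terminal domain content: no known domain → FBU;
exactly one of LRR/Kelch/FBA/FBD/TUB/PP2/WD40 → the dedicated subfamily
(FBL/FBK/FBA/FBD/FBT/FBP/FBW); any other single known domain (e.g.,
Actin) or more than one known domain → FBO. Domain names absent from the
map are treated as "other known" by default (configurable to be an
error). The rule is total: every gene receives exactly one of the nine
labels.

## Protein physical properties

Molecular weight is the sum of average residue masses plus one water
(Biopython's table). The theoretical pI solves net charge = 0 by
bisection (to |charge| < 1e-4) of the Henderson–Hasselbalch sum over the
termini and ionizable side chains using the EMBOSS pKa set (N-term 8.6,
C-term 3.6, C 8.5, D 3.9, E 4.1, H 6.5, K 10.8, R 12.5, Y 10.1). Web
tools differ in pKa tables; fixing one published set keeps results
reproducible.

## Phylogeny

p-distance with pairwise deletion: for each sequence pair, columns where
either member carries a gap are dropped and the distance is mismatches
over remaining columns; a pair with no comparable column is an error
naming the pair.

Neighbor joining follows Saitou & Nei in the Studier–Keppler form.
Taxa are processed in sorted-label order and Q-matrix ties break at the
lowest (row, column) index, so the output does not depend on input row
order; for tie-free additive matrices the generating topology and branch
lengths are recovered exactly (verified to 1e-9 against a random
additive-tree generator, and cross-checked against scikit-bio's
independent NJ). Negative branch-length estimates are clamped to zero
and the clamped deficit is logged, mirroring common tree-viewer behavior.

Bootstrap supports resample alignment columns with replacement, rebuild
each replicate through the same p-distance + NJ path, and report the
percentage of usable replicates containing each internal bipartition
(canonical two-sided leaf-set comparison, integer percentages).
Replicates in which a pair loses all comparable columns are dropped and
counted. Note one consequence of deterministic tie-breaking: a replicate
that collapses several taxa to zero distance resolves its ties by label
order, so bootstrap supports are exactly invariant under order-preserving
renamings but can shift by a few replicates under arbitrary relabelings
of degenerate data.

## Duplication analysis

Candidate paralog pairs are cherries (two leaves on one internal node);
cherries are disjoint, so each gene joins at most one pair. A pair is
kept when its subtending edge support exceeds 90%, global BLOSUM62
alignment identity (matches over non-gap-pair columns) exceeds 0.70, and
coverage (aligned columns over the longer protein) exceeds 0.80.
Non-cherry relationships are reported separately as rejected candidates,
not counted as pairs.

Classification: same chromosome within 20 locus ranks → tandem;
different chromosomes → segmental; same chromosome beyond the window →
"dispersed" (a third class rather than forcing the binary onto a case
its definition does not cover); genes on scaffolds/unplaced contigs →
undetermined. "Within 20 loci" is gene-count distance (locus rank), not
base pairs.

Ka/Ks uses the Nei–Gojobori (1986) unweighted-pathway method: per-codon
synonymous site fractions (mutations to stops counted as nonsynonymous),
site counts averaged between the two sequences, differences per codon
averaged over all minimal pathways excluding those through stop codons
(falling back, flagged, to all pathways when every one hits a stop), and
the Jukes–Cantor correction K = −¾ ln(1 − 4p/3) applied to both
proportions (switchable to raw proportions). p ≥ 0.75 is reported as
saturated with an explicit flag, never silently NaN. Codons containing
gaps or ambiguity codes are skipped pairwise. The implementation is
verified against an independent brute-force enumerator to 1e-9.

Dating: T = Ks / (2λ) with λ = 6.1 × 10⁻⁹ synonymous substitutions per
site per year (the standard plant nuclear clock), exposed as a
parameter. Selection: Ka/Ks < 1 purifying, > 1 positive, with an
optional neutral band around 1; Ks = 0 with Ka > 0 is called positive
with an infinite-ratio flag; Ka = Ks = 0 is undetermined.

## Expression analysis

Matrices are log2(value + pseudocount) transformed (pseudocount default
1; all-zero rows optionally dropped first). Tissue clustering is
agglomerative with average linkage on 1 − Pearson correlation distance —
neither is canonical for such surveys, so both are parameters — cut into
k groups (default 6). BH FDR is the standard step-up adjustment
(delegated to statsmodels; verified against the literal definition to
1e-12).

DE calling: fold change is the pseudocount-stabilized ratio of condition
means; the p-value is a two-sided Welch t-test on log2 values, or
precomputed p-values can be passed through (public RNA-seq datasets
usually ship p-values from count-based models whose exact form is not
reproducible here). A gene is called when |log2 FC| > log2(2) and FDR <
0.05 — two-sided, so 4-fold down counts like 4-fold up. An optional
variance-ratio filter (threshold 20) masks genes with wildly unequal
replicate variances.

Power note: an unmoderated Welch test on 3 + 3 replicates has ~4 degrees
of freedom, capping its attainable p-values near 0.005 at 4-fold changes
— too weak to survive BH correction across thousands of genes at any
dispersion. The package's power study therefore uses 6 replicates per
condition at dispersion 0.1 (recall ≈ 0.95 for |log2 FC| = 2 among 2000
genes), while the null false-discovery simulation uses the 3 + 3 design
(fraction of null runs with any call ≈ 0.01–0.05). With few replicates a
moderated test (limma/DESeq2-style) or pass-through p-values should be
preferred; that is exactly why the pass-through mode exists.

qPCR: ΔCt = Ct_target − Ct_reference per sample; ΔΔCt = mean
ΔCt(condition) − mean ΔCt(control); relative expression = 2^−ΔΔCt,
computed from condition means of ΔCt (replicates are biological pools).
Per-condition significance is a two-sided t-test of replicate ΔCt against
control. The estimator is exactly invariant to plate-wide Ct offsets and
recovers planted fold changes exactly on noise-free tables.

## The simulator

The generator emulates the inputs of a genome-wide family survey with
full ground truth:

- **Motif model**: per position, one consensus residue at a frequency
  drawn from [0.55, 0.9], the remainder spread as background — a
  caricature of a ~48-residue family motif. Seed alignments and planted
  motif instances are both sampled from it, so observed conservation
  converges to the generating frequencies.
- **Codon evolution**: each lineage of a duplicate pair accrues
  substitutions as a Poisson process — synonymous events at rate λ per
  NG86 synonymous site and nonsynonymous events at ω·λ per nonsynonymous
  site; proposals creating stops are rejected and redrawn. This inverts
  the dating formula: before saturation the expected pairwise pS is
  2λT, so recovered ages and Ka/Ks can be checked against the planted T
  and ω (measured: mean Ks within a few percent of 2λT at T = 10 Mya,
  300 codons).
- **Loci**: tandem pairs occupy adjacent loci on one chromosome (rank gap
  1 ≤ 20); segmental pairs sit on different chromosomes; everything else
  is placed uniformly at random. Locus rank is the 1-based ordinal of
  gene start per chromosome.
- **Domains**: family genes cycle through ten archetype domain lists
  covering all nine subfamilies; duplicate partners share domains.
- **Expression**: gamma-Poisson (negative binomial) counts with
  log-normal baselines (log2 mean 6, sd 1.5), gene dispersion 0.3 by
  default; planted genes' condition means are shifted by the planted
  log2 fold change. The default designs mirror a 14-tissue atlas and a
  salt time course (0/1/6/12 h × 3 replicates).
- **qPCR**: Ct = base − log2(abundance) + Gaussian noise, reference gene
  constant across conditions.

What the simulator does **not** emulate: real synteny and collinearity
(segmental pairs are placed, not derived from duplicated blocks), intron
structure and alternative splicing, motif insertions/deletions (planted
motifs are gap-free, so the scan calibration is optimistic about indel
divergence), sequencing-depth composition effects, or the correlated
noise structure of real RNA-seq. Passing tests demonstrate internal
correctness and recoverability under the stated models, not performance
on any particular real genome; headline counts from real surveys depend
on database versions and annotation tools and are deliberately out of
scope.

## Problem sizes and numerics

The default verification scale — chosen to keep the whole suite fast on
one CPU — is: 40 family + 100 background genes of 300 codons with 10
tandem and 10 segmental pairs; 200 bootstrap replicates in tests (1000
remains the pipeline default); 100 random additive matrices of 5–8 taxa;
500 random codon-aligned pairs of 50–300 codons against the Ka/Ks
oracle; 1000 random p-vectors against the BH oracle; 200 Monte-Carlo
null DE runs of 2000 genes. Reproducibility: a single integer seed
drives every random draw through numpy Generators; reruns are
bit-identical. Degenerate inputs (all-gap columns, saturated p, zero-
variance replicates, incomparable pairs) are handled by explicit flags
or errors rather than NaNs. File writes are atomic (temp file + rename).
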