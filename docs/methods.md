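# Methods

`crasskit` reimplements, as a tested pipeline, the analysis chain used to
characterize crAss-like phages in gut metagenomes: viral-contig retention,
dual-route crAss identification, species-rank dereplication into vOTUs,
TerL-tree family classification by MRCA label propagation, genetic-code and
genome-structure characterization, CRISPR-spacer host linkage, and
coverage-gated RPKM quantification with two-group association. Because the
real inputs (hundreds of public metagenomes and external predictor
databases) are not reproducible at desk scale, every stage is validated
against a synthetic community generator that plants all ground truth.

## The synthetic community

`crasskit.simulate` builds a community from a single integer seed; the same
spec and seed reproduce every file byte-for-byte. The default spec is the
fixture used throughout the tests and by `scripts/acceptance.py`:

- **20 phage genomes** drawn between 70 and 110 kb (zeta-family genomes
  scaled 1.5x longer, mirroring the much larger genomes of that cluster),
  plus 2 mutant genomes (2% substitution copies of the first two phages,
  with nonsense substitutions in genes reverted — purifying selection) that
  must co-cluster with their parents, plus 3 marker-free decoy contigs.
- Each genome carries the five landmark genes in the canonical order
  IHF_54 … MCP … portal … TerL … primase, with family-specific filler-gene
  counts between them (alpha/delta: many genes between IHF_54 and MCP, few
  between MCP and portal; beta/zeta reversed; zeta with a large
  TerL–primase replication block). A polymerase gene derived from the
  UGP_018 signature is also planted. Marker coding sequences are drawn from
  synthetic consensus proteins shipped as package data, mutated ~20% per
  family and ~5% per genome, giving ≥ 25% TerL divergence between families.
- **Genetic codes**: each genome is assigned code 11, 15 (TAG→Q) or 4
  (TGA→W) from a configurable mixture. In recoded genomes half the filler
  genes use the reassigned stop for a random half of their Q (or W)
  codons, and a suppressor-tRNA cassette (anticodon CTA for code 15, TCA
  for code 4) is inserted. Landmark and signature genes are never recoded,
  so the signature route stays exercised on recoded genomes; the six-frame
  structural route covers recoded genes by construction.
- **30 bacterial genomes** (40 kb backbones; Bacteroidota-weighted
  7-rank taxonomy strings) carry 1–2 CRISPR arrays of identical 28–32 bp
  repeats and 30–35 bp spacers. Half the spacers are copied from random
  phage positions on either strand with 0 or 1 planted substitutions
  (true links); every array also carries one 2-substitution decoy spacer
  that must never produce a link. Planted substitutions avoid the two
  outermost spacer positions so repeat-boundary jitter in the detector
  cannot change a spacer's Hamming distance.
- **16 samples in an 8 fat / 8 lean design**, 30,000 substitution-only
  reads of 150 bp per sample (error rate 0.005). Per-genome base relative
  abundances are lognormal(0, 1) with lognormal(0, 0.3) per-sample jitter;
  the two effect vOTUs get planted log2 fold-changes (+2 and −2 by
  default) in fat samples, and are floored at 1.5x the median base
  abundance so the fold-change, not the detection gate, carries the
  signal. The generator records the true per-sample covered fraction of
  every vOTU representative from the planted read positions, so detection
  calls can be compared exactly.

What the generator does **not** emulate: real crAssphage sequence
composition and GC skew, indel sequencing errors, strain mixtures within a
vOTU beyond uniform substitution, provirus boundaries, or bacterial reads.
Passing tests therefore demonstrate that the decision rules and algorithms
are implemented exactly and recover planted signal under clean conditions —
not that the pipeline is robust to assembler chimeras or alignment noise in
real data.

## Stage-by-stage notes

**Retention and detection.** The four retention criteria use the printed
boundary conventions exactly (≥ for the high score gates, strict > for the
0.7 gates, strict < for the p-value gates); missing scores fail the
criteria that need them. Route 1 calls genes under code 11 only and aligns
the two signature proteins with Smith–Waterman (BLOSUM62, gap open 11 /
extend 1, via Biopython's `PairwiseAligner`); E-values use ungapped
Karlin–Altschul statistics (λ = 0.267, K = 0.041, search space m·n) — the
1e-5 decision threshold dominates, so a full BLAST statistic is
unnecessary. A hit needs E < 1e-5 and ≥ 350 aligned residues (the source
criterion prints "350 bp" for protein hits; residues is the only coherent
unit, and the gate is configurable). Route 2 six-frame translates with
stops masked to X, splits on X runs into peptides ≥ 50 aa, and scans
position-specific log-odds profiles (PSSMs built from seed alignments with
0.5 pseudocounts over a uniform background) for the three conserved
structural proteins. Each profile's hit threshold is calibrated once as
the 99.9th percentile of best-placement scores over 10,000 seeded
composition-matched random proteins (null length at least 500 aa so the
per-protein false-hit rate transfers to real gene calls). The two routes
are combined as a union by default ("combined" read disjunctively);
an intersection mode is available.

**Clustering.** ANI/AF comes from k-mer (k = 15) anchored, per-diagonal
chained gapless blocks: ANI is column-weighted identity over blocks, AF is
the merged aligned span divided by the shorter genome's length (the
dereplication-style choice; a query-based alternative would change
borderline cases). Greedy centroid clustering scans genomes longest-first
(ties lexicographic), joining the first centroid with ANI ≥ 95 and
AF ≥ 85; the canonical scan order makes the partition input-order
invariant, and representatives are the longest members by construction.

**Phylogeny and taxonomy.** The TerL tree uses a deliberately simple
stack — progressive MSA (UPGMA guide tree on 3-mer Jaccard distances,
profile–profile Needleman–Wunsch with BLOSUM62 and linear gap 4),
p-distances over gap-free column pairs, canonical Saitou–Nei neighbor
joining (negative branches clamped to zero with the deficit moved to the
sibling), and midpoint rooting — because the scientific content being
exercised is the MRCA propagation rule, not tree search. Pre-built Newick
trees can be supplied instead. For each family, the MRCA of its reference
leaves is found; every descendant leaf is assignable to that family;
leaves under nested labeled MRCAs take the smallest enclosing clade (the
reference clades in the source analysis were disjoint, so this tie rule is
this package's choice); leaves under no labeled MRCA are unclassified and
dropped from downstream family tables after assignment. NJ correctness is
pinned by the additivity theorem (exact recovery of random additive trees)
and cross-checked against scikit-bio; midpoint rooting is checked against
the half-diameter optimum and dendropy.

**Genetic codes and genome features.** Code inference calls ORFs
(ATG-to-stop, min 60 aa) under codes 11, 4 and 15 and compares coding
density (union of ORF spans / genome length); an alternative code must
beat code 11 by δ = 0.05 to be called, which protects standard-code
genomes against the small density gain smaller stop sets always enjoy.
Suppressor tRNAs are found by ≥ 90%-identity template matching against the
package's synthetic tRNA template (anticodon positions excluded from
scoring), reading the anticodon at the template's fixed offset — a
pattern stand-in, not covariance-model scoring. Marker annotation labels
ORFs ≥ 100 aa with the best profile above threshold and then resolves
overlapping reading frames greedily and strand-aware (marker-labeled
first, then longer; drop an ORF once more than 75% of it overlaps kept
genes, or more than 50% overlaps kept genes on the opposite strand). The
asymmetry matters: a same-strand call that runs through a chance
stop-free stretch into its neighbor is a legitimately extended gene,
while a deep opposite-strand overlap is almost always a spurious mirror
frame — such frames would otherwise displace short real genes like
IHF_54. The rule is symmetric under reverse complementation. Gene-block counts use the gene-midpoint rule
strictly between the two flanking markers, the shorter arc on circular
genomes, and are undefined when a marker is missing (as for primase in
epsilon-cluster genomes). Rank-sum comparisons are two-sided: exact by
full enumeration of labelings when n + m ≤ 10 (correct under ties), else
the tie- and continuity-corrected normal approximation.

**Host linkage.** CRISPR arrays are found CRT/MinCED-style: a k-mer seed
recurring ≥ 3 times at array-like spacing is extended across all copies
(≤ 1 internal mismatch per copy tolerated; boundary columns with any
mismatch trimmed), with repeat length 23–47, spacer length 17–50, spacer
count = repeats − 1, and overlapping candidates resolved to the higher
repeat count. Spacer matching is an exhaustive Hamming scan of both
strands with ≤ 1 mismatch over the full spacer — the published criterion
is exactly a Hamming condition, so no heuristic aligner is needed and the
scan is provably exact (no indels by construction). Hits aggregate to
vOTU × bacterial genome with taxonomy joined and per-vOTU genus breadth
(single- vs multi-genus).

**Quantification and association.** Reads map gaplessly by 31-mer
seed-and-extend against the vOTU representatives (stride-4 seed index, all
read offsets tried until a perfect placement is found, best identity wins
with ties to the first representative in canonical order). Alignments
under 90% identity or under 95% of the read length are dropped. RPKM is
count × 10⁹ / (genome length × total reads). The two published coverage
clauses are implemented literally: abundance is zeroed only when the
covered fraction is **< 75%**, while detection requires **> 75%** — an
exactly-75% cell keeps its abundance but is not detected; both boundaries
are unit-tested. Association is a MaAsLin-style per-feature model:
total-sum scaling, y = log2(x + half the minimum nonzero value), per-vOTU
linear regression on the group indicator, BH correction, signed score
−log10(q)·sign(coeff) (log base 10; the source figure omits the base), and
significance at q < 0.05 (configurable). Only features observed in at
least half the samples are tested: with the coverage gate zeroing sparse
features, the linear model's p-values are calibrated (label-permutation
p-values uniform by KS) only for well-observed features; this mirrors
MaAsLin's prevalence filtering, tightened for small cohorts.

## Problem sizes and numerical choices

The default community (20 + 2 phage genomes, 30 bacteria, 16 × 30,000
reads) runs end-to-end in a few minutes on one CPU; the code-recovery
study uses 300 planted-code genomes of ~70 kb, and oracle-equivalence
suites use 500 random instances per primitive at small sizes where the
brute-force oracles are exact. Deterministic tie-breaking is used
everywhere (first-occurring, then lexicographic); all randomness flows
from a single integer seed through fixed stream offsets; coordinates are
0-based half-open in memory and 1-based inclusive in GFF3.

## Known limitations

- The mapper is gapless and substitution-only, matched to the read
  simulator; real data should enter through the PAF/alignment import path
  rather than the internal mapper.
- PSSM search is ungapped and full-profile-width, so a profile cannot hit
  a fragment shorter than itself; recoded genomes are still detected
  because detection uses the union of two routes.
- The E-value statistic is ungapped Karlin–Altschul, adequate for a
  decision threshold of 1e-5 but not for ranking marginal hits.
- MRCA propagation requires reference leaves to span at least the
  diversity of the query leaves; with too-narrow references, queries fall
  outside every labeled clade and are (correctly) unclassified.
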