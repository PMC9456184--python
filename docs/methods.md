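# Methods

## Scope

`lncsponge` reimplements, at desk scale, an in-silico workflow for
identifying consensus lncRNAs across multiple assembled tick transcriptomes
and ranking them as candidate sponges of host miRNAs. Upstream read
processing (QC, trimming, de-novo assembly, read mapping and quantification)
is out of scope: assembled transcript sets and an expected-count matrix are
inputs. External web-service enrichment (KEGG/pathway analysis of targeted
miRNAs) is out of scope; the pipeline exports ranked miRNA lists for such
tools instead.

## Transcript classification

An ORF is an `ATG..stop` span; every ATG opens a candidate closed by the
first in-frame stop, scanned in all six frames (assembled contigs have
unknown orientation; `both_strands=False` restricts to the forward strand).
ORFs without a stop codon are discarded — a deterministic, conservative
convention. "Longer than 50 amino acids" is read strictly (`aa_length > 50`,
stop excluded); the boundary is covered by a test.

The homology gate defaults to a precomputed hit table (two-column TSV:
transcript id, 0/1) so that results of an external protein-database search
can be injected. The built-in alternative is Smith-Waterman local alignment
with BLOSUM62, gap open 11 / extend 1, calling a hit at raw score ≥ 60;
raw-score thresholding stands in for a database E-value cut-off because
Karlin-Altschul calibration is deliberately out of scope. A transcript is
coding iff it has a qualifying ORF *and* the gate fires; the partition is
exhaustive and disjoint. lncRNA candidates are the noncoding transcripts
with 200 ≤ length ≤ 1800 nt — the bounds are read inclusively and are
configurable.

## Consensus clustering

Clustering follows CD-HIT's greedy incremental algorithm: sequences sorted
by length descending (ties by id), each joining the first cluster whose
*representative* it matches, else founding a new cluster. Membership is
checked against representatives only — true CD-HIT semantics, keeping the
cost at O(n·k). The match criterion is a global alignment of the shorter
sequence against the longer with free end gaps on the longer (match +1,
mismatch −1, gap −2): identity = matches over the columns spanned by the
shorter sequence, coverage = fraction of the shorter aligned to residues of
the longer; thresholds 0.98 and 0.80. An 8-mer prefilter skips alignments
whose shared-k-mer count cannot reach the identity/coverage thresholds; the
bound is deliberately slack (a factor-two margin over the worst case) and a
property test asserts the prefiltered clustering is identical to the
unfiltered one.

A cluster is *consensus-eligible* when its members include at least one
sequence from the midgut+salivary-gland source and at least one from the
salivary-gland-only or whole-body sources; the consensus sequence is the
longest member regardless of source (ties by id). The stricter reading — the
representative must itself come from MG-SG — is available behind
`require_mgsg_representative`. Coding RNAs run through the identical
clustering/consensus path.

## Expression and differential expression

FPKM = count / (length/1000) / (library/10⁶). The expression filter keeps a
transcript if it reaches ≥ 5 FPKM in *every* sample of at least one group,
where the groups are: all unfed samples, and the fed samples of each
timepoint (all fed samples when no timepoint is recorded).

TMM normalization follows Robinson-Oshlack: reference = sample whose
upper-quartile library-scaled count is closest to the mean upper quartile;
M- and A-values on transcripts positive in both samples; two-sided trimming
of 30% on M and 5% on A using average ranks; precision weights from the
asymptotic (delta-method) variance of M; factors rescaled to geometric mean
one. Factors are permutation-equivariant and multiply to one.

The common NB dispersion is estimated by the method of moments on counts
scaled to a common effective library size: per transcript, pooled
within-group variance s² and mean m give φ_t = max(0, (s²−m)/m²); the
estimate is the median of φ_t over transcripts with m > 1 — simple, robust
to the DE minority, and validated by parameter recovery (planted φ = 0.2
recovered within [0.1, 0.3]; Poisson data give ≈ 0).

Differential expression uses the classic two-group exact NB test with a
single common dispersion (not tagwise or GLM flavours — the exact test is
fully specifiable and testable by enumeration). Counts are scaled by
factor × library size to the geometric-mean effective size and summed per
group (sums rounded to integers); conditional on the total t, with
μ = t/(n₁+n₂), group sums are modelled NB(n_g μ, φ/n_g) (a sum of n i.i.d.
NB(μ, φ) variables), and the two-sided p-value adds the probabilities of
all splits no more probable than the observed one. At φ = 0 this reduces to
the binomial-conditioned Poisson exact test. log2FC is fed over unfed on
normalized group means with a prior count of 0.125 per group to avoid
infinities at zero. Calls use BH-adjusted p-values at α = 0.05 (the
workflow this emulates states no threshold; 0.05 is the conventional
default and is configurable). Type-I error at nominal 0.05 is 0.05–0.06 in
a 2000-transcript null simulation (φ = 0.1, 4 vs 4).

The small default pipeline panel (~50 consensus features, most planted
sponges forced up-in-fed) inflates the pipeline's own DE percentages:
normalization over a tiny, asymmetrically DE feature set cannot fully
absorb the composition shift. This is a property of the miniature panel,
not of the test — at 1000 features with sign-balanced DE the observed FDR
is ≤ 0.07 (measured by the acceptance script).

## Target prediction

Seed matching scans the lncRNA sense strand (miRNA targeting acts on the
mature transcript) for exact reverse complements of miRNA positions 2-7 and
classifies each match upward: pairing through position 8 gives 7mer-m8, an
`A` in the target opposite position 1 gives 7mer-A1, both give an 8mer.
Overlapping sites at distinct starts are counted separately, matching the
count-based sponge scoring downstream.

The hybridization stage aligns the full miRNA antiparallel to a window
extending 30 nt 3′-ward of the seed site: Watson-Crick pair +5, G:U wobble
+2, mismatch −3, gap open −8 / extend −2 (affine Gotoh), with pair scores
doubled at miRNA seed positions 2-8; negative best scores are reported
as 0. A site is a *consensus* site when the seed type reaches
`min_site_type` (default 7mer: 6mers never qualify) and the hybridization
score reaches `min_hybrid_score`. The default threshold is 70 — exactly the
score of a perfectly paired seed at positions 2-8 — so every well-formed
7mer-m8 or 8mer site passes deterministically, while 7mer-A1 sites must
earn the balance through productive 3′ pairing. A machine-learned third
predictor was considered and rejected (no principled weights to ship);
two-of-two agreement between the seed and hybridization stages plays the
role of a multi-algorithm consensus.

The shuffled null repeats the identical prediction on shuffled copies of
every lncRNA. The default shuffle is a mononucleotide permutation (the
behaviour of the classic `shuffleseq` tool); a dinucleotide-preserving
Euler-path shuffle is provided because seed-site statistics are sensitive
to dinucleotide composition. The null replicate count defaults to 19, so
the smallest attainable permutation p-value is 1/20 = 0.05.

## Sponge detection

Three rankings: maximum consensus-site count for a (miRNA, lncRNA) pair;
maximum sites per kb (count × 1000 / length); and Apriori frequent
itemsets over the binarized matrix (transactions = lncRNAs, items =
miRNAs, support = number of lncRNAs targeted by every member). Minimum
support defaults to max(3, 5% of lncRNA transactions). Ties in the two
single-pair rankings break lexicographically on (lncRNA id, miRNA id).

Itemset significance is the permutation estimator p = (1 + r)/(1 + n),
where r counts null replicates whose support reaches the observed one —
never zero, standard for permutation nulls — BH-adjusted across itemsets.
The final report takes the max-count pair, the max-density pair, and up to
three significant itemset groups chosen greedily by ascending p subject to
pairwise-disjoint supporting lncRNA sets. p-ties are broken toward larger
itemsets, then larger support: by downward closure every subset of a
co-targeting combination attains at least its support (and here the same
p), and the maximal combination is the informative sponge group. Candidate
lncRNAs are annotated with per-tissue log2 fold changes (the heat-map
table).

The per-miRNA normalized target ratio divides each set's target totals by
the set maximum — with a pseudocount of 1, since the ratio is undefined at
zero — and ranks miRNAs by N_fed/N_unfed; the top 3 per tissue are flagged
for downstream pathway analysis.

## Synthetic data generator

The generator emulates the study design end to end and is the pipeline's
acceptance surface. Defaults (all configurable): 60 transcript clusters,
60% coding (roughly the published consensus coding/lncRNA ratio), lengths
uniform on 300-1500 nt, source-presence probabilities (0.9, 0.7, 0.6) for
(MG_SG, SG, WB), substitution rate 0.005 between same-cluster copies,
20 miRNAs of 22 nt with a 5′ U (the dominant first base of real mature
miRNAs), two tissues × (unfed, fed) × 6 replicates, NB dispersion 0.15,
25% planted DE at |log2FC| = 2 with random sign, per-sample library-size
factors log-uniform on [0.5, 2], and a planted sponge structure: one
high-count lncRNA (10 sites for one miRNA), one high-density lncRNA
(8 sites in 400 nt), and three disjoint groups of four lncRNAs, each group
co-targeted by a distinct miRNA triple (2 sites per miRNA per lncRNA).
lncRNA base expression is scaled so lncRNAs carry ≈ 30% of total
expression in the unfed state. Planted sponge clusters are forced into
MG_SG and SG (so they survive consensus selection) and planted up-in-fed.

Background sequence is i.i.d. uniform over {A,C,G,T} — the simplest null
compatible with seed-site statistics. Planted ORFs occupy frame 0 of the
forward strand (deterministic, verifiable by the six-frame oracle);
noncoding cluster sequences are rejection-sampled until free of ORFs
> 50 aa. Three deliberate idealizations make planted truth exact rather
than probable, and should be kept in mind when generalizing test results
to real data:

- same-cluster copies receive exactly round(rate × length) substitutions
  (random positions, fixed count), bounding pairwise divergence at 2 × rate
  so planted clusters cannot straddle the identity threshold;
- planted ORF and seed-site windows are masked from substitution, so every
  copy provably retains its class and its sites at the recorded
  coordinates;
- planted sites are exact seed complements in random background — real
  sites sit in conserved, composition-biased context.

The generator also omits splice isoforms, assembly artifacts and chimeras,
fragmented/truncated contigs, expression correlation between transcripts,
and read-level noise; passing planted-recovery tests therefore demonstrates
algorithmic correctness, not robustness to assembly pathology. All outputs
are byte-reproducible from the seed; each operation draws from its own
stream (seed + fixed offset) so stages can be rerun independently.

## Numerical conventions

Internal coordinates are 0-based half-open; TSV outputs print 1-based
inclusive starts. Percentages round half-up to one decimal. Empirical
p-values use (r+1)/(n+1). Tie-breaks are lexicographic and documented per
operation, making every pipeline output byte-deterministic for a given
configuration and seed. Problem sizes in the test-suite and acceptance
simulations (e.g. 2000-transcript null panels, 20-cluster recovery runs,
19 null replicates) were chosen as the smallest sizes at which the checked
statistics are stable, keeping the default runs fast on a single CPU.

## Known limitations

- The exact test equalizes library sizes by linear scaling (not
  quantile-to-quantile adjustment); with strongly unequal libraries and
  very small counts the conditional distribution is approximate.
- The hybridization score is a fixed-weight alignment, not a thermodynamic
  duplex model; scores are comparable within a run, not across scoring
  schemes.
- Clustering compares members to representatives only; as with the original
  greedy algorithm, a member can be < 98% identical to a non-representative
  member of its cluster.
- Itemset mining is exact and exhaustive above the support threshold; very
  low thresholds on large miRNA sets grow combinatorially.
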