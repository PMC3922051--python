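# Methods

This note records the models, conventions and numerical choices behind
`brine18s`, what the synthetic data does and does not emulate, and the
known limitations.

## The analysis being reconstructed

The pipeline mirrors a pyrosequencing survey of eukaryotic 18S rRNA
V1–V3 amplicons from seven habitats in and around a deep-sea brine pool:
multiplexed 454 reads are demultiplexed by 8-nt barcodes, quality
filtered, screened against false-positive (non-rRNA) amplification,
clustered into OTUs at two dissimilarity levels (3% for diversity, 20%
for phylogenetic placement), summarised as rarefied alpha-diversity
indices, placed *de novo* on a neighbor-joining tree against a
23-kingdom reference panel, and compared across samples by Bray–Curtis
dissimilarity and principal-coordinates analysis of the per-clade read
percentages. Raw flowgram denoising, chimera removal and database
(classifier-based) taxonomy are out of scope: they belong to external
tools in the original protocol and are orthogonal to the stages built
here.

## Synthetic reads and ground truth

The generator is the test bed for everything downstream, so its contract
is exact bookkeeping rather than maximal realism.

**Reference panels.** One random ancestor sequence per panel; per-kingdom
roots are mutated from it at rate `inter/2` (pairwise root divergence ≈
`inter`), members from their root at `intra/2`. The forward primer
occupies the template start and the two probes sit at fixed offsets
(Euk381 at min(180, L−80), Euk422 41 nt downstream, echoing their true
spacing); these windows are never mutated. Homopolymer runs > 6 bp in a
template are broken by substitution — a template that itself violates the
homopolymer rule could never yield passing reads.

**Reads.** `barcode + template[0:insert_length]` with insert length
uniform between "probes + margin" and full template length; substitutions
at `substitution_rate` (default 0.005 → reads of one template are ~1%
apart) outside the conserved windows; ±1 indels at homopolymer runs ≥ 3 nt
(per-run rate 0.01), the dominant 454 error mode. Qualities decay
linearly from Q38 at the first base to Q28 at the last, ±2 jitter. The
decay floor sits above the Q25 filter threshold deliberately: with a
lower floor every full-length read would fail the 50-bp windowed-mean
rule and no clean class would exist; planted `LOWQ` reads instead carry
an explicit 50-bp Q10 window.

**Planted violations.** Each read carries at most one violation; class
counts are ⌊fraction × n⌋ with the remainder clean, assignment permuted by
the run's RNG. False amplicons are `primer + random sequence`
rejection-sampled to be ≥ 3 mismatches from both probes at every offset,
so the probe screen's classes are separable by construction and its
precision/recall against ground truth must be exactly 1. Because errors
spare the conserved windows, the observed read–template Hamming distance
is `substitution_rate × (mutable positions)`, and the generator's
property test uses that effective length.

**Not emulated:** flowgrams/SFF, chimeras, reverse-orientation reads (off
by default behind `reverse_complement_fraction`), and the real taxonomic
composition of the brine-pool samples. Passing tests therefore demonstrate
algorithmic correctness on controllable inputs, not fidelity to the
original deposited reads.

## Read QC

Filters run in a fixed order — barcode, mean quality < 25, any 50-bp
window with mean quality < 25, ≥ 1 ambiguous base, length < 150 nt,
homopolymer > 6 bp, complete-primer check, probe check — and each read is
charged to the first failing rule, so `input = qualified + Σ rejected`
holds per sample. The legacy "average flowgram score < 25" is read as
mean Phred quality < 25 from FASTQ; the "quality window of < 50 bp"
becomes rejection when any sliding 50-bp window falls below the same
threshold (rejection, not truncation, to keep read identity stable).
Barcode and primer matching are exact — the protocol demands a *complete*
barcode and primer — while probes tolerate ≤ 2 mismatches via a
Hamming-window scan (no indels; `N` counts as a mismatch). The reverse
primer 564R is stored but not searched: 454 reads frequently end before
reaching it. Coordinates are 0-based half-open; sequences uppercase.

## OTU clustering

Greedy abundance-ordered centroid clustering: unique sequences sorted by
decreasing total count (ties: longer first, then lexicographic) join the
first centroid with pairwise identity ≥ 1 − level, else found a new one.
Alignments use match +1 / mismatch −1 / gap −2 with **free terminal
gaps**: 454 reads of one template differ mainly in where they end, and
penalised end gaps make an optimal global path scatter a short read's
tail through a longer read instead of leaving one clean terminal gap.
Identity is matches / columns with terminal-gap columns excluded, so
length differences do not dominate at the 20% level. A q-gram prefilter
(k = 8, error budget ⌈level × (len_a + len_b)⌉ via the q-gram lemma) skips
alignments that provably cannot reach the threshold; the test suite
asserts the output is identical with the prefilter on and off.
Representatives are the most-abundant member (ties: centroid, then
lexicographic); singleton OTUs (total count 1) can be dropped, as done
before phylogenetic placement.

## Diversity

Samples are rarefied to the smallest library by a multivariate
hypergeometric draw (one seeded draw by default; averaging over R draws
is available). Shannon uses log₂ (base e behind a flag — the convention
is not universal); Chao1 is the bias-corrected form
S_obs + n₁(n₁−1)/(2(n₂+1)), defined also when doubletons are absent, with
the classic n₁²/(2n₂) form behind a flag; Good's coverage is 1 − n₁/N.

## Phylogenetic placement

**Alignment.** Progressive profile–profile alignment along a UPGMA guide
tree built from shared 6-mer distances; column base-frequency profiles are
scored with the same match/mismatch scheme, linear gaps, free ends.
Columns beyond the reads' extent (end blocks with > 90% gaps) are trimmed,
emulating the original trimming of the alignment downstream of the reads.

**Distances.** Jukes–Cantor, d = −¾ ln(1 − 4p/3), on columns where both
rows have bases; p ≥ 0.75 saturates at d = 5.0. Pairs sharing fewer than
20 columns are flagged unreliable and assigned the cap: a distance
estimated from a handful of columns carries no signal, and capping pushes
such sequences onto long branches where the NOVEL rules catch them.

**Trees.** Canonical Saitou–Nei neighbor joining; Q-criterion ties break
at the smallest index pair; negative limb lengths are clamped to zero
with the deficit moved to the sibling edge, preserving pairwise path
lengths (NJ therefore stays exact on additive matrices, which the tests
verify to 1e−9). Bootstrap resamples alignment columns with replacement;
the support of each internal bipartition of the full-data tree is the
fraction of replicate trees containing it. Tests use 100 replicates, the
CLI default is 1000.

**Clade assignment.** The tree is midpoint-rooted (no outgroup is defined
for the global tree). Each query takes the kingdom set of the smallest
ancestral clade with support ≥ 0.5 containing at least one reference —
the 0.5 threshold mirrors the posterior-probability acceptance rule used
with Bayesian consensus trees, and NJ + bootstrap replaces the original
Bayesian stage because clade membership, not branch-length inference, is
what downstream consumes. A query is NOVEL when that clade is the whole
tree, or when its terminal branch exceeds the 95th percentile of
reference terminal branches — a reproducible stand-in for the manual
"long branch" judgement, guarding against long-branch attraction. With
queries drawn from the same divergence distribution as the panel this
flag trims ~5% of genuine placements, which is the main cost in the
≥ 90% recovery check. A `drop_ids` hook excludes named representatives,
replacing manual alignment curation.

## Ordination

The clade matrix rows (percentages summing to 100) are compared with
Bray–Curtis; "PCA on a Bray–Curtis input" is performed as classical
metric scaling (PCoA): eigendecomposition of −½ J D² J. Negative
eigenvalues — possible for non-Euclidean Bray–Curtis — are reported
unchanged and excluded from variance-explained denominators (no Lingoes
correction by default); axis signs are fixed by making the
largest-magnitude coordinate positive. A covariance PCA of the raw
percentages is available for comparison. Group separation is the mean
silhouette over samples on the first two axes.

## Pipeline and reproducibility

Stage order: simulate/load → QC → cluster 3% → diversity → cluster 20% →
drop singletons → classify → ordinate. Per-stage seeds are the first four
bytes of BLAKE2b("{master_seed}:{stage}") mod 2³¹, so a stage can be
re-run in isolation. All tables are TSV with a `#` header line; trees are
Newick with supports as internal labels. The manifest records per-stage
counts and SHA-256 digests of every output; two runs from one config are
byte-identical.

## Problem sizes

The bundled designs are sized for deskside iteration: QC oracle fixtures
of ~5,000 reads; clustering designs of ~350 qualified reads from 10
templates (5 kingdoms × 2, within-kingdom template divergence 12% —
distinct at 3%, merged at 20%); placement panels of 23 kingdoms × 5
references (~400 nt) with 100 planted and 5 unrelated queries at 100
bootstrap replicates; pipeline fixtures of 40–60 reads per sample over
5–6 kingdom panels.

## Known limitations

- Greedy clustering is order-dependent by design; its contract is the
  recorded ordering, not equivalence to any external tool. Reads whose
  error draw exceeds ~3% from their template's centroid can found spurious
  OTUs (always pure, occasionally splitting a template).
- Progressive alignment is heuristic; no iterative refinement.
- Jukes–Cantor ignores rate heterogeneity and base composition; it is the
  deliberate minimal model for the placement stage.
- The long-branch NOVEL rule depends on the reference panel's terminal
  branch distribution; panels of closely related references make it
  stricter.
- Good's coverage and Chao1 are reported per rarefied draw; with R = 1
  they inherit that draw's sampling noise.
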