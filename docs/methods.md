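# Methods

This note records the models and procedures implemented in `centrosat`,
the parameters that matter, the design choices that were genuinely open,
and what the synthetic-data experiments do and do not demonstrate.

## Telomere scanning

Plant telomeres are tandem arrays of the heptamer TTTAGGG on the G-rich
strand; chromosome 5' ends therefore expose the reverse-complement family
(rotations of CCCTAAA, which include the conventional search query
AAACCCT) and 3' ends the forward family. `count_terminal_repeats` counts
non-overlapping, greedy left-to-right matches of any of the seven
circular rotations of the appropriate family inside a terminal window.
Accepting all rotations means register shifts inside an array (e.g. after
an interstitial insertion) do not split counts, mirroring how telomere
scanners normalize their query motif.

Parameters:

* `window` (bp, default 10 000) — terminal search window. Telomere arrays
  in the genomes this targets run to a few kb per end, so 10 kb bounds the
  array comfortably; sequences shorter than two windows are scanned with
  half-length windows and flagged `truncated`.
* `min_copies` (default 20) — presence threshold. Real per-telomere counts
  in T2T plant assemblies are reported in the hundreds to thousands, so 20
  sits far below genuine telomeres and far above background. The expected
  background rate of the 7-rotation family on random sequence is
  7/4⁷ ≈ 4.3·10⁻⁴ per bp, i.e. ≈ 4 hits per 10 kb window — well below the
  threshold, and the scan's specificity on motif-free sequence is tested
  empirically at that level.

A chromosome is telomere-to-telomere (T2T) when both ends are present.

## Tandem-repeat discovery

`find_arrays` is a simplified tandem-repeat finder in the spirit of
Benson's TRF. The classic parameterization (match +2, mismatch −7,
indel −7, 80% match probability, 10% indel probability, minimum score 50,
maximum period 500) supplies the scoring weights and acceptance
thresholds; the Bernoulli-model candidate detection of the original tool
is replaced by something simpler and fully deterministic:

1. **Candidates.** Within 20-kb windows (10-kb step), positions of
   repeated 12-mers are collected; the distance between same-k-mer
   occurrences votes for a candidate period. Distances with ≥ 3 supporting
   seed pairs become candidates (k = 12 and the window size are chosen so
   100–200 bp monomers at ≤ 10% divergence still leave many surviving
   seeds; both are configurable module constants).
2. **Verification and extension.** Each candidate (period p, anchor) takes
   the anchor's p bases as a provisional consensus and walks copy-by-copy
   left and right with banded prefix alignments (edlib), accepting a copy
   while its edit distance is within (1 − 0.80)·p. A per-column majority
   vote over the collected full-length copies (ties → lexicographically
   smallest base) yields the consensus, and a second extension pass with
   the voted consensus recovers copies the (itself mutated) provisional
   copy missed. This two-pass scheme matters at high divergence: a copy
   compared to another mutated copy sits near the 80% identity floor,
   while compared to the true consensus it sits near 1 − d.
3. **Scoring and filters.** Arrays are scored per copy against the
   consensus from the edlib alignment counts
   (2·matches − 7·mismatches − 7·indels) and dropped below score 50, above
   period 500, or below 1.8 copies.
4. **Harmonic suppression.** A true array with period p also produces
   candidates at 2p, 3p, …. Candidates are processed shortest-period
   first; a candidate anchored inside an accepted array, or whose interval
   is ≥ 50% covered by accepted shorter-period arrays, is skipped.
   Overlapping same-period (±1) calls from adjacent windows are merged and
   re-scored over the union.

Monomers are canonicalized as the lexicographic minimum over all
rotations of the consensus and of its reverse complement, making
downstream comparisons register- and strand-invariant; both strands are
handled by this canonicalization rather than by a second scan.
`filter_monomers` keeps arrays with periods in 100–200 bp, the length
band of plant centromeric satellite monomers.

Scoring caveat: when copies differ from the consensus, edit-distance
co-optimal alignments can trade a mismatch for two indels, so the
match/mismatch/indel decomposition (and hence the exact score) is
well-defined only relative to the alignment edlib reports. The test suite
asserts exact scores on noise-free arrays (where the decomposition is
unambiguous) and score/extent self-consistency bounds on diverged ones.

## Monomer clustering

`greedy_cluster` is CD-HIT-style greedy incremental clustering: monomers
sorted by length descending (ties by canonical sequence) either join the
first cluster whose representative they match at ≥ the identity threshold
(default 0.80) or found a new cluster; the representative is the founding
(longest) member. CD-HIT's word-filter heuristic is unnecessary at
monomer-set scale and is replaced by exact alignment.

Identity is computed **circularly**: the query is globally aligned into
the doubled representative (both strands) and identity is
matches / alignment columns. Plain global identity on canonical strings is
not register-safe — a single substitution can change which rotation is
lexicographically minimal, which would make two 99%-identical monomers
look unrelated — so the circular definition is the one that delivers the
intended register/strand invariance. Clusters are ranked by total copy
number (ties → lexicographically smaller representative);
`major_monomer` reports the top cluster's representative, its modal
member length, and the full length histogram.

## Centromere localization

The dominant monomer cluster is scanned along each chromosome
(`monomer_hit_track`): candidate loci are pre-filtered by shared 12-mers
with the doubled representative (catching every register, both strands),
then verified with rotation/strand-tolerant edit distance at ≥ 0.80
identity; verified hits are binned into windows (default 10 kb window and
step). `call_centromere` thresholds windows at ≥ `min_density` hits
(default 5), merges runs separated by ≤ `max_gap` (default 2) empty
windows — so megabase arrays punctuated by retrotransposon insertions are
not split — takes the longest run (ties → highest total hits), and snaps
the boundaries to the outermost verified hit. No window above threshold
means "no definite centromere" rather than a forced call, and the model is
monocentric: at most one call per chromosome. The published pipelines this
reproduces never quantify "continuous and high-frequency"; the defaults
here are validated by the planted-truth recovery experiments and are all
exposed as arguments.

`evidence_check` encodes the two corroborating signals used for real
centromere calls: gene density inside the call must be lower than
outside, and class-I (retrotransposon) density inside must be at least
the outside level. A failed criterion downgrades the call to `warn` but
never deletes it, since density evidence is corroborative, not
definitional. Coordinates are 0-based half-open internally; printed
reports are 1-based inclusive.

`similarity_heatmap` gives the windowed self-similarity view in which
satellite blocks light up: Jaccard fraction of shared canonical 21-mers
between 50-kb windows. A k-mer measure rather than alignment is chosen
for speed; exact 21-mer sharing decays quickly with divergence, so the
absolute values are meaningful as contrast (array windows vs arm
windows), not as percent identity.

## Reference-guided contig anchoring

`anchor_contigs` places contigs on guide pseudochromosomes using exact
31-mer anchors restricted to k-mers that occur exactly once in the guide
(repeats thus contribute no anchors and cannot mis-place a contig). Per
guide and orientation, anchors ordered by contig position are chained by
longest increasing subsequence on guide coordinates; the best chain wins,
an exact score tie across guides/orientations marks the contig
`ambiguous` and leaves it unplaced. The placement interval is the
diagonal extrapolation of the chain to the full contig, clipped to the
guide; it must span ≥ `min_anchor_len` (default 5 kb) and align to the
guide segment at ≥ `min_identity` (default 0.95, verified by edit
distance). Overlap conflicts are resolved score-first: small overlaps
(< 50% of the loser) truncate the loser, larger ones unplace it.

Gaps are emitted between consecutive placements whose guide intervals are
not adjacent, with the intervening guide span as the length estimate
(AGP `N` lines); gaps of unknown size are supported as `U`/100 bp per AGP
convention. `write_agp` emits AGP v2.1 with object coordinates starting
at the first placed component; `read_agp` inverts it, and
write→read→write reproduces the text byte-for-byte. Gap *filling* (e.g.
with long reads) is deliberately out of scope — gaps are reported, not
closed.

## Allele-specific expression

Counts are normalized as FPKM = c·10⁹/(L·N) (c mapped fragments, L gene
length in bp, N library size). Per sample, the allele contrast is
log2FC = log2 of the pseudocounted FPKM ratio (pseudocount 1 on raw
counts, for stability at low counts), and significance comes from a
two-sided exact binomial test of the allele-A count among the pair total
against the library-size-expected proportion N_A/(N_A+N_B). A sample is
ASE when |log2FC| > 1 and p < 0.05 — a deliberate raw-p threshold, so no
multiple-testing correction is applied by default (Benjamini–Hochberg
across the table is available via `fdr=True`). The binomial allelic-
imbalance test stands in for negative-binomial DE machinery: within one
sample the two alleles share library composition and gene length, which
is exactly the pairing the binomial exploits; its null is exact given the
pair total, though it treats biological overdispersion as signal, which
is why the planted-truth experiments also measure the realized null flag
rate.

Across samples (the motivating design has six: four fruit stages, leaf,
stem), a pair with ≥ 1 significant sample and no direction conflict among
significant samples is `consistent`; significant samples in both
directions make it `inconsistent`; otherwise `not_ase`. Samples with zero
counts for both alleles are excluded from pattern assignment. Allele
pairing itself (synteny) is an input, not computed here; `cds_identity`
provides the companion per-pair coding-similarity summary.

### Ka/Ks (NG86)

`kaks_ng86` implements Nei–Gojobori (1986): per codon, each of the nine
single-base mutations contributes ⅓ site, synonymous if it preserves the
amino acid (changes to stop codons count as nonsynonymous); site totals
are averaged over the two sequences. Observed differences are averaged
over all orderings of the differing codon positions, excluding pathways
through stop codons unless every pathway is blocked. The Jukes–Cantor
correction d = −¾·ln(1 − 4p/3) is applied separately to pS and pN;
p ≥ ¾ is flagged `saturated` (undefined), and the ratio is undefined when
Ks = 0. Note that very short inputs saturate easily — a single codon
carrying one synonymous change has pS = 3 — so meaningful Ka/Ks requires
realistic CDS lengths; the implementation is checked against an
independent brute-force pathway-enumeration oracle to 10⁻⁹ on 30-codon
pairs.

## Synthetic data: what it emulates, what it does not

A simulated chromosome is `[5' telomere][arm][centromere][arm][3'
telomere]` with every stochastic choice drawn from one seeded generator
(byte-identical outputs for identical spec + seed; the seed is recorded
in FASTA headers). Defaults are deliberately "desk-scale study
conditions": 5 chromosomes × 500 kb, 300 telomere copies per end at 2%
per-base mutation, a 153-bp seed monomer (the length of the major
kiwifruit centromeric monomer) tandem-repeated to ~31 kb at 5% per-copy
divergence, 10% TE density, 40 genes per chromosome. Background DNA is
uniform 25% per base (real kiwifruit GC is ~36%; composition is uniform
for simplicity and configurable only through the module's generator).
TE-like cassettes are a fixed library of three elements reused at 2%
per-copy mutation — two long class-I elements (1.5–3 kb) and one shorter
class-II element (0.5–1.5 kb), reflecting that LTR retrotransposons
dominate pericentromeric repeat mass. The centromeric array is split into
blocks by class-I insertions (about one per 10 kb of array), which both
mimics real plant centromeres and exercises the caller's gap merging;
genes are placed only on the arms, mirroring the low gene density of real
centromeres and grounding the evidence check. Satellite arrays are simple
head-to-tail repeats: any higher-order repeat structure of real
centromeres is not modelled, and the simulator makes no attempt at reads,
Hi-C contacts, sequencing error profiles, or assembly graphs.

`fragment_contigs` partitions chromosomes at breakpoints drawn with a
minimum spacing (default 10 kb, i.e. assembler-scale pieces, and safely
above the anchorer's `min_anchor_len`); withheld and inverted piece
counts use half-up rounding of fraction × pieces, documented because the
tests rely on the exact count. `simulate_allele_counts` draws
negative-binomial counts (dispersion 0.05, a ~22% biological CV — chosen
a priori as typical for within-condition RNA-seq, and the level at which
the |log2FC| > 1 filter keeps the realized null flag rate within the
nominal test level) around symmetric allele means; planted ASE pairs get
a 4-fold mean ratio (≥ 2.5 by construction) and inconsistent pairs flip
direction in a random proper subset of samples.

Passing the planted-truth experiments therefore shows the algorithms
recover structure under substitution-style divergence, fragmentation and
count noise at these scales; it does not certify performance on real
assemblies with segmental duplications, nested/higher-order repeats,
indel-rich divergence, or mapping-bias-driven allelic artifacts.

## Problem sizes and numerics

The recovery experiments run at: 10 genomes × 5 chromosomes (telomeres);
50 planted-array trials (10–200 copies, 0–10% divergence) plus 1-Mb
random controls (tandem finder); 20 two-family trials (clustering); 50
chromosomes with 60–200 kb arrays (centromere calling); 3 × 300 kb
chromosomes in 7 pieces (anchoring); 1 000 pairs × 6 samples at depth 200
(ASE); 100 random 30-codon pairs (Ka/Ks). These sizes keep the whole
suite and the acceptance script in the minutes range on one CPU while
leaving each recovery statistically meaningful.

Deterministic tie-breaks are used throughout: majority-vote consensus
ties go to the lexicographically smallest base, cluster presort ties to
the canonical sequence, cluster-rank ties to the smaller representative,
centromere run ties to the higher total hit count, and anchoring score
ties mark a contig ambiguous rather than guessing. Degenerate inputs
(empty monomer sets, all-zero tracks, zero-count samples, saturated
substitution proportions) return explicit empty/None/flagged results
rather than raising, except where the input violates a precondition
(invalid rates, non-codon-length CDS, internal stops), which raises
`ValueError`.
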