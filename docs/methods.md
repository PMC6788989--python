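# Methods

`phasecall` calls and phases single-nucleotide variants (SNVs) in a diploid
genome from noisy single-molecule long reads (PacBio CLR-like error
profiles: ~15% total error, dominated by short insertions and deletions).
The method proceeds in four stages; a read simulator and a truth-set
evaluator close the loop so every stage is testable without external data.

## 1. Candidate identification

At every pileup column the genotype likelihood is the standard
short-read-style product over observations. With per-observation error
probability `e_i` derived from the base quality,

    P(b_i | hom aa) = 1 - e_i            if b_i = a, else e_i / 3
    P(b_i | het ab) = P(b_i|a)/2 + P(b_i|b)/2

The prior over the ten diploid genotypes is Li-style: heterozygous
ref/alt mass `theta` (default 1e-3, the human heterozygosity scale),
homozygous non-reference mass `theta/2`, non-reference/non-reference het
mass `theta^2`, each split over the three alternate bases (optionally
transition-weighted). A site is nominated as a candidate biallelic SNV when

* depth >= 6,
* alternate-allele count >= 3 and fraction >= 0.125 (inclusive, so 3/24
  passes its own boundary),
* posterior probability of any non-reference genotype > 0.01.

The alt allele is the most frequent non-reference base, ties broken
A<C<G<T. When reads carry no base qualities, a flat phred 10 (the
single-pass SMS error scale) is substituted; the pileup stage only
nominates sites, and allele confidence is re-estimated by realignment.
Candidate selection is deliberately permissive — the goal is to minimize
false negatives and let the later stages remove false positives.

Two implementations exist and are tested against each other: a
per-observation reference path over explicit pileup columns, and a
single-pass vectorized scan (numba) that accumulates, per position and
base, the three log-likelihood terms the genotype likelihood needs. The
scan makes multi-megabase regions cheap.

## 2. Pair-HMM local realignment (allelotyping)

Indel errors cause reference bias: alignments around a true SNV often hide
the alternate allele in gap placements. For each read covering a candidate
site we therefore re-align a short read segment against two local
haplotype sequences (reference and alternate) with a three-state
pair hidden Markov model (match/insert/delete, no I<->D transitions,
insert emissions uniform over bases, match emissions `1-sub` / `sub/3`).
The forward algorithm sums over all alignments, which is exactly what is
needed in low-complexity sequence where many gap placements are equally
likely. N bases always take the mismatch emission, pulling quality toward
zero without biasing the allele.

**Parameters** are estimated from the input alignments themselves:
insertion/deletion opening rates as CIGAR op openings per alignment event
(aligned positions + openings), extension rates as the `(len-1)/len` mass
of the op-length distribution, substitution rate as the mismatch fraction
of aligned bases, over a capped sample of reads (default 10 000). Note the
mismatch fraction includes true SNV mismatches (~0.0015 at human
heterozygosity), a small conservative bias.

**Windows.** The window around a site (or a cluster of nearby sites) is
delimited by the innermost anchors: length-k (default 6) stretches where
the read matches the reference exactly and contiguously, whose reference
k-mer is *non-repetitive* — at least three distinct bases, not a repeat of
period 1 or 2 — and occurs exactly once within the anchor search span.
This forces windows to extend past homopolymers, where anchor placement
would otherwise be ambiguous. The search gives up 200 bp from the
outermost site (window scale 50–200 bp); a read without a valid window
contributes no call at that site. Candidate sites closer than 10 bp share
a window; clusters larger than 3 sites are split at their widest gap to
bound the 2^n local-haplotype enumeration.

**Banded forward.** The DP is restricted to a band of half-width b
(default 20) around the length-proportional diagonal `j ~ i*n/m`, giving
O(m·b) per evaluation; the band covers the indel excursions seen at CLR
error rates (verified against the full DP on errored read/haplotype
pairs). If the band excludes every complete path the evaluation returns a
log(0) sentinel and the call is discarded. The recursion runs in
probability space with per-row rescaling (no per-cell exp/log), compiled
with numba.

**Allele and quality.** With `p_ref = P(read(W)|ref(W))` and
`p_alt = P(read(W)|alt(W))`, the called allele is the argmax and its
quality is

    q = -10 log10(1 - p_max / (p_ref + p_alt))

computed in log space. Calls with q < 7.0 are discarded; an exact tie
gives q ~= 3.01 and is always discarded, so the ref-wins tie-break is
inert. For multi-site windows the per-site allele is taken from the
marginal over the 2^n local haplotypes, same quality formula and discard
rule; a single-site cluster reduces exactly to the two-haplotype case.

**Strand bias.** Sites whose post-realignment allele calls are
over-represented on one strand (two-tailed Fisher exact p < 0.01 on the
2x2 allele-by-strand table) are excluded from haplotype-informed
genotyping and emitted with a `strand_bias` FILTER label carrying their
realignment-based genotype. Note that at significance 0.01 roughly 1% of
genuine variant sites acquire this label by chance; they are annotated,
not dropped, so downstream consumers can decide.

## 3. Haplotype-informed genotyping

Allele calls are collapsed into per-read fragments over the candidate
sites. Assuming reads are independent and drawn fairly from the two
haplotypes,

    p(R|H) = prod_r [p(r|H1) + p(r|H2)] / 2,
    p(r|Hk) = prod over fragment sites of (1-e) on agreement else e

with `e = 10^(-q/10)` from the allele-call quality. Inference alternates:

1. **Haplotype assembly** of the current heterozygous sites by a greedy
   likelihood phaser: blocks are connected components of fragment
   co-coverage; initial phases come from a maximum spanning tree
   (edges weighted by cis/trans majority votes between consecutively
   co-covered sites); hill-climbing over single-site flips and suffix
   switches then runs until no move increases p(R|H). Suffix-switch deltas
   touch only fragments straddling the switch point (fragments wholly
   inside the suffix merely swap haplotype labels), which keeps a pass
   linear in total fragment length.
2. **Per-site genotype updates** over the four phased genotypes
   G = {0|0, 0|1, 1|0, 1|1}:

       p(H[i]=g | R, H) ∝ p(g) · p(R | H^{i,g})

   swept left to right until a full sweep changes nothing. `p(g)` uses the
   nomination prior's zygosity masses with the het mass split evenly
   between the two orderings. Ties keep the current genotype, making the
   sweep deterministic.

The outer loop stops when the relative improvement of log p(R|H) drops
below delta = 1e-5 or after 10 iterations (a safety cap; convergence is
delta-driven and in practice takes 2–3 iterations). Because the update
rule is a posterior argmax, the quantity that is monotone under the sweeps
is the penalized objective log p(H) + log p(R|H) (exposed as
`objective_trace`); the pure data term can dip when the genotype prior
overrides weak single-site evidence, which is the desired behaviour at
low coverage.

GQ is the phred-scaled probability that the called *zygosity* is wrong,
from the final per-site posterior with 0|1 and 1|0 merged (GQ scores
genotype, not phase, matching VCF convention). Heterozygous calls carry a
PS tag equal to the 1-based position of the first het site of their block.
Reads are assigned to haplotypes when one haplotype is at least 100 times
more likely (posterior > 0.99 under equal priors).

## 4. Filtering

Three independent, idempotent, order-insensitive filters annotate (never
drop) calls:

* **GQ**: fixed cutoff 50 by default (the simulation setting); a
  depth-scaled mode uses cutoff = c·(median depth) with c = 1.0 exposed as
  a flag, for data where true indels masquerade as high-GQ SNVs.
* **Depth**: flag depth > d + 5·sqrt(d), d = median raw pileup depth over
  the region — a copy-number-amplification guard.
* **Density**: flag every call inside any 500-bp window containing more
  than 10 calls (sliding windows, any placement — tiled bins would miss
  straddling clusters); dense clusters typically betray mismapping or CNVs.

## Simulator

The simulator defines the study conditions: random uniform-composition
references (optionally salted with homopolymer runs to exercise anchor
logic); het SNVs at 1e-3 and hom SNVs at 5e-4 per base, alt base uniform
over the three non-reference bases, truth phased; log-normal read lengths
(median 7 500 bp, sigma 0.35 — spread chosen to look like single-pass CLR
length distributions while keeping the median the controlled quantity);
coverage set by drawing reads until the requested base total is reached.

Errors follow a Markov alignment-event chain: each event is an insertion
run (p=0.11), a deletion run (p=0.04) or an aligned base substituted with
p=0.01; run lengths are geometric with mean 1.5 (short-indel-dominated, as
in CLR data; exposed in config). Adjacent same-type runs are forbidden and
the chain's transition probabilities are solved so that the *emitted
CIGAR op* statistics match the configured rates exactly in expectation —
the same statistics `estimate_hmm_params` measures, making parameter
recovery a sharp test rather than an approximation. Reads carry base
qualities equal to the phred of the substitution rate (a calibrated
instrument; capped at Q60). Start positions are drawn over
`[-len+1, L-1]` and clipped, so expected coverage is uniform up to the
region edges, as for a window cut from a larger genome. The emitted SAM
records the *true* alignment from the simulator's own error trace, so the
pipeline runs without an external aligner; externally aligned BAMs are
accepted through the same `call` interface.

What the simulator does not emulate: context-specific (e.g. nanopore
homopolymer-length) error models, quality-value variation along reads,
chimeric/supplementary alignments, mapping errors, and structural or indel
variation. Passing tests on this simulator therefore demonstrate the
correctness of the algorithm under its own model assumptions — reference
bias from indel noise, haplotype structure, strand artifacts — not
robustness to every artifact of real instruments.

## Evaluator

Precision/recall use exact matching on (chrom, pos, ref, alt) plus
unphased genotype; a genotype mismatch counts as both FP and FN (the
vcfeval convention). Phasing error is the combined switch + mismatch rate:
within each block, under the error-minimizing gauge, an isolated
single-site disagreement is one mismatch and each remaining
agree/disagree transition is one switch; the denominator is the number of
adjacent het pairs assessed (evaluated at sites het in both call set and
truth). Block completeness is N50 over block spans (last minus first
phased site).

## Numerical choices and degenerate inputs

* All per-cell DP work is multiply/add with per-row rescaling; logs are
  taken once per row. log-sum-exp is used wherever two log-probabilities
  combine.
* Allele-call error probabilities are clipped to [1e-10, 0.5]; GQ is
  capped at 500.
* Zero-depth columns raise; empty fragments have log-likelihood 0;
  an empty candidate set yields a valid header-only VCF.
* Internal coordinates are 0-based half-open everywhere; the single
  conversion to 1-based happens at VCF serialization.
* `=`/`X` CIGAR ops are folded into `M`; hard clips are dropped; soft
  clips never enter pileups or windows; reads containing `N` (ref-skip)
  ops are skipped with a warning.

## Problem sizes used in the test suite

The acceptance-style checks run on scaled-down replicates chosen to give
stable statistics at desk scale: three 2-Mb diploid genomes at 40x for
precision and allele-quality calibration (~9 000 calls, ~350 000 allele
observations), a 1-Mb region at 30x for phasing accuracy (~600 assessed
het pairs), and a 200-kb error-free region at 20x for the exact-closure
check. Oracle comparisons (path enumeration, exhaustive 4^n genotype
search, hypergeometric tail sums, all-windows density) run at the largest
sizes where exhaustive computation is itself trivially correct.

## Known limitations

* Indels are not called, and indel variants in real data can surface as
  clustered false SNVs (the density and depth-scaled-GQ filters exist to
  blunt this).
* The greedy phaser guarantees only local optimality (no single flip or
  suffix switch improves the likelihood); it is not a reimplementation of
  a graph-cut haplotype assembler, though within the iteration it plays
  the same role and the exhaustive-search tests show it reaches the global
  optimum on small instances.
* Multiallelic sites are reduced to the top alternate allele.
* The strand-bias test randomly labels ~1% of true sites at its 0.01
  significance level; consumers wanting maximum recall should not exclude
  `strand_bias`-labelled records blindly.
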