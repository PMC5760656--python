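# Methods

This note documents the models, conventions, and numerical choices behind
`pirna_profiler`, and what the simulation-based tests do and do not
establish about real sequencing data.

## Read preprocessing

Adapter clipping keeps the 5′ portion preceding the leftmost occurrence of
the full 3′ adapter; when the full adapter is absent, the longest adapter
*prefix* of ≥5 nt anchored at the read's 3′ end is treated as read-through
evidence and trimmed. Trimming iterates to a fixed point, which makes
clipping idempotent (a clipped product can itself end in an adapter prefix);
the cost is that a genuine insert coincidentally ending in ≥5 adapter bases
(~10⁻³ per read for a random insert) loses those bases — the same
false-positive mode single-pass clippers have. The minimum overlap of 5 nt
and the fate of unclipped reads (`keep_unclipped`, default true for
simulated input, false appropriate for raw sequencer FASTQ) are echoed in
every run report so they are auditable. Quality scores are parsed and
ignored; no step of the procedure uses them.

Length windows: mature piRNAs 24–32 nt inclusive; the miRNA proxy 21–23 nt;
CLIP fragments ≥15 nt with no upper bound (histograms are reported on 15–60
nt for legibility only). The piRNA window and the miRNA proxy are disjoint
by construction.

## Matching and annotation

Matching is ungapped with at most one mismatch and no indels — the behavior
of `bowtie -v 1` — implemented natively so small references need no external
aligner. The implementation seeds with 12-mers under the pigeonhole
guarantee (with ≤1 mismatch, one half of the read is exact; for reads
shorter than 24 nt a substring-scan fallback preserves exactness) and
verifies candidates by Hamming distance, with `N` counting as a mismatch on
either side. An exhaustive numpy brute-force scan serves as the independent
oracle in the test suite; the two agree placement-for-placement on
randomized fixtures.

Sequential exclusion assigns each read to the first category, in hierarchy
order (piRNA clusters, coding RNA, non-coding RNA, repeats, introns, then
`other`), in which it has at least one alignment. Within the winning
category a single deterministic winner is chosen: fewest mismatches, then
lexicographically smallest target name, then smallest start, then sense
before antisense. Each read is counted exactly once; fractional multimapper
weighting was rejected because single-winner assignment keeps every
downstream tally auditable and conservation exact. Strand policy defaults to
sense-only (cluster precursors are single-stranded transcripts) except
repeats and introns, which are matched on both strands; the policy and every
other matching choice are hashed into `params_digest` and recorded in run
reports.

Coordinates are 0-based half-open internally; BED output follows the same
convention.

## Normalization and fold changes

For paired total-RNA libraries the scale factor is the ratio of miRNA-proxy
(21–23 nt) counts, `s = miRNA_ref / miRNA_alt`, applied to alt-library
counts; miRNA abundance is treated as genotype-independent, which the
simulator enforces by construction. IP libraries use total retained reads
instead. A zero denominator is an error, never a silent infinity. The
miRNA proxy is defined purely by length, measured on adapter-clipped reads
*before* the 24–32 nt window filter; an annotated-miRNA restriction could be
added but is not needed for paired ratios.

Per-cluster fold change uses a pseudocount (default 1.0, applied to
normalized counts) so empty clusters are defined; with pseudocount 0 and
positive counts, reversing the direction inverts every fold change exactly.
Cluster ranking uses within-library counts only and is therefore invariant
to the normalization factor. Aggregation over cluster sets uses the
geometric mean (log-scale averaging), the natural choice for ratios; the
arithmetic mean of window fold changes is also reported where a "≈1" check
is the target.

## Positional analyses

Density tracks count read **5′ start** positions, not full-length coverage:
the 5′ end is the biogenesis-defined feature of a mature piRNA, and
start-based tracks make bin conservation exact (metagene bins sum to the
cluster-assigned read count at scale 1).

The 5′-window analysis anchors the window at offset 0 of each cluster
sequence — cluster FASTA/BED records must therefore be TSS-anchored — with
window 300 nt and top-k 50 by default (top-k selection always uses the
reference/wild-type ranking). A window longer than a cluster degrades to the
whole cluster, logged rather than raised. The paired t-test operates on
`log2(FC_full) − log2(FC_window)` across clusters, two-sided with n−1
degrees of freedom; the all-zero-difference degenerate case returns p = 1.0
with a warning, and a single-cluster analysis reports NaN rather than a
statistic. Bidirectional (divergently transcribed) clusters should be
provided as two separate TSS-anchored records.

Metagene binning maps a start `p` on a cluster of length `L` to bin
`⌊p·n_bins/L⌋` with `n_bins = 100`; clusters shorter than the bin count are
valid (positions map many-to-few). Profile correlation is plain Pearson,
with R² reported; constant vectors raise rather than returning an undefined
value.

## CLIP branch

CLIP fragments reuse the same clipping, matching, annotation, and density
machinery; with an identical length window the CLIP-mode and piRNA-mode
results are identical by construction. Defaults: ≥15 nt, no upper bound,
same ≤1-mismatch sense-policy annotation as piRNAs (the appropriate CLIP
alignment parameters are not better constrained, and recording them in the
run report keeps the choice visible). Co-density is the Pearson R² of the
two 100-bin metagene vectors, invariant to scaling either library's counts.

## The simulator

The generator emulates the statistical structure of adult-testis small-RNA
libraries, not their sequence content:

* **Cluster abundances**: power law with exponent 1.5 over rank, so the top
  quarter of clusters carries ~90% of cluster-derived reads — the observed
  concentration of piRNA output in a small set of top precursors.
* **Within-cluster starts**: 50 hotspot sites per cluster with
  Dirichlet(0.3) weights plus 10% uniform background, giving spiky,
  piRNA-like tracks while keeping all metagene bins populated. This is a
  declared stand-in — no quantitative within-cluster start distribution is
  established for real precursors — so all recovery claims are stated
  against the truth table, not against biology.
* **Lengths**: a 50/50 mixture of a MILI-like (25–28 nt) and a MIWI-like
  (29–32 nt) component with peaked within-range weights
  (0.15/0.35/0.35/0.15), producing a genuinely bimodal size distribution
  with interior modes.
* **First nucleotide**: position 1 is overwritten to U with probability
  `u1_prob` (default 0.8), otherwise to a uniform draw over the other three
  bases, so the measured 1U fraction is exactly Bernoulli(`u1_prob`) and
  binomial recovery bounds are exact statements. CLIP fragments use the same
  scheme with A (`a1_prob`, default 0.5).
* **Genotypes**: binomial read thinning of the *same* base draw (paired
  design). `uniform_depletion(f)` retains each cluster read with probability
  1/f. `five_prime_sparing(window, f, top_k)` thins only reads starting at
  or beyond `window` in the `top_k` most abundant clusters; the expected
  full-length WT/KO fold change per cluster is then the closed form
  `1/(w + (1−w)/f)` with `w` the cluster's within-window read fraction. The
  optional `miwi_global_factor` additionally thins the MIWI-like length
  component everywhere (the knockout's reduced 29–32 nt population); it
  defaults to 1.0 so the positional signal is isolated and the closed form
  holds exactly.
* **miRNA proxy and non-cluster reads** are never thinned, making the
  normalization factor exactly 1 in paired simulations and non-cluster
  composition genotype-invariant.

Two presets are provided. The full-size scenario mirrors the study system's
scale (214 clusters of 2–20 kb, 80% of window reads cluster-derived). The
**desk preset** — 20 clusters of 0.5–2 kb, 50,000 window reads, 8,000 miRNA
reads, knockout = 5′-sparing with factor 7 over the top 10 clusters, 50,000
CLIP fragments — keeps every end-to-end analysis, including annotation of
all four libraries, within seconds on one core; it is the problem size used
by the test suite and the acceptance script. What passing these tests shows:
the pipeline's bookkeeping, normalization, and estimators are correct
against a known generative model. What they do not show: robustness to
sequencing error, ping-pong secondary biogenesis, multimapping across
near-identical clusters, or adapter chemistry quirks, none of which the
generator models.

All randomness derives from one scenario seed through fixed per-stage
streams (reference, library, genotype, CLIP); identical configuration gives
byte-identical FASTQ, FASTA, BED, and TSV outputs.

## Degenerate inputs and tie-breaks

Empty libraries raise at composition and signature computation (a zero
denominator is never silently propagated); clusters with zero reads are
listed with count 0 and rank after all positive clusters, ties broken
lexicographically by cluster id; adapter shorter than 5 nt, negative
pseudocounts, thinning factors below 1, and probabilities outside [0, 1]
are configuration errors at construction time. An infeasible sparing window
(longer than every cluster) warns and degrades rather than failing, since
the thinned set is simply empty.
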