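# pirna-profiler

Small-RNA informatics for **pachytene piRNA cluster profiling** in mammalian
testes: hierarchical read annotation, miRNA-normalized paired-library
comparison, per-cluster fold-change ranking, within-precursor positional
analysis, and HITS-CLIP co-density analysis — together with a seeded
scenario simulator so every stage is verifiable against a known truth table
without any sequencing downloads.

## Who this is for

Groups comparing small-RNA libraries between wild-type and knockout animals
(e.g. a piRNA-pathway factor conditionally deleted in the germline) who need
to answer, reproducibly:

* What fraction of 24–32 nt reads derive from annotated piRNA clusters vs
  coding RNA, non-coding RNA, repeats, and introns?
* How does piRNA output change per cluster after normalizing libraries by
  their 21–23 nt miRNA content?
* Is depletion uniform along each precursor, or is the 5′ end (~300 nt
  downstream of the TSS) spared — the signature of a factor acting after 5′
  processing?
* Do CLIP fragments of an RNA-binding protein co-localize with piRNA
  production along precursors?

## The method

**Preprocessing.** Reads are 3′-adapter-clipped (leftmost full-adapter
occurrence, or a ≥5 nt adapter prefix anchored at the 3′ end, trimmed to a
fixed point so clipping is idempotent), then split into the piRNA window
(24–32 nt) and the miRNA proxy (21–23 nt). CLIP libraries use a permissive
≥15 nt filter with no upper bound.

**Annotation.** Each window read is matched ungapped with at most one
mismatch (Bowtie `-v 1` semantics, no indels; `N` always mismatches) against
an *ordered* category hierarchy — piRNA clusters, coding RNA, non-coding
RNA, repeats, introns — and assigned to the **first** category with any hit
(sequential exclusion); unmatched reads are `other`. Within the winning
category a single deterministic placement is chosen (fewest mismatches, then
lexicographic target, smallest start, sense before antisense), so category
counts partition the library exactly. The matcher is native (pigeonhole
k-mer seeding + Hamming verification) and is tested read-for-read against an
exhaustive brute-force oracle.

**Quantification.** Paired libraries are scaled by the miRNA-proxy ratio
(`ref_miRNA / alt_miRNA`; total-read normalization for IP libraries). Per
cluster `c`, the fold change is

    FC_c = (n_ref,c + ψ) / (s · n_alt,c + ψ)

with scale factor `s` and pseudocount `ψ` (default 1). Clusters are ranked
by wild-type abundance.

**Positional analysis.** Density tracks count read 5′ starts per position.
The 5′-window analysis computes, for the top-k wild-type-ranked clusters,
`FC_window` (reads starting < 300 nt) vs `FC_full` (all cluster reads) and
tests the uncoupling with a paired two-sided t-test on
`log2 FC_full − log2 FC_window`. Metagene profiles divide every cluster into
100 equal fragments (`bin = ⌊p·100/L⌋`) and sum read starts across clusters;
CLIP/piRNA co-density is the Pearson R² of the two metagene vectors.

**Simulation.** The scenario generator draws cluster abundances from a
power law (a top subset dominates), read starts from per-cluster Dirichlet
hotspot mixtures, lengths from a bimodal 25–28 nt ("MILI-like") / 29–32 nt
("MIWI-like") mixture, and first nucleotides with an exact Bernoulli U bias.
Knockouts are binomial thinnings of the same base draw: uniform depletion,
or 5′-window-sparing depletion of the top clusters, for which the expected
full-length fold change has the closed form `1/(w + (1−w)/f)` given each
cluster's within-window read fraction `w` and thinning factor `f`.

## Worked example

```python
import pirna_profiler as pp
from pirna_profiler.io_preprocess import length_filter, select_mirna_proxy

cfg = pp.ScenarioConfig.desk(seed=11)          # 20 clusters, 50k window reads
reference, wt, ko = pp.simulate_pair(cfg)      # cKO = 5'-sparing, factor 7, top 10
hierarchy = reference.to_hierarchy()

libs = {}
for label, sim in (("WT", wt), ("cKO", ko)):
    window = length_filter(sim.reads, 24, 32)
    mirna = select_mirna_proxy(sim.reads)
    libs[label] = pp.annotate_sequential(window, hierarchy, max_mismatch=1,
                                         mirna_count=len(mirna))

comp = pp.composition(libs["WT"], hierarchy.category_names)
print(comp.to_string(index=False))

pair = pp.PairedComparison(libs["WT"], libs["cKO"])
analysis = pp.window_vs_full(pair, reference.cluster_lengths(),
                             window_nt=300, top_k=10)
print(f"normalization factor: {pair.scale_factor:.3f}")
print(f"mean FC (5' 300 nt): {analysis.table['fc_window'].mean():.2f}")
print(f"geo-mean FC (full length): {pp.geometric_mean(analysis.table['fc_full']):.2f}")
print(f"paired t-test p = {analysis.p_value:.2e}")
```

Output:

```
      category  count  fraction
piRNA_clusters  40000      0.80
    coding_RNA   3000      0.06
 noncoding_RNA   1500      0.03
       repeats   2500      0.05
        intron   2000      0.04
         other   1000      0.02
normalization factor: 1.000
mean FC (5' 300 nt): 1.00
geo-mean FC (full length): 3.03
paired t-test p = 1.39e-05
```

Reading it: 80% of window reads are cluster-derived in the wild type; the
libraries are already on a common scale (miRNA content is genotype-
independent); piRNA output from the first 300 nt of the top clusters is
unchanged (FC ≈ 1) while whole-precursor output drops ~3-fold — the
geometric mean of `1/(w + (1−w)/7)` across clusters whose 5′ windows hold a
sizeable share of reads — and the window/full uncoupling is highly
significant. The depletion beyond the window itself recovers the generating
factor of 7.

The same analyses are scriptable from the shell via the `profiler` CLI
(`simulate`, `preprocess`, `annotate`, `quantify`, `positional`, `clip`,
`report`); every subcommand writes a JSON run report with parameters, file
digests, and stage counts, and `profiler report` audits a chain of reports
for count conservation.

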