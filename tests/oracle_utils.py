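"""Independent brute-force oracles used to verify the native matcher.

The oracle path is numpy: every placement of the read on every target is
scored by vectorized Hamming comparison — no seeds, no indexing — so it
shares no code with the pigeonhole matcher it checks.
"""

from __future__ import annotations

import numpy as np

from pirna_profiler.annotate import ANTISENSE, SENSE, CategoryHierarchy, reverse_complement
from pirna_profiler.io_preprocess import SmallRNARead


def hamming_scan(query: str, target: str, max_mismatch: int) -> list[tuple[int, int]]:
    """All ``(start, mismatches)`` placements with Hamming distance <= limit."""
    m, n = len(query), len(target)
    if m == 0 or m > n:
        return []
    t = np.frombuffer(target.encode(), dtype=np.uint8)
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(t, m)
    mms = (windows != q).sum(axis=1)
    return [(int(s), int(mms[s])) for s in np.nonzero(mms <= max_mismatch)[0]]


def oracle_annotate(read: SmallRNARead, hierarchy: CategoryHierarchy, max_mismatch: int):
    """Brute-force sequential-exclusion assignment of one read.

    Returns ``(category, target, start, strand)`` under the same multimapper
    policy as the pipeline (fewest mismatches, lexicographic target, smallest
    start, sense first).
    """
    for cat, targets in hierarchy.categories:
        hits = []
        for strand_rank, strand in enumerate(hierarchy.strand_policy[cat]):
            q = read.seq if strand == SENSE else reverse_complement(read.seq)
            for tname, tseq in targets.items():
                for start, mm in hamming_scan(q, tseq, max_mismatch):
                    hits.append((mm, tname, start, strand_rank, strand))
        if hits:
            mm, tname, start, _, strand = min(hits)
            return cat, tname, start, strand
    return hierarchy.fallthrough_name, None, None, None


def random_fixture(seed: int, n_reads: int = 200):
    """Random small reference set (<= 5 kb) plus reads derived from it.

    Reads are target substrings with 0-2 point mutations (N allowed), a
    fraction reverse-complemented, plus pure-random reads that should fall
    through to ``other``.
    """
    rng = np.random.default_rng(seed)

    def rand_seq(n: int) -> str:
        return "".join("ACGT"[i] for i in rng.integers(0, 4, n))

    cats = []
    pool = []
    for cat in ("piRNA_clusters", "coding_RNA", "repeats"):
        targets = {}
        for j in range(int(rng.integers(2, 4))):
            seq = rand_seq(int(rng.integers(200, 600)))
            targets[f"{cat}_t{j}"] = seq
            pool.append(seq)
        cats.append((cat, targets))
    hierarchy = CategoryHierarchy(cats)
    reads = []
    for i in range(n_reads):
        if rng.random() < 0.8:
            src = pool[int(rng.integers(len(pool)))]
            m = int(rng.integers(18, 33))
            p = int(rng.integers(0, len(src) - m))
            s = list(src[p : p + m])
            for _ in range(int(rng.integers(0, 3))):
                s[int(rng.integers(m))] = "ACGTN"[int(rng.integers(5))]
            seq = "".join(s)
            if rng.random() < 0.3:
                seq = reverse_complement(seq)
            reads.append(SmallRNARead(f"r{i}", seq))
        else:
            reads.append(SmallRNARead(f"r{i}", rand_seq(int(rng.integers(18, 33)))))
    return hierarchy, reads
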