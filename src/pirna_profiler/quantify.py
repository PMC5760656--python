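"""Library composition, paired normalization, and per-cluster fold changes.

Absolute read yield is not comparable between libraries, so paired wild-type
and knockout libraries are put on a common scale using the miRNA proxy: the
21-23 nt read count of each library. miRNA abundance is genotype-independent
in this system, so the ratio of miRNA counts is the sequencing-depth ratio.
IP libraries (MILI/MIWI-bound) are instead normalized by total retained reads.

Fold changes are computed per piRNA cluster, with clusters ordered by their
abundance rank in the reference (wild-type) library.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .annotate import AnnotatedLibrary
from .io_preprocess import SmallRNARead

MIRNA_PROXY = "mirna_proxy"
TOTAL_READS = "total_reads"

REF_OVER_ALT = "ref_over_alt"
ALT_OVER_REF = "alt_over_ref"

#: read-length domain of size-distribution histograms (nt, inclusive)
SIZE_HIST_DOMAIN = (15, 40)


class NormalizationError(ValueError):
    """Raised when a normalization denominator is zero or invalid."""


def composition(
    lib: AnnotatedLibrary, category_order: Sequence[str], fallthrough: str = "other"
) -> pd.DataFrame:
    """Per-category read counts and fractions, in hierarchy order.

    Returns a DataFrame with columns ``category``, ``count``, ``fraction``;
    the fallthrough category is listed last. Fractions sum to 1.
    """
    if lib.total_window_reads == 0:
        raise ValueError("no reads in piRNA window")
    counts = lib.category_counts()
    order = [c for c in category_order if c != fallthrough] + [fallthrough]
    rows = [
        {"category": cat, "count": counts.get(cat, 0)}
        for cat in order
    ]
    df = pd.DataFrame(rows)
    df["fraction"] = df["count"] / lib.total_window_reads
    return df


def normalization_factor(
    ref: AnnotatedLibrary, alt: AnnotatedLibrary, mode: str = MIRNA_PROXY
) -> float:
    """Factor by which to multiply alt-library counts to compare with ref.

    ``mirna_proxy`` uses each library's 21-23 nt read count (total small-RNA
    libraries); ``total_reads`` uses total retained window reads (IP
    libraries).
    """
    if mode == MIRNA_PROXY:
        num, den = ref.mirna_count, alt.mirna_count
    elif mode == TOTAL_READS:
        num, den = ref.total_window_reads, alt.total_window_reads
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if den <= 0:
        raise NormalizationError(f"{mode} denominator count is {den}; cannot normalize")
    if num <= 0:
        raise NormalizationError(f"{mode} reference count is {num}; cannot normalize")
    return num / den


@dataclass
class PairedComparison:
    """Two annotated libraries on a common scale (e.g. wild type vs knockout)."""

    ref: AnnotatedLibrary
    alt: AnnotatedLibrary
    normalization_mode: str = MIRNA_PROXY
    direction: str = REF_OVER_ALT
    scale_factor: float = field(init=False)

    def __post_init__(self) -> None:
        if self.direction not in (REF_OVER_ALT, ALT_OVER_REF):
            raise ValueError(f"unknown direction {self.direction!r}")
        self.scale_factor = normalization_factor(self.ref, self.alt, self.normalization_mode)


def _raw_cluster_counts(
    lib: AnnotatedLibrary, cluster_ids: Sequence[str], category: str
) -> dict[str, int]:
    counts = dict.fromkeys(cluster_ids, 0)
    for a in lib.annotations:
        if a.category == category and a.target_name in counts:
            counts[a.target_name] += 1
    return counts


def cluster_counts(
    lib: AnnotatedLibrary,
    cluster_ids: Sequence[str],
    scale: float = 1.0,
    category: str = "piRNA_clusters",
) -> pd.DataFrame:
    """Raw and normalized per-cluster read counts with abundance ranks.

    Clusters with zero reads are listed with count 0. Rank 1 is the most
    abundant cluster by normalized count; ties break lexicographically by
    cluster id. Ranking is invariant to ``scale``.
    """
    raw = _raw_cluster_counts(lib, cluster_ids, category)
    df = pd.DataFrame(
        {"cluster_id": list(cluster_ids), "raw_count": [raw[c] for c in cluster_ids]}
    )
    df["normalized_count"] = df["raw_count"] * scale
    df = df.sort_values(
        ["normalized_count", "cluster_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def cluster_fold_change(
    comparison: PairedComparison,
    cluster_ids: Sequence[str],
    pseudocount: float = 1.0,
    category: str = "piRNA_clusters",
) -> pd.DataFrame:
    """Per-cluster fold change between the paired libraries.

    Alt-library counts are put on the ref scale with the pair's normalization
    factor; ``FC = (ref + pc) / (alt_scaled + pc)`` in the ``ref_over_alt``
    direction (reciprocal for ``alt_over_ref``). Rows are ordered by the
    ref-library abundance rank, most abundant first.
    """
    if pseudocount < 0:
        raise ValueError(f"pseudocount must be >= 0, got {pseudocount}")
    ref_df = cluster_counts(comparison.ref, cluster_ids, 1.0, category)
    alt_raw = _raw_cluster_counts(comparison.alt, cluster_ids, category)
    df = ref_df.rename(columns={"raw_count": "ref_count", "rank": "ref_rank"})
    df = df.drop(columns=["normalized_count"])
    df["alt_count"] = [alt_raw[c] for c in df["cluster_id"]]
    df["alt_scaled"] = df["alt_count"] * comparison.scale_factor
    num = df["ref_count"] + pseudocount
    den = df["alt_scaled"] + pseudocount
    if pseudocount == 0 and ((num == 0) | (den == 0)).any():
        raise ValueError("zero cluster count with pseudocount 0; use a pseudocount")
    fc = num / den
    if comparison.direction == ALT_OVER_REF:
        fc = 1.0 / fc
    df["fold_change"] = fc
    return df


def geometric_mean(values: Iterable[float]) -> float:
    arr = np.asarray(list(values), dtype=float)
    if len(arr) == 0 or (arr <= 0).any():
        raise ValueError("geometric mean requires positive values")
    return float(np.exp(np.log(arr).mean()))


def size_distribution(
    reads: Sequence[SmallRNARead],
    scale: float = 1.0,
    domain: tuple[int, int] = SIZE_HIST_DOMAIN,
) -> pd.Series:
    """Read-length histogram over a fixed domain, optionally rescaled.

    Input should be adapter-clipped but *not* window-filtered, so that both
    the miRNA and piRNA peaks are visible. ``scale`` is the paired
    normalization factor when comparing against a reference library.
    """
    lo, hi = domain
    lengths = pd.Series([len(r) for r in reads], dtype=int)
    counts = lengths.value_counts().reindex(range(lo, hi + 1), fill_value=0).sort_index()
    counts = counts.astype(float) * scale
    counts.index.name = "length"
    counts.name = "count"
    return counts


def first_nt_composition(reads: Sequence[SmallRNARead]) -> dict[str, float]:
    """Fraction of reads beginning with each nucleotide (T reported as U)."""
    if not reads:
        raise ValueError("first_nt_composition requires at least one read")
    counts = {"A": 0, "C": 0, "G": 0, "U": 0, "N": 0}
    for r in reads:
        first = r.seq[0]
        counts["U" if first == "T" else first] += 1
    n = len(reads)
    return {k: v / n for k, v in counts.items()}
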