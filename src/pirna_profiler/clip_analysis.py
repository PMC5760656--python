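"""CLIP-read branch of the pipeline.

HITS-CLIP fragments report protein-bound RNA rather than mature piRNAs, so
the length filter is permissive (>= 15 nt, no upper bound) and the expected
first-nucleotide signature differs: endogenous nuclease digestion leaves a
predominant A at position 1, in contrast to the mature-piRNA 1U bias. All
matching, annotation and density machinery is shared with the piRNA branch —
with an identical length window the two branches produce identical results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import quantify
from .annotate import AnnotatedLibrary, CategoryHierarchy, annotate_sequential
from .io_preprocess import PreprocessParams, SmallRNARead, clip_reads, length_filter
from .positional import metagene, profile_correlation

CLIP_MIN_LEN_DEFAULT = 15
#: reporting cap for CLIP length histograms (fragments may be long)
CLIP_HIST_DOMAIN = (15, 60)


@dataclass
class ClipLibrary:
    """Preprocessed CLIP fragments, optionally annotated."""

    reads: list[SmallRNARead]
    min_len: int = CLIP_MIN_LEN_DEFAULT
    annotations: Optional[AnnotatedLibrary] = None

    def __post_init__(self) -> None:
        short = [r.read_id for r in self.reads if len(r) < self.min_len]
        if short:
            raise ValueError(f"{len(short)} CLIP reads shorter than min_len {self.min_len}")


def clip_preprocess(
    reads: Sequence[SmallRNARead],
    adapter: str,
    min_len: int = CLIP_MIN_LEN_DEFAULT,
    keep_unclipped: bool = True,
) -> tuple[ClipLibrary, dict]:
    """Adapter-clip CLIP reads and apply the permissive >= ``min_len`` filter.

    Behaves exactly like the piRNA preprocessing with an unbounded upper
    length limit.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    params = PreprocessParams(
        adapter=adapter, min_len=min_len, max_len=10**9, keep_unclipped=keep_unclipped
    )
    clipped, counts = clip_reads(reads, params)
    kept = length_filter(clipped, min_len, params.max_len)
    counts = dict(counts, min_len=min_len, output=len(kept))
    return ClipLibrary(kept, min_len=min_len), counts


def annotate_clip(
    lib: ClipLibrary, hierarchy: CategoryHierarchy, max_mismatch: int = 1
) -> ClipLibrary:
    """Annotate CLIP fragments with the shared sequential-exclusion machinery."""
    lib.annotations = annotate_sequential(
        lib.reads, hierarchy, max_mismatch=max_mismatch, source="CLIP"
    )
    return lib


def clip_signatures(
    lib: ClipLibrary, domain: tuple[int, int] = CLIP_HIST_DOMAIN
) -> tuple[pd.Series, dict[str, float]]:
    """Length histogram (broad domain) and first-nucleotide composition."""
    if not lib.reads:
        raise ValueError("empty CLIP library")
    hist = quantify.size_distribution(lib.reads, domain=domain)
    first_nt = quantify.first_nt_composition(lib.reads)
    return hist, first_nt


def clip_pirna_codensity(
    clip: AnnotatedLibrary,
    pirna: AnnotatedLibrary,
    cluster_lengths: Mapping[str, int],
    n_bins: int = 100,
    category: str = "piRNA_clusters",
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Compare CLIP and piRNA densities over a shared cluster set.

    Returns per-cluster count pairs (with log10 columns for scatter reports;
    zero counts yield ``-inf``) and the Pearson ``(r, r_squared)`` of the two
    ``n_bins``-bin metagene vectors. Raises if no cluster has reads in both
    libraries.
    """
    cluster_ids = list(cluster_lengths)
    clip_counts = quantify.cluster_counts(clip, cluster_ids, category=category)
    pirna_counts = quantify.cluster_counts(pirna, cluster_ids, category=category)
    scatter = (
        clip_counts[["cluster_id", "raw_count"]]
        .rename(columns={"raw_count": "clip_count"})
        .merge(
            pirna_counts[["cluster_id", "raw_count"]].rename(
                columns={"raw_count": "pirna_count"}
            ),
            on="cluster_id",
        )
        .sort_values("cluster_id", kind="mergesort")
        .reset_index(drop=True)
    )
    if not ((scatter["clip_count"] > 0) & (scatter["pirna_count"] > 0)).any():
        raise ValueError("no cluster has reads in both CLIP and piRNA libraries")
    with np.errstate(divide="ignore"):
        scatter["log10_clip"] = np.log10(scatter["clip_count"].astype(float))
        scatter["log10_pirna"] = np.log10(scatter["pirna_count"].astype(float))
    clip_prof = metagene(clip, cluster_lengths, n_bins=n_bins, category=category)
    pirna_prof = metagene(pirna, cluster_lengths, n_bins=n_bins, category=category)
    r, r2 = profile_correlation(clip_prof, pirna_prof)
    return scatter, (r, r2)
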