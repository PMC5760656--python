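"""Sequential-exclusion annotation of small-RNA reads.

Reads are matched ungapped with at most one mismatch (Bowtie ``-v 1``-style
semantics, no indels) against an ordered hierarchy of reference categories —
by default piRNA clusters, then coding RNA, non-coding RNA, repeats, introns —
and each read is assigned to the first category in which it aligns at all.
Reads matching no category fall through to ``other``. This sequential
exclusion makes the category counts a partition of the library.

The matcher is native: a pigeonhole seed search (either half of the read must
match the target exactly when at most one mismatch is allowed) followed by
Hamming verification. ``N`` in a read mismatches every reference base, so a
read with two or more ``N`` can never align.
"""

from __future__ import annotations

import hashlib
import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import yaml

from .io_preprocess import SmallRNARead

SENSE = "sense"
ANTISENSE = "antisense"
_STRAND_ORDER = {SENSE: 0, ANTISENSE: 1}

#: category order used by the default hierarchy (fallthrough appended last)
DEFAULT_CATEGORY_ORDER = (
    "piRNA_clusters",
    "coding_RNA",
    "noncoding_RNA",
    "repeats",
    "intron",
)
#: categories matched on both strands by default; cluster precursors are
#: single-stranded transcripts and are matched sense-only
DEFAULT_BOTH_STRAND_CATEGORIES = frozenset({"repeats", "intron"})

FALLTHROUGH_DEFAULT = "other"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class HierarchyConfigError(ValueError):
    """Invalid category hierarchy (duplicate names, empty categories...)."""


@dataclass(frozen=True, order=True)
class Alignment:
    """One ungapped placement of a read on a reference target."""

    target_name: str
    start: int  # 0-based offset on the target
    strand: str
    mismatches: int

    @property
    def sort_key(self):
        return (self.mismatches, self.target_name, self.start, _STRAND_ORDER[self.strand])


@dataclass(frozen=True)
class ReadAnnotation:
    """Category (and, when matched, target/position) assignment of one read."""

    read_id: str
    category: str
    target_name: Optional[str] = None
    start: Optional[int] = None
    strand: Optional[str] = None
    mismatches: Optional[int] = None


class CategoryHierarchy:
    """Ordered reference categories for sequential-exclusion annotation.

    Parameters
    ----------
    categories
        Ordered ``(name, targets)`` pairs where ``targets`` maps target name
        to an upper-case nucleotide sequence. Order is the annotation
        priority. Category and target names must be globally unique.
    fallthrough_name
        Label for reads matching no category.
    strand_policy
        Optional per-category strand tuple; defaults to sense-only except for
        ``repeats``/``intron`` which are matched on both strands.
    """

    def __init__(
        self,
        categories: Sequence[tuple[str, Mapping[str, str]]],
        fallthrough_name: str = FALLTHROUGH_DEFAULT,
        strand_policy: Optional[Mapping[str, Sequence[str]]] = None,
    ):
        if not categories:
            raise HierarchyConfigError("hierarchy must contain at least one category")
        names = [name for name, _ in categories]
        if len(set(names)) != len(names):
            raise HierarchyConfigError(f"duplicate category names in {names}")
        if fallthrough_name in names:
            raise HierarchyConfigError(f"fallthrough {fallthrough_name!r} clashes with a category")
        seen_targets: dict[str, str] = {}
        for cat, targets in categories:
            for tname in targets:
                if tname in seen_targets:
                    raise HierarchyConfigError(
                        f"target {tname!r} appears in both {seen_targets[tname]!r} and {cat!r}"
                    )
                seen_targets[tname] = cat
        self.categories: list[tuple[str, dict[str, str]]] = [
            (name, dict(targets)) for name, targets in categories
        ]
        self.fallthrough_name = fallthrough_name
        policy = dict(strand_policy or {})
        self.strand_policy: dict[str, tuple[str, ...]] = {}
        for name, _ in self.categories:
            if name in policy:
                self.strand_policy[name] = tuple(policy[name])
            elif name in DEFAULT_BOTH_STRAND_CATEGORIES:
                self.strand_policy[name] = (SENSE, ANTISENSE)
            else:
                self.strand_policy[name] = (SENSE,)

    @property
    def category_names(self) -> list[str]:
        return [name for name, _ in self.categories]

    def targets(self, category: str) -> dict[str, str]:
        for name, targets in self.categories:
            if name == category:
                return targets
        raise KeyError(category)

    def target_lengths(self, category: str) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.targets(category).items()}

    def params_digest(self, max_mismatch: int) -> str:
        """Stable digest of every annotation policy choice, for run reports."""
        payload = {
            "category_order": self.category_names,
            "fallthrough": self.fallthrough_name,
            "strand_policy": {k: list(v) for k, v in self.strand_policy.items()},
            "max_mismatch": max_mismatch,
            "matching": "ungapped-hamming",
            "multimapper": "fewest-mismatches/lex-target/smallest-start/sense-first",
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]

    @classmethod
    def from_fasta_files(
        cls,
        category_fastas: Sequence[tuple[str, str | Path]],
        fallthrough_name: str = FALLTHROUGH_DEFAULT,
        strand_policy: Optional[Mapping[str, Sequence[str]]] = None,
    ) -> "CategoryHierarchy":
        """Build a hierarchy from ordered ``(category_name, fasta_path)`` pairs."""
        from Bio import SeqIO

        cats = []
        for name, path in category_fastas:
            targets = {
                rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
            }
            cats.append((name, targets))
        return cls(cats, fallthrough_name=fallthrough_name, strand_policy=strand_policy)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CategoryHierarchy":
        """Load a hierarchy config: ordered categories, FASTA paths, strands.

        Paths are resolved relative to the YAML file's directory.
        """
        path = Path(path)
        cfg = yaml.safe_load(path.read_text())
        pairs = [(c["name"], path.parent / c["fasta"]) for c in cfg["categories"]]
        policy = {
            c["name"]: c["strands"] for c in cfg["categories"] if "strands" in c
        }
        return cls.from_fasta_files(
            pairs,
            fallthrough_name=cfg.get("fallthrough", FALLTHROUGH_DEFAULT),
            strand_policy=policy or None,
        )


def _hamming_within(a: str, b: str, limit: int) -> int:
    """Mismatch count of equal-length strings, or ``limit + 1`` once exceeded.

    ``N`` on either side counts as a mismatch.
    """
    mm = 0
    for x, y in zip(a, b):
        if x != y or x == "N":
            mm += 1
            if mm > limit:
                return mm
    return mm


def _candidate_starts(query: str, target: str) -> set[int]:
    # pigeonhole: with <=1 mismatch, one half of the read matches exactly
    m = len(query)
    half = m // 2
    starts: set[int] = set()
    limit = len(target) - m
    for seed, offset in ((query[:half], 0), (query[half:], half)):
        i = target.find(seed)
        while i != -1:
            s = i - offset
            if 0 <= s <= limit:
                starts.add(s)
            i = target.find(seed, i + 1)
    return starts


def match_read(
    read: SmallRNARead | str,
    target_name: str,
    target_seq: str,
    max_mismatch: int = 1,
    strands: Sequence[str] = (SENSE,),
) -> list[Alignment]:
    """All ungapped placements of a read on one target within ``max_mismatch``.

    Results are sorted by ``(mismatches, start, strand)``. An empty list means
    no hit. ``max_mismatch`` must be 0 or 1 (the pigeonhole seed search is
    exact only in that regime).
    """
    if max_mismatch not in (0, 1):
        raise ValueError(f"max_mismatch must be 0 or 1, got {max_mismatch}")
    seq = read.seq if isinstance(read, SmallRNARead) else read
    m = len(seq)
    hits: list[Alignment] = []
    if m == 0 or m > len(target_seq):
        return hits
    for strand in strands:
        query = seq if strand == SENSE else reverse_complement(seq)
        if max_mismatch == 0:
            starts: Iterable[int] = []
            found = []
            i = target_seq.find(query)
            while i != -1:
                found.append(i)
                i = target_seq.find(query, i + 1)
            starts = found
        elif m < 2:
            starts = range(len(target_seq) - m + 1)
        else:
            starts = sorted(_candidate_starts(query, target_seq))
        for s in starts:
            mm = _hamming_within(query, target_seq[s : s + m], max_mismatch)
            if mm <= max_mismatch:
                hits.append(Alignment(target_name, s, strand, mm))
    hits.sort(key=lambda a: (a.mismatches, a.start, _STRAND_ORDER[a.strand]))
    return hits


class _CategoryIndex:
    """Concatenated-target search index for one category.

    Targets are joined with a ``#`` separator; candidate placements from the
    pigeonhole seed scan are kept only when fully contained in one target, so
    results are identical to per-target :func:`match_read`.
    """

    KMER = 12

    def __init__(self, targets: Mapping[str, str]):
        self.names: list[str] = []
        self.starts: list[int] = []
        parts: list[str] = []
        pos = 0
        for name, seq in targets.items():
            self.names.append(name)
            self.starts.append(pos)
            parts.append(seq)
            pos += len(seq) + 1
        self.concat = "#".join(parts)
        self.ends = [s + len(targets[n]) for s, n in zip(self.starts, self.names)]
        k = self.KMER
        kmers: dict[str, list[int]] = {}
        concat = self.concat
        for i in range(len(concat) - k + 1):
            kmers.setdefault(concat[i : i + k], []).append(i)
        self.kmers = kmers

    def _locate(self, s: int, m: int) -> Optional[int]:
        import bisect

        i = bisect.bisect_right(self.starts, s) - 1
        if i >= 0 and s + m <= self.ends[i]:
            return i
        return None

    def hits(self, query: str, max_mismatch: int, strand: str) -> list[Alignment]:
        m = len(query)
        out: list[Alignment] = []
        if m == 0:
            return out
        concat = self.concat
        k = self.KMER
        half = m // 2
        seen: set[int] = set()
        limit = len(concat) - m
        if max_mismatch == 0 and m >= k:
            # any exact placement has an exact leading k-mer
            for i in self.kmers.get(query[:k], ()):
                if i <= limit:
                    seen.add(i)
        elif max_mismatch == 1 and half >= k:
            # pigeonhole: one half is exact, so its leading k-mer is exact
            for seed, offset in ((query[:k], 0), (query[half : half + k], half)):
                for i in self.kmers.get(seed, ()):
                    s = i - offset
                    if 0 <= s <= limit:
                        seen.add(s)
        elif max_mismatch == 0:
            i = concat.find(query)
            while i != -1:
                seen.add(i)
                i = concat.find(query, i + 1)
        elif half == 0:
            seen.update(range(limit + 1))
        else:
            for seed, offset in ((query[:half], 0), (query[half:], half)):
                i = concat.find(seed)
                while i != -1:
                    s = i - offset
                    if 0 <= s <= limit:
                        seen.add(s)
                    i = concat.find(seed, i + 1)
        for s in seen:
            ti = self._locate(s, m)
            if ti is None:
                continue
            mm = _hamming_within(query, concat[s : s + m], max_mismatch)
            if mm <= max_mismatch:
                out.append(Alignment(self.names[ti], s - self.starts[ti], strand, mm))
        return out


def assign_within_category(alignments: Sequence[Alignment]) -> Alignment:
    """Deterministic single winner among a read's hits within one category.

    Policy: fewest mismatches, then lexicographically smallest target name,
    then smallest start, then sense before antisense. Each read is counted
    once; fractional multimapper weighting is deliberately not offered so
    every tally is auditable.
    """
    if not alignments:
        raise ValueError("assign_within_category requires at least one alignment")
    return min(alignments, key=lambda a: a.sort_key)


@dataclass
class AnnotatedLibrary:
    """Per-read annotations plus the library-level tallies downstream stages need."""

    annotations: list[ReadAnnotation]
    mirna_count: int
    total_window_reads: int
    params_digest: str
    source: str = "total"

    def __post_init__(self) -> None:
        if len(self.annotations) != self.total_window_reads:
            raise ValueError(
                f"{len(self.annotations)} annotations != total_window_reads "
                f"{self.total_window_reads}"
            )

    def category_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for a in self.annotations:
            counts[a.category] = counts.get(a.category, 0) + 1
        return counts

    def cluster_annotations(self, category: str = "piRNA_clusters") -> list[ReadAnnotation]:
        return [a for a in self.annotations if a.category == category]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "read_id": a.read_id,
                    "category": a.category,
                    "target": a.target_name if a.target_name is not None else "",
                    "start": "" if a.start is None else a.start,
                    "strand": a.strand if a.strand is not None else "",
                    "mismatches": "" if a.mismatches is None else a.mismatches,
                }
                for a in self.annotations
            ],
            columns=["read_id", "category", "target", "start", "strand", "mismatches"],
        )

    def to_tsv(self, path: str | Path) -> None:
        """Serialize annotations with library tallies in header comments."""
        buf = io.StringIO()
        buf.write(f"#mirna_count={self.mirna_count}\n")
        buf.write(f"#total_window_reads={self.total_window_reads}\n")
        buf.write(f"#params_digest={self.params_digest}\n")
        buf.write(f"#source={self.source}\n")
        self.to_dataframe().to_csv(buf, sep="\t", index=False)
        Path(path).write_text(buf.getvalue())

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AnnotatedLibrary":
        path = Path(path)
        meta: dict[str, str] = {}
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                key, _, value = line[1:].rstrip("\n").partition("=")
                meta[key] = value
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            df = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)
        annotations = [
            ReadAnnotation(
                read_id=row.read_id,
                category=row.category,
                target_name=row.target or None,
                start=int(row.start) if row.start != "" else None,
                strand=row.strand or None,
                mismatches=int(row.mismatches) if row.mismatches != "" else None,
            )
            for row in df.itertuples(index=False)
        ]
        return cls(
            annotations=annotations,
            mirna_count=int(meta.get("mirna_count", 0)),
            total_window_reads=int(meta.get("total_window_reads", len(annotations))),
            params_digest=meta.get("params_digest", ""),
            source=meta.get("source", "total"),
        )


def annotate_sequential(
    reads: Sequence[SmallRNARead],
    hierarchy: CategoryHierarchy,
    max_mismatch: int = 1,
    mirna_count: int = 0,
    source: str = "total",
) -> AnnotatedLibrary:
    """Assign each read to the first category (in hierarchy order) it aligns to.

    Reads aligning nowhere receive the hierarchy's fallthrough label. Within
    the winning category the placement is chosen by
    :func:`assign_within_category`.
    """
    if max_mismatch not in (0, 1):
        raise ValueError(f"max_mismatch must be 0 or 1, got {max_mismatch}")
    indices = getattr(hierarchy, "_indices", None)
    if indices is None:
        indices = {name: _CategoryIndex(targets) for name, targets in hierarchy.categories}
        hierarchy._indices = indices
    annotations: list[ReadAnnotation] = []
    for read in reads:
        hit: Optional[Alignment] = None
        category = hierarchy.fallthrough_name
        for cat_name, _ in hierarchy.categories:
            strands = hierarchy.strand_policy[cat_name]
            index = indices[cat_name]
            cat_hits: list[Alignment] = []
            for strand in strands:
                query = read.seq if strand == SENSE else reverse_complement(read.seq)
                cat_hits.extend(index.hits(query, max_mismatch, strand))
            if cat_hits:
                hit = assign_within_category(cat_hits)
                category = cat_name
                break
        if hit is None:
            annotations.append(ReadAnnotation(read.read_id, category))
        else:
            annotations.append(
                ReadAnnotation(
                    read.read_id, category, hit.target_name, hit.start, hit.strand,
                    hit.mismatches,
                )
            )
    return AnnotatedLibrary(
        annotations=annotations,
        mirna_count=mirna_count,
        total_window_reads=len(reads),
        params_digest=hierarchy.params_digest(max_mismatch),
        source=source,
    )
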