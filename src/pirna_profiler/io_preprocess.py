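"""Sequence I/O and read preprocessing for small-RNA libraries.

Raw sequencer output is adapter-clipped (the 3' sequencing adapter is read
through whenever the insert is shorter than the read), then partitioned by
length: 24-32 nt reads form the piRNA analysis window, while 21-23 nt reads
serve as the miRNA proxy used to normalize paired libraries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO

log = logging.getLogger(__name__)

ALPHABET = frozenset("ACGTN")

#: length window of mature piRNAs (nt), inclusive
PIRNA_MIN_LEN, PIRNA_MAX_LEN = 24, 32
#: length window of the miRNA proxy population (nt), inclusive
MIRNA_MIN_LEN, MIRNA_MAX_LEN = 21, 23
#: minimum 3'-anchored adapter prefix accepted as evidence of read-through
MIN_ADAPTER_OVERLAP = 5

SOURCES = ("total", "MILI-IP", "MIWI-IP", "CLIP", "simulated")


class PreprocessConfigError(ValueError):
    """Invalid preprocessing parameterization (e.g. too-short adapter)."""


class SequenceParseError(ValueError):
    """Malformed record in a FASTA/FASTQ input; message names the record index."""


@dataclass(frozen=True)
class SmallRNARead:
    """A single sequenced small-RNA read.

    Attributes
    ----------
    read_id : str
        Record identifier from the sequence file.
    seq : str
        Upper-case nucleotide string over ``{A, C, G, T, N}``.
    source : str
        Library provenance, one of :data:`SOURCES`.
    """

    read_id: str
    seq: str
    source: str = "simulated"

    def __post_init__(self) -> None:
        if not set(self.seq) <= ALPHABET:
            bad = sorted(set(self.seq) - ALPHABET)
            raise ValueError(f"read {self.read_id!r}: invalid symbols {bad}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class PreprocessParams:
    """Adapter-clipping and length-filter settings.

    ``keep_unclipped`` controls the fate of reads in which no adapter (nor a
    3'-anchored adapter prefix of >= 5 nt) is found: they are kept verbatim
    when True (appropriate for simulated, pre-clipped input) and discarded
    when False (raw sequencer FASTQ, where absence of the adapter means the
    insert ran past the read end).
    """

    adapter: str
    min_len: int = PIRNA_MIN_LEN
    max_len: int = PIRNA_MAX_LEN
    keep_unclipped: bool = True

    def __post_init__(self) -> None:
        if len(self.adapter) < MIN_ADAPTER_OVERLAP:
            raise PreprocessConfigError(
                f"adapter must be >= {MIN_ADAPTER_OVERLAP} nt, got {len(self.adapter)}"
            )
        if not (1 <= self.min_len <= self.max_len):
            raise PreprocessConfigError(
                f"need 1 <= min_len <= max_len, got [{self.min_len}, {self.max_len}]"
            )


def _guess_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".fq", ".fastq"}:
        return "fastq"
    if suffix in {".fa", ".fasta", ".fna"}:
        return "fasta"
    raise ValueError(f"cannot infer sequence format from {path.name!r}; pass format=")


def read_sequences(
    path: str | Path, format: Optional[str] = None, source: str = "total"
) -> list[SmallRNARead]:
    """Parse a FASTA/FASTQ file into :class:`SmallRNARead` records.

    Order is preserved and sequences are upper-cased. An empty file yields an
    empty list; a malformed record raises :class:`SequenceParseError` naming
    the 0-based index of the offending record.
    """
    path = Path(path)
    fmt = format or _guess_format(path)
    reads: list[SmallRNARead] = []
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), fmt)):
            reads.append(SmallRNARead(rec.id, str(rec.seq).upper(), source=source))
    except ValueError as exc:
        raise SequenceParseError(
            f"{path.name}: malformed {fmt} record at index {len(reads)}: {exc}"
        ) from exc
    return reads


def write_sequences(
    reads: Iterable[SmallRNARead], path: str | Path, format: str = "fasta"
) -> None:
    """Write reads as unwrapped FASTA or 4-line FASTQ (constant 'I' qualities)."""
    path = Path(path)
    with open(path, "w") as fh:
        for r in reads:
            if format == "fasta":
                fh.write(f">{r.read_id}\n{r.seq}\n")
            elif format == "fastq":
                fh.write(f"@{r.read_id}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")
            else:
                raise ValueError(f"unsupported output format {format!r}")


def clip_adapter(read: SmallRNARead, params: PreprocessParams) -> Optional[SmallRNARead]:
    """Remove 3' adapter read-through from a read.

    If the full adapter occurs anywhere in the read, the 5' portion preceding
    its leftmost occurrence is kept. Otherwise the longest adapter prefix of
    length >= 5 anchored at the read's 3' end is trimmed. Trimming repeats
    until no adapter evidence remains, so clipping is idempotent. With no
    evidence at all the read is returned unchanged when ``keep_unclipped``,
    else ``None`` (discard). Reads clipped to nothing return ``None``.
    """

    def _evidence(seq: str) -> int:
        pos = seq.find(params.adapter)
        if pos != -1:
            return pos
        for k in range(min(len(params.adapter), len(seq)) - 1, MIN_ADAPTER_OVERLAP - 1, -1):
            if seq.endswith(params.adapter[:k]):
                return len(seq) - k
        return -1

    seq = read.seq
    pos = _evidence(seq)
    if pos == -1:
        return read if params.keep_unclipped else None
    while pos != -1:
        if pos == 0:
            return None
        seq = seq[:pos]
        pos = _evidence(seq)
    return replace(read, seq=seq)


def clip_reads(
    reads: Sequence[SmallRNARead], params: PreprocessParams
) -> tuple[list[SmallRNARead], dict]:
    """Adapter-clip a library; returns kept reads and stage counts."""
    kept: list[SmallRNARead] = []
    n_clipped = n_unclipped = n_discarded = 0
    for read in reads:
        out = clip_adapter(read, params)
        if out is None:
            n_discarded += 1
            continue
        if out.seq is read.seq or len(out) == len(read):
            n_unclipped += 1
        else:
            n_clipped += 1
        kept.append(out)
    counts = {
        "input": len(reads),
        "clipped": n_clipped,
        "unclipped_kept": n_unclipped,
        "discarded": n_discarded,
        "output": len(kept),
    }
    log.info("adapter clipping: %s", counts)
    return kept, counts


def length_filter(
    reads: Sequence[SmallRNARead], min_len: int, max_len: int
) -> list[SmallRNARead]:
    """Retain reads with ``min_len <= length <= max_len``, order preserved."""
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    kept = [r for r in reads if min_len <= len(r) <= max_len]
    log.info(
        "length filter [%d, %d]: retained %d, removed %d",
        min_len, max_len, len(kept), len(reads) - len(kept),
    )
    return kept


def select_mirna_proxy(reads: Sequence[SmallRNARead]) -> list[SmallRNARead]:
    """Return the miRNA-proxy subset (21-23 nt) of an adapter-clipped library.

    The size of this set is the library's miRNA count used for paired-library
    normalization; callers must treat a zero count as an error at that stage.
    """
    return [r for r in reads if MIRNA_MIN_LEN <= len(r) <= MIRNA_MAX_LEN]


def preprocess(
    reads: Sequence[SmallRNARead], params: PreprocessParams
) -> tuple[list[SmallRNARead], list[SmallRNARead], dict]:
    """Full preprocessing: clip, then split into window reads and miRNA proxy.

    Returns ``(window_reads, mirna_proxy_reads, stage_counts)`` where the
    window is ``[params.min_len, params.max_len]``.
    """
    clipped, counts = clip_reads(reads, params)
    window = length_filter(clipped, params.min_len, params.max_len)
    mirna = select_mirna_proxy(clipped)
    counts = dict(counts)
    counts.update(
        window_reads=len(window),
        mirna_proxy_reads=len(mirna),
        window=[params.min_len, params.max_len],
    )
    return window, mirna, counts
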