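"""Raw FASTQ -> length-filtered unique tags with counts.

The small-RNA preprocessing ladder: parse Phred+33 FASTQ, drop low-quality
reads, trim the 3' sequencing adapter by exact prefix search, keep inserts of
18-30 nt, and collapse identical sequences into unique tags.  Counts are
conserved at every stage (retained + dropped = input) and the whole ladder is
a pure function of the input bytes.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._seq import to_rna

DEFAULT_MIN_LEN = 18
DEFAULT_MAX_LEN = 30


class FastqParseError(ValueError):
    """Malformed FASTQ record; carries the 1-based record index."""


@dataclass(frozen=True)
class SmallRNARead:
    """One sequencing read: id, uppercased sequence and decoded Phred scores."""

    id: str
    sequence: str
    quality: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(
                f"read {self.id!r}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.quality)}"
            )

    @property
    def mean_quality(self) -> float:
        return sum(self.quality) / len(self.quality) if self.quality else 0.0


@dataclass(frozen=True)
class UniqueTag:
    """A distinct insert sequence (RNA-space) with its aggregate read count."""

    tag_id: str
    sequence: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("tag count must be >= 1")


@dataclass
class PreprocessStats:
    raw_reads: int = 0
    post_quality: int = 0
    post_adapter: int = 0
    post_length: int = 0
    unique_tags: int = 0

    def validate(self) -> None:
        if not (
            self.raw_reads >= self.post_quality >= self.post_adapter >= self.post_length
        ):
            raise ValueError(f"stage counts must be non-increasing: {self}")
        if self.unique_tags > self.post_length:
            raise ValueError("unique tags cannot exceed retained reads")


def read_fastq(stream) -> Iterator[SmallRNARead]:
    """Stream 4-line Phred+33 FASTQ records as :class:`SmallRNARead`.

    ``stream`` may be a path or an open text handle.  Sequences are
    uppercased (alphabet is validated downstream, DNA or RNA accepted).
    Truncated records and sequence/quality length mismatches raise
    :class:`FastqParseError` naming the offending record.
    """
    if isinstance(stream, (str,)):
        handle: io.TextIOBase = open(stream)
        own = True
    else:
        handle, own = stream, False
    try:
        it = FastqGeneralIterator(handle)
        index = 0
        while True:
            index += 1
            try:
                title, seq, qual = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise FastqParseError(f"record {index}: {exc}") from exc
            if len(seq) != len(qual):
                raise FastqParseError(
                    f"record {index} ({title.split()[0] if title else '?'}): "
                    f"sequence and quality lengths differ ({len(seq)} vs {len(qual)})"
                )
            yield SmallRNARead(
                id=title.split()[0] if title else f"read{index}",
                sequence=seq.upper(),
                quality=tuple(ord(c) - 33 for c in qual),
            )
    finally:
        if own:
            handle.close()


def quality_filter(
    reads: Iterable[SmallRNARead],
    min_mean_phred: float = 20.0,
    max_n: int = 0,
) -> list[SmallRNARead]:
    """Keep reads with mean Phred >= threshold and at most ``max_n`` N bases."""
    kept = []
    for read in reads:
        if read.mean_quality >= min_mean_phred and read.sequence.count("N") <= max_n:
            kept.append(read)
    return kept


def find_adapter_start(
    sequence: str, adapter3: str, min_overlap: int = 6
) -> int | None:
    """Leftmost position where a prefix of ``adapter3`` (>= ``min_overlap`` nt,
    or the full adapter if it fits) starts in ``sequence``; None if absent.

    Exact matching only: the stage stays an oracle-checkable string search.
    """
    if not adapter3:
        raise ValueError("adapter must be non-empty")
    seq = to_rna(sequence)
    adapter = to_rna(adapter3)
    n, m = len(seq), len(adapter)
    for start in range(n):
        k = min(m, n - start)
        if k < min(m, min_overlap):
            break
        if seq[start : start + k] == adapter[:k]:
            return start
    return None


@dataclass(frozen=True)
class TrimmedRead:
    id: str
    insert: str  # RNA-space
    adapter_found: bool


def trim_adapter(
    read: SmallRNARead, adapter3: str, min_overlap: int = 6
) -> TrimmedRead | None:
    """Return the 5' insert of ``read``; None when the insert is empty.

    Reads without an adapter hit are returned untrimmed with
    ``adapter_found=False`` (they are typically discarded later by the
    length filter).
    """
    seq = to_rna(read.sequence)
    start = find_adapter_start(seq, adapter3, min_overlap=min_overlap)
    if start is None:
        return TrimmedRead(read.id, seq, adapter_found=False)
    if start == 0:
        return None
    return TrimmedRead(read.id, seq[:start], adapter_found=True)


def length_filter(
    inserts: Iterable[TrimmedRead],
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> list[TrimmedRead]:
    """Keep inserts with min_len <= length <= max_len (both ends inclusive)."""
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    return [r for r in inserts if min_len <= len(r.insert) <= max_len]


def collapse(sequences: Iterable[str]) -> list[UniqueTag]:
    """Collapse reads into unique tags (T->U normalized).

    One tag per distinct sequence; count = multiplicity.  Tag ids are
    assigned in descending-count order, ties broken lexicographically, so the
    result is invariant to input order.
    """
    counts = Counter(to_rna(s) for s in sequences)
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [
        UniqueTag(tag_id=f"tag{i + 1}", sequence=seq, count=n)
        for i, (seq, n) in enumerate(ordered)
    ]


@dataclass
class PreprocessResult:
    tags: list[UniqueTag]
    stats: PreprocessStats
    inserts: pd.DataFrame = field(repr=False)  # read_id, insert, adapter_found
    """Per-read insert table (post-quality reads), for truth-table round trips."""


def run(
    reads: Iterable[SmallRNARead],
    adapter3: str,
    *,
    min_mean_phred: float = 20.0,
    max_n: int = 0,
    min_overlap: int = 6,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> PreprocessResult:
    """Full ladder: quality filter -> adapter trim -> length filter -> collapse."""
    reads = list(reads)
    stats = PreprocessStats(raw_reads=len(reads))
    hq = quality_filter(reads, min_mean_phred=min_mean_phred, max_n=max_n)
    stats.post_quality = len(hq)
    trimmed: list[TrimmedRead] = []
    rows = []
    for read in hq:
        t = trim_adapter(read, adapter3, min_overlap=min_overlap)
        if t is not None:
            trimmed.append(t)
            rows.append((t.id, t.insert, t.adapter_found))
    stats.post_adapter = len(trimmed)
    sized = length_filter(trimmed, min_len=min_len, max_len=max_len)
    stats.post_length = len(sized)
    tags = collapse(r.insert for r in sized)
    stats.unique_tags = len(tags)
    stats.validate()
    inserts = pd.DataFrame(rows, columns=["read_id", "insert", "adapter_found"])
    return PreprocessResult(tags=tags, stats=stats, inserts=inserts)


def run_fastq(path, adapter3: str, **kwargs) -> PreprocessResult:
    return run(read_fastq(path), adapter3, **kwargs)


def write_collapsed_fasta(tags: Sequence[UniqueTag], path) -> None:
    """Collapsed-FASTA dialect: ``>tagN_xCOUNT`` headers."""
    with open(path, "w") as fh:
        for tag in tags:
            fh.write(f">{tag.tag_id}_x{tag.count}\n{tag.sequence}\n")
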