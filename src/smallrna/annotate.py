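"""Hierarchical tag annotation against a genome and reference sequence sets.

Each unique tag receives exactly one category, with the precedence
conserved miRNA > rRNA > tRNA > snoRNA > other ncRNA; tags matching no
reference are genome-mapped (ungapped, mismatch-tolerant, both strands) and
become either novel-prediction input or remain unannotated.

Reference matching is ungapped containment with a substitution cap - at toy
scale this is an exact, deterministic stand-in for the BLAST-style matching
used on real libraries.  Conserved-miRNA matching additionally tolerates
small 5'/3' end offsets so terminal isomiRs are still assigned to their
miRNA, but the alignment must cover the reference seed (positions 2-8).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import revcomp_rna, to_rna
from .preprocess import UniqueTag

CATEGORY_ORDER = [
    "conserved_mirna",
    "rrna",
    "trna",
    "snorna",
    "other_ncrna",
    "novel_input",
    "unannotated",
]

#: reference-set key -> category it assigns
REF_CATEGORY = {
    "mature": "conserved_mirna",
    "rrna": "rrna",
    "trna": "trna",
    "snorna": "snorna",
    "other": "other_ncrna",
}


@dataclass(frozen=True)
class GenomeAlignment:
    tag_id: str
    chrom: str
    start: int  # 0-based
    end: int  # exclusive
    strand: str  # '+' or '-'
    n_mismatches: int
    mismatch_positions: tuple[int, ...]  # 1-based in tag


@dataclass(frozen=True)
class ReferenceHit:
    reference_id: str
    n_mismatches: int
    offset: int  # 0-based start of the tag within the reference
    offset5: int = 0  # end offsets; only used by conserved-miRNA matching
    offset3: int = 0


@dataclass(frozen=True)
class AnnotationRecord:
    tag_id: str
    category: str
    reference_id: str = ""
    n_mismatches: int = 0

    def __post_init__(self) -> None:
        if self.category not in CATEGORY_ORDER:
            raise ValueError(f"unknown category {self.category!r}")
        if (self.reference_id == "") != (
            self.category in ("novel_input", "unannotated")
        ):
            raise ValueError(
                "reference_id must be empty iff category is novel_input/unannotated"
            )


class GenomeIndex:
    """Sliding-window mismatch search over a (small) genome, both strands.

    The genome is held as byte arrays; for a query of length L the mismatch
    count at every offset is a single vectorized comparison against the
    cached window view for L.
    """

    def __init__(self, genome: Mapping[str, str] | str):
        if isinstance(genome, str):
            genome = {"chr1": genome}
        self.chroms: dict[str, str] = {c: to_rna(s) for c, s in genome.items()}
        self._enc = {
            c: np.frombuffer(s.encode(), dtype=np.uint8) for c, s in self.chroms.items()
        }
        self._windows: dict[tuple[str, int], np.ndarray] = {}

    def _window_view(self, chrom: str, length: int) -> np.ndarray | None:
        key = (chrom, length)
        if key not in self._windows:
            enc = self._enc[chrom]
            if length > enc.size:
                self._windows[key] = None
            else:
                self._windows[key] = np.lib.stride_tricks.sliding_window_view(
                    enc, length
                )
        return self._windows[key]

    def search(self, sequence: str, max_mm: int) -> list[tuple[str, int, str, int, tuple[int, ...]]]:
        """All ungapped hits of ``sequence`` with <= max_mm substitutions.

        Returns (chrom, start, strand, n_mismatches, mismatch_positions)
        tuples; mismatch positions are 1-based in the query as given (for
        minus-strand hits, in the original tag orientation).
        """
        seq = to_rna(sequence)
        hits = []
        queries = {"+": seq, "-": revcomp_rna(seq)}
        L = len(seq)
        for chrom in self.chroms:
            windows = self._window_view(chrom, L)
            if windows is None:
                continue
            for strand, q in queries.items():
                qarr = np.frombuffer(q.encode(), dtype=np.uint8)
                diff = windows != qarr
                mm = diff.sum(axis=1)
                for start in np.flatnonzero(mm <= max_mm):
                    pos = np.flatnonzero(diff[start])  # 0-based in genome orientation
                    if strand == "-":
                        pos = L - 1 - pos[::-1]
                    hits.append(
                        (chrom, int(start), strand, int(mm[start]),
                         tuple(int(p) + 1 for p in pos))
                    )
        return hits


def map_to_genome(
    tag: UniqueTag | str,
    genome: GenomeIndex | Mapping[str, str] | str,
    max_mm: int = 1,
) -> list[GenomeAlignment]:
    """All ungapped genome alignments of a tag with <= ``max_mm`` mismatches,
    sorted by (n_mismatches, chrom, start, strand)."""
    if not isinstance(genome, GenomeIndex):
        genome = GenomeIndex(genome)
    seq = tag.sequence if isinstance(tag, UniqueTag) else to_rna(tag)
    tag_id = tag.tag_id if isinstance(tag, UniqueTag) else ""
    out = [
        GenomeAlignment(
            tag_id=tag_id,
            chrom=chrom,
            start=start,
            end=start + len(seq),
            strand=strand,
            n_mismatches=mm,
            mismatch_positions=pos,
        )
        for chrom, start, strand, mm, pos in genome.search(seq, max_mm)
    ]
    out.sort(key=lambda a: (a.n_mismatches, a.chrom, a.start, a.strand))
    return out


def match_reference_set(
    tag: UniqueTag | str,
    refs: Mapping[str, str],
    max_mm: int = 1,
) -> ReferenceHit | None:
    """Best ungapped containment of the tag within any reference.

    Best = fewest mismatches; ties broken by reference order (insertion
    order of ``refs``) then smallest offset.  None when nothing aligns
    within ``max_mm`` substitutions.
    """
    if not refs:
        raise ValueError("reference set is empty")
    seq = tag.sequence if isinstance(tag, UniqueTag) else to_rna(tag)
    L = len(seq)
    qarr = np.frombuffer(seq.encode(), dtype=np.uint8)
    best: ReferenceHit | None = None
    for ref_id, ref_seq in refs.items():
        ref = to_rna(ref_seq)
        if L > len(ref):
            continue
        rarr = np.frombuffer(ref.encode(), dtype=np.uint8)
        windows = np.lib.stride_tricks.sliding_window_view(rarr, L)
        mm = (windows != qarr).sum(axis=1)
        idx = int(np.argmin(mm))
        if mm[idx] <= max_mm and (best is None or mm[idx] < best.n_mismatches):
            best = ReferenceHit(ref_id, int(mm[idx]), idx)
    return best


def match_conserved_mirna(
    tag: UniqueTag | str,
    mature_refs: Mapping[str, str],
    max_mm: int = 2,
    max_end_offset: int = 3,
) -> ReferenceHit | None:
    """Assign a tag to a mature miRNA, tolerating terminal-isomiR end offsets.

    The tag is anchored to each reference at 5' offsets in
    [-max_end_offset, +max_end_offset] (positive = tag extends past the
    reference 5' end); the implied 3' offset must obey the same bound.
    Substitutions are counted over the overlap only (end extensions are
    free), the overlap must cover reference seed positions 2-8, and at most
    ``max_mm`` substitutions are allowed.  Best hit by
    (mismatches, |5' offset|, reference order).
    """
    seq = tag.sequence if isinstance(tag, UniqueTag) else to_rna(tag)
    L = len(seq)
    best: tuple[int, int, int] | None = None  # (mm, |o5|, ref_index)
    best_hit: ReferenceHit | None = None
    for ref_index, (ref_id, ref_seq) in enumerate(mature_refs.items()):
        ref = to_rna(ref_seq)
        C = len(ref)
        for o5 in sorted(range(-max_end_offset, max_end_offset + 1), key=abs):
            o3 = (L - o5) - C
            if abs(o3) > max_end_offset:
                continue
            # reference position c (0-based) aligns to tag position c + o5
            lo = max(0, -o5)
            hi = min(C, L - o5)
            if hi <= lo:
                continue
            if lo > 1 or hi < 8:  # must cover seed positions 2-8 (1-based)
                continue
            mm = sum(1 for c in range(lo, hi) if ref[c] != seq[c + o5])
            if mm > max_mm:
                continue
            key = (mm, abs(o5), ref_index)
            if best is None or key < best:
                best = key
                best_hit = ReferenceHit(ref_id, mm, lo, offset5=o5, offset3=o3)
    return best_hit


@dataclass
class ClassifyResult:
    records: list[AnnotationRecord]
    alignments: dict[str, list[GenomeAlignment]] = field(repr=False)
    """Genome alignments for novel_input tags (input to hairpin discovery)."""
    counts: pd.DataFrame = field(repr=False)
    """Per-category totals in read and unique-tag units."""


def classify(
    tags: Sequence[UniqueTag],
    genome: GenomeIndex | Mapping[str, str] | str,
    ref_sets: Mapping[str, Mapping[str, str]],
    *,
    genome_max_mm: int = 1,
    mirna_max_mm: int = 2,
    mirna_max_end_offset: int = 3,
    ncrna_max_mm: int = 1,
) -> ClassifyResult:
    """Assign one category per tag and tabulate counts.

    ``ref_sets`` maps class keys ('mature', 'rrna', 'trna', 'snorna',
    'other') to {name: sequence} mappings; any subset may be present, but a
    reference name may not recur across sets.  Genome mapping is only
    consulted for tags that match no reference set.
    """
    if not isinstance(genome, GenomeIndex):
        genome = GenomeIndex(genome)
    seen: dict[str, str] = {}
    for key, refs in ref_sets.items():
        if key not in REF_CATEGORY:
            raise ValueError(f"unknown reference set {key!r}")
        for name in refs:
            if name in seen:
                raise ValueError(
                    f"reference name {name!r} appears in both {seen[name]!r} and {key!r}"
                )
            seen[name] = key

    records: list[AnnotationRecord] = []
    alignments: dict[str, list[GenomeAlignment]] = {}
    for tag in tags:
        record = None
        for key in ("mature", "rrna", "trna", "snorna", "other"):
            refs = ref_sets.get(key)
            if not refs:
                continue
            if key == "mature":
                hit = match_conserved_mirna(
                    tag, refs, max_mm=mirna_max_mm, max_end_offset=mirna_max_end_offset
                )
            else:
                hit = match_reference_set(tag, refs, max_mm=ncrna_max_mm)
            if hit is not None:
                record = AnnotationRecord(
                    tag.tag_id, REF_CATEGORY[key], hit.reference_id, hit.n_mismatches
                )
                break
        if record is None:
            hits = map_to_genome(tag, genome, max_mm=genome_max_mm)
            if hits:
                alignments[tag.tag_id] = hits
                record = AnnotationRecord(tag.tag_id, "novel_input")
            else:
                record = AnnotationRecord(tag.tag_id, "unannotated")
        records.append(record)

    by_tag = {t.tag_id: t for t in tags}
    rows = []
    for cat in CATEGORY_ORDER:
        cat_records = [r for r in records if r.category == cat]
        rows.append(
            {
                "category": cat,
                "total_reads": sum(by_tag[r.tag_id].count for r in cat_records),
                "unique_tags": len(cat_records),
            }
        )
    counts = pd.DataFrame(rows)
    return ClassifyResult(records=records, alignments=alignments, counts=counts)
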