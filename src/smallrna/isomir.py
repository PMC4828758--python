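"""IsomiR classification: relate each miRNA-assigned tag to its canonical
mature sequence and summarize variant classes.

A tag is anchored to the canonical by an ungapped end-offset alignment
(each end offset within +/-5 nt, chosen to minimize substitutions), then
classified: 5' isomiR (altered 5' end), 3' isomiR (trimming, templated
extension, or non-templated A/U addition), internal isomiR (substitutions
only; flagged in/out of the seed, canonical positions 2-8), or mixed when
several component edits co-occur.  Summaries are read-weighted, matching the
convention in which isomiR percentages are fractions of reads.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from ._seq import to_rna

MAX_END_OFFSET = 5
MAX_SUBSTITUTIONS = 2

CLASSES = ("canonical", "iso5", "iso3", "internal", "mixed")


class IsomirAssignmentError(ValueError):
    """No alignment with <= 2 substitutions within the end-offset bounds."""


def extract_seed(sequence: str) -> str:
    """The 7-nt seed: positions 2-8 (1-based, inclusive) of the mature 5'->3'."""
    seq = to_rna(sequence)
    if len(seq) < 8:
        raise ValueError(f"sequence shorter than 8 nt: {seq!r}")
    return seq[1:8]


@dataclass(frozen=True)
class Substitution:
    position: int  # 1-based in the canonical-aligned frame
    ref: str
    alt: str

    @property
    def in_seed(self) -> bool:
        return 2 <= self.position <= 8


@dataclass(frozen=True)
class CanonicalAlignment:
    tag: str
    canonical: str
    offset5: int  # negative = 5' trimmed, positive = 5' extended
    offset3: int
    substitutions: tuple[Substitution, ...]


def align_to_canonical(
    tag: str,
    canonical: str,
    max_offset: int = MAX_END_OFFSET,
    max_substitutions: int = MAX_SUBSTITUTIONS,
) -> CanonicalAlignment:
    """Ungapped anchored alignment of a tag to its canonical mature.

    Scans all 5' end offsets within +/-``max_offset`` (the 3' offset is then
    fixed by the length difference) and keeps the offset pair minimizing
    substitutions in the overlap; ties prefer the smallest |5' offset|.
    Raises :class:`IsomirAssignmentError` when nothing aligns with at most
    ``max_substitutions`` substitutions.
    """
    tag = to_rna(tag)
    canonical = to_rna(canonical)
    L, C = len(tag), len(canonical)
    best: CanonicalAlignment | None = None
    best_key: tuple[int, int, int] | None = None
    for o5 in sorted(range(-max_offset, max_offset + 1), key=lambda o: (abs(o), o)):
        o3 = (L - o5) - C
        if abs(o3) > max_offset:
            continue
        lo = max(0, -o5)  # canonical coordinates of the overlap
        hi = min(C, L - o5)
        if hi <= lo:
            continue
        subs = tuple(
            Substitution(c + 1, canonical[c], tag[c + o5])
            for c in range(lo, hi)
            if canonical[c] != tag[c + o5]
        )
        key = (len(subs), abs(o5), abs(o3))
        if best_key is None or key < best_key:
            best_key = key
            best = CanonicalAlignment(tag, canonical, o5, o3, subs)
    if best is None or len(best.substitutions) > max_substitutions:
        raise IsomirAssignmentError(
            f"tag {tag!r} does not align to {canonical!r} within "
            f"+/-{max_offset} nt end offsets and {max_substitutions} substitutions"
        )
    return best


@dataclass(frozen=True)
class IsomiRRecord:
    mirna_id: str
    tag_id: str
    count: int
    isomir_class: str  # canonical | iso5 | iso3 | internal | mixed
    subtype5: str  # none | trim | ext_templated | ext_nontemplated
    subtype3: str  # none | trim | ext_templated | add_nontemplated
    add3_nucleotide: str | None  # A | U | other (non-templated additions only)
    offset5: int
    offset3: int
    substitutions: tuple[Substitution, ...]

    def __post_init__(self) -> None:
        if self.isomir_class not in CLASSES:
            raise ValueError(f"unknown isomiR class {self.isomir_class!r}")
        canonical = (
            self.offset5 == 0 and self.offset3 == 0 and not self.substitutions
        )
        if canonical != (self.isomir_class == "canonical"):
            raise ValueError("class inconsistent with offsets/substitutions")


def classify_isomir(
    alignment: CanonicalAlignment,
    context: str | None = None,
    *,
    mirna_id: str = "",
    tag_id: str = "",
    count: int = 1,
) -> IsomiRRecord:
    """Classify an aligned tag into the isomiR taxonomy.

    ``context`` is the strand-local genomic sequence containing the
    canonical mature (any flank length); it is required whenever the tag
    extends past a canonical end, to decide templated vs non-templated.
    """
    o5, o3 = alignment.offset5, alignment.offset3
    tag, canonical = alignment.tag, alignment.canonical

    flank5 = flank3 = None
    if context is not None:
        ctx = to_rna(context)
        idx = ctx.find(canonical)
        if idx < 0:
            raise ValueError("canonical sequence not found in context")
        flank5, flank3 = ctx[:idx], ctx[idx + len(canonical) :]

    subtype5 = "none"
    if o5 < 0:
        subtype5 = "trim"
    elif o5 > 0:
        if flank5 is None:
            raise ValueError("precursor context required to classify a 5' extension")
        added = tag[:o5]
        subtype5 = (
            "ext_templated" if added == flank5[-o5:] else "ext_nontemplated"
        )

    subtype3 = "none"
    add3 = None
    if o3 < 0:
        subtype3 = "trim"
    elif o3 > 0:
        if flank3 is None:
            raise ValueError("precursor context required to classify a 3' extension")
        added = tag[len(tag) - o3 :]
        if added == flank3[:o3]:
            subtype3 = "ext_templated"
        else:
            subtype3 = "add_nontemplated"
            uniq = set(added)
            add3 = added[0] if uniq <= {"A"} or uniq <= {"U"} else "other"

    components = sum([o5 != 0, o3 != 0, bool(alignment.substitutions)])
    if components == 0:
        cls = "canonical"
    elif components > 1:
        cls = "mixed"
    elif o5 != 0:
        cls = "iso5"
    elif o3 != 0:
        cls = "iso3"
    else:
        cls = "internal"

    return IsomiRRecord(
        mirna_id=mirna_id,
        tag_id=tag_id,
        count=count,
        isomir_class=cls,
        subtype5=subtype5,
        subtype3=subtype3,
        add3_nucleotide=add3,
        offset5=o5,
        offset3=o3,
        substitutions=alignment.substitutions,
    )


@dataclass
class IsomirSummary:
    n_reads: int
    read_fractions: dict[str, float]  # over all classes, sums to 1
    tag_fractions: dict[str, float]
    noncanonical_read_fractions: dict[str, float]  # over iso5/iso3/internal/mixed
    iso3_trim_fraction: float  # reads with pure 3'-trim among iso3 reads
    per_mirna_isomirs: pd.DataFrame  # mirna_id, arm, n_isomirs (distinct tags)


def _arm_of(mirna_id: str) -> str:
    if mirna_id.endswith("-5p"):
        return "5p"
    if mirna_id.endswith("-3p"):
        return "3p"
    return "na"


def summarize_isomirs(records: Sequence[IsomiRRecord] | Iterable[IsomiRRecord]) -> IsomirSummary:
    """Read-weighted class fractions plus per-miRNA distinct-isomiR counts.

    Fractions are invariant to record order and to splitting one tag's count
    across duplicate records (everything is count-weighted).
    """
    records = list(records)
    if not records:
        raise ValueError("no isomiR records to summarize")
    total = sum(r.count for r in records)
    read_counts = {c: 0 for c in CLASSES}
    tag_seqs: dict[str, set[str]] = {c: set() for c in CLASSES}
    iso3_reads = iso3_trim_reads = 0
    for r in records:
        read_counts[r.isomir_class] += r.count
        tag_seqs[r.isomir_class].add(r.tag_id)
        if r.isomir_class == "iso3":
            iso3_reads += r.count
            if r.subtype3 == "trim":
                iso3_trim_reads += r.count
    n_tags = sum(len(s) for s in tag_seqs.values())
    read_fractions = {c: read_counts[c] / total for c in CLASSES}
    tag_fractions = {c: len(tag_seqs[c]) / n_tags for c in CLASSES}
    noncanon = total - read_counts["canonical"]
    noncanonical_read_fractions = {
        c: (read_counts[c] / noncanon if noncanon else 0.0)
        for c in CLASSES
        if c != "canonical"
    }
    per = (
        pd.DataFrame(
            [
                {"mirna_id": r.mirna_id, "arm": _arm_of(r.mirna_id), "tag_id": r.tag_id}
                for r in records
            ]
        )
        .groupby(["mirna_id", "arm"])["tag_id"]
        .nunique()
        .rename("n_isomirs")
        .reset_index()
    )
    return IsomirSummary(
        n_reads=total,
        read_fractions=read_fractions,
        tag_fractions=tag_fractions,
        noncanonical_read_fractions=noncanonical_read_fractions,
        iso3_trim_fraction=(iso3_trim_reads / iso3_reads) if iso3_reads else 0.0,
        per_mirna_isomirs=per,
    )
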