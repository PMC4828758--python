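"""Novel-miRNA discovery from genomic windows around unannotated tag clusters.

The discovery loop mirrors the MIREAP recipe: cluster genome alignments of
candidate tags, excise flanking windows on both sides of the cluster anchor,
fold, and accept loci whose structure is a single stem-loop with the mature
read on one arm, well paired, and supported by at least two distinct reads
starting at mature (or star) positions.

Folding is a weighted Nussinov dynamic program (pair weights G-C=3, A-U=2,
G-U=1, minimum hairpin loop 3 nt) rather than a thermodynamic model: at toy
scale the maximum-weight structure of a designed hairpin is the designed
stem, and the DP is exactly checkable against brute-force enumeration.  The
``fold_fn`` argument of :func:`evaluate_hairpin` allows substituting an
external thermodynamic folder.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from ._seq import check_rna, revcomp_rna, to_rna
from .annotate import GenomeAlignment

DEFAULT_PAIR_WEIGHTS = {"GC": 3, "AU": 2, "GU": 1}
MIN_LOOP = 3

_WEIGHT_KEY = {
    ("G", "C"): "GC", ("C", "G"): "GC",
    ("A", "U"): "AU", ("U", "A"): "AU",
    ("G", "U"): "GU", ("U", "G"): "GU",
}


def pair_weight(a: str, b: str, weights: Mapping[str, int] = DEFAULT_PAIR_WEIGHTS) -> int:
    key = _WEIGHT_KEY.get((a, b))
    return weights[key] if key else 0


@dataclass(frozen=True)
class FoldResult:
    sequence: str
    structure: str  # dot-bracket
    pairs: tuple[tuple[int, int], ...]  # 1-based, i < j
    score: int

    @property
    def paired_positions(self) -> dict[int, int]:
        """1-based position -> partner, both directions."""
        out = {}
        for i, j in self.pairs:
            out[i] = j
            out[j] = i
        return out


def _weight_matrix(seq: str, weights: Mapping[str, int]) -> np.ndarray:
    n = len(seq)
    pw = np.zeros((n, n), dtype=np.int32)
    for i in range(n):
        for j in range(n):
            pw[i, j] = pair_weight(seq[i], seq[j], weights)
    return pw


def fold(
    sequence: str,
    min_loop: int = MIN_LOOP,
    weights: Mapping[str, int] = DEFAULT_PAIR_WEIGHTS,
) -> FoldResult:
    """Maximum-weight nested secondary structure (weighted Nussinov).

    Recurrence on interval weight W(i,j): leave i or j unpaired, pair (i,j)
    when allowed (|j-i| > min_loop, canonical pair), or split the interval.
    Diagonals are computed vectorized; the traceback is deterministic
    (pair > leave-i > leave-j > split at the largest split point).
    """
    seq = to_rna(sequence)
    check_rna(seq)
    n = len(seq)
    if n == 0:
        return FoldResult("", "", (), 0)
    pw = _weight_matrix(seq, weights)
    W = np.zeros((n, n), dtype=np.int32)
    for span in range(min_loop + 1, n):
        i = np.arange(0, n - span)
        j = i + span
        best = np.maximum(W[i + 1, j], W[i, j - 1])
        best = np.maximum(best, W[i + 1, j - 1] + pw[i, j])
        for d in range(span - 1):
            best = np.maximum(best, W[i, i + d] + W[i + d + 1, j])
        W[i, j] = best

    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= min_loop:
            continue
        w = W[i, j]
        if w == 0:
            continue
        if pw[i, j] > 0 and w == W[i + 1, j - 1] + pw[i, j]:
            pairs.append((i + 1, j + 1))
            stack.append((i + 1, j - 1))
            continue
        if w == W[i + 1, j]:
            stack.append((i + 1, j))
            continue
        if w == W[i, j - 1]:
            stack.append((i, j - 1))
            continue
        for k in range(j - 1, i, -1):
            if w == W[i, k] + W[k + 1, j]:
                stack.append((i, k))
                stack.append((k + 1, j))
                break

    structure = ["."] * n
    for i, j in pairs:
        structure[i - 1] = "("
        structure[j - 1] = ")"
    pairs.sort()
    return FoldResult(seq, "".join(structure), tuple(pairs), int(W[0, n - 1]))


def pairs_from_dotbracket(structure: str) -> list[tuple[int, int]]:
    """1-based pair list; raises on unbalanced strings."""
    stack: list[int] = []
    pairs = []
    for idx, ch in enumerate(structure, start=1):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {idx}")
            pairs.append((stack.pop(), idx))
        elif ch != ".":
            raise ValueError(f"invalid dot-bracket character {ch!r}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return sorted(pairs)


def is_unbranched(structure: str) -> bool:
    """True iff no pair encloses two disjoint pairs (no internal multiloop).

    Disjoint stems at the exterior level are allowed by this predicate;
    single-stem-loop enforcement is done by the hairpin evaluator, which
    additionally requires exactly one hairpin loop.
    """
    # children-per-pair count via a stack parse
    stack: list[list[int]] = [[0]]  # child counters; stack[0] is the exterior
    for idx, ch in enumerate(structure, start=1):
        if ch == "(":
            stack.append([0])
        elif ch == ")":
            if len(stack) == 1:
                raise ValueError(f"unbalanced ')' at position {idx}")
            children = stack.pop()[0]
            if children >= 2:
                return False
            stack[-1][0] += 1
        elif ch != ".":
            raise ValueError(f"invalid dot-bracket character {ch!r}")
    if len(stack) != 1:
        raise ValueError("unbalanced '(' in structure")
    return True


def filter_short_helices(
    pairs: Sequence[tuple[int, int]], min_helix: int = 3
) -> list[tuple[int, int]]:
    """Drop helices shorter than ``min_helix`` stacked pairs.

    A maximum-weight fold decorates loops and bulges with thermodynamically
    implausible lone pairs; topology criteria (stem-loop, arm membership)
    are therefore judged on the structure with short helices removed, the
    counterpart of the no-lone-pair convention in thermodynamic folders.
    """
    pairs = sorted(pairs)
    pair_set = set(pairs)
    kept: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    for p in pairs:
        if p in seen:
            continue
        helix = [p]
        i, j = p
        while (i + 1, j - 1) in pair_set:
            i, j = i + 1, j - 1
            helix.append((i, j))
        seen.update(helix)
        if len(helix) >= min_helix:
            kept.extend(helix)
    return kept


def structure_from_pairs(n: int, pairs: Sequence[tuple[int, int]]) -> str:
    out = ["."] * n
    for i, j in pairs:
        out[i - 1] = "("
        out[j - 1] = ")"
    return "".join(out)


def n_hairpin_loops(structure: str) -> int:
    """Number of terminal (hairpin) loops = pairs enclosing no other pair."""
    stack: list[int] = []
    count = 0
    for ch in structure:
        if ch == "(":
            stack.append(0)
        elif ch == ")":
            if stack.pop() == 0:
                count += 1
            if stack:
                stack[-1] += 1
    return count


# ---------------------------------------------------------------------------
# clustering and window excision


@dataclass
class Cluster:
    chrom: str
    strand: str
    start: int  # 0-based, half-open union of member intervals
    end: int
    members: list[GenomeAlignment] = field(default_factory=list)
    anchor: GenomeAlignment | None = None  # highest-count member


def cluster_tags(
    alignments: Iterable[GenomeAlignment],
    tag_counts: Mapping[str, int],
    merge_gap: int = 10,
) -> list[Cluster]:
    """Merge same-strand alignments whose intervals are within ``merge_gap`` nt.

    The cluster anchor is the highest-count tag (ties: lexicographic tag id),
    taken as the putative mature read.
    """
    by_key: dict[tuple[str, str], list[GenomeAlignment]] = defaultdict(list)
    for aln in alignments:
        by_key[(aln.chrom, aln.strand)].append(aln)
    clusters: list[Cluster] = []
    for (chrom, strand), alns in sorted(by_key.items()):
        alns.sort(key=lambda a: (a.start, a.end, a.tag_id))
        current: Cluster | None = None
        for aln in alns:
            if current is not None and aln.start <= current.end + merge_gap:
                current.end = max(current.end, aln.end)
                current.members.append(aln)
            else:
                if current is not None:
                    clusters.append(current)
                current = Cluster(chrom, strand, aln.start, aln.end, [aln])
        if current is not None:
            clusters.append(current)
    for cluster in clusters:
        cluster.anchor = max(
            cluster.members,
            key=lambda a: (tag_counts.get(a.tag_id, 0), a.tag_id),
        )
    return clusters


@dataclass
class Window:
    """An excised genomic window in strand-local orientation (5'->3').

    ``seq`` is RNA-space; ``mature_local`` is the anchor-tag interval within
    ``seq`` (0-based half-open).  ``arm`` is the hypothesis under which the
    window was excised: '5p' places the anchor at the window 5' end with the
    flank downstream, '3p' the reverse.
    """

    chrom: str
    strand: str
    start: int  # genomic, 0-based half-open, plus-strand coordinates
    end: int
    seq: str
    mature_local: tuple[int, int]
    arm: str
    truncated: bool = False

    def local_to_genomic(self, pos: int) -> int:
        """Strand-local 0-based position -> plus-strand genomic position."""
        if self.strand == "+":
            return self.start + pos
        return self.end - 1 - pos


def excise_windows(
    genome: Mapping[str, str] | str,
    cluster: Cluster,
    flank: int = 150,
    proximal: int = 20,
) -> list[Window]:
    """Two candidate windows per cluster: anchor as 5p arm (flank downstream)
    and anchor as 3p arm (flank upstream).  Windows truncated at chromosome
    edges are flagged.  Minus-strand windows are reverse-complemented so the
    mature read always appears 5'->3'."""
    if isinstance(genome, str):
        genome = {"chr1": genome}
    chrom_seq = to_rna(genome[cluster.chrom])
    anchor = cluster.anchor
    if anchor is None:
        raise ValueError("cluster has no anchor")
    a0, a1 = anchor.start, anchor.end
    n = len(chrom_seq)
    windows = []
    # geometry is defined on the strand-local 5'->3' axis
    if cluster.strand == "+":
        spans = [("5p", a0 - proximal, a1 + flank), ("3p", a0 - flank, a1 + proximal)]
    else:
        spans = [("5p", a0 - flank, a1 + proximal), ("3p", a0 - proximal, a1 + flank)]
    for arm, lo, hi in spans:
        truncated = lo < 0 or hi > n
        lo_c, hi_c = max(0, lo), min(n, hi)
        seq = chrom_seq[lo_c:hi_c]
        if cluster.strand == "+":
            m0, m1 = a0 - lo_c, a1 - lo_c
        else:
            seq = revcomp_rna(seq)
            m0, m1 = hi_c - a1, hi_c - a0
        windows.append(
            Window(
                chrom=cluster.chrom,
                strand=cluster.strand,
                start=lo_c,
                end=hi_c,
                seq=seq,
                mature_local=(m0, m1),
                arm=arm,
                truncated=truncated,
            )
        )
    return windows


# ---------------------------------------------------------------------------
# hairpin evaluation


@dataclass
class HairpinThresholds:
    min_paired_fraction: float = 0.6
    min_support: int = 2  # distinct reads at mature/star positions
    support_tolerance: int = 3  # nt around the mature/star 5' ends
    precursor_extensions: tuple[int, ...] = (20, 24, 28, 32, 36, 40, 44, 48, 52)
    precursor_pad: int = 3  # bases kept on the proximal side of the mature
    min_helix: int = 3  # helices shorter than this are topological noise


@dataclass
class HairpinCandidate:
    name: str  # assigned by name_candidates; '' until then
    chrom: str
    strand: str
    start: int  # precursor, genomic plus-strand, 0-based half-open
    end: int
    precursor: str
    fold: FoldResult
    arm: str
    mature_local: tuple[int, int]  # in precursor, 0-based half-open
    star_local: tuple[int, int] | None
    mature_sequence: str
    supporting_tags: list[tuple[str, int]]
    flags: dict[str, bool]

    @property
    def accepted(self) -> bool:
        return all(self.flags.values())

    @property
    def total_support(self) -> int:
        return sum(c for _, c in self.supporting_tags)


def _evaluate_precursor(
    prec: str, m0: int, m1: int, fold_fn, min_helix: int = 3
) -> tuple[FoldResult, dict[str, bool], float, tuple[int, int] | None]:
    """Fold one candidate precursor and score the structural criteria.

    Returns (fold, structural flags, mature paired fraction, star interval).
    The mature interval [m0, m1) indexes into ``prec``.  Topology flags are
    judged after removing helices shorter than ``min_helix`` stacked pairs.
    """
    fr = fold_fn(prec)
    clean = filter_short_helices(fr.pairs, min_helix=min_helix)
    partner: dict[int, int] = {}
    for i, j in clean:
        partner[i] = j
        partner[j] = i
    structure = structure_from_pairs(len(prec), clean)
    unbranched = is_unbranched(structure) and n_hairpin_loops(structure) == 1
    mature_pos = range(m0 + 1, m1 + 1)  # 1-based
    paired = [p for p in mature_pos if p in partner]
    frac = len(paired) / max(1, m1 - m0)
    # mature on one arm: partners all on one side of the mature, and no
    # mature base inside a terminal loop
    one_arm = bool(paired)
    if paired:
        partners = [partner[p] for p in paired]
        if not (all(q > m1 for q in partners) or all(q <= m0 for q in partners)):
            one_arm = False
    # terminal loops: innermost pairs enclose only unpaired bases
    inner_pairs = [
        (i, j)
        for i, j in clean
        if not any(i < a and b < j for a, b in clean if (a, b) != (i, j))
    ]
    for i, j in inner_pairs:
        if any(i < p < j for p in mature_pos):
            one_arm = False
    star = None
    if paired:
        pmin, pmax = min(paired), max(paired)
        q_hi, q_lo = partner[pmin], partner[pmax]
        lo, hi = min(q_lo, q_hi), max(q_lo, q_hi)
        # canonical Drosha/Dicer geometry: star 3' end has a 2-nt overhang
        star = (lo - 1, min(len(prec), hi + 2))  # 0-based half-open
    return fr, {"unbranched": unbranched, "mature_in_one_arm": one_arm}, frac, star


def evaluate_hairpin(
    window: Window,
    anchor_tag,
    supporting: Sequence[tuple[str, int, int]],
    thresholds: HairpinThresholds | None = None,
    fold_fn: Callable[[str], FoldResult] | None = None,
) -> HairpinCandidate:
    """Judge one excised window as a miRNA precursor.

    ``anchor_tag`` is the mature-candidate :class:`~smallrna.preprocess.UniqueTag`;
    ``supporting`` lists (tag_id, count, genomic 5' start on the window's
    strand) for every cluster member (anchor included).  Acceptance requires
    all four criteria flags:

    - ``unbranched``: the precursor folds into a single stem-loop;
    - ``mature_in_one_arm``: the mature read lies on one arm, outside the
      terminal loop;
    - ``pairing_fraction_ok``: >= 60 % of mature bases paired;
    - ``support_ok``: >= 2 distinct tags starting within +/-3 nt of the
      mature or star 5' end.

    Because the excised window carries up to 150 nt of flank, the evaluator
    folds a small grid of precursor-sized subwindows anchored at the mature
    read and keeps the best-scoring one that satisfies the structural
    criteria (a precursor search, in the spirit of MIREAP).
    """
    th = thresholds or HairpinThresholds()
    fold_fn = fold_fn or fold
    seq = window.seq
    m0, m1 = window.mature_local
    mlen = m1 - m0
    candidates: list[tuple[tuple, int, int, FoldResult, dict, tuple | None]] = []
    for ext in th.precursor_extensions:
        if window.arm == "5p":
            lo = max(0, m0 - th.precursor_pad)
            hi = min(len(seq), m1 + ext)
        else:
            lo = max(0, m0 - ext)
            hi = min(len(seq), m1 + th.precursor_pad)
        if hi - lo < mlen + MIN_LOOP + 2:
            continue
        prec = seq[lo:hi]
        fr, flags, frac, star = _evaluate_precursor(
            prec, m0 - lo, m1 - lo, fold_fn, min_helix=th.min_helix
        )
        flags["pairing_fraction_ok"] = frac >= th.min_paired_fraction
        structural_ok = all(flags.values())
        rank = (structural_ok, sum(flags.values()), fr.score)
        candidates.append((rank, lo, hi, fr, flags, star))
    if not candidates:
        raise ValueError("window too short to evaluate")
    rank, lo, hi, fr, flags, star = max(candidates, key=lambda c: c[0])

    # support: distinct tags whose strand-local 5' start is near the mature
    # or star 5' end (genomic coordinates, strand-aware)
    mature_g5 = window.local_to_genomic(m0)
    star_g5 = window.local_to_genomic(lo + star[0]) if star else None
    supporters = []
    for tag_id, count, g5 in supporting:
        near_mature = abs(g5 - mature_g5) <= th.support_tolerance
        near_star = star_g5 is not None and abs(g5 - star_g5) <= th.support_tolerance
        if near_mature or near_star:
            supporters.append((tag_id, count))
    flags["support_ok"] = len({t for t, _ in supporters}) >= th.min_support

    if window.strand == "+":
        g_start, g_end = window.start + lo, window.start + hi
    else:
        g_start, g_end = window.end - hi, window.end - lo
    anchor_seq = anchor_tag.sequence if hasattr(anchor_tag, "sequence") else str(anchor_tag)
    return HairpinCandidate(
        name="",
        chrom=window.chrom,
        strand=window.strand,
        start=g_start,
        end=g_end,
        precursor=fr.sequence,
        fold=fr,
        arm=window.arm,
        mature_local=(m0 - lo, m1 - lo),
        star_local=(star[0], star[1]) if star else None,
        mature_sequence=anchor_seq,
        supporting_tags=sorted(supporters, key=lambda t: (-t[1], t[0])),
        flags=flags,
    )


def discover(
    genome: Mapping[str, str] | str,
    alignments: Iterable[GenomeAlignment],
    tag_counts: Mapping[str, int],
    tag_sequences: Mapping[str, str],
    *,
    merge_gap: int = 10,
    flank: int = 150,
    thresholds: HairpinThresholds | None = None,
    fold_fn: Callable[[str], FoldResult] | None = None,
) -> list[HairpinCandidate]:
    """Cluster -> excise -> evaluate -> name.  Returns accepted, named candidates."""
    clusters = cluster_tags(alignments, tag_counts, merge_gap=merge_gap)
    accepted: list[HairpinCandidate] = []
    for cluster in clusters:
        anchor = cluster.anchor
        support = []
        for aln in cluster.members:
            g5 = aln.start if cluster.strand == "+" else aln.end - 1
            support.append((aln.tag_id, tag_counts.get(aln.tag_id, 0), g5))
        best: HairpinCandidate | None = None
        for window in excise_windows(genome, cluster, flank=flank):
            cand = evaluate_hairpin(
                window,
                tag_sequences[anchor.tag_id],
                support,
                thresholds=thresholds,
                fold_fn=fold_fn,
            )
            if cand.accepted and (best is None or cand.fold.score > best.fold.score):
                best = cand
        if best is not None:
            accepted.append(best)
    return name_candidates(deduplicate_candidates(accepted))


def deduplicate_candidates(
    candidates: Sequence[HairpinCandidate],
) -> list[HairpinCandidate]:
    """Collapse candidates whose precursors overlap into one locus.

    A hairpin attracts its own reads twice: at the mature arm and, reverse-
    complemented, at the near-complementary star arm on the opposite strand.
    Overlapping precursor intervals (either strand) are one locus; the
    better-supported candidate is kept.
    """
    ordered = sorted(
        candidates, key=lambda c: (-c.total_support, c.chrom, c.start, c.strand)
    )
    kept: list[HairpinCandidate] = []
    for cand in ordered:
        clash = any(
            k.chrom == cand.chrom and cand.start < k.end and k.start < cand.end
            for k in kept
        )
        if not clash:
            kept.append(cand)
    return kept


def name_candidates(candidates: Sequence[HairpinCandidate]) -> list[HairpinCandidate]:
    """Order by descending total support and assign Novel-N names.

    Candidates sharing an identical mature sequence from distinct loci share
    a number and get letter suffixes in rank order (a = most supported).
    """
    ordered = sorted(
        candidates,
        key=lambda c: (-c.total_support, c.chrom, c.start, c.strand),
    )
    groups: dict[str, list[int]] = defaultdict(list)
    for idx, cand in enumerate(ordered):
        groups[cand.mature_sequence].append(idx)
    number = 0
    names: dict[int, str] = {}
    assigned: set[str] = set()
    for idx, cand in enumerate(ordered):
        if cand.mature_sequence in assigned:
            continue
        assigned.add(cand.mature_sequence)
        number += 1
        members = groups[cand.mature_sequence]
        if len(members) == 1:
            names[idx] = f"Novel-{number}"
        else:
            for letter, m in zip("abcdefghij", members):
                names[m] = f"Novel-{number}{letter}"
    return [replace(c, name=names[i]) for i, c in enumerate(ordered)]


# ---------------------------------------------------------------------------
# shuffle control


def dinucleotide_shuffle(sequence: str, rng: np.random.Generator) -> str:
    """Random shuffle preserving dinucleotide counts (Altschul-Erickson).

    Builds the dinucleotide transition multigraph and samples a random
    Eulerian path with the same start/end as the original sequence.
    """
    seq = to_rna(sequence)
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = defaultdict(list)
    for a, b in zip(seq, seq[1:]):
        edges[a].append(b)
    last = seq[-1]
    vertices = sorted(edges)
    for _ in range(1000):
        shuffled = {v: list(rng.permutation(edges[v])) for v in vertices}
        # the designated last exit from each non-terminal vertex must reach
        # the terminal vertex through other last-exit edges
        ok = True
        for v in vertices:
            if v == last or not shuffled[v]:
                continue
            seen = {v}
            cur = v
            while cur != last:
                nxt = shuffled[cur][-1] if shuffled[cur] else None
                if nxt is None or nxt in seen:
                    ok = False
                    break
                seen.add(nxt)
                cur = nxt
            if not ok:
                break
        if not ok:
            continue
        counters = {v: 0 for v in vertices}
        out = [seq[0]]
        cur = seq[0]
        total = len(seq) - 1
        for _ in range(total):
            nxt = shuffled[cur][counters[cur]]
            counters[cur] += 1
            out.append(nxt)
            cur = nxt
        return "".join(out)
    return seq  # degenerate composition; give up and return the input
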