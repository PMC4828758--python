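"""Independent brute-force oracles used by unit and acceptance tests.

Every oracle here is written against the *definition* of an operation
(exhaustive enumeration, naive scanning, plain recursion) and never shares
code with the implementation it checks.
"""

from __future__ import annotations

from functools import lru_cache

from smallrna._seq import revcomp_rna, to_rna
from smallrna.targets import (
    GAP_EXTEND,
    GAP_OPEN,
    GU_SCORE,
    MISMATCH_SCORE,
    SEED_SCALE,
    WC_SCORE,
)

_PAIR_WEIGHT = {
    ("G", "C"): 3, ("C", "G"): 3,
    ("A", "U"): 2, ("U", "A"): 2,
    ("G", "U"): 1, ("U", "G"): 1,
}

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "U"), ("U", "G")}


def brute_force_max_fold_weight(seq: str, min_loop: int = 3) -> int:
    """Maximum total pair weight over all nested structures, by enumeration.

    Recursion over the ordered set of free positions: the first position is
    either unpaired, or paired with some later position (splitting the rest
    into inside/outside, which enforces nesting).  Exponential; for
    sequences up to ~14 nt only.
    """
    seq = to_rna(seq)

    def rec(positions: tuple[int, ...]) -> int:
        if not positions:
            return 0
        i, rest = positions[0], positions[1:]
        best = rec(rest)
        for j in rest:
            if j - i <= min_loop:
                continue
            w = _PAIR_WEIGHT.get((seq[i], seq[j]))
            if not w:
                continue
            inside = tuple(p for p in rest if i < p < j)
            outside = tuple(p for p in rest if p > j)
            best = max(best, w + rec(inside) + rec(outside))
        return best

    return rec(tuple(range(len(seq))))


def branched_by_pairwise_check(pairs: list[tuple[int, int]]) -> bool:
    """A structure is branched iff some pair encloses two disjoint pairs."""
    for i, j in pairs:
        inner = [(a, b) for a, b in pairs if i < a and b < j]
        for x, (a1, b1) in enumerate(inner):
            for a2, b2 in inner[x + 1 :]:
                disjoint = b1 < a2 or b2 < a1
                if disjoint:
                    return True
    return False


def scan_genome_naive(
    tag: str, genome: str, max_mm: int
) -> list[tuple[int, str, int]]:
    """Every (start, strand, mismatches) hit by scanning all offsets/strands."""
    tag = to_rna(tag)
    genome = to_rna(genome)
    hits = []
    L = len(tag)
    for strand, q in (("+", tag), ("-", revcomp_rna(tag))):
        for start in range(len(genome) - L + 1):
            mm = 0
            for a, b in zip(q, genome[start : start + L]):
                if a != b:
                    mm += 1
                    if mm > max_mm:
                        break
            else:
                hits.append((start, strand, mm))
    return hits


def best_containment_naive(
    tag: str, refs: dict[str, str], max_mm: int
) -> tuple[str, int] | None:
    """Best (reference, mismatches) by scanning every reference offset."""
    tag = to_rna(tag)
    best = None
    for name, ref in refs.items():
        ref = to_rna(ref)
        for start in range(len(ref) - len(tag) + 1):
            mm = sum(1 for a, b in zip(tag, ref[start : start + len(tag)]) if a != b)
            if mm <= max_mm and (best is None or mm < best[1]):
                best = (name, mm)
    return best


def seed_sites_naive(mirna: str, utr: str) -> list[tuple[int, str]]:
    """(0-based 6mer-core start, site type) at every UTR offset, from the
    definitions: core = WC complement of miRNA 2-7 read antiparallel."""
    mirna = to_rna(mirna)
    utr = to_rna(utr)
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
    core_rc = "".join(comp[b] for b in mirna[1:7])[::-1]
    out = []
    for x in range(len(utr) - 5):
        if utr[x : x + 6] != core_rc:
            continue
        m8 = x >= 1 and utr[x - 1] == comp.get(mirna[7])
        a1 = x + 6 < len(utr) and utr[x + 6] == "A"
        if m8 and a1:
            t = "8mer"
        elif m8:
            t = "7mer-m8"
        elif a1:
            t = "7mer-A1"
        else:
            t = "6mer"
        out.append((x, t))
    return out


def duplex_score_naive(mirna: str, window: str) -> float:
    """Affine-gap complementarity alignment score by plain state recursion."""
    m = to_rna(mirna)[::-1]  # 3'->5'
    w = to_rna(window)
    n1, n2 = len(m), len(w)

    def col_score(i: int, j: int) -> float:
        a, b = m[i], w[j]
        if (a, b) in _WC:
            s = WC_SCORE
        elif (a, b) in _GU:
            s = GU_SCORE
        else:
            s = MISMATCH_SCORE
        m_pos = n1 - i  # 1-based miRNA position 5'->3'
        return s * SEED_SCALE if 2 <= m_pos <= 8 else s

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, state: str) -> float:
        if i == n1 and j == n2:
            return 0.0
        best = float("-inf")
        if i < n1 and j < n2:
            best = max(best, col_score(i, j) + rec(i + 1, j + 1, "M"))
        if i < n1:
            g = GAP_EXTEND if state == "X" else GAP_OPEN
            best = max(best, g + rec(i + 1, j, "X"))
        if j < n2:
            g = GAP_EXTEND if state == "Y" else GAP_OPEN
            best = max(best, g + rec(i, j + 1, "Y"))
        return best

    result = rec(0, 0, "S")
    rec.cache_clear()
    return result


def align_offsets_naive(
    tag: str, canonical: str, max_offset: int = 5
) -> tuple[int, int, int]:
    """(offset5, offset3, n_substitutions) minimizing substitutions, by
    building both padded strings explicitly for every candidate offset."""
    tag = to_rna(tag)
    canonical = to_rna(canonical)
    best = None
    for o5 in range(-max_offset, max_offset + 1):
        o3 = (len(tag) - o5) - len(canonical)
        if abs(o3) > max_offset:
            continue
        # pad both to a common frame and count aligned differences
        pad_tag = ("." * max(0, -o5)) + tag + ("." * max(0, -o3))
        pad_can = ("." * max(0, o5)) + canonical + ("." * max(0, o3))
        assert len(pad_tag) == len(pad_can)
        subs = sum(
            1 for a, b in zip(pad_tag, pad_can) if "." not in (a, b) and a != b
        )
        key = (subs, abs(o5), abs(o3))
        if best is None or key < best:
            best = key
            out = (o5, o3, subs)
    return out
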