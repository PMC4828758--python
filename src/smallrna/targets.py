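"""miRNA target-site prediction in 3'UTRs.

Canonical seed matching (6mer / 7mer-m8 / 7mer-A1 / 8mer), a
complementarity duplex alignment in the classic three-line notation
('|' Watson-Crick, ':' G:U wobble, '-' gap), an alignment score, and a
simplified nearest-neighbor duplex free energy.

Scoring follows miRanda-like conventions: +5 per Watson-Crick pair, +2 per
G:U wobble, -3 per mismatch, affine gaps (-8 open, -2 extend), with seed
positions 2-8 of the miRNA scaled x4.  The duplex energy sums Turner-style
stacking terms over consecutive pair stacks (embedded as data), +4 kcal/mol
per interior loop or bulge, +4.1 duplex initiation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from ._seq import check_rna, is_gu, is_wc, to_rna

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")

WC_SCORE = 5.0
GU_SCORE = 2.0
MISMATCH_SCORE = -3.0
GAP_OPEN = -8.0
GAP_EXTEND = -2.0
SEED_SCALE = 4.0  # multiplier on pair/mismatch scores at miRNA positions 2-8

DEFAULT_MIN_SCORE = 140.0
DEFAULT_MAX_ENERGY = -14.0

# Turner 2004 Watson-Crick nearest-neighbor stacks, kcal/mol, in the usual
# "top/bottom" notation with BOTH strands written 5'->3' (align the bottom
# by reversing it): "CA/UG" is 5'-CA-3' over 3'-GU-5', pairs (C,G), (A,U).
_WC_STACKS_RAW = {
    ("AA", "UU"): -0.93,
    ("AU", "AU"): -1.10,
    ("UA", "UA"): -1.33,
    ("CU", "AG"): -2.08,
    ("CA", "UG"): -2.11,
    ("GU", "AC"): -2.24,
    ("GA", "UC"): -2.35,
    ("CG", "CG"): -2.36,
    ("GG", "CC"): -3.26,
    ("GC", "GC"): -3.42,
}
#: Approximate stacking term applied to any stack involving a G:U pair.
GU_STACK_ENERGY = -1.2
LOOP_PENALTY = 4.0
DUPLEX_INITIATION = 4.1


def _expand_stacks() -> dict[tuple[tuple[str, str], tuple[str, str]], float]:
    """Expand the 10 unique WC stacks to all 16 oriented keys.

    Keys are ((pair1), (pair2)): two consecutive pairs read along one
    strand 5'->3'.  A stack read from the other strand reverses the order
    and flips each pair: ((a,x),(b,y)) == ((y,b),(x,a)).
    """
    table: dict[tuple[tuple[str, str], tuple[str, str]], float] = {}
    for (top, bottom), dg in _WC_STACKS_RAW.items():
        pair1 = (top[0], bottom[1])
        pair2 = (top[1], bottom[0])
        table[(pair1, pair2)] = dg
        flipped = ((pair2[1], pair2[0]), (pair1[1], pair1[0]))
        table[flipped] = dg
    return table


WC_STACKS = _expand_stacks()


def stack_energy(pair1: tuple[str, str], pair2: tuple[str, str]) -> float:
    """Stacking free energy of two consecutive pairs along the miRNA strand."""
    key = (pair1, pair2)
    if key in WC_STACKS:
        return WC_STACKS[key]
    if (is_wc(*pair1) or is_gu(*pair1)) and (is_wc(*pair2) or is_gu(*pair2)):
        return GU_STACK_ENERGY
    return 0.0


@dataclass(frozen=True)
class SeedSite:
    utr_id: str
    site_type: str
    #: 1-based inclusive interval of the seed-matched UTR region (including
    #: the m8 and/or A1 positions the site type claims)
    start: int
    end: int
    #: 0-based UTR index of the base pairing miRNA position 2 (site 3' side)
    core_end: int


@dataclass(frozen=True)
class TargetSite:
    mirna_id: str
    utr_id: str
    site_type: str
    start: int  # 1-based inclusive, full aligned window in the UTR
    end: int
    alignment: str  # three-line rendering
    score: float
    duplex_energy: float


def find_seed_sites(mirna: str, utr: str, utr_id: str = "") -> list[SeedSite]:
    """All canonical seed matches of a miRNA in a UTR (RNA-space).

    The 6mer core is a Watson-Crick reverse-complement match of miRNA
    positions 2-7; position 8 pairing upgrades to 7mer-m8, an A opposite
    position 1 to 7mer-A1, and both to 8mer.
    """
    mirna = to_rna(mirna)
    utr = to_rna(utr)
    check_rna(mirna, what="miRNA")
    if len(mirna) < 8:
        raise ValueError("miRNA shorter than 8 nt")
    sites = []
    # antiparallel: miRNA position p (1-based) pairs UTR index x + 7 - p
    # for a 6mer whose 5'-most UTR index is x (pairing position 7) .. x+5
    # (pairing position 2)
    for x in range(len(utr) - 5):
        core = utr[x : x + 6]
        if not all(is_wc(mirna[p - 1], core[7 - p]) for p in range(2, 8)):
            continue
        m8 = x > 0 and is_wc(mirna[7], utr[x - 1])
        a1 = x + 6 < len(utr) and utr[x + 6] == "A"
        if m8 and a1:
            site_type, lo, hi = "8mer", x - 1, x + 6
        elif m8:
            site_type, lo, hi = "7mer-m8", x - 1, x + 5
        elif a1:
            site_type, lo, hi = "7mer-A1", x, x + 6
        else:
            site_type, lo, hi = "6mer", x, x + 5
        sites.append(
            SeedSite(
                utr_id=utr_id,
                site_type=site_type,
                start=lo + 1,
                end=hi + 1,
                core_end=x + 5,
            )
        )
    return sites


# ---------------------------------------------------------------------------
# duplex alignment (affine Needleman-Wunsch on complementarity)


def _pair_score(m_base: str, u_base: str, m_pos: int) -> float:
    """Score of pairing miRNA position ``m_pos`` (1-based) with a UTR base."""
    if is_wc(m_base, u_base):
        s = WC_SCORE
    elif is_gu(m_base, u_base):
        s = GU_SCORE
    else:
        s = MISMATCH_SCORE
    if 2 <= m_pos <= 8:
        s *= SEED_SCALE
    return s


@dataclass(frozen=True)
class DuplexAlignment:
    mirna: str  # 5'->3'
    window: str  # UTR window, 5'->3'
    score: float
    #: aligned columns as (miRNA index | None, UTR index | None), 0-based;
    #: miRNA indices descend along the alignment (3'->5'), UTR ascend
    columns: tuple[tuple[int | None, int | None], ...]

    @property
    def pairs(self) -> list[tuple[int, int]]:
        """Paired columns (miRNA index, UTR index), canonical pairs only."""
        out = []
        for mi, ui in self.columns:
            if mi is not None and ui is not None:
                a, b = self.mirna[mi], self.window[ui]
                if is_wc(a, b) or is_gu(a, b):
                    out.append((mi, ui))
        return out

    def render(self) -> str:
        """Three-line rendering: miRNA 3'->5' / symbols / UTR 5'->3'."""
        top, mid, bot = [], [], []
        for mi, ui in self.columns:
            a = self.mirna[mi] if mi is not None else "-"
            b = self.window[ui] if ui is not None else "-"
            top.append(a)
            bot.append(b)
            if mi is None or ui is None:
                mid.append(" ")
            elif is_wc(a, b):
                mid.append("|")
            elif is_gu(a, b):
                mid.append(":")
            else:
                mid.append(" ")
        return (
            "miRNA  3' " + "".join(top) + " 5'\n"
            "          " + "".join(mid) + "\n"
            "UTR    5' " + "".join(bot) + " 3'"
        )


def align_duplex(mirna: str, window: str) -> DuplexAlignment:
    """Global affine complementarity alignment of a miRNA against a UTR window.

    The miRNA is taken 3'->5' against the window 5'->3' (antiparallel), so
    the rendering reads like a duplex.  Deterministic traceback
    (diagonal > miRNA-gap > UTR-gap on ties).
    """
    mirna = to_rna(mirna)
    window = to_rna(window)
    if len(window) < 6:
        raise ValueError("UTR window shorter than the seed")
    m = mirna[::-1]  # 3'->5'
    n1, n2 = len(m), len(window)
    NEG = float("-inf")
    # M = align m[i-1] with window[j-1]; X = gap in window; Y = gap in miRNA
    M = [[NEG] * (n2 + 1) for _ in range(n1 + 1)]
    X = [[NEG] * (n2 + 1) for _ in range(n1 + 1)]
    Y = [[NEG] * (n2 + 1) for _ in range(n1 + 1)]
    M[0][0] = 0.0
    for i in range(1, n1 + 1):
        X[i][0] = GAP_OPEN + GAP_EXTEND * (i - 1)
    for j in range(1, n2 + 1):
        Y[0][j] = GAP_OPEN + GAP_EXTEND * (j - 1)
    for i in range(1, n1 + 1):
        m_pos = n1 - i + 1  # 1-based miRNA position (5'->3')
        for j in range(1, n2 + 1):
            s = _pair_score(m[i - 1], window[j - 1], m_pos)
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(
                M[i - 1][j] + GAP_OPEN,
                X[i - 1][j] + GAP_EXTEND,
                Y[i - 1][j] + GAP_OPEN,
            )
            Y[i][j] = max(
                M[i][j - 1] + GAP_OPEN,
                Y[i][j - 1] + GAP_EXTEND,
                X[i][j - 1] + GAP_OPEN,
            )
    score = max(M[n1][n2], X[n1][n2], Y[n1][n2])

    cols: list[tuple[int | None, int | None]] = []
    i, j = n1, n2
    mats = {"M": M, "X": X, "Y": Y}
    state = max(("M", "X", "Y"), key=lambda s: mats[s][i][j])
    while i > 0 or j > 0:
        if i == 0:
            state = "Y"
        elif j == 0:
            state = "X"
        if state == "M":
            cols.append((n1 - i, j - 1))  # original miRNA index (5'->3')
            prev = max(("M", "X", "Y"), key=lambda s: mats[s][i - 1][j - 1])
            i, j = i - 1, j - 1
            state = prev
        elif state == "X":
            cols.append((n1 - i, None))
            v = X[i][j]
            if v == M[i - 1][j] + GAP_OPEN:
                state = "M"
            elif v == X[i - 1][j] + GAP_EXTEND:
                state = "X"
            else:
                state = "Y"
            i -= 1
        else:
            cols.append((None, j - 1))
            v = Y[i][j]
            if v == M[i][j - 1] + GAP_OPEN:
                state = "M"
            elif v == Y[i][j - 1] + GAP_EXTEND:
                state = "Y"
            else:
                state = "X"
            j -= 1
    cols.reverse()
    return DuplexAlignment(mirna=mirna, window=window, score=score, columns=tuple(cols))


def duplex_energy(alignment: DuplexAlignment) -> float:
    """Simplified nearest-neighbor duplex free energy, kcal/mol.

    Consecutive aligned pair columns form stacks scored from the embedded
    table; every interruption (mismatch, bulge or interior loop) between two
    stacks costs +4 kcal/mol; a duplex with any pair pays +4.1 initiation.
    No pairs -> 0.
    """
    pair_cols = []
    for idx, (mi, ui) in enumerate(alignment.columns):
        if mi is None or ui is None:
            continue
        a, b = alignment.mirna[mi], alignment.window[ui]
        if is_wc(a, b) or is_gu(a, b):
            pair_cols.append((idx, (a, b)))
    if not pair_cols:
        return 0.0
    energy = DUPLEX_INITIATION
    for (idx1, p1), (idx2, p2) in zip(pair_cols, pair_cols[1:]):
        if idx2 == idx1 + 1:
            energy += stack_energy(p1, p2)
        else:
            energy += LOOP_PENALTY
    return energy


# ---------------------------------------------------------------------------
# site pipeline


def _site_window(utr: str, mirna_len: int, site: SeedSite, max_gap: int = 4) -> tuple[int, int]:
    """UTR slice (0-based half-open) covering the full miRNA plus gap slack."""
    x = site.core_end - 5  # UTR index pairing miRNA position 7
    lo = max(0, x - (mirna_len - 7) - max_gap)
    hi = min(len(utr), site.core_end + 3)  # room for position-1 / A1 base
    return lo, hi


def scan(
    mirna: str,
    utr: str,
    *,
    mirna_id: str = "",
    utr_id: str = "",
    max_gap: int = 4,
) -> list[TargetSite]:
    """Seed-match scan + duplex alignment + energy for every candidate site."""
    mirna = to_rna(mirna)
    utr = to_rna(utr)
    out = []
    for site in find_seed_sites(mirna, utr, utr_id=utr_id):
        lo, hi = _site_window(utr, len(mirna), site, max_gap=max_gap)
        aln = align_duplex(mirna, utr[lo:hi])
        out.append(
            TargetSite(
                mirna_id=mirna_id,
                utr_id=utr_id,
                site_type=site.site_type,
                start=lo + 1,
                end=hi,
                alignment=aln.render(),
                score=aln.score,
                duplex_energy=duplex_energy(aln),
            )
        )
    return out


def score_and_filter(
    sites: Iterable[TargetSite],
    min_score: float = DEFAULT_MIN_SCORE,
    max_energy: float = DEFAULT_MAX_ENERGY,
) -> list[TargetSite]:
    """Keep sites with score >= min_score and energy <= max_energy,
    sorted by (utr_id, position)."""
    kept = [
        s for s in sites if s.score >= min_score and s.duplex_energy <= max_energy
    ]
    kept.sort(key=lambda s: (s.utr_id, s.start, s.end, s.mirna_id))
    return kept


def parse_alignment(rendered: str) -> list[str]:
    """Re-parse a three-line rendering into per-column pair symbols.

    Round-trip check: '|' and ':' columns must agree with re-deriving the
    symbols from the two sequence lines.
    """
    lines = rendered.split("\n")
    if len(lines) != 3:
        raise ValueError("expected a three-line alignment")
    top = lines[0][10:-3]
    mid = lines[1][10:]
    bot = lines[2][10:-3]
    symbols = []
    for k in range(len(top)):
        a, b = top[k], bot[k]
        sym = mid[k] if k < len(mid) else " "
        if a == "-" or b == "-":
            derived = " "
        elif is_wc(a, b):
            derived = "|"
        elif is_gu(a, b):
            derived = ":"
        else:
            derived = " "
        if sym != derived:
            raise ValueError(f"column {k}: symbol {sym!r} inconsistent with bases")
        symbols.append(derived)
    return symbols
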