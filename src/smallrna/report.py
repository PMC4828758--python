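"""Summary artifacts: read-statistics tables with percentages, length
distributions, top-novel-candidate tables, and 2^-ddCt qPCR fold changes.

Percentages are rounded half-up to 2 decimals; the denominator for category
percentages is the high-quality read total (the convention that makes the
classic read-statistics table internally consistent).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .hairpin import HairpinCandidate
from .isomir import extract_seed
from .preprocess import UniqueTag


def percentage(part: int, whole: int) -> float:
    """100 * part / whole, rounded half-up to 2 decimals."""
    if whole == 0:
        raise ZeroDivisionError("percentage undefined for whole == 0")
    if part > whole:
        raise ValueError(f"part {part} exceeds whole {whole}")
    frac = Decimal(100) * Decimal(part) / Decimal(whole)
    return float(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def category_stats(
    rows: Sequence[tuple[str, int, int | None]],
    high_quality_total: int,
) -> pd.DataFrame:
    """Read-statistics table: (item, total reads, unique tags) rows plus a
    2-decimal percentage column over the high-quality total."""
    out = []
    for label, total_reads, unique_tags in rows:
        out.append(
            {
                "item": label,
                "total_reads": total_reads,
                "unique_tags": unique_tags,
                "percent": percentage(total_reads, high_quality_total),
            }
        )
    return pd.DataFrame(out)


def length_distribution(
    tags: Sequence[UniqueTag],
    min_len: int = 18,
    max_len: int = 30,
) -> tuple[pd.Series, int]:
    """Read-weighted insert-length histogram and the modal length.

    Ties on the mode break toward the shorter length.
    """
    counts = pd.Series(0, index=range(min_len, max_len + 1), dtype=int)
    for tag in tags:
        L = len(tag.sequence)
        if min_len <= L <= max_len:
            counts[L] += tag.count
    mode = int(counts.index[np.argmax(counts.values)])  # argmax -> first = shortest
    return counts, mode


@dataclass(frozen=True)
class NovelCandidateRow:
    name: str
    total_count: int
    n_isomirs: int
    most_expressed_sequence: str
    length: int
    most_expressed_count: int
    seed: str

    def __post_init__(self) -> None:
        if self.seed != extract_seed(self.most_expressed_sequence):
            raise ValueError("seed column inconsistent with sequence")
        if self.length != len(self.most_expressed_sequence):
            raise ValueError("length column inconsistent with sequence")
        if self.most_expressed_count > self.total_count:
            raise ValueError("most-expressed count exceeds total")
        if self.n_isomirs < 1:
            raise ValueError("a reported candidate has at least one isomiR")


def top_novel_table(
    candidates: Sequence[HairpinCandidate],
    tag_sequences: Mapping[str, str],
    n: int = 10,
    descending: bool = True,
) -> list[NovelCandidateRow]:
    """Top novel candidates ranked by their most-expressed read count.

    ``tag_sequences`` maps tag ids to sequences; each candidate's distinct
    supporting tags are its isomiRs, the highest-count one its representative
    sequence.
    """
    rows = []
    for cand in candidates:
        if not cand.supporting_tags:
            continue
        best_id, best_count = max(cand.supporting_tags, key=lambda t: (t[1], t[0]))
        seq = tag_sequences[best_id]
        rows.append(
            NovelCandidateRow(
                name=cand.name,
                total_count=cand.total_support,
                n_isomirs=len({t for t, _ in cand.supporting_tags}),
                most_expressed_sequence=seq,
                length=len(seq),
                most_expressed_count=best_count,
                seed=extract_seed(seq),
            )
        )
    rows.sort(key=lambda r: r.most_expressed_count, reverse=descending)
    return rows[:n]


def novel_table_frame(rows: Iterable[NovelCandidateRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "Name": r.name,
                "Total count": r.total_count,
                "isomiRs": r.n_isomirs,
                "Most expressed sequence": r.most_expressed_sequence,
                "Length(nt)": r.length,
                "Counts": r.most_expressed_count,
                "Seed": r.seed,
            }
            for r in rows
        ]
    )


# ---------------------------------------------------------------------------
# qPCR relative quantification


def ddct(
    target_ct_sample: float,
    ref_ct_sample: float,
    target_ct_calibrator: float,
    ref_ct_calibrator: float,
) -> float:
    """Relative expression by 2^-ddCt.

    ddCt = (target - reference) in the sample minus the same difference in
    the calibrator; the result is the fold change relative to the calibrator.
    """
    delta_sample = target_ct_sample - ref_ct_sample
    delta_cal = target_ct_calibrator - ref_ct_calibrator
    return float(2.0 ** (-(delta_sample - delta_cal)))


def summarize_qpcr(
    measurements: pd.DataFrame,
    calibrator_tissue: str = "brain",
    dispersion: str = "se",
) -> pd.DataFrame:
    """Per-tissue fold changes (mean +/- SE over replicates) per target.

    ``measurements`` columns: tissue, target, target_ct, ref_ct, replicate.
    Each replicate's ddCt uses the calibrator tissue's mean delta-Ct for the
    same target.  ``dispersion`` may be 'se' (default) or 'sd'.
    """
    if dispersion not in ("se", "sd"):
        raise ValueError("dispersion must be 'se' or 'sd'")
    df = measurements.copy()
    if (df[["target_ct", "ref_ct"]] <= 0).any().any():
        raise ValueError("Ct values must be positive")
    df["delta_ct"] = df["target_ct"] - df["ref_ct"]
    out = []
    for target, group in df.groupby("target", sort=True):
        cal = group[group["tissue"] == calibrator_tissue]
        if cal.empty:
            raise ValueError(f"no calibrator ({calibrator_tissue}) rows for {target}")
        cal_delta = cal["delta_ct"].mean()
        for tissue, sub in group.groupby("tissue", sort=True):
            fold = 2.0 ** (-(sub["delta_ct"] - cal_delta))
            n = len(fold)
            spread = fold.std(ddof=1) if n > 1 else 0.0
            if dispersion == "se" and n > 1:
                spread = spread / np.sqrt(n)
            out.append(
                {
                    "target": target,
                    "tissue": tissue,
                    "n": n,
                    "fold_change_mean": fold.mean(),
                    f"fold_change_{dispersion}": spread,
                }
            )
    return pd.DataFrame(out)
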