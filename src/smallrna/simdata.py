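"""Ground-truth simulator: a toy genome with planted miRNA hairpins and a
synthetic adapter-ligated small-RNA library with known isomiR structure.

The generator emulates a pooled small-RNA sequencing library: reads are a
mixture of canonical miRNA reads, isomiR variants drawn from a configurable
mixture (3' trimming dominating, as in real libraries), fragments of
rRNA/tRNA/snoRNA references, and uniform-random background.  Inserts carry
the 3' sequencing adapter and Phred+33 qualities; sequencing errors are
planted at a per-base rate and flagged by low quality scores.  Every read is
paired with a truth-table row recording its source and exact edit, so every
downstream stage (preprocessing, annotation, hairpin discovery, isomiR
classification) can be scored against ground truth.

Planted mature arms are drawn with lengths peaked at 22 nt; hairpins are
mature + pairing-inert loop + near-reverse-complement star, so the designed
stem is the maximum-weight fold.  Mature arms, their immediate flanks and
ncRNA references are screened against the first 6 nt of the 3' adapter so
exact-prefix adapter trimming is lossless on planted inserts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from ._seq import revcomp_rna, to_dna, to_rna

RNA_BASES = np.array(list("ACGU"))
DNA_BASES = np.array(list("ACGT"))

DEFAULT_ADAPTER3 = "TGGAATTCTCGGGTGCCAAGG"  # TruSeq small-RNA 3' adapter prefix

ISOMIR_EDITS = (
    "canonical",
    "trim3",
    "trim5",
    "ext3_templated",
    "add3_nontemplated",
    "shift5",
    "substitution",
)

EDIT_TO_CLASS = {
    "canonical": "canonical",
    "trim3": "iso3",
    "ext3_templated": "iso3",
    "add3_nontemplated": "iso3",
    "trim5": "iso5",
    "shift5": "iso5",
    "substitution": "internal",
}


@dataclass(frozen=True)
class IsomirRates:
    """Mixture weights of the per-read isomiR edit classes (must sum to 1).

    ``trim3_geom_p`` is the geometric step parameter for 3' trim lengths;
    ``add3_au_weights`` weights the A/U choice for non-templated additions
    when the genomic flank allows either.
    """

    p_canonical: float = 0.55
    p_trim3: float = 0.25
    p_trim5: float = 0.04
    p_ext3_templated: float = 0.04
    p_add3_nontemplated: float = 0.04
    p_shift5: float = 0.04
    p_substitution: float = 0.04
    trim3_geom_p: float = 0.5
    add3_au_weights: tuple[float, float] = (0.5, 0.5)

    def probs(self) -> np.ndarray:
        p = np.array(
            [
                self.p_canonical,
                self.p_trim3,
                self.p_trim5,
                self.p_ext3_templated,
                self.p_add3_nontemplated,
                self.p_shift5,
                self.p_substitution,
            ]
        )
        return p

    def validate(self) -> None:
        p = self.probs()
        if (p < 0).any() or (p > 1).any():
            raise ValueError("isomiR rates must be probabilities in [0, 1]")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"isomiR class probabilities must sum to 1, got {p.sum()}")


@dataclass(frozen=True)
class SimConfig:
    rng_seed: int = 0
    genome_length: int = 50_000
    n_mirna_genes: int = 20
    n_ncrna_refs: int = 5  # per class (rRNA / tRNA / snoRNA)
    mature_length_range: tuple[int, int] = (20, 24)
    modal_mature_length: int = 22
    loop_length_range: tuple[int, int] = (8, 15)
    stem_mismatch_rate: float = 0.08
    n_reads: int = 50_000
    expression_lognormal_mu: float = 2.0
    expression_lognormal_sigma: float = 1.0
    adapter3: str = DEFAULT_ADAPTER3
    error_rate: float = 0.005
    read_length: int = 50
    isomir_rates: IsomirRates = field(default_factory=IsomirRates)
    background_fraction: float = 0.10
    ncrna_fraction: float = 0.15
    p_known_mirna: float = 0.5  # fraction of planted genes in the toy miRBase

    def validate(self) -> None:
        for name in (
            "stem_mismatch_rate",
            "error_rate",
            "background_fraction",
            "ncrna_fraction",
            "p_known_mirna",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.background_fraction + self.ncrna_fraction > 1.0:
            raise ValueError("read-class mixture fractions exceed 1")
        lo, hi = self.mature_length_range
        if not (18 <= lo <= hi <= 30):
            raise ValueError("mature_length_range must lie within [18, 30]")
        if not lo <= self.modal_mature_length <= hi:
            raise ValueError("modal mature length outside mature_length_range")
        self.isomir_rates.validate()


@dataclass(frozen=True)
class MirnaLocus:
    gene_id: str
    chrom: str
    strand: str
    arm: str  # which arm the mature sits on: '5p' or '3p'
    precursor_start: int  # genomic plus-strand, 0-based half-open
    precursor_end: int
    mature_start: int
    mature_end: int
    mature_rna: str
    known: bool  # True -> part of the toy conserved (miRBase-like) set


class GenomeSizingError(ValueError):
    """Genome too short to place all loci without overlap."""


def _rand_seq(rng: np.random.Generator, length: int, bases=RNA_BASES) -> str:
    return "".join(rng.choice(bases, size=length))


def _mature_length(cfg: SimConfig, rng: np.random.Generator) -> int:
    lo, hi = cfg.mature_length_range
    lengths = list(range(lo, hi + 1))
    if len(lengths) == 1:
        return lengths[0]
    # peaked at the modal length so the library's insert-length mode is
    # the modal mature length
    weights = np.full(len(lengths), 0.4 / (len(lengths) - 1))
    weights[lengths.index(cfg.modal_mature_length)] = 0.6
    return int(rng.choice(lengths, p=weights))


def _mutate_star(star: str, rate: float, rng: np.random.Generator) -> str:
    out = list(star)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = rng.choice([b for b in "ACGU" if b != out[i]])
    return "".join(out)


def _seed_streams(cfg: SimConfig) -> list[np.random.Generator]:
    children = np.random.SeedSequence(cfg.rng_seed).spawn(3)
    return [np.random.default_rng(c) for c in children]


def _is_clean_hairpin(precursor: str, arm: str, mature_len: int) -> bool:
    """True when the planted precursor satisfies the discovery criteria
    (single stem-loop, mature on one arm outside the loop, >= 60 % of mature
    bases paired) under the package's own folder.  Draws that fail are
    rejected so ground-truth loci are genuine hairpins under the model."""
    from .hairpin import HairpinThresholds, _evaluate_precursor, fold

    th = HairpinThresholds()
    if arm == "5p":
        m0, m1 = 0, mature_len
    else:
        m0, m1 = len(precursor) - mature_len, len(precursor)
    _fr, flags, frac, _star = _evaluate_precursor(
        precursor, m0, m1, fold, min_helix=th.min_helix
    )
    return all(flags.values()) and frac >= th.min_paired_fraction


def make_genome(config: SimConfig) -> tuple[str, list[MirnaLocus]]:
    """Random DNA genome with ``n_mirna_genes`` planted hairpin precursors.

    Each precursor is mature arm + loop + near-reverse-complement star arm
    (or the mirror for 3p-arm genes), embedded at non-overlapping loci on a
    random strand with >= 40 nt of spacing.  Deterministic in the config.
    """
    config.validate()
    rng = _seed_streams(config)[0]
    adapter6 = to_rna(config.adapter3)[:6]
    n = config.genome_length
    # capacity check before any sampling
    lo_l, hi_l = config.loop_length_range
    max_prec = config.mature_length_range[1] * 2 + hi_l
    if config.n_mirna_genes * (max_prec + 80) + 40 > n:
        raise GenomeSizingError(
            f"genome of {n} nt cannot hold {config.n_mirna_genes} loci "
            f"with spacing"
        )
    genome = list(_rand_seq(rng, n, DNA_BASES))
    placed: list[tuple[int, int]] = []
    manifest: list[MirnaLocus] = []
    known_flags = rng.random(config.n_mirna_genes) < config.p_known_mirna
    for g in range(config.n_mirna_genes):
        for _attempt in range(2000):
            mlen = _mature_length(config, rng)
            loop_len = int(rng.integers(lo_l, hi_l + 1))
            mature = _rand_seq(rng, mlen)
            if adapter6 in mature:
                continue
            star = _mutate_star(revcomp_rna(mature), config.stem_mismatch_rate, rng)
            loop = _rand_seq(rng, loop_len, np.array(list("AC")))  # pairing-inert
            arm = "5p" if rng.random() < 0.5 else "3p"
            local = mature + loop + star if arm == "5p" else star + loop + mature
            if not _is_clean_hairpin(local, arm, mlen):
                continue  # ground-truth hairpins must be hairpins under the model
            flank5 = _rand_seq(rng, 8)
            flank3 = _rand_seq(rng, 8)
            segment = flank5 + local + flank3
            if adapter6 in segment:
                continue
            plen = len(local)
            start = int(rng.integers(30, n - plen - 30))
            if any(start - 40 < e and s - 40 < start + plen for s, e in placed):
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            emit = segment if strand == "+" else revcomp_rna(segment)
            genome[start - 8 : start + plen + 8] = list(to_dna(emit))
            placed.append((start - 8, start + plen + 8))
            if arm == "5p":
                m_lo, m_hi = 0, mlen  # local coords within precursor
            else:
                m_lo, m_hi = plen - mlen, plen
            if strand == "+":
                mature_start, mature_end = start + m_lo, start + m_hi
            else:
                mature_start, mature_end = start + plen - m_hi, start + plen - m_lo
            manifest.append(
                MirnaLocus(
                    gene_id=f"mir-sim-{g + 1}",
                    chrom="chr1",
                    strand=strand,
                    arm=arm,
                    precursor_start=start,
                    precursor_end=start + plen,
                    mature_start=mature_start,
                    mature_end=mature_end,
                    mature_rna=mature,
                    known=bool(known_flags[g]),
                )
            )
            break
        else:
            raise GenomeSizingError(
                f"could not place locus {g + 1} in a {n}-nt genome"
            )
    return "".join(genome), manifest


NCRNA_LENGTHS = {"rRNA": 120, "tRNA": 75, "snoRNA": 100}


def make_reference_sets(config: SimConfig) -> dict[str, dict[str, str]]:
    """Random rRNA/tRNA/snoRNA reference sequences (RNA-space), keyed the way
    :func:`smallrna.annotate.classify` expects ('rrna', 'trna', 'snorna')."""
    rng = _seed_streams(config)[1]
    adapter6 = to_rna(config.adapter3)[:6]
    refs: dict[str, dict[str, str]] = {"rrna": {}, "trna": {}, "snorna": {}}
    for cls, key in (("rRNA", "rrna"), ("tRNA", "trna"), ("snoRNA", "snorna")):
        for i in range(config.n_ncrna_refs):
            while True:
                seq = _rand_seq(rng, NCRNA_LENGTHS[cls])
                if adapter6 not in seq:
                    break
            refs[key][f"{cls}-{i + 1}"] = seq
    return refs


@dataclass(frozen=True)
class GroundTruthRecord:
    """Truth label for one simulated read."""

    read_id: str
    source: str  # gene id | 'rRNA'/'tRNA'/'snoRNA' | 'background'
    isomir_class: str  # canonical | iso5 | iso3 | internal | '' (non-miRNA)
    edit: str  # the generative edit name, e.g. 'trim3'
    offset5: int
    offset3: int
    substituted_positions: tuple[int, ...]  # 1-based in the emitted insert
    templated: bool | None  # None when no extension was made
    insert: str  # emitted insert, RNA-space, pre-error


def apply_isomir(
    canonical: str,
    context: str,
    rates: IsomirRates,
    rng: np.random.Generator,
) -> tuple[str, GroundTruthRecord]:
    """Draw one isomiR edit of ``canonical`` from the rate mixture.

    ``context`` is the strand-local genomic sequence containing the
    canonical mature with at least 8 nt of flank on both sides; templated
    extensions copy flank bases, non-templated additions append an A or U
    that does not match the flank.
    """
    canonical = to_rna(canonical)
    context = to_rna(context)
    idx = context.find(canonical)
    if idx < 0:
        raise ValueError("canonical sequence not found in context")
    flank5, flank3 = context[:idx], context[idx + len(canonical) :]
    if len(flank5) < 8 or len(flank3) < 8:
        raise ValueError("context must provide >= 8 nt flanks")
    rates.validate()
    edit = str(rng.choice(np.array(ISOMIR_EDITS), p=rates.probs()))
    L = len(canonical)
    room = L - 18  # trims may not take the insert below the length filter
    variant = canonical
    o5 = o3 = 0
    subs: tuple[int, ...] = ()
    templated: bool | None = None

    if edit == "trim3":
        cap = min(3, room)
        if cap < 1:
            edit = "canonical"
        else:
            t = min(int(rng.geometric(rates.trim3_geom_p)), cap)
            variant = canonical[:-t]
            o3 = -t
    elif edit == "trim5":
        if room < 1:
            edit = "canonical"
        else:
            variant = canonical[1:]
            o5 = -1
    elif edit == "ext3_templated":
        e = min(int(rng.geometric(0.5)), 2)
        variant = canonical + flank3[:e]
        o3 = e
        templated = True
    elif edit == "add3_nontemplated":
        f = flank3[0]
        if f == "A":
            base = "U"
        elif f == "U":
            base = "A"
        else:
            base = str(rng.choice(np.array(["A", "U"]), p=np.array(rates.add3_au_weights)))
        variant = canonical + base
        o3 = 1
        templated = False
    elif edit == "shift5":
        if rng.random() < 0.5 and room >= 1:
            variant = canonical[1:]
            o5 = -1
        else:
            variant = flank5[-1] + canonical
            o5 = 1
            templated = True
    elif edit == "substitution":
        pos = int(rng.integers(0, L))
        new = str(rng.choice(np.array([b for b in "ACGU" if b != canonical[pos]])))
        variant = canonical[:pos] + new + canonical[pos + 1 :]
        subs = (pos + 1,)

    record = GroundTruthRecord(
        read_id="",
        source="",
        isomir_class=EDIT_TO_CLASS[edit],
        edit=edit,
        offset5=o5,
        offset3=o3,
        substituted_positions=subs,
        templated=templated,
        insert=variant,
    )
    return variant, record


def mature_context(genome: str, locus: MirnaLocus, flank: int = 8) -> str:
    """Strand-local RNA context of a locus's mature arm with ``flank`` nt flanks."""
    lo = locus.mature_start - flank
    hi = locus.mature_end + flank
    seq = to_rna(genome[lo:hi])
    return seq if locus.strand == "+" else revcomp_rna(seq)


@dataclass
class SimResult:
    config: SimConfig
    genome: str  # DNA
    manifest: list[MirnaLocus]
    ncrna_refs: dict[str, dict[str, str]]
    reads: list[tuple[str, str, str]]  # (read_id, DNA sequence, quality string)
    truth: pd.DataFrame

    def mature_refs(self, known_only: bool = True) -> dict[str, str]:
        return {
            loc.gene_id: loc.mature_rna
            for loc in self.manifest
            if loc.known or not known_only
        }


def simulate_library(config: SimConfig) -> SimResult:
    """Generate the full synthetic library: genome, references, FASTQ reads
    and the per-read truth table.  Byte-deterministic in the config."""
    config.validate()
    genome, manifest = make_genome(config)
    ncrna_refs = make_reference_sets(config)
    rng = _seed_streams(config)[2]

    expr = rng.lognormal(
        config.expression_lognormal_mu,
        config.expression_lognormal_sigma,
        size=len(manifest),
    )
    gene_probs = expr / expr.sum()
    contexts = {loc.gene_id: mature_context(genome, loc) for loc in manifest}
    ncrna_classes = ["rRNA", "tRNA", "snoRNA"]
    adapter = to_dna(config.adapter3)

    reads: list[tuple[str, str, str]] = []
    truth_rows = []
    for i in range(config.n_reads):
        read_id = f"read{i + 1}"
        u = rng.random()
        if u < config.background_fraction:
            insert = _rand_seq(rng, int(rng.integers(15, 36)))
            record = GroundTruthRecord(
                read_id, "background", "", "", 0, 0, (), None, insert
            )
        elif u < config.background_fraction + config.ncrna_fraction:
            cls = ncrna_classes[int(rng.integers(0, 3))]
            key = {"rRNA": "rrna", "tRNA": "trna", "snoRNA": "snorna"}[cls]
            name = f"{cls}-{int(rng.integers(1, config.n_ncrna_refs + 1))}"
            ref = ncrna_refs[key][name]
            frag_len = int(rng.integers(18, 31))
            start = int(rng.integers(0, len(ref) - frag_len + 1))
            insert = ref[start : start + frag_len]
            record = GroundTruthRecord(read_id, cls, "", "", 0, 0, (), None, insert)
        else:
            gene = manifest[int(rng.choice(len(manifest), p=gene_probs))]
            insert, record = apply_isomir(
                gene.mature_rna, contexts[gene.gene_id], config.isomir_rates, rng
            )
            record = replace(record, read_id=read_id, source=gene.gene_id)

        raw = to_dna(insert) + adapter
        if len(raw) < config.read_length:
            raw += _rand_seq(rng, config.read_length - len(raw), DNA_BASES)
        raw = raw[: config.read_length]
        quals = rng.integers(30, 41, size=len(raw))
        if config.error_rate > 0:
            err = rng.random(len(raw)) < config.error_rate
            if err.any():
                bases = list(raw)
                for p in np.flatnonzero(err):
                    bases[p] = str(
                        rng.choice(np.array([b for b in "ACGT" if b != bases[p]]))
                    )
                    quals[p] = int(rng.integers(2, 16))
                raw = "".join(bases)
        qual_str = "".join(chr(int(q) + 33) for q in quals)
        reads.append((read_id, raw, qual_str))
        truth_rows.append(
            {
                "read_id": record.read_id,
                "source": record.source,
                "isomir_class": record.isomir_class,
                "edit": record.edit,
                "offset5": record.offset5,
                "offset3": record.offset3,
                "substituted_positions": ";".join(
                    map(str, record.substituted_positions)
                ),
                "templated": record.templated,
                "insert": record.insert,
                "insert_len": len(record.insert),
            }
        )
    truth = pd.DataFrame(truth_rows)
    return SimResult(config, genome, manifest, ncrna_refs, reads, truth)


# ---------------------------------------------------------------------------
# writers (FASTQ / FASTA / GFF3 / TSV)


def write_fastq(reads, path) -> None:
    with open(path, "w") as fh:
        for read_id, seq, qual in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")


def write_genome_fasta(genome: str, path, chrom: str = "chr1") -> None:
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(genome), 70):
            fh.write(genome[i : i + 70] + "\n")


def write_reference_fasta(refs: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in refs.items():
            fh.write(f">{name}\n{to_dna(seq)}\n")


def write_manifest_gff3(manifest, path) -> None:
    """GFF3 locus manifest (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for loc in manifest:
            fh.write(
                "\t".join(
                    [
                        loc.chrom, "smallrna-sim", "pre_miRNA",
                        str(loc.precursor_start + 1), str(loc.precursor_end),
                        ".", loc.strand, ".",
                        f"ID={loc.gene_id};known={int(loc.known)}",
                    ]
                )
                + "\n"
            )
            fh.write(
                "\t".join(
                    [
                        loc.chrom, "smallrna-sim", "miRNA",
                        str(loc.mature_start + 1), str(loc.mature_end),
                        ".", loc.strand, ".",
                        f"ID={loc.gene_id}-mature;Parent={loc.gene_id};arm={loc.arm}",
                    ]
                )
                + "\n"
            )
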