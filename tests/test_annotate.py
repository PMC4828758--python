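"""Genome mapping, reference containment, conserved-miRNA matching, and the
hierarchical classifier, checked against naive exhaustive-scan oracles."""

import numpy as np
import pytest

from smallrna import annotate
from smallrna._seq import revcomp_rna
from smallrna.annotate import (
    AnnotationRecord,
    GenomeIndex,
    classify,
    map_to_genome,
    match_conserved_mirna,
    match_reference_set,
)
from smallrna.preprocess import UniqueTag

from .oracles import best_containment_naive, scan_genome_naive


def _random_rna(rng, n):
    return "".join(rng.choice(list("ACGU"), size=n))


class TestMapToGenome:
    def test_planted_substring_found_exactly(self, rng):
        genome = _random_rna(rng, 500)
        tag = genome[100:122]
        hits = map_to_genome(tag, genome, max_mm=1)
        exact = [h for h in hits if h.n_mismatches == 0 and h.strand == "+"]
        assert any(h.start == 100 and h.end == 122 for h in exact)

    def test_mismatch_threshold_boundary(self, rng):
        genome = _random_rna(rng, 400)
        tag = list(genome[50:72])
        tag[5] = {"A": "C", "C": "A", "G": "U", "U": "G"}[tag[5]]
        one_mm = map_to_genome("".join(tag), genome, max_mm=1)
        assert any(h.start == 50 and h.n_mismatches == 1 for h in one_mm)
        tag[15] = {"A": "C", "C": "A", "G": "U", "U": "G"}[tag[15]]
        assert (
            map_to_genome("".join(tag), genome, max_mm=1) == []
            or all(h.start != 50 for h in map_to_genome("".join(tag), genome, max_mm=1))
        )

    def test_minus_strand_hit(self, rng):
        genome = _random_rna(rng, 300)
        tag = revcomp_rna(genome[40:62])
        hits = map_to_genome(tag, genome, max_mm=0)
        assert any(h.strand == "-" and h.start == 40 for h in hits)

    def test_agrees_with_naive_scan(self, rng):
        """Vectorized mapping equals brute-force scanning of every offset."""
        genome = _random_rna(rng, 1500)
        index = GenomeIndex(genome)
        for _ in range(60):
            if rng.random() < 0.5:
                tag = _random_rna(rng, int(rng.integers(18, 26)))
            else:  # planted with noise so hits exist
                start = int(rng.integers(0, 1400))
                L = int(rng.integers(18, 26))
                tag = list(genome[start : start + L])
                if rng.random() < 0.7:
                    p = int(rng.integers(0, L))
                    tag[p] = {"A": "C", "C": "G", "G": "U", "U": "A"}[tag[p]]
                tag = "".join(tag)
                if rng.random() < 0.5:
                    tag = revcomp_rna(tag)
            got = {
                (h.start, h.strand, h.n_mismatches)
                for h in map_to_genome(tag, index, max_mm=1)
            }
            want = set(scan_genome_naive(tag, genome, max_mm=1))
            assert got == want

    def test_sorted_by_mismatches_then_position(self, rng):
        genome = "AAAAUUUUGGGGAAAAUUUUGGGG" * 4
        hits = map_to_genome("AAAAUUUUGGGG", genome, max_mm=1)
        keys = [(h.n_mismatches, h.chrom, h.start, h.strand) for h in hits]
        assert keys == sorted(keys)


class TestMatchReferenceSet:
    def test_internal_window_zero_mismatches(self, rng):
        ref = _random_rna(rng, 120)
        hit = match_reference_set(ref[37:57], {"rRNA-1": ref}, max_mm=1)
        assert hit is not None
        assert hit.reference_id == "rRNA-1"
        assert hit.n_mismatches == 0

    def test_no_match_returns_none(self):
        assert match_reference_set("ACGU" * 5, {"r": "GGGG" * 30}, max_mm=0) is None

    def test_agrees_with_naive_containment(self, rng):
        refs = {f"ref{i}": _random_rna(rng, 80) for i in range(5)}
        for _ in range(150):
            if rng.random() < 0.5:
                tag = _random_rna(rng, 20)
            else:
                ref = refs[f"ref{int(rng.integers(0, 5))}"]
                s = int(rng.integers(0, 60))
                tag = list(ref[s : s + 20])
                if rng.random() < 0.6:
                    p = int(rng.integers(0, 20))
                    tag[p] = {"A": "G", "G": "A", "C": "U", "U": "C"}[tag[p]]
                tag = "".join(tag)
            got = match_reference_set(tag, refs, max_mm=1)
            want = best_containment_naive(tag, refs, max_mm=1)
            if want is None:
                assert got is None
            else:
                assert got is not None
                assert got.n_mismatches == want[1]

    def test_empty_refs_rejected(self):
        with pytest.raises(ValueError):
            match_reference_set("ACGU" * 5, {})


class TestMatchConservedMirna:
    MATURE = "UGAGGUAGUAGGUUGUAUAGUU"  # 22 nt

    def test_identical_tag_hits_with_zero_offsets(self):
        hit = match_conserved_mirna(self.MATURE, {"let7": self.MATURE})
        assert (hit.reference_id, hit.n_mismatches, hit.offset5, hit.offset3) == (
            "let7", 0, 0, 0,
        )

    def test_3prime_trimmed_isomir_still_assigned(self):
        hit = match_conserved_mirna(self.MATURE[:-2], {"let7": self.MATURE})
        assert hit is not None
        assert hit.offset3 == -2

    def test_three_substitutions_rejected_at_max_two(self):
        tag = "ACC" + self.MATURE[3:]  # differs from UGA at all three positions
        assert match_conserved_mirna(tag, {"let7": self.MATURE}, max_mm=2) is None

    def test_deep_5prime_trim_uncovers_seed_and_misses(self):
        # removing 4 nt from the 5' end leaves seed positions 2-4 uncovered
        assert match_conserved_mirna(self.MATURE[4:], {"let7": self.MATURE}) is None

    def test_end_offset_bound(self):
        tag = "ACGU" + self.MATURE  # 5' extension of 4 > max_end_offset 3
        assert match_conserved_mirna(tag, {"let7": self.MATURE}) is None
        tag = "CGU" + self.MATURE[:-3]
        hit = match_conserved_mirna(tag, {"let7": self.MATURE})
        assert hit is not None and hit.offset5 == 3


class TestClassify:
    def test_precedence_mirna_beats_rrna_despite_mismatch(self, rng):
        mature = _random_rna(rng, 22)
        tag_seq = mature[:10] + ("A" if mature[10] != "A" else "C") + mature[11:]
        rrna = _random_rna(rng, 40) + tag_seq + _random_rna(rng, 40)
        tags = [UniqueTag("tag1", tag_seq, 5)]
        res = classify(
            tags,
            _random_rna(rng, 300),
            {"mature": {"mir-x": mature}, "rrna": {"rRNA-1": rrna}},
        )
        assert res.records[0].category == "conserved_mirna"

    def test_counts_partition_tags(self, small_clean_classified):
        sim, pre, res = small_clean_classified
        assert res.counts["unique_tags"].sum() == len(pre.tags)
        assert res.counts["total_reads"].sum() == sum(t.count for t in pre.tags)

    def test_noise_free_truth_agreement(self, small_clean_classified):
        """Planted tags get their truth category; background stays unannotated."""
        sim, pre, res = small_clean_classified
        truth = sim.truth
        cat_by_tag = {r.tag_id: r.category for r in res.records}
        tag_by_seq = {t.sequence: t.tag_id for t in pre.tags}
        expected = {
            "rRNA": "rrna", "tRNA": "trna", "snoRNA": "snorna",
        }
        n_checked = 0
        bg_total = bg_unannotated = 0
        for row in truth.itertuples():
            if not 18 <= len(row.insert) <= 30:
                continue
            tag_id = tag_by_seq.get(row.insert)
            if tag_id is None:
                continue
            cat = cat_by_tag[tag_id]
            if row.source == "background":
                bg_total += 1
                bg_unannotated += cat == "unannotated"
            elif row.source in expected:
                assert cat == expected[row.source], row
                n_checked += 1
            else:  # planted miRNA gene; all matures were given as references
                assert cat == "conserved_mirna", row
                n_checked += 1
        assert n_checked > 1000
        assert bg_unannotated / bg_total >= 0.99

    def test_annotation_order_invariance(self, rng):
        genome = _random_rna(rng, 400)
        tags = [
            UniqueTag(f"tag{i}", genome[i * 30 : i * 30 + 20], i + 1)
            for i in range(5
            )
        ]
        refs = {"rrna": {"rRNA-1": genome[0:60]}}
        a = classify(tags, genome, refs).records
        b = classify(list(reversed(tags)), genome, refs).records
        assert {r.tag_id: r.category for r in a} == {r.tag_id: r.category for r in b}

    def test_duplicate_reference_names_rejected(self, rng):
        genome = _random_rna(rng, 100)
        with pytest.raises(ValueError, match="appears in both"):
            classify(
                [],
                genome,
                {"rrna": {"dup": genome[:50]}, "trna": {"dup": genome[50:]}},
            )

    def test_record_invariants(self):
        with pytest.raises(ValueError):
            AnnotationRecord("t", "novel_input", reference_id="x")
        with pytest.raises(ValueError):
            AnnotationRecord("t", "rrna", reference_id="")
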