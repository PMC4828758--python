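"""Folding DP vs enumeration, structure predicates, clustering, window
geometry, hairpin evaluation, and candidate naming."""

import dataclasses

import pytest

from smallrna import hairpin
from smallrna._seq import revcomp_rna
from smallrna.annotate import GenomeAlignment
from smallrna.hairpin import (
    Cluster,
    cluster_tags,
    dinucleotide_shuffle,
    evaluate_hairpin,
    excise_windows,
    filter_short_helices,
    fold,
    is_unbranched,
    n_hairpin_loops,
    name_candidates,
    pairs_from_dotbracket,
)

from .oracles import branched_by_pairwise_check, brute_force_max_fold_weight


def _random_rna(rng, n):
    return "".join(rng.choice(list("ACGU"), size=n))


class TestFold:
    def test_three_gc_stem(self):
        fr = fold("GGGAAACCC")
        assert fr.structure == "(((...)))"
        assert fr.score == 9
        assert fr.pairs == ((1, 9), (2, 8), (3, 7))

    def test_no_complementary_pairs(self):
        fr = fold("AAAAAA")
        assert fr.structure == "......"
        assert fr.score == 0

    def test_min_loop_forbids_short_hairpin(self):
        fr = fold("GC")
        assert fr.structure == ".."
        assert fr.score == 0

    def test_rejects_non_acgu(self):
        with pytest.raises(ValueError):
            fold("ACGX")

    def test_matches_enumeration_on_short_sequences(self, rng):
        """DP max weight equals brute-force enumeration for lengths <= 14."""
        for _ in range(60):
            seq = _random_rna(rng, int(rng.integers(5, 15)))
            assert fold(seq).score == brute_force_max_fold_weight(seq)

    def test_structure_invariants_on_random_sequences(self, rng):
        for _ in range(40):
            seq = _random_rna(rng, int(rng.integers(10, 60)))
            fr = fold(seq)
            pairs = pairs_from_dotbracket(fr.structure)
            assert pairs == list(fr.pairs)
            total = 0
            for i, j in fr.pairs:
                assert j - i > 3
                assert (seq[i - 1], seq[j - 1]) in {
                    ("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"),
                    ("G", "U"), ("U", "G"),
                }
                total += hairpin.pair_weight(seq[i - 1], seq[j - 1])
            assert total == fr.score  # traceback consistent with DP optimum

    def test_deterministic(self):
        seq = "GGCAUGCAUCCGAUCGGAUCGAUGCC"
        assert fold(seq) == fold(seq)


class TestStructurePredicates:
    def test_single_stem_unbranched(self):
        assert is_unbranched("((((...))))")

    def test_enclosed_bifurcation_branched(self):
        assert not is_unbranched("(((..))..((..)))")

    def test_unbalanced_raises(self):
        with pytest.raises(ValueError):
            is_unbranched("((..)")
        with pytest.raises(ValueError):
            is_unbranched("(..))")

    def test_agrees_with_pairwise_oracle(self, rng):
        """Stack-parse predicate equals the quadratic enclosure check on
        random folded structures."""
        for _ in range(200):
            seq = _random_rna(rng, int(rng.integers(12, 50)))
            fr = fold(seq)
            pairs = list(fr.pairs)
            assert is_unbranched(fr.structure) == (
                not branched_by_pairwise_check(pairs)
            )

    def test_hairpin_loop_count(self):
        assert n_hairpin_loops("((((...))))") == 1
        assert n_hairpin_loops("((..))((..))") == 2
        assert n_hairpin_loops("......") == 0

    def test_short_helix_filter(self):
        pairs = [(1, 20), (2, 19), (3, 18), (8, 13)]  # 3-stack + lone pair
        kept = filter_short_helices(pairs, min_helix=3)
        assert kept == [(1, 20), (2, 19), (3, 18)]


class TestClusterTags:
    def _aln(self, tag, start, end, strand="+"):
        return GenomeAlignment(tag, "chr1", start, end, strand, 0, ())

    def test_overlapping_same_strand_merge(self):
        clusters = cluster_tags(
            [self._aln("a", 100, 122), self._aln("b", 107, 129)], {"a": 5, "b": 3}
        )
        assert len(clusters) == 1
        assert (clusters[0].start, clusters[0].end) == (100, 129)
        assert clusters[0].anchor.tag_id == "a"

    def test_opposite_strands_stay_separate(self):
        clusters = cluster_tags(
            [self._aln("a", 100, 122, "+"), self._aln("b", 100, 122, "-")],
            {"a": 1, "b": 1},
        )
        assert len(clusters) == 2

    def test_gap_beyond_merge_gap_splits(self):
        clusters = cluster_tags(
            [self._aln("a", 100, 120), self._aln("b", 135, 155)], {"a": 1, "b": 1}
        )
        assert len(clusters) == 2
        merged = cluster_tags(
            [self._aln("a", 100, 120), self._aln("b", 128, 148)], {"a": 1, "b": 1}
        )
        assert len(merged) == 1


class TestExciseWindows:
    def test_plus_strand_arithmetic(self, rng):
        genome = _random_rna(rng, 2000)
        cluster = Cluster("chr1", "+", 1000, 1022)
        cluster.members = [GenomeAlignment("a", "chr1", 1000, 1022, "+", 0, ())]
        cluster.anchor = cluster.members[0]
        w5, w3 = excise_windows(genome, cluster, flank=150)
        assert (w5.start, w5.end) == (980, 1172)
        assert (w3.start, w3.end) == (850, 1042)
        assert w5.seq[w5.mature_local[0] : w5.mature_local[1]] == genome[1000:1022]

    def test_edge_truncation_flagged(self, rng):
        genome = _random_rna(rng, 500)
        cluster = Cluster("chr1", "+", 5, 27)
        cluster.members = [GenomeAlignment("a", "chr1", 5, 27, "+", 0, ())]
        cluster.anchor = cluster.members[0]
        w5, _ = excise_windows(genome, cluster, flank=150)
        assert w5.truncated
        assert w5.start == 0

    def test_minus_strand_mature_is_5prime_to_3prime(self, rng):
        genome = _random_rna(rng, 600)
        cluster = Cluster("chr1", "-", 300, 322)
        cluster.members = [GenomeAlignment("a", "chr1", 300, 322, "-", 0, ())]
        cluster.anchor = cluster.members[0]
        for w in excise_windows(genome, cluster, flank=60):
            m0, m1 = w.mature_local
            assert w.seq[m0:m1] == revcomp_rna(genome[300:322])

    def test_planted_window_contains_precursor(self, small_clean_sim):
        sim = small_clean_sim
        for loc in sim.manifest[:5]:
            aln = GenomeAlignment(
                "t", loc.chrom, loc.mature_start, loc.mature_end, loc.strand, 0, ()
            )
            cluster = Cluster(loc.chrom, loc.strand, loc.mature_start, loc.mature_end)
            cluster.members = [aln]
            cluster.anchor = aln
            spans = [
                (w.start, w.end) for w in excise_windows(sim.genome, cluster)
            ]
            assert any(
                s <= loc.precursor_start and e >= loc.precursor_end for s, e in spans
            )


def _perfect_window(rng, mlen=22, loop=10):
    mature = _random_rna(rng, mlen)
    prec = mature + "".join(rng.choice(list("AC"), size=loop)) + revcomp_rna(mature)
    flank = _random_rna(rng, 60)
    seq = prec + flank
    from smallrna.hairpin import Window

    return Window(
        chrom="chr1", strand="+", start=0, end=len(seq), seq=seq,
        mature_local=(0, mlen), arm="5p",
    ), mature


class TestEvaluateHairpin:
    def test_perfect_hairpin_with_support_accepted(self, rng):
        window, mature = _perfect_window(rng)
        support = [("t1", 50, 0), ("t2", 10, 1), ("t3", 4, 2)]
        cand = evaluate_hairpin(window, mature, support)
        assert cand.accepted, cand.flags
        assert cand.flags == {
            "unbranched": True,
            "mature_in_one_arm": True,
            "pairing_fraction_ok": True,
            "support_ok": True,
        }
        assert cand.mature_sequence == mature

    def test_single_supporting_tag_rejected(self, rng):
        window, mature = _perfect_window(rng)
        cand = evaluate_hairpin(window, mature, [("t1", 50, 0)])
        assert not cand.accepted
        assert cand.flags["support_ok"] is False
        assert cand.flags["unbranched"] is True

    def test_support_outside_tolerance_ignored(self, rng):
        window, mature = _perfect_window(rng)
        support = [("t1", 50, 0), ("t2", 10, 8)]  # 8 nt away > tolerance 3
        cand = evaluate_hairpin(window, mature, support)
        assert cand.flags["support_ok"] is False

    def test_star_positioned_read_counts_as_support(self, rng):
        window, mature = _perfect_window(rng, mlen=22, loop=10)
        # star 5' end is at local position mlen + loop (start of revcomp arm)
        support = [("t1", 50, 0), ("t2", 3, 32)]
        cand = evaluate_hairpin(window, mature, support)
        assert cand.flags["support_ok"] is True

    def test_shuffled_windows_rarely_accepted(self, rng):
        """Dinucleotide-shuffled windows lose the planted stem-loop."""
        n_acc = 0
        n = 60
        for k in range(n):
            window, mature = _perfect_window(rng)
            shuffled = dataclasses.replace(
                window, seq=dinucleotide_shuffle(window.seq, rng)
            )
            support = [("t1", 50, 0), ("t2", 10, 1)]
            cand = evaluate_hairpin(shuffled, mature[: len(mature)], support)
            n_acc += cand.accepted
        assert n_acc / n < 0.05


class TestNameCandidates:
    def _candidate(self, rng, mature, support, chrom="chr1", start=0):
        fr = fold(mature + "AAAA" + revcomp_rna(mature))
        return hairpin.HairpinCandidate(
            name="", chrom=chrom, strand="+", start=start, end=start + len(fr.sequence),
            precursor=fr.sequence, fold=fr, arm="5p", mature_local=(0, len(mature)),
            star_local=None, mature_sequence=mature,
            supporting_tags=[(f"t{start}", support)], flags={"support_ok": True},
        )

    def test_single_candidate_named_novel_1(self, rng):
        cands = name_candidates([self._candidate(rng, _random_rna(rng, 20), 10)])
        assert cands[0].name == "Novel-1"

    def test_identical_mature_from_two_loci_get_letters(self, rng):
        mature = _random_rna(rng, 22)
        other = _random_rna(rng, 22)
        named = name_candidates(
            [
                self._candidate(rng, mature, 100, start=0),
                self._candidate(rng, other, 50, start=500),
                self._candidate(rng, mature, 20, start=1000),
            ]
        )
        names = {c.start: c.name for c in named}
        assert names[0] == "Novel-1a"
        assert names[1000] == "Novel-1b"
        assert names[500] == "Novel-2"

    def test_ordering_invariant_under_permutation(self, rng):
        cands = [
            self._candidate(rng, _random_rna(rng, 20 + i % 3), 10 * (i + 1), start=i * 300)
            for i in range(5)
        ]
        a = [(c.start, c.name) for c in name_candidates(cands)]
        b = [(c.start, c.name) for c in name_candidates(list(reversed(cands)))]
        assert sorted(a) == sorted(b)


class TestDinucleotideShuffle:
    def test_preserves_dinucleotide_counts(self, rng):
        from collections import Counter

        for _ in range(20):
            seq = _random_rna(rng, 80)
            sh = dinucleotide_shuffle(seq, rng)
            assert len(sh) == len(seq)
            assert Counter(zip(seq, seq[1:])) == Counter(zip(sh, sh[1:]))
            assert sh[0] == seq[0] and sh[-1] == seq[-1]


class TestDiscoveryRecovery:
    def test_noise_free_recovery_is_complete(self, small_clean_classified):
        """Every planted locus with >= 2 distinct reads is reported when the
        mature reference set is withheld and noise is off."""
        from smallrna.annotate import classify

        sim, pre, _ = small_clean_classified
        res = classify(pre.tags, sim.genome, dict(sim.ncrna_refs))
        tag_counts = {t.tag_id: t.count for t in pre.tags}
        tag_seqs = {t.tag_id: t.sequence for t in pre.tags}
        alns = [a for al in res.alignments.values() for a in al]
        cands = hairpin.discover(sim.genome, alns, tag_counts, tag_seqs)
        per_gene = (
            sim.truth[sim.truth.source.str.startswith("mir-")]
            .groupby("source")["insert"]
            .nunique()
        )
        eligible = set(per_gene[per_gene >= 2].index)
        recovered = sum(
            1
            for loc in sim.manifest
            if loc.gene_id in eligible
            and any(
                c.chrom == loc.chrom
                and c.start < loc.mature_end
                and loc.mature_start < c.end
                for c in cands
            )
        )
        assert recovered == len(eligible)
        # every reported mature is a substring of its precursor
        for c in cands:
            m0, m1 = c.mature_local
            assert c.precursor[m0:m1] in c.precursor
            assert len(c.precursor) >= (m1 - m0)
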