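"""Known-miRNA counting, clustering, hairpin folding (against an exhaustive
oracle), candidate evaluation and star identification."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mirdeg.annotate import Hit
from mirdeg.io_core import Library, revcomp, to_rna
from mirdeg.mirna_discovery import (DiscoveryConfig, MiRNACandidate, ReadCluster,
                                    ClusterMember, assess_duplex, count_known,
                                    evaluate_precursor, extract_clusters,
                                    find_star, fold_hairpin, max_pairing)

_CAN_PAIR = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def brute_force_max_pairs(seq: str, min_loop: int = 3) -> int:
    """Exhaustive enumeration over all nested structures (oracle, n <= 12)."""
    seq = to_rna(seq)

    def best(positions: tuple[int, ...]) -> int:
        if len(positions) < 2:
            return 0
        first, rest = positions[0], positions[1:]
        score = best(rest)  # first unpaired
        for idx, j in enumerate(rest):
            if j - first > min_loop and (seq[first], seq[j]) in _CAN_PAIR:
                inside = tuple(p for p in rest[:idx])
                outside = tuple(p for p in rest[idx + 1:])
                score = max(score, 1 + best(inside) + best(outside))
        return score

    return best(tuple(range(len(seq))))


class TestCountKnown:
    DB = {"mir1": "TGACAGAAGAGAGTGAGCACA", "mir2": "TTGGACTGAAGGGAGCTCCCT"}

    def test_exact_match_counted(self):
        lib = Library(records={"TGACAGAAGAGAGTGAGCACA": 7})
        counts, assigned = count_known(lib, self.DB)
        assert counts == {"mir1": 7, "mir2": 0}
        assert assigned == {"TGACAGAAGAGAGTGAGCACA": "mir1"}

    def test_one_mismatch_not_counted_at_zero_tolerance(self):
        read = "AGACAGAAGAGAGTGAGCACA"  # pos-1 mismatch
        counts, _ = count_known(Library(records={read: 3}), self.DB)
        assert counts["mir1"] == 0

    def test_3prime_length_variants_counted(self):
        lib = Library(records={"TGACAGAAGAGAGTGAGCAC": 2,     # -1 nt
                               "TGACAGAAGAGAGTGAGCACAA": 3})  # +1 nt
        counts, _ = count_known(lib, self.DB)
        assert counts["mir1"] == 5

    def test_length_difference_beyond_two_excluded(self):
        counts, _ = count_known(Library(records={"TGACAGAAGAGAGTGAGC": 4}), self.DB)
        assert counts["mir1"] == 0

    def test_empty_mature_set_errors(self):
        with pytest.raises(ValueError):
            count_known(Library(), {})

    def test_recovers_planted_counts_exactly(self, small_truth):
        from mirdeg.preprocess import run_preprocess
        from mirdeg.synthetic_data import simulate_srna
        raw, real = simulate_srna(small_truth, "wild", 5)
        clean, _ = run_preprocess(raw, small_truth.cfg.clean_config())
        counts, _ = count_known(clean, small_truth.known_mature_db())
        for p in small_truth.known_loci:
            assert counts[p.mirna_id] == real.mirna_counts[p.mirna_id]


class TestExtractClusters:
    def test_distant_reads_make_two_clusters(self):
        hits = {"A" * 21: [Hit("c", 100, "+")], "C" * 21: [Hit("c", 600, "+")]}
        lib = Library(records={"A" * 21: 1, "C" * 21: 1})
        clusters = extract_clusters(hits, lib, merge_gap=100)
        assert len(clusters) == 2

    def test_identical_loci_merge(self):
        hits = {"A" * 21: [Hit("c", 100, "+")], "AC" * 10: [Hit("c", 100, "+")]}
        lib = Library(records={"A" * 21: 2, "AC" * 10: 1})
        clusters = extract_clusters(hits, lib, merge_gap=100)
        assert len(clusters) == 1 and clusters[0].total_count == 3

    def test_strands_do_not_merge(self):
        hits = {"A" * 21: [Hit("c", 100, "+")], "C" * 21: [Hit("c", 100, "-")]}
        lib = Library(records={"A" * 21: 1, "C" * 21: 1})
        assert len(extract_clusters(hits, lib)) == 2

    def test_multilocus_weight_split_conserves_counts(self):
        hits = {"A" * 21: [Hit("c", 100, "+"), Hit("c", 900, "+")]}
        lib = Library(records={"A" * 21: 6})
        clusters = extract_clusters(hits, lib)
        assert sum(c.total_count for c in clusters) == pytest.approx(6)
        assert all(c.total_count == pytest.approx(3) for c in clusters)

    def test_dominant_tie_breaks_lexicographically(self):
        cluster = ReadCluster("c", "+", 0, 21, [
            ClusterMember("C" * 21, 0, 21, 2.0),
            ClusterMember("A" * 21, 0, 21, 2.0)])
        assert cluster.dominant.seq == "A" * 21


class TestFolding:
    def test_no_complementarity_gives_zero_pairs(self):
        structure = fold_hairpin("A" * 40)
        assert structure.pairing_score == 0 and structure.weighted_score == 0

    def test_simple_stem_loop(self):
        pairs, n, weight = max_pairing("GGGGAAAACCCC")
        assert n == 4
        assert weight == 12  # four GC pairs

    def test_length_bounds_enforced(self):
        with pytest.raises(ValueError):
            fold_hairpin("ACGU" * 5)  # 20 nt < 40
        with pytest.raises(ValueError):
            fold_hairpin("ACGU" * 120)

    def test_full_sweep_small_lengths_matches_oracle(self):
        for n in (5, 6):
            for tup in itertools.product("ACGU", repeat=n):
                seq = "".join(tup)
                assert max_pairing(seq)[1] == brute_force_max_pairs(seq), seq

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(st.text(alphabet="ACGU", min_size=7, max_size=12))
    def test_random_lengths_7_to_12_match_oracle(self, seq):
        assert max_pairing(seq)[1] == brute_force_max_pairs(seq)

    def test_min_loop_respected(self):
        for pairs, _, _ in [max_pairing("GAAAC"), max_pairing("GC")]:
            for i, j in pairs:
                assert j - i > 3


def _perfect_cluster(genome_seq, m_start, mature, count=100.0, strand="+"):
    member = ClusterMember(mature, m_start, m_start + len(mature), count)
    return ReadCluster("c", strand, m_start, m_start + len(mature), [member])


@pytest.fixture(scope="module")
def planted_locus():
    """A hand-planted hairpin inside a neutral window (rejection-sampled
    so the window folds into a valid candidate hairpin)."""
    from mirdeg.synthetic_data import (_build_hairpin, _random_seq,
                                       _validate_precursor)
    for seed in range(11, 60):
        rng = np.random.default_rng(seed)
        mature = "T" + "".join(rng.choice(list("ACGT"), 20))
        hairpin = _build_hairpin(rng, mature, "5p", 8, 2)
        flank_l, flank_r = _random_seq(rng, 150), _random_seq(rng, 150)
        block = flank_l + hairpin + flank_r
        if _validate_precursor(block, len(flank_l), 21, DiscoveryConfig()):
            return {"c": block}, len(flank_l), mature
    raise RuntimeError("no valid planted locus found")


class TestEvaluatePrecursor:
    def test_rejects_length_19(self, planted_locus):
        genome, m_start, mature = planted_locus
        cluster = _perfect_cluster(genome["c"], m_start, mature[:19])
        cand, reason = evaluate_precursor(cluster, genome)
        assert cand is None and "length" in reason

    def test_rejects_specificity_070(self, planted_locus):
        genome, m_start, mature = planted_locus
        cluster = _perfect_cluster(genome["c"], m_start, mature, 70.0)
        cluster.members.append(ClusterMember("G" * 21, m_start + 30,
                                             m_start + 51, 30.0))
        cand, reason = evaluate_precursor(cluster, genome)
        assert cand is None and "specificity" in reason

    def test_rejects_low_support(self, planted_locus):
        genome, m_start, mature = planted_locus
        cluster = _perfect_cluster(genome["c"], m_start, mature, 2.0)
        cand, reason = evaluate_precursor(cluster, genome)
        assert cand is None and "support" in reason

    def test_accepts_planted_hairpin(self, planted_locus):
        genome, m_start, mature = planted_locus
        cluster = _perfect_cluster(genome["c"], m_start, mature)
        cand, reason = evaluate_precursor(cluster, genome)
        assert reason is None
        assert cand.mature == to_rna(mature)
        assert cand.arm == "5p"

    def test_acceptance_monotone_in_specificity(self, planted_locus):
        """Raising the dominant read's weight never flips accept -> reject."""
        genome, m_start, mature = planted_locus
        base = _perfect_cluster(genome["c"], m_start, mature, 50.0)
        base.members.append(ClusterMember("G" * 21, m_start + 40,
                                          m_start + 61, 10.0))
        accepted_at = None
        for dom_weight in (50.0, 100.0, 400.0):
            cluster = ReadCluster("c", "+", base.start, base.end, [
                ClusterMember(mature, m_start, m_start + len(mature), dom_weight),
                ClusterMember("G" * 21, m_start + 40, m_start + 61, 10.0)])
            cand, _ = evaluate_precursor(cluster, genome)
            if accepted_at is not None:
                assert cand is not None  # once accepted, stays accepted
            if cand is not None and accepted_at is None:
                accepted_at = dom_weight
        assert accepted_at is not None


class TestFindStar:
    def _perfect_stem_structure(self):
        """A hand-built 21-bp stem (8-nt loop) with 2 nt of 3' tail.

        The partner map is the contract input of star finding, so the
        structure is constructed explicitly rather than folded.
        """
        from mirdeg.mirna_discovery import HairpinStructure, PAIR_WEIGHT
        mature = "TGACAGAAGAGAGTGAGCACA"  # 21 nt
        seq = to_rna(mature + "GTGTGTGT" + revcomp(mature) + "AA")  # n = 52
        pairs = frozenset((i, 49 - i) for i in range(21))
        weight = sum(PAIR_WEIGHT[(seq[i], seq[j])] for i, j in pairs)
        structure = HairpinStructure(
            sequence=seq, pairs=pairs, pairing_score=len(pairs),
            weighted_score=weight, five_prime_arm=(0, 21), loop=(21, 29),
            three_prime_arm=(29, 52))
        cand = MiRNACandidate(
            mature=to_rna(mature), star=None, precursor=seq,
            chrom="c", start=0, end=52, strand="+",
            mature_offset=0, arm="5p", specificity=1.0)
        return cand, structure

    def test_two_nt_overhang_geometry(self):
        cand, structure = self._perfect_stem_structure()
        star, span, reason = find_star(cand, structure)
        assert reason is None
        a, b = 0, 20
        partner = structure.partner
        # star = segment pairing the mature, shifted 2 nt toward 3'
        assert span == (partner[b - 2], partner[a] + 2 + 1)
        assert span == (31, 52)
        assert len(star) == 21
        assert star[:19] == to_rna(revcomp(cand.mature))[2:]

    def test_star_observed_flag(self):
        from mirdeg.io_core import to_dna
        from mirdeg.mirna_discovery import star_observed
        cand, structure = self._perfect_stem_structure()
        star, _, _ = find_star(cand, structure)
        lib = Library(records={to_dna(star): 4})
        assert star_observed(star, lib)
        assert not star_observed(star, Library())

    def test_mature_spanning_loop_gives_no_star(self):
        cand, structure = self._perfect_stem_structure()
        spanning = MiRNACandidate(
            mature="A" * 21, star=None, precursor=structure.sequence,
            chrom="c", start=0, end=52, strand="+",
            mature_offset=15, arm="5p", specificity=1.0)  # straddles the loop
        star, _, reason = find_star(spanning, structure)
        assert star is None and reason is not None
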