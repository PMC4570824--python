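"""t-plots, cleavage categories, duplex scoring (vs brute-force oracle)
and degradome-evidenced target calling."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from mirdeg.degradome import (TargetConfig, TPlot, classify_category,
                              find_targets, map_tags, pair_class, score_duplex,
                              ungapped_score)
from mirdeg.io_core import Library, revcomp, to_rna

MIRNA = "TGACAGAAGAGAGTGAGCACA"  # 21 nt


class TestMapTags:
    def test_tag_at_transcript_prefix_counts_position_one(self):
        transcripts = {"t1": "ACGGTTCACAGGTGTCCTTAAGCTGATCGA"}
        tags = Library(records={transcripts["t1"][:20]: 4})
        tplots, unmapped = map_tags(tags, transcripts)
        assert tplots["t1"].counts == {0: 4}
        assert unmapped == 0

    def test_unmapped_tag_tallied(self):
        tplots, unmapped = map_tags(Library(records={"A" * 20: 3}),
                                    {"t1": "C" * 60})
        assert unmapped == 3 and tplots["t1"].counts == {}

    def test_tags_truncated_to_20nt(self):
        transcripts = {"t1": "ACGTACGTACGTACGTACGTGGGGGG"}
        tag21 = transcripts["t1"][2:23]  # 21 nt, matches by its first 20
        tplots, _ = map_tags(Library(records={tag21: 2}), transcripts)
        assert tplots["t1"].counts == {2: 2}


class TestClassifyCategory:
    def test_single_dominant_position_is_category_0(self):
        tp = TPlot("t", 100, {10: 10})
        assert classify_category(tp, 10) == 0

    def test_all_singletons_are_category_4(self):
        tp = TPlot("t", 100, {5: 1, 20: 1, 40: 1})
        assert all(classify_category(tp, p) == 4 for p in (5, 20, 40))

    def test_shared_maximum_is_category_1(self):
        tp = TPlot("t", 100, {5: 8, 20: 8, 40: 2})
        assert classify_category(tp, 5) == 1

    def test_zero_count_position_errors(self):
        with pytest.raises(ValueError):
            classify_category(TPlot("t", 100, {5: 2}), 50)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.dictionaries(st.integers(0, 50), st.integers(1, 20),
                           min_size=1, max_size=12))
    def test_matches_independent_rule(self, counts):
        """Direct re-implementation of the rule, evaluated per position."""
        tp = TPlot("t", 60, {k: float(v) for k, v in counts.items()})
        positive = sorted(v for v in counts.values())
        mid = positive[len(positive) // 2] if len(positive) % 2 else \
            (positive[len(positive) // 2 - 1] + positive[len(positive) // 2]) / 2
        mx = max(positive)
        for pos, c in counts.items():
            if c == 1:
                expect = 4
            elif c == mx:
                expect = 0 if positive.count(mx) == 1 else 1
            elif c > mid:
                expect = 2
            else:
                expect = 3
            assert classify_category(tp, pos) == expect


class TestScoreDuplex:
    def test_perfect_reverse_complement_scores_zero(self):
        aln = score_duplex(MIRNA, revcomp(MIRNA))
        assert aln.score == 0.0
        assert all(s == "match" for s in aln.states)

    def test_mismatch_position_weighting(self):
        window = list(revcomp(MIRNA))
        # miRNA position 1 opposes the window's last base; U x C = mismatch
        w1 = window.copy()
        w1[-1] = "C"
        assert score_duplex(MIRNA, "".join(w1)).score == 1.0
        # position 11 lies in the doubled 2-13 window
        w11 = window.copy()
        w11[-11] = "C" if w11[-11] != "C" else "A"
        assert score_duplex(MIRNA, "".join(w11)).score == 2.0

    def test_gu_wobble_half_penalty(self):
        window = list(revcomp(MIRNA))
        # miRNA position 1 is U; target G opposite makes a U·G wobble
        window[-1] = "G"
        assert score_duplex(MIRNA, "".join(window)).score == 0.5

    def test_window_length_out_of_band_errors(self):
        with pytest.raises(ValueError):
            score_duplex(MIRNA, revcomp(MIRNA)[:18])

    def _oracle(self, m, w):
        """All alignments with <= 1 gap (none, one in miRNA, one in target)."""
        m, w = to_rna(m), to_rna(w)[::-1]
        pen = {"match": 0.0, "GU": 0.5, "mismatch": 1.0}

        def mult(i):
            return 2.0 if 2 <= i <= 13 else 1.0

        def ungapped(mm, ww, offset=0):
            return sum(pen[pair_class(a, b)] * mult(i + 1)
                       for i, (a, b) in enumerate(zip(mm, ww)))

        best = float("inf")
        if len(m) == len(w):
            best = ungapped(m, w)
        if len(w) == len(m) - 1:  # one gap in the target
            for g in range(len(m)):
                mm = m[:g] + m[g + 1:]
                cost = 2.0 * mult(g + 1) + sum(
                    pen[pair_class(a, b)] * mult(i + 1 if i < g else i + 2)
                    for i, (a, b) in enumerate(zip(mm, w)))
                best = min(best, cost)
        if len(w) == len(m) + 1:  # one gap in the miRNA
            for g in range(len(w)):
                ww = w[:g] + w[g + 1:]
                cost = 2.0 * mult(min(g + 1, len(m))) + ungapped(m, ww)
                best = min(best, cost)
        return best

    @settings(max_examples=120, derandomize=True, deadline=None)
    @given(st.data())
    def test_banded_dp_matches_one_gap_oracle(self, data):
        m = data.draw(st.text(alphabet="ACGU", min_size=6, max_size=12))
        delta = data.draw(st.sampled_from([-1, 0, 0, 1]))
        w = data.draw(st.text(alphabet="ACGU", min_size=len(m) + delta,
                              max_size=len(m) + delta))
        assert score_duplex(m, w).score == pytest.approx(self._oracle(m, w))

    def test_pair_classification_symmetric(self):
        for a, b in itertools.product("ACGU", repeat=2):
            assert pair_class(a, b) == pair_class(b, a)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.text(alphabet="ACGU", min_size=8, max_size=16),
           st.text(alphabet="ACGU", min_size=8, max_size=16))
    def test_uniform_weight_score_symmetric_under_strand_swap(self, a, b):
        n = min(len(a), len(b))
        a, b = a[:n], b[:n]
        s1 = ungapped_score(a, b, double_start=0, double_end=-1)
        s2 = ungapped_score(b, a, double_start=0, double_end=-1)
        assert s1 == pytest.approx(s2)


class TestFindTargets:
    def _setup(self, site_tags=8.0):
        mature = MIRNA
        site = revcomp(mature)
        transcript = "ACGTTCAG" * 5 + site + "TTGACCGA" * 5
        start = 40
        cleave0 = start + len(mature) - 10
        tplot = TPlot("t1", len(transcript), {cleave0: site_tags, 5: 1.0})
        return ({"mirX": mature}, {"t1": tplot}, {"t1": transcript}, cleave0)

    def test_planted_site_reported_category_0(self):
        mirnas, tplots, transcripts, cleave0 = self._setup()
        pairs = find_targets(mirnas, tplots, transcripts)
        assert len(pairs) == 1
        p = pairs[0]
        assert p.cleavage_pos == cleave0 + 1
        assert p.category == 0
        assert p.score == 0.0

    def test_high_score_site_not_reported(self):
        mirnas, tplots, transcripts, _ = self._setup()
        pairs = find_targets({"mirY": "TTTTTTTTTTTTTTTTTTTTT"},
                             tplots, transcripts)
        assert pairs == []

    def test_min_tags_threshold(self):
        mirnas, tplots, transcripts, _ = self._setup(site_tags=1.0)
        assert find_targets(mirnas, tplots, transcripts) == []

    def test_multiple_targets_per_mirna(self):
        mature = MIRNA
        site = revcomp(mature)
        t1 = "ACGTTCAG" * 5 + site + "TTGACCGA" * 5
        t2 = "GGATCCAT" * 5 + site + "CATGGATC" * 5
        cleave0 = 40 + len(mature) - 10
        tplots = {"t1": TPlot("t1", len(t1), {cleave0: 6.0}),
                  "t2": TPlot("t2", len(t2), {cleave0: 9.0})}
        pairs = find_targets({"mirX": mature}, tplots, {"t1": t1, "t2": t2})
        assert {p.transcript_id for p in pairs} == {"t1", "t2"}

    def test_every_reported_pair_has_min_tag_evidence(self):
        mirnas, tplots, transcripts, _ = self._setup()
        cfg = TargetConfig(min_tags=2.0)
        for p in find_targets(mirnas, tplots, transcripts, cfg):
            assert p.tag_count >= cfg.min_tags
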