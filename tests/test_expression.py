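"""RPM, fold change, exact count-difference test, calls, qPCR arithmetic."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import nbinom

from mirdeg.expression import (DEConfig, ac_test, bh_adjust,
                               build_expression_table, call_sets, ddct,
                               log2_fold_change, rpm_normalize)


class TestRpm:
    def test_basic_scaling(self):
        assert rpm_normalize(1, 10 ** 6) == 1.0
        assert rpm_normalize(5, 5) == 10 ** 6

    def test_linearity_over_library(self):
        counts = {"a": 10, "b": 30, "c": 60}
        total = 1000
        rpm_sum = sum(rpm_normalize(c, total) for c in counts.values())
        assert rpm_sum == pytest.approx(1e6 * sum(counts.values()) / total)

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            rpm_normalize(1, 0)


class TestFoldChange:
    def test_equal_is_zero(self):
        assert log2_fold_change(5.0, 5.0) == 0.0

    def test_twofold_is_one(self):
        assert log2_fold_change(10.0, 5.0) == 1.0

    def test_antisymmetry(self):
        for a, b in [(3.0, 7.0), (120.0, 11.0)]:
            assert log2_fold_change(a, b) == pytest.approx(-log2_fold_change(b, a))

    def test_both_zero_undefined(self):
        assert math.isnan(log2_fold_change(0.0, 0.0, pseudo_rpm=1.0))


def _ac_exact(x, y, Nx, Ny):
    """Exact-rational oracle for the two-sided count-difference test."""
    r = Fraction(Ny) / Fraction(Nx)
    def pmf(t):
        return r ** t * Fraction(math.comb(x + t, t)) / (1 + r) ** (x + t + 1)
    p_le = sum(pmf(t) for t in range(y + 1))
    p_ge = 1 - sum(pmf(t) for t in range(y))
    return min(Fraction(1), 2 * min(p_le, p_ge))


class TestAcTest:
    def test_matches_exact_oracle_all_pairs_to_50(self):
        for s in range(0, 51):
            for x in range(0, s + 1):
                y = s - x
                got = ac_test(x, y, 10 ** 6, 10 ** 6)
                want = float(_ac_exact(x, y, 10 ** 6, 10 ** 6))
                assert got == pytest.approx(want, rel=1e-9), (x, y)

    def test_unequal_totals_match_oracle(self):
        for x, y in [(0, 5), (3, 9), (12, 4), (20, 20)]:
            got = ac_test(x, y, 10 ** 6, 3 * 10 ** 6)
            want = float(_ac_exact(x, y, 10 ** 6, 3 * 10 ** 6))
            assert got == pytest.approx(want, rel=1e-9)

    def test_x5_y0_equal_totals(self):
        # exact value 2 * (1/2)^6 = 0.03125
        assert ac_test(5, 0, 10 ** 6, 10 ** 6) == pytest.approx(0.03125, rel=1e-10)

    def test_symmetric_center_not_significant(self):
        for x in (1, 5, 17, 60):
            assert ac_test(x, x, 10 ** 6, 10 ** 6) >= 0.5

    def test_monotone_in_count_difference(self):
        base = [ac_test(50, y, 10 ** 6, 10 ** 6) for y in range(51, 120)]
        assert all(a >= b - 1e-12 for a, b in zip(base, base[1:]))

    def test_agrees_with_negative_binomial_form(self):
        """Independent cross-check: p(y|x) is NB(x+1, Nx/(Nx+Ny))."""
        x, Nx, Ny = 7, 10 ** 6, 2 * 10 ** 6
        dist = nbinom(x + 1, Nx / (Nx + Ny))
        for y in (0, 3, 14, 30):
            want = min(1.0, 2 * min(dist.cdf(y), dist.sf(y - 1)))
            assert ac_test(x, y, Nx, Ny) == pytest.approx(want, rel=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ac_test(1, 1, 0, 10)
        with pytest.raises(ValueError):
            ac_test(-1, 1, 10, 10)

    def test_null_calibration(self):
        """Under equal Poisson rates across 1,000 tags, ~5% reach p < 0.05."""
        rng = np.random.default_rng(42)
        xs = rng.poisson(100, 1000)
        ys = rng.poisson(100, 1000)
        ps = np.array([ac_test(int(a), int(b), 10 ** 6, 10 ** 6)
                       for a, b in zip(xs, ys)])
        frac = float((ps < 0.05).mean())
        assert 0.03 <= frac <= 0.07


class TestCalls:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["mirna_id", "count_wild", "count_mutant",
                                           "rpm_wild", "rpm_mutant", "log2_fc",
                                           "p_value"])

    def test_specific_mutant(self):
        out = build_expression_table({"m": 0}, {"m": 50}, 10 ** 5, 10 ** 5)
        assert out.iloc[0]["call"] == "specific_mutant"

    def test_below_fc_threshold_unchanged(self):
        df = self._table([("m", 100, 55, 1000.0, 536.0, 0.9, 1e-8)])
        assert call_sets(df).iloc[0]["call"] == "unchanged"

    def test_direction_follows_wild_over_mutant_sign(self):
        df = self._table([("up", 10, 400, 100.0, 4000.0, -2.0, 1e-6),
                          ("down", 400, 10, 4000.0, 100.0, 2.0, 1e-6)])
        out = call_sets(df)
        assert list(out["call"]) == ["up_in_mutant", "down_in_mutant"]

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 500), st.integers(0, 500)),
                    min_size=1, max_size=30))
    def test_five_calls_partition_all_records(self, counts):
        cw = {f"m{i}": a for i, (a, _) in enumerate(counts)}
        cm = {f"m{i}": b for i, (_, b) in enumerate(counts)}
        out = build_expression_table(cw, cm, 10 ** 5, 10 ** 5)
        assert len(out) == len(counts)
        assert out["call"].isin(["specific_wild", "specific_mutant",
                                 "up_in_mutant", "down_in_mutant",
                                 "unchanged"]).all()

    def test_direction_accuracy_on_planted_fold_changes(self, default_run):
        """Planted 4x up/down miRNAs are called in the right direction."""
        truth = default_run.truth
        table = default_run.expression.set_index("mirna_id")
        correct = total = 0
        for mid, e in truth.expression.items():
            if e["call"] not in ("up_in_mutant", "down_in_mutant"):
                continue
            if min(e["mean_wild"], e["mean_mutant"]) < 100:
                continue
            row = None
            if mid in table.index:
                row = table.loc[mid]
            else:  # novel miRNAs appear under their candidate id
                mature = truth.mature_of(mid)
                for cand in default_run.candidates:
                    if cand.mature_dna == mature:
                        row = table.loc[cand.counts["id"]]
                        break
            if row is None:
                continue
            total += 1
            correct += (row["call"] == e["call"])
        assert total >= 5
        assert correct / total >= 0.95


class TestBhAdjust:
    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        p = np.array([0.001, 0.01, 0.02, 0.5, 0.04, 0.9])
        want = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(bh_adjust(p), want)


class TestDdct:
    def test_all_equal_is_one(self):
        assert ddct(20, 20, 20, 20) == 1.0

    def test_one_cycle_doubling(self):
        assert ddct(19, 20, 20, 20) == 2.0

    def test_reciprocity(self):
        a, b, c, d = 18.2, 21.4, 19.9, 22.0
        assert ddct(a, b, c, d) * ddct(c, d, a, b) == pytest.approx(1.0)
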