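import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from venomics import venom_compare as vc


# --- independent oracles -----------------------------------------------------

def wilcoxon_oracle(x, y, alternative="two-sided"):
    """Brute-force enumeration of all 2^n sign assignments."""
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    total = ranks.sum()
    mu = total / 2.0
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        if alternative == "greater":
            hit = w >= w_obs - 1e-9
        elif alternative == "less":
            hit = w <= w_obs + 1e-9
        else:
            hit = abs(w - mu) >= abs(w_obs - mu) - 1e-9
        count += hit
    return count / 2.0**n


def fisher_oracle(a, b, c, d):
    """Exact-rational enumeration of all tables with the observed margins."""
    n = a + b + c + d
    row1, col1 = a + b, a + c

    def pmf(k):
        return Fraction(
            math.comb(col1, k) * math.comb(n - col1, row1 - k), math.comb(n, row1)
        )

    k_min = max(0, row1 + col1 - n)
    k_max = min(row1, col1)
    observed = pmf(a)
    return float(sum(pmf(k) for k in range(k_min, k_max + 1) if pmf(k) <= observed))


def _rows(entries):
    """entries: (qseqid, sseqid, evalue, bitscore)"""
    return pd.DataFrame(
        [
            {
                "qseqid": q, "sseqid": s, "pident": 50.0, "length": 100,
                "mismatch": 50, "gapopen": 0, "qstart": 1, "qend": 100,
                "sstart": 1, "send": 100, "evalue": e, "bitscore": b,
            }
            for q, s, e, b in entries
        ],
        columns=vc.OUTFMT6_COLUMNS,
    )


class TestBestHits:
    def test_minimum_evalue_kept(self):
        hits = vc.best_hits(_rows([("q", "s1", 1e-10, 80), ("q", "s2", 1e-3, 90)]))
        assert hits["q"][2] == "s1"

    def test_evalue_tie_broken_by_bitscore(self):
        hits = vc.best_hits(_rows([("q", "s1", 1e-8, 60), ("q", "s2", 1e-8, 80)]))
        assert hits["q"] == (1e-8, 80.0, "s2")

    def test_full_tie_broken_lexicographically(self):
        hits = vc.best_hits(_rows([("q", "sB", 1e-8, 80), ("q", "sA", 1e-8, 80)]))
        assert hits["q"][2] == "sA"

    def test_query_without_rows_absent(self):
        assert "other" not in vc.best_hits(_rows([("q", "s", 1e-8, 80)]))


class TestHomologyCall:
    def test_inclusive_boundary(self):
        assert vc.homology_call(1e-5, 50.0)

    def test_evalue_fails(self):
        assert not vc.homology_call(1e-4, 200.0)

    def test_bitscore_fails(self):
        assert not vc.homology_call(1e-20, 49.0)


class TestVennPartition:
    def _paired(self, spec_list):
        paired = []
        for i, (nv_pass, oep_pass) in enumerate(spec_list):
            ps = vc.PairedScore(f"p{i}")
            if nv_pass is not None:
                ps.ev_nv = 1e-10 if nv_pass else 1e-2
                ps.bs_nv = 100.0 if nv_pass else 30.0
            if oep_pass is not None:
                ps.ev_oep = 1e-10 if oep_pass else 1e-2
                ps.bs_oep = 100.0 if oep_pass else 30.0
            paired.append(ps)
        return paired

    def test_four_way_partition(self):
        paired = self._paired(
            [(True, True), (True, False), (False, True), (False, False), (None, None)]
        )
        assignments, counts = vc.venn_partition(paired)
        assert counts == (2, 1, 1, 1)
        assert assignments[0].label == "both"
        assert assignments[4].label == "unique"

    def test_all_absent_all_unique(self):
        paired = self._paired([(None, None)] * 5)
        _, counts = vc.venn_partition(paired)
        assert counts == (5, 0, 0, 0)

    def test_counts_sum_to_query_size(self):
        rng = np.random.default_rng(3)
        choices = [True, False, None]
        paired = self._paired(
            [(rng.choice(choices), rng.choice(choices)) for _ in range(50)]
        )
        for bs in (0.0, 30.0, 50.0, 90.0, 1e9):
            _, counts = vc.venn_partition(paired, bs_min=bs)
            assert sum(counts) == 50

    def test_planted_design_recovered(self, simulated):
        from venomics.synthetic_data import generate_homology_tables

        indir, truth, config = simulated
        nv, oep, _ = generate_homology_tables(config, truth)
        paired = vc.build_paired_scores(sorted(truth.venom_ids), nv, oep)
        assignments, counts = vc.venn_partition(paired)
        assert counts == config.venn_design
        labels = {a.protein_id: a.label for a in assignments}
        assert labels == truth.venn_labels


class TestPairedBetterFraction:
    def test_printed_fraction_arithmetic(self):
        paired = []
        for i in range(70):
            ps = vc.PairedScore(f"p{i}")
            better = i < 48
            ps.ev_nv, ps.bs_nv = (1e-20, 100.0) if better else (1e-6, 55.0)
            ps.ev_oep, ps.bs_oep = 1e-10, 70.0
            paired.append(ps)
        n_ev, _, fractions = vc.paired_better_fraction(paired)
        assert n_ev == 48
        assert round(100 * fractions[0], 1) == 68.6

    def test_all_equal_pairs(self):
        paired = []
        for i in range(5):
            ps = vc.PairedScore(f"p{i}")
            ps.ev_nv = ps.ev_oep = 1e-10
            ps.bs_nv = ps.bs_oep = 80.0
            paired.append(ps)
        n_ev, n_bs, _ = vc.paired_better_fraction(paired)
        assert (n_ev, n_bs) == (0, 0)

    def test_absent_oep_counts_for_nv(self):
        ps = vc.PairedScore("p", ev_nv=1e-10, bs_nv=80.0)
        n_ev, n_bs, _ = vc.paired_better_fraction([ps])
        assert (n_ev, n_bs) == (1, 1)

    def test_counts_partition_n(self):
        rng = np.random.default_rng(5)
        paired = []
        for i in range(60):
            ps = vc.PairedScore(f"p{i}")
            if rng.random() < 0.8:
                ps.ev_nv = float(10.0 ** -rng.integers(3, 40))
                ps.bs_nv = float(rng.integers(20, 300))
            if rng.random() < 0.8:
                ps.ev_oep = float(10.0 ** -rng.integers(3, 40))
                ps.bs_oep = float(rng.integers(20, 300))
            paired.append(ps)
        n_ev, _, _ = vc.paired_better_fraction(paired)
        worse_or_tie = 0
        for ps in paired:
            if ps.ev_nv is None:
                worse_or_tie += 1  # nv absent: never better
            elif ps.ev_oep is not None and not (ps.ev_nv < ps.ev_oep):
                worse_or_tie += 1
        assert n_ev + worse_or_tie == 60


class TestWilcoxonSignedRank:
    def test_all_positive_one_sided(self):
        r = vc.wilcoxon_signed_rank([5, 6, 7, 8, 9], [1, 2, 3, 4, 4.5], "greater")
        assert r.p_value == pytest.approx(1 / 32)

    def test_all_positive_two_sided(self):
        r = vc.wilcoxon_signed_rank([5, 6, 7, 8, 9], [1, 2, 3, 4, 4.5])
        assert r.p_value == pytest.approx(0.0625)

    def test_all_zero_differences(self):
        r = vc.wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])
        assert r.p_value == 1.0 and r.n_used == 0

    def test_matches_enumeration_oracle_random(self):
        rng = np.random.default_rng(17)
        for trial in range(100):
            n = int(rng.integers(1, 13))
            x = rng.integers(0, 6, size=n).astype(float)  # integer data forces ties
            y = rng.integers(0, 6, size=n).astype(float)
            for alt in ("two-sided", "greater", "less"):
                got = vc.wilcoxon_signed_rank(x, y, alt)
                want = wilcoxon_oracle(x, y, alt)
                assert got.p_value == pytest.approx(want, abs=1e-12), (trial, alt)

    def test_normal_approximation_near_exact(self):
        rng = np.random.default_rng(23)
        x = rng.normal(0.5, 1, size=30)
        y = rng.normal(0.0, 1, size=30)
        exact = vc.wilcoxon_signed_rank(x, y, exact_n_max=40)
        approx = vc.wilcoxon_signed_rank(x, y, exact_n_max=25)
        assert approx.method == "wilcoxon-signed-rank-normal"
        assert approx.p_value == pytest.approx(exact.p_value, rel=0.15)

    def test_scipy_agreement_no_ties(self):
        rng = np.random.default_rng(29)
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        ours = vc.wilcoxon_signed_rank(x, y)
        ref = stats.wilcoxon(x, y, alternative="two-sided", method="exact")
        assert ours.p_value == pytest.approx(ref.pvalue)


class TestFisherExact:
    def test_paper_style_table(self):
        r = vc.fisher_exact_2x2(13, 57, 3, 76)
        assert round(r.p_value, 3) == 0.006

    def test_identical_proportions(self):
        assert vc.fisher_exact_2x2(5, 5, 5, 5).p_value == pytest.approx(1.0)

    def test_odds_ratio(self):
        r = vc.fisher_exact_2x2(13, 57, 3, 76)
        assert r.statistic == pytest.approx((13 * 76) / (57 * 3))

    def test_empty_table_errors(self):
        with pytest.raises(ValueError):
            vc.fisher_exact_2x2(0, 0, 0, 0)

    def test_negative_errors(self):
        with pytest.raises(ValueError):
            vc.fisher_exact_2x2(-1, 2, 3, 4)

    def test_matches_enumeration_oracle_exhaustive(self):
        for n in range(1, 13):
            for a in range(n + 1):
                for b in range(n + 1 - a):
                    for c in range(n + 1 - a - b):
                        d = n - a - b - c
                        got = vc.fisher_exact_2x2(a, b, c, d).p_value
                        want = fisher_oracle(a, b, c, d)
                        assert got == pytest.approx(want, rel=1e-7), (a, b, c, d)

    def test_matches_oracle_random_larger_margins(self):
        rng = np.random.default_rng(31)
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 16, size=4))
            if a + b + c + d == 0:
                continue
            got = vc.fisher_exact_2x2(a, b, c, d).p_value
            assert got == pytest.approx(fisher_oracle(a, b, c, d), rel=1e-7)

    def test_transposition_invariance(self):
        rng = np.random.default_rng(37)
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(0, 20, size=4))
            if a + b + c + d == 0:
                continue
            p1 = vc.fisher_exact_2x2(a, b, c, d).p_value
            p2 = vc.fisher_exact_2x2(a, c, b, d).p_value
            assert p1 == pytest.approx(p2, rel=1e-9)

    def test_one_sided_tails(self):
        greater = vc.fisher_exact_2x2(13, 57, 3, 76, "greater").p_value
        less = vc.fisher_exact_2x2(13, 57, 3, 76, "less").p_value
        ref_g = stats.fisher_exact([[13, 57], [3, 76]], alternative="greater")[1]
        ref_l = stats.fisher_exact([[13, 57], [3, 76]], alternative="less")[1]
        assert greater == pytest.approx(ref_g)
        assert less == pytest.approx(ref_l)


class TestCutoffSensitivity:
    def _paired(self):
        paired = []
        for i, bs in enumerate([30.0, 45.0, 55.0, 80.0, 120.0]):
            ps = vc.PairedScore(f"p{i}", ev_nv=1e-10, bs_nv=bs, ev_oep=1e-10, bs_oep=200.0 - bs)
            paired.append(ps)
        paired.append(vc.PairedScore("p_none"))
        return paired

    def test_default_cutoff_row_matches_partition(self):
        paired = self._paired()
        table = vc.cutoff_sensitivity(paired, [50.0])
        _, counts = vc.venn_partition(paired)
        assert tuple(table.iloc[0][list(vc.VENN_LABELS)]) == counts

    def test_unique_monotone_in_cutoff(self):
        paired = self._paired()
        table = vc.cutoff_sensitivity(paired, [0.0, 40.0, 50.0, 100.0, 250.0])
        assert table["unique"].is_monotonic_increasing

    def test_zero_cutoff_unique_equals_no_hit_queries(self):
        paired = self._paired()
        table = vc.cutoff_sensitivity(paired, [0.0])
        assert table.iloc[0]["unique"] == 1  # only p_none has no rows

    def test_empty_grid_errors(self):
        with pytest.raises(ValueError):
            vc.cutoff_sensitivity(self._paired(), [])
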