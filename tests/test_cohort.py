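"""Rank statistics, content comparisons, and stratifications."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from disprof.cohort import (
    compare_content,
    correlate_zprofiles,
    filter_splice_free,
    genic_gc,
    group_by_go,
    mann_whitney_u,
    significance_stars,
    spearman_rho,
    stratify_by_expression,
    stratify_by_gc,
)
from disprof.profiles import ZProfile
from disprof.proteomes import Proteome, ProteinRecord

from conftest import make_random_proteome


class TestMannWhitney:
    def test_fully_separated_small_sample(self):
        u, p = mann_whitney_u([1, 2], [3, 4], method="exact")
        assert u == 0.0
        assert p == pytest.approx(2 / 6)

    def test_identical_samples(self):
        u, p = mann_whitney_u([3.0, 3.0, 3.0], [3.0, 3.0, 3.0])
        assert p >= 0.99

    @given(
        x=st.lists(st.integers(0, 20), min_size=1, max_size=8),
        y=st.lists(st.integers(0, 20), min_size=1, max_size=8),
    )
    def test_u_symmetry(self, x, y):
        ux, _ = mann_whitney_u(x, y, method="asymptotic")
        uy, _ = mann_whitney_u(y, x, method="asymptotic")
        assert ux + uy == pytest.approx(len(x) * len(y))

    def test_exact_matches_scipy_without_ties(self, rng):
        for _ in range(25):
            x = rng.normal(size=rng.integers(2, 6))
            y = rng.normal(size=rng.integers(2, 6))
            u, p = mann_whitney_u(x, y, method="exact")
            ref = sps.mannwhitneyu(x, y, method="exact", alternative="two-sided")
            assert u == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)

    def test_approximation_close_to_exact_at_n8(self, rng):
        for _ in range(20):
            x = rng.normal(size=8)
            y = rng.normal(loc=rng.normal(), size=8)
            _, p_exact = mann_whitney_u(x, y, method="exact")
            _, p_approx = mann_whitney_u(x, y, method="asymptotic")
            assert abs(p_exact - p_approx) < 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            mann_whitney_u([], [1.0])


class TestSpearman:
    def test_monotone_limits(self):
        x = [1, 2, 3, 4, 5]
        assert spearman_rho(x, [2, 4, 9, 16, 30])[0] == pytest.approx(1.0)
        assert spearman_rho(x, [5, 4, 3, 1, 0])[0] == pytest.approx(-1.0)

    def test_matches_scipy_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 30))
            x = rng.normal(size=n)
            y = rng.normal(size=n) + 0.5 * x
            rho, p = spearman_rho(x, y)
            ref = sps.spearmanr(x, y)
            assert rho == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_rho([1, 1, 1], [1, 2, 3])

    def test_short_input_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            spearman_rho([1, 2], [3, 4])


class TestCompareContent:
    def test_identical_constants(self):
        cmp = compare_content([5.0] * 10, [[5.0] * 10, [5.0] * 10], "pct_dis_all")
        assert cmp.p_value >= 0.99
        assert cmp.real_mean == cmp.random_mean
        assert cmp.n_random == 20

    def test_shifted_real_detected(self, rng):
        real = rng.normal(30, 5, size=200)
        reps = [rng.normal(20, 5, size=200) for _ in range(3)]
        cmp = compare_content(real, reps, "pct_dis30")
        assert cmp.p_value < 0.05
        assert cmp.real_mean > cmp.random_mean
        assert cmp.stars in ("*", "**", "***")

    @pytest.mark.parametrize(
        "p,stars",
        [
            (0.5, "ns"), (0.04, "*"), (3e-5, "**"), (5e-7, "***"),
            (0.05, "ns"), (1e-4, "*"), (1e-6, "**"),  # thresholds are strict
        ],
    )
    def test_star_thresholds(self, p, stars):
        assert significance_stars(p) == stars

    def test_metric_checked(self):
        with pytest.raises(ValueError, match="metric"):
            compare_content([1.0], [[1.0]], "pct_bogus")


class TestStratifications:
    def _with_cds(self, gc_values):
        recs = []
        for i, gc in enumerate(gc_values):
            # build a CDS of 30 nt with the requested GC fraction
            n_gc = int(round(gc * 30))
            cds = "G" * n_gc + "A" * (30 - n_gc)
            recs.append(ProteinRecord(f"p{i}", "M" * 10, cds=cds))
        return Proteome(recs)

    def test_gc_bins_by_edges(self):
        p = self._with_cds([0.30, 0.50, 0.70])
        bins = stratify_by_gc(p, bins=[0.4, 0.6])
        assert [len(sub) for _, sub in bins] == [1, 1, 1]

    def test_gc_all_in_one_bin(self):
        p = self._with_cds([0.50, 0.50, 0.50])
        bins = stratify_by_gc(p, bins=[0.1, 0.9])
        assert [len(sub) for _, sub in bins] == [0, 3, 0]

    def test_gc_assignment_matches_bruteforce(self, rng):
        gcs = rng.uniform(0.2, 0.8, size=40).round(2)
        p = self._with_cds(gcs)
        edges = [0.35, 0.5, 0.65]
        bins = stratify_by_gc(p, bins=edges)
        full = [-np.inf, *edges, np.inf]
        for b, (_, sub) in enumerate(bins):
            for rec in sub:
                g = genic_gc(rec)
                assert full[b] <= g < full[b + 1]
        assert sum(len(sub) for _, sub in bins) == len(p)

    def test_gc_requires_cds(self):
        p = Proteome([ProteinRecord("a", "M")])
        with pytest.raises(ValueError, match="without CDS"):
            stratify_by_gc(p)

    @pytest.mark.parametrize(
        "first,last,single,kept",
        [
            (350, 400, False, True),
            (300, 400, False, False),  # boundary: 300 is not > 300
            (400, 300, False, False),
            (None, None, True, True),  # single-exon flag wins
        ],
    )
    def test_splice_filter_boundaries(self, first, last, single, kept):
        rec = ProteinRecord("a", "M" * 10, first_exon_len=first,
                            last_exon_len=last, single_exon=single)
        out, unannotated = filter_splice_free(Proteome([rec]))
        assert (len(out) == 1) is kept

    def test_splice_filter_logs_unannotated(self):
        p = Proteome([ProteinRecord("a", "M"), ProteinRecord("b", "M",
                                                             single_exon=True)])
        out, unannotated = filter_splice_free(p)
        assert out.ids == ["b"] and unannotated == ["a"]

    def test_expression_quartiles_match_sort_oracle(self):
        recs = [ProteinRecord(f"p{i}", "M", expression=float(i)) for i in
                range(1, 101)]
        high, low = stratify_by_expression(Proteome(recs), q=0.25)
        assert sorted(r.expression for r in low) == list(map(float, range(1, 26)))
        assert sorted(r.expression for r in high) == list(map(float, range(76, 101)))

    def test_expression_half_split_is_bipartition(self):
        recs = [ProteinRecord(f"p{i}", "M", expression=float(i)) for i in range(10)]
        high, low = stratify_by_expression(Proteome(recs), q=0.5)
        assert len(high) == 5 and len(low) == 5
        assert set(high.ids) | set(low.ids) == {f"p{i}" for i in range(10)}

    def test_expression_all_equal_warns(self):
        recs = [ProteinRecord(f"p{i}", "M", expression=1.0) for i in range(8)]
        with pytest.warns(UserWarning, match="equal"):
            high, low = stratify_by_expression(Proteome(recs), q=0.25)
        assert len(high) == len(low) == 2

    def test_expression_needs_annotations(self):
        p = Proteome([ProteinRecord("a", "M"), ProteinRecord("b", "M")])
        with pytest.raises(ValueError, match="annotated"):
            stratify_by_expression(p)

    def test_go_grouping_boundaries(self):
        recs = []
        for i in range(120):
            recs.append(ProteinRecord(f"a{i}", "M" * 201,
                                      go_terms=frozenset({"GO:big"})))
        for i in range(99):
            recs.append(ProteinRecord(f"b{i}", "M" * 201,
                                      go_terms=frozenset({"GO:small"})))
        recs.append(ProteinRecord("short", "M" * 200,
                                  go_terms=frozenset({"GO:big"})))
        groups = group_by_go(Proteome(recs), min_proteins=100, min_length=200)
        assert set(groups) == {"GO:big"}
        assert "short" not in groups["GO:big"].ids  # 200 is not > 200

    def test_go_exact_threshold_dropped(self):
        recs = [ProteinRecord(f"a{i}", "M" * 250, go_terms=frozenset({"GO:x"}))
                for i in range(100)]
        assert group_by_go(Proteome(recs), min_proteins=100) == {}

    def test_go_multi_membership(self):
        rec = ProteinRecord("a", "M" * 250,
                            go_terms=frozenset({"GO:1", "GO:2", "GO:3"}))
        groups = group_by_go(Proteome([rec]), min_proteins=0, min_length=200)
        assert set(groups) == {"GO:1", "GO:2", "GO:3"}
        assert all("a" in g.ids for g in groups.values())


def make_zprofile(z):
    z = np.asarray(z, float)
    n = z.size
    return ZProfile(anchor="N", n_positions=n, z=z, z_ratio=z,
                    p_value=np.full(n, 0.5), real_mean=z, null_mean=np.zeros(n),
                    null_sd=np.ones(n), n_replicates=10)


class TestCorrelateZProfiles:
    def test_self_and_negated(self, rng):
        a = make_zprofile(rng.normal(size=50))
        rho, _ = correlate_zprofiles(a, a)
        assert rho == pytest.approx(1.0)
        rho_neg, _ = correlate_zprofiles(a, make_zprofile(-a.z))
        assert rho_neg == pytest.approx(-1.0)

    def test_nonfinite_positions_excluded(self, rng):
        z = rng.normal(size=20)
        z2 = z.copy()
        z[0] = np.inf
        rho, _ = correlate_zprofiles(make_zprofile(z), make_zprofile(z2))
        assert rho == pytest.approx(1.0)

    def test_too_few_finite_positions(self):
        a = make_zprofile([np.inf, np.inf, 1.0, 2.0])
        with pytest.raises(ValueError, match="finite"):
            correlate_zprofiles(a, a)

    def test_independent_profiles_rarely_significant(self):
        hits = 0
        for s in range(100):
            rng = np.random.default_rng(1000 + s)
            a = make_zprofile(rng.normal(size=150))
            b = make_zprofile(rng.normal(size=150))
            _, p = correlate_zprofiles(a, b)
            if p > 0.05:
                hits += 1
        assert hits >= 90
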