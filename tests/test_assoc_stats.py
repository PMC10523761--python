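import numpy as np
import pytest
from scipy import stats as sps

from modulimpact.assoc_stats import (
    chi2_independence,
    compare_selected_vs_rest,
    disease_fraction,
    multiset_expected,
    multiset_intersection_distribution,
    multiset_intersection_p,
    rip_prevalence,
    wilcoxon_rank_sum,
)
from modulimpact.module_library import FunctionalModule, ModuleLibrary

from oracles import (
    chi2_textbook,
    multiset_mean_enum,
    multiset_tail_enum,
    wilcoxon_exact_enum,
)


def mod(tid, nodes):
    return FunctionalModule(tid, tid, frozenset(nodes), (frozenset(nodes),))


class TestDiseaseFraction:
    def test_fractions(self):
        m = mod("M", [f"G{i}" for i in range(10)])
        disease = {"G0": True, "G1": True}
        assert disease_fraction(m, disease) == pytest.approx(20.0)
        assert disease_fraction(m, {}) == 0.0
        assert disease_fraction(m, {f"G{i}": True for i in range(10)}) == 100.0


class TestWilcoxon:
    def test_derived_exact_value(self):
        res = wilcoxon_rank_sum([3, 4], [1, 2])
        assert res.method == "exact"
        assert res.p == pytest.approx(1 / 3, rel=1e-9)

    def test_identical_samples(self):
        assert wilcoxon_rank_sum([5, 5, 5], [5, 5, 5]).p == pytest.approx(1.0)
        res = wilcoxon_rank_sum([10, 20, 30], [10, 20, 30], alternative="greater")
        assert res.p >= 0.5

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    def test_exact_matches_enumeration(self):
        """All tie-free instances up to pooled size 8, random values."""
        rng = np.random.default_rng(23)
        for nx_ in range(1, 5):
            for ny in range(1, 5):
                for _ in range(3):
                    pooled = rng.permutation(20)[: nx_ + ny].astype(float)
                    x, y = list(pooled[:nx_]), list(pooled[nx_:])
                    for alt in ("two-sided", "greater", "less"):
                        got = wilcoxon_rank_sum(x, y, alternative=alt)
                        assert got.method == "exact"
                        assert got.p == pytest.approx(
                            wilcoxon_exact_enum(x, y, alt), rel=1e-9
                        ), (x, y, alt)

    def test_large_samples_use_corrected_normal(self):
        rng = np.random.default_rng(5)
        x = list(rng.normal(1.0, 1.0, size=30))
        y = list(rng.normal(0.0, 1.0, size=25))
        res = wilcoxon_rank_sum(x, y, alternative="greater")
        assert res.method == "asymptotic"
        assert res.p < 0.05


class TestChi2:
    def test_perfect_independence(self):
        res = chi2_independence([[10, 10], [10, 10]])
        assert res.chi2 == 0.0
        assert res.p == pytest.approx(1.0)

    def test_derived_values(self):
        assert chi2_independence([[10, 0], [0, 10]], yates=True).chi2 == pytest.approx(16.2)
        assert chi2_independence([[10, 0], [0, 10]], yates=False).chi2 == pytest.approx(20.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi2_independence([[0, 0], [5, 5]])

    def test_uncorrected_matches_textbook_formula(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            t = rng.integers(1, 50, size=(2, 2)).tolist()
            got = chi2_independence(t, yates=False)
            assert got.chi2 == pytest.approx(chi2_textbook(t), rel=1e-12)

    def test_agrees_with_reference_implementation(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            t = rng.integers(1, 40, size=(2, 2))
            for yates in (True, False):
                ref_chi2, ref_p, _, _ = sps.chi2_contingency(t, correction=yates)
                got = chi2_independence(t.tolist(), yates=yates)
                assert got.chi2 == pytest.approx(ref_chi2, rel=1e-10)
                assert got.p == pytest.approx(ref_p, rel=1e-10)


class TestMultisetIntersection:
    def test_expected_closed_form(self):
        assert multiset_expected(100, [50, 50, 50]) == pytest.approx(12.5)
        assert multiset_expected(100, [0, 50]) == 0.0
        assert multiset_expected(100, [37]) == pytest.approx(37.0)

    def test_derived_micro_values(self):
        assert multiset_intersection_p(4, [2, 2], 2).p_upper == pytest.approx(1 / 6, rel=1e-9)
        assert multiset_intersection_p(3, [2, 2, 2], 1).p_upper == pytest.approx(7 / 9, rel=1e-9)
        assert multiset_intersection_p(50, [10, 20], 0).p_upper == 1.0

    def test_distribution_normalizes(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            N = int(rng.integers(20, 200))
            k = int(rng.integers(2, 5))
            sizes = rng.integers(1, N + 1, size=k).tolist()
            dist = multiset_intersection_distribution(N, sizes)
            assert dist.sum() == pytest.approx(1.0, abs=1e-12)

    def test_matches_enumeration_small(self):
        """Exact agreement with full enumeration for N <= 6, k <= 3."""
        cases = [
            (4, [2, 2]), (5, [2, 3]), (5, [3, 3]), (6, [2, 4]),
            (4, [2, 2, 2]), (5, [2, 2, 3]), (5, [3, 3, 2]), (6, [3, 2, 2]),
        ]
        for N, sizes in cases:
            for m in range(0, min(sizes) + 1):
                got = multiset_intersection_p(N, sizes, m).p_upper
                want = multiset_tail_enum(N, sizes, m)
                assert got == pytest.approx(want, abs=1e-12), (N, sizes, m)

    def test_mean_matches_closed_form_and_enumeration(self):
        for N, sizes in [(5, [2, 3]), (5, [2, 2, 3]), (6, [3, 3])]:
            dist = multiset_intersection_distribution(N, sizes)
            mean = float(np.arange(len(dist)) @ dist)
            assert mean == pytest.approx(multiset_expected(N, sizes), rel=1e-9)
            assert mean == pytest.approx(multiset_mean_enum(N, sizes), rel=1e-9)

    def test_monte_carlo_agreement(self):
        """Chained-hypergeometric tail agrees with simulation at N=100."""
        N, sizes, m = 100, [30, 40, 50], 8
        p = multiset_intersection_p(N, sizes, m).p_upper
        rng = np.random.default_rng(77)
        draws = 100_000
        hits = 0
        chunk = 10_000
        for start in range(0, draws, chunk):
            r = min(chunk, draws - start)
            common = np.ones((r, N), dtype=bool)
            for s in sizes:
                u = rng.random((r, N))
                kth = np.partition(u, s - 1, axis=1)[:, s - 1 : s]
                common &= u <= kth
            hits += int((common.sum(axis=1) >= m).sum())
        mc = hits / draws
        se = np.sqrt(p * (1 - p) / draws)
        assert abs(mc - p) <= 3 * se + 1e-12

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            multiset_intersection_p(10, [5, 5], 6)
        with pytest.raises(ValueError):
            multiset_intersection_distribution(10, [5])


class TestSelectedVsRest:
    def test_identical_fractions_give_p_one(self):
        lib = ModuleLibrary(tuple(
            mod(f"M{i}", [f"G{i}_{j}" for j in range(10)]) for i in range(6)
        ))
        disease = {f"G{i}_0": True for i in range(6)}  # 10% everywhere
        res, x, y = compare_selected_vs_rest(lib, {"M0", "M1", "M2"}, disease)
        assert res.p == pytest.approx(1.0)

    def test_all_selected_is_an_error(self):
        lib = ModuleLibrary((mod("M0", ["A"]), mod("M1", ["B"])))
        with pytest.raises(ValueError):
            compare_selected_vs_rest(lib, {"M0", "M1"}, {})


class TestRipPrevalence:
    def test_fraction_arithmetic(self):
        groups = {"a": {"G1", "G2", "G3", "G4"}, "b": set()}
        fracs, tests = rip_prevalence(groups, {"G1"})
        assert fracs["a"] == pytest.approx(25.0)
        assert fracs["b"] is None
        assert tests == []

    def test_equal_fractions_chi2_zero(self):
        groups = {"a": {"A1", "A2"}, "b": {"B1", "B2"}}
        fracs, tests = rip_prevalence(groups, {"A1", "B1"})
        [(_, _, res)] = tests
        assert res.chi2 == 0.0

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError):
            rip_prevalence({"a": {"G"}, "b": {"G"}}, set())


def test_planted_disease_and_rip_effects_detected(default_result):
    """The planted disease-label and RIP-binding enrichments of selected
    modules reach significance in the expected direction."""
    assert default_result.disease_test is not None
    assert default_result.disease_test.p < 0.05
    sel, rest = default_result.disease_fractions
    assert np.median(sel) > np.median(rest)

    fracs = default_result.rip_fractions
    assert fracs["selected_modules"] > fracs["no_module"]
    chi = {
        (a, b): r for a, b, r in default_result.rip_tests
    }[("selected_modules", "no_module")]
    assert chi.p < 0.05
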