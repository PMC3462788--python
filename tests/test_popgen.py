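"""Diversity statistics, neutrality tests and AMOVA against independent oracles."""

import math

import numpy as np
import pytest

from phyloniche import (
    DistanceMatrix,
    InsufficientSampleError,
    amova,
    best_grouping_search,
    fus_Fs,
    haplotype_diversity,
    nm_from_fst,
    nucleotide_diversity,
    pairwise_phist,
    raw_difference_matrix,
    tajimas_D,
)
from phyloniche.alignment import Alignment, PopulationAssignment
from phyloniche.popgen import mean_pairwise_differences, segregating_sites


# ---------------------------------------------------------------------------
# independent oracles


def brute_amova_components(d, pop_of, group_of=None):
    """Explicit double-loop AMOVA oracle on a distance matrix d (squared
    internally).  Independent of the library implementation: every SSD term
    is accumulated pair by pair."""
    n = len(pop_of)
    d2 = [[d[i][j] ** 2 for j in range(n)] for i in range(n)]
    pops = sorted(set(pop_of))

    def ssd_of(members):
        s = 0.0
        for i in members:
            for j in members:
                s += d2[i][j]
        return s / (2.0 * len(members))

    everyone = list(range(n))
    ssd_total = ssd_of(everyone)
    ssd_wp = sum(ssd_of([i for i in everyone if pop_of[i] == p]) for p in pops)
    sizes = {p: sum(1 for q in pop_of if q == p) for p in pops}

    if group_of is None:
        P = len(pops)
        df_a, df_c = P - 1, n - P
        sigma_c = ssd_wp / df_c
        n_c = (n - sum(s * s for s in sizes.values()) / n) / df_a
        sigma_a = ((ssd_total - ssd_wp) / df_a - sigma_c) / n_c
        return sigma_a, sigma_c

    groups = sorted(set(group_of.values()))
    ssd_wg = sum(
        ssd_of([i for i in everyone if group_of[pop_of[i]] == g]) for g in groups
    )
    G, P = len(groups), len(pops)
    df_a, df_b, df_c = G - 1, P - G, n - P
    n_g = {g: sum(sizes[p] for p in pops if group_of[p] == g) for g in groups}
    sum_sq_over_g = sum(
        sum(sizes[p] ** 2 for p in pops if group_of[p] == g) / n_g[g] for g in groups
    )
    sum_sq_total = sum(s * s for s in sizes.values()) / n
    sigma_c = ssd_wp / df_c
    if df_b > 0:
        n1 = (n - sum_sq_over_g) / df_b
        sigma_b = ((ssd_wg - ssd_wp) / df_b - sigma_c) / n1
    else:
        sigma_b = 0.0
    n2 = (sum_sq_over_g - sum_sq_total) / df_a
    n3 = (n - sum(v * v for v in n_g.values()) / n) / df_a
    sigma_a = ((ssd_total - ssd_wg) / df_a - sigma_c - n2 * sigma_b) / n3
    return sigma_a, sigma_b, sigma_c


def ewens_tail_exact(n, theta, k0):
    """Pr(K >= k0) via sympy's exact Stirling numbers and rational arithmetic."""
    from fractions import Fraction

    from sympy.functions.combinatorial.numbers import stirling

    th = Fraction(theta).limit_denominator(10**6)
    rising = Fraction(1)
    for i in range(n):
        rising *= th + i
    total = Fraction(0)
    for k in range(k0, n + 1):
        total += Fraction(int(stirling(n, k, kind=1, signed=False))) * th**k / rising
    return total


# ---------------------------------------------------------------------------
# diversity


class TestHaplotypeDiversity:
    @pytest.mark.parametrize(
        "counts, expected, places",
        [
            ((2, 1, 1), 0.833, 3),
            ((5, 5), 0.5556, 4),
            ((7,), 0.0, 6),
        ],
    )
    def test_values(self, counts, expected, places):
        assert haplotype_diversity(counts) == pytest.approx(expected, abs=10**-places / 2)

    def test_insufficient_sample(self):
        with pytest.raises(InsufficientSampleError):
            haplotype_diversity([1])


class TestNucleotideDiversity:
    def test_identical_is_zero(self):
        aln = Alignment.from_sequences(["a", "b"], ["ACGT" * 25] * 2)
        assert nucleotide_diversity(aln) == 0.0

    def test_two_sequences_three_diffs(self):
        s1 = "A" * 100
        s2 = "C" * 3 + "A" * 97
        aln = Alignment.from_sequences(["a", "b"], [s1, s2])
        assert nucleotide_diversity(aln) == pytest.approx(0.03)

    def test_three_sequence_enumeration(self):
        # pairwise diffs 1 (a,b), 1 (a,c), 2 (b,c) over 100 sites
        a = "A" * 100
        b = "C" + "A" * 99
        c = "A" * 99 + "G"
        aln = Alignment.from_sequences(["a", "b", "c"], [a, b, c])
        assert nucleotide_diversity(aln) == pytest.approx((1 + 1 + 2) / 3 / 100)

    def test_pairwise_policy_uses_per_pair_sites(self):
        # (a,b): sites 2-3, 0 diffs; (a,c): sites 2-4, 1 diff; (b,c): sites 1-3, 0
        aln = Alignment.from_sequences(["a", "b", "c"], ["NCGT", "ACGN", "ACGA"])
        pi_pair = nucleotide_diversity(aln, "pairwise")
        assert pi_pair == pytest.approx((0 / 2 + 1 / 3 + 0 / 3) / 3, abs=1e-12)


class TestTajimasD:
    def test_undefined_when_no_variation(self):
        assert tajimas_D(0, 10, 0.0) is None

    def test_zero_at_numerator_symmetry(self):
        n, S = 10, 16
        a1 = sum(1 / i for i in range(1, n))
        assert tajimas_D(S, n, S / a1) == pytest.approx(0.0, abs=1e-12)

    def test_matches_independent_constant_evaluation(self):
        # oracle: direct recomputation of the constants from their definitions
        n, S, k_hat = 10, 16, 3.888
        a1 = sum(1.0 / i for i in range(1, n))
        a2 = sum(1.0 / i**2 for i in range(1, n))
        b1 = (n + 1) / (3 * (n - 1))
        b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
        c1 = b1 - 1 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1, e2 = c1 / a1, c2 / (a1**2 + a2)
        expected = (k_hat - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))
        assert tajimas_D(S, n, k_hat) == pytest.approx(expected, rel=1e-12)

    def test_small_sample_rejected(self):
        with pytest.raises(InsufficientSampleError):
            tajimas_D(5, 3, 1.0)


class TestFusFs:
    def test_single_haplotype_is_plus_infinity(self):
        assert fus_Fs(10, 2.0, 1) == math.inf

    def test_exact_enumeration_example(self):
        # |s(4,.)| = (6, 11, 6, 1); S' = (6 + 1)/24 at theta = 1
        assert fus_Fs(4, 1.0, 3) == pytest.approx(math.log((6 + 1) / (24 - 7)), rel=1e-10)

    def test_tiny_theta_goes_to_minus_infinity(self):
        # Pr(K = n) ~ theta^(n-1) underflows to 0 -> explicit -inf marker
        assert fus_Fs(6, 1e-100, 6) == -math.inf

    @pytest.mark.parametrize("theta", [0.5, 1.0, 5.0])
    @pytest.mark.parametrize("n", range(2, 13))
    def test_matches_exact_stirling_enumeration(self, n, theta):
        for k0 in range(2, n + 1):
            s_prime = ewens_tail_exact(n, theta, k0)
            if s_prime in (0, 1):
                continue
            expected = math.log(float(s_prime / (1 - s_prime)))
            assert fus_Fs(n, theta, k0) == pytest.approx(expected, rel=1e-9)


# ---------------------------------------------------------------------------
# differentiation


class TestNmFromFst:
    @pytest.mark.parametrize(
        "fst, expected", [(0.59, 0.35), (0.63, 0.29), (0.77, 0.15), (0.5, 0.5)]
    )
    def test_published_conversions(self, fst, expected):
        assert round(nm_from_fst(fst), 2) == expected

    def test_boundaries(self):
        assert nm_from_fst(0.0) == math.inf
        assert nm_from_fst(1.0) == 0.0


def _random_instance(rng, n_pops, min_size=2, max_size=6, sites=30):
    sizes = rng.integers(min_size, max_size + 1, n_pops)
    ids, pop_of = [], []
    for p, size in enumerate(sizes):
        for i in range(size):
            ids.append(f"p{p}_{i}")
            pop_of.append(f"pop{p}")
    seqs = ["".join(rng.choice(list("ACGT"), sites)) for _ in ids]
    aln = Alignment.from_sequences(ids, seqs)
    pops = PopulationAssignment(dict(zip(ids, pop_of)))
    return aln, pops


class TestPairwisePhiST:
    def test_identical_compositions_not_positive(self):
        seqs = ["AAAA", "AATT"] * 2
        aln = Alignment.from_sequences(["a1", "a2", "b1", "b2"], seqs)
        pops = PopulationAssignment({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        dm = raw_difference_matrix(aln)
        (phi, p, nm), = pairwise_phist(dm, pops, n_perm=200, seed=1).values()
        assert phi <= 0
        assert p > 0.5
        assert nm == math.inf

    def test_fixed_difference_gives_one(self):
        aln = Alignment.from_sequences(
            ["a1", "a2", "b1", "b2"], ["AAAA", "AAAA", "AAAT", "AAAT"]
        )
        pops = PopulationAssignment({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        (phi, p, nm), = pairwise_phist(
            raw_difference_matrix(aln), pops, n_perm=200, seed=1
        ).values()
        assert phi == pytest.approx(1.0)
        assert nm == 0.0

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            aln, pops = _random_instance(rng, 2)
            dm = raw_difference_matrix(aln)
            (phi, _, _), = pairwise_phist(dm, pops, n_perm=10, seed=0).values()
            pop_of = [pops.sample_to_pop[s] for s in aln.sample_ids]
            sa, sc = brute_amova_components(dm.matrix, pop_of)
            assert phi == pytest.approx(sa / (sa + sc), abs=1e-10)


class TestAmova:
    def test_identical_sequences_undefined(self):
        aln = Alignment.from_sequences([f"s{i}" for i in range(6)], ["ACGT"] * 6)
        pops = PopulationAssignment(
            {f"s{i}": f"p{i % 3}" for i in range(6)},
            {"p0": "g1", "p1": "g1", "p2": "g2"},
        )
        res = amova(raw_difference_matrix(aln), pops, n_perm=10, seed=0)
        assert res.phi_CT is None and res.phi_ST is None
        assert res.ssd == (0.0, 0.0, 0.0)

    def test_one_pop_per_group_fixed_difference(self):
        aln = Alignment.from_sequences(
            ["a1", "a2", "b1", "b2"], ["AAAA", "AAAA", "TTTT", "TTTT"]
        )
        pops = PopulationAssignment(
            {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}, {"A": "g1", "B": "g2"}
        )
        res = amova(raw_difference_matrix(aln), pops, n_perm=10, seed=0)
        assert res.phi_CT == pytest.approx(1.0)

    def test_matches_brute_force_oracle_three_level(self, rng):
        for _ in range(20):
            aln, pops = _random_instance(rng, 4)
            grouping = {"pop0": "g1", "pop1": "g1", "pop2": "g2", "pop3": "g2"}
            dm = raw_difference_matrix(aln)
            res = amova(dm, pops.with_groups(grouping), n_perm=5, seed=0)
            pop_of = [pops.sample_to_pop[s] for s in aln.sample_ids]
            sa, sb, sc = brute_amova_components(dm.matrix, pop_of, grouping)
            assert res.sigma2_a == pytest.approx(sa, abs=1e-10)
            assert res.sigma2_b == pytest.approx(sb, abs=1e-10)
            assert res.sigma2_c == pytest.approx(sc, abs=1e-10)
            total = sa + sb + sc
            assert res.phi_ST == pytest.approx((sa + sb) / total, abs=1e-10)

    def test_df_sum_to_n_minus_one(self, rng):
        aln, pops = _random_instance(rng, 3)
        grouping = {"pop0": "g1", "pop1": "g2", "pop2": "g2"}
        res = amova(raw_difference_matrix(aln), pops.with_groups(grouping),
                    n_perm=5, seed=0)
        assert sum(res.df) == aln.n_samples - 1

    def test_one_pop_per_group_reduces_to_pairwise_phist(self, rng):
        aln, pops = _random_instance(rng, 2)
        dm = raw_difference_matrix(aln)
        grouping = {"pop0": "g1", "pop1": "g2"}
        res = amova(dm, pops.with_groups(grouping), n_perm=10, seed=0)
        (phi, _, _), = pairwise_phist(dm, pops, n_perm=10, seed=0).values()
        assert res.phi_CT == pytest.approx(phi, abs=1e-10)

    def test_permutation_p_seed_stable(self):
        rng = np.random.default_rng(3)
        aln, pops = _random_instance(rng, 2, min_size=5, max_size=5)
        dm = raw_difference_matrix(aln)
        ps = []
        for seed in (11, 22):
            (_, p, _), = pairwise_phist(dm, pops, n_perm=5000, seed=seed).values()
            ps.append(p)
        assert abs(ps[0] - ps[1]) < 0.02


class TestGroupingSearch:
    def test_single_candidate_ranked_first(self, rng):
        aln, pops = _random_instance(rng, 2)
        dm = raw_difference_matrix(aln)
        ranked = best_grouping_search(dm, pops, [{"pop0": "g1", "pop1": "g2"}],
                                      n_perm=10, seed=0)
        assert len(ranked) == 1 and ranked[0]["error"] is None

    def test_degenerate_candidate_sinks_to_bottom(self, rng):
        aln, pops = _random_instance(rng, 2)
        dm = raw_difference_matrix(aln)
        ranked = best_grouping_search(
            dm, pops,
            [{"pop0": "same", "pop1": "same"}, {"pop0": "g1", "pop1": "g2"}],
            n_perm=10, seed=0,
        )
        assert ranked[-1]["phi_CT"] is None  # all-one-group candidate last


class TestDistanceMatrixInterfaces:
    def test_tsv_round_trip(self, tmp_path, rng):
        from phyloniche.popgen import read_distance_matrix, write_distance_matrix

        aln, _ = _random_instance(rng, 2)
        dm = raw_difference_matrix(aln)
        p = tmp_path / "dm.tsv"
        write_distance_matrix(dm, p)
        back = read_distance_matrix(p)
        assert back.sample_ids == dm.sample_ids
        np.testing.assert_allclose(back.matrix, dm.matrix)

    def test_haplotype_indicator_gives_frequency_based_fst(self):
        from phyloniche.popgen import haplotype_indicator_matrix

        # two populations fixed for different haplotypes: F_ST = 1 either way
        aln = Alignment.from_sequences(
            ["a1", "a2", "b1", "b2"], ["ACGT", "ACGT", "ACGA", "ACGA"]
        )
        pops = PopulationAssignment({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        dm = haplotype_indicator_matrix(aln)
        assert set(np.unique(dm.matrix)) == {0.0, 1.0}
        (fst, _, _), = pairwise_phist(dm, pops, n_perm=20, seed=0).values()
        assert fst == pytest.approx(1.0)
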