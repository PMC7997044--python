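"""Comparison statistics: similarity, nMI, nestedness, sizes, boundaries, A/B."""

import numpy as np
import pytest

from multicd import (
    DomainSolution,
    GenomicBinning,
    SignalTrack,
    assign_AB,
    binary_similarity,
    boundary_correlation,
    compartment_track_correlation,
    nestedness,
    nmi,
    size_stats,
)
from multicd.evaluation import domain_boundaries
from multicd.types import BalancedContactMap


class TestBinarySimilarity:
    def test_identical_solution(self):
        s = DomainSolution(np.array([1, 1, 2, 2, 3]))
        assert binary_similarity(s, s) == pytest.approx(1.0)

    def test_label_permutation_invariant(self):
        s1 = DomainSolution(np.array([1, 1, 2, 2, 3]))
        s2 = DomainSolution(np.array([3, 3, 1, 1, 2]))
        assert binary_similarity(s1, s2) == pytest.approx(1.0)

    def test_independent_partitions_near_zero(self, rng):
        n, K = 500, 10
        vals = []
        for _ in range(5):
            a = DomainSolution(rng.integers(1, K + 1, n)).canonical()
            b = DomainSolution(rng.integers(1, K + 1, n)).canonical()
            vals.append(binary_similarity(a, b))
        assert np.abs(np.mean(vals)) < 0.05

    def test_single_domain_undefined(self):
        s1 = DomainSolution(np.ones(5, dtype=int))
        s2 = DomainSolution(np.array([1, 1, 2, 2, 2]))
        with pytest.warns(UserWarning, match="zero variance"):
            assert binary_similarity(s1, s2) is None


class TestNMI:
    def test_deterministic_relation_is_one(self):
        s = DomainSolution(np.repeat([1, 2, 3], 5))
        A = (s.labels[:, None] == s.labels[None, :]).astype(float)
        assert nmi(A, s) == pytest.approx(1.0)

    def test_shuffled_data_near_zero(self, rng):
        n = 300
        s = DomainSolution(np.repeat(np.arange(1, 11), 30))
        A = rng.standard_normal((n, n))
        A = (A + A.T) / 2
        assert nmi(A, s) < 0.02

    def test_constant_matrix_undefined(self):
        s = DomainSolution(np.array([1, 1, 2, 2]))
        with pytest.warns(UserWarning, match="constant"):
            assert nmi(np.zeros((4, 4)), s) is None

    def test_in_unit_interval(self, rng):
        n = 60
        s = DomainSolution(np.repeat(np.arange(1, 7), 10))
        B = (s.labels[:, None] == s.labels[None, :]).astype(float)
        A = B + 0.5 * rng.standard_normal((n, n))
        A = (A + A.T) / 2
        val = nmi(A, s)
        assert 0.0 <= val <= 1.0
        assert val > 0.1  # clearly informative


class TestNestedness:
    def test_perfect_nesting(self, rng):
        small = DomainSolution(np.repeat(np.arange(1, 11), 10))
        large = DomainSolution(np.repeat(np.arange(1, 3), 50))
        res = nestedness(small, large, rng=rng)
        assert res.h == pytest.approx(1.0, abs=1e-12)
        assert all(pd[1] == 1.0 for pd in res.per_domain)

    def test_independent_solutions_near_chance(self, rng):
        n = 500
        small = DomainSolution(rng.integers(1, 26, n)).canonical()
        large = DomainSolution(rng.integers(1, 6, n)).canonical()
        res = nestedness(small, large, rng=rng)
        assert abs(res.h) <= 0.05

    def test_half_split_raw_overlap(self, rng):
        # one small domain split half-and-half across two equal large domains
        small = DomainSolution(np.array([1] * 10 + [2] * 10))
        large = DomainSolution(np.array([1] * 5 + [2] * 10 + [1] * 5))
        res = nestedness(small, large, rng=rng)
        first = [pd for pd in res.per_domain if pd[0] == 1][0]
        assert first[1] == pytest.approx(0.5)

    def test_reference_single_domain_undefined(self, rng):
        small = DomainSolution(np.array([1, 1, 2, 2]))
        large = DomainSolution(np.ones(4, dtype=int))
        with pytest.warns(UserWarning, match="chance level"):
            res = nestedness(small, large, rng=rng)
        assert all(pd[3] is None for pd in res.per_domain)


class TestSizeStats:
    def test_equal_sizes_zero_dispersion(self):
        s = DomainSolution(np.repeat([1, 2, 3], 4))
        st = size_stats(s, GenomicBinning("c", 50_000, 12))
        assert st.dispersion == pytest.approx(0.0, abs=1e-12)
        assert st.mean_size_bins == pytest.approx(4.0)

    def test_single_domain(self):
        s = DomainSolution(np.ones(10, dtype=int))
        st = size_stats(s, GenomicBinning("c", 50_000, 10))
        assert st.mean_size_mb == pytest.approx(0.5)
        assert st.dispersion == 0.0

    def test_arithmetic(self):
        s = DomainSolution(np.array([1, 2, 2, 3, 3, 3]))
        st = size_stats(s, GenomicBinning("c", 50_000, 6))
        assert st.mean_size_mb == pytest.approx(0.1)
        mb = np.array([1, 2, 3]) * 0.05
        assert st.dispersion == pytest.approx(mb.var() / mb.mean())


class TestBoundaryCorrelation:
    def _track(self, values, bin_size=50_000):
        n = len(values)
        return SignalTrack(np.asarray(values, float), GenomicBinning("c", bin_size, n))

    def test_psi_marks_run_starts(self):
        s = DomainSolution(np.array([1, 1, 2, 2, 1, 3]))
        psi = domain_boundaries(s)
        np.testing.assert_array_equal(psi, [1, 0, 1, 0, 1, 1])

    def test_constant_track_zero_chi(self):
        s = DomainSolution(np.repeat([1, 2, 3, 4], 5))
        bc = boundary_correlation(self._track(np.ones(20)), s, d_max=3)
        np.testing.assert_allclose(bc.chi, 0.0, atol=1e-12)

    def test_spikes_at_boundaries_peak_at_zero(self):
        s = DomainSolution(np.repeat(np.arange(1, 6), 6))
        psi = domain_boundaries(s)
        bc = boundary_correlation(self._track(psi.copy()), s, d_max=4)
        i0 = np.where(bc.d == 0)[0][0]
        assert bc.chi[i0] == np.nanmax(bc.chi)
        assert all(bc.chi[i0] > bc.chi[i] for i in range(len(bc.d)) if i != i0)

    def test_matches_double_loop_oracle(self, rng):
        n, d_max = 40, 5
        s = DomainSolution(rng.integers(1, 5, n)).canonical()
        phi = rng.standard_normal(n)
        bc = boundary_correlation(self._track(phi), s, d_max=d_max)
        psi = domain_boundaries(s)
        dphi = phi - phi.mean()
        for a, d in enumerate(range(-d_max, d_max + 1)):
            acc = [dphi[i + d] * psi[i] for i in range(n) if 0 <= i + d < n]
            expect = np.mean(acc) / psi.mean()
            assert bc.chi[a] == pytest.approx(expect, abs=1e-12)

    def test_exponential_length_recovered(self):
        # track = boundary indicator convolved with exp(-|d|/l0); boundaries
        # are sparse so the mean-centering offset stays negligible
        n, ell0 = 2000, 4.0
        s = DomainSolution((np.arange(n) // 200) + 1)
        psi = domain_boundaries(s)
        kern = np.exp(-np.abs(np.arange(-40, 41)) / ell0)
        phi = np.convolve(psi, kern, mode="same")
        bc = boundary_correlation(self._track(phi), s, d_max=8)
        assert bc.correlation_length_bp == pytest.approx(ell0 * 50_000, rel=0.2)

    def test_single_domain_errors(self):
        s = DomainSolution(np.ones(10, dtype=int))
        # a single contiguous domain still has its leftmost-bin boundary,
        # but a fully masked interior with no runs must fail
        s_empty = DomainSolution(np.ones(10, dtype=int), np.zeros(10, dtype=bool))
        with pytest.raises(ValueError):
            boundary_correlation(self._track(np.arange(10.0)), s_empty, d_max=2)


class TestAssignAB:
    def _map(self, values, bin_size=50_000):
        n = values.shape[0]
        return BalancedContactMap(
            values, np.ones(n), GenomicBinning("c", bin_size, n), np.ones(n, dtype=bool)
        )

    def _two_domain_map(self, short_range_factor=2.0):
        n = 40
        labels = np.repeat([1, 2], 20)
        vals = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                d = abs(i - j)
                if d == 0:
                    continue
                base = 1.0 / (1 + d)
                if labels[i] == labels[j] == 1:
                    vals[i, j] = base * short_range_factor
                elif labels[i] == labels[j] == 2:
                    vals[i, j] = base
                else:
                    vals[i, j] = 0.05 * base
        return DomainSolution(labels), self._map(vals)

    def test_compact_domain_is_B(self):
        s, M = self._two_domain_map(2.0)
        a_label, b_label, profiles = assign_AB(s, M)
        assert b_label == 1 and a_label == 2
        assert np.nanmean(profiles[1][1:11]) > np.nanmean(profiles[2][1:11])

    def test_tie_warns(self):
        s, M = self._two_domain_map(1.0)
        with pytest.warns(UserWarning, match="tie"):
            a_label, b_label, _ = assign_AB(s, M)
        assert {a_label, b_label} == {1, 2}

    def test_short_range_window_drives_decision(self):
        # domain 1 compact at short range but weaker at long range
        n = 60
        labels = np.repeat([1, 2], 30)
        vals = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                d = abs(i - j)
                if d == 0 or labels[i] != labels[j]:
                    continue
                if labels[i] == 1:
                    vals[i, j] = 2.0 if d <= 10 else 0.1
                else:
                    vals[i, j] = 1.0 if d <= 10 else 0.5
        s = DomainSolution(labels)
        _, b_label, _ = assign_AB(s, self._map(vals))
        assert b_label == 1


class TestCompartmentTrackCorrelation:
    def test_perfectly_aligned_track(self):
        s = DomainSolution(np.repeat([1, 2], 10))
        track = SignalTrack(
            np.where(s.labels == 1, 1.0, -1.0), GenomicBinning("c", 50_000, 20)
        )
        cA, cB = compartment_track_correlation(s, 1, 2, track)
        assert cA == pytest.approx(1.0)
        assert cB == pytest.approx(-1.0)

    def test_orthogonal_track(self):
        s = DomainSolution(np.repeat([1, 2], 2))
        track = SignalTrack(np.array([1.0, -1.0, 1.0, -1.0]), GenomicBinning("c", 1, 4))
        cA, _ = compartment_track_correlation(s, 1, 2, track)
        assert cA == pytest.approx(0.0, abs=1e-12)

    def test_two_domain_antisymmetry(self, rng):
        s = DomainSolution(np.repeat([1, 2], 15))
        track = SignalTrack(rng.standard_normal(30), GenomicBinning("c", 1, 30))
        cA, cB = compartment_track_correlation(s, 1, 2, track)
        assert cB == pytest.approx(-cA)
        assert -1.0 <= cA <= 1.0
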