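"""Hi-C statistics: balancing convergence, insulation exactness, boundary
calling and matching, compartment recovery, P(s) invariances."""

import numpy as np
import pytest

import chromoquant as cq
from chromoquant import hic


def uniform_matrix(n=120, value=5.0, bin_size=10_000):
    return cq.ContactMatrix(np.full((n, n), value), bin_size=bin_size, balanced=True)


class TestBalance:
    def test_doubly_stochastic_fixed_point(self):
        n = 30
        m = cq.ContactMatrix(np.full((n, n), 1.0 / n))
        b = cq.balance_matrix(m)
        np.testing.assert_allclose(b.counts, m.counts, rtol=1e-9)
        np.testing.assert_allclose(b.bias[np.isfinite(b.bias)], 1.0, rtol=1e-6)

    def test_zero_row_masked_others_balanced(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(1, 5, size=(20, 20))
        c = (a + a.T) / 2
        c[3, :] = 0.0
        c[:, 3] = 0.0
        b = cq.balance_matrix(cq.ContactMatrix(c))
        assert np.isnan(b.bias[3])
        sums = np.nansum(b.counts, axis=0)
        valid = np.isfinite(b.bias)
        np.testing.assert_allclose(sums[valid], 1.0, rtol=1e-4)

    def test_random_positive_matrix_marginals_converge(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0.5, 4, size=(50, 50))
        c = a + a.T
        b = cq.balance_matrix(cq.ContactMatrix(c), tol=1e-8)
        sums = np.nansum(b.counts, axis=0)
        valid = np.isfinite(b.bias)
        assert np.std(sums[valid]) / np.mean(sums[valid]) < 1e-7

    def test_all_masked_rejected(self):
        m = cq.ContactMatrix(np.zeros((10, 10)))
        with pytest.raises(ValueError, match="masked"):
            cq.balance_matrix(m)


class TestPsCurve:
    def test_constant_matrix_flat_curve(self):
        curve = cq.ps_curve(uniform_matrix())
        assert curve.probs.std() / curve.probs.mean() < 1e-9

    def test_depth_rescaling_leaves_curve_invariant(self):
        m = cq.simulate_hic(cq.HicSimSpec(n_bins=200, depth=100.0, seed=3))
        m2 = cq.ContactMatrix(m.counts * 7.0, bin_size=m.bin_size)
        a, b = cq.ps_curve(m), cq.ps_curve(m2)
        np.testing.assert_allclose(a.probs, b.probs, rtol=1e-12)

    def test_slope_recovers_decay_exponent(self):
        slopes = []
        for seed in range(3):
            m = cq.simulate_hic(cq.HicSimSpec(n_bins=300, decay_exponent=1.0,
                                              depth=200.0, seed=seed))
            slopes.append(cq.fit_ps_slope(cq.ps_curve(m), 3e4, 7e5))
        assert np.mean(slopes) == pytest.approx(-1.0, abs=0.1)


class TestInsulation:
    def test_uniform_matrix_score_identically_zero(self):
        track = cq.insulation(uniform_matrix())
        defined = np.isfinite(track.scores)
        assert defined.sum() > 0
        np.testing.assert_array_equal(track.scores[defined], 0.0)

    def test_undefined_near_edges(self):
        track = cq.insulation(uniform_matrix(n=120))
        w = 50
        assert np.all(~np.isfinite(track.scores[:w]))
        assert np.all(~np.isfinite(track.scores[-w:]))

    def test_two_block_junction_is_global_minimum(self):
        n, w = 61, 10
        c = np.zeros((n, n))
        half = n // 2
        c[:half + 1, :half + 1] = 4.0
        c[half:, half:] = 4.0
        c[half, half] = 4.0
        m = cq.ContactMatrix(c, bin_size=10_000, balanced=True)
        track = cq.insulation(m, window=w * 10_000)
        assert np.nanargmin(track.scores) == half

    def test_short_chromosome_all_undefined(self):
        with pytest.warns(UserWarning, match="shorter"):
            track = cq.insulation(uniform_matrix(n=50))
        assert not np.isfinite(track.scores).any()

    def test_window_must_divide(self):
        with pytest.raises(ValueError, match="multiple"):
            cq.insulation(uniform_matrix(), window=505_001)

    def test_planted_boundaries_are_local_minima(self, tad_matrix):
        track = cq.insulation(tad_matrix)
        s = track.scores
        hits = 0
        for b in tad_matrix.tad_boundaries:
            lo, hi = b - 2, b + 3
            window = s[lo - 1 : hi + 1]
            hits += np.nanmin(window) == np.nanmin(s[lo:hi])
        assert hits >= 9


class TestBoundaries:
    def test_monotone_track_has_no_boundaries(self):
        track = hic.InsulationTrack(np.linspace(-1, 1, 40))
        assert len(cq.call_boundaries(track)) == 0

    def test_v_shape_strength_is_depth(self):
        s = np.zeros(21)
        s[10] = -0.5
        track = hic.InsulationTrack(s)
        bset = cq.call_boundaries(track)
        assert len(bset) == 1
        b = bset.boundaries[0]
        assert b.bin_index == 10
        assert b.strength == pytest.approx(0.5, rel=1e-12)

    def test_weak_minimum_filtered(self):
        s = np.zeros(21)
        s[10] = -0.05
        assert len(cq.call_boundaries(hic.InsulationTrack(s))) == 0

    def test_planted_count_recovered(self, tad_matrix):
        bset = cq.call_boundaries(cq.insulation(tad_matrix))
        assert abs(len(bset) - 10) <= 1


def _bset(bins, bin_size=10_000):
    return hic.BoundarySet(
        [hic.Boundary(b, b * bin_size, (b + 1) * bin_size, 0.5) for b in bins],
        bin_size=bin_size,
    )


class TestCompareBoundaries:
    def test_identical_sets_all_shared(self):
        a = _bset([10, 50, 90])
        cmp = cq.compare_boundaries(a, _bset([10, 50, 90]))
        assert cmp.n_shared == 3
        assert not cmp.a_specific and not cmp.b_specific

    def test_60kb_separation_matches(self):
        # zone half-width 55 kb → zones overlap iff center distance < 110 kb
        cmp = cq.compare_boundaries(_bset([10]), _bset([16]))
        assert cmp.n_shared == 1

    def test_200kb_separation_does_not_match(self):
        cmp = cq.compare_boundaries(_bset([10]), _bset([30]))
        assert cmp.n_shared == 0
        assert len(cmp.a_specific) == 1 and len(cmp.b_specific) == 1

    def test_symmetry(self):
        a, b = _bset([10, 40, 80, 120]), _bset([12, 60, 81])
        ab = cq.compare_boundaries(a, b)
        ba = cq.compare_boundaries(b, a)
        assert ab.n_shared == ba.n_shared
        assert len(ab.a_specific) == len(ba.b_specific)
        assert len(ab.b_specific) == len(ba.a_specific)

    def test_venn_arithmetic_one_to_one(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a = _bset(sorted(rng.choice(200, size=12, replace=False)))
            b = _bset(sorted(rng.choice(200, size=9, replace=False)))
            cmp = cq.compare_boundaries(a, b)
            assert len(a) == cmp.n_shared + len(cmp.a_specific)
            assert len(b) == cmp.n_shared + len(cmp.b_specific)

    def test_bin_size_mismatch_rejected(self):
        with pytest.raises(ValueError, match="bin size"):
            cq.compare_boundaries(_bset([1]), _bset([1], bin_size=5000))


class TestCompartments:
    def test_sign_matches_planted_labels(self, compartment_matrix, alternating_labels_300):
        track = cq.compartments(
            compartment_matrix, orientation_track=alternating_labels_300.astype(float)
        )
        valid = np.isfinite(track.e1)
        acc = np.mean(np.sign(track.e1[valid]) == alternating_labels_300[valid])
        assert acc >= 0.95

    def test_sign_equivariance_under_flipped_covariate(
        self, compartment_matrix, alternating_labels_300
    ):
        ref = alternating_labels_300.astype(float)
        t1 = cq.compartments(compartment_matrix, orientation_track=ref)
        t2 = cq.compartments(compartment_matrix, orientation_track=-ref)
        np.testing.assert_allclose(t1.e1, -t2.e1, equal_nan=True)

    def test_matches_full_eigendecomposition(self, compartment_matrix):
        # independent route: explicit O/E + corrcoef + eigh on dense matrix
        m = compartment_matrix
        valid = m.valid_bins
        oe = cq.observed_over_expected(m)[np.ix_(valid, valid)]
        oe = np.where(np.isfinite(oe), oe, 0.0)
        corr = np.corrcoef(oe, rowvar=False)
        corr = np.where(np.isfinite(corr), corr, 0.0)
        w, v = np.linalg.eigh(corr)
        lead = v[:, np.argmax(w)]
        track = cq.compartments(m)
        e1 = track.e1[valid]
        cos = abs(e1 @ lead) / (np.linalg.norm(e1) * np.linalg.norm(lead))
        assert cos > 0.999

    def test_null_matrix_flagged_low_confidence(self):
        m = cq.simulate_hic(cq.HicSimSpec(n_bins=200, depth=200.0, seed=8))
        with pytest.warns(UserWarning, match="low-confidence"):
            track = cq.compartments(cq.balance_matrix(m))
        assert track.low_confidence
        assert not track.oriented

    def test_unbalanced_rejected(self):
        m = cq.simulate_hic(cq.HicSimSpec(n_bins=50, seed=0))
        with pytest.raises(ValueError, match="balanced"):
            cq.compartments(m)


class TestSwitchesAndStrength:
    def test_identical_tracks_zero_switching(self, compartment_matrix, alternating_labels_300):
        t = cq.compartments(compartment_matrix,
                            orientation_track=alternating_labels_300.astype(float))
        sw = cq.compartment_switches(t, t)
        assert sw.a_to_b == 0 and sw.b_to_a == 0
        assert sw.pct_switched == 0.0

    def test_full_flip_switches_everything(self, compartment_matrix, alternating_labels_300):
        ref = alternating_labels_300.astype(float)
        t1 = cq.compartments(compartment_matrix, orientation_track=ref)
        flipped = hic.CompartmentTrack(
            e1=-t1.e1,
            labels=np.where(t1.labels == "A", "B",
                            np.where(t1.labels == "B", "A", "")).astype(object),
            oriented=True,
        )
        sw = cq.compartment_switches(t1, flipped)
        assert sw.pct_switched == 100.0
        assert sw.stable_a == 0 and sw.stable_b == 0

    def test_same_compartment_contacts_exceed_cross(self, compartment_matrix,
                                                    alternating_labels_300):
        track = cq.compartments(compartment_matrix,
                                orientation_track=alternating_labels_300.astype(float))
        st = cq.compartment_strength(compartment_matrix, track)
        assert st.aa > st.ab and st.bb > st.ab

    def test_null_amplitude_equalizes_groups(self):
        labels = np.where((np.arange(200) // 50) % 2 == 0, 1, -1)
        m = cq.simulate_hic(cq.HicSimSpec(n_bins=200, compartment_labels=labels,
                                          compartment_amplitude=0.0, depth=200.0, seed=2))
        mb = cq.balance_matrix(m)
        track = hic.CompartmentTrack(
            e1=labels.astype(float),
            labels=np.where(labels > 0, "A", "B").astype(object),
            oriented=True,
        )
        st = cq.compartment_strength(mb, track)
        assert st.aa == pytest.approx(st.ab, rel=0.05)
        assert st.bb == pytest.approx(st.ab, rel=0.05)

    def test_strength_increases_with_amplitude(self):
        labels = np.where((np.arange(200) // 50) % 2 == 0, 1, -1)
        ratios = []
        for amp in (0.1, 0.3, 0.5):
            vals = []
            for seed in range(3):
                m = cq.simulate_hic(cq.HicSimSpec(
                    n_bins=200, compartment_labels=labels,
                    compartment_amplitude=amp, depth=200.0, seed=seed))
                mb = cq.balance_matrix(m)
                track = cq.compartments(mb, orientation_track=labels.astype(float))
                st = cq.compartment_strength(mb, track)
                vals.append(st.aa / st.ab)
            ratios.append(np.mean(vals))
        assert ratios[0] < ratios[1] < ratios[2]


class TestAggregateProfiles:
    def test_single_center_equals_slice(self, tad_matrix):
        track = cq.insulation(tad_matrix)
        c = int(tad_matrix.tad_boundaries[4])
        offsets, mean, sd, n_used = cq.aggregate_insulation_profiles(track, [c])
        k = 50
        np.testing.assert_array_equal(mean, track.scores[c - k : c + k + 1])
        assert n_used == 1

    def test_boundary_centers_dip_at_middle(self, tad_matrix):
        track = cq.insulation(tad_matrix)
        centers = [b for b in tad_matrix.tad_boundaries if 105 <= b <= 395]
        offsets, mean, sd, n_used = cq.aggregate_insulation_profiles(track, centers)
        mid = len(mean) // 2
        assert np.argmin(mean) in range(mid - 2, mid + 3)

    def test_random_centers_flat_profile(self, tad_matrix):
        track = cq.insulation(tad_matrix)
        rng = np.random.default_rng(0)
        # bins at least 5 bins away from any planted boundary
        candidates = [
            i for i in range(110, 390)
            if np.min(np.abs(np.asarray(tad_matrix.tad_boundaries) - i)) > 5
        ]
        centers = rng.choice(candidates, size=30, replace=False)
        _, mean, _, _ = cq.aggregate_insulation_profiles(track, centers)
        mid = len(mean) // 2
        center_depth = mean[mid] - np.median(mean)
        assert abs(center_depth) < 0.15

    def test_no_usable_centers_rejected(self, tad_matrix):
        track = cq.insulation(tad_matrix)
        with pytest.warns(UserWarning, match="dropped"):
            with pytest.raises(ValueError, match="usable"):
                cq.aggregate_insulation_profiles(track, [1])


class TestMannWhitney:
    def test_shifted_distributions_detected(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 200)
        b = rng.normal(0.5, 1, 200)
        _, p = cq.compare_insulation_distributions(a, b, alternative="less")
        assert p < 0.01
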