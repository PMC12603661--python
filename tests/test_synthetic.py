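import warnings
from dataclasses import replace

import numpy as np
import pytest

from zerolag.connectivity import phase_delay_matrix, plv_matrix, wrap_angle
from zerolag.spectral import analytic_signal, bandpass_filter
from zerolag.synthetic import (StructuralConnectome, StructuralConnectomeParams,
                               SyntheticCohortSpec, draw_coupling,
                               leakage_matrix, make_geometry,
                               make_structural_connectome, normalised_log_count,
                               simulate_cohort, simulate_epoch,
                               transmission_delays)


class TestGeometry:
    @pytest.mark.parametrize("n", [4, 68])
    def test_homotopic_partnering_is_mirror_involution(self, n):
        geom = make_geometry(n, seed=1)
        partner = geom.homotopic_partner
        assert len(geom.homotopic_pairs()) == n // 2
        np.testing.assert_array_equal(partner[partner], np.arange(n))
        for i, j in geom.homotopic_pairs():
            assert geom.hemisphere[i] != geom.hemisphere[j]
            np.testing.assert_allclose(geom.centroids[i] * [-1, 1, 1],
                                       geom.centroids[j])

    def test_all_pairwise_distances_positive(self):
        d = make_geometry(68, seed=2).distance_matrix()
        off = d[~np.eye(68, dtype=bool)]
        assert off.min() > 0

    def test_odd_region_count_rejected(self):
        with pytest.raises(ValueError):
            make_geometry(7, seed=0)

    def test_seed_determinism(self):
        g1 = make_geometry(20, seed=9)
        g2 = make_geometry(20, seed=9)
        np.testing.assert_array_equal(g1.centroids, g2.centroids)
        assert g1.names == g2.names


class TestStructuralConnectome:
    def test_invariants(self, geometry16, connectome16):
        conn = connectome16
        iu = np.triu_indices(16, k=1)
        assert conn.norm_log_count.max() == pytest.approx(1.0)
        d = geometry16.distance_matrix()
        sel = conn.connected[iu]
        assert np.all(conn.median_length[iu][sel] >= d[iu][sel])
        assert np.all(conn.median_hmoa[iu][sel] > 0)

    def test_count_hmoa_positively_rank_correlated(self, connectome16):
        from scipy import stats
        iu = np.triu_indices(16, k=1)
        sel = connectome16.connected[iu]
        rho, _ = stats.spearmanr(connectome16.streamline_count[iu][sel],
                                 connectome16.median_hmoa[iu][sel])
        assert rho > 0

    def test_homotopic_boost_elevates_homotopic_counts(self, geometry16):
        conn = make_structural_connectome(
            geometry16, StructuralConnectomeParams(homotopic_boost=60.0),
            seed=1)
        hp = geometry16.homotopic_pairs()
        het = geometry16.heterotopic_interhemispheric_pairs()
        homo = np.median([conn.streamline_count[i, j] for i, j in hp])
        hete = np.median([conn.streamline_count[i, j] for i, j in het])
        assert homo > hete

    def test_unit_tortuosity_lengths_equal_distance(self, geometry16):
        conn = make_structural_connectome(
            geometry16, StructuralConnectomeParams(tortuosity_sd=0.0), seed=1)
        d = geometry16.distance_matrix()
        iu = np.triu_indices(16, k=1)
        sel = conn.connected[iu]
        np.testing.assert_allclose(conn.median_length[iu][sel], d[iu][sel])

    def test_flat_decay_limit_gives_equal_counts(self, geometry16):
        # decay length >> any distance and no Poisson noise: every pair's
        # expected count is the amplitude
        conn = make_structural_connectome(
            geometry16,
            StructuralConnectomeParams(decay_mm=1e12, homotopic_boost=1.0,
                                       poisson_noise=False), seed=1)
        iu = np.triu_indices(16, k=1)
        assert np.unique(conn.streamline_count[iu]).size == 1


class TestLeakage:
    def test_rows_sum_to_one(self, geometry16):
        m = leakage_matrix(geometry16, 20.0)
        np.testing.assert_allclose(m.sum(axis=1), 1.0)

    def test_zero_sigma_is_identity(self, geometry16):
        np.testing.assert_array_equal(leakage_matrix(geometry16, 0.0),
                                      np.eye(16))


class TestSimulateEpoch:
    def test_known_delay_plants_the_expected_phase(self):
        # closed form: a coupled pair at delay dt measures a circular-mean
        # delay of wrap(2 pi f dt) in a narrow band around f
        geom = make_geometry(4, seed=1)
        count = np.zeros((4, 4))
        count[0, 1] = count[1, 0] = 100.0
        length = np.zeros((4, 4))
        length[0, 1] = length[1, 0] = 150.0
        hmoa = np.zeros((4, 4))
        hmoa[0, 1] = hmoa[1, 0] = 0.05
        conn = StructuralConnectome(count, normalised_log_count(count),
                                    length, hmoa)
        spec = SyntheticCohortSpec(n_regions=4, leakage_sigma=0.0,
                                   coupling_strength=4.0, noise_level=0.05,
                                   homotopic_gain=0.0, zero_lag_fraction=0.0,
                                   coupling_strength_range=(1.0, 1.0))
        dt = transmission_delays(conn, spec)[0, 1]
        epoch = simulate_epoch(geom, conn, spec, band=(9.0, 11.0), seed=7)
        tau = phase_delay_matrix(analytic_signal(
            bandpass_filter(epoch, (9.0, 11.0)))).tau
        planted = wrap_angle(2 * np.pi * 10.0 * dt)
        assert abs(wrap_angle(tau[0, 1] - planted)) < 0.3

    def test_uncoupled_plv_at_chance_level(self):
        geom = make_geometry(10, seed=1)
        conn = make_structural_connectome(geom, seed=1)
        spec = SyntheticCohortSpec(n_regions=10, leakage_sigma=0.0,
                                   coupling_strength=0.0, homotopic_gain=0.0,
                                   zero_lag_fraction=0.0)
        epoch = simulate_epoch(geom, conn, spec, band=(9.0, 11.0), seed=3)
        p = plv_matrix(analytic_signal(
            bandpass_filter(epoch, (9.0, 11.0)))).weights
        iu = np.triu_indices(10, k=1)
        # ~2 Hz x 20 s of effective samples: chance PLV is around 0.14
        assert np.median(p[iu]) < 0.25
        assert p[iu].max() < 0.6

    def test_leakage_elevates_short_range_zero_lag_plv(self):
        geom = make_geometry(68, seed=4)
        conn = make_structural_connectome(geom, seed=4)
        spec = SyntheticCohortSpec(leakage_sigma=20.0, coupling_strength=0.0,
                                   homotopic_gain=0.0, zero_lag_fraction=0.0)
        epoch = simulate_epoch(geom, conn, spec, band="alpha", seed=5)
        p = plv_matrix(analytic_signal(bandpass_filter(epoch, "alpha"))).weights
        d = geom.distance_matrix()
        iu = np.triu_indices(68, k=1)
        near = p[iu][d[iu] < 20]
        far = p[iu][d[iu] > 80]
        assert np.median(near) > np.median(far) + 0.3

    def test_excessive_delay_rejected(self):
        geom = make_geometry(4, seed=1)
        count = np.zeros((4, 4))
        count[0, 1] = count[1, 0] = 10.0
        length = np.zeros((4, 4))
        length[0, 1] = length[1, 0] = 5000.0
        hmoa = np.zeros((4, 4))
        hmoa[0, 1] = hmoa[1, 0] = 0.001
        conn = StructuralConnectome(count, normalised_log_count(count),
                                    length, hmoa)
        spec = SyntheticCohortSpec(n_regions=4, epoch_seconds=3.0)
        with pytest.raises(ValueError, match="delay"):
            simulate_epoch(geom, conn, spec, band="alpha", seed=0)

    def test_band_outside_nyquist_rejected(self, geometry16, connectome16):
        spec = SyntheticCohortSpec(n_regions=16)
        with pytest.raises(ValueError, match="Nyquist|band"):
            simulate_epoch(geometry16, connectome16, spec, band=(100.0, 140.0),
                           seed=0)


class TestSimulateCohort:
    def test_seed_determinism_is_bitwise(self):
        spec = SyntheticCohortSpec(n_regions=8, n_participants=10,
                                   epoch_seconds=3.0, seed=13)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            c1 = simulate_cohort(spec)
            c2 = simulate_cohort(spec)
        np.testing.assert_array_equal(c1.epochs[3][0].data,
                                      c2.epochs[3][0].data)
        np.testing.assert_array_equal(c1.epochs[7][1].data,
                                      c2.epochs[7][1].data)
        assert c1.table.equals(c2.table)

    def test_epoch_pairs_share_coupling_but_not_noise(self, small_cohort):
        a, b = small_cohort.epochs[0]
        assert not np.allclose(a.data, b.data)
        coupling = small_cohort.couplings[0]
        assert coupling.gains.shape == (16, 16)

    def test_covariates_in_plausible_ranges(self, small_cohort):
        tab = small_cohort.table
        assert tab.age.between(6, 31).all()
        assert tab.head_circumference.between(40, 62).all()
        assert (tab.swm_errors_t1 >= 0).all()
        assert tab.t2_t1_interval.between(12, 30).all()

    def test_minimum_cohort_size_enforced(self):
        with pytest.raises(ValueError):
            simulate_cohort(SyntheticCohortSpec(n_regions=8, n_participants=5))

    def test_planted_effects_recorded(self, small_cohort):
        planted = small_cohort.planted
        assert planted["swm_beta"] == small_cohort.spec.swm_beta
        assert planted["true_pathlength"].shape == (12,)
        assert np.isfinite(planted["true_pathlength"]).all()


class TestInvalidSpecs:
    @pytest.mark.parametrize("kw", [
        {"sampling_rate": 0.0}, {"epoch_seconds": -1.0},
        {"conduction_velocity": 0.0}, {"synaptic_delay": -0.1},
        {"leakage_sigma": -5.0},
    ])
    def test_nonphysical_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            SyntheticCohortSpec(**kw)
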