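import numpy as np
import pytest

from idrslab.fixtures import (
    PlantedSlabSpec,
    make_charged_gas,
    make_order_parameter_series,
    make_planted_slab,
)
from idrslab.forcefield import Configuration, ModelParams, Topology
from idrslab.sequences import assign_charges
from idrslab.slab_analysis import (
    DensityProfile,
    chain_displacement,
    chain_pair_rdf,
    classify_forms,
    density_profile,
    electrostatic_contacts,
    fit_critical,
    head_end_distance,
    mean_profile,
    phase_metric,
    slab_center,
    tcr_threshold,
    windowed_stats,
)
from oracles import brute_contacts


def profile_from_p(p_gamma, n=3000):
    p_gamma = np.asarray(p_gamma, dtype=float)
    return DensityProfile(
        m_gamma=np.round(p_gamma * n).astype(np.int64),
        p_gamma=p_gamma,
        window_length=10.0,
    )


class TestDensityProfile:
    def test_single_window_delta(self):
        pos = np.zeros((50, 3))
        pos[:, 2] = 12.0  # all in window [10, 20) of 30 x 10 nm windows
        cfg = Configuration(pos, np.array([20.0, 20.0, 300.0]))
        prof = density_profile(cfg)
        assert prof.p_gamma[1] == 1.0
        assert prof.p_gamma.sum() == pytest.approx(1.0)
        assert prof.m_gamma.sum() == 50

    def test_uniform_lattice(self):
        z = (np.arange(30_000) + 0.5) * (300.0 / 30_000)
        pos = np.zeros((30_000, 3))
        pos[:, 2] = z
        cfg = Configuration(pos, np.array([20.0, 20.0, 300.0]))
        prof = density_profile(cfg)
        assert np.allclose(prof.p_gamma, 1.0 / 30.0)

    def test_window_conventions(self):
        # bead exactly on an interior edge belongs to the upper window
        pos = np.array([[0.0, 0.0, 10.0]])
        cfg = Configuration(pos, np.array([5.0, 5.0, 300.0]))
        prof = density_profile(cfg)
        assert prof.m_gamma[1] == 1

    def test_counts_conserved_random(self):
        rng = np.random.default_rng(0)
        pos = rng.uniform(-500, 500, size=(777, 3))
        cfg = Configuration(pos, np.array([20.0, 20.0, 300.0]))
        prof = density_profile(cfg)
        assert prof.m_gamma.sum() == 777

    def test_d_gamma_units(self):
        pos = np.zeros((100, 3))
        pos[:, 2] = 5.0
        cfg = Configuration(pos, np.array([10.0, 10.0, 300.0]))
        prof = density_profile(cfg)
        # 100 beads in one 10 x 10 x 10 nm window
        assert prof.d_gamma[0] == pytest.approx(0.1)

    def test_planted_slab_matches_construction(self):
        spec = PlantedSlabSpec(
            n_chains=200, chain_length=20, box=(20.0, 20.0, 300.0),
            condensed_fraction=0.7, half_width=20.0, seed=3,
        )
        _, cfg, expected = make_planted_slab(spec)
        prof = density_profile(cfg)
        assert np.abs(prof.p_gamma - expected.p_gamma).max() < 0.05


class TestPhaseMetric:
    def test_uniform_profile(self):
        point = phase_metric([profile_from_p(np.full(30, 1 / 30))])
        assert point.order_parameter == pytest.approx(0.0)
        assert point.llps_absent and not point.llps_obvious

    def test_single_window_delta(self):
        p = np.zeros(30)
        p[4] = 1.0
        point = phase_metric([profile_from_p(p)])
        assert point.order_parameter == pytest.approx(1.0)
        assert point.llps_obvious

    def test_hand_arithmetic_three_dense_windows(self):
        # three windows at 0.30, remaining 0.10 spread over 27 windows
        p = np.full(30, 0.1 / 27)
        p[[10, 11, 12]] = 0.3
        point = phase_metric([profile_from_p(p, n=2700)])
        assert point.p_h == pytest.approx(0.3)
        assert point.p_l == pytest.approx(0.1 / 27)
        assert point.order_parameter == pytest.approx(0.3 - 0.1 / 27)

    def test_profile_first_vs_frame_first(self):
        p1 = np.zeros(30); p1[0] = 1.0
        p2 = np.zeros(30); p2[15] = 1.0
        frames = [profile_from_p(p1), profile_from_p(p2)]
        assert phase_metric(frames).p_h == pytest.approx(0.5)
        assert phase_metric(frames, order="frame-first").p_h == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            phase_metric([])

    def test_invariant_under_rigid_z_translation(self):
        rng = np.random.default_rng(9)
        pos = np.zeros((500, 3))
        pos[:, 2] = rng.normal(150.0, 12.0, 500) % 300.0
        box = np.array([20.0, 20.0, 300.0])
        base = phase_metric([density_profile(Configuration(pos, box))])
        shifted = pos.copy()
        shifted[:, 2] = (shifted[:, 2] + 137.0) % 300.0  # any rigid shift
        moved = phase_metric([density_profile(Configuration(shifted, box))])
        # shifts by a non-multiple of the window length re-bin beads, so
        # compare at window granularity: shift by whole windows is exact
        exact = pos.copy()
        exact[:, 2] = (exact[:, 2] + 10.0 * 7) % 300.0
        same = phase_metric([density_profile(Configuration(exact, box))])
        assert same.order_parameter == pytest.approx(base.order_parameter)
        assert abs(moved.order_parameter - base.order_parameter) < 0.05


class TestTcrThreshold:
    def test_exact_boundary(self):
        est = tcr_threshold([(1.0, 0.5), (2.0, 0.07)])
        assert est.t_cr == pytest.approx(2.0)
        assert est.status == "crossing"

    def test_hand_interpolation(self):
        est = tcr_threshold([(3.0, 0.10), (4.0, 0.04)])
        assert est.t_cr == pytest.approx(3.5)

    def test_never_above_threshold(self):
        est = tcr_threshold([(1.0, 0.01), (2.0, 0.02)])
        assert est.t_cr is None and est.status == "no-llps"

    def test_never_below_threshold_lower_bound(self):
        with pytest.warns(UserWarning):
            est = tcr_threshold([(1.0, 0.5), (2.0, 0.4)])
        assert est.t_cr == 2.0 and est.status == "lower-bound"

    def test_non_monotone_uses_highest_crossing(self):
        with pytest.warns(UserWarning):
            est = tcr_threshold(
                [(1.0, 0.5), (2.0, 0.01), (3.0, 0.5), (4.0, 0.01)]
            )
        assert 3.0 < est.t_cr < 4.0

    def test_monotone_in_values(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            temps = np.sort(rng.uniform(1, 4, size=6))
            vals = np.sort(rng.uniform(0, 0.4, size=6))[::-1]
            base = tcr_threshold(list(zip(temps, vals)))
            raised = tcr_threshold(list(zip(temps, vals + 0.01)))
            if base.t_cr is not None and raised.t_cr is not None:
                assert raised.t_cr >= base.t_cr - 1e-12


class TestFitCritical:
    def test_noiseless_recovery(self):
        series = make_order_parameter_series(
            1.0, 3.5, 0.325, [1.0, 1.5, 2.0, 2.5, 3.0], noise_sd=0.0
        )
        fit = fit_critical(series)
        assert fit.converged
        assert fit.amplitude == pytest.approx(1.0, abs=1e-6)
        assert fit.t_cr == pytest.approx(3.5, abs=1e-6)
        assert fit.beta == pytest.approx(0.325, abs=1e-6)

    def test_noisy_recovery_median(self):
        errs = []
        for seed in range(50):
            series = make_order_parameter_series(
                1.0, 3.5, 0.325, [1.0, 1.5, 2.0, 2.5, 3.0],
                noise_sd=0.01, seed=seed,
            )
            fit = fit_critical(series)
            if fit.converged:
                errs.append(abs(fit.t_cr - 3.5))
        assert np.median(errs) < 0.1

    def test_too_few_points_threshold_only(self):
        fit = fit_critical([(1.0, 0.5), (2.0, 0.2), (3.0, 0.05)])
        assert not fit.converged and fit.t_cr is None
        assert fit.threshold_t_cr is not None


class TestHeadEndDistance:
    def test_straight_chain_l79(self):
        L = 79
        pos = np.zeros((L, 3))
        pos[:, 0] = 1.0 + np.arange(L) * 0.38
        cfg = Configuration(pos, np.array([40.0, 40.0, 300.0]))
        topo = Topology.from_charges(np.zeros(L, dtype=np.int64), 1)
        d = head_end_distance(cfg, topo)
        assert d[0] == pytest.approx(78 * 3.8)  # 296.4 Angstrom

    def test_four_bead_hand_geometry(self):
        a = 0.38
        pos = np.array([
            [1.0, 1.0, 1.0],
            [1.0 + a, 1.0, 1.0],
            [1.0 + a, 1.0 + a, 1.0],
            [1.0, 1.0 + a, 1.0],
        ])
        cfg = Configuration(pos, np.array([10.0, 10.0, 10.0]))
        topo = Topology.from_charges(np.zeros(4, dtype=np.int64), 1)
        assert head_end_distance(cfg, topo)[0] == pytest.approx(3.8)

    def test_invariant_across_periodic_boundary(self):
        L = 10
        pos = np.zeros((L, 3))
        pos[:, 2] = 5.0 + np.arange(L) * 0.38
        box = np.array([10.0, 10.0, 8.0])  # chain wraps in z
        topo = Topology.from_charges(np.zeros(L, dtype=np.int64), 1)
        d1 = head_end_distance(Configuration(pos.copy(), box), topo)
        wrapped = pos.copy()
        wrapped[:, 2] %= box[2]
        d2 = head_end_distance(Configuration(wrapped, box), topo)
        assert d1[0] == pytest.approx(d2[0])

    def test_broken_unwrap_detected(self):
        pos = np.array([[1.0, 1.0, 1.0], [1.0, 1.0, 3.0]])  # 2 nm >> 2a
        cfg = Configuration(pos, np.array([10.0, 10.0, 10.0]))
        topo = Topology.from_charges(np.zeros(2, dtype=np.int64), 1)
        with pytest.raises(ValueError, match="unwrap"):
            head_end_distance(cfg, topo)


class TestSlabCenter:
    def _slab(self, center, box_z=300.0, n=2000, width=10.0, seed=0):
        rng = np.random.default_rng(seed)
        pos = np.zeros((n, 3))
        pos[:, 2] = (center + rng.uniform(-width, width, n)) % box_z
        return Configuration(pos, np.array([20.0, 20.0, box_z]))

    def test_centered_slab(self):
        sc = slab_center(self._slab(150.0))
        assert not sc.degenerate
        assert sc.z0 == pytest.approx(150.0, abs=1.0)

    def test_slab_across_boundary(self):
        sc = slab_center(self._slab(2.0))
        assert not sc.degenerate
        # center near z = 2, not at the box middle
        assert min(sc.z0, 300.0 - sc.z0 + 2.0) < 5.0

    def test_uniform_gas_falls_back(self):
        pos = np.zeros((3000, 3))
        pos[:, 2] = (np.arange(3000) + 0.5) * 0.1
        cfg = Configuration(pos, np.array([20.0, 20.0, 300.0]))
        sc = slab_center(cfg)
        assert sc.degenerate


class TestChainDisplacement:
    def _one_bead_chain(self, z, box_z=300.0):
        topo = Topology.from_charges(np.zeros(1, dtype=np.int64), 1)
        cfg = Configuration(
            np.array([[1.0, 1.0, z]]), np.array([20.0, 20.0, box_z])
        )
        return topo, cfg

    def test_chain_at_center(self):
        topo, cfg = self._one_bead_chain(40.0)
        assert chain_displacement(cfg, topo, 40.0)[0] == pytest.approx(0.0)

    def test_mirror_minimum(self):
        topo, cfg = self._one_bead_chain(299.0)
        assert chain_displacement(cfg, topo, 0.0)[0] == pytest.approx(1.0)

    def test_maximum_is_half_box(self):
        topo, cfg = self._one_bead_chain(150.0)
        assert chain_displacement(cfg, topo, 0.0)[0] == pytest.approx(150.0)


class TestWindowedStats:
    def test_single_window_equal_values(self):
        ws = windowed_stats(
            np.full(10, 42.0), np.full(10, 1.0), box_z=300.0
        )
        assert ws.fraction[0] == pytest.approx(1.0)
        assert ws.mean[0] == pytest.approx(42.0)
        assert ws.sem[0] == pytest.approx(0.0)

    def test_two_value_hand_arithmetic(self):
        ws = windowed_stats(
            np.array([10.0, 20.0]), np.array([2.0, 3.0]), box_z=300.0
        )
        # both in window [0, 5): mean 15, sem = sd(ddof=1)/sqrt(2) = 5
        assert ws.mean[0] == pytest.approx(15.0)
        assert ws.sem[0] == pytest.approx(5.0)

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(1)
        ws = windowed_stats(
            rng.normal(size=200), rng.uniform(0, 150, 200), box_z=300.0
        )
        assert ws.fraction.sum() == pytest.approx(1.0)

    def test_boundary_windows_flagged_excluded(self):
        ws = windowed_stats(np.ones(5), np.ones(5), box_z=300.0)
        # windows [140,145) and [145,150] at 5 nm width
        assert ws.excluded.sum() == 2
        assert ws.excluded[28] and ws.excluded[29]

    def test_empty_window_not_fabricated(self):
        ws = windowed_stats(np.array([1.0]), np.array([1.0]), box_z=300.0)
        assert ws.fraction[10] == 0.0
        assert np.isnan(ws.mean[10]) and np.isnan(ws.sem[10])

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError):
            windowed_stats(np.ones(3), np.ones(4), box_z=300.0)


class TestElectrostaticContacts:
    def test_opposite_pair_across_chains(self, params_10mm):
        topo, cfg = make_charged_gas(
            2, (10.0, 10.0, 10.0), "alternating",
            positions=np.array([[1.0, 1.0, 1.0], [2.0, 1.0, 1.0]]),
        )
        e_intra, e_inter = electrostatic_contacts(cfg, topo, params_10mm)
        assert e_inter.tolist() == [1, 1]
        assert e_intra.tolist() == [0, 0]

    def test_like_charges_not_counted(self, params_10mm):
        topo = Topology(
            n_chains=2, chain_length=1,
            charges=np.array([1, 1]), bonds=np.empty((0, 2), dtype=np.int64),
        )
        cfg = Configuration(
            np.array([[1.0, 1.0, 1.0], [1.5, 1.0, 1.0]]),
            np.array([10.0, 10.0, 10.0]),
        )
        e_intra, e_inter = electrostatic_contacts(cfg, topo, params_10mm)
        assert e_inter.sum() == 0

    def test_intra_chain_counted_on_owner(self, params_10mm):
        topo = Topology.from_sequence(assign_charges("EK"), 1)
        cfg = Configuration(
            np.array([[1.0, 1.0, 1.0], [1.38, 1.0, 1.0]]),
            np.array([10.0, 10.0, 10.0]),
        )
        e_intra, e_inter = electrostatic_contacts(cfg, topo, params_10mm)
        assert e_intra.tolist() == [1] and e_inter.tolist() == [0]

    def test_screened_mode_refused(self, params_screened):
        topo, cfg = make_charged_gas(10, (10.0, 10.0, 10.0), seed=1)
        with pytest.raises(ValueError, match="screened"):
            electrostatic_contacts(cfg, topo, params_screened)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_gas(self, seed, params_10mm):
        topo, cfg = make_charged_gas(100, (8.0, 8.0, 8.0), "random", seed=seed)
        got = electrostatic_contacts(cfg, topo, params_10mm)
        want = brute_contacts(cfg, topo, 1.2)
        assert np.array_equal(got[0], want[0])
        assert np.array_equal(got[1], want[1])


class TestChainPairRdf:
    def test_fixed_offset_pair(self):
        # two single-bead chains at fixed separation d = 3 nm
        topo, cfg = make_charged_gas(
            2, (12.0, 12.0, 12.0), "neutral",
            positions=np.array([[2.0, 2.0, 2.0], [5.0, 2.0, 2.0]]),
        )
        rdf = chain_pair_rdf([cfg], topo, bin_width=0.2)
        assert abs(rdf.peak1[0] - 3.0) <= 0.2

    def test_uniform_gas_normalizes_to_one(self):
        rng = np.random.default_rng(4)
        box = np.array([12.0, 12.0, 12.0])
        L = 400
        topo = Topology.from_charges(np.zeros(L, dtype=np.int64), 2)
        frames = [
            Configuration(rng.uniform(0, 1, (2 * L, 3)) * box, box)
            for _ in range(5)
        ]
        rdf = chain_pair_rdf(frames, topo, bin_width=0.25)
        far = rdf.r > 2.0
        assert np.abs(rdf.g[0][far].mean() - 1.0) < 0.1

    def test_partner_count_199_for_200_chains(self):
        topo, cfg = make_charged_gas(200, (15.0, 15.0, 15.0), "neutral", seed=2)
        rdf = chain_pair_rdf([cfg], topo, bin_width=0.5)
        assert len(rdf.peak1) == 199
        assert len(rdf.partners) == 199


class TestClassifyForms:
    def test_uniform_all_f(self):
        out = classify_forms(np.full(30, 1 / 30), box_z=300.0)
        assert out.window_labels == ["F"] * 30

    def test_planted_slab_labels(self):
        p = np.full(30, 0.1 / 27)
        p[[14, 15, 16]] = 0.3
        out = classify_forms(p, box_z=300.0)
        labels = np.array(out.window_labels)
        assert set(labels[[14, 15, 16]]) == {"P"}
        assert set(np.delete(labels, [14, 15, 16])) == {"D"}

    def test_wrapping_condensed_region(self):
        p = np.full(30, 0.1 / 27)
        p[[0, 29]] = 0.45  # slab straddles the periodic boundary
        out = classify_forms(p, box_z=300.0)
        assert out.window_labels[0] == "P" and out.window_labels[29] == "P"
        assert out.window_labels[15] == "D"

    def test_sigma_ordering_on_planted_fixture(self):
        # condensed chains near-straight (low D spread), dilute chains as
        # random coils (high D spread): pooled sigma(P) < sigma(D)
        spec = PlantedSlabSpec(
            n_chains=150, chain_length=20, box=(20.0, 20.0, 300.0),
            condensed_fraction=0.6, half_width=15.0,
            condensed_mode="extended", dilute_mode="compact-coil", seed=8,
        )
        topo, cfg, _ = make_planted_slab(spec)
        from idrslab.slab_analysis import chain_centers

        prof = density_profile(cfg)
        d = head_end_distance(cfg, topo)
        cz = chain_centers(cfg, topo)[:, 2]
        out = classify_forms(prof.p_gamma, box_z=300.0, chain_z=cz, chain_values=d)
        assert out.sigma_by_label["P"] < out.sigma_by_label["D"]
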