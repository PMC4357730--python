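"""Synthetic-data generator: worm-like chains, position/angle/volume samplers."""

import numpy as np
import pytest
from scipy import stats

import afmscan as a


class TestWormLikeChain:
    def test_point_count_and_arc_length(self, rng):
        pts = a.generate_wlc_chain(165.0, 50.0, 2.5, rng)
        assert len(pts) == int(np.ceil(165.0 / 2.5)) + 1
        L = np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()
        assert abs(L - 165.0) <= 2.5

    def test_infinite_stiffness_gives_straight_line(self, rng):
        pts = a.generate_wlc_chain(165.0, 1e12, 2.5, rng)
        e2e = np.linalg.norm(pts[-1] - pts[0])
        assert abs(e2e - 165.0) < 1e-6

    def test_mean_squared_end_to_end_matches_2d_wlc_closed_form(self):
        # closed form for a 2-D chain with tangent correlation exp(-s/2P):
        # <R^2> = 4 P L [1 - (2P/L)(1 - exp(-L/2P))]
        L, P = 165.0, 50.0
        rng = np.random.default_rng(42)
        r2 = [np.sum((c[-1] - c[0]) ** 2)
              for c in (a.generate_wlc_chain(L, P, 2.5, rng)
                        for _ in range(10000))]
        closed = 4 * P * L * (1 - (2 * P / L) * (1 - np.exp(-L / (2 * P))))
        se = np.std(r2) / np.sqrt(len(r2))
        assert abs(np.mean(r2) - closed) < 3 * se

    def test_tangent_autocorrelation_decay(self):
        # <t(0).t(s)> = exp(-s/2P) for the 2-D equilibrated chain
        L, P, step = 300.0, 50.0, 2.5
        rng = np.random.default_rng(7)
        lags = [4, 10, 20]
        acc = {k: [] for k in lags}
        for _ in range(2000):
            pts = a.generate_wlc_chain(L, P, step, rng)
            t = np.diff(pts, axis=0)
            t /= np.linalg.norm(t, axis=1, keepdims=True)
            for k in lags:
                acc[k].append(np.mean(np.sum(t[:-k] * t[k:], axis=1)))
        for k in lags:
            expected = np.exp(-k * step / (2 * P))
            assert np.mean(acc[k]) == pytest.approx(expected, abs=0.02)

    @pytest.mark.parametrize("bad", [dict(contour_length_nm=-1.0),
                                     dict(step=-2.0),
                                     dict(persistence_length=0.0)])
    def test_invalid_geometry_rejected(self, bad):
        kwargs = dict(contour_length_nm=165.0, persistence_length=50.0, step=2.5)
        kwargs.update(bad)
        with pytest.raises(a.InvalidParameterError):
            a.generate_wlc_chain(**kwargs)


class TestPositionSampler:
    def test_s_of_one_gives_uniform_positions(self):
        f = a.sample_positions(50000, 1.0, 494, end_fraction=0.0, rng=1)
        kept = f[f > 0.05]
        # KS against uniform over the considered range
        d, p = stats.kstest(kept, stats.uniform(0.05, 0.45).cdf)
        assert p > 0.01

    def test_specific_share_matches_inverted_specificity(self):
        # S = 163, N = 494 -> phi = r/(1+r) with r = 162/494
        n = 100000
        f = a.sample_positions(n, 163.0, 494, end_fraction=0.0,
                               peak_center=0.46, peak_width=0.032, rng=2)
        phi = (162 / 494) / (1 + 162 / 494)
        assert phi == pytest.approx(0.2469, abs=1e-4)
        near = np.abs(f - 0.46) <= 3 * 0.032
        # window [0.364, 0.5] (clipped at the centre); specific mass ~99.7%
        # lands inside it after folding, background contributes its width
        window = 0.5 - (0.46 - 3 * 0.032)
        expected = phi * 0.9973 + (1 - phi) * window / 0.45
        assert np.mean(near) == pytest.approx(expected, abs=0.01)

    def test_specific_vs_background_chi2_gof(self):
        # binned mixture frequencies match the generating model at n = 1e5
        n = 100000
        S, N, w, c = 163.0, 494, 0.032, 0.46
        f = a.sample_positions(n, S, N, end_fraction=0.15, rng=3)
        r = (S - 1) / N
        phi = r / (1 + r)
        edges = np.arange(0.0, 0.525, 0.025)  # aligned with the 5% end zone
        counts, _ = np.histogram(f, bins=edges)
        gauss = stats.norm(c, w)
        p_spec = (gauss.cdf(edges[1:]) - gauss.cdf(edges[:-1])
                  + gauss.cdf(1 - edges[:-1]) - gauss.cdf(1 - edges[1:]))
        width = np.diff(edges)
        p_end = np.where(edges[1:] <= 0.05, width / 0.05, 0.0)
        p_nsp = np.where(edges[:-1] >= 0.05, width / 0.45, 0.0)
        probs = 0.15 * p_end + 0.85 * (phi * p_spec + (1 - phi) * p_nsp)
        probs /= probs.sum()
        chi2, p = stats.chisquare(counts, n * probs)
        assert p > 0.01

    def test_all_positions_folded_into_half(self):
        f = a.sample_positions(20000, 358.0, 494, rng=4)
        assert np.all((f >= 0) & (f <= 0.5))

    def test_invalid_specificity_rejected(self):
        with pytest.raises(a.InvalidParameterError):
            a.sample_positions(10, 0.5, 494)


class TestBendAngleSampler:
    def test_half_normal_mean(self):
        ang = a.sample_bend_angles(100000, [(0.0, 1.0)], 10.0, rng=5)
        assert np.mean(ang) == pytest.approx(10 * np.sqrt(2 / np.pi), abs=0.15)

    def test_degenerate_mixture_single_state(self):
        ang = a.sample_bend_angles(5000, [(0.0, 0.0), (70.0, 1.0)], 8.0, rng=6)
        assert np.all(ang >= 0)
        assert np.mean(ang) == pytest.approx(70.0, abs=0.5)

    def test_empirical_cdf_matches_folded_mixture(self):
        states, sd = [(29.0, 0.33), (68.0, 0.67)], 10.0
        ang = a.sample_bend_angles(100000, states, sd, rng=7)

        def cdf(x):
            x = np.atleast_1d(x)
            out = np.zeros_like(x, float)
            for m, w in states:
                out += w * (stats.norm.cdf(x, m, sd) - stats.norm.cdf(-x, m, sd))
            return out

        d, p = stats.kstest(ang, cdf)
        assert p > 0.01

    def test_empty_state_list_rejected(self):
        with pytest.raises(a.InvalidParameterError):
            a.sample_bend_angles(10, [], 10.0)


class TestVolumeSampler:
    def test_noiseless_monomer_volume_from_calibration(self):
        # inverse of MW = (V + 5.9)/1.2 at 46 kDa
        _, v = a.sample_volumes(100, 46.0, dimer_fraction=0.0,
                                noise_sd=0.0, rng=8)
        assert np.allclose(v, 1.2 * 46.0 - 5.9)
        assert v[0] == pytest.approx(49.3)

    def test_single_mode_when_no_dimers(self):
        state, v = a.sample_volumes(2000, 46.0, 0.0, 5.0, rng=9)
        assert np.all(state == 1)
        assert np.std(v) == pytest.approx(5.0, rel=0.1)

    def test_majority_classifies_monomeric(self):
        state, v = a.sample_volumes(5000, 46.0, dimer_fraction=0.2,
                                    noise_sd=5.0, rng=10)
        mw = a.volume_to_mw(v)
        monomer = mw < 1.5 * 46.0
        assert np.mean(monomer) >= 0.80


class TestDatasetAssembly:
    def test_ground_truth_bijection_and_determinism(self):
        cfg = a.SimulationConfig(n_fragments=8, n_experiments=2, seed=3)
        tr1, rec1, truth1 = a.simulate_dataset(cfg)
        tr2, rec2, truth2 = a.simulate_dataset(cfg)
        assert len(rec1) == len(truth1) == 16
        assert truth1.equals(truth2)
        for t_a, t_b in zip(tr1[0], tr2[0]):
            assert np.array_equal(t_a.points, t_b.points)
        keys1 = {(r.experiment, r.fragment_id) for r in rec1}
        keys2 = set(zip(truth1.experiment, truth1.fragment_id))
        assert keys1 == keys2

    def test_truth_positions_in_half_interval(self):
        cfg = a.SimulationConfig(n_fragments=20, n_experiments=1, seed=4)
        _, _, truth = a.simulate_dataset(cfg)
        assert truth.true_position_fraction.between(0, 0.5).all()

    def test_config_validation(self):
        with pytest.raises(a.InvalidParameterError):
            a.SimulationConfig(specificity_S_true=0.2)
        with pytest.raises(a.InvalidParameterError):
            a.SimulationConfig(bend_states=[(30.0, 0.4), (70.0, 0.4)])
        with pytest.raises(a.InvalidParameterError):
            a.SimulationConfig(rise_per_bp=-0.3)

    def test_imposed_kink_sets_local_turning_angle(self, straight_chain, rng):
        pts = a.impose_kink(straight_chain.points, 80.0, 30.0, rng)
        beta = a.bend_angle(a.PolylineTrace(0, pts), 80.0)
        assert beta == pytest.approx(30.0, abs=1.0)

    def test_experiment_seeds_distinct_and_stable(self):
        s = a.experiment_seeds(5, 3)
        assert len(set(s)) == 3
        assert s == a.experiment_seeds(5, 3)
        assert all(0 <= x < 2**31 for x in s)
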