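"""Dirac-mixture size distribution, moments, envelopes, and mixtures."""

import numpy as np
import pytest

from celldiv import (
    InitialSizeSpec,
    ModelParams,
    SimulationConfig,
    envelope_atoms,
    initial_size_mixture,
    simulate_ensemble,
    size_atoms,
    size_moments,
)


class TestSizeAtoms:
    def test_initial_point_mass(self, dist7, params):
        a = size_atoms(dist7, 0.0, params)
        heavy = a.atoms[a.atoms["weight"] > 1e-9]
        assert len(heavy) == 1
        assert heavy.iloc[0]["size"] == pytest.approx(params.s0)
        assert heavy.iloc[0]["weight"] == pytest.approx(1.0, abs=1e-9)

    def test_sizes_halve_between_consecutive_counts(self, dist7, params):
        a = size_atoms(dist7, 3 * params.tau, params)
        sizes = a.atoms.sort_values("i")["size"].to_numpy()
        assert np.allclose(sizes[1:] / sizes[:-1], 0.5, rtol=1e-12)

    def test_mass_concentrates_near_expected_count(self, dist7, params):
        # at t = 7 tau the size factor e^{mu t} = 2^7, so mass sits at
        # s0 * 2^{7-i} with i near 7 — within a factor 2 of s0
        a = size_atoms(dist7, 7 * params.tau, params)
        top = a.atoms.nlargest(3, "weight")
        assert np.all(top["size"] >= params.s0 / 2 - 1e-9)
        assert np.all(top["size"] <= 2 * params.s0 + 1e-9)

    def test_mass_conservation(self, dist7, params):
        for t in (0.0, 2 * params.tau, 7 * params.tau):
            a = size_atoms(dist7, t, params)
            assert a.total_weight() + a.leak == pytest.approx(1.0, abs=1e-8)

    def test_off_grid_time_rejected(self, dist7, params):
        with pytest.raises(ValueError):
            size_atoms(dist7, 0.1234, params)

    def test_output_frame_drops_dust_only(self, dist7, params):
        a = size_atoms(dist7, 7 * params.tau, params)
        out = a.output_frame()
        assert (out["weight"] >= 1e-12).all()
        assert out["weight"].sum() == pytest.approx(a.total_weight(), abs=1e-11)


class TestSizeMoments:
    def test_initial_moments(self, dist7, params):
        m = size_moments(dist7, params)
        assert m.mean[0] == pytest.approx(params.s0, abs=1e-9)
        assert m.var[0] == pytest.approx(0.0, abs=1e-9)

    def test_consistent_with_atom_sets(self, dist7, params):
        m = size_moments(dist7, params)
        for t in (params.tau, 5 * params.tau):
            j = dist7.time_index(t)
            a = size_atoms(dist7, t, params)
            assert a.mean() == pytest.approx(m.mean[j], rel=1e-12)
            assert a.var() == pytest.approx(m.var[j], rel=1e-12, abs=1e-15)

    def test_mean_size_is_tau_periodic_at_late_times(self, dist7, params):
        m = size_moments(dist7, params)
        j6 = dist7.time_index(6 * params.tau)
        j7 = dist7.time_index(7 * params.tau)
        assert abs(m.mean[j7] - m.mean[j6]) < 1e-3 * params.s0

    def test_fsp_moments_inside_ssa_confidence_band(self, params, grid7, dist7):
        cfg = SimulationConfig(n_cells=10_000, t_final=grid7[-1], seed=0, record_grid=grid7)
        s = simulate_ensemble(cfg, params)
        m = size_moments(dist7, params)
        cov_mean = np.mean(np.abs(m.mean - s.mean_s) <= s.ci_s + 1e-12)
        cov_var = np.mean(np.abs(m.var - s.var_s) <= s.ci_var_s + 1e-12)
        assert cov_mean >= 0.90 and cov_var >= 0.90


class TestEnvelope:
    def test_single_source_reduces_to_size_atoms(self, params):
        t = 4 * params.tau
        env = envelope_atoms([params.s0], t, params)
        assert env.atoms["source_s0"].nunique() == 1
        # weights are a probability distribution over counts, as size_atoms
        assert env.total_weight() + env.leak == pytest.approx(1.0, abs=1e-8)
        sizes = env.atoms.sort_values("i")["size"].to_numpy()
        assert np.allclose(sizes[1:] / sizes[:-1], 0.5)

    def test_three_source_envelope_conserves_mass(self, params):
        s0s = [params.s0, 4 * params.s0 / 3, 5 * params.s0 / 3]
        env = envelope_atoms(s0s, 7 * params.tau, params)
        assert sorted(env.atoms["source_s0"].unique()) == pytest.approx(sorted(s0s))
        assert env.total_weight() + env.leak == pytest.approx(1.0, abs=1e-8)

    def test_each_source_matches_its_ssa_histogram(self, params):
        # per-source atom weights vs a 5000-cell simulated histogram of the
        # division count, compared in total variation
        t = 7 * params.tau
        s0s = [params.s0, 4 * params.s0 / 3, 5 * params.s0 / 3]
        env = envelope_atoms(s0s, t, params)
        for m, s0 in enumerate(s0s):
            sub = env.atoms[np.isclose(env.atoms["source_s0"], s0)].sort_values("i")
            w = sub["weight"].to_numpy() * len(s0s)  # undo equal-source weighting
            cfg = SimulationConfig(
                n_cells=5000, t_final=t, seed=100 + m, record_grid=np.array([0.0, t])
            )
            counts = simulate_ensemble(cfg, ModelParams(mu=params.mu, k=params.k, s0=s0)).counts[:, -1]
            h = np.bincount(counts, minlength=w.size) / counts.size
            k = max(h.size, w.size)
            tv = 0.5 * np.abs(np.pad(h, (0, k - h.size)) - np.pad(w, (0, k - w.size))).sum()
            assert tv < 0.03

    def test_invalid_sizes_rejected(self, params):
        with pytest.raises(ValueError):
            envelope_atoms([1.0, -2.0], params.tau, params)


class TestInitialSizeMixture:
    def test_point_mass_reduces_to_single_source(self, params):
        t = 3 * params.tau
        for n_nodes in (1, 8):
            mix = initial_size_mixture(InitialSizeSpec.fixed(params.s0), n_nodes, t, params)
            single = envelope_atoms([params.s0], t, params)
            w_mix = mix.atoms.sort_values("size")["weight"].to_numpy()
            w_one = single.atoms.sort_values("size")["weight"].to_numpy()
            assert np.allclose(w_mix[-w_one.size :], w_one[-w_mix.size :], atol=1e-12)

    def test_two_point_mixture_merges_coincident_atoms(self, params):
        # size depends on s0 only through s0/2^n, so the 2 s0 component's
        # atoms coincide with the s0 component's shifted by one index
        t = 4 * params.tau
        spec = InitialSizeSpec.atoms([params.s0, 2 * params.s0], [0.5, 0.5])
        mix = initial_size_mixture(spec, 2, t, params)
        sizes = np.sort(mix.atoms["size"].to_numpy())
        assert np.all(np.diff(sizes) / sizes[:-1] > 1e-9)  # merged: all distinct
        raw = envelope_atoms([params.s0, 2 * params.s0], t, params)
        assert len(mix.atoms) < len(raw.atoms)
        assert mix.total_weight() == pytest.approx(raw.total_weight(), abs=1e-12)

    def test_lognormal_mixture_mean_matches_ssa(self, params):
        t = 7 * params.tau
        spec = InitialSizeSpec.lognormal(0.0, 0.1)
        mix = initial_size_mixture(spec, 32, t, params)
        cfg = SimulationConfig(
            n_cells=5000, t_final=t, seed=7, record_grid=np.array([0.0, t]),
            initial_size_spec=spec,
        )
        s = simulate_ensemble(cfg, params)
        assert abs(mix.mean() - s.mean_s[-1]) <= s.ci_s[-1]

    def test_mixture_conserves_mass(self, params):
        mix = initial_size_mixture(InitialSizeSpec.uniform(1.0, 2.0), 8, 5 * params.tau, params)
        assert mix.total_weight() + mix.leak == pytest.approx(1.0, abs=1e-8)
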