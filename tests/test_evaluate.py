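"""FC computation, FC-FC / SC-FC scoring, sweeps, and permutation tests."""

import numpy as np
import pytest

from wcdyn import (Connectome, FCMatrix, SimulationConfig, build_network,
                   compute_fc, fcfc_score, perturbation_field,
                   permutation_test, remove_transient, replicate_scores,
                   scfc_score, sigma_sweep, simulate, sweep_grid)


def fc_from(values, labels=None):
    v = np.asarray(values, dtype=float)
    labels = labels or tuple(f"r{i}" for i in range(v.shape[0]))
    return FCMatrix(values=v, labels=labels)


def random_fc(n, seed):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, n + 5))
    return fc_from(np.corrcoef(x))


class TestComputeFC:
    def test_matches_brute_force_pearson(self, model12, short_cfg):
        r = remove_transient(simulate(model12, short_cfg.with_(T=2000.0)))
        fc = compute_fc(r)
        E = r.E
        n = E.shape[0]
        for a in (0, 3, 7):
            for b in (1, 5, 11):
                x, y = E[a] - E[a].mean(), E[b] - E[b].mean()
                rho = (x @ y) / np.sqrt((x @ x) * (y @ y))
                assert fc.values[a, b] == pytest.approx(rho, abs=1e-12)
        np.testing.assert_allclose(np.diagonal(fc.values), 1.0)

    def test_identical_and_flipped_series(self, model12, short_cfg):
        r = remove_transient(simulate(model12, short_cfg.with_(T=2000.0)))
        E = r.E.copy()
        E[1] = E[0]
        E[2] = -E[0] + 1.0  # sign-flipped fluctuations
        r2 = type(r)(t=r.t, E=E, I=r.I, seed=r.seed, config=r.config,
                     model=r.model, transient_removed=True)
        fc = compute_fc(r2)
        assert fc.values[0, 1] == pytest.approx(1.0)
        assert fc.values[0, 2] == pytest.approx(-1.0)

    def test_constant_series_names_region(self, model12, short_cfg):
        r = remove_transient(simulate(model12, short_cfg.with_(T=2000.0)))
        E = r.E.copy()
        E[4] = 0.5
        r2 = type(r)(t=r.t, E=E, I=r.I, seed=r.seed, config=r.config,
                     model=r.model, transient_removed=True)
        with pytest.raises(ValueError, match="R04"):
            compute_fc(r2)

    def test_requires_transient_removed(self, model12, short_cfg):
        with pytest.raises(ValueError, match="transient"):
            compute_fc(simulate(model12, short_cfg.with_(T=2000.0)))


class TestFCFCScore:
    def test_identity_scores_one(self):
        fc = random_fc(8, 0)
        assert fcfc_score(fc, fc) == pytest.approx(1.0)

    def test_rank_reversal_scores_minus_one(self):
        fc = random_fc(8, 1)
        iu = np.triu_indices(8, 1)
        v = fc.values.copy()
        # map each upper-triangle value to its rank-reversed partner
        vals = v[iu]
        order = np.argsort(vals)
        flipped = np.empty_like(vals)
        flipped[order] = vals[order[::-1]]
        v[iu] = flipped
        v.T[iu] = flipped
        assert fcfc_score(fc_from(v), fc) == pytest.approx(-1.0)

    def test_monotone_transform_invariance(self):
        fc = random_fc(10, 2)
        v = np.tanh(2.5 * np.arctanh(np.clip(fc.values, -0.999, 0.999)))
        np.fill_diagonal(v, 1.0)
        assert fcfc_score(fc_from(v), random_fc(10, 3)) == pytest.approx(
            fcfc_score(fc, random_fc(10, 3)), abs=1e-12)

    def test_symmetric_in_arguments(self):
        a, b = random_fc(9, 4), random_fc(9, 5)
        assert fcfc_score(a, b) == pytest.approx(fcfc_score(b, a))

    def test_label_mismatch_rejected(self):
        a = random_fc(5, 6)
        b = FCMatrix(values=random_fc(5, 7).values,
                     labels=tuple("vwxyz"))
        with pytest.raises(ValueError, match="labels"):
            fcfc_score(a, b)

    def test_needs_three_regions(self):
        a = random_fc(2, 8)
        with pytest.raises(ValueError):
            fcfc_score(a, a)


class TestSCFCScore:
    def test_rank_matching_fc_scores_one(self, connectome12):
        sym = np.maximum(connectome12.A, connectome12.A.T)
        v = 0.2 + 0.3 * sym  # FC strictly increasing in symmetrized SC
        np.fill_diagonal(v, 1.0)
        fc = FCMatrix(values=v, labels=connectome12.labels)
        assert scfc_score(connectome12, fc) == pytest.approx(1.0)

    def test_constant_sc_rejected(self):
        n = 5
        A = 1.0 - np.eye(n)
        c = Connectome(A=A, labels=tuple(f"r{i}" for i in range(n)),
                       groups=("g",) * n)
        with pytest.raises(ValueError, match="constant"):
            scfc_score(c, random_fc(n, 9, ))

    def test_matches_rank_correlation_oracle(self, connectome12):
        from scipy.stats import rankdata

        fc = random_fc(12, 10)
        fc = FCMatrix(values=fc.values, labels=connectome12.labels)
        iu = np.triu_indices(12, 1)
        sc = np.maximum(connectome12.A, connectome12.A.T)[iu]
        ra, rb = rankdata(sc), rankdata(fc.values[iu])
        oracle = np.corrcoef(ra, rb)[0, 1]
        assert scfc_score(connectome12, fc) == pytest.approx(oracle,
                                                             abs=1e-12)


class TestReplicateScores:
    def test_zero_noise_replicates_differ_only_by_init(self, model12,
                                                       target_fc12):
        # with explicit initial state and no noise every replicate is equal
        cfg = SimulationConfig(dt=0.1, T=3000.0, transient=1000.0,
                               noise_s=0.0,
                               initial_state=np.vstack([np.full(12, 0.3),
                                                        np.full(12, 0.2)]))
        rep = replicate_scores(model12, cfg, target_fc12, n_rep=3,
                               seed_base=0)
        assert rep.sd == 0.0
        assert len(set(rep.rhos)) == 1

    def test_single_replicate_sd_zero(self, model12, target_fc12, short_cfg):
        rep = replicate_scores(model12, short_cfg.with_(T=3000.0),
                               target_fc12, n_rep=1, seed_base=5)
        assert rep.sd == 0.0 and len(rep.rhos) == 1

    def test_rerun_invariance(self, model12, target_fc12, short_cfg):
        cfg = short_cfg.with_(T=3000.0)
        r1 = replicate_scores(model12, cfg, target_fc12, 3, seed_base=2)
        r2 = replicate_scores(model12, cfg, target_fc12, 3, seed_base=2)
        assert r1.rhos == r2.rhos


class TestSweeps:
    def test_single_cell_reduces_to_replicates(self, connectome12, lc_params,
                                               target_fc12, short_cfg):
        cfg = short_cfg.with_(T=3000.0)
        sw = sweep_grid(connectome12, lc_params, [0.7], [1.5], cfg,
                        target_fc12, n_rep=3, seed_base=1)
        rep = replicate_scores(build_network(connectome12,
                                             lc_params.with_(B_e=1.5), 0.7),
                               cfg, target_fc12, 3, seed_base=1)
        np.testing.assert_allclose(sw.scores[0, 0], rep.rhos)

    def test_cell_values_independent_of_axis_order(self, connectome12,
                                                   lc_params, target_fc12,
                                                   short_cfg):
        cfg = short_cfg.with_(T=2000.0)
        G = [0.5, 0.7]
        Be = [1.2, 1.8]
        sw = sweep_grid(connectome12, lc_params, G, Be, cfg, target_fc12,
                        n_rep=2, seed_base=0)
        sw_rev = sweep_grid(connectome12, lc_params, G[::-1], Be[::-1], cfg,
                            target_fc12, n_rep=2, seed_base=0)
        np.testing.assert_allclose(sw.scores, sw_rev.scores[::-1, ::-1])

    def test_sigma_zero_cell_equals_homogeneous(self, connectome12,
                                                lc_params, densities12,
                                                target_fc12, short_cfg):
        cfg = short_cfg.with_(T=3000.0)
        sw = sigma_sweep(connectome12, lc_params.with_(B_e=1.5), [0.0, 0.2],
                         densities12, 0.7, cfg, target_fc12, n_rep=2,
                         seed_base=3)
        m_hom = build_network(connectome12, lc_params.with_(B_e=1.5), 0.7)
        rep = replicate_scores(m_hom, cfg, target_fc12, 2, seed_base=3)
        assert tuple(sw.scores[0]) == rep.rhos  # bit-identical

    def test_infeasible_sigma_marked(self, connectome12, lc_params,
                                     densities12, target_fc12, short_cfg):
        sigma_bad = 1.0 / max(-densities12.e_z.min(),
                              -densities12.i_z.min()) + 0.5
        sw = sigma_sweep(connectome12, lc_params, [sigma_bad], densities12,
                         0.7, short_cfg.with_(T=2000.0), target_fc12,
                         n_rep=2)
        assert np.isnan(sw.scores).all()
        assert len(sw.infeasible) == 1

    def test_empty_axis_rejected(self, connectome12, lc_params, target_fc12,
                                 short_cfg):
        with pytest.raises(ValueError):
            sweep_grid(connectome12, lc_params, [], [1.5], short_cfg,
                       target_fc12)


class TestPermutationEquivariance:
    def test_relabeling_regions_preserves_dynamics_and_score(
            self, connectome12, lc_params, target_fc12, short_cfg):
        # consistent region relabeling permutes short deterministic
        # trajectories (up to summation rounding) ...
        perm = np.random.default_rng(11).permutation(12)
        x0 = np.vstack([np.linspace(0.2, 0.4, 12), np.full(12, 0.25)])
        cfg = SimulationConfig(dt=0.1, T=50.0, transient=0.0, noise_s=0.0,
                               initial_state=x0)
        m = build_network(connectome12, lc_params, 0.7)
        r = simulate(m, cfg)

        labels_p = tuple(connectome12.labels[i] for i in perm)
        groups_p = tuple(connectome12.groups[i] for i in perm)
        c_p = Connectome(A=connectome12.A[np.ix_(perm, perm)],
                         labels=labels_p, groups=groups_p)
        m_p = build_network(c_p, lc_params, 0.7)
        r_p = simulate(m_p, cfg.with_(initial_state=x0[:, perm]))
        np.testing.assert_allclose(r_p.E, r.E[perm], atol=1e-12)

        # ... and leaves every downstream score exactly unchanged
        r_full = remove_transient(simulate(m, short_cfg.with_(T=3000.0)))
        fc = compute_fc(r_full)
        fc_p = FCMatrix(values=fc.values[np.ix_(perm, perm)],
                        labels=labels_p)
        tgt_p = FCMatrix(values=target_fc12.values[np.ix_(perm, perm)],
                         labels=labels_p)
        assert fcfc_score(fc_p, tgt_p) == pytest.approx(
            fcfc_score(fc, target_fc12), abs=1e-12)


class TestPermutationTest:
    def test_constant_field_null_equals_observed(self, connectome12,
                                                 lc_params, densities12,
                                                 target_fc12, short_cfg):
        # sigma = 0: every permutation rebuilds the identical model -> p = 1
        rep = permutation_test(connectome12, lc_params.with_(B_e=1.5),
                               densities12, 0.0, 0.7,
                               short_cfg.with_(T=2000.0), target_fc12,
                               n_perm=19, n_rep=1)
        assert all(x == rep.observed for x in rep.null)
        assert rep.p_value == 1.0

    def test_minimum_p_when_observed_beats_all(self, connectome12, lc_params,
                                               densities12, short_cfg):
        from wcdyn import synth_target_fc

        f = perturbation_field(densities12, 0.3)
        m_true = build_network(connectome12, lc_params.with_(B_e=1.5), 0.7, f)
        tgt = synth_target_fc(m_true,
                              SimulationConfig(dt=0.1, T=6000.0,
                                               transient=1000.0),
                              observation_noise_sd=0.01, seed=77)
        rep = permutation_test(connectome12, lc_params.with_(B_e=1.5),
                               densities12, 0.3, 0.7,
                               short_cfg.with_(T=3000.0), tgt,
                               n_perm=19, n_rep=1, perm_seed=3)
        assert rep.p_value >= 1.0 / (rep.n_permutations + 1)
        if all(x < rep.observed for x in rep.null):
            assert rep.p_value == pytest.approx(
                1.0 / (rep.n_permutations + 1))

    def test_n_perm_floor(self, connectome12, lc_params, densities12,
                          target_fc12, short_cfg):
        with pytest.raises(ValueError):
            permutation_test(connectome12, lc_params, densities12, 0.2, 0.7,
                             short_cfg, target_fc12, n_perm=5)


class TestFCMatrixValidation:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="symmetric"):
            fc_from([[1, 0.5], [0.2, 1]])
        with pytest.raises(ValueError, match="diagonal"):
            fc_from([[0.9, 0.1], [0.1, 0.9]])
        with pytest.raises(ValueError, match=r"\[-1, 1\]"):
            fc_from([[1, 1.5], [1.5, 1]])
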