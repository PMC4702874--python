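"""Spectral engine: eigendecomposition and GNM observables."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import nodeset_from_points, path_nodes, random_connected_nodes
from gnmkit.errors import (
    ContractError,
    DisconnectedNetworkError,
    MissingDataError,
    UndefinedCorrelationError,
)
from gnmkit.network import build_kirchhoff
from gnmkit.spectral import (
    collectivity,
    collectivity_table,
    compute_fluctuations,
    cross_correlation,
    decompose,
    decompose_partial,
    mode_contribution,
    pseudo_inverse,
    soft_mode_count,
    theoretical_b_factors,
)


def _path_spectrum(n):
    return decompose(build_kirchhoff(path_nodes(n), 7.3))


class TestDecompose:
    def test_three_node_path_eigenvalues(self):
        sp = _path_spectrum(3)
        np.testing.assert_allclose(sp.eigenvalues, [0.0, 1.0, 3.0], atol=1e-10)
        assert sp.n_zero_modes == 1

    @pytest.mark.parametrize("n", [3, 10, 50])
    def test_path_closed_form_spectrum(self, n):
        # the N-path Laplacian has eigenvalues 4 sin^2(k pi / 2N)
        sp = _path_spectrum(n)
        k = np.arange(1, n)
        expected = 4.0 * np.sin(k * np.pi / (2 * n)) ** 2
        np.testing.assert_allclose(
            sp.nonzero_eigenvalues(), np.sort(expected), atol=1e-8
        )

    def test_two_clusters_give_two_zero_modes(self, rng):
        a = rng.uniform(0, 8, size=(5, 3))
        b = rng.uniform(0, 8, size=(5, 3)) + 100.0
        g = build_kirchhoff(nodeset_from_points(np.vstack([a, b])), 7.3)
        assert decompose(g).n_zero_modes == 2

    def test_eigenvectors_orthonormal(self, rng):
        nodes = random_connected_nodes(40, rng)
        sp = decompose(build_kirchhoff(nodes, 7.3))
        U = sp.eigenvectors
        np.testing.assert_allclose(U.T @ U, np.eye(40), atol=1e-8)

    def test_sign_convention_is_deterministic(self, rng):
        nodes = random_connected_nodes(30, rng)
        g = build_kirchhoff(nodes, 7.3)
        u1 = decompose(g).mode(1)[1]
        u2 = decompose(g).mode(1)[1]
        np.testing.assert_array_equal(u1, u2)
        assert u1[np.argmax(np.abs(u1))] > 0

    def test_partial_agrees_with_dense_on_overlap(self):
        nodes = path_nodes(1000)
        g = build_kirchhoff(nodes, 7.3)
        full = decompose(g)
        part = decompose_partial(g, n_low=40, n_high=10)
        np.testing.assert_allclose(
            part.eigenvalues[:40], full.eigenvalues[:40], atol=1e-6
        )
        np.testing.assert_allclose(
            part.eigenvalues[-10:], full.eigenvalues[-10:], atol=1e-6
        )
        for k in (1, 5, 20):
            _, up = part.mode(k)
            _, uf = full.mode(k)
            # overall sign is solver-dependent when |u| has tied extrema
            dist = min(np.abs(up - uf).max(), np.abs(up + uf).max())
            assert dist < 1e-6


class TestPseudoInverse:
    def test_three_node_path_diagonal(self):
        G = pseudo_inverse(_path_spectrum(3))
        np.testing.assert_allclose(np.diag(G), [5 / 9, 2 / 9, 5 / 9], atol=1e-10)

    def test_matches_generic_pinv_oracle(self, rng):
        for _ in range(5):
            nodes = random_connected_nodes(rng.integers(10, 60), rng)
            g = build_kirchhoff(nodes, 7.3)
            G = pseudo_inverse(decompose(g))
            np.testing.assert_allclose(G, np.linalg.pinv(g.dense(), rcond=1e-10), atol=1e-8)

    def test_gamma_G_gamma_identity(self, rng):
        nodes = random_connected_nodes(35, rng)
        g = build_kirchhoff(nodes, 7.3).dense()
        G = pseudo_inverse(decompose(build_kirchhoff(nodes, 7.3)))
        np.testing.assert_allclose(g @ G @ g, g, atol=1e-8)

    def test_ring_has_constant_diagonal(self):
        n = 20
        th = 2 * np.pi * np.arange(n) / n
        r = 3.8 / (2 * np.sin(np.pi / n))
        nodes = nodeset_from_points(
            np.column_stack([r * np.cos(th), r * np.sin(th), np.zeros(n)])
        )
        G = pseudo_inverse(decompose(build_kirchhoff(nodes, 7.3)))
        d = np.diag(G)
        np.testing.assert_allclose(d, d[0], atol=1e-8)

    def test_disconnected_raises_without_override(self, rng):
        a = rng.uniform(0, 8, size=(5, 3))
        b = rng.uniform(0, 8, size=(5, 3)) + 100.0
        g = build_kirchhoff(nodeset_from_points(np.vstack([a, b])), 7.3)
        sp = decompose(g)
        with pytest.raises(DisconnectedNetworkError):
            pseudo_inverse(sp, gamma=g)
        G = pseudo_inverse(sp, allow_disconnected=True)
        np.testing.assert_allclose(G, np.linalg.pinv(g.dense(), rcond=1e-10), atol=1e-8)


class TestModeContribution:
    def test_rank_one_and_trace(self, rng):
        sp = decompose(build_kirchhoff(random_connected_nodes(25, rng), 7.3))
        C3 = mode_contribution(sp, 3)
        assert np.linalg.matrix_rank(C3, tol=1e-8) == 1
        lam, _ = sp.mode(3)
        assert np.trace(C3) == pytest.approx(1.0 / lam)

    def test_contributions_sum_to_pseudo_inverse(self, rng):
        sp = decompose(build_kirchhoff(random_connected_nodes(30, rng), 7.3))
        total = sum(mode_contribution(sp, k) for k in range(1, sp.n_nonzero + 1))
        np.testing.assert_allclose(total, pseudo_inverse(sp), atol=1e-8)

    def test_softest_mode_dominates(self, rng):
        sp = decompose(build_kirchhoff(random_connected_nodes(30, rng), 7.3))
        traces = [np.trace(mode_contribution(sp, k))
                  for k in range(1, sp.n_nonzero + 1)]
        assert traces[0] == max(traces)

    def test_path3_mode1_contribution(self):
        C1 = mode_contribution(_path_spectrum(3), 1)
        np.testing.assert_allclose(np.diag(C1), [0.5, 0.0, 0.5], atol=1e-10)

    def test_out_of_range_mode(self):
        with pytest.raises(IndexError):
            mode_contribution(_path_spectrum(3), 3)


class TestFluctuations:
    def test_msf_positive_and_additive_over_modes(self, rng):
        sp = decompose(build_kirchhoff(random_connected_nodes(40, rng), 7.3))
        prof = compute_fluctuations(sp)
        assert np.all(prof.msf > 0)
        np.testing.assert_allclose(
            prof.mode_shapes.sum(axis=0), prof.msf, atol=1e-8
        )
        np.testing.assert_allclose(
            prof.msf, np.diag(pseudo_inverse(sp)), atol=1e-10
        )

    def test_symmetry_transfer_in_exact_dimer(self):
        # ladder graph: two paths joined by rungs, swap is an automorphism
        base = path_nodes(8).positions
        pts = np.vstack([base, base + [0.0, 6.0, 0.0]])
        sp = decompose(build_kirchhoff(nodeset_from_points(pts), 7.3))
        msf = compute_fluctuations(sp).msf
        np.testing.assert_allclose(msf[:8], msf[8:], atol=1e-8)

    def test_symmetry_transfer_in_c2_assembly(self, tmp_path):
        # the dimer fixture's second BIOMT operator is a proper 2-fold
        # rotation, so assembly mates are exact symmetry partners
        from gnmkit import fixtures as fx
        from gnmkit.structure import build_assembly, parse_pdb
        from gnmkit.network import select_nodes
        p = tmp_path / "dm.pdb"
        fx.generate(fx.FixtureSpec("dimer_biomt", 25), p)
        nodes = select_nodes(build_assembly(parse_pdb(p), "first_assembly"))
        msf = compute_fluctuations(
            decompose(build_kirchhoff(nodes, 7.3))
        ).msf
        np.testing.assert_allclose(msf[:25], msf[25:], atol=1e-8)


class TestCrossCorrelation:
    def test_diagonal_is_exactly_one(self, rng):
        sp = decompose(build_kirchhoff(random_connected_nodes(20, rng), 7.3))
        cc = cross_correlation(sp, [1, 2])
        np.testing.assert_array_equal(np.diag(cc.values), np.ones(20))
        np.testing.assert_allclose(cc.values, cc.values.T, atol=1e-12)
        assert np.abs(cc.values).max() <= 1.0

    def test_single_mode_subset_gives_sign_pattern(self, rng):
        sp = decompose(build_kirchhoff(random_connected_nodes(20, rng), 7.3))
        _, u = sp.mode(1)
        assert np.all(np.abs(u) > 0)  # generic graph: no exact zeros
        cc = cross_correlation(sp, [1])
        np.testing.assert_allclose(
            cc.values, np.sign(np.outer(u, u)), atol=1e-9
        )

    def test_full_subset_equals_pinv_normalization_oracle(self, rng):
        base = path_nodes(8).positions
        pts = np.vstack([base, base + [0.0, 6.0, 0.0]])
        g = build_kirchhoff(nodeset_from_points(pts), 7.3)
        sp = decompose(g)
        cc = cross_correlation(sp)
        G = np.linalg.pinv(g.dense(), rcond=1e-10)
        d = np.sqrt(np.outer(np.diag(G), np.diag(G)))
        np.testing.assert_allclose(cc.values, G / d, atol=1e-8)

    def test_zero_subset_fluctuation_raises(self):
        # mode 1 of the 3-path has an exact node at the middle residue
        sp = _path_spectrum(3)
        with pytest.raises(UndefinedCorrelationError):
            cross_correlation(sp, [1])

    def test_empty_subset_rejected(self, rng):
        sp = decompose(build_kirchhoff(random_connected_nodes(10, rng), 7.3))
        with pytest.raises(ContractError):
            cross_correlation(sp, [])


class TestCollectivity:
    def test_uniform_mode_reaches_one(self):
        # ring modes come in degenerate pairs with uniform |u| in the pair
        # sum; use a hand-built spectrum for the exact extreme instead
        from gnmkit.spectral import ModeSpectrum
        n = 16
        u = np.full(n, 1 / np.sqrt(n))
        sp = ModeSpectrum(
            eigenvalues=np.array([0.0, 1.0]),
            eigenvectors=np.column_stack([np.ones(n) / np.sqrt(n), u]),
            n_zero_modes=1, n_nodes=n,
        )
        assert collectivity(sp, 1) == pytest.approx(1.0, abs=1e-12)

    def test_delta_mode_reaches_one_over_n(self):
        from gnmkit.spectral import ModeSpectrum
        n = 16
        u = np.zeros(n)
        u[3] = 1.0
        sp = ModeSpectrum(
            eigenvalues=np.array([0.0, 1.0]),
            eigenvectors=np.column_stack([np.ones(n) / np.sqrt(n), u]),
            n_zero_modes=1, n_nodes=n,
        )
        assert collectivity(sp, 1) == pytest.approx(1.0 / n, abs=1e-12)

    def test_half_support_mode(self):
        from gnmkit.spectral import ModeSpectrum
        u = np.array([np.sqrt(0.5), np.sqrt(0.5), 0.0, 0.0])
        sp = ModeSpectrum(
            eigenvalues=np.array([0.0, 1.0]),
            eigenvectors=np.column_stack([np.ones(4) / 2.0, u]),
            n_zero_modes=1, n_nodes=4,
        )
        assert collectivity(sp, 1) == pytest.approx(0.5, abs=1e-12)

    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(5, 40))
    def test_bounds_on_random_graphs(self, seed, n):
        pts = np.random.default_rng(seed).uniform(0, 16, size=(n, 3))
        sp = decompose(build_kirchhoff(nodeset_from_points(pts), 7.3))
        for k in range(1, sp.n_nonzero + 1):
            kap = collectivity(sp, k)
            assert 1 / n - 1e-12 <= kap <= 1 + 1e-12

    def test_table_covers_tenth_of_dynamics(self, rng):
        sp = decompose(build_kirchhoff(random_connected_nodes(40, rng), 7.3))
        tab = collectivity_table(sp, 0.1)
        assert tab.n_soft_reported == soft_mode_count(sp, 0.1)
        assert len(tab.kappa) == tab.n_soft_reported


class TestSoftModeCount:
    def test_equal_eigenvalues_need_one_mode_for_a_tenth(self):
        from gnmkit.spectral import ModeSpectrum
        sp = ModeSpectrum(
            eigenvalues=np.concatenate([[0.0], np.ones(9)]),
            eigenvectors=np.eye(10),
            n_zero_modes=1, n_nodes=10,
        )
        assert soft_mode_count(sp, 0.1) == 1  # 1/9 > 1/10

    def test_fraction_one_takes_whole_spectrum(self, rng):
        sp = decompose(build_kirchhoff(random_connected_nodes(15, rng), 7.3))
        assert soft_mode_count(sp, 1.0) == sp.n_nonzero

    def test_dominant_soft_mode(self):
        from gnmkit.spectral import ModeSpectrum
        sp = ModeSpectrum(
            eigenvalues=np.array([0.0, 1.0, 10.0, 10.0, 10.0]),
            eigenvectors=np.eye(5),
            n_zero_modes=1, n_nodes=5,
        )
        assert soft_mode_count(sp, 0.1) == 1  # 1 >= 0.1 * 1.3


class TestBFactors:
    def test_unit_scale_constant_msf(self):
        from gnmkit.spectral import FluctuationProfile
        prof = FluctuationProfile(
            msf=np.ones(5), mode_shapes=np.ones((1, 5)),
            mode_eigenvalues=np.ones(1),
        )
        b = theoretical_b_factors(prof, "unit")
        np.testing.assert_allclose(b, 8 * np.pi**2 / 3, atol=1e-10)

    def test_fit_recovers_exact_proportionality(self, rng):
        sp = decompose(build_kirchhoff(random_connected_nodes(20, rng), 7.3))
        prof = compute_fluctuations(sp)
        exp = 4.2 * (8 * np.pi**2 / 3) * prof.msf
        b = theoretical_b_factors(prof, "fit", exp)
        np.testing.assert_allclose(b, exp, atol=1e-8)

    def test_correlation_invariant_under_scale_policy(self, rng):
        from gnmkit.analysis import bfactor_correlation
        sp = decompose(build_kirchhoff(random_connected_nodes(20, rng), 7.3))
        prof = compute_fluctuations(sp)
        exp = prof.msf + rng.normal(0, 0.1, 20)
        r_unit = bfactor_correlation(theoretical_b_factors(prof, "unit"), exp)
        r_fit = bfactor_correlation(
            theoretical_b_factors(prof, "fit", exp), exp
        )
        assert r_unit == pytest.approx(r_fit, abs=1e-12)

    def test_fit_without_experimental_raises(self):
        from gnmkit.spectral import FluctuationProfile
        prof = FluctuationProfile(
            msf=np.ones(5), mode_shapes=np.ones((1, 5)),
            mode_eigenvalues=np.ones(1),
        )
        with pytest.raises(MissingDataError):
            theoretical_b_factors(prof, "fit")


class TestGammaInvariance:
    def test_spring_constant_rescales_msf_only(self, rng):
        from gnmkit.network import KirchhoffMatrix
        nodes = random_connected_nodes(25, rng)
        g = build_kirchhoff(nodes, 7.3)
        g2 = KirchhoffMatrix(matrix=g.dense() * 3.5, cutoff_rc=7.3)
        sp1, sp2 = decompose(g), decompose(g2)
        prof1, prof2 = compute_fluctuations(sp1), compute_fluctuations(sp2)
        np.testing.assert_allclose(prof2.msf, prof1.msf / 3.5, atol=1e-10)
        cc1 = cross_correlation(sp1, [1, 2, 3]).values
        cc2 = cross_correlation(sp2, [1, 2, 3]).values
        np.testing.assert_allclose(cc2, cc1, atol=1e-10)
        for k in (1, 2, 5):
            assert collectivity(sp2, k) == pytest.approx(
                collectivity(sp1, k), abs=1e-10
            )
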