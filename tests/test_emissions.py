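"""Emission and HMM-algorithm tests, anchored by brute-force oracles:
pruning vs explicit internal-node enumeration, and forward/posterior vs
exhaustive hidden-path sums on short sequences."""

import itertools

import numpy as np
import pytest

from ilshmm.demography import DemographyParams, coalescent_units
from ilshmm.discretization import default_cutpoints
from ilshmm.emissions import (
    HmmModel,
    MISSING_BASE,
    emission_distribution,
    emission_table,
    forward_loglik,
    jc69_transition,
    _branch_lengths,
)
from ilshmm.transitions import enumerate_hidden_states


class TestJC69:
    def test_zero_time_is_identity(self):
        np.testing.assert_allclose(jc69_transition(0.0), np.eye(4))

    def test_infinite_time_is_uniform(self):
        np.testing.assert_allclose(jc69_transition(1e6), np.full((4, 4), 0.25))

    def test_half_identity_time(self):
        # solve 1/4 + 3/4 e^(-4t/3) = 1/2  ->  t = (3/4) ln 3
        t = 0.75 * np.log(3.0)
        P = jc69_transition(t)
        np.testing.assert_allclose(np.diag(P), 0.5, rtol=1e-12)

    def test_rows_sum_to_one(self):
        for t in (0.0, 0.01, 0.5, 3.0):
            np.testing.assert_allclose(jc69_transition(t).sum(axis=1), 1.0)

    def test_negative_time_raises(self):
        with pytest.raises(ValueError):
            jc69_transition(-0.1)


class TestEmissionDistribution:
    def test_rows_sum_to_one(self, model_params):
        grid = default_cutpoints(2, 2, coalescent_units(model_params).T2)
        E = emission_table(model_params, grid)
        np.testing.assert_allclose(E.sum(axis=1), 1.0, atol=1e-10)
        assert (E >= 0).all()

    def test_vanishing_branches_concentrate_on_constant_patterns(self):
        eps = 1e-12
        p = DemographyParams.ultrametric(
            t_1=eps, t_2=2 * eps, t_upper=eps, N_AB=2 * eps, N_ABC=2 * eps,
            rho_over_mu=0.0,
        )
        grid = default_cutpoints(1, 1, coalescent_units(p).T2)
        for s in enumerate_hidden_states(1, 1):
            v = emission_distribution(s, p, grid)
            constant = [0, 85, 170, 255]  # AAAA, CCCC, GGGG, TTTT
            assert v[constant].sum() == pytest.approx(1.0, abs=1e-6)
            for c in constant:
                assert v[c] == pytest.approx(0.25, abs=1e-6)

    def test_ab_exchange_symmetry_for_species_topology(self, model_params, grid33):
        """With t_A = t_B, swapping the A and B digits of every pattern
        leaves a V0 state's distribution unchanged."""
        s = enumerate_hidden_states(3, 3)[4]
        assert s.topology == "V0"
        v = emission_distribution(s, model_params, grid33).reshape(4, 4, 4, 4)
        np.testing.assert_allclose(v, np.transpose(v, (1, 0, 2, 3)), atol=1e-15)

    def test_pruning_matches_internal_node_enumeration(self, model_params, grid11):
        """Sum over all 4^3 internal-node assignments, done explicitly."""
        for s in enumerate_hidden_states(1, 1):
            pair, la, lb, lc, l1, lr, ld = _branch_lengths(s, model_params, grid11)
            Pa, Pb, Pc = jc69_transition(la), jc69_transition(lb), jc69_transition(lc)
            P1, Pr, Pd = jc69_transition(l1), jc69_transition(lr), jc69_transition(ld)
            brute = np.zeros((4, 4, 4, 4))
            for x, y, r in itertools.product(range(4), repeat=3):
                # x: first coalescence node, y: ingroup root, r: outgroup join
                w = 0.25 * Pr[r, y] * P1[y, x] * Pd[r]
                contrib = (
                    Pa[x][:, None, None, None]
                    * Pb[x][None, :, None, None]
                    * Pc[y][None, None, :, None]
                    * w[None, None, None, :]
                )
                brute += contrib
            if s.topology in ("V0", "V1"):
                want = brute
            elif s.topology == "V2":  # cherry tips are (A, C)
                want = np.transpose(brute, (0, 2, 1, 3))
            else:  # V3: cherry tips are (B, C)
                want = np.transpose(brute, (2, 0, 1, 3))
            got = emission_distribution(s, model_params, grid11).reshape(4, 4, 4, 4)
            np.testing.assert_allclose(got, want, atol=1e-12)


def _brute_force_posterior(model, codes):
    """Exhaustive path sum over hidden-state sequences."""
    E = model.emission
    T, pi = model.transition, model.stationary
    S = len(pi)
    L = len(codes)
    post = np.zeros((L, S))
    total = 0.0
    for path in itertools.product(range(S), repeat=L):
        p = pi[path[0]] * E[path[0], codes[0]]
        for t in range(1, L):
            p *= T[path[t - 1], path[t]] * E[path[t], codes[t]]
        total += p
        for t, s in enumerate(path):
            post[t, s] += p
    return total, post / total


class TestForwardAndPosterior:
    def test_length_one_sequence(self, model11):
        code = np.array([0])
        expect = np.log((model11.stationary * model11.emission[:, 0]).sum())
        assert model11.loglik(code) == pytest.approx(expect, rel=1e-12)

    def test_forward_matches_path_enumeration(self, model11):
        codes = np.array([0, 17, 255])
        total, _ = _brute_force_posterior(model11, codes)
        assert model11.loglik(codes) == pytest.approx(np.log(total), rel=1e-10)

    def test_posterior_matches_path_enumeration(self, model11):
        codes = np.array([0, 17, 255, 3])
        _, brute = _brute_force_posterior(model11, codes)
        track = model11.posterior(codes)
        np.testing.assert_allclose(track.posterior, brute, atol=1e-10)

    def test_posterior_rows_sum_to_one(self, decoded100kb):
        np.testing.assert_allclose(
            decoded100kb.posterior.sum(axis=1), 1.0, atol=1e-9
        )

    def test_modal_topology_recovers_truth_on_simulated_data(
        self, decoded100kb, sim100kb
    ):
        modal = decoded100kb.topology.argmax(axis=1)
        assert (modal == sim100kb.topology).mean() > 0.5

    def test_all_missing_sequence_has_zero_loglik(self, model11):
        codes = np.full(5, MISSING_BASE)  # mask 0: nothing observed
        assert model11.loglik(codes) == pytest.approx(0.0, abs=1e-12)

    def test_empty_sequence_warns_and_returns_zero(self, model11):
        with pytest.warns(UserWarning):
            assert model11.loglik(np.array([], dtype=int)) == 0.0

    def test_missing_data_marginalisation(self, model11):
        """A column with D missing scores the D-marginalised emission."""
        full = np.arange(4)  # patterns 0..3 differ only in the D base
        marg_code = MISSING_BASE + 7 * 256 + 0  # mask 0b0111: A,B,C present
        ll_marg = model11.loglik(np.array([marg_code]))
        probs = [
            np.exp(model11.loglik(np.array([c]))) for c in full
        ]
        assert ll_marg == pytest.approx(np.log(sum(probs)), rel=1e-10)

    def test_label_swap_invariance(self, model_params, grid33, sim100kb):
        """Relabelling A<->B (swap digits, V2<->V3) leaves the likelihood
        unchanged when t_A = t_B."""
        model = HmmModel(model_params, grid33)
        codes = sim100kb.codes()[:2000]
        a = (codes // 64) % 4
        b = (codes // 16) % 4
        swapped = codes - a * 64 - b * 16 + b * 64 + a * 16
        keep = codes < 256
        assert keep.all()
        ll = model.loglik(codes)
        ll_sw = model.loglik(swapped)
        assert ll_sw == pytest.approx(ll, abs=1e-6)


class TestGroupedTracks:
    def test_groupings_partition_the_posterior(self, decoded100kb):
        np.testing.assert_allclose(decoded100kb.topology.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(decoded100kb.first.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(decoded100kb.second.sum(axis=1), 1.0, atol=1e-9)

    def test_grouped_shapes(self, decoded100kb, grid33):
        assert decoded100kb.topology.shape[1] == 4
        assert decoded100kb.first.shape[1] == grid33.n_ab + grid33.n_abc
        assert decoded100kb.second.shape[1] == grid33.n_abc
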