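"""Transition-probability tests: hidden-state bookkeeping, closed-form
marginal laws and structural properties of the joint genealogy matrix."""

import numpy as np
import pytest

from ilshmm.demography import coalescent_units
from ilshmm.discretization import (
    default_cutpoints,
    phase_type_cdf,
    second_coalescent_phase_type,
)
from ilshmm.transitions import (
    HiddenState,
    classify_genealogy,
    enumerate_hidden_states,
    hidden_state_index,
    joint_genealogy_probabilities,
    topology_label,
    transition_matrix,
)


class TestHiddenStates:
    @pytest.mark.parametrize(
        "n_ab,n_abc,count", [(3, 3, 27), (1, 1, 4), (5, 5, 70), (2, 4, 38)]
    )
    def test_counts_match_formula(self, n_ab, n_abc, count):
        states = enumerate_hidden_states(n_ab, n_abc)
        assert len(states) == count
        assert len(states) == n_ab * n_abc + 3 * n_abc * (n_abc + 1) // 2

    def test_one_interval_grid_has_one_state_per_topology(self):
        states = enumerate_hidden_states(1, 1)
        assert [s.topology for s in states] == ["V0", "V1", "V2", "V3"]

    @pytest.mark.parametrize("n_ab,n_abc", [(1, 1), (3, 3), (2, 5)])
    def test_index_function_matches_enumeration(self, n_ab, n_abc):
        for pos, s in enumerate(enumerate_hidden_states(n_ab, n_abc)):
            assert hidden_state_index(s, n_ab, n_abc) == pos

    def test_deep_states_require_ordered_intervals(self):
        with pytest.raises(ValueError):
            HiddenState("V2", first=3, second=2)


class TestJointMatrix:
    def test_no_recombination_is_diagonal(self, model_params, grid33):
        J = joint_genealogy_probabilities(
            model_params.replace(rho_over_mu=0.0), grid33
        )
        off = J.matrix - np.diag(np.diag(J.matrix))
        assert np.abs(off).max() == 0.0

    def test_total_mass_and_symmetry(self, model_params, grid33):
        J = joint_genealogy_probabilities(model_params, grid33)
        assert J.matrix.sum() == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(J.matrix, J.matrix.T, atol=1e-15)
        assert (J.matrix >= 0).all()

    def test_rows_sum_to_one_and_stationarity(self, model_params, grid33):
        J = joint_genealogy_probabilities(model_params, grid33)
        T, pi = transition_matrix(J)
        np.testing.assert_allclose(T.sum(axis=1), 1.0, atol=1e-10)
        np.testing.assert_allclose(pi @ T, pi, atol=1e-12)
        assert pi.sum() == pytest.approx(1.0, abs=1e-10)

    def test_no_recombination_gives_identity_transitions(self, model_params, grid33):
        J = joint_genealogy_probabilities(
            model_params.replace(rho_over_mu=0.0), grid33
        )
        T, _ = transition_matrix(J)
        np.testing.assert_allclose(T, np.eye(len(J.states)), atol=1e-12)

    def test_topology_marginals_match_closed_forms(self, model_params, grid33):
        """V0 mass is 1 - e^-T2; each discordant topology carries
        e^-T2 / 3, so total ILS is (2/3) e^-T2."""
        J = joint_genealogy_probabilities(model_params, grid33)
        _, pi = transition_matrix(J)
        mass = {t: 0.0 for t in ("V0", "V1", "V2", "V3")}
        for s, m in zip(J.states, pi):
            mass[s.topology] += m
        T2 = coalescent_units(model_params).T2
        assert mass["V0"] == pytest.approx(1 - np.exp(-T2), abs=1e-10)
        assert mass["V2"] == pytest.approx(np.exp(-T2) / 3, abs=1e-10)
        assert mass["V3"] == pytest.approx(np.exp(-T2) / 3, abs=1e-10)
        assert mass["V2"] + mass["V3"] == pytest.approx(
            (2 / 3) * np.exp(-T2), abs=1e-10
        )

    def test_first_coalescent_follows_truncated_exponential(
        self, model_params, grid33
    ):
        J = joint_genealogy_probabilities(model_params, grid33)
        _, pi = transition_matrix(J)
        ab_mass = np.zeros(grid33.n_ab)
        for s, m in zip(J.states, pi):
            if s.topology == "V0":
                ab_mass[s.first - 1] += m
        expected = np.exp(-grid33.ab[:-1]) - np.exp(-grid33.ab[1:])
        np.testing.assert_allclose(ab_mass, expected, atol=1e-10)

    def test_second_coalescent_matches_phase_type_cdf(self, model_params, grid33):
        """Hidden-state marginals reproduce the phase-type (S, pi) law of
        the second coalescent at every cutpoint."""
        J = joint_genealogy_probabilities(model_params, grid33)
        _, pi = transition_matrix(J)
        by_second = np.zeros(grid33.n_abc)
        for s, m in zip(J.states, pi):
            by_second[s.second - 1] += m
        T2 = coalescent_units(model_params).T2
        S, piv = second_coalescent_phase_type(T2)
        model_cdf = np.cumsum(by_second)
        target = phase_type_cdf(grid33.abc[1:], S, piv)
        np.testing.assert_allclose(model_cdf, target, atol=1e-6)

    def test_off_diagonal_mass_increases_with_recombination(
        self, model_params, grid33
    ):
        masses = []
        for rho in (0.05, 0.2, 0.8):
            J = joint_genealogy_probabilities(
                model_params.replace(rho_over_mu=rho), grid33
            )
            T, _ = transition_matrix(J)
            masses.append(1.0 - np.diag(T).mean())
        assert masses[0] < masses[1] < masses[2]

    def test_grid_epoch_mismatch_raises(self, model_params):
        bad = default_cutpoints(2, 2, T2=coalescent_units(model_params).T2 * 2)
        with pytest.raises(ValueError):
            joint_genealogy_probabilities(model_params, bad)


def test_transition_tsv_export(tmp_path, model_params, grid33):
    from ilshmm.transitions import write_transition_tsv

    J = joint_genealogy_probabilities(model_params, grid33)
    T, pi = transition_matrix(J)
    out = tmp_path / "T.tsv"
    write_transition_tsv(T, pi, J.states, out)
    lines = out.read_text().splitlines()
    assert len(lines) == len(J.states) + 1
    assert lines[0].split("\t")[2] == J.states[0].label()


def test_state_list_tsv_export(tmp_path):
    from ilshmm.state_spaces import write_states_tsv

    out = tmp_path / "states2.tsv"
    write_states_tsv(2, out)
    lines = out.read_text().splitlines()
    assert len(lines) == 16  # header + 15 states
    assert sum(line.endswith("\t1") for line in lines[1:]) == 2  # absorbing


class TestClassification:
    def test_topology_labels(self, sim_params):
        t_split2 = sim_params.t_A + sim_params.t_2
        assert topology_label((0, 1), t_split2 - 1.0, sim_params) == "V0"
        assert topology_label((0, 1), t_split2 + 1.0, sim_params) == "V1"
        assert topology_label((0, 2), t_split2 + 1.0, sim_params) == "V2"
        assert topology_label((1, 2), t_split2 + 1.0, sim_params) == "V3"

    def test_interval_assignment(self, sim_params):
        cu = coalescent_units(sim_params)
        grid = default_cutpoints(2, 3, cu.T2)
        t1 = sim_params.t_A
        t2 = t1 + sim_params.t_2
        h = classify_genealogy(
            (0, 1), t1 + 0.01 * cu.ab_scale, t2 + 0.01 * cu.abc_scale,
            sim_params, grid,
        )
        assert (h.topology, h.first, h.second) == ("V0", 1, 1)
        deep = t2 + 50.0 * cu.abc_scale  # far tail -> last interval
        h = classify_genealogy((1, 2), deep, deep + 1.0, sim_params, grid)
        assert (h.topology, h.first, h.second) == ("V3", 3, 3)
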