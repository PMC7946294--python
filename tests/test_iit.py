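"""Repertoires, mechanism phi, concepts, cuts and system-level Phi."""

import numpy as np
import pytest

import oracle
import iistruct as ii
from iistruct.iit import (
    CAUSE,
    EFFECT,
    apply_cut,
    big_phi_and_phis,
    cause_repertoire,
    ces_distance,
    compute_big_phi,
    compute_ces,
    concept,
    core_repertoire,
    effect_repertoire,
    enumerate_cuts,
    phi_mip,
)


def _swap_tpm():
    """Deterministic 2-node swap: A' = B, B' = A."""
    probs = np.zeros((4, 2))
    for s in range(4):
        probs[s, 0] = (s >> 1) & 1
        probs[s, 1] = s & 1
    return ii.StateByNodeTPM(probs, n_nodes=2)


def _flat_tpm(n):
    return ii.StateByNodeTPM(np.full((2**n, n), 0.5), n_nodes=n)


class TestRepertoires:
    def test_flat_tpm_gives_uniform_repertoires(self):
        tpm = _flat_tpm(3)
        er = effect_repertoire(tpm, (0,), (1,), (0, 1))
        cr = cause_repertoire(tpm, (0, 2), (1, 0), (1,))
        assert np.allclose(er.probs, 0.25)
        assert np.allclose(cr.probs, 0.5)

    def test_deterministic_swap_effect_is_a_point_mass(self):
        tpm = _swap_tpm()
        rep = effect_repertoire(tpm, (1,), (1,), (0,))  # B='1' -> A'=1
        assert np.allclose(rep.probs, [0.0, 1.0])

    def test_deterministic_swap_cause_inverts_the_copy(self):
        tpm = _swap_tpm()
        rep = cause_repertoire(tpm, (0,), (1,), (1,))  # A='1' <- B was 1
        assert np.allclose(rep.probs, [0.0, 1.0])

    def test_repertoires_match_bruteforce_enumeration(self, random_tpm):
        tpm = random_tpm(3, seed=21)
        bits = (1, 0, 1)
        for mmask in range(1, 8):
            mech = tuple(i for i in range(3) if (mmask >> i) & 1)
            mstate = tuple(bits[i] for i in mech)
            for pmask in range(1, 8):
                purv = tuple(i for i in range(3) if (pmask >> i) & 1)
                er = effect_repertoire(tpm, mech, mstate, purv)
                assert np.allclose(
                    er.probs,
                    oracle.effect_rep(tpm.probs, 3, mech, mstate, purv),
                    atol=1e-12,
                )
                cr = cause_repertoire(tpm, mech, mstate, purv)
                assert np.allclose(
                    cr.probs,
                    oracle.cause_rep(tpm.probs, 3, mech, mstate, purv),
                    atol=1e-12,
                )

    def test_normalization_and_support(self, random_tpm):
        tpm = random_tpm(4, seed=3)
        rep = cause_repertoire(tpm, (0, 3), (1, 1), (1, 2))
        assert rep.probs.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(rep.probs >= 0)

    def test_out_of_system_node_rejected(self, random_tpm):
        tpm = random_tpm(2, seed=0)
        with pytest.raises(IndexError):
            effect_repertoire(tpm, (0,), (1,), (2,))


class TestPhiMip:
    def test_factorizing_mechanism_is_reducible(self):
        # two independent nodes: any cross-partition changes nothing
        p1 = ii.make_recurrent_tpm(1, 2.0, seed=1).probs
        p2 = ii.make_recurrent_tpm(1, 2.0, seed=2).probs
        probs = np.zeros((4, 2))
        for s in range(4):
            probs[s, 0] = p1[s & 1, 0]
            probs[s, 1] = p2[(s >> 1) & 1, 0]
        tpm = ii.StateByNodeTPM(probs, n_nodes=2)
        phi, _ = phi_mip(tpm, (0, 1), (0, 1), (0, 1), EFFECT)
        assert phi == pytest.approx(0.0, abs=1e-12)

    def test_minimal_disconnection_severs_the_weak_cross_link(
        self, self_coupled_2node
    ):
        """With strong self- and weak cross-coupling, noising A->B hurts least."""
        phi, part = phi_mip(self_coupled_2node, (0,), (0,), (0, 1), EFFECT)
        assert phi > 0
        # the minimal partition leaves A over A intact and noises B
        assert part.part1 == ((0,), (0,)) and part.part2 == ((), (1,))

    def test_matches_oracle_over_random_systems(self, random_tpm):
        for seed in (31, 32):
            tpm = random_tpm(3, seed=seed)
            bits = (0, 1, 1)
            for mech, purv in [((0,), (0, 1)), ((0, 2), (1, 2)), ((0, 1, 2), (0, 1, 2))]:
                mstate = tuple(bits[i] for i in mech)
                for direction in (CAUSE, EFFECT):
                    got, _ = phi_mip(tpm, mech, mstate, purv, direction)
                    want = oracle.phi_mip(
                        tpm.probs, 3, mech, mstate, purv, direction
                    )
                    assert got == pytest.approx(want, abs=1e-6)


class TestConcepts:
    def test_source_mechanism_specifies_no_cause(self):
        """A coin-flip node takes no inputs, so its cause side is zero."""
        tpm = ii.make_feedforward_tpm(3, 0.9)
        core = core_repertoire(tpm, (0,), (1,), CAUSE)
        assert core.phi == pytest.approx(0.0, abs=1e-12)

    def test_sink_mechanism_specifies_no_effect(self):
        """The chain's last node feeds nothing, so its effect side is zero."""
        tpm = ii.make_feedforward_tpm(3, 0.9)
        core = core_repertoire(tpm, (2,), (0,), EFFECT)
        assert core.phi == pytest.approx(0.0, abs=1e-12)

    def test_core_effect_prefers_the_strong_self_purview(
        self, self_coupled_2node
    ):
        core = core_repertoire(self_coupled_2node, (0,), (0,), EFFECT)
        assert core.purview == (0,)

    def test_phi_is_min_of_cause_and_effect(self, random_tpm):
        tpm = random_tpm(3, seed=8)
        c = concept(tpm, (0, 1), (1, 1, 0))
        assert c.phi == pytest.approx(
            min(c.core_cause.phi, c.core_effect.phi)
        )

    def test_flat_tpm_has_all_zero_concepts(self):
        ces = compute_ces(_flat_tpm(3), (0, 0, 0))
        assert np.allclose(ces.phis(), 0.0)

    def test_core_selection_matches_oracle(self, random_tpm):
        tpm = random_tpm(3, seed=40)
        bits = (1, 1, 0)
        for mech in [(0,), (1, 2), (0, 1, 2)]:
            mstate = tuple(bits[i] for i in mech)
            for direction in (CAUSE, EFFECT):
                got = core_repertoire(tpm, mech, mstate, direction)
                want_phi, _ = oracle.core(
                    tpm.probs, 3, mech, mstate, direction
                )
                assert got.phi == pytest.approx(want_phi, abs=1e-6)


class TestCauseEffectStructure:
    def test_four_node_census(self, random_tpm):
        ces = compute_ces(random_tpm(4, seed=5), (0, 1, 0, 1))
        assert len(ces.concepts) == 15
        sizes = [len(c.mechanism) for c in ces.concepts]
        assert [sizes.count(k) for k in (1, 2, 3, 4)] == [4, 6, 4, 1]

    def test_identical_structures_are_at_zero_distance(self, random_tpm):
        tpm = random_tpm(3, seed=6)
        a = compute_ces(tpm, (1, 0, 0))
        b = compute_ces(tpm, (1, 0, 0))
        assert ces_distance(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_distance_matches_independent_formula(self, random_tpm):
        tpm = random_tpm(3, seed=61)
        state = (0, 1, 1)
        cut = enumerate_cuts(3)[2]
        full_ces = compute_ces(tpm, state)
        cut_ces = compute_ces(apply_cut(tpm, cut), state)
        cut_ces.label = "cut"
        got = ces_distance(full_ces, cut_ces)
        o_full = oracle.ces(tpm.probs, 3, np.array(state))
        o_cut = oracle.ces(
            oracle.apply_cut(tpm.probs, 3, cut.from_part), 3, np.array(state)
        )
        want = oracle.ces_distance_full(o_full, o_cut, 3, tpm.probs)
        assert got == pytest.approx(want, abs=1e-6)

    def test_census_mismatch_rejected(self, random_tpm):
        a = compute_ces(random_tpm(2, seed=1), (0, 0))
        b = compute_ces(random_tpm(3, seed=1), (0, 0, 0))
        with pytest.raises(ValueError):
            ces_distance(a, b)


class TestCuts:
    def test_cut_counts(self):
        assert len(enumerate_cuts(2)) == 2
        assert len(enumerate_cuts(4)) == 14

    def test_cut_parts_partition_the_node_set(self):
        for cut in enumerate_cuts(4):
            assert sorted(cut.from_part + cut.to_part) == [0, 1, 2, 3]
            assert cut.from_part and cut.to_part

    def test_single_node_system_rejected(self):
        with pytest.raises(ValueError):
            enumerate_cuts(1)

    def test_cutting_a_nonexistent_connection_changes_nothing(self):
        """Severing feedback in a feedforward chain is a no-op."""
        tpm = ii.make_feedforward_tpm(3, 0.8)
        # downstream -> upstream influences do not exist
        cut = ii.SystemCut(from_part=(2,), to_part=(0, 1))
        assert np.allclose(apply_cut(tpm, cut).probs, tpm.probs, atol=1e-15)

    def test_cut_is_idempotent(self, random_tpm):
        tpm = random_tpm(3, seed=13)
        cut = ii.SystemCut(from_part=(0, 2), to_part=(1,))
        once = apply_cut(tpm, cut)
        twice = apply_cut(once, cut)
        assert np.allclose(once.probs, twice.probs, atol=1e-15)

    def test_cut_matches_explicit_averaging_oracle(self, random_tpm):
        tpm = random_tpm(3, seed=17)
        for cut in enumerate_cuts(3):
            got = apply_cut(tpm, cut).probs
            want = oracle.apply_cut(tpm.probs, 3, cut.from_part)
            assert np.allclose(got, want, atol=1e-12)


class TestBigPhi:
    def test_feedforward_system_has_zero_big_phi(self):
        tpm = ii.make_feedforward_tpm(3, 0.85)
        for s in range(8):
            res = compute_big_phi(tpm, (s >> np.arange(3)) & 1)
            assert res.big_phi == pytest.approx(0.0, abs=1e-9)

    def test_independent_subsystems_have_zero_big_phi(self):
        p1 = ii.make_recurrent_tpm(2, 1.5, seed=1).probs
        p2 = ii.make_recurrent_tpm(2, 1.5, seed=2).probs
        probs = np.zeros((16, 4))
        for s in range(16):
            probs[s, :2] = p1[s & 3]
            probs[s, 2:] = p2[(s >> 2) & 3]
        tpm = ii.StateByNodeTPM(probs, n_nodes=4)
        bp, _ = big_phi_and_phis(tpm, (1, 0, 1, 1))
        assert bp == pytest.approx(0.0, abs=1e-9)

    def test_recurrent_system_is_irreducible_and_matches_oracle(
        self, random_tpm
    ):
        tpm = ii.make_recurrent_tpm(3, 2.0, seed=19)
        state = (1, 1, 0)
        res = compute_big_phi(tpm, state)
        assert res.big_phi > 0
        assert res.big_phi == pytest.approx(
            oracle.big_phi(tpm.probs, 3, np.array(state)), abs=1e-6
        )

    def test_stronger_coupling_gives_more_integration(self):
        """State-averaged Phi grows with the logistic coupling strength."""
        means = []
        for coupling in (0.2, 2.0):
            tpm = ii.make_recurrent_tpm(4, coupling, seed=7)
            vals = [
                big_phi_and_phis(tpm, (s >> np.arange(4)) & 1)[0]
                for s in range(16)
            ]
            means.append(np.mean(vals))
        assert means[1] > means[0]

    def test_big_phi_is_the_minimum_over_explicit_cut_distances(self):
        """Phi equals the smallest CES distance over all unidirectional
        cuts, and ties go to the first cut in enumeration order."""
        probs = np.zeros((4, 2))
        for s in range(4):
            a, b = s & 1, (s >> 1) & 1
            probs[s, 0] = 0.5 + 0.02 * (2 * b - 1)  # B barely drives A
            probs[s, 1] = 0.1 + 0.8 * a  # A strongly drives B
        tpm = ii.StateByNodeTPM(probs, n_nodes=2)
        state = (0, 0)
        res = compute_big_phi(tpm, state)
        full_ces = compute_ces(tpm, state)
        dists = []
        for cut in enumerate_cuts(2):
            cut_ces = compute_ces(apply_cut(tpm, cut), state)
            dists.append(ces_distance(full_ces, cut_ces))
        assert res.big_phi > 0
        assert res.big_phi == pytest.approx(min(dists), abs=1e-12)
        # both cuts tie in this symmetric-phi system: first one wins
        assert dists[0] == pytest.approx(dists[1], abs=1e-12)
        assert res.minimal_cut.from_part == (0,)
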