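"""Point-charge Coulomb engine and the deletion scan."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dipolescan.electro import (
    COULOMB_K,
    coulomb,
    deletion_scan,
    read_scan_tsv,
    state_interaction,
    write_scan_tsv,
)
from dipolescan.structio import AtomRecord, QMRegion, ReactionStatePair, Structure
from dipolescan.synthgen import ToyEnzymeSpec, make_toy_enzyme, toy_ncs_spec

from _oracles import naive_coulomb, naive_deletion_scan, random_pair


def _atom(serial, name, resname, resid, x, y, z, q, chain="A"):
    return AtomRecord(serial, name, resname, resid, chain, x, y, z, q, 1.5)


class TestCoulomb:
    def test_unit_charges_give_minus_hundred(self):
        a = (np.array([[0.0, 0.0, 0.0]]), np.array([1.0]))
        b = (np.array([[3.320637, 0.0, 0.0]]), np.array([-1.0]))
        assert coulomb(a, b) == pytest.approx(-100.0, abs=1e-9)

    def test_zero_charge_group_gives_exactly_zero(self):
        rng = np.random.default_rng(0)
        a = (rng.normal(size=(5, 3)), rng.normal(size=5))
        b = (rng.normal(size=(4, 3)) + 10.0, np.zeros(4))
        assert coulomb(a, b) == 0.0

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(1)
        a = (rng.normal(size=(6, 3)), rng.normal(size=6))
        b = (rng.normal(size=(7, 3)) + 8.0, rng.normal(size=7))
        assert coulomb(a, b) == pytest.approx(coulomb(b, a), abs=1e-12)

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(3)
        a = (rng.uniform(-3, 3, size=(10, 3)), rng.uniform(-1, 1, size=10))
        b = (rng.uniform(-3, 3, size=(10, 3)) + 12.0, rng.uniform(-1, 1, size=10))
        assert coulomb(a, b) == pytest.approx(naive_coulomb(a, b), abs=1e-9)

    def test_overlapping_atoms_error_names_pair(self):
        a = (np.array([[0.0, 0.0, 0.0], [5.0, 0.0, 0.0]]), np.array([1.0, 1.0]))
        b = (np.array([[5.0, 0.0, 0.0]]), np.array([-1.0]))
        with pytest.raises(ValueError, match="atom 1 and group B atom 0"):
            coulomb(a, b)

    def test_uniform_dielectric_scales_energy(self):
        a = (np.array([[0.0, 0.0, 0.0]]), np.array([1.0]))
        b = (np.array([[4.0, 0.0, 0.0]]), np.array([-1.0]))
        assert coulomb(a, b, epsilon=4.0) == pytest.approx(coulomb(a, b) / 4.0)


def _exchange_pair(probe_q=1.0, r_donor=6.0, r_acceptor=6.0):
    """Donor/acceptor that exchange −1e between states; one probe residue."""
    qm_atoms = [_atom(1, "OX", "QIN", 900, -2.0, 0.0, 0.0, 0.0),
                _atom(2, "OE1", "GLU", 109, 2.0, 0.0, 0.0, -1.0)]
    # place probe so its distances to donor/acceptor are as requested
    # (donor at (-2,0,0), acceptor at (2,0,0)): solve on the x/y plane
    d2, a2 = r_donor ** 2, r_acceptor ** 2
    x = (d2 - a2) / 8.0
    y = np.sqrt(max(d2 - (x + 2.0) ** 2, 0.0))
    probe = _atom(3, "NZ", "LYS", 5, x, y, 0.0, probe_q)
    s = Structure(qm_atoms + [probe])
    qm = QMRegion([0, 1], np.array([0.0, -1.0]), np.array([-1.0, 0.0]))
    return ReactionStatePair(s, Structure(list(s.atoms)), qm)


class TestStateInteraction:
    def test_zero_charge_residue_gives_zero_both_states(self):
        pair = _exchange_pair(probe_q=0.0)
        ie = state_interaction(pair, ("A", 5, "LYS"))
        assert ie.V_R == 0.0 and ie.V_TS == 0.0

    def test_equidistant_probe_sees_identical_states_under_exchange(self):
        pair = _exchange_pair(probe_q=1.0, r_donor=6.0, r_acceptor=6.0)
        ie = state_interaction(pair, ("A", 5, "LYS"))
        assert ie.V_R == pytest.approx(ie.V_TS, abs=1e-9)

    def test_qm_overlap_rejected(self):
        pair = _exchange_pair()
        with pytest.raises(ValueError, match="overlaps the QM region"):
            state_interaction(pair, ("A", 900, "QIN"))

    def test_planted_residue_matches_ground_truth(self, toy_fixture):
        gt = toy_fixture.ground_truth.per_residue
        for key in [("A", 64, "ASP"), ("A", 105, "ARG")]:
            ie = state_interaction(toy_fixture.pair, key)
            assert ie.V_R == pytest.approx(gt[key]["V_R"], abs=1e-9)
            assert ie.V_TS == pytest.approx(gt[key]["V_TS"], abs=1e-9)


class TestDeletionScan:
    def test_neutral_residue_classified_neutral(self):
        pair = _exchange_pair(probe_q=0.0)
        (res,) = deletion_scan(pair, dE_wt=10.6, eligible=[("A", 5, "LYS")])
        assert res.ddE == 0.0
        assert res.effect_class == "neutral"
        assert res.dE_m == pytest.approx(10.6)

    def test_hand_evaluated_four_term_example(self):
        # +1e probe 4 Å from the acceptor and 10 Å from the donor;
        # acceptor -1e -> -0.5e, donor 0 -> -0.5e between R and TS.
        # V_R = k*(-1/4); V_TS = k*(-0.5/4 - 0.5/10); ddE = -(V_TS - V_R)
        qm_atoms = [_atom(1, "OX", "QIN", 900, 0.0, 0.0, 0.0, 0.0),
                    _atom(2, "OE1", "GLU", 109, 6.0, 0.0, 0.0, -1.0)]
        probe = _atom(3, "NZ", "LYS", 5, 10.0, 0.0, 0.0, 1.0)
        s = Structure(qm_atoms + [probe])
        qm = QMRegion([0, 1], np.array([0.0, -1.0]), np.array([-0.5, -0.5]))
        pair = ReactionStatePair(s, Structure(list(s.atoms)), qm)
        (res,) = deletion_scan(pair, dE_wt=10.6, eligible=[("A", 5, "LYS")])
        expected = -(COULOMB_K * (-0.5 / 4.0 - 0.5 / 10.0) - COULOMB_K * (-1.0 / 4.0))
        assert expected == pytest.approx(-24.9047775)
        assert res.ddE == pytest.approx(expected, abs=1e-9)
        assert res.effect_class == "anticatalytic"

    def test_matches_ground_truth_everywhere(self, toy_fixture):
        gt = toy_fixture.ground_truth.per_residue
        results = deletion_scan(toy_fixture.pair, eligible=sorted(gt))
        for r in results:
            assert r.ddE == pytest.approx(gt[r.residue_key]["ddE"], abs=1e-9)

    def test_additivity_of_per_residue_contributions(self, toy_fixture):
        pair = toy_fixture.pair
        gt_keys = sorted(toy_fixture.ground_truth.per_residue)
        results = deletion_scan(pair, eligible=gt_keys)
        qm_idx = set(pair.qm.atom_indices)
        env_idx = [i for i in range(len(pair.reactant))
                   if i not in qm_idx]
        coords = pair.reactant.coords
        v_r = coulomb((coords[env_idx], pair.reactant.charges[env_idx]),
                      (coords[list(pair.qm.atom_indices)], pair.qm.charges_R))
        t_coords = pair.transition_state.coords
        v_ts = coulomb((t_coords[env_idx], pair.transition_state.charges[env_idx]),
                       (t_coords[list(pair.qm.atom_indices)], pair.qm.charges_TS))
        assert sum(r.ddE for r in results) == pytest.approx(-(v_ts - v_r), abs=1e-9)

    def test_results_sorted_ascending_by_ddE(self, toy_fixture):
        results = deletion_scan(toy_fixture.pair,
                                eligible=sorted(toy_fixture.ground_truth.per_residue))
        values = [r.ddE for r in results]
        assert values == sorted(values)

    def test_strict_threshold_classification(self):
        pair = _exchange_pair(probe_q=0.0)
        (res,) = deletion_scan(pair, eligible=[("A", 5, "LYS")], threshold=0.0)
        assert res.effect_class == "neutral"  # ddE == 0 is not > 0 strictly

    def test_tsv_round_trip_full_precision(self, toy_fixture, tmp_path):
        results = deletion_scan(toy_fixture.pair,
                                eligible=sorted(toy_fixture.ground_truth.per_residue))
        path = tmp_path / "scan.tsv"
        write_scan_tsv(results, path, header=["test"])
        back = read_scan_tsv(path)
        assert back == results


class TestScanProperties:
    def test_oracle_equivalence_on_random_fixtures(self):
        rng = np.random.default_rng(2024)
        for _ in range(10):
            pair = random_pair(rng, n_residues=int(rng.integers(5, 20)))
            eligible = sorted({a.residue_key for a in pair.reactant.atoms
                               if a.residue_key[1] != 900})
            expected = naive_deletion_scan(pair, eligible)
            for r in deletion_scan(pair, eligible=eligible):
                assert r.ddE == pytest.approx(expected[r.residue_key], abs=1e-9)

    @settings(max_examples=20, derandomize=True)
    @given(lam=st.floats(0.0, 1.0), seed=st.integers(0, 10_000))
    def test_lambda_linearity(self, lam, seed):
        """With rigid geometry, every ΔΔE is linear in the transfer fraction."""
        spec_ref = ToyEnzymeSpec(n_env_residues=5, transfer_fraction=1.0, seed=seed)
        spec_lam = ToyEnzymeSpec(n_env_residues=5, transfer_fraction=lam, seed=seed)
        ref = make_toy_enzyme(spec_ref).ground_truth.per_residue
        got = make_toy_enzyme(spec_lam).ground_truth.per_residue
        for key, info in got.items():
            assert info["ddE"] == pytest.approx(lam * ref[key]["ddE"], abs=1e-9)

    def test_geometry_scaling_inverse_in_s(self):
        pair = _exchange_pair(probe_q=1.0, r_donor=8.0, r_acceptor=5.0)
        (base,) = deletion_scan(pair, eligible=[("A", 5, "LYS")])
        s = 2.5

        def scaled(structure):
            return Structure([
                AtomRecord(a.serial, a.atom_name, a.residue_name, a.residue_id,
                           a.chain_id, a.x * s, a.y * s, a.z * s, a.charge, a.radius)
                for a in structure.atoms
            ])

        scaled_pair = ReactionStatePair(scaled(pair.reactant),
                                        scaled(pair.transition_state), pair.qm)
        (res,) = deletion_scan(scaled_pair, eligible=[("A", 5, "LYS")])
        assert res.ddE == pytest.approx(base.ddE / s, abs=1e-9)

    @settings(max_examples=40, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_macrodipole_sign_law(self, seed):
        """A positive probe nearer the acceptor is anticatalytic, and its
        effect weakens monotonically as it retreats along the dipole axis."""
        rng = np.random.default_rng(seed)
        sep = rng.uniform(2.0, 6.0)
        q = rng.uniform(0.1, 1.5)
        start = rng.uniform(3.0, 8.0)
        lam = rng.uniform(0.1, 1.0)
        magnitudes = []
        for step in range(4):
            d_acc = start + 4.0 * step
            qm_atoms = [_atom(1, "OX", "QIN", 900, -sep / 2, 0.0, 0.0, 0.0),
                        _atom(2, "OE1", "GLU", 109, sep / 2, 0.0, 0.0, -1.0)]
            probe = _atom(3, "NZ", "LYS", 5, sep / 2 + d_acc, 0.0, 0.0, q)
            s = Structure(qm_atoms + [probe])
            qm = QMRegion([0, 1], np.array([0.0, -1.0]), np.array([-lam, -1.0 + lam]))
            pair = ReactionStatePair(s, Structure(list(s.atoms)), qm)
            (res,) = deletion_scan(pair, eligible=[("A", 5, "LYS")])
            assert res.ddE < 0
            magnitudes.append(abs(res.ddE))
        assert all(a > b for a, b in zip(magnitudes, magnitudes[1:]))
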