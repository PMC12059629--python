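"""Potential profiles, the DeltaP imbalance, turn-off scans, and PCA."""

import numpy as np
import pytest

from pocketquench import synthetic_data as sd
from pocketquench.core_model import partition
from pocketquench.pocket_electrostatics import (
    PotentialProfile,
    delta_p,
    pca_potentials,
    potential_on_atoms,
    turn_off_scan,
)
from pocketquench.state_mixing import MixingParameters
from pocketquench.tresp import SingularityError

from conftest import toy_model


class TestPotential:
    def test_single_unit_charge_coulomb_definition(self):
        model = toy_model([[0, 0, 0], [1.4, 0, 0]], [([0.0, 1.0, 0.0], 1.0, "SER")])
        prof = potential_on_atoms(model, model.chromophores[0])
        assert prof.phi[0] == pytest.approx(1.0, abs=1e-12)  # 1 e at 1 A

    def test_empty_environment_gives_zero(self):
        model = toy_model([[0, 0, 0], [1.4, 0, 0]], [])
        prof = potential_on_atoms(model, model.chromophores[0])
        np.testing.assert_array_equal(prof.phi, 0.0)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(4)
        chrom = [[1.4 * i, 0, 0] for i in range(4)]
        env = [(rng.uniform(-5, 5, 3) + [0, 6, 0], rng.normal(), "SER") for _ in range(3)]
        model = toy_model(chrom, env)
        prof = potential_on_atoms(model, model.chromophores[0])
        for i, rc in enumerate(chrom):
            expected = sum(
                q / np.linalg.norm(np.asarray(rc) - np.asarray(p)) for p, q, _ in env
            )
            assert prof.phi[i] == pytest.approx(expected, rel=1e-12)

    def test_superposition_over_disjoint_environments(self, ocp1_synth):
        model = ocp1_synth.model
        chrom = model.chromophore("CAN")
        keys = [g.residue_key for g in model.environment]
        half_a, half_b = set(keys[::2]), set(keys[1::2])
        full = potential_on_atoms(model, chrom, exclude_side_chains_only=False)
        only_a = potential_on_atoms(
            model, chrom, exclude=half_b, exclude_side_chains_only=False
        )
        only_b = potential_on_atoms(
            model, chrom, exclude=half_a, exclude_side_chains_only=False
        )
        unassigned = potential_on_atoms(
            model, chrom, exclude=set(keys), exclude_side_chains_only=False
        )
        np.testing.assert_allclose(
            only_a.phi + only_b.phi - unassigned.phi, full.phi, rtol=1e-12, atol=1e-14
        )

    def test_coincident_atom_raises(self):
        model = toy_model([[0, 0, 0], [1.4, 0, 0]], [([0.0, 0.0, 0.0], 1.0, "SER")])
        with pytest.raises(SingularityError):
            potential_on_atoms(model, model.chromophores[0])


class TestDeltaP:
    def _chrom(self, n):
        model = toy_model([[1.4 * i, 0, 0] for i in range(n)], [])
        return model.chromophores[0]

    def test_uniform_profile_gives_zero(self):
        prof = PotentialProfile(0, np.full(4, 0.7))
        assert delta_p(prof, self._chrom(4)).delta_p == 0.0

    def test_four_atom_arithmetic(self):
        prof = PotentialProfile(0, np.array([1.0, 1.0, -1.0, -1.0]))
        assert delta_p(prof, self._chrom(4)).delta_p == pytest.approx(2.0)

    def test_odd_chain_drops_middle_atom(self):
        prof = PotentialProfile(0, np.array([1.0, 1.0, 99.0, -1.0, -1.0]))
        assert delta_p(prof, self._chrom(5)).delta_p == pytest.approx(2.0)

    def test_mirror_symmetric_environment_cancels(self):
        # charges mirror-imaged about the chain midplane
        chrom = [[1.4 * i, 0, 0] for i in range(6)]
        mid = 1.4 * 5 / 2
        env = []
        for dx, y, q in [(3.0, 4.0, 0.5), (6.5, -5.0, -0.8)]:
            env.append(([mid - dx, y, 0.0], q, "SER"))
            env.append(([mid + dx, y, 0.0], q, "SER"))
        model = toy_model(chrom, env)
        prof = potential_on_atoms(model, model.chromophores[0])
        assert abs(delta_p(prof, model.chromophores[0]).delta_p) < 1e-12

    def test_odd_under_chain_reversal(self):
        rng = np.random.default_rng(9)
        phi = rng.normal(size=8)
        fwd = delta_p(PotentialProfile(0, phi), self._chrom(8)).delta_p
        rev = delta_p(PotentialProfile(0, phi[::-1]), self._chrom(8)).delta_p
        assert rev == pytest.approx(-fwd, abs=1e-14)

    def test_too_short_chain_rejected(self):
        with pytest.raises(Exception):
            delta_p(PotentialProfile(0, np.array([1.0])), self._chrom(2))


class TestTurnOffScan:
    def _tiny_ensemble(self):
        """2-frame ensemble: chain + one negative residue at the tail end."""
        chrom = [[1.4 * i, 0, 0] for i in range(6)]
        env = [([10.0, 2.0, 0.0], -1.0, "GLU"), ([3.5, -8.0, 0.0], 0.0, "ALA")]
        frames = []
        for f in range(2):
            m = toy_model(chrom, env)
            m.frame_id = f
            frames.append(m)
        from pocketquench.core_model import Ensemble

        return Ensemble(frames=frames)

    def _params(self):
        return MixingParameters(k_mix=0.5, mu_bright_diabatic=19.0,
                                e_dark=2.05, e_bright=2.25)

    def test_zero_charge_residue_has_exactly_zero_effect(self):
        ens = self._tiny_ensemble()
        ala = [g for g in ens.frames[0].environment if g.residue_key[1] == "ALA"]
        effects = turn_off_scan(ens, "CHR", ala, self._params())
        np.testing.assert_array_equal(effects[0].values, 0.0)

    def test_sole_asymmetry_source_gives_negative_effect(self):
        # the single charged residue drives |DeltaP|; zeroing it shrinks the
        # dark TDM, so log10(mu/mu_ref) < 0
        ens = self._tiny_ensemble()
        glu = [g for g in ens.frames[0].environment if g.residue_key[1] == "GLU"]
        effects = turn_off_scan(ens, "CHR", glu, self._params())
        assert np.all(effects[0].values < 0)
        assert len(effects[0].values) == 2

    def test_turn_off_all_leaves_only_unassigned_contribution(self, ocp1_synth):
        model = ocp1_synth.model
        chrom = model.chromophore("CAN")
        keys = {g.residue_key for g in model.environment}
        prof = potential_on_atoms(model, chrom, exclude=keys,
                                  exclude_side_chains_only=False)
        solvent_only = [i for i in model.unassigned_atom_ids]
        expected = np.zeros(len(chrom.atom_ids))
        for i in solvent_only:
            a = model.atom(i)
            for k, cid in enumerate(chrom.atom_ids):
                expected[k] += a.partial_charge / np.linalg.norm(
                    model.atom(cid).position - a.position
                )
        np.testing.assert_allclose(prof.phi, expected, rtol=1e-10, atol=1e-12)

    def test_scan_on_preset_ensemble_has_box_stats(self, ocp1_ensemble, ocp1_synth):
        from pocketquench.core_model import neighbors_within

        chrom = ocp1_synth.model.chromophore("CAN")
        residues = neighbors_within(
            ocp1_synth.model, chrom, 10.0, classes=["positive", "negative", "polar"]
        )
        params = MixingParameters(
            k_mix=0.7, mu_bright_diabatic=19.0,
            e_dark=ocp1_ensemble.metadata["e_dark"],
            e_bright=ocp1_ensemble.metadata["e_bright"],
        )
        effects = turn_off_scan(ocp1_ensemble, "CAN", residues, params)
        assert len(effects) == len(residues)
        for e in effects:
            s = e.summary
            assert s["n"] == len(ocp1_ensemble)
            assert s["q1"] <= s["median"] <= s["q3"]
            assert s["whisker_low"] <= s["q1"] and s["q3"] <= s["whisker_high"]

    def test_unknown_residue_rejected(self, ocp1_ensemble):
        with pytest.raises(ValueError, match="not in the environment"):
            turn_off_scan(ocp1_ensemble, "CAN", [("Z", "GLY", 999)], self._params())


class TestPCA:
    def test_rank_one_variation_gives_single_component(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=10)
        direction = rng.normal(size=10)
        profiles = [PotentialProfile(i, base + t * direction)
                    for i, t in enumerate(np.linspace(-1, 1, 12))]
        res = pca_potentials(profiles)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-10)

    def test_duplicated_frames_get_identical_scores(self):
        rng = np.random.default_rng(8)
        phis = [rng.normal(size=6) for _ in range(4)]
        profiles = [PotentialProfile(i, p) for i, p in enumerate(phis + phis)]
        res = pca_potentials(profiles)
        np.testing.assert_allclose(res.scores[:4], res.scores[4:], atol=1e-10)

    def test_explained_variances_sum_to_one(self):
        rng = np.random.default_rng(12)
        profiles = [PotentialProfile(i, rng.normal(size=5)) for i in range(8)]
        res = pca_potentials(profiles)
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-10)

    def test_constant_matrix_flagged_degenerate(self):
        profiles = [PotentialProfile(i, np.ones(5)) for i in range(4)]
        res = pca_potentials(profiles)
        assert res.degenerate

    def test_projection_of_second_ensemble(self, ocp1_synth, hcp2_synth):
        ens_a = sd.generate_ensemble(ocp1_synth, n_frames=8, seed=3)
        ens_b = sd.generate_ensemble(hcp2_synth, n_frames=8, seed=4)

        def profs(ens):
            out = []
            for fr in ens.frames:
                ch = fr.chromophore("CAN")
                out.append(potential_on_atoms(fr, ch))
            return out

        ref = pca_potentials(profs(ens_a))
        proj = ref.project(profs(ens_b))
        assert proj.shape == (8, ref.components.shape[0])
        # the two pockets occupy clearly different regions along PC1
        own = ref.scores[:, 0]
        assert abs(proj[:, 0].mean() - own.mean()) > 5 * own.std()
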