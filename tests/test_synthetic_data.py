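"""Generator determinism, preset construction, and statistical behaviour."""

import numpy as np
import pytest

from pocketquench import synthetic_data as sd
from pocketquench.core_model import write_pqr
from pocketquench.pocket_electrostatics import delta_p, potential_on_atoms
from pocketquench.tresp import transition_dipole


def static_delta_p(synth):
    chrom = synth.model.chromophore("CAN")
    return delta_p(potential_on_atoms(synth.model, chrom), chrom).delta_p


class TestBuildComplex:
    def test_same_seed_gives_byte_identical_files(self, tmp_path):
        p1, p2 = tmp_path / "a.pqr", tmp_path / "b.pqr"
        write_pqr(sd.build_complex(sd.ocp1_like(), seed=3).model, p1)
        write_pqr(sd.build_complex(sd.ocp1_like(), seed=3).model, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_presets_differ_only_at_declared_sites(self, ocp1_synth, hcp5_synth):
        declared = {34, 60, 77, 78, 84, 133}
        a = {x.id: x for x in ocp1_synth.model.atoms}
        b = {x.id: x for x in hcp5_synth.model.atoms}
        assert a.keys() == b.keys()
        for i in a:
            at_a, at_b = a[i], b[i]
            np.testing.assert_array_equal(at_a.position, at_b.position)
            same = (
                at_a.partial_charge == at_b.partial_charge
                and at_a.residue_key[1] == at_b.residue_key[1]
            )
            if at_a.residue_key[2] in declared:
                continue  # may legitimately differ
            assert same, f"atom {i} differs outside the declared sites"
        diff_res = {
            a[i].residue_key[2]
            for i in a
            if a[i].residue_key[1] != b[i].residue_key[1]
        }
        assert diff_res == declared

    def test_imbalance_ordering_of_presets(self, ocp1_synth, hcp5_synth, hcp2_synth):
        dp1 = abs(static_delta_p(ocp1_synth))
        dp5 = abs(static_delta_p(hcp5_synth))
        dp2 = abs(static_delta_p(hcp2_synth))
        assert dp2 < dp1 < dp5

    def test_donor_charges_hit_target_bright_tdm(self, ocp1_synth):
        pos = ocp1_synth.model.positions(ocp1_synth.donor_tcs.atom_ids)
        mu = np.linalg.norm(transition_dipole(ocp1_synth.donor_tcs, pos))
        assert mu == pytest.approx(ocp1_synth.preset.mu_bright_diabatic, rel=1e-12)

    def test_acceptors_at_declared_distances(self, ocp1_synth):
        model = ocp1_synth.model
        donor_pos = model.positions(model.chromophore("CAN").atom_ids)
        for label, expected in (("APC1", 15.0), ("APC2", 25.0)):
            acc_pos = model.positions(model.chromophore(label).atom_ids)
            dmin = min(
                np.linalg.norm(p - q) for p in acc_pos for q in donor_pos
            )
            assert dmin == pytest.approx(expected, abs=1.0)

    def test_output_validates_core_invariants(self, hcp5_synth):
        hcp5_synth.model.validate_partition()  # raises on violation
        for tcs in (hcp5_synth.donor_tcs, *hcp5_synth.acceptor_tcs.values()):
            assert abs(tcs.charges.sum()) < 1e-10


class TestGenerateEnsemble:
    def test_zero_jitter_freezes_all_frames(self, ocp1_synth):
        ens = sd.generate_ensemble(ocp1_synth, n_frames=4, jitter_sigma=0.0, seed=1)
        ref = ens.frames[0].positions()
        for fr in ens.frames[1:]:
            np.testing.assert_array_equal(fr.positions(), ref)

    def test_backbone_and_pigments_fixed_under_jitter(self, ocp1_synth):
        ens = sd.generate_ensemble(ocp1_synth, n_frames=3, seed=2)
        base = ocp1_synth.model
        pigment_ids = {i for c in base.chromophores for i in c.atom_ids}
        for fr in ens.frames:
            for a in fr.atoms:
                ref = base.atom(a.id)
                if a.id in pigment_ids or a.is_backbone:
                    np.testing.assert_array_equal(a.position, ref.position)
                else:
                    assert np.any(a.position != ref.position)

    def test_imbalance_spread_grows_with_jitter(self, ocp1_synth):
        sds = []
        for sigma in (0.1, 0.3, 0.6):
            ens = sd.generate_ensemble(ocp1_synth, n_frames=40,
                                       jitter_sigma=sigma, seed=21)
            dps = []
            for fr in ens.frames:
                ch = fr.chromophore("CAN")
                dps.append(delta_p(potential_on_atoms(fr, ch), ch).delta_p)
            sds.append(np.std(dps))
        assert sds[0] < sds[1] < sds[2]

    def test_seeded_reproducibility(self, ocp1_synth):
        e1 = sd.generate_ensemble(ocp1_synth, n_frames=5, seed=33)
        e2 = sd.generate_ensemble(ocp1_synth, n_frames=5, seed=33)
        np.testing.assert_array_equal(e1.frames[3].positions(), e2.frames[3].positions())
        np.testing.assert_array_equal(e1.metadata["e_dark"], e2.metadata["e_dark"])

    def test_frames_share_topology_and_unique_ids(self, ocp1_ensemble):
        ids = [a.id for a in ocp1_ensemble.frames[0].atoms]
        for fr in ocp1_ensemble.frames:
            assert [a.id for a in fr.atoms] == ids
        fids = [fr.frame_id for fr in ocp1_ensemble.frames]
        assert len(set(fids)) == len(fids)

    def test_planted_charge_magnitude_moves_mean_imbalance_linearly(self):
        """Mean DeltaP responds linearly to the magnitude of the extra
        pocket charges (parameter recovery for the driving variable)."""
        from scipy import stats

        base = sd.ocp1_like()
        extra_resnums = {34, 60, 77, 78, 84, 133}
        cs = np.linspace(0.25, 1.0, 6)  # keep the sites charged (c=0 would
        # fall back to the neutral-polar construction, a different layout)
        means = []
        for c in cs:
            residues = tuple(
                sd.ResidueSite(h.resname, h.resnum, h.site, c * h.charge)
                if h.resnum in extra_resnums else h
                for h in sd.hcp5_like().residues
            )
            preset = base.with_(name="sweep", residues=residues)
            synth = sd.build_complex(preset)
            ens = sd.generate_ensemble(synth, n_frames=12, seed=5)
            dps = []
            for fr in ens.frames:
                ch = fr.chromophore("CAN")
                dps.append(delta_p(potential_on_atoms(fr, ch), ch).delta_p)
            means.append(np.mean(dps))
        fit = stats.linregress(cs, means)
        assert fit.rvalue**2 >= 0.99
        assert fit.slope > 0

    def test_invalid_frame_count_rejected(self, ocp1_synth):
        with pytest.raises(ValueError):
            sd.generate_ensemble(ocp1_synth, n_frames=0)


class TestCensusFixture:
    def test_tallies_match_generating_composition(self):
        comp = {"HCP4": 2, "HCP5": 1, "HCP4+HCP5": 1, "": 1}
        fix = sd.census_fixture(composition=comp, seed=4)
        assert len(fix.complements) == 5
        h4only = sum(
            1 for c in fix.complements.values() if "HCP4" in c and "HCP5" not in c
        )
        h5only = sum(
            1 for c in fix.complements.values() if "HCP5" in c and "HCP4" not in c
        )
        both = sum(1 for c in fix.complements.values() if {"HCP4", "HCP5"} <= set(c))
        assert (h4only, h5only, both) == (2, 1, 1)

    def test_score_margins_positive_and_truth_recoverable(self, census_fix):
        df = census_fix.score_table
        for seq_id, grp in df.groupby("sequence_id"):
            top = grp.sort_values("bit_score", ascending=False)
            genome = top.iloc[0]["genome_id"]
            assert top.iloc[0]["bit_score"] > top.iloc[1]["bit_score"]
            assert top.iloc[0]["clade"] in census_fix.complements[genome]

    def test_fully_conserved_column_has_max_information(self, census_fix):
        from pocketquench.census import conservation

        mat = conservation(census_fix.alignment)
        for col, cons in enumerate(census_fix.column_conservation):
            if cons == 1.0:
                assert mat.information_content[col] == pytest.approx(
                    np.log2(20), abs=1e-12
                )

    def test_unknown_clade_rejected(self):
        with pytest.raises(ValueError, match="unknown clade"):
            sd.census_fixture(composition={"HCP99": 1})

    def test_default_composition_sizes(self, census_fix):
        assert len(fix_complements := census_fix.complements) == 690
        n_ocp = sum(
            1 for c in fix_complements.values() if any(x.startswith("OCP") for x in c)
        )
        assert n_ocp == 621
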