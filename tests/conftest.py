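import numpy as np
import pytest

from pocketquench import synthetic_data as sd
from pocketquench.core_model import Atom, ComplexModel, partition


@pytest.fixture(scope="session")
def ocp1_synth():
    return sd.build_complex(sd.ocp1_like())


@pytest.fixture(scope="session")
def hcp5_synth():
    return sd.build_complex(sd.hcp5_like())


@pytest.fixture(scope="session")
def hcp2_synth():
    return sd.build_complex(sd.hcp2_like())


@pytest.fixture(scope="session")
def ocp1_ensemble(ocp1_synth):
    return sd.generate_ensemble(ocp1_synth, n_frames=12, seed=7)


def make_atom(i, pos, q=0.0, name="C1", resname="LIG", resnum=1, chain="A",
              element=None, backbone=False):
    return Atom(
        id=i,
        name=name,
        element=element or name[0],
        residue_key=(chain, resname, resnum),
        position=np.asarray(pos, dtype=float),
        partial_charge=q,
        is_backbone=backbone,
    )


def toy_model(chrom_positions, env_entries, chrom_charges=None):
    """Model with one chromophore chain and point-like environment residues.

    env_entries: list of (position, charge, resname); each becomes its own
    single-atom residue (atom name CB, so it is side chain).
    """
    atoms = []
    n = len(chrom_positions)
    for i, p in enumerate(chrom_positions):
        q = 0.0 if chrom_charges is None else chrom_charges[i]
        atoms.append(make_atom(i + 1, p, q=q, name=f"C{i + 1}", resname="CHR"))
    for j, (p, q, resname) in enumerate(env_entries):
        atoms.append(
            make_atom(n + j + 1, p, q=q, name="CB", resname=resname, resnum=10 + j)
        )
    model = ComplexModel(atoms=atoms)
    return partition(model, list(range(1, n + 1)), label="CHR")


@pytest.fixture(scope="session")
def census_fix():
    return sd.census_fixture(seed=11)
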