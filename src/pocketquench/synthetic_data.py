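"""Seeded generators of toy pigment-protein complexes and census fixtures.

The structural generator emulates the statistical setting the analysis
assumes: a linear 20-atom conjugated "carotenoid" chain (1.4 A spacing) held
fixed inside a pocket of protein residues whose backbone sites are fixed
while side-chain and solvent atoms jitter isotropically frame to frame
(a stand-in for backbone-restrained MD).  Three pocket presets encode the
electrostatic scenarios of interest:

* ``ocp1-like``  -- a moderately asymmetric pocket: one positive residue at
  the PBS-adjacent (head) end, negative residues at the tail end.
* ``hcp5-like``  -- the same scaffold with the quencher-enhancing
  substitutions: an arginine replacing a serine at the head, and additional
  aspartates/glutamates (partly offset by an extra arginine) at the tail,
  increasing the end-to-end potential imbalance.  Its diabatic dark/bright
  gap is also narrower (bright state red-shifted).
* ``hcp2-like``  -- a near-symmetric charge layout whose imbalance stays
  close to zero, with a wider diabatic gap (bright state blue-shifted).

Transition charges on the chain alternate in sign, giving a head-to-tail
extended dipole whose magnitude is set by the target diabatic bright-state
TDM; two static bilin-like acceptor chromophores sit beyond the head end at
roughly 15 and 25 A.  All randomness flows from one explicit seed; child
streams use fixed spawn keys.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core_model import (
    Atom,
    Chromophore,
    ComplexModel,
    Ensemble,
    classify_residue,
    partition,
)
from .tresp import TransitionChargeSet
from .units import EANGSTROM_TO_DEBYE

CHAIN_N_ATOMS = 20
CHAIN_SPACING = 1.4  # Angstrom; conjugated C-C
CHAIN_LENGTH = (CHAIN_N_ATOMS - 1) * CHAIN_SPACING

_TERMINAL_NAMES = {
    "ASP": "OD1", "GLU": "OE1", "ARG": "NH1", "LYS": "NZ", "HIS": "NE2",
    "SER": "OG", "THR": "OG1", "ASN": "OD1", "GLN": "OE1", "TYR": "OH",
}


@dataclass(frozen=True)
class ResidueSite:
    """One pocket residue: name, number, side-chain charge site and charge."""

    resname: str
    resnum: int
    site: tuple[float, float, float]  # position of the charged/polar tip (A)
    charge: float  # total side-chain charge (e)


@dataclass(frozen=True)
class PocketPreset:
    """Declarative description of one pocket-electrostatics scenario."""

    name: str
    residues: tuple[ResidueSite, ...]
    jitter_sigma: float = 0.3  # A, isotropic, side chains + solvent
    e_dark_mean: float = 2.05  # eV
    e_dark_sd: float = 0.03
    e_bright_mean: float = 2.25
    e_bright_sd: float = 0.03
    mu_bright_diabatic: float = 19.0  # D
    acceptor_tdm: float = 13.0  # D, static bilin-like acceptors
    n_waters: int = 8

    def with_(self, **kw) -> "PocketPreset":
        return replace(self, **kw)


_SCAFFOLD = (
    ResidueSite("TYR", 201, (6.0, 4.5, 0.0), 0.0),
    ResidueSite("TRP", 202, (20.0, 4.5, 0.0), 0.0),
    ResidueSite("SER", 203, (13.3, -4.5, 0.0), 0.0),
    ResidueSite("ASN", 204, (13.3, 0.0, 4.5), 0.0),
    ResidueSite("PHE", 205, (10.0, 0.0, -4.5), 0.0),
    ResidueSite("LYS", 49, (-3.5, 2.5, 0.0), 1.0),
    ResidueSite("GLU", 106, (30.1, 2.5, 0.0), -1.0),
)

#: Substitution-site residues in the reference (OCP1-like) pocket.
_OCP1_SITES = (
    ResidueSite("GLU", 34, (31.5, -4.0, 3.0), -1.0),
    ResidueSite("LEU", 77, (30.5, -9.0, 0.0), 0.0),
    ResidueSite("GLN", 78, (16.0, -9.0, 0.0), 0.0),
    ResidueSite("ALA", 133, (13.3, 6.0, -6.0), 0.0),
    ResidueSite("SER", 60, (-4.0, -7.5, 0.0), 0.0),
    ResidueSite("SER", 84, (28.5, 4.0, 0.0), 0.0),
)

#: The HCP5-like substitutions at the same sites: R replaces S at the
#: PBS-adjacent head; D/E replace neutral residues on the opposite side,
#: partly offset by an extra arginine on the solvent-exposed face, for a
#: modest net increase of the end-to-end imbalance.
_HCP5_SITES = (
    ResidueSite("ASP", 34, (31.5, -4.0, 3.0), -1.0),
    ResidueSite("ASP", 77, (30.5, -9.0, 0.0), -1.0),
    ResidueSite("GLU", 78, (16.0, -9.0, 0.0), -1.0),
    ResidueSite("ASP", 133, (13.3, 6.0, -6.0), -1.0),
    ResidueSite("ARG", 60, (-4.0, -7.5, 0.0), 1.0),
    ResidueSite("ARG", 84, (28.5, 4.0, 0.0), 1.0),
)

#: HCP2-like: charged residues arranged so head and tail contributions
#: nearly cancel, leaving an imbalance close to zero.
_HCP2_SITES = (
    ResidueSite("GLU", 112, (-4.0, -3.0, 0.0), -1.0),
    ResidueSite("GLU", 34, (31.5, -4.0, 3.0), -1.0),
    ResidueSite("GLU", 35, (-4.9, -4.0, 3.0), -1.0),
    ResidueSite("LYS", 110, (30.6, -3.0, 0.0), 1.0),
    ResidueSite("LEU", 77, (30.5, -9.0, 0.0), 0.0),
    ResidueSite("GLN", 78, (16.0, -9.0, 0.0), 0.0),
    ResidueSite("ALA", 133, (13.3, 6.0, -6.0), 0.0),
    ResidueSite("SER", 60, (-4.0, -7.5, 0.0), 0.0),
    ResidueSite("SER", 84, (28.5, 4.0, 0.0), 0.0),
)


def ocp1_like() -> PocketPreset:
    return PocketPreset("ocp1-like", _SCAFFOLD + _OCP1_SITES)


def hcp5_like() -> PocketPreset:
    return PocketPreset(
        "hcp5-like",
        _SCAFFOLD + _HCP5_SITES,
        e_dark_mean=2.02,
        e_dark_sd=0.04,
        e_bright_mean=2.10,
        e_bright_sd=0.04,
    )


def hcp2_like() -> PocketPreset:
    return PocketPreset(
        "hcp2-like",
        _SCAFFOLD + _HCP2_SITES,
        e_dark_mean=2.05,
        e_dark_sd=0.015,
        e_bright_mean=2.30,
        e_bright_sd=0.03,
    )


PRESETS = {"ocp1-like": ocp1_like, "hcp5-like": hcp5_like, "hcp2-like": hcp2_like}


@dataclass
class SyntheticComplex:
    """A built toy complex plus its pigments' transition-charge sets."""

    model: ComplexModel
    donor_tcs: TransitionChargeSet
    acceptor_tcs: dict[str, TransitionChargeSet]
    preset: PocketPreset


def _alternating_charges(n: int, positions: np.ndarray, target_tdm: float) -> np.ndarray:
    """Alternating +/-q pattern scaled so |sum q_i r_i| equals target_tdm (D)."""
    signs = np.array([1.0 if i % 2 == 0 else -1.0 for i in range(n)])
    mu_unit = EANGSTROM_TO_DEBYE * np.linalg.norm((signs[:, None] * positions).sum(axis=0))
    return signs * (target_tdm / mu_unit)


def _chain_atoms(
    start_id: int,
    origin: np.ndarray,
    direction: np.ndarray,
    n: int,
    resname: str,
    resnum: int,
    chain_id: str,
) -> list[Atom]:
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    return [
        Atom(
            id=start_id + i,
            name=f"C{i + 1}",
            element="C",
            residue_key=(chain_id, resname, resnum),
            position=np.asarray(origin, dtype=float) + i * CHAIN_SPACING * direction,
            partial_charge=0.0,
        )
        for i in range(n)
    ]


def _residue_atoms(site: ResidueSite, start_id: int, chain_id: str = "P") -> list[Atom]:
    pos = np.asarray(site.site, dtype=float)
    # direction pointing away from the chain axis (the x axis segment)
    anchor = np.array([min(max(pos[0], 0.0), CHAIN_LENGTH), 0.0, 0.0])
    away = pos - anchor
    away = away / np.linalg.norm(away)
    perp = np.cross(away, [1.0, 0.0, 0.0])
    if np.linalg.norm(perp) < 1e-8:
        perp = np.cross(away, [0.0, 1.0, 0.0])
    perp = perp / np.linalg.norm(perp)
    key = (chain_id, site.resname, site.resnum)
    ca = pos + 3.0 * away
    if site.charge != 0.0:
        q_tip, q_cb = 0.7 * site.charge, 0.3 * site.charge
    elif site.resname in _TERMINAL_NAMES:  # neutral polar: a +/- dipole
        q_tip, q_cb = 0.3, -0.3
    else:
        q_tip = q_cb = 0.0
    tip_name = _TERMINAL_NAMES.get(site.resname, "CG")
    mk = lambda i, name, elem, p, q, bb: Atom(  # noqa: E731
        id=start_id + i, name=name, element=elem, residue_key=key,
        position=p, partial_charge=q, is_backbone=bb,
    )
    return [
        mk(0, "N", "N", ca + 1.3 * perp, 0.0, True),
        mk(1, "CA", "C", ca, 0.0, True),
        mk(2, "C", "C", ca - 1.3 * perp, 0.0, True),
        mk(3, "O", "O", ca - 1.3 * perp + 1.2 * away, 0.0, True),
        mk(4, "CB", "C", pos + 1.5 * away, q_cb, False),
        mk(5, tip_name, tip_name[0], pos, q_tip, False),
    ]


def _water_atoms(start_id: int, origin: np.ndarray, resnum: int) -> list[Atom]:
    key = ("W", "HOH", resnum)
    o = np.asarray(origin, dtype=float)
    mk = lambda i, name, elem, p, q: Atom(  # noqa: E731
        id=start_id + i, name=name, element=elem, residue_key=key,
        position=p, partial_charge=q,
    )
    return [
        mk(0, "OW", "O", o, -0.834),
        mk(1, "HW1", "H", o + np.array([0.96, 0.0, 0.0]), 0.417),
        mk(2, "HW2", "H", o + np.array([-0.24, 0.93, 0.0]), 0.417),
    ]


def _water_sites(n_waters: int) -> list[np.ndarray]:
    """Water oxygens mirror-symmetric about the chain midplane (static
    solvent contribution to the imbalance cancels exactly)."""
    ring = [(7.0, 0.0), (-7.0, 0.0), (0.0, 7.0), (0.0, -7.0)]
    xs = [CHAIN_LENGTH / 2 - 6.65, CHAIN_LENGTH / 2 + 6.65]
    sites = [np.array([x, y, z]) for x in xs for (y, z) in ring]
    return sites[:n_waters]


def build_complex(preset: PocketPreset, seed: int = 0) -> SyntheticComplex:
    """Build one (deterministic) frame of the toy complex for a preset.

    The layout is fully determined by the preset; ``seed`` is recorded for
    provenance only.  Returns the partitioned model plus the donor chain's
    diabatic-bright transition charges and the two static acceptor sets.
    """
    atoms: list[Atom] = []
    next_id = 1
    donor = _chain_atoms(next_id, np.zeros(3), [1, 0, 0], CHAIN_N_ATOMS, "CAN", 1, "X")
    atoms += donor
    next_id += CHAIN_N_ATOMS
    acc1 = _chain_atoms(next_id, np.array([-15.0, 2.0, 0.0]), [-1, 0, 0], 10, "PCB", 1, "B")
    atoms += acc1
    next_id += 10
    acc2 = _chain_atoms(next_id, np.array([-25.0, -3.0, 0.0]), [-2, -1, 0], 10, "PCB", 2, "C")
    atoms += acc2
    next_id += 10
    for site in preset.residues:
        atoms += _residue_atoms(site, next_id)
        next_id += 6
    for w, origin in enumerate(_water_sites(preset.n_waters)):
        atoms += _water_atoms(next_id, origin, 300 + w)
        next_id += 3

    model = ComplexModel(atoms=atoms, frame_id=0)
    model = partition(
        model,
        {
            "CAN": [a.id for a in donor],
            "APC1": [a.id for a in acc1],
            "APC2": [a.id for a in acc2],
        },
    )

    donor_pos = model.positions([a.id for a in donor])
    donor_tcs = TransitionChargeSet(
        "CAN",
        tuple(a.id for a in donor),
        _alternating_charges(CHAIN_N_ATOMS, donor_pos, preset.mu_bright_diabatic),
    )
    acceptor_tcs = {}
    for label, chain in (("APC1", acc1), ("APC2", acc2)):
        pos = model.positions([a.id for a in chain])
        acceptor_tcs[label] = TransitionChargeSet(
            label,
            tuple(a.id for a in chain),
            _alternating_charges(10, pos, preset.acceptor_tdm),
        )
    return SyntheticComplex(model, donor_tcs, acceptor_tcs, preset)


def generate_ensemble(
    synth: SyntheticComplex,
    n_frames: int = 60,
    jitter_sigma: float | None = None,
    seed: int = 0,
) -> Ensemble:
    """Pseudo-restrained ensemble: backbone and pigment sites fixed,
    side-chain/solvent atoms displaced by isotropic Gaussian jitter, and
    per-frame diabatic energies drawn from the preset distributions."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    sigma = synth.preset.jitter_sigma if jitter_sigma is None else jitter_sigma
    rng_jitter = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))
    rng_energy = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2,)))

    base = synth.model
    pigment_ids = {i for c in base.chromophores for i in c.atom_ids}
    mobile = [
        a.id
        for a in base.atoms
        if a.id not in pigment_ids and not a.is_backbone
    ]
    mobile_set = set(mobile)

    frames: list[ComplexModel] = []
    for f in range(n_frames):
        disp = {i: rng_jitter.normal(0.0, sigma, 3) if sigma > 0 else np.zeros(3) for i in mobile}
        new_atoms = [
            Atom(
                id=a.id,
                name=a.name,
                element=a.element,
                residue_key=a.residue_key,
                position=a.position + disp[a.id] if a.id in mobile_set else a.position,
                partial_charge=a.partial_charge,
                is_backbone=a.is_backbone,
            )
            for a in base.atoms
        ]
        frames.append(
            ComplexModel(
                atoms=new_atoms,
                chromophores=list(base.chromophores),
                environment=list(base.environment),
                unassigned_atom_ids=base.unassigned_atom_ids,
                frame_id=f,
            )
        )
    e_dark = rng_energy.normal(synth.preset.e_dark_mean, synth.preset.e_dark_sd, n_frames)
    e_bright = rng_energy.normal(
        synth.preset.e_bright_mean, synth.preset.e_bright_sd, n_frames
    )
    return Ensemble(
        frames=frames,
        metadata={
            "seed": seed,
            "jitter_sigma": sigma,
            "preset": synth.preset.name,
            "e_dark": e_dark,
            "e_bright": e_bright,
        },
    )


# ---------------------------------------------------------------------------
# Census fixtures
# ---------------------------------------------------------------------------

CLADES = tuple(f"HCP{i}" for i in range(1, 10)) + ("OCP1", "OCP2", "OCP3")

#: Default genome composition, anchored to the headline complement counts of
#: the 690-genome survey (any OCP 90%, any HCP 63%, 137 HCP4-without-HCP5,
#: 69 HCP5-without-HCP4, one genome with both, OCP co-occurring in 111/138
#: HCP4-containing and 46/70 HCP5-containing genomes).
DEFAULT_COMPOSITION: dict[str, int] = {
    "HCP4+HCP5+HCP7+OCP2": 1,
    "HCP4+HCP3+OCP1": 85,
    "HCP4+HCP3": 19,
    "HCP4+OCP1": 25,
    "HCP4": 8,
    "HCP5+OCP1": 30,
    "HCP5": 13,
    "HCP5+HCP2+OCP1": 15,
    "HCP5+HCP2": 11,
    "HCP1+OCP1": 76,
    "HCP2+OCP1": 76,
    "HCP3+OCP1": 76,
    "OCP1": 200,
    "OCP3": 37,
    "": 18,
}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class CensusFixture:
    """Generated census inputs plus their generating truth."""

    complements: dict[str, tuple[str, ...]]  # genome -> clades present
    score_table: pd.DataFrame  # sequence_id, genome_id, clade, bit_score
    alignment: list[tuple[str, str]]  # (sequence id, aligned sequence)
    column_conservation: tuple[float, ...]  # designed per-column dominance
    composition: dict[str, int]


def census_fixture(
    composition: dict[str, int] | None = None,
    seed: int = 0,
    n_aligned: int = 20,
    alignment_columns: tuple[float, ...] = (1.0, 1.0, 0.9, 0.7, 0.5, 0.3, 1.0, 0.6),
) -> CensusFixture:
    """Generate genome complements, a clade score table, and a toy alignment.

    ``composition`` maps a '+'-joined complement signature (e.g. 'HCP4+OCP1')
    to a genome count; the empty string means no OCP-related genes.  Each
    sequence's true clade receives the top score with a strictly positive
    margin, so clade assignment recovers the truth exactly.
    """
    comp = dict(DEFAULT_COMPOSITION if composition is None else composition)
    for sig in comp:
        for clade in filter(None, sig.split("+")):
            if clade not in CLADES:
                raise ValueError(f"unknown clade {clade!r} in composition")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(3,)))

    complements: dict[str, tuple[str, ...]] = {}
    rows = []
    g = 0
    for sig, count in comp.items():
        clades = tuple(filter(None, sig.split("+")))
        for _ in range(count):
            g += 1
            genome = f"g{g:04d}"
            complements[genome] = clades
            for k, clade in enumerate(clades):
                seq_id = f"{genome}_seq{k + 1}"
                true_score = rng.uniform(90.0, 150.0)
                margin = rng.uniform(5.0, 40.0)
                for c in CLADES:
                    score = true_score if c == clade else true_score - margin - rng.uniform(0, 30)
                    rows.append((seq_id, genome, c, round(float(score), 2)))
    score_table = pd.DataFrame(
        rows, columns=["sequence_id", "genome_id", "clade", "bit_score"]
    )

    alignment = []
    dominant = [AMINO_ACIDS[rng.integers(20)] for _ in alignment_columns]
    for s in range(n_aligned):
        seq = []
        for col, cons in enumerate(alignment_columns):
            if s == 0 or rng.random() < cons:
                seq.append(dominant[col])
            else:
                others = AMINO_ACIDS.replace(dominant[col], "")
                seq.append(others[rng.integers(len(others))])
        alignment.append((f"aln{s + 1:03d}", "".join(seq)))

    return CensusFixture(
        complements=complements,
        score_table=score_table,
        alignment=alignment,
        column_conservation=tuple(alignment_columns),
        composition=comp,
    )
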