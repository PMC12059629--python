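"""Structures, charges, and chromophore/environment partitioning.

A :class:`ComplexModel` is one frame of a pigment-protein complex: every atom
carries a position (Angstrom) and a fixed partial charge (elementary charge
units).  The pigment of interest is singled out as a :class:`Chromophore`
(an *ordered* list of conjugated-chain atoms -- the order encodes the chain
topology end to end and is what downstream imbalance statistics rely on);
the remaining atoms are grouped into per-residue :class:`ResidueGroup`
entries, with solvent and ions kept as unassigned atoms.

File I/O (PDB, multi-model PDB, PQR, TSV charge tables) is delegated to
MDAnalysis; coordinates are Angstrom throughout and no periodic boundary
handling is applied (analysis frames are finite clusters).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

#: Atom names treated as protein backbone; everything else is side chain.
BACKBONE_ATOM_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})

#: Residue names treated as solvent/ions (left unassigned by partition()).
SOLVENT_RESNAMES = frozenset({"HOH", "WAT", "SOL", "TIP3", "NA", "CL", "K", "MG", "CA2"})

#: Fixed residue-name -> classification lookup.
RESIDUE_CLASSIFICATION: dict[str, str] = {
    "ARG": "positive", "LYS": "positive", "HIS": "positive",
    "ASP": "negative", "GLU": "negative",
    "SER": "polar", "THR": "polar", "ASN": "polar", "GLN": "polar",
    "TYR": "polar", "CYS": "polar",
    "ALA": "nonpolar", "VAL": "nonpolar", "LEU": "nonpolar", "ILE": "nonpolar",
    "PRO": "nonpolar", "PHE": "nonpolar", "MET": "nonpolar", "GLY": "nonpolar",
    "TRP": "nonpolar",
}


class StructureError(ValueError):
    """Malformed or internally inconsistent structure."""


class StructureParseError(StructureError):
    """Unreadable input file."""


class SelectionError(StructureError):
    """A chromophore selection did not resolve to a usable atom set."""


def classify_residue(resname: str) -> str:
    """Classification for a residue name; unknown names count as nonpolar."""
    return RESIDUE_CLASSIFICATION.get(resname.upper(), "nonpolar")


@dataclass(frozen=True)
class Atom:
    """One atom: identity, residue membership, position (A), charge (e)."""

    id: int
    name: str
    element: str
    residue_key: tuple[str, str, int]  # (chain id, residue name, residue number)
    position: np.ndarray
    partial_charge: float = 0.0
    is_backbone: bool = False

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise StructureError(f"atom {self.id}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if not self.residue_key or len(self.residue_key) != 3:
            raise StructureError(f"atom {self.id}: residue_key must be (chain, resname, resnum)")
        if self.is_backbone and self.name.upper() not in BACKBONE_ATOM_NAMES:
            raise StructureError(
                f"atom {self.id} ({self.name}): is_backbone set but name not in backbone set"
            )

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


@dataclass(frozen=True)
class Chromophore:
    """Ordered conjugated-chain atom ids of one pigment."""

    label: str
    atom_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        ids = tuple(int(i) for i in self.atom_ids)
        if len(ids) < 2:
            raise SelectionError(f"chromophore {self.label}: needs >= 2 atoms, got {len(ids)}")
        if len(set(ids)) != len(ids):
            raise SelectionError(f"chromophore {self.label}: duplicate atom ids")
        object.__setattr__(self, "atom_ids", ids)


@dataclass(frozen=True)
class ResidueGroup:
    """All atoms of one environment residue, with its side-chain subset."""

    residue_key: tuple[str, str, int]
    atom_ids: tuple[int, ...]
    side_chain_atom_ids: tuple[int, ...]
    classification: str

    def __post_init__(self) -> None:
        if not set(self.side_chain_atom_ids) <= set(self.atom_ids):
            raise StructureError(f"residue {self.residue_key}: side chain not a subset of atoms")
        if self.classification not in {"positive", "negative", "polar", "nonpolar"}:
            raise StructureError(f"residue {self.residue_key}: bad classification")


@dataclass
class ComplexModel:
    """One frame: all atoms, chromophores, and the partitioned environment."""

    atoms: list[Atom]
    chromophores: list[Chromophore] = field(default_factory=list)
    environment: list[ResidueGroup] = field(default_factory=list)
    unassigned_atom_ids: tuple[int, ...] = ()
    frame_id: int = 0

    def __post_init__(self) -> None:
        ids = [a.id for a in self.atoms]
        if len(set(ids)) != len(ids):
            dup = pd.Series(ids).value_counts()
            raise StructureError(f"duplicate atom ids: {list(dup[dup > 1].index)[:5]}")
        self._by_id = {a.id: a for a in self.atoms}
        self.validate_partition()

    # -- lookups ---------------------------------------------------------
    def atom(self, atom_id: int) -> Atom:
        return self._by_id[atom_id]

    def positions(self, atom_ids: Iterable[int] | None = None) -> np.ndarray:
        if atom_ids is None:
            return np.array([a.position for a in self.atoms])
        return np.array([self._by_id[i].position for i in atom_ids])

    def charges(self, atom_ids: Iterable[int] | None = None) -> np.ndarray:
        if atom_ids is None:
            return np.array([a.partial_charge for a in self.atoms])
        return np.array([self._by_id[i].partial_charge for i in atom_ids])

    def chromophore(self, label: str) -> Chromophore:
        for c in self.chromophores:
            if c.label == label:
                return c
        raise SelectionError(f"no chromophore labelled {label!r}")

    @property
    def environment_atom_ids(self) -> tuple[int, ...]:
        ids: list[int] = []
        for grp in self.environment:
            ids.extend(grp.atom_ids)
        ids.extend(self.unassigned_atom_ids)
        return tuple(ids)

    # -- invariants ------------------------------------------------------
    def validate_partition(self) -> None:
        """Chromophore and environment atoms must be disjoint; if the model is
        partitioned at all, the partition must be exhaustive."""
        chrom_ids: set[int] = set()
        for c in self.chromophores:
            overlap = chrom_ids & set(c.atom_ids)
            if overlap:
                raise SelectionError(f"chromophores overlap on atoms {sorted(overlap)[:5]}")
            missing = [i for i in c.atom_ids if i not in self._by_id]
            if missing:
                raise SelectionError(f"chromophore {c.label}: unknown atom ids {missing[:5]}")
            chrom_ids |= set(c.atom_ids)
        env_ids = set(self.environment_atom_ids)
        if chrom_ids & env_ids:
            raise StructureError("chromophore and environment atoms overlap")
        if self.environment or self.unassigned_atom_ids:
            covered = chrom_ids | env_ids
            if covered != set(self._by_id):
                raise StructureError("partition is not exhaustive")


@dataclass
class Ensemble:
    """Ordered frames sharing one topology (atom count, ids, ordering)."""

    frames: list[ComplexModel]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.frames:
            raise StructureError("ensemble needs >= 1 frame")
        ref = [a.id for a in self.frames[0].atoms]
        for fr in self.frames[1:]:
            if [a.id for a in fr.atoms] != ref:
                raise StructureError("frames do not share topology (atom ids/order differ)")
        fids = [fr.frame_id for fr in self.frames]
        if len(set(fids)) != len(fids):
            raise StructureError("duplicate frame_ids in ensemble")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_charge_table(path: str | Path) -> dict[tuple[str, str], float]:
    """TSV with columns residue_name, atom_name, charge -> lookup dict."""
    df = pd.read_csv(path, sep="\t")
    required = {"residue_name", "atom_name", "charge"}
    if not required <= set(df.columns):
        raise StructureParseError(f"charge table {path}: needs columns {sorted(required)}")
    return {
        (str(r.residue_name).upper(), str(r.atom_name).upper()): float(r.charge)
        for r in df.itertuples()
    }


def _element_from(name: str, element: str | None) -> str:
    if element and element.strip():
        return element.strip().capitalize()
    stripped = name.strip().lstrip("0123456789")
    if stripped[:1].upper() == "H":
        return "H"
    return stripped[:1].upper() or "X"


def _universe(path: str | Path):
    import MDAnalysis as mda

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return mda.Universe(str(path))
    except Exception as exc:  # noqa: BLE001 - surface as a parse error
        raise StructureParseError(f"cannot read {path}: {exc}") from exc


def _frame_atoms(
    u,
    charges: Mapping[tuple[str, str], float] | None,
    have_charges: bool,
) -> list[Atom]:
    atoms: list[Atom] = []
    missing = 0
    elements = getattr(u.atoms, "elements", None)
    chainids = getattr(u.atoms, "chainIDs", None)
    icodes = getattr(u.atoms, "icodes", None)
    for idx, at in enumerate(u.atoms):
        name = str(at.name).strip()
        resname = str(at.resname).strip().upper()
        chain = ""
        if chainids is not None:
            chain = str(chainids[idx]).strip()
        if not chain:
            chain = str(getattr(at, "segid", "")).strip() or "A"
        resnum = int(at.resid)
        # insertion codes folded into the residue-number key
        if icodes is not None and str(icodes[idx]).strip():
            resnum = resnum * 100 + (ord(str(icodes[idx]).strip()[0]) - ord("A") + 1)
        if have_charges:
            q = float(at.charge)
        elif charges is not None:
            key = (resname, name.upper())
            if key in charges:
                q = charges[key]
            else:
                q = 0.0
                missing += 1
                logger.warning("no charge mapping for %s %s; using 0", resname, name)
        else:
            q = 0.0
            missing += 1
            logger.warning("no charge table; charge of %s %s set to 0", resname, name)
        elem = _element_from(name, elements[idx] if elements is not None else None)
        atoms.append(
            Atom(
                id=int(at.id),
                name=name,
                element=elem,
                residue_key=(chain, resname, resnum),
                position=at.position.astype(float).copy(),
                partial_charge=q,
                is_backbone=name.upper() in BACKBONE_ATOM_NAMES,
            )
        )
    if missing:
        logger.warning("%d atoms received a default charge of 0", missing)
    return atoms


def read_structure(path: str | Path, charge_table: str | Path | None = None) -> ComplexModel:
    """Read a PDB (first model) or PQR file into an unpartitioned ComplexModel.

    PQR files carry their own charges.  For PDB input, ``charge_table`` maps
    (residue name, atom name) to a partial charge; atoms without a mapping get
    charge 0 with a logged warning.  Altloc conflicts resolve to the first
    conformer listed.
    """
    u = _universe(path)
    have_charges = str(path).lower().endswith(".pqr")
    charges = read_charge_table(charge_table) if charge_table else None
    if getattr(u.atoms, "altLocs", None) is not None:
        alts = [str(a).strip() for a in u.atoms.altLocs]
        first_alt = sorted({a for a in alts if a})
        keep = [i for i, al in enumerate(alts) if al in ("", first_alt[0] if first_alt else "")]
        if 0 < len(keep) < len(u.atoms):
            u = __import__("MDAnalysis").Merge(u.atoms[keep])
    return ComplexModel(atoms=_frame_atoms(u, charges, have_charges), frame_id=0)


def read_ensemble(path: str | Path, charge_table: str | Path | None = None) -> Ensemble:
    """Read a multi-model PDB into an Ensemble (one frame per model)."""
    u = _universe(path)
    have_charges = str(path).lower().endswith(".pqr")
    charges = read_charge_table(charge_table) if charge_table else None
    frames = []
    for i, _ts in enumerate(u.trajectory):
        atoms = _frame_atoms(u, charges, have_charges)
        frames.append(ComplexModel(atoms=atoms, frame_id=i))
    return Ensemble(frames=frames, metadata={"source": str(path)})


def write_pqr(model: ComplexModel, path: str | Path, default_radius: float = 1.5) -> None:
    """Write one frame as PQR (positions to 0.001 A, charges to 0.0001 e)."""
    import MDAnalysis as mda

    n = len(model.atoms)
    u = mda.Universe.empty(n, n_residues=n, atom_resindex=np.arange(n), trajectory=True)
    # one MDA residue per atom row would inflate the file; regroup properly
    keys = [a.residue_key for a in model.atoms]
    uniq: list[tuple[str, str, int]] = []
    resindex = np.empty(n, dtype=int)
    for i, k in enumerate(keys):
        if not uniq or uniq[-1] != k:
            uniq.append(k)
        resindex[i] = len(uniq) - 1
    chains = sorted({k[0] for k in uniq}) or ["A"]
    chain_index = {c: i for i, c in enumerate(chains)}
    u = mda.Universe.empty(
        n,
        n_residues=len(uniq),
        n_segments=len(chains),
        atom_resindex=resindex,
        residue_segindex=[chain_index[k[0]] for k in uniq],
        trajectory=True,
    )
    u.add_TopologyAttr("names", [a.name for a in model.atoms])
    u.add_TopologyAttr("elements", [a.element for a in model.atoms])
    u.add_TopologyAttr("resnames", [k[1] for k in uniq])
    u.add_TopologyAttr("resids", [k[2] for k in uniq])
    u.add_TopologyAttr("segids", chains)
    u.add_TopologyAttr("charges", [a.partial_charge for a in model.atoms])
    u.add_TopologyAttr("radii", [default_radius] * n)
    u.add_TopologyAttr("ids", [a.id for a in model.atoms])
    u.atoms.positions = model.positions()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


# ---------------------------------------------------------------------------
# Partitioning and neighbour search
# ---------------------------------------------------------------------------

Selection = Sequence[int] | str | Callable[[Atom], bool]


def resolve_selection(model: ComplexModel, selection: Selection) -> list[int]:
    """Resolve a selection (atom-id list, 'resname XXX' string, or predicate)."""
    if callable(selection):
        return [a.id for a in model.atoms if selection(a)]
    if isinstance(selection, str):
        parts = selection.split()
        if len(parts) == 2 and parts[0].lower() == "resname":
            target = parts[1].upper()
            return [a.id for a in model.atoms if a.residue_key[1] == target]
        raise SelectionError(f"unsupported selection string {selection!r}")
    return [int(i) for i in selection]


def _group_environment(
    atoms_by_id: Mapping[int, Atom], env_ids: Iterable[int]
) -> tuple[list[ResidueGroup], tuple[int, ...]]:
    groups: dict[tuple[str, str, int], list[int]] = {}
    unassigned: list[int] = []
    for i in env_ids:
        a = atoms_by_id[i]
        if a.residue_key[1] in SOLVENT_RESNAMES:
            unassigned.append(i)
        else:
            groups.setdefault(a.residue_key, []).append(i)
    residue_groups = [
        ResidueGroup(
            residue_key=key,
            atom_ids=tuple(ids),
            side_chain_atom_ids=tuple(i for i in ids if not atoms_by_id[i].is_backbone),
            classification=classify_residue(key[1]),
        )
        for key, ids in groups.items()
    ]
    return residue_groups, tuple(unassigned)


def partition(
    model: ComplexModel,
    chromophore_spec: Selection | Mapping[str, Selection],
    label: str = "CHROM",
) -> ComplexModel:
    """Partition a model into chromophore(s) and per-residue environment.

    ``chromophore_spec`` is a single selection or a mapping label -> selection
    for multiple pigments; selections must be disjoint and resolve to >= 2
    atoms each.  Solvent/ion atoms stay unassigned.
    """
    if isinstance(chromophore_spec, Mapping):
        specs = dict(chromophore_spec)
    else:
        specs = {label: chromophore_spec}
    by_id = {a.id: a for a in model.atoms}
    chromophores: list[Chromophore] = []
    taken: set[int] = set()
    for lab, sel in specs.items():
        ids = resolve_selection(model, sel)
        if len(ids) < 2:
            raise SelectionError(f"selection for {lab!r} resolves to {len(ids)} atoms (need >= 2)")
        if taken & set(ids):
            raise SelectionError(f"selection for {lab!r} overlaps a previous chromophore")
        taken |= set(ids)
        chromophores.append(Chromophore(label=lab, atom_ids=tuple(ids)))
    env_ids = [a.id for a in model.atoms if a.id not in taken]
    environment, unassigned = _group_environment(by_id, env_ids)
    return ComplexModel(
        atoms=list(model.atoms),
        chromophores=chromophores,
        environment=environment,
        unassigned_atom_ids=unassigned,
        frame_id=model.frame_id,
    )


def neighbors_within(
    model: ComplexModel,
    chromophore: Chromophore,
    cutoff: float,
    classes: Iterable[str] | None = None,
) -> list[ResidueGroup]:
    """Environment residues whose minimum heavy-atom distance to the
    chromophore is <= cutoff (A), optionally filtered by classification."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    wanted = set(classes) if classes is not None else None
    chrom_pos = np.array(
        [model.atom(i).position for i in chromophore.atom_ids if model.atom(i).is_heavy]
    )
    out: list[ResidueGroup] = []
    for grp in model.environment:
        if wanted is not None and grp.classification not in wanted:
            continue
        heavy = [model.atom(i).position for i in grp.atom_ids if model.atom(i).is_heavy]
        if not heavy:
            continue
        if cdist(np.array(heavy), chrom_pos).min() <= cutoff:
            out.append(grp)
    return out
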