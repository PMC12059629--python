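"""Pocket electrostatics: potentials on the chromophore, the DeltaP
imbalance statistic, the per-residue charge turn-off scan, and PCA of
potential profiles.

The environment potential at chromophore atom i is the bare Coulomb sum
phi_i = sum_j q_j / r_ij over all environment atoms (protein, solvent, ions;
no cutoff, no screening), in e/Angstrom.  DeltaP condenses the profile into
a signed end-to-end imbalance along the conjugated chain: the mean potential
over the first half of the ordered chain minus the mean over the second half
(odd chains drop the middle atom).  It is the driving variable of the
dark/bright mixing surrogate.

The turn-off scan zeroes one residue's *side-chain* charges at a time
(backbone retained), recomputes DeltaP and the adiabatic dark-state TDM mu,
and reports log10(mu / mu_ref) per frame against the all-on reference,
summarized as box statistics (median, quartiles, 1.5*IQR whiskers, outliers).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .core_model import Chromophore, ComplexModel, Ensemble, ResidueGroup
from .state_mixing import MixingParameters, diagonalize_two_state, mixing_coupling
from .tresp import SingularityError

logger = logging.getLogger(__name__)

#: e/Angstrom -> volts (e / (4 pi eps0 Angstrom)).
E_PER_ANGSTROM_TO_VOLT = 14.3996


class DegenerateReferenceError(ValueError):
    """All-on reference TDM is zero; effects are undefined."""


@dataclass(frozen=True)
class PotentialProfile:
    """Environment potential (e/A) at each chromophore atom of one frame."""

    frame_id: int
    phi: np.ndarray
    source_mask: str = "all"

    def __post_init__(self) -> None:
        phi = np.asarray(self.phi, dtype=float)
        if not np.all(np.isfinite(phi)):
            raise ValueError("potential profile contains non-finite values")
        object.__setattr__(self, "phi", phi)

    def in_volts(self) -> np.ndarray:
        return self.phi * E_PER_ANGSTROM_TO_VOLT


@dataclass(frozen=True)
class ImbalanceStat:
    """Signed end-to-end potential imbalance DeltaP (e/A) of one frame."""

    frame_id: int
    delta_p: float


@dataclass
class ResidueEffect:
    """Per-frame turn-off effects log10(mu/mu_ref) for one residue."""

    residue_key: tuple[str, str, int]
    classification: str
    values: np.ndarray
    skipped_frames: list[int] = field(default_factory=list)

    @property
    def summary(self) -> dict[str, float]:
        v = np.asarray(self.values, dtype=float)
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = v[(v >= lo_fence) & (v <= hi_fence)]
        return {
            "median": float(med),
            "q1": float(q1),
            "q3": float(q3),
            "whisker_low": float(inside.min()) if inside.size else float(med),
            "whisker_high": float(inside.max()) if inside.size else float(med),
            "n_outliers": int(((v < lo_fence) | (v > hi_fence)).sum()),
            "n": int(v.size),
        }


def potential_on_atoms(
    model: ComplexModel,
    chromophore: Chromophore,
    exclude: Iterable[tuple[str, str, int]] | None = None,
    exclude_side_chains_only: bool = True,
) -> PotentialProfile:
    """Coulomb potential of the environment on each chromophore atom.

    ``exclude`` names residues whose charges are dropped from the sum; with
    ``exclude_side_chains_only`` (the turn-off convention) only their
    side-chain atoms are dropped, backbone charges remain.
    """
    excluded_ids: set[int] = set()
    if exclude:
        keys = set(exclude)
        for grp in model.environment:
            if grp.residue_key in keys:
                excluded_ids |= set(
                    grp.side_chain_atom_ids if exclude_side_chains_only else grp.atom_ids
                )
    env_ids = [i for i in model.environment_atom_ids if i not in excluded_ids]
    chrom_pos = model.positions(chromophore.atom_ids)
    if not env_ids:
        return PotentialProfile(model.frame_id, np.zeros(len(chromophore.atom_ids)))
    env_pos = model.positions(env_ids)
    env_q = model.charges(env_ids)
    r = cdist(chrom_pos, env_pos)
    if r.min() <= 0.0:
        i, j = np.unravel_index(np.argmin(r), r.shape)
        raise SingularityError(
            f"environment atom {env_ids[j]} coincides with chromophore atom "
            f"{chromophore.atom_ids[i]}"
        )
    phi = (1.0 / r) @ env_q
    mask = "all" if not exclude else f"all minus {sorted(set(exclude))}"
    return PotentialProfile(model.frame_id, phi, source_mask=mask)


def delta_p(profile: PotentialProfile, chromophore: Chromophore) -> ImbalanceStat:
    """Half-chain mean potential difference along the conjugated-atom order."""
    n = len(chromophore.atom_ids)
    if n < 2 or len(profile.phi) != n:
        raise ValueError("need a profile over a chromophore with >= 2 atoms")
    half = n // 2
    first = profile.phi[:half]
    second = profile.phi[n - half:]
    return ImbalanceStat(profile.frame_id, float(first.mean() - second.mean()))


def _frame_mu_dark(
    model: ComplexModel,
    chromophore: Chromophore,
    params: MixingParameters,
    frame_index: int,
    exclude: Iterable[tuple[str, str, int]] | None = None,
) -> tuple[float, float]:
    prof = potential_on_atoms(model, chromophore, exclude=exclude)
    dp = delta_p(prof, chromophore).delta_p
    res = diagonalize_two_state(
        params.diabatic(frame_index), mixing_coupling(dp, params), model.frame_id
    )
    return dp, res.mu_dark_state


def turn_off_scan(
    ensemble: Ensemble,
    chromophore_label: str,
    residues: Sequence[ResidueGroup | tuple[str, str, int]],
    params: MixingParameters,
) -> list[ResidueEffect]:
    """Per-residue electrostatic turn-off effects on the dark-state TDM.

    For each residue r and frame f, the residue's side-chain charges are
    zeroed, DeltaP and the adiabatic dark TDM mu are recomputed, and the
    effect log10(mu / mu_ref) is recorded against the frame's all-on
    reference.  Frames with mu_ref = 0 are skipped with a warning.
    """
    keys: list[tuple[str, str, int]] = []
    classes: dict[tuple[str, str, int], str] = {}
    for r in residues:
        key = r.residue_key if isinstance(r, ResidueGroup) else tuple(r)
        keys.append(key)
    first = ensemble.frames[0]
    for grp in first.environment:
        classes[grp.residue_key] = grp.classification
    missing = [k for k in keys if k not in classes]
    if missing:
        raise ValueError(f"residues not in the environment: {missing[:5]}")

    effects: dict[tuple[str, str, int], list[float]] = {k: [] for k in keys}
    skipped: dict[tuple[str, str, int], list[int]] = {k: [] for k in keys}
    for fi, frame in enumerate(ensemble.frames):
        chrom = frame.chromophore(chromophore_label)
        _, mu_ref = _frame_mu_dark(frame, chrom, params, fi)
        if mu_ref == 0.0:
            logger.warning("frame %d: reference dark TDM is 0; frame skipped", frame.frame_id)
            for k in keys:
                skipped[k].append(frame.frame_id)
            continue
        for k in keys:
            _, mu = _frame_mu_dark(frame, chrom, params, fi, exclude=[k])
            effects[k].append(np.log10(mu / mu_ref) if mu > 0 else -np.inf)
    return [
        ResidueEffect(
            residue_key=k,
            classification=classes[k],
            values=np.asarray(effects[k]),
            skipped_frames=skipped[k],
        )
        for k in keys
    ]


@dataclass
class PCAPotentials:
    """Principal components of frame-by-atom potential profiles."""

    components: np.ndarray  # (n_components, n_atoms)
    explained_variance_ratio: np.ndarray
    scores: np.ndarray  # (n_frames, n_components)
    mean: np.ndarray
    degenerate: bool = False

    def project(self, profiles: Sequence[PotentialProfile] | np.ndarray) -> np.ndarray:
        """Project another ensemble's profiles onto these components."""
        x = _profile_matrix(profiles)
        return (x - self.mean) @ self.components.T


def _profile_matrix(profiles: Sequence[PotentialProfile] | np.ndarray) -> np.ndarray:
    if isinstance(profiles, np.ndarray):
        return profiles
    return np.vstack([p.phi for p in profiles])


def pca_potentials(
    profiles: Sequence[PotentialProfile] | np.ndarray,
    n_components: int | None = None,
) -> PCAPotentials:
    """PCA (column-mean-centered SVD) of the frames x atoms potential matrix."""
    from sklearn.decomposition import PCA

    x = _profile_matrix(profiles)
    if x.shape[0] < 2:
        raise ValueError("PCA needs >= 2 frames")
    if np.allclose(x, x[0]):
        return PCAPotentials(
            components=np.zeros((0, x.shape[1])),
            explained_variance_ratio=np.zeros(0),
            scores=np.zeros((x.shape[0], 0)),
            mean=x.mean(axis=0),
            degenerate=True,
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    return PCAPotentials(
        components=pca.components_,
        explained_variance_ratio=pca.explained_variance_ratio_,
        scores=scores,
        mean=pca.mean_,
    )
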