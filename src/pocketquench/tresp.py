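"""Transition charges (TrEsp): fitting, rescaling, and EET couplings.

The TrEsp approximation represents a pigment's transition density by atomic
point charges :math:`q_i^{tr}`.  The Coulomb excitation-energy-transfer
coupling between chromophores A and B is then the unscreened double sum

.. math::

    V_{AB} = \\sum_{i \\in A} \\sum_{j \\in B} \\frac{q_i^{tr} q_j^{tr}}{r_{ij}}

evaluated here in e^2/Angstrom and converted to cm^-1 (14.3996 eV*A/e^2,
8065.544 cm^-1/eV).  Transition charges sum to zero, as the transition
density they discretize integrates to zero; the fit enforces this with a
Lagrange multiplier rather than post-hoc shifting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .units import COULOMB_EV_ANGSTROM, EANGSTROM_TO_DEBYE, EV_TO_INVCM

ZERO_SUM_TOL = 1e-10


class SingularityError(ValueError):
    """Two atoms from different charge sets coincide."""


class ConditioningError(ValueError):
    """The charge-fitting design matrix is effectively rank deficient."""


class UndefinedScalingError(ValueError):
    """Rescaling requested for a set with zero transition dipole."""


@dataclass(frozen=True)
class TransitionChargeSet:
    """Per-atom transition charges (e) of one pigment state in one frame."""

    pigment_label: str
    atom_ids: tuple[int, ...]
    charges: np.ndarray
    frame_id: int = 0
    residual_norm: float | None = None

    def __post_init__(self) -> None:
        q = np.asarray(self.charges, dtype=float)
        if q.shape != (len(self.atom_ids),):
            raise ValueError("one charge per atom id required")
        if abs(q.sum()) > ZERO_SUM_TOL:
            raise ValueError(f"transition charges must sum to 0 (got {q.sum():.3e})")
        object.__setattr__(self, "charges", q)
        object.__setattr__(self, "atom_ids", tuple(int(i) for i in self.atom_ids))

    def scaled(self, factor: float) -> "TransitionChargeSet":
        return TransitionChargeSet(
            self.pigment_label, self.atom_ids, self.charges * factor, self.frame_id
        )


@dataclass(frozen=True)
class CouplingResult:
    """Coulomb EET coupling between one donor/acceptor pair (cm^-1)."""

    donor: str
    acceptor: str
    v_ab: float
    frame_id: int = 0


def transition_dipole(tcs: TransitionChargeSet, positions: np.ndarray) -> np.ndarray:
    """Transition dipole vector (Debye) of a charge set at given positions."""
    positions = np.asarray(positions, dtype=float)
    return EANGSTROM_TO_DEBYE * (tcs.charges[:, None] * positions).sum(axis=0)


def coupling(
    a: TransitionChargeSet,
    positions_a: np.ndarray,
    b: TransitionChargeSet,
    positions_b: np.ndarray,
    screening: float = 1.0,
) -> CouplingResult:
    """TrEsp Coulomb coupling V_AB in cm^-1.

    ``screening`` is an optional uniform multiplier (default 1: vacuum
    Coulomb, no distance cutoff).
    """
    ra = np.asarray(positions_a, dtype=float)
    rb = np.asarray(positions_b, dtype=float)
    r = cdist(ra, rb)
    if r.min() <= 0.0:
        i, j = np.unravel_index(np.argmin(r), r.shape)
        raise SingularityError(
            f"atoms {a.atom_ids[i]} (donor) and {b.atom_ids[j]} (acceptor) coincide"
        )
    v_e2_per_ang = a.charges @ (1.0 / r) @ b.charges
    v_cm = screening * v_e2_per_ang * COULOMB_EV_ANGSTROM * EV_TO_INVCM
    return CouplingResult(
        donor=a.pigment_label,
        acceptor=b.pigment_label,
        v_ab=float(v_cm),
        frame_id=a.frame_id,
    )


def fit_transition_charges(
    atom_positions: np.ndarray,
    sample_points: np.ndarray,
    sample_values: np.ndarray,
    atom_ids: tuple[int, ...] | None = None,
    pigment_label: str = "PIG",
    frame_id: int = 0,
    cond_threshold: float = 1e12,
) -> TransitionChargeSet:
    """Fit zero-sum point charges to a sampled transition potential.

    Minimizes sum_k (sum_i q_i/|r_k - r_i| - phi_k)^2 subject to sum_i q_i = 0,
    solved as an equality-constrained linear least-squares (KKT) system.
    Potential samples are in e/Angstrom at points distinct from the atoms.
    """
    pos = np.asarray(atom_positions, dtype=float)
    pts = np.asarray(sample_points, dtype=float)
    phi = np.asarray(sample_values, dtype=float)
    n, m = len(pos), len(pts)
    if m < n:
        raise ValueError(f"need at least as many samples ({m}) as atoms ({n})")
    r = cdist(pts, pos)
    if r.min() <= 0.0:
        raise SingularityError("a sample point coincides with an atom position")
    design = 1.0 / r
    # KKT system for min ||A q - phi||^2 s.t. 1^T q = 0
    kkt = np.zeros((n + 1, n + 1))
    kkt[:n, :n] = 2.0 * design.T @ design
    kkt[:n, n] = 1.0
    kkt[n, :n] = 1.0
    rhs = np.concatenate([2.0 * design.T @ phi, [0.0]])
    if np.linalg.cond(kkt) > cond_threshold:
        raise ConditioningError(
            "charge fit is ill-conditioned (samples do not distinguish the atoms)"
        )
    sol = np.linalg.solve(kkt, rhs)
    q = sol[:n]
    q -= q.sum() / n  # remove numerical zero-sum residue
    residual = float(np.linalg.norm(design @ q - phi))
    ids = atom_ids if atom_ids is not None else tuple(range(n))
    return TransitionChargeSet(
        pigment_label=pigment_label,
        atom_ids=tuple(ids),
        charges=q,
        frame_id=frame_id,
        residual_norm=residual,
    )


def rescale_to_dipole(
    tcs: TransitionChargeSet, positions: np.ndarray, target_tdm: float
) -> TransitionChargeSet:
    """Scale charges so the transition dipole magnitude equals target_tdm (D)."""
    mu = float(np.linalg.norm(transition_dipole(tcs, positions)))
    if mu <= 0.0:
        raise UndefinedScalingError("current transition dipole is zero; scaling undefined")
    return tcs.scaled(target_tdm / mu)
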