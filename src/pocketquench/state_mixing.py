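"""Two-state surrogate for electrostatically induced dark/bright mixing.

An isolated carotenoid's S1 (2Ag-) state is optically forbidden (dark) while
S2 (1Bu+) is allowed (bright).  An asymmetric electrostatic environment mixes
the two, lending the dark state transition dipole strength ("intensity
borrowing").  We model this with an essential-state 2x2 Hamiltonian in the
diabatic {dark, bright} basis:

    H = [[E_dark, W], [W, E_bright]],   W = k_mix * DeltaP,

where DeltaP is the pocket potential-imbalance statistic (e/Angstrom) and
k_mix (eV per e/Angstrom) converts imbalance into diabatic coupling.
Diagonalization gives the mixing angle theta = 1/2 atan2(2W, E_b - E_d);
the dark-character adiabatic state acquires TDM |sin(theta)| * mu_bright and
the bright-character state keeps |cos(theta)| * mu_bright, so the total
dipole strength mu_1^2 + mu_2^2 is conserved exactly.  Frames where
|theta| > pi/4 have the energetic order of the dark- and bright-character
states inverted (near-degeneracy, very strong mixing).

k_mix is not predicted from first principles; it is calibrated once so a
reference ensemble reproduces a reference dark-state TDM (see calibrate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq


class CalibrationError(ValueError):
    """The calibration target cannot be reached by any k_mix."""


@dataclass(frozen=True)
class DiabaticStates:
    """Unmixed dark/bright energies (eV) and the bright-state TDM (D).

    The diabatic dark state is strictly forbidden: mu_dark = 0 by construction.
    """

    e_dark: float
    e_bright: float
    mu_bright: float

    mu_dark: float = field(default=0.0, init=False)

    def __post_init__(self) -> None:
        if not (np.isfinite(self.e_dark) and np.isfinite(self.e_bright)):
            raise ValueError("diabatic energies must be finite")
        if not self.mu_bright > 0:
            raise ValueError("diabatic bright TDM must be positive")


@dataclass(frozen=True)
class AdiabaticResult:
    """Mixed-state energies (eV), TDMs (D) and mixing diagnostics for a frame.

    e1/e2 are ordered by energy (mu_1/mu_2 follow that order); mu_dark_state /
    mu_bright_state follow diabatic *character* instead, so trends remain
    well defined across the inversion.
    """

    frame_id: int
    e1: float
    e2: float
    mu_1: float
    mu_2: float
    theta: float
    w: float
    inverted: bool

    @property
    def gap(self) -> float:
        return self.e2 - self.e1

    @property
    def mu_dark_state(self) -> float:
        """TDM of the adiabatic state with dominant dark character."""
        return self.mu_2 if self.inverted else self.mu_1

    @property
    def mu_bright_state(self) -> float:
        return self.mu_1 if self.inverted else self.mu_2


@dataclass
class MixingParameters:
    """Calibrated surrogate parameters.

    e_dark/e_bright may be scalars or per-frame arrays (the synthetic
    generator draws them per frame, which is what allows the inversion
    phenomenology to appear at strong mixing).
    """

    k_mix: float
    mu_bright_diabatic: float
    e_dark: float | np.ndarray = 2.05
    e_bright: float | np.ndarray = 2.25
    seed: int | None = None
    diagnostics: dict = field(default_factory=dict)

    def diabatic(self, frame_index: int = 0) -> DiabaticStates:
        ed = np.atleast_1d(np.asarray(self.e_dark, dtype=float))
        eb = np.atleast_1d(np.asarray(self.e_bright, dtype=float))
        return DiabaticStates(
            e_dark=float(ed[frame_index % len(ed)]),
            e_bright=float(eb[frame_index % len(eb)]),
            mu_bright=self.mu_bright_diabatic,
        )


def mixing_coupling(delta_p: float, params: MixingParameters) -> float:
    """Diabatic coupling W = k_mix * DeltaP (eV, signed)."""
    return params.k_mix * float(delta_p)


def diagonalize_two_state(d: DiabaticStates, w: float, frame_id: int = 0) -> AdiabaticResult:
    """Diagonalize the 2x2 diabatic Hamiltonian under coupling w (eV)."""
    delta = d.e_bright - d.e_dark
    theta = 0.5 * math.atan2(2.0 * w, delta)
    half_split = 0.5 * math.hypot(delta, 2.0 * w)
    mean = 0.5 * (d.e_dark + d.e_bright)
    # lower eigenstate = cos(theta)|dark> - sin(theta)|bright>, so its TDM is
    # |sin(theta)|*mu_bright regardless of branch; the upper carries the rest.
    mu_lower = abs(math.sin(theta)) * d.mu_bright
    mu_upper = abs(math.cos(theta)) * d.mu_bright
    inverted = abs(theta) > math.pi / 4.0
    return AdiabaticResult(
        frame_id=frame_id,
        e1=mean - half_split,
        e2=mean + half_split,
        mu_1=mu_lower,
        mu_2=mu_upper,
        theta=theta,
        w=w,
        inverted=inverted,
    )


def mean_mu_dark(delta_ps: np.ndarray, params: MixingParameters) -> float:
    """Ensemble-mean dark-character TDM under the current parameters."""
    out = []
    for i, dp in enumerate(np.asarray(delta_ps, dtype=float)):
        res = diagonalize_two_state(params.diabatic(i), mixing_coupling(dp, params), i)
        out.append(res.mu_dark_state)
    return float(np.mean(out))


def calibrate(
    delta_ps: np.ndarray,
    reference_mu_dark: float,
    mu_bright_diabatic: float,
    e_dark: float | np.ndarray = 2.05,
    e_bright: float | np.ndarray = 2.25,
    k_max: float = 1e4,
    xtol: float = 1e-12,
) -> MixingParameters:
    """Solve for k_mix so the ensemble-mean dark TDM hits reference_mu_dark (D).

    The response is monotone in k_mix >= 0, so a bracketed bisection
    (scipy brentq) suffices.  Raises CalibrationError when the target is
    unreachable (e.g. all DeltaP = 0, or target above the saturation mean).
    """
    delta_ps = np.asarray(delta_ps, dtype=float)
    if reference_mu_dark < 0:
        raise CalibrationError("reference dark TDM must be >= 0")
    if reference_mu_dark == 0.0:
        return MixingParameters(0.0, mu_bright_diabatic, e_dark, e_bright)
    if np.allclose(delta_ps, 0.0):
        raise CalibrationError("all DeltaP are 0; no coupling can produce a dark TDM")

    def objective(k: float) -> float:
        p = MixingParameters(k, mu_bright_diabatic, e_dark, e_bright)
        return mean_mu_dark(delta_ps, p) - reference_mu_dark

    lo, hi = 0.0, 1.0
    while objective(hi) < 0.0:
        hi *= 4.0
        if hi > k_max:
            raise CalibrationError(
                f"target {reference_mu_dark} D unreachable (saturates below it)"
            )
    k_fit = float(brentq(objective, lo, hi, xtol=xtol))
    params = MixingParameters(k_fit, mu_bright_diabatic, e_dark, e_bright)
    params.diagnostics = {
        "target_mu_dark": reference_mu_dark,
        "achieved_mu_dark": mean_mu_dark(delta_ps, params),
        "n_frames": int(len(delta_ps)),
    }
    return params
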