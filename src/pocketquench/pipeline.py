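"""End-to-end workflow glue: presets -> ensembles -> calibrated mixing ->
per-frame tables and cross-preset comparisons.

The calibration convention: the mixing strength k_mix is fitted once, on the
reference (OCP1-like) ensemble, so its mean adiabatic dark-state TDM equals
the reference anchor of 8.2 D; the same k_mix is then applied unchanged to
every other preset (only the per-frame diabatic energies differ, drawn from
each preset's own distribution).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import synthetic_data as sd
from .core_model import Ensemble
from .ensemble_analysis import EnsembleSummary, per_frame_table, summarize
from .pocket_electrostatics import delta_p, potential_on_atoms
from .state_mixing import MixingParameters, calibrate

REFERENCE_MU_DARK = 8.2  # D; dark-state TDM anchor of the reference complex
DEFAULT_N_FRAMES = 60


@dataclass
class PresetAnalysis:
    """Everything computed for one preset ensemble."""

    preset_name: str
    ensemble: Ensemble
    params: MixingParameters
    table: pd.DataFrame
    summary: EnsembleSummary


def ensemble_delta_ps(ensemble: Ensemble, chromophore_label: str = "CAN") -> np.ndarray:
    out = []
    for frame in ensemble.frames:
        chrom = frame.chromophore(chromophore_label)
        out.append(delta_p(potential_on_atoms(frame, chrom), chrom).delta_p)
    return np.asarray(out)


def build_preset_ensemble(
    preset_name: str, seed: int, n_frames: int = DEFAULT_N_FRAMES
) -> tuple[sd.SyntheticComplex, Ensemble]:
    synth = sd.build_complex(sd.PRESETS[preset_name]())
    return synth, sd.generate_ensemble(synth, n_frames=n_frames, seed=seed)


def calibrate_reference(
    seed: int,
    n_frames: int = DEFAULT_N_FRAMES,
    reference_mu_dark: float = REFERENCE_MU_DARK,
    reference_preset: str = "ocp1-like",
) -> MixingParameters:
    """Fit k_mix on the reference preset's ensemble (see module docstring)."""
    synth, ens = build_preset_ensemble(reference_preset, seed, n_frames)
    dps = ensemble_delta_ps(ens)
    return calibrate(
        dps,
        reference_mu_dark,
        synth.preset.mu_bright_diabatic,
        ens.metadata["e_dark"],
        ens.metadata["e_bright"],
    )


def analyze_preset(
    preset_name: str,
    seed: int,
    k_mix: float,
    n_frames: int = DEFAULT_N_FRAMES,
) -> PresetAnalysis:
    """Run the full per-frame analysis for one preset under a given k_mix."""
    synth, ens = build_preset_ensemble(preset_name, seed, n_frames)
    params = MixingParameters(
        k_mix=k_mix,
        mu_bright_diabatic=synth.preset.mu_bright_diabatic,
        e_dark=ens.metadata["e_dark"],
        e_bright=ens.metadata["e_bright"],
        seed=seed,
    )
    table = per_frame_table(ens, "CAN", params, synth.donor_tcs, synth.acceptor_tcs)
    return PresetAnalysis(
        preset_name=preset_name,
        ensemble=ens,
        params=params,
        table=table,
        summary=summarize(table, label=preset_name),
    )


def run_all_presets(
    seed: int, n_frames: int = DEFAULT_N_FRAMES
) -> dict[str, PresetAnalysis]:
    """Calibrate on the OCP1-like preset, then analyze all three presets."""
    ref = calibrate_reference(seed, n_frames)
    return {
        name: analyze_preset(name, seed, ref.k_mix, n_frames) for name in sd.PRESETS
    }
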