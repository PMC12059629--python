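"""Distributions, summaries, and cross-complex comparisons over frames.

This is the analysis layer that turns per-frame mixing results and EET
couplings into the quantities compared between complexes: distributions of
excitation energies and TDMs, the dark-TDM-vs-imbalance correlation, the
inversion fraction, and per-acceptor coupling distributions.  Couplings use
donor transition charges rescaled per frame to that frame's adiabatic
dark-state TDM (acceptor charge sets are static).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_model import Ensemble
from .pocket_electrostatics import delta_p, potential_on_atoms
from .state_mixing import MixingParameters, diagonalize_two_state, mixing_coupling
from .tresp import TransitionChargeSet, coupling, rescale_to_dipole


def per_frame_table(
    ensemble: Ensemble,
    chromophore_label: str,
    params: MixingParameters,
    donor_tcs: TransitionChargeSet,
    acceptor_tcs: dict[str, TransitionChargeSet] | None = None,
) -> pd.DataFrame:
    """Per-frame DeltaP, mixing results, and couplings to each acceptor.

    Columns: frame_id, delta_p, w, e1, e2, gap, mu_dark, mu_bright, theta,
    inverted, plus one ``v_<acceptor>`` column (cm^-1) per acceptor.
    """
    acceptor_tcs = acceptor_tcs or {}
    rows = []
    for fi, frame in enumerate(ensemble.frames):
        chrom = frame.chromophore(chromophore_label)
        prof = potential_on_atoms(frame, chrom)
        dp = delta_p(prof, chrom).delta_p
        res = diagonalize_two_state(
            params.diabatic(fi), mixing_coupling(dp, params), frame.frame_id
        )
        row = {
            "frame_id": frame.frame_id,
            "delta_p": dp,
            "w": res.w,
            "e1": res.e1,
            "e2": res.e2,
            "gap": res.gap,
            "mu_dark": res.mu_dark_state,
            "mu_bright": res.mu_bright_state,
            "theta": res.theta,
            "inverted": res.inverted,
        }
        donor_pos = frame.positions(donor_tcs.atom_ids)
        if res.mu_dark_state > 0:
            donor_frame = rescale_to_dipole(donor_tcs, donor_pos, res.mu_dark_state)
        else:
            donor_frame = donor_tcs.scaled(0.0)
        for label, acc in acceptor_tcs.items():
            acc_pos = frame.positions(acc.atom_ids)
            row[f"v_{label}"] = coupling(donor_frame, donor_pos, acc, acc_pos).v_ab
        rows.append(row)
    return pd.DataFrame(rows)


QUANTITIES = ("gap", "mu_dark", "mu_bright", "delta_p")


@dataclass
class EnsembleSummary:
    """Summary statistics of one complex's per-frame results."""

    label: str
    n_frames: int
    stats: dict[str, dict[str, float]]
    inversion_fraction: float
    fit_mu_dark_vs_delta_p: dict[str, float]
    acceptors: tuple[str, ...] = ()

    def mean(self, quantity: str) -> float:
        return self.stats[quantity]["mean"]


def _col_stats(x: np.ndarray) -> dict[str, float]:
    q = np.percentile(x, [5, 25, 50, 75, 95])
    return {
        "mean": float(np.mean(x)),
        "sd": float(np.std(x, ddof=1)) if len(x) > 1 else 0.0,
        "q05": float(q[0]), "q25": float(q[1]), "median": float(q[2]),
        "q75": float(q[3]), "q95": float(q[4]),
    }


def summarize(df: pd.DataFrame, label: str = "") -> EnsembleSummary:
    """Mean/sd/quantiles of every tracked quantity, the inversion fraction,
    and the linear fit of mu_dark against DeltaP across frames."""
    if len(df) < 2:
        raise ValueError("need >= 2 frames to summarize")
    acceptors = tuple(c[2:] for c in df.columns if c.startswith("v_"))
    out: dict[str, dict[str, float]] = {}
    for q in QUANTITIES:
        out[q] = _col_stats(df[q].to_numpy())
    for acc in acceptors:
        v = df[f"v_{acc}"].to_numpy()
        out[f"v_{acc}"] = _col_stats(v)
        out[f"v_{acc}"]["mean_abs"] = float(np.mean(np.abs(v)))
    if np.ptp(df["delta_p"].to_numpy()) > 0:
        fit = stats.linregress(df["delta_p"], df["mu_dark"])
        fit_d = {
            "slope": float(fit.slope),
            "intercept": float(fit.intercept),
            "r2": float(fit.rvalue**2),
        }
    else:
        fit_d = {"slope": float("nan"), "intercept": float("nan"), "r2": float("nan")}
    return EnsembleSummary(
        label=label,
        n_frames=len(df),
        stats=out,
        inversion_fraction=float(df["inverted"].mean()),
        fit_mu_dark_vs_delta_p=fit_d,
        acceptors=acceptors,
    )


def compare(
    df_a: pd.DataFrame,
    df_b: pd.DataFrame,
    label_a: str = "A",
    label_b: str = "B",
    n_boot: int = 1000,
    seed: int = 0,
) -> dict[str, dict[str, float]]:
    """Per-quantity B/A ratios and differences of means with bootstrap CIs.

    Couplings are compared through the mean of |V|.  Bootstrap: ``n_boot``
    frame resamples per ensemble with a fixed seed; 95% percentile CIs.
    """
    acc_a = {c for c in df_a.columns if c.startswith("v_")}
    acc_b = {c for c in df_b.columns if c.startswith("v_")}
    if acc_a != acc_b:
        raise ValueError(f"acceptor sets differ: {sorted(acc_a)} vs {sorted(acc_b)}")
    rng = np.random.default_rng(seed)
    report: dict[str, dict[str, float]] = {"labels": {"A": label_a, "B": label_b}}
    quantities = [(q, False) for q in QUANTITIES] + [(c, True) for c in sorted(acc_a)]
    for q, use_abs in quantities:
        a = df_a[q].to_numpy()
        b = df_b[q].to_numpy()
        if use_abs:
            a, b = np.abs(a), np.abs(b)
        ratios = np.empty(n_boot)
        for i in range(n_boot):
            am = a[rng.integers(0, len(a), len(a))].mean()
            bm = b[rng.integers(0, len(b), len(b))].mean()
            ratios[i] = bm / am if am != 0 else np.nan
        name = f"abs_{q}" if use_abs else q
        report[name] = {
            "mean_a": float(a.mean()),
            "mean_b": float(b.mean()),
            "ratio": float(b.mean() / a.mean()) if a.mean() != 0 else float("nan"),
            "diff": float(b.mean() - a.mean()),
            "ratio_ci_low": float(np.nanpercentile(ratios, 2.5)),
            "ratio_ci_high": float(np.nanpercentile(ratios, 97.5)),
        }
    return report


@dataclass
class CouplingDistribution:
    """Histogram and means of per-frame couplings to one acceptor."""

    acceptor: str
    counts: np.ndarray
    bin_edges: np.ndarray
    mean_v: float
    mean_abs_v: float
    values: np.ndarray = field(repr=False, default=None)


def coupling_distributions(
    df: pd.DataFrame, acceptors: tuple[str, ...] | None = None, bins="fd"
) -> dict[str, CouplingDistribution]:
    """Per-acceptor coupling histograms (Freedman-Diaconis bins by default)."""
    if acceptors is None:
        acceptors = tuple(c[2:] for c in df.columns if c.startswith("v_"))
    out = {}
    for acc in acceptors:
        v = df[f"v_{acc}"].to_numpy()
        counts, edges = np.histogram(v, bins=bins)
        out[acc] = CouplingDistribution(
            acceptor=acc,
            counts=counts,
            bin_edges=edges,
            mean_v=float(v.mean()),
            mean_abs_v=float(np.abs(v).mean()),
            values=v,
        )
    return out
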