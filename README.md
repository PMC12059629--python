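# pocketquench

Why does one carotenoid-binding quencher drain a phycobilisome faster than
another?  In cyanobacterial photoprotection, the orange carotenoid protein
(OCP) and its single-domain homologs, the helical carotenoid proteins
(HCPs), bind a carotenoid (canthaxanthin, CAN) whose first excited state
S1 (2Ag⁻) is optically forbidden in isolation.  An asymmetric electrostatic
pocket mixes S1 with the bright S2 (1Bu⁺) state, lending the dark state
transition dipole strength; that borrowed dipole sets the Coulomb
excitation-energy-transfer (EET) coupling to the nearby bilin acceptors of
the phycobilisome core, and hence the quenching rate.

`pocketquench` is a Python toolkit for that analysis chain, aimed at people
studying pigment–protein electrostatics and EET:

1. **Structures and charges** (`core_model`): PDB/PQR input (MDAnalysis
   underneath), per-atom partial charges, chromophore/environment
   partitioning, residue classification, neighbour search, multi-frame
   ensembles.
2. **Pocket electrostatics** (`pocket_electrostatics`): the environment
   Coulomb potential φᵢ = Σⱼ qⱼ/rᵢⱼ on each conjugated-chain atom, the
   end-to-end imbalance statistic ΔP (mean φ over the first half of the
   chain minus the second half), per-residue side-chain "turn-off" scans
   reported as log₁₀(µ/µ_ref), and PCA of potential profiles across frames.
3. **Two-state mixing** (`state_mixing`): a closed-form surrogate
   H = [[E_dark, W], [W, E_bright]] with W = k_mix·ΔP; mixing angle
   θ = ½·atan2(2W, E_b − E_d), adiabatic energies
   E∓ = Ē ∓ ½√((E_b−E_d)² + 4W²), dark-state TDM |sin θ|·µ_bright, exact
   dipole-strength conservation, and detection of dark/bright energy-order
   inversion (|θ| > π/4).  k_mix is calibrated so a reference ensemble
   reproduces a reference dark TDM (8.2 D).
4. **TrEsp couplings** (`tresp`): transition charges fitted to sampled
   transition potentials under a zero-sum constraint, per-frame rescaling to
   the adiabatic dark TDM, and the Coulomb coupling
   V_AB = Σᵢ∈A Σⱼ∈B qᵢ qⱼ / rᵢⱼ in cm⁻¹.
5. **Ensemble statistics** (`ensemble_analysis`): distributions, summaries,
   bootstrap comparisons between complexes, coupling histograms.
6. **Synthetic complexes** (`synthetic_data`): seeded toy pigment–protein
   complexes with OCP1-like, HCP5-like, and HCP2-like pocket-charge
   layouts, and pseudo-restrained ensembles (fixed backbone, jittered side
   chains/solvent) emulating backbone-restrained MD.
7. **Gene-family census** (`census`): clade assignment from score tables,
   per-genome OCP/HCP complement tallies, alignment conservation matrices
   (information content in bits), and global pairwise identities.

## Worked example

Calibrate the mixing strength on the OCP1-like pocket and compare the three
presets (60 frames each):

```python
from pocketquench.pipeline import run_all_presets

results = run_all_presets(seed=1, n_frames=60)
for name, res in results.items():
    s = res.summary
    print(f"{name:10s} mu_dark={s.mean('mu_dark'):5.2f} D "
          f"gap={s.mean('gap'):.3f} eV "
          f"|V|_APC1={s.stats['v_APC1']['mean_abs']:5.1f} cm^-1 "
          f"inverted={s.inversion_fraction:.0%}")
```

prints

```
ocp1-like  mu_dark= 8.20 D gap=0.313 eV |V|_APC1= 41.4 cm^-1 inverted=0%
hcp5-like  mu_dark=11.31 D gap=0.287 eV |V|_APC1= 57.2 cm^-1 inverted=12%
hcp2-like  mu_dark= 0.78 D gap=0.247 eV |V|_APC1=  3.9 cm^-1 inverted=0%
```

Reading: after anchoring the OCP1-like ensemble at a dark-state TDM of
8.2 D, the HCP5-like pocket — same scaffold plus an arginine at the
PBS-adjacent end and extra aspartates/glutamates (partly offset by a second
arginine) at the other — produces a larger potential imbalance and a
narrower dark/bright gap, hence stronger mixing: a larger dark TDM, a
smaller adiabatic gap, occasional state-order inversions, and ~40% larger
couplings to both bilin acceptors.  The near-symmetric HCP2-like pocket
keeps ΔP close to zero and its dark state stays nearly forbidden.

The same pipeline is scriptable from the shell:

```sh
pocketquench simulate --preset hcp5-like --seed 1 --out frames.tsv
pocketquench scan-residues --preset hcp5-like --cutoff 10 --out effects.tsv
pocketquench census tally --scores scores.tsv
```

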