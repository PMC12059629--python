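# Methods

## The physical picture

A carotenoid's S0→S1 transition (2Ag⁻ symmetry) is one-photon forbidden, so
an isolated carotenoid cannot transfer its S1 excitation Coulombically.
Inside a protein, the pocket's electric field breaks the symmetry and mixes
S1 with the strongly allowed S2 (1Bu⁺), so the "dark" state borrows
transition dipole strength.  For a quencher bound to a phycobilisome, the
borrowed dipole enters the Coulomb EET coupling to the bilins and therefore
controls the quenching rate.  This package quantifies the chain

    pocket charges → potential on the chain → imbalance ΔP → mixing →
    dark-state TDM µ → EET coupling V

on explicit structures and on synthetic ensembles designed to isolate each
link.

## Electrostatics

The environment potential at conjugated-chain atom *i* is the bare Coulomb
sum φᵢ = Σⱼ qⱼ/rᵢⱼ over every environment atom (protein, solvent, ions) with
no cutoff or dielectric screening; units are e/Å (multiply by 14.3996 for
volts).  Hydrogens are included whenever the input provides them with
charges; chains prepared without hydrogens will see a slightly different φ,
which is why the potential routine is kept free of element filters.

**ΔP (imbalance).**  ΔP = mean(φ over the first half of the ordered
conjugated chain) − mean(φ over the second half); odd-length chains drop the
middle atom.  This is the simplest functional that is antisymmetric under
chain reversal and measures an end-to-end bias; alternatives (end-atom
difference, projection onto the transition density) would serve the same
role, and the definition is isolated in a single function
(`pocket_electrostatics.delta_p`) so it can be substituted.

**Turn-off scan.**  For each selected residue (by default the charged and
polar residues within 10 Å of the chain, minimum heavy-atom distance,
inclusive) the residue's *side-chain* charges are zeroed (backbone N, CA, C,
O, OXT retained), φ, ΔP, and the dark TDM are recomputed, and the effect is
log₁₀(µ/µ_ref) against the same frame's all-on reference.  Effects are
summarized as box statistics (median, quartiles, 1.5×IQR whiskers,
outliers).  Superposition makes the scan cheap: the excluded side chain's
contribution is subtracted rather than recomputing the full sum.

## The two-state mixing surrogate

The excited-state electronic-structure step is replaced by an essential-state
model — deliberately, and this is the central approximation of the package.
In the diabatic {dark, bright} basis:

    H = [[E_dark, W], [W, E_bright]],     W = k_mix · ΔP.

Diagonalization gives θ = ½·atan2(2W, E_bright − E_dark) with θ ∈ (−π/2,
π/2]; adiabatic energies E∓ = Ē ∓ ½√(Δ² + 4W²); the lower eigenstate is
cos θ·|dark⟩ − sin θ·|bright⟩, so the lower/upper TDMs are |sin θ|·µ_bright
and |cos θ|·µ_bright and µ₁² + µ₂² = µ_bright² exactly.  State *character*
(dark/bright) follows the dominant diabatic amplitude and swaps at
|θ| = π/4; frames beyond that point are flagged "inverted" (the energetic
order of dark- and bright-character states has flipped, which happens when
the diabatic gap jitters through zero under strong mixing).

Assumptions worth stating plainly:

* linear response W ∝ ΔP — adequate for the modest imbalances sampled here;
* exact two-state dipole conservation — a real multi-state calculation
  leaks some strength to higher states (reported dark/bright TDM pairs in
  the literature conserve dipole strength only approximately);
* diabatic energies are *inputs*, drawn per frame by the generator, not
  predicted from the electrostatics.  Consequently the across-frame
  correlation between ΔP and µ_dark is masked by the independent energy
  jitter; the linearity of µ_dark in ΔP is therefore demonstrated (tests,
  acceptance script) at fixed diabatic energies, where R² ≥ 0.99.

**Calibration.**  k_mix (eV per e/Å) is not derivable inside the surrogate;
it is fitted once, by bracketed bisection on the monotone response, so that
the reference (OCP1-like) ensemble's mean adiabatic dark TDM equals 8.2 D.
The same k_mix is then applied unchanged to every other pocket.  With the
default generator this lands near k_mix ≈ 0.69.

## TrEsp couplings

Transition charges represent a pigment's transition density as atomic point
charges constrained to sum to zero (the constraint is imposed with a
Lagrange multiplier in the least-squares fit, not by post-hoc shifting,
because a transition density integrates to zero).  The coupling is the
unscreened vacuum double sum V = Σᵢⱼ qᵢqⱼ/rᵢⱼ, converted with
14.3996 eV·Å·e⁻² and 8065.544 cm⁻¹/eV; 1 e·Å = 4.80321 D.  Donor charges
are rescaled each frame to that frame's adiabatic dark TDM; acceptor charge
sets are static.  At separations large against the pigment extents the sum
converges to the ideal-dipole form κ µ_A µ_B/R³ (verified to 5% at ≥20×
extent); at phycobilisome-like distances (~15 Å) the extended-dipole
structure matters and the full sum is used.

## The synthetic generator

The generator emulates the *statistical* setting of a backbone-restrained
MD study, not its energetics: geometry is jittered, not Boltzmann-sampled.

* Donor: a linear 20-atom conjugated chain, 1.4 Å spacing (≈26.6 Å, a
  carotenoid-like extent), transition charges alternating ± and scaled to a
  diabatic bright TDM of 19 D.
* Acceptors: two 10-atom bilin-like chains beyond the chain's
  "PBS-adjacent" end at minimum distances ≈15 Å and ≈25 Å, static charges
  scaled to 13 D.
* Pocket residues: each a 6-atom caricature (4 zero-charge backbone atoms,
  a CB, and a terminal atom carrying the side-chain charge, split 0.3/0.7);
  classification follows the standard residue-name lookup.
* Solvent: eight TIP3P-like waters placed mirror-symmetrically about the
  chain midplane, so their *static* ΔP contribution cancels exactly and
  they act purely as a fluctuation source.
* Ensembles: backbone and pigment atoms fixed; side-chain and water atoms
  displaced by isotropic Gaussian jitter (σ = 0.3 Å default); per-frame
  diabatic energies drawn from preset-specific normals; 60 frames per
  ensemble by default.  One seed drives three independent child streams
  (jitter, energies, census) through fixed spawn keys.

**Presets.**  The three pocket layouts encode the scenarios of interest.
The OCP1-like reference has one positive residue near the head (PBS-adjacent
end) and negatives near the tail, giving a static ΔP ≈ 0.18 e/Å.  The
HCP5-like layout differs at six declared sites only: Ser→Arg at the head,
and Asp/Glu replacing neutral residues on the opposite side, partly offset
by a second Arg — net static ΔP ≈ 0.20 e/Å.  The site positions were chosen
from their per-unit-charge ΔP contributions so the HCP5/OCP1 imbalance
ratio stays modest (≈1.1): in a two-state model the adiabatic gap
√(Δ² + 4W²) *grows* with W, so reproducing "stronger mixing *and* a smaller
adiabatic gap" simultaneously requires the HCP5-like diabatic gap to be
narrower (0.08 eV vs 0.20 eV mean, bright state red-shifted) with only a
moderately larger W.  The HCP2-like layout balances head and tail charges
(static ΔP ≈ 0.01 e/Å) and widens the diabatic gap (0.25 eV, bright state
blue-shifted, narrower dark-state energy spread).

What passing tests on these ensembles shows: that the pipeline's mechanics
(superposition, imbalance, calibration, mixing, coupling) behave exactly as
specified and that the qualitative ordering between pockets is a robust
consequence of the declared charge layouts.  What it does not show: anything
about real force fields, real solvent structure, correlated side-chain
motions, or the actual magnitude of mixing in any real protein — the
synthetic dark TDMs and couplings are anchored only at the single calibrated
reference value.

## Census layer

Clade assignment takes a per-sequence × clade bit-score table (TSV, or the
'#'-commented space-delimited tabular output of a standard homology search)
and assigns argmax scores; exact ties break lexicographically with a logged
warning, and an optional floor leaves weak sequences unassigned.  Tallies
report the four-way HCP4/HCP5 partition (exhaustive and mutually
exclusive), OCP co-occurrence as a percent of each parent group, and overall
OCP/HCP prevalence.  The default census fixture generates 690 genomes whose
complement composition reproduces the headline survey tallies (OCP in 90%,
HCP in 63%, 137 HCP4-without-HCP5, 69 HCP5-without-HCP4, one genome with
both, OCP in 111/138 HCP4-containing and 46/70 HCP5-containing genomes);
prevalences of the remaining HCP clades are filler and not meaningful.

Conservation matrices use gap-excluded column frequencies and
IC = log₂20 − H in bits (no small-sample correction by default); annotation
flags are mapped from reference-sequence residue numbers to alignment
columns.  Pairwise identity uses a global alignment (BLOSUM62, gap open
−11, extend −1) with identity counted over columns where neither sequence
is gapped — the most common convention; the identity of a published pair of
sequences depends on this choice and on whether the published value came
from a curated multiple alignment, so small discrepancies against printed
values are expected.

## Numerical choices and edge cases

* Distances: minimum heavy-atom distance, inclusive cutoffs.
* Altloc: first conformer; insertion codes folded into the residue number.
* Atoms without a charge mapping get q = 0 with a logged warning.
* Coincident atoms across interacting sets raise a singularity error naming
  the pair; they are never silently skipped.
* The charge fit raises a conditioning error when the KKT system's
  condition number exceeds 10¹² (e.g., all samples equidistant from all
  atoms).
* Calibration raises when the target is unreachable (all ΔP = 0, or target
  above the saturation mean).
* Frames whose all-on reference TDM is exactly 0 are skipped in the
  turn-off scan with a warning.
* PCA of a constant potential matrix returns a flagged degenerate result
  instead of components.
* Problem sizes: 60 frames per ensemble, ~300-atom complexes, 690-genome
  fixtures — the full pipeline runs in seconds on one core.

## Known limitations

* The two-state surrogate cannot shift absolute excitation energies or
  describe vibronic structure; "inversion" statistics depend on the
  generator's energy-jitter widths.
* ΔP is one admissible imbalance functional among several.
* Jitter is geometric; the ensemble has no thermodynamic weight.
* The census layer neither trains nor runs HMMs; garbage score tables in,
  garbage tallies out.
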