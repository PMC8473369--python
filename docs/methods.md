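# Methods

## Problem and model

Designed Armadillo-type repeat proteins (dArmRPs) are α-solenoids: N
sequence-identical three-helix modules (M1…Mn) flanked by capping modules
(Y, A), stacked along a superhelix.  Because the modules are nearly
identical, NOE-based assignment and structure determination are hard; what
*can* be measured are backbone amide pseudocontact shifts (PCSs) induced by
lanthanide tags attached at a few surface sites.  A PCS reports on the
position of a nucleus relative to the tag's anisotropic susceptibility
tensor:

    δ_PCS = 10⁴ / (12 π r³) · [Δχ_ax (3cos²θ − 1) + 3/2 Δχ_rh sin²θ cos2φ]

with r in Å, Δχ in 10⁻³² m³ and δ in ppm; (r, θ, φ) are the spherical
coordinates of the nucleus in the tensor principal frame.  Equivalently,
for the traceless symmetric tensor **χ** in an arbitrary frame,
δ = 10⁴/(4π r⁵) · **r**ᵀ**χ** **r**.

The refinement assumes that each module's internal geometry is essentially
correct in the starting model and that only the *curvature* of the solenoid
(the relative poses of the modules) needs correction.  Scaffold restraints
hold each module near its canonical geometry; the PCS data, which depend
sharply on the global arrangement, drive the curvature.

## Restraint classes

Generated from the current model each cycle:

* **UPL** — upper distance limits on all intra-module heavy-atom pairs with
  model distance in 2.5–5.0 Å, limit = distance + 0.5 Å; minimum residue
  separation 2 (closer pairs are covalently determined).
* **ACO** — φ/ψ restraints at the model values ± 5°, across the entire
  sequence.
* **ORI** — upper + lower limits (± 0.5 Å) from each metal pseudo-atom to
  its six nearest Cα atoms.
* **Connectivity** — upper + lower limits (± 0.05 Å, weight 10) on every
  peptide C–N bond.  A Cartesian rigid-body sampler does not conserve
  covalent geometry across module junctions the way a torsion-angle engine
  does; these restraints are the minimal replacement.
* **Regularization** — per-atom flat-bottom wells of half-width 0.3 Å
  around the model coordinates, in two parts:
  1. a *module-internal* tether (weight 1.0): the reference module is
     rigidly superposed onto the current module before deviations are
     measured, so only internal deformation is penalized and module poses
     remain free — this is what allows the data to re-orient modules;
  2. a weak *pose prior* (weight 0.02) on the inter-module arrangement:
     the whole reference structure is superposed once onto the current
     state and the same flat-bottom well is applied.  With module poses
     otherwise free, directions the PCS data do not constrain random-walk;
     the prior damps that wander while its barrier stays far below the
     PCS energies that drive genuine curvature corrections.  Both parts
     are rigid-motion invariant.

Default global weights follow the restrained-calculation convention:
UPL/LOL = 1, VdW = 2, ACO = 5; in the iterative protocol the PCS weight is
raised to 30–50 (we use 50 for noiseless synthetic data, the high-quality
end of that range, and 30 as the general default).  The per-record PCS
tolerance (flat-bottom half-width) is 0.02 ppm.

## Sampler

Conformations are sampled by Metropolis Monte Carlo over a move set matched
to the repeat-protein physics: junction rotations (everything downstream of
a module junction rotates rigidly about the junction Cα), rigid single-module
rotations/translations, bounded backbone torsion moves (tail rotations about
N–Cα / Cα–C axes) and metal pseudo-atom translations.  Tags ride their
modules: when a move displaces the module carrying a tag's anchor residue,
the metal position *and* the tensor frame co-rotate.  The fitted tensor
magnitudes (Δχ_ax, Δχ_rh) stay fixed within a cycle while the frame follows
the structure — with the frame fixed in space, the cycle-one tensors (fitted
to a wrong model) would make the target function *increase* along the path
to the true structure.

Four annealing phases mirror the classic schedule: reduced heavy-atom
radii in phases 1–3 (soft-sphere radius multipliers 0.25, 0.25, 0.25, 1.0),
geometric temperature ramps, snapshots every 200 steps.  Because starts are
perturbations of the current model rather than random coils, the schedule
opens warm (relative temperature 0.1) rather than hot and ends in a
near-greedy polish.  "Temperature" is a unitless Metropolis scale; the
absolute scale is auto-calibrated per run so that a relative temperature of
1.0 would accept ≈80 % of initial moves.  Move amplitudes adapt within a
run (per move type, factor 0.8/1.2 on a 200-step window) to keep acceptance
in a productive band.  The lowest-energy state visited is returned.

The energy is evaluated by numba-compiled kernels (~10⁴ restraint terms in
tens of microseconds); a pure-numpy reference implementation
(`restraint_energy`) mirrors the kernel term by term and is cross-checked
against it in the tests.

## Iterative protocol

Per cycle: (i) fit a Δχ-tensor per tag (linear least squares for the five
components nested inside a Nelder–Mead search over the metal position)
against the *current* model with the fixed experimental PCS values;
(ii) regenerate all restraints from the current model; (iii) compute an
ensemble of annealed conformers from perturbed starts (default 100 starts ×
5000 steps); (iv) re-fit tensors to the 20–30 best conformers by energy and
select the one with the lowest Q-factor averaged over tags,

    Q = sqrt( Σ_i (Σ_m [PCS_exp − PCS_calc])² / Σ_i (Σ_m PCS_exp)² ),

which becomes the next cycle's model.  PCS values are never modified.  The
stop rule is a fixed cycle count (default 10); a convergence flag records
whether the mean Q changed by <1 % over the last two cycles.

## Synthetic benchmark

The generator builds proline-free poly-Ala backbones (N, H, Cα, C', O) by
internal-coordinate construction with ideal bond geometry and a torsion
pattern that repeats every 42 residues (three 12-residue helices joined by
fixed turn torsions), so consecutive modules are exactly screw-related
(naturally ≈49° twist and ≈6.3 Å rise per module) and the chain is
covalently ideal.  The benchmark system is Y + M1–M4 + A (252 residues),
matching the size of the experimental target protein.

Three virtual tag sites mirror the experimental attachment strategy (first
and middle internal module and the C-cap), each ~12 Å off the anchor Cα
pointing away from the solenoid core, with template tensor components
Δχ_ax = 40, Δχ_rh = 8 (10⁻³² m³), the scale of Tm-DOTA-type tags (proton
PCSs up to a few ppm at observable distances).  Virtual PCSs are
back-calculated at every amide, with optional Gaussian noise, a PRE
exclusion radius (default 10 Å — closer amides are unobservable), and
residue-level assignment subsampling (H and N kept or dropped together;
count = floor(fraction × eligible residues)).

Distorted starting models are produced by rigid rotations at module
junctions, with the rotation magnitude calibrated by bisection to a target
backbone RMSD (the 0.6 / 1.9 / 2.7 Å regime of mis-curved models), either
at one central junction or at every junction.

What the generator does **not** emulate: side chains (packing and its
steric information), real dArmRP sequence and cap asymmetry, ¹⁵N CSA
contamination of nitrogen PCSs, tag-linker mobility, or assignment errors.
Passing benchmarks therefore demonstrate the protocol's information flow
and stability, not performance on experimental spectra.

## Problem sizes and defaults

| parameter | default | note |
|---|---|---|
| internal modules | 4 | benchmark system, 252 residues with caps |
| residues / module | 42 | three 12-residue helices |
| tags | 3 | Δχ_ax 40, Δχ_rh 8 ×10⁻³² m³ |
| PCS tolerance | 0.02 ppm | flat-bottom half-width |
| PRE exclusion | 10 Å | eligible-amide cutoff |
| starts × steps | 100 × 5000 | per cycle (positive control) |
| retained (k) | 20–30 | Q-ranked subset |
| bundle | 10 | precision metric |
| cycles | 10 | fixed stop rule |
| w_PCS | 30 (50 for noiseless data) | iterative phase |
| regularize cap | 0.3 Å | both tether parts |
| w_tether / w_pose | 1.0 / 0.02 | module-internal / inter-module |
| start perturbation | 6 junctions × ±3°, torsions ±0.2° | ensemble diversity |

The convergence benchmark (distorted 2.5 Å start) uses 40 starts × 4000
steps per cycle and the no-PCS ablation 20 × 3000 — module-pose information
saturates well below the positive-control sampling volume, and the smaller
ensembles keep a full 10-cycle run in a few minutes on one core.

## Numerical choices

* Tensor canonicalization: eigenvalues ordered |χ_zz| ≥ |χ_yy| ≥ |χ_xx|,
  Δχ_ax = 3/2 χ_zz, Δχ_rh = χ_xx − χ_yy (0 ≤ Δχ_rh/Δχ_ax ≤ 2/3 follows);
  ZYZ Euler angles from the right-handed eigenvector frame.
* Position search: Nelder–Mead, convergence on simplex size < 0.01 Å (the
  objective plateau is data-dependent and does not gate termination).
* Spins closer than 0.5 Å to the metal are rejected (PRE-dominated regime).
* H/N consistency filter: discard the amide pair when |H−N|/max(|H|,|N|) >
  0.2 and max(|H|,|N|) ≥ 0.02 ppm (the floor keeps near-zero PCSs whose
  relative difference is noise-dominated); denominator choice documented,
  config-exposed.
* Kabsch superposition uses SVD with a determinant guard (proper rotations
  only); precision = mean pairwise backbone RMSD (order-independent), with
  an RMSD-to-mean variant available.
* Dihedral restraints wrap circularly; violations are measured in radians
  from the nearest interval edge.
* Chain breaks (C–N > 2.5 Å) skip the spanning dihedrals with a warning.

## Known limitations

* The sampler's torsion moves require the backbone-only atom layout
  (N, [H], Cα, C, O per residue); with full-atom input, torsion moves are
  disabled and only rigid-module moves act.  The intended inputs are
  backbone models.
* In the positive control the selected-model accuracy is comparable to —
  and can fall slightly below — the pairwise spread of the energy-ranked
  bundle: the sampler is unbiased, so its residuals are mostly stochastic,
  whereas engines with a systematic sampling bias report bundles tighter
  than their accuracy floor.  Precision should therefore be read together
  with accuracy, not as a lower bound on it.
* The accuracy of the converged models plateaus at a few tenths of an Å —
  the PCS tolerance and the tensor-refit freedom leave a shallow,
  degenerate optimum, so the selected model performs a bounded walk inside
  it.  The same plateau (~0.5 Å) is a known property of this class of
  protocol.
* Q-factor selection cannot detect systematically swapped assignments
  between symmetry-related modules within one cycle; per-tag Q values are
  exposed so such errors can be spotted across runs.
* mmCIF, insertion codes and multi-chain models are not supported.
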