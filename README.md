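# pcsrefine

Iterative refinement of repeat-protein structures against sparse backbone
pseudocontact shifts (PCSs).

α-solenoid repeat proteins — N near-identical three-helix modules stacked
along a superhelix — are notoriously hard to solve by conventional NOE-based
NMR because their spectra are massively degenerate.  Backbone amide PCSs
from a few lanthanide tags are measurable even there, and they encode
exactly the quantity a good homology model gets wrong: the solenoid's
curvature.  `pcsrefine` implements the full refinement loop for this
setting:

* **Δχ-tensor machinery** — PCS back-calculation, linear least-squares
  component fits, full 8-parameter fits (metal position + components),
  Q-factors and the ¹H/¹⁵N 20 % consistency filter;
* **scaffold restraints** — intra-module upper distance limits (2.5–5.0 Å
  + 0.5 Å), φ/ψ restraints (±5°), metal-position (ORI) limits to the six
  nearest Cα, and flat-bottom regularization (0.3 Å) of each module's
  internal geometry;
* **a restrained simulated-annealing Monte-Carlo engine** over rigid-module
  / junction / torsion moves (numba-compiled, ~10⁵ steps per minute on a
  single core for a 250-residue system);
* **the iterative driver** — per cycle: refit tensors against the current
  model with fixed PCS data, regenerate the scaffold, compute an ensemble,
  re-rank the best conformers by the mean Q-factor over tags

      Q = sqrt( Σ_i (Σ_m [PCS_exp − PCS_calc])² / Σ_i (Σ_m PCS_exp)² )

  and feed the winner into the next cycle;
* **a synthetic benchmark generator** — idealized α-solenoids with exactly
  screw-related modules, calibrated junction distortions (mis-curved input
  models of prescribed RMSD) and virtual PCS datasets from template
  tensors, so every part of the protocol can be validated in closed loop
  without external data.

PCS convention: δ(ppm) = 10⁴/(12π r³)·[Δχ_ax(3cos²θ−1) + 3/2 Δχ_rh sin²θ cos2φ],
with r in Å and Δχ in 10⁻³² m³.

See `docs/methods.md` for the model, the sampler and all defaults.

## Worked example

Refine a deliberately mis-curved model of a synthetic 6-module solenoid
(Y + M1–M4 + A, 252 residues) against noiseless virtual PCSs from three
tags:

```python
import numpy as np
from pcsrefine import (
    RepeatSpec, build_repeat_protein, default_tags, generate_virtual_pcs,
    calibrate_distortion, apply_distortion, consistency_filter,
    refine_iterative, RefineParams, backbone_rmsd,
)
from pcsrefine.restraints import ScaffoldParams
from pcsrefine.synthetic import true_tensor

spec = RepeatSpec(n_internal_modules=4)
target = build_repeat_protein(spec)
seg = spec.segmentation()
tags = default_tags(target, seg)
pcs, tensors = generate_virtual_pcs(target, tags, seed=1)
pcs, _ = consistency_filter(pcs)

distortion = calibrate_distortion(target, seg, 2.5, mode="all_junctions", seed=3)
start = apply_distortion(target, seg, distortion)
print(f"input model error: {backbone_rmsd(target, start):.2f} A")

guesses = {t.tag_id: true_tensor(target, t).metal_position + 2.0 for t in tags}
params = RefineParams(n_starts=40, anneal_steps=4000, k_best=30,
                      scaffold=ScaffoldParams(w_pcs=50.0))
result = refine_iterative(start, pcs, seg, guesses, n_cycles=10,
                          params=params, seed=7, target=target)
for c in result.cycles:
    print(f"cycle {c.cycle}: mean Q {c.mean_q:.4f}  accuracy {c.accuracy:.2f} A")
```

Output (seed 7):

```
input model error: 2.47 A
cycle 1: mean Q 0.0133  accuracy 2.17 A
cycle 2: mean Q 0.0108  accuracy 2.00 A
cycle 3: mean Q 0.0102  accuracy 1.92 A
...
cycle 9: mean Q 0.0087  accuracy 1.56 A
cycle 10: mean Q 0.0090  accuracy 1.53 A
```

The distorted model's own data misfit (mean Q 0.042) collapses immediately
and keeps falling; the full-sequence RMSD above is dominated by the floppy
caps — over the internal modules the same run converges from 1.43 Å to
0.84 Å.  `evaluate_run(result, target, exclusion=[...])` tabulates
per-cycle accuracy and precision over any residue selection, e.g. with the
caps excluded.

The same pipeline is scriptable from the shell:

```
pcsrefine simulate --n-modules 4 --distort 2.5 --outdir sim
pcsrefine refine --model sim/input_B.pdb --config sim/config.yaml \
    --pcs tag1=sim/tag1.npc --pcs tag2=sim/tag2.npc --pcs tag3=sim/tag3.npc \
    --target sim/target.pdb --cycles 10 --seed 7
```

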