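"""Iterative refinement of repeat-protein structures against sparse backbone PCSs.

The package implements a desk-scale pipeline for pseudocontact-shift (PCS)
driven refinement of alpha-solenoid repeat proteins:

* Δχ-tensor fitting and PCS back-calculation (:mod:`pcsrefine.tensor`)
* scaffold / metal-position restraint generation (:mod:`pcsrefine.restraints`)
* restrained simulated-annealing Monte Carlo (:mod:`pcsrefine.anneal`)
* Q-factor driven iterative model updating (:mod:`pcsrefine.refine`)
* a synthetic repeat-protein and virtual-PCS generator used for positive
  controls and convergence experiments (:mod:`pcsrefine.synthetic`)

Submodules are imported lazily: ``pcsrefine.anneal`` JIT-compiles its Monte
Carlo kernels on first use.
"""

from importlib import import_module

__version__ = "0.1.0"

_EXPORTS = {
    "structure": [
        "AtomRecord",
        "Structure",
        "ModuleRange",
        "ModuleSegmentation",
        "BACKBONE_ATOMS",
    ],
    "geometry": [
        "SuperpositionResult",
        "kabsch_superpose",
        "backbone_rmsd",
        "bundle_precision",
    ],
    "tensor": [
        "DeltaChiTensor",
        "PcsRecord",
        "PcsDataset",
        "TensorFitResult",
        "backcalc_pcs",
        "backcalc_pcs_many",
        "fit_components",
        "fit_tensor",
        "qfactor",
        "mean_q_over_tags",
        "consistency_filter",
    ],
    "synthetic": [
        "RepeatSpec",
        "DistortionSpec",
        "JunctionDistortion",
        "VirtualTagSpec",
        "build_repeat_protein",
        "apply_distortion",
        "calibrate_distortion",
        "generate_virtual_pcs",
        "default_tags",
        "true_tensor",
        "module_screw",
    ],
    "restraints": [
        "DistanceRestraint",
        "DihedralRestraint",
        "RestraintSet",
        "make_scaffold_upl",
        "make_scaffold_aco",
        "make_ori",
        "make_connectivity_restraints",
        "regenerate_scaffold",
    ],
    "anneal": [
        "AnnealPhase",
        "AnnealSchedule",
        "EnergyBreakdown",
        "Conformer",
        "Trajectory",
        "restraint_energy",
        "perturb_start",
        "anneal",
        "calc_ensemble",
    ],
    "refine": [
        "RefineParams",
        "CycleResult",
        "RefinementResult",
        "select_best_by_q",
        "run_cycle",
        "refine_iterative",
        "evaluate_run",
    ],
    "io": [
        "read_pdb",
        "write_pdb",
        "read_npc",
        "write_npc",
        "write_restraints",
        "read_restraints",
        "load_config",
        "ConfigBundle",
    ],
}

_ATTR_TO_MODULE = {name: mod for mod, names in _EXPORTS.items() for name in names}

__all__ = sorted(_ATTR_TO_MODULE) + ["__version__"]


def __getattr__(name: str):
    mod = _ATTR_TO_MODULE.get(name)
    if mod is None:
        raise AttributeError(f"module 'pcsrefine' has no attribute {name!r}")
    value = getattr(import_module(f"pcsrefine.{mod}"), name)
    globals()[name] = value
    return value


def __dir__():
    return __all__
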