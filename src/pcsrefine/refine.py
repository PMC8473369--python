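"""Q-factor driven iterative refinement.

Each cycle: (i) fit a Δχ-tensor per tag against the current model using the
fixed experimental PCS values; (ii) regenerate scaffold, ORI and
regularization restraints from the current model; (iii) compute an ensemble
of annealed conformers; (iv) re-fit tensors to the best-ranked conformers
and select the one with the lowest Q-factor averaged over tags, which
becomes the next cycle's model.  PCS values are never modified — only the
scaffold and the tensors are updated, so the (correct) experimental data
can steadily pull an approximate model toward the true structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from pcsrefine.anneal import (
    AnnealSchedule,
    Conformer,
    PerturbAmplitudes,
    calc_ensemble,
)
from pcsrefine.geometry import backbone_rmsd, bundle_precision
from pcsrefine.restraints import ScaffoldParams, regenerate_scaffold
from pcsrefine.structure import ModuleSegmentation, Structure
from pcsrefine.tensor import DeltaChiTensor, PcsDataset, fit_tensor


@dataclass
class RefineParams:
    """Protocol parameters of one refinement run (desk-scale defaults)."""

    n_starts: int = 100
    anneal_steps: int = 5000
    k_best: int = 20  # conformers re-ranked by Q (20–30)
    n_bundle: int = 10  # best structures merged for the precision metric
    scaffold: ScaffoldParams = field(default_factory=ScaffoldParams)
    perturb: PerturbAmplitudes = field(default_factory=PerturbAmplitudes)
    schedule: AnnealSchedule | None = None
    convergence_dq: float = 0.01  # relative mean-Q change declaring convergence
    divergence_factor: float = 1.5

    def make_schedule(self) -> AnnealSchedule:
        return self.schedule or AnnealSchedule.default(self.anneal_steps)


@dataclass
class CycleResult:
    cycle: int
    tensors: dict[str, DeltaChiTensor]  # fitted to the selected conformer
    model_tensors: dict[str, DeltaChiTensor]  # fitted to the cycle's input model
    model_mean_q: float  # fit quality of the cycle's input model
    selected: Conformer
    mean_q: float
    per_tag_q: dict[str, float]
    precision: float
    energies: list[float]
    bundle: list[Structure]
    accuracy: float | None = None  # full-sequence RMSD to target, test mode


@dataclass
class RefinementResult:
    cycles: list[CycleResult]
    final_structure: Structure
    converged: bool
    seed: int

    def __post_init__(self):
        for i, c in enumerate(self.cycles):
            if c.cycle != i + 1:
                raise ValueError("cycle indices must be contiguous from 1")

    @property
    def mean_q_trace(self) -> list[float]:
        return [c.mean_q for c in self.cycles]

    @property
    def accuracy_trace(self) -> list[float | None]:
        return [c.accuracy for c in self.cycles]


def select_best_by_q(
    conformers: Sequence[Conformer],
    pcs: PcsDataset,
    k: int = 20,
) -> tuple[Conformer, dict[str, DeltaChiTensor]]:
    """Lowest mean-Q conformer among the top-k by energy.

    For each retained conformer a full Δχ-tensor fit (position + components)
    is performed per tag, starting from the conformer's own metal position;
    the mean of the per-tag Q-factors ranks the conformers.  Ties keep the
    lower-energy conformer.  Conformers whose fit fails are excluded with a
    warning; it is an error if every conformer is excluded.
    """
    if not conformers:
        raise ValueError("no conformers")
    top = list(conformers)[: max(1, min(k, len(conformers)))]
    best = None
    for conf in top:
        per_tag_q: dict[str, float] = {}
        tensors: dict[str, DeltaChiTensor] = {}
        try:
            for tag in pcs.tags():
                fit = fit_tensor(
                    pcs.for_tag(tag), conf.structure, conf.metal_positions[tag]
                )
                per_tag_q[tag] = fit.q_factor
                tensors[tag] = fit.tensor
        except (RuntimeError, ValueError) as err:
            warnings.warn(f"conformer excluded from Q ranking: {err}", stacklevel=2)
            continue
        mean_q = float(np.mean(list(per_tag_q.values())))
        if best is None or mean_q < best[0]:
            best = (mean_q, conf, per_tag_q, tensors)
    if best is None:
        raise RuntimeError("tensor fit failed for every retained conformer")
    _, conf, per_tag_q, tensors = best
    conf.per_tag_q = per_tag_q
    return conf, tensors


def run_cycle(
    model: Structure,
    pcs: PcsDataset,
    segmentation: ModuleSegmentation,
    metal_guesses: dict[str, np.ndarray],
    params: RefineParams | None = None,
    seed: int = 0,
    cycle_index: int = 1,
    target: Structure | None = None,
    previous_mean_q: float | None = None,
) -> CycleResult:
    """One refinement cycle on `model` with fixed PCS data.

    `metal_guesses` seeds the per-tag position searches (first cycle: any
    reasonable guess near the tag site; later cycles: the previous cycle's
    fitted positions).
    """
    p = params or RefineParams()
    model_tensors: dict[str, DeltaChiTensor] = {}
    model_q: dict[str, float] = {}
    for tag in pcs.tags():
        fit = fit_tensor(pcs.for_tag(tag), model, metal_guesses[tag])
        model_tensors[tag] = fit.tensor
        model_q[tag] = fit.q_factor
    restraints = regenerate_scaffold(model, segmentation, model_tensors, p.scaffold)
    conformers = calc_ensemble(
        model,
        restraints,
        pcs,
        model_tensors,
        n_starts=p.n_starts,
        schedule=p.make_schedule(),
        seed=seed,
        segmentation=segmentation,
        perturb_amplitudes=p.perturb,
    )
    selected, tensors = select_best_by_q(conformers, pcs, k=p.k_best)
    bundle = [c.structure for c in conformers[: p.n_bundle]]
    precision = bundle_precision(bundle) if len(bundle) >= 2 else 0.0
    mean_q = selected.mean_q
    if previous_mean_q is not None and mean_q > p.divergence_factor * previous_mean_q:
        warnings.warn(
            f"cycle {cycle_index}: mean Q rose from {previous_mean_q:.4f} to "
            f"{mean_q:.4f} (possible divergence)",
            stacklevel=2,
        )
    accuracy = backbone_rmsd(target, selected.structure) if target is not None else None
    return CycleResult(
        cycle=cycle_index,
        tensors=tensors,
        model_tensors=model_tensors,
        model_mean_q=float(np.mean(list(model_q.values()))),
        selected=selected,
        mean_q=mean_q,
        per_tag_q=dict(selected.per_tag_q),
        precision=precision,
        energies=[c.energy.total for c in conformers],
        bundle=bundle,
        accuracy=accuracy,
    )


def refine_iterative(
    model: Structure,
    pcs: PcsDataset,
    segmentation: ModuleSegmentation,
    metal_guesses: dict[str, np.ndarray],
    n_cycles: int = 10,
    params: RefineParams | None = None,
    seed: int = 0,
    target: Structure | None = None,
) -> RefinementResult:
    """Iterative refinement: chain `n_cycles` cycles, feeding each selected
    structure (and its fitted metal positions) into the next.

    The stop rule is the fixed cycle count; the result additionally records
    whether the mean Q-factor change fell below `params.convergence_dq`
    over the last two cycles.  `target` enables test mode (per-cycle
    accuracy bookkeeping); it does not influence the refinement.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    p = params or RefineParams()
    cycle_seeds = np.random.SeedSequence(seed).generate_state(n_cycles) % (2**31)
    current = model
    guesses = dict(metal_guesses)
    cycles: list[CycleResult] = []
    prev_q: float | None = None
    for i in range(n_cycles):
        result = run_cycle(
            current,
            pcs,
            segmentation,
            guesses,
            params=p,
            seed=int(cycle_seeds[i]),
            cycle_index=i + 1,
            target=target,
            previous_mean_q=prev_q,
        )
        cycles.append(result)
        current = result.selected.structure
        guesses = {tag: t.metal_position for tag, t in result.tensors.items()}
        prev_q = result.mean_q
    converged = False
    if len(cycles) >= 3:
        q = [c.mean_q for c in cycles[-3:]]
        scale = max(abs(q[-2]), 1e-12)
        converged = (
            abs(q[-1] - q[-2]) / scale < p.convergence_dq
            and abs(q[-2] - q[-3]) / max(abs(q[-3]), 1e-12) < p.convergence_dq
        )
    return RefinementResult(
        cycles=cycles, final_structure=current, converged=converged, seed=seed
    )


def evaluate_run(
    result: RefinementResult,
    target: Structure,
    exclusion: Sequence[tuple[int, int]] = (),
) -> list[dict]:
    """Per-cycle accuracy/precision table over the included residue region.

    `exclusion` lists inclusive residue ranges left out of the RMSD
    computations (e.g. a floppy cap and the adjacent module).
    """
    residues = sorted(r for _, r in target.residues())
    excluded = {r for lo, hi in exclusion for r in range(lo, hi + 1)}
    included = [r for r in residues if r not in excluded]
    if not included:
        raise ValueError("empty included region")
    ranges = _as_ranges(included)
    rows = []
    for c in result.cycles:
        rows.append(
            {
                "cycle": c.cycle,
                "mean_q": c.mean_q,
                "accuracy": backbone_rmsd(target, c.selected.structure, ranges),
                "precision": bundle_precision(c.bundle, ranges)
                if len(c.bundle) >= 2
                else 0.0,
                "best_energy": min(c.energies),
            }
        )
    return rows


def report_tsv(rows: list[dict]) -> str:
    """TSV rendering of an :func:`evaluate_run` table."""
    if not rows:
        return ""
    cols = list(rows[0])
    lines = ["\t".join(cols)]
    for r in rows:
        lines.append(
            "\t".join(
                f"{r[c]:.4f}" if isinstance(r[c], float) else str(r[c]) for c in cols
            )
        )
    return "\n".join(lines) + "\n"


def _as_ranges(residues: list[int]) -> list[tuple[int, int]]:
    ranges = []
    start = prev = residues[0]
    for r in residues[1:]:
        if r != prev + 1:
            ranges.append((start, prev))
            start = r
        prev = r
    ranges.append((start, prev))
    return ranges
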