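"""Single-pipeline refinement protocol.

One pipeline refines its assigned helices through three greedy stages —
rigid translation, spin about the helix axis, tilt against the membrane
normal — then re-closes a randomly chosen assigned loop.  Every proposal
is scored with the full-pose energy (so cross-helix clashes are felt) and
accepted only on a strict decrease; rejected proposals are fully
discarded, so the accepted-energy trajectory is strictly decreasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .loops import LoopRefineConfig, refine_loops_randomly
from .moves import (
    MoveRanges,
    greedy_accept,
    sample_spin,
    sample_translation,
    spin_helix,
    tilt_helix,
    translate_helix,
)
from .packing import EnergyModel, EnergyReport
from .structure import BackboneStructure, MembraneFrame, fit_helix_axis


@dataclass
class PipelineConfig:
    """Iteration counts and region assignment of one pipeline.

    ``assigned_helices`` must be a non-empty contiguous run of helix
    indices (the 8-pipeline framework assigns at most an adjacent pair;
    running the full protocol over all seven helices is also supported).
    ``refresh_axes`` re-fits helix axes and the membrane frame before each
    stage pass; switching it off freezes the geometry computed at entry,
    matching a protocol that derives axes once up front.
    """

    stage2_cycles: int = 10
    stage3_cycles: int = 10
    stage4_cycles: int = 10
    iterations: int = 1
    assigned_helices: tuple[int, ...] = tuple(range(1, 8))
    assigned_loops: tuple[int, ...] | None = None
    refresh_axes: bool = True

    def __post_init__(self) -> None:
        for name in ("stage2_cycles", "stage3_cycles", "stage4_cycles", "iterations"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        hs = tuple(sorted(self.assigned_helices))
        if not hs:
            raise ValueError("assigned_helices must be non-empty")
        if any(h < 1 or h > 7 for h in hs):
            raise ValueError("helix indices must be in 1..7")
        if any(b - a != 1 for a, b in zip(hs, hs[1:])):
            raise ValueError("assigned_helices must be contiguous")
        self.assigned_helices = hs


@dataclass
class PipelineState:
    """Current and best-so-far pose of a pipeline with bookkeeping."""

    current: BackboneStructure
    current_energy: EnergyReport
    best: BackboneStructure
    best_energy: EnergyReport
    accept_counts: dict[str, int] = field(
        default_factory=lambda: {"translate": 0, "spin": 0, "tilt": 0}
    )
    energy_trace: list[float] = field(default_factory=list)

    @classmethod
    def from_start(cls, start: BackboneStructure, energy: EnergyReport) -> "PipelineState":
        return cls(
            current=start,
            current_energy=energy,
            best=start,
            best_energy=energy,
        )

    def _maybe_update_best(self) -> None:
        if self.current_energy.total < self.best_energy.total:
            self.best = self.current
            self.best_energy = self.current_energy

    def accept(self, stage: str, structure: BackboneStructure, energy: EnergyReport) -> None:
        self.current = structure
        self.current_energy = energy
        self.accept_counts[stage] += 1
        self.energy_trace.append(energy.total)
        self._maybe_update_best()


def _frame_for(
    state: PipelineState, energy_model: EnergyModel, frame: MembraneFrame | None
) -> MembraneFrame:
    if frame is not None:
        return frame
    from .structure import derive_membrane_frame

    return derive_membrane_frame(state.current, energy_model.topology)


def run_stage_translation(
    state: PipelineState,
    config: PipelineConfig,
    energy_model: EnergyModel,
    rng: np.random.Generator,
    ranges: MoveRanges | None = None,
) -> PipelineState:
    """Stage 2: greedy rigid translations of each assigned helix."""
    ranges = ranges or MoveRanges()
    topo = energy_model.topology
    for _ in range(config.stage2_cycles):
        for h in config.assigned_helices:
            delta = sample_translation(ranges, rng)
            proposal = translate_helix(state.current, topo.tm_ranges[h - 1], delta)
            energy = energy_model.evaluate(proposal)
            if greedy_accept(state.current_energy.total, energy.total):
                state.accept("translate", proposal, energy)
    return state


def run_stage_spin(
    state: PipelineState,
    config: PipelineConfig,
    energy_model: EnergyModel,
    rng: np.random.Generator,
    ranges: MoveRanges | None = None,
) -> PipelineState:
    """Stage 3: greedy spins of each assigned helix about its own axis."""
    ranges = ranges or MoveRanges()
    topo = energy_model.topology
    segments = {
        h: fit_helix_axis(state.current, topo.tm_ranges[h - 1], index=h)
        for h in config.assigned_helices
    }
    for _ in range(config.stage3_cycles):
        for h in config.assigned_helices:
            seg = (
                fit_helix_axis(state.current, topo.tm_ranges[h - 1], index=h)
                if config.refresh_axes
                else segments[h]
            )
            angle = sample_spin(ranges, rng)
            proposal = spin_helix(state.current, seg, angle, max_angle=ranges.spin_max)
            energy = energy_model.evaluate(proposal)
            if greedy_accept(state.current_energy.total, energy.total):
                state.accept("spin", proposal, energy)
    return state


def run_stage_tilt(
    state: PipelineState,
    config: PipelineConfig,
    energy_model: EnergyModel,
    rng: np.random.Generator,
    ranges: MoveRanges | None = None,
    frame: MembraneFrame | None = None,
) -> PipelineState:
    """Stage 4: greedy re-tilting of each assigned helix."""
    ranges = ranges or MoveRanges()
    topo = energy_model.topology
    segments = {
        h: fit_helix_axis(state.current, topo.tm_ranges[h - 1], index=h)
        for h in config.assigned_helices
    }
    for _ in range(config.stage4_cycles):
        mem_frame = _frame_for(state, energy_model, frame if frame is not None else energy_model.frame)
        for h in config.assigned_helices:
            seg = (
                fit_helix_axis(state.current, topo.tm_ranges[h - 1], index=h)
                if config.refresh_axes
                else segments[h]
            )
            proposal, _tilt = tilt_helix(state.current, seg, mem_frame, rng, ranges)
            energy = energy_model.evaluate(proposal)
            if greedy_accept(state.current_energy.total, energy.total):
                state.accept("tilt", proposal, energy)
    return state


def run_pipeline(
    start: BackboneStructure,
    energy_model: EnergyModel,
    config: PipelineConfig | None = None,
    rng: np.random.Generator | None = None,
    move_ranges: MoveRanges | None = None,
    loop_config: LoopRefineConfig | None = None,
) -> PipelineState:
    """Full single-pipeline protocol: stages 2→3→4, then loop refinement.

    Loop refinement re-closes one randomly chosen assigned loop; the
    resulting pose replaces the current pose (chain validity takes
    precedence over the energy at this step) and competes for best-so-far
    on energy.
    """
    if config is None:
        config = PipelineConfig()
    if rng is None:
        rng = np.random.default_rng()
    move_ranges = move_ranges or MoveRanges()
    topo = energy_model.topology
    state = PipelineState.from_start(start, energy_model.evaluate(start))
    loop_indices = (
        list(config.assigned_loops)
        if config.assigned_loops is not None
        else list(range(len(topo.loop_ranges)))
    )
    for _it in range(config.iterations):
        state = run_stage_translation(state, config, energy_model, rng, move_ranges)
        state = run_stage_spin(state, config, energy_model, rng, move_ranges)
        state = run_stage_tilt(state, config, energy_model, rng, move_ranges)
        if loop_indices:
            refined = refine_loops_randomly(
                state.current, topo, loop_config, rng, loop_indices
            )
            energy = energy_model.evaluate(refined)
            state.current = refined
            state.current_energy = energy
            state._maybe_update_best()
    return state
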