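"""Parallelised multi-template refinement framework.

Eight pipelines each own an adjacent helix-pair region (the first and last
own a single terminal helix plus the terminus).  Each iteration every
pipeline picks a starting pose — a template on the first iteration, an
elite-pool entry afterwards — refines its region with the single-pipeline
protocol, and then shares its best-so-far helices with the other pipelines
in the crossing step: a helix graft is kept only if it strictly lowers the
recipient's total energy.  Improved poses are conserved in a bounded,
energy-sorted elite pool that seeds the next iteration, so well-modelled
regions from different templates propagate across both pipelines and
iterations.

Pipelines are logically independent; this implementation executes them
sequentially within an iteration (a deterministic barrier schedule) so a
run is bitwise reproducible from the master seed.  Crossing reads an
immutable snapshot of the best-so-far states taken at the iteration
boundary, which is exactly the consistency contract a threaded executor
would have to honour.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .loops import LoopRefineConfig, close_loop
from .moves import MoveRanges
from .packing import EnergyModel, EnergyReport
from .pipeline import PipelineConfig, PipelineState, run_pipeline
from .structure import BackboneStructure, Topology

logger = logging.getLogger(__name__)


@dataclass
class FrameworkConfig:
    """Framework-level knobs: pipelines, iterations, pool, crossing."""

    n_pipelines: int = 8
    iterations: int = 3
    elite_capacity: int | None = None  # default 4 x number of templates
    crossing_enabled: bool = True
    master_seed: int = 0
    accumulate_decoys: bool = False

    def __post_init__(self) -> None:
        if self.n_pipelines < 2:
            raise ValueError("need at least 2 pipelines")
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")


@dataclass
class PipelineAssignment:
    helices: tuple[int, ...]
    loops: tuple[int, ...]


def assign_pipelines(topology: Topology, n_pipelines: int = 8) -> list[PipelineAssignment]:
    """Region assignment: terminal helices to the end pipelines, adjacent
    pairs to the middle ones.

    For the canonical 8 pipelines over 7 helices: pipeline 1 → {TM1} plus
    the N-terminal tail, pipeline k (2..7) → {TM(k-1), TMk} plus the loop
    between them, pipeline 8 → {TM7} plus the C-terminal tail.  For other
    pipeline counts the same windows are sampled proportionally; every
    loop is then attached to the nearest window so coverage is complete.
    """
    if len(topology.tm_ranges) != 7:
        raise ValueError("pipeline assignment requires a 7-helix topology")
    windows: list[tuple[int, ...]] = [(1,)] + [(k - 1, k) for k in range(2, 8)] + [(7,)]
    if n_pipelines == len(windows):
        chosen = windows
    else:
        idx = np.linspace(0, len(windows) - 1, n_pipelines).round().astype(int)
        chosen = [windows[i] for i in idx]

    loop_sets: list[set[int]] = [set() for _ in range(n_pipelines)]
    for li in range(len(topology.loop_ranges)):
        kind = topology.loop_kind(li)
        if kind == "nterm":
            loop_sets[0].add(li)
            continue
        if kind == "cterm":
            loop_sets[-1].add(li)
            continue
        # internal loop between helix j and j+1: attach to the pipeline
        # whose window straddles it, else the nearest window
        lo, _ = topology.loop_ranges[li]
        j = sum(1 for _, e in topology.tm_ranges if e < lo)  # helix before the loop
        best, best_d = 0, float("inf")
        for p, win in enumerate(chosen):
            if j in win and j + 1 in win:
                best, best_d = p, -1
                break
            d = min(abs(h - j) + abs(h - (j + 1)) for h in win)
            if d < best_d:
                best, best_d = p, d
        loop_sets[best].add(li)
    return [
        PipelineAssignment(helices=tuple(chosen[p]), loops=tuple(sorted(loop_sets[p])))
        for p in range(n_pipelines)
    ]


@dataclass
class PoolEntry:
    structure: BackboneStructure
    energy: float
    provenance: tuple  # (template id or lineage, iteration, pipeline)
    order: int = 0


class ElitePool:
    """Bounded, energy-sorted store of the best conformations.

    Ties break by insertion order (stable).  Conformations with
    non-finite energy are never admitted.
    """

    def __init__(self, capacity: int):
        if capacity < 1:
            raise ValueError("elite pool capacity must be >= 1")
        self.capacity = capacity
        self.entries: list[PoolEntry] = []
        self._counter = 0

    def update(self, candidates: list[PoolEntry]) -> "ElitePool":
        for c in candidates:
            if not np.isfinite(c.energy):
                logger.warning("discarding pool candidate with non-finite energy")
                continue
            c.order = self._counter
            self._counter += 1
            self.entries.append(c)
        self.entries.sort(key=lambda e: (e.energy, e.order))
        del self.entries[self.capacity :]
        return self

    @property
    def best(self) -> PoolEntry:
        if not self.entries:
            raise ValueError("elite pool is empty")
        return self.entries[0]

    def __len__(self) -> int:
        return len(self.entries)


def select_start(
    pool: ElitePool,
    templates: list[BackboneStructure],
    rng: np.random.Generator,
) -> tuple[BackboneStructure, tuple]:
    """Uniform random start: an elite-pool entry if any, else a template."""
    if len(pool):
        e = pool.entries[int(rng.integers(len(pool)))]
        return e.structure, e.provenance
    if not templates:
        raise ValueError("no templates and empty pool: nothing to start from")
    i = int(rng.integers(len(templates)))
    return templates[i], ("template", i)


def _graft_helix(
    recipient: BackboneStructure,
    donor: BackboneStructure,
    helix_range: tuple[int, int],
) -> BackboneStructure:
    lo, hi = helix_range
    out = recipient.copy()
    out.coords[lo - 1 : hi] = donor.coords[lo - 1 : hi]
    return out


def cross_helices(
    states: list[PipelineState],
    assignments: list[PipelineAssignment],
    energy_model: EnergyModel,
    loop_config: LoopRefineConfig | None = None,
) -> list[PipelineState]:
    """Exchange best-so-far helices between pipelines.

    For each recipient pipeline and each helix it owns, donor pipelines'
    best poses are tried in pipeline order; the first graft that strictly
    lowers the recipient's best total energy is kept.  Loops are excluded
    from grafting; junctions broken by a graft are re-closed before
    scoring.  Crossing operates on a snapshot of the incoming best poses,
    so donor order is deterministic and donors are not affected.
    """
    if len(states) < 2:
        raise ValueError("crossing requires at least 2 pipelines")
    topo = energy_model.topology
    n = states[0].best.n_residues
    for st in states:
        if st.best.n_residues != n:
            raise ValueError("pipelines hold poses of different lengths")
    snapshot = [st.best for st in states]

    def adjacent_loops(h: int) -> list[int]:
        lo, hi = topo.tm_ranges[h - 1]
        out = []
        for li, (a, b) in enumerate(topo.loop_ranges):
            if b == lo - 1 or a == hi + 1:
                out.append(li)
        return out

    for r, (state, assignment) in enumerate(zip(states, assignments)):
        for h in assignment.helices:
            for d in range(len(states)):
                if d == r:
                    continue
                grafted = _graft_helix(state.best, snapshot[d], topo.tm_ranges[h - 1])
                energy = energy_model.evaluate(grafted)
                if energy.total < state.best_energy.total:
                    # graft accepted: restore chain validity at the broken
                    # junctions, then keep the re-scored closed pose
                    for li in adjacent_loops(h):
                        grafted, _, _ = close_loop(grafted, topo, li, loop_config)
                    energy = energy_model.evaluate(grafted)
                    state.best = grafted
                    state.best_energy = energy
                    if energy.total < state.current_energy.total:
                        state.current = grafted
                        state.current_energy = energy
                    break
    return states


@dataclass
class RunReport:
    """Per-iteration summary of a framework run."""

    rows: list[dict] = field(default_factory=list)

    def log(self, **kw) -> None:
        self.rows.append(kw)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


@dataclass
class RunResult:
    best: BackboneStructure
    best_energy: EnergyReport
    decoys: list[PoolEntry]
    report: RunReport


def run_patgpcr(
    templates: list[BackboneStructure],
    energy_model: EnergyModel,
    framework_config: FrameworkConfig | None = None,
    pipeline_config: PipelineConfig | None = None,
    move_ranges: MoveRanges | None = None,
    loop_config: LoopRefineConfig | None = None,
) -> RunResult:
    """Multi-template refinement: T iterations of refine → cross → pool.

    ``pipeline_config`` provides the per-stage cycle counts; region
    assignments override its helix/loop fields per pipeline.  The run is
    fully reproducible from ``framework_config.master_seed``.
    """
    fw = framework_config or FrameworkConfig()
    base = pipeline_config or PipelineConfig()
    topo = energy_model.topology
    if not templates:
        raise ValueError("at least one template is required")
    n = templates[0].n_residues
    for t in templates:
        if t.n_residues != n:
            raise ValueError("templates must share the target length")
    topo.validate_coverage(n)

    assignments = assign_pipelines(topo, fw.n_pipelines)
    capacity = fw.elite_capacity or 4 * len(templates)
    pool = ElitePool(capacity)
    pool.update(
        [
            PoolEntry(t, energy_model.evaluate(t).total, ("template", i, 0))
            for i, t in enumerate(templates)
        ]
    )
    report = RunReport()
    ss = np.random.SeedSequence(fw.master_seed)
    all_decoys: list[PoolEntry] = []

    for it in range(1, fw.iterations + 1):
        streams = [
            np.random.default_rng(s) for s in ss.spawn(fw.n_pipelines)
        ]
        states: list[PipelineState] = []
        start_energies: list[float] = []
        for p in range(fw.n_pipelines):
            start, _prov = select_start(pool, templates, streams[p])
            cfg = PipelineConfig(
                stage2_cycles=base.stage2_cycles,
                stage3_cycles=base.stage3_cycles,
                stage4_cycles=base.stage4_cycles,
                iterations=base.iterations,
                assigned_helices=assignments[p].helices,
                assigned_loops=assignments[p].loops,
                refresh_axes=base.refresh_axes,
            )
            state = run_pipeline(
                start, energy_model, cfg, streams[p], move_ranges, loop_config
            )
            start_energies.append(energy_model.evaluate(start).total)
            states.append(state)
        if fw.crossing_enabled:
            states = cross_helices(states, assignments, energy_model, loop_config)
        # improved-only admission keeps the pool elitist
        candidates = [
            PoolEntry(st.best, st.best_energy.total, ("refined", it, p))
            for p, st in enumerate(states)
            if st.best_energy.total < start_energies[p]
        ]
        pool.update(candidates)
        if fw.accumulate_decoys:
            all_decoys.extend(candidates)
        report.log(
            iteration=it,
            pool_best=pool.best.energy,
            pool_size=len(pool),
            admitted=len(candidates),
            accepts=sum(sum(st.accept_counts.values()) for st in states),
        )

    decoys = all_decoys if fw.accumulate_decoys else list(pool.entries)
    best_entry = pool.best
    return RunResult(
        best=best_entry.structure,
        best_energy=energy_model.evaluate(best_entry.structure),
        decoys=decoys,
        report=report,
    )
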