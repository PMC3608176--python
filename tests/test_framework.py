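"""Multi-template framework: assignment, elite pool, crossing, full runs."""

import numpy as np
import pytest

from gpcrbundle.fixtures import make_complementary_templates
from gpcrbundle.framework import (
    ElitePool,
    FrameworkConfig,
    PoolEntry,
    assign_pipelines,
    cross_helices,
    run_patgpcr,
    select_start,
)
from gpcrbundle.moves import translate_helix
from gpcrbundle.pipeline import PipelineState
from gpcrbundle.structure import region_rmsd


class TestAssignPipelines:
    def test_canonical_eight_pipeline_layout(self, bundle):
        _, topo, _ = bundle
        a = assign_pipelines(topo, 8)
        assert len(a) == 8
        assert a[0].helices == (1,)
        assert a[7].helices == (7,)
        for k in range(2, 8):
            assert a[k - 1].helices == (k - 1, k)
        # TM1 is covered by pipelines 1 and 2
        assert [1 in x.helices for x in a].count(True) == 2

    def test_loop_union_covers_all_loops(self, bundle):
        _, topo, _ = bundle
        for n_pipelines in (4, 6, 8):
            a = assign_pipelines(topo, n_pipelines)
            covered = set()
            for x in a:
                covered.update(x.loops)
            assert covered == set(range(len(topo.loop_ranges)))

    def test_windowing_for_other_pipeline_counts(self, bundle):
        _, topo, _ = bundle
        a = assign_pipelines(topo, 4)
        assert len(a) == 4
        assert a[0].helices == (1,)
        assert a[-1].helices == (7,)
        helix_union = set()
        for x in a:
            helix_union.update(x.helices)
        # windows are sampled, so not every helix need appear, but the
        # layout must stay ordered and contiguous per pipeline
        for x in a:
            hs = sorted(x.helices)
            assert all(b - a_ == 1 for a_, b in zip(hs, hs[1:]))

    def test_non_seven_topology_rejected(self):
        class Fake:
            tm_ranges = [(1, 10)] * 6

        with pytest.raises(ValueError, match="7-helix"):
            assign_pipelines(Fake(), 8)


class TestElitePool:
    def entry(self, s, e):
        return PoolEntry(structure=s, energy=e, provenance=("t", 0, 0))

    def test_keeps_lowest_energies(self, small_bundle):
        s, _, _ = small_bundle
        pool = ElitePool(capacity=5)
        pool.update([self.entry(s, e) for e in [9, 3, 7, 1, 5, 8, 2, 6, 4, 0]])
        assert [e.energy for e in pool.entries] == [0, 1, 2, 3, 4]

    def test_worse_candidate_leaves_full_pool_unchanged(self, small_bundle):
        s, _, _ = small_bundle
        pool = ElitePool(capacity=3)
        pool.update([self.entry(s, e) for e in [1.0, 2.0, 3.0]])
        before = [e.energy for e in pool.entries]
        pool.update([self.entry(s, 99.0)])
        assert [e.energy for e in pool.entries] == before

    def test_minimum_energy_non_increasing(self, small_bundle, rng):
        s, _, _ = small_bundle
        pool = ElitePool(capacity=4)
        minima = []
        for _ in range(20):
            pool.update([self.entry(s, float(rng.uniform(0, 100)))])
            minima.append(pool.best.energy)
        assert all(b <= a for a, b in zip(minima, minima[1:]))

    def test_non_finite_energy_never_admitted(self, small_bundle):
        s, _, _ = small_bundle
        pool = ElitePool(capacity=3)
        pool.update([self.entry(s, float("nan")), self.entry(s, float("inf"))])
        assert len(pool) == 0

    def test_stable_tie_break(self, small_bundle):
        s, _, _ = small_bundle
        pool = ElitePool(capacity=2)
        first, second = self.entry(s, 1.0), self.entry(s, 1.0)
        pool.update([first, second])
        assert pool.entries[0] is first


class TestSelectStart:
    def test_single_template_empty_pool(self, small_bundle, rng):
        s, _, _ = small_bundle
        pool = ElitePool(capacity=2)
        start, prov = select_start(pool, [s], rng)
        assert start is s
        assert prov == ("template", 0)

    def test_deterministic_for_fixed_seed(self, small_bundle):
        s, _, _ = small_bundle
        templates = [s, s.copy(), s.copy()]
        pool = ElitePool(capacity=2)
        a = [select_start(pool, templates, np.random.default_rng(3))[1] for _ in range(10)]
        b = [select_start(pool, templates, np.random.default_rng(3))[1] for _ in range(10)]
        assert a == b

    def test_uniform_over_templates(self, small_bundle):
        """Multinomial oracle: each of 3 templates chosen about 1/3 of the
        time, within 3 standard errors."""
        s, _, _ = small_bundle
        templates = [s, s.copy(), s.copy()]
        pool = ElitePool(capacity=2)
        rng = np.random.default_rng(0)
        n = 3000
        counts = np.zeros(3)
        for _ in range(n):
            _, prov = select_start(pool, templates, rng)
            counts[prov[1]] += 1
        se = np.sqrt(n * (1 / 3) * (2 / 3))
        assert np.all(np.abs(counts - n / 3) < 3 * se)

    def test_both_empty_rejected(self, rng):
        with pytest.raises(ValueError, match="nothing to start"):
            select_start(ElitePool(capacity=1), [], rng)


class TestCrossHelices:
    def states_for(self, structures, energy_model, assignments):
        return [
            PipelineState.from_start(s, energy_model.evaluate(s)) for s in structures
        ]

    def test_identical_pipelines_never_substitute(self, small_bundle, small_energy_model):
        s, topo, _ = small_bundle
        assignments = assign_pipelines(topo, 8)
        states = self.states_for([s.copy() for _ in range(8)], small_energy_model, assignments)
        out = cross_helices(states, assignments, small_energy_model)
        for st in out:
            np.testing.assert_array_equal(st.best.coords, s.coords)

    def test_clean_donor_helix_accepted_into_clashing_recipient(
        self, small_bundle, small_energy_model
    ):
        s, topo, _ = small_bundle
        # recipient: TM3 rammed into the bundle core -> steric/wells penalty
        broken = translate_helix(
            s, topo.tm_ranges[2], -0.6 * np.asarray(s.ca[topo.tm_indices()].mean(axis=0))
        )
        broken = translate_helix(broken, topo.tm_ranges[2], np.array([-6.0, -6.0, 0.0]))
        assignments = assign_pipelines(topo, 8)
        structures = [broken if p == 2 else s.copy() for p in range(8)]
        states = self.states_for(structures, small_energy_model, assignments)
        e_before = states[2].best_energy.total
        out = cross_helices(states, assignments, small_energy_model)
        assert out[2].best_energy.total < e_before
        # recipient's non-TM3, non-adjacent-loop residues are untouched
        lo, hi = topo.tm_ranges[2]
        touched = np.zeros(s.n_residues, bool)
        touched[lo - 1 : hi] = True
        for a, b in topo.loop_ranges:
            if b == lo - 1 or a == hi + 1:
                touched[a - 1 : b] = True
        np.testing.assert_array_equal(
            out[2].best.coords[~touched], broken.coords[~touched]
        )

    def test_requires_two_pipelines(self, small_bundle, small_energy_model):
        s, topo, _ = small_bundle
        assignments = assign_pipelines(topo, 8)
        with pytest.raises(ValueError, match="at least 2"):
            cross_helices(
                self.states_for([s], small_energy_model, assignments[:1]),
                assignments[:1],
                small_energy_model,
            )


class TestRunPatgpcr:
    def test_zero_iterations_returns_scored_templates(self, small_bundle, small_energy_model, rng):
        s, topo, frame = small_bundle
        templates = make_complementary_templates(
            s, topo, frame, [[1, 2, 3, 4], [5, 6, 7]], 6.0, rng
        )
        result = run_patgpcr(
            templates, small_energy_model, FrameworkConfig(iterations=0, master_seed=0)
        )
        energies = sorted(small_energy_model.evaluate(t).total for t in templates)
        assert len(result.decoys) == len(templates)
        assert result.best_energy.total == pytest.approx(energies[0])

    def test_pool_best_non_increasing_over_iterations(self, small_bundle, small_energy_model, rng):
        from gpcrbundle.pipeline import PipelineConfig

        s, topo, frame = small_bundle
        templates = make_complementary_templates(
            s, topo, frame, [[1, 2, 3, 4], [5, 6, 7]], 6.0, rng
        )
        result = run_patgpcr(
            templates,
            small_energy_model,
            FrameworkConfig(iterations=3, master_seed=1),
            PipelineConfig(stage2_cycles=4, stage3_cycles=2, stage4_cycles=2),
        )
        best = result.report.to_dataframe()["pool_best"].tolist()
        assert all(b <= a + 1e-12 for a, b in zip(best, best[1:]))

    def test_mismatched_template_lengths_rejected(self, small_bundle, small_energy_model):
        s, _, _ = small_bundle
        from gpcrbundle.structure import BackboneStructure

        short = BackboneStructure(
            residue_ids=s.residue_ids[:-1].copy(), coords=s.coords[:-1].copy()
        )
        with pytest.raises(ValueError, match="share the target length"):
            run_patgpcr([s, short], small_energy_model)

    def test_run_reduces_tm_rmsd_of_best_decoy(self, small_bundle, small_energy_model, rng):
        from gpcrbundle.pipeline import PipelineConfig

        s, topo, frame = small_bundle
        templates = make_complementary_templates(
            s, topo, frame, [[1, 2, 3, 4], [5, 6, 7]], 6.0, rng
        )
        start_best = min(region_rmsd(t, s, "TM", topo) for t in templates)
        result = run_patgpcr(
            templates,
            small_energy_model,
            FrameworkConfig(iterations=2, master_seed=3),
            PipelineConfig(stage2_cycles=6, stage3_cycles=2, stage4_cycles=3),
        )
        final_best = min(
            region_rmsd(e.structure, s, "TM", topo) for e in result.decoys
        )
        assert final_best < start_best
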