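import numpy as np
import pytest

from thaploseq.fragments import Fragment, FragmentMatrix
from thaploseq.genome_model import DiploidHaplotypes, VariantSet
from thaploseq.phaser import (
    PhasingResult,
    brute_force_phase,
    build_graph,
    lcp_refine,
    max_cut_phase,
    mec_score,
    write_phased_vcf,
)
from thaploseq.simulator import (
    SimulationConfig,
    run_simulation,
    simulate_panel,
    simulate_variants,
)


def matrix_from(obs_lists, n_variants, quals=30):
    frags = []
    for i, obs in enumerate(obs_lists):
        frags.append(
            Fragment(f"F{i}", [(v, a, quals) for v, a in obs], [1] * len(obs))
        )
    return FragmentMatrix.from_fragments(frags, n_variants)


@pytest.fixture
def three_fragment_matrix():
    # F1=(v0:0, v1:0), F2=(v0:1, v1:1), F3=(v0:0, v1:1)
    return matrix_from([[(0, 0), (1, 0)], [(0, 1), (1, 1)], [(0, 0), (1, 1)]], 2)


def random_matrix(rng, n_variants, n_fragments):
    obs_lists = []
    for _ in range(n_fragments):
        k = int(rng.integers(2, min(4, n_variants) + 1))
        vis = np.sort(rng.choice(n_variants, size=k, replace=False))
        obs_lists.append([(int(v), int(rng.integers(0, 2))) for v in vis])
    return matrix_from(obs_lists, n_variants)


class TestMecScore:
    def test_equal_phase_costs_one_correction(self, three_fragment_matrix):
        assert mec_score(three_fragment_matrix, [0, 0]) == 1

    def test_opposite_phase_costs_two(self, three_fragment_matrix):
        assert mec_score(three_fragment_matrix, [0, 1]) == 2

    def test_single_observation_fragments_cost_nothing(self):
        m = matrix_from([[(0, 0)], [(1, 1)], [(2, 0)]], 3)
        for phase in ([0, 0, 0], [1, 0, 1], [1, 1, 1]):
            assert mec_score(m, phase) == 0

    def test_global_flip_leaves_score_unchanged(self):
        rng = np.random.default_rng(3)
        m = random_matrix(rng, 8, 25)
        phase = rng.integers(0, 2, 8)
        assert mec_score(m, phase) == mec_score(m, 1 - phase)


class TestBruteForce:
    def test_three_fragment_optimum(self, three_fragment_matrix):
        res = brute_force_phase(three_fragment_matrix)
        assert res.mec_score == 1
        ph = res.phase_array()
        assert ph.tolist() in ([0, 0], [1, 1])

    def test_single_variant_component_unresolved(self):
        m = matrix_from([[(0, 0)]], 1)
        res = brute_force_phase(m)
        assert res.blocks == [] and res.unresolved.tolist() == [0]

    def test_oversized_component_rejected(self):
        rng = np.random.default_rng(0)
        m = random_matrix(rng, 20, 100)
        with pytest.raises(ValueError, match="exceeds"):
            brute_force_phase(m, max_component=16)

    def test_optimum_never_above_heuristic(self):
        rng = np.random.default_rng(10)
        for trial in range(50):
            n_var = int(rng.integers(2, 11))
            m = random_matrix(rng, n_var, int(rng.integers(4, 31)))
            exact = brute_force_phase(m)
            heur = max_cut_phase(m, n_restarts=10, seed=trial)
            assert exact.mec_score <= heur.mec_score


class TestMaxCut:
    def test_concordant_fragments_recover_relative_phase(self):
        m = matrix_from([[(0, 0), (1, 1)]] * 5, 2)
        res = max_cut_phase(m, seed=0)
        assert res.mec_score == 0
        ph = res.phase_array()
        assert ph[0] != ph[1]

    def test_three_fragment_example_reaches_optimum(self, three_fragment_matrix):
        res = max_cut_phase(three_fragment_matrix, seed=0)
        assert res.mec_score == 1
        assert res.phase_array().tolist() in ([0, 0], [1, 1])

    def test_no_linking_fragments_leaves_all_unresolved(self):
        m = matrix_from([[(0, 0)], [(1, 1)], [(2, 0)]], 3)
        res = max_cut_phase(m, seed=0)
        assert res.blocks == []
        assert sorted(res.unresolved.tolist()) == [0, 1, 2]

    def test_result_mec_is_self_consistent(self):
        rng = np.random.default_rng(4)
        for trial in range(10):
            m = random_matrix(rng, 12, 40)
            res = max_cut_phase(m, n_restarts=5, seed=trial)
            assert mec_score(m, res.phase_array()) == res.mec_score

    def test_block_partition_counts_every_variant_once(self):
        rng = np.random.default_rng(6)
        m = random_matrix(rng, 15, 30)
        res = max_cut_phase(m, seed=0)
        seen = list(res.unresolved)
        for b in res.blocks:
            seen.extend(b.members)
        assert sorted(seen) == list(range(15))

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(8)
        m = random_matrix(rng, 20, 60)
        r1 = max_cut_phase(m, seed=123)
        r2 = max_cut_phase(m, seed=123)
        np.testing.assert_array_equal(r1.phase_array(), r2.phase_array())
        assert r1.mec_score == r2.mec_score

    def test_adding_concordant_fragments_never_raises_optimum(self):
        rng = np.random.default_rng(9)
        for trial in range(10):
            m = random_matrix(rng, 6, 12)
            base = brute_force_phase(m)
            ph = base.phase_array()
            extra_v = np.sort(rng.choice(6, size=2, replace=False))
            extra = [(int(v), int(ph[v]) if ph[v] >= 0 else 0) for v in extra_v]
            frags = [m.fragment(i) for i in range(m.n_fragments)]
            frags.append(Fragment("extra", [(v, a, 30) for v, a in extra], [1, 1]))
            m2 = FragmentMatrix.from_fragments(frags, 6)
            assert brute_force_phase(m2).mec_score <= base.mec_score


class TestBuildGraph:
    def test_no_colinked_variants_gives_empty_graph(self):
        m = matrix_from([[(0, 0)], [(1, 1)]], 2)
        assert build_graph(m) == {}

    def test_concordant_votes_sum_quality_weights(self):
        m = matrix_from([[(0, 0), (1, 0)]] * 3, 2, quals=30)
        edges = build_graph(m)
        assert set(edges) == {(0, 1)}
        assert edges[(0, 1)] == pytest.approx(90.0)

    def test_component_partition_matches_union_find_oracle(self):
        rng = np.random.default_rng(12)
        m = random_matrix(rng, 20, 15)
        # union-find oracle over fragment co-coverage
        parent = list(range(20))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i in range(m.n_fragments):
            obs = m.fragment(i).observations
            for (v1, _, _), (v2, _, _) in zip(obs, obs[1:]):
                parent[find(v1)] = find(v2)
        oracle = {}
        for v in range(20):
            oracle.setdefault(find(v), set()).add(v)
        res = max_cut_phase(m, seed=0)
        got = [set(b.members.tolist()) for b in res.blocks]
        want = [grp for grp in oracle.values() if len(grp) >= 2]
        assert sorted(map(sorted, got)) == sorted(map(sorted, want))


class TestNoiseFreeRecovery:
    def test_clean_simulation_phases_perfectly(self):
        cfg = SimulationConfig.fast(
            seed=21,
            locus_length=200_000,
            n_fragments=60_000,
            htrans_rate=0.0,
            seq_error=0.0,
            lfr_n=100,
            n_genes=3,
        )
        out = run_simulation(cfg)
        res = max_cut_phase(out.fragments, n_restarts=5, seed=21)
        assert res.mec_score == 0
        truth = out.truth.hapA
        for b in res.blocks:
            rel = b.phase ^ truth[b.members]
            assert len(np.unique(rel)) == 1  # exact up to global block flip


class TestLcpRefine:
    def _scaffold_result(self, n, resolved_mask, phase):
        members = np.flatnonzero(resolved_mask)
        block = None
        if len(members):
            from thaploseq.phaser import HaplotypeBlock

            block = HaplotypeBlock(
                block_id=int(members[0]) + 1,
                members=members,
                phase=phase[members],
                support=np.zeros(len(members), dtype=np.int64),
                sources=np.array(["mec"] * len(members)),
            )
        return PhasingResult(
            n,
            [block] if block else [],
            0,
            np.flatnonzero(~resolved_mask),
        )

    def test_no_unresolved_variants_is_identity(self):
        cfg = SimulationConfig.fast(seed=30, locus_length=100_000)
        vs, hap = simulate_variants(cfg)
        res = self._scaffold_result(len(vs), np.ones(len(vs), bool), hap.hapA)
        out = lcp_refine(res, vs, simulate_panel(cfg, vs, hap))
        assert out is res

    def test_truth_panel_phases_every_unresolved_variant_correctly(self):
        cfg = SimulationConfig.fast(
            seed=31, locus_length=100_000, panel_mutation_rate=0.0, panel_switches=0.0
        )
        vs, hap = simulate_variants(cfg)
        mask = np.ones(len(vs), bool)
        mask[::5] = False  # drop every 5th variant from the scaffold
        res = self._scaffold_result(len(vs), mask, hap.hapA)
        panel = simulate_panel(cfg, vs, hap)
        out = lcp_refine(res, vs, panel)
        assert len(out.unresolved) == 0
        ph = out.phase_array()
        assert (ph == hap.hapA).all()

    def test_empty_panel_is_noop_with_warning(self, caplog):
        cfg = SimulationConfig.fast(seed=32, locus_length=100_000)
        vs, hap = simulate_variants(cfg)
        mask = np.ones(len(vs), bool)
        mask[0] = False
        res = self._scaffold_result(len(vs), mask, hap.hapA)
        out = lcp_refine(res, vs, np.zeros((0, len(vs))))
        assert out is res

    def test_noisy_panel_assignments_beat_coin_flip(self):
        cfg = SimulationConfig.fast(
            seed=33,
            locus_length=500_000,
            panel_mutation_rate=0.02,
            panel_switches=5.0,
            panel_size=20,
        )
        vs, hap = simulate_variants(cfg)
        rng = np.random.default_rng(33)
        mask = np.ones(len(vs), bool)
        drop = rng.choice(len(vs), size=500, replace=False)
        mask[drop] = False
        res = self._scaffold_result(len(vs), mask, hap.hapA)
        out = lcp_refine(res, vs, simulate_panel(cfg, vs, hap))
        assigned = [
            v for v in drop if out.phase_array()[v] >= 0
        ]
        assert len(assigned) > 100
        acc = np.mean([out.phase_array()[v] == hap.hapA[v] for v in assigned])
        assert acc > 0.9  # far above the 50 % unassigned baseline


class TestPhasedVcf:
    def test_round_trip_preserves_phase_bits(self, tmp_path, tiny_sim):
        from thaploseq.genome_model import read_variants_vcf

        out = tiny_sim
        res = max_cut_phase(out.fragments, n_restarts=5, seed=1)
        path = tmp_path / "phased.vcf"
        write_phased_vcf(res, out.variants, out.locus, str(path))
        back, _ = read_variants_vcf(str(path))
        ph = res.phase_array()
        np.testing.assert_array_equal(back.truth_phase, ph)

    def test_single_block_shares_one_ps_value(self, tmp_path):
        m = matrix_from([[(0, 0), (1, 1)], [(1, 1), (2, 0)]], 3)
        res = max_cut_phase(m, seed=0)
        assert len(res.blocks) == 1
        vs = VariantSet([10, 20, 30], ["A", "A", "A"], ["C", "C", "C"])
        from thaploseq.genome_model import ReferenceLocus

        locus = ReferenceLocus("x", "A" * 100)
        path = tmp_path / "p.vcf"
        write_phased_vcf(res, vs, locus, str(path))
        ps_values = {
            line.split("\t")[9].split(":")[1]
            for line in path.read_text().splitlines()
            if not line.startswith("#") and ":" in line.split("\t")[9]
        }
        assert len(ps_values) == 1

    def test_empty_result_writes_header_only_unphased(self, tmp_path):
        vs = VariantSet([10], ["A"], ["C"])
        from thaploseq.genome_model import ReferenceLocus

        locus = ReferenceLocus("x", "A" * 100)
        res = PhasingResult(1, [], 0, np.array([0]))
        path = tmp_path / "e.vcf"
        write_phased_vcf(res, vs, locus, str(path))
        body = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert len(body) == 1 and "0/1" in body[0]
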