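import numpy as np
import pytest
from scipy import stats as sps

from thaploseq.fragments import Fragment, FragmentMatrix
from thaploseq.genome_model import DiploidHaplotypes, VariantSet
from thaploseq.phaser import HaplotypeBlock, PhasingResult, lcp_refine, max_cut_phase
from thaploseq.probe_design import ProbeSet
from thaploseq.qc_metrics import (
    binned_contact_correlation,
    concordance_filter,
    enrichment_fold,
    evaluate_phasing,
    htrans_report,
    probe_sensitivity,
)
from thaploseq.simulator import (
    SimulationConfig,
    apply_capture,
    plant_truth_errors,
    run_simulation,
    simulate_lfr_fragments,
    simulate_proximity_fragments,
    simulate_variants,
)


def _variants(n, spacing=300):
    pos = np.arange(n) * spacing + 10
    return VariantSet(pos, ["A"] * n, ["C"] * n, truth_phase=[0] * n)


def _matrix(obs_lists, n_variants, ends=None):
    frags = []
    for i, obs in enumerate(obs_lists):
        e = ends[i] if ends else [1] * len(obs)
        frags.append(Fragment(f"F{i}", [(v, a, 30) for v, a in obs], e))
    return FragmentMatrix.from_fragments(frags, n_variants)


class TestHtransReport:
    def test_consistent_fragments_give_zero_ratio(self):
        vs = _variants(5)
        hap = DiploidHaplotypes(np.zeros(5, dtype=np.int8))
        m = _matrix([[(0, 0), (1, 0)], [(2, 1), (3, 1)]], 5)
        rep = htrans_report(m, hap, vs)
        assert rep.n_informative == 2 and rep.htrans_ratio == 0.0

    def test_flipped_variant_makes_all_its_pairs_htrans(self):
        vs = _variants(5)
        truth = np.zeros(5, dtype=np.int8)
        m = _matrix([[(0, 0), (2, 0)], [(1, 0), (2, 0)], [(3, 0), (4, 0)]], 5)
        reported = truth.copy()
        reported[2] = 1  # reported phase flip at v2
        rep = htrans_report(m, DiploidHaplotypes(reported), vs)
        assert rep.n_htrans == 2
        assert rep.htrans_ratio == pytest.approx(2 / 3)
        assert rep.htrans_count[2] == 2

    def test_generative_htrans_rate_recovered_within_ci(self):
        cfg = SimulationConfig.fast(
            seed=40, locus_length=500_000, n_fragments=60_000, htrans_rate=0.05, seq_error=0.0
        )
        vs, hap = simulate_variants(cfg)
        m = simulate_proximity_fragments(cfg, vs, hap)
        rep = htrans_report(m, hap, vs)
        # cross-end pairs are h-trans with probability tau; same-end never are.
        # restrict the check to cross-end informative pairs via origin metadata
        assert rep.n_informative > 1000
        inf = m.informative_mask()
        frac_htrans_frag = m.origin["is_htrans"][inf].mean()
        lo, hi = sps.binom.ppf([0.005, 0.995], int(inf.sum()), 0.05) / int(inf.sum())
        assert lo <= frac_htrans_frag <= hi
        assert 0.0 < rep.htrans_ratio <= 0.05 + 0.01

    def test_same_end_fraction_identifies_planted_flips(self):
        # all pairs same-end, one reported flip -> same-end fraction 1
        vs = _variants(4, spacing=50)
        truth = np.zeros(4, dtype=np.int8)
        reported = truth.copy()
        reported[1] = 1
        m = _matrix([[(0, 0), (1, 0)], [(1, 0), (2, 0)]], 4)
        rep = htrans_report(m, DiploidHaplotypes(reported), vs)
        assert rep.n_htrans == 2 and rep.same_end_fraction == 1.0


class TestConcordanceFilter:
    def test_no_htrans_anywhere_gives_empty_blacklist(self):
        vs = _variants(5)
        hap = DiploidHaplotypes(np.zeros(5, dtype=np.int8))
        pl = _matrix([[(0, 0), (1, 0)]], 5)
        lfr = _matrix([[(0, 0), (1, 0), (2, 0)]], 5)
        rep = htrans_report(pl, hap, vs)
        bl = concordance_filter(rep, lfr, hap, vs)
        assert bl.tolist() == []

    def test_planted_flip_blacklisted_when_both_datasets_agree(self):
        vs = _variants(6, spacing=100)
        truth = np.zeros(6, dtype=np.int8)
        reported = truth.copy()
        reported[3] = 1
        pl = _matrix(
            [[(2, 0), (3, 0)], [(3, 0), (4, 0)], [(0, 0), (1, 0)]], 6
        )
        lfr = _matrix([[(2, 0), (3, 0), (4, 0)]] * 3, 6)
        hap = DiploidHaplotypes(reported)
        rep = htrans_report(pl, hap, vs)
        bl = concordance_filter(rep, lfr, hap, vs, min_lfr_support=2)
        assert bl.tolist() == [3]

    def test_simulation_recall_and_precision_at_defaults(self, fast_sim):
        out = fast_sim
        rep = htrans_report(out.fragments, out.reported_truth, out.variants)
        bl = concordance_filter(rep, out.lfr, out.reported_truth, out.variants)
        flips = set(out.planted_flips.tolist())
        hits = set(bl.tolist())
        recall = len(flips & hits) / len(flips)
        precision = len(flips & hits) / len(hits)
        assert recall >= 0.8
        assert precision >= 0.9


class TestEvaluatePhasing:
    def _result_with_phase(self, phase, n=None):
        n = n if n is not None else len(phase)
        members = np.arange(len(phase))
        block = HaplotypeBlock(
            block_id=1,
            members=members,
            phase=np.asarray(phase, dtype=np.int8),
            support=np.zeros(len(phase), dtype=np.int64),
            sources=np.array(["mec"] * len(phase)),
        )
        return PhasingResult(n, [block], 0, np.arange(len(phase), n))

    def test_single_flip_metrics_match_hand_count(self):
        truth = DiploidHaplotypes(np.zeros(10, dtype=np.int8))
        phase = np.zeros(10, dtype=np.int8)
        phase[4] = 1
        ev = evaluate_phasing(self._result_with_phase(phase), truth, _variants(10))
        assert ev.resolution == 1.0
        assert ev.accuracy == pytest.approx(0.9)
        assert ev.switch_error == pytest.approx(2 / 9)

    def test_perfect_phasing_is_perfect(self):
        truth = DiploidHaplotypes(np.zeros(10, dtype=np.int8))
        ev = evaluate_phasing(
            self._result_with_phase(np.zeros(10, dtype=np.int8)), truth, _variants(10)
        )
        assert ev.accuracy == 1.0 and ev.switch_error == 0.0

    def test_global_block_flip_leaves_metrics_unchanged(self):
        rng = np.random.default_rng(50)
        truth_bits = rng.integers(0, 2, 20).astype(np.int8)
        truth = DiploidHaplotypes(truth_bits)
        phase = truth_bits.copy()
        phase[rng.choice(20, 3, replace=False)] ^= 1
        vs = _variants(20)
        ev1 = evaluate_phasing(self._result_with_phase(phase), truth, vs)
        ev2 = evaluate_phasing(self._result_with_phase(1 - phase), truth, vs)
        assert ev1.accuracy == ev2.accuracy
        assert ev1.switch_error == ev2.switch_error

    def test_blacklist_leaves_both_numerator_and_denominator(self):
        truth = DiploidHaplotypes(np.zeros(10, dtype=np.int8))
        phase = np.zeros(10, dtype=np.int8)
        phase[4] = 1
        ev = evaluate_phasing(
            self._result_with_phase(phase), truth, _variants(10), blacklist=np.array([4])
        )
        assert ev.accuracy == 1.0
        assert ev.n_evaluated == 9
        assert ev.n_excluded_blacklist == 1

    def test_blacklisting_never_lowers_accuracy_on_planted_errors(self, fast_sim):
        out = fast_sim
        res = max_cut_phase(out.fragments, n_restarts=5, seed=1)
        res = lcp_refine(res, out.variants, out.panel)
        rep = htrans_report(out.fragments, out.reported_truth, out.variants)
        bl = concordance_filter(rep, out.lfr, out.reported_truth, out.variants)
        before = evaluate_phasing(res, out.reported_truth, out.variants)
        after = evaluate_phasing(res, out.reported_truth, out.variants, blacklist=bl)
        assert after.accuracy >= before.accuracy

    def test_gene_level_counts_partition(self, tiny_sim):
        out = tiny_sim
        res = max_cut_phase(out.fragments, n_restarts=5, seed=7)
        ev = evaluate_phasing(res, out.truth, out.variants, genes=out.locus.genes)
        df = ev.gene_level
        assert len(df) == len(out.locus.genes)
        assert (df["n_correct"] <= df["n_resolved"]).all()
        assert (df["n_resolved"] <= df["n_het"]).all()


class TestEnrichment:
    def test_uniform_fragments_half_locus_fold_near_one(self):
        cfg = SimulationConfig.fast(seed=41, locus_length=500_000, n_fragments=20_000)
        vs, hap = simulate_variants(cfg)
        m = simulate_proximity_fragments(cfg, vs, hap)
        rep = enrichment_fold(m, [(0, 250_000)], 500_000)
        # span decay makes a contiguous half slightly over-represented
        assert 0.8 < rep.fold < 1.6

    def test_everything_on_target_reports_infinity(self):
        cfg = SimulationConfig.fast(seed=41, locus_length=100_000, n_fragments=500)
        vs, hap = simulate_variants(cfg)
        m = simulate_proximity_fragments(cfg, vs, hap)
        rep = enrichment_fold(m, [(0, 100_000)], 100_000)
        assert rep.fold == float("inf")

    def test_capture_thinning_measured_within_band(self):
        cfg = SimulationConfig.fast(
            seed=42, n_fragments=20_000, enrichment_fold=50.0, decay_exponent=3.0
        )
        rng = np.random.default_rng(42)
        vs, hap = simulate_variants(cfg, rng=rng)
        m = simulate_proximity_fragments(cfg, vs, hap, rng)
        half = [(0, cfg.locus_length // 2)]
        probes = ProbeSet([(0, cfg.locus_length // 2, "cut_site")], target_intervals=half)
        cap = apply_capture(m, probes, cfg, rng)
        rep = enrichment_fold(cap, half, cfg.locus_length)
        assert 40.0 <= rep.fold <= 60.0

    def test_probe_sensitivity_reflects_capture(self, tiny_sim):
        out = tiny_sim
        # uniform read anchors spread the captured fragments' distal ends
        # over the whole locus, so the per-probe ratio over virtual probes
        # sits near the 3-5x range rather than the junction-anchored regime
        frac = probe_sensitivity(
            out.fragments, out.probe_set, out.restriction_map, out.locus,
            seed=1, min_fold=3.0,
        )
        assert frac > 0.9
        assert 0.0 <= probe_sensitivity(
            out.fragments, out.probe_set, out.restriction_map, out.locus, seed=1
        ) <= 1.0


class TestContactCorrelation:
    def test_dataset_against_itself_is_exactly_one(self, tiny_sim):
        r2 = binned_contact_correlation(
            tiny_sim.fragments, tiny_sim.fragments, len(tiny_sim.locus)
        )
        assert r2 == 1.0

    def test_shared_contact_law_gives_high_r2_across_seeds(self):
        base = SimulationConfig.fast(seed=43, n_fragments=50_000)
        vs, hap = simulate_variants(base)
        m1 = simulate_proximity_fragments(base, vs, hap, np.random.default_rng(101))
        m2 = simulate_proximity_fragments(base, vs, hap, np.random.default_rng(202))
        r2 = binned_contact_correlation(m1, m2, base.locus_length)
        assert r2 > 0.8

    def test_permuted_bin_pair_counts_decorrelate(self):
        cfg = SimulationConfig.fast(seed=44, n_fragments=20_000)
        vs, hap = simulate_variants(cfg)
        m = simulate_proximity_fragments(cfg, vs, hap)
        rng = np.random.default_rng(44)
        bin_size = 100_000
        n_bins = cfg.locus_length // bin_size
        pairs = [(i, j) for i in range(n_bins) for j in range(i, n_bins)]
        mapping = dict(zip(pairs, [pairs[k] for k in rng.permutation(len(pairs))]))
        lo = np.minimum(m.origin["start1"], m.origin["start2"]) // bin_size
        hi = np.maximum(m.origin["start1"], m.origin["start2"]) // bin_size
        new_lo = np.array([mapping[(int(a), int(b))][0] for a, b in zip(lo, hi)])
        new_hi = np.array([mapping[(int(a), int(b))][1] for a, b in zip(lo, hi)])
        perm = m.subset(np.ones(m.n_fragments, bool))
        perm.origin["start1"] = new_lo * bin_size + 1
        perm.origin["start2"] = new_hi * bin_size + 1
        assert len(pairs) >= 50
        r2 = binned_contact_correlation(m, perm, cfg.locus_length)
        assert r2 < 0.2

    def test_too_few_bin_pairs_is_an_error(self):
        m = FragmentMatrix.from_fragments([], 2)
        m.origin = {"start1": np.zeros(0, dtype=np.int64), "start2": np.zeros(0, dtype=np.int64)}
        with pytest.raises(ValueError):
            binned_contact_correlation(m, m, 1_000_000)
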