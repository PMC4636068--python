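"""Synthetic targeted proximity-ligation data with known diploid truth.

The generator emulates the statistical structure a targeted Hi-C phasing
experiment relies on: a megabase-scale diploid locus carrying ~2.7
heterozygous SNVs per kb, intra-chromosomal contacts whose genomic span
follows a truncated power law, a small homologous-trans (h-trans)
ligation rate, hybrid-capture enrichment of fragments touching probe
intervals, per-base sequencing error, a long-fragment-read (LFR)
companion dataset, and a "reported truth" whose phase is deliberately
corrupted at a fraction of high-variant-density sites — the failure
mode of trio-derived truth sets that the h-trans/LFR concordance filter
is designed to catch.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from thaploseq import intervals as iv
from thaploseq.fragments import ALT, OTHER, REF, FragmentMatrix
from thaploseq.genome_model import (
    DiploidHaplotypes,
    Gene,
    ReferenceLocus,
    RestrictionMap,
    VariantSet,
    assign_density_flags,
    find_restriction_sites,
    haplotype_sequences,
)
from thaploseq.probe_design import ProbeSet, design_cut_site_probes, exon_targets

logger = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    """All generative parameters — the truth-generating contract.

    Defaults are the full study-scale conditions: a 3.5-Mb MHC-like
    locus with ~9,400 het SNVs, 50-fold capture enrichment, h-trans rate
    0.02 and per-base error 0.005. ``fast()`` gives a 1-Mb profile with
    the same densities for CI-scale runs.
    """

    locus_length: int = 3_500_000
    snv_density: float = 9400 / 3_500_000  # SNVs per bp
    n_fragments: int = 1_040_000  # proximity-ligation fragments before capture
    read_length: int = 100
    decay_exponent: float = 1.08  # contact span p(s) ~ s^-alpha
    min_span: int = 2_000
    htrans_rate: float = 0.02
    enrichment_fold: float = 50.0
    seq_error: float = 0.005  # per-base; wrong base uniform over 3 alternatives
    lfr_n: int = 8_750
    lfr_length: int = 4_000
    planted_error_fraction: float = 0.0  # phase flips among high-density variants
    seed: int = 0
    # locus annotation model
    repeat_fraction: float = 0.2
    mean_repeat_length: int = 500
    n_genes: int = 60
    exons_per_gene: int = 5
    exon_length: int = 200
    # probe design defaults (mirrors probe_design)
    probe_length: int = 120
    tiling_density: int = 4
    flank: int = 400
    enzyme_motif: str = "AAGCTT"
    cut_offset: int = 1
    # high-variant-density definition
    density_window: int = 2_000
    density_top_fraction: float = 0.1
    # LCP reference panel model
    panel_size: int = 10
    panel_mutation_rate: float = 0.02
    panel_switches: float = 3.0  # expected recombination switches per panel haplotype

    def __post_init__(self) -> None:
        for name in ("htrans_rate", "seq_error", "planted_error_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.decay_exponent <= 0:
            raise ValueError("decay_exponent must be positive")
        if self.enrichment_fold < 1:
            raise ValueError("enrichment_fold must be >= 1")
        if self.locus_length * self.snv_density < 2:
            raise ValueError("locus too small / density too low: need >= 2 SNVs")

    @classmethod
    def paper(cls, seed: int = 0, **overrides) -> "SimulationConfig":
        return cls(seed=seed, **overrides)

    @classmethod
    def fast(cls, seed: int = 0, **overrides) -> "SimulationConfig":
        """1-Mb CI profile keeping the full-scale per-bp densities."""
        defaults = dict(
            locus_length=1_000_000,
            n_fragments=297_000,
            lfr_n=2_500,
            n_genes=20,
        )
        defaults.update(overrides)
        return cls(seed=seed, **defaults)

    def to_flat(self) -> Dict[str, str]:
        return {f.name: str(getattr(self, f.name)) for f in dataclasses.fields(self)}


def _phred(err: float) -> int:
    return int(round(-10.0 * math.log10(max(err, 1e-9)))) if err > 0 else 60


# ---------------------------------------------------------------------------
# locus and variants


def simulate_locus(config: SimulationConfig, rng: np.random.Generator) -> ReferenceLocus:
    """Random locus: uniform DNA, random repeat intervals, evenly spaced genes."""
    L = config.locus_length
    seq = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=L).tobytes().decode()

    repeats: List[Tuple[int, int]] = []
    target = config.repeat_fraction * L
    covered = 0.0
    while covered < target:
        length = max(50, int(rng.exponential(config.mean_repeat_length)))
        start = int(rng.integers(0, max(1, L - length)))
        repeats.append((start, start + length))
        covered += length
    repeats = iv.clip(repeats, 0, L)

    genes: List[Gene] = []
    if config.n_genes > 0:
        gene_span = config.exons_per_gene * (config.exon_length + 800)
        starts = np.linspace(0, max(1, L - gene_span - 1), config.n_genes).astype(int)
        jitter = rng.integers(0, 500, size=config.n_genes)
        for gi, s in enumerate(starts + jitter):
            exons = []
            pos = int(s)
            for _ in range(config.exons_per_gene):
                exons.append((pos, min(L, pos + config.exon_length)))
                pos += config.exon_length + 800
            exons = [x for x in exons if x[1] > x[0]]
            if exons:
                genes.append(Gene(f"GENE{gi:03d}", exons[0][0], exons[-1][1], exons))
    return ReferenceLocus("sim_locus", seq, repeats=repeats, genes=genes)


def simulate_variants(
    config: SimulationConfig,
    locus: Optional[ReferenceLocus] = None,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[VariantSet, DiploidHaplotypes]:
    """Place het SNVs uniformly; truth phase bits are i.i.d. fair coins.

    High-variant-density flags mark sites in the densest decile of
    2-kb windows.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    L = config.locus_length
    n = int(round(L * config.snv_density))
    if n > L // 2:
        raise ValueError("SNV density too high to place variants without conflicts")
    pos = np.sort(rng.choice(L, size=n, replace=False))
    if locus is not None:
        ref = np.frombuffer(locus.sequence.encode(), dtype="S1")[pos].astype("U1")
    else:
        ref = rng.choice(list("ACGT"), size=n)
    bases = np.array(list("ACGT"))
    shift = rng.integers(1, 4, size=n)
    base_idx = np.searchsorted(bases, ref)
    alt = bases[(base_idx + shift) % 4]
    phase = rng.integers(0, 2, size=n).astype(np.int8)
    vs = VariantSet(pos, ref, alt, truth_phase=phase)
    vs = assign_density_flags(vs, config.density_window, config.density_top_fraction)
    return vs, DiploidHaplotypes(phase.copy())


# ---------------------------------------------------------------------------
# fragment generation


def _sample_truncated_power_law(
    rng: np.random.Generator, n: int, alpha: float, smin: float, smax: float
) -> np.ndarray:
    """Inverse-CDF sampling of p(s) ~ s^-alpha on [smin, smax]."""
    u = rng.random(n)
    if abs(alpha - 1.0) < 1e-12:
        return smin * (smax / smin) ** u
    a = 1.0 - alpha
    return (smin**a + u * (smax**a - smin**a)) ** (1.0 / a)


def _observe(
    rng: np.random.Generator,
    true_allele: np.ndarray,
    seq_error: float,
) -> np.ndarray:
    """Apply per-base sequencing error to true allele bits.

    An erroneous base is uniform over the three wrong bases: it hits the
    opposite allele with probability seq_error/3 (flipping the bit) and a
    third, non-allelic base with probability 2*seq_error/3 (coded OTHER
    and excluded from phasing input).
    """
    obs = true_allele.astype(np.int8).copy()
    err = rng.random(len(obs)) < seq_error
    if err.any():
        kind = rng.random(int(err.sum()))
        idx = np.flatnonzero(err)
        flip = idx[kind < 1.0 / 3.0]
        other = idx[kind >= 1.0 / 3.0]
        obs[flip] = 1 - obs[flip]
        obs[other] = OTHER
    return obs


def _ranges_concat(lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Concatenate integer ranges [lo_i, hi_i) into one index array."""
    lens = hi - lo
    total = int(lens.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64)
    out_off = np.repeat(np.cumsum(lens) - lens, lens)
    return np.repeat(lo, lens) + (np.arange(total) - out_off)


def simulate_proximity_fragments(
    config: SimulationConfig,
    variants: VariantSet,
    haplotypes: DiploidHaplotypes,
    rng: Optional[np.random.Generator] = None,
    n_fragments: Optional[int] = None,
) -> FragmentMatrix:
    """Generate paired-end proximity-ligation fragments with truth metadata.

    Each fragment anchors one read uniformly, draws its genomic span from
    the truncated power law, and reads both ends from a fair-coin source
    haplotype; with probability ``htrans_rate`` the second end reads the
    homologous copy (an h-trans ligation, recorded in origin metadata).
    """
    if len(variants) < 2:
        raise ValueError("need at least 2 variants to simulate linking fragments")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = int(n_fragments if n_fragments is not None else config.n_fragments)
    L, rl = config.locus_length, config.read_length
    if config.min_span >= L:
        raise ValueError("min_span must be smaller than the locus")

    a1 = rng.integers(0, L - rl + 1, size=n)
    span = _sample_truncated_power_law(
        rng, n, config.decay_exponent, config.min_span, L
    ).astype(np.int64)
    direction = rng.choice([-1, 1], size=n)
    a2 = a1 + direction * span
    a2 = np.abs(a2)  # reflect at the left bound
    over = a2 > L - rl
    a2[over] = 2 * (L - rl) - a2[over]  # reflect at the right bound
    a2 = np.clip(a2, 0, L - rl)

    hap1 = rng.integers(0, 2, size=n).astype(np.int8)
    is_htrans = rng.random(n) < config.htrans_rate
    hap2 = np.where(is_htrans, 1 - hap1, hap1).astype(np.int8)

    pos = variants.pos
    lo1 = np.searchsorted(pos, a1)
    hi1 = np.searchsorted(pos, a1 + rl)
    lo2 = np.searchsorted(pos, a2)
    hi2 = np.searchsorted(pos, a2 + rl)

    # order the two ends by genomic position so per-fragment observations
    # come out sorted by variant index
    swap = a2 < a1
    flo = np.where(swap, lo2, lo1)
    fhi = np.where(swap, hi2, hi1)
    slo = np.where(swap, lo1, lo2)
    shi = np.where(swap, hi1, hi2)
    fhap = np.where(swap, hap2, hap1)
    shap = np.where(swap, hap1, hap2)
    fend = np.where(swap, 2, 1).astype(np.int8)
    send = np.where(swap, 1, 2).astype(np.int8)
    # reflection can bring the ends close enough to co-cover a variant;
    # truncate the second end's window at the first's so each variant is
    # observed at most once per fragment
    slo = np.maximum(slo, fhi)
    shi = np.maximum(shi, slo)

    c1 = fhi - flo
    c2 = shi - slo
    counts = c1 + c2
    ptr = np.concatenate([[0], np.cumsum(counts)])

    n_obs = int(counts.sum())
    var_idx = np.empty(n_obs, dtype=np.int32)
    end_lab = np.empty(n_obs, dtype=np.int8)
    src_hap = np.empty(n_obs, dtype=np.int8)

    first_dst = _ranges_concat(ptr[:-1], ptr[:-1] + c1)
    second_dst = _ranges_concat(ptr[:-1] + c1, ptr[1:])
    var_idx[first_dst] = _ranges_concat(flo, fhi)
    var_idx[second_dst] = _ranges_concat(slo, shi)
    end_lab[first_dst] = np.repeat(fend, c1)
    end_lab[second_dst] = np.repeat(send, c2)
    src_hap[first_dst] = np.repeat(fhap, c1)
    src_hap[second_dst] = np.repeat(shap, c2)

    hapA = haplotypes.hapA
    true_allele = np.where(src_hap == 0, hapA[var_idx], 1 - hapA[var_idx])
    allele = _observe(rng, true_allele, config.seq_error)
    qual = np.full(n_obs, _phred(config.seq_error), dtype=np.int16)

    origin = {
        "hap_end1": hap1,
        "hap_end2": hap2,
        "is_htrans": is_htrans,
        "start1": a1,
        "start2": a2,
        "len1": np.full(n, rl, dtype=np.int64),
        "len2": np.full(n, rl, dtype=np.int64),
    }
    return FragmentMatrix(
        len(variants), ptr, var_idx, allele, qual, end_lab, origin=origin
    )


def apply_capture(
    matrix: FragmentMatrix,
    probe_set: ProbeSet,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> FragmentMatrix:
    """Hybrid-capture enrichment: keep on-target fragments, thin the rest.

    A fragment is on-target when at least one of its reads overlaps a
    probe interval; off-target fragments survive with probability
    1/enrichment_fold.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    F = config.enrichment_fold
    if F == 1.0 or matrix.n_fragments == 0:
        return matrix
    ivs = probe_set.probe_intervals()
    on = fragments_on_target(matrix, ivs)
    keep = on | (rng.random(matrix.n_fragments) < 1.0 / F)
    out = matrix.subset(keep)
    out.filter_stats["capture_kept"] = int(keep.sum())
    out.filter_stats["capture_dropped"] = int((~keep).sum())
    return out


def fragments_on_target(matrix: FragmentMatrix, target_intervals) -> np.ndarray:
    """Per fragment, True iff any read overlaps a target interval."""
    n = matrix.n_fragments
    if not target_intervals or n == 0:
        return np.zeros(n, dtype=bool)
    starts = np.array([s for s, _ in target_intervals])
    ends = np.array([e for _, e in target_intervals])

    def read_overlaps(rs: np.ndarray, rlen: np.ndarray) -> np.ndarray:
        i = np.searchsorted(ends, rs, side="right")
        ok = i < len(starts)
        res = np.zeros(len(rs), dtype=bool)
        res[ok] = starts[i[ok]] < rs[ok] + rlen[ok]
        return res

    org = matrix.origin
    on = read_overlaps(org["start1"], org["len1"])
    if "start2" in org:
        has2 = org["len2"] > 0
        on2 = read_overlaps(org["start2"], org["len2"]) & has2
        on |= on2
    return on


def simulate_lfr_fragments(
    config: SimulationConfig,
    variants: VariantSet,
    haplotypes: DiploidHaplotypes,
    rng: Optional[np.random.Generator] = None,
) -> FragmentMatrix:
    """Contiguous single-haplotype long fragments (Moleculo-like witness)."""
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    n = config.lfr_n
    L = config.locus_length
    flen = min(config.lfr_length, L)
    starts = rng.integers(0, L - flen + 1, size=n)
    hap = rng.integers(0, 2, size=n).astype(np.int8)
    pos = variants.pos
    lo = np.searchsorted(pos, starts)
    hi = np.searchsorted(pos, starts + flen)
    counts = hi - lo
    ptr = np.concatenate([[0], np.cumsum(counts)])
    var_idx = _ranges_concat(lo, hi).astype(np.int32)
    src = np.repeat(hap, counts)
    hapA = haplotypes.hapA
    true_allele = np.where(src == 0, hapA[var_idx], 1 - hapA[var_idx])
    allele = _observe(rng, true_allele, config.seq_error)
    qual = np.full(len(var_idx), _phred(config.seq_error), dtype=np.int16)
    end_lab = np.ones(len(var_idx), dtype=np.int8)
    origin = {
        "hap_end1": hap,
        "hap_end2": np.full(n, -1, dtype=np.int8),
        "is_htrans": np.zeros(n, dtype=bool),
        "start1": starts,
        "start2": np.full(n, -1, dtype=np.int64),
        "len1": np.full(n, flen, dtype=np.int64),
        "len2": np.zeros(n, dtype=np.int64),
    }
    return FragmentMatrix(
        len(variants), ptr, var_idx, allele, qual, end_lab, origin=origin
    )


# ---------------------------------------------------------------------------
# reported-truth corruption and reference panel


def plant_truth_errors(
    variants: VariantSet,
    haplotypes: DiploidHaplotypes,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[DiploidHaplotypes, np.ndarray]:
    """Corrupt the reported truth at high-density sites.

    Among density-flagged variants, each reported phase bit flips
    independently with probability ``planted_error_fraction``; returns
    the corrupted haplotypes and the flipped variant indices. The
    generative truth is left untouched.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 3)
    reported = haplotypes.hapA.copy()
    flagged = np.flatnonzero(variants.density_flag)
    flip = flagged[rng.random(len(flagged)) < config.planted_error_fraction]
    reported[flip] = 1 - reported[flip]
    return DiploidHaplotypes(reported), flip


def simulate_panel(
    config: SimulationConfig,
    variants: VariantSet,
    haplotypes: DiploidHaplotypes,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Reference panel of full-length haplotypes derived from the truth.

    Each panel haplotype copies one of the two truth haplotypes, switching
    copy at a Poisson number of uniformly placed recombination points, then
    mutates each site independently at the panel mutation rate. Returns a
    (panel_size, n_variants) allele-bit array.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 4)
    n = len(variants)
    K = config.panel_size
    hapA = haplotypes.hapA
    panel = np.empty((K, n), dtype=np.int8)
    for k in range(K):
        cur = int(rng.integers(0, 2))
        n_sw = rng.poisson(config.panel_switches)
        switches = np.sort(rng.integers(0, n, size=n_sw)) if n_sw else np.array([], dtype=int)
        source = np.full(n, cur, dtype=np.int8)
        for s in switches:
            cur = 1 - cur
            source[s:] = cur
        hap = np.where(source == 0, hapA, 1 - hapA)
        mut = rng.random(n) < config.panel_mutation_rate
        hap = np.where(mut, 1 - hap, hap)
        panel[k] = hap
    return panel


# ---------------------------------------------------------------------------
# SAM emission (exercises fragment_builder on alignment-shaped input)


def write_sam(
    matrix: FragmentMatrix,
    locus: ReferenceLocus,
    variants: VariantSet,
    haplotypes: DiploidHaplotypes,
    path: str,
    base_qual: int = 30,
) -> None:
    """Emit the simulated reads as an aligned SAM file.

    Read sequences are taken from the source haplotype and then patched
    with each fragment's observed alleles, so extracting fragments from
    the SAM reproduces the matrix. Requires origin metadata.
    """
    import pysam

    if not matrix.origin:
        raise ValueError("write_sam needs simulator origin metadata")
    hapseqA, hapseqB = haplotype_sequences(locus, variants, haplotypes)
    hapseqs = (hapseqA, hapseqB)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "queryname"},
            "SQ": [{"SN": locus.name, "LN": len(locus)}],
        }
    )
    org = matrix.origin
    pos_arr = variants.pos
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for i in range(matrix.n_fragments):
            frag = matrix.fragment(i)
            paired = org["len2"][i] > 0
            for end in (1, 2) if paired else (1,):
                start = int(org[f"start{end}"][i])
                rlen = int(org[f"len{end}"][i])
                hap = int(org[f"hap_end{end}"][i])
                seq = list(hapseqs[hap][start : start + rlen])
                quals = [base_qual] * rlen
                for (vi, al, q), el in zip(frag.observations, frag.end_labels):
                    if el != end:
                        continue
                    p = int(pos_arr[vi]) - start
                    if 0 <= p < rlen:
                        quals[p] = min(93, max(0, int(q)))
                        if al == REF:
                            seq[p] = str(variants.ref[vi])
                        elif al == ALT:
                            seq[p] = str(variants.alt[vi])
                        else:
                            third = next(
                                b
                                for b in "ACGT"
                                if b not in (str(variants.ref[vi]), str(variants.alt[vi]))
                            )
                            seq[p] = third
                a = pysam.AlignedSegment(header)
                a.query_name = matrix.fragment_id(i)
                a.query_sequence = "".join(seq)
                a.reference_id = 0
                a.reference_start = start
                a.mapping_quality = 60
                a.cigarstring = f"{rlen}M"
                a.query_qualities = quals
                flag = 0
                if paired:
                    flag |= 0x1 | 0x2
                    flag |= 0x40 if end == 1 else 0x80
                    mate_end = 2 if end == 1 else 1
                    a.next_reference_id = 0
                    a.next_reference_start = int(org[f"start{mate_end}"][i])
                a.flag = flag
                out.write(a)


# ---------------------------------------------------------------------------
# bundled run + design evaluation


@dataclass
class SimulationOutput:
    """Everything one simulated experiment produces."""

    config: SimulationConfig
    locus: ReferenceLocus
    restriction_map: RestrictionMap
    probe_set: ProbeSet
    variants: VariantSet
    truth: DiploidHaplotypes
    reported_truth: DiploidHaplotypes
    planted_flips: np.ndarray
    fragments: FragmentMatrix  # post-capture proximity-ligation fragments
    pre_capture_n: int
    lfr: FragmentMatrix
    panel: np.ndarray


def run_simulation(config: SimulationConfig) -> SimulationOutput:
    """Full generative pipeline: locus -> probes -> fragments -> companions."""
    rng = np.random.default_rng(config.seed)
    locus = simulate_locus(config, rng)
    rmap = find_restriction_sites(locus, config.enzyme_motif, config.cut_offset)
    probes = design_cut_site_probes(
        locus, rmap, config.flank, config.probe_length, config.tiling_density
    ).merged_with(exon_targets(locus, config.probe_length, config.tiling_density))
    variants, truth = simulate_variants(config, locus, rng)
    frags = simulate_proximity_fragments(config, variants, truth, rng)
    captured = apply_capture(frags, probes, config, rng)
    lfr = simulate_lfr_fragments(config, variants, truth, rng)
    reported, flips = plant_truth_errors(variants, truth, config, rng)
    panel = simulate_panel(config, variants, truth, rng)
    return SimulationOutput(
        config=config,
        locus=locus,
        restriction_map=rmap,
        probe_set=probes,
        variants=variants,
        truth=truth,
        reported_truth=reported,
        planted_flips=flips,
        fragments=captured,
        pre_capture_n=frags.n_fragments,
        lfr=lfr,
        panel=panel,
    )


def evaluate_design(
    config: SimulationConfig,
    probe_set_candidates: Dict[str, Tuple[int, int]],
    n_fragments: int = 50_000,
):
    """Compare candidate tiling designs by simulated phasing performance.

    ``probe_set_candidates`` maps a design name to (probe_length,
    tiling_density); density 0 means no probes (capture thinning only).
    Returns a pandas DataFrame with resolution and accuracy per design.
    """
    import pandas as pd

    from thaploseq.phaser import lcp_refine, max_cut_phase
    from thaploseq.qc_metrics import evaluate_phasing

    rng = np.random.default_rng(config.seed)
    locus = simulate_locus(config, rng)
    rmap = find_restriction_sites(locus, config.enzyme_motif, config.cut_offset)
    variants, truth = simulate_variants(config, locus, rng)
    base_frags = simulate_proximity_fragments(
        config, variants, truth, rng, n_fragments=n_fragments
    )
    rows = []
    for name, (plen, dens) in probe_set_candidates.items():
        if dens >= 1:
            probes = design_cut_site_probes(locus, rmap, config.flank, plen, dens)
        else:
            probes = ProbeSet([], plen, max(dens, 1), config.flank)
        cap_rng = np.random.default_rng(config.seed + 11)
        captured = apply_capture(base_frags, probes, config, cap_rng)
        result = max_cut_phase(captured, seed=config.seed)
        result = lcp_refine(
            result, variants, simulate_panel(config, variants, truth)
        )
        ev = evaluate_phasing(result, truth, variants)
        rows.append(
            {
                "design": name,
                "probe_length": plen,
                "tiling_density": dens,
                "n_probes": len(probes),
                "n_fragments_kept": captured.n_fragments,
                "resolution": ev.resolution,
                "accuracy": ev.accuracy,
            }
        )
    return pd.DataFrame(rows)
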