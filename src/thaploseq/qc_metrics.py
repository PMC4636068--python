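"""Evaluation layer: h-trans diagnostics, phasing metrics, enrichment, contacts.

The h-trans ratio — the fraction of allele-observation pairs linking the
two homologous chromosome copies — is the quantity whose rarity
underwrites proximity-ligation phasing. Pairs that look h-trans against
a *reported* truth set can instead be errors in that truth set; the
diagnostics here (same-end fraction, variant-density stratification and
the long-fragment-read concordance filter) separate the two causes and
produce a blacklist of suspect variants.

Phasing is scored by completeness/resolution (all het SNVs vs those in
the single spanning haplotype), per-variant accuracy (worst-case: every
wrong variant counts) and the conventional switch error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from thaploseq import intervals as ivl
from thaploseq.fragments import OTHER, FragmentMatrix
from thaploseq.genome_model import (
    DiploidHaplotypes,
    Gene,
    ReferenceLocus,
    RestrictionMap,
    VariantSet,
)
from thaploseq.phaser import PhasingResult
from thaploseq.probe_design import ProbeSet
from thaploseq.simulator import fragments_on_target

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# pair extraction


def _iter_pair_arrays(matrix: FragmentMatrix):
    """All within-fragment observation pairs as parallel arrays.

    Returns (frag, vi, vj, ai, aj, ei, ej) with vi < vj. Pure-numpy for
    two-observation fragments; small python loop for larger ones.
    """
    usable = matrix.allele != OTHER
    frag_of_obs = np.repeat(np.arange(matrix.n_fragments), np.diff(matrix.ptr))
    sel = np.flatnonzero(usable)
    f = frag_of_obs[sel]
    order = np.argsort(f, kind="stable")
    f = f[order]
    v = matrix.var_idx[sel][order]
    a = matrix.allele[sel][order]
    e = matrix.end_label[sel][order]
    counts = np.bincount(f, minlength=matrix.n_fragments)
    starts = np.concatenate([[0], np.cumsum(np.bincount(f, minlength=matrix.n_fragments))])

    frag_l: List[np.ndarray] = []
    cols: List[List[np.ndarray]] = [[], [], [], [], [], []]
    two = np.flatnonzero(counts == 2)
    if len(two):
        s = starts[two]
        frag_l.append(two)
        for arrs, src in zip(cols, (v[s], v[s + 1], a[s], a[s + 1], e[s], e[s + 1])):
            arrs.append(src)
    multi = np.flatnonzero(counts > 2)
    for fi in multi:
        s, t = starts[fi], starts[fi] + counts[fi]
        idx = np.arange(s, t)
        ii, jj = np.triu_indices(len(idx), k=1)
        frag_l.append(np.full(len(ii), fi))
        for arrs, src in zip(
            cols,
            (v[idx[ii]], v[idx[jj]], a[idx[ii]], a[idx[jj]], e[idx[ii]], e[idx[jj]]),
        ):
            arrs.append(src)
    if not frag_l:
        z = np.zeros(0, dtype=np.int64)
        return z, z, z, z, z, z, z
    frag = np.concatenate(frag_l)
    vi, vj, ai, aj, ei, ej = (np.concatenate(c) for c in cols)
    return frag, vi, vj, ai, aj, ei, ej


@dataclass
class HTransReport:
    n_informative: int
    n_htrans: int
    htrans_ratio: float
    same_end_fraction: float  # of h-trans pairs that are same-end
    per_density_bin: Dict[int, float]
    blacklist: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    # per-variant pair statistics (for the concordance filter)
    pair_count: np.ndarray = field(default=None, repr=False)
    htrans_count: np.ndarray = field(default=None, repr=False)
    same_end_htrans_count: np.ndarray = field(default=None, repr=False)
    htrans_frag_count: np.ndarray = field(default=None, repr=False)


def _density_deciles(variants: VariantSet, window: int = 2000, bins: int = 10) -> np.ndarray:
    """Per-variant density decile (0 = sparsest) from fixed-window SNV counts."""
    win = variants.pos // window
    uniq, inv, counts = np.unique(win, return_inverse=True, return_counts=True)
    dens = counts[inv]
    edges = np.quantile(dens, np.linspace(0, 1, bins + 1)[1:-1])
    return np.searchsorted(edges, dens, side="right")


def htrans_report(
    matrix: FragmentMatrix,
    reported_haplotypes: DiploidHaplotypes,
    variants: VariantSet,
    density_bins: int = 10,
    density_window: int = 2000,
) -> HTransReport:
    """Classify every within-fragment observation pair cis vs h-trans.

    A pair is cis when its allele XOR equals the reported relative phase
    of the two variants, h-trans otherwise. Stratifies the ratio by
    variant-density decile (a pair falls in the denser of its two
    variants' deciles) and records per-variant counts.
    """
    h = reported_haplotypes.hapA
    frag, vi, vj, ai, aj, ei, ej = _iter_pair_arrays(matrix)
    n_pairs = len(vi)
    n_var = len(variants)
    if n_pairs == 0:
        z = np.zeros(n_var, dtype=np.int64)
        return HTransReport(0, 0, 0.0, 0.0, {}, np.zeros(0, dtype=np.int64), z, z, z, z)
    htrans = (ai ^ aj) != (h[vi] ^ h[vj])
    same_end = ei == ej
    n_ht = int(htrans.sum())
    same_end_frac = float((htrans & same_end).sum() / n_ht) if n_ht else 0.0

    deciles = _density_deciles(variants, density_window, density_bins)
    pair_bin = np.maximum(deciles[vi], deciles[vj])
    per_bin: Dict[int, float] = {}
    for b in range(density_bins):
        m = pair_bin == b
        if m.any():
            per_bin[b] = float(htrans[m].mean())

    pair_count = np.bincount(vi, minlength=n_var) + np.bincount(vj, minlength=n_var)
    htrans_count = np.bincount(vi[htrans], minlength=n_var) + np.bincount(
        vj[htrans], minlength=n_var
    )
    se_ht = htrans & same_end
    se_count = np.bincount(vi[se_ht], minlength=n_var) + np.bincount(
        vj[se_ht], minlength=n_var
    )
    # distinct fragments with >=1 h-trans pair touching each variant
    fv = np.concatenate([np.stack([frag[htrans], vi[htrans]]), np.stack([frag[htrans], vj[htrans]])], axis=1)
    if fv.shape[1]:
        uniq_fv = np.unique(fv.T, axis=0)
        frag_count = np.bincount(uniq_fv[:, 1], minlength=n_var)
    else:
        frag_count = np.zeros(n_var, dtype=np.int64)

    return HTransReport(
        n_informative=n_pairs,
        n_htrans=n_ht,
        htrans_ratio=float(n_ht / n_pairs),
        same_end_fraction=same_end_frac,
        per_density_bin=per_bin,
        pair_count=pair_count,
        htrans_count=htrans_count,
        same_end_htrans_count=se_count,
        htrans_frag_count=frag_count,
    )


def concordance_filter(
    report_hic: HTransReport,
    lfr_matrix: FragmentMatrix,
    reported_haplotypes: DiploidHaplotypes,
    variants: VariantSet,
    min_lfr_support: int = 2,
) -> np.ndarray:
    """Blacklist variants whose reported phase both datasets contradict.

    A variant qualifies when (a) in the proximity-ligation data it sits in
    at least one h-trans pair and h-trans pairs are the majority of its
    informative pairs, and (b) at least ``min_lfr_support`` LFR fragments
    show an inter-haplotype pairing at it and LFR h-trans pairs are
    likewise the majority there. The majority condition is what separates
    a genuinely mis-phased variant (h-trans against nearly every partner)
    from its innocent partners (h-trans only against the mis-phased one);
    the same-end fraction stays a report-level diagnostic rather than a
    filter condition, since a mis-phased variant without a close enough
    neighbour on the same read is still contradicted by both datasets.
    """
    lfr_rep = htrans_report(lfr_matrix, reported_haplotypes, variants)
    pl_majority = report_hic.htrans_count * 2 > report_hic.pair_count
    pl_hit = (report_hic.htrans_count > 0) & pl_majority
    lfr_majority = lfr_rep.htrans_count * 2 > lfr_rep.pair_count
    lfr_hit = (lfr_rep.htrans_frag_count >= min_lfr_support) & lfr_majority
    blacklist = np.flatnonzero(pl_hit & lfr_hit)
    report_hic.blacklist = blacklist
    return blacklist


# ---------------------------------------------------------------------------
# phasing evaluation


@dataclass
class PhasingEvaluation:
    n_total_het: int
    n_resolved: int
    resolution: float
    n_correct: int
    n_evaluated: int
    accuracy: float
    error: float
    switch_error: float
    n_excluded_no_truth: int = 0
    n_excluded_blacklist: int = 0
    gene_level: Optional[object] = None  # pandas DataFrame when genes given


def evaluate_phasing(
    result: PhasingResult,
    truth: DiploidHaplotypes,
    variants: VariantSet,
    genes: Optional[List[Gene]] = None,
    blacklist: Optional[np.ndarray] = None,
    all_blocks: bool = False,
    exonic_only: bool = False,
) -> PhasingEvaluation:
    """Resolution, per-variant (worst-case) accuracy and switch error.

    Resolution counts members of the single largest haplotype structure
    (all blocks with ``all_blocks=True``). Each block is oriented to
    maximise truth agreement (majority vote) before counting per-variant
    errors — so a globally flipped block scores identically. When a
    blacklist is supplied those variants leave both the numerator and
    denominator of accuracy.
    """
    n_total = len(variants)
    blocks = result.blocks if all_blocks else (
        [result.largest_block] if result.largest_block is not None else []
    )
    truth_h = truth.hapA

    bl = set() if blacklist is None else set(int(b) for b in np.asarray(blacklist))
    n_resolved = sum(len(b) for b in blocks)

    n_correct = 0
    n_eval = 0
    n_no_truth = 0
    n_bl = 0
    switch_flips = 0
    switch_pairs = 0
    member_correct: Dict[int, bool] = {}
    for b in blocks:
        mem = b.members
        ph = b.phase
        has_truth = truth_h[mem] >= 0
        n_no_truth += int((~has_truth).sum())
        ok = has_truth.copy()
        for t, m in enumerate(mem):
            if int(m) in bl:
                ok[t] = False
        n_bl += int((has_truth & ~ok).sum())
        if not ok.any():
            continue
        agree = ph[ok] == truth_h[mem[ok]]
        orient = 1 if agree.mean() >= 0.5 else -1
        correct = agree if orient == 1 else ~agree
        n_correct += int(correct.sum())
        n_eval += int(ok.sum())
        for m, c in zip(mem[ok], correct):
            member_correct[int(m)] = bool(c)
        # switch error over adjacent evaluated members of this block
        rel = (ph[ok] ^ truth_h[mem[ok]]).astype(np.int8)
        flips = np.abs(np.diff(rel))
        switch_flips += int(flips.sum())
        switch_pairs += len(rel) - 1

    accuracy = n_correct / n_eval if n_eval else float("nan")
    ev = PhasingEvaluation(
        n_total_het=n_total,
        n_resolved=n_resolved,
        resolution=n_resolved / n_total if n_total else 0.0,
        n_correct=n_correct,
        n_evaluated=n_eval,
        accuracy=accuracy,
        error=1.0 - accuracy if n_eval else float("nan"),
        switch_error=switch_flips / switch_pairs if switch_pairs > 0 else 0.0,
        n_excluded_no_truth=n_no_truth,
        n_excluded_blacklist=n_bl,
    )

    if genes:
        import pandas as pd

        resolved_set = {int(m) for b in blocks for m in b.members}
        rows = []
        for g in genes:
            span = g.exons if exonic_only else [(g.start, g.end)]
            merged = ivl.merge(span)
            in_gene = [
                i
                for i in range(n_total)
                if ivl.contains(merged, int(variants.pos[i]))
            ]
            res = [i for i in in_gene if i in resolved_set]
            cor = [i for i in res if member_correct.get(i, False)]
            rows.append(
                {
                    "gene": g.name,
                    "n_het": len(in_gene),
                    "n_resolved": len(res),
                    "n_correct": len(cor),
                }
            )
        ev.gene_level = pd.DataFrame(rows)
    return ev


# ---------------------------------------------------------------------------
# capture enrichment


@dataclass
class EnrichmentReport:
    fold: float
    n_on_target: int
    n_off_target: int
    on_target_bases: int
    off_target_bases: int
    reads_per_bin: Dict[int, int]
    bin_size: int
    probe_sensitivity: Optional[float] = None  # fraction of probes >= 5x virtual mean


def enrichment_fold(
    matrix: FragmentMatrix,
    target_intervals: Sequence[Tuple[int, int]],
    locus_length: int,
    bin_size: int = 100_000,
) -> EnrichmentReport:
    """Capture enrichment: on-target vs off-target fragment rate per base.

    A fragment counts as on-target when any of its reads overlaps a
    target interval (the whole ligation product is captured together, so
    per-read counting would misattribute the distal ends of captured
    fragments). Returns infinity when the off-target side is empty.
    """
    targets = ivl.merge(target_intervals)
    on = fragments_on_target(matrix, targets)
    n_on = int(on.sum())
    n_off = int((~on).sum())
    b_on = ivl.total_length(targets)
    b_off = locus_length - b_on

    reads_per_bin: Dict[int, int] = {}
    org = matrix.origin
    if org:
        for key in ("start1", "start2"):
            if key in org:
                valid = org[key] >= 0
                for b, c in zip(*np.unique(org[key][valid] // bin_size, return_counts=True)):
                    reads_per_bin[int(b)] = reads_per_bin.get(int(b), 0) + int(c)

    if b_off <= 0 or n_off == 0:
        fold = float("inf")
    elif b_on <= 0 or n_on == 0:
        fold = 0.0
    else:
        fold = (n_on / b_on) / (n_off / b_off)
    return EnrichmentReport(
        fold, n_on, n_off, b_on, b_off, reads_per_bin, bin_size
    )


def probe_sensitivity(
    matrix: FragmentMatrix,
    probe_set: ProbeSet,
    restriction_map: RestrictionMap,
    locus: ReferenceLocus,
    seed: int = 0,
    min_fold: float = 5.0,
) -> float:
    """Fraction of probes with >= ``min_fold`` x the virtual-probe mean depth.

    Virtual probes are size-matched intervals drawn (seeded) near random
    cut sites but outside the real target footprint — the same negative
    control the probe-level sensitivity claim uses.
    """
    rng = np.random.default_rng(seed)
    targets = probe_set.probe_intervals()
    sites = np.asarray(restriction_map.sites)
    L = len(locus)
    plen = probe_set.probe_length

    def read_cov(intervals: List[Tuple[int, int]]) -> np.ndarray:
        starts = np.array([s for s, _ in intervals])
        ends = np.array([e for _, e in intervals])
        cov = np.zeros(len(intervals), dtype=np.int64)
        org = matrix.origin
        for key, lkey in (("start1", "len1"), ("start2", "len2")):
            if key not in org:
                continue
            rs = org[key]
            rl = org[lkey]
            valid = (rs >= 0) & (rl > 0)
            rs, rl = rs[valid], rl[valid]
            for i, (s, e) in enumerate(zip(starts, ends)):
                cov[i] += int(((rs < e) & (rs + rl > s)).sum())
        return cov

    n_virtual = min(len(probe_set.probes), 200)
    virtual: List[Tuple[int, int]] = []
    attempts = 0
    while len(virtual) < n_virtual and attempts < 50 * n_virtual:
        attempts += 1
        site = int(sites[rng.integers(0, len(sites))])
        offset = int(rng.integers(500, 5000)) * (1 if rng.random() < 0.5 else -1)
        s = max(0, min(L - plen, site + offset))
        if not ivl.overlaps_any(targets, s, s + plen):
            virtual.append((s, s + plen))
    if not virtual:
        logger.warning("could not place virtual probes; sensitivity undefined")
        return float("nan")
    vmean = read_cov(virtual).mean()
    if vmean == 0:
        return 1.0
    real = [(s, e) for s, e, _ in probe_set.probes]
    if len(real) > 2000:
        pick = rng.choice(len(real), size=2000, replace=False)
        real = [real[i] for i in pick]
    rcov = read_cov(real)
    return float((rcov >= min_fold * vmean).mean())


# ---------------------------------------------------------------------------
# contact-profile concordance


def binned_contact_correlation(
    matrix_a: FragmentMatrix,
    matrix_b: FragmentMatrix,
    locus_length: int,
    bin_size: int = 100_000,
) -> float:
    """Squared Pearson correlation of log-scaled binned contact counts.

    Both datasets are reduced to counts of fragments linking each bin
    pair (i <= j, from read anchor positions); the correlation runs over
    bin pairs with a nonzero count in either dataset.
    """
    n_bins = -(-locus_length // bin_size)

    def counts(m: FragmentMatrix) -> np.ndarray:
        org = m.origin
        if not org or "start1" not in org:
            raise ValueError("contact correlation needs fragment anchor positions")
        s1 = org["start1"]
        s2 = org.get("start2", np.full(len(s1), -1))
        valid = (s1 >= 0) & (s2 >= 0)
        b1 = s1[valid] // bin_size
        b2 = s2[valid] // bin_size
        lo = np.minimum(b1, b2)
        hi = np.maximum(b1, b2)
        key = lo * n_bins + hi
        return np.bincount(key.astype(np.int64), minlength=n_bins * n_bins).astype(float)

    ca = counts(matrix_a)
    cb = counts(matrix_b)
    nz = (ca > 0) | (cb > 0)
    if nz.sum() < 2:
        raise ValueError("fewer than 2 nonzero bin pairs: correlation undefined")
    la = np.log10(1 + ca[nz])
    lb = np.log10(1 + cb[nz])
    if np.allclose(la, la[0]) or np.allclose(lb, lb[0]):
        raise ValueError("degenerate contact profile: zero variance")
    if np.array_equal(ca, cb):
        return 1.0  # a dataset against itself, exactly
    r = np.corrcoef(la, lb)[0, 1]
    return float(r * r)
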