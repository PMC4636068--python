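"""Haplotype assembly by minimum-error-correction (MEC) max-cut search.

Each phasing-informative fragment links the variants it covers: if two
observed alleles came from one chromosome copy, their relative phase is
determined up to the fragment's own errors. The MEC objective asks for
the diploid phase assignment that minimises the number of allele
observations that must be corrected for every fragment to be consistent
with one of the two haplotypes. The search here works per connected
component of the fragment graph: a greedy weighted-majority propagation
builds an initial phase, then single-variant flips and suffix (segment)
flips — the moves that repair isolated errors and switch errors
respectively — are applied until no move lowers the MEC, with random
restarts.

Variants no fragment links are phased afterwards by a local conditional
procedure (LCP) against a reference panel: panel haplotypes that agree
with the assembled scaffold near the variant vote on its allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from thaploseq.fragments import OTHER, FragmentMatrix
from thaploseq.genome_model import DiploidHaplotypes, ReferenceLocus, VariantSet

logger = logging.getLogger(__name__)


@dataclass
class HaplotypeBlock:
    """One phased block: members, their hapA allele bits and support."""

    block_id: int  # 1-based position of the first member (the PS tag)
    members: np.ndarray  # variant indices, sorted
    phase: np.ndarray  # allele on haplotype A per member
    support: np.ndarray  # consistent minus inconsistent fragment votes
    sources: np.ndarray  # per member: "mec" or "lcp"

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class PhasingResult:
    n_variants: int
    blocks: List[HaplotypeBlock] = field(default_factory=list)
    mec_score: int = 0
    unresolved: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))

    @property
    def largest_block(self) -> Optional[HaplotypeBlock]:
        return max(self.blocks, key=len) if self.blocks else None

    def phase_array(self) -> np.ndarray:
        """Full-length hapA allele array; -1 where unresolved."""
        out = np.full(self.n_variants, -1, dtype=np.int8)
        for b in self.blocks:
            out[b.members] = b.phase
        return out

    def block_id_array(self) -> np.ndarray:
        out = np.full(self.n_variants, -1, dtype=np.int64)
        for b in self.blocks:
            out[b.members] = b.block_id
        return out

    def lcp_array(self) -> np.ndarray:
        out = np.zeros(self.n_variants, dtype=bool)
        for b in self.blocks:
            out[b.members[b.sources == "lcp"]] = True
        return out


# ---------------------------------------------------------------------------
# flattened phasing input


class _Flat:
    """Informative fragments flattened to parallel obs arrays."""

    def __init__(self, matrix: FragmentMatrix) -> None:
        usable = matrix.allele != OTHER
        frag_of_obs = np.repeat(
            np.arange(matrix.n_fragments), np.diff(matrix.ptr)
        )
        inf = matrix.informative_mask()
        sel = usable & inf[frag_of_obs]
        old_f = frag_of_obs[sel]
        # re-index fragments densely
        uniq, self.f = np.unique(old_f, return_inverse=True)
        self.n_frags = len(uniq)
        self.v = matrix.var_idx[sel].astype(np.int64)
        self.a = matrix.allele[sel].astype(np.int8)
        self.w = matrix.qual[sel].astype(np.float64)
        self.k = np.bincount(self.f, minlength=self.n_frags)
        self.n_obs = len(self.v)


def build_graph(matrix: FragmentMatrix) -> Dict[Tuple[int, int], float]:
    """Variant graph: edge (i, j) -> quality-weighted cis-minus-trans votes.

    A positive weight means fragments favour the two variants carrying
    *equal* hapA-allele bits; negative favours opposite bits. Connected
    components of this graph are the maximal possible phase blocks.
    """
    flat = _Flat(matrix)
    edges: Dict[Tuple[int, int], float] = {}
    order = np.lexsort((flat.v, flat.f))
    v, a, w, f = flat.v[order], flat.a[order], flat.w[order], flat.f[order]
    for s in range(len(v) - 1):
        for t in range(s + 1, len(v)):
            if f[t] != f[s]:
                break
            key = (int(v[s]), int(v[t]))
            vote = min(w[s], w[t]) * (1.0 if a[s] == a[t] else -1.0)
            edges[key] = edges.get(key, 0.0) + vote
    return edges


def _components(flat: _Flat, n_variants: int) -> np.ndarray:
    """Component label per variant (-1 for variants with no informative obs)."""
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    if flat.n_obs == 0:
        return np.full(n_variants, -1, dtype=np.int64)
    # chain-link consecutive obs of each fragment: same connectivity, O(n_obs)
    same = flat.f[1:] == flat.f[:-1]
    i = flat.v[:-1][same]
    j = flat.v[1:][same]
    g = coo_matrix(
        (np.ones(len(i)), (i, j)), shape=(n_variants, n_variants)
    )
    _, labels = connected_components(g, directed=False)
    covered = np.zeros(n_variants, dtype=bool)
    covered[flat.v] = True
    labels = labels.astype(np.int64)
    labels[~covered] = -1
    return labels


# ---------------------------------------------------------------------------
# MEC objective


def mec_score(matrix: FragmentMatrix, phase: Sequence[int]) -> int:
    """Total corrected observations: sum over fragments of
    min(mismatches vs hap A, mismatches vs hap B) over phased observations."""
    phase = np.asarray(phase, dtype=np.int8)
    usable = (matrix.allele != OTHER) & (phase[matrix.var_idx] >= 0)
    frag_of_obs = np.repeat(np.arange(matrix.n_fragments), np.diff(matrix.ptr))
    mism = (matrix.allele != phase[matrix.var_idx]) & usable
    d = np.bincount(frag_of_obs[mism], minlength=matrix.n_fragments)
    k = np.bincount(frag_of_obs[usable], minlength=matrix.n_fragments)
    return int(np.minimum(d, k - d).sum())


def _flat_mec(flat: _Flat, h: np.ndarray) -> Tuple[int, np.ndarray]:
    mism = flat.a != h[flat.v]
    d = np.bincount(flat.f, weights=mism, minlength=flat.n_frags).astype(np.int64)
    return int(np.minimum(d, flat.k - d).sum()), d


# ---------------------------------------------------------------------------
# heuristic search


def _greedy_init(
    adj_ptr: np.ndarray,
    adj_nbr: np.ndarray,
    adj_wt: np.ndarray,
    members: np.ndarray,
    rng: np.random.Generator,
    n_variants: int,
) -> np.ndarray:
    """Weighted-majority BFS propagation from a random root."""
    h = np.full(n_variants, -1, dtype=np.int8)
    member_set = members
    order = rng.permutation(member_set)
    pos_in_queue = {}
    from collections import deque

    queue: deque = deque()
    for root in order:
        if h[root] >= 0:
            continue
        h[root] = 0
        queue.append(root)
        while queue:
            u = queue.popleft()
            for e in range(adj_ptr[u], adj_ptr[u + 1]):
                nb = adj_nbr[e]
                if h[nb] >= 0:
                    continue
                # weighted vote from already-phased neighbours
                score = 0.0
                for e2 in range(adj_ptr[nb], adj_ptr[nb + 1]):
                    nb2 = adj_nbr[e2]
                    if h[nb2] >= 0:
                        # positive weight favours equal bits
                        score += adj_wt[e2] * (1.0 - 2.0 * h[nb2])
                h[nb] = 0 if score >= 0 else 1
                queue.append(nb)
    return h


def _local_search(flat: _Flat, h: np.ndarray, max_iters: int) -> np.ndarray:
    """Single-variant flips until no positive-gain flip remains."""
    for _ in range(max_iters):
        mism = flat.a != h[flat.v]
        d = np.bincount(flat.f, weights=mism, minlength=flat.n_frags)
        k = flat.k
        cost = np.minimum(d, k - d)
        delta = np.where(mism, -1.0, 1.0)  # change in d if the obs's variant flips
        d_new = d[flat.f] + delta
        cost_new = np.minimum(d_new, k[flat.f] - d_new)
        contrib = cost[flat.f] - cost_new
        gain = np.bincount(flat.v, weights=contrib, minlength=len(h))
        cand = np.flatnonzero(gain > 1e-9)
        if len(cand) == 0:
            return h
        # flip a fragment-disjoint subset, best gains first
        cand = cand[np.argsort(-gain[cand], kind="stable")]
        blocked = np.zeros(flat.n_frags, dtype=bool)
        var_obs: Dict[int, np.ndarray] = {}
        obs_by_var_order = np.argsort(flat.v, kind="stable")
        v_sorted = flat.v[obs_by_var_order]
        starts = np.searchsorted(v_sorted, cand)
        ends = np.searchsorted(v_sorted, cand, side="right")
        flipped_any = False
        for c, s, e in zip(cand, starts, ends):
            frs = flat.f[obs_by_var_order[s:e]]
            if blocked[frs].any():
                continue
            h[c] = 1 - h[c]
            blocked[frs] = True
            flipped_any = True
        if not flipped_any:
            return h
    return h


class _CompObs:
    """One component's observations, ordered by (fragment, member rank)."""

    def __init__(self, flat: _Flat, members: np.ndarray) -> None:
        self.members = members
        rank_of = {int(v): r for r, v in enumerate(members)}
        in_comp = np.isin(flat.v, members)
        fsel = np.unique(flat.f[in_comp])
        sub = np.isin(flat.f, fsel)
        order = np.lexsort((flat.v[sub], flat.f[sub]))
        self.f = np.searchsorted(fsel, flat.f[sub][order])
        self.rv = np.array([rank_of[int(x)] for x in flat.v[sub][order]], dtype=np.int64)
        self.a = flat.a[sub][order]
        self.n_frags = len(fsel)
        self.k = np.bincount(self.f, minlength=self.n_frags)
        self.frag_start = np.searchsorted(self.f, np.arange(self.n_frags))
        self.frag_end = np.searchsorted(self.f, np.arange(self.n_frags), side="right")
        self.two_obs = self.k == 2


def _suffix_pass(comp: _CompObs, h: np.ndarray, max_iters: int) -> np.ndarray:
    """Repair switch errors: flip the best phase suffix while it helps.

    Boundary b sits after the b-th member (in position order); flipping
    all members with rank > b changes only fragments straddling b.
    """
    members = comp.members
    m = len(members)
    if m < 2:
        return h
    for _ in range(max_iters):
        mism = comp.a != h[members[comp.rv]]
        d_all = np.bincount(comp.f, weights=mism, minlength=comp.n_frags)
        cost_all = np.minimum(d_all, comp.k - d_all)
        gain = np.zeros(m + 1, dtype=np.float64)  # diff array over boundaries

        # vectorised path: fragments with exactly two observations
        two = comp.two_obs
        if two.any():
            s_idx = comp.frag_start[two]
            lo, hi = comp.rv[s_idx], comp.rv[s_idx + 1]
            mism2 = mism[s_idx + 1]
            d_new = d_all[two] + np.where(mism2, -1.0, 1.0)
            g = cost_all[two] - np.minimum(d_new, 2 - d_new)
            straddle = hi > lo
            np.add.at(gain, lo[straddle], g[straddle])
            np.add.at(gain, hi[straddle], -g[straddle])

        for fidx in np.flatnonzero(~two & (comp.k >= 2)):
            s, e = comp.frag_start[fidx], comp.frag_end[fidx]
            kf = e - s
            d0 = d_all[fidx]
            c0 = cost_all[fidx]
            suffix_delta = 0.0
            for j in range(e - 1, s, -1):
                suffix_delta += -1.0 if mism[j] else 1.0
                d_new = d0 + suffix_delta
                g = c0 - min(d_new, kf - d_new)
                lo_b, hi_b = comp.rv[j - 1], comp.rv[j]
                if hi_b > lo_b:
                    gain[lo_b] += g
                    gain[hi_b] -= g
        cum = np.cumsum(gain[:m])
        b = int(np.argmax(cum))
        if cum[b] <= 1e-9:
            return h
        flip_members = members[b + 1 :]
        h[flip_members] = 1 - h[flip_members]
    return h


def _segment_pass(comp: _CompObs, h: np.ndarray, max_len: int = 10) -> np.ndarray:
    """Exhaustive short-segment flips (the move single flips and suffix
    flips both miss: a short mis-oriented run pinned by long-range links
    on both sides). Scans every segment of up to ``max_len`` members and
    flips while any has positive exact MEC gain."""
    members = comp.members
    m = len(members)
    if m < 2:
        return h
    order = np.argsort(comp.rv, kind="stable")
    rv_s = comp.rv[order]
    improved = True
    while improved:
        improved = False
        mism = comp.a != h[members[comp.rv]]
        d_all = np.bincount(comp.f, weights=mism, minlength=comp.n_frags)
        cost_all = np.minimum(d_all, comp.k - d_all)
        delta = np.where(mism, -1.0, 1.0)
        dd = np.zeros(comp.n_frags)
        for r1 in range(m):
            s = np.searchsorted(rv_s, r1)
            for r2 in range(r1, min(m, r1 + max_len)):
                e = np.searchsorted(rv_s, r2, side="right")
                if s == e:
                    continue
                oi = order[s:e]
                fr = comp.f[oi]
                np.add.at(dd, fr, delta[oi])
                af = np.unique(fr)
                d_new = d_all[af] + dd[af]
                g = (cost_all[af] - np.minimum(d_new, comp.k[af] - d_new)).sum()
                dd[af] = 0.0
                if g > 1e-9:
                    seg = members[r1 : r2 + 1]
                    h[seg] = 1 - h[seg]
                    improved = True
                    mism = comp.a != h[members[comp.rv]]
                    d_all = np.bincount(comp.f, weights=mism, minlength=comp.n_frags)
                    cost_all = np.minimum(d_all, comp.k - d_all)
                    delta = np.where(mism, -1.0, 1.0)
    return h


def _support(flat: _Flat, h: np.ndarray) -> np.ndarray:
    """Per variant: consistent minus inconsistent fragment votes."""
    mism = flat.a != h[flat.v]
    d = np.bincount(flat.f, weights=mism, minlength=flat.n_frags)
    side_b = d > (flat.k - d)  # fragment better explained by hap B
    consistent = mism == side_b[flat.f]
    contrib = np.where(consistent, 1, -1)
    return np.bincount(flat.v, weights=contrib, minlength=len(h)).astype(np.int64)


def max_cut_phase(
    matrix: FragmentMatrix,
    n_restarts: int = 20,
    max_iters: int = 100,
    seed: int = 0,
) -> PhasingResult:
    """Assemble haplotype blocks minimising MEC per connected component.

    Deterministic under a fixed seed. Components of a single variant and
    variants without informative fragments are left unresolved.
    """
    n_var = matrix.n_variants
    flat = _Flat(matrix)
    labels = _components(flat, n_var)
    comp_ids = [c for c in np.unique(labels) if c >= 0]
    comp_members = {c: np.flatnonzero(labels == c) for c in comp_ids}
    comp_ids = [c for c in comp_ids if len(comp_members[c]) >= 2]

    rng = np.random.default_rng(seed)

    # adjacency over aggregated pairwise votes (for the greedy init)
    adj_ptr, adj_nbr, adj_wt = _adjacency(flat, n_var)

    frag_comp = np.full(flat.n_frags, -1, dtype=np.int64)
    if flat.n_obs:
        order = np.argsort(flat.f, kind="stable")
        first_obs = np.searchsorted(flat.f[order], np.arange(flat.n_frags))
        frag_comp = labels[flat.v[order][first_obs]]

    comp_obs = {c: _CompObs(flat, comp_members[c]) for c in comp_ids}
    best_h = np.full(n_var, -1, dtype=np.int8)
    best_comp_cost: Dict[int, float] = {c: np.inf for c in comp_ids}
    member_arrays = np.concatenate([comp_members[c] for c in comp_ids]) if comp_ids else np.zeros(0, dtype=np.int64)

    for _ in range(max(1, n_restarts)):
        h = _greedy_init(adj_ptr, adj_nbr, adj_wt, member_arrays, rng, n_var)
        for _ in range(max_iters):
            before = h.copy()
            h = _local_search(flat, h, max_iters)
            for c in comp_ids:
                h = _suffix_pass(comp_obs[c], h, max_iters)
            if np.array_equal(before, h):
                break
        # keep the best phase per component
        _, d = _flat_mec(flat, np.where(h >= 0, h, 0).astype(np.int8))
        cost_f = np.minimum(d, flat.k - d)
        for c in comp_ids:
            cc = float(cost_f[frag_comp == c].sum())
            if cc < best_comp_cost[c]:
                best_comp_cost[c] = cc
                best_h[comp_members[c]] = h[comp_members[c]]

    # polish the best solution: short-segment flips, then re-descend
    if comp_ids:
        h = np.where(best_h >= 0, best_h, 0).astype(np.int8)
        for _ in range(max_iters):
            before = h.copy()
            for c in comp_ids:
                h = _segment_pass(comp_obs[c], h, max_len=10)
            h = _local_search(flat, h, max_iters)
            for c in comp_ids:
                h = _suffix_pass(comp_obs[c], h, max_iters)
            if np.array_equal(before, h):
                break
        _, d = _flat_mec(flat, h)
        cost_f = np.minimum(d, flat.k - d)
        for c in comp_ids:
            cc = float(cost_f[frag_comp == c].sum())
            if cc < best_comp_cost[c]:
                best_comp_cost[c] = cc
                best_h[comp_members[c]] = h[comp_members[c]]

    support = _support(flat, np.where(best_h >= 0, best_h, 0).astype(np.int8))

    blocks: List[HaplotypeBlock] = []
    phased_mask = np.zeros(n_var, dtype=bool)
    for c in comp_ids:
        mem = comp_members[c]
        ph = best_h[mem].astype(np.int8)
        if ph[0] == 1:  # canonical orientation: first member carries ref on hap A
            ph = (1 - ph).astype(np.int8)
        blocks.append(
            HaplotypeBlock(
                block_id=int(mem[0]) + 1,
                members=mem,
                phase=ph,
                support=support[mem],
                sources=np.array(["mec"] * len(mem)),
            )
        )
        phased_mask[mem] = True
    blocks.sort(key=lambda b: b.block_id)
    result = PhasingResult(
        n_variants=n_var,
        blocks=blocks,
        unresolved=np.flatnonzero(~phased_mask),
    )
    result.mec_score = mec_score(matrix, result.phase_array())
    return result


def _adjacency(flat: _Flat, n_var: int):
    """CSR adjacency of aggregated signed pair votes (equal-bit positive)."""
    order = np.lexsort((flat.v, flat.f))
    v, a, w, f = flat.v[order], flat.a[order], flat.w[order], flat.f[order]
    ii: List[int] = []
    jj: List[int] = []
    ww: List[float] = []
    start = 0
    no = len(v)
    # fragments are contiguous after the lexsort
    boundaries = np.flatnonzero(np.diff(f)) + 1
    frag_slices = np.split(np.arange(no), boundaries)
    for sl in frag_slices:
        if len(sl) < 2:
            continue
        for x in range(len(sl)):
            for y in range(x + 1, len(sl)):
                s, t = sl[x], sl[y]
                vote = min(w[s], w[t]) * (1.0 if a[s] == a[t] else -1.0)
                ii.append(int(v[s]))
                jj.append(int(v[t]))
                ww.append(vote)
    if not ii:
        return np.zeros(n_var + 1, dtype=np.int64), np.zeros(0, dtype=np.int64), np.zeros(0)
    i_arr = np.array(ii + jj)
    j_arr = np.array(jj + ii)
    w_arr = np.array(ww + ww)
    # aggregate duplicate (i, j) votes
    key = i_arr * n_var + j_arr
    uk, inv = np.unique(key, return_inverse=True)
    agg = np.bincount(inv, weights=w_arr)
    i_u = (uk // n_var).astype(np.int64)
    j_u = (uk % n_var).astype(np.int64)
    order2 = np.argsort(i_u, kind="stable")
    i_u, j_u, agg = i_u[order2], j_u[order2], agg[order2]
    ptr = np.searchsorted(i_u, np.arange(n_var + 1))
    return ptr, j_u, agg


# ---------------------------------------------------------------------------
# exhaustive oracle


def brute_force_phase(matrix: FragmentMatrix, max_component: int = 16) -> PhasingResult:
    """Exact MEC optimum by enumerating 2^(m-1) relative phasings per
    component; ties break to the lexicographically smallest phase vector."""
    n_var = matrix.n_variants
    flat = _Flat(matrix)
    labels = _components(flat, n_var)
    comp_ids = [c for c in np.unique(labels) if c >= 0]
    h = np.full(n_var, -1, dtype=np.int8)
    blocks: List[HaplotypeBlock] = []
    phased = np.zeros(n_var, dtype=bool)
    for c in comp_ids:
        mem = np.flatnonzero(labels == c)
        m = len(mem)
        if m < 2:
            continue
        if m > max_component:
            raise ValueError(f"component of {m} variants exceeds limit {max_component}")
        in_comp = np.isin(flat.v, mem)
        fsel = np.unique(flat.f[in_comp])
        sub = np.isin(flat.f, fsel)
        v_s, a_s, f_s = flat.v[sub], flat.a[sub], flat.f[sub]
        local = np.searchsorted(mem, v_s)
        k_s = np.bincount(f_s, minlength=flat.n_frags)[fsel]
        f_local = np.searchsorted(fsel, f_s)
        best_cost, best_bits = None, None
        for bits in range(2 ** (m - 1)):
            ph = np.zeros(m, dtype=np.int8)
            for b in range(m - 1):
                ph[m - 1 - b] = (bits >> b) & 1
            mism = a_s != ph[local]
            d = np.bincount(f_local, weights=mism, minlength=len(fsel))
            cost = int(np.minimum(d, k_s - d).sum())
            if best_cost is None or cost < best_cost:
                best_cost, best_bits = cost, ph.copy()
        h[mem] = best_bits
        phased[mem] = True
        blocks.append(
            HaplotypeBlock(
                block_id=int(mem[0]) + 1,
                members=mem,
                phase=best_bits,
                support=np.zeros(m, dtype=np.int64),
                sources=np.array(["mec"] * m),
            )
        )
    blocks.sort(key=lambda b: b.block_id)
    result = PhasingResult(n_var, blocks, 0, np.flatnonzero(~phased))
    result.mec_score = mec_score(matrix, result.phase_array())
    return result


# ---------------------------------------------------------------------------
# LCP refinement


def lcp_refine(
    result: PhasingResult,
    variants: VariantSet,
    panel_haplotypes: np.ndarray,
    window: int = 10,
    vote_threshold: float = 0.9,
    scaffold_match: float = 0.8,
) -> PhasingResult:
    """Phase residual unlinked variants onto the scaffold via panel voting.

    For each unresolved variant, panel haplotypes that match the
    largest-block scaffold's hap-A alleles at >= ``scaffold_match`` of the
    ``window`` nearest scaffold sites vote for the variant's hap-A allele;
    a winning fraction >= ``vote_threshold`` assigns it (source "lcp").
    One pass — newly assigned variants never serve as scaffold.
    """
    if panel_haplotypes is None or len(panel_haplotypes) == 0:
        logger.warning("empty reference panel: LCP refinement skipped")
        return result
    scaffold = result.largest_block
    if scaffold is None or len(result.unresolved) == 0:
        return result
    panel = np.asarray(panel_haplotypes, dtype=np.int8)
    sc_mem = scaffold.members
    sc_phase = scaffold.phase
    sc_pos = variants.pos[sc_mem]

    new_members: List[int] = []
    new_phase: List[int] = []
    still_unresolved: List[int] = []
    for v in result.unresolved:
        p = int(variants.pos[v])
        ins = np.searchsorted(sc_pos, p)
        lo = max(0, ins - window)
        hi = min(len(sc_mem), ins + window)
        idx = np.arange(lo, hi)
        if len(idx) > window:
            dist = np.abs(sc_pos[idx] - p)
            idx = idx[np.argsort(dist, kind="stable")[:window]]
        if len(idx) == 0:
            still_unresolved.append(int(v))
            continue
        agree = (panel[:, sc_mem[idx]] == sc_phase[idx]).mean(axis=1)
        voters = agree >= scaffold_match
        if not voters.any():
            still_unresolved.append(int(v))
            continue
        votes = panel[voters, v]
        frac_alt = votes.mean()
        if frac_alt >= vote_threshold:
            new_members.append(int(v))
            new_phase.append(1)
        elif 1.0 - frac_alt >= vote_threshold:
            new_members.append(int(v))
            new_phase.append(0)
        else:
            still_unresolved.append(int(v))

    if not new_members:
        return result
    mem = np.concatenate([scaffold.members, np.asarray(new_members)])
    ph = np.concatenate([scaffold.phase, np.asarray(new_phase, dtype=np.int8)])
    sup = np.concatenate([scaffold.support, np.zeros(len(new_members), dtype=np.int64)])
    src = np.concatenate([scaffold.sources, np.array(["lcp"] * len(new_members))])
    order = np.argsort(mem, kind="stable")
    new_block = HaplotypeBlock(
        block_id=int(mem[order][0]) + 1,
        members=mem[order],
        phase=ph[order],
        support=sup[order],
        sources=src[order],
    )
    blocks = [new_block if b is scaffold else b for b in result.blocks]
    blocks.sort(key=lambda b: b.block_id)
    return PhasingResult(
        result.n_variants,
        blocks,
        result.mec_score,
        np.asarray(sorted(still_unresolved), dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# output


def write_phased_vcf(
    result: PhasingResult,
    variants: VariantSet,
    locus: ReferenceLocus,
    path: str,
) -> None:
    """Phased VCF 4.2: GT with PS phase-set tags, LCP INFO flag."""
    from thaploseq.genome_model import write_variants_vcf

    write_variants_vcf(
        path,
        variants,
        locus,
        phase=result.phase_array(),
        phase_sets=result.block_id_array(),
        lcp_flags=result.lcp_array(),
    )


def write_block_report(result: PhasingResult, variants: VariantSet, path: str) -> None:
    """TSV block report: block_id, n_members, span_bp, n_lcp."""
    with open(path, "w") as fh:
        fh.write("block_id\tn_members\tspan_bp\tn_lcp\n")
        for b in result.blocks:
            span = int(variants.pos[b.members[-1]] - variants.pos[b.members[0]])
            n_lcp = int((b.sources == "lcp").sum())
            fh.write(f"{b.block_id}\t{len(b)}\t{span}\t{n_lcp}\n")
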