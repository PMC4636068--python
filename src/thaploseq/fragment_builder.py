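"""Build the allele-observation fragment matrix from aligned reads.

Both mates of a read pair become one Fragment (one ligation molecule);
per covered het site the base call maps to allele 0/1 (or 2 for a third
base), with MAPQ/base-quality filters and read-end labels retained for
the same-end h-trans diagnostics downstream.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Optional, Tuple

import numpy as np
import pysam

from thaploseq.fragments import (
    OTHER,
    Fragment,
    FragmentMatrix,
    read_fragments,
    write_fragments,
)
from thaploseq.genome_model import VariantSet

logger = logging.getLogger(__name__)

__all__ = ["extract_fragments", "write_fragments", "read_fragments"]


def _obs_from_read(
    read: pysam.AlignedSegment,
    variants: VariantSet,
    min_baseq: int,
    stats: Dict[str, int],
) -> List[Tuple[int, int, int]]:
    """Allele observations (variant index, allele, qual) from one alignment."""
    out: List[Tuple[int, int, int]] = []
    start, end = read.reference_start, read.reference_end
    if start is None or end is None:
        return out
    pos = variants.pos
    lo = int(np.searchsorted(pos, start))
    hi = int(np.searchsorted(pos, end))
    if lo == hi:
        return out
    ref_ptr = read.get_aligned_pairs(matches_only=True)
    by_ref = {rp: qp for qp, rp in ref_ptr}
    seq = read.query_sequence
    quals = read.query_qualities
    for vi in range(lo, hi):
        qp = by_ref.get(int(pos[vi]))
        if qp is None:
            continue
        base = seq[qp].upper()
        q = int(quals[qp]) if quals is not None else 0
        if q < min_baseq:
            stats["baseq"] = stats.get("baseq", 0) + 1
            continue
        if base == str(variants.ref[vi]):
            allele = 0
        elif base == str(variants.alt[vi]):
            allele = 1
        else:
            stats["allele_mismatch"] = stats.get("allele_mismatch", 0) + 1
            allele = OTHER
        out.append((vi, allele, q))
    return out


def extract_fragments(
    sam_path: str,
    variants: VariantSet,
    min_mapq: int = 30,
    min_baseq: int = 20,
) -> FragmentMatrix:
    """Convert an aligned SAM into the fragment matrix.

    Mates sharing a query name merge into one fragment; reads below
    ``min_mapq``, unmapped or secondary/supplementary alignments are
    dropped and counted. Conflicting duplicate observations of one
    variant inside a fragment keep the higher-quality call; quality ties
    drop the site (counted).
    """
    stats: Dict[str, int] = {}
    pending: Dict[str, List[Tuple[int, List[Tuple[int, int, int]], int, int]]] = {}
    fragments: List[Fragment] = []
    origin_rows: List[Tuple[int, int, int, int]] = []

    def _flush(qname: str) -> None:
        parts = pending.pop(qname)
        obs: List[Tuple[int, int, int, int]] = []  # (vi, allele, qual, end)
        for end, oset, _s, _l in parts:
            for vi, al, q in oset:
                obs.append((vi, al, q, end))
        obs.sort(key=lambda t: (t[0], -t[2], t[3]))
        merged: List[Tuple[int, int, int, int]] = []
        i = 0
        while i < len(obs):
            j = i
            while j < len(obs) and obs[j][0] == obs[i][0]:
                j += 1
            group = obs[i:j]
            if len(group) == 1:
                merged.append(group[0])
            else:
                alleles = {g[1] for g in group}
                if len(alleles) == 1:
                    merged.append(group[0])
                else:
                    best, second = group[0], group[1]
                    if best[2] > second[2]:
                        stats["dup_conflict_kept_hiq"] = stats.get("dup_conflict_kept_hiq", 0) + 1
                        merged.append(best)
                    else:
                        stats["dup_conflict_dropped"] = stats.get("dup_conflict_dropped", 0) + 1
            i = j
        starts = {end: (s, l) for end, _o, s, l in parts}
        s1, l1 = starts.get(1, (-1, 0))
        s2, l2 = starts.get(2, (-1, 0))
        origin_rows.append((s1, l1, s2, l2))
        fragments.append(
            Fragment(
                qname,
                [(vi, al, q) for vi, al, q, _e in merged],
                [e for _vi, _al, _q, e in merged],
            )
        )

    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as sam:
        for read in sam:
            if read.is_unmapped:
                stats["unmapped"] = stats.get("unmapped", 0) + 1
                continue
            if read.is_secondary or read.is_supplementary:
                stats["secondary"] = stats.get("secondary", 0) + 1
                continue
            if read.mapping_quality < min_mapq:
                stats["mapq"] = stats.get("mapq", 0) + 1
                continue
            end = 2 if (read.is_paired and read.is_read2) else 1
            obs = _obs_from_read(read, variants, min_baseq, stats)
            pending.setdefault(read.query_name, []).append(
                (end, obs, read.reference_start, read.reference_length or 0)
            )
            if (not read.is_paired) or len(pending[read.query_name]) == 2:
                _flush(read.query_name)
    # unpaired leftovers (mate filtered out) still form single-end fragments
    for qname in sorted(pending):
        stats["mate_missing"] = stats.get("mate_missing", 0) + 1
        _flush(qname)

    # collapse exact duplicates: same anchors and same observations
    seen: Dict[Tuple, int] = {}
    keep: List[int] = []
    for i, (frag, org) in enumerate(zip(fragments, origin_rows)):
        key = (org, tuple(frag.observations), tuple(frag.end_labels))
        if key in seen:
            stats["duplicates_collapsed"] = stats.get("duplicates_collapsed", 0) + 1
        else:
            seen[key] = i
            keep.append(i)
    fragments = [fragments[i] for i in keep]
    origin_rows = [origin_rows[i] for i in keep]

    matrix = FragmentMatrix.from_fragments(fragments, len(variants))
    if origin_rows:
        arr = np.asarray(origin_rows, dtype=np.int64)
        matrix.origin = {
            "start1": arr[:, 0],
            "len1": arr[:, 1],
            "start2": arr[:, 2],
            "len2": arr[:, 3],
        }
    matrix.filter_stats = stats
    return matrix
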