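"""Fragment containers: per-molecule allele observations at het sites.

A Fragment is what one proximity-ligation (or long-fragment-read)
molecule says about the variants it covers: for each covered het site,
the observed allele (0=ref, 1=alt, 2=third base), a Phred quality and a
read-end label. The FragmentMatrix stores many fragments columnar (CSR
layout) so simulation-scale data stays in numpy.

Fragment file format (tab-separated, bit-exact round trip)::

    #targeted-haploseq-fragments v1
    frag_id <TAB> n_obs <TAB> obs ... <TAB> quals

where each obs is ``index:allele:endlabel`` (endlabel in {1,2}) and
quals is a Phred+33 string aligned to the observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

HEADER = "#targeted-haploseq-fragments v1"

#: allele codes
REF, ALT, OTHER = 0, 1, 2


@dataclass
class Fragment:
    """One molecule's allele observations, sorted by variant index."""

    id: str
    observations: List[Tuple[int, int, int]]  # (variant index, allele, phred qual)
    end_labels: List[int]  # per observation, 1 or 2
    origin: Optional[dict] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if len(self.end_labels) != len(self.observations):
            raise ValueError("end_labels must align with observations")
        idx = [o[0] for o in self.observations]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("observations must be strictly increasing in variant index")

    @property
    def n_obs(self) -> int:
        return len(self.observations)

    def phasing_informative(self) -> bool:
        """At least two usable (non-third-base) allele observations."""
        return sum(1 for _, a, _ in self.observations if a != OTHER) >= 2


class FragmentMatrix:
    """Columnar collection of fragments over a fixed variant set."""

    def __init__(
        self,
        n_variants: int,
        ptr: np.ndarray,
        var_idx: np.ndarray,
        allele: np.ndarray,
        qual: np.ndarray,
        end_label: np.ndarray,
        frag_ids: Optional[List[str]] = None,
        origin: Optional[Dict[str, np.ndarray]] = None,
        filter_stats: Optional[Dict[str, int]] = None,
    ) -> None:
        self.n_variants = int(n_variants)
        self.ptr = np.asarray(ptr, dtype=np.int64)
        self.var_idx = np.asarray(var_idx, dtype=np.int32)
        self.allele = np.asarray(allele, dtype=np.int8)
        self.qual = np.asarray(qual, dtype=np.int16)
        self.end_label = np.asarray(end_label, dtype=np.int8)
        self.frag_ids = frag_ids
        self.origin = origin or {}
        self.filter_stats = dict(filter_stats or {})

    # -- construction -------------------------------------------------------

    @classmethod
    def from_fragments(cls, fragments: Iterable[Fragment], n_variants: int) -> "FragmentMatrix":
        ids, vi, al, qu, el = [], [], [], [], []
        ptr = [0]
        for f in fragments:
            ids.append(f.id)
            for (i, a, q), e in zip(f.observations, f.end_labels):
                vi.append(i)
                al.append(a)
                qu.append(q)
                el.append(e)
            ptr.append(len(vi))
        return cls(
            n_variants,
            np.asarray(ptr),
            np.asarray(vi, dtype=np.int32),
            np.asarray(al, dtype=np.int8),
            np.asarray(qu, dtype=np.int16),
            np.asarray(el, dtype=np.int8),
            frag_ids=ids,
        )

    # -- accessors ----------------------------------------------------------

    @property
    def n_fragments(self) -> int:
        return len(self.ptr) - 1

    def obs_count(self, i: int) -> int:
        return int(self.ptr[i + 1] - self.ptr[i])

    def fragment_id(self, i: int) -> str:
        return self.frag_ids[i] if self.frag_ids is not None else f"F{i}"

    def fragment(self, i: int) -> Fragment:
        s, e = int(self.ptr[i]), int(self.ptr[i + 1])
        obs = [
            (int(self.var_idx[j]), int(self.allele[j]), int(self.qual[j]))
            for j in range(s, e)
        ]
        origin = None
        if self.origin:
            origin = {k: v[i] for k, v in self.origin.items()}
        return Fragment(
            self.fragment_id(i), obs, [int(x) for x in self.end_label[s:e]], origin
        )

    def __iter__(self):
        return (self.fragment(i) for i in range(self.n_fragments))

    def __len__(self) -> int:
        return self.n_fragments

    # -- derived views ------------------------------------------------------

    def usable_obs_counts(self) -> np.ndarray:
        """Per fragment, number of non-third-base observations."""
        if self.n_fragments == 0:
            return np.zeros(0, dtype=np.int64)
        frag_of_obs = np.repeat(np.arange(self.n_fragments), np.diff(self.ptr))
        return np.bincount(
            frag_of_obs[self.allele != OTHER], minlength=self.n_fragments
        )

    def informative_mask(self) -> np.ndarray:
        """Fragments usable for phasing: >= 2 non-third-base observations."""
        return self.usable_obs_counts() >= 2

    def subset(self, mask: np.ndarray) -> "FragmentMatrix":
        """Keep fragments where mask is True (origin metadata follows)."""
        mask = np.asarray(mask, dtype=bool)
        keep = np.flatnonzero(mask)
        lens = np.diff(self.ptr)[keep]
        new_ptr = np.concatenate([[0], np.cumsum(lens)])
        if len(keep) and lens.sum():
            starts = self.ptr[keep]
            offsets = np.arange(lens.sum()) - np.repeat(new_ptr[:-1], lens)
            obs_take = np.repeat(starts, lens) + offsets
        else:
            obs_take = np.empty(0, dtype=np.int64)
        ids = [self.frag_ids[i] for i in keep] if self.frag_ids is not None else None
        origin = {k: v[keep] for k, v in self.origin.items()} if self.origin else None
        return FragmentMatrix(
            self.n_variants,
            new_ptr,
            self.var_idx[obs_take],
            self.allele[obs_take],
            self.qual[obs_take],
            self.end_label[obs_take],
            frag_ids=ids,
            origin=origin,
            filter_stats=self.filter_stats,
        )

    def variant_informative_depth(self) -> np.ndarray:
        """Per variant, number of phasing-informative fragments covering it."""
        inf = self.informative_mask()
        depth = np.zeros(self.n_variants, dtype=np.int64)
        frag_of_obs = np.repeat(np.arange(self.n_fragments), np.diff(self.ptr))
        sel = inf[frag_of_obs] & (self.allele != OTHER)
        np.add.at(depth, self.var_idx[sel], 1)
        return depth


# ---------------------------------------------------------------------------
# file I/O


def write_fragments(matrix: FragmentMatrix, path: str) -> None:
    """Write the matrix in the tab-separated fragment format (lossless)."""
    with open(path, "w") as fh:
        fh.write(HEADER + "\n")
        for i in range(matrix.n_fragments):
            s, e = int(matrix.ptr[i]), int(matrix.ptr[i + 1])
            obs = [
                f"{matrix.var_idx[j]}:{matrix.allele[j]}:{matrix.end_label[j]}"
                for j in range(s, e)
            ]
            quals = "".join(
                chr(33 + min(93, max(0, int(q)))) for q in matrix.qual[s:e]
            )
            fh.write("\t".join([matrix.fragment_id(i), str(e - s), *obs, quals]) + "\n")


def read_fragments(path: str, n_variants: Optional[int] = None) -> FragmentMatrix:
    """Read a fragment file; rejects malformed lines with their line number."""
    ids: List[str] = []
    vi: List[int] = []
    al: List[int] = []
    qu: List[int] = []
    el: List[int] = []
    ptr = [0]
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first != HEADER:
            raise ValueError(f"{path}:1: missing fragment file header {HEADER!r}")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            try:
                n_obs = int(fields[1])
                if len(fields) != 3 + n_obs:
                    raise ValueError("field count mismatch")
                prev = -1
                for tok in fields[2 : 2 + n_obs]:
                    i_s, a_s, e_s = tok.split(":")
                    i, a, e = int(i_s), int(a_s), int(e_s)
                    if i <= prev or a not in (0, 1, 2) or e not in (1, 2):
                        raise ValueError(f"bad observation {tok!r}")
                    prev = i
                    vi.append(i)
                    al.append(a)
                    el.append(e)
                quals = fields[2 + n_obs]
                if len(quals) != n_obs:
                    raise ValueError("quality string length mismatch")
                qu.extend(ord(c) - 33 for c in quals)
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed fragment line ({exc})")
            ids.append(fields[0])
            ptr.append(len(vi))
    if n_variants is None:
        n_variants = (max(vi) + 1) if vi else 0
    return FragmentMatrix(
        n_variants,
        np.asarray(ptr),
        np.asarray(vi, dtype=np.int32),
        np.asarray(al, dtype=np.int8),
        np.asarray(qu, dtype=np.int16),
        np.asarray(el, dtype=np.int8),
        frag_ids=ids,
    )
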