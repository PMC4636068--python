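"""Diploid target locus model: sequence, variants, haplotypes, restriction map.

Coordinate convention: 0-based half-open everywhere in memory and in BED
files; VCF I/O converts to/from 1-based. A locus is a single contiguous
reference segment (e.g. the ~3.5-Mb MHC region on chr6); `offset` records
where it sits on its source chromosome but all internal coordinates are
locus-relative.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from pyfaidx import Fasta

from thaploseq import intervals as iv

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class Gene:
    """A named gene interval with exon sub-intervals (0-based half-open)."""

    name: str
    start: int
    end: int
    exons: List[Tuple[int, int]] = field(default_factory=list)


@dataclass
class ReferenceLocus:
    """One contiguous reference segment with repeat and gene annotation."""

    name: str
    sequence: str
    offset: int = 0
    repeats: List[Tuple[int, int]] = field(default_factory=list)
    genes: List[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if set(self.sequence) - set("ACGTN"):
            bad = sorted(set(self.sequence) - set("ACGTN"))
            raise ValueError(f"non-ACGTN bases in locus sequence: {bad}")
        self.repeats = iv.clip(self.repeats, 0, len(self.sequence))

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def exon_intervals(self) -> List[Tuple[int, int]]:
        return iv.merge(e for g in self.genes for e in g.exons)


@dataclass(frozen=True)
class VariantSite:
    """One heterozygous biallelic SNV — the atom of phasing."""

    index: int
    pos: int
    ref_allele: str
    alt_allele: str
    truth_phase: Optional[int] = None  # allele on haplotype A: 0=ref, 1=alt
    density_flag: bool = False


class VariantSet:
    """Array-backed collection of heterozygous SNVs, sorted by position.

    `truth_phase` is -1 where unknown. `density_flag` marks variants in
    high-variant-density windows, where both real phasing errors and
    truth-set errors concentrate.
    """

    def __init__(
        self,
        pos: Sequence[int],
        ref: Sequence[str],
        alt: Sequence[str],
        truth_phase: Optional[Sequence[int]] = None,
        density_flag: Optional[Sequence[bool]] = None,
    ) -> None:
        self.pos = np.asarray(pos, dtype=np.int64)
        self.ref = np.asarray(list(ref), dtype="U1")
        self.alt = np.asarray(list(alt), dtype="U1")
        n = len(self.pos)
        if truth_phase is None:
            self.truth_phase = np.full(n, -1, dtype=np.int8)
        else:
            self.truth_phase = np.asarray(truth_phase, dtype=np.int8)
        if density_flag is None:
            self.density_flag = np.zeros(n, dtype=bool)
        else:
            self.density_flag = np.asarray(density_flag, dtype=bool)
        if n and np.any(np.diff(self.pos) <= 0):
            raise ValueError("variant positions must be strictly increasing")
        if np.any(self.ref == self.alt):
            raise ValueError("ref allele equals alt allele at some site")

    def __len__(self) -> int:
        return len(self.pos)

    def __getitem__(self, i: int) -> VariantSite:
        tp = int(self.truth_phase[i])
        return VariantSite(
            index=i,
            pos=int(self.pos[i]),
            ref_allele=str(self.ref[i]),
            alt_allele=str(self.alt[i]),
            truth_phase=None if tp < 0 else tp,
            density_flag=bool(self.density_flag[i]),
        )

    def __iter__(self):
        return (self[i] for i in range(len(self)))


@dataclass
class RestrictionMap:
    """Cut positions of one restriction enzyme over the locus."""

    enzyme_name: str
    motif: str
    cut_offset: int
    sites: List[int]


@dataclass
class DiploidHaplotypes:
    """Phase bit-vectors for both chromosome copies over all het sites.

    hapA[i] is the allele (0=ref, 1=alt) carried by copy A at variant i;
    every site is heterozygous so hapB is the complement.
    """

    hapA: np.ndarray

    def __post_init__(self) -> None:
        self.hapA = np.asarray(self.hapA, dtype=np.int8)

    @property
    def hapB(self) -> np.ndarray:
        return (1 - self.hapA).astype(np.int8)

    def __len__(self) -> int:
        return len(self.hapA)


# ---------------------------------------------------------------------------
# loading


def _parse_bed(path: str, min_cols: int = 3):
    """Yield (start, end, name) from a BED file; raises with line numbers."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < min_cols:
                raise ValueError(f"{path}:{lineno}: expected >= {min_cols} BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer BED coordinates") from exc
            if start < 0 or end < start:
                raise ValueError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            name = fields[3] if len(fields) > 3 else f"feature_{lineno}"
            yield start, end, name


def load_locus(
    fasta_path: str,
    repeats_bed_path: Optional[str] = None,
    genes_bed_path: Optional[str] = None,
    record: Optional[str] = None,
    offset: int = 0,
) -> ReferenceLocus:
    """Load a single-record locus FASTA plus repeat and gene/exon BEDs.

    Soft-masked (lower-case) FASTA stretches are added to the repeat set
    before upper-casing, so a masker's output is honored even without a
    repeat BED. Gene BED lines are exons; lines sharing a name (column 4)
    belong to one gene whose interval is the span of its exons.
    """
    fa = Fasta(fasta_path, as_raw=True, sequence_always_upper=False)
    names = list(fa.keys())
    if record is None:
        if len(names) != 1:
            raise ValueError(
                f"{fasta_path} has {len(names)} records; select one with record="
            )
        record = names[0]
    elif record not in names:
        raise ValueError(f"record {record!r} not found in {fasta_path}")
    raw = str(fa[record][:])
    n = len(raw)

    repeats: List[Tuple[int, int]] = []
    for m in re.finditer(r"[a-z]+", raw):
        repeats.append((m.start(), m.end()))
    if repeats_bed_path is not None:
        repeats.extend((s, e, None)[:2] for s, e, _ in _parse_bed(repeats_bed_path))
    repeats = iv.clip(repeats, 0, n)

    genes: List[Gene] = []
    if genes_bed_path is not None:
        by_name: Dict[str, List[Tuple[int, int]]] = {}
        order: List[str] = []
        for s, e, name in _parse_bed(genes_bed_path):
            if name not in by_name:
                by_name[name] = []
                order.append(name)
            by_name[name].append((max(0, s), min(n, e)))
        for name in order:
            exons = iv.merge(by_name[name])
            if exons:
                genes.append(Gene(name, exons[0][0], exons[-1][1], exons))

    return ReferenceLocus(
        name=record, sequence=raw.upper(), offset=offset, repeats=repeats, genes=genes
    )


# ---------------------------------------------------------------------------
# restriction digestion


def _iupac_regex(motif: str) -> str:
    parts = []
    for ch in motif.upper():
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC character {ch!r} in motif {motif!r}")
        alts = IUPAC[ch]
        parts.append(alts if len(alts) == 1 else f"[{alts}]")
    return "".join(parts)


def find_restriction_sites(
    locus: ReferenceLocus,
    motif: str = "AAGCTT",
    cut_offset: int = 1,
    enzyme_name: str = "HindIII",
) -> RestrictionMap:
    """Locate every cut position of an enzyme motif along the locus.

    Overlapping matches are allowed. Palindromic motifs (HindIII's AAGCTT
    is its own reverse complement) need only a forward scan; otherwise the
    reverse strand is scanned too and its cut positions mirrored.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    if not 0 <= cut_offset <= len(motif):
        raise ValueError("cut_offset outside [0, len(motif)]")
    motif = motif.upper()
    pattern = re.compile(f"(?=({_iupac_regex(motif)}))")
    sites = {m.start() + cut_offset for m in pattern.finditer(locus.sequence)}
    rc = reverse_complement(motif)
    if rc != motif:
        rc_pattern = re.compile(f"(?=({_iupac_regex(rc)}))")
        # a reverse-strand match at forward position m cuts at the mirrored offset
        for m in rc_pattern.finditer(locus.sequence):
            sites.add(m.start() + len(motif) - cut_offset)
    return RestrictionMap(enzyme_name, motif, cut_offset, sorted(sites))


# ---------------------------------------------------------------------------
# haplotype sequences


def haplotype_sequences(
    locus: ReferenceLocus, variants: VariantSet, haplotypes: DiploidHaplotypes
) -> Tuple[str, str]:
    """Reconstruct both chromosome-copy sequences from reference + phase bits."""
    seq = np.frombuffer(locus.sequence.encode(), dtype="S1").copy()
    ref_at = seq[variants.pos].astype("U1")
    mism = ref_at != variants.ref
    if np.any(mism):
        i = int(np.flatnonzero(mism)[0])
        raise ValueError(
            f"ref allele mismatch at pos {int(variants.pos[i])}: "
            f"VCF says {variants.ref[i]}, reference has {ref_at[i]}"
        )
    out = []
    for hap in (haplotypes.hapA, haplotypes.hapB):
        s = seq.copy()
        alt_mask = hap.astype(bool)
        s[variants.pos[alt_mask]] = variants.alt[alt_mask].astype("S1")
        out.append(s.tobytes().decode())
    return out[0], out[1]


# ---------------------------------------------------------------------------
# density flags


def assign_density_flags(
    variants: VariantSet, window: int = 2000, top_fraction: float = 0.1
) -> VariantSet:
    """Flag variants lying in the densest `top_fraction` of fixed windows.

    The locus is cut into `window`-bp tiles; tiles whose SNV count reaches
    the (1 - top_fraction) quantile of non-empty tile counts are "high
    variant density" — the regime where ligation-junction mapping and
    truth-set phasing are least reliable.
    """
    if len(variants) == 0:
        return variants
    win = variants.pos // window
    uniq, counts = np.unique(win, return_counts=True)
    k = len(counts)
    target = max(1, int(round(top_fraction * k)))
    boundary = np.sort(counts)[::-1][min(target, k) - 1]
    if boundary <= counts.min() and k > target:
        # degenerate tie at the floor (near-uniform windows): only
        # genuinely denser-than-typical windows qualify
        dense = set(uniq[counts > boundary].tolist())
    else:
        dense = set(uniq[counts >= boundary].tolist())
    flags = np.array([int(w) in dense for w in win])
    return VariantSet(
        variants.pos, variants.ref, variants.alt, variants.truth_phase, flags
    )


# ---------------------------------------------------------------------------
# VCF I/O


def read_variants_vcf(path: str, locus_name: Optional[str] = None):
    """Read heterozygous biallelic SNVs from a VCF.

    Returns (VariantSet, stats dict). Indels, multi-allelic records and
    non-het genotypes are skipped and counted. Truth phase is taken from a
    phased GT ("0|1" -> hapA carries ref).
    """
    import pysam

    pos: List[int] = []
    ref: List[str] = []
    alt: List[str] = []
    phase: List[int] = []
    stats = {"indel": 0, "multiallelic": 0, "not_het": 0, "kept": 0}
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            if locus_name is not None and rec.chrom != locus_name:
                continue
            if rec.alts is None or len(rec.alts) != 1:
                stats["multiallelic"] += 1
                continue
            if len(rec.ref) != 1 or len(rec.alts[0]) != 1:
                stats["indel"] += 1
                continue
            if rec.samples:
                s = rec.samples[0]
                gt = s.get("GT")
                if gt is None or set(gt) != {0, 1}:
                    stats["not_het"] += 1
                    continue
                if s.phased:
                    phase.append(int(gt[0]))
                else:
                    phase.append(-1)
            else:
                phase.append(-1)
            pos.append(rec.pos - 1)
            ref.append(rec.ref)
            alt.append(rec.alts[0])
            stats["kept"] += 1
    order = np.argsort(pos, kind="stable")
    vs = VariantSet(
        np.asarray(pos)[order],
        np.asarray(ref)[order],
        np.asarray(alt)[order],
        np.asarray(phase)[order],
    )
    return vs, stats


def write_variants_vcf(
    path: str,
    variants: VariantSet,
    locus: ReferenceLocus,
    phase: Optional[np.ndarray] = None,
    phase_sets: Optional[np.ndarray] = None,
    lcp_flags: Optional[np.ndarray] = None,
    sample: str = "SAMPLE",
) -> None:
    """Write variants as VCF 4.2; phased GT where `phase` >= 0, else het 0/1.

    `phase_sets` gives the PS tag (1-based position of the first block
    member); `lcp_flags` marks panel-refined phases with an LCP INFO flag.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={locus.name},length={len(locus)}>\n")
        fh.write('##INFO=<ID=LCP,Number=0,Type=Flag,Description="Phased by local conditional phasing against a reference panel">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set identifier">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for i in range(len(variants)):
            p = -1 if phase is None else int(phase[i])
            info = "."
            if lcp_flags is not None and lcp_flags[i]:
                info = "LCP"
            if p >= 0:
                gt = f"{p}|{1 - p}"
                if phase_sets is not None and phase_sets[i] >= 0:
                    fmt, val = "GT:PS", f"{gt}:{int(phase_sets[i])}"
                else:
                    fmt, val = "GT", gt
            else:
                fmt, val = "GT", "0/1"
            fh.write(
                f"{locus.name}\t{int(variants.pos[i]) + 1}\t.\t{variants.ref[i]}\t"
                f"{variants.alt[i]}\t.\tPASS\t{info}\t{fmt}\t{val}\n"
            )
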