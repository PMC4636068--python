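"""De novo genotype calling from captured-read allele counts.

Proximity-ligation capture data is blind to genotyping: allele counts at
candidate sites support genotype calls without any prior variant list.
The caller is a frequency-threshold rule with an explicit ambiguous
no-call zone — at capture-style uneven depth, borderline minor-allele
fractions are the dominant failure mode for homozygous calls, so the
rule abstains rather than guessing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from thaploseq.fragments import ALT, OTHER, REF, FragmentMatrix
from thaploseq.genome_model import VariantSet

HOM_REF, HET, HOM_ALT, NO_CALL = "hom_ref", "het", "hom_alt", "no_call"


@dataclass
class SiteCounts:
    pos: int
    ref_count: int
    alt_count: int
    other_count: int

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count + self.other_count


def pileup_counts(
    matrix: FragmentMatrix, variants: VariantSet, min_baseq: int = 20
) -> List[SiteCounts]:
    """Per candidate site, counts of ref/alt/other allele observations."""
    n = len(variants)
    sel = matrix.qual >= min_baseq
    vi = matrix.var_idx[sel]
    al = matrix.allele[sel]
    refc = np.bincount(vi[al == REF], minlength=n)
    altc = np.bincount(vi[al == ALT], minlength=n)
    othc = np.bincount(vi[al == OTHER], minlength=n)
    return [
        SiteCounts(int(variants.pos[i]), int(refc[i]), int(altc[i]), int(othc[i]))
        for i in range(n)
    ]


def call_genotype(
    counts: SiteCounts,
    min_depth: int = 8,
    het_minor_frac: float = 0.2,
    hom_minor_frac: float = 0.05,
    min_minor_count: int = 2,
) -> str:
    """Frequency-threshold genotype call with an ambiguous no-call zone."""
    if not 0 < hom_minor_frac < het_minor_frac < 1:
        raise ValueError("need 0 < hom_minor_frac < het_minor_frac < 1")
    depth = counts.ref_count + counts.alt_count
    if counts.depth < min_depth or depth == 0:
        return NO_CALL
    minor = min(counts.ref_count, counts.alt_count)
    frac = minor / depth
    if frac >= het_minor_frac and minor >= min_minor_count:
        return HET
    if frac <= hom_minor_frac:
        return HOM_REF if counts.ref_count >= counts.alt_count else HOM_ALT
    return NO_CALL


def evaluate_genotyping(
    calls: Sequence[str], truth_genotypes: Sequence[str]
) -> Dict[str, Optional[float]]:
    """Call rate plus het/hom accuracy against truth genotype labels.

    Truth labels use the same vocabulary as calls; accuracies are over
    the *called* sites of each class and are None when no such call was
    made (matching how an empty class is reported, not as zero).
    """
    calls = list(calls)
    truth = list(truth_genotypes)
    if len(calls) != len(truth):
        raise ValueError("calls and truth must align")
    n = len(calls)
    called = [i for i in range(n) if calls[i] != NO_CALL]
    het_calls = [i for i in called if calls[i] == HET]
    hom_calls = [i for i in called if calls[i] in (HOM_REF, HOM_ALT)]
    het_acc = (
        sum(truth[i] == HET for i in het_calls) / len(het_calls) if het_calls else None
    )
    hom_acc = (
        sum(truth[i] == calls[i] for i in hom_calls) / len(hom_calls)
        if hom_calls
        else None
    )
    return {
        "call_rate": len(called) / n if n else 0.0,
        "het_accuracy": het_acc,
        "hom_accuracy": hom_acc,
        "n_called": float(len(called)),
    }


def sample_site_counts(
    truth_genotype: str,
    depth: int,
    seq_error: float,
    rng: np.random.Generator,
) -> SiteCounts:
    """Site-level count simulation for genotype-caller evaluation.

    Draws `depth` base calls from the truth genotype with per-base error
    `seq_error` (an erroneous base is uniform over the three wrong bases,
    so it crosses to the other allele a third of the time). Complements
    the diploid fragment simulator, which by construction carries only
    heterozygous sites.
    """
    if truth_genotype == HET:
        true_alt = rng.binomial(depth, 0.5)
    elif truth_genotype == HOM_ALT:
        true_alt = depth
    elif truth_genotype == HOM_REF:
        true_alt = 0
    else:
        raise ValueError(f"unknown truth genotype {truth_genotype!r}")
    ref_n = depth - true_alt
    alt_n = true_alt
    ref_c = alt_c = oth_c = 0
    for true_is_alt, n_bases in ((False, ref_n), (True, alt_n)):
        err = rng.binomial(n_bases, seq_error)
        cross = rng.binomial(err, 1.0 / 3.0)
        other = err - cross
        good = n_bases - err
        if true_is_alt:
            alt_c += good
            ref_c += cross
        else:
            ref_c += good
            alt_c += cross
        oth_c += other
    return SiteCounts(0, ref_c, alt_c, oth_c)


def write_genotype_vcf(
    path: str,
    variants: VariantSet,
    counts: List[SiteCounts],
    calls: Sequence[str],
    locus_name: str,
    locus_length: int,
    sample: str = "SAMPLE",
) -> None:
    """VCF with GT, DP and allele-depth AD for every candidate site."""
    gt_map = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", NO_CALL: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={locus_name},length={locus_length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for i, (c, call) in enumerate(zip(counts, calls)):
            fh.write(
                f"{locus_name}\t{int(variants.pos[i]) + 1}\t.\t{variants.ref[i]}\t"
                f"{variants.alt[i]}\t.\tPASS\t.\tGT:DP:AD\t"
                f"{gt_map[call]}:{c.depth}:{c.ref_count},{c.alt_count}\n"
            )
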