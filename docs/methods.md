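# Methods

## The phasing problem and the evidence model

Every heterozygous SNV in the target locus is a coordinate where the two
chromosome copies differ. A phase assignment is a bit vector h over the
SNVs — h_i is the allele (0 = ref, 1 = alt) carried by copy A — and the
complement describes copy B. Proximity-ligation fragments supply the
evidence: a ligation product joins two chromatin segments that were
spatially adjacent in the nucleus, which for intra-chromosomal contacts
means both segments come from the *same* chromosome copy. Each fragment
therefore contributes a set of allele observations that should all lie
on one haplotype, up to two noise processes: per-base sequencing error
(rate ε), and homologous-trans (h-trans) ligations joining the two
copies (rate τ), whose rarity is what makes the approach work.

## MEC max-cut assembly

The assembly objective is minimum error correction: find h minimising

    MEC(h) = Σ_f min( d_A(f, h), d_B(f, h) )

where d_A/d_B count a fragment's observations that disagree with copy
A/B. Only fragments with ≥2 usable observations constrain h; the graph
whose edges connect co-observed variants decomposes the problem into
connected components, each yielding one haplotype block (singleton
components stay unresolved).

The search, per component:

1. **Greedy propagation.** Breadth-first traversal from a random root;
   each newly reached variant takes the phase that the quality-weighted
   majority of its already-phased neighbours votes for. On low-noise
   data this alone satisfies almost every edge.
2. **Single-variant flips.** Exact per-variant MEC gains are computed
   vectorised over all observations; a fragment-disjoint set of
   positive-gain variants is flipped per sweep, until none remains.
   Zero-gain flips are rejected (determinism).
3. **Suffix flips.** A switch error — the whole tail of a block in the
   wrong orientation — cannot be repaired one variant at a time. For
   every boundary between consecutive block members the exact gain of
   flipping the entire suffix is accumulated with a difference array
   (closed form for two-observation fragments, a short walk for larger
   ones); the best positive suffix is flipped, repeatedly.
4. **Short-segment polish.** A short mis-oriented run pinned by
   long-range links on *both* sides is invisible to moves 2 and 3
   individually. After the restart loop, every segment of ≤10
   consecutive members is tested exhaustively for positive exact gain.
   On 3.5-Mb simulations this step closes the remaining gap to the MEC
   value of the generative truth itself.

Moves 1–3 run under 20 random restarts (seeded; best phase kept per
component); move 4 polishes the winner. `brute_force_phase` enumerates
all 2^(m−1) relative phasings of components up to 16 variants and is the
test oracle: on random instances the heuristic never beats it (it is a
lower bound) and ties it in ≳90 % of cases.

The optimiser minimises the unweighted MEC count (the reported integer
`mec_score`); pairwise graph weights are base-quality weighted. With the
simulator's constant base qualities the two orderings agree.

## LCP refinement

Variants no fragment links (about 1–2 % after capture) are phased by a
deliberately simple haplotype-copying vote rather than a full
Li–Stephens HMM: for each unresolved variant, the 10 nearest
already-phased scaffold variants of the largest block are located; every
panel haplotype agreeing with the scaffold's copy-A alleles at ≥80 % of
those positions votes for the variant's allele, and a ≥90 % majority
assigns it (source `lcp` in the output, `LCP` INFO flag in the VCF).
One pass only — LCP-assigned variants never recruit further ones, so
panel noise cannot chain. Variants failing the vote stay unresolved,
trading resolution for accuracy.

## The simulator

The generator produces the statistical structure the method assumes; its
defaults are the study conditions, not tuning knobs.

| parameter | default (paper / fast profile) | meaning |
|---|---|---|
| locus_length | 3.5 Mb / 1 Mb | MHC-scale target |
| snv_density | 9400 / 3.5 Mb ≈ 2.7 kb⁻¹ | het SNVs, uniform positions, fair-coin phase |
| n_fragments | 1,040,000 / 297,000 | pre-capture ligation fragments |
| read_length | 100 bp | per ligation end |
| decay_exponent α | 1.08 | contact span p(s) ∝ s^−α, truncated to [min_span, L] |
| min_span | 2 kb | shortest simulated contact |
| htrans_rate τ | 0.02 | second end reads the homologous copy |
| enrichment_fold F | 50 | off-target fragments survive capture w.p. 1/F |
| seq_error ε | 0.005 /base | erroneous base uniform over the 3 wrong bases |
| lfr_n × lfr_length | 8,750 / 2,500 × 4 kb | ≈10× LFR coverage, single-haplotype molecules |
| planted_error_fraction | 0 (0.1 in truth-error studies) | reported-truth flips among high-density variants |
| panel_size / mutation / switches | 10 / 0.02 / 3 | LCP reference panel derived from truth |

Notes on the less obvious choices:

* **Contact law.** The canonical intra-chromosomal distance decay
  (power law, α ≈ 1.08 at these scales) with inverse-CDF sampling; the
  second anchor reflects at the locus bounds. KS distance of 50,000
  samples against the analytic CDF is asserted < 0.02 in the tests.
* **Error model.** ε is a per-base error; a wrong base hits the
  opposite allele with probability ε/3 (flipping the observation) and a
  third base with probability 2ε/3 (code 2, excluded from phasing input
  but counted in genotyping pileups). This makes fragment evidence and
  pileup compositions consistent with one error process.
* **Coverage calibration.** n_fragments is set once so the median number
  of phasing-informative fragments per variant is ≈5 at both profiles —
  the coverage regime the whole evaluation is defined at.
* **High variant density** is operationalised as the top decile of 2-kb
  windows by SNV count (rank-based; near-uniform window counts flag only
  windows strictly above the tie floor). Planted reported-truth errors
  are confined to these variants, emulating the failure mode of
  trio-derived truth sets in complex regions.
* **The reference panel** copies the two truth haplotypes with Poisson
  recombination switch points and 2 % per-site mutation — enough noise
  that LCP's scaffold-agreement screen matters, while preserving the
  linkage structure a real population panel would carry.
* **Locus annotation.** Repeats are random exponential-length intervals
  covering ~20 % of the locus; genes are evenly spaced five-exon models.
  Both exist to exercise the repeat-avoidance and exon-targeting rules
  of the probe designer and the gene-level evaluation, not to model real
  MHC architecture.

## h-trans diagnostics and the concordance blacklist

For a reported haplotype pair, an observation pair inside one fragment
is h-trans when its allele XOR disagrees with the reported relative
phase. Three diagnostics separate genuine h-trans ligations from errors
*in the reported truth*: (i) truth errors concentrate in high-density
windows (the ratio is stratified by density decile); (ii) truth errors
produce h-trans pairs on a single read end ("same-end"), which a
ligation artifact between ends cannot; (iii) contiguous long-fragment
reads, which have no ligation step at all, confirm the same
inter-haplotype pairing.

The blacklist requires, per variant: h-trans pairs form the majority of
its informative pairs in the proximity-ligation data, *and* ≥2 LFR
fragments show an inter-haplotype pairing there with LFR h-trans pairs
likewise in the majority. The majority condition is what separates a
genuinely mis-phased variant (h-trans against essentially every partner)
from its innocent partners (h-trans only against the mis-phased one);
without it the filter blacklists both ends of every discordant pair and
its precision collapses. Same-end fraction is reported as a diagnostic
but is not a filter condition: at ~100-bp reads and ~220-bp spacing even
in dense windows, most mis-phased variants have no same-read neighbour,
yet both datasets still contradict them. On fast-profile simulations
with 10 % planted flips the blacklist reaches recall ≈0.85–0.91 at
precision ≈1.0, and excluding it from evaluation removes ~65–73 % of the
measured error.

## Evaluation metrics

* **Resolution** = members of the single largest haplotype structure
  (including LCP additions) / all het SNVs; completeness is the
  denominator. An `all_blocks` flag counts every block instead.
* **Per-variant accuracy** orients each block by majority vote against
  the truth and then scores every variant independently — the worst-case
  convention, unlike switch error which penalises a flipped tail once.
  Both are invariant to global block flips. When a blacklist is given,
  those variants leave numerator and denominator.
* **Switch error** = flips of relative phase between adjacent resolved
  variants / adjacent pairs.
* **Enrichment fold** counts whole fragments: a fragment is on-target
  iff any of its reads overlaps a target interval, normalised by on/off
  target bases. Read-level counting would misattribute the distal ends
  of captured molecules (both ends are captured together) and cannot
  recover the thinning factor. Under a long-tailed contact law a
  contiguous target boundary still blurs the classification by the
  fragments that straddle it (~+30 % at α = 1.08 with a half-locus
  target); the capture-validation fixtures therefore use a steep decay
  (α = 3) where straddling is negligible and the measured fold equals
  the configured one within sampling noise.
* **Probe sensitivity** compares per-probe read coverage with
  size-matched "virtual probes" placed off-target near cut sites
  (seeded). Because the simulator anchors reads uniformly rather than at
  ligation junctions, captured data shows a ~3–5× real/virtual ratio;
  junction-anchored real libraries sit far higher. The threshold is a
  parameter (`min_fold`).
* **Contact concordance**: fragments are binned by 100-kb anchor-bin
  pairs; r² of log10(1+count) over pairs non-zero in either dataset.
  A dataset against itself returns exactly 1.

## De novo genotyping

The caller is a frequency-threshold rule on pileup counts: no call below
depth 8; het if the minor-allele fraction ≥0.2 with ≥2 minor reads; hom
if ≤0.05; the zone between abstains. The deliberate no-call zone
reflects that borderline minor fractions at capture-style uneven depth
are overwhelmingly mis-calls of homozygous sites. Site-level count
simulation (`sample_site_counts`) supplies homozygous truth sites, which
the diploid fragment simulator — heterozygous by construction — cannot.

## Problem sizes and determinism

The test suite runs at reduced scale (loci of 0.1–1 Mb, tens of
thousands of fragments); the acceptance script runs the full 3.5-Mb,
~9,400-SNV configuration over three seeds plus three 1-Mb replicates for
the truth-error ablation. Every stochastic step takes an explicit
`numpy.random.Generator` or seed; fixed seeds give byte-identical
fragment files, BEDs and summaries.

## Known limitations

* The simulator omits PCR duplicates, chimeric re-ligation, mappability
  bias and indels; read anchors are uniform rather than junction-bound,
  which depresses probe-level (not fragment-level) enrichment relative
  to real capture Hi-C.
* LCP is a local vote, not an HMM with a genetic map; it will not phase
  variants whose neighbourhood the panel does not tag.
* The MEC search is a heuristic; optimality is verified only against
  exhaustive enumeration on small components.
* Passing tests demonstrate correct behaviour under the generative
  model's assumptions — real libraries add alignment artifacts in
  repeats and reference bias that the model does not emulate.
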