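# Methods

This note documents the models, parameter choices, and numerical decisions
behind `t2tdup`, and what the synthetic-data experiments do and do not
demonstrate about real genomes.

## Synthetic genomes and the truth ledger

The generator's job is to emulate the statistical structure the analyses
assume, at desk scale, with every planted feature recorded for recovery
testing. Background sequence is i.i.d. uniform A/C/G/T (GC 50%) — the
simplest null that still exercises context calling and alignment
statistics. Defaults: 17 chromosomes × 300 kb (tests and acceptance) with
a 2 Mb per-chromosome option for demonstrations.

Layout per chromosome: a (CCCTAAA)₁₀₀ array at the 5′ end and (TTTAGGG)₁₀₀
at the 3′ end (the orientation convention is fixed here; real assemblies
follow it by construction); one centered 100-kb centromeric array of a
198-bp monomer whose copies are independently mutated at 5% per base,
interleaved with 1.5-kb labeled retrotransposon chunks (28% of the span;
Gypsy share tracked deterministically at 80% so per-chromosome fractions
sit on target rather than fluctuating binomially); segmental duplications,
gene pairs, singleton genes, and TE annotations packed into the arms by
rejection sampling (1000 attempts, then a packing error). Satellite blocks
are reserved with a 2.5-kb margin so no other feature abuts them — the
separation repeats and genes show in real assemblies, and it keeps
repeat-masking from truncating adjacent features.

The centromere span default of 100 kb is set by the analysis geometry: the
density track uses 10-kb bins, so called boundaries snap to bin edges and
a reciprocal overlap of ≥ 0.9 with truth is only achievable for arrays an
order of magnitude larger than the bin.

SDs are planted copy-paste-mutate: the copy receives i.i.d. substitutions
at rate 1 − identity; when the segment is long enough it hosts a gene
whose copy is instead mutated codon-aware (below), with the ledger
recording the identity *realized* by global alignment of the two final
segments. Collinear (WGD-like) gene runs are planted in order across
chromosome pairs at Ks ≈ 0.20, inside the 0.15–0.30 extraction window.

**Codon-aware divergence planting.** `mutate_cds_to_target_ks` inverts the
Jukes–Cantor correction (p = ¾(1 − e^(−4k/3))) to get a target difference
proportion, then places `round(p·S)` single-base synonymous substitutions
at distinct codons (never through a stop), and likewise `round(p·N)`
nonsynonymous ones at other codons. Because every mutated codon differs by
exactly one change of the intended class, the NG pathway count is exact
and estimator recovery is limited only by integer rounding and the small
shift mutations cause in per-codon site counts — empirically ≤ 0.002 at
Ks ≤ 0.25 with 1000 codons. A target is rejected when its required count
rounds to zero on the given sequence (e.g. one codon at Ks 0.5) or when p
reaches the Jukes–Cantor pole at ¾.

**Expression.** Counts are negative binomial (var = m + φm², φ = 0.02 by
default — tissue-replicate scale) over 11 samples × 3 replicates,
mirroring a multi-tissue fruit sampling design. Partners share a lognormal
sample profile (log-sd 0.7) plus a small per-gene sample effect (log-sd
0.12); planted effects multiply the dominant gene by 6 in the affected
samples (⌈M/3⌉+1 samples for AED, ≥ 1 per side for Sub). These defaults
put the planted classes clearly inside the classifier's power at 3
replicates, so classification recovery isolates the rule logic rather
than t-test power; the per-gene sample effect is kept small because a
sample-level offset is indistinguishable from a true expression difference
to any within-sample test.

**Methylation.** One row per cytosine on both strands with
Binomial(depth, context mean) methylated counts; defaults CG 0.6, CHG 0.3,
CHH 0.1 — typical plant gene-body/flank magnitudes. Per-gene overrides
plant category contrasts. Output can be restricted to regions (gene bodies
± 2 kb by default in bundles) to keep files at desk scale.

What passing recovery tests does **not** show: robustness to indels and
rearrangements inside SDs (mutation is substitution-only), to satellite
higher-order repeat structure, to GC/coverage bias in methylation counts,
or to count-model misspecification in expression — real-data behavior on
those axes is untested by construction.

## Detectors

**Telomeres.** Exact motif matches are compressed into perfectly tandem
blocks; the maximal-copy run with purity ≥ 0.8 is found exhaustively over
block ranges, which is provably equivalent to the search over all match
ranges (extending into an adjacent perfect block raises both copies and
purity). Defaults — 150-kb windows, ≥ 10 copies, purity ≥ 0.8 — reject
random sequence (a chance run of 10 units is vanishingly unlikely) while
tolerating 20% interruptions.

**Tandem arrays.** Candidate periods come from distances between repeated
12-mers (spaced-match voting); each candidate period p is verified on the
self-match profile m[i] = [s[i] = s[i+p]], with arrays as maximal runs
where the p-windowed mean is ≥ 0.8. The array start is then refined by a
two-rate changepoint (background match rate 0.25 vs in-array ≈ 0.9,
log-likelihood weights +1.28/−2.01), because the windowed threshold
crossing systematically leads the boundary by ~0.15p — and the start fixes
the monomer phase, which the consensus inherits. Smaller periods are
scanned first; intervals already explained are not re-reported at their
multiples. This is deliberately not a reimplementation of a
general-purpose tandem-repeat finder: only the downstream contract
(arrays, monomers, consensus) is reproduced.

**Monomer clustering.** Greedy, length-descending; a monomer joins the
first cluster whose representative it matches at ≥ 0.8 identity in the
better strand orientation, and is stored in the representative's
orientation (per-member canonicalization by lexicographic order is
unstable under divergence and was rejected). Consensus is per-column
majority over members of the representative's length — exact for the
substitution-only generator, and adequate for low-indel satellites.

**Density track and calls.** Windows one consensus long are tested
against the *doubled* consensus in infix mode, making the hit test
rotation-invariant (a window out of phase with the monomer is an exact
infix of the doubled sequence). Hits merge before binning; the centromere
is the longest run of bins ≥ 0.3 density (ties: leftmost). Hi-C evidence,
which the motivating study used qualitatively for boundaries, is out of
scope; boundaries rest on monomer density alone with gene/TE annotations
reported alongside.

**Self-alignment.** Canonical 31-mers; k-mers occurring > 20 times are
skipped (satellites, telomeres), and detected tandem arrays plus
telomeres, padded by 2 kb, are masked before seeding — the equivalent of
running on a soft-masked assembly, and the pad absorbs sub-threshold
partial monomer runs at array edges. Seeds chain within a 100-bp diagonal
band and 2-kb gaps; chains of ≥ 5 seeds are extended by 300 bp, globally
aligned (edlib), and trimmed to the best-scoring alignment window (Kadane
over cigar runs, +1/−2/−3 per match/mismatch/gap base) so the margin's
flanking sequence cannot dilute identity. Identity is gap-compressed —
matches / (matches + mismatches + gap openings) — the convention common in
SD catalogs; the ≥ 90% and ≥ 1 kb thresholds are inclusive ("at least" in
the definition). Foldback hits (same-chromosome interval pairs overlapping
> 50%) are discarded.

**WGD exclusion.** A candidate is excluded when both intervals are ≥ 80%
covered by the two sides of one collinear block, where a block side is the
union of its anchor-gene spans merged across intergenic gaps ≤ 10 kb — not
the block's convex hull, which stray chained anchors can stretch across
half a chromosome at desk scale. The segment form also carries the right
semantics: a WGD-derived duplication contains dense collinear genes; an
SD does not.

**Collinearity.** Anchors are reciprocal-best (and near-best, within 5%)
translated-CDS matches at ≥ 50% identity, with tandem-like pairs (same
chromosome, rank distance ≤ 5) excluded so tandem arrays cannot masquerade
as blocks. Chaining is iterated sparse DP per chromosome pair and
orientation (score = pairs − 0.01 × skipped ranks, gaps ≤ 25 ranks),
verified against exhaustive enumeration on small instances. Block Ks is
summarized by the median (robust, since the window rule gives no
statistic), and the 0.15–0.30 window is closed on both ends.

**NG86 conventions.** Standard nuclear code only. Site counting treats
substitutions to stops as nonsynonymous; difference counting excludes
pathways through stops and averages over the rest, flagging the (rare)
pairs where every pathway is blocked by assigning all differences as
nonsynonymous. ps or pn ≥ ¾ is reported as saturated; Ks = 0 with Ka > 0
yields a +∞ ratio sentinel excluded from summaries. Codon alignment trims
trailing stops, aligns proteins globally (BLOSUM62, −11/−1 affine), and
drops gap columns and ambiguous codons.

**Expression contract.** The motivating analysis ran a count-model package
between the two *genes* of a pair within a tissue — a nonstandard use that
is not reproducible from its description. The recorded contract here is
Welch's t-test on log2(TPM+1) with BH across all pair×sample tests and the
joint FDR/|log2FC| gate; the classification layer on top (Sub before AED;
"one third" = ⌈M/3⌉; "never lower" = zero significant calls in the
partner's favor) is the part the definitions actually specify, and it is
test-method-agnostic. TPM is recomputed from counts and CDS lengths
(rate = count/length, column-normalized to 10⁶).

**Methylation.** Weighted levels only (read-sum over read-sum); metagene
tracks use 60 gene-body bins and 20 bins per 2-kb flank, orientation-
flipped for minus-strand genes, weighted within genes and averaged across
the genes of a category. The methylation–expression correlation flags a
pair when either member's per-sample gene-body level correlates with its
log2(TPM+1) at BH-FDR < 0.05 in any context — one defensible reading of a
procedure the source text leaves underdetermined.

## Numerical and reporting choices

Ratio summaries round half-away-from-zero at 2 decimals, matching how the
printed percentages and fold values behave. The Wilcoxon comparison of
intra- vs inter-chromosomal Ks uses the two-sided normal approximation
with tie correction. All randomness flows from a single integer seed via
`SeedSequence.spawn`; identical plan and seed give byte-identical output
files, and the pipeline's JSON bundle is timestamp-free so reruns diff
clean.

## Problem sizes

The validation suite uses 2–4-chromosome genomes of 120–300 kb for module
tests, the full 17 × 300 kb plan for the feature census, 1000-codon
sequences × 50 seeds for Ks recovery, 100 seeds for classification
recovery, and 50 two-chromosome genomes for SD recovery — sizes chosen so
the whole suite exercises every code path in a couple of minutes on one
CPU while keeping the statistical assertions well-powered.

## Known limitations

No Hi-C, CENH3, or read-level evidence; no indel-aware consensus; NG86
only (no GY94/codon-frequency corrections, no Ks-to-time conversion); the
self-aligner targets desk-scale genomes (≲ 50 Mb) — use external PAF for
larger inputs; single-genome analyses only (no cross-cultivar SV calling
beyond the printed-ratio summarizer).
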