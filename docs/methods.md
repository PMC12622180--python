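# Methods

This note documents the models, parameter choices and numerical conventions
behind `lucfam`, and what the synthetic-data tests do and do not demonstrate
about real amplicon data.

## Coordinates and site classification

All positions are 1-based, inclusive, in alignment-column space. A
`GeneModel` lists exon intervals plus a frame offset (codon phase of the
first exonic column); codons may span exon junctions. Analysis windows are
applied with `restrict`, which re-derives the frame so retained columns keep
their codon phase and drops codons truncated by the window. Degenerate
codons (gap, N, or stop in either sequence of a pair) are excluded from
codon statistics, and noncoding columns are compared under pairwise gap
deletion — the conservative convention of classic polymorphism software. N
matches nothing in diagnostic-site logic and scores mismatch/2 in alignment.

## Pairwise alignment

The caller's aligner is a banded global Needleman–Wunsch with affine gaps
(first gap base `gap_open`, each further base `gap_extend`; defaults
+1/−1/−3/−1). Cells satisfy |j − i| ≤ band. If the optimal in-band traceback
touches the band edge the aligner raises instead of returning a possibly
suboptimal path; callers retry with a wider band. Indel events are reported
in 1-based reference coordinates and left-aligned within homopolymer runs so
that the artifact-indel filter sees one canonical placement — the natural
convention for a platform whose dominant error mode is homopolymer slippage.
The kernel is numba-compiled; correctness is checked against Biopython's
unbanded C aligner.

## Synthetic data: what it encodes

The generator realizes the structure the analysis assumes, with known truth:

- **Families.** A random ancestor (sense codons in exons, uniform bases in
  noncoding columns) is evolved along a star tree. Branch lengths are solved
  from the target divergence matrix (b_i = (R_i − S/(n−1))/(n−2)), minus half
  of each family's within-family diversity target, because the divergence
  estimator is the *raw* mean between-group distance, which includes the
  within-family components. Within a family, haplotypes radiate
  independently from the founder along branches of π/2 (no coalescent
  machinery; targets are imposed, not emergent).
- **Substitution process.** Proposals arrive as Poisson(branch × length),
  uniform over sites, with transition:transversion weighting R = 2 — the
  same weighting the Nei–Gojobori site counting assumes, so the estimators
  are exercised under their own model. Noncoding and synonymous proposals
  are always accepted; nonsynonymous ones with probability ω (default 0.05);
  stop-creating proposals never (the ORF is preserved). Silent divergence
  per silent site therefore equals the branch length in expectation, and
  K_A/K_silent ≈ ω.
- **Defaults are the study conditions**: three families; silent divergence
  targets 0.82 (1↔2) and 0.164 (2↔3); within-family silent π 0.160, 0.156,
  0.130; ω = 0.05; 1–6 gene copies per individual per family; three
  individuals; ~360-column amplicons (~300 for family 3); ≤400 bp reads.
- **Read errors.** Substitutions at 0.5% per base; 1–2 nt indels inside
  homopolymer runs (probability 1% per run base, deletion-vs-insertion
  biased 80/20 by strand); constant quality 35 with 15 at injected error
  sites (qualities are carried but unused — the filters are sequence-level).
  The per-base rates are plausible mid-range values for semiconductor
  amplicon runs, chosen once and documented here; the source study does not
  report its run's rates.
- **Chimeras.** A configurable fraction of reads joins two distinct parent
  alleles of the same amplicon at a uniform breakpoint (single switch;
  multi-breakpoint chimeras are out of scope). Default rate 2%.

Limits: no flowgram-level simulation, no primer/barcode artifacts, no
coverage bias between alleles beyond multinomial sampling, no coalescent
genealogy. Passing tests show the estimators and filters behave correctly
under their own assumptions — not that those assumptions hold for any
particular instrument run.

## Haplotype calling

Reads longer than the length floor (default 150, strict >) are aligned to
the family reference amplicon and projected into reference columns;
identical projections form clusters. A mixture over components — clusters
with ≥ 2 reads — with a single per-base error rate ε is fitted by EM
(P(read|component) = (ε/3)^d (1−ε)^(L−d); ≤ 500 iterations, tolerance 1e−9).
Fitting one component per distinct string would be degenerate (ε → 0 with
empirical frequencies maximizes the likelihood), which is why singleton
clusters enter as data but not components.

Each cluster's posterior compares "real haplotype at frequency f_s seen
error-free", per-read likelihood f_s(1−ε)^L, against "error derivative of a
more frequent component h", likelihood f_h·C(L,d)·ε^d(1−ε)^(L−d) — the
binomial factor because any of the C(L,d)3^d strings at distance d is an
equally good error outcome; omitting it would make every specific multi-error
singleton look impossibly rare and hence "real". Both are raised to the
cluster's read count and normalized. Clusters above the cutoff (default
0.95, strict >) are candidate haplotypes; reads of failing clusters are
re-attributed to their best component (error correction), so downstream
frequencies reflect all reads, as in amplicon reconstruction tools.

Filter chain, in order: length → posterior → artifact indel → frequency
with rescue. The artifact filter rejects candidates carrying an indel of
length ≤ 2 not matched (kind, position, length, allele) in a trusted clone
set, and — when a gene model is supplied — premature stops absent from the
trusted set; longer indels pass (they are real structural variants, not the
platform's error mode). The frequency filter requires ≥ 15% of a sample's
corrected reads in at least one sample; failures are rescued by exact
sequence match to a trusted clone over the reference window, or by posterior-
passing detection in ≥ 2 independent samples. The frequency denominator uses
posterior-passed candidates by default (`frequency_denominator` switches to
all candidates; the choice is ambiguous in the source workflow). Every
rejected candidate carries exactly one primary reason, and raising either
cutoff can only shrink the passing set.

## Recombinant screen

Diagnostic sites are columns where two families are each fixed for distinct
non-gap alleles. A haplotype's diagnostic votes are scanned over all single
breakpoints (prefix-sum scan, verified against brute force); it is MOSAIC
when the best two-segment model has strictly fewer misassigned votes than
the best single family *and* each segment contains ≥ `min_run` (default 3)
consecutive concordant sites. Three concordant fixed differences per side
make a chance arrangement unlikely at the divergences involved while keeping
the false-positive rate on pure alleles below 1%. Haplotypes with
insufficient informative sites, ties, or patterns needing ≥ 2 breakpoints
are UNDETERMINED, never force-fit. Exclusive variants (alleles absent from
the segment's family panel) shared by ≥ 2 haplotypes group putative
single-origin recombinant lineages. Mosaics are removed before all
evolutionary statistics.

## Evolutionary statistics

- π(JC) is the mean of pairwise JC-corrected class proportions (correction
  before averaging). The silent denominator is noncoding sites plus the
  pair-mean weighted synonymous site count.
- Site counting: each possible change is weighted R = 2 (transition) or 1
  (each transversion), normalized per position; changes to stops count as
  nonsynonymous; syn + nonsyn = 3 exactly. Differences average over minimal
  pathways excluding stop intermediates (falling back to all pathways if
  every one is blocked).
- Tajima's D uses all gap-complete columns of the analyzed window (not
  class-restricted), n ≥ 4, S ≥ 1.
- Divergence K is the raw mean over between-group pairs; saturated pairs
  (p ≥ 0.75) are dropped from the mean and counted. When the groups
  coincide, K reduces to π by construction.
- MK counts use complete deletion; a site polymorphic in the ingroup
  contributes (alleles − 1) polymorphic changes classified by substitution
  into the majority ingroup codon; a fixed difference requires ingroup
  monomorphism with all outgroup alleles different; sites both polymorphic
  and divergent count as polymorphic only; multi-allelic sites contribute
  per-allele counts against the major allele. P-values are two-tailed Fisher
  exact, reported raw (per-locus tests, no multiplicity correction).

## Phylogeny

Distances use synonymous sites only (introns of deeply diverged paralogs do
not align), gamma-rate JC with shape a = 1. NJ follows Saitou–Nei with exact
Q ties broken by lexicographic label pair; negative branch lengths are
clamped to zero for output with the count retained. The bootstrap resamples
whole codons (the distance is codon-based, so the codon is the exchangeable
unit; single-column resampling would break codons apart). Replicates with a
saturated pair are dropped and counted. Support is the percentage of usable
replicates containing each internal bipartition of the reference tree.

## A structural consequence of the study conditions

The default calibration pins within-family silent π at 0.13–0.16 *and* the
family-2↔3 raw divergence at 0.164. Because raw divergence is the sum of
the net founder separation and half of each family's diversity, these values
force the net 2↔3 separation to ≈ 0.02 — so under the defaults families 2
and 3 share almost no fixed differences, diagnostic sites between them are
scarce, and no method could resolve them as supported clades. This is a
property of the target numbers, not of the implementation. The chimera
screen and tree-support checks therefore run under configurations where
divergence genuinely exceeds diversity (e.g. K 0.164–0.4 with π 0.01–0.04,
300 codons for the tree check), which is the regime in which those
operations are meaningful. Conversely, very deep pairs (K ≈ 0.8 under
gamma-JC with a = 1) sit near saturation, where distance variance explodes;
bootstrap supports across such edges are unstable, which is why the tree
check uses moderate divergence rather than the deepest target.

## Problem sizes

Test and acceptance runs use 900–1,200-column loci (200–300 codons), 3–4
haplotypes per family, 3 individuals, and 150–300 reads per sample;
calibration checks average 30 replicates, the caller soundness check runs 50
seeded replicates, and screen operating points use 1,000 replicates. These
sizes put every check well inside a normal CI budget while keeping binomial
noise far below the asserted tolerances.

## Known limitations

- The caller assumes reads span the reference window; partially covering
  reads are dropped (counted in the report), so very short fragments do not
  contribute.
- The EM error model is substitution-only; indel errors reach the candidate
  stage and are handled by the artifact-indel filter rather than inside ε.
- Family assignment uses mean distance to panel members, not a likelihood
  over within-family variation; ties go to UNDETERMINED.
- The mosaic screen models exactly one breakpoint.
- The exon-1/intron-1 boundary of the third family is treated as user
  input (six candidate splice-motif combinations exist in the real locus);
  the package never infers splice boundaries.
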