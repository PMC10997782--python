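# Methods

## Genotype models and likelihood

An allele is a multiset of *ace-1* copy classes (R; S; S_D1, a
susceptible copy carrying the AvaI site diagnostic of the D1(S)
sequence) spread over one or more tandem amplicons. The basic PCR-RFLP
assay reports [RR] iff every copy across both of an individual's
alleles is resistant, [SS] iff none is, and [RS] otherwise; the D1
assay splits the non-[RR] classes into D1+/D1− on the presence of at
least one S_D1 copy. Under panmixia a genotype pairing alleles *i* and
*j* has frequency *w·f_i·f_j* (*w* = 1 for homozygotes, 2 for
heterozygotes), and a phenotype class's probability is the sum over the
genotypes mapping to it.

All k(k+1)/2 unordered allele pairs are enumerated. Published genotype
grids for these models sometimes merge pairs that are phenotypically
indistinguishable (13 rather than 15 genotypes for five alleles, 9
rather than 10 for four); because the genotype→phenotype map is
many-to-one, enumeration differences of this kind leave every class
probability — and hence the likelihood — unchanged. A property test
asserts this invariance directly.

Three canonical models ship as data (`data/models.yaml`): **A**
(R, S, D on the three-class partition), **B** (R, S, S_D1, D1 on the
five-class partition) and **C** (B plus a generic further duplication
D_i). Multi-copy susceptible alleles (S^x) are representable through
`amplicon_count` but not instantiated by default, since the assays
cannot distinguish them from single-copy S.

## Maximum likelihood and its checks

The multinomial log-likelihood *L(f) = Σ n_i ln p_i(f)* is maximised on
the simplex by simulated annealing — geometric cooling from T₀ = 1 with
ratio 0.95 down to 10⁻³, 200 proposals per temperature, proposals drawn
from a Dirichlet centred on the current point (concentration 60) — from
`n_restarts` independent starts, followed by a Nelder-Mead polish on a
normalized-softplus transform of the simplex. Classes with n = 0
contribute nothing to L, and frequencies may hit 0 exactly (values
below 10⁻⁸ are snapped to the boundary). Zero predicted probability on
an observed class returns a −∞ sentinel.

Models A and C are saturated for their partitions (free parameters =
degrees of freedom), so their optima invert algebraically:
r = √f[RR], s = √f[SS(,D1−)], s1 = √(s² + f[SS,D1+]) − s, and d1 solves
d1² − 2(1−s1)d1 + (f[RS,D1+] − 2s1(1−s−s1)) = 0 with d_i the remainder.
These closed forms are the independent oracle for the optimiser: the
test-suite requires agreement to |Δf| < 10⁻⁴ on every packaged sample.
A few published estimates (Yamoussoukro 2015 Model A S printed as 0.53
vs the exact 0.50; likelihood-ratio statistics printed as
9.27/11.94/14.84 vs exact 9.56/12.85/14.9x) disagree with these closed
forms; we treat them as noise from the original optimiser and exclude
them from reproduction checks, which the acceptance-test docstring
records.

Support limits are profile-likelihood intervals: one allele's frequency
is fixed while the others are re-optimised on the reduced simplex, and
the limits are where the profile drops by ΔL = 1.92 (χ²₁;0.95/2, the
conventional "equivalent to a 95% CI"), located by bisection to 10⁻⁴
and clipped to [0, 1]. Likelihood-ratio tests use 2ΔL against χ² with
df = 1, also when the null sits on the simplex boundary (the
mixture-χ² refinement would halve boundary p-values but is not the
procedure the frequencies were originally analysed with); fits on
different phenotype partitions refuse comparison. The two-allele
Hardy-Weinberg null is fitted by allele counting,
f_R = (2n[RR] + n[RS]) / 2N.

## Synthetic data

**Phenotype counts** are i.i.d. multinomial draws of N diploid
genotypes under panmixia, mapped through the phenotype classes.
Empirical class frequencies converge to the model probabilities (tested
at N = 10⁵ within 3σ), and five-allele frequencies are recovered within
±0.02 at N = 10,000 across 20 seeds.

**Haplotype populations** emulate a sample of duplication carriers
typed over an 817-bp aligned fragment: one shared R haplotype (a single
resistant sequence segregates in the species), one fixed D(S) haplotype
per D allele shared by all its carriers, and single-copy S alleles
drawn as independent mutants (a finite shared pool is available via
`n_s_alleles` for stress-testing the assignment rules). Defaults: 28
individuals, 9 D alleles with carrier weights 11:8:3:2:1:1:1:1:1, one
duplication homozygote. Substitutions are placed at intronic sites at
rate 0.0135 per lineage and at third codon positions of exons at 0.012
(≈ 0.004 per exonic site), so pairwise divergences land near the
targets d_introns ≈ 0.027 and d_exons ≈ 0.008 with an intron/exon ratio
≈ 3. Each D allele also carries one intronic diagnostic site at which
the R haplotype and its D(S) copy hold two distinct non-ancestral
bases; these sites, excluded from background mutation, guarantee the
triple-peak signature in every carrier — the in-silico counterpart of
the SNP differences the chromatogram assay relies on. What this
generator does **not** model: recombination within the fragment,
sequencing/PCR error, indels, or shared ancestry between D(S) copies
and contemporary S alleles; passing tests therefore demonstrate the
logic of the assignment cascade, not its error rates on real traces.

**Alignments** are generated at the alignment level: fragments are
drawn uniformly from each haplotype's true tandem-duplicated sequence
(Gaussian inserts, 350 ± 50 bp, truncated at the 150-bp read length)
and placed against the single-copy reference deterministically, exactly
as an aligner places them — interval depth scaled by copies/2, reads
crossing an amplicon junction soft-clipped at the breakpoint with the
longer segment aligned, junction-straddling pairs discordant with
apparent template length ≈ amplicon size. This keeps the simulator
dependency-free and byte-reproducible per seed; it idealises away
mapping ambiguity and base errors. Default frame: a 400-kb window of
chromosome 2R (3,340,001–3,740,000) with the packaged D1 amplicon
(202,910 bp; breakpoints 3,436,927 / 3,639,836) planted at 2, 3 or 4
total copies, 30× depth (`data/d1_architecture.json`).

## Duplication calling

Per-base depth is accumulated from M/=/X CIGAR blocks (duplicate
flagging is not consulted; the simulator emits none). µDoC comes from
caller-designated baseline intervals when available (the desk-scale
stand-in for a chromosome-wide mean); otherwise a robust single-copy
baseline is estimated by anchoring on the 25th percentile of 1-kb bin
means and averaging the bins within ±35% of the anchor — unbiased to
<2% at 8× and excluding duplicated bins whenever less than ~75% of the
region is amplified.

The calling track is the mean standardized depth per 100-bp bin over
500-bp sliding windows. The amplicon is the longest run of bins ≥
`min_fold` = 1.25 (midway between the single-copy level 1 and the
lowest duplicated level 1.5 — the threshold itself is a package choice,
not a published value) spanning ≥ 10 kb; because window smoothing
correlates neighbouring bins, dips up to 30 bins (3 kb) do not break a
run, and each boundary is then polished by a least-squares step fit.
Copy number is round(2 × fold).

Breakpoint refinement exploits the two junction signatures jointly.
Junction-straddling discordant pairs (apparent insert ≥ 10 kb) first
localise the breakpoints — the 5th percentile of their leftmost read
starts and 95th percentile of their rightmost read ends sit within
~100 bp of the true junction, far closer than the depth step under
correlated coverage noise. Each breakpoint is then the soft-clip pileup
maximum within ±1 kb of its candidate, accepted when the two sides
jointly reach max(3, 10% of local single-copy depth) clipped reads with
at least 2 per side; with insufficient support the coarse call is
returned flagged, never silently refined. The amplicon-size estimate is
the median apparent insert of the discordant pairs; by construction it
under-reports by roughly (mean insert − 2 read lengths) ≈ 50 bp, which
vanishes at kilobase rounding. Recovery on seeded 30× simulations is
exact (both breakpoints) in ≥ 19/20 replicates.

The junction PCR check performs exact-match primer search on both
strands and reports a product iff a forward/reverse-facing pair spans
≤ 5 kb; the packaged layout places a 460-bp product across the tandem
junction and no product on the single-copy reference.

## Haplotype assignment

S haplotypes are clustered by exact sequence identity (clusters ordered
by size, then representative sequence, making the partition input-order
free). The assignment cascade then labels D(S) copies versus
single-copy S alleles; every label carries the rule that produced it:

1. haplotypes within a configurable tolerance (default 1 mismatch) of a
   known reference D(S) take that allele's name — within-dataset
   clustering stays at exact identity;
2. clusters shared by ≥ 2 individuals become new D alleles, numbered in
   cluster-size order (duplications are enriched by both selection and
   the carrier-targeted sampling);
3. once one haplotype of a carrier is D-labelled, the other defaults to
   single-copy S (conservative: possible D_iD_j heterozygotes are
   under-counted, never over-counted);
4. an independent copy number of 4 overrides the default to a D_kD_m
   call; contradictory copy information is surfaced as a conflict;
5. a copy number of 3 pins the weaker-supported haplotype (reference
   match, then carrier count; evidence ties stay unresolved) as the
   single-copy S, and that sequence propagates: identical haplotypes
   elsewhere are single-copy S too, which in turn pins their partner
   haplotypes as possibly new D(S) copies — iterated to a fixed point;
6. carriers whose two S haplotypes are both singletons with no copy
   information stay "undetermined", still counting one new D allele
   with its D(S) unassigned.

The inferred D count is the number of distinct D labels actually
assigned plus one per undetermined carrier. On simulated populations
this construction is conservative (inferred ≤ true), recovers every
multi-carrier D allele, is invariant to input permutation up to label
renaming, and never loses alleles when copy-number information is
added — all property-tested.

Diversity statistics: the distinct-vs-repeated haplotype comparison
between two groups is a 2×2 χ² with Yates continuity correction
(df = 1) — the construal under which the published comparison of 9/29
distinct D(S) versus 17/27 distinct S yields χ² = 4.5, p = 0.03 — and
is cross-checked against an independent library implementation over all
small tables. Divergence *d* is the uncorrected mean pairwise
p-distance with gap columns excluded pairwise, stratified by a
caller-supplied exon mask (the fragment's true exon boundaries are not
published; the generator's default mask is 0–180, 360–600, 720–817).

## Orchestration and problem sizes

Pipeline runs are configured as YAML stage lists; every stochastic
stage receives a seed derived deterministically from the global seed,
and a manifest records parameters, seeds and SHA-256 checksums of all
outputs (fixed config ⇒ byte-identical re-runs). Simulation-backed
checks use 20 seeded replicates at 30× over the 400-kb frame, and
parameter-recovery checks use N = 10,000 phenotyped individuals —
sizes at which the stochastic targets (fold 1.5/2.0, 203-kb insert
median, exact breakpoints) are stable from run to run while a full
suite completes in minutes.

## Known limitations

- The annealing schedule is a reconstruction; exactness is anchored to
  the closed-form oracles rather than to any particular optimiser
  trajectory.
- Boundary p-values use plain χ²₁ (see above); support limits depend
  mildly on the ΔL = 1.92 convention, exposed as a parameter.
- The read simulator emits no duplicate, multi-mapping, or erroneous
  reads, so the duplication caller's thresholds (min_fold = 1.25,
  soft-clip support) are validated for clean data only.
- Assignment operates on exact identity; real chromatogram or
  long-read data would first need error correction/consensus, which is
  out of scope here (phased haplotypes are an input).
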