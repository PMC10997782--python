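"""Seeded generators for every input the pipeline consumes.

Three generators emulate the study's data-producing processes:

* :func:`simulate_phenotype_counts` — multinomial sampling of diploid
  genotypes under Hardy-Weinberg equilibrium, mapped through the
  PCR-RFLP phenotype classes;
* :func:`simulate_haplotype_population` — a population of phased ace-1
  haplotypes with the characteristic D(S)-cluster structure: one shared
  R haplotype, one fixed D(S) haplotype per duplicated allele, and
  independently mutated single-copy S alleles, with intronic sites
  mutating faster than (third-position) exonic sites;
* :func:`simulate_duplication_alignments` — paired-end alignments over a
  planted 203-kb tandem duplication, written as an aligner would place
  them against the non-duplicated reference: inflated depth inside the
  interval, soft-clipped reads at the junction coordinates and
  junction-straddling pairs with apparent insert close to the amplicon
  size.

The read simulator is deliberately alignment-level (it emits records as
bwa-mem would place them rather than running an aligner on raw
sequence): the mapping of a tandem-duplicated haplotype onto a
single-copy reference is deterministic, and keeping it in-process makes
every dataset reproducible from a single integer seed.

Every generator returns its ground truth alongside the dataset so that
downstream callers can be scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pysam

from .allele_model import AlleleSpec, enumerate_genotypes, phenotype_of, phenotype_partition
from .freq_inference import CountTable
from .hap_diversity import HaplotypeRecord

BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def load_d1_architecture() -> dict:
    """The packaged D1 duplication fixture: breakpoints, amplicon size,
    ace-1 interval and junction-PCR layout (2R coordinates, 1-based)."""
    with resources.files("acedup.data").joinpath("d1_architecture.json").open() as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# phenotype counts

@dataclass
class PhenotypeSimTruth:
    freqs: dict[str, float]
    genotype_counts: dict[str, int]


def simulate_phenotype_counts(
    freqs: Mapping[str, float] | Sequence[float],
    model: Sequence[AlleleSpec],
    d1_test: bool,
    N: int,
    seed: int,
    population: str = "sim",
    year: int = 0,
) -> tuple[CountTable, PhenotypeSimTruth]:
    """Draw N diploid genotypes i.i.d. under panmixia and phenotype them."""
    model = list(model)
    if isinstance(freqs, Mapping):
        fvec = np.array([float(freqs[a.name]) for a in model])
    else:
        fvec = np.asarray(freqs, dtype=float)
    if np.any(fvec < 0) or abs(fvec.sum() - 1.0) > 1e-9:
        raise ValueError("allele frequencies must be a simplex")
    fmap = {a.name: f for a, f in zip(model, fvec)}
    genotypes = enumerate_genotypes(model)
    probs = np.array([g.hwe_weight * fmap[g.a.name] * fmap[g.b.name] for g in genotypes])
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(N, probs) if N > 0 else np.zeros(len(probs), dtype=int)
    counts = {cls: 0 for cls in phenotype_partition(d1_test)}
    for g, n in zip(genotypes, draws):
        counts[phenotype_of(g, d1_test)] += int(n)
    table = CountTable(population, year, counts)
    truth = PhenotypeSimTruth(
        freqs={a.name: float(f) for a, f in zip(model, fvec)},
        genotype_counts={g.name: int(n) for g, n in zip(genotypes, draws) if n > 0},
    )
    return table, truth


# ---------------------------------------------------------------------------
# haplotype populations

@dataclass
class HaplotypeSimConfig:
    """Population of triple-peak (duplication-carrying) individuals.

    Defaults emulate the study conditions: 28 carriers typed over an
    817-bp aligned fragment, 9 distinct D alleles with a skewed carrier
    distribution (the two major alleles account for most D sequences),
    one duplication homozygote, independently mutated single-copy S
    alleles, and intron sites diverging roughly 3x faster than exon
    sites (where substitutions are confined to third codon positions);
    the default rates give expected pairwise divergences near 0.008
    (exons) and 0.027 (introns).
    """

    seed: int = 0
    locus_length: int = 817
    exon_intervals: tuple[tuple[int, int], ...] = ((0, 180), (360, 600), (720, 817))
    g119s_position: int = 100              # exonic site carrying the R substitution
    n_individuals: int = 28
    n_d_alleles: int = 9
    d_allele_weights: tuple[float, ...] = (11, 8, 3, 2, 1, 1, 1, 1, 1)
    n_dd_individuals: int = 1
    #: None (default): every single-copy S allele is an independent
    #: mutant, so S haplotypes are effectively unique per carrier; an
    #: integer instead draws carriers' S alleles from a finite pool of
    #: that size (allowing repeated S alleles across individuals)
    n_s_alleles: int | None = None
    #: substitution prob per lineage at mutable sites; exonic mutations
    #: hit third codon positions only, so the effective per-exon-site
    #: rate is exon_rate / 3 and pairwise divergences land near
    #: d_exons = 0.008 and d_introns = 0.027
    exon_rate: float = 0.012
    intron_rate: float = 0.0135

    def exon_mask(self) -> np.ndarray:
        mask = np.zeros(self.locus_length, dtype=bool)
        for a, b in self.exon_intervals:
            mask[a:b] = True
        return mask


@dataclass
class HaplotypeSimTruth:
    ds_sequences: dict[str, str]           # D allele name -> D(S) sequence
    s_sequences: list[str]                 # single-copy S allele pool
    genotypes: dict[str, str]              # individual -> e.g. "D2S", "D2D3"
    copy_numbers: dict[str, int]           # individual -> total ace-1 copies


def _mutate(
    seq: np.ndarray,
    cfg: HaplotypeSimConfig,
    rng: np.random.Generator,
    protected: np.ndarray | None = None,
) -> np.ndarray:
    """One lineage: exonic substitutions restricted to third codon
    positions (synonymous-coded), intronic sites free; the G119S site and
    any ``protected`` sites never mutate in the background process."""
    out = seq.copy()
    mask = cfg.exon_mask()
    exon_third = np.zeros(cfg.locus_length, dtype=bool)
    for a, b in cfg.exon_intervals:
        idx = np.arange(a, b)
        exon_third[idx[(idx - a) % 3 == 2]] = True
    p = np.where(exon_third, cfg.exon_rate, np.where(mask, 0.0, cfg.intron_rate))
    p[cfg.g119s_position] = 0.0
    if protected is not None:
        p[protected] = 0.0
    hits = np.nonzero(rng.random(cfg.locus_length) < p)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != out[i]]
        out[i] = choices[rng.integers(3)]
    return out


def simulate_haplotype_population(
    cfg: HaplotypeSimConfig,
) -> tuple[list[HaplotypeRecord], HaplotypeSimTruth]:
    """Generate phased haplotypes for a set of duplication carriers.

    One R haplotype is shared by every resistance copy (a single R
    sequence segregates in the species); each D allele owns one fixed
    D(S) haplotype shared by all its carriers; single-copy S alleles are
    drawn from a pool of independent mutants.  Every carrier therefore
    shows three haplotypes (R + two distinct S) and a triple-peak signal
    whenever the two S haplotypes differ from each other somewhere the R
    differs too.
    """
    rng = np.random.default_rng(cfg.seed)
    ancestral = BASES[rng.integers(4, size=cfg.locus_length)]
    if not cfg.exon_mask()[cfg.g119s_position]:
        raise ValueError("g119s_position must be exonic")
    ancestral[cfg.g119s_position] = "G"

    # The R lineage is its own diverged haplotype, not the susceptible
    # ancestor plus G119S: the triple-peak signal of a duplication
    # carrier needs positions where the R haplotype differs from the
    # ancestral base AND the carrier's two S haplotypes differ from each
    # other.  One intronic diagnostic site per D allele (R and the D(S)
    # copy each carrying a distinct non-ancestral base) plants that
    # signal explicitly, mirroring the SNP differences the assay relies
    # on in real chromatograms.
    intron_sites = np.nonzero(~cfg.exon_mask())[0]
    # with a degenerate zero-rate model every lineage collapses onto the
    # ancestral sequence, diagnostic sites included
    plant_diagnostics = cfg.intron_rate > 0 or cfg.exon_rate > 0
    diag_sites = rng.choice(intron_sites, size=cfg.n_d_alleles, replace=False)
    r_hap = _mutate(ancestral, cfg, rng, protected=diag_sites)
    r_hap[cfg.g119s_position] = "A"        # the G119S substitution (AluI site)

    weights = np.asarray(cfg.d_allele_weights, dtype=float)
    if len(weights) != cfg.n_d_alleles:
        raise ValueError("d_allele_weights length must equal n_d_alleles")
    weights = weights / weights.sum()
    ds_seqs = {}
    for k in range(cfg.n_d_alleles):
        hap = _mutate(ancestral, cfg, rng, protected=diag_sites)
        if plant_diagnostics:
            site = int(diag_sites[k])
            anc_b = ancestral[site]
            r_b = [b for b in "ACGT" if b != anc_b][int(rng.integers(3))]
            r_hap[site] = r_b
            hap[site] = [b for b in "ACGT" if b not in (anc_b, r_b)][int(rng.integers(2))]
        ds_seqs[f"D{k + 1}"] = "".join(hap)
    r_seq = "".join(r_hap)
    s_pool = (
        ["".join(_mutate(ancestral, cfg, rng, protected=diag_sites)) for _ in range(cfg.n_s_alleles)]
        if cfg.n_s_alleles is not None
        else None
    )
    s_drawn: list[str] = []

    records: list[HaplotypeRecord] = []
    truth = HaplotypeSimTruth(ds_sequences=ds_seqs, s_sequences=[], genotypes={}, copy_numbers={})
    d_names = list(ds_seqs)
    for i in range(cfg.n_individuals):
        ind = f"Sim-{i + 1:02d}"
        is_dd = i < cfg.n_dd_individuals
        d1_name = d_names[rng.choice(cfg.n_d_alleles, p=weights)]
        if is_dd:
            others = [k for k in range(cfg.n_d_alleles) if d_names[k] != d1_name]
            w = weights[others] / weights[others].sum()
            d2_name = d_names[others[rng.choice(len(others), p=w)]]
            s1, s2 = ds_seqs[d1_name], ds_seqs[d2_name]
            truth.genotypes[ind] = "".join(sorted((d1_name, d2_name)))
            truth.copy_numbers[ind] = 4
        else:
            s1 = ds_seqs[d1_name]
            if s_pool is not None:
                s2 = s_pool[rng.integers(cfg.n_s_alleles)]
            else:
                s2 = "".join(_mutate(ancestral, cfg, rng, protected=diag_sites))
                s_drawn.append(s2)
            truth.genotypes[ind] = f"{d1_name}S"
            truth.copy_numbers[ind] = 3
        d1_ref = ds_seqs.get("D1")
        records.append(HaplotypeRecord(ind, "R", r_seq, "R", False))
        records.append(HaplotypeRecord(ind, "S1", s1, "S", s1 == d1_ref))
        records.append(HaplotypeRecord(ind, "S2", s2, "S", s2 == d1_ref))
    truth.s_sequences = s_pool if s_pool is not None else s_drawn
    return records, truth


# ---------------------------------------------------------------------------
# duplication alignments

@dataclass
class DuplicationSimConfig:
    """Paired-end alignment simulation over a planted tandem duplication.

    Coordinates are 1-based inclusive in the reference frame of the 2R
    chromosome; defaults plant the packaged D1 amplicon (202,910 bp,
    breakpoints 3,436,927 / 3,639,836) inside a 400-kb window, sequenced
    at 30x with 150-bp reads and 350 +/- 50 bp inserts.  ``copies`` gives
    the amplicon copy count of each of the two haplotypes: (1, 1) is a
    non-duplicated SS individual, (2, 1) a DS heterozygote (3 total
    copies), (2, 2) a DD homozygote (4 copies).
    """

    seed: int = 0
    reference_name: str = "2R"
    region_start: int = 3_340_001
    region_end: int = 3_740_000
    dup_start: int = 3_436_927
    dup_end: int = 3_639_836
    copies: tuple[int, ...] = (2, 1)
    read_length: int = 150
    insert_mean: float = 350.0
    insert_sd: float = 50.0
    depth: float = 30.0

    def __post_init__(self) -> None:
        if not (self.region_start <= self.dup_start < self.dup_end <= self.region_end):
            raise ValueError("duplication interval must lie within the simulated region")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if len(self.copies) != 2 or any(c < 1 for c in self.copies):
            raise ValueError("copies must give >= 1 amplicon count per haplotype")

    @property
    def region_length(self) -> int:
        return self.region_end - self.region_start + 1

    @property
    def amplicon_size(self) -> int:
        return self.dup_end - self.dup_start + 1

    @classmethod
    def from_fixture(cls, seed: int = 0, copies: tuple[int, int] = (2, 1), **overrides) -> "DuplicationSimConfig":
        fx = load_d1_architecture()
        return cls(
            seed=seed,
            reference_name=fx["reference"],
            region_start=fx["region"]["start"],
            region_end=fx["region"]["end"],
            dup_start=fx["breakpoints"]["five_prime"],
            dup_end=fx["breakpoints"]["three_prime"],
            copies=copies,
            **overrides,
        )


@dataclass
class AlignmentSimTruth:
    breakpoints: tuple[int, int]
    amplicon_size: int
    copies: tuple[int, ...]
    total_copies: int
    n_pairs: int


def synthetic_reference(cfg: DuplicationSimConfig) -> str:
    """The region's reference sequence, reproducible from the seed alone
    (drawn from a sub-stream so read sampling does not perturb it)."""
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(2)[0])
    return "".join(BASES[rng.integers(4, size=cfg.region_length)])


def duplicated_haplotype(refseq: str, cfg: DuplicationSimConfig, copies: int) -> str:
    """The true sequence of a haplotype with ``copies`` tandem amplicons."""
    s5 = cfg.dup_start - cfg.region_start          # 0-based inclusive
    e3 = cfg.dup_end - cfg.region_start + 1        # 0-based exclusive
    return refseq[:e3] + refseq[s5:e3] * (copies - 1) + refseq[e3:]


def _map_hap_to_ref(h: int, s5: int, e3: int, copies: int) -> int:
    """0-based haplotype coordinate -> 0-based reference coordinate."""
    A = e3 - s5
    if h < e3:
        return h
    extra = h - e3
    k, within = divmod(extra, A)
    if k < copies - 1:
        return s5 + within
    return h - (copies - 1) * A


def simulate_duplication_alignments(
    cfg: DuplicationSimConfig, out_sam: str
) -> AlignmentSimTruth:
    """Write a sorted SAM of paired-end reads over the planted duplication.

    Fragments are drawn uniformly from each haplotype's true (tandem-
    duplicated) sequence and their reads are placed against the
    non-duplicated reference the way an aligner would: reads inside the
    amplicon pile up at depth scaled by total copies / 2; a read crossing
    the amplicon junction keeps its longer segment aligned and the
    remainder soft-clipped exactly at a breakpoint; a pair straddling the
    junction maps with an apparent template length close to the amplicon
    size.
    """
    rng = np.random.default_rng(cfg.seed)
    refseq = synthetic_reference(cfg)
    s5 = cfg.dup_start - cfg.region_start
    e3 = cfg.dup_end - cfg.region_start + 1
    A = e3 - s5
    rl = cfg.read_length
    chrom_off = cfg.region_start - 1               # local 0-based -> chrom 0-based

    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": cfg.reference_name, "LN": cfg.region_end}],
            "PG": [{"ID": "acedup-sim", "PN": "acedup-sim"}],
        }
    )
    records: list[tuple[int, "pysam.AlignedSegment"]] = []
    qual = pysam.qualitystring_to_array("I" * rl)
    n_pairs_total = 0

    for hap_idx, copies in enumerate(cfg.copies):
        hapseq = duplicated_haplotype(refseq, cfg, copies)
        L = len(hapseq)
        junctions = [e3 + k * A for k in range(copies - 1)]
        n_pairs = int(round(L * (cfg.depth / 2.0) / (2.0 * rl)))
        n_pairs_total += n_pairs
        inserts = np.maximum(rl, np.rint(rng.normal(cfg.insert_mean, cfg.insert_sd, n_pairs)).astype(int))
        inserts = np.minimum(inserts, L)
        starts = (rng.random(n_pairs) * (L - inserts + 1)).astype(int)

        def place(h0: int) -> tuple[int, list[tuple[int, int]], int]:
            """Alignment of read [h0, h0+rl): (ref_pos0, cigar, aligned_end0)."""
            cross = [j for j in junctions if h0 < j < h0 + rl]
            if not cross:
                p = _map_hap_to_ref(h0, s5, e3, copies)
                return p, [(0, rl)], p + rl  # 150M
            j = cross[0]
            len1 = j - h0
            len2 = rl - len1
            if len1 >= len2:
                p = _map_hap_to_ref(h0, s5, e3, copies)
                return p, [(0, len1), (4, len2)], p + len1
            return s5, [(4, len1), (0, len2)], s5 + len2

        for i in range(n_pairs):
            h1, ins = int(starts[i]), int(inserts[i])
            h2 = h1 + ins - rl
            p1, cig1, end1 = place(h1)
            p2, cig2, end2 = place(h2)
            left_start = min(p1, p2)
            right_end = max(end1, end2)
            span = right_end - left_start
            proper = abs(span - cfg.insert_mean) <= 10 * cfg.insert_sd and p1 <= p2

            for mate, (h0, p, cig, end, pnext, is_read2) in enumerate(
                (
                    (h1, p1, cig1, end1, p2, False),
                    (h2, p2, cig2, end2, p1, True),
                )
            ):
                a = pysam.AlignedSegment(header)
                a.query_name = f"sim{hap_idx}_{i}"
                a.reference_id = 0
                a.reference_start = chrom_off + p
                a.mapping_quality = 60
                a.cigartuples = cig
                a.query_sequence = hapseq[h0 : h0 + rl]
                a.query_qualities = qual
                flag = 0x1 | 0x40 if not is_read2 else 0x1 | 0x80
                if proper:
                    flag |= 0x2
                if is_read2:
                    flag |= 0x10
                else:
                    flag |= 0x20
                a.flag = flag
                a.next_reference_id = 0
                a.next_reference_start = chrom_off + pnext
                tlen = span if p == left_start else -span
                if p == pnext == left_start and is_read2:
                    tlen = -span
                a.template_length = tlen
                records.append((a.reference_start, a))

    records.sort(key=lambda t: t[0])
    with pysam.AlignmentFile(out_sam, "w", header=header) as fh:
        for _, a in records:
            fh.write(a)
    return AlignmentSimTruth(
        breakpoints=(cfg.dup_start, cfg.dup_end),
        amplicon_size=cfg.amplicon_size,
        copies=tuple(cfg.copies),
        total_copies=int(sum(cfg.copies)),
        n_pairs=n_pairs_total,
    )


def junction_primers(
    refseq: str, cfg: DuplicationSimConfig, product_size: int = 460, primer_length: int = 20
) -> tuple[str, str]:
    """Primer pair whose product spans the amplicon junction.

    The forward primer anneals near the 3' end of the amplicon, the
    reverse primer (reverse complement) near its 5' start; on a tandem-
    duplicated haplotype they face each other across the junction and
    amplify ``product_size`` bp, while on the single-copy reference the
    reverse binding site lies ~200 kb upstream of the forward one and no
    product forms.
    """
    half = product_size // 2
    s5 = cfg.dup_start - cfg.region_start
    e3 = cfg.dup_end - cfg.region_start + 1
    fwd = refseq[e3 - half : e3 - half + primer_length]
    rev = revcomp(refseq[s5 + (product_size - half) - primer_length : s5 + (product_size - half)])
    return fwd, rev
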