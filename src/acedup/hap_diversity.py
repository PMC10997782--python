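"""Haplotype diversity and D(S)-copy assignment for *ace-1* duplications.

Each heterogeneous duplication (D allele) couples one resistant copy,
D(R), with a susceptible copy, D(S), on the same chromosome.  All
resistant haplotypes recovered in *An. gambiae s.l.* are identical, so D
alleles can only be told apart by their D(S) copy.  Given the phased
haplotypes of "triple-peak" individuals (those whose mixed PCR product
shows three bases at some position, hence at least three haplotypes and
therefore a duplication), this module:

* detects triple-peak positions,
* clusters susceptible haplotypes by exact sequence identity,
* applies a conservative rule cascade to decide which haplotype of each
  carrier is the D(S) copy and which is a single-copy S allele, using
  reference D(S) sequences and (when available) per-individual total
  copy number from whole-genome coverage,
* computes the diversity statistics (distinct-haplotype contingency
  test, mean pairwise divergence by exon/intron stratum, expected
  heterozygote frequencies under panmixia).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import chi2

GAP_CHARS = set("-.Nn")


@dataclass
class HaplotypeRecord:
    """One phased *ace-1* haplotype of one individual.

    ``copy_label`` is the per-individual arbitrary tag (S1, S2 or R);
    ``resistance_class`` is R iff the haplotype carries G119S.
    """

    individual: str
    copy_label: str
    sequence: str
    resistance_class: str = "S"
    avaI_positive: bool = False

    @property
    def hap_id(self) -> str:
        return f"{self.individual}-{self.copy_label}"


@dataclass
class Assignment:
    label: str            # "D1(S)", "D2(S)", ..., "S", or "unassigned"
    rule: str             # which rule of the cascade produced the label


@dataclass
class AssignmentState:
    records: list[HaplotypeRecord]
    clusters: list[list[str]] = field(default_factory=list)        # hap_ids, deterministic order
    labels: dict[str, Assignment] = field(default_factory=dict)    # hap_id -> assignment
    genotype_calls: dict[str, str] = field(default_factory=dict)   # individual -> call
    copy_number_info: dict[str, int] = field(default_factory=dict)
    n_d_alleles: int = 0
    conflicts: list[str] = field(default_factory=list)


def fasta_header(rec: HaplotypeRecord) -> str:
    flags = []
    if rec.resistance_class == "R":
        flags.append("R")
    if rec.avaI_positive:
        flags.append("avaI+")
    return f"{rec.individual}|{rec.copy_label}|{','.join(flags) or '-'}"


def parse_fasta_records(path) -> list[HaplotypeRecord]:
    """Read haplotypes from a multi-FASTA with individual|copy|flags headers."""
    from Bio import SeqIO

    out = []
    for sr in SeqIO.parse(str(path), "fasta"):
        parts = sr.id.split("|")
        ind = parts[0]
        copy = parts[1] if len(parts) > 1 else "S1"
        flags = parts[2].split(",") if len(parts) > 2 else []
        out.append(
            HaplotypeRecord(
                individual=ind,
                copy_label=copy,
                sequence=str(sr.seq).upper(),
                resistance_class="R" if "R" in flags else "S",
                avaI_positive="avaI+" in flags,
            )
        )
    return out


def write_fasta_records(records: Iterable[HaplotypeRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{fasta_header(rec)}\n{rec.sequence}\n")


# ---------------------------------------------------------------------------
# triple peaks & clustering

def detect_triple_peaks(haplotypes: Sequence[str]) -> list[int]:
    """Positions (0-based) where >= 3 distinct bases occur across one
    individual's haplotypes — the chromatogram signature of a duplication
    carrier.  With only two haplotypes a position can never show three
    bases, so standard heterozygotes are never flagged."""
    if len(haplotypes) < 2:
        raise ValueError("need at least two haplotypes")
    lengths = {len(h) for h in haplotypes}
    if len(lengths) != 1:
        raise ValueError("haplotypes must be aligned to equal length")
    arr = np.array([list(h.upper()) for h in haplotypes])
    out = []
    for pos in range(arr.shape[1]):
        col = {b for b in arr[:, pos] if b not in GAP_CHARS}
        if len(col) >= 3:
            out.append(pos)
    return out


def cluster_haplotypes(records: Sequence[HaplotypeRecord]) -> list[list[str]]:
    """Partition S-class haplotypes by exact sequence identity.

    Clusters are ordered by size (descending), ties broken by the
    lexicographically smallest sequence, so the partition is independent
    of input order.
    """
    groups: dict[str, list[str]] = defaultdict(list)
    for rec in records:
        if rec.resistance_class != "R":
            groups[rec.sequence].append(rec.hap_id)
    for ids in groups.values():
        ids.sort()
    return [
        groups[seq]
        for seq in sorted(groups, key=lambda s: (-len(groups[s]), s))
    ]


def _mismatches(a: str, b: str) -> int:
    if len(a) != len(b):
        return max(len(a), len(b))
    return sum(1 for x, y in zip(a, b) if x != y and x not in GAP_CHARS and y not in GAP_CHARS)


# ---------------------------------------------------------------------------
# assignment cascade

def assign_ds_copies(
    records: Sequence[HaplotypeRecord],
    reference_DS: Mapping[str, str] | None = None,
    copy_number_info: Mapping[str, int] | None = None,
    reference_tolerance: int = 1,
) -> AssignmentState:
    """Label D(S) copies vs single-copy S alleles by a deterministic cascade.

    The cascade (each label records the rule that produced it):

    1. *reference*: a haplotype within ``reference_tolerance`` mismatches
       of a known D(S) sequence (e.g. the canonical D1(S)) takes that
       allele's label.
    2. *cluster*: identical S haplotypes shared by several individuals
       are taken as D(S) copies of a new allele D_k (duplications are
       selected for and the sampling targeted D carriers, so shared
       haplotypes are most likely the duplicated ones); D_k indices
       follow cluster size, then representative sequence.
    3. *conservative default*: once one haplotype of an individual is
       D-labelled, the other defaults to single-copy S — the individual
       is called a D_kS heterozygote even when the second haplotype sits
       in another D cluster (it could be a D_kD_m heterozygote, but the
       data cannot show it).
    4. *four copies*: an independent total copy number of 4 overrides
       the default: both haplotypes are D(S) copies, call D_kD_m.
    5. *three copies*: a copy number of 3 forces exactly one D(S); the
       weaker-supported haplotype becomes the single-copy S, and its
       sequence is propagated: identical haplotypes in other individuals
       are single-copy S too, which in turn pins their partner haplotype
       as a (possibly new) D(S).
    6. *undetermined*: a carrier whose two S haplotypes are both
       singletons with no copy information gets genotype "undetermined";
       it still evidences one new D allele, whose D(S) stays unassigned.

    Contradictory copy information (e.g. 4 copies but a single S
    haplotype) is flagged in ``state.conflicts``, not silently dropped.
    """
    reference_DS = dict(reference_DS or {})
    copy_number_info = dict(copy_number_info or {})
    state = AssignmentState(records=list(records), copy_number_info=copy_number_info)
    s_records = [r for r in records if r.resistance_class != "R"]
    by_individual: dict[str, list[HaplotypeRecord]] = defaultdict(list)
    for r in s_records:
        by_individual[r.individual].append(r)
    for ind in by_individual:
        by_individual[ind].sort(key=lambda r: r.copy_label)

    clusters = cluster_haplotypes(records)
    state.clusters = clusters
    cluster_of: dict[str, int] = {}
    for ci, ids in enumerate(clusters):
        for hid in ids:
            cluster_of[hid] = ci
    seq_of = {r.hap_id: r.sequence for r in s_records}
    cluster_seq = [seq_of[ids[0]] for ids in clusters]
    n_individuals_in = [len({h.rsplit("-", 1)[0] for h in ids}) for ids in clusters]

    # rule 1: reference D(S) matches; rule 2: multi-individual clusters
    cluster_label: dict[int, str] = {}
    cluster_rule: dict[int, str] = {}
    used_names = set()
    for ref_name in sorted(reference_DS):
        ref_seq = reference_DS[ref_name]
        best = None
        for ci, cseq in enumerate(cluster_seq):
            mm = _mismatches(cseq, ref_seq)
            if mm <= reference_tolerance and (best is None or mm < best[1]):
                best = (ci, mm)
        if best is not None:
            cluster_label[best[0]] = ref_name
            cluster_rule[best[0]] = "reference"
            used_names.add(ref_name)
    next_k = 1
    for ci in range(len(clusters)):
        if ci in cluster_label or n_individuals_in[ci] < 2:
            continue
        while f"D{next_k}(S)" in used_names:
            next_k += 1
        cluster_label[ci] = f"D{next_k}(S)"
        cluster_rule[ci] = "cluster"
        used_names.add(cluster_label[ci])

    def support(hid: str) -> tuple[int, int, str]:
        """Evidence strength for the D-label of a haplotype (higher wins)."""
        ci = cluster_of[hid]
        ref = 1 if cluster_rule.get(ci) == "reference" else 0
        return (ref, n_individuals_in[ci], cluster_seq[ci])

    labels = state.labels
    forced_single: set[str] = set()   # sequences known to be single-copy S
    d_allele_names: set[str] = set(cluster_label.values())

    # first pass: copy-number-3 individuals settle which haplotype is S,
    # and propagate that sequence (rule 5); iterate to a fixed point
    changed = True
    while changed:
        changed = False
        for ind in sorted(by_individual):
            haps = by_individual[ind]
            if copy_number_info.get(ind) != 3 or len(haps) != 2:
                continue
            a, b = haps
            a_single = a.sequence in forced_single
            b_single = b.sequence in forced_single
            la = None if a_single else cluster_label.get(cluster_of[a.hap_id])
            lb = None if b_single else cluster_label.get(cluster_of[b.hap_id])
            if la and lb:
                # both D-labelled but only one D(S) possible: demote the
                # weaker-supported cluster (reference match, then carrier
                # count); an evidence tie stays unresolved here — the
                # conservative default settles it per individual
                sa, sb = support(a.hap_id)[:2], support(b.hap_id)[:2]
                if sa == sb:
                    continue
                weak = a if sa < sb else b
                if weak.sequence not in forced_single:
                    forced_single.add(weak.sequence)
                    changed = True
                continue
            if la or b_single:
                dhap, shap = a, b
            elif lb or a_single:
                dhap, shap = b, a
            else:
                continue  # no evidence either way yet
            if shap.sequence not in forced_single:
                forced_single.add(shap.sequence)
                changed = True
            ci = cluster_of[dhap.hap_id]
            if ci not in cluster_label:
                while f"D{next_k}(S)" in used_names:
                    next_k += 1
                cluster_label[ci] = f"D{next_k}(S)"
                cluster_rule[ci] = "copy-number-3"
                used_names.add(cluster_label[ci])
                d_allele_names.add(cluster_label[ci])
                changed = True

    # propagation of forced single-copy sequences to other carriers
    changed = True
    while changed:
        changed = False
        for ind in sorted(by_individual):
            haps = by_individual[ind]
            if len(haps) != 2:
                continue
            a, b = haps
            a_single = a.sequence in forced_single
            b_single = b.sequence in forced_single
            if a_single and not b_single:
                other = b
            elif b_single and not a_single:
                other = a
            else:
                continue
            ci = cluster_of[other.hap_id]
            if ci not in cluster_label:
                while f"D{next_k}(S)" in used_names:
                    next_k += 1
                cluster_label[ci] = f"D{next_k}(S)"
                cluster_rule[ci] = "propagated-single-copy"
                used_names.add(cluster_label[ci])
                d_allele_names.add(cluster_label[ci])
                changed = True

    # final per-individual labelling and genotype calls
    for ind in sorted(by_individual):
        haps = by_individual[ind]
        copies = copy_number_info.get(ind)
        if copies is not None and copies >= 4 and len(haps) < 2:
            state.conflicts.append(
                f"{ind}: reported {copies} ace-1 copies but only {len(haps)} S haplotype(s)"
            )
        if len(haps) == 1:
            hid = haps[0].hap_id
            lab = cluster_label.get(cluster_of[hid])
            labels[hid] = Assignment(lab or "unassigned", cluster_rule.get(cluster_of[hid], "viii"))
            state.genotype_calls[ind] = "undetermined"
            continue
        a, b = haps
        la = cluster_label.get(cluster_of[a.hap_id])
        lb = cluster_label.get(cluster_of[b.hap_id])
        a_single = a.sequence in forced_single
        b_single = b.sequence in forced_single
        if a_single:
            la = None
        if b_single:
            lb = None
        if copies == 4:
            if la and lb and la != lb:
                labels[a.hap_id] = Assignment(la, "copy-number-4")
                labels[b.hap_id] = Assignment(lb, "copy-number-4")
                state.genotype_calls[ind] = _dd_call(la, lb)
            elif la and lb:
                labels[a.hap_id] = Assignment(la, "copy-number-4")
                labels[b.hap_id] = Assignment(lb, "copy-number-4")
                state.genotype_calls[ind] = _dd_call(la, lb)
                state.conflicts.append(f"{ind}: 4 copies but both S haplotypes identical to {la}")
            else:
                # 4 copies force both to be D(S); unlabeled ones become new alleles
                for hap, lab in ((a, la), (b, lb)):
                    if lab is None:
                        ci = cluster_of[hap.hap_id]
                        while f"D{next_k}(S)" in used_names:
                            next_k += 1
                        cluster_label[ci] = f"D{next_k}(S)"
                        cluster_rule[ci] = "copy-number-4"
                        used_names.add(cluster_label[ci])
                        d_allele_names.add(cluster_label[ci])
                la = cluster_label[cluster_of[a.hap_id]]
                lb = cluster_label[cluster_of[b.hap_id]]
                labels[a.hap_id] = Assignment(la, "copy-number-4")
                labels[b.hap_id] = Assignment(lb, "copy-number-4")
                state.genotype_calls[ind] = _dd_call(la, lb)
            continue
        if la and lb:
            # conservative: keep the better-supported D, default the other to S
            if support(a.hap_id) >= support(b.hap_id):
                keep, drop = a, b
                lab = la
            else:
                keep, drop = b, a
                lab = lb
            labels[keep.hap_id] = Assignment(lab, cluster_rule[cluster_of[keep.hap_id]])
            labels[drop.hap_id] = Assignment("S", "conservative-default")
            state.genotype_calls[ind] = f"{lab.split('(')[0]}S"
        elif la or lb:
            dhap, shap, lab = (a, b, la) if la else (b, a, lb)
            labels[dhap.hap_id] = Assignment(lab, cluster_rule[cluster_of[dhap.hap_id]])
            srule = "forced-single-copy" if shap.sequence in forced_single else "conservative-default"
            labels[shap.hap_id] = Assignment("S", srule)
            state.genotype_calls[ind] = f"{lab.split('(')[0]}S"
        else:
            # both singletons, no copy info: one of them is a new D(S),
            # but which one cannot be decided
            labels[a.hap_id] = Assignment("unassigned", "undetermined-pair")
            labels[b.hap_id] = Assignment("unassigned", "undetermined-pair")
            state.genotype_calls[ind] = "undetermined"

    # count D alleles actually evidenced: distinct D labels in the final
    # assignments, plus one per undetermined carrier (it must hold a new
    # D allele even though its D(S) cannot be named)
    used_d = {a.label for a in labels.values() if a.label not in ("S", "unassigned")}
    n_undetermined = sum(
        1 for ind, call in state.genotype_calls.items() if call == "undetermined"
    )
    state.n_d_alleles = len(used_d) + n_undetermined
    return state


def _dd_call(la: str, lb: str) -> str:
    ka, kb = la.split("(")[0], lb.split("(")[0]
    ka, kb = sorted((ka, kb))
    return f"{ka}{kb}"


# ---------------------------------------------------------------------------
# diversity statistics

def distinct_count_test(k1: int, n1: int, k2: int, n2: int) -> tuple[float, int, float]:
    """Compare the proportion of distinct haplotypes between two groups.

    Builds the 2x2 table (distinct vs repeated) x (group1 vs group2) and
    applies the chi-square test with Yates continuity correction (df=1).
    Used to show that D(S) diversity is below the neutral expectation set
    by single-copy S alleles sampled from the same individuals.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if not 0 <= k <= n:
            raise ValueError("need 0 <= distinct <= total")
    O = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    E = np.outer(O.sum(axis=1), O.sum(axis=0)) / O.sum()
    if np.any(E == 0):
        return 0.0, 1, 1.0
    stat = float((((np.abs(O - E) - 0.5).clip(min=0) ** 2) / E).sum())
    return stat, 1, float(chi2.sf(stat, 1))


@dataclass
class DivergenceResult:
    d: float
    d_exons: float
    d_introns: float
    n_exon_sites: int
    n_intron_sites: int


def pairwise_divergence(
    records: Sequence[HaplotypeRecord] | Sequence[str],
    exon_mask: Sequence[bool],
) -> DivergenceResult:
    """Mean pairwise p-distance, overall and by exon/intron stratum.

    For every unordered pair of sequences the proportion of differing
    sites is computed over pairwise-comparable (non-gap) columns; strata
    follow ``exon_mask`` (True = exonic site).  The overall d is the
    site-count-weighted combination of the strata.  Uncorrected distances
    (no multiple-hit correction): divergences here are small.
    """
    seqs = [r.sequence if isinstance(r, HaplotypeRecord) else r for r in records]
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs) or len(exon_mask) != L:
        raise ValueError("sequences and mask must share one aligned length")
    arr = np.array([list(s.upper()) for s in seqs])
    gap = np.isin(arr, list(GAP_CHARS))
    mask = np.asarray(exon_mask, dtype=bool)

    sums = {True: 0.0, False: 0.0, "all": 0.0}
    npairs = 0
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            ok = ~gap[i] & ~gap[j]
            diff = (arr[i] != arr[j]) & ok
            for stratum, sel in ((True, mask), (False, ~mask)):
                n_ok = int((ok & sel).sum())
                if n_ok:
                    sums[stratum] += diff[sel].sum() / n_ok
            if ok.sum():
                sums["all"] += diff.sum() / ok.sum()
            npairs += 1
    return DivergenceResult(
        d=sums["all"] / npairs,
        d_exons=sums[True] / npairs,
        d_introns=sums[False] / npairs,
        n_exon_sites=int(mask.sum()),
        n_intron_sites=int((~mask).sum()),
    )


def expected_het_freq(f_i: float, f_j: float, same_allele: bool = False) -> float:
    """Expected genotype frequency under panmixia: 2 f_i f_j (f_i^2 if
    the two alleles are the same)."""
    for f in (f_i, f_j):
        if not 0.0 <= f <= 1.0:
            raise ValueError("frequencies must lie in [0, 1]")
    return f_i * f_j if same_allele else 2.0 * f_i * f_j


def assignment_table(state: AssignmentState) -> "pd.DataFrame":
    """TSV-ready table: individual, haplotype, label, rule, genotype call."""
    import pandas as pd

    rows = []
    for rec in state.records:
        if rec.resistance_class == "R":
            continue
        a = state.labels.get(rec.hap_id)
        rows.append(
            {
                "individual": rec.individual,
                "haplotype": rec.hap_id,
                "label": a.label if a else "unassigned",
                "rule": a.rule if a else "-",
                "genotype_call": state.genotype_calls.get(rec.individual, "undetermined"),
            }
        )
    return pd.DataFrame(rows)
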