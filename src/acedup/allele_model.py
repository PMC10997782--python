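"""Duplication-aware allele and genotype models for the *ace-1* locus.

The *ace-1* locus of *Anopheles gambiae s.l.* segregates single-copy
resistant (R, carrying G119S) and susceptible (S) alleles, homogeneous
duplications (R^x: several tandem R copies) and heterogeneous duplications
(D alleles: one resistant and one susceptible copy in tandem).  Two
PCR-RFLP tests phenotype individuals:

* the *ace-1* phenotype test (AluI) separates [RR] / [RS] / [SS];
* the D1 test (AvaI) flags carriers of the D1(S)-diagnostic sequence,
  splitting [RS] and [SS] into D1+ / D1- subclasses.

Because a D allele couples an R and an S copy on one chromosome, its
carriers type as [RS]; allele frequencies must therefore be inferred from
phenotype-class counts under panmixia rather than read off directly.  This
module encodes alleles as bags of copy classes, enumerates diploid
genotypes with their Hardy-Weinberg weights, and maps genotypes to
phenotype classes for any allele model.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import yaml

#: The three copy classes: R carries G119S (AluI site present), S_D1 is a
#: susceptible copy carrying the AvaI diagnostic site of the D1(S) copy,
#: S is any other susceptible copy.
COPY_CLASSES = ("R", "S", "S_D1")


@dataclass(frozen=True)
class AlleleSpec:
    """One allele: a multiset of ace-1 copy classes in tandem amplicons.

    ``amplicon_count`` is the number of tandem amplicons (1 for
    single-copy alleles, 2 for heterogeneous D alleles, x for R^x).
    """

    name: str
    copies: tuple[str, ...]
    amplicon_count: int = 1

    def __post_init__(self) -> None:
        if not self.copies:
            raise ValueError(f"allele {self.name!r} must carry >= 1 copy")
        bad = set(self.copies) - set(COPY_CLASSES)
        if bad:
            raise ValueError(f"unknown copy class(es) {sorted(bad)} in allele {self.name!r}")
        if len(self.copies) != self.amplicon_count:
            raise ValueError(
                f"allele {self.name!r}: {len(self.copies)} copies but "
                f"amplicon_count={self.amplicon_count}"
            )
        # multi-copy S alleles (S^x) are representable but nothing in the
        # default models instantiates them

    @property
    def is_duplication(self) -> bool:
        return self.amplicon_count > 1

    @property
    def has_resistant_copy(self) -> bool:
        return "R" in self.copies

    @property
    def has_susceptible_copy(self) -> bool:
        return any(c != "R" for c in self.copies)


@dataclass(frozen=True)
class Genotype:
    """Unordered pair of alleles with its Hardy-Weinberg weight.

    Under panmixia the genotype frequency is ``hwe_weight * f_i * f_j``
    (weight 1 for homozygotes, 2 for heterozygotes).
    """

    a: AlleleSpec
    b: AlleleSpec

    @property
    def hwe_weight(self) -> int:
        return 1 if self.a.name == self.b.name else 2

    @property
    def copies(self) -> tuple[str, ...]:
        return self.a.copies + self.b.copies

    @property
    def name(self) -> str:
        return f"{self.a.name}/{self.b.name}"


@dataclass(frozen=True, order=True)
class PhenotypeClass:
    """Resistance class plus (optional) D1-test status.

    ``resistance`` is one of ``RR``, ``RS``, ``SS``; ``d1_status`` is
    ``D1+``, ``D1-`` or ``untested``.  [RR] individuals carry no
    susceptible copy, so the D1 split never applies to them.
    """

    resistance: str
    d1_status: str = "untested"

    def __str__(self) -> str:
        if self.d1_status == "untested":
            return f"[{self.resistance}]"
        return f"[{self.resistance}, {self.d1_status}]"

    @classmethod
    def parse(cls, text: str) -> "PhenotypeClass":
        inner = text.strip().strip("[]")
        parts = [p.strip() for p in inner.split(",")]
        if len(parts) == 1:
            return cls(parts[0])
        return cls(parts[0], parts[1])


def phenotype_partition(d1_test: bool) -> tuple[PhenotypeClass, ...]:
    """The phenotype classes observable with / without the D1 test.

    Three classes without it; five with it ([RR] is never split).
    """
    if not d1_test:
        return tuple(PhenotypeClass(r) for r in ("RR", "RS", "SS"))
    return (
        PhenotypeClass("RR"),
        PhenotypeClass("RS", "D1+"),
        PhenotypeClass("RS", "D1-"),
        PhenotypeClass("SS", "D1+"),
        PhenotypeClass("SS", "D1-"),
    )


def enumerate_genotypes(alleles: Sequence[AlleleSpec]) -> list[Genotype]:
    """All k(k+1)/2 unordered diploid genotypes for k alleles.

    Every unordered pair is enumerated; the genotype-to-phenotype map is
    many-to-one, so enumerating pairs that later merge into one phenotype
    class leaves all class frequencies (and hence likelihoods) unchanged.
    """
    if not alleles:
        raise ValueError("allele list is empty")
    names = [a.name for a in alleles]
    if len(set(names)) != len(names):
        raise ValueError(f"allele names not unique: {names}")
    return [Genotype(a, b) for a, b in itertools.combinations_with_replacement(alleles, 2)]


def phenotype_of(genotype: Genotype, d1_test: bool = False) -> PhenotypeClass:
    """Map a genotype to the phenotype class the PCR-RFLP tests report.

    [RR] iff every copy across both alleles is R; [SS] iff no copy is R;
    [RS] otherwise (this is what makes D alleles invisible to the basic
    test).  With the D1 test, non-[RR] classes split on presence of at
    least one S_D1 copy, whether it sits on a D1 allele or on a
    single-copy S_D1 allele.
    """
    copies = genotype.copies
    n_r = sum(1 for c in copies if c == "R")
    if n_r == len(copies):
        resistance = "RR"
    elif n_r == 0:
        resistance = "SS"
    else:
        resistance = "RS"
    if not d1_test or resistance == "RR":
        return PhenotypeClass(resistance)
    return PhenotypeClass(resistance, "D1+" if "S_D1" in copies else "D1-")


def expected_phenotype_freqs(
    freqs: Mapping[str, float] | Sequence[float],
    model: Sequence[AlleleSpec],
    d1_test: bool = False,
    *,
    tol: float = 1e-9,
) -> dict[PhenotypeClass, float]:
    """Expected phenotype-class frequencies under Hardy-Weinberg.

    Each class frequency is the sum of ``hwe_weight * f_i * f_j`` over the
    genotypes mapping to it; the output sums to 1 whenever ``freqs`` does.
    """
    if isinstance(freqs, Mapping):
        fvec = [float(freqs[a.name]) for a in model]
    else:
        fvec = [float(x) for x in freqs]
        if len(fvec) != len(model):
            raise ValueError("freqs length does not match model")
    if any(f < -tol for f in fvec):
        raise ValueError("negative allele frequency")
    if abs(sum(fvec) - 1.0) > max(tol, 1e-9):
        raise ValueError(f"allele frequencies sum to {sum(fvec)}, not 1")
    fmap = {a.name: f for a, f in zip(model, fvec)}

    out: dict[PhenotypeClass, float] = {cls: 0.0 for cls in phenotype_partition(d1_test)}
    for g in enumerate_genotypes(list(model)):
        cls = phenotype_of(g, d1_test)
        out[cls] += g.hwe_weight * fmap[g.a.name] * fmap[g.b.name]
    return out


# ---------------------------------------------------------------------------
# canonical models (data-driven; see data/models.yaml for the shipped copy)

_DEFAULT_MODELS: dict[str, list[tuple[str, tuple[str, ...]]]] = {
    # basic phenotyping only: R, S and a generic heterogeneous duplication D
    "A": [("R", ("R",)), ("S", ("S",)), ("D", ("R", "S"))],
    # D1 test added: the D1 allele and the single-copy S_D1 allele become visible
    "B": [("R", ("R",)), ("S", ("S",)), ("S_D1", ("S_D1",)), ("D1", ("R", "S_D1"))],
    # at least one further heterogeneous duplication Di
    "C": [
        ("R", ("R",)),
        ("S", ("S",)),
        ("S_D1", ("S_D1",)),
        ("D1", ("R", "S_D1")),
        ("Di", ("R", "S")),
    ],
    # two-allele Hardy-Weinberg null (no duplication): the LRT baseline
    "RS": [("R", ("R",)), ("S", ("S",))],
}


def model_uses_d1_test(name: str) -> bool:
    """Models B and C are fitted to the five-class (D1-tested) partition."""
    return name.upper() in {"B", "C"}


def canonical_model(name: str) -> list[AlleleSpec]:
    """One of the built-in allele models: A, B, C or the RS null."""
    try:
        defs = _DEFAULT_MODELS[name.upper()]
    except KeyError:
        raise KeyError(f"unknown model {name!r}; expected one of {sorted(_DEFAULT_MODELS)}")
    return [AlleleSpec(n, c, len(c)) for n, c in defs]


def load_model(stream) -> list[AlleleSpec]:
    """Load an allele model from a YAML/JSON mapping.

    Format: ``alleles: [{name, copies, amplicon_count?}, ...]`` — allele
    definitions are data, so new models (e.g. an R^2 distinct from R) can
    be expressed without code changes.
    """
    doc = yaml.safe_load(stream)
    entries = doc["alleles"] if isinstance(doc, Mapping) else doc
    out = []
    for e in entries:
        copies = tuple(e["copies"])
        out.append(AlleleSpec(e["name"], copies, int(e.get("amplicon_count", len(copies)))))
    return out


def genotype_phenotype_table(model: Sequence[AlleleSpec], d1_test: bool) -> list[tuple[str, int, str]]:
    """(genotype name, HWE weight, phenotype) rows — the Fig-style grid."""
    return [
        (g.name, g.hwe_weight, str(phenotype_of(g, d1_test)))
        for g in enumerate_genotypes(list(model))
    ]
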