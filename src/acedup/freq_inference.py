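"""Maximum-likelihood allele-frequency inference from phenotype counts.

Given phenotype-class counts n_i for one population sample and an allele
model, the multinomial log-likelihood of allele frequencies f (via the
Hardy-Weinberg genotype frequencies and the genotype-to-phenotype map) is

    L(f) = sum_i n_i ln p_i(f)

with p_i the predicted frequency of phenotype class i.  L is maximised on
the simplex with a simulated-annealing search followed by a
derivative-free polish; support limits (profile-likelihood intervals,
equivalent to 95% confidence intervals) and likelihood-ratio tests
between nested allele models complete the inference.

For saturated models (free parameters = data degrees of freedom) the
class frequencies are fitted exactly and invert algebraically;
:func:`saturated_closed_form` provides those solutions and anchors the
numerical optimiser in the test-suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import chi2

from .allele_model import (
    AlleleSpec,
    PhenotypeClass,
    expected_phenotype_freqs,
    phenotype_partition,
)

NEG_INF = float("-inf")


@dataclass
class CountTable:
    """Observed phenotype-class counts for one population x year sample."""

    population: str
    year: int
    counts: dict[PhenotypeClass, int]

    def __post_init__(self) -> None:
        for cls, n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative count for {cls}")
        keys = tuple(sorted(self.counts))
        for d1 in (False, True):
            if keys == tuple(sorted(phenotype_partition(d1))):
                self.d1_test = d1
                break
        else:
            raise ValueError(f"counts keys {list(map(str, keys))} are not a 3- or 5-class partition")

    @property
    def N(self) -> int:
        return sum(self.counts.values())

    def vector(self, partition: Sequence[PhenotypeClass]) -> np.ndarray:
        return np.array([self.counts[c] for c in partition], dtype=float)

    def saturated_logL(self) -> float:
        """Upper bound: the saturated multinomial log-likelihood sum n ln(n/N)."""
        N = self.N
        return sum(n * math.log(n / N) for n in self.counts.values() if n > 0)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> list["CountTable"]:
        """Parse long-format CSV rows: population, year, phenotype_class, count."""
        tables = []
        for (pop, year), grp in df.groupby(["population", "year"], sort=False):
            counts = {
                PhenotypeClass.parse(r.phenotype_class): int(r.count)
                for r in grp.itertuples()
            }
            tables.append(cls(str(pop), int(year), counts))
        return tables

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "population": self.population,
                "year": self.year,
                "phenotype_class": [str(c) for c in self.counts],
                "count": list(self.counts.values()),
            }
        )


@dataclass
class MLResult:
    model: list[AlleleSpec]
    freqs: dict[str, float]
    logL: float
    support_limits: dict[str, tuple[float, float]] = field(default_factory=dict)
    d1_test: bool | None = None          # phenotype partition the fit used
    seed: int | None = None
    n_restarts: int = 0
    converged: bool = True

    def freq_vector(self) -> np.ndarray:
        return np.array([self.freqs[a.name] for a in self.model])


@dataclass
class LRTResult:
    statistic: float
    df: int
    p_value: float


def log_likelihood(
    table: CountTable,
    freqs: Mapping[str, float] | Sequence[float],
    model: Sequence[AlleleSpec],
    d1_test: bool,
) -> float:
    """Multinomial log-likelihood L = sum_i n_i ln p_i of allele freqs.

    Classes with n = 0 contribute nothing even when their predicted
    frequency is 0; a class with n > 0 but predicted frequency 0 returns
    the -inf sentinel.
    """
    if d1_test != table.d1_test:
        raise ValueError("phenotype partition of table does not match d1_test flag")
    expected = expected_phenotype_freqs(freqs, model, d1_test)
    L = 0.0
    for cls, n in table.counts.items():
        if n == 0:
            continue
        p = expected[cls]
        if p <= 0.0:
            return NEG_INF
        L += n * math.log(p)
    return L


# ---------------------------------------------------------------------------
# optimisation

class _ModelKernel:
    """Precomputed genotype->phenotype weight tensor for fast likelihoods.

    W[c, i, j] holds the HWE weight of the (i, j) allele pair if that
    genotype maps to class c, so class probabilities are the quadratic
    form einsum('cij,i,j->c', W, f, f).  Equivalent to
    :func:`~acedup.allele_model.expected_phenotype_freqs` (tested), but
    ~100x faster inside the optimiser.
    """

    def __init__(self, model: Sequence[AlleleSpec], d1_test: bool):
        from .allele_model import enumerate_genotypes, phenotype_of

        self.model = list(model)
        self.d1_test = d1_test
        self.partition = phenotype_partition(d1_test)
        idx = {c: ci for ci, c in enumerate(self.partition)}
        k = len(self.model)
        pos = {a.name: i for i, a in enumerate(self.model)}
        W = np.zeros((len(self.partition), k, k))
        for g in enumerate_genotypes(self.model):
            c = idx[phenotype_of(g, d1_test)]
            i, j = pos[g.a.name], pos[g.b.name]
            W[c, i, j] += g.hwe_weight
        self.W = W

    def class_probs(self, fvec: np.ndarray) -> np.ndarray:
        return np.einsum("cij,i,j->c", self.W, fvec, fvec)

    def nll(self, fvec: np.ndarray, nvec: np.ndarray) -> float:
        p = self.class_probs(fvec)
        mask = nvec > 0
        if np.any(p[mask] <= 0):
            return 1e300  # finite sentinel keeps Nelder-Mead arithmetic clean
        return -float(np.sum(nvec[mask] * np.log(p[mask])))


def _softplus_simplex(x: np.ndarray) -> np.ndarray:
    # normalized softplus: smooth, surjective onto the open simplex,
    # well-behaved when the optimum sits on the boundary
    s = np.logaddexp(0.0, x)
    return s / s.sum()


def _anneal(nll, k, rng, t0=1.0, ratio=0.95, steps_per_temp=200, t_min=1e-3,
            concentration=60.0):
    """Simulated annealing on the simplex with Dirichlet-perturbation proposals."""
    f = rng.dirichlet(np.ones(k))
    best = cur = nll(f)
    best_f = f
    t = t0
    while t > t_min:
        for _ in range(steps_per_temp):
            prop = rng.dirichlet(f * concentration + 0.5)
            e = nll(prop)
            if e < cur or rng.random() < math.exp(-(e - cur) / t):
                f, cur = prop, e
                if e < best:
                    best, best_f = e, prop
        t *= ratio
    return best_f, best


def fit_ml(
    table: CountTable,
    model: Sequence[AlleleSpec],
    d1_test: bool,
    seed: int = 0,
    n_restarts: int = 3,
    compute_support_limits: bool = False,
    sl_delta: float = 1.92,
) -> MLResult:
    """Maximise the multinomial likelihood over allele frequencies.

    Simulated annealing (geometric cooling, T0=1, ratio 0.95, 200 steps
    per temperature, Dirichlet proposals) explores the simplex from
    ``n_restarts`` starts; a Nelder-Mead polish on the normalized-softplus
    transform refines the incumbent.  Deterministic given ``seed``.
    """
    model = list(model)
    if len(model) < 2:
        raise ValueError("model must contain at least 2 alleles")
    if d1_test != table.d1_test:
        raise ValueError("phenotype partition of table does not match d1_test flag")
    kernel = _ModelKernel(model, d1_test)
    nvec = table.vector(kernel.partition)
    k = len(model)

    def nll(fvec):
        return kernel.nll(np.asarray(fvec, float), nvec)

    rng = np.random.default_rng(seed)
    best_f, best_e = None, math.inf
    for _ in range(max(1, n_restarts)):
        f, e = _anneal(nll, k, rng)
        if e < best_e:
            best_f, best_e = f, e

    # derivative-free polish on an unconstrained parameterization
    x0 = np.log(np.expm1(np.maximum(best_f, 1e-10)))
    res = minimize(
        lambda x: nll(_softplus_simplex(x)),
        x0,
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000, "maxfev": 20000},
    )
    converged = bool(res.success) or res.fun <= best_e + 1e-9
    if res.fun < best_e:
        best_f, best_e = _softplus_simplex(res.x), float(res.fun)

    # frequencies are allowed to hit 0 exactly: snap tiny boundary values
    best_f = np.where(best_f < 1e-8, 0.0, best_f)
    best_f = best_f / best_f.sum()
    logL = -nll(best_f)
    result = MLResult(
        model=model,
        freqs={a.name: float(f) for a, f in zip(model, best_f)},
        logL=float(logL),
        d1_test=d1_test,
        seed=seed,
        n_restarts=n_restarts,
        converged=converged,
    )
    if not converged:
        raise RuntimeError("ML fit failed to converge after all restarts")
    if compute_support_limits:
        result.support_limits = support_limits(table, model, result, sl_delta)
    return result


def saturated_closed_form(
    table: CountTable, model: Sequence[AlleleSpec], d1_test: bool
) -> dict[str, float] | None:
    """Exact algebraic ML solutions for the canonical saturated models.

    Model A (R, S, D on three classes): r = sqrt(f[RR]), s = sqrt(f[SS]),
    d = 1 - r - s.  Model C (five alleles on five classes): additionally
    s1 from f[SS,D1+] = s1^2 + 2 s s1 and d1 from the [RS,D1+] class
    frequency d1(2 - d1 - ...) (see below); di is the remainder.  Returns
    ``None`` ("not invertible") when the model is not saturated for the
    table's partition or the solution leaves the simplex.
    """
    names = sorted(a.name for a in model)
    N = table.N
    f = {str(c): n / N for c, n in table.counts.items()}
    if not d1_test and names == ["D", "R", "S"]:
        r = math.sqrt(f["[RR]"])
        s = math.sqrt(f["[SS]"])
        d = 1.0 - r - s
        if d < -1e-12:
            return None
        return {"R": r, "S": s, "D": max(d, 0.0)}
    if d1_test and names == ["D1", "Di", "R", "S", "S_D1"]:
        r = math.sqrt(f["[RR]"])
        s = math.sqrt(f["[SS, D1-]"])
        # f[SS,D1+] = s1^2 + 2 s s1  ->  s1 = sqrt(s^2 + fSSp) - s
        s1 = math.sqrt(s * s + f["[SS, D1+]"]) - s
        # [RS,D1+] collects every genotype carrying both an R copy and an
        # S_D1 copy: D1 paired with anything, plus R/S_D1 and Di/S_D1:
        #   f = d1^2 + 2 d1 (r + s + s1 + di) + 2 s1 (r + di)
        #     = d1 (2 - d1) + 2 s1 (1 - s - s1 - d1)   [r + di = 1-s-s1-d1]
        # which is quadratic in d1:
        #   d1^2 - 2 (1 - s1) d1 + (f - 2 s1 (1 - s - s1)) = 0
        fRSp = f["[RS, D1+]"]
        disc = (1.0 - s1) ** 2 - fRSp + 2.0 * s1 * (1.0 - s - s1)
        if disc < 0:
            return None
        d1 = (1.0 - s1) - math.sqrt(disc)
        di = 1.0 - r - s - s1 - d1
        if di < -1e-12 or d1 < -1e-12:
            return None
        return {"R": r, "S": s, "S_D1": max(s1, 0.0), "D1": max(d1, 0.0), "Di": max(di, 0.0)}
    return None


def support_limits(
    table: CountTable,
    model: Sequence[AlleleSpec],
    mlresult: MLResult,
    delta_logL: float = 1.92,
    tol: float = 1e-4,
) -> dict[str, tuple[float, float]]:
    """Profile-likelihood support limits per allele.

    For each allele the frequency is fixed while the others are
    re-optimised on the reduced simplex; the limits are where the profile
    log-likelihood drops by ``delta_logL`` (1.92 = chi2(1, 0.95)/2, the
    conventional 95% interval), located by bisection and clipped to [0,1].
    """
    model = list(model)
    kernel = _ModelKernel(model, table.d1_test)
    nvec = table.vector(kernel.partition)
    names = [a.name for a in model]
    fhat = mlresult.freq_vector()
    Lhat = mlresult.logL
    target = Lhat - delta_logL

    def profile(i: int, value: float) -> float:
        """Max log-likelihood with allele i frequency fixed at ``value``."""
        others = [j for j in range(len(model)) if j != i]
        rest = 1.0 - value

        def assemble(sub: np.ndarray) -> np.ndarray:
            f = np.empty(len(model))
            f[i] = value
            f[others] = sub * rest
            return f

        if rest <= 1e-12:
            f = np.zeros(len(model))
            f[i] = 1.0
            return -kernel.nll(f, nvec)
        start = fhat[others]
        start = start / start.sum() if start.sum() > 0 else np.ones(len(others)) / len(others)
        x0 = np.log(np.expm1(np.maximum(start, 1e-10)))
        res = minimize(
            lambda x: kernel.nll(assemble(_softplus_simplex(x)), nvec),
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-10, "maxiter": 8000, "maxfev": 8000},
        )
        return -float(res.fun)

    limits = {}
    for i, name in enumerate(names):
        fi = fhat[i]
        # lower limit
        if fi <= tol or profile(i, 0.0) >= target:
            lo = 0.0
        else:
            a, b = 0.0, fi  # profile(a) < target <= profile(b)
            while b - a > tol:
                m = 0.5 * (a + b)
                if profile(i, m) >= target:
                    b = m
                else:
                    a = m
            lo = b
        # upper limit
        if fi >= 1.0 - tol or profile(i, 1.0) >= target:
            hi = 1.0
        else:
            a, b = fi, 1.0  # profile(a) >= target > profile(b)
            while b - a > tol:
                m = 0.5 * (a + b)
                if profile(i, m) >= target:
                    a = m
                else:
                    b = m
            hi = a
        limits[name] = (max(0.0, min(lo, fi)), min(1.0, max(hi, fi)))
    return limits


def lrt(null_fit: MLResult, alt_fit: MLResult, df: int = 1) -> LRTResult:
    """Likelihood-ratio test between nested allele models.

    Both fits must come from the same counts and phenotype partition
    (models fitted to 3-class vs 5-class data are not comparable).  The
    statistic 2(L_alt - L_null) is clamped at 0 and referred to a
    chi-square upper tail with ``df`` degrees of freedom.
    """
    null_names = {a.name for a in null_fit.model}
    alt_names = {a.name for a in alt_fit.model}
    if not null_names <= alt_names:
        raise ValueError(f"models not nested: {sorted(null_names)} vs {sorted(alt_names)}")
    if (
        null_fit.d1_test is not None
        and alt_fit.d1_test is not None
        and null_fit.d1_test != alt_fit.d1_test
    ):
        raise ValueError("fits use different phenotype partitions and cannot be compared")
    stat = 2.0 * (alt_fit.logL - null_fit.logL)
    if stat < -1e-6:
        raise ValueError(f"alternative fit has lower likelihood ({stat=:.3g}); check convergence")
    stat = max(stat, 0.0)
    return LRTResult(statistic=stat, df=df, p_value=float(chi2.sf(stat, df)))


def allele_counting_null(table: CountTable) -> MLResult:
    """Two-allele Hardy-Weinberg null fitted by allele counting.

    On 3-class data the R frequency MLE is (2 n_RR + n_RS) / 2N; this is
    the no-duplication baseline of the Model-A likelihood-ratio test.
    On 5-class data the D1 split is pooled first.
    """
    from .allele_model import canonical_model

    n_rr = sum(n for c, n in table.counts.items() if c.resistance == "RR")
    n_rs = sum(n for c, n in table.counts.items() if c.resistance == "RS")
    n_ss = sum(n for c, n in table.counts.items() if c.resistance == "SS")
    N = table.N
    p = (2 * n_rr + n_rs) / (2 * N)
    model = canonical_model("RS")
    # evaluate on the table's own partition so the LRT precondition holds
    L = log_likelihood(table, {"R": p, "S": 1 - p}, model, table.d1_test) if not table.d1_test else None
    if table.d1_test:
        # with no S_D1-bearing allele the D1+ classes have probability 0;
        # such nulls are only comparable on pooled 3-class data
        raise ValueError("allele-counting null applies to the 3-class partition; pool the D1 split first")
    return MLResult(model=model, freqs={"R": p, "S": 1 - p}, logL=float(L), d1_test=False)
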