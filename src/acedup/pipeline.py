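"""End-to-end orchestration: fixtures, stage running, manifests.

A run is described by a plain mapping (usually YAML): a global seed, an
output directory and an ordered list of stages with parameter blocks.
Each stochastic stage receives a seed derived deterministically from the
global seed and its position, so a config re-run reproduces every output
byte-for-byte; a JSON manifest records inputs, outputs, seeds and
checksums of everything emitted.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from importlib import resources
from pathlib import Path
from typing import Callable, Mapping

import pandas as pd

from . import __version__
from .allele_model import canonical_model, model_uses_d1_test
from .freq_inference import CountTable, allele_counting_null, fit_ml, lrt

log = logging.getLogger("acedup")


def table1_fixture() -> list[CountTable]:
    """The six packaged phenotype-count samples (five-class counts).

    Yopougon and Yamoussoukro, 2012/2015/2016; total N over the six
    samples is 305.  Pool with :func:`pool_d1` for three-class analyses.
    """
    with resources.files("acedup.data").joinpath("table1_counts.csv").open() as fh:
        df = pd.read_csv(fh)
    return CountTable.from_frame(df)


def pool_d1(table: CountTable) -> CountTable:
    """Collapse the D1 split, giving the 3-class basic-phenotyping table."""
    from .allele_model import PhenotypeClass

    pooled: dict = {}
    for cls, n in table.counts.items():
        key = PhenotypeClass(cls.resistance)
        pooled[key] = pooled.get(key, 0) + n
    return CountTable(table.population, table.year, pooled)


def get_sample(tables: list[CountTable], population: str, year: int) -> CountTable:
    for t in tables:
        if t.population == population and t.year == year:
            return t
    raise KeyError(f"no sample {population} {year}")


def fit_all_models(seed: int = 0, n_restarts: int = 2, support: bool = False) -> pd.DataFrame:
    """Fit Models A, B and C to every packaged sample; long-format frame.

    Model A rows carry the LRT against the two-allele Hardy-Weinberg
    null; Model C rows the LRT against Model B (same five-class data).
    """
    rows = []
    for t5 in table1_fixture():
        t3 = pool_d1(t5)
        fits = {}
        for model_name in ("A", "B", "C"):
            model = canonical_model(model_name)
            d1 = model_uses_d1_test(model_name)
            table = t5 if d1 else t3
            fit = fit_ml(table, model, d1, seed=seed, n_restarts=n_restarts,
                         compute_support_limits=support)
            fits[model_name] = fit
            stat = p = None
            if model_name == "A":
                res = lrt(allele_counting_null(t3), fit)
                stat, p = res.statistic, res.p_value
            elif model_name == "C":
                res = lrt(fits["B"], fit)
                stat, p = res.statistic, res.p_value
            for allele, f in fit.freqs.items():
                sl = fit.support_limits.get(allele)
                rows.append(
                    {
                        "population": t5.population,
                        "year": t5.year,
                        "model": model_name,
                        "allele": allele,
                        "freq": f,
                        "sl_lo": sl[0] if sl else None,
                        "sl_hi": sl[1] if sl else None,
                        "logL": fit.logL,
                        "lrt_stat": stat,
                        "lrt_p": p,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pipeline runner

def _stage_seed(global_seed: int, index: int) -> int:
    return (global_seed * 1_000_003 + 7919 * (index + 1)) % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_counts(params: Mapping, outdir: Path, seed: int) -> list[Path]:
    source = params.get("source", "table1")
    out = outdir / "counts.csv"
    if source == "table1":
        df = pd.concat([t.to_frame() for t in table1_fixture()], ignore_index=True)
    elif source == "simulate":
        from .synthetic_data import simulate_phenotype_counts

        model = canonical_model(params.get("model", "A"))
        d1 = model_uses_d1_test(params.get("model", "A"))
        table, truth = simulate_phenotype_counts(
            params["freqs"], model, d1, int(params.get("N", 100)), seed
        )
        df = table.to_frame()
        (outdir / "counts_truth.json").write_text(json.dumps(truth.__dict__, indent=1))
    else:
        raise ValueError(f"unknown counts source {source!r}")
    df.to_csv(out, index=False)
    return [out]


def _stage_fit(params: Mapping, outdir: Path, seed: int) -> list[Path]:
    df = pd.read_csv(outdir / "counts.csv")
    tables = CountTable.from_frame(df)
    model_name = params.get("model", "A")
    model = canonical_model(model_name)
    d1 = model_uses_d1_test(model_name)
    results = {}
    for t in tables:
        table = t if d1 == t.d1_test else (pool_d1(t) if not d1 else None)
        if table is None:
            raise ValueError(f"sample {t.population} {t.year} lacks D1-test counts")
        fit = fit_ml(table, model, d1, seed=seed,
                     n_restarts=int(params.get("restarts", 2)),
                     compute_support_limits=bool(params.get("support_limits", False)))
        entry = {"freqs": fit.freqs, "logL": fit.logL,
                 "support_limits": fit.support_limits}
        if model_name == "A":
            res = lrt(allele_counting_null(table), fit)
            entry["lrt_vs_RS_null"] = {"statistic": res.statistic, "df": res.df,
                                       "p_value": res.p_value}
        results[f"{t.population}-{t.year}"] = entry
    out = outdir / f"fit_model{model_name}.json"
    out.write_text(json.dumps(results, indent=1))
    return [out]


def _stage_reads(params: Mapping, outdir: Path, seed: int) -> list[Path]:
    from .synthetic_data import DuplicationSimConfig, simulate_duplication_alignments

    copies = tuple(params.get("copies", (2, 1)))
    cfg = DuplicationSimConfig.from_fixture(
        seed=seed, copies=copies, depth=float(params.get("depth", 30.0))
    )
    sam = outdir / "reads.sam"
    truth = simulate_duplication_alignments(cfg, str(sam))
    tj = outdir / "reads_truth.json"
    tj.write_text(json.dumps(truth.__dict__, indent=1))
    return [sam, tj]


def _stage_call(params: Mapping, outdir: Path, seed: int) -> list[Path]:
    from .dup_architecture import call_amplicon, coverage_profile, refine_breakpoints
    from .synthetic_data import load_d1_architecture

    fx = load_d1_architecture()
    sam = str(params.get("sam", outdir / "reads.sam"))
    region = (fx["reference"], fx["region"]["start"], fx["region"]["end"])
    profile = coverage_profile(sam, region)
    coarse = call_amplicon(profile, min_fold=float(params.get("min_fold", 1.25)))
    out = outdir / "duplication_call.json"
    bed = outdir / "duplication_call.bed"
    if coarse is None:
        out.write_text(json.dumps({"call": None}, indent=1))
        bed.write_text("")
        return [out, bed]
    call = refine_breakpoints(sam, coarse, fx["reference"],
                              window=int(params.get("window", 1000)))
    out.write_text(json.dumps({
        "call": {"start": call.start, "end": call.end, "fold": call.fold,
                 "copy_estimate": call.copy_estimate, "size_kb": call.size_kb,
                 "refined": call.refined, "evidence": call.evidence}}, indent=1))
    # BED is 0-based half-open on disk
    bed.write_text(f"{fx['reference']}\t{call.start - 1}\t{call.end}\tamplicon\t{call.copy_estimate}\n")
    return [out, bed]


def _stage_haps(params: Mapping, outdir: Path, seed: int) -> list[Path]:
    from .hap_diversity import write_fasta_records
    from .synthetic_data import HaplotypeSimConfig, simulate_haplotype_population

    cfg = HaplotypeSimConfig(seed=seed, **{k: v for k, v in params.items() if k != "source"})
    records, truth = simulate_haplotype_population(cfg)
    fasta = outdir / "haplotypes.fasta"
    write_fasta_records(records, fasta)
    tj = outdir / "haplotypes_truth.json"
    tj.write_text(json.dumps(truth.__dict__, indent=1))
    return [fasta, tj]


def _stage_assign(params: Mapping, outdir: Path, seed: int) -> list[Path]:
    from .hap_diversity import assign_ds_copies, assignment_table, parse_fasta_records

    records = parse_fasta_records(params.get("fasta", outdir / "haplotypes.fasta"))
    refs = dict(params.get("reference_DS", {}))
    copy_info = {k: int(v) for k, v in params.get("copy_number_info", {}).items()}
    state = assign_ds_copies(records, refs, copy_info)
    out = outdir / "assignments.tsv"
    assignment_table(state).to_csv(out, sep="\t", index=False)
    stats = outdir / "assignment_stats.json"
    stats.write_text(json.dumps({
        "n_d_alleles": state.n_d_alleles,
        "n_clusters": len(state.clusters),
        "conflicts": state.conflicts,
        "genotype_calls": state.genotype_calls,
    }, indent=1))
    return [out, stats]


def _stage_diversity(params: Mapping, outdir: Path, seed: int) -> list[Path]:
    from .hap_diversity import distinct_count_test, pairwise_divergence, parse_fasta_records
    from .synthetic_data import HaplotypeSimConfig

    records = [r for r in parse_fasta_records(params.get("fasta", outdir / "haplotypes.fasta"))
               if r.resistance_class != "R"]
    mask = HaplotypeSimConfig(**params.get("mask_params", {})).exon_mask()
    div = pairwise_divergence(records, mask)
    payload = {"d": div.d, "d_exons": div.d_exons, "d_introns": div.d_introns}
    if "distinct_counts" in params:
        k1, n1, k2, n2 = params["distinct_counts"]
        stat, df, p = distinct_count_test(k1, n1, k2, n2)
        payload["distinct_count_test"] = {"chi2": stat, "df": df, "p": p}
    out = outdir / "diversity.json"
    out.write_text(json.dumps(payload, indent=1))
    return [out]


_STAGES: dict[str, Callable[[Mapping, Path, int], list[Path]]] = {
    "counts": _stage_counts,
    "fit": _stage_fit,
    "simulate_reads": _stage_reads,
    "call_duplication": _stage_call,
    "simulate_haplotypes": _stage_haps,
    "assign_haplotypes": _stage_assign,
    "diversity": _stage_diversity,
}


def run_pipeline(config: Mapping) -> dict:
    """Execute the configured stages in order; return (and write) the manifest.

    ``config`` keys: ``seed`` (global), ``outdir``, ``stages`` — a list of
    ``{stage: name, params: {...}}`` blocks.  A failing stage aborts the
    run with the stage named; outputs of earlier stages are kept.
    """
    seed = int(config.get("seed", 0))
    outdir = Path(config.get("outdir", "acedup-run"))
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": seed, "stages": []}
    for idx, block in enumerate(config.get("stages", [])):
        name = block.get("stage")
        params = block.get("params", {})
        if name not in _STAGES:
            raise ValueError(f"unknown stage {name!r} (known: {sorted(_STAGES)})")
        stage_seed = _stage_seed(seed, idx)
        log.info("[%s] starting (seed=%d)", name, stage_seed)
        try:
            outputs = _STAGES[name](params, outdir, stage_seed)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"].append(
            {
                "stage": name,
                "seed": stage_seed,
                "params": params,
                "outputs": {str(p.name): _sha256(p) for p in outputs},
            }
        )
        log.info("[%s] done: %s", name, ", ".join(p.name for p in outputs))
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, level.upper()),
        format="%(name)s %(levelname)s %(message)s",
    )
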