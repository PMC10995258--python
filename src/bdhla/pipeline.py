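"""End-to-end pipeline driver: simulate -> call -> associate -> haplo.

Each stage is toggleable; any failure is re-raised with the stage name so
partial runs are diagnosable.  A JSON run summary (config, versions,
seed, per-stage counts) accompanies the TSV outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .association import (
    associate_all,
    read_cohort_tsv,
    results_to_frame,
    write_cohort_tsv,
)
from .caller import MappingParams, call_sample
from .haplotype import genotypes_from_cohort, pairwise_scan
from .nomenclature import parse_allele_name, write_reference_fasta
from .synthdata import (
    ReadSimParams,
    RiskModel,
    simulate_cohort,
    simulate_reads,
    study_pool,
    synthetic_registry,
)

log = logging.getLogger("bdhla")


class PipelineError(RuntimeError):
    """A stage failure, named after the stage that raised it."""


@dataclass
class PipelineConfig:
    out_dir: str = "bdhla_run"
    seed: int = 17
    stages: tuple[str, ...] = ("simulate", "call", "associate", "haplo")
    # cohort / risk model
    n_case: int = 56
    n_control: int = 192
    risk_locus: str = "B"
    risk_allele: str = "B*51:01:01"
    target_or: float = 3.033
    # association
    resolution: int = 3
    p_method: str = "wald"
    # caller
    min_reads: int = 50
    max_candidates: int = 4
    min_identity: float = 0.995
    het_ratio: float = 0.25
    call_samples: int = 3  # read-level calling is run for this many subjects
    read_depth: float = 100.0
    read_error: float = 0.001
    # haplotype
    loci: tuple[str, ...] = ("B", "C")
    pairs: tuple[tuple[str, str], ...] = (("B", "C"),)
    n_perm: int = 1000
    # optional external inputs
    cohort_tsv: str | None = None
    reference_fasta: str | None = None

    def validate(self) -> None:
        unknown = set(self.stages) - {"simulate", "call", "associate", "haplo"}
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.p_method not in ("wald", "fisher"):
            raise ValueError("p_method must be wald or fisher")
        if not 1 <= self.resolution <= 4:
            raise ValueError("resolution must be 1-4 fields")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "loci" in raw:
            raw["loci"] = tuple(raw["loci"])
        if "pairs" in raw:
            raw["pairs"] = tuple(tuple(p) for p in raw["pairs"])
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_pipeline(config: PipelineConfig) -> dict:
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
    }
    cohort = None
    truth = None
    registry = None

    def stage(name):
        return name in config.stages

    try:
        if stage("simulate") and config.cohort_tsv is None:
            t0 = time.perf_counter()
            pool = study_pool(seed=config.seed)
            cohort, truth = simulate_cohort(
                pool,
                n_case=config.n_case,
                n_control=config.n_control,
                risk=RiskModel(config.risk_allele, config.target_or),
                risk_locus=config.risk_locus,
                seed=config.seed,
            )
            write_cohort_tsv(cohort, out / "cohort.tsv")
            truth_json = {
                "p_carrier_control": truth.p_carrier_control,
                "p_carrier_case": truth.p_carrier_case,
                "risk_allele": config.risk_allele,
                "target_or": config.target_or,
                "pool_version": f"study_pool(seed={config.seed})",
            }
            (out / "truth.json").write_text(json.dumps(truth_json, indent=2))
            summary["stages"]["simulate"] = {
                "n_case": cohort.n_case,
                "n_control": cohort.n_control,
                "seconds": round(time.perf_counter() - t0, 3),
            }
            log.info("simulate: %d cases / %d controls", cohort.n_case, cohort.n_control)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage simulate: {exc}") from exc

    try:
        if config.cohort_tsv is not None:
            cohort = read_cohort_tsv(config.cohort_tsv)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage load-cohort: {exc}") from exc

    try:
        if stage("call"):
            if cohort is None:
                raise ValueError("no cohort available (enable simulate or pass cohort_tsv)")
            t0 = time.perf_counter()
            if config.reference_fasta is not None:
                from .nomenclature import load_reference_fasta

                registry = load_reference_fasta(config.reference_fasta)
            else:
                # registry covering the simulated pool's alleles
                genes: dict[str, list[str]] = {}
                for s in cohort.subjects:
                    for gene, call in s.genotypes.items():
                        for a in call.alleles:
                            genes.setdefault(gene, [])
                            if str(a) not in genes[gene]:
                                genes[gene].append(str(a))
                registry = synthetic_registry(
                    {g: sorted(a) for g, a in genes.items()}, seed=config.seed
                )
                write_reference_fasta(registry, out / "reference.fasta")
            params = MappingParams(min_identity=config.min_identity)
            rows = []
            concordant = 0
            checked = 0
            for s in cohort.subjects[: config.call_samples]:
                for gene, true_call in s.genotypes.items():
                    reads = simulate_reads(
                        true_call,
                        registry,
                        ReadSimParams(
                            mean_depth=config.read_depth,
                            error_rate=config.read_error,
                            seed=config.seed + checked,
                        ),
                    )
                    called = call_sample(
                        reads,
                        registry,
                        params,
                        min_reads=config.min_reads,
                        max_candidates=config.max_candidates,
                        het_ratio=config.het_ratio,
                        sample_id=s.subject_id,
                    )[gene]
                    checked += 1
                    same = set(called.alleles) == set(true_call.alleles)
                    concordant += same
                    rows.append(
                        {
                            "sample": s.subject_id,
                            "gene": gene,
                            "true": "/".join(map(str, true_call.alleles)),
                            "called": "/".join(map(str, called.alleles)) or "-",
                            "zygosity": called.zygosity,
                            "counts": ",".join(map(str, called.supporting_counts)),
                            "concordant": same,
                        }
                    )
            import pandas as pd

            pd.DataFrame(rows).to_csv(out / "calls.tsv", sep="\t", index=False)
            summary["stages"]["call"] = {
                "genotypes_checked": checked,
                "concordant": concordant,
                "seconds": round(time.perf_counter() - t0, 3),
            }
            log.info("call: %d/%d concordant", concordant, checked)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage call: {exc}") from exc

    try:
        if stage("associate"):
            if cohort is None:
                raise ValueError("no cohort available")
            t0 = time.perf_counter()
            results = associate_all(
                cohort, resolution=config.resolution, p_method=config.p_method
            )
            frame = results_to_frame(results)
            frame.to_csv(out / "association.tsv", sep="\t", index=False)
            summary["stages"]["associate"] = {
                "n_alleles": len(results),
                "seconds": round(time.perf_counter() - t0, 3),
            }
            log.info("associate: %d alleles", len(results))
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage associate: {exc}") from exc

    try:
        if stage("haplo"):
            if cohort is None:
                raise ValueError("no cohort available")
            t0 = time.perf_counter()
            cases, controls = genotypes_from_cohort(
                cohort, tuple(config.loci), resolution=config.resolution
            )
            scan = pairwise_scan(
                cases,
                controls,
                [tuple(p) for p in config.pairs],
                n_perm=config.n_perm,
                seed=config.seed,
            )
            import pandas as pd

            pd.DataFrame(
                [
                    {
                        "pair": ":".join(r.loci),
                        "statistic": round(r.observed_statistic, 4),
                        "p_perm": round(r.p_perm, 6),
                        "pc": round(r.pc, 6),
                        "n_perm": r.n_perm,
                        "seed": r.seed,
                    }
                    for r in scan
                ]
            ).to_csv(out / "haplotype_scan.tsv", sep="\t", index=False)
            summary["stages"]["haplo"] = {
                "n_pairs": len(scan),
                "seconds": round(time.perf_counter() - t0, 3),
            }
            log.info("haplo: %d pairs scanned", len(scan))
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage haplo: {exc}") from exc

    (out / "run_summary.json").write_text(json.dumps(summary, indent=2))
    return summary
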