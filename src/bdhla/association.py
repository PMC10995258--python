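"""Carrier-based case-control association statistics.

The unit of association is the *carrier* 2x2 table: subjects carrying at
least one copy of an allele versus non-carriers, in cases versus
controls.  For each allele we compute the odds ratio, its Woolf logit
95% confidence interval, a two-sided Wald p-value on ln(OR), the
two-sided Fisher exact p-value, and a per-locus Bonferroni-corrected
Pc = p x m, where m is the number of distinct alleles observed at that
locus in the combined cohort.  Pc is deliberately left uncapped.

Report formatting mirrors the conventions of the source tables this
pipeline reproduces: odds ratios and CI bounds are truncated (not
rounded) at 3 decimals, p-values are rounded to 3 decimals, and the
default Pc is computed from the rounded p so that printed Pc values are
exact products of printed p and m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .caller import GenotypeCall
from .nomenclature import GENES, AlleleName, parse_allele_name

PHENOTYPE_FLAGS = ("ocular", "vascular", "skin", "cns", "gi", "pathergy")


@dataclass(frozen=True)
class CarrierTable:
    """2x2 table: a/b = case carriers/non-carriers, c/d = controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("carrier table cells must be non-negative")

    @property
    def n_case(self) -> int:
        return self.a + self.b

    @property
    def n_control(self) -> int:
        return self.c + self.d

    @property
    def has_zero_cell(self) -> bool:
        return min(self.a, self.b, self.c, self.d) == 0


def odds_ratio(t: CarrierTable) -> float | None:
    """(a*d)/(b*c); None (rendered as a dash) when any cell is zero."""
    if t.has_zero_cell:
        return None
    return (t.a * t.d) / (t.b * t.c)


def _log_or_se(t: CarrierTable) -> float:
    return math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)


def woolf_ci(t: CarrierTable, level: float = 0.95) -> tuple[float, float] | None:
    """Woolf logit CI: exp(ln OR +/- z * sqrt(1/a+1/b+1/c+1/d))."""
    orr = odds_ratio(t)
    if orr is None:
        return None
    z = stats.norm.ppf((1 + level) / 2)
    se = _log_or_se(t)
    return math.exp(math.log(orr) - z * se), math.exp(math.log(orr) + z * se)


def wald_p(t: CarrierTable) -> float | None:
    """Two-sided normal p for z = ln(OR) / SE(ln OR)."""
    orr = odds_ratio(t)
    if orr is None:
        return None
    z = math.log(orr) / _log_or_se(t)
    return float(2 * stats.norm.sf(abs(z)))


def fisher_exact_two_sided(t: CarrierTable) -> float:
    """Two-sided Fisher exact p (sum of hypergeometric outcomes no more
    probable than the observed table, margins fixed)."""
    return float(
        stats.fisher_exact([[t.a, t.b], [t.c, t.d]], alternative="two-sided")[1]
    )


def bonferroni(p: float, m: int) -> float:
    """Per-locus Bonferroni correction, uncapped (Pc may exceed 1)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return p * m


def pearson_chi2_p(table: list[list[int]]) -> float:
    """Pearson chi-square p without continuity correction (demographic
    comparisons such as the case/control sex distribution)."""
    return float(stats.chi2_contingency(table, correction=False)[1])


# -- formatting helpers (match the reporting conventions described above) --

def trunc3(x: float) -> float:
    """Truncate toward zero at 3 decimals (table OR/CI convention)."""
    return math.trunc(x * 1000) / 1000


def round3(x: float) -> float:
    return round(x, 3)


# -- cohort containers ------------------------------------------------------


@dataclass(frozen=True)
class SubjectRecord:
    """One subject: group label, phenotype flags, per-gene genotype call."""

    subject_id: str
    group: str  # "case" | "control"
    genotypes: dict[str, GenotypeCall] = field(default_factory=dict)
    phenotypes: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in ("case", "control"):
            raise ValueError(f"group must be case/control, got {self.group!r}")

    def carries(self, allele: AlleleName, resolution: int) -> bool:
        call = self.genotypes.get(allele.gene)
        if call is None or not call.is_call:
            return False
        target = allele.truncate(min(resolution, allele.resolution))
        for called in call.alleles:
            if called.resolution >= target.resolution and (
                called.truncate(target.resolution) == target
            ):
                return True
        return False


@dataclass
class CohortTable:
    subjects: list[SubjectRecord]

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("subject_ids must be unique")

    @property
    def cases(self) -> list[SubjectRecord]:
        return [s for s in self.subjects if s.group == "case"]

    @property
    def controls(self) -> list[SubjectRecord]:
        return [s for s in self.subjects if s.group == "control"]

    @property
    def n_case(self) -> int:
        return len(self.cases)

    @property
    def n_control(self) -> int:
        return len(self.controls)

    def genes(self) -> tuple[str, ...]:
        seen = {g for s in self.subjects for g in s.genotypes}
        return tuple(g for g in GENES if g in seen)

    def observed_alleles(self, gene: str, resolution: int) -> list[AlleleName]:
        seen = set()
        for s in self.subjects:
            call = s.genotypes.get(gene)
            if call is None or not call.is_call:
                continue
            for a in call.alleles:
                seen.add(a.truncate(min(resolution, a.resolution)))
        return sorted(seen)


def carrier_table(
    cohort: CohortTable, allele: AlleleName, resolution: int | None = None
) -> CarrierTable:
    """Carrier 2x2 for one allele at a given resolution.

    A subject is a carrier when either called allele truncates to the
    target; homozygotes count once.
    """
    resolution = resolution if resolution is not None else allele.resolution
    if allele.gene not in cohort.genes():
        raise KeyError(f"gene {allele.gene} absent from cohort genotypes")
    a = sum(s.carries(allele, resolution) for s in cohort.cases)
    c = sum(s.carries(allele, resolution) for s in cohort.controls)
    return CarrierTable(a=a, b=cohort.n_case - a, c=c, d=cohort.n_control - c)


def locus_test_counts(cohort: CohortTable, resolution: int) -> dict[str, int]:
    """Bonferroni multiplier per gene: distinct alleles observed in the
    combined cohort at the given resolution."""
    return {
        g: len(cohort.observed_alleles(g, resolution)) for g in cohort.genes()
    }


@dataclass(frozen=True)
class AssociationResult:
    """Full per-allele association record."""

    allele: AlleleName
    table: CarrierTable
    or_: float | None
    ci_low: float | None
    ci_high: float | None
    p_wald: float | None
    p_fisher: float
    m: int
    pc: float | None  # from p rounded to 3 dp (reporting convention)
    pc_exact: float | None
    p_method: str = "wald"

    @property
    def p(self) -> float | None:
        return self.p_wald if self.p_method == "wald" else self.p_fisher


def associate_one(
    allele: AlleleName,
    table: CarrierTable,
    m: int = 1,
    p_method: str = "wald",
) -> AssociationResult:
    orr = odds_ratio(table)
    ci = woolf_ci(table)
    pw = wald_p(table)
    pf = fisher_exact_two_sided(table)
    p = pw if p_method == "wald" else pf
    return AssociationResult(
        allele=allele,
        table=table,
        or_=orr,
        ci_low=ci[0] if ci else None,
        ci_high=ci[1] if ci else None,
        p_wald=pw,
        p_fisher=pf,
        m=m,
        pc=bonferroni(round3(p), m) if p is not None else None,
        pc_exact=bonferroni(p, m) if p is not None else None,
        p_method=p_method,
    )


def associate_all(
    cohort: CohortTable, resolution: int = 3, p_method: str = "wald"
) -> list[AssociationResult]:
    """One association per observed allele per gene, with per-locus
    Bonferroni multipliers, sorted by gene then allele."""
    mult = locus_test_counts(cohort, resolution)
    out: list[AssociationResult] = []
    for gene in cohort.genes():
        for allele in cohort.observed_alleles(gene, resolution):
            t = carrier_table(cohort, allele, resolution)
            out.append(associate_one(allele, t, m=mult[gene], p_method=p_method))
    return out


def phenotype_association(
    cohort: CohortTable,
    phenotype: str,
    allele: AlleleName,
    comparator: str = "case_subset_vs_control",
    resolution: int | None = None,
) -> AssociationResult:
    """Association between an allele and a clinical phenotype subset.

    ``case_subset_vs_control``: phenotype-positive cases vs controls.
    ``case_vs_case``: phenotype-positive vs phenotype-negative cases.
    """
    resolution = resolution if resolution is not None else allele.resolution
    positives = [s for s in cohort.cases if s.phenotypes.get(phenotype, False)]
    if not positives:
        raise ValueError(f"no cases positive for phenotype {phenotype!r}")
    if comparator == "case_subset_vs_control":
        others = cohort.controls
    elif comparator == "case_vs_case":
        others = [s for s in cohort.cases if not s.phenotypes.get(phenotype, False)]
        if not others:
            raise ValueError(
                f"phenotype {phenotype!r} positive in all cases; "
                "case_vs_case comparator has an empty reference group"
            )
    else:
        raise ValueError(f"unknown comparator {comparator!r}")
    a = sum(s.carries(allele, resolution) for s in positives)
    c = sum(s.carries(allele, resolution) for s in others)
    t = CarrierTable(a=a, b=len(positives) - a, c=c, d=len(others) - c)
    return associate_one(allele, t, m=1)


# -- TSV interchange --------------------------------------------------------


def results_to_frame(results: list[AssociationResult]) -> pd.DataFrame:
    """Association results as a report table (truncated OR/CI, rounded p,
    dashes for undefined values)."""
    def fmt(x, f):
        return "-" if x is None else f"{f(x):.3f}"

    rows = []
    for r in results:
        rows.append(
            {
                "gene": r.allele.gene,
                "allele": str(r.allele),
                "case_carriers": r.table.a,
                "case_pct": round(100 * r.table.a / r.table.n_case, 2),
                "control_carriers": r.table.c,
                "control_pct": round(100 * r.table.c / r.table.n_control, 2),
                "odds_ratio": fmt(r.or_, trunc3),
                "p_wald": fmt(r.p_wald, round3),
                "p_fisher": f"{round3(r.p_fisher):.3f}",
                "ci_low": fmt(r.ci_low, trunc3),
                "ci_high": fmt(r.ci_high, trunc3),
                "m": r.m,
                "pc": fmt(r.pc, round3),
            }
        )
    return pd.DataFrame(rows)


def cohort_to_frame(cohort: CohortTable) -> pd.DataFrame:
    rows = []
    for s in cohort.subjects:
        row: dict = {"subject_id": s.subject_id, "group": s.group}
        for flag in PHENOTYPE_FLAGS:
            row[flag] = int(s.phenotypes.get(flag, False))
        for gene in GENES:
            call = s.genotypes.get(gene)
            if call is None or not call.is_call:
                row[gene] = "-"
            else:
                pair = call.allele_pair()
                row[gene] = f"{pair[0]}/{pair[1]}"
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_from_frame(df: pd.DataFrame) -> CohortTable:
    """Read a cohort table (one column per gene, ``allele1/allele2``)."""
    subjects = []
    genes = [g for g in GENES if g in df.columns]
    for _, row in df.iterrows():
        genotypes: dict[str, GenotypeCall] = {}
        for gene in genes:
            cell = str(row[gene])
            if cell in ("-", "nan", ""):
                continue
            a1_s, _, a2_s = cell.partition("/")
            a1 = parse_allele_name(a1_s)
            a2 = parse_allele_name(a2_s) if a2_s else a1
            alleles = (a1,) if a1 == a2 else (a1, a2)
            genotypes[gene] = GenotypeCall(
                sample_id=str(row["subject_id"]),
                gene=gene,
                alleles=alleles,
                zygosity="homozygous" if a1 == a2 else "heterozygous",
            )
        phenos = {
            f: bool(int(row[f])) for f in PHENOTYPE_FLAGS if f in df.columns
        }
        subjects.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                genotypes=genotypes,
                phenotypes=phenos,
            )
        )
    return CohortTable(subjects=subjects)


def read_cohort_tsv(path) -> CohortTable:
    return cohort_from_frame(pd.read_csv(path, sep="\t", dtype=str))


def write_cohort_tsv(cohort: CohortTable, path) -> None:
    cohort_to_frame(cohort).to_csv(path, sep="\t", index=False)
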