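"""Synthetic cohorts, reference registries and consensus reads.

The generator emulates the statistical structure of a case-control HLA
study so that every downstream stage (calling, association, haplotype
analysis) can be exercised end to end without external data:

* a haplotype pool with per-locus allele-frequency spectra and optional
  pairwise linkage disequilibrium (a target D' between two focal
  alleles, induced by moving joint mass while preserving marginals);
* control diplotypes drawn independently from the pool (Hardy-Weinberg
  equilibrium); case diplotypes rejection-sampled so that carriage of a
  designated risk allele follows the carrier odds ratio implied by
  retrospective (case-control) sampling;
* a synthetic reference registry of 1 kb allele sequences whose
  same-gene alleles diverge by >= 4%, and Poisson-depth consensus reads
  with uniform per-base substitution errors.

All generators are pure functions of their parameters and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .association import CohortTable, SubjectRecord
from .caller import GenotypeCall, ConsensusRead, reverse_complement
from .nomenclature import (
    AlleleName,
    AlleleRegistry,
    ReferenceAllele,
    parse_allele_name,
)

Hap = tuple[str, ...]


def case_carrier_probability(p_control: float, or_: float) -> float:
    """Carrier probability among cases implied by a control carrier
    probability and a target carrier odds ratio:
    odds_case = OR * odds_control."""
    if not 0.0 < p_control < 1.0:
        raise ValueError("p_control must be in (0, 1)")
    if or_ <= 0:
        raise ValueError("odds ratio must be positive")
    odds = or_ * p_control / (1.0 - p_control)
    return odds / (1.0 + odds)


@dataclass(frozen=True)
class RiskModel:
    """A planted carrier-level disease association for one allele."""

    risk_allele: str
    target_or: float

    def __post_init__(self) -> None:
        if self.target_or <= 0:
            raise ValueError("target odds ratio must be positive")


@dataclass
class HaplotypePool:
    """A multi-locus haplotype distribution to draw diplotypes from."""

    loci: tuple[str, ...]
    frequencies: dict[Hap, float]

    def __post_init__(self) -> None:
        total = sum(self.frequencies.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"haplotype frequencies sum to {total}, not 1")
        if any(f < 0 for f in self.frequencies.values()):
            raise ValueError("haplotype frequencies must be non-negative")
        for h in self.frequencies:
            if len(h) != len(self.loci):
                raise ValueError("haplotype arity must match loci")

    @property
    def haplotypes(self) -> list[Hap]:
        return list(self.frequencies)

    def marginal(self, locus: str, allele: str) -> float:
        k = self.loci.index(locus)
        return sum(f for h, f in self.frequencies.items() if h[k] == allele)

    def carrier_probability(self, locus: str, allele: str) -> float:
        """P(subject carries >= 1 copy) under HWE."""
        p = self.marginal(locus, allele)
        return 1.0 - (1.0 - p) ** 2


def independent_pool(
    loci: tuple[str, ...], allele_freqs: list[dict[str, float]]
) -> HaplotypePool:
    """Pool with independent loci (linkage equilibrium): haplotype
    frequency = product of allele frequencies."""
    freqs: dict[Hap, float] = {}

    def build(prefix: Hap, p: float, k: int) -> None:
        if k == len(loci):
            freqs[prefix] = p
            return
        for allele, f in allele_freqs[k].items():
            build(prefix + (allele,), p * f, k + 1)

    build((), 1.0, 0)
    total = sum(freqs.values())
    freqs = {h: f / total for h, f in freqs.items()}
    return HaplotypePool(loci=tuple(loci), frequencies=freqs)


def with_ld(
    pool: HaplotypePool,
    locus_a: str,
    allele_a: str,
    locus_b: str,
    allele_b: str,
    d_prime: float,
) -> HaplotypePool:
    """Rearrange joint mass to hit a target D' between two focal alleles
    while preserving all marginals.

    The pool is collapsed to the 2x2 table (focal allele vs rest at each
    locus); D = D' * Dmax mass is moved into the focal-focal cell and
    compensated proportionally within the complementary cells.
    """
    if not 0.0 <= d_prime <= 1.0:
        raise ValueError("target D' must be in [0, 1]")
    ka, kb = pool.loci.index(locus_a), pool.loci.index(locus_b)
    p_a, p_b = pool.marginal(locus_a, allele_a), pool.marginal(locus_b, allele_b)
    if not (0 < p_a < 1 and 0 < p_b < 1):
        raise ValueError("focal alleles must be polymorphic")
    p_ab = sum(
        f for h, f in pool.frequencies.items()
        if h[ka] == allele_a and h[kb] == allele_b
    )
    d_target = d_prime * min(p_a * (1 - p_b), (1 - p_a) * p_b)
    delta = (p_a * p_b + d_target) - p_ab  # mass to add to the AB cell
    cells: dict[tuple[bool, bool], float] = {}
    for h, f in pool.frequencies.items():
        key = (h[ka] == allele_a, h[kb] == allele_b)
        cells[key] = cells.get(key, 0.0) + f
    new_cells = {
        (True, True): cells.get((True, True), 0.0) + delta,
        (True, False): cells.get((True, False), 0.0) - delta,
        (False, True): cells.get((False, True), 0.0) - delta,
        (False, False): cells.get((False, False), 0.0) + delta,
    }
    if any(v < -1e-12 for v in new_cells.values()):
        raise ValueError(
            f"target D'={d_prime} infeasible for marginals "
            f"p_A={p_a:.3f}, p_B={p_b:.3f}"
        )
    freqs: dict[Hap, float] = {}
    for h, f in pool.frequencies.items():
        key = (h[ka] == allele_a, h[kb] == allele_b)
        old = cells[key]
        scale = new_cells[key] / old if old > 0 else 0.0
        nf = f * scale
        if nf > 0:
            freqs[h] = nf
    # haplotypes may be created by LD that had zero mass under independence
    missing = new_cells[(True, True)] - sum(
        f for h, f in freqs.items() if h[ka] == allele_a and h[kb] == allele_b
    )
    if missing > 1e-12:
        raise ValueError("LD target requires creating unrepresented haplotypes")
    total = sum(freqs.values())
    freqs = {h: f / total for h, f in freqs.items()}
    return HaplotypePool(loci=pool.loci, frequencies=freqs)


@dataclass
class PlantedTruth:
    """Ground truth stored alongside a simulated cohort."""

    pool: HaplotypePool
    risk: RiskModel | None
    risk_locus: str | None
    p_carrier_control: float | None
    p_carrier_case: float | None
    diplotypes: dict[str, tuple[Hap, Hap]] = field(default_factory=dict)


def _draw_diplotype(rng: np.random.Generator, haps: list[Hap], p: np.ndarray):
    i, j = rng.choice(len(haps), size=2, p=p)
    return haps[i], haps[j]


def _carries(diplo: tuple[Hap, Hap], k: int, allele: str) -> bool:
    return diplo[0][k] == allele or diplo[1][k] == allele


def simulate_cohort(
    pool: HaplotypePool,
    n_case: int = 56,
    n_control: int = 192,
    risk: RiskModel | None = None,
    risk_locus: str | None = None,
    seed: int = 0,
    phenotype_rates: dict[str, float] | None = None,
    resolution_fields: int = 3,
) -> tuple[CohortTable, PlantedTruth]:
    """Simulate a case-control cohort from a haplotype pool.

    Controls are two iid pool draws (HWE).  When a risk model is given,
    each case's carrier status for the risk allele is first drawn
    Bernoulli at the case carrier probability implied by the target OR,
    then a diplotype matching that status is rejection-sampled from the
    pool.  Optional phenotype flags are iid Bernoulli among cases at the
    given rates (the study's organ-involvement frequencies by default).
    """
    rng = np.random.default_rng(seed)
    haps = pool.haplotypes
    p = np.array([pool.frequencies[h] for h in haps])
    truth = PlantedTruth(
        pool=pool, risk=risk, risk_locus=risk_locus,
        p_carrier_control=None, p_carrier_case=None,
    )
    k = None
    if risk is not None:
        if risk_locus is None:
            raise ValueError("risk_locus required with a risk model")
        k = pool.loci.index(risk_locus)
        q0 = pool.carrier_probability(risk_locus, risk.risk_allele)
        if not 0.0 < q0 < 1.0:
            raise ValueError(
                f"risk allele {risk.risk_allele} has carrier probability "
                f"{q0}; planted OR {risk.target_or} unattainable"
            )
        truth.p_carrier_control = q0
        truth.p_carrier_case = case_carrier_probability(q0, risk.target_or)

    phenotype_rates = phenotype_rates or {}
    subjects: list[SubjectRecord] = []

    def record(sid: str, group: str, diplo: tuple[Hap, Hap]) -> SubjectRecord:
        truth.diplotypes[sid] = diplo
        genotypes: dict[str, GenotypeCall] = {}
        for idx, locus in enumerate(pool.loci):
            a1 = parse_allele_name(diplo[0][idx])
            a2 = parse_allele_name(diplo[1][idx])
            alleles = (a1,) if a1 == a2 else tuple(sorted((a1, a2)))
            genotypes[locus] = GenotypeCall(
                sample_id=sid, gene=locus, alleles=alleles,
                zygosity="homozygous" if a1 == a2 else "heterozygous",
            )
        phenos = {}
        if group == "case":
            for flag, rate in phenotype_rates.items():
                phenos[flag] = bool(rng.random() < rate)
        return SubjectRecord(
            subject_id=sid, group=group, genotypes=genotypes, phenotypes=phenos
        )

    for i in range(n_control):
        subjects.append(record(f"CTRL{i:04d}", "control", _draw_diplotype(rng, haps, p)))
    for i in range(n_case):
        if risk is None:
            diplo = _draw_diplotype(rng, haps, p)
        else:
            want_carrier = bool(rng.random() < truth.p_carrier_case)
            while True:
                diplo = _draw_diplotype(rng, haps, p)
                if _carries(diplo, k, risk.risk_allele) == want_carrier:
                    break
        subjects.append(record(f"CASE{i:04d}", "case", diplo))

    return CohortTable(subjects=subjects), truth


# -- synthetic reference sequences and reads --------------------------------

REFERENCE_LENGTH = 1000
_VARIANT_BLOCK = 25  # disjoint per-allele variant blocks => >=4% pairwise divergence
_BASES = np.array(list("ACGT"))


def synthetic_registry(
    gene_alleles: dict[str, list[str]],
    length: int = REFERENCE_LENGTH,
    seed: int = 0,
) -> AlleleRegistry:
    """Build a registry of synthetic reference alleles.

    Alleles of one gene share a random core sequence and each mutates its
    own disjoint block of ``_VARIANT_BLOCK`` positions, so any two
    same-gene alleles differ at 2 x 25 = 50 of 1000 positions (5%
    divergence) while different genes are unrelated random sequences.
    """
    registry = AlleleRegistry(version=f"synthetic-seed{seed}")
    for gene, alleles in gene_alleles.items():
        if len(alleles) * _VARIANT_BLOCK > length:
            raise ValueError(f"too many alleles for gene {gene}")
        grng = np.random.default_rng(
            np.random.SeedSequence([seed, sum(map(ord, gene))])
        )
        core = grng.integers(0, 4, size=length)
        for i, allele_text in enumerate(alleles):
            name = parse_allele_name(allele_text)
            if name.gene != gene:
                raise ValueError(f"allele {allele_text} not of gene {gene}")
            seq = core.copy()
            block = slice(i * _VARIANT_BLOCK, (i + 1) * _VARIANT_BLOCK)
            seq[block] = (seq[block] + grng.integers(1, 4, size=_VARIANT_BLOCK)) % 4
            registry.add(
                ReferenceAllele(name=name, sequence="".join(_BASES[seq]))
            )
    return registry


@dataclass(frozen=True)
class ReadSimParams:
    """Consensus-read simulation: Poisson depth per true allele, iid
    per-base substitution errors, random strand."""

    mean_depth: float = 100.0
    error_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if not 0.0 <= self.error_rate <= 0.2:
            raise ValueError("error_rate must be in [0, 0.2]")


def simulate_reads(
    genotype: GenotypeCall,
    registry: AlleleRegistry,
    params: ReadSimParams,
) -> list[ConsensusRead]:
    """Simulate consensus reads for one gene's true genotype.

    Each true allele receives an independent Poisson(mean_depth) number
    of reads copied from its reference with iid substitutions; each read
    is reverse-complemented with probability 1/2.
    """
    rng = np.random.default_rng(params.seed)
    reads: list[ConsensusRead] = []
    for allele in genotype.alleles:
        if allele not in registry:
            raise KeyError(f"true allele {allele} missing from registry")
        ref = np.array(list(registry.get(allele).sequence))
        base_codes = {b: i for i, b in enumerate("ACGT")}
        codes = np.array([base_codes.get(b, 0) for b in ref])
        depth = rng.poisson(params.mean_depth)
        for r in range(depth):
            seq = codes.copy()
            if params.error_rate > 0:
                errs = np.flatnonzero(rng.random(len(seq)) < params.error_rate)
                seq[errs] = (seq[errs] + rng.integers(1, 4, size=len(errs))) % 4
            text = "".join(_BASES[seq])
            if rng.random() < 0.5:
                text = reverse_complement(text)
            reads.append(
                ConsensusRead(
                    read_id=f"{genotype.sample_id}|{allele}|{r}",
                    sequence=text,
                    sample_id=genotype.sample_id,
                )
            )
    return reads


# -- a ready-made study-like scenario ---------------------------------------

def study_pool(seed: int = 0) -> HaplotypePool:
    """A B-C haplotype pool loosely shaped like the study's class I
    spectrum: a common B*51:01:01-C*14:02:01 coupling (the study's
    strong-LD pair) over a background of common Thai alleles."""
    allele_freqs = [
        {  # HLA-B carrier-spectrum-inspired marginals
            "B*51:01:01": 0.04,
            "B*46:01:01": 0.14,
            "B*15:02:01": 0.10,
            "B*40:01:02": 0.09,
            "B*58:01:01": 0.07,
            "B*13:01:01": 0.06,
            "B*38:02:01": 0.05,
            "B*44:03:02": 0.45,
        },
        {
            "C*14:02:01": 0.05,
            "C*01:02:01": 0.17,
            "C*07:02:01": 0.17,
            "C*08:01:01": 0.12,
            "C*03:04:01": 0.09,
            "C*04:01:01": 0.40,
        },
    ]
    pool = independent_pool(("B", "C"), allele_freqs)
    return with_ld(pool, "B", "B*51:01:01", "C", "C*14:02:01", d_prime=0.8)
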