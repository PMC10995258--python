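"""Reusable simulation experiments over the pipeline.

Each function runs one self-contained study at the package's reference
conditions (sample sizes and noise levels chosen to mirror the cohort
the pipeline is built for) and returns plain numbers, so test suites,
the acceptance script and the analysis drivers all exercise exactly the
same code paths.
"""

from __future__ import annotations

import numpy as np

from .caller import Candidate, MappingParams, assign_genotype, call_sample
from .haplotype import (
    em_haplotype_frequencies,
    genotypes_from_cohort,
    haplotype_case_control_test,
)
from .synthdata import (
    HaplotypePool,
    ReadSimParams,
    independent_pool,
    simulate_cohort,
    simulate_reads,
    synthetic_registry,
    with_ld,
)

_CALLER_ALLELES = [
    "B*51:01:01", "B*46:01:01", "B*15:02:01",
    "B*40:01:02", "B*58:01:01", "B*13:01:01",
]

EM_TRUTH_POOL = {
    ("a", "b"): 0.5, ("a", "B"): 0.3, ("A", "b"): 0.15, ("A", "B"): 0.05,
}
"""Known two-locus pool used for EM-recovery experiments."""


def caller_recovery_rate(
    n_samples: int = 200,
    error_rate: float = 0.0,
    min_identity: float = 0.995,
    mean_depth: float = 100.0,
    seed: int = 0,
) -> float:
    """Fraction of simulated samples whose planted genotype is recovered
    exactly by the counting caller.

    Genotypes are drawn uniformly (with replacement) from a six-allele
    single-gene registry; the identity threshold for noisy runs should
    budget for the error rate (reads carry ~2*error_rate*length expected
    differences from the wrong allele's 4-5% divergence baseline).
    """
    registry = synthetic_registry({"B": _CALLER_ALLELES}, seed=seed)
    names = [a.name for a in registry.gene_alleles("B")]
    rng = np.random.default_rng(seed)
    params = MappingParams(min_identity=min_identity)
    recovered = 0
    for i in range(n_samples):
        pair = rng.choice(len(names), size=2, replace=True)
        truth = sorted({names[pair[0]], names[pair[1]]})
        truth_call = assign_genotype(
            [Candidate(a, 100) for a in truth], sample_id=f"s{i}", gene="B"
        )
        reads = simulate_reads(
            truth_call,
            registry,
            ReadSimParams(mean_depth, error_rate, seed=int(rng.integers(2**31))),
        )
        called = call_sample(reads, registry, params, sample_id=f"s{i}")["B"]
        recovered += set(called.alleles) == set(truth)
    return recovered / n_samples


def em_recovery_max_error(n: int = 500, seed: int = 0) -> float:
    """Max absolute error of EM haplotype-frequency estimates against the
    known two-locus pool they were sampled from."""
    haps = list(EM_TRUTH_POOL)
    p = np.array(list(EM_TRUTH_POOL.values()))
    rng = np.random.default_rng(seed)
    from .haplotype import MultiLocusGenotype

    genotypes = []
    for i in range(n):
        i1, i2 = rng.choice(len(haps), size=2, p=p)
        h1, h2 = haps[i1], haps[i2]
        genotypes.append(
            MultiLocusGenotype(
                f"s{i}",
                ("L0", "L1"),
                (tuple(sorted((h1[0], h2[0]))), tuple(sorted((h1[1], h2[1])))),
            )
        )
    est = em_haplotype_frequencies(genotypes, seed=seed)
    return max(abs(est.frequency(h) - f) for h, f in EM_TRUTH_POOL.items())


def _null_pool() -> HaplotypePool:
    return independent_pool(
        ("B", "C"),
        [
            {"B*51:01:01": 0.3, "B*46:01:01": 0.5, "B*15:02:01": 0.2},
            {"C*14:02:01": 0.25, "C*01:02:01": 0.45, "C*07:02:01": 0.3},
        ],
    )


def null_permutation_pvalues(
    n_replicates: int = 200,
    n_case: int = 40,
    n_control: int = 40,
    n_perm: int = 99,
    seed: int = 0,
) -> list[float]:
    """Permutation p-values when cases and controls are drawn from the
    same pool (should be approximately uniform)."""
    pool = _null_pool()
    ps = []
    for rep in range(n_replicates):
        cohort, _ = simulate_cohort(
            pool, n_case=n_case, n_control=n_control, seed=seed * 100003 + rep
        )
        cases, controls = genotypes_from_cohort(cohort, ("B", "C"))
        res = haplotype_case_control_test(
            cases, controls, n_perm=n_perm, seed=seed + rep
        )
        ps.append(res.p_perm)
    return ps


def ld_power_detection_rate(
    n_replicates: int = 20,
    n_per_group: int = 100,
    d_prime: float = 0.8,
    n_perm: int = 199,
    alpha: float = 0.01,
    seed: int = 0,
) -> float:
    """Fraction of replicates in which the permutation test detects
    (p <= alpha) a planted B-C coupling in cases absent from controls."""
    null_pool = _null_pool()
    coupled = with_ld(
        null_pool, "B", "B*51:01:01", "C", "C*14:02:01", d_prime=d_prime
    )
    detected = 0
    for rep in range(n_replicates):
        ctrl_cohort, _ = simulate_cohort(
            null_pool, n_case=0, n_control=n_per_group, seed=seed * 1009 + rep
        )
        case_cohort, _ = simulate_cohort(
            coupled, n_case=0, n_control=n_per_group, seed=seed * 2003 + rep
        )
        _, controls = genotypes_from_cohort(ctrl_cohort, ("B", "C"))
        _, cases = genotypes_from_cohort(case_cohort, ("B", "C"))
        res = haplotype_case_control_test(
            cases, controls, n_perm=n_perm, seed=seed + rep
        )
        detected += res.p_perm <= alpha
    return detected / n_replicates
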