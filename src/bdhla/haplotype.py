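"""EM haplotype-frequency estimation, linkage disequilibrium, and a
permutation case-control haplotype test.

Phase is unobserved: a subject heterozygous at h of the analysed loci is
consistent with 2^(h-1) unordered haplotype pairs.  Under Hardy-Weinberg
equilibrium the EM algorithm alternates between assigning each subject
posterior weights over its phase pairs (proportional to f(h1)f(h2), twice
that for heterozygous pairs) and re-estimating haplotype frequencies from
the weighted counts.  The case-control test compares haplotype
distributions between groups with the likelihood-ratio heterogeneity
statistic 2(LL_cases + LL_controls - LL_pooled), calibrated by permuting
group labels.

The EM inner loop is vectorised over a precomputed phase-pair expansion
(flat numpy arrays of subject / haplotype indices), which is what makes
permutation nulls with thousands of EM fits affordable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .association import CohortTable

PRUNE_THRESHOLD = 1e-6  # haplotypes below this mass are dropped between iterations


@dataclass(frozen=True)
class MultiLocusGenotype:
    """Unphased genotype over an ordered subset of loci.

    ``allele_pairs[k]`` is the unordered allele pair at ``loci[k]``;
    alleles are opaque labels (formatted allele names in practice).
    """

    subject_id: str
    loci: tuple[str, ...]
    allele_pairs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if len(self.loci) != len(self.allele_pairs):
            raise ValueError("one allele pair required per locus")
        # canonicalise pair order so equality is orientation-free
        object.__setattr__(
            self,
            "allele_pairs",
            tuple(tuple(sorted(p)) for p in self.allele_pairs),
        )

    def restrict(self, loci: tuple[str, ...]) -> "MultiLocusGenotype":
        idx = [self.loci.index(l) for l in loci]
        return MultiLocusGenotype(
            self.subject_id, tuple(loci), tuple(self.allele_pairs[i] for i in idx)
        )

    @property
    def n_het(self) -> int:
        return sum(a != b for a, b in self.allele_pairs)


Haplotype = tuple[str, ...]


def enumerate_phase_pairs(
    g: MultiLocusGenotype,
) -> list[tuple[Haplotype, Haplotype]]:
    """All unordered haplotype pairs consistent with an unphased genotype:
    2^(h-1) pairs for h >= 1 heterozygous loci, 1 pair for h = 0."""
    het = [k for k, (a, b) in enumerate(g.allele_pairs) if a != b]
    base = [a for a, _ in g.allele_pairs]
    if not het:
        hap = tuple(base)
        return [(hap, hap)]
    # fix the orientation of the first heterozygous locus to avoid
    # double-counting unordered pairs
    pairs = []
    for choices in product((0, 1), repeat=len(het) - 1):
        h1, h2 = list(base), [b for _, b in g.allele_pairs]
        # first het locus: h1 keeps allele a, h2 keeps allele b (already set)
        for k, flip in zip(het[1:], choices):
            if flip:
                a, b = g.allele_pairs[k]
                h1[k], h2[k] = b, a
        pairs.append((tuple(h1), tuple(h2)))
    return pairs


@dataclass
class HaplotypeFrequencyEstimate:
    frequencies: dict[Haplotype, float]
    log_likelihood: float
    iterations: int
    converged: bool
    loci: tuple[str, ...] = ()

    def frequency(self, hap: Haplotype) -> float:
        return self.frequencies.get(tuple(hap), 0.0)


class _PhaseExpansion:
    """Flat phase-pair expansion of a genotype list, reusable across
    subject subsets (the permutation test refits EM on label-permuted
    subsets of one pooled expansion)."""

    def __init__(self, genotypes: list[MultiLocusGenotype]):
        if not genotypes:
            raise ValueError("at least one genotype required")
        self.loci = genotypes[0].loci
        for g in genotypes:
            if g.loci != self.loci:
                raise ValueError("all genotypes must share the same loci")
        self.n_subjects = len(genotypes)
        hap_index: dict[Haplotype, int] = {}
        subj, h1, h2 = [], [], []
        for i, g in enumerate(genotypes):
            for a, b in enumerate_phase_pairs(g):
                subj.append(i)
                h1.append(hap_index.setdefault(a, len(hap_index)))
                h2.append(hap_index.setdefault(b, len(hap_index)))
        self.haplotypes: list[Haplotype] = list(hap_index)
        self.n_haps = len(hap_index)
        self.subj = np.asarray(subj, dtype=np.intp)
        self.h1 = np.asarray(h1, dtype=np.intp)
        self.h2 = np.asarray(h2, dtype=np.intp)
        self.coef = np.where(self.h1 == self.h2, 1.0, 2.0)
        # allele-product initialisation: product of locus-wise allele
        # frequencies counted directly from the genotypes
        locus_freqs: list[dict[str, float]] = []
        for k in range(len(self.loci)):
            counts: dict[str, float] = {}
            for g in genotypes:
                for allele in g.allele_pairs[k]:
                    counts[allele] = counts.get(allele, 0.0) + 1.0
            total = sum(counts.values())
            locus_freqs.append({a: c / total for a, c in counts.items()})
        prod_init = np.array(
            [
                np.prod([locus_freqs[k][h[k]] for k in range(len(self.loci))])
                for h in self.haplotypes
            ]
        )
        self.allele_product_init = prod_init / prod_init.sum()

    def em(
        self,
        include: np.ndarray | None = None,
        init: np.ndarray | str = "allele_product",
        tol: float = 1e-8,
        max_iter: int = 1000,
    ) -> tuple[np.ndarray, float, int, bool]:
        """Run EM on the subjects selected by the boolean ``include`` mask.

        Returns (frequencies over self.haplotypes, log-likelihood,
        iterations, converged).
        """
        if include is None:
            row_mask = np.ones(len(self.subj), dtype=bool)
            n_inc = self.n_subjects
        else:
            row_mask = include[self.subj]
            n_inc = int(include.sum())
            if n_inc == 0:
                raise ValueError("empty subject subset")
        if isinstance(init, str):
            if init == "uniform":
                f = np.full(self.n_haps, 1.0 / self.n_haps)
            elif init == "allele_product":
                f = self.allele_product_init.copy()
            else:
                raise ValueError(f"unknown init {init!r}")
        else:
            f = np.asarray(init, dtype=float)
            f = f / f.sum()

        subj, h1, h2 = self.subj[row_mask], self.h1[row_mask], self.h2[row_mask]
        coef = self.coef[row_mask]
        ll_prev = -np.inf
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            w = coef * f[h1] * f[h2]
            tot = np.bincount(subj, weights=w, minlength=self.n_subjects)
            tot_rows = tot[subj]
            ll = float(np.sum(np.log(tot[tot > 0])))
            post = w / np.where(tot_rows > 0, tot_rows, 1.0)
            counts = np.bincount(h1, weights=post, minlength=self.n_haps)
            counts += np.bincount(h2, weights=post, minlength=self.n_haps)
            f_new = counts / (2.0 * n_inc)
            # prune negligible-mass haplotypes, renormalise
            f_new[f_new < PRUNE_THRESHOLD] = 0.0
            f_new = f_new / f_new.sum()
            if ll < ll_prev - 1e-9:
                raise AssertionError(
                    f"EM log-likelihood decreased: {ll_prev} -> {ll}"
                )
            if ll - ll_prev < tol:
                f = f_new
                converged = True
                break
            f, ll_prev = f_new, ll
        return f, ll, it, converged


def em_haplotype_frequencies(
    genotypes: list[MultiLocusGenotype],
    tol: float = 1e-8,
    max_iter: int = 1000,
    init: str = "allele_product",
    n_restarts: int = 3,
    seed: int = 0,
) -> HaplotypeFrequencyEstimate:
    """Maximum-likelihood haplotype frequencies under HWE via EM.

    Beyond the deterministic first run (with the requested ``init``),
    ``n_restarts - 1`` additional runs start from seeded random Dirichlet
    points to guard against local optima; the best log-likelihood wins.
    """
    exp = _PhaseExpansion(genotypes)
    best = exp.em(init=init, tol=tol, max_iter=max_iter)
    rng = np.random.default_rng(seed)
    for _ in range(max(0, n_restarts - 1)):
        trial = exp.em(
            init=rng.dirichlet(np.ones(exp.n_haps)), tol=tol, max_iter=max_iter
        )
        if trial[1] > best[1]:
            best = trial
    f, ll, iters, converged = best
    freqs = {
        hap: float(f[i]) for i, hap in enumerate(exp.haplotypes) if f[i] > 0
    }
    return HaplotypeFrequencyEstimate(
        frequencies=freqs,
        log_likelihood=ll,
        iterations=iters,
        converged=converged,
        loci=exp.loci,
    )


def ld_stats(
    est: HaplotypeFrequencyEstimate, target: Haplotype
) -> tuple[float, float, float]:
    """Two-locus linkage disequilibrium (D, D', r^2) for a focal
    haplotype AB in a two-locus frequency estimate.

    D = p_AB - p_A p_B; D' normalises D by its attainable extreme given
    the marginals; r^2 = D^2 / (p_A(1-p_A) p_B(1-p_B)).
    """
    if len(target) != 2:
        raise ValueError("LD target must be a two-locus haplotype")
    a, b = target
    p_ab = est.frequency(target)
    p_a = sum(f for h, f in est.frequencies.items() if h[0] == a)
    p_b = sum(f for h, f in est.frequencies.items() if h[1] == b)
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    if denom <= 0:
        raise ValueError("monomorphic locus: LD undefined")
    d = p_ab - p_a * p_b
    if d > 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    elif d < 0:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    else:
        return 0.0, 0.0, 0.0
    return d, d / d_max, d * d / denom


@dataclass(frozen=True)
class PermutationResult:
    observed_statistic: float
    p_perm: float
    n_perm: int
    seed: int
    pc: float
    loci: tuple[str, ...] = ()
    target: tuple[str, ...] | None = None


def haplotype_case_control_test(
    cases: list[MultiLocusGenotype],
    controls: list[MultiLocusGenotype],
    n_perm: int = 10000,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> PermutationResult:
    """Permutation test of haplotype-frequency heterogeneity between
    cases and controls.

    Statistic: 2(LL_cases + LL_controls - LL_pooled) at the EM optima.
    Null: group labels permuted; p by the add-one rule
    (1 + #{perm >= obs}) / (1 + n_perm).
    """
    if not cases or not controls:
        raise ValueError("both groups must be non-empty")
    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} gives a coarse permutation p", stacklevel=2
        )
    exp = _PhaseExpansion(list(cases) + list(controls))
    n_case = len(cases)
    n_all = exp.n_subjects
    labels = np.zeros(n_all, dtype=bool)
    labels[:n_case] = True

    _, ll_pooled, _, _ = exp.em(tol=tol, max_iter=max_iter)

    def split_stat(case_mask: np.ndarray) -> float:
        _, ll_case, _, _ = exp.em(include=case_mask, tol=tol, max_iter=max_iter)
        _, ll_ctrl, _, _ = exp.em(include=~case_mask, tol=tol, max_iter=max_iter)
        return 2.0 * (ll_case + ll_ctrl - ll_pooled)

    observed = split_stat(labels)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        exceed += split_stat(rng.permutation(labels)) >= observed
    p = (1 + exceed) / (1 + n_perm)
    return PermutationResult(
        observed_statistic=observed,
        p_perm=p,
        n_perm=n_perm,
        seed=seed,
        pc=p,
        loci=exp.loci,
    )


def pairwise_scan(
    cases: list[MultiLocusGenotype],
    controls: list[MultiLocusGenotype],
    locus_pairs: list[tuple[str, str]],
    n_perm: int = 10000,
    seed: int = 0,
) -> list[PermutationResult]:
    """One permutation test per locus pair, Bonferroni-corrected by the
    number of pairs scanned (pc capped at 1 in the scan report)."""
    if not locus_pairs:
        raise ValueError("at least one locus pair required")
    m = len(locus_pairs)
    results = []
    for i, pair in enumerate(locus_pairs):
        res = haplotype_case_control_test(
            [g.restrict(pair) for g in cases],
            [g.restrict(pair) for g in controls],
            n_perm=n_perm,
            seed=seed + i,
        )
        results.append(
            PermutationResult(
                observed_statistic=res.observed_statistic,
                p_perm=res.p_perm,
                n_perm=res.n_perm,
                seed=res.seed,
                pc=min(1.0, res.p_perm * m),
                loci=tuple(pair),
            )
        )
    return results


def genotypes_from_cohort(
    cohort: CohortTable, loci: tuple[str, ...], resolution: int = 3
) -> tuple[list[MultiLocusGenotype], list[MultiLocusGenotype]]:
    """Extract (cases, controls) multi-locus genotypes from a cohort,
    dropping subjects with a no-call at any requested locus."""
    def convert(subjects):
        out = []
        for s in subjects:
            pairs = []
            for locus in loci:
                call = s.genotypes.get(locus)
                if call is None or not call.is_call:
                    break
                a1, a2 = call.allele_pair()
                pairs.append(
                    (
                        str(a1.truncate(min(resolution, a1.resolution))),
                        str(a2.truncate(min(resolution, a2.resolution))),
                    )
                )
            else:
                out.append(
                    MultiLocusGenotype(s.subject_id, tuple(loci), tuple(pairs))
                )
        return out

    return convert(cohort.cases), convert(cohort.controls)
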