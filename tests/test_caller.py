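import numpy as np
import pytest

from bdhla.caller import (
    Candidate,
    ConsensusRead,
    MappingParams,
    assign_genotype,
    call_sample,
    count_reads,
    map_read_to_allele,
    reverse_complement,
    select_candidates,
    verify_assignment,
)
from bdhla.nomenclature import AlleleRegistry, ReferenceAllele, parse_allele_name
from bdhla.synthdata import ReadSimParams, simulate_reads, synthetic_registry


def _ref(allele: str, seq: str) -> ReferenceAllele:
    return ReferenceAllele(name=parse_allele_name(allele), sequence=seq)


def _random_seq(n: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


@pytest.fixture
def kilobase_ref():
    return _ref("B*51:01:01", _random_seq(1000, 7))


def _substitute(seq: str, positions, rng) -> str:
    out = list(seq)
    for p in positions:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)


class TestMapping:
    def test_exact_read_maps_at_identity_one(self, kilobase_ref):
        read = ConsensusRead("r1", kilobase_ref.sequence)
        v = map_read_to_allele(read, kilobase_ref, MappingParams())
        assert v.mapped and v.identity == 1.0

    def test_reverse_complement_maps_when_both_strands(self, kilobase_ref):
        read = ConsensusRead("r1", reverse_complement(kilobase_ref.sequence))
        both = map_read_to_allele(read, kilobase_ref, MappingParams())
        assert both.mapped and both.strand == "-"
        fwd_only = map_read_to_allele(
            read, kilobase_ref, MappingParams(check_both_strands=False)
        )
        assert not fwd_only.mapped

    def test_substitution_identity_matches_edit_distance(
        self, kilobase_ref, edit_distance_oracle
    ):
        """2 substitutions on 1 kb -> identity 0.998, passes 0.995;
        10 substitutions -> 0.990, fails.  Identity cross-checked against
        an independent DP edit distance on a 300-base slice."""
        rng = np.random.default_rng(0)
        params = MappingParams(min_identity=0.995)
        two = ConsensusRead("r2", _substitute(kilobase_ref.sequence, [100, 500], rng))
        v2 = map_read_to_allele(two, kilobase_ref, params)
        assert v2.mapped and v2.identity == pytest.approx(0.998, abs=1e-9)
        ten = ConsensusRead(
            "r10", _substitute(kilobase_ref.sequence, range(50, 1000, 100), rng)
        )
        v10 = map_read_to_allele(ten, kilobase_ref, params)
        assert not v10.mapped
        # independent oracle on a short slice: distance == substitutions
        short_ref = _ref("B*51:01:02", kilobase_ref.sequence[:300])
        short_read = ConsensusRead("rs", two.sequence[:300])
        d = edit_distance_oracle(short_read.sequence, short_ref.sequence)
        v = map_read_to_allele(short_read, short_ref, MappingParams(min_identity=0.5))
        assert v.identity == pytest.approx((300 - d) / 300, abs=1e-9)

    def test_degenerate_short_read_never_maps(self, kilobase_ref):
        v = map_read_to_allele(
            ConsensusRead("tiny", "ACGT" * 10), kilobase_ref, MappingParams()
        )
        assert not v.mapped


class TestCounting:
    def test_identical_reads_count_only_their_allele(self):
        refs = [
            _ref("B*51:01:01", _random_seq(500, 1)),
            _ref("A*11:01:01", _random_seq(500, 2)),
            _ref("C*01:02:01", _random_seq(500, 3)),
        ]
        registry = AlleleRegistry(version="t", alleles=refs)
        reads = [ConsensusRead(f"r{i}", refs[0].sequence) for i in range(100)]
        per_gene = count_reads(reads, registry)
        assert per_gene["B"].counts[refs[0].name] == 100
        assert per_gene["A"].counts[refs[1].name] == 0
        assert per_gene["C"].counts[refs[2].name] == 0

    def test_no_reads_all_zero(self):
        registry = AlleleRegistry(alleles=[_ref("B*51:01:01", _random_seq(500, 1))])
        per_gene = count_reads([], registry)
        assert set(per_gene["B"].counts.values()) == {0}

    def test_counts_proportional_to_simulated_mixture(self):
        """Error-free reads from two alleles at 60:40 produce counts in
        exactly that proportion (planted-truth oracle)."""
        registry = synthetic_registry({"B": ["B*51:01:01", "B*46:01:01"]}, seed=5)
        a1, a2 = (a.name for a in registry.gene_alleles("B"))
        reads = [
            ConsensusRead(f"x{i}", registry.get(a1).sequence) for i in range(60)
        ] + [ConsensusRead(f"y{i}", registry.get(a2).sequence) for i in range(40)]
        counts = count_reads(reads, registry)["B"].counts
        assert counts[a1] == 60 and counts[a2] == 40

    def test_raising_min_identity_never_increases_counts(self):
        registry = synthetic_registry({"B": ["B*51:01:01", "B*46:01:01"]}, seed=6)
        truth = assign_genotype(
            [Candidate(a.name, 100) for a in registry.gene_alleles("B")]
        )
        reads = simulate_reads(truth, registry, ReadSimParams(30, 0.01, seed=9))
        prev = None
        for ident in (0.95, 0.97, 0.99, 0.995):
            counts = count_reads(reads, registry, MappingParams(min_identity=ident))
            total = {g: dict(c.counts) for g, c in counts.items()}
            if prev is not None:
                for g in total:
                    for allele, n in total[g].items():
                        assert n <= prev[g][allele]
            prev = total


class TestCandidatesAndGenotype:
    def _cands(self, counts):
        registry_names = [
            "B*51:01:01", "B*46:01:01", "B*15:02:01", "B*40:01:02", "B*58:01:01",
        ]
        from bdhla.caller import AlleleReadCounts

        return AlleleReadCounts(
            sample_id="s",
            gene="B",
            counts={
                parse_allele_name(n): c for n, c in zip(registry_names, counts)
            },
        )

    def test_threshold_and_truncation(self):
        got = select_candidates(self._cands([400, 350, 60, 55, 49]))
        assert [c.count for c in got] == [400, 350, 60, 55]

    def test_single_candidate(self):
        got = select_candidates(self._cands([400, 0, 0, 0, 0]))
        assert len(got) == 1 and got[0].count == 400

    def test_tie_break_is_lexicographic_and_total(self):
        got = select_candidates(self._cands([100, 100, 100, 100, 100]))
        assert len(got) == 4
        names = [str(c.allele) for c in got]
        assert names == sorted(names)
        assert select_candidates(self._cands([100] * 5)) == got  # deterministic

    def test_raising_min_reads_never_lengthens_list(self):
        counts = self._cands([400, 350, 60, 55, 49])
        lengths = [
            len(select_candidates(counts, min_reads=m)) for m in (1, 50, 60, 400, 500)
        ]
        assert lengths == sorted(lengths, reverse=True)

    def test_heterozygous_pair(self):
        call = assign_genotype(
            [
                Candidate(parse_allele_name("A*11:01:01"), 420),
                Candidate(parse_allele_name("A*24:02:01"), 390),
            ]
        )
        assert call.zygosity == "heterozygous"
        assert {str(a) for a in call.alleles} == {"A*11:01:01", "A*24:02:01"}

    def test_homozygous_when_second_below_ratio(self):
        call = assign_genotype(
            [
                Candidate(parse_allele_name("B*51:01:01"), 500),
                Candidate(parse_allele_name("B*35:01:01"), 60),
            ],
            het_ratio=0.25,
        )
        assert call.zygosity == "homozygous"
        assert [str(a) for a in call.alleles] == ["B*51:01:01"]

    def test_third_passing_candidate_flags_ambiguous(self):
        call = assign_genotype(
            [
                Candidate(parse_allele_name("B*51:01:01"), 400),
                Candidate(parse_allele_name("B*46:01:01"), 380),
                Candidate(parse_allele_name("B*15:02:01"), 150),
            ]
        )
        assert call.zygosity == "ambiguous" and len(call.alleles) == 3

    def test_empty_candidates_is_no_call(self):
        call = assign_genotype([], sample_id="s", gene="B")
        assert not call.is_call and call.alleles == ()


class TestVerifyAssignment:
    def test_exact_consensus(self, kilobase_ref):
        rep = verify_assignment(
            ConsensusRead("c", kilobase_ref.sequence), kilobase_ref
        )
        assert rep.is_exact and not rep.potential_novel

    def test_single_substitution_reported(self, kilobase_ref):
        rng = np.random.default_rng(1)
        mutated = _substitute(kilobase_ref.sequence, [250], rng)
        rep = verify_assignment(ConsensusRead("c", mutated), kilobase_ref)
        assert rep.substitutions == 1 and rep.indels == 0
        assert rep.potential_novel

    def test_indel_reported(self, kilobase_ref):
        seq = kilobase_ref.sequence[:400] + kilobase_ref.sequence[403:]
        rep = verify_assignment(ConsensusRead("c", seq), kilobase_ref)
        assert rep.deletions == 3 and rep.substitutions == 0

    def test_unrelated_sequences_flagged_novel(self, edit_distance_oracle):
        """Random 1 kb vs unrelated 1 kb: identity far below any call
        threshold; counts agree with the DP oracle on a 200-base slice."""
        a, b = _random_seq(1000, 10), _random_seq(1000, 11)
        rep = verify_assignment(ConsensusRead("c", a), _ref("B*51:01:01", b))
        assert 0.2 < rep.identity < 0.55
        assert rep.potential_novel
        short = verify_assignment(
            ConsensusRead("c", a[:200]), _ref("B*51:01:02", b[:200])
        )
        d = edit_distance_oracle(a[:200], b[:200])
        assert short.substitutions + short.insertions + short.deletions == d


class TestEndToEnd:
    def test_error_free_recovery_and_determinism(self):
        registry = synthetic_registry(
            {"B": ["B*51:01:01", "B*46:01:01", "B*15:02:01"]}, seed=2
        )
        a1, a2, _ = (a.name for a in registry.gene_alleles("B"))
        truth = assign_genotype([Candidate(a1, 100), Candidate(a2, 100)])
        for seed in range(5):
            reads = simulate_reads(truth, registry, ReadSimParams(100, 0.0, seed=seed))
            call = call_sample(reads, registry, sample_id="s")["B"]
            again = call_sample(reads, registry, sample_id="s")["B"]
            assert set(call.alleles) == {a1, a2}
            assert call == again  # deterministic

    def test_depth_below_min_reads_gives_no_call(self):
        registry = synthetic_registry({"B": ["B*51:01:01", "B*46:01:01"]}, seed=2)
        a1 = registry.gene_alleles("B")[0].name
        truth = assign_genotype([Candidate(a1, 100)])
        reads = simulate_reads(truth, registry, ReadSimParams(10, 0.0, seed=0))
        call = call_sample(reads, registry, sample_id="s")["B"]
        assert not call.is_call
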