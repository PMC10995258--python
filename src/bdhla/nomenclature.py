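"""HLA allele nomenclature and the reference-allele registry.

HLA alleles are named by gene plus up to four colon-separated fields
(``HLA-B*51:01:02``): field 1 is the allele group, field 2 the specific
protein, field 3 synonymous coding changes, field 4 non-coding changes.
"Six-digit" typing in the older digit-counting idiom corresponds to
three-field resolution.  Fields are kept as strings so that leading zeros
and rare expression-suffix letters (e.g. ``N``) survive a round trip.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from Bio import SeqIO

GENES = ("A", "B", "C", "DPB1", "DQB1", "DRB1")
"""The six classical loci handled: class I (A, B, C) and class II (DPB1, DQB1, DRB1)."""

# gene, then 1-4 fields; digits with an optional trailing expression letter
# on the last field only.
_ALLELE_RE = re.compile(
    r"^(?:HLA-)?(?P<gene>[A-Z]+[0-9]*)\*(?P<fields>[0-9]+(?::[0-9]+){0,3}[A-Z]?)$"
)
_FIELD_RE = re.compile(r"^[0-9]+[A-Z]?$")


class AlleleNameError(ValueError):
    """Raised when a string cannot be parsed as a valid HLA allele name."""


@dataclass(frozen=True, order=True)
class AlleleName:
    """A structured HLA allele name: gene symbol plus 1-4 resolution fields."""

    gene: str
    fields: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.gene not in GENES:
            raise AlleleNameError(f"unknown HLA gene symbol: {self.gene!r}")
        if not 1 <= len(self.fields) <= 4:
            raise AlleleNameError(
                f"allele must have 1-4 fields, got {len(self.fields)}"
            )
        for i, f in enumerate(self.fields):
            ok = _FIELD_RE.match(f) and (f[-1].isdigit() or i == len(self.fields) - 1)
            if not ok:
                raise AlleleNameError(f"malformed allele field: {f!r}")

    @property
    def resolution(self) -> int:
        """Number of fields (2 = protein level, 3 = 'six-digit')."""
        return len(self.fields)

    def truncate(self, n_fields: int) -> "AlleleName":
        """Reduce to the first ``n_fields`` fields (gene unchanged)."""
        if not 1 <= n_fields <= len(self.fields):
            raise AlleleNameError(
                f"cannot truncate {self} to {n_fields} fields "
                f"(has {len(self.fields)})"
            )
        return AlleleName(self.gene, self.fields[:n_fields])

    def __str__(self) -> str:
        return f"{self.gene}*{':'.join(self.fields)}"


def parse_allele_name(text: str) -> AlleleName:
    """Parse ``HLA-B*51:01:02`` / ``B*51:01:02`` into an :class:`AlleleName`."""
    m = _ALLELE_RE.match(text.strip())
    if m is None:
        raise AlleleNameError(f"not a valid HLA allele name: {text!r}")
    gene = m.group("gene")
    if gene not in GENES:
        raise AlleleNameError(f"unknown HLA gene symbol: {gene!r} in {text!r}")
    return AlleleName(gene, tuple(m.group("fields").split(":")))


def format_allele_name(name: AlleleName, hla_prefix: bool = False) -> str:
    """Render an allele name, optionally with the ``HLA-`` prefix."""
    return ("HLA-" if hla_prefix else "") + str(name)


def truncate_resolution(name: AlleleName, n_fields: int) -> AlleleName:
    return name.truncate(n_fields)


@dataclass(frozen=True)
class ReferenceAllele:
    """A reference allele sequence from the registry."""

    name: AlleleName
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for reference allele {self.name}")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(
                f"non-nucleotide characters {sorted(bad)} in {self.name}"
            )


@dataclass
class AlleleRegistry:
    """A set of reference alleles indexed by gene and by name.

    ``version`` is a free-text tag (e.g. the database release the sequences
    were taken from, or a synthetic-registry seed tag) and is surfaced in
    reports.
    """

    version: str = "unversioned"
    alleles: list[ReferenceAllele] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_name: dict[AlleleName, ReferenceAllele] = {}
        self._by_gene: dict[str, list[ReferenceAllele]] = {}
        for a in list(self.alleles):
            self._index(a)

    def _index(self, allele: ReferenceAllele) -> None:
        if allele.name in self._by_name:
            raise ValueError(f"duplicate allele name in registry: {allele.name}")
        self._by_name[allele.name] = allele
        self._by_gene.setdefault(allele.name.gene, []).append(allele)

    def add(self, allele: ReferenceAllele) -> None:
        self._index(allele)
        if allele not in self.alleles:
            self.alleles.append(allele)

    def get(self, name: AlleleName) -> ReferenceAllele:
        return self._by_name[name]

    def __contains__(self, name: AlleleName) -> bool:
        return name in self._by_name

    def __len__(self) -> int:
        return len(self.alleles)

    def __iter__(self) -> Iterator[ReferenceAllele]:
        return iter(self.alleles)

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(g for g in GENES if g in self._by_gene)

    def gene_alleles(self, gene: str) -> list[ReferenceAllele]:
        return list(self._by_gene.get(gene, []))


def _allele_from_header(header: str) -> AlleleName:
    """Extract the first parseable allele token from a FASTA header.

    Accepts both the plain ``>HLA-B*51:01:01`` dialect and database-dump
    headers like ``>HLA:HLA00344 B*51:01:01 1063 bp`` — the first
    whitespace-separated token that parses as an allele name wins.
    """
    for token in header.replace(",", " ").split():
        try:
            return parse_allele_name(token)
        except AlleleNameError:
            continue
    raise AlleleNameError(f"no parseable allele name in FASTA header: {header!r}")


def load_reference_fasta(path, version: str = "unversioned") -> AlleleRegistry:
    """Load a reference-allele FASTA into an :class:`AlleleRegistry`.

    Duplicate allele names raise; an empty file yields an empty registry
    with a warning.
    """
    registry = AlleleRegistry(version=version)
    for record in SeqIO.parse(str(path), "fasta"):
        name = _allele_from_header(record.description)
        seq = str(record.seq).upper()
        registry.add(ReferenceAllele(name=name, sequence=seq))
    if len(registry) == 0:
        warnings.warn(f"no reference alleles found in {path}", stacklevel=2)
    return registry


def write_reference_fasta(registry: AlleleRegistry, path) -> None:
    with open(path, "w") as fh:
        for allele in registry:
            fh.write(f">HLA-{allele.name} synthetic\n")
            seq = allele.sequence
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
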