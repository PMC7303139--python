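"""Shared record types for proteome mining.

All genomic coordinates are GFF3-style: 1-based, inclusive on both ends.
Interval arithmetic elsewhere in the package assumes this convention, so the
intron between exons ``(s1, e1)`` and ``(s2, e2)`` spans ``(e1+1, s2-1)`` and
has length ``s2 - e1 - 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: The 20 canonical amino-acid letters. ``X`` is the only ambiguity code
#: accepted anywhere in the package; it scores zero against everything.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = CANONICAL_AA + "X"

_VALID = frozenset(ALPHABET)


class FormatError(ValueError):
    """A file or record violates the expected format."""


def validate_sequence(seq: str, *, where: str = "sequence") -> str:
    """Uppercase and validate an amino-acid string.

    Only the 20 canonical letters plus ``X`` are accepted; other ambiguity
    codes (B, Z, J, U, O, ``*``) are rejected.
    """
    if not seq:
        raise FormatError(f"{where}: empty sequence")
    seq = seq.upper()
    bad = set(seq) - _VALID
    if bad:
        raise FormatError(
            f"{where}: invalid amino-acid letter(s) {sorted(bad)}; "
            f"only the 20 canonical letters plus X are accepted"
        )
    return seq


@dataclass
class ProteinRecord:
    """An identified amino-acid sequence, optionally tied to a gene model."""

    id: str
    sequence: str
    description: str = ""
    scaffold_id: str | None = None
    gene_index_on_scaffold: int | None = None

    def __post_init__(self) -> None:
        self.sequence = validate_sequence(self.sequence, where=f"protein {self.id!r}")
        if self.gene_index_on_scaffold is not None and self.gene_index_on_scaffold < 0:
            raise ValueError(f"protein {self.id!r}: negative gene index")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneModel:
    """A protein-coding gene model: ordered exons on a scaffold.

    Exons are stored in ascending genomic coordinates regardless of strand;
    strand is retained for reporting only (tandem-array detection works in
    genomic order).
    """

    gene_id: str
    scaffold_id: str
    strand: str
    exons: list[tuple[int, int]]
    protein_id: str
    gene_index_on_scaffold: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id!r}: strand must be '+' or '-'")
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        prev_end = None
        for s, e in self.exons:
            if s > e or s < 1:
                raise FormatError(f"gene {self.gene_id!r}: bad exon ({s}, {e})")
            if prev_end is not None and s <= prev_end:
                raise FormatError(f"gene {self.gene_id!r}: overlapping exons")
            prev_end = e

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def exon_lengths(self) -> list[int]:
        return [e - s + 1 for s, e in self.exons]

    def intron_lengths(self) -> list[int]:
        return [
            self.exons[i + 1][0] - self.exons[i][1] - 1
            for i in range(len(self.exons) - 1)
        ]


@dataclass
class ArchetypeEntry:
    """A previously characterised anticoagulant used as a search archetype.

    ``synonyms`` hold lower-cased description substrings considered
    family-consistent when judging reciprocal-search hits.
    """

    name: str
    family: str
    accession: str
    species: str
    sequence: str
    known_cys_count: int | None = None
    synonyms: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.family:
            raise FormatError(f"archetype {self.name!r}: empty family")
        self.sequence = validate_sequence(self.sequence, where=f"archetype {self.name!r}")
        self.synonyms = [s.lower() for s in self.synonyms if s]
        if self.known_cys_count is not None and self.known_cys_count < 0:
            raise ValueError(f"archetype {self.name!r}: negative cysteine count")

    def as_protein(self) -> ProteinRecord:
        return ProteinRecord(id=self.accession or self.name, sequence=self.sequence,
                             description=f"{self.name} [{self.species}]")


@dataclass
class SignalPeptideAnnotation:
    """Externally computed signal-peptide call for one protein."""

    protein_id: str
    present: bool
    region: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.region is not None:
            if not self.present:
                raise FormatError(
                    f"{self.protein_id}: signal-peptide region given but present=False"
                )
            s, e = self.region
            if s != 1 or e < s:
                raise FormatError(
                    f"{self.protein_id}: signal-peptide region must start at 1"
                )

    def __str__(self) -> str:
        if self.present and self.region:
            return f"Yes ({self.region[0]}-{self.region[1]})"
        return "Yes" if self.present else "No"
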