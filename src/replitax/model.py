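"""Domain types shared by all pipeline stages.

Coordinates follow GFF conventions on input (1-based, inclusive); helpers
for converting to 0-based half-open slices are provided here and used
internally everywhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "Replicon",
    "GeneRecord",
    "ProteinRecord",
    "GenomeAssembly",
    "ValidationError",
    "to_slice",
    "from_slice",
]

_DNA_ALPHABET = frozenset("ACGTN")
_AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants."""


def to_slice(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive (GFF) -> 0-based half-open (python slice)."""
    if start < 1 or end < start:
        raise ValidationError(f"bad 1-based interval [{start}, {end}]")
    return start - 1, end


def from_slice(lo: int, hi: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    if lo < 0 or hi <= lo:
        raise ValidationError(f"bad 0-based interval [{lo}, {hi})")
    return lo + 1, hi


@dataclass
class Replicon:
    """One circular (or linear) DNA sequence of an assembly."""

    id: str
    sequence: str
    topology: str = "circular"

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValidationError(f"replicon {self.id!r}: empty sequence")
        bad = set(self.sequence) - _DNA_ALPHABET
        if bad:
            raise ValidationError(
                f"replicon {self.id!r}: invalid characters {sorted(bad)}"
            )
        if self.topology not in ("circular", "linear"):
            raise ValidationError(
                f"replicon {self.id!r}: topology must be circular|linear"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class GeneRecord:
    """Annotated gene location. 1-based inclusive coordinates, GFF style."""

    gene_id: str
    replicon_id: str
    start: int
    end: int
    strand: str
    product: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"gene {self.gene_id!r}: start {self.start} > end {self.end}"
            )
        if self.start < 1:
            raise ValidationError(f"gene {self.gene_id!r}: start < 1")
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"gene {self.gene_id!r}: strand must be '+' or '-'"
            )

    @property
    def slice(self) -> tuple[int, int]:
        return to_slice(self.start, self.end)


@dataclass
class ProteinRecord:
    gene_id: str
    aa_sequence: str

    def __post_init__(self) -> None:
        self.aa_sequence = self.aa_sequence.upper().rstrip("*")
        if not self.aa_sequence:
            raise ValidationError(f"protein {self.gene_id!r}: empty sequence")
        bad = set(self.aa_sequence) - _AA_ALPHABET
        if bad:
            raise ValidationError(
                f"protein {self.gene_id!r}: invalid residues {sorted(bad)}"
            )


@dataclass
class GenomeAssembly:
    """Ordered replicons of one strain plus its annotation and proteome."""

    strain: str
    replicons: list[Replicon] = field(default_factory=list)
    genes: list[GeneRecord] = field(default_factory=list)
    proteome: list[ProteinRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rep in self.replicons:
            if rep.id in seen:
                raise ValidationError(
                    f"assembly {self.strain!r}: duplicate replicon id {rep.id!r}"
                )
            seen.add(rep.id)
        dangling = sorted(
            {g.replicon_id for g in self.genes if g.replicon_id not in seen}
        )
        if dangling:
            raise ValidationError(
                f"assembly {self.strain!r}: genes reference unknown replicons "
                f"{dangling}"
            )
        by_id = {r.id: r for r in self.replicons}
        for g in self.genes:
            if g.end > by_id[g.replicon_id].length:
                raise ValidationError(
                    f"gene {g.gene_id!r}: end {g.end} beyond replicon "
                    f"{g.replicon_id!r} length {by_id[g.replicon_id].length}"
                )

    @property
    def total_length(self) -> int:
        return sum(r.length for r in self.replicons)

    def replicon(self, replicon_id: str) -> Replicon:
        for r in self.replicons:
            if r.id == replicon_id:
                return r
        raise KeyError(replicon_id)

    def genes_on(self, replicon_id: str) -> list[GeneRecord]:
        """Genes on one replicon, sorted by start coordinate."""
        return sorted(
            (g for g in self.genes if g.replicon_id == replicon_id),
            key=lambda g: (g.start, g.gene_id),
        )

    def protein(self, gene_id: str) -> ProteinRecord:
        for p in self.proteome:
            if p.gene_id == gene_id:
                return p
        raise KeyError(gene_id)

    @property
    def proteins_by_id(self) -> dict[str, str]:
        return {p.gene_id: p.aa_sequence for p in self.proteome}
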