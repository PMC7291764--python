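"""Core domain types: sequences, lineages, training sets.

A training set is a FASTA collection in which every sequence carries its full
taxonomic lineage in the header, the format consumed by naive Bayesian
(RDP-style) classifiers.  Lineages are either 7 ranks deep
(Kingdom..Genus,Species) or 8 ranks deep with a training-set-specific
``Supraspecies`` rank inserted between Genus and Species.  Supraspecies groups
species whose sequences over the targeted gene region are indistinguishable or
phylogenetically too close to separate reliably; it is not a formal taxonomic
rank.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

RANKS7: tuple[str, ...] = (
    "Kingdom", "Phylum", "Class", "Order", "Family", "Genus", "Species",
)
RANKS8: tuple[str, ...] = (
    "Kingdom", "Phylum", "Class", "Order", "Family", "Genus",
    "Supraspecies", "Species",
)

#: characters allowed in sequences (IUPAC nucleotide codes + gap for alignments)
IUPAC_CODES = frozenset("ACGTURYSWKMBDHVN")
GAP_CHARS = frozenset("-.")


class HabitaxError(Exception):
    """Base class for all errors raised by this package."""


class MalformedTrainingSetError(HabitaxError):
    """A training-set FASTA violates the lineage-header contract."""


def concat_label(components: Iterable[str]) -> str:
    """Join label components with ":" in lexicographic order.

    Components that are themselves concatenated are first split, so the result
    is always a flat, sorted, duplicate-free ":"-join.
    """
    flat: set[str] = set()
    for c in components:
        flat.update(c.split(":"))
    return ":".join(sorted(flat))


def label_components(label: str) -> frozenset[str]:
    """Component set of a possibly ":"-concatenated label."""
    return frozenset(label.split(":"))


@dataclass(frozen=True)
class Lineage:
    """An ordered, fixed-depth taxonomic lineage.

    ``labels`` holds one label per rank, Kingdom first.  Depth 7 uses
    :data:`RANKS7`; depth 8 inserts Supraspecies before Species.  Labels may
    not contain ";" (the header separator); ":" concatenates merged taxa
    within a single label.
    """

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) not in (7, 8):
            raise ValueError(
                f"lineage must have 7 or 8 ranks, got {len(self.labels)}: "
                f"{self.labels!r}"
            )
        for lab in self.labels:
            if ";" in lab:
                raise ValueError(f"lineage label contains ';': {lab!r}")

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_header(cls, header: str) -> "Lineage":
        """Parse a ";"-separated lineage header (trailing ";" tolerated)."""
        text = header.strip()
        if text.startswith(">"):
            text = text[1:]
        if text.endswith(";"):
            text = text[:-1]
        parts = tuple(p.strip() for p in text.split(";"))
        if len(parts) not in (7, 8):
            raise MalformedTrainingSetError(
                f"header has {len(parts)} ';'-separated fields, "
                f"expected 7 or 8: {header!r}"
            )
        return cls(parts)

    def to_header(self) -> str:
        return ";".join(self.labels)

    # -- accessors ------------------------------------------------------------

    @property
    def depth(self) -> int:
        return len(self.labels)

    @property
    def rank_names(self) -> tuple[str, ...]:
        return RANKS7 if self.depth == 7 else RANKS8

    def label(self, rank: str) -> str:
        try:
            return self.labels[self.rank_names.index(rank)]
        except ValueError:
            raise KeyError(f"rank {rank!r} not present at depth {self.depth}")

    @property
    def genus(self) -> str:
        return self.label("Genus")

    @property
    def species(self) -> str:
        return self.label("Species")

    @property
    def supraspecies(self) -> str:
        return self.label("Supraspecies")

    def items(self) -> Iterator[tuple[str, str]]:
        return zip(self.rank_names, self.labels)

    # -- depth conversions ----------------------------------------------------

    def with_supraspecies(self, supraspecies: Optional[str] = None) -> "Lineage":
        """Return the depth-8 version of a depth-7 lineage.

        When ``supraspecies`` is None the species label is repeated, the
        convention for taxa that were not merged with any other.
        """
        if self.depth != 7:
            raise ValueError("with_supraspecies requires a depth-7 lineage")
        supra = self.species if supraspecies is None else supraspecies
        return Lineage(self.labels[:6] + (supra, self.labels[6]))

    def replace(self, rank: str, label: str) -> "Lineage":
        i = self.rank_names.index(rank)
        return Lineage(self.labels[:i] + (label,) + self.labels[i + 1:])


@dataclass(frozen=True)
class NucleotideSequence:
    """A named nucleotide sequence over IUPAC codes, stored uppercase."""

    id: str
    seq: str
    description: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")
        object.__setattr__(self, "seq", self.seq.upper())
        bad = set(self.seq) - IUPAC_CODES - GAP_CHARS
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-IUPAC symbols: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def ungapped(self) -> "NucleotideSequence":
        s = "".join(c for c in self.seq if c not in GAP_CHARS)
        return NucleotideSequence(self.id, s, self.description)


@dataclass(frozen=True)
class TrainingSequence:
    """A sequence bound to its lineage and a stable taxon identifier."""

    sequence: NucleotideSequence
    lineage: Lineage
    taxon_id: str

    @property
    def id(self) -> str:
        return self.sequence.id


FULL_LENGTH = "full_length"


@dataclass
class TrainingSet:
    """A collection of lineage-annotated sequences of uniform depth.

    ``region`` is :data:`FULL_LENGTH` for close-to-full-length gene sets or a
    named sub-region (e.g. "V1V3") for trimmed sets.
    """

    members: list[TrainingSequence]
    depth: int
    region: str = FULL_LENGTH

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("training set must have at least one member")
        if self.depth not in (7, 8):
            raise ValueError(f"depth must be 7 or 8, got {self.depth}")
        seen: set[str] = set()
        for m in self.members:
            if m.lineage.depth != self.depth:
                raise MalformedTrainingSetError(
                    f"member {m.id!r} has depth {m.lineage.depth}, "
                    f"training set has depth {self.depth} "
                    f"(header {m.lineage.to_header()!r})"
                )
            if m.id in seen:
                raise ValueError(f"duplicate sequence id {m.id!r}")
            seen.add(m.id)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterator[TrainingSequence]:
        return iter(self.members)

    def ids(self) -> list[str]:
        return [m.id for m in self.members]

    def lineage_of(self, seq_id: str) -> Lineage:
        for m in self.members:
            if m.id == seq_id:
                return m.lineage
        raise KeyError(seq_id)

    def unique_sequences(self) -> list[TrainingSequence]:
        """First member for each distinct sequence string, in member order."""
        seen: set[str] = set()
        out = []
        for m in self.members:
            if m.sequence.seq not in seen:
                seen.add(m.sequence.seq)
                out.append(m)
        return out


@dataclass
class AbundanceTable:
    """Read counts per sequence id (ASV abundances)."""

    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, v in self.counts.items():
            if v < 0:
                raise ValueError(f"negative count for {k!r}: {v}")

    def __getitem__(self, key: str) -> int:
        return self.counts[key]

    def get(self, key: str, default: int = 0) -> int:
        return self.counts.get(key, default)

    def total(self, ids: Optional[Sequence[str]] = None) -> int:
        if ids is None:
            return sum(self.counts.values())
        return sum(self.counts.get(i, 0) for i in ids)
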