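"""Domain types shared across the screening pipeline.

The unit of analysis is a *clone*: one sequenced plasmid insert sampling one
repeat variant of the nuclear ribosomal DNA cistron
(18S–ITS1–5.8S–ITS2–26S) from one individual.  Coordinates are 0-based
half-open internally; human-readable reports print 1-based inclusive
positions (the "nt-16" convention used in the pseudogene literature).
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: IUPAC nucleotide codes accepted in clone sequences ('-' only in alignments).
IUPAC_DNA = set("ACGTRYSWKMBDHVN")
ALIGNED_ALPHABET = IUPAC_DNA | {"-"}

#: Unambiguous bases; everything else is excluded from GC and diversity tallies.
UNAMBIGUOUS = set("ACGT")

#: Base pairs accepted when testing helix foldability: Watson–Crick plus the
#: G·U wobble (G·T at the DNA level).  Ambiguity codes never pair.
PAIRING = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}

COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}

REGION_NAMES = ("ITS1", "5.8S", "ITS2")


class ItsScreenError(Exception):
    """Base class for all errors raised by this package."""


class InputError(ItsScreenError):
    """Malformed or missing user input (bad FASTA, unmapped clone, ...)."""


class DelimitError(ItsScreenError):
    """The 5.8S anchor could not be placed on a clone."""


def normalize_sequence(seq: str) -> str:
    """Uppercase a nucleotide string and normalize RNA U to DNA T."""
    return seq.upper().replace("U", "T")


def validate_sequence(seq: str, *, clone_id: str = "?", allow_gaps: bool = False) -> None:
    alphabet = ALIGNED_ALPHABET if allow_gaps else IUPAC_DNA
    if not seq:
        raise InputError(f"clone {clone_id!r}: empty sequence")
    bad = set(seq) - alphabet
    if bad:
        raise InputError(f"clone {clone_id!r}: non-IUPAC characters {sorted(bad)}")


def reverse_complement(seq: str) -> str:
    table = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")
    return seq.translate(table)[::-1]


@dataclass(frozen=True)
class Partition:
    """Region boundaries of one clone, 0-based half-open on the ungapped sequence.

    ``truncated_left``/``truncated_right`` record a missing 18S tail / 26S head
    flank, in which case the corresponding outer boundary is the sequence end.
    """

    its1: tuple[int, int]
    s58: tuple[int, int]
    its2: tuple[int, int]
    truncated_left: bool = False
    truncated_right: bool = False

    def __post_init__(self) -> None:
        for name, (a, b) in zip(REGION_NAMES, (self.its1, self.s58, self.its2)):
            if b - a < 1:
                raise ValueError(f"{name} interval {a}..{b} has length < 1")
        if not (self.its1[1] <= self.s58[0] and self.s58[1] <= self.its2[0]):
            raise ValueError("regions must be ordered ITS1 < 5.8S < ITS2 without overlap")

    def region(self, name: str) -> tuple[int, int]:
        return {"ITS1": self.its1, "5.8S": self.s58, "ITS2": self.its2}[name]

    def length(self, name: str) -> int:
        a, b = self.region(name)
        return b - a

    def extract(self, sequence: str, name: str) -> str:
        a, b = self.region(name)
        return sequence[a:b]

    @property
    def entire(self) -> tuple[int, int]:
        """ITS1 start through ITS2 end (spacers plus 5.8S, excluding flanks)."""
        return (self.its1[0], self.its2[1])


@dataclass
class ItsClone:
    """One cloned ITS sequence with its sample (individual) membership."""

    clone_id: str
    sample_id: str
    sequence: str
    partition: Partition | None = None

    def __post_init__(self) -> None:
        self.sequence = normalize_sequence(self.sequence)
        validate_sequence(self.sequence, clone_id=self.clone_id)
        if not self.sample_id:
            raise InputError(f"clone {self.clone_id!r}: missing sample_id")


@dataclass(frozen=True)
class ReferenceSet:
    """Anchor sequences used to delimit ITS1/5.8S/ITS2 on a clone.

    The packaged default is a synthetic, constraint-satisfying reference (it
    contains the three conserved 5.8S motifs exactly once each, in order, and
    every forced helix base pair is Watson–Crick); a user-supplied reference
    set overrides it.
    """

    ref_5_8S: str
    ref_18S_tail: str
    ref_26S_head: str

    def __post_init__(self) -> None:
        for name in ("ref_5_8S", "ref_18S_tail", "ref_26S_head"):
            validate_sequence(getattr(self, name), clone_id=name)


@dataclass
class CollapseResult:
    """Grouping of clones by exact sequence identity (haplotype collapse)."""

    n_total: int
    n_distinct: int
    groups: list[list[str]] = field(default_factory=list)  # clone_ids, first-occurrence order

    @property
    def representative_ids(self) -> list[str]:
        return [g[0] for g in self.groups]
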