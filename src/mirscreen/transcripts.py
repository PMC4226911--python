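"""Core sequence types: regionalized target transcripts and miRNA specs.

Transcripts are held as RNA (uppercase, T mapped to U) with 0-based
half-open region coordinates. Regions partition (part of) the transcript
into ``five_prime_utr`` / ``orf`` / ``three_prime_utr`` / ``other``;
positions not covered by any region are only visible to full-length scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

REGION_NAMES = ("five_prime_utr", "orf", "three_prime_utr", "other")
FULL_LENGTH = "full_length"

# IUPAC nucleotide codes in RNA space, with complements.
IUPAC_COMPLEMENT = {
    "A": "U", "C": "G", "G": "C", "U": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}
UNAMBIGUOUS = frozenset("ACGU")
IUPAC_CODES = frozenset(IUPAC_COMPLEMENT)


class SequenceError(ValueError):
    """Raised for malformed sequences or region annotations."""


def normalize_rna(seq: str, *, allow_iupac: bool = False, allow_n: bool = False) -> str:
    """Uppercase, map T to U, and validate the alphabet.

    ``allow_iupac`` admits every IUPAC ambiguity code; ``allow_n`` admits
    only N (used for length-only transcript skeletons).
    """
    s = seq.upper().replace("T", "U")
    if allow_iupac:
        allowed = IUPAC_CODES
    elif allow_n:
        allowed = UNAMBIGUOUS | {"N"}
    else:
        allowed = UNAMBIGUOUS
    bad = set(s) - allowed
    if bad:
        raise SequenceError(f"unknown characters in sequence: {sorted(bad)!r}")
    return s


def reverse_complement(seq: str) -> str:
    """Reverse complement in RNA space (IUPAC-aware)."""
    try:
        return "".join(IUPAC_COMPLEMENT[b] for b in reversed(seq.upper().replace("T", "U")))
    except KeyError as exc:  # pragma: no cover - message detail only
        raise SequenceError(f"cannot complement character {exc.args[0]!r}") from exc


@dataclass(frozen=True)
class Region:
    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.name not in REGION_NAMES:
            raise SequenceError(
                f"unknown region name {self.name!r}; expected one of {REGION_NAMES}"
            )
        if not (0 <= self.start < self.end):
            raise SequenceError(
                f"region {self.name!r}: need 0 <= start < end, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


def validate_regions(regions: Sequence[Region], length: int) -> tuple[Region, ...]:
    """Sort regions and check bounds and pairwise disjointness."""
    ordered = tuple(sorted(regions, key=lambda r: r.start))
    prev_end = 0
    prev: Region | None = None
    for reg in ordered:
        if reg.end > length:
            raise SequenceError(
                f"region {reg.name!r} [{reg.start}, {reg.end}) exceeds transcript length {length}"
            )
        if prev is not None and reg.start < prev_end:
            raise SequenceError(
                f"regions {prev.name!r} and {reg.name!r} overlap at position {reg.start}"
            )
        prev_end, prev = reg.end, reg
    return ordered


@dataclass(frozen=True)
class TargetTranscript:
    """A transcript with non-overlapping, sorted region annotations."""

    transcript_id: str
    sequence: str
    regions: tuple[Region, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_rna(self.sequence, allow_n=True))
        object.__setattr__(
            self, "regions", validate_regions(tuple(self.regions), len(self.sequence))
        )

    def __len__(self) -> int:
        return len(self.sequence)

    def region_at(self, position: int) -> str | None:
        """Region name covering ``position``, or None if uncovered."""
        for reg in self.regions:
            if reg.start <= position < reg.end:
                return reg.name
        return None

    def region_sequence(self, name: str) -> str:
        parts = [self.sequence[r.start:r.end] for r in self.regions if r.name == name]
        if not parts:
            raise SequenceError(f"transcript {self.transcript_id!r} has no region {name!r}")
        return "".join(parts)


@dataclass(frozen=True)
class MiRNASpec:
    """A mature miRNA guide strand, 5'->3'.

    Mixed (IUPAC) bases are admitted only at explicitly declared positions
    (1-based), mirroring synthesis of isomir pools with A-to-I edited or
    untemplated sites. The seed region itself must stay unambiguous for
    seed scanning, which is enforced at scan time, not here.
    """

    name: str
    guide: str
    mixed_positions: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        guide = normalize_rna(self.guide, allow_iupac=True)
        object.__setattr__(self, "guide", guide)
        object.__setattr__(self, "mixed_positions", frozenset(self.mixed_positions))
        if len(guide) < 16:
            raise SequenceError(
                f"miRNA {self.name!r}: guide must be >= 16 nt, got {len(guide)}"
            )
        for pos1, base in enumerate(guide, start=1):
            if base not in UNAMBIGUOUS and pos1 not in self.mixed_positions:
                raise SequenceError(
                    f"miRNA {self.name!r}: ambiguous base {base!r} at position {pos1} "
                    "not declared in mixed_positions"
                )

    def __len__(self) -> int:
        return len(self.guide)


def as_mirna(obj: "MiRNASpec | tuple[str, str] | str", name: str = "miRNA") -> MiRNASpec:
    """Coerce a bare guide string or (name, guide) pair into a MiRNASpec."""
    if isinstance(obj, MiRNASpec):
        return obj
    if isinstance(obj, tuple):
        return MiRNASpec(name=obj[0], guide=obj[1])
    return MiRNASpec(name=name, guide=obj)
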