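"""Core genomic domain types.

All coordinates are 0-based, half-open (``[start, end)``), the BED
convention, at every module boundary.  1-based inputs must be converted
explicitly (``mitoloop convert``); nothing in the library guesses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

STRANDS = ("+", "-", ".")

#: Mitotic-retention categories for CTCF motif sites: full binding retained
#: (bookmarked), partial (reduced), none (lost), plus the union of all
#: interphase-bound sites.
CATEGORIES = ("bookmarked", "reduced", "lost", "interphase_all")


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants."""


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chrom must be nonempty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Nonempty intersection of half-open intervals on the same chromosome."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class MotifSite:
    """An oriented CTCF motif with a mitotic-retention category label.

    The site *center* (floor of the interval midpoint) anchors V-plots and
    Hi-C pile-ups.
    """

    interval: GenomicInterval
    category: str = "interphase_all"

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValidationError("MotifSite requires an explicit strand (+ or -)")
        if self.category not in CATEGORIES:
            raise ValidationError(
                f"category must be one of {CATEGORIES}, got {self.category!r}"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def center(self) -> int:
        return (self.interval.start + self.interval.end) // 2


@dataclass(frozen=True)
class Fragment:
    """A sequenced ATAC fragment, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end - self.start < 1:
            raise ValidationError(f"fragment length must be >= 1, got [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        """Fragment midpoint; half-integral for odd lengths."""
        return (self.start + self.end) / 2


@dataclass(frozen=True)
class Contact:
    """A single Hi-C pair record with multiplicity."""

    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    count: int = 1

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValidationError("count must be >= 1")
        if self.chrom1 == self.chrom2 and self.pos1 > self.pos2:
            raise ValidationError("intra-chromosomal contacts must have pos1 <= pos2")


class ContactList:
    """Column-oriented container of Hi-C pair records.

    Intra-chromosomal records are normalized so ``pos1 <= pos2`` on
    construction.  Backed by numpy arrays; iterating yields
    :class:`Contact` objects.
    """

    __slots__ = ("chrom1", "pos1", "chrom2", "pos2", "count")

    def __init__(self, chrom1, pos1, chrom2, pos2, count=None) -> None:
        self.chrom1 = np.asarray(chrom1, dtype=object)
        self.pos1 = np.asarray(pos1, dtype=np.int64)
        self.chrom2 = np.asarray(chrom2, dtype=object)
        self.pos2 = np.asarray(pos2, dtype=np.int64)
        n = len(self.pos1)
        if count is None:
            self.count = np.ones(n, dtype=np.int64)
        else:
            self.count = np.asarray(count, dtype=np.int64)
        if not (len(self.chrom1) == len(self.chrom2) == len(self.pos2) == len(self.count) == n):
            raise ValidationError("all contact columns must have equal length")
        if np.any(self.count < 1):
            raise ValidationError("contact counts must be >= 1")
        # normalize intra-chromosomal orientation
        intra = self.chrom1 == self.chrom2
        flip = intra & (self.pos1 > self.pos2)
        if np.any(flip):
            p1 = self.pos1.copy()
            self.pos1 = np.where(flip, self.pos2, self.pos1)
            self.pos2 = np.where(flip, p1, self.pos2)

    @classmethod
    def empty(cls) -> "ContactList":
        return cls([], [], [], [])

    @classmethod
    def from_contacts(cls, contacts: Sequence[Contact]) -> "ContactList":
        return cls(
            [c.chrom1 for c in contacts],
            [c.pos1 for c in contacts],
            [c.chrom2 for c in contacts],
            [c.pos2 for c in contacts],
            [c.count for c in contacts],
        )

    @classmethod
    def concat(cls, parts: Sequence["ContactList"]) -> "ContactList":
        return cls(
            np.concatenate([p.chrom1 for p in parts]) if parts else [],
            np.concatenate([p.pos1 for p in parts]) if parts else [],
            np.concatenate([p.chrom2 for p in parts]) if parts else [],
            np.concatenate([p.pos2 for p in parts]) if parts else [],
            np.concatenate([p.count for p in parts]) if parts else [],
        )

    def __len__(self) -> int:
        return len(self.pos1)

    def __iter__(self) -> Iterator[Contact]:
        for i in range(len(self)):
            yield Contact(
                self.chrom1[i], int(self.pos1[i]),
                self.chrom2[i], int(self.pos2[i]), int(self.count[i]),
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ContactList):
            return NotImplemented
        return (
            len(self) == len(other)
            and bool(np.all(self.chrom1 == other.chrom1))
            and bool(np.all(self.pos1 == other.pos1))
            and bool(np.all(self.chrom2 == other.chrom2))
            and bool(np.all(self.pos2 == other.pos2))
            and bool(np.all(self.count == other.count))
        )

    def chroms(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chrom1:
            seen.setdefault(c, None)
        for c in self.chrom2:
            seen.setdefault(c, None)
        return list(seen)

    def intra(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(pos1, pos2, count) arrays of intra-chromosomal contacts on *chrom*."""
        sel = (self.chrom1 == chrom) & (self.chrom2 == chrom)
        return self.pos1[sel], self.pos2[sel], self.count[sel]

    @property
    def n_inter(self) -> int:
        return int(np.sum(self.chrom1 != self.chrom2))


@dataclass(frozen=True)
class KaryotypeRecord:
    chrom: str
    length_bp: int
    centromere_bp: int

    def __post_init__(self) -> None:
        if not (0 < self.centromere_bp < self.length_bp):
            raise ValidationError(
                f"centromere must lie strictly inside the chromosome, got "
                f"{self.centromere_bp} on length {self.length_bp}"
            )


@dataclass(frozen=True)
class CompactionRecord:
    """One measured chromatid: physical length and genomic q-arm size."""

    group: str
    chromatid_length_um: float
    qarm_mb: float

    def __post_init__(self) -> None:
        if self.chromatid_length_um <= 0 or self.qarm_mb <= 0:
            raise ValidationError("chromatid length and q-arm size must be positive")
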