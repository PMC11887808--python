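"""Circular reference genome handling.

Provides the circular mtDNA-like reference container plus the
sequence-level primitives the rest of the pipeline relies on:
trinucleotide context extraction with origin wrap-around,
pyrimidine-centered context frequencies per strand (used to normalize
mutational spectra), homopolymer masking (artifact-prone tracts), and
functional-region annotation.

Coordinates are 1-based inclusive throughout, following the rCRS
convention; position arithmetic wraps modulo the genome length.
The FASTA sequence is declared the light (L) strand; the heavy (H)
strand is its reverse complement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

logger = logging.getLogger(__name__)

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
PYRIMIDINES = frozenset("CT")
PURINES = frozenset("AG")
VALID_BASES = frozenset("ACGTN")

#: Overlap resolution priority: a coding consequence dominates reporting.
REGION_PRIORITY = ("protein_coding", "rRNA", "tRNA", "noncoding")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.translate(COMPLEMENT)[::-1]


class ContextUnavailableError(ValueError):
    """Raised when a trinucleotide window contains N."""


@dataclass(frozen=True)
class CircularReference:
    """A circular genome (the L strand) with 1-based positions.

    Parameters
    ----------
    name :
        Sequence identifier (e.g. ``"chrM"``).
    sequence :
        Uppercase string over ``{A, C, G, T, N}``, length >= 3.
    """

    name: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 3:
            raise ValueError("circular reference must be at least 3 bp")
        bad = set(seq) - VALID_BASES
        if bad:
            raise ValueError(f"invalid bases in reference: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "CircularReference":
        """Read a single-record FASTA file."""
        records = list(SeqIO.parse(str(path), "fasta"))
        if len(records) != 1:
            raise ValueError(
                f"expected a single-record FASTA, found {len(records)} records"
            )
        rec = records[0]
        return cls(name=rec.id, sequence=str(rec.seq).upper())

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f">{self.name}\n")
            for i in range(0, self.length, 70):
                fh.write(self.sequence[i : i + 70] + "\n")

    def _check_pos(self, pos: int) -> None:
        if not 1 <= pos <= self.length:
            raise ValueError(f"position {pos} outside 1..{self.length}")

    def base(self, pos: int) -> str:
        """Base at a 1-based position."""
        self._check_pos(pos)
        return self.sequence[pos - 1]

    def trinucleotide_context(self, pos: int) -> str:
        """Bases at (pos-1, pos, pos+1) with circular wrap-around."""
        self._check_pos(pos)
        n = self.length
        i = pos - 1
        return (
            self.sequence[(i - 1) % n]
            + self.sequence[i]
            + self.sequence[(i + 1) % n]
        )

    def context_frequencies(self, strand: str = "L") -> dict[str, int]:
        """Counts of pyrimidine-centered trinucleotide contexts on a strand.

        For strand ``"L"`` every window whose center base is C or T is
        tallied; for strand ``"H"`` the same is done on the reverse
        complement. Windows containing N are skipped (and logged).
        """
        if strand == "L":
            seq = self.sequence
        elif strand == "H":
            seq = revcomp(self.sequence)
        else:
            raise ValueError(f"strand must be 'L' or 'H', got {strand!r}")
        n = len(seq)
        counts: dict[str, int] = {}
        skipped = 0
        for i in range(n):
            if seq[i] not in PYRIMIDINES:
                continue
            tri = seq[(i - 1) % n] + seq[i] + seq[(i + 1) % n]
            if "N" in tri:
                skipped += 1
                continue
            counts[tri] = counts.get(tri, 0) + 1
        if skipped:
            logger.info("context_frequencies: skipped %d N-containing windows", skipped)
        return counts

    def find_homopolymers(self, min_run: int = 5) -> frozenset[int]:
        """Positions inside maximal same-base runs of length >= min_run.

        Runs spanning the circular origin are detected. Variants at these
        positions are excluded downstream as likely sequencing artifacts.
        """
        if min_run < 2:
            raise ValueError("min_run must be >= 2")
        n = self.length
        seq = self.sequence
        if len(set(seq)) == 1:
            return frozenset(range(1, n + 1))
        # rotate so position 0 starts a new run; runs then never wrap
        start = 0
        while seq[start - 1] == seq[start % n] and start < n:
            start += 1
        rot = seq[start:] + seq[:start]
        masked: set[int] = set()
        i = 0
        while i < n:
            j = i
            while j < n and rot[j] == rot[i]:
                j += 1
            if j - i >= min_run:
                for k in range(i, j):
                    masked.add((start + k) % n + 1)
            i = j
        return frozenset(masked)


@dataclass(frozen=True)
class Region:
    """One annotated interval, 1-based inclusive; start > end wraps the origin."""

    start: int
    end: int
    region_class: str
    label: str

    def __post_init__(self) -> None:
        if self.region_class not in REGION_PRIORITY:
            raise ValueError(
                f"region_class must be one of {REGION_PRIORITY}, "
                f"got {self.region_class!r}"
            )

    def contains(self, pos: int, length: int) -> bool:
        if self.start <= self.end:
            return self.start <= pos <= self.end
        # wrap-around interval
        return pos >= self.start or pos <= self.end


@dataclass
class RegionAnnotation:
    """Functional-region annotation of the circular genome.

    Positions not covered by any record are implicitly ``noncoding``.
    Overlaps are resolved by priority
    protein_coding > rRNA > tRNA > noncoding, ties by record order.
    """

    length: int
    regions: list[Region] = field(default_factory=list)

    @classmethod
    def from_tsv(cls, path: str | Path, length: int) -> "RegionAnnotation":
        """Read a 4+-column TSV (start, end, region_class, label); '#' comments."""
        regions = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise ValueError(f"annotation line has <4 columns: {line!r}")
                start, end = int(parts[0]), int(parts[1])
                if not (1 <= start <= length and 1 <= end <= length):
                    raise ValueError(f"annotation interval {start}-{end} outside 1..{length}")
                regions.append(Region(start, end, parts[2], parts[3]))
        return cls(length=length, regions=regions)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# 1-based inclusive coordinates; start>end wraps the origin\n")
            fh.write("# start\tend\tregion_class\tlabel\n")
            for r in self.regions:
                fh.write(f"{r.start}\t{r.end}\t{r.region_class}\t{r.label}\n")

    def annotate_position(self, pos: int) -> tuple[str, str]:
        """(region_class, label) for a position; uncovered -> noncoding."""
        if not 1 <= pos <= self.length:
            raise ValueError(f"position {pos} outside 1..{self.length}")
        hits = [r for r in self.regions if r.contains(pos, self.length)]
        if not hits:
            return ("noncoding", "")
        best = min(hits, key=lambda r: REGION_PRIORITY.index(r.region_class))
        return (best.region_class, best.label)

    def annotate_many(self, positions: Iterable[int]) -> list[tuple[str, str]]:
        return [self.annotate_position(p) for p in positions]
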