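"""Genome binning, fragments and interval arithmetic.

Every matrix and table in the pipeline is indexed by a dense universe of
fixed-size genomic bins ("fragments", 1 Mb by default).  Coordinates are
0-based half-open (BED convention) throughout; converters live at the I/O
boundary only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

DEFAULT_BIN_SIZE = 1_000_000

COMPARTMENT_OPEN = "A"
COMPARTMENT_CLOSED = "B"
COMPARTMENT_UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open interval on one chromosome with an optional numeric value.

    ``value`` carries whatever payload the context needs: a peak height,
    a chromatin-state index, or a homology-hit marker.
    """

    chrom: str
    start: int
    end: int
    value: float = 0.0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Length in bp of the overlap of two half-open intervals (0 across chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


@dataclass(frozen=True)
class Fragment:
    """One genome bin: the unit of all proximity matrices."""

    index: int
    chrom: str
    start: int
    end: int
    compartment: str = COMPARTMENT_UNASSIGNED

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> float:
        return 0.5 * (self.start + self.end)

    def as_interval(self, value: float = 0.0) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, value)


class GenomeBinning:
    """Tiling of a multi-chromosome genome into fixed-size bins.

    Fragment indices are global, dense (0..F-1), and ordered by
    (chromosome order, start).  The last bin of a chromosome may be shorter
    than ``bin_size``; such tails are retained.
    """

    def __init__(self, chromosome_lengths: dict[str, int],
                 bin_size: int = DEFAULT_BIN_SIZE):
        if bin_size <= 0:
            raise ValueError("bin_size must be positive")
        for name, length in chromosome_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has nonpositive length {length}")
        self.bin_size = int(bin_size)
        self.chromosome_names: list[str] = list(chromosome_lengths)
        self.chromosome_lengths: dict[str, int] = {
            c: int(l) for c, l in chromosome_lengths.items()
        }
        self.fragments: list[Fragment] = []
        self._first_index: dict[str, int] = {}
        idx = 0
        for chrom in self.chromosome_names:
            length = self.chromosome_lengths[chrom]
            self._first_index[chrom] = idx
            for start in range(0, length, self.bin_size):
                end = min(start + self.bin_size, length)
                self.fragments.append(Fragment(idx, chrom, start, end))
                idx += 1
        self.n_fragments = idx
        self._chrom_codes = np.array(
            [self.chromosome_names.index(f.chrom) for f in self.fragments],
            dtype=np.int64,
        )

    # -- basic accessors -------------------------------------------------

    def __len__(self) -> int:
        return self.n_fragments

    def __iter__(self) -> Iterator[Fragment]:
        return iter(self.fragments)

    @property
    def chrom_codes(self) -> np.ndarray:
        """Per-fragment integer chromosome code (for vectorized masking)."""
        return self._chrom_codes

    @property
    def fragment_lengths(self) -> np.ndarray:
        return np.array([f.length for f in self.fragments], dtype=np.int64)

    def fragments_of(self, chrom: str) -> list[Fragment]:
        first = self._first_index[chrom]
        n = self.n_bins_of(chrom)
        return self.fragments[first:first + n]

    def n_bins_of(self, chrom: str) -> int:
        length = self.chromosome_lengths[chrom]
        return -(-length // self.bin_size)  # ceil division

    def locate(self, chrom: str, pos: int) -> int:
        """Global fragment index of base ``pos`` (half-open bin rule)."""
        if chrom not in self._first_index:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if not 0 <= pos < self.chromosome_lengths[chrom]:
            raise ValueError(f"position {pos} outside {chrom}")
        return self._first_index[chrom] + pos // self.bin_size

    def set_compartments(self, labels) -> None:
        """Replace per-fragment compartment labels (sequence of length F)."""
        labels = list(labels)
        if len(labels) != self.n_fragments:
            raise ValueError("one label per fragment required")
        self.fragments = [
            Fragment(f.index, f.chrom, f.start, f.end, lab)
            for f, lab in zip(self.fragments, labels)
        ]

    @property
    def compartments(self) -> list[str]:
        return [f.compartment for f in self.fragments]

    # -- pair enumeration -------------------------------------------------

    def interchromosomal_mask(self) -> np.ndarray:
        """F x F boolean matrix, True where the two fragments sit on
        different chromosomes."""
        codes = self._chrom_codes
        return codes[:, None] != codes[None, :]

    def interchromosomal_pairs(self) -> Iterator[tuple[int, int]]:
        """Unordered (i < j) fragment pairs on different chromosomes."""
        if len(self.chromosome_names) < 2:
            warnings.warn("single-chromosome genome: no interchromosomal pairs")
            return iter(())
        codes = self._chrom_codes
        return (
            (i, j)
            for i in range(self.n_fragments)
            for j in range(i + 1, self.n_fragments)
            if codes[i] != codes[j]
        )

    def n_interchromosomal_pairs(self) -> int:
        per_chrom = np.bincount(self._chrom_codes)
        F = self.n_fragments
        return int((F * F - np.sum(per_chrom ** 2)) // 2)


def make_binning(chromosome_lengths: dict[str, int],
                 bin_size: int = DEFAULT_BIN_SIZE) -> GenomeBinning:
    """Build the fragment universe for a genome. See :class:`GenomeBinning`."""
    return GenomeBinning(chromosome_lengths, bin_size)


def alignment_percent_identity(read_length: int, mismatches: int) -> float:
    """Percent identity of an ungapped alignment with the given mismatch count.

    The homology filter's 92% identity cutoff corresponds to a 75-nt read
    carrying 6 mismatches: (75 - 6) / 75 * 100 = 92.
    """
    if read_length <= 0:
        raise ValueError("read_length must be positive")
    if not 0 <= mismatches <= read_length:
        raise ValueError("mismatches outside [0, read_length]")
    return (read_length - mismatches) / read_length * 100.0
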