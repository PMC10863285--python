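"""Sequence containers, one-hot encodings, coordinate arithmetic and FASTA/BED I/O.

Conventions used throughout the package:

* all internal coordinates are 0-based; BED input is 0-based half-open
  (a summit record ``[start, start+1)`` yields ``position = start``);
  bedGraph output is 0-based half-open;
* the channel row order of every encoding is ``[A, C, G, T]``;
* soft-masked (lowercase) FASTA residues are uppercased on load, never filtered;
* ``N`` one-hot encodes to an all-zero column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO

ALPHABET = "ACGTN"
CHANNELS = "ACGT"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# index into the 4-row channel order; N -> -1 sentinel
_BASE_INDEX = np.full(256, -2, dtype=np.int8)
for _i, _b in enumerate(CHANNELS):
    _BASE_INDEX[ord(_b)] = _i
_BASE_INDEX[ord("N")] = -1


class InvalidAlphabetError(ValueError):
    """A residue outside {A, C, G, T, N} was encountered."""


class OutOfBoundsError(ValueError):
    """A requested window extends past a chromosome end."""


class BedFormatError(ValueError):
    """A malformed BED/bedGraph line (message carries the line number)."""


@dataclass(frozen=True)
class GenomeSequence:
    """One chromosome: a name and its residues over {A, C, G, T, N}."""

    name: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError(f"chromosome {self.name!r} is empty")
        _validate(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GenomicSite:
    """A single break coordinate: chromosome, 0-based position, strand."""

    chrom: str
    position: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError(f"negative position {self.position} on {self.chrom}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")


@dataclass(frozen=True)
class SequenceEncoding:
    """A 4 x L real matrix over channels [A, C, G, T].

    Columns of one-hot encodings sum to 1 (or 0 at N positions); the GC-content
    baseline has every column equal to (0.3, 0.2, 0.2, 0.3).
    """

    matrix: np.ndarray

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 4:
            raise ValueError(f"encoding must be 4 x L, got shape {self.matrix.shape}")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]


def _validate(seq: str) -> None:
    for i, ch in enumerate(seq):
        if ch not in ALPHABET:
            raise InvalidAlphabetError(
                f"invalid residue {ch!r} at position {i} (alphabet is A/C/G/T/N)"
            )


def one_hot_encode(seq: str) -> SequenceEncoding:
    """One-hot encode a DNA string as a 4 x L matrix, rows [A, C, G, T].

    Entry (j, i) is 1 iff residue i equals channel j; ``N`` gives an all-zero
    column.  Raises :class:`InvalidAlphabetError` naming the first offending
    position for any other character.
    """
    if not seq:
        raise InvalidAlphabetError("empty sequence")
    idx = _BASE_INDEX[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    bad = np.nonzero(idx == -2)[0]
    if bad.size:
        i = int(bad[0])
        raise InvalidAlphabetError(
            f"invalid residue {seq[i]!r} at position {i} (alphabet is A/C/G/T/N)"
        )
    mat = np.zeros((4, len(seq)), dtype=np.float32)
    cols = np.nonzero(idx >= 0)[0]
    mat[idx[cols], cols] = 1.0
    return SequenceEncoding(mat)


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A, C, G, T, N}; N maps to N."""
    _validate(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def extract_context(genome: GenomeSequence, site: GenomicSite, flank: int = 125) -> str:
    """Residues at ``[position - flank, position + flank]`` inclusive (2*flank+1 bp)."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    if site.chrom != genome.name:
        raise ValueError(f"site on {site.chrom!r} but genome is {genome.name!r}")
    lo = site.position - flank
    hi = site.position + flank + 1
    if lo < 0 or hi > len(genome):
        raise OutOfBoundsError(
            f"window [{lo}, {hi}) around {site.chrom}:{site.position} exceeds "
            f"chromosome bounds [0, {len(genome)})"
        )
    return genome.residues[lo:hi]


def count_cpg(seq: str) -> int:
    """Number of overlapping CG dinucleotides (CpG count)."""
    return seq.count("CG")


def gc_baseline_encoding(L: int) -> SequenceEncoding:
    """The neutral GC-content baseline: every column is (0.3, 0.2, 0.2, 0.3)."""
    if L < 1:
        raise ValueError("baseline length must be >= 1")
    col = np.array([0.3, 0.2, 0.2, 0.3], dtype=np.float32)
    return SequenceEncoding(np.repeat(col[:, None], L, axis=1))


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, GenomeSequence]:
    """Read a multi-record FASTA into a name -> GenomeSequence map (uppercased)."""
    genomes: dict[str, GenomeSequence] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        genomes[rec.id] = GenomeSequence(rec.id, str(rec.seq).upper())
    if not genomes:
        raise ValueError(f"no FASTA records found in {path}")
    return genomes


def write_fasta(genomes: Mapping[str, GenomeSequence], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in genomes:
            fh.write(f">{name}\n")
            res = genomes[name].residues
            for i in range(0, len(res), width):
                fh.write(res[i : i + width] + "\n")


def read_bed_sites(path: str | Path) -> list[GenomicSite]:
    """Read break sites from BED (chrom, start, end[, name, score, strand]).

    Each record yields one site at ``position = start`` (summit convention,
    0-based).  Malformed lines raise :class:`BedFormatError` with the line number.
    """
    sites: list[GenomicSite] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedFormatError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
            chrom, start_s, end_s = fields[0], fields[1], fields[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise BedFormatError(f"{path}:{lineno}: non-integer interval bounds") from None
            if start < 0 or end <= start:
                raise BedFormatError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            strand = fields[5] if len(fields) >= 6 else "."
            if strand not in ("+", "-", "."):
                raise BedFormatError(f"{path}:{lineno}: invalid strand {strand!r}")
            sites.append(GenomicSite(chrom, start, strand))
    return sites


def write_bed_sites(sites: Iterable[GenomicSite], path: str | Path, scores: Iterable[float] | None = None) -> None:
    """Write sites as single-base BED records ([pos, pos+1), 0-based half-open)."""
    scores_list = list(scores) if scores is not None else None
    with open(path, "w") as fh:
        for i, site in enumerate(sites):
            score = f"{scores_list[i]:.6f}" if scores_list is not None else "0"
            fh.write(f"{site.chrom}\t{site.position}\t{site.position + 1}\tsite_{i}\t{score}\t{site.strand}\n")


def write_bedgraph(chrom: str, starts: Iterable[int], values: Iterable[float], path: str | Path, span: int = 1) -> None:
    """Write a bedGraph track (chrom, start, start+span, value), 0-based half-open."""
    with open(path, "w") as fh:
        for start, value in zip(starts, values):
            fh.write(f"{chrom}\t{start}\t{start + span}\t{value:.6f}\n")


def read_bedgraph(path: str | Path) -> list[tuple[str, int, int, float]]:
    records: list[tuple[str, int, int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise BedFormatError(f"{path}:{lineno}: expected 4 tab-separated fields")
            try:
                records.append((fields[0], int(fields[1]), int(fields[2]), float(fields[3])))
            except ValueError:
                raise BedFormatError(f"{path}:{lineno}: malformed bedGraph record") from None
    return records
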