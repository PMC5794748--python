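"""Reference genome access, in-silico recognition-site scans, binned coverage.

Coordinates are 1-based inclusive throughout (SAM convention); BED export
converts to 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .enzyme import EnzymeSpec, iupac_pattern_regex

__all__ = [
    "GenomeSequence",
    "RecognitionOccurrence",
    "load_genome",
    "scan_recognition_sites",
    "bin_site_coverage",
    "occurrences_to_bed",
]

_VALID_REF_CHARS = frozenset("ACGTRYSWKMBDHVN")


class GenomeError(ValueError):
    pass


@dataclass(frozen=True)
class RecognitionOccurrence:
    """A genomic interval whose forward-strand sequence matches the enzyme
    recognition pattern; ``start``/``end`` are 1-based inclusive."""

    contig: str
    start: int
    end: int


class GenomeSequence:
    """Random-access reference genome with 1-based inclusive fetch.

    Backed by pyfaidx (a ``.fai`` index is built on first open if absent).
    Soft-masked lowercase is uppercased on fetch.
    """

    def __init__(self, fasta_path: str | Path):
        path = Path(fasta_path)
        if not path.exists():
            raise GenomeError(f"FASTA not found: {path}")
        if path.stat().st_size == 0:
            raise GenomeError(f"empty FASTA: {path}")
        try:
            self._fasta = Fasta(str(path), sequence_always_upper=True)
        except Exception as exc:  # pyfaidx raises several flavours
            raise GenomeError(f"cannot index FASTA {path}: {exc}") from exc
        names = list(self._fasta.keys())
        if len(set(names)) != len(names):
            raise GenomeError(f"duplicate contig names in {path}")
        if not names:
            raise GenomeError(f"no sequences in {path}")
        self.path = path
        self.contigs: list[tuple[str, int]] = [
            (name, len(self._fasta[name])) for name in names
        ]
        self._lengths = dict(self.contigs)

    def contig_names(self) -> list[str]:
        return [name for name, _ in self.contigs]

    def contig_length(self, name: str) -> int:
        try:
            return self._lengths[name]
        except KeyError:
            raise GenomeError(f"unknown contig {name!r}") from None

    def fetch(self, name: str, start: int, end: int) -> str:
        """Sequence over [start, end], 1-based inclusive; out-of-range is an error."""
        length = self.contig_length(name)
        if not (1 <= start <= end <= length):
            raise GenomeError(
                f"fetch range {name}:{start}-{end} outside [1, {length}]"
            )
        return str(self._fasta[name][start - 1 : end])


def load_genome(fasta_path: str | Path, validate_alphabet: bool = True) -> GenomeSequence:
    """Open a (multi-)FASTA as a :class:`GenomeSequence`.

    Works for wrapped and single-line FASTA alike. With ``validate_alphabet``
    every contig is checked to contain only IUPAC nucleotide letters.
    """
    genome = GenomeSequence(fasta_path)
    if validate_alphabet:
        for name, length in genome.contigs:
            seq = genome.fetch(name, 1, length)
            bad = set(seq) - _VALID_REF_CHARS
            if bad:
                raise GenomeError(
                    f"contig {name!r} contains non-nucleotide characters: {sorted(bad)}"
                )
    return genome


def scan_recognition_sites(
    genome: GenomeSequence,
    enzyme: EnzymeSpec,
    contigs: list[str] | None = None,
) -> list[RecognitionOccurrence]:
    """All forward-strand recognition occurrences, overlapping ones included.

    Sorted by (contig order as in the FASTA, start). For a palindromic enzyme
    this is the complete occurrence set of both strands.
    """
    regex = iupac_pattern_regex(enzyme.recognition)
    wanted = contigs if contigs is not None else genome.contig_names()
    out: list[RecognitionOccurrence] = []
    for name in wanted:
        seq = genome.fetch(name, 1, genome.contig_length(name))
        for m in regex.finditer(seq):
            start = m.start() + 1
            out.append(RecognitionOccurrence(name, start, start + enzyme.length - 1))
    return out


def bin_site_coverage(
    genome: GenomeSequence,
    occurrences: list[RecognitionOccurrence],
    bin_size: int,
    contigs: list[str] | None = None,
) -> tuple[pd.DataFrame, float]:
    """Tile each contig into ``bin_size`` windows and count occurrence starts.

    Bins are [1, b], [b+1, 2b], ...; the last bin may be short. An occurrence
    belongs to the bin containing its start. Returns the per-bin table
    (contig, bin_start, n_sites) and the overall fraction of bins holding at
    least one occurrence.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    wanted = contigs if contigs is not None else genome.contig_names()
    frames = []
    for name in wanted:
        length = genome.contig_length(name)
        n_bins = -(-length // bin_size)  # ceil
        counts = np.zeros(n_bins, dtype=int)
        starts = [o.start for o in occurrences if o.contig == name]
        if starts:
            idx = (np.asarray(starts) - 1) // bin_size
            np.add.at(counts, idx, 1)
        frames.append(
            pd.DataFrame(
                {
                    "contig": name,
                    "bin_start": np.arange(n_bins) * bin_size + 1,
                    "n_sites": counts,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    fraction = float((table["n_sites"] >= 1).mean()) if len(table) else 0.0
    return table, fraction


def occurrences_to_bed(
    occurrences: list[RecognitionOccurrence], path: str | Path, name: str = "site"
) -> None:
    """Write occurrences as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for i, occ in enumerate(occurrences):
            fh.write(f"{occ.contig}\t{occ.start - 1}\t{occ.end}\t{name}{i + 1}\t0\t+\n")
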