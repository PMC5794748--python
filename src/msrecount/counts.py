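"""Cut-site count tables: raw 5'-end counting from BAM and recognition-site
verification against the reference genome.

In an MRE-seq library each sequenced fragment starts at an enzyme cleavage
point, so the 5' end of every correctly mapped read sits at a fixed offset
inside a recognition occurrence. ``raw_counts`` tallies reads by their 5'-end
coordinate and strand; ``check_cuts`` projects each observed 5'-end event onto
the recognition window it implies and keeps only events whose window actually
matches the enzyme's recognition sequence in the reference — discarding
mis-mapped reads before any downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .enzyme import EnzymeSpec, iupac_match, revcomp_iupac
from .genome import GenomeSequence

__all__ = [
    "ReadFilters",
    "ReadEndEvent",
    "CutSiteCountTable",
    "VerificationReport",
    "read_five_prime_event",
    "raw_counts",
    "implied_window",
    "check_cuts",
    "collapse_strands",
]


class CountTableError(ValueError):
    pass


@dataclass(frozen=True)
class ReadFilters:
    """Alignment inclusion rules for counting.

    Defaults are permissive (MAPQ 0, duplicates dropped): primary, mapped,
    non-supplementary, non-QC-fail alignments are counted.
    """

    min_mapq: int = 0
    drop_duplicates: bool = True
    read1_only: bool = False
    max_5p_softclip: int | None = None


@dataclass(frozen=True)
class ReadEndEvent:
    """A read's biological start: leftmost aligned base for forward
    alignments, rightmost for reverse alignments (1-based)."""

    contig: str
    five_prime_pos: int
    strand: str  # '+' or '-'


def read_five_prime_event(
    rec: pysam.AlignedSegment, filters: ReadFilters = ReadFilters()
) -> ReadEndEvent | None:
    """Map one alignment record to its 5'-end event, or None when filtered out."""
    if rec.is_unmapped:
        return None
    if rec.is_secondary or rec.is_supplementary or rec.is_qcfail:
        return None
    if filters.drop_duplicates and rec.is_duplicate:
        return None
    if rec.mapping_quality < filters.min_mapq:
        return None
    if filters.read1_only and rec.is_paired and not rec.is_read1:
        return None
    if rec.reference_start is None or rec.reference_start < 0:
        raise CountTableError(f"mapped record without coordinates: {rec.query_name}")
    if filters.max_5p_softclip is not None:
        cig = rec.cigartuples or []
        clip = 0
        if rec.is_reverse:
            if cig and cig[-1][0] == 4:
                clip = cig[-1][1]
        else:
            if cig and cig[0][0] == 4:
                clip = cig[0][1]
        if clip > filters.max_5p_softclip:
            return None
    if rec.is_reverse:
        # reference_end is 0-based exclusive == 1-based inclusive rightmost
        return ReadEndEvent(rec.reference_name, rec.reference_end, "-")
    return ReadEndEvent(rec.reference_name, rec.reference_start + 1, "+")


@dataclass
class CutSiteCountTable:
    """Sites-by-samples integer count matrix with genomic site keys.

    ``sites`` has columns contig, position, strand (plus occurrence_start /
    occurrence_end once verified); rows align with ``counts`` rows, and
    ``counts`` columns align with ``samples``. ``verified`` records whether
    the table has passed recognition-site verification.
    """

    sites: pd.DataFrame
    counts: np.ndarray
    samples: list[str]
    sample_meta: pd.DataFrame
    verified: bool = False
    contig_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape != (len(self.sites), len(self.samples)):
            raise CountTableError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sites)} sites x {len(self.samples)} samples"
            )
        if (self.counts < 0).any():
            raise CountTableError("negative counts")
        if len(set(self.samples)) != len(self.samples):
            raise CountTableError("duplicate sample ids")
        if not self.contig_order:
            self.contig_order = list(dict.fromkeys(self.sites["contig"]))

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0).astype(float)

    def site_keys(self) -> list[tuple]:
        return list(
            zip(self.sites["contig"], self.sites["position"], self.sites["strand"])
        )

    def subset_rows(self, index) -> "CutSiteCountTable":
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        sites = self.sites.iloc[idx].reset_index(drop=True)
        counts = self.counts[idx]
        return CutSiteCountTable(
            sites=sites,
            counts=counts,
            samples=list(self.samples),
            sample_meta=self.sample_meta.copy(),
            verified=self.verified,
            contig_order=list(self.contig_order),
        )

    def to_tsv(self, path: str | Path) -> None:
        df = self.sites.copy()
        for j, s in enumerate(self.samples):
            df[s] = self.counts[:, j]
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls, path: str | Path, sample_meta: pd.DataFrame, verified: bool | None = None
    ) -> "CutSiteCountTable":
        df = pd.read_csv(path, sep="\t")
        site_cols = [
            c
            for c in ("contig", "position", "strand", "occurrence_start", "occurrence_end")
            if c in df.columns
        ]
        samples = [c for c in df.columns if c not in site_cols]
        missing = set(samples) - set(sample_meta["sample"])
        if missing:
            raise CountTableError(f"samples in table but not metadata: {sorted(missing)}")
        if verified is None:
            verified = "occurrence_start" in df.columns
        meta = sample_meta.set_index("sample").loc[samples].reset_index()
        return cls(
            sites=df[site_cols].copy(),
            counts=df[samples].to_numpy(dtype=np.int64),
            samples=samples,
            sample_meta=meta,
            verified=verified,
        )


@dataclass
class VerificationReport:
    n_candidates: int
    n_verified: int
    n_rejected: int
    rejected: pd.DataFrame  # contig, position, strand, window_start, window_end, found_sequence

    def __post_init__(self) -> None:
        assert self.n_candidates == self.n_verified + self.n_rejected

    def to_tsv(self, path: str | Path) -> None:
        self.rejected.to_csv(path, sep="\t", index=False)

    def summary(self) -> str:
        return (
            f"{self.n_candidates} candidate sites: "
            f"{self.n_verified} verified, {self.n_rejected} rejected"
        )


def _open_alignment(path: str | Path) -> pysam.AlignmentFile:
    p = str(path)
    mode = "r" if p.endswith(".sam") else "rb"
    return pysam.AlignmentFile(p, mode)


def _check_bam_ready(af: pysam.AlignmentFile, path: str | Path) -> None:
    so = (af.header.get("HD") or {}).get("SO")
    if so != "coordinate":
        raise CountTableError(f"BAM not coordinate-sorted (SO={so}): {path}")
    try:
        ok = af.check_index()
    except (ValueError, AttributeError):
        ok = False
    if not ok:
        raise CountTableError(f"BAM has no index (.bai): {path}")


def _sort_site_frame(df: pd.DataFrame, contig_order: list[str]) -> pd.DataFrame:
    order = {c: i for i, c in enumerate(contig_order)}
    strand_rank = {"+": 0, "-": 1, "*": 2}
    key = df.assign(
        _c=df["contig"].map(order), _s=df["strand"].map(strand_rank)
    ).sort_values(["_c", "position", "_s"], kind="mergesort")
    return key.drop(columns=["_c", "_s"]).reset_index(drop=True)


def raw_counts(
    bam_paths: list[str | Path],
    sample_meta: pd.DataFrame,
    filters: ReadFilters = ReadFilters(),
) -> CutSiteCountTable:
    """Tally read 5'-end events per (contig, position, strand) across samples.

    One BAM per sample, aligned with the rows of ``sample_meta`` (columns:
    sample, group, optional block). Every BAM must be coordinate-sorted and
    indexed, and all BAM headers must agree on the contig set. Rows are the
    union of events over samples; a sample with no read at a site holds 0.
    """
    if len(bam_paths) != len(sample_meta):
        raise CountTableError(
            f"{len(bam_paths)} BAMs but {len(sample_meta)} metadata rows"
        )
    samples = list(sample_meta["sample"])
    contig_order: list[str] | None = None
    per_sample: list[dict[tuple, int]] = []
    for path in bam_paths:
        with _open_alignment(path) as af:
            if str(path).endswith((".bam", ".cram")):
                _check_bam_ready(af, path)
            contigs = list(af.references)
            if contig_order is None:
                contig_order = contigs
            elif set(contigs) != set(contig_order):
                raise CountTableError(
                    f"contig set mismatch between {bam_paths[0]} and {path}"
                )
            tally: dict[tuple, int] = {}
            for rec in af.fetch(until_eof=True):
                ev = read_five_prime_event(rec, filters)
                if ev is None:
                    continue
                key = (ev.contig, ev.five_prime_pos, ev.strand)
                tally[key] = tally.get(key, 0) + 1
            per_sample.append(tally)
    assert contig_order is not None
    all_keys = sorted(
        set().union(*per_sample) if per_sample else set(),
        key=lambda k: (contig_order.index(k[0]), k[1], k[2]),
    )
    counts = np.zeros((len(all_keys), len(samples)), dtype=np.int64)
    index = {k: i for i, k in enumerate(all_keys)}
    for j, tally in enumerate(per_sample):
        for k, n in tally.items():
            counts[index[k], j] = n
    sites = pd.DataFrame(all_keys, columns=["contig", "position", "strand"])
    return CutSiteCountTable(
        sites=sites,
        counts=counts,
        samples=samples,
        sample_meta=sample_meta.reset_index(drop=True),
        verified=False,
        contig_order=contig_order,
    )


def implied_window(
    contig: str, five_prime_pos: int, strand: str, enzyme: EnzymeSpec
) -> tuple[str, int, int]:
    """Recognition window implied by a 5'-end event.

    A cut inside an occurrence [s, s+L-1] with cut offset c releases a
    downstream fragment whose forward read starts at s+c, and an upstream
    fragment whose reverse read 5'-end sits at s+L-c-1; inverting those
    relations recovers the candidate window from an observed event.
    """
    c, L = enzyme.cut_offset, enzyme.length
    if strand == "+":
        start = five_prime_pos - c
    elif strand == "-":
        start = five_prime_pos - L + c + 1
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    return contig, start, start + L - 1


def check_cuts(
    table: CutSiteCountTable,
    genome: GenomeSequence,
    enzyme: EnzymeSpec,
) -> tuple[CutSiteCountTable, VerificationReport]:
    """Keep only rows whose implied recognition window matches the enzyme.

    '+' rows are matched against the recognition sequence, '-' rows against
    its reverse complement (identical for palindromic enzymes). Windows
    falling outside contig bounds are rejected, not an error. Idempotent on
    already-verified tables.
    """
    missing = set(table.sites["contig"]) - set(genome.contig_names())
    if missing:
        raise CountTableError(
            f"contigs in count table absent from genome: {sorted(missing)}"
        )
    pat_fwd = enzyme.recognition
    pat_rev = revcomp_iupac(pat_fwd)
    # fetch each contig once; tables are small relative to the genome
    contig_seq = {
        c: genome.fetch(c, 1, genome.contig_length(c))
        for c in dict.fromkeys(table.sites["contig"])
    }
    keep = np.zeros(table.n_sites, dtype=bool)
    occ_start = np.zeros(table.n_sites, dtype=np.int64)
    occ_end = np.zeros(table.n_sites, dtype=np.int64)
    rejected_rows = []
    for i, (contig, pos, strand) in enumerate(
        zip(table.sites["contig"], table.sites["position"], table.sites["strand"])
    ):
        _, ws, we = implied_window(contig, int(pos), strand, enzyme)
        seq = contig_seq[contig]
        if ws < 1 or we > len(seq):
            found = ""
            ok = False
        else:
            found = seq[ws - 1 : we]
            pattern = pat_fwd if strand == "+" else pat_rev
            ok = iupac_match(pattern, found)
        keep[i] = ok
        occ_start[i], occ_end[i] = ws, we
        if not ok:
            rejected_rows.append((contig, int(pos), strand, ws, we, found))
    sites = table.sites.copy()
    sites["occurrence_start"] = occ_start
    sites["occurrence_end"] = occ_end
    kept_sites = sites.loc[keep].reset_index(drop=True)
    verified = CutSiteCountTable(
        sites=kept_sites,
        counts=table.counts[keep],
        samples=list(table.samples),
        sample_meta=table.sample_meta.copy(),
        verified=True,
        contig_order=list(table.contig_order),
    )
    report = VerificationReport(
        n_candidates=table.n_sites,
        n_verified=int(keep.sum()),
        n_rejected=int((~keep).sum()),
        rejected=pd.DataFrame(
            rejected_rows,
            columns=[
                "contig", "position", "strand",
                "window_start", "window_end", "found_sequence",
            ],
        ),
    )
    return verified, report


def collapse_strands(table: CutSiteCountTable) -> CutSiteCountTable:
    """Sum the '+' and '-' rows flanking one recognition occurrence.

    Requires a verified table (occurrence coordinates must exist). The
    resulting rows are keyed by occurrence start with strand '*'; per-sample
    column totals are conserved.
    """
    if not table.verified:
        raise CountTableError("collapse_strands requires a verified table")
    df = table.sites.copy()
    for j, s in enumerate(table.samples):
        df[f"__c{j}"] = table.counts[:, j]
    grouped = (
        df.groupby(["contig", "occurrence_start", "occurrence_end"], sort=False)[
            [f"__c{j}" for j in range(len(table.samples))]
        ]
        .sum()
        .reset_index()
    )
    sites = pd.DataFrame(
        {
            "contig": grouped["contig"],
            "position": grouped["occurrence_start"],
            "strand": "*",
            "occurrence_start": grouped["occurrence_start"],
            "occurrence_end": grouped["occurrence_end"],
        }
    )
    counts = grouped[[f"__c{j}" for j in range(len(table.samples))]].to_numpy()
    order = {c: i for i, c in enumerate(table.contig_order)}
    idx = np.lexsort((sites["position"].to_numpy(), sites["contig"].map(order).to_numpy()))
    return CutSiteCountTable(
        sites=sites.iloc[idx].reset_index(drop=True),
        counts=counts[idx],
        samples=list(table.samples),
        sample_meta=table.sample_meta.copy(),
        verified=True,
        contig_order=list(table.contig_order),
    )
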