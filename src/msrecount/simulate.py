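"""Synthetic MRE-seq data with known ground truth.

The generator emulates the data the pipeline consumes: a reference genome
that contains recognition occurrences only where they were planted (so the
planted truth is the complete truth), negative-binomial read counts per site
with group structure and planted differential methylation, and per-sample
coordinate-sorted indexed BAM files whose reads are 5'-anchored at the cut
positions — with a configurable fraction of reads deliberately displaced off
any occurrence to exercise the verification step.

All randomness flows from a single seeded generator, so every output is
bit-reproducible given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .enzyme import IUPAC_CODES, EnzymeSpec, iupac_pattern_regex, revcomp_iupac
from .genome import RecognitionOccurrence

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_genome",
    "simulate_count_matrix",
    "simulate_experiment",
    "write_fasta",
]

_BASES = np.array(list("ACGT"))


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic experiment.

    Defaults describe a small two-group MRE-seq study: a 100 kb genome with
    200 planted cut sites, six biological replicates per group, ~20k reads
    per sample (about 100 reads per site), biological NB dispersion 0.1,
    10% of sites differentially methylated at a 4-fold mean change, and
    perfectly mapped reads (mismap_fraction 0).
    """

    seed: int
    genome_length: int = 100_000
    n_target_sites: int = 200
    groups: tuple[tuple[str, int], ...] = (("control", 6), ("treatment", 6))
    mean_depth: int = 20_000
    dispersion: float = 0.1
    dm_fraction: float = 0.1
    effect_fold: float = 4.0
    mismap_fraction: float = 0.0
    read_length: int = 75
    baseline_sd: float = 1.0

    def __post_init__(self) -> None:
        for name in ("dm_fraction", "mismap_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise SimulationError(f"{name} must be in [0, 1], got {v}")
        if self.effect_fold <= 0:
            raise SimulationError("effect_fold must be > 0")
        if self.dispersion < 0:
            raise SimulationError("dispersion must be >= 0")


@dataclass
class SimTruth:
    """Planted truth: occurrence coordinates, per-group expected counts,
    differential flags, and the realized on-target read count per sample."""

    occurrences: pd.DataFrame  # contig, start, end, dm_flag, mean_<group>...
    counts: np.ndarray  # occurrences x samples, on-target (correctly placed) reads
    samples: list[str]
    sample_totals: pd.DataFrame  # sample, emitted_reads (incl. mismapped)

    def to_tsv(self, path: str | Path) -> None:
        df = self.occurrences.copy()
        for j, s in enumerate(self.samples):
            df[s] = self.counts[:, j]
        df.to_csv(path, sep="\t", index=False)


def _realize_pattern(pattern: str, rng: np.random.Generator) -> str:
    return "".join(rng.choice(sorted(IUPAC_CODES[c])) for c in pattern)


def simulate_genome(
    config: SimConfig, enzyme: EnzymeSpec, contig: str = "chr1"
) -> tuple[str, list[RecognitionOccurrence]]:
    """Random genome containing recognition matches only at planted positions.

    Planted occurrences are uniformly spaced with jitter, separated by at
    least twice the read length; spurious matches of the recognition pattern
    (or its reverse complement) arising in the random background are mutated
    away, so an in-silico digest of the emitted sequence returns exactly the
    planted occurrence list.
    """
    rng = np.random.default_rng(config.seed)
    L = enzyme.length
    margin = 2 * config.read_length
    span = config.genome_length - 2 * margin - L
    if config.n_target_sites < 1 or span <= 0:
        raise SimulationError("genome too short for the requested margins")
    spacing = span / config.n_target_sites
    if spacing < 2 * config.read_length + L:
        raise SimulationError(
            f"cannot place {config.n_target_sites} sites with >= 2x read_length "
            f"spacing in {config.genome_length} bases"
        )
    jitter = rng.uniform(-spacing / 4, spacing / 4, config.n_target_sites)
    centres = margin + spacing * (np.arange(config.n_target_sites) + 0.5)
    starts = (centres + jitter).astype(int) + 1
    seq = rng.choice(_BASES, size=config.genome_length)
    planted = set()
    for s in starts:
        seq[s - 1 : s - 1 + L] = list(_realize_pattern(enzyme.recognition, rng))
        planted.add(int(s))
    planted_bases = np.zeros(config.genome_length, dtype=bool)
    for s in planted:
        planted_bases[s - 1 : s - 1 + L] = True
    patterns = {enzyme.recognition, revcomp_iupac(enzyme.recognition)}
    regexes = [iupac_pattern_regex(p) for p in patterns]
    for _ in range(200):
        text = "".join(seq)
        spurious = set()
        for rx in regexes:
            for m in rx.finditer(text):
                start = m.start() + 1
                if start not in planted:
                    spurious.add(start)
        if not spurious:
            break
        for start in spurious:
            window = np.arange(start - 1, start - 1 + L)
            mutable = window[~planted_bases[window]]
            pos = int(rng.choice(mutable))
            current = seq[pos]
            seq[pos] = rng.choice([b for b in "ACGT" if b != current])
    else:
        raise SimulationError("could not purge spurious recognition matches")
    occurrences = [
        RecognitionOccurrence(contig, int(s), int(s) + L - 1) for s in sorted(planted)
    ]
    return "".join(seq), occurrences


def write_fasta(sequence: str, path: str | Path, contig: str = "chr1", width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{contig}\n")
        for i in range(0, len(sequence), width):
            fh.write(sequence[i : i + width] + "\n")


def simulate_count_matrix(
    n_sites: int,
    rng: np.random.Generator,
    n_per_group: tuple[int, int] = (6, 6),
    mean_count: float = 100.0,
    dispersion: float = 0.1,
    dm_fraction: float = 0.0,
    effect_fold: float = 1.0,
    baseline_sd: float = 1.0,
    block_sd: float = 0.0,
) -> dict:
    """NB count matrix with two groups, planted effects, optional block effects.

    Baseline site abundances are log-normal; ``round(dm_fraction * n_sites)``
    sites have their group-2 mean multiplied (half) or divided (half) by
    ``effect_fold``. With ``block_sd > 0`` samples are assigned to blocks
    that span both groups unevenly (emulating litters whose offspring are
    split unequally between conditions) and every (site, block) pair carries
    its own log-normal methylation effect of that magnitude — so ignoring
    the block leaks shared within-litter variation into the group contrast.
    Dispersion 0 draws Poisson counts.
    """
    n1, n2 = n_per_group
    baseline = mean_count * np.exp(rng.normal(0.0, baseline_sd, n_sites) - baseline_sd**2 / 2)
    n_dm = int(round(dm_fraction * n_sites))
    dm_idx = rng.choice(n_sites, size=n_dm, replace=False)
    dm_flags = np.zeros(n_sites, dtype=bool)
    dm_flags[dm_idx] = True
    effect = np.ones(n_sites)
    up = rng.random(n_dm) < 0.5
    effect[dm_idx[up]] = effect_fold
    effect[dm_idx[~up]] = 1.0 / effect_fold
    mean_g1 = baseline
    mean_g2 = baseline * effect
    groups = ["g1"] * n1 + ["g2"] * n2
    mu = np.column_stack(
        [mean_g1[:, None].repeat(n1, axis=1), mean_g2[:, None].repeat(n2, axis=1)]
    )
    if block_sd > 0:
        if n1 != n2 or n1 % 2:
            raise SimulationError("block assignment needs equal, even group sizes")
        n_blocks = (n1 + n2) // 3
        if n_blocks < 2:
            raise SimulationError("too few samples for block structure")
        # skewed litter allocation (3+0, 2+1, 1+2, 0+3, ...): litters lean
        # toward one condition, so within-litter variation contaminates the
        # group contrast unless the block is modelled
        per_block_g1 = [(3, 2, 1, 0)[k % 4] for k in range(n_blocks)]
        deficit = n1 - sum(per_block_g1)
        per_block_g1 = [min(3, max(0, v + (deficit > 0) - (deficit < 0))) for v in per_block_g1] \
            if deficit else per_block_g1
        blocks_g1 = [f"b{k + 1}" for k in range(n_blocks) for _ in range(per_block_g1[k])]
        blocks_g2 = [f"b{k + 1}" for k in range(n_blocks) for _ in range(3 - per_block_g1[k])]
        blocks = blocks_g1 + blocks_g2
        if len(blocks_g1) != n1 or len(blocks_g2) != n2:
            raise SimulationError("cannot tile blocks over the samples")
        block_levels = sorted(set(blocks), key=lambda b: int(b[1:]))
        block_effect = np.exp(rng.normal(0.0, block_sd, (n_sites, len(block_levels))))
        col_of = {b: k for k, b in enumerate(block_levels)}
        mu = mu * block_effect[:, [col_of[b] for b in blocks]]
    else:
        blocks = None
    if dispersion <= 0:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    return {
        "counts": counts.astype(np.int64),
        "dm_flags": dm_flags,
        "groups": groups,
        "blocks": blocks,
        "mean_g1": mean_g1,
        "mean_g2": mean_g2,
    }


def _revcomp_seq(s: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[c] for c in reversed(s))


def simulate_experiment(
    sequence: str,
    occurrences: list[RecognitionOccurrence],
    config: SimConfig,
    enzyme: EnzymeSpec,
    outdir: str | Path,
    contig: str = "chr1",
) -> tuple[list[Path], SimTruth, pd.DataFrame]:
    """Emit per-sample sorted+indexed BAMs, the truth table, and sample metadata.

    Per sample and site the read count is NB(depth-scaled mean, dispersion);
    each on-target read is anchored at the cut (forward reads start at
    occurrence start + cut offset, reverse reads 5'-end at occurrence
    end - cut offset, 50:50), sequence copied from the reference (reverse
    complemented on '-'), full-match CIGAR. A ``mismap_fraction`` of reads
    is instead placed uniformly away from any occurrence.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed + 1)
    c, L = enzyme.cut_offset, enzyme.length
    rl = config.read_length
    glen = len(sequence)
    occ_starts = np.array([o.start for o in occurrences])
    n_sites = len(occurrences)
    samples = [f"{g}{i + 1}" for g, n in config.groups for i in range(n)]
    group_of = [g for g, n in config.groups for _ in range(n)]
    if len(config.groups) != 2:
        raise SimulationError("the experiment simulator models exactly two groups")
    (g1, n1), (g2, n2) = config.groups
    mean_count = config.mean_depth / max(n_sites, 1)
    sim = simulate_count_matrix(
        n_sites,
        rng,
        n_per_group=(n1, n2),
        mean_count=mean_count,
        dispersion=config.dispersion,
        dm_fraction=config.dm_fraction,
        effect_fold=config.effect_fold,
        baseline_sd=config.baseline_sd,
    )
    counts = sim["counts"]

    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": contig, "LN": glen}],
            "CO": [f"msrecount simulate: {config}"],
        }
    )
    # positions a displaced read's 5' end must avoid: within L of any occurrence
    forbidden = np.sort(occ_starts)

    def displaced_position(strand: str) -> int:
        while True:
            pos5 = int(rng.integers(2 * rl, glen - 2 * rl))
            i = np.searchsorted(forbidden, pos5)
            near = []
            if i > 0:
                near.append(forbidden[i - 1])
            if i < len(forbidden):
                near.append(forbidden[i])
            if all(abs(pos5 - s) > 2 * L for s in near):
                return pos5

    bam_paths: list[Path] = []
    on_target = np.zeros((n_sites, len(samples)), dtype=np.int64)
    totals = []
    qual = pysam.qualitystring_to_array("I" * rl)
    for j, sample in enumerate(samples):
        records = []
        n_read = 0
        for i, occ in enumerate(occurrences):
            k = int(counts[i, j])
            if k == 0:
                continue
            n_mis = rng.binomial(k, config.mismap_fraction) if config.mismap_fraction > 0 else 0
            on_target[i, j] = k - n_mis
            fwd = rng.random(k) < 0.5
            for m in range(k):
                strand = "+" if fwd[m] else "-"
                if m < k - n_mis:
                    if strand == "+":
                        pos5 = occ.start + c
                    else:
                        pos5 = occ.end - c
                else:
                    pos5 = displaced_position(strand)
                left = pos5 if strand == "+" else pos5 - rl + 1
                seq = sequence[left - 1 : left - 1 + rl]
                a = pysam.AlignedSegment(header)
                a.query_name = f"{sample}:r{n_read}"
                a.flag = 16 if strand == "-" else 0
                a.reference_id = 0
                a.reference_start = left - 1
                a.mapping_quality = 60
                a.cigarstring = f"{rl}M"
                a.query_sequence = seq if strand == "+" else _revcomp_seq(seq)
                a.query_qualities = qual
                records.append(a)
                n_read += 1
        records.sort(key=lambda r: r.reference_start)
        path = outdir / f"{sample}.bam"
        with pysam.AlignmentFile(path, "wb", header=header) as bf:
            for rec in records:
                bf.write(rec)
        pysam.index(str(path))
        bam_paths.append(path)
        totals.append(n_read)

    occ_df = pd.DataFrame(
        {
            "contig": contig,
            "start": [o.start for o in occurrences],
            "end": [o.end for o in occurrences],
            "dm_flag": sim["dm_flags"],
            f"mean_{g1}": sim["mean_g1"],
            f"mean_{g2}": sim["mean_g2"],
        }
    )
    truth = SimTruth(
        occurrences=occ_df,
        counts=on_target,
        samples=samples,
        sample_totals=pd.DataFrame({"sample": samples, "emitted_reads": totals}),
    )
    meta = pd.DataFrame({"sample": samples, "group": group_of})
    return bam_paths, truth, meta
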