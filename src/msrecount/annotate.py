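"""Nearest-gene annotation of differentially methylated sites."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["GeneModel", "load_gene_models", "nearest_gene"]


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    contig: str
    start: int  # 1-based inclusive
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")


def _dedupe_ids(models: list[GeneModel]) -> list[GeneModel]:
    seen: dict[str, int] = {}
    out = []
    for m in models:
        if m.gene_id in seen:
            seen[m.gene_id] += 1
            m = GeneModel(
                f"{m.gene_id}.{seen[m.gene_id]}", m.contig, m.start, m.end, m.strand
            )
        else:
            seen[m.gene_id] = 0
        out.append(m)
    return out


def load_gene_models(
    path: str | Path, fmt: str | None = None, feature_type: str = "gene"
) -> list[GeneModel]:
    """Read gene models from GFF3, GTF or BED.

    BED intervals (0-based half-open) are converted to 1-based inclusive;
    GFF3/GTF are already 1-based and only records of ``feature_type`` are
    kept. Duplicate ids are suffixed deterministically (.1, .2, ...).
    """
    p = Path(path)
    if fmt is None:
        suffix = p.suffix.lower().lstrip(".")
        fmt = {"gff": "gff3", "gff3": "gff3", "gtf": "gtf", "bed": "bed"}.get(suffix)
        if fmt is None:
            raise ValueError(f"cannot infer gene-model format from {p.name!r}")
    models: list[GeneModel] = []
    if fmt == "bed":
        df = pd.read_csv(p, sep="\t", header=None, comment="#")
        if df.shape[1] < 4:
            raise ValueError("BED gene models need at least 4 columns (name)")
        for row in df.itertuples(index=False):
            strand = str(row[5]) if df.shape[1] >= 6 else "."
            models.append(
                GeneModel(str(row[3]), str(row[0]), int(row[1]) + 1, int(row[2]), strand)
            )
    elif fmt in ("gff3", "gtf"):
        import gffutils

        db = gffutils.create_db(
            str(p),
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
        for feat in db.features_of_type(feature_type):
            gid = (
                feat.attributes.get("gene_id", [None])[0]
                or feat.attributes.get("ID", [None])[0]
                or feat.id
            )
            models.append(
                GeneModel(str(gid), feat.seqid, feat.start, feat.end, feat.strand)
            )
    else:
        raise ValueError(f"unknown gene-model format {fmt!r}")
    models = _dedupe_ids(models)
    models.sort(key=lambda m: (m.contig, m.start, m.gene_id))
    return models


def nearest_gene(
    sites: pd.DataFrame, gene_models: list[GeneModel]
) -> pd.DataFrame:
    """Nearest gene per site (columns ``contig`` and ``position``).

    Distance is 0 inside the gene body, otherwise the gap to the nearer
    boundary; ties go to the gene with the smallest start, then the
    lexicographically smallest id. Sites on contigs without any gene get a
    null annotation. Distances are strand-agnostic; the gene strand is
    reported for downstream use.
    """
    by_contig: dict[str, list[GeneModel]] = {}
    for m in sorted(gene_models, key=lambda m: (m.contig, m.start, m.gene_id)):
        by_contig.setdefault(m.contig, []).append(m)
    arrays = {
        c: (
            np.array([m.start for m in ms]),
            np.array([m.end for m in ms]),
            ms,
        )
        for c, ms in by_contig.items()
    }
    out = []
    for contig, pos in zip(sites["contig"], sites["position"]):
        entry = arrays.get(str(contig))
        if entry is None:
            out.append((None, np.nan, None))
            continue
        starts, ends, ms = entry
        pos = int(pos)
        dist = np.where(
            (starts <= pos) & (pos <= ends),
            0,
            np.minimum(np.abs(starts - pos), np.abs(ends - pos)),
        )
        best = np.min(dist)
        cand = np.flatnonzero(dist == best)
        # ties: smallest start, then lexicographic id (models pre-sorted that way)
        chosen = ms[cand[0]]
        out.append((chosen.gene_id, int(best), chosen.strand))
    res = sites[["contig", "position"]].copy()
    res["gene_id"] = [o[0] for o in out]
    res["distance"] = [o[1] for o in out]
    res["gene_strand"] = [o[2] for o in out]
    return res
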