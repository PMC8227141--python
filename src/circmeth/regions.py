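"""Genomic region construction and probe-to-region assignment.

Each circRNA contributes three strand-aware regions: a 2 kb flank 5' of the
back-splice span (``Pre2000``), the span itself (``Interior``), and a 2 kb
flank 3' of it (``After2000``).  Genes contribute a 2 kb promoter upstream
of the TSS plus the gene body.  Coordinates are 1-based inclusive
throughout; BED I/O converts at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

FLANK = 2000

CIRC_REGION_LABELS = ("Pre2000", "Interior", "After2000")
GENE_REGION_LABELS = ("promoter", "gene_body")


@dataclass(frozen=True)
class CircRecord:
    """One circRNA back-splice locus."""

    id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str = "+"
    origin: str = "exonic"  # exonic | intronic | intergenic
    gene_id: str | None = None

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.id}: start {self.start} > end {self.end}")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"{self.id}: bad strand {self.strand!r}")
        if self.origin not in {"exonic", "intronic", "intergenic"}:
            raise ValueError(f"{self.id}: bad origin {self.origin!r}")
        if self.origin in {"exonic", "intronic"} and self.gene_id is None:
            raise ValueError(f"{self.id}: {self.origin} circRNA lacks parental gene")


@dataclass(frozen=True)
class GeneRecord:
    id: str
    chrom: str
    start: int
    end: int
    strand: str
    tss: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.id}: start > end")
        if not (self.start <= self.tss <= self.end):
            raise ValueError(f"{self.id}: TSS {self.tss} outside span")


@dataclass(frozen=True)
class Region:
    feature_id: str
    label: str
    chrom: str
    start: int  # 1-based inclusive
    end: int


@dataclass(frozen=True)
class RegionAssignment:
    probe_id: str
    feature_id: str
    label: str


def _effective_strand(strand: str) -> str:
    # unknown strand defaults to '+' (logged by callers that care)
    return "-" if strand == "-" else "+"


def circ_regions(
    circ: CircRecord,
    chrom_length: int | None = None,
    flank: int = FLANK,
    convention: str = "strand-aware",
) -> list[Region]:
    """Three labeled intervals for one circRNA.

    ``strand-aware`` places Pre2000 on the 5' side of the back-splice span
    (genomic left for '+', genomic right for '-'); ``genomic-left`` ignores
    strand.  Flanks are clamped at position 1 and, when ``chrom_length`` is
    given, at the chromosome end.
    """
    if convention not in {"strand-aware", "genomic-left"}:
        raise ValueError(f"unknown flank convention {convention!r}")
    strand = "+" if convention == "genomic-left" else _effective_strand(circ.strand)

    left = (max(1, circ.start - flank), circ.start - 1)
    right = (circ.end + 1, circ.end + flank)
    if chrom_length is not None:
        if circ.end > chrom_length:
            raise ValueError(f"{circ.id}: end beyond chromosome length")
        right = (right[0], min(right[1], chrom_length))

    if strand == "+":
        pre, after = left, right
    else:
        pre, after = right, left

    out = [Region(circ.id, "Interior", circ.chrom, circ.start, circ.end)]
    if pre[0] <= pre[1]:
        out.insert(0, Region(circ.id, "Pre2000", circ.chrom, pre[0], pre[1]))
    if after[0] <= after[1]:
        out.append(Region(circ.id, "After2000", circ.chrom, after[0], after[1]))
    return out


def gene_regions(
    gene: GeneRecord, chrom_length: int | None = None, flank: int = FLANK
) -> list[Region]:
    """Promoter (2 kb 5' of TSS, strand-aware) and gene-body intervals."""
    strand = _effective_strand(gene.strand)
    if strand == "+":
        prom = (max(1, gene.tss - flank), gene.tss - 1)
    else:
        prom = (gene.tss + 1, gene.tss + flank)
        if chrom_length is not None:
            prom = (prom[0], min(prom[1], chrom_length))
    out = [Region(gene.id, "gene_body", gene.chrom, gene.start, gene.end)]
    if prom[0] <= prom[1]:
        out.insert(0, Region(gene.id, "promoter", gene.chrom, prom[0], prom[1]))
    return out


def map_probes(
    probe_ids: Sequence[str],
    probe_chroms: Sequence[str],
    probe_positions: Sequence[int],
    regions: Iterable[Region],
) -> list[RegionAssignment]:
    """All (probe, region) containments; a probe may hit many regions.

    Sorted-sweep implementation: probes are sorted per chromosome and each
    region interval is resolved with two binary searches.
    """
    regions = list(regions)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    pids = np.asarray(probe_ids, dtype=object)
    pchrom = np.asarray(probe_chroms, dtype=object)
    ppos = np.asarray(probe_positions, dtype=np.int64)
    for chrom in np.unique(pchrom):
        mask = pchrom == chrom
        order = np.argsort(ppos[mask], kind="stable")
        by_chrom[str(chrom)] = (ppos[mask][order], pids[mask][order])

    out: list[RegionAssignment] = []
    for reg in regions:
        hit = by_chrom.get(reg.chrom)
        if hit is None:
            continue
        pos, ids = hit
        lo = np.searchsorted(pos, reg.start, side="left")
        hi = np.searchsorted(pos, reg.end, side="right")
        for pid in ids[lo:hi]:
            out.append(RegionAssignment(str(pid), reg.feature_id, reg.label))
    out.sort(key=lambda a: (a.probe_id, a.feature_id, a.label))
    return out


def assignments_frame(assignments: Iterable[RegionAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [(a.probe_id, a.feature_id, a.label) for a in assignments],
        columns=["probe_id", "feature_id", "region"],
    )


def build_circ_regions(
    catalog: pd.DataFrame,
    chrom_lengths: Mapping[str, int] | None = None,
    convention: str = "strand-aware",
) -> list[Region]:
    """Regions for every circRNA in a catalog frame (id, chrom, start, end, strand, origin, gene_id)."""
    out: list[Region] = []
    for row in catalog.itertuples(index=False):
        rec = CircRecord(
            id=row.id,
            chrom=row.chrom,
            start=int(row.start),
            end=int(row.end),
            strand=row.strand,
            origin=row.origin,
            gene_id=None if pd.isna(row.gene_id) else row.gene_id,
        )
        clen = None if chrom_lengths is None else chrom_lengths.get(rec.chrom)
        out.extend(circ_regions(rec, chrom_length=clen, convention=convention))
    return out


def build_gene_regions(
    annotation: pd.DataFrame, chrom_lengths: Mapping[str, int] | None = None
) -> list[Region]:
    out: list[Region] = []
    for row in annotation.itertuples(index=False):
        rec = GeneRecord(
            id=row.id,
            chrom=row.chrom,
            start=int(row.start),
            end=int(row.end),
            strand=row.strand,
            tss=int(row.tss),
        )
        clen = None if chrom_lengths is None else chrom_lengths.get(rec.chrom)
        out.extend(gene_regions(rec, chrom_length=clen))
    return out
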