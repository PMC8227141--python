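"""Multi-omics bundle container and plain-text round-trip I/O.

A bundle holds everything one paired tumor/normal analysis needs: gene
annotation, circRNA catalog (BED6 + attribute sidecar + sequences), three
count matrices, a probe table with per-sample beta values, the sample
design, a validated miRNA-target table, and miRNA sequences.  All files are
plain text (TSV / BED6 / FASTA / JSON) and round-trip exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class MultiOmicsBundle:
    annotation: pd.DataFrame  # id chrom start end strand tss
    catalog: pd.DataFrame  # id chrom start end strand origin gene_id
    gene_counts: pd.DataFrame  # features x samples (int)
    circ_counts: pd.DataFrame
    mirna_counts: pd.DataFrame
    probes: pd.DataFrame  # index probe id; chrom, pos, then one beta column per sample
    design: pd.DataFrame  # sample_id condition pair_id
    mirna_targets: pd.DataFrame  # mirna_id gene_id
    mirna_seqs: dict[str, str]
    circ_seqs: dict[str, str]
    chrom_lengths: dict[str, int]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.design["sample_id"])

    @property
    def condition(self) -> np.ndarray:
        """Boolean tumor indicator aligned with sample_ids."""
        return (self.design["condition"] == "tumor").to_numpy()

    def beta_matrix(self) -> pd.DataFrame:
        return self.probes[self.sample_ids]

    def validate(self) -> list[str]:
        """Schema/consistency diagnostics; empty list means clean."""
        problems: list[str] = []
        samples = self.sample_ids
        for name, mat in (
            ("gene_counts", self.gene_counts),
            ("circ_counts", self.circ_counts),
            ("mirna_counts", self.mirna_counts),
        ):
            if list(mat.columns) != samples:
                problems.append(f"{name}: columns do not match design sample ids")
            if (mat.to_numpy() < 0).any():
                problems.append(f"{name}: negative counts")
        missing = [s for s in samples if s not in self.probes.columns]
        if missing:
            problems.append(f"probes: missing sample columns {missing}")
        else:
            b = self.beta_matrix().to_numpy()
            if ((b <= 0) | (b >= 1)).any():
                problems.append("probes: beta values outside (0, 1)")
        if (self.catalog["start"] > self.catalog["end"]).any():
            problems.append("catalog: start > end")
        genic = self.catalog["origin"].isin(["exonic", "intronic"])
        known = set(self.annotation["id"])
        orphans = self.catalog.loc[genic & ~self.catalog["gene_id"].isin(known), "id"]
        if len(orphans):
            problems.append(f"catalog: parental genes missing from annotation: {list(orphans[:5])}")
        counts = self.design.groupby("pair_id")["condition"].nunique()
        if (counts != 2).any():
            problems.append("design: pair without both tumor and normal member")
        return problems


def _write_fasta(seqs: dict[str, str], path: Path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")


def _read_fasta(path: Path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def write_bundle(bundle: MultiOmicsBundle, out_dir: str | Path, manifest: dict | None = None) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    bundle.annotation.to_csv(out / "genes.tsv", sep="\t", index=False)

    # BED6 is 0-based half-open; internal coordinates are 1-based inclusive
    bed = pd.DataFrame(
        {
            "chrom": bundle.catalog["chrom"],
            "start": bundle.catalog["start"] - 1,
            "end": bundle.catalog["end"],
            "name": bundle.catalog["id"],
            "score": 0,
            "strand": bundle.catalog["strand"],
        }
    )
    bed.to_csv(out / "circ_catalog.bed", sep="\t", index=False, header=False)
    bundle.catalog[["id", "origin", "gene_id"]].to_csv(out / "circ_attrs.tsv", sep="\t", index=False)

    for name, mat in (
        ("counts_gene.tsv", bundle.gene_counts),
        ("counts_circ.tsv", bundle.circ_counts),
        ("counts_mirna.tsv", bundle.mirna_counts),
    ):
        mat.to_csv(out / name, sep="\t", index_label="feature_id")

    bundle.probes.to_csv(out / "probes.tsv", sep="\t", index_label="probe_id")
    bundle.design.to_csv(out / "design.tsv", sep="\t", index=False)
    bundle.mirna_targets.to_csv(out / "mirna_targets.tsv", sep="\t", index=False)
    _write_fasta(bundle.mirna_seqs, out / "mirna.fasta")
    _write_fasta(bundle.circ_seqs, out / "circ_sequences.fasta")
    with open(out / "chrom_lengths.tsv", "w") as fh:
        for chrom, length in bundle.chrom_lengths.items():
            fh.write(f"{chrom}\t{length}\n")
    if manifest is not None:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
    return out


def read_bundle(in_dir: str | Path) -> tuple[MultiOmicsBundle, dict | None]:
    d = Path(in_dir)
    annotation = pd.read_csv(d / "genes.tsv", sep="\t")
    bed = pd.read_csv(
        d / "circ_catalog.bed",
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    attrs = pd.read_csv(d / "circ_attrs.tsv", sep="\t")
    catalog = pd.DataFrame(
        {
            "id": bed["name"],
            "chrom": bed["chrom"],
            "start": bed["start"] + 1,
            "end": bed["end"],
            "strand": bed["strand"],
        }
    ).merge(attrs, on="id", how="left")
    gene_counts = pd.read_csv(d / "counts_gene.tsv", sep="\t", index_col="feature_id")
    circ_counts = pd.read_csv(d / "counts_circ.tsv", sep="\t", index_col="feature_id")
    mirna_counts = pd.read_csv(d / "counts_mirna.tsv", sep="\t", index_col="feature_id")
    probes = pd.read_csv(d / "probes.tsv", sep="\t", index_col="probe_id")
    design = pd.read_csv(d / "design.tsv", sep="\t")
    targets = pd.read_csv(d / "mirna_targets.tsv", sep="\t")
    mirna_seqs = _read_fasta(d / "mirna.fasta")
    circ_seqs = _read_fasta(d / "circ_sequences.fasta")
    chrom_lengths: dict[str, int] = {}
    with open(d / "chrom_lengths.tsv") as fh:
        for line in fh:
            chrom, length = line.split("\t")
            chrom_lengths[chrom] = int(length)
    manifest = None
    mpath = d / "manifest.json"
    if mpath.exists():
        with open(mpath) as fh:
            manifest = json.load(fh)
    bundle = MultiOmicsBundle(
        annotation=annotation,
        catalog=catalog,
        gene_counts=gene_counts,
        circ_counts=circ_counts,
        mirna_counts=mirna_counts,
        probes=probes,
        design=design,
        mirna_targets=targets,
        mirna_seqs=mirna_seqs,
        circ_seqs=circ_seqs,
        chrom_lengths=chrom_lengths,
    )
    return bundle, manifest


def bundles_equal(a: MultiOmicsBundle, b: MultiOmicsBundle) -> bool:
    frames = [
        (a.annotation, b.annotation),
        (a.catalog.fillna(""), b.catalog.fillna("")),
        (a.gene_counts, b.gene_counts),
        (a.circ_counts, b.circ_counts),
        (a.mirna_counts, b.mirna_counts),
        (a.probes, b.probes),
        (a.design, b.design),
        (a.mirna_targets, b.mirna_targets),
    ]
    for x, y in frames:
        try:
            pd.testing.assert_frame_equal(x, y, check_dtype=False)
        except AssertionError:
            return False
    return a.mirna_seqs == b.mirna_seqs and a.circ_seqs == b.circ_seqs and a.chrom_lengths == b.chrom_lengths
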