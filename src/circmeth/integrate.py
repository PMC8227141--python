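"""Expression/methylation integration.

Links the differential layers: catalog support filtering, identification of
DE circRNAs harboring DM sites whose parental genes are NOT differentially
expressed ("decoupled"), opposite-pattern circRNA/gene pairs, Spearman
methylation-expression correlation, region-level DM summaries, chromosome
density normalization, overlap Fisher tests, and a hypergeometric
over-representation test.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

SPEARMAN_P_CUTOFF = 0.05


def filter_catalog(
    circ_counts: pd.DataFrame, min_samples: int = 2, min_reads: int = 2
) -> pd.Index:
    """circRNAs with BSJ count >= min_reads in >= min_samples samples."""
    support = (circ_counts.to_numpy() >= min_reads).sum(axis=1)
    return circ_counts.index[support >= min_samples]


def spearman(x: np.ndarray, y: np.ndarray, exact_n_max: int = 9) -> tuple[float, float]:
    """Tie-aware Spearman rho with a two-sided p-value.

    rho is the Pearson correlation of mid-ranks.  For n <= exact_n_max the
    p-value is computed by full permutation enumeration; otherwise by the
    t-approximation t = rho * sqrt((n-2)/(1-rho^2)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 4:
        raise ValueError("need n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: Spearman undefined")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_n_max:
        perms = np.array(list(itertools.permutations(range(n))), dtype=np.intp)
        ryp = ry[perms]  # (n!, n)
        rxc = rx - rx.mean()
        ryc = ryp - ryp.mean(axis=1, keepdims=True)
        r = (ryc @ rxc) / (np.sqrt((rxc**2).sum()) * np.sqrt((ryc**2).sum(axis=1)))
        p = float(np.mean(np.abs(r) >= abs(rho) - 1e-12))
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
            p = 2.0 * stats.t.sf(abs(t), n - 2)
    return rho, float(p)


@dataclass
class DecoupledCirc:
    """A DE circRNA with >= 1 DM probe whose parental gene is not DE."""

    circ_id: str
    direction: str  # up | down
    gene_id: str
    gene_p_adj: float
    dm_probes: list[tuple[str, str, str]]  # (probe_id, region, dm_call)
    correlations: dict[str, tuple[float, float]] = field(default_factory=dict)


def decoupled_circrnas(
    circ_de: pd.DataFrame,
    gene_de: pd.DataFrame,
    assignments: pd.DataFrame,
    dm_calls: pd.Series,
    circ_gene: dict[str, str | None],
) -> list[DecoupledCirc]:
    """circRNAs with call != ns, >= 1 DM probe in their regions, and a
    non-DE parental gene.  Intergenic circRNAs (no parental gene) are
    excluded; a genic circRNA whose gene is missing from the gene table is
    an error."""
    dm_probe_ids = set(dm_calls.index[dm_calls != "ns"])
    hits = assignments[assignments["probe_id"].isin(dm_probe_ids)]
    dm_by_circ: dict[str, list[tuple[str, str, str]]] = {}
    for row in hits.itertuples(index=False):
        dm_by_circ.setdefault(row.feature_id, []).append(
            (row.probe_id, row.region, dm_calls[row.probe_id])
        )

    de_circ = circ_de.index[circ_de["call"] != "ns"]
    missing = [
        c
        for c in de_circ
        if circ_gene.get(c) is not None and circ_gene[c] not in gene_de.index
    ]
    if missing:
        raise KeyError(f"circRNAs reference genes absent from gene results: {missing[:5]}")

    out: list[DecoupledCirc] = []
    for circ_id in de_circ:
        gene_id = circ_gene.get(circ_id)
        if gene_id is None:
            continue
        probes = dm_by_circ.get(circ_id)
        if not probes:
            continue
        if gene_de.loc[gene_id, "call"] != "ns":
            continue
        out.append(
            DecoupledCirc(
                circ_id=circ_id,
                direction=str(circ_de.loc[circ_id, "call"]),
                gene_id=gene_id,
                gene_p_adj=float(gene_de.loc[gene_id, "p_adj"]),
                dm_probes=sorted(probes),
            )
        )
    out.sort(key=lambda d: d.circ_id)
    return out


def normalized_circ_expression(
    circ_counts: pd.DataFrame, size_factors: np.ndarray
) -> pd.DataFrame:
    """log2(count / size_factor + 1) — the expression scale used for the
    methylation correlation."""
    return np.log2(circ_counts / np.asarray(size_factors)[None, :] + 1.0)


def correlate_methylation_expression(
    decoupled: list[DecoupledCirc],
    circ_expr: pd.DataFrame,
    m_matrix: pd.DataFrame,
    p_cutoff: float = SPEARMAN_P_CUTOFF,
    adjust: bool = False,
) -> pd.DataFrame:
    """Spearman test of each decoupled circRNA's expression against each of
    its DM probes' M-values, across all samples jointly.

    Returns one row per (circ, probe) with rho, p, significance; when
    ``adjust`` is set, significance uses BH-adjusted p instead of raw p.
    """
    if list(circ_expr.columns) != list(m_matrix.columns):
        raise ValueError("sample columns of expression and methylation differ")
    rows = []
    for d in decoupled:
        x = circ_expr.loc[d.circ_id].to_numpy(dtype=float)
        for probe_id, region, call in d.dm_probes:
            y = m_matrix.loc[probe_id].to_numpy(dtype=float)
            try:
                rho, p = spearman(x, y)
            except ValueError:
                rho, p = np.nan, 1.0
            rows.append((d.circ_id, probe_id, region, call, rho, p))
    cor = pd.DataFrame(
        rows, columns=["circ_id", "probe_id", "region", "dm_call", "rho", "p"]
    )
    if len(cor):
        cor["p_adj"] = bh_adjust(cor["p"].to_numpy())
        cor["significant"] = (cor["p_adj"] if adjust else cor["p"]) < p_cutoff
    else:
        cor["p_adj"] = pd.Series(dtype=float)
        cor["significant"] = pd.Series(dtype=bool)
    return cor


def multi_probe_circs(correlations: pd.DataFrame) -> list[str]:
    """circRNAs significantly correlated with more than one DM site."""
    sig = correlations[correlations["significant"]]
    counts = sig.groupby("circ_id").size()
    return sorted(counts.index[counts > 1])


@dataclass
class RegionDMSummary:
    site_counts: pd.DataFrame  # index (direction, region), columns hyper/hypo
    region_counts_per_circ: pd.Series  # circ -> number of distinct regions with DM
    one_region_fraction: dict[str, float]  # per direction


def region_dm_summary(
    assignments: pd.DataFrame,
    dm_calls: pd.Series,
    circ_calls: pd.Series,
) -> RegionDMSummary:
    """DM-site counts per (circRNA direction x region x hyper/hypo) and the
    per-circRNA count of distinct regions harboring DM sites."""
    directions = ("up", "down")
    regions_ = ("Pre2000", "Interior", "After2000")
    idx = pd.MultiIndex.from_product([directions, regions_], names=["direction", "region"])
    counts = pd.DataFrame(0, index=idx, columns=["hyper", "hypo"])

    dm_probe_ids = set(dm_calls.index[dm_calls != "ns"])
    de_circ = set(circ_calls.index[circ_calls != "ns"])
    hits = assignments[
        assignments["probe_id"].isin(dm_probe_ids)
        & assignments["feature_id"].isin(de_circ)
        & assignments["region"].isin(regions_)
    ]
    per_circ_regions: dict[str, set[str]] = {}
    for row in hits.itertuples(index=False):
        direction = circ_calls[row.feature_id]
        call = dm_calls[row.probe_id]
        counts.loc[(direction, row.region), call] += 1
        per_circ_regions.setdefault(row.feature_id, set()).add(row.region)

    region_counts = pd.Series(
        {c: len(r) for c, r in per_circ_regions.items()}, dtype=int
    ).sort_index()
    one_region = {}
    for direction in directions:
        ids = [c for c in region_counts.index if circ_calls[c] == direction]
        one_region[direction] = (
            float(np.mean([region_counts[c] == 1 for c in ids])) if ids else float("nan")
        )
    return RegionDMSummary(counts, region_counts, one_region)


def opposite_pattern(
    circ_de: pd.DataFrame, gene_de: pd.DataFrame, circ_gene: dict[str, str | None]
) -> list[str]:
    """DE circRNAs whose parental gene is DE with the opposite sign."""
    out = []
    for circ_id in circ_de.index[circ_de["call"] != "ns"]:
        gene_id = circ_gene.get(circ_id)
        if gene_id is None or gene_id not in gene_de.index:
            continue
        if gene_de.loc[gene_id, "call"] == "ns":
            continue
        if np.sign(circ_de.loc[circ_id, "log2FC"]) != np.sign(gene_de.loc[gene_id, "log2FC"]):
            out.append(circ_id)
    return sorted(out)


def chromosome_density(
    de_circ_ids: list[str],
    catalog: pd.DataFrame,
    annotation: pd.DataFrame,
) -> pd.Series:
    """Per-chromosome DE-circRNA count normalized by gene count, sorted
    descending.  Chromosomes without genes are excluded."""
    circ_chrom = catalog.set_index("id")["chrom"]
    de_counts = circ_chrom.loc[[c for c in de_circ_ids if c in circ_chrom.index]].value_counts()
    gene_counts = annotation["chrom"].value_counts()
    ratios = {}
    for chrom, n_genes in gene_counts.items():
        if n_genes == 0:
            continue
        ratios[chrom] = float(de_counts.get(chrom, 0)) / float(n_genes)
    return pd.Series(ratios).sort_values(ascending=False)


def overlap_fisher(
    detected: set[str], catalog: set[str], universe_size: int
) -> tuple[float, float]:
    """Two-sided Fisher exact test of set overlap against a universe.

    Returns (odds_ratio, p).  The 2x2 table is membership in `detected` x
    membership in `catalog` over `universe_size` items.
    """
    both = len(detected & catalog)
    only_d = len(detected) - both
    only_c = len(catalog) - both
    neither = universe_size - both - only_d - only_c
    if neither < 0:
        raise ValueError("universe smaller than the union of the two sets")
    odds, p = stats.fisher_exact([[both, only_d], [only_c, neither]], alternative="two-sided")
    return float(odds), float(p)


def enrichment_ora(
    query: set[str],
    gene_sets: dict[str, set[str]],
    universe: set[str],
    fdr_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query gene list in each set.

    Upper-tail p = P(X >= overlap) with X ~ Hypergeom(N, K, n); BH across
    sets; significant iff FDR < cutoff.
    """
    if not query:
        raise ValueError("empty query")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    N = len(universe)
    n = len(query)
    rows = []
    for name, members in gene_sets.items():
        members = members & universe
        K = len(members)
        k = len(query & members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((name, K, k, p))
    out = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "p"]).set_index("set")
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["p_adj"] < fdr_cutoff
    return out
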