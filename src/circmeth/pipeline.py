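"""Pipeline orchestration: simulate -> DE -> DM -> regions -> integrate ->
ceRNA -> classify, with a run report of headline counts."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import bundle as bundle_mod
from . import cerna, diffexpr, diffmeth, evaluate, integrate
from . import regions as reg
from .simulate import SimConfig, GroundTruthManifest, simulate_bundle


@dataclass
class PipelineConfig:
    """Every threshold of the analysis, defaulting to the published values."""

    seed: int = 0
    out_dir: str = "circmeth_out"
    p_adj_cutoff: float = 0.05
    lfc_cutoff: float = 1.0  # gene/miRNA layers
    junction_min_reads: int = 2
    junction_min_samples: int = 2
    dm_cutoff: float = 0.5
    spearman_p_cutoff: float = 0.05
    spearman_adjust: bool = False
    score_cutoff: float = 140.0
    energy_cutoff: float = -20.0
    require_both_routes: bool = True
    flank_convention: str = "strand-aware"
    paired: bool = False
    nested: bool = False
    cv_folds: int = 10
    sim: SimConfig = field(default_factory=SimConfig)

    def validate(self) -> None:
        if not 0 < self.p_adj_cutoff <= 1:
            raise ValueError("p_adj_cutoff must lie in (0, 1]")
        if self.dm_cutoff < 0 or self.lfc_cutoff < 0:
            raise ValueError("cutoffs must be nonnegative")
        if self.flank_convention not in {"strand-aware", "genomic-left"}:
            raise ValueError("unknown flank convention")


def validate_inputs(bundle: bundle_mod.MultiOmicsBundle) -> list[str]:
    """Schema diagnostics for an assembled bundle (empty = clean)."""
    return bundle.validate()


@dataclass
class PipelineResult:
    report: dict
    de: dict[str, diffexpr.DELayerResult]
    dm: diffmeth.DMResult
    assignments: pd.DataFrame
    decoupled: list[integrate.DecoupledCirc]
    correlations: pd.DataFrame
    summary: integrate.RegionDMSummary
    opposite: list[str]
    network: "cerna.nx.Graph"
    cv: evaluate.CVResult | None


def run_pipeline(
    config: PipelineConfig,
    bundle: bundle_mod.MultiOmicsBundle | None = None,
    manifest: GroundTruthManifest | None = None,
    write: bool = True,
) -> PipelineResult:
    config.validate()
    if bundle is None:
        sim_cfg = config.sim
        sim_cfg.seed = config.seed
        bundle, manifest = simulate_bundle(sim_cfg)

    problems = validate_inputs(bundle)
    if problems:
        raise ValueError("input validation failed:\n" + "\n".join(problems))

    cond = bundle.condition
    pairs = bundle.design["pair_id"].to_numpy() if config.paired else None

    # differential expression, all three layers
    de: dict[str, diffexpr.DELayerResult] = {}
    kept = integrate.filter_catalog(
        bundle.circ_counts, config.junction_min_samples, config.junction_min_reads
    )
    layer_counts = {
        "gene": bundle.gene_counts,
        "circ": bundle.circ_counts.loc[kept],
        "mirna": bundle.mirna_counts,
    }
    for layer, counts in layer_counts.items():
        kwargs = dict(p_adj_cutoff=config.p_adj_cutoff)
        if layer != "circ":
            kwargs["lfc_cutoff"] = config.lfc_cutoff
        else:
            kwargs["junction_min_reads"] = config.junction_min_reads
            kwargs["junction_min_samples"] = config.junction_min_samples
        de[layer] = diffexpr.run_de(counts, cond, layer, pairs=pairs, **kwargs)

    # differential methylation
    dm = diffmeth.run_dm(
        bundle.beta_matrix(), cond, dm_cutoff=config.dm_cutoff, p_adj_cutoff=config.p_adj_cutoff
    )

    # regions + probe assignment (circRNA regions only feed the integration)
    circ_regions = reg.build_circ_regions(
        bundle.catalog[bundle.catalog["id"].isin(kept)],
        bundle.chrom_lengths,
        convention=config.flank_convention,
    )
    assignments = reg.assignments_frame(
        reg.map_probes(
            list(bundle.probes.index),
            list(bundle.probes["chrom"]),
            list(bundle.probes["pos"]),
            circ_regions,
        )
    )

    circ_gene = {
        row.id: (None if pd.isna(row.gene_id) else row.gene_id)
        for row in bundle.catalog.itertuples(index=False)
    }
    decoupled = integrate.decoupled_circrnas(
        de["circ"].table, de["gene"].table, assignments, dm.table["call"], circ_gene
    )
    circ_expr = integrate.normalized_circ_expression(
        layer_counts["circ"], de["circ"].size_factors
    )
    m_matrix = pd.DataFrame(
        diffmeth.beta_to_m(bundle.beta_matrix().to_numpy()),
        index=bundle.probes.index,
        columns=bundle.sample_ids,
    )
    correlations = integrate.correlate_methylation_expression(
        decoupled,
        circ_expr,
        m_matrix,
        p_cutoff=config.spearman_p_cutoff,
        adjust=config.spearman_adjust,
    )
    summary = integrate.region_dm_summary(
        assignments, dm.table["call"], de["circ"].table["call"]
    )
    opposite = integrate.opposite_pattern(de["circ"].table, de["gene"].table, circ_gene)

    # ceRNA network over decoupled circRNAs
    decoupled_ids = [d.circ_id for d in decoupled]
    circ_calls = de["circ"].table.loc[decoupled_ids, "call"] if decoupled_ids else pd.Series(dtype=object)
    mirna_calls = de["mirna"].table["call"]
    gene_calls = de["gene"].table["call"]
    circ_mirna = cerna.predict_pairs(
        {m: s for m, s in bundle.mirna_seqs.items() if mirna_calls.get(m, "ns") != "ns"},
        {c: bundle.circ_seqs[c] for c in decoupled_ids},
        score_cutoff=config.score_cutoff,
        energy_cutoff=config.energy_cutoff,
        require_both=config.require_both_routes,
    )
    network = cerna.build_cerna(
        circ_calls[circ_calls != "ns"],
        mirna_calls[mirna_calls != "ns"],
        gene_calls[gene_calls != "ns"],
        circ_mirna,
        bundle.mirna_targets,
    )

    # classification on DE-circRNA expression features
    de_circ_ids = de["circ"].table.index[de["circ"].table["call"] != "ns"]
    cv = None
    if len(de_circ_ids) >= 2:
        X = circ_expr.loc[de_circ_ids].to_numpy().T
        cv = evaluate.cv_auc(
            X, cond, evaluate.NearestCentroidClassifier(), k=config.cv_folds, seed=config.seed
        )

    sig_circ = sorted(correlations.loc[correlations["significant"], "circ_id"].unique()) if len(correlations) else []
    de_circ_with_dm = sorted(
        set(assignments.loc[assignments["probe_id"].isin(dm.table.index[dm.table["call"] != "ns"]), "feature_id"])
        & set(de_circ_ids)
    )
    report = {
        "seed": config.seed,
        "thresholds": {
            "p_adj": config.p_adj_cutoff,
            "lfc": config.lfc_cutoff,
            "junction": [config.junction_min_reads, config.junction_min_samples],
            "dm": config.dm_cutoff,
            "spearman_p": config.spearman_p_cutoff,
            "score": config.score_cutoff,
            "energy": config.energy_cutoff,
        },
        "n_circ_retained": int(len(kept)),
        "n_de_gene": int((de["gene"].table["call"] != "ns").sum()),
        "n_de_mirna": int((de["mirna"].table["call"] != "ns").sum()),
        "n_de_circ": int(len(de_circ_ids)),
        "n_dm_sites": int((dm.table["call"] != "ns").sum()),
        "n_de_circ_with_dm": len(de_circ_with_dm),
        "n_decoupled": len(decoupled),
        "n_correlated": len(sig_circ),
        "n_opposite": len(opposite),
        "network_nodes": int(network.number_of_nodes()),
        "network_edges": int(network.number_of_edges()),
        "mean_cv_auc": None if cv is None else cv.mean_auc,
        "decoupled_ids": decoupled_ids,
        "correlated_ids": sig_circ,
        "de_circ_with_dm_ids": de_circ_with_dm,
    }

    if write:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for layer, res in de.items():
            res.table.to_csv(out / f"de_{layer}.tsv", sep="\t", index_label="feature_id")
        dm.table.to_csv(out / "dm.tsv", sep="\t", index_label="probe_id")
        assignments.to_csv(out / "assignments.tsv", sep="\t", index=False)
        correlations.to_csv(out / "correlations.tsv", sep="\t", index=False)
        summary.site_counts.to_csv(out / "region_dm_summary.tsv", sep="\t")
        summary.region_counts_per_circ.to_csv(
            out / "regions_per_circ.tsv", sep="\t", index_label="circ_id", header=["n_regions"]
        )
        cerna.edges_frame(network).to_csv(out / "cerna_edges.tsv", sep="\t", index=False)
        cerna.write_graphml(network, str(out / "cerna.graphml"))
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)

    return PipelineResult(
        report=report,
        de=de,
        dm=dm,
        assignments=assignments,
        decoupled=decoupled,
        correlations=correlations,
        summary=summary,
        opposite=opposite,
        network=network,
        cv=cv,
    )
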