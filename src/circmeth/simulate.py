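"""Synthetic paired tumor/normal multi-omics generation with planted effects.

Every generated bundle carries a ground-truth manifest recording exactly
which features were perturbed and how: per-layer planted log2 fold changes,
per-probe planted M-shifts with their region labels, copula-coupled
circRNA/probe pairs, circRNAs planted as "decoupled" (circ DE + DM site,
parental gene null) and as "opposite" (circ and parental gene DE with
opposite signs).

Randomness is split into one independent stream per data layer from the
master seed, so enlarging one layer never perturbs another.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from . import regions as reg
from .bundle import MultiOmicsBundle

_RNA = np.array(list("ACGU"))
_COMPLEMENT = {"A": "U", "C": "G", "G": "C", "U": "A"}


@dataclass
class SimConfig:
    """All simulator knobs; defaults mirror the emulated study design."""

    n_pairs: int = 20
    n_genes: int = 600
    n_circ: int = 300
    n_mirna: int = 80
    n_probes: int = 2000
    n_chroms: int = 4
    nb_dispersion: float = 0.1
    beta_precision: float = 30.0
    m_sd: float = 0.5
    de_fraction: float = 0.1
    dm_fraction: float = 0.3  # fraction of circ-region probes given a planted shift
    lfc_effect: float = 2.0
    dm_effect: float = 1.0
    coupling_rho: float = 0.8
    origin_props: tuple[float, float, float] = (0.90, 0.04, 0.06)  # exonic, intronic, intergenic
    n_decoupled: int = 30
    n_opposite: int = 6
    n_coupled: int = 20
    null_beta: bool = False  # draw unperturbed probes from a Beta instead of logit-normal
    seed: int = 0

    def validate(self) -> None:
        if self.n_pairs < 2:
            raise ValueError("n_pairs must be >= 2")
        for name in ("n_genes", "n_circ", "n_mirna", "n_probes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if abs(sum(self.origin_props) - 1.0) > 1e-9:
            raise ValueError("origin_props must sum to 1")
        if any(p < 0 for p in self.origin_props):
            raise ValueError("origin_props must be nonnegative")
        if not 0 <= self.de_fraction <= 1 or not 0 <= self.dm_fraction <= 1:
            raise ValueError("de_fraction/dm_fraction must lie in [0, 1]")
        if not -1 <= self.coupling_rho <= 1:
            raise ValueError("coupling_rho must lie in [-1, 1]")
        if self.nb_dispersion <= 0 or self.beta_precision <= 0:
            raise ValueError("dispersions must be positive")
        if self.dm_fraction > 0 and self.dm_effect <= 0:
            raise ValueError("dm_effect must be positive when dm_fraction > 0")
        n_classes = sum(1 for p in self.origin_props if p > 0)
        if self.n_circ < n_classes:
            raise ValueError("n_circ smaller than the number of origin classes")


@dataclass
class GroundTruthManifest:
    de_features: dict[str, dict[str, float]] = field(default_factory=lambda: {"gene": {}, "circ": {}, "mirna": {}})
    dm_probes: dict[str, dict] = field(default_factory=dict)  # probe -> {dM, region, circ_id}
    coupled_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    decoupled_circ: list[str] = field(default_factory=list)
    opposite_circ: list[str] = field(default_factory=list)
    size_factors: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["coupled_pairs"] = [list(t) for t in self.coupled_pairs]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruthManifest":
        m = cls(**{k: d[k] for k in d if k in cls.__dataclass_fields__})
        m.coupled_pairs = [tuple(t) for t in m.coupled_pairs]
        return m


def _layer_rngs(seed: int) -> dict[str, np.random.Generator]:
    names = ["annotation", "gene", "circ", "mirna", "methylation", "coupling", "sequence", "design"]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


def make_design(n_pairs: int) -> pd.DataFrame:
    rows = []
    for i in range(1, n_pairs + 1):
        rows.append((f"T{i:02d}", "tumor", f"P{i:02d}"))
    for i in range(1, n_pairs + 1):
        rows.append((f"N{i:02d}", "normal", f"P{i:02d}"))
    return pd.DataFrame(rows, columns=["sample_id", "condition", "pair_id"])


def simulate_annotation(
    config: SimConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Gene annotation + circRNA catalog with origin classes in the
    configured proportions; exonic/intronic circRNAs nest inside a parental
    gene's span, intergenic ones fall in inter-gene gaps."""
    config.validate()
    chroms = [f"chr{i}" for i in range(1, config.n_chroms + 1)]
    gene_rows = []
    cursor = {c: 10_000 for c in chroms}
    gaps: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for i in range(config.n_genes):
        chrom = chroms[i % len(chroms)]
        gap = int(rng.integers(6_000, 25_000))
        length = int(rng.integers(5_000, 50_000))
        start = cursor[chrom] + gap
        end = start + length - 1
        gaps[chrom].append((cursor[chrom] + 1, start - 1))
        cursor[chrom] = end
        strand = "+" if rng.random() < 0.5 else "-"
        tss = start if strand == "+" else end
        gene_rows.append((f"G{i:04d}", chrom, start, end, strand, tss))
    annotation = pd.DataFrame(gene_rows, columns=["id", "chrom", "start", "end", "strand", "tss"])
    chrom_lengths = {c: cursor[c] + 50_000 for c in chroms}

    origins = rng.choice(
        ["exonic", "intronic", "intergenic"], size=config.n_circ, p=list(config.origin_props)
    )
    usable_gaps = [
        (chrom, lo, hi) for chrom, pairs in gaps.items() for lo, hi in pairs if hi - lo > 2_000
    ]
    circ_rows = []
    seen: set[str] = set()
    for origin in origins:
        for _ in range(200):  # redraw on id collision
            if origin == "intergenic":
                chrom, lo, hi = usable_gaps[int(rng.integers(len(usable_gaps)))]
                length = int(rng.integers(200, min(2_000, hi - lo)))
                start = int(rng.integers(lo, hi - length + 1))
                end = start + length - 1
                strand = "+" if rng.random() < 0.5 else "-"
                gene_id = None
            else:
                g = annotation.iloc[int(rng.integers(len(annotation)))]
                span = int(g.end - g.start + 1)
                length = int(rng.integers(200, max(201, min(8_000, span))))
                start = int(rng.integers(g.start, g.end - length + 2))
                end = start + length - 1
                strand = g.strand
                gene_id = g.id
            cid = f"{chrom if origin == 'intergenic' else g.chrom}:{start}-{end}"
            if cid not in seen:
                seen.add(cid)
                break
        circ_rows.append(
            (cid, cid.split(":")[0], start, end, strand, origin, gene_id)
        )
    catalog = pd.DataFrame(
        circ_rows, columns=["id", "chrom", "start", "end", "strand", "origin", "gene_id"]
    )
    return annotation, catalog, chrom_lengths


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB with mean mu and variance mu + alpha*mu^2."""
    if alpha <= 0:
        return rng.poisson(mean)
    n = 1.0 / alpha
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def simulate_layer_counts(
    feature_ids: list[str],
    design: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
    lfc: dict[str, float] | None = None,
    mean_range: tuple[float, float] = (20.0, 1000.0),
) -> tuple[pd.DataFrame, dict[str, float], np.ndarray, np.ndarray]:
    """One count matrix: NB(mean mu_i * s_j * 2^(x_j * lfc_i), dispersion).

    ``lfc`` maps feature id -> planted log2FC; when None a de_fraction of
    features get |log2FC| = lfc_effect with random sign.  Returns (matrix,
    planted lfc map, size factors, base means).
    """
    m = len(feature_ids)
    tumor = (design["condition"] == "tumor").to_numpy().astype(float)
    sf = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=len(design)))
    mu = np.exp(rng.uniform(np.log(mean_range[0]), np.log(mean_range[1]), size=m))
    if lfc is None:
        lfc = {}
        if config.de_fraction > 0 and config.lfc_effect != 0:
            n_de = int(round(config.de_fraction * m))
            idx = rng.choice(m, size=n_de, replace=False)
            signs = rng.choice([-1.0, 1.0], size=n_de)
            lfc = {feature_ids[i]: float(s * config.lfc_effect) for i, s in zip(idx, signs)}
    lfc_vec = np.array([lfc.get(f, 0.0) for f in feature_ids])
    mean = mu[:, None] * sf[None, :] * 2.0 ** (lfc_vec[:, None] * tumor[None, :])
    counts = _nb_draw(rng, mean, config.nb_dispersion)
    mat = pd.DataFrame(counts, index=pd.Index(feature_ids, name="feature_id"), columns=design["sample_id"])
    mat.columns.name = None
    return mat, lfc, sf, mu


def simulate_counts(
    catalog: pd.DataFrame,
    annotation: pd.DataFrame,
    design: pd.DataFrame,
    config: SimConfig,
    rngs: dict[str, np.random.Generator],
    gene_lfc: dict[str, float] | None = None,
    circ_lfc: dict[str, float] | None = None,
) -> dict:
    """Gene, circRNA (BSJ) and miRNA count matrices plus generation params."""
    gene_ids = list(annotation["id"])
    circ_ids = list(catalog["id"])
    mirna_ids = [f"miR-{i:03d}" for i in range(config.n_mirna)]
    gmat, glfc, gsf, gmu = simulate_layer_counts(
        gene_ids, design, config, rngs["gene"], lfc=gene_lfc
    )
    cmat, clfc, csf, cmu = simulate_layer_counts(
        circ_ids, design, config, rngs["circ"], lfc=circ_lfc, mean_range=(5.0, 200.0)
    )
    mmat, mlfc, msf, mmu = simulate_layer_counts(
        mirna_ids, design, config, rngs["mirna"], mean_range=(50.0, 2000.0)
    )
    return {
        "gene": {"counts": gmat, "lfc": glfc, "sf": gsf, "mu": gmu},
        "circ": {"counts": cmat, "lfc": clfc, "sf": csf, "mu": cmu},
        "mirna": {"counts": mmat, "lfc": mlfc, "sf": msf, "mu": mmu},
    }


def simulate_methylation(
    catalog: pd.DataFrame,
    annotation: pd.DataFrame,
    design: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
    chrom_lengths: dict[str, int],
    forced_dm_circ: list[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, dict], np.ndarray, np.ndarray]:
    """Probe table with beta values and planted tumor M-shifts.

    Probes are scattered genome-wide with part of them deliberately placed
    inside circRNA regions.  A dm_fraction of in-region probes receives a
    tumor-group M shift of +/- dm_effect; each circRNA in ``forced_dm_circ``
    is guaranteed at least one shifted probe in its Interior.  Returns
    (probe table, dm map, baseline M per probe, planted shift per probe).
    """
    config.validate()
    chroms = list(chrom_lengths)
    n_target = int(round(0.45 * config.n_probes))
    n_free = config.n_probes - n_target

    pos_rows: list[tuple[str, int]] = []
    for _ in range(n_free):
        chrom = chroms[int(rng.integers(len(chroms)))]
        pos_rows.append((chrom, int(rng.integers(1, chrom_lengths[chrom] + 1))))
    circ_region_list = reg.build_circ_regions(catalog, chrom_lengths)
    for _ in range(n_target):
        r = circ_region_list[int(rng.integers(len(circ_region_list)))]
        pos_rows.append((r.chrom, int(rng.integers(r.start, r.end + 1))))
    order = rng.permutation(len(pos_rows))
    pos_rows = [pos_rows[i] for i in order]
    probe_ids = [f"cg{i:06d}" for i in range(len(pos_rows))]

    assignments = reg.map_probes(
        probe_ids, [c for c, _ in pos_rows], [p for _, p in pos_rows], circ_region_list
    )
    in_region: dict[str, list[tuple[str, str]]] = {}
    for a in assignments:
        in_region.setdefault(a.probe_id, []).append((a.feature_id, a.label))
    by_circ: dict[str, list[tuple[str, str]]] = {}
    for pid, hits in in_region.items():
        for circ_id, label in hits:
            by_circ.setdefault(circ_id, []).append((pid, label))

    dm_map: dict[str, dict] = {}
    if config.dm_fraction > 0:
        eligible = sorted(in_region)
        n_dm = int(round(config.dm_fraction * len(eligible)))
        chosen = rng.choice(len(eligible), size=min(n_dm, len(eligible)), replace=False)
        for i in chosen:
            pid = eligible[i]
            circ_id, label = in_region[pid][int(rng.integers(len(in_region[pid])))]
            sign = -1.0 if rng.random() < 0.5 else 1.0
            dm_map[pid] = {"dM": sign * config.dm_effect, "region": label, "circ_id": circ_id}
    for circ_id in forced_dm_circ or []:
        hits = by_circ.get(circ_id, [])
        if not any(pid in dm_map for pid, _ in hits):
            if not hits:
                warnings.warn(f"{circ_id}: no probe landed in its regions; cannot force DM")
                continue
            pid, label = hits[int(rng.integers(len(hits)))]
            sign = -1.0 if rng.random() < 0.5 else 1.0
            dm_map[pid] = {"dM": sign * config.dm_effect, "region": label, "circ_id": circ_id}

    tumor = (design["condition"] == "tumor").to_numpy().astype(float)
    base_m = rng.normal(0.0, 1.5, size=len(probe_ids))
    shift = np.array([dm_map.get(pid, {}).get("dM", 0.0) for pid in probe_ids])
    M = base_m[:, None] + shift[:, None] * tumor[None, :] + rng.normal(
        0.0, config.m_sd, size=(len(probe_ids), len(design))
    )
    betas = np.exp2(M) / (1.0 + np.exp2(M))
    if config.null_beta:
        null = shift == 0.0
        mean_b = np.exp2(base_m[null]) / (1.0 + np.exp2(base_m[null]))
        a = mean_b * config.beta_precision
        b = (1.0 - mean_b) * config.beta_precision
        draw = rng.beta(a[:, None], b[:, None], size=(null.sum(), len(design)))
        betas[null] = np.clip(draw, 1e-6, 1 - 1e-6)

    idx = pd.Index(probe_ids, name="probe_id")
    probes = pd.concat(
        [
            pd.DataFrame(
                {"chrom": [c for c, _ in pos_rows], "pos": [p for _, p in pos_rows]}, index=idx
            ),
            pd.DataFrame(betas, index=idx, columns=list(design["sample_id"])),
        ],
        axis=1,
    )
    return probes, dm_map, base_m, shift


def gaussian_copula_pair(
    rng: np.random.Generator,
    nb_mean: np.ndarray,
    nb_alpha: float,
    m_mean: np.ndarray,
    m_sd: float,
    rho: float,
) -> tuple[np.ndarray, np.ndarray]:
    """One (count row, beta row) draw from a Gaussian copula with latent
    correlation ``rho``, preserving the NB and logit-normal margins."""
    if not -1.0 <= rho <= 1.0:
        raise ValueError("|rho| must be <= 1")
    n = len(nb_mean)
    z1 = rng.standard_normal(n)
    z2 = rho * z1 + np.sqrt(max(0.0, 1.0 - rho**2)) * rng.standard_normal(n)
    u1 = np.clip(stats.norm.cdf(z1), 1e-12, 1 - 1e-12)
    r = 1.0 / nb_alpha
    p = r / (r + nb_mean)
    counts = stats.nbinom.ppf(u1, r, p).astype(np.int64)
    M = m_mean + m_sd * z2
    betas = np.exp2(M) / (1.0 + np.exp2(M))
    return counts, betas


def couple_circ_methylation(
    circ_counts: pd.DataFrame,
    probes: pd.DataFrame,
    coupled_pairs: list[tuple[str, str, float]],
    config: SimConfig,
    rng: np.random.Generator,
    circ_params: dict,
    probe_params: dict,
    design: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rewrite each coupled (circRNA, probe) pair's rows from a Gaussian
    copula so their per-sample values share latent correlation while both
    margins keep their planted parameters."""
    circ_counts = circ_counts.copy()
    probes = probes.copy()
    tumor = (design["condition"] == "tumor").to_numpy().astype(float)
    samples = list(design["sample_id"])
    circ_ids = list(circ_counts.index)
    for circ_id, probe_id, rho in coupled_pairs:
        if circ_id not in circ_counts.index or probe_id not in probes.index:
            raise KeyError(f"coupled pair references unknown ids ({circ_id}, {probe_id})")
        i = circ_ids.index(circ_id)
        mu = circ_params["mu"][i]
        lfc = circ_params["lfc"].get(circ_id, 0.0)
        nb_mean = mu * circ_params["sf"] * 2.0 ** (lfc * tumor)
        m_mean = probe_params["base_m"][probe_id] + probe_params["shift"][probe_id] * tumor
        counts, betas = gaussian_copula_pair(
            rng, nb_mean, config.nb_dispersion, m_mean, config.m_sd, rho
        )
        circ_counts.loc[circ_id, samples] = counts
        probes.loc[probe_id, samples] = betas
    return circ_counts, probes


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_RNA[rng.integers(0, 4, size=length)])


def reverse_complement_rna(seq: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(seq.replace("T", "U")))


def simulate_bundle(config: SimConfig) -> tuple[MultiOmicsBundle, GroundTruthManifest]:
    """Full coherent bundle + manifest.

    Planting order: annotation first; then the decoupled/opposite circRNA
    classes are chosen among genic circRNAs; gene and circRNA fold changes
    are assigned so decoupled parental genes stay null and opposite parental
    genes flip sign; methylation guarantees a DM probe for every decoupled
    circRNA; finally selected (circ, probe) pairs are copula-coupled.
    """
    config.validate()
    rngs = _layer_rngs(config.seed)
    design = make_design(config.n_pairs)
    annotation, catalog, chrom_lengths = simulate_annotation(config, rngs["annotation"])

    rng_plan = rngs["design"]
    genic = catalog.loc[catalog["gene_id"].notna()]
    genic_ids = list(genic["id"])
    rng_plan.shuffle(genic_ids)
    n_dec = min(config.n_decoupled, len(genic_ids))
    decoupled = sorted(genic_ids[:n_dec])
    remaining = genic_ids[n_dec:]
    n_opp = min(config.n_opposite, len(remaining))
    opposite = sorted(remaining[:n_opp])
    gene_of = dict(zip(catalog["id"], catalog["gene_id"]))

    # circ fold changes: planted DE fraction plus every decoupled/opposite circ
    circ_ids = list(catalog["id"])
    circ_lfc: dict[str, float] = {}
    n_de = int(round(config.de_fraction * len(circ_ids)))
    for cid in rng_plan.permutation(circ_ids)[:n_de]:
        circ_lfc[cid] = float(rng_plan.choice([-1, 1]) * config.lfc_effect)
    for cid in decoupled + opposite:
        circ_lfc.setdefault(cid, float(rng_plan.choice([-1, 1]) * config.lfc_effect))

    # gene fold changes: de_fraction of genes, excluding decoupled parents;
    # opposite parents forced DE with the opposite sign of their circRNA
    decoupled_parents = {gene_of[c] for c in decoupled}
    opposite_parents = {gene_of[c]: c for c in opposite}
    gene_ids = list(annotation["id"])
    gene_lfc: dict[str, float] = {}
    n_de_g = int(round(config.de_fraction * len(gene_ids)))
    for gid in rng_plan.permutation(gene_ids):
        if len(gene_lfc) >= n_de_g:
            break
        if gid in decoupled_parents or gid in opposite_parents:
            continue
        gene_lfc[gid] = float(rng_plan.choice([-1, 1]) * config.lfc_effect)
    for gid, cid in opposite_parents.items():
        gene_lfc[gid] = -np.sign(circ_lfc[cid]) * config.lfc_effect

    layers = simulate_counts(catalog, annotation, design, config, rngs, gene_lfc=gene_lfc, circ_lfc=circ_lfc)

    probes, dm_map, base_m, shift = simulate_methylation(
        catalog, annotation, design, config, rngs["methylation"], chrom_lengths, forced_dm_circ=decoupled
    )
    # drop decoupled circ that could not receive a DM probe
    dm_circ = {v["circ_id"] for v in dm_map.values()}
    decoupled = [c for c in decoupled if c in dm_circ]

    # copula coupling between decoupled circRNAs and their DM probes
    probe_of_circ: dict[str, str] = {}
    for pid, info in dm_map.items():
        probe_of_circ.setdefault(info["circ_id"], pid)
    couple_candidates = [c for c in decoupled if c in probe_of_circ]
    rng_plan.shuffle(couple_candidates)
    coupled = [
        (c, probe_of_circ[c], float(config.coupling_rho))
        for c in sorted(couple_candidates[: config.n_coupled])
    ]
    base_m_map = dict(zip(probes.index, base_m))
    shift_map = dict(zip(probes.index, shift))
    circ_counts, probes = couple_circ_methylation(
        layers["circ"]["counts"],
        probes,
        coupled,
        config,
        rngs["coupling"],
        {"mu": layers["circ"]["mu"], "lfc": layers["circ"]["lfc"], "sf": layers["circ"]["sf"]},
        {"base_m": base_m_map, "shift": shift_map},
        design,
    )
    layers["circ"]["counts"] = circ_counts

    # sequences: random miRNAs; circ sequences embed full complements of a
    # couple of DE miRNAs for every decoupled circRNA so the ceRNA stage has
    # signal to find
    rng_seq = rngs["sequence"]
    mirna_ids = list(layers["mirna"]["counts"].index)
    mirna_seqs = {mid: _random_seq(rng_seq, 22) for mid in mirna_ids}
    de_mirnas = [m for m in mirna_ids if m in layers["mirna"]["lfc"]]
    circ_seqs: dict[str, str] = {}
    for cid in catalog["id"]:
        s = _random_seq(rng_seq, int(rng_seq.integers(200, 401)))
        if cid in decoupled and de_mirnas:
            for mid in rng_seq.choice(de_mirnas, size=min(2, len(de_mirnas)), replace=False):
                site = reverse_complement_rna(mirna_seqs[mid])
                pos = int(rng_seq.integers(0, len(s) - len(site)))
                s = s[:pos] + site + s[pos + len(site):]
        circ_seqs[cid] = s

    # validated miRNA-target table: random pairs plus direction-consistent
    # pairs for DE miRNAs
    rows = []
    for mid in mirna_ids:
        for gid in rng_seq.choice(gene_ids, size=3, replace=False):
            rows.append((mid, gid))
    de_genes_by_sign = {
        1.0: [g for g, l in gene_lfc.items() if l > 0],
        -1.0: [g for g, l in gene_lfc.items() if l < 0],
    }
    for mid in de_mirnas:
        sign = -np.sign(layers["mirna"]["lfc"][mid])
        pool = de_genes_by_sign.get(sign, [])
        if pool:
            for gid in rng_seq.choice(pool, size=min(2, len(pool)), replace=False):
                rows.append((mid, gid))
    mirna_targets = pd.DataFrame(sorted(set(rows)), columns=["mirna_id", "gene_id"])

    bundle = MultiOmicsBundle(
        annotation=annotation,
        catalog=catalog,
        gene_counts=layers["gene"]["counts"],
        circ_counts=layers["circ"]["counts"],
        mirna_counts=layers["mirna"]["counts"],
        probes=probes,
        design=design,
        mirna_targets=mirna_targets,
        mirna_seqs=mirna_seqs,
        circ_seqs=circ_seqs,
        chrom_lengths=chrom_lengths,
    )
    manifest = GroundTruthManifest(
        de_features={"gene": gene_lfc, "circ": circ_lfc, "mirna": layers["mirna"]["lfc"]},
        dm_probes=dm_map,
        coupled_pairs=coupled,
        decoupled_circ=decoupled,
        opposite_circ=opposite,
        size_factors={
            layer: dict(zip(design["sample_id"], map(float, layers[layer]["sf"])))
            for layer in ("gene", "circ", "mirna")
        },
    )
    return bundle, manifest
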