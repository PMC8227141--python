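"""circRNA-miRNA seed matching, simplified duplex scoring, and
direction-constrained ceRNA network assembly.

Seed sites follow the canonical classification: scan the target for
Watson-Crick complements of miRNA positions 2-7/2-8 and classify as 8mer
(2-8 match plus target A opposite position 1), 7mer-m8 (2-8), 7mer-A1
(2-7 plus A), or 6mer (2-7).  The duplex score is a documented simplified
complementarity scheme (match +5, G:U wobble +2, mismatch -3, seed
positions weighted x4) with a stacked-pair energy proxy; a pair is retained
iff score > 140 and energy < -20.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

VALID = set("ACGU")
_PAIR = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}
_WOBBLE = {("G", "U"), ("U", "G")}

SCORE_CUTOFF = 140.0
ENERGY_CUTOFF = -20.0

MATCH = 5.0
WOBBLE = 2.0
MISMATCH = -3.0
SEED_WEIGHT = 4.0
SEED_SPAN = (1, 8)  # 0-based miRNA positions 2..8

# crude per-pair stacking energies (kcal/mol-like)
_ENERGY = {"GC": -3.0, "AU": -2.0, "GU": -1.0}


def _norm(seq: str) -> str:
    s = seq.upper().replace("T", "U")
    if set(s) - VALID:
        raise ValueError(f"invalid characters in sequence: {sorted(set(s) - VALID)}")
    return s


def _complement(base: str) -> str:
    return {"A": "U", "U": "A", "C": "G", "G": "C"}[base]


@dataclass(frozen=True)
class SeedSite:
    target_id: str
    position: int  # 0-based position in the target of the seed-match 3' end (site t1)
    site_type: str  # 8mer | 7mer-m8 | 7mer-A1 | 6mer
    score: float = float("nan")
    energy: float = float("nan")


def seed_match(mirna: str, target: str, target_id: str = "target") -> list[SeedSite]:
    """All canonical seed sites of one miRNA in one target sequence.

    The target is scanned 5'->3'; a site matches when the target bases
    pairing miRNA positions 2-7 (6mer core) are exact Watson-Crick
    complements, read antiparallel.
    """
    mi = _norm(mirna)
    tg = _norm(target)
    if len(mi) < 8:
        raise ValueError("miRNA must be at least 8 nt")
    # target site (5'->3') complementary to miRNA positions 2..7 is
    # revcomp(mi[1:7]); position 8 pairs one base further 5' on the target.
    core6 = "".join(_complement(b) for b in reversed(mi[1:7]))
    m8 = _complement(mi[7])
    sites: list[SeedSite] = []
    for i in range(len(tg) - 5):
        if tg[i : i + 6] != core6:
            continue
        has_m8 = i >= 1 and tg[i - 1] == m8
        # the base opposite miRNA position 1 sits 3' of the core on the target
        has_a1 = i + 6 < len(tg) and tg[i + 6] == "A"
        if has_m8 and has_a1:
            site_type = "8mer"
        elif has_m8:
            site_type = "7mer-m8"
        elif has_a1:
            site_type = "7mer-A1"
        else:
            site_type = "6mer"
        sites.append(SeedSite(target_id, i, site_type))
    return sites


def duplex_score(mirna: str, window: str) -> tuple[float, float]:
    """Simplified complementarity score + energy proxy for a gapless
    antiparallel alignment of the miRNA against a target window.

    The window is aligned so its 3' end pairs the miRNA 5' end.  Seed
    positions (miRNA 2-8) are weighted x4.  Raises if the window is shorter
    than the miRNA.
    """
    mi = _norm(mirna)
    win = _norm(window)
    if len(win) < len(mi):
        raise ValueError("window shorter than miRNA")
    paired = win[::-1][: len(mi)]  # antiparallel: reversed window vs miRNA 5'->3'
    score = 0.0
    energy = 0.0
    for k, (a, b) in enumerate(zip(mi, paired)):
        if (a, b) in _PAIR:
            s = MATCH
            energy += _ENERGY["GC"] if {a, b} == {"G", "C"} else _ENERGY["AU"]
        elif (a, b) in _WOBBLE:
            s = WOBBLE
            energy += _ENERGY["GU"]
        else:
            s = MISMATCH
            energy += 0.5
        if SEED_SPAN[0] <= k < SEED_SPAN[1]:
            s *= SEED_WEIGHT
        score += s
    return score, energy


def predict_pairs(
    mirna_seqs: dict[str, str],
    target_seqs: dict[str, str],
    score_cutoff: float = SCORE_CUTOFF,
    energy_cutoff: float = ENERGY_CUTOFF,
    require_both: bool = True,
) -> pd.DataFrame:
    """Predicted miRNA-target pairs.

    A pair passes the seed route when it has >= 1 canonical seed site, and
    the duplex route when some window clears the score/energy thresholds.
    ``require_both`` intersects the two routes (default), else unions them.
    """
    rows = []
    for mid, mseq in mirna_seqs.items():
        mlen = len(_norm(mseq))
        for tid, tseq in target_seqs.items():
            sites = seed_match(mseq, tseq, target_id=tid)
            best_score, best_energy, duplex_ok = -np.inf, np.inf, False
            tnorm = _norm(tseq)
            for site in sites:
                # window: miRNA-length stretch whose 3' end covers the site
                end = min(len(tnorm), site.position + 7)
                start = end - mlen
                if start < 0:
                    continue
                s, e = duplex_score(mseq, tnorm[start:end])
                if s > best_score:
                    best_score, best_energy = s, e
                if s > score_cutoff and e < energy_cutoff:
                    duplex_ok = True
            seed_ok = bool(sites)
            keep = (seed_ok and duplex_ok) if require_both else (seed_ok or duplex_ok)
            if keep:
                rank = {"8mer": 0, "7mer-m8": 1, "7mer-A1": 2, "6mer": 3}
                best_type = min((s.site_type for s in sites), key=rank.__getitem__, default="")
                rows.append((mid, tid, len(sites), best_type, best_score, best_energy))
    return pd.DataFrame(
        rows, columns=["mirna_id", "target_id", "n_sites", "site_type", "score", "energy"]
    )


def build_cerna(
    circ_calls: pd.Series,
    mirna_calls: pd.Series,
    gene_calls: pd.Series,
    circ_mirna_pairs: pd.DataFrame,  # columns mirna_id, target_id (circ)
    validated_targets: pd.DataFrame,  # columns mirna_id, gene_id
) -> nx.Graph:
    """Tripartite ceRNA graph under the opposite-direction constraint.

    Edges: circ-miRNA where predicted and the two calls are opposite
    (up/down); miRNA-mRNA where validated and opposite.  Only miRNAs that
    bridge a circRNA and an mRNA survive; isolated nodes are dropped.
    """
    for name, calls in (("circ", circ_calls), ("mirna", mirna_calls), ("gene", gene_calls)):
        if calls.isna().any():
            raise ValueError(f"{name}: missing direction labels")
    opposite = {"up": "down", "down": "up"}
    g = nx.Graph()
    for row in circ_mirna_pairs.itertuples(index=False):
        cid, mid = row.target_id, row.mirna_id
        if cid not in circ_calls.index or mid not in mirna_calls.index:
            continue
        cdir, mdir = circ_calls[cid], mirna_calls[mid]
        if cdir in opposite and mdir == opposite[cdir]:
            g.add_node(cid, kind="circ", direction=cdir)
            g.add_node(mid, kind="mirna", direction=mdir)
            g.add_edge(cid, mid, evidence="predicted")
    for row in validated_targets.itertuples(index=False):
        mid, gid = row.mirna_id, row.gene_id
        if mid not in g or gid not in gene_calls.index:
            continue
        mdir, gdir = mirna_calls[mid], gene_calls[gid]
        if gdir in opposite and mdir == opposite[gdir]:
            g.add_node(gid, kind="gene", direction=gdir)
            g.add_edge(mid, gid, evidence="validated")
    # prune miRNAs lacking either side, then orphaned nodes
    for node in [n for n, d in g.nodes(data=True) if d["kind"] == "mirna"]:
        kinds = {g.nodes[nb]["kind"] for nb in g.neighbors(node)}
        if not {"circ", "gene"} <= kinds:
            g.remove_node(node)
    g.remove_nodes_from([n for n in g if g.degree(n) == 0])
    return g


def network_stats(g: nx.Graph) -> pd.DataFrame:
    """Per-node degree table with the hub flag on max-degree circRNA(s)."""
    if g.number_of_nodes() == 0:
        return pd.DataFrame(columns=["kind", "direction", "degree", "hub"])
    rows = [
        (n, d["kind"], d["direction"], g.degree(n)) for n, d in g.nodes(data=True)
    ]
    out = pd.DataFrame(rows, columns=["node", "kind", "direction", "degree"]).set_index("node")
    circ = out[out["kind"] == "circ"]
    max_deg = circ["degree"].max() if len(circ) else 0
    out["hub"] = (out["kind"] == "circ") & (out["degree"] == max_deg) & (max_deg > 0)
    return out.sort_values("degree", ascending=False)


def write_graphml(g: nx.Graph, path: str) -> None:
    nx.write_graphml(g, path)


def edges_frame(g: nx.Graph) -> pd.DataFrame:
    rows = []
    for u, v, d in g.edges(data=True):
        # orient circ->mirna->gene
        if g.nodes[u]["kind"] != "circ" and g.nodes[v]["kind"] in ("circ", "mirna"):
            u, v = v, u
        rows.append((u, g.nodes[u]["kind"], v, g.nodes[v]["kind"], d["evidence"]))
    return pd.DataFrame(rows, columns=["source", "source_kind", "target", "target_kind", "evidence"])
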