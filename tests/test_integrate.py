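import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from circmeth import integrate
from circmeth.simulate import gaussian_copula_pair


class TestFilterCatalog:
    def test_two_samples_with_two_reads_kept(self):
        counts = pd.DataFrame([[2, 2, 0, 0]], index=["c1"])
        assert list(integrate.filter_catalog(counts)) == ["c1"]

    def test_single_supported_sample_dropped(self):
        counts = pd.DataFrame([[5, 0, 0, 0]], index=["c1"])
        assert list(integrate.filter_catalog(counts)) == []

    def test_all_zero_dropped(self):
        counts = pd.DataFrame([[0, 0, 0, 0]], index=["c1"])
        assert list(integrate.filter_catalog(counts)) == []

    def test_one_read_not_enough(self):
        counts = pd.DataFrame([[1, 1, 1, 1]], index=["c1"])
        assert list(integrate.filter_catalog(counts)) == []


def spearman_permutation_oracle(x, y):
    """Full-enumeration Spearman: rho of mid-ranks + exact two-sided p."""
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    obs = np.corrcoef(rx, ry)[0, 1]
    hits = total = 0
    for perm in itertools.permutations(ry):
        r = np.corrcoef(rx, perm)[0, 1]
        total += 1
        if abs(r) >= abs(obs) - 1e-12:
            hits += 1
    return obs, hits / total


class TestSpearman:
    def test_monotone_is_one(self):
        rho, _ = integrate.spearman(np.array([1, 2, 3, 4.0]), np.array([2, 4, 6, 8.0]))
        assert rho == pytest.approx(1.0)

    def test_reversed_is_minus_one(self):
        rho, _ = integrate.spearman(np.array([1, 2, 3, 4.0]), np.array([8, 6, 4, 2.0]))
        assert rho == pytest.approx(-1.0)

    def test_ties_match_enumeration_oracle(self, rng):
        for _ in range(10):
            x = rng.integers(0, 4, size=6).astype(float)
            y = rng.integers(0, 4, size=6).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rho, p = integrate.spearman(x, y)
            rho_o, p_o = spearman_permutation_oracle(x, y)
            assert rho == pytest.approx(rho_o, abs=1e-12)
            assert p == pytest.approx(p_o, abs=1e-12)

    def test_large_n_matches_scipy_t_approximation(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        rho, p = integrate.spearman(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            integrate.spearman(np.ones(6), np.arange(6.0))

    def test_short_vectors_rejected(self):
        with pytest.raises(ValueError):
            integrate.spearman(np.arange(3.0), np.arange(3.0))


def _de_frame(entries):
    return pd.DataFrame(
        {
            "log2FC": {k: v[0] for k, v in entries.items()},
            "p_adj": {k: v[1] for k, v in entries.items()},
            "call": {k: v[2] for k, v in entries.items()},
        }
    )


class TestDecoupled:
    def setup_method(self):
        self.circ_de = _de_frame({"c1": (2.0, 0.01, "up"), "c2": (2.0, 0.01, "up"), "c3": (0.1, 0.8, "ns")})
        self.gene_de = _de_frame({"g1": (0.2, 0.3, "ns"), "g2": (2.0, 0.01, "up")})
        self.assignments = pd.DataFrame(
            {"probe_id": ["p1", "p2"], "feature_id": ["c1", "c2"], "region": ["Interior", "Pre2000"]}
        )
        self.dm_calls = pd.Series({"p1": "hyper", "p2": "hyper"})
        self.circ_gene = {"c1": "g1", "c2": "g2", "c3": "g1"}

    def test_included_when_gene_ns(self):
        got = integrate.decoupled_circrnas(
            self.circ_de, self.gene_de, self.assignments, self.dm_calls, self.circ_gene
        )
        assert [d.circ_id for d in got] == ["c1"]
        assert got[0].direction == "up" and got[0].gene_id == "g1"
        assert got[0].dm_probes == [("p1", "Interior", "hyper")]

    def test_excluded_when_gene_de(self):
        got = integrate.decoupled_circrnas(
            self.circ_de, self.gene_de, self.assignments, self.dm_calls, self.circ_gene
        )
        assert "c2" not in [d.circ_id for d in got]

    def test_ns_circ_excluded(self):
        assignments = pd.DataFrame(
            {"probe_id": ["p1"], "feature_id": ["c3"], "region": ["Interior"]}
        )
        got = integrate.decoupled_circrnas(
            self.circ_de, self.gene_de, assignments, self.dm_calls, self.circ_gene
        )
        assert got == []

    def test_intergenic_excluded(self):
        circ_gene = dict(self.circ_gene, c1=None)
        got = integrate.decoupled_circrnas(
            self.circ_de, self.gene_de, self.assignments, self.dm_calls, circ_gene
        )
        assert got == []

    def test_missing_gene_errors(self):
        circ_gene = dict(self.circ_gene, c1="missing")
        with pytest.raises(KeyError, match="absent"):
            integrate.decoupled_circrnas(
                self.circ_de, self.gene_de, self.assignments, self.dm_calls, circ_gene
            )

    def test_matches_brute_force_oracle_fuzz(self, rng):
        for trial in range(200):
            n_circ, n_gene, n_probe = 12, 6, 15
            circ_ids = [f"c{i}" for i in range(n_circ)]
            gene_ids = [f"g{i}" for i in range(n_gene)]
            probe_ids = [f"p{i}" for i in range(n_probe)]
            circ_calls = rng.choice(["up", "down", "ns"], n_circ)
            gene_calls = rng.choice(["up", "down", "ns"], n_gene)
            dm = pd.Series(rng.choice(["hyper", "hypo", "ns"], n_probe), index=probe_ids)
            circ_de = _de_frame(
                {c: (1.0 if v == "up" else -1.0, 0.01, v) for c, v in zip(circ_ids, circ_calls)}
            )
            gene_de = _de_frame(
                {g: (1.0 if v == "up" else -1.0, 0.01, v) for g, v in zip(gene_ids, gene_calls)}
            )
            circ_gene = {
                c: (None if rng.random() < 0.2 else gene_ids[int(rng.integers(n_gene))])
                for c in circ_ids
            }
            rows = []
            for _ in range(20):
                rows.append(
                    (
                        probe_ids[int(rng.integers(n_probe))],
                        circ_ids[int(rng.integers(n_circ))],
                        ["Pre2000", "Interior", "After2000"][int(rng.integers(3))],
                    )
                )
            assignments = pd.DataFrame(rows, columns=["probe_id", "feature_id", "region"])

            got = {
                d.circ_id
                for d in integrate.decoupled_circrnas(circ_de, gene_de, assignments, dm, circ_gene)
            }
            # brute-force three-way intersection
            expected = set()
            for c in circ_ids:
                if circ_de.loc[c, "call"] == "ns" or circ_gene[c] is None:
                    continue
                if gene_de.loc[circ_gene[c], "call"] != "ns":
                    continue
                has_dm = any(
                    dm[p] != "ns"
                    for p, f in zip(assignments["probe_id"], assignments["feature_id"])
                    if f == c
                )
                if has_dm:
                    expected.add(c)
            assert got == expected


class TestCorrelation:
    def _decoupled(self, circ_id, probes):
        return integrate.DecoupledCirc(circ_id, "up", "g1", 0.5, probes)

    def test_coupled_pair_significant(self):
        n = 40
        counts, betas = gaussian_copula_pair(
            np.random.default_rng(0), np.full(n, 100.0), 0.1, np.zeros(n), 0.5, 0.9
        )
        cols = [f"s{i}" for i in range(n)]
        expr = pd.DataFrame([np.log2(counts + 1.0)], index=["c1"], columns=cols)
        m = pd.DataFrame([np.log2(betas / (1 - betas))], index=["p1"], columns=cols)
        cor = integrate.correlate_methylation_expression(
            [self._decoupled("c1", [("p1", "Interior", "hyper")])], expr, m
        )
        assert bool(cor["significant"].iloc[0])

    def test_null_rate_close_to_alpha(self, rng):
        n = 40
        hits = []
        cols = [f"s{i}" for i in range(n)]
        for _ in range(400):
            expr = pd.DataFrame([rng.normal(size=n)], index=["c1"], columns=cols)
            m = pd.DataFrame([rng.normal(size=n)], index=["p1"], columns=cols)
            cor = integrate.correlate_methylation_expression(
                [self._decoupled("c1", [("p1", "Interior", "hyper")])], expr, m
            )
            hits.append(bool(cor["significant"].iloc[0]))
        assert 0.02 <= np.mean(hits) <= 0.09

    def test_multi_probe_counted(self, rng):
        n = 40
        cols = [f"s{i}" for i in range(n)]
        x = rng.normal(size=n)
        expr = pd.DataFrame([x], index=["c1"], columns=cols)
        m = pd.DataFrame([x + rng.normal(0, 0.1, n), x + rng.normal(0, 0.1, n)],
                         index=["p1", "p2"], columns=cols)
        cor = integrate.correlate_methylation_expression(
            [self._decoupled("c1", [("p1", "Interior", "hyper"), ("p2", "Pre2000", "hyper")])],
            expr, m,
        )
        assert integrate.multi_probe_circs(cor) == ["c1"]

    def test_sample_mismatch_rejected(self):
        expr = pd.DataFrame([[1.0, 2.0]], index=["c1"], columns=["a", "b"])
        m = pd.DataFrame([[1.0, 2.0]], index=["p1"], columns=["b", "a"])
        with pytest.raises(ValueError):
            integrate.correlate_methylation_expression(
                [self._decoupled("c1", [("p1", "Interior", "hyper")])], expr, m
            )


class TestRegionSummary:
    def test_single_interior_hyper(self):
        assignments = pd.DataFrame(
            {"probe_id": ["p1"], "feature_id": ["c1"], "region": ["Interior"]}
        )
        dm = pd.Series({"p1": "hyper"})
        circ = pd.Series({"c1": "up"})
        s = integrate.region_dm_summary(assignments, dm, circ)
        assert s.site_counts.loc[("up", "Interior"), "hyper"] == 1
        assert s.site_counts.to_numpy().sum() == 1
        assert s.one_region_fraction["up"] == 1.0

    def test_all_three_regions(self):
        assignments = pd.DataFrame(
            {
                "probe_id": ["p1", "p2", "p3"],
                "feature_id": ["c1"] * 3,
                "region": ["Pre2000", "Interior", "After2000"],
            }
        )
        dm = pd.Series({"p1": "hyper", "p2": "hypo", "p3": "hyper"})
        circ = pd.Series({"c1": "down"})
        s = integrate.region_dm_summary(assignments, dm, circ)
        assert s.region_counts_per_circ["c1"] == 3
        assert s.one_region_fraction["down"] == 0.0

    def test_empty_dm_all_zero(self):
        assignments = pd.DataFrame(
            {"probe_id": ["p1"], "feature_id": ["c1"], "region": ["Interior"]}
        )
        s = integrate.region_dm_summary(assignments, pd.Series({"p1": "ns"}), pd.Series({"c1": "up"}))
        assert s.site_counts.to_numpy().sum() == 0

    def test_marginals_conserved(self, rng):
        probes = [f"p{i}" for i in range(30)]
        circs = [f"c{i}" for i in range(10)]
        assignments = pd.DataFrame(
            {
                "probe_id": rng.choice(probes, 50),
                "feature_id": rng.choice(circs, 50),
                "region": rng.choice(["Pre2000", "Interior", "After2000"], 50),
            }
        )
        dm = pd.Series(rng.choice(["hyper", "hypo", "ns"], 30), index=probes)
        circ = pd.Series(rng.choice(["up", "down", "ns"], 10), index=circs)
        s = integrate.region_dm_summary(assignments, dm, circ)
        expected = sum(
            1
            for row in assignments.itertuples(index=False)
            if dm[row.probe_id] != "ns" and circ[row.feature_id] != "ns"
        )
        assert s.site_counts.to_numpy().sum() == expected


class TestOppositePattern:
    def setup_method(self):
        self.gene_de = _de_frame({"g1": (-2.0, 0.01, "down"), "g2": (2.0, 0.01, "up"), "g3": (0.1, 0.9, "ns")})
        self.circ_gene = {"c1": "g1", "c2": "g2", "c3": "g3"}

    def test_opposite_flagged(self):
        circ_de = _de_frame({"c1": (2.0, 0.01, "up")})
        assert integrate.opposite_pattern(circ_de, self.gene_de, self.circ_gene) == ["c1"]

    def test_same_direction_not_flagged(self):
        circ_de = _de_frame({"c2": (2.0, 0.01, "up")})
        assert integrate.opposite_pattern(circ_de, self.gene_de, self.circ_gene) == []

    def test_gene_ns_not_flagged(self):
        circ_de = _de_frame({"c3": (2.0, 0.01, "up")})
        assert integrate.opposite_pattern(circ_de, self.gene_de, self.circ_gene) == []


class TestChromosomeDensity:
    def test_simple_ratio(self):
        catalog = pd.DataFrame({"id": ["c1"], "chrom": ["chr1"]})
        annotation = pd.DataFrame({"chrom": ["chr1"] * 100})
        d = integrate.chromosome_density(["c1"] * 1, catalog, annotation)
        # one DE circ over 100 genes
        assert d["chr1"] == pytest.approx(0.01)

    def test_doubling_genes_halves_ratio(self):
        catalog = pd.DataFrame({"id": ["c1"], "chrom": ["chr1"]})
        a1 = pd.DataFrame({"chrom": ["chr1"] * 50})
        a2 = pd.DataFrame({"chrom": ["chr1"] * 100})
        d1 = integrate.chromosome_density(["c1"], catalog, a1)
        d2 = integrate.chromosome_density(["c1"], catalog, a2)
        assert d1["chr1"] == pytest.approx(2 * d2["chr1"])

    def test_planted_enrichment_ranks_first(self, rng):
        chroms = ["chr1", "chr2", "chr3"]
        annotation = pd.DataFrame({"chrom": list(np.repeat(chroms, 50))})
        ids = [f"c{i}" for i in range(30)]
        catalog = pd.DataFrame({"id": ids, "chrom": ["chr2"] * 20 + list(rng.choice(["chr1", "chr3"], 10))})
        d = integrate.chromosome_density(ids, catalog, annotation)
        assert d.index[0] == "chr2"


def hypergeom_two_sided_oracle(table):
    (a, b), (c, d) = table
    N, K, n = a + b + c + d, a + c, a + b
    lo, hi = max(0, n - (N - K)), min(n, K)
    probs = {k: stats.hypergeom.pmf(k, N, K, n) for k in range(lo, hi + 1)}
    obs = probs[a]
    return sum(p for p in probs.values() if p <= obs * (1 + 1e-10))


class TestFisher:
    def test_diagonal_table(self):
        # [[2,0],[0,2]]: detected={x,y}, catalog={x,y}, universe 4
        _, p = integrate.overlap_fisher({"x", "y"}, {"x", "y"}, 4)
        assert p == pytest.approx(1 / 3, abs=1e-12)

    def test_balanced_table_p_one(self):
        _, p = integrate.overlap_fisher({"x", "y"}, {"x", "z"}, 4)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_universe_too_small_rejected(self):
        with pytest.raises(ValueError):
            integrate.overlap_fisher({"a", "b"}, {"c", "d"}, 3)

    def test_matches_hypergeometric_oracle_fuzz(self, rng):
        for _ in range(100):
            a, b, c, d = rng.integers(0, 40, size=4)
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            detected = {f"d{i}" for i in range(a + b)}
            catalog = {f"d{i}" for i in range(a)} | {f"k{i}" for i in range(c)}
            _, p = integrate.overlap_fisher(detected, catalog, a + b + c + d)
            assert p == pytest.approx(hypergeom_two_sided_oracle([[a, b], [c, d]]), abs=1e-10)


class TestEnrichment:
    def test_identical_set_minimal_p(self):
        universe = {f"g{i}" for i in range(50)}
        query = {f"g{i}" for i in range(5)}
        out = integrate.enrichment_ora(query, {"hit": set(query), "other": {"g40", "g41"}}, universe)
        assert out.loc["hit", "p"] < 1e-6
        assert bool(out.loc["hit", "significant"])

    def test_expected_overlap_not_significant(self):
        universe = {f"g{i}" for i in range(100)}
        query = {f"g{i}" for i in range(10)}
        # set of 50 genes, expected overlap 5, observed 5
        members = {f"g{i}" for i in range(5)} | {f"g{i}" for i in range(10, 55)}
        out = integrate.enrichment_ora(query, {"s": members}, universe)
        assert out.loc["s", "p"] >= 0.5

    def test_equals_one_sided_fisher(self, rng):
        universe = {f"g{i}" for i in range(60)}
        query = set(rng.choice(sorted(universe), 12, replace=False))
        members = set(rng.choice(sorted(universe), 20, replace=False))
        out = integrate.enrichment_ora(query, {"s": members}, universe)
        k = len(query & members)
        table = [
            [k, len(query) - k],
            [len(members) - k, 60 - len(query | members) + 0],
        ]
        # complete the 2x2: universe minus query minus members plus overlap
        table[1][1] = 60 - len(query) - len(members) + k
        _, p_ref = stats.fisher_exact(table, alternative="greater")
        assert out.loc["s", "p"] == pytest.approx(p_ref, rel=1e-9)

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError):
            integrate.enrichment_ora(set(), {"s": {"a"}}, {"a"})
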