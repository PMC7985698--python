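import math

import numpy as np
import pytest
from scipy import stats as sps

from creascan.stats import (
    ContingencyTable,
    EnrichmentError,
    GOCycleError,
    benjamini_hochberg,
    fisher_exact_two_sided,
    go_enrichment,
    hypergeometric_upper_tail,
    motif_set_enrichment,
    percent_increase,
    propagate_go,
)
from creascan.motifs import build_presence_table
from creascan.simulate import generate_enrichment_scenario

from oracles import fisher_two_sided_oracle


class TestFisher:
    def test_enumeration_example(self):
        odds, p = fisher_exact_two_sided(ContingencyTable(8, 2, 4, 6))
        assert odds == 6.0
        # Full enumeration over x in 2..10 of C(12,x) C(8,10-x) / C(20,10).
        assert p == pytest.approx(0.1698, abs=1e-4)

    def test_symmetric_table(self):
        odds, p = fisher_exact_two_sided(ContingencyTable(5, 5, 5, 5))
        assert odds == 1.0
        assert p == 1.0

    def test_degenerate_margin(self):
        odds, p = fisher_exact_two_sided(ContingencyTable(0, 10, 0, 10))
        assert math.isnan(odds)
        assert p == 1.0

    def test_infinite_odds_ratio(self):
        odds, _ = fisher_exact_two_sided(ContingencyTable(3, 0, 0, 3))
        assert odds == math.inf

    def test_negative_counts_rejected(self):
        with pytest.raises(EnrichmentError):
            ContingencyTable(-1, 2, 3, 4)

    def test_matches_exact_enumeration_on_random_tables(self, rng):
        for _ in range(300):
            cells = [int(x) for x in rng.integers(0, 16, size=4)]
            if sum(cells) == 0:
                continue
            _, p = fisher_exact_two_sided(ContingencyTable(*cells))
            assert p == pytest.approx(float(fisher_two_sided_oracle(*cells)), abs=1e-10)

    def test_matches_scipy_on_random_tables(self, rng):
        # Cross-check against an independent implementation of the same rule.
        for _ in range(100):
            cells = [int(x) for x in rng.integers(0, 25, size=4)]
            if sum(cells) == 0:
                continue
            _, p = fisher_exact_two_sided(ContingencyTable(*cells))
            expected = sps.fisher_exact(np.array(cells).reshape(2, 2))[1]
            assert p == pytest.approx(expected, rel=1e-6)

    def test_large_table_log_space_path(self):
        table = ContingencyTable(716, 1596, 2044, 7644)
        _, p = fisher_exact_two_sided(table)
        expected = sps.fisher_exact([[716, 1596], [2044, 7644]])[1]
        assert p == pytest.approx(expected, rel=1e-8)


class TestHypergeometric:
    def test_worked_example(self):
        assert hypergeometric_upper_tail(20, 5, 5, 3) == pytest.approx(
            1126 / 15504, abs=1e-12
        )

    def test_zero_successes_is_whole_support(self):
        assert hypergeometric_upper_tail(50, 10, 8, 0) == 1.0

    def test_point_masses_normalize(self):
        N, K, n = 30, 12, 9
        total = sum(
            sps.hypergeom.pmf(k, N, K, n) for k in range(0, min(n, K) + 1)
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_upper_plus_strict_lower_is_one(self, rng):
        for _ in range(50):
            N = int(rng.integers(5, 80))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            lo = max(0, n - (N - K))
            k = int(rng.integers(lo, min(n, K) + 1))
            upper = hypergeometric_upper_tail(N, K, n, k)
            strict_lower = float(sps.hypergeom.cdf(k - 1, N, K, n))
            assert upper + strict_lower == pytest.approx(1.0, abs=1e-10)

    def test_impossible_margins_rejected(self):
        with pytest.raises(EnrichmentError, match="impossible"):
            hypergeometric_upper_tail(10, 3, 5, 4)


class TestBenjaminiHochberg:
    def test_step_up_by_hand(self):
        adjusted = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert list(adjusted) == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_value(self):
        assert list(benjamini_hochberg([0.5])) == [0.5]

    def test_adjusted_at_least_raw_and_order_preserved(self, rng):
        p = rng.uniform(size=40)
        adjusted = benjamini_hochberg(p)
        assert np.all(adjusted >= p)
        assert np.all(adjusted <= 1.0)

    def test_permutation_equivariance(self, rng):
        p = rng.uniform(size=25)
        perm = rng.permutation(25)
        direct = benjamini_hochberg(p)[perm]
        permuted = benjamini_hochberg(p[perm])
        assert np.allclose(direct, permuted)

    def test_out_of_range_rejected(self):
        with pytest.raises(EnrichmentError):
            benjamini_hochberg([0.5, 1.2])


class TestPercentIncrease:
    @pytest.mark.parametrize(
        "prop_set, prop_bg, expected",
        [(0.2, 0.2, 0.0), (0.3, 0.2, 50.0), (0.1, 0.2, -50.0)],
    )
    def test_arithmetic(self, prop_set, prop_bg, expected):
        assert percent_increase(prop_set, prop_bg) == pytest.approx(expected)

    def test_zero_background_rejected(self):
        with pytest.raises(EnrichmentError):
            percent_increase(0.5, 0.0)


class TestPropagateGO:
    def test_chain_closure(self):
        closed = propagate_go({"g": {"t1"}}, {"t1": {"t2"}, "t2": {"t3"}})
        assert closed == {"g": frozenset({"t1", "t2", "t3"})}

    def test_no_parents_identity(self):
        closed = propagate_go({"g": {"t1", "t2"}}, {})
        assert closed == {"g": frozenset({"t1", "t2"})}

    def test_diamond_counts_once(self):
        parents = {"t1": {"t2", "t3"}, "t2": {"t4"}, "t3": {"t4"}}
        closed = propagate_go({"g": {"t1"}}, parents)
        assert closed["g"] == frozenset({"t1", "t2", "t3", "t4"})

    def test_cycle_is_named(self):
        with pytest.raises(GOCycleError, match="t1"):
            propagate_go({"g": {"t1"}}, {"t1": {"t2"}, "t2": {"t1"}})


class TestGOEnrichment:
    def _setup(self):
        background = [f"g{i}" for i in range(20)]
        annotations = {g: {"T"} for g in background[:5]}
        gene_set = background[:3] + background[10:12]
        return gene_set, annotations, background

    def test_matches_hypergeometric_example(self):
        gene_set, annotations, background = self._setup()
        result = go_enrichment(gene_set, annotations, background)
        row = result[result["feature"] == "T"].iloc[0]
        assert (row["k_set"], row["k_bg"], row["n_set"], row["n_bg"]) == (3, 5, 5, 20)
        assert row["p"] == pytest.approx(1126 / 15504, abs=1e-12)

    def test_set_equal_background_gives_p_one(self):
        _, annotations, background = self._setup()
        result = go_enrichment(background, annotations, background)
        assert (result["p"] == 1.0).all()

    def test_unannotated_terms_not_tested(self):
        gene_set, annotations, background = self._setup()
        annotations["g15"] = {"OTHER"}  # not in the gene set
        result = go_enrichment(gene_set, annotations, background)
        assert "OTHER" not in set(result["feature"])

    def test_term_universe_restricts_testing(self):
        gene_set, annotations, background = self._setup()
        annotations["g0"] = {"T", "EXTRA"}
        result = go_enrichment(
            gene_set, annotations, background, term_universe={"T"}
        )
        assert set(result["feature"]) == {"T"}

    def test_permuted_labels_are_calibrated(self):
        # Under random gene sets the hypergeometric p should be roughly
        # uniform: the fraction of term tests below 0.05 stays near 0.05.
        rng = np.random.default_rng(42)
        background = [f"g{i}" for i in range(1000)]
        annotations = {g: set() for g in background}
        for t in range(40):
            for g in rng.choice(background, size=100, replace=False):
                annotations[g].add(f"term{t}")
        hits = trials = 0
        for _ in range(100):
            gene_set = rng.choice(background, size=100, replace=False)
            result = go_enrichment(gene_set, annotations, background)
            hits += int((result["p"] < 0.05).sum())
            trials += len(result)
        assert 0.02 <= hits / trials <= 0.08


class TestMotifSetEnrichment:
    def _presence(self, genes_with, all_genes, motif="M"):
        import pandas as pd

        rows = [
            {
                "gene_id": g,
                "motif": motif,
                "match_count": int(g in genes_with),
                "has_single": g in genes_with,
                "pair_count": 0,
                "has_adjacent_pair": False,
                "window": 100,
            }
            for g in all_genes
        ]
        return pd.DataFrame(rows)

    def test_proportions_and_percent_increase(self):
        background = [f"g{i}" for i in range(100)]
        with_feature = set(background[:40])
        gene_set = background[:8] + background[50:52]  # 8 of 10 with feature
        table = self._presence(with_feature, background)
        result = motif_set_enrichment(gene_set, table, "single", background)
        row = result.iloc[0]
        assert row["prop_set"] == pytest.approx(0.8)
        assert row["prop_bg"] == pytest.approx(0.4)
        assert row["percent_increase"] == pytest.approx(100.0)

    def test_set_equal_background(self):
        background = [f"g{i}" for i in range(50)]
        table = self._presence(set(background[:20]), background)
        result = motif_set_enrichment(background, table, "single", background)
        row = result.iloc[0]
        assert row["percent_increase"] == pytest.approx(0.0)
        assert row["p"] == 1.0

    def test_gene_missing_from_table_rejected(self):
        background = ["g0", "g1", "gX"]
        table = self._presence({"g0"}, ["g0", "g1"])
        with pytest.raises(EnrichmentError, match="absent"):
            motif_set_enrichment(["gX"], table, "single", background)

    def test_planted_scenario_recovers_enrichment(self, arar_motif):
        promoters, labels, _ = generate_enrichment_scenario(
            500, 500, p_set=0.6, p_bg=0.2, motif=arar_motif, seed=7
        )
        table = build_presence_table(promoters, [arar_motif])
        result = motif_set_enrichment(labels, table, "single", set(promoters))
        assert result.iloc[0]["p"] < 1e-6
        assert result.iloc[0]["percent_increase"] > 0
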