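"""Enrichment core: ranking, running score vs naive oracles, permutation p."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import leading_edge_naive, running_es_naive
from sigscore import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    RankedList,
    batch_gsea,
    leading_edge,
    permutation_test,
    rank_genes,
    running_enrichment,
)
from sigscore.exceptions import EmptyIntersectionError, GroupingError
from sigscore.gsea import _null_es_gene_label


def _ranked(stats, genes=None):
    stats = np.asarray(stats, dtype=float)
    if genes is None:
        genes = [f"g{i:02d}" for i in range(len(stats))]
    order = np.lexsort((np.asarray(genes, dtype=object), -stats))
    return RankedList(np.asarray(genes, dtype=object)[order], stats[order])


class TestRankGenes:
    def test_constant_gene_gets_zero_statistic(self):
        data = pd.DataFrame(
            {"s1": [1.0, 3.0], "s2": [1.0, 1.0], "s3": [1.0, 4.0], "s4": [1.0, 0.0]},
            index=["flat", "varying"],
        )
        annotations = pd.DataFrame(
            {"group": ["control", "control", "case", "case"]},
            index=["s1", "s2", "s3", "s4"],
        )
        ranked = rank_genes(ExpressionMatrix(data), annotations)
        assert dict(zip(ranked.genes, ranked.stats))["flat"] == 0.0

    def test_sd_floor_keeps_zero_variance_shift_positive(self):
        data = pd.DataFrame(
            {"c1": [0.0, 5.0], "c2": [0.0, 5.0], "a1": [2.0, 5.0], "a2": [2.0, 5.0]},
            index=["shifted", "null"],
        )
        annotations = pd.DataFrame(
            {"group": ["control", "control", "case", "case"]},
            index=["c1", "c2", "a1", "a2"],
        )
        ranked = rank_genes(ExpressionMatrix(data), annotations)
        stats = dict(zip(ranked.genes, ranked.stats))
        assert stats["shifted"] > 0 == stats["null"]
        assert list(ranked.genes) == ["shifted", "null"]

    def test_signal_to_noise_matches_independent_recomputation(self, random_matrix):
        rng = np.random.default_rng(0)
        groups = rng.permutation(["case"] * 15 + ["control"] * 15)
        annotations = pd.DataFrame({"group": groups}, index=random_matrix.samples)
        ranked = rank_genes(random_matrix, annotations)

        # brute-force per-gene recomputation of the same formula
        expected = {}
        for gene in random_matrix.genes:
            case = random_matrix.data.loc[gene, annotations["group"] == "case"].to_numpy()
            ctrl = random_matrix.data.loc[gene, annotations["group"] == "control"].to_numpy()
            stats = []
            for arr in (case, ctrl):
                m = arr.mean()
                s = arr.std(ddof=1)
                s = max(s, 0.2 * abs(m) if m != 0 else 0.2)
                stats.append((m, s))
            expected[gene] = (stats[0][0] - stats[1][0]) / (stats[0][1] + stats[1][1])
        for gene, stat in zip(ranked.genes, ranked.stats):
            assert stat == pytest.approx(expected[gene], abs=1e-12)

    def test_single_group_rejected(self, random_matrix):
        annotations = pd.DataFrame(
            {"group": ["case"] * len(random_matrix.samples)}, index=random_matrix.samples
        )
        with pytest.raises(GroupingError):
            rank_genes(random_matrix, annotations)


class TestRunningEnrichment:
    def test_single_top_gene_has_full_score_at_first_position(self):
        ranked = _ranked([5.0, 1.0, 0.5, 0.2])
        es, profile, peak = running_enrichment(ranked, GeneSet("top", (ranked.genes[0],)))
        assert es == pytest.approx(1.0)
        assert peak == 1

    def test_set_of_all_genes_reaches_one_with_no_misses(self):
        ranked = _ranked([3.0, 2.0, 1.0])
        es, profile, peak = running_enrichment(ranked, GeneSet("all", tuple(ranked.genes)))
        assert es == pytest.approx(1.0)
        assert peak == 3
        assert profile[-1] == pytest.approx(1.0)

    def test_unweighted_form_matches_classical_ks_closed_form(self):
        # two members at the top of four genes: steps +1/2 +1/2 -1/2 -1/2
        ranked = _ranked([4.0, 3.0, 2.0, 1.0])
        es, profile, peak = running_enrichment(
            ranked, GeneSet("s", tuple(ranked.genes[:2])), exponent=0.0
        )
        assert profile == pytest.approx([0.5, 1.0, 0.5, 0.0])
        assert es == pytest.approx(1.0) and peak == 2

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("exponent", [0.0, 1.0, 2.0])
    def test_matches_naive_prefix_oracle_on_random_instances(self, seed, exponent):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 40))
        stats = np.round(rng.normal(0, 2, n), 2)  # rounding forces ties
        ranked = _ranked(stats)
        k = int(rng.integers(1, n + 1))
        members = rng.choice(ranked.genes, size=k, replace=False)
        mask = [g in set(members) for g in ranked.genes]

        es, profile, peak = running_enrichment(ranked, GeneSet("s", tuple(members)), exponent)
        es_naive, profile_naive, peak_naive = running_es_naive(ranked.stats, mask, exponent)
        assert es == pytest.approx(es_naive, abs=1e-12)
        assert peak == peak_naive
        assert profile == pytest.approx(profile_naive, abs=1e-12)
        edge = leading_edge(ranked, GeneSet("s", tuple(members)), es, peak)
        assert edge == leading_edge_naive(ranked.genes, mask, es_naive, peak_naive)

    def test_disjoint_set_raises_empty_intersection(self):
        ranked = _ranked([1.0, 0.5])
        with pytest.raises(EmptyIntersectionError):
            running_enrichment(ranked, GeneSet("other", ("absent",)))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_es_is_bounded_by_one(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 60))
        ranked = _ranked(rng.normal(0, 3, n))
        k = int(rng.integers(1, n + 1))
        members = tuple(rng.choice(ranked.genes, size=k, replace=False))
        es, _, _ = running_enrichment(ranked, GeneSet("s", members))
        assert abs(es) <= 1.0 + 1e-12


class TestLeadingEdge:
    def test_single_member_positive_es_returns_that_gene(self):
        ranked = _ranked([5.0, 1.0, 0.5])
        gs = GeneSet("one", (ranked.genes[1],))
        es, _, peak = running_enrichment(ranked, gs)
        assert leading_edge(ranked, gs, es, peak) == (ranked.genes[1],)

    def test_all_genes_leading_edge_is_entire_list(self):
        ranked = _ranked([3.0, 2.0, 1.0])
        gs = GeneSet("all", tuple(ranked.genes))
        es, _, peak = running_enrichment(ranked, gs)
        assert leading_edge(ranked, gs, es, peak) == tuple(ranked.genes)

    def test_zero_es_yields_empty_edge(self):
        ranked = _ranked([1.0, 0.5])
        assert leading_edge(ranked, GeneSet("s", (ranked.genes[0],)), 0.0, 1) == ()


class TestPermutationTest:
    def test_addone_estimator_floor(self):
        """p can never fall below 1/(n_perm + 1); extreme ES attains it."""
        rng = np.random.default_rng(1)
        stats = np.concatenate([np.full(5, 10.0), rng.normal(0, 0.5, 95)])
        ranked = _ranked(stats)
        gs = GeneSet("planted", tuple(ranked.genes[:5]))
        res = permutation_test(ranked, gs, n_perm=1000, seed=5)
        assert res.pvalue >= 1 / 1001
        # the observed ES here beats every permutation: add-one floor exactly
        null = _null_es_gene_label(ranked.stats, 5, 1.0, 1000, np.random.default_rng(5))
        if (np.abs(null) < res.es).all():
            assert res.pvalue == pytest.approx(1 / 1001)

    def test_null_es_helper_agrees_with_profile_path(self):
        """The O(k) permutation ES equals the full running-sum computation."""
        rng = np.random.default_rng(3)
        stats = np.sort(np.round(rng.normal(0, 2, 30), 2))[::-1]
        ranked = _ranked(stats)
        null = _null_es_gene_label(ranked.stats, 4, 1.0, 50, np.random.default_rng(9))
        # recompute each via the profile path on an explicitly permuted membership
        pos = np.argsort(np.random.default_rng(9).random((50, 30)), axis=1, kind="stable")[:, :4]
        for row, expected in zip(pos, null):
            members = tuple(ranked.genes[sorted(row)])
            es, _, _ = running_enrichment(ranked, GeneSet("perm", members))
            assert es == pytest.approx(expected, abs=1e-12)

    def test_same_seed_reproduces_result(self, small_cohort, planted_set):
        matrix, annotations, _ = small_cohort
        r1 = permutation_test(matrix, planted_set, n_perm=100, seed=7, annotations=annotations)
        r2 = permutation_test(matrix, planted_set, n_perm=100, seed=7, annotations=annotations)
        assert r1.es == r2.es and r1.pvalue == r2.pvalue and r1.nes == r2.nes
        assert r1.leading_edge == r2.leading_edge

    def test_phenotype_scheme_on_planted_cohort(self, small_cohort, planted_set):
        matrix, annotations, _ = small_cohort
        res = permutation_test(
            matrix, planted_set, n_perm=50, scheme="phenotype", seed=2, annotations=annotations
        )
        assert 0 < res.pvalue <= 1
        assert res.es > 0

    def test_null_calibration_scaled(self):
        """Type-I error of the permutation p sits near the nominal level."""
        from sigscore import SyntheticCohortConfig, generate_bulk_cohort

        hits = 0
        reps = 200
        for seed in range(reps):
            config = SyntheticCohortConfig(
                n_genes=20, n_controls=10, n_cases=10, n_signature_genes=5,
                effect_size=0.0, seed=seed,
            )
            matrix, annotations, truth = generate_bulk_cohort(config)
            res = permutation_test(
                matrix, GeneSet("s", truth.signature_genes),
                n_perm=100, seed=seed + 1, annotations=annotations,
            )
            hits += res.pvalue < 0.05
        assert 0.02 <= hits / reps <= 0.09

    def test_invalid_nperm_rejected(self, small_cohort, planted_set):
        matrix, annotations, _ = small_cohort
        with pytest.raises(ValueError):
            permutation_test(matrix, planted_set, n_perm=0, annotations=annotations)


class TestBatchGsea:
    def test_planted_set_attains_minimum_p(self, small_cohort, planted_set):
        from sigscore import generate_gene_set_collection

        matrix, annotations, truth = small_cohort
        wins = 0
        for seed in range(5):
            collection = generate_gene_set_collection(
                10, (8, 15), truth.signature_genes, list(matrix.genes), seed=seed
            )
            table = batch_gsea(
                matrix, collection, n_perm=200, seed=seed, annotations=annotations
            )
            planted_p = table.loc[table["set"] == "PLANTED_SIGNATURE", "pvalue"].iloc[0]
            wins += planted_p <= table["pvalue"].min()
        assert wins >= 3
        assert set(table.columns) >= {"set", "size", "es", "nes", "pvalue", "qvalue"}

    def test_qvalues_dominate_pvalues(self, small_cohort, planted_set):
        from sigscore import generate_gene_set_collection

        matrix, annotations, truth = small_cohort
        collection = generate_gene_set_collection(
            8, (8, 15), truth.signature_genes, list(matrix.genes), seed=0
        )
        table = batch_gsea(matrix, collection, n_perm=100, seed=0, annotations=annotations)
        assert (table["qvalue"] >= table["pvalue"] - 1e-12).all()

    def test_empty_collection_rejected(self, small_cohort):
        matrix, annotations, _ = small_cohort
        with pytest.raises(EmptyIntersectionError):
            batch_gsea(matrix, GeneSetCollection([]), annotations=annotations)

    def test_all_sets_filtered_raises_with_reasons(self, small_cohort):
        matrix, annotations, _ = small_cohort
        tiny = GeneSetCollection([GeneSet("tiny", tuple(matrix.genes[:2]))])
        with pytest.raises(EmptyIntersectionError, match="tiny"):
            batch_gsea(matrix, tiny, annotations=annotations)

    def test_same_seed_identical_tables(self, small_cohort, planted_set):
        from sigscore import generate_gene_set_collection

        matrix, annotations, truth = small_cohort
        collection = generate_gene_set_collection(
            5, (8, 15), truth.signature_genes, list(matrix.genes), seed=2
        )
        t1 = batch_gsea(matrix, collection, n_perm=100, seed=3, annotations=annotations)
        t2 = batch_gsea(matrix, collection, n_perm=100, seed=3, annotations=annotations)
        pd.testing.assert_frame_equal(t1, t2)


class TestAgainstExternalReference:
    def test_es_matches_bioconductor_fgsea(self, tmp_path):
        """The running-score ES agrees with fgsea::calcGseaStat on a shared input."""
        rng = np.random.default_rng(12)
        stats = np.sort(rng.normal(0, 2, 80))[::-1]
        ranked = _ranked(stats)
        member_pos = np.sort(rng.choice(80, size=12, replace=False))
        members = tuple(ranked.genes[member_pos])
        es, _, _ = running_enrichment(ranked, GeneSet("s", members))

        stats_file = tmp_path / "stats.txt"
        stats_file.write_text("\n".join(f"{s:.12g}" for s in ranked.stats))
        idx_file = tmp_path / "idx.txt"
        idx_file.write_text("\n".join(str(p + 1) for p in member_pos))
        script = (
            f"suppressMessages(library(fgsea));"
            f"s <- scan('{stats_file}', quiet=TRUE);"
            f"i <- scan('{idx_file}', quiet=TRUE);"
            f"cat(sprintf('%.12f', calcGseaStat(s, i, gseaParam=1)))"
        )
        try:
            out = subprocess.run(
                ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
            )
        except (FileNotFoundError, subprocess.TimeoutExpired):
            pytest.skip("Rscript unavailable")
        if out.returncode != 0:
            pytest.skip(f"fgsea unavailable: {out.stderr[:200]}")
        assert es == pytest.approx(float(out.stdout), abs=1e-9)
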