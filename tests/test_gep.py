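"""Expression pipeline: loading, dispersion, aggregation, normalization,
distances, classification, z-profiles, exports."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cytonet import (
    aggregate_median,
    build_matrix,
    classify_lineage,
    cluster_stats,
    export_profiles,
    gene_zscores,
    histogram_bins,
    load_expression_table,
    manhattan_matrix,
    minmax_normalize,
    regression_r2,
    summarize_dispersion,
)
from cytonet.gep import GepFormatError, PipelineError

from conftest import DEFA5_TSV, EXPR_HEADER, TABLE1_TSV


def toy_aggregated():
    return {
        "L one": {"g1": 0.0, "g2": 1.0, "g3": 5.0},
        "L two": {"g1": 5.0, "g2": 1.0, "g3": 0.0},
        "L three": {"g1": 10.0, "g2": 1.0, "g3": 2.5},
    }


class TestLoad:
    def test_table1_rows_load(self, table1_records):
        assert len(table1_records) == 6
        assert {r.gene_symbol for r in table1_records} == {"TSPAN6"}
        assert table1_records[0].ntpm == 62.3

    def test_header_order_insensitive(self):
        reordered = "\n".join([
            "nTPM\tGene\tCell.type\tGene.name\tCluster\tTissue\tRead.count",
            "5.5\tENSG1\tmyocytes\tTTN\tc-1\tHeart muscle\t12",
        ])
        records = load_expression_table(reordered)
        assert records[0].gene_symbol == "TTN"
        assert records[0].ntpm == 5.5

    def test_negative_and_non_numeric_ntpm_rejected(self):
        text = "\n".join([
            EXPR_HEADER,
            "E1\tG1\tLiver\tc-1\thepatocytes\t1\t-3",
            "E1\tG1\tLiver\tc-2\thepatocytes\t1\tnot_a_number",
            "E1\tG1\tLiver\tc-3\thepatocytes\t1\t7.5",
        ])
        records = load_expression_table(text)
        assert [r.ntpm for r in records] == [7.5]

    def test_missing_header_named_in_error(self):
        with pytest.raises(GepFormatError, match="Cluster"):
            load_expression_table("Gene\tGene.name\tTissue\tCell.type\t"
                                  "Read.count\tnTPM\nE\tG\tT\tC\t1\t2\n")


class TestClusterStats:
    def test_defa5_sample_sd_and_cv(self, defa5_records):
        stats = cluster_stats(defa5_records)
        assert len(stats) == 1
        s = stats[0]
        assert s.lineage == "Small intestine undifferentiated cells"
        assert s.sd == pytest.approx(541585, abs=0.5)
        assert s.cv_percent == pytest.approx(171.56, abs=0.01)
        assert s.median == 5116.4

    def test_singleton_group_gets_na(self, table1_records):
        stats = {s.lineage: s for s in cluster_stats(table1_records)}
        assert math.isnan(stats["Placenta t-cells"].sd)
        assert math.isnan(stats["Placenta t-cells"].cv_percent)
        assert not math.isnan(stats["Placenta smooth muscle cells"].sd)

    def test_constant_group_has_zero_sd_and_cv(self):
        text = "\n".join([EXPR_HEADER] + [
            f"E1\tG1\tLiver\tc-{i}\thepatocytes\t1\t5" for i in range(3)
        ])
        s = cluster_stats(load_expression_table(text))[0]
        assert s.sd == 0.0
        assert s.cv_percent == 0.0

    def test_dispersion_summary_excludes_na(self):
        text = "\n".join([
            EXPR_HEADER,
            "E1\tG1\tLiver\tc-1\thepatocytes\t1\t1",
            "E1\tG1\tLiver\tc-2\thepatocytes\t1\t3",
            "E2\tG2\tLiver\tc-1\thepatocytes\t1\t9",   # singleton -> NA
        ])
        stats = cluster_stats(load_expression_table(text))
        summary = summarize_dispersion(stats)
        assert summary["mean_sd"] == pytest.approx(np.std([1, 3], ddof=1))
        assert summary["excluded_sd_groups"] == 1

    def test_all_singletons_summary_is_na(self):
        text = "\n".join([EXPR_HEADER, "E1\tG1\tLiver\tc-1\thepatocytes\t1\t2"])
        summary = summarize_dispersion(cluster_stats(load_expression_table(text)))
        assert math.isnan(summary["mean_sd"])

    def test_matches_brute_force_on_synthetic(self, synth_expression):
        tsv_text, _ = synth_expression
        records = load_expression_table(tsv_text)
        stats = cluster_stats(records)
        brute: dict = {}
        for rec in records:
            key = (rec.gene_symbol, f"{rec.tissue} {rec.cell_type}")
            brute.setdefault(key, []).append(rec.ntpm)
        for s in stats[:100]:
            values = brute[(s.gene_symbol, s.lineage)]
            assert s.mean == pytest.approx(np.mean(values))
            assert s.sd == pytest.approx(np.std(values, ddof=1))


class TestAggregate:
    def test_table1_merge_takes_median(self, table1_records):
        merged = aggregate_median(table1_records, "merge")
        assert merged["Placenta smooth muscle cells"]["TSPAN6"] == \
            pytest.approx(40.8)
        assert merged["Placenta t-cells"]["TSPAN6"] == 3.3

    def test_table1_retain_keeps_six_keys(self, table1_records):
        retained = aggregate_median(table1_records, "retain")
        assert len(retained) == 6
        assert retained["Placenta smooth muscle cells c-1"]["TSPAN6"] == 62.3
        assert retained["Placenta smooth muscle cells c-2"]["TSPAN6"] == 19.3

    def test_retain_collapsed_by_median_equals_merge(self, synth_expression):
        tsv_text, _ = synth_expression
        records = load_expression_table(tsv_text)
        merge = aggregate_median(records, "merge")
        retain = aggregate_median(records, "retain")
        collapsed: dict = {}
        for key, genes in retain.items():
            base = key.rsplit(" c-", 1)[0]
            for gene, value in genes.items():
                collapsed.setdefault(base, {}).setdefault(gene, []).append(value)
        for key, genes in collapsed.items():
            for gene, values in genes.items():
                assert float(np.median(values)) == pytest.approx(merge[key][gene])

    def test_unknown_mode_rejected(self, table1_records):
        with pytest.raises(ValueError):
            aggregate_median(table1_records, "average")


class TestMatrix:
    def test_constant_and_zero_columns_dropped(self):
        agg = {
            "L a": {"zero": 0.0, "const": 7.0, "varies": 1.0},
            "L b": {"zero": 0.0, "const": 7.0, "varies": 2.0},
        }
        matrix = build_matrix(agg)
        assert matrix.col_genes == ["varies"]
        assert sorted(matrix.dropped_genes) == ["const", "zero"]

    def test_missing_cells_fill_zero(self):
        agg = {"L a": {"g1": 3.0}, "L b": {"g2": 4.0}}
        matrix = build_matrix(agg)
        assert matrix.values.loc["L a", "g2"] == 0.0
        assert matrix.values.loc["L b", "g1"] == 0.0

    def test_fewer_than_two_rows_is_pipeline_error(self):
        with pytest.raises(PipelineError):
            build_matrix({"only": {"g": 1.0}})

    def test_surviving_columns_on_noiseless_synthetic(self):
        """With zero noise only marker genes vary across lineages."""
        from cytonet import ExpressionGroundTruth, make_expression_table
        truth = ExpressionGroundTruth(seed=3, noise_sigma=0.0)
        tsv_text, manifest = make_expression_table(truth)
        records = load_expression_table(tsv_text)
        matrix = build_matrix(aggregate_median(records, "merge"))
        expected = {g for genes in manifest["markers"].values() for g in genes}
        expected |= {g for gm in manifest["group_markers"].values()
                     for g in gm["genes"]}
        assert set(matrix.col_genes) == expected


class TestNormalize:
    def test_minmax_column(self):
        matrix = build_matrix(toy_aggregated())
        normalized = minmax_normalize(matrix)
        assert list(normalized.values["g1"]) == [0.0, 1.0, 0.5]

    def test_bounds_and_extrema_on_synthetic(self, synth_expression):
        tsv_text, _ = synth_expression
        matrix = build_matrix(
            aggregate_median(load_expression_table(tsv_text), "merge")
        )
        normalized = minmax_normalize(matrix)
        values = normalized.values
        assert float(values.min().min()) >= 0.0
        assert float(values.max().max()) <= 1.0
        assert np.allclose(values.min(axis=0), 0.0)
        assert np.allclose(values.max(axis=0), 1.0)

    def test_idempotent_and_monotone(self):
        matrix = build_matrix(toy_aggregated())
        once = minmax_normalize(matrix)
        twice = minmax_normalize(once)
        assert np.allclose(once.values, twice.values)
        for gene in matrix.col_genes:
            raw_order = np.argsort(matrix.values[gene].to_numpy())
            norm_order = np.argsort(once.values[gene].to_numpy())
            assert (raw_order == norm_order).all()

    def test_constant_column_is_invariant_error(self):
        from cytonet.gep import ExpressionMatrix
        import pandas as pd
        frame = pd.DataFrame({"g": [1.0, 1.0]}, index=["a", "b"])
        with pytest.raises(PipelineError):
            minmax_normalize(ExpressionMatrix(values=frame))


class TestDistances:
    def test_two_gene_toy_distances(self):
        import pandas as pd
        from cytonet.gep import ExpressionMatrix
        frame = pd.DataFrame([[0.0, 0.0], [1.0, 1.0]],
                             index=["a", "b"], columns=["g1", "g2"])
        m = ExpressionMatrix(values=frame, normalization={"g1": (0, 1),
                                                          "g2": (0, 1)})
        l1 = manhattan_matrix(m, "L1")
        l2 = manhattan_matrix(m, "L2")
        assert l1.d.loc["a", "b"] == pytest.approx(2.0)
        assert l2.d.loc["a", "b"] == pytest.approx(math.sqrt(2.0))

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        import pandas as pd
        from cytonet.gep import ExpressionMatrix
        data = rng.random((5, 4))
        frame = pd.DataFrame(data, index=list("abcde"), columns=list("wxyz"))
        d = manhattan_matrix(ExpressionMatrix(values=frame)).d.to_numpy()
        for i in range(5):
            for j in range(5):
                assert d[i, j] == pytest.approx(
                    sum(abs(data[i, k] - data[j, k]) for k in range(4))
                )

    def test_metric_axioms_on_synthetic(self, synth_expression):
        tsv_text, _ = synth_expression
        matrix = minmax_normalize(build_matrix(
            aggregate_median(load_expression_table(tsv_text), "merge")
        ))
        d = manhattan_matrix(matrix).d.to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        rng = np.random.default_rng(0)
        n = d.shape[0]
        for _ in range(1000):
            i, j, k = rng.integers(0, n, 3)
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


@pytest.fixture(scope="module")
def normalized(synth_expression):
    tsv_text, _ = synth_expression
    matrix = build_matrix(
        aggregate_median(load_expression_table(tsv_text), "merge")
    )
    return matrix, minmax_normalize(matrix)


class TestClassifier:
    def test_self_query_is_rank_one_distance_zero(self, normalized):
        matrix, norm = normalized
        for key in matrix.row_keys:
            ranked = classify_lineage(matrix.values.loc[key].to_dict(), norm, 1)
            assert ranked[0][0] == key
            assert ranked[0][1] == pytest.approx(0.0, abs=1e-9)

    def test_group_lineages_are_mutually_proximal(self, synth_expression,
                                                  normalized):
        """Lineages sharing planted marker blocks sit nearest each other."""
        _, manifest = synth_expression
        matrix, norm = normalized
        group = manifest["group_markers"]["smooth_muscle"]["lineages"]
        a, b = group[0], group[1]
        ranked = classify_lineage(matrix.values.loc[a].to_dict(), norm,
                                  len(matrix.row_keys))
        keys = [k for k, _ in ranked]
        assert keys[0] == a
        assert keys[1] == b

    def test_perturbed_queries_recover_source_lineage(self, normalized):
        matrix, norm = normalized
        rng = np.random.default_rng(0)
        keys = matrix.row_keys
        correct = 0
        for i in range(200):
            key = keys[i % len(keys)]
            raw = matrix.values.loc[key].to_numpy()
            noisy = raw * np.exp(rng.normal(0.0, 0.2, raw.size))
            ranked = classify_lineage(dict(zip(matrix.col_genes, noisy)), norm, 1)
            correct += ranked[0][0] == key
        assert correct / 200 >= 0.95

    def test_extra_query_genes_ignored_missing_zero_filled(self, normalized):
        matrix, norm = normalized
        key = matrix.row_keys[0]
        query = matrix.values.loc[key].to_dict()
        query["NOT_A_GENE"] = 1e9
        ranked = classify_lineage(query, norm, 1)
        assert ranked[0][0] == key

    def test_empty_intersection_is_error(self, normalized):
        _, norm = normalized
        with pytest.raises(PipelineError):
            classify_lineage({"NOPE": 1.0}, norm, 1)

    def test_unnormalized_matrix_rejected(self, normalized):
        matrix, _ = normalized
        with pytest.raises(PipelineError):
            classify_lineage({"GENE0000": 1.0}, matrix, 1)


class TestZProfiles:
    def test_single_high_lineage_is_very_significant(self):
        # 19 silent lineages + 1 expressing: z_hot = 95/sqrt(500) ~ 4.25
        agg = {f"L {i:02d}": {"g": 0.0, "pad": float(i)} for i in range(19)}
        agg["L hot"] = {"g": 100.0, "pad": 19.0}
        profile = gene_zscores(build_matrix(agg), "g")
        tiers = {key: tier for key, _, _, tier in profile.per_lineage}
        zs = {key: z for key, _, z, _ in profile.per_lineage}
        assert tiers["L hot"] == "very_significant"
        assert max(zs, key=zs.get) == "L hot"
        assert all(t == "none" for k, t in tiers.items() if k != "L hot")

    def test_standardization_identity(self, synth_expression):
        tsv_text, _ = synth_expression
        matrix = build_matrix(
            aggregate_median(load_expression_table(tsv_text), "merge")
        )
        for gene in matrix.col_genes[:25]:
            profile = gene_zscores(matrix, gene)
            zs = np.array([z for _, _, z, _ in profile.per_lineage])
            assert abs(zs.mean()) < 1e-9
            assert abs(zs.std(ddof=1) - 1.0) < 1e-9

    def test_constant_gene_all_zero(self):
        import pandas as pd
        from cytonet.gep import ExpressionMatrix
        frame = pd.DataFrame({"g": [2.0, 2.0, 2.0]}, index=["a", "b", "c"])
        profile = gene_zscores(ExpressionMatrix(values=frame), "g")
        assert all(z == 0.0 and tier == "none"
                   for _, _, z, tier in profile.per_lineage)

    def test_unknown_gene_lists_near_matches(self):
        matrix = build_matrix(toy_aggregated())
        with pytest.raises(KeyError, match="g1"):
            gene_zscores(matrix, "g11")


class TestRegression:
    def test_perfect_line(self):
        x = [1.0, 2.0, 3.0, 4.0]
        fit = regression_r2(x, [2 * v + 1 for v in x])
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.slope == pytest.approx(2.0)

    def test_independent_noise_has_low_r2(self):
        rng = np.random.default_rng(0)
        x = rng.random(1000)
        y = rng.random(1000)
        assert regression_r2(list(x), list(y)).r_squared < 0.05

    def test_r2_invariant_under_affine_rescale(self):
        rng = np.random.default_rng(1)
        x = list(rng.random(50))
        y = list(rng.random(50))
        base = regression_r2(x, y).r_squared
        scaled = regression_r2([3.0 * v - 7.0 for v in x], y).r_squared
        assert scaled == pytest.approx(base)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            regression_r2([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestHistogram:
    def test_even_split(self):
        edges, counts = histogram_bins([float(i) for i in range(10)], 2)
        assert counts == [5, 5]
        assert edges[0] == 0.0 and edges[-1] == 9.0

    def test_all_equal_single_occupied_bin(self):
        _, counts = histogram_bins([5.0, 5.0, 5.0], 4)
        assert sum(1 for c in counts if c) == 1
        assert sum(counts) == 3

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=50),
           st.integers(1, 10))
    def test_counts_conserved(self, values, n_bins):
        _, counts = histogram_bins(values, n_bins)
        assert sum(counts) == len(values)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            histogram_bins([], 3)


class TestExport:
    def test_file_count_rule_and_determinism(self, tmp_path, synth_expression):
        tsv_text, _ = synth_expression
        records = load_expression_table(tsv_text)
        matrix = build_matrix(aggregate_median(records, "merge"))
        stats = cluster_stats(records)
        manifest = export_profiles(matrix, stats, tmp_path / "a")
        expected = len(matrix.row_keys) + len(matrix.col_genes) + 1
        assert manifest["n_files"] == expected
        written = {p.name for p in (tmp_path / "a").glob("*.tsv")}
        assert written == set(manifest["files"])
        export_profiles(matrix, stats, tmp_path / "b")
        for name in manifest["files"]:
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()

    def test_per_gene_file_ordering_matches_zscores(self, tmp_path):
        agg = toy_aggregated()
        matrix = build_matrix(agg)
        manifest = export_profiles(matrix, [], tmp_path)
        assert manifest["n_files"] == 3 + len(matrix.col_genes) + 1
        gene = matrix.col_genes[0]
        lines = (tmp_path / f"gene_{gene}.tsv").read_text().splitlines()[1:]
        zs = [float(line.split("\t")[2]) for line in lines]
        assert zs == sorted(zs, reverse=True)
        profile = gene_zscores(matrix, gene)
        expected = [k for k, _, _, _ in
                    sorted(profile.per_lineage, key=lambda r: (-r[2], r[0]))]
        assert [line.split("\t")[0] for line in lines] == expected
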