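"""Tissue signatures, cosine classification, HCPC and the combined report."""

import numpy as np
import pandas as pd
import pytest

import tissuemap as tm
from tissuemap.containers import DegenerateInputError, EmptyResultError, ValidationError
from tissuemap.tissue_identity import TissuePanel


def _log_panel(values: dict, genes) -> tm.ExpressionMatrix:
    frame = pd.DataFrame(values, index=genes)
    return tm.ExpressionMatrix(values=frame, scale="log2TPM", pseudocount=1.0)


def _identity_map(columns) -> pd.Series:
    return pd.Series({c: c for c in columns})


class TestTissueEnrichedGenes:
    def test_hand_computed_centering_and_argmax(self):
        panel = _log_panel({"t1": [6.0], "t2": [2.0], "t3": [1.0]}, ["gene"])
        sig = tm.tissue_enriched_genes(panel, _identity_map(panel.sample_ids), top_n=5)
        row = sig.assignment.loc["gene"]
        assert row["tissue"] == "t1"
        assert row["score"] == pytest.approx(3.0)  # 6 - mean(6,2,1)
        assert row["rank"] == 1

    def test_replicates_averaged_within_tissue(self):
        panel = _log_panel(
            {"t1_r1": [5.0], "t1_r2": [7.0], "t2_r1": [2.0], "t2_r2": [2.0]}, ["gene"]
        )
        tissue_map = pd.Series({"t1_r1": "t1", "t1_r2": "t1", "t2_r1": "t2", "t2_r2": "t2"})
        sig = tm.tissue_enriched_genes(panel, tissue_map, top_n=5)
        assert sig.assignment.loc["gene", "score"] == pytest.approx(2.0)  # 6 - mean(6,2)

    def test_tied_gene_excluded(self):
        panel = _log_panel({"t1": [3.0, 5.0], "t2": [3.0, 1.0]}, ["flat", "informative"])
        sig = tm.tissue_enriched_genes(panel, _identity_map(panel.sample_ids), top_n=5)
        assert "flat" not in sig.assignment.index
        assert "informative" in sig.assignment.index

    def test_top_n_truncation_and_boundary(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(40)]
        panel = _log_panel(
            {"t1": rng.normal(5, 2, 40), "t2": rng.normal(5, 2, 40)}, genes
        )
        small = tm.tissue_enriched_genes(panel, _identity_map(panel.sample_ids), top_n=3)
        for tissue in small.tissues:
            assert len(small.genes_for(tissue)) <= 3
        # top_n exceeding the assigned count returns the full list
        big = tm.tissue_enriched_genes(panel, _identity_map(panel.sample_ids), top_n=10_000)
        assert len(big.gene_union) == 40  # two-tissue centering never ties off-diagonal

    def test_centered_scores_sum_to_zero_and_lists_disjoint(self, default_study):
        panel = default_study.panel
        mean = panel.tissue_mean()
        log2 = tm.log_transform(tm.ExpressionMatrix(values=mean, scale="TPM"))
        sig = tm.tissue_enriched_genes(log2, _identity_map(mean.columns), top_n=70)
        # oracle: recompute centering; rows must sum to ~0 and match scores
        centered = log2.values.sub(log2.values.mean(axis=1), axis=0)
        np.testing.assert_allclose(centered.sum(axis=1), 0.0, atol=1e-9)
        for gene, row in sig.assignment.iterrows():
            assert row["score"] == pytest.approx(centered.loc[gene].max())
        lists = [sig.genes_for(t) for t in sig.tissues]
        flat = [g for lst in lists for g in lst]
        assert len(flat) == len(set(flat))

    def test_single_tissue_degenerate(self):
        panel = _log_panel({"t1": [1.0]}, ["g"])
        with pytest.raises(DegenerateInputError):
            tm.tissue_enriched_genes(panel, pd.Series({"t1": "t1"}), top_n=5)
        two_cols = _log_panel({"t1_r1": [1.0], "t1_r2": [2.0]}, ["g"])
        with pytest.raises(DegenerateInputError):
            tm.tissue_enriched_genes(
                two_cols, pd.Series({"t1_r1": "t1", "t1_r2": "t1"}), top_n=5
            )


class TestCombineProfiles:
    def _toy(self):
        genes = [f"g{i}" for i in range(6)]
        rng = np.random.default_rng(1)
        cluster = tm.ExpressionMatrix(
            values=pd.DataFrame(rng.uniform(0, 100, (6, 2)), index=genes,
                                columns=["C1", "C2"]),
            scale="TPM",
        )
        panel = tm.ExpressionMatrix(
            values=pd.DataFrame(rng.uniform(0, 100, (6, 3)), index=genes,
                                columns=["lung", "liver", "heart"]),
            scale="TPM",
        )
        assignment = pd.DataFrame(
            {"tissue": ["lung", "lung", "liver"], "score": [3.0, 2.0, 1.0], "rank": [1, 2, 1]},
            index=["g0", "g2", "g4"],
        )
        sig = tm.TissueSignature(assignment=assignment, top_n=2)
        return cluster, panel, sig

    def test_rows_equal_signature_union(self):
        cluster, panel, sig = self._toy()
        combined = tm.combine_profiles(cluster, panel, sig)
        assert list(combined.gene_ids) == ["g0", "g2", "g4"]
        assert combined.scale == "log2TPM"
        assert list(combined.column_roles.unique()) == ["cluster", "tissue"]

    def test_set_algebra_matches_oracle_with_missing_genes(self):
        cluster, panel, sig = self._toy()
        panel_small = tm.ExpressionMatrix(values=panel.values.drop(index=["g2"]), scale="TPM")
        combined = tm.combine_profiles(cluster, panel_small, sig)
        sig_union = set(sig.gene_union)
        oracle = [g for g in cluster.gene_ids
                  if g in sig_union and g in set(panel_small.gene_ids)]
        assert list(combined.gene_ids) == oracle

    def test_optional_bulk_and_empty_error(self):
        cluster, panel, sig = self._toy()
        bulk = tm.ExpressionMatrix(
            values=panel.values.iloc[:, :1].set_axis(["bulk1"], axis=1), scale="TPM"
        )
        combined = tm.combine_profiles(cluster, panel, sig, bulk_tpm=bulk)
        assert (combined.column_roles == "bulk").sum() == 1
        empty_sig = tm.TissueSignature(
            assignment=pd.DataFrame(columns=["tissue", "score", "rank"]), top_n=2
        )
        with pytest.raises(EmptyResultError):
            tm.combine_profiles(cluster, panel, empty_sig)


class TestCosineSimilarity:
    def _matrix(self, columns: dict) -> tm.ExpressionMatrix:
        genes = [f"g{i}" for i in range(len(next(iter(columns.values()))))]
        return tm.ExpressionMatrix(
            values=pd.DataFrame(columns, index=genes), scale="log2TPM", pseudocount=1.0
        )

    def test_self_similarity_is_one(self):
        m = self._matrix({"q": [1.0, 2.0, 3.0], "r1": [1.0, 2.0, 3.0], "r2": [3.0, 1.0, 0.0]})
        sim = tm.cosine_similarity(m, ["q"], ["r1", "r2"])
        assert sim.values.at["q", "r1"] == pytest.approx(1.0)
        assert sim.best_tissue["q"] == "r1"
        assert sim.margin["q"] >= 0

    def test_hand_computed_values(self):
        m = self._matrix({"orth_q": [1.0, 0.0, 0.0], "half_q": [1.0, 1.0, 0.0],
                          "r1": [0.0, 1.0, 0.0], "r2": [1.0, 0.0, 1.0]})
        sim = tm.cosine_similarity(m, ["orth_q", "half_q"], ["r1", "r2"])
        assert sim.values.at["orth_q", "r1"] == pytest.approx(0.0)
        assert sim.values.at["half_q", "r2"] == pytest.approx(0.5)  # 1/(sqrt2*sqrt2)

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        q = rng.uniform(0, 5, 10)
        m = self._matrix({"q": q, "q_scaled": 7.3 * q, "r": rng.uniform(0, 5, 10)})
        sim = tm.cosine_similarity(m, ["q", "q_scaled"], ["r"])
        assert sim.values.at["q", "r"] == pytest.approx(sim.values.at["q_scaled", "r"])

    def test_errors(self):
        m = self._matrix({"q": [1.0, 0.0], "zero": [0.0, 0.0], "r": [1.0, 1.0]})
        with pytest.raises(ValidationError, match="zero"):
            tm.cosine_similarity(m, ["q", "zero"], ["r"])
        with pytest.raises(ValidationError):
            tm.cosine_similarity(m, ["q"], ["q", "r"])

    def test_panel_self_classification(self, default_study):
        """Each tissue column classified against the panel returns itself at 1."""
        mean = default_study.panel.tissue_mean()
        queries = mean.add_prefix("query_")
        frame = pd.concat([np.log2(queries + 1), np.log2(mean + 1)], axis=1)
        m = tm.ExpressionMatrix(values=frame, scale="log2TPM", pseudocount=1.0)
        sim = tm.cosine_similarity(m, queries.columns, mean.columns)
        for tissue in mean.columns:
            assert sim.best_tissue[f"query_{tissue}"] == tissue
            assert sim.values.at[f"query_{tissue}", tissue] == pytest.approx(1.0)


class TestHCPC:
    def test_duplicate_pairs_are_grouped(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, (20, 3))
        values = np.concatenate([base, base], axis=1)[:, [0, 3, 1, 4, 2, 5]]
        frame = pd.DataFrame(values, index=[f"g{i}" for i in range(20)],
                             columns=["a1", "a2", "b1", "b2", "c1", "c2"])
        m = tm.ExpressionMatrix(values=frame, scale="log2TPM", pseudocount=1.0)
        result = tm.hcpc(m, n_components=3)
        assert result.n_clusters == 3
        assert result.partition["a1"] == result.partition["a2"]
        assert result.partition["b1"] == result.partition["b2"]
        assert result.partition["c1"] == result.partition["c2"]

    def test_sample_permutation_invariance(self):
        rng = np.random.default_rng(1)
        frame = pd.DataFrame(rng.normal(0, 1, (30, 8)),
                             index=[f"g{i}" for i in range(30)],
                             columns=[f"s{j}" for j in range(8)])
        m = tm.ExpressionMatrix(values=frame, scale="log2TPM", pseudocount=1.0)
        perm = rng.permutation(8)
        mp = tm.ExpressionMatrix(values=frame.iloc[:, perm], scale="log2TPM", pseudocount=1.0)
        a, b = tm.hcpc(m), tm.hcpc(mp)
        assert a.n_clusters == b.n_clusters
        groups_a = {s: a.partition[s] for s in frame.columns}
        groups_b = {s: b.partition[s] for s in frame.columns}
        # same partition as a set system, labels may differ
        from sklearn.metrics import adjusted_rand_score

        order = list(frame.columns)
        assert adjusted_rand_score(
            [groups_a[s] for s in order], [groups_b[s] for s in order]
        ) == 1.0

    def test_recovers_planted_tissue_groups(self, default_study):
        panel = default_study.panel
        logged = np.log2(panel.values.iloc[:, :9] + 1)  # 3 tissues x 3 replicates
        m = tm.ExpressionMatrix(values=logged, scale="log2TPM", pseudocount=1.0)
        result = tm.hcpc(m, n_components=5)
        truth = default_study.panel.tissue_of_sample.loc[logged.columns]
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(truth, result.partition.loc[logged.columns]) == 1.0

    def test_dendrogram_heights_non_decreasing(self, default_study):
        logged = np.log2(default_study.panel.values + 1)
        m = tm.ExpressionMatrix(values=logged, scale="log2TPM", pseudocount=1.0)
        result = tm.hcpc(m)
        heights = result.linkage[:, 2]
        assert np.all(np.diff(heights) >= -1e-9)

    def test_too_few_samples(self):
        frame = pd.DataFrame(np.ones((4, 2)), columns=["a", "b"])
        m = tm.ExpressionMatrix(values=frame, scale="log2TPM", pseudocount=1.0)
        with pytest.raises(ValidationError):
            tm.hcpc(m)


class TestClassifyClusters:
    def test_planted_identity_recovered_in_all_views(self, default_study, default_clustered):
        filtered, _, clusters = default_clustered
        report = tm.classify_clusters(filtered, clusters, default_study.panel, seed=5)
        truth_cluster = default_study.truth.cell_cluster
        # map consensus labels to generating programs by majority vote
        program_of_label = {}
        for lab in sorted(clusters.labels.unique()):
            members = clusters.members(lab)
            program_of_label[lab] = (
                default_study.truth.cell_program.loc[members].mode().iloc[0]
            )
        best = report.similarity.best_tissue
        maxima = report.similarity.values.max(axis=1)
        mixture_cols, pure_cols = [], {}
        for lab, program in program_of_label.items():
            col = f"C{lab}"
            if "+" in program:
                mixture_cols.append(col)
            else:
                pure_cols[col] = program
        for col, program in pure_cols.items():
            assert best[col] == program  # argmax cosine finds the generating tissue
        for col in mixture_cols:
            assert all(maxima[col] < maxima[p] for p in pure_cols)
        # HCPC: each pure cluster shares its partition cell with its tissue
        partition = report.hcpc.partition
        for col, program in pure_cols.items():
            assert partition[col] == partition[program]
        # embedding: pure clusters sit nearer their tissue than any other tissue
        coords = report.embedding.coords
        for col, program in pure_cols.items():
            d = ((coords.loc[report.similarity.values.columns] - coords.loc[col]) ** 2).sum(axis=1)
            assert d.idxmin() == program

    def test_duplicated_panel_column_as_query(self, default_study):
        """A query identical to a tissue profile is classified as that tissue at 1."""
        panel = default_study.panel
        mean = panel.tissue_mean()
        sig_input = tm.log_transform(tm.ExpressionMatrix(values=mean, scale="TPM"))
        sig = tm.tissue_enriched_genes(sig_input, pd.Series({t: t for t in mean.columns}))
        query = tm.ExpressionMatrix(
            values=mean[["lung"]].set_axis(["copycat"], axis=1), scale="TPM"
        )
        panel_expr = tm.ExpressionMatrix(values=mean, scale="TPM")
        combined = tm.combine_profiles(query, panel_expr, sig)
        sim = tm.cosine_similarity(combined, ["copycat"], mean.columns)
        assert sim.best_tissue["copycat"] == "lung"
        assert sim.values.at["copycat", "lung"] == pytest.approx(1.0)
        result = tm.hcpc(combined, n_components=5)
        # the duplicate pair merges first: identical scores, same partition cell
        assert result.partition["copycat"] == result.partition["lung"]
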