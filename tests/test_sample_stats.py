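"""Sample correlation, PCA, UMAP embedding and coverage reporting."""

import numpy as np
import pandas as pd
import pytest

from protatlas.binning import BinnedMatrix
from protatlas.postprocess import ExpressionMatrix
from protatlas.sample_stats import (
    coverage_report,
    pairwise_sample_correlation,
    pca_samples,
    umap_embed,
)

from conftest import make_annotation


def binned_from(values: dict[str, list], ann_rows) -> BinnedMatrix:
    runs = list(values)
    genes = [f"g{i}" for i in range(len(next(iter(values.values()))))]
    df = pd.DataFrame(values, index=genes, dtype=float)
    ann = make_annotation(ann_rows)
    return BinnedMatrix(df, level="run", run_batches=ann.batches().loc[runs])


ANN2 = [("r1", "t", "brain", "ds1"), ("r2", "t", "brain", "ds1")]


class TestCorrelation:
    def test_diagonal_is_one_and_matrix_symmetric(self):
        b = binned_from({"r1": [1, 2, 3, 4, 5], "r2": [2, 1, 4, 3, 5]}, ANN2)
        corr, _, _ = pairwise_sample_correlation(b)
        assert np.allclose(np.diag(corr), 1.0)
        assert np.allclose(corr, corr.T)

    def test_reversed_ranks_give_minus_one(self):
        b = binned_from({"r1": [1, 2, 3, 4, 5], "r2": [5, 4, 3, 2, 1]}, ANN2)
        corr, _, _ = pairwise_sample_correlation(b)
        assert corr.loc["r1", "r2"] == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        b = binned_from({"r1": [1, 2, 3, 4, 5], "r2": [1, 2, 3, 5, 4]}, ANN2)
        corr, _, _ = pairwise_sample_correlation(b)
        assert corr.loc["r1", "r2"] == pytest.approx(0.9)

    def test_pairwise_complete_observations(self):
        b = binned_from(
            {"r1": [1, 2, 3, 4, np.nan], "r2": [1, 2, 3, np.nan, 5]}, ANN2
        )
        corr, _, _ = pairwise_sample_correlation(b)
        # only the 3 complete pairs enter: perfectly correlated
        assert corr.loc["r1", "r2"] == pytest.approx(1.0)

    def test_too_few_common_genes_left_missing_with_warning(self):
        b = binned_from(
            {"r1": [1, 2, np.nan, np.nan], "r2": [np.nan, np.nan, 3, 4]}, ANN2
        )
        with pytest.warns(UserWarning, match="common genes"):
            corr, _, _ = pairwise_sample_correlation(b)
        assert np.isnan(corr.loc["r1", "r2"])

    def test_per_organ_median_r2(self):
        ann = [
            ("b1", "t", "brain", "ds1"), ("b2", "t", "brain", "ds1"),
            ("l1", "t2", "liver", "ds1"), ("l2", "t2", "liver", "ds1"),
        ]
        b = binned_from(
            {
                "b1": [1, 2, 3, 4, 5],
                "b2": [1, 2, 3, 5, 4],
                "l1": [5, 4, 3, 2, 1],
                "l2": [5, 4, 3, 1, 2],
            },
            ann,
        )
        _, organ_r2, _ = pairwise_sample_correlation(b)
        assert organ_r2["brain"] == pytest.approx(0.81)
        assert organ_r2["liver"] == pytest.approx(0.81)


class TestPca:
    def _binned(self, n_samples=6, n_genes=30, seed=0, sparse_gene=True):
        rng = np.random.default_rng(seed)
        vals = rng.integers(1, 6, size=(n_genes, n_samples)).astype(float)
        if sparse_gene:
            vals[0, : n_samples - 2] = np.nan  # well below 50% presence
        runs = [f"r{i}" for i in range(n_samples)]
        ann = make_annotation([(r, "t", "brain", "ds1") for r in runs])
        df = pd.DataFrame(vals, index=[f"g{i}" for i in range(n_genes)], columns=runs)
        return BinnedMatrix(df, level="run", run_batches=ann.batches())

    def test_low_presence_gene_excluded_and_shapes(self):
        b = self._binned()
        coords, evr = pca_samples(b, min_presence=0.5)
        assert coords.shape == (6, 2) and len(evr) == 2
        # the sparse gene alone cannot influence the fit: dropping it changes nothing
        b2 = self._binned()
        b2.values.drop(index="g0", inplace=True)
        coords2, _ = pca_samples(b2, min_presence=0.5)
        assert np.allclose(np.abs(coords), np.abs(coords2))

    def test_coordinates_invariant_to_sample_order_up_to_sign(self):
        b = self._binned(sparse_gene=False)
        coords, _ = pca_samples(b)
        shuffled = BinnedMatrix(
            b.values[list(b.values.columns[::-1])], level="run", run_batches=b.run_batches
        )
        coords2, _ = pca_samples(shuffled)
        aligned = coords2.loc[coords.index]
        for c in ("PC1", "PC2"):
            assert np.allclose(aligned[c], coords[c], atol=1e-8) or np.allclose(
                aligned[c], -coords[c], atol=1e-8
            )

    def test_no_passing_gene_is_error(self):
        b = self._binned()
        b.values.iloc[:, 0] = np.nan
        b.values.iloc[:] = np.nan
        with pytest.raises(ValueError, match="presence"):
            pca_samples(b)


class TestUmap:
    def _ortholog_binned(self, seed=0):
        rng = np.random.default_rng(seed)
        n_genes, n_samples = 40, 24
        organ = np.array(["brain", "liver"]).repeat(n_samples // 2)
        vals = rng.integers(1, 6, size=(n_genes, n_samples)).astype(float)
        vals[:10, organ == "brain"] += rng.uniform(1, 2)  # organ signal
        vals = np.clip(vals, 1, 5)
        runs = [f"{s}_{o}" for s, o in zip(range(n_samples), organ)]
        ann = make_annotation(
            [(r, f"t_{o}", o, "ds1", sp)
             for r, o, sp in zip(runs, organ, ["mouse", "rat"] * (n_samples // 2))]
        )
        df = pd.DataFrame(vals, index=[f"g{i}" for i in range(n_genes)], columns=runs)
        return BinnedMatrix(df, level="run", run_batches=ann.batches())

    def test_deterministic_under_seed_and_row_count(self):
        b = self._ortholog_binned()
        c1, overlay = umap_embed(b, seed=42)
        c2, _ = umap_embed(b, seed=42)
        assert np.allclose(c1[["x", "y"]], c2[["x", "y"]])
        assert len(c1) == b.values.shape[1]
        assert len(overlay) == b.values.shape[1] * b.values.shape[0]

    def test_overlay_joins_full_bins_to_fixed_coordinates(self):
        b = self._ortholog_binned()
        coords, overlay = umap_embed(b, seed=1)
        one = overlay[overlay["gene"] == "g0"].set_index("sample")
        assert np.allclose(one[["x", "y"]], coords[["x", "y"]])
        got = one["bin"].reindex(b.values.columns)
        assert np.allclose(got, b.values.loc["g0"], equal_nan=True)

    def test_too_few_layout_genes_is_error(self):
        b = self._ortholog_binned()
        b.values.iloc[5:, :4] = np.nan  # most genes now below 90% presence
        with pytest.raises(ValueError, match="presence filter"):
            umap_embed(b, seed=0)


class TestCoverage:
    def test_unique_and_ubiquitous_counts(self):
        values = pd.DataFrame(
            {
                "rA": [1.0, 2.0, 3.0],
                "rB": [np.nan, 4.0, 5.0],
            },
            index=["g1", "g2", "g3"],
        )
        ann = make_annotation([("rA", "t1", "A", "ds1"), ("rB", "t2", "B", "ds2")])
        rep = coverage_report(ExpressionMatrix(values), ann)
        assert rep["n_genes_detected"] == 3
        assert rep["genes_unique_to_one_organ"] == 1
        assert rep["genes_in_all_organs"] == 2
        assert rep["genes_per_organ"] == {"A": 3, "B": 2}
        assert rep["genes_per_dataset"] == {"ds1": 3, "ds2": 2}
        assert rep["genes_unique_per_organ"] == {"A": 1, "B": 0}

    def test_empty_matrix_gives_zeros(self):
        values = pd.DataFrame(
            {"rA": [np.nan], "rB": [np.nan]}, index=["g1"]
        )
        ann = make_annotation([("rA", "t1", "A", "ds1"), ("rB", "t2", "B", "ds1")])
        rep = coverage_report(ExpressionMatrix(values), ann)
        assert rep["n_genes_detected"] == 0
        assert rep["frac_unique_to_one_organ"] == 0.0

    def test_counts_permutation_invariant_and_match_fixture_truth(self, small_fixture):
        from protatlas.postprocess import build_expression_matrix

        expr, _ = build_expression_matrix(
            small_fixture.tables_for_species("mouse"), small_fixture.gene_map
        )
        ann = small_fixture.annotation.subset_species("mouse")
        rep = coverage_report(expr, ann)
        shuffled = ExpressionMatrix(expr.values.iloc[::-1, ::-1])
        rep2 = coverage_report(shuffled, ann)
        assert rep == rep2
        assert rep["n_genes_detected"] == len(expr.genes)
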