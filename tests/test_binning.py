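"""Rank-bin transformation: boundary rule, ties, merging, batch cancellation."""

import math
from collections import defaultdict
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from protatlas.binning import bin_transform, merge_runs_to_tissue, merge_tissues_to_organ
from protatlas.io_formats import ConsistencyError
from protatlas.postprocess import ExpressionMatrix, build_expression_matrix
from protatlas.synthetic_data import SimulationConfig, generate_study

from conftest import make_annotation


def brute_force_bins(values, n_bins=5):
    """Independent oracle: sort, average-rank, ceil(rank*n_bins/m) in exact
    rational arithmetic."""
    obs = [(v, i) for i, v in enumerate(values) if v is not None and not math.isnan(v)]
    m = len(obs)
    out = [float("nan")] * len(values)
    positions = defaultdict(list)
    for r, v in enumerate(sorted(v for v, _ in obs), start=1):
        positions[v].append(r)
    for v, i in obs:
        rank = Fraction(sum(positions[v]), len(positions[v]))
        out[i] = math.ceil(rank * n_bins / m)
    return out


def _one_run_matrix(values):
    df = pd.DataFrame({"r1": values}, index=[f"g{i}" for i in range(len(values))], dtype=float)
    ann = make_annotation([("r1", "t", "o", "ds")])
    return ExpressionMatrix(df), ann


class TestBinTransform:
    def test_ten_distinct_values_fill_bins_in_pairs(self):
        matrix, ann = _one_run_matrix(list(range(10, 110, 10)))
        bins = bin_transform(matrix, ann).values["r1"]
        assert bins.tolist() == [1, 1, 2, 2, 3, 3, 4, 4, 5, 5]

    def test_scale_invariance_within_run(self):
        vals = [3.0, 1.0, 4.0, 1.5, 9.0, 2.6, np.nan]
        m1, ann = _one_run_matrix(vals)
        m2, _ = _one_run_matrix([v * 3 for v in vals])
        pd.testing.assert_frame_equal(
            bin_transform(m1, ann).values, bin_transform(m2, ann).values
        )

    def test_five_equal_values_all_get_middle_bin(self):
        matrix, ann = _one_run_matrix([7.0] * 5)
        assert bin_transform(matrix, ann).values["r1"].tolist() == [3.0] * 5

    def test_missing_never_binned(self):
        matrix, ann = _one_run_matrix([1.0, np.nan, 5.0])
        bins = bin_transform(matrix, ann).values["r1"]
        # m=2 observed: ranks 1,2 -> bins ceil(5/2)=3 and ceil(10/2)=5
        assert np.isnan(bins["g1"]) and bins["g0"] == 3 and bins["g2"] == 5

    def test_unannotated_run_is_error(self):
        df = pd.DataFrame({"rX": [1.0]}, index=["g0"])
        ann = make_annotation([("r1", "t", "o", "ds")])
        with pytest.raises(ConsistencyError, match="rX"):
            bin_transform(ExpressionMatrix(df), ann)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_matches_brute_force_oracle_with_ties_and_missing(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 60))
        vals = rng.choice([1.0, 2.0, 2.0, 5.0, 8.0, 13.0, np.nan], size=n).tolist()
        if all(math.isnan(v) for v in vals):
            vals[0] = 1.0
        matrix, ann = _one_run_matrix(vals)
        got = bin_transform(matrix, ann).values["r1"].tolist()
        expected = brute_force_bins(vals)
        assert all(
            (math.isnan(g) and math.isnan(e)) or g == e for g, e in zip(got, expected)
        )

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_monotone_and_occupancy_within_run(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(1, 80))
        vals = rng.permutation(rng.uniform(1, 1e6, size=m)).tolist()  # distinct
        matrix, ann = _one_run_matrix(vals)
        bins = bin_transform(matrix, ann).values["r1"]
        order = np.argsort(vals)
        assert (np.diff(bins.to_numpy()[order]) >= 0).all()
        occupancy = bins.value_counts()
        assert occupancy.min() >= math.floor(m / 5) or m < 5
        assert occupancy.max() <= math.ceil(m / 5)


class TestMerging:
    ANN = [
        ("r1", "cortex", "brain", "ds1"),
        ("r2", "cortex", "brain", "ds1"),
        ("r3", "cortex", "brain", "ds1"),
        ("r4", "cerebellum", "brain", "ds1"),
        ("r5", "liver", "liver", "ds1"),
    ]

    def _binned(self, rows, genes=None):
        genes = genes or [f"g{i}" for i in range(len(rows))]
        df = pd.DataFrame(rows, index=genes, columns=[a[0] for a in self.ANN], dtype=float)
        ann = make_annotation(self.ANN)
        from protatlas.binning import BinnedMatrix

        return BinnedMatrix(df, level="run", run_batches=ann.batches())

    def test_median_of_three_runs(self):
        b = self._binned([[2, 3, 4, 1, 5]])
        tissue = merge_runs_to_tissue(b)
        assert tissue.values.loc["g0", ("ds1", "cortex")] == 3

    def test_even_count_midpoint_half_integer(self):
        b = self._binned([[3, 4, np.nan, 1, 5]])
        tissue = merge_runs_to_tissue(b)
        assert tissue.values.loc["g0", ("ds1", "cortex")] == 3.5

    def test_median_over_observed_runs_only(self):
        b = self._binned([[np.nan, 5, np.nan, 1, 2]])
        tissue = merge_runs_to_tissue(b)
        assert tissue.values.loc["g0", ("ds1", "cortex")] == 5

    def test_gene_missing_in_whole_batch_stays_missing(self):
        b = self._binned([[np.nan, np.nan, np.nan, 2, 3]])
        tissue = merge_runs_to_tissue(b)
        assert np.isnan(tissue.values.loc["g0", ("ds1", "cortex")])
        organ = merge_tissues_to_organ(tissue)
        assert organ.values.loc["g0", "brain"] == 2  # only cerebellum contributes

    def test_organ_median_over_tissues(self):
        b = self._binned([[4, 4, 5, 4, 1]])
        organ = merge_tissues_to_organ(merge_runs_to_tissue(b))
        assert organ.values.loc["g0", "brain"] == 4
        assert organ.values.loc["g0", "liver"] == 1  # single tissue: identity


class TestBatchEffectCancellation:
    def test_scaling_one_dataset_leaves_all_levels_identical(self, small_fixture):
        tables = small_fixture.tables_for_species("mouse")
        gm = small_fixture.gene_map
        ann = small_fixture.annotation

        def levels(tabs):
            expr, _ = build_expression_matrix(tabs, gm)
            run = bin_transform(expr, ann)
            tissue = merge_runs_to_tissue(run)
            organ = merge_tissues_to_organ(tissue)
            return run, tissue, organ

        ds = sorted(tables)[0]
        scaled = dict(tables)
        scaled[ds] = tables[ds].with_intensities(tables[ds].intensities * 1000.0)
        for a, b in zip(levels(tables), levels(scaled)):
            av, bv = a.values.to_numpy(), b.values.to_numpy()
            assert ((av == bv) | (np.isnan(av) & np.isnan(bv))).all()

    def test_bins_disagree_less_between_datasets_than_log_ppb(self):
        """With dataset batch effects, a gene's organ-level value disagrees
        less between two datasets on the bin scale than on raw log-ppb,
        measured relative to each scale's between-gene spread (the
        rationale for binning)."""
        cfg = SimulationConfig(
            n_genes=400, batch_sigma=0.5, frac_organ_enriched=0.0, seed=5
        )
        fx = generate_study(cfg)
        gm, ann = fx.gene_map, fx.annotation

        organ_bin, organ_log = [], []
        for ds_id, table in fx.tables_for_species("mouse").items():
            expr, _ = build_expression_matrix({ds_id: table}, gm)
            run = bin_transform(expr, ann)
            organ = merge_tissues_to_organ(merge_runs_to_tissue(run))
            organ_bin.append(organ.values)
            organs = ann.batches().loc[list(expr.runs), "organ"]
            logv = np.log10(expr.values)
            organ_log.append(logv.T.groupby(organs.to_numpy()).median().T)

        def rel_disagreement(a, b):
            d = (a - b).abs().stack().mean()
            spread = pd.concat([a, b]).stack().std()
            return d / spread

        assert rel_disagreement(*organ_bin) < rel_disagreement(*organ_log)
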