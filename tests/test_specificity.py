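"""Organ-specificity classification and conserved expression sets."""

import numpy as np
import pandas as pd
import pytest

from protatlas.specificity import (
    GROUP_ENRICHED,
    MIXED,
    ORGAN_ENRICHED,
    SpecificityConfig,
    classify_specificity,
    conserved_expression_sets,
    elevated_summary,
)


def bins(rows: dict[str, list], organs: list[str]) -> pd.DataFrame:
    return pd.DataFrame.from_dict(rows, orient="index", columns=organs, dtype=float)


class TestClassify:
    def test_single_high_organ_is_organ_enriched(self):
        B = bins({"g": [5, 1, 1, 1]}, list("ABCD"))
        call = classify_specificity(B).loc["g"]
        assert call["class"] == ORGAN_ENRICHED
        assert call["elevated_organs"] == ("A",)
        assert call["mean_bin"] == 2.0 and call["threshold_used"] == 4.0

    def test_flat_profile_is_mixed(self):
        B = bins({"g": [3, 3, 3, 3]}, list("ABCD"))
        call = classify_specificity(B).loc["g"]
        assert call["class"] == MIXED and call["elevated_organs"] == ()

    def test_two_elevated_organs_with_presence_is_group_enriched(self):
        # rat-style threshold: present in 6 >= 4 organs
        B = bins({"g": [5, 5, 1, 1, 1, 1]}, list("ABCDEF"))
        call = classify_specificity(
            B, SpecificityConfig(min_present_organs=4)
        ).loc["g"]
        assert call["class"] == GROUP_ENRICHED
        assert call["elevated_organs"] == ("A", "B")
        assert call["threshold_used"] == pytest.approx(2 * 14 / 6)

    def test_two_elevated_without_presence_is_mixed(self):
        B = bins({"g": [5, 5, np.nan, np.nan, np.nan, np.nan]}, list("ABCDEF"))
        call = classify_specificity(
            B, SpecificityConfig(min_present_organs=7)
        ).loc["g"]
        assert call["class"] == MIXED

    def test_all_organs_mean_counts_absent_as_zero(self):
        # detected only at home: all-organs mean makes it maximally enriched
        B = bins({"g": [5, np.nan, np.nan, np.nan]}, list("ABCD"))
        call = classify_specificity(
            B, SpecificityConfig(mean_policy="all-organs")
        ).loc["g"]
        assert call["class"] == ORGAN_ENRICHED and call["mean_bin"] == 1.25

    def test_observed_only_mean_never_calls_single_organ_genes(self):
        B = bins({"g": [5, np.nan, np.nan, np.nan]}, list("ABCD"))
        call = classify_specificity(
            B, SpecificityConfig(mean_policy="observed-only")
        ).loc["g"]
        assert call["class"] == MIXED

    def test_detected_single_reading_requires_one_present_organ(self):
        cfg = SpecificityConfig(reading="detected-single")
        lone = bins({"g": [5, np.nan, np.nan, np.nan]}, list("ABCD"))
        multi = bins({"h": [5, 1, 1, 1]}, list("ABCD"))
        assert classify_specificity(lone, cfg).loc["g", "class"] == ORGAN_ENRICHED
        assert classify_specificity(multi, cfg).loc["h", "class"] == MIXED

    def test_absent_gene_excluded_with_warning(self):
        B = bins({"g": [5, 1, 1, 1], "x": [np.nan] * 4}, list("ABCD"))
        with pytest.warns(UserWarning, match="absent"):
            calls = classify_specificity(B)
        assert list(calls.index) == ["g"]

    def test_partition_every_present_gene_has_one_class(self):
        rng = np.random.default_rng(0)
        vals = rng.integers(1, 6, size=(200, 8)).astype(float)
        vals[rng.random(vals.shape) < 0.3] = np.nan
        vals[0] = np.nan  # one fully absent gene
        B = pd.DataFrame(vals, index=[f"g{i}" for i in range(200)], columns=list("ABCDEFGH"))
        with pytest.warns(UserWarning):
            calls = classify_specificity(B)
        assert len(calls) == 199
        assert calls["class"].isin([ORGAN_ENRICHED, GROUP_ENRICHED, MIXED]).all()

    def test_elevated_set_shrinks_as_fold_rises(self):
        rng = np.random.default_rng(3)
        vals = rng.integers(1, 6, size=(100, 6)).astype(float)
        vals[rng.random(vals.shape) < 0.2] = np.nan
        B = pd.DataFrame(vals, index=[f"g{i}" for i in range(100)], columns=list("ABCDEF"))
        prev = None
        for fold in (1.2, 1.6, 2.0, 3.0):
            calls = classify_specificity(B, SpecificityConfig(fold=fold))
            elev = {g: set(e) for g, e in calls["elevated_organs"].items()}
            # recompute the raw elevated sets (before class gating)
            mean = B.fillna(0).mean(axis=1)
            raw = {
                g: set(B.columns[(B.loc[g] >= fold * mean[g]) & B.loc[g].notna()])
                for g in B.index
            }
            if prev is not None:
                assert all(raw[g] <= prev[g] for g in B.index)
            prev = raw

    def test_planted_enrichment_recovered_on_fixture(self, small_fixture):
        from protatlas.pipeline import run_species_pipeline

        res = run_species_pipeline(
            small_fixture.tables_for_species("mouse"),
            small_fixture.annotation,
            small_fixture.gene_map,
            "mouse",
        )
        truth = small_fixture.truth.loc["mouse"]
        planted = truth.index[truth["planted_class"] == "organ-enriched"]
        well = [
            g
            for g in planted
            if g in res.calls.index and res.calls.loc[g, "n_present_organs"] >= 4
        ]
        called = res.calls.loc[well, "class"] == ORGAN_ENRICHED
        assert called.mean() >= 0.9
        mixed = truth.index[truth["planted_class"] == "mixed"]
        fp = (res.calls["class"].reindex(mixed) == ORGAN_ENRICHED).mean()
        assert fp <= 0.05


class TestElevatedSummary:
    def test_group_enriched_attributed_to_every_elevated_organ(self):
        calls = pd.DataFrame(
            {
                "class": [ORGAN_ENRICHED, GROUP_ENRICHED, MIXED],
                "elevated_organs": [("A",), ("A", "B"), ()],
            },
            index=["g1", "g2", "g3"],
        )
        out = elevated_summary(calls)
        assert out.loc["A", "n_organ_enriched"] == 1
        assert out.loc["A", "n_group_enriched"] == 1
        assert out.loc["B", "n_group_enriched"] == 1
        assert out.attrs["n_elevated_total"] == 2

    def test_no_calls_gives_empty_summary(self):
        calls = pd.DataFrame({"class": [], "elevated_organs": []})
        out = elevated_summary(calls)
        assert out.empty and out.attrs["n_elevated_total"] == 0

    def test_organ_enriched_fractions_sum_to_their_share(self):
        calls = pd.DataFrame(
            {
                "class": [ORGAN_ENRICHED, ORGAN_ENRICHED, GROUP_ENRICHED],
                "elevated_organs": [("A",), ("B",), ("A", "B")],
            },
            index=["g1", "g2", "g3"],
        )
        out = elevated_summary(calls)
        assert out["frac_organ_enriched"].sum() == pytest.approx(2 / 3)


class TestConservedSets:
    def test_high_in_three_organs(self):
        B = bins({"g": [5, 5, 5, 1]}, list("ABCD"))
        high, low = conserved_expression_sets(B)
        assert high == ["g"] and low == []

    def test_boundary_is_strict(self):
        B = bins({"g": [4, 4, 4, 4]}, list("ABCD"))
        high, low = conserved_expression_sets(B)
        assert high == [] and low == []

    def test_two_qualifying_organs_insufficient(self):
        B = bins({"g": [1, 1, 5]}, list("ABC"))
        high, low = conserved_expression_sets(B, min_organs=3)
        assert low == [] and high == []
        high2, low2 = conserved_expression_sets(B, min_organs=2)
        assert low2 == ["g"]
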