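"""End-to-end orchestration: filter → normalise → aggregate → bin → merge
→ classify → compare, per species, with optional cross-species stages.

This is the programmatic counterpart of the command-line interface: a
config (YAML/JSON-shaped dict) lists the per-dataset protein-group
tables, the sample annotation, the gene map and optional ortholog
pairs, plus stage parameters; the pipeline writes the ppb matrix, the
bin matrices at run/tissue/organ level, specificity calls, coverage and
filter reports, and a machine-readable log of every parameter used.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import binning, crossspecies, postprocess, sample_stats, specificity
from .io_formats import (
    GeneMap,
    QuantTable,
    SampleAnnotation,
    read_gene_map,
    read_ortholog_pairs,
    read_protein_groups,
    read_sample_annotation,
    write_expression_matrix,
    write_json_report,
)

__all__ = ["PipelineParams", "SpeciesResult", "run_species_pipeline", "run_pipeline"]

# presence-count preconditions of the group-enriched class in the two
# study designs (12 well-covered organs in mouse, 8 in rat)
DEFAULT_MIN_PRESENT = {"mouse": 7, "rat": 4}


@dataclass(frozen=True)
class PipelineParams:
    min_psm: int = 2
    n_bins: int = 5
    ties: str = "average"
    fold: float = 2.0
    min_present_organs: int | None = None  # None: per-species default, else fixed
    mean_policy: str = "all-organs"
    reading: str = "elevated"
    high_threshold: float = 4.0
    low_threshold: float = 2.0
    min_organs: int = 3
    pca_min_presence: float = 0.5
    umap_layout_presence: float = 0.9
    comparison_scale: str = "log10"
    seed: int = 0

    def min_present_for(self, species: str) -> int:
        if self.min_present_organs is not None:
            return self.min_present_organs
        return DEFAULT_MIN_PRESENT.get(species, 7)


@dataclass
class SpeciesResult:
    species: str
    expression: postprocess.ExpressionMatrix
    filter_reports: dict[str, postprocess.FilterReport]
    run_bins: binning.BinnedMatrix
    tissue_bins: binning.BinnedMatrix
    organ_bins: binning.BinnedMatrix
    calls: pd.DataFrame
    coverage: dict
    organ_ppb: pd.DataFrame
    high_set: list[str] = field(default_factory=list)
    low_set: list[str] = field(default_factory=list)


def run_species_pipeline(
    tables: dict[str, QuantTable],
    annotation: SampleAnnotation,
    gene_map: GeneMap,
    species: str,
    params: PipelineParams = PipelineParams(),
) -> SpeciesResult:
    """Run the full single-species chain on in-memory tables."""
    ann = annotation.subset_species(species)
    expr, reports = postprocess.build_expression_matrix(
        tables, gene_map, min_psm=params.min_psm
    )
    run_bins = binning.bin_transform(expr, ann, n_bins=params.n_bins, ties=params.ties)
    tissue_bins = binning.merge_runs_to_tissue(run_bins)
    organ_bins = binning.merge_tissues_to_organ(tissue_bins)
    calls = specificity.classify_specificity(
        organ_bins,
        specificity.SpecificityConfig(
            fold=params.fold,
            min_present_organs=params.min_present_for(species),
            mean_policy=params.mean_policy,
            reading=params.reading,
        ),
    )
    high, low = specificity.conserved_expression_sets(
        organ_bins,
        high_threshold=params.high_threshold,
        low_threshold=params.low_threshold,
        min_organs=params.min_organs,
    )
    coverage = sample_stats.coverage_report(expr, ann)
    organ_ppb = crossspecies.organ_median_ppb(expr, ann)
    return SpeciesResult(
        species=species,
        expression=expr,
        filter_reports=reports,
        run_bins=run_bins,
        tissue_bins=tissue_bins,
        organ_bins=organ_bins,
        calls=calls,
        coverage=coverage,
        organ_ppb=organ_ppb,
        high_set=high,
        low_set=low,
    )


def _load_config_inputs(config: dict):
    for key in ("datasets", "annotation", "gene_map"):
        if key not in config:
            raise KeyError(f"pipeline config missing mandatory field '{key}'")
    tables = {}
    for entry in config["datasets"]:
        if "id" not in entry or "protein_groups" not in entry:
            raise KeyError("each dataset entry needs 'id' and 'protein_groups'")
        tables[entry["id"]] = read_protein_groups(entry["protein_groups"])
    annotation = read_sample_annotation(config["annotation"])
    gene_map = read_gene_map(config["gene_map"])
    orthologs = (
        read_ortholog_pairs(config["orthologs"]) if config.get("orthologs") else None
    )
    return tables, annotation, gene_map, orthologs


def run_pipeline(config: dict, outdir: str | Path) -> dict[str, SpeciesResult]:
    """Execute the whole pipeline from a config dict and write outputs.

    Dataset tables are grouped by the species of their runs; each
    species is processed independently, and if an ortholog pair table is
    given the first two species are compared organ by organ.
    """
    params = PipelineParams(**config.get("params", {}))
    tables, annotation, gene_map, orthologs = _load_config_inputs(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    species_of_ds = (
        annotation.table.groupby("dataset_id")["species"].first().to_dict()
    )
    by_species: dict[str, dict[str, QuantTable]] = {}
    for ds_id, table in tables.items():
        if ds_id not in species_of_ds:
            raise KeyError(f"dataset '{ds_id}' has no annotated runs")
        by_species.setdefault(species_of_ds[ds_id], {})[ds_id] = table

    results: dict[str, SpeciesResult] = {}
    for species in sorted(by_species):
        res = run_species_pipeline(
            by_species[species], annotation, gene_map, species, params
        )
        results[species] = res
        tag = species.replace(" ", "_")
        if not res.expression.values.empty:
            write_expression_matrix(res.expression, outdir / f"{tag}_ppb.tsv")
            write_expression_matrix(res.run_bins, outdir / f"{tag}_bins_run.tsv")
            write_expression_matrix(res.tissue_bins, outdir / f"{tag}_bins_tissue.tsv")
            write_expression_matrix(res.organ_bins, outdir / f"{tag}_bins_organ.tsv")
        res.calls.assign(
            elevated_organs=res.calls["elevated_organs"].map(lambda t: ";".join(t))
        ).to_csv(outdir / f"{tag}_specificity.tsv", sep="\t")
        write_json_report(
            {ds: r.as_dict() for ds, r in res.filter_reports.items()},
            outdir / f"{tag}_filter_report.json",
        )
        write_json_report(res.coverage, outdir / f"{tag}_coverage.json")
        write_json_report(
            {"high_set": res.high_set, "low_set": res.low_set},
            outdir / f"{tag}_conserved_sets.json",
        )

    if (
        orthologs is not None
        and len(results) >= 2
        and all(len(r.expression.genes) for r in results.values())
    ):
        src, tgt = sorted(results)[:2]
        omap = crossspecies.categorize_orthologs(
            orthologs,
            list(results[src].expression.genes),
            list(results[tgt].expression.genes),
        )
        fits = {}
        shared_organs = sorted(
            set(results[src].organ_ppb.columns) & set(results[tgt].organ_ppb.columns)
        )
        for organ in shared_organs:
            try:
                fit = crossspecies.compare_ortholog_abundance(
                    results[src].organ_ppb,
                    results[tgt].organ_ppb,
                    omap,
                    organ,
                    scale=params.comparison_scale,
                )
            except ValueError:
                continue
            fits[organ] = asdict(fit)
        write_json_report(
            {
                "source_species": src,
                "target_species": tgt,
                "category_counts": omap.category_counts().to_dict(),
                "category_fractions": omap.category_fractions().to_dict(),
                "fits_per_organ": fits,
            },
            outdir / "crossspecies.json",
        )

    write_json_report({"params": asdict(params)}, outdir / "pipeline_params.json")
    return results
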