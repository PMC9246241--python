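"""Quality filtering, fraction-of-total normalisation and gene aggregation.

The post-quantification chain applied to each dataset's protein-group
table:

1. remove potential contaminants, decoys and groups with fewer than
   ``min_psm`` peptide-spectrum matches;
2. scale each MS run's iBAQ intensities to the total signal observed in
   that run and express them as parts per billion (ppb),
   ``ppb_i = iBAQ_i / sum_j iBAQ_j * 1e9``;
3. map each protein group's majority accessions to genes and keep only
   groups that map to a single unique gene ("canonical protein"),
   aggregating multiple groups of one gene by the median.

Normalisation precedes aggregation, so gene-level columns need not sum
to 1e9 — the per-run conservation invariant holds at the protein-group
level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io_formats import GeneMap, QuantTable

__all__ = [
    "FilterReport",
    "ExpressionMatrix",
    "filter_protein_groups",
    "fot_normalize",
    "aggregate_to_genes",
    "build_expression_matrix",
]

PPB_SCALE = 1e9


@dataclass
class FilterReport:
    """Counts of protein-group removals, one count per reason.

    A row failing several criteria is counted once under each reason;
    ``n_removed`` counts distinct rows.
    """

    n_input: int = 0
    n_contaminant: int = 0
    n_reverse: int = 0
    n_low_psm: int = 0
    n_removed: int = 0
    n_retained: int = 0
    min_psm: int = 2

    def as_dict(self) -> dict:
        return asdict(self)


def filter_protein_groups(
    table: QuantTable, min_psm: int = 2
) -> tuple[QuantTable, FilterReport]:
    """Drop contaminant, decoy and low-evidence protein groups.

    Retains rows with ``is_contaminant == False``, ``is_reverse == False``
    and ``psm_count >= min_psm`` (the default removes groups with fewer
    than 2 PSMs).  Idempotent.  An empty result is allowed.
    """
    g = table.groups
    con = g["is_contaminant"].to_numpy(bool)
    rev = g["is_reverse"].to_numpy(bool)
    low = g["psm_count"].to_numpy() < min_psm
    keep = ~(con | rev | low)
    report = FilterReport(
        n_input=len(g),
        n_contaminant=int(con.sum()),
        n_reverse=int(rev.sum()),
        n_low_psm=int(low.sum()),
        n_removed=int((~keep).sum()),
        n_retained=int(keep.sum()),
        min_psm=min_psm,
    )
    kept_ids = g.index[keep]
    return table.subset(kept_ids), report


def fot_normalize(table: QuantTable) -> QuantTable:
    """Fraction-of-total normalisation of each MS run to ppb.

    Every non-missing intensity is divided by the sum of non-missing
    intensities in its run and scaled by 1e9, so each run with at least
    one observation sums to exactly 1e9 parts per billion.  Missing
    values stay missing.  A run with no positive observation is emitted
    all-missing with a warning.  The transform is invariant to any
    positive rescaling of a run's intensities.
    """
    inten = table.intensities.astype(float)
    totals = inten.sum(axis=0, skipna=True)
    dead = totals[totals <= 0].index.tolist()
    if dead:
        warnings.warn(
            f"runs with no positive intensities left all-missing: {dead}",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        ppb = inten.div(totals.where(totals > 0), axis=1) * PPB_SCALE
    return table.with_intensities(ppb)


@dataclass
class ExpressionMatrix:
    """Canonical-protein (gene) × MS-run matrix of ppb abundances.

    ``values`` is a gene-indexed DataFrame (lexicographic gene order)
    with ``NaN`` for genes unobserved in a run.  ``provenance`` records
    which protein groups contributed to each gene; groups whose majority
    accessions map to more than one gene are excluded and listed in
    ``excluded_multigene_groups``, unmapped groups in
    ``unmapped_groups``.
    """

    values: pd.DataFrame
    provenance: dict[str, list[str]] = field(default_factory=dict)
    excluded_multigene_groups: list[tuple[str, frozenset]] = field(default_factory=list)
    unmapped_groups: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise ValueError("duplicate gene identifiers")
        with np.errstate(invalid="ignore"):
            if (self.values.to_numpy(dtype=float) < 0).any():
                raise ValueError("negative abundance values")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def runs(self) -> list[str]:
        return list(self.values.columns)


def aggregate_to_genes(table: QuantTable, gene_map: GeneMap) -> ExpressionMatrix:
    """Collapse a (FOT-normalised) protein-group table to canonical proteins.

    For each group the union of gene mappings over its majority
    accessions is computed; only groups mapping to exactly one gene are
    kept.  Per gene and run, the value is the median over the
    contributing groups' observed ppb values (missing if none observed;
    the median of an even count is the midpoint of the central pair).
    """
    if len(gene_map) == 0:
        warnings.warn("empty gene map: all groups unmapped", stacklevel=2)
    gene_of_group: dict[str, str] = {}
    excluded: list[tuple[str, frozenset]] = []
    unmapped: list[str] = []
    for gid, accs in table.groups["majority_accessions"].items():
        genes = gene_map.genes_for(accs)
        if len(genes) == 1:
            gene_of_group[gid] = next(iter(genes))
        elif len(genes) == 0:
            unmapped.append(gid)
        else:
            excluded.append((gid, genes))

    if not gene_of_group:
        empty = pd.DataFrame(index=pd.Index([], name="gene"), columns=table.runs, dtype=float)
        return ExpressionMatrix(empty, {}, excluded, unmapped)

    kept = table.intensities.loc[list(gene_of_group)]
    genes = pd.Series(gene_of_group)
    values = kept.groupby(genes).median().sort_index()
    values.index.name = "gene"
    provenance: dict[str, list[str]] = {}
    for gid, gene in gene_of_group.items():
        provenance.setdefault(gene, []).append(gid)
    return ExpressionMatrix(values, provenance, excluded, unmapped)


def build_expression_matrix(
    tables: dict[str, QuantTable],
    gene_map: GeneMap,
    min_psm: int = 2,
) -> tuple[ExpressionMatrix, dict[str, FilterReport]]:
    """Run filter → normalise → aggregate per dataset and join the runs.

    Datasets are processed independently (each run is normalised within
    its own table) and the per-dataset gene matrices are outer-joined on
    genes; run identifiers must be globally unique.
    """
    reports: dict[str, FilterReport] = {}
    pieces: list[ExpressionMatrix] = []
    for ds_id in sorted(tables):
        filtered, reports[ds_id] = filter_protein_groups(tables[ds_id], min_psm=min_psm)
        pieces.append(aggregate_to_genes(fot_normalize(filtered), gene_map))
    values = pd.concat([p.values for p in pieces], axis=1).sort_index()
    if not values.columns.is_unique:
        raise ValueError("run identifiers collide across datasets")
    merged = ExpressionMatrix(values)
    for p in pieces:
        for gene, gids in p.provenance.items():
            merged.provenance.setdefault(gene, []).extend(gids)
        merged.excluded_multigene_groups.extend(p.excluded_multigene_groups)
        merged.unmapped_groups.extend(p.unmapped_groups)
    return merged, reports
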