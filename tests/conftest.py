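"""Shared fixtures: hand-built quantification tables and small simulated
studies used across the suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from protatlas.io_formats import GeneMap, QuantTable, SampleAnnotation
from protatlas.synthetic_data import DatasetDesign, SimulationConfig, generate_study


def make_quant(
    intensities: dict[str, dict[str, float]],
    psm: dict[str, int] | None = None,
    contaminant: set[str] = frozenset(),
    reverse: set[str] = frozenset(),
    accessions: dict[str, tuple[str, ...]] | None = None,
) -> QuantTable:
    """Build a QuantTable from {group_id: {run_id: value}} (NaN for missing)."""
    gids = list(intensities)
    runs = sorted({r for row in intensities.values() for r in row})
    inten = pd.DataFrame(
        [[intensities[g].get(r, np.nan) for r in runs] for g in gids],
        index=pd.Index(gids, name="group_id"),
        columns=runs,
        dtype=float,
    )
    groups = pd.DataFrame(
        {
            "majority_accessions": [
                (accessions or {}).get(g, (f"ACC_{g}",)) for g in gids
            ],
            "psm_count": [(psm or {}).get(g, 5) for g in gids],
            "is_contaminant": [g in contaminant for g in gids],
            "is_reverse": [g in reverse for g in gids],
        },
        index=inten.index,
    )
    return QuantTable(groups, inten)


def make_annotation(rows: list[tuple]) -> SampleAnnotation:
    """Rows of (run_id, tissue, organ, dataset_id[, species[, sample_id]])."""
    records = []
    for row in rows:
        run, tissue, organ, ds = row[:4]
        species = row[4] if len(row) > 4 else "mouse"
        sample = row[5] if len(row) > 5 else run
        records.append(
            {
                "run_id": run,
                "sample_id": sample,
                "tissue": tissue,
                "organ": organ,
                "dataset_id": ds,
                "species": species,
                "strain": "",
                "fraction_id": "",
            }
        )
    return SampleAnnotation(pd.DataFrame(records).set_index("run_id"))


def identity_gene_map(table: QuantTable) -> GeneMap:
    """Map every accession ACC_x -> gene x."""
    mapping = {}
    for accs in table.groups["majority_accessions"]:
        for a in accs:
            mapping[a] = frozenset([a.removeprefix("ACC_")])
    return GeneMap(mapping)


@pytest.fixture(scope="session")
def small_fixture():
    """A 300-gene single-species study with all planted artefact types."""
    return generate_study(SimulationConfig(n_genes=300, seed=7))


@pytest.fixture(scope="session")
def two_species_fixture():
    """A 400-gene two-species study with an ortholog table."""
    cfg = SimulationConfig(
        n_genes=400,
        species=("mouse", "rat"),
        datasets=(DatasetDesign("ds1", None, 2), DatasetDesign("ds2", None, 2)),
        seed=11,
    )
    return generate_study(cfg)
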