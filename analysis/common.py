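"""Shared study definition for the analysis drivers.

All drivers analyse the same deterministic two-species synthetic study
(seed 1): 2000 genes per species, eight organs, two datasets per
species, with planted organ-enriched proteins, contaminant/decoy/low-PSM
rows and a cross-species ortholog table (rho = 0.8).  Regenerating it is
fast, so every driver is standalone.
"""

from pathlib import Path

from protatlas.pipeline import PipelineParams, run_species_pipeline
from protatlas.synthetic_data import SimulationConfig, generate_study

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

STUDY_SEED = 1


def study_config() -> SimulationConfig:
    return SimulationConfig(
        n_genes=2000,
        species=("mouse", "rat"),
        seed=STUDY_SEED,
    )


def load_study():
    return generate_study(study_config())


def run_all_species(fixture, params: PipelineParams = PipelineParams()):
    return {
        sp: run_species_pipeline(
            fixture.tables_for_species(sp),
            fixture.annotation,
            fixture.gene_map,
            sp,
            params,
        )
        for sp in fixture.config.species
    }
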