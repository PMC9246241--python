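"""Synthetic multi-dataset, multi-species proteomics study generator.

Produces fixtures with the statistical structure the analysis pipeline
assumes, so every downstream stage is testable without any external
download:

* per-gene baseline log10 abundances drawn from a normal distribution
  (label-free iBAQ intensities are approximately log-normal);
* a configurable fraction of organ-enriched genes, multiplied by
  ``enrichment_fold`` in their home organ; their baselines are drawn
  from a low quantile band of the abundance distribution
  (``enriched_baseline_quantiles``), reflecting that organ-specific
  proteins show low — but quantifiable — background expression outside
  their home organ (a gene whose boosted home abundance still fell
  below the detection limit would carry an unmeasurable truth label);
* dataset-level multiplicative batch effects: each dataset biases each
  protein by its own log-normal factor (sample preparation, digestion
  and instrument response are protein-specific), shared by all runs of
  the dataset.  A protein-specific bias survives fraction-of-total
  normalisation — unlike a scalar per-dataset factor, which FOT removes
  exactly — and is the nuisance the rank-bin transform mitigates;
* abundance-dependent missingness: detection probability is logistic in
  log10 abundance, so low-abundance proteins drop out more often (the
  data-dependent-acquisition behaviour of the reanalysed datasets);
* protein groups such that a fraction of genes is represented by two
  groups (exercising median aggregation) and a fraction of extra groups
  maps to two genes (exercising exclusion);
* planted contaminant, decoy and low-PSM rows in exact configured
  proportions; genuine groups carry 2+ PSMs so the evidence filter
  removes exactly the planted rows;
* an optional second species whose per-gene log effects correlate with
  the first at ``ortholog_rho``, plus an ortholog pair table containing
  one-to-one, one-to-many, many-to-one, many-to-many and unmapped
  genes.

Everything is driven by one integer seed; the same config and seed give
byte-identical fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr, ndtri

from .io_formats import (
    GeneMap,
    QuantTable,
    SampleAnnotation,
    write_gene_map,
    write_ortholog_pairs,
    write_protein_groups,
    write_sample_annotation,
)

__all__ = [
    "DatasetDesign",
    "SimulationConfig",
    "StudyFixture",
    "generate_study",
    "truth_table",
    "write_fixture",
    "DEFAULT_ORGANS",
]

DEFAULT_ORGANS: dict[str, list[str]] = {
    "brain": ["cerebellum", "cortex", "hippocampus"],
    "heart": ["left ventricle", "right atrium"],
    "kidney": ["renal cortex", "renal medulla"],
    "liver": ["liver"],
    "lung": ["lung"],
    "muscle": ["skeletal muscle"],
    "spleen": ["spleen"],
    "testis": ["testis"],
}


@dataclass(frozen=True)
class DatasetDesign:
    """One dataset of the simulated study: which organs it sampled and
    how many MS runs (= samples) it acquired per tissue."""

    dataset_id: str
    organs: tuple[str, ...] | None = None  # None = all organs of the study
    runs_per_tissue: int = 3


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a simulated study; defaults give a two-dataset,
    eight-organ design per species.

    Abundance model: baseline log10 intensity ~ N(``baseline_log10_mean``,
    ``baseline_log10_sd``); observed run intensity multiplies in a
    protein-specific per-dataset batch bias (log10 sd ``batch_sigma``,
    shared across the dataset's runs) and per-run noise
    (``run_noise_sd``).  Detection probability is
    ``logistic(detection_steepness * (log10 x - detection_midpoint))``
    with the midpoint defaulting to the baseline mean, i.e. the median
    protein is a coin-flip detection in any one run.
    """

    n_genes: int = 2000
    organs: tuple[tuple[str, tuple[str, ...]], ...] = tuple(
        (o, tuple(t)) for o, t in DEFAULT_ORGANS.items()
    )
    datasets: tuple[DatasetDesign, ...] = (
        DatasetDesign("ds1", None, 3),
        DatasetDesign("ds2", None, 3),
    )
    species: tuple[str, ...] = ("mouse",)
    frac_organ_enriched: float = 0.05
    enrichment_fold: float = 8.0
    enriched_baseline_quantiles: tuple[float, float] = (0.15, 0.45)
    baseline_log10_mean: float = 6.0
    baseline_log10_sd: float = 0.8
    batch_sigma: float = 0.15
    run_noise_sd: float = 0.10
    detection_steepness: float = 3.0
    detection_midpoint: float | None = None
    frac_contaminant: float = 0.02
    frac_reverse: float = 0.02
    frac_low_psm: float = 0.03
    frac_multi_group_genes: float = 0.10
    frac_multigene_groups: float = 0.05
    ortholog_rho: float = 0.8
    frac_one_to_many: float = 0.10
    frac_unmapped: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if not self.datasets:
            raise ValueError("at least one dataset required")
        if not self.organs:
            raise ValueError("at least one organ required")
        for name in (
            "frac_organ_enriched",
            "frac_contaminant",
            "frac_reverse",
            "frac_low_psm",
            "frac_multi_group_genes",
            "frac_multigene_groups",
            "frac_one_to_many",
            "frac_unmapped",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        lo, hi = self.enriched_baseline_quantiles
        if not (0 <= lo < hi <= 1):
            raise ValueError("enriched_baseline_quantiles must satisfy 0 <= lo < hi <= 1")
        if not self.enrichment_fold > 1:
            raise ValueError("enrichment_fold must exceed 1")
        if not 0 <= self.ortholog_rho <= 1:
            raise ValueError("ortholog_rho must lie in [0, 1]")
        if self.frac_organ_enriched > 0 and len(self.organs) < 2:
            raise ValueError("organ enrichment needs at least 2 organs")
        if any(d.runs_per_tissue < 1 for d in self.datasets):
            raise ValueError("runs_per_tissue must be positive")

    @property
    def organ_map(self) -> dict[str, tuple[str, ...]]:
        return dict(self.organs)

    @property
    def midpoint(self) -> float:
        return (
            self.baseline_log10_mean
            if self.detection_midpoint is None
            else self.detection_midpoint
        )


@dataclass
class StudyFixture:
    """A generated study: quantification tables, annotation, maps, truth."""

    config: SimulationConfig
    quant_tables: dict[str, QuantTable]  # dataset_id -> table
    annotation: SampleAnnotation
    gene_map: GeneMap
    ortholog_pairs: pd.DataFrame | None
    truth: pd.DataFrame  # (species, gene) indexed: planted_class, home_organ, baseline_log10
    true_tissue_log10: dict[str, pd.DataFrame]  # species -> gene x tissue
    qc_rows: pd.DataFrame  # group_id indexed: reason
    expected_ortholog_category: pd.Series | None = None

    def genes(self, species: str) -> list[str]:
        return list(self.truth.loc[species].index)

    def tables_for_species(self, species: str) -> dict[str, QuantTable]:
        ds_ids = self.annotation.table.loc[
            self.annotation.table["species"] == species, "dataset_id"
        ].unique()
        return {d: self.quant_tables[d] for d in sorted(ds_ids)}


def _gene_ids(species: str, n: int) -> list[str]:
    tag = species[:3].lower()
    return [f"{tag}_g{i:05d}" for i in range(n)]


def _squeeze_to_quantile_band(z: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Map standard-normal draws monotonically into the [lo, hi] quantile
    band of the standard normal (quantile-preserving squeeze)."""
    u = lo + ndtr(z) * (hi - lo)
    return ndtri(np.clip(u, 1e-12, 1 - 1e-12))


def _simulate_species(
    cfg: SimulationConfig,
    species: str,
    z: np.ndarray,
    enriched_idx: np.ndarray,
    home_organ: np.ndarray,
    rng: np.random.Generator,
) -> tuple[dict[str, QuantTable], pd.DataFrame, dict, pd.DataFrame, pd.DataFrame]:
    n = cfg.n_genes
    genes = _gene_ids(species, n)
    organ_map = cfg.organ_map
    tissues = [(o, t) for o, ts in organ_map.items() for t in ts]

    z = z.copy()
    z[enriched_idx] = _squeeze_to_quantile_band(
        z[enriched_idx], *cfg.enriched_baseline_quantiles
    )
    baseline = cfg.baseline_log10_mean + cfg.baseline_log10_sd * z
    dfold = np.log10(cfg.enrichment_fold)

    # true tissue-level log abundance
    tissue_log = pd.DataFrame(
        np.tile(baseline[:, None], (1, len(tissues))),
        index=genes,
        columns=pd.MultiIndex.from_tuples(tissues, names=["organ", "tissue"]),
    )
    for gi, organ in zip(enriched_idx, home_organ[enriched_idx]):
        cols = [c for c in tissue_log.columns if c[0] == organ]
        tissue_log.iloc[gi, [tissue_log.columns.get_loc(c) for c in cols]] += dfold

    # protein-group roster
    n_multi = int(round(cfg.frac_multi_group_genes * n))
    multi_genes = rng.choice(n, size=n_multi, replace=False) if n_multi else np.array([], int)
    group_gene: list[int] = list(range(n)) + list(multi_genes)
    group_ids = [f"{species[:3]}_G{genes[g][len(species[:3]) + 2:]}" for g in range(n)]
    group_ids += [f"{species[:3]}_G{genes[g][len(species[:3]) + 2:]}b" for g in multi_genes]
    group_offset = np.concatenate(
        [np.zeros(n), rng.normal(0.0, 0.10, size=n_multi)]
    )  # log10 offset of a gene's secondary group

    n_real = len(group_gene)
    n_multigene = int(round(cfg.frac_multigene_groups * n_real))
    # extra groups whose accessions span two adjacent genes -> excluded downstream
    mg_first = rng.choice(n - 1, size=n_multigene, replace=False) if n_multigene else np.array([], int)

    annotation_rows = []
    per_run_log: dict[str, np.ndarray] = {}
    run_dataset: dict[str, str] = {}
    for ds in cfg.datasets:
        ds_id = f"{species[:3]}_{ds.dataset_id}"
        ds_organs = list(organ_map) if ds.organs is None else list(ds.organs)
        # per-protein multiplicative dataset bias, shared across the runs
        batch = rng.normal(0.0, cfg.batch_sigma, size=n)
        for organ in ds_organs:
            for tissue in organ_map[organ]:
                for r in range(ds.runs_per_tissue):
                    run_id = f"{ds_id}.{tissue.replace(' ', '_')}.r{r + 1}"
                    noise = rng.normal(0.0, cfg.run_noise_sd, size=n)
                    per_run_log[run_id] = (
                        tissue_log[(organ, tissue)].to_numpy() + batch + noise
                    )
                    run_dataset[run_id] = ds_id
                    annotation_rows.append(
                        {
                            "run_id": run_id,
                            "sample_id": run_id,
                            "tissue": tissue,
                            "organ": organ,
                            "dataset_id": ds_id,
                            "species": species,
                            "strain": "",
                            "fraction_id": "",
                        }
                    )

    runs = list(per_run_log)
    gene_log = np.column_stack([per_run_log[r] for r in runs])  # n x runs

    # group-level observed log intensity and detection
    idx = np.asarray(group_gene)
    group_log = gene_log[idx, :] + group_offset[:, None]
    det_p = expit(cfg.detection_steepness * (group_log - cfg.midpoint))
    detected = rng.random(det_p.shape) < det_p
    group_int = np.where(detected, 10.0**group_log, np.nan)

    # multi-gene (excluded) groups: geometric mean of two genes' signals
    if n_multigene:
        mg_log = 0.5 * (gene_log[mg_first, :] + gene_log[mg_first + 1, :])
        mg_p = expit(cfg.detection_steepness * (mg_log - cfg.midpoint))
        mg_det = rng.random(mg_p.shape) < mg_p
        mg_int = np.where(mg_det, 10.0**mg_log, np.nan)
    else:
        mg_int = np.empty((0, len(runs)))
    mg_ids = [f"{species[:3]}_MG{i:05d}" for i in range(n_multigene)]

    # QC rows, planted in exact proportions of the real group count
    n_con = int(round(cfg.frac_contaminant * n_real))
    n_rev = int(round(cfg.frac_reverse * n_real))
    n_low = int(round(cfg.frac_low_psm * n_real))
    mu, sd = cfg.baseline_log10_mean, cfg.baseline_log10_sd

    def _qc_intensities(count: int, loc: float) -> np.ndarray:
        qlog = rng.normal(loc, sd / 2, size=(count, 1)) + rng.normal(
            0.0, cfg.run_noise_sd, size=(count, len(runs))
        )
        qdet = rng.random((count, len(runs))) < 0.7
        return np.where(qdet, 10.0**qlog, np.nan)

    con_ids = [f"{species[:3]}_CONG{i:04d}" for i in range(n_con)]
    rev_ids = [f"{species[:3]}_REVG{i:04d}" for i in range(n_rev)]
    low_ids = [f"{species[:3]}_LPG{i:04d}" for i in range(n_low)]
    con_int = _qc_intensities(n_con, mu + sd)
    rev_int = _qc_intensities(n_rev, mu - sd)
    low_int = _qc_intensities(n_low, mu - sd)

    # assemble the global group roster
    acc_of_gene = {g: f"ACC_{g}" for g in genes}
    majority = [(acc_of_gene[genes[g]],) for g in group_gene]
    majority += [(acc_of_gene[genes[i]], acc_of_gene[genes[i + 1]]) for i in mg_first]
    majority += [(f"CON__{species[:3]}c{i:04d}",) for i in range(n_con)]
    majority += [(f"REV__{species[:3]}r{i:04d}",) for i in range(n_rev)]
    majority += [(f"ACC_{species[:3]}_lp{i:04d}",) for i in range(n_low)]

    psm_rate = np.clip(2.0 * (group_log.mean(axis=1) - (mu - 2 * sd)), 0.1, None)
    psm = 2 + rng.poisson(psm_rate)
    psm_extra = 2 + rng.poisson(3.0, size=n_multigene + n_con + n_rev)
    psm_low = rng.integers(0, 2, size=n_low)
    all_psm = np.concatenate([psm, psm_extra, psm_low])

    all_ids = group_ids + mg_ids + con_ids + rev_ids + low_ids
    is_con = [False] * (n_real + n_multigene) + [True] * n_con + [False] * (n_rev + n_low)
    is_rev = (
        [False] * (n_real + n_multigene + n_con) + [True] * n_rev + [False] * n_low
    )
    all_int = np.vstack([group_int, mg_int, con_int, rev_int, low_int])

    groups_df = pd.DataFrame(
        {
            "majority_accessions": majority,
            "psm_count": all_psm.astype(int),
            "is_contaminant": is_con,
            "is_reverse": is_rev,
        },
        index=pd.Index(all_ids, name="group_id"),
    )
    inten_df = pd.DataFrame(all_int, index=groups_df.index, columns=runs)

    # per-dataset tables: groups observed in >=1 run of the dataset, plus QC rows
    qc_set = set(con_ids) | set(rev_ids) | set(low_ids)
    tables: dict[str, QuantTable] = {}
    for ds_id in sorted(set(run_dataset.values())):
        ds_runs = [r for r in runs if run_dataset[r] == ds_id]
        sub = inten_df[ds_runs]
        seen = sub.notna().any(axis=1) | groups_df.index.isin(qc_set)
        tables[ds_id] = QuantTable(groups_df[seen].copy(), sub[seen].copy())

    annotation = pd.DataFrame(annotation_rows).set_index("run_id")
    gmap = {acc_of_gene[g]: frozenset([g]) for g in genes}
    truth = pd.DataFrame(
        {
            "species": species,
            "gene": genes,
            "planted_class": "mixed",
            "home_organ": "",
            "baseline_log10": baseline,
        }
    )
    truth.loc[enriched_idx, "planted_class"] = "organ-enriched"
    truth.loc[enriched_idx, "home_organ"] = home_organ[enriched_idx]
    qc = pd.DataFrame(
        {
            "reason": ["contaminant"] * n_con + ["reverse"] * n_rev + ["low_psm"] * n_low
        },
        index=pd.Index(con_ids + rev_ids + low_ids, name="group_id"),
    )
    return tables, annotation, gmap, truth, qc, tissue_log


def _ortholog_blocks(
    cfg: SimulationConfig, genes_a: list[str], genes_b: list[str], rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.Series]:
    n = cfg.n_genes
    order = rng.permutation(n)
    n_unmapped = int(round(cfg.frac_unmapped * n))
    n_non11 = int(round(cfg.frac_one_to_many * n))
    block = max(n_non11 // 3, 0)

    pos = 0
    unmapped = order[pos : pos + n_unmapped]; pos += n_unmapped
    o2m = order[pos : pos + 2 * block]; pos += 2 * block
    m2o = order[pos : pos + 2 * block]; pos += 2 * block
    m2m = order[pos : pos + 2 * block]; pos += 2 * block
    one_to_one = order[pos:]

    pairs: list[tuple[str, str]] = []
    expected: dict[str, str] = {g: "not-mapped" for g in genes_a}
    for i in one_to_one:
        pairs.append((genes_a[i], genes_b[i]))
        expected[genes_a[i]] = "one-to-one"
    for i, j in zip(o2m[0::2], o2m[1::2]):
        pairs += [(genes_a[i], genes_b[i]), (genes_a[i], genes_b[j])]
        expected[genes_a[i]] = "one-to-many"  # genes_a[j] stays not-mapped
    for i, j in zip(m2o[0::2], m2o[1::2]):
        pairs += [(genes_a[i], genes_b[i]), (genes_a[j], genes_b[i])]
        expected[genes_a[i]] = expected[genes_a[j]] = "many-to-one"
    for i, j in zip(m2m[0::2], m2m[1::2]):
        pairs += [
            (genes_a[i], genes_b[i]),
            (genes_a[i], genes_b[j]),
            (genes_a[j], genes_b[i]),
            (genes_a[j], genes_b[j]),
        ]
        expected[genes_a[i]] = expected[genes_a[j]] = "many-to-many"
    df = pd.DataFrame(sorted(pairs), columns=["source_gene", "target_gene"])
    return df, pd.Series(expected, name="category")


def generate_study(config: SimulationConfig) -> StudyFixture:
    """Generate a complete study fixture from a :class:`SimulationConfig`.

    Deterministic under a fixed seed.  With two species configured, the
    second species' per-gene standard-normal log effects are built as
    ``rho * z_A + sqrt(1 - rho^2) * eps`` so that their sample
    correlation with the first species approaches ``ortholog_rho``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes

    n_enriched = int(round(cfg.frac_organ_enriched * n))
    enriched_idx = np.sort(rng.choice(n, size=n_enriched, replace=False))
    organ_names = list(cfg.organ_map)
    home_organ = np.array([""] * n, dtype=object)
    home_organ[enriched_idx] = [
        organ_names[k % len(organ_names)] for k in range(n_enriched)
    ]

    z_a = rng.standard_normal(n)
    species_z = {cfg.species[0]: z_a}
    for sp in cfg.species[1:]:
        eps = rng.standard_normal(n)
        species_z[sp] = cfg.ortholog_rho * z_a + np.sqrt(1 - cfg.ortholog_rho**2) * eps

    all_tables: dict[str, QuantTable] = {}
    ann_frames, truth_frames, qc_frames = [], [], []
    gene_map: dict[str, frozenset[str]] = {}
    tissue_truth: dict[str, pd.DataFrame] = {}
    for sp in cfg.species:
        tables, ann, gmap, truth, qc, tlog = _simulate_species(
            cfg, sp, species_z[sp], enriched_idx, home_organ, rng
        )
        all_tables.update(tables)
        ann_frames.append(ann)
        truth_frames.append(truth)
        qc_frames.append(qc)
        gene_map.update(gmap)
        tissue_truth[sp] = tlog

    annotation = SampleAnnotation(pd.concat(ann_frames))
    truth = pd.concat(truth_frames).set_index(["species", "gene"])
    qc_rows = pd.concat(qc_frames)

    ortholog_pairs, expected_cat = None, None
    if len(cfg.species) >= 2:
        ortholog_pairs, expected_cat = _ortholog_blocks(
            cfg,
            _gene_ids(cfg.species[0], n),
            _gene_ids(cfg.species[1], n),
            rng,
        )

    return StudyFixture(
        config=cfg,
        quant_tables=all_tables,
        annotation=annotation,
        gene_map=GeneMap(gene_map),
        ortholog_pairs=ortholog_pairs,
        truth=truth,
        true_tissue_log10=tissue_truth,
        qc_rows=qc_rows,
        expected_ortholog_category=expected_cat,
    )


def truth_table(fixture: StudyFixture) -> pd.DataFrame:
    """Tabular export of the per-gene ground truth (for recovery scoring)."""
    out = fixture.truth.reset_index()
    return out[["species", "gene", "planted_class", "home_organ", "baseline_log10"]]


def write_fixture(fixture: StudyFixture, outdir: str | Path) -> None:
    """Write a fixture to disk in the same formats the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for ds_id, table in sorted(fixture.quant_tables.items()):
        write_protein_groups(table, outdir / f"proteinGroups_{ds_id}.tsv")
    write_sample_annotation(fixture.annotation, outdir / "annotation.tsv")
    write_gene_map(fixture.gene_map, outdir / "gene_map.tsv")
    if fixture.ortholog_pairs is not None:
        write_ortholog_pairs(fixture.ortholog_pairs, outdir / "orthologs.tsv")
    truth_table(fixture).to_csv(outdir / "truth.tsv", sep="\t", index=False)
    fixture.qc_rows.to_csv(outdir / "qc_rows.tsv", sep="\t")
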