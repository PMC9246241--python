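"""Sample-level comparisons: correlation heatmap inputs, PCA, UMAP, coverage.

All operations consume bin-transformed matrices, the scale on which
samples from different datasets are comparable.  Pearson correlations
are computed on pairwise-complete observations; PCA uses genes detected
in at least half the samples; the UMAP co-embedding of multi-species
samples lays out the common orthologs present in at least 90% of
samples and then joins full bin profiles onto the fixed coordinates for
per-gene overlays.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from .binning import BinnedMatrix
from .io_formats import SampleAnnotation
from .postprocess import ExpressionMatrix

__all__ = [
    "pairwise_sample_correlation",
    "pca_samples",
    "umap_embed",
    "coverage_report",
]


def _values(binned) -> pd.DataFrame:
    return binned.values if isinstance(binned, BinnedMatrix) else binned


def pairwise_sample_correlation(
    binned: BinnedMatrix, min_common: int = 3
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Pairwise Pearson correlation of samples on binned values.

    Correlations use the genes observed in both members of each pair;
    pairs sharing fewer than ``min_common`` genes get a missing entry
    (with a warning).  Returns the symmetric correlation matrix, the
    per-organ median R² over within-organ sample pairs, and the
    hierarchical-clustering leaf order (Euclidean distances, complete
    linkage) for heatmap reproduction.
    """
    values = _values(binned)
    if values.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    corr = values.corr(method="pearson", min_periods=min_common)
    np.fill_diagonal(corr.to_numpy(), 1.0)
    if corr.isna().any().any():
        warnings.warn("sample pairs with too few common genes left missing", stacklevel=2)

    organ_r2: dict[str, float] = {}
    if isinstance(binned, BinnedMatrix) and binned.run_batches is not None:
        organs = binned.run_batches.loc[list(values.columns), "organ"]
        for organ, runs in organs.groupby(organs).groups.items():
            runs = list(runs)
            if len(runs) < 2:
                continue
            sub = corr.loc[runs, runs].to_numpy() ** 2
            iu = np.triu_indices(len(runs), k=1)
            vals = sub[iu]
            vals = vals[~np.isnan(vals)]
            if len(vals):
                organ_r2[organ] = float(np.median(vals))
    median_r2 = pd.Series(organ_r2, dtype=float).sort_index()

    dist = pdist(corr.fillna(0.0).to_numpy())
    order = hierarchy.leaves_list(hierarchy.linkage(dist, method="complete"))
    leaf_order = [corr.columns[i] for i in order]
    return corr, median_r2, leaf_order


def _presence_filter_and_impute(
    values: pd.DataFrame, min_presence: float, impute: str
) -> pd.DataFrame:
    presence = values.notna().mean(axis=1)
    kept = values[presence >= min_presence]
    if impute == "median":
        fill = kept.median(axis=1)
        kept = kept.apply(lambda row: row.fillna(fill[row.name]), axis=1)
    elif impute == "zero":
        kept = kept.fillna(0.0)
    else:
        raise ValueError(f"unknown imputation {impute!r}")
    return kept


def pca_samples(
    binned: BinnedMatrix | pd.DataFrame,
    min_presence: float = 0.5,
    impute: str = "median",
    n_components: int = 2,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Centred PCA of samples on binned abundances.

    Genes detected in fewer than ``min_presence`` of the samples are
    dropped; residual missing values are imputed with the gene's median
    bin (or zero).  Returns per-sample coordinates and the explained
    variance fractions of the leading components.
    """
    values = _values(binned)
    if values.shape[1] < 3:
        raise ValueError("need at least 3 samples for PCA")
    kept = _presence_filter_and_impute(values, min_presence, impute)
    if kept.empty:
        raise ValueError(f"no gene passes the {min_presence:.0%} presence filter")
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(kept.T.to_numpy())
    out = pd.DataFrame(
        coords,
        index=values.columns,
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )
    return out, pca.explained_variance_ratio_


def umap_embed(
    binned: BinnedMatrix | pd.DataFrame,
    seed: int,
    layout_presence: float = 0.9,
    min_genes: int = 10,
    sample_meta: pd.DataFrame | None = None,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded UMAP layout of samples on a common-ortholog bin matrix.

    The layout is computed only on genes present in at least
    ``layout_presence`` of the samples (median-imputed); the overlay
    table then joins the *full* bin matrix onto the fixed coordinates,
    one row per (sample, gene), so per-gene expression can be painted
    onto an unchanging embedding.  ``sample_meta`` (organ/species/...)
    is carried into both outputs when given.
    """
    import umap  # deferred: heavy import

    values = _values(binned)
    layout = _presence_filter_and_impute(values, layout_presence, "median")
    if layout.shape[0] < min_genes:
        raise ValueError(
            f"only {layout.shape[0]} genes pass the {layout_presence:.0%} "
            f"presence filter (need >= {min_genes})"
        )
    nn = min(n_neighbors, layout.shape[1] - 1)
    reducer = umap.UMAP(
        n_components=2, n_neighbors=nn, min_dist=min_dist, random_state=seed
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # umap warns that a fixed seed disables parallelism
        coords = reducer.fit_transform(layout.T.to_numpy())
    coord_df = pd.DataFrame(coords, index=values.columns, columns=["x", "y"])
    if sample_meta is not None:
        coord_df = coord_df.join(sample_meta.reindex(coord_df.index))

    overlay = values.T.copy()
    overlay.insert(0, "x", coord_df["x"])
    overlay.insert(1, "y", coord_df["y"])
    overlay = overlay.reset_index(names="sample")
    overlay = overlay.melt(
        id_vars=["sample", "x", "y"], var_name="gene", value_name="bin"
    )
    return coord_df, overlay


def coverage_report(
    matrix: ExpressionMatrix, annotation: SampleAnnotation
) -> dict:
    """Gene coverage per dataset and per organ.

    Counts, per dataset and per organ, the genes with at least one
    observation; plus, over organs, how many genes are unique to a
    single organ and how many are ubiquitous (observed in every organ),
    with fractions of the total detected gene count.
    """
    annotation.require_runs(matrix.runs)
    batches = annotation.batches().loc[list(matrix.runs)]
    observed = matrix.values.notna()

    def _counts(by: str) -> dict[str, int]:
        out = {}
        for key, runs in batches.groupby(by).groups.items():
            out[str(key)] = int(observed[list(runs)].any(axis=1).sum())
        return out

    organ_presence = {}
    for organ, runs in batches.groupby("organ").groups.items():
        organ_presence[organ] = observed[list(runs)].any(axis=1)
    presence = pd.DataFrame(organ_presence)
    n_organs_per_gene = presence.sum(axis=1)
    detected = n_organs_per_gene > 0
    n_detected = int(detected.sum())
    unique_mask = n_organs_per_gene == 1
    per_organ_unique = {
        str(o): int((presence[o] & unique_mask).sum()) for o in presence.columns
    }
    n_unique = int(unique_mask.sum())
    n_ubiquitous = int((n_organs_per_gene == presence.shape[1]).sum())
    return {
        "n_genes_detected": n_detected,
        "genes_per_dataset": _counts("dataset_id"),
        "genes_per_organ": _counts("organ"),
        "genes_unique_to_one_organ": n_unique,
        "genes_unique_per_organ": per_organ_unique,
        "genes_in_all_organs": n_ubiquitous,
        "frac_unique_to_one_organ": n_unique / n_detected if n_detected else 0.0,
        "frac_in_all_organs": n_ubiquitous / n_detected if n_detected else 0.0,
    }
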