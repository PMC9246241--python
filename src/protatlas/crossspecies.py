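"""Cross-species comparison of protein expression via orthologs.

Ortholog pairings between two species' gene sets are first restricted to
the genes actually identified in each study (the backgrounds) and then
categorised by mapping cardinality: one-to-one, one-to-many,
many-to-one, many-to-many, or not-mapped.  Only one-to-one orthologs
enter quantitative comparisons: per organ, the organ-aggregated ppb
abundances of the two species are related by an ordinary least-squares
fit (on log10 by default, where the multiplicative ppb scale becomes
additive) and summarised by the coefficient of determination.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .binning import BinnedMatrix
from .io_formats import SampleAnnotation
from .postprocess import ExpressionMatrix

__all__ = [
    "OrthologMap",
    "OrthologFit",
    "categorize_orthologs",
    "organ_median_ppb",
    "compare_ortholog_abundance",
    "conserved_ortholog_sets",
]

CATEGORIES = ("one-to-one", "one-to-many", "many-to-one", "many-to-many", "not-mapped")


@dataclass
class OrthologMap:
    """Cross-species gene pairing with per-source-gene cardinality category.

    ``pairs`` holds the (source_gene, target_gene) pairs surviving the
    restriction to the two identification backgrounds; ``categories``
    maps every source-background gene to its category (genes with no
    surviving pair are ``not-mapped``).
    """

    pairs: pd.DataFrame
    categories: pd.Series
    source_background: list[str] = field(default_factory=list)
    target_background: list[str] = field(default_factory=list)

    def one_to_one(self) -> pd.DataFrame:
        keep = self.categories[self.categories == "one-to-one"].index
        return self.pairs[self.pairs["source_gene"].isin(keep)].reset_index(drop=True)

    def category_counts(self) -> pd.Series:
        return self.categories.value_counts().reindex(CATEGORIES, fill_value=0)

    def category_fractions(self) -> pd.Series:
        counts = self.category_counts()
        return counts / max(counts.sum(), 1)


def categorize_orthologs(
    pairs: pd.DataFrame,
    source_background: list[str],
    target_background: list[str],
) -> OrthologMap:
    """Restrict ortholog pairs to identified genes and categorise sources.

    A source gene is one-to-one iff it maps to exactly one target and
    that target maps back to it alone; one-to-many if it has several
    targets that each map back uniquely; many-to-one if its single
    target is shared; many-to-many otherwise.  Source-background genes
    with no surviving pair are not-mapped.  Counts are invariant to the
    order of the pair list.
    """
    if not source_background or not target_background:
        raise ValueError("ortholog backgrounds must be non-empty")
    src_bg = pd.Index(sorted(set(source_background)))
    tgt_bg = set(target_background)
    p = pairs[["source_gene", "target_gene"]].drop_duplicates()
    p = p[p["source_gene"].isin(set(src_bg)) & p["target_gene"].isin(tgt_bg)]
    p = p.sort_values(["source_gene", "target_gene"]).reset_index(drop=True)

    n_targets = p.groupby("source_gene")["target_gene"].nunique()
    n_sources = p.groupby("target_gene")["source_gene"].nunique()
    tgt_multi = p["target_gene"].map(n_sources).gt(1)
    any_shared_target = tgt_multi.groupby(p["source_gene"]).any()

    categories = pd.Series("not-mapped", index=src_bg, name="category")
    for src in n_targets.index:
        one_target = n_targets[src] == 1
        shared = bool(any_shared_target[src])
        if one_target and not shared:
            categories[src] = "one-to-one"
        elif one_target and shared:
            categories[src] = "many-to-one"
        elif not one_target and not shared:
            categories[src] = "one-to-many"
        else:
            categories[src] = "many-to-many"
    return OrthologMap(p, categories, sorted(src_bg), sorted(tgt_bg))


def organ_median_ppb(
    matrix: ExpressionMatrix, annotation: SampleAnnotation
) -> pd.DataFrame:
    """Aggregate a gene × run ppb matrix to organ level.

    Organ abundance is the median over the organ's samples (runs),
    ignoring runs where the gene was not detected.
    """
    annotation.require_runs(matrix.runs)
    organs = annotation.batches().loc[list(matrix.runs), "organ"]
    out = matrix.values.T.groupby(organs.to_numpy()).median().T
    return out.sort_index(axis=1)


@dataclass(frozen=True)
class OrthologFit:
    r_squared: float
    slope: float
    intercept: float
    n: int


def compare_ortholog_abundance(
    expr_source: pd.DataFrame,
    expr_target: pd.DataFrame,
    ortholog_map: OrthologMap,
    organ: str,
    scale: str = "log10",
    min_pairs: int = 3,
) -> OrthologFit:
    """OLS comparison of one-to-one ortholog abundances in one organ.

    ``expr_source`` / ``expr_target`` are gene × organ ppb matrices (see
    :func:`organ_median_ppb`).  Over the pairwise-complete one-to-one
    orthologs of the given organ, the target abundance is regressed on
    the source abundance on the chosen scale; the squared correlation
    (R²) is symmetric in the two species.
    """
    if scale not in ("log10", "linear"):
        raise ValueError(f"unknown scale {scale!r}")
    for expr, name in ((expr_source, "source"), (expr_target, "target")):
        if organ not in expr.columns:
            raise KeyError(f"organ {organ!r} absent from {name} matrix")
    oto = ortholog_map.one_to_one()
    x = expr_source[organ].reindex(oto["source_gene"]).to_numpy(dtype=float)
    y = expr_target[organ].reindex(oto["target_gene"]).to_numpy(dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    if scale == "log10":
        ok &= (x > 0) & (y > 0)
    x, y = x[ok], y[ok]
    if len(x) < min_pairs:
        raise ValueError(
            f"only {len(x)} complete one-to-one pairs in organ {organ!r} "
            f"(need >= {min_pairs})"
        )
    if scale == "log10":
        x, y = np.log10(x), np.log10(y)
    fit = stats.linregress(x, y)
    return OrthologFit(
        r_squared=float(fit.rvalue**2),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n=int(len(x)),
    )


def conserved_ortholog_sets(
    binned_by_species: dict[str, BinnedMatrix | pd.DataFrame],
    ortholog_index: pd.DataFrame | None = None,
    high_threshold: float = 4.0,
    low_threshold: float = 2.0,
) -> tuple[list[str], list[str]]:
    """Orthologs with conserved high/low expression across species.

    Joins the organ-level bin matrices of several species on a common
    ortholog universe (``ortholog_index`` maps a shared ortholog id to
    each species' gene id; if omitted, gene ids are assumed shared) and
    takes each ortholog's median bin over all (species, organ) columns.
    High set: median strictly above ``high_threshold``; low set: median
    strictly below ``low_threshold``.
    """
    frames = []
    for species in sorted(binned_by_species):
        vals = binned_by_species[species]
        vals = vals.values if isinstance(vals, BinnedMatrix) else vals
        if ortholog_index is not None:
            col = ortholog_index[species]
            vals = vals.reindex(col.to_numpy())
            vals.index = ortholog_index.index
        vals = vals.copy()
        vals.columns = [f"{species}:{c}" for c in vals.columns]
        frames.append(vals)
    if not frames:
        return [], []
    joined = pd.concat(frames, axis=1, join="inner")
    if joined.empty:
        return [], []
    med = joined.median(axis=1)
    high = sorted(med.index[med > high_threshold])
    low = sorted(med.index[med < low_threshold])
    return high, low
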