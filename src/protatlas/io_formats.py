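"""Readers and writers for every external table the pipeline touches.

All file-dialect knowledge lives here: MaxQuant ``proteinGroups.txt``
quantification tables, SDRF-like sample annotation, accession→gene maps,
ortholog pair lists, and Expression-Atlas-style expression/bin matrices.
Everything is plain TSV; writers emit canonically sorted output so files
are byte-reproducible, and readers invert the writers exactly
(``read(write(x)) == x``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ConsistencyError",
    "MaxQuantDialect",
    "QuantTable",
    "SampleAnnotation",
    "GeneMap",
    "read_protein_groups",
    "write_protein_groups",
    "read_sample_annotation",
    "write_sample_annotation",
    "read_gene_map",
    "write_gene_map",
    "read_ortholog_pairs",
    "write_ortholog_pairs",
    "read_expression_matrix",
    "write_expression_matrix",
    "write_json_report",
]


class FormatError(ValueError):
    """A file does not conform to the expected tabular dialect."""


class ConsistencyError(ValueError):
    """A table violates an internal consistency invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MaxQuantDialect:
    """Column-name conventions of a MaxQuant ``proteinGroups.txt`` file.

    MaxQuant versions differ in capitalisation and in whether decoys and
    contaminants are marked by flag columns ("+" vs empty) or by accession
    prefixes (``REV__`` / ``CON__``); both conventions are recognised and
    either sets the corresponding boolean.

    ``zero_as_missing`` controls how a literal ``0`` iBAQ cell is read.
    MaxQuant writes 0 for non-detection, so the default treats it as
    missing; set it to False to keep explicit zeros.
    """

    id_col: str = "id"
    majority_col: str = "Majority protein IDs"
    psm_col: str = "MS/MS count"
    reverse_col: str = "Reverse"
    contaminant_col: str = "Potential contaminant"
    ibaq_prefix: str = "iBAQ "
    decoy_accession_prefix: str = "REV__"
    contaminant_accession_prefix: str = "CON__"
    zero_as_missing: bool = True


DEFAULT_DIALECT = MaxQuantDialect()

_ANNOTATION_COLUMNS = [
    "sample_id",
    "tissue",
    "organ",
    "dataset_id",
    "species",
    "strain",
    "fraction_id",
]


@dataclass
class QuantTable:
    """A parsed protein-group quantification table.

    Parameters
    ----------
    groups
        One row per protein group, indexed by the opaque ``group_id``.
        Columns: ``majority_accessions`` (tuple of accession strings, in
        file order), ``psm_count`` (int, the MaxQuant MS/MS count),
        ``is_contaminant`` and ``is_reverse`` (bool).
    intensities
        Protein group × MS run matrix of raw (or FOT-normalised) iBAQ
        values, ``NaN`` marking non-detection.  Index aligned with
        ``groups``.
    """

    groups: pd.DataFrame
    intensities: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.groups.index.is_unique:
            dupes = self.groups.index[self.groups.index.duplicated()].unique()
            raise ConsistencyError(f"duplicate protein group ids: {list(dupes)[:5]}")
        if not self.groups.index.equals(self.intensities.index):
            raise ConsistencyError("groups and intensities indexes differ")
        with np.errstate(invalid="ignore"):
            if (self.intensities.to_numpy(dtype=float) < 0).any():
                raise ConsistencyError("negative intensity values")
        empty = [
            gid
            for gid, accs in self.groups["majority_accessions"].items()
            if len(accs) == 0
        ]
        if empty:
            raise ConsistencyError(f"groups with no majority accessions: {empty[:5]}")

    @property
    def runs(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def subset(self, group_ids: Iterable[str]) -> "QuantTable":
        ids = list(group_ids)
        return QuantTable(self.groups.loc[ids].copy(), self.intensities.loc[ids].copy())

    def with_intensities(self, intensities: pd.DataFrame) -> "QuantTable":
        return QuantTable(self.groups.copy(), intensities)

    def equals(self, other: "QuantTable") -> bool:
        """Content equality, insensitive to row/run order (writers sort)."""
        if sorted(self.groups.index) != sorted(other.groups.index):
            return False
        if sorted(self.intensities.columns) != sorted(other.intensities.columns):
            return False
        ga, gb = self.groups.sort_index(), other.groups.sort_index()
        same_meta = all(
            ga[c].tolist() == gb[c].tolist()
            for c in ("majority_accessions", "psm_count", "is_contaminant", "is_reverse")
        )
        cols = sorted(self.intensities.columns)
        a = self.intensities.sort_index()[cols].to_numpy(dtype=float)
        b = other.intensities.sort_index()[cols].to_numpy(dtype=float)
        same_vals = ((a == b) | (np.isnan(a) & np.isnan(b))).all()
        return bool(same_meta and same_vals)


@dataclass
class SampleAnnotation:
    """SDRF-style mapping of MS run → sample → tissue → organ → dataset.

    A 'tissue' is a distinct functional or structural region within an
    'organ' (e.g. cerebellum, cortex and hippocampus are tissues of the
    brain); within one species each tissue belongs to exactly one organ.
    MS runs from one tissue within one dataset form a batch for the
    rank-bin transformation.
    """

    table: pd.DataFrame  # indexed by run_id

    def __post_init__(self) -> None:
        if not self.table.index.is_unique:
            dupes = self.table.index[self.table.index.duplicated()].unique()
            raise ConsistencyError(f"duplicate run ids: {list(dupes)[:5]}")
        for col in _ANNOTATION_COLUMNS:
            if col not in self.table.columns:
                if col in ("strain", "fraction_id"):
                    self.table[col] = ""
                else:
                    raise FormatError(f"annotation missing mandatory column '{col}'")
        bad = (
            self.table.groupby(["species", "tissue"])["organ"].nunique()
        )
        conflicted = bad[bad > 1]
        if len(conflicted):
            names = sorted({t for (_, t) in conflicted.index})
            raise ConsistencyError(
                f"tissue(s) mapped to more than one organ within a species: {names}"
            )

    @property
    def runs(self) -> list[str]:
        return list(self.table.index)

    def require_runs(self, runs: Iterable[str]) -> None:
        missing = [r for r in runs if r not in self.table.index]
        if missing:
            raise ConsistencyError(f"runs absent from annotation: {missing[:5]}")

    def batches(self) -> pd.DataFrame:
        """Per-run batch assignment: dataset_id, tissue, organ, species."""
        return self.table[["dataset_id", "tissue", "organ", "species", "sample_id"]].copy()

    def organ_of_tissue(self, species: str) -> dict[str, str]:
        sub = self.table[self.table["species"] == species]
        return dict(zip(sub["tissue"], sub["organ"]))

    def subset_species(self, species: str) -> "SampleAnnotation":
        return SampleAnnotation(self.table[self.table["species"] == species].copy())

    def equals(self, other: "SampleAnnotation") -> bool:
        """Content equality, insensitive to row order (writers sort)."""
        a = self.table[_ANNOTATION_COLUMNS].fillna("").sort_index()
        b = other.table[_ANNOTATION_COLUMNS].fillna("").sort_index()
        return list(a.index) == list(b.index) and a.equals(b)


@dataclass
class GeneMap:
    """Map from protein accession to the set of gene identifiers it encodes.

    Unmapped accessions are simply absent; ``genes_for`` returns the union
    over a group's majority accessions, which downstream aggregation uses
    to decide whether a protein group maps to a single unique gene.
    """

    mapping: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        empty = [a for a, g in self.mapping.items() if not g]
        if empty:
            raise ConsistencyError(f"accessions mapped to empty gene sets: {empty[:5]}")

    def genes_for(self, accessions: Iterable[str]) -> frozenset[str]:
        out: set[str] = set()
        for acc in accessions:
            out |= self.mapping.get(acc, frozenset())
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.mapping)

    def equals(self, other: "GeneMap") -> bool:
        return self.mapping == other.mapping


# ---------------------------------------------------------------------------
# proteinGroups.txt
# ---------------------------------------------------------------------------


def _parse_intensity(cell: str, zero_as_missing: bool) -> float:
    s = cell.strip()
    if s == "" or s.lower() == "nan":
        return np.nan
    v = float(s)
    if v < 0:
        raise FormatError(f"negative iBAQ value {v!r}")
    if v == 0 and zero_as_missing:
        return np.nan
    return v


def read_protein_groups(
    path: str | Path, dialect: MaxQuantDialect = DEFAULT_DIALECT
) -> QuantTable:
    """Parse a MaxQuant-style ``proteinGroups.txt`` into a :class:`QuantTable`.

    The file must be tab-separated with a header naming (per the dialect)
    the majority-protein-ID, MS/MS-count, Reverse and Potential-contaminant
    columns, plus at least one per-run iBAQ column.  Semicolon-separated
    majority IDs become an ordered accession tuple; a ``+`` in either flag
    column, or a decoy/contaminant accession prefix on the leading majority
    ID, sets the corresponding boolean.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in (dialect.majority_col, dialect.psm_col):
        if col not in df.columns:
            raise FormatError(f"{path.name}: missing mandatory column '{col}'")
    ibaq_cols = [
        c
        for c in df.columns
        if c.startswith(dialect.ibaq_prefix)
        and c not in (dialect.ibaq_prefix.strip(), "iBAQ peptides")
    ]
    if not ibaq_cols:
        raise FormatError(f"{path.name}: no per-run '{dialect.ibaq_prefix}<run>' column")

    if dialect.id_col in df.columns:
        ids = df[dialect.id_col].tolist()
    else:
        ids = [f"pg{i}" for i in range(len(df))]
    if len(set(ids)) != len(ids):
        raise FormatError(f"{path.name}: duplicate protein group rows")

    majority = [tuple(filter(None, cell.split(";"))) for cell in df[dialect.majority_col]]
    psm = df[dialect.psm_col].replace("", "0").astype(int)

    def _flag(colname: str) -> pd.Series:
        if colname in df.columns:
            return df[colname].str.strip() == "+"
        return pd.Series(False, index=df.index)

    is_rev = _flag(dialect.reverse_col)
    is_con = _flag(dialect.contaminant_col)
    # accession-prefix convention (older MaxQuant versions)
    lead = pd.Series([m[0] if m else "" for m in majority], index=df.index)
    is_rev |= lead.str.startswith(dialect.decoy_accession_prefix)
    is_con |= lead.str.startswith(dialect.contaminant_accession_prefix)

    groups = pd.DataFrame(
        {
            "majority_accessions": majority,
            "psm_count": psm.to_numpy(),
            "is_contaminant": is_con.to_numpy(),
            "is_reverse": is_rev.to_numpy(),
        },
        index=pd.Index(ids, name="group_id"),
    )
    inten = pd.DataFrame(
        {
            c[len(dialect.ibaq_prefix):]: [
                _parse_intensity(v, dialect.zero_as_missing) for v in df[c]
            ]
            for c in ibaq_cols
        },
        index=groups.index,
        dtype=float,
    )
    inten = inten[sorted(inten.columns)]
    return QuantTable(groups, inten)


def write_protein_groups(
    table: QuantTable, path: str | Path, dialect: MaxQuantDialect = DEFAULT_DIALECT
) -> None:
    """Write a :class:`QuantTable` back to the MaxQuant TSV dialect.

    Rows are sorted by group id and run columns lexicographically, so the
    output bytes are a canonical function of the table contents.
    """
    g = table.groups.sort_index()
    runs = sorted(table.intensities.columns)
    inten = table.intensities.loc[g.index, runs]
    out = pd.DataFrame(index=g.index)
    out[dialect.id_col] = g.index
    out[dialect.majority_col] = [";".join(a) for a in g["majority_accessions"]]
    out[dialect.psm_col] = g["psm_count"].astype(int)
    out[dialect.reverse_col] = np.where(g["is_reverse"], "+", "")
    out[dialect.contaminant_col] = np.where(g["is_contaminant"], "+", "")
    for r in runs:
        out[dialect.ibaq_prefix + r] = [
            "" if np.isnan(v) else repr(float(v)) for v in inten[r]
        ]
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Sample annotation (SDRF-like)
# ---------------------------------------------------------------------------


def read_sample_annotation(path: str | Path) -> SampleAnnotation:
    """Read the run→sample→tissue→organ→dataset annotation table.

    Validates that, within each species, every tissue maps to a single
    organ; an empty file yields an empty (valid) annotation.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "run_id" not in df.columns:
        raise FormatError(f"{Path(path).name}: missing mandatory column 'run_id'")
    for col in ("sample_id", "tissue", "organ", "dataset_id", "species"):
        if col not in df.columns:
            raise FormatError(f"{Path(path).name}: missing mandatory column '{col}'")
    for col in ("strain", "fraction_id"):
        if col not in df.columns:
            df[col] = ""
    return SampleAnnotation(df.set_index("run_id")[_ANNOTATION_COLUMNS])


def write_sample_annotation(annotation: SampleAnnotation, path: str | Path) -> None:
    out = annotation.table[_ANNOTATION_COLUMNS].fillna("").sort_index()
    out.index.name = "run_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Gene map / ortholog pairs
# ---------------------------------------------------------------------------


def read_gene_map(path: str | Path) -> GeneMap:
    """Read an accession→gene TSV (one pair per row, repeated rows for
    multi-mapping accessions)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("accession", "gene"):
        if col not in df.columns:
            raise FormatError(f"{Path(path).name}: missing mandatory column '{col}'")
    mapping: dict[str, set[str]] = {}
    for acc, gene in zip(df["accession"], df["gene"]):
        if gene:
            mapping.setdefault(acc, set()).add(gene)
    return GeneMap({a: frozenset(g) for a, g in mapping.items()})


def write_gene_map(gene_map: GeneMap, path: str | Path) -> None:
    rows = [
        (acc, gene)
        for acc in sorted(gene_map.mapping)
        for gene in sorted(gene_map.mapping[acc])
    ]
    pd.DataFrame(rows, columns=["accession", "gene"]).to_csv(path, sep="\t", index=False)


def read_ortholog_pairs(path: str | Path) -> pd.DataFrame:
    """Read a source_gene→target_gene ortholog pair list."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("source_gene", "target_gene"):
        if col not in df.columns:
            raise FormatError(f"{Path(path).name}: missing mandatory column '{col}'")
    return df[["source_gene", "target_gene"]]

def write_ortholog_pairs(pairs: pd.DataFrame, path: str | Path) -> None:
    out = pairs[["source_gene", "target_gene"]].sort_values(
        ["source_gene", "target_gene"]
    )
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Expression / bin matrices (Expression Atlas-style TSV)
# ---------------------------------------------------------------------------

_MULTI_SEP = "|"


def write_expression_matrix(matrix, path: str | Path) -> None:
    """Write a gene × column abundance or bin matrix as TSV.

    Accepts an :class:`~protatlas.postprocess.ExpressionMatrix`, a
    :class:`~protatlas.binning.BinnedMatrix` or a bare DataFrame.  Genes
    are written in lexicographic order, missing values as empty cells;
    tissue-level ``(dataset, tissue)`` columns are joined with ``|``.
    """
    values = getattr(matrix, "values_df", None)
    if values is None:
        values = matrix if isinstance(matrix, pd.DataFrame) else matrix.values
    if values.empty:
        raise ValueError("refusing to write an empty matrix")
    out = values.sort_index()
    if isinstance(out.columns, pd.MultiIndex):
        out = out.copy()
        out.columns = [_MULTI_SEP.join(map(str, c)) for c in out.columns]
    out = out[sorted(out.columns)]
    out.index.name = "gene"
    out.to_csv(path, sep="\t", na_rep="")


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read a matrix written by :func:`write_expression_matrix`.

    Columns containing ``|`` are split back into a ``(dataset, tissue)``
    MultiIndex.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if any(_MULTI_SEP in c for c in df.columns):
        df.columns = pd.MultiIndex.from_tuples(
            [tuple(c.split(_MULTI_SEP, 1)) for c in df.columns]
        )
    return df.astype(float)


def write_json_report(report: Mapping, path: str | Path) -> None:
    """Write a run report (filter counts, coverage, parameters) as JSON."""

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (set, frozenset, tuple)):
            return sorted(o)
        raise TypeError(f"unserialisable object of type {type(o)}")

    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True, default=_default) + "\n")
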