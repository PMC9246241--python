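"""Organ-specificity classification of canonical proteins.

Following the modified Uhlén-style scheme on organ-level bin values,
each gene is assigned one of three classes:

* **organ-enriched** — elevated in exactly one organ, where "elevated"
  means a bin value at least ``fold`` (default 2) times the gene's mean
  bin value across organs;
* **group-enriched** — elevated in two or more organs while being
  present in at least ``min_present_organs`` organs (7 for the mouse
  study design, 4 for rat);
* **mixed** — everything else.

Two readings of the mean are supported.  ``all-organs`` (default) takes
the mean across every organ of the study, counting an organ where the
gene was never detected as 0 — the literal "mean bin value across all
organs", under which a protein detected only in its home organ is
maximally enriched.  ``observed-only`` averages over detected organs
only, under which single-organ proteins can never reach the 2-fold
threshold.

The module also extracts conserved high/low expression sets: genes whose
organ bin value exceeds a threshold in at least ``min_organs`` organs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binning import BinnedMatrix

__all__ = [
    "SpecificityConfig",
    "classify_specificity",
    "elevated_summary",
    "conserved_expression_sets",
]

ORGAN_ENRICHED = "organ-enriched"
GROUP_ENRICHED = "group-enriched"
MIXED = "mixed"


@dataclass(frozen=True)
class SpecificityConfig:
    """Parameters of the three-way specificity classification.

    fold
        Elevation threshold as a multiple of the mean bin value (> 1).
    min_present_organs
        Presence-count precondition for the group-enriched class
        (per-species: 7 in the mouse design, 4 in rat).
    mean_policy
        'all-organs' counts undetected organs as bin 0 in the mean;
        'observed-only' averages detected organs only.
    reading
        'elevated': organ-enriched means exactly one elevated organ;
        'detected-single': the literal detected-in-one-organ-only
        reading (the single organ must still pass the threshold).
    """

    fold: float = 2.0
    min_present_organs: int = 7
    mean_policy: str = "all-organs"
    reading: str = "elevated"

    def __post_init__(self) -> None:
        if not self.fold > 1:
            raise ValueError("fold must exceed 1")
        if self.min_present_organs < 1:
            raise ValueError("min_present_organs must be >= 1")
        if self.mean_policy not in ("all-organs", "observed-only"):
            raise ValueError(f"unknown mean_policy {self.mean_policy!r}")
        if self.reading not in ("elevated", "detected-single"):
            raise ValueError(f"unknown reading {self.reading!r}")


def _values(organ_bins) -> pd.DataFrame:
    return organ_bins.values if isinstance(organ_bins, BinnedMatrix) else organ_bins


def classify_specificity(
    organ_bins: BinnedMatrix | pd.DataFrame,
    config: SpecificityConfig = SpecificityConfig(),
) -> pd.DataFrame:
    """Classify every gene of an organ-level bin matrix for one species.

    Returns a gene-indexed DataFrame with columns ``class``,
    ``elevated_organs`` (tuple), ``mean_bin``, ``n_present_organs`` and
    ``threshold_used`` (fold × mean).  Genes absent from every organ are
    excluded with a warning.
    """
    B = _values(organ_bins)
    present = B.notna()
    n_present = present.sum(axis=1)
    absent = n_present == 0
    if absent.any():
        warnings.warn(
            f"{int(absent.sum())} gene(s) absent from all organs excluded",
            stacklevel=2,
        )
        B, present, n_present = B[~absent], present[~absent], n_present[~absent]

    if config.mean_policy == "all-organs":
        mean_bin = B.fillna(0.0).mean(axis=1)
    else:
        mean_bin = B.mean(axis=1)
    threshold = config.fold * mean_bin
    elevated = B.ge(threshold, axis=0) & present
    n_elev = elevated.sum(axis=1)

    if config.reading == "elevated":
        organ_enriched = n_elev == 1
    else:
        organ_enriched = (n_present == 1) & (n_elev == 1)
    group_enriched = (
        ~organ_enriched & (n_elev >= 2) & (n_present >= config.min_present_organs)
    )
    cls = pd.Series(MIXED, index=B.index)
    cls[organ_enriched] = ORGAN_ENRICHED
    cls[group_enriched] = GROUP_ENRICHED

    organs = np.asarray(B.columns)
    elev_sets = [
        tuple(organs[row]) if c in (ORGAN_ENRICHED, GROUP_ENRICHED) else ()
        for row, c in zip(elevated.to_numpy(bool), cls)
    ]
    out = pd.DataFrame(
        {
            "class": cls,
            "elevated_organs": elev_sets,
            "mean_bin": mean_bin,
            "n_present_organs": n_present.astype(int),
            "threshold_used": threshold,
        }
    )
    out.index.name = "gene"
    return out


def elevated_summary(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-organ counts and fractions of elevated (enriched) genes.

    Each organ-enriched gene counts toward its single organ; each
    group-enriched gene is attributed to every organ in its elevated
    set.  Fractions are relative to the total number of elevated genes
    (organ- plus group-enriched).
    """
    counts: dict[str, dict[str, int]] = {}
    for _, row in calls.iterrows():
        if row["class"] == ORGAN_ENRICHED:
            key = "n_organ_enriched"
        elif row["class"] == GROUP_ENRICHED:
            key = "n_group_enriched"
        else:
            continue
        for organ in row["elevated_organs"]:
            entry = counts.setdefault(
                organ, {"n_organ_enriched": 0, "n_group_enriched": 0}
            )
            entry[key] += 1
    out = pd.DataFrame.from_dict(counts, orient="index").sort_index()
    if out.empty:
        out = pd.DataFrame(columns=["n_organ_enriched", "n_group_enriched"], dtype=int)
    n_elevated = int((calls["class"] != MIXED).sum())
    out["frac_organ_enriched"] = out.get("n_organ_enriched", 0) / max(n_elevated, 1)
    out["frac_group_enriched"] = out.get("n_group_enriched", 0) / max(n_elevated, 1)
    out.attrs["n_elevated_total"] = n_elevated
    out.index.name = "organ"
    return out


def conserved_expression_sets(
    organ_bins: BinnedMatrix | pd.DataFrame,
    high_threshold: float = 4.0,
    low_threshold: float = 2.0,
    min_organs: int = 3,
) -> tuple[list[str], list[str]]:
    """Genes with conserved high (or low) expression across organs.

    The high set holds genes whose organ bin value strictly exceeds
    ``high_threshold`` in at least ``min_organs`` organs; the low set is
    the analogue with bin values strictly below ``low_threshold``.
    Thresholds are strict, so a bin value of exactly 4 never counts as
    "more than 4".
    """
    B = _values(organ_bins)
    high = B.gt(high_threshold).sum(axis=1) >= min_organs
    low = B.lt(low_threshold).sum(axis=1) >= min_organs
    return sorted(B.index[high]), sorted(B.index[low])
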