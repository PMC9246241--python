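"""UMAP co-embedding of both species' samples on common orthologs.

Builds the joint bin matrix of one-to-one orthologs across mouse and
rat, computes a seeded UMAP layout on the >= 90%-present genes, and
writes the per-sample coordinates (with organ and species labels) to
results/umap_coordinates.tsv.
"""

import numpy as np
import pandas as pd

from common import RESULTS, STUDY_SEED, load_study, run_all_species
from protatlas.binning import BinnedMatrix
from protatlas.crossspecies import categorize_orthologs
from protatlas.sample_stats import umap_embed

fixture = load_study()
results = run_all_species(fixture)
RESULTS.mkdir(exist_ok=True)

omap = categorize_orthologs(
    fixture.ortholog_pairs,
    results["mouse"].expression.genes,
    results["rat"].expression.genes,
)
oto = omap.one_to_one()
mouse = results["mouse"].run_bins.values.reindex(oto["source_gene"])
rat = results["rat"].run_bins.values.reindex(oto["target_gene"])
mouse.index = rat.index = oto["source_gene"]
joint = pd.concat([mouse, rat], axis=1)
batches = pd.concat(
    [results[sp].run_bins.run_batches for sp in ("mouse", "rat")]
).loc[joint.columns]
binned = BinnedMatrix(joint, level="run", run_batches=batches)

coords, overlay = umap_embed(binned, seed=STUDY_SEED, sample_meta=batches)
coords.index.name = "sample"
coords.to_csv(RESULTS / "umap_coordinates.tsv", sep="\t")

d = coords[["x", "y"]].to_numpy()
dist = np.linalg.norm(d[:, None, :] - d[None, :, :], axis=-1)
organ = batches.loc[coords.index, "organ"].to_numpy()
same = organ[:, None] == organ[None, :]
iu = np.triu_indices(len(d), 1)
w, b = dist[iu][same[iu]].mean(), dist[iu][~same[iu]].mean()
print(
    f"embedded {len(coords)} samples from both species on "
    f"{len(oto)} one-to-one orthologs"
)
print(f"mean within-organ distance {w:.2f} vs between-organ {b:.2f}")
print(f"-> {RESULTS / 'umap_coordinates.tsv'}")
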