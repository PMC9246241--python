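"""Compare protein expression between the two species via orthologs.

Categorises ortholog mapping cardinalities after restriction to the
identified genes, fits mouse-vs-rat organ abundances over one-to-one
orthologs (log10 ppb), and extracts orthologs with conserved high/low
binned expression across both species.  Writes
results/crossspecies_summary.json.
"""

import pandas as pd

from common import RESULTS, load_study, run_all_species
from protatlas.crossspecies import (
    categorize_orthologs,
    compare_ortholog_abundance,
    conserved_ortholog_sets,
)
from protatlas.io_formats import write_json_report

fixture = load_study()
results = run_all_species(fixture)
RESULTS.mkdir(exist_ok=True)

omap = categorize_orthologs(
    fixture.ortholog_pairs,
    results["mouse"].expression.genes,
    results["rat"].expression.genes,
)
fractions = omap.category_fractions().round(3)
print("ortholog mapping categories (fraction of identified mouse genes):")
print("  " + ", ".join(f"{k}={v:.3f}" for k, v in fractions.items()))

fits = {}
shared = sorted(
    set(results["mouse"].organ_ppb.columns) & set(results["rat"].organ_ppb.columns)
)
for organ in shared:
    fit = compare_ortholog_abundance(
        results["mouse"].organ_ppb, results["rat"].organ_ppb, omap, organ
    )
    fits[organ] = {"r_squared": round(fit.r_squared, 3), "slope": round(fit.slope, 3), "n": fit.n}
print("mouse-vs-rat organ fits over one-to-one orthologs (log10 ppb):")
for organ, f in fits.items():
    print(f"  {organ}: R^2={f['r_squared']:.2f} slope={f['slope']:.2f} n={f['n']}")

oto = omap.one_to_one()
idx = pd.DataFrame(
    {"mouse": oto["source_gene"].to_numpy(), "rat": oto["target_gene"].to_numpy()},
    index=oto["source_gene"].to_numpy(),
)
high, low = conserved_ortholog_sets(
    {"mouse": results["mouse"].organ_bins, "rat": results["rat"].organ_bins},
    ortholog_index=idx,
)
print(
    f"conserved across species: {len(high)} orthologs high (median bin > 4), "
    f"{len(low)} low (median bin < 2)"
)
write_json_report(
    {
        "category_fractions": fractions.to_dict(),
        "fits_per_organ": fits,
        "n_conserved_high": len(high),
        "n_conserved_low": len(low),
    },
    RESULTS / "crossspecies_summary.json",
)
print(f"-> {RESULTS / 'crossspecies_summary.json'}")
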