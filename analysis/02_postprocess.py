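"""Filter, FOT-normalise and aggregate the study to canonical proteins.

Reports the QC filter counts per dataset and the gene coverage per
organ/dataset (how many canonical proteins each organ sees, how many are
organ-unique, how many ubiquitous) to results/.
"""

import json

from common import RESULTS, load_study, run_all_species
from protatlas.io_formats import write_json_report

fixture = load_study()
results = run_all_species(fixture)
RESULTS.mkdir(exist_ok=True)

report = {}
for sp, res in results.items():
    report[sp] = {
        "filters": {ds: r.as_dict() for ds, r in res.filter_reports.items()},
        "coverage": res.coverage,
        "n_excluded_multigene_groups": len(res.expression.excluded_multigene_groups),
        "n_unmapped_groups": len(res.expression.unmapped_groups),
    }
write_json_report(report, RESULTS / "postprocess_report.json")

for sp, res in results.items():
    cov = res.coverage
    removed = sum(r.n_removed for r in res.filter_reports.values())
    print(
        f"{sp}: {cov['n_genes_detected']} canonical proteins detected; "
        f"{removed} group rows removed by QC filters; "
        f"{cov['genes_unique_to_one_organ']} genes "
        f"({cov['frac_unique_to_one_organ']:.1%}) seen in a single organ, "
        f"{cov['genes_in_all_organs']} ({cov['frac_in_all_organs']:.1%}) in every organ."
    )
print(f"-> {RESULTS / 'postprocess_report.json'}")
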